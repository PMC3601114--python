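"""End-to-end per-subject workflow: unperturbed (UPT) vs perturbed (PTB)
comparison of modular control, co-contraction and kinetics.

The study design is one subject performing repeated cutting manoeuvres, all
but the last unperturbed; the final trial receives an unexpected support-
surface translation at initial contact.  The pipeline

1. amplitude-normalizes the cycle-normalized envelope trials against the
   pooled UPT+PTB per-muscle peak,
2. selects the number of motor modules from the VAF curve of the UPT
   concatenation, then extracts module sets per condition,
3. compares conditions via matched similarities of weightings and
   activation signals, and by fixed-factor cross-reconstruction of the PTB
   EMG from UPT factors (with random-matrix baselines),
4. computes activation-signal peak timings,
5. derives stance events, CoM power phases, external work, approach speed
   and horizontal force peaks from the kinetic traces, and
6. computes stance-normalized epoch amplitudes and knee CCR/CCI per
   condition.

`run_subject` consumes a :class:`StudyConfig` pointing at envelope CSVs and
kinetics TSVs (as written by ``synergyflow simulate`` or ``preprocess``);
`analyze_subject` is the in-memory equivalent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import analysis, cocontraction, factorization, kinetics as kin, synthetic
from .io import (
    read_emg_csv,
    read_kinetics_tsv,
    write_emg_csv,
    write_kinetics_tsv,
    write_truth_json,
)
from .preprocess import EnvelopeMatrix, epoch_normalize_amplitude, normalize_amplitude

__all__ = ["StudyConfig", "run_subject", "analyze_subject", "simulate_subject"]


@dataclass(frozen=True)
class StudyConfig:
    """Paths and tunables for one subject's analysis."""

    upt_trials: tuple[str, ...]
    ptb_trials: tuple[str, ...]
    kinetics_upt: tuple[str, ...] = ()
    kinetics_ptb: tuple[str, ...] = ()
    body_mass: float = 71.0
    n_points: int = 200
    n_module_range: tuple[int, ...] = tuple(range(1, 9))
    vaf_floor: float = 0.80
    gain_eps: float = 3.0
    n_restarts: int = 20
    max_iter: int = 1000
    tol: float = 1e-6
    crossfit_iterations: int = 1000
    kin_lead_ms: float = 150.0  # recording time before the analyzed cycle starts
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if len(self.upt_trials) < 1:
            raise ValueError("at least one unperturbed trial required")
        if len(self.ptb_trials) > 1:
            raise ValueError("at most one perturbed trial per subject")
        object.__setattr__(self, "upt_trials", tuple(self.upt_trials))
        object.__setattr__(self, "ptb_trials", tuple(self.ptb_trials))
        object.__setattr__(self, "kinetics_upt", tuple(self.kinetics_upt))
        object.__setattr__(self, "kinetics_ptb", tuple(self.kinetics_ptb))
        object.__setattr__(self, "n_module_range", tuple(self.n_module_range))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__}, sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _kinetic_summary(trace: kin.CycleKinetics, lead_ms: float = 150.0) -> dict:
    events = kin.detect_stance(trace.fz, trace.rate, left_ic=0)
    power = kin.com_power(
        trace.grf, trace.com_velocity, trace.body_mass, trace.rate, events=events
    )
    summary = {
        "stance_ms": 1000.0 * (events.toe_off - events.ic) / trace.rate,
        "w_lac": power.w_lac,
        "w_prp": power.w_prp,
    }
    hf_ap, hf_ml = kin.horizontal_force_peaks(trace.grf, events, trace.body_mass)
    summary.update(hf_ap=hf_ap, hf_ml=hf_ml)
    if trace.com_position is not None:
        summary["com_speed"] = kin.com_speed(
            trace.com_position, trace.rate, events.ic
        )
    left_ic = int(
        trace.meta.get("planted_left_ic", round(lead_ms / 1000.0 * trace.rate))
    )
    return {
        "summary": summary,
        "events": kin.GaitEvents(ic=events.ic, toe_off=events.toe_off, left_ic=left_ic),
        "power": power,
    }


def analyze_subject(
    upt: Sequence[EnvelopeMatrix],
    ptb: Sequence[EnvelopeMatrix],
    kinetics_upt: Sequence[kin.CycleKinetics] = (),
    kinetics_ptb: Sequence[kin.CycleKinetics] = (),
    config: StudyConfig | None = None,
) -> dict:
    """Run the full comparison on in-memory trials; returns the report dict."""
    cfg = config or StudyConfig(upt_trials=("<memory>",), ptb_trials=())
    all_trials = list(upt) + list(ptb)
    normalized = normalize_amplitude(all_trials)
    upt_n, ptb_n = normalized[: len(upt)], normalized[len(upt) :]

    upt_cat = factorization.concatenate_trials(upt_n)
    curve = factorization.vaf_curve(
        upt_cat,
        cfg.n_module_range,
        seed=cfg.seed,
        n_restarts=cfg.n_restarts,
        max_iter=cfg.max_iter,
        tol=cfg.tol,
    )
    n_sel = factorization.select_dimensionality(curve, cfg.vaf_floor, cfg.gain_eps)

    fit_kw = dict(
        n_restarts=cfg.n_restarts, max_iter=cfg.max_iter, tol=cfg.tol
    )
    upt_set = _reorder_by_cycle_peak(
        factorization.nmf(upt_cat, n_sel, seed=cfg.seed + 1, **fit_kw), cfg.n_points
    )
    report: dict = {
        "n_modules": n_sel,
        "vaf_curve": {"n": list(curve.n_values), "vaf": list(curve.vaf_values)},
        "upt": {
            "vaf": factorization.vaf(upt_cat.values, upt_set.reconstruction).global_vaf,
            "peak_timing_pct": analysis.peak_timing(
                analysis.cycle_average(upt_set.activations, cfg.n_points)
            ).tolist(),
        },
        "provenance": {"config_digest": cfg.digest(), "seed": cfg.seed},
    }

    ptb_set = None
    if ptb_n:
        ptb_cat = factorization.concatenate_trials(ptb_n)
        ptb_set = _reorder_by_cycle_peak(
            factorization.nmf(ptb_cat, n_sel, seed=cfg.seed + 2, **fit_kw),
            cfg.n_points,
        )
        report["ptb"] = {
            "vaf": factorization.vaf(ptb_cat.values, ptb_set.reconstruction).global_vaf,
            "peak_timing_pct": analysis.peak_timing(
                analysis.cycle_average(ptb_set.activations, cfg.n_points)
            ).tolist(),
        }
        # activation signals are compared on the shared normalized cycle
        upt_cyc = factorization.MotorModuleSet(
            weightings=upt_set.weightings,
            activations=analysis.cycle_average(upt_set.activations, cfg.n_points),
            n_modules=n_sel,
        )
        ptb_cyc = factorization.MotorModuleSet(
            weightings=ptb_set.weightings,
            activations=analysis.cycle_average(ptb_set.activations, cfg.n_points),
            n_modules=n_sel,
        )
        for on in ("weightings", "activations"):
            rep = analysis.match_modules(upt_cyc, ptb_cyc, on=on)
            report.setdefault("similarity", {})[on] = {
                "pairs": rep.pair_similarities.tolist(),
                "median": float(rep.median[0]),
                "similar": rep.threshold_flags.tolist(),
            }
        # cross-reconstruction of perturbed EMG from fixed unperturbed factors
        cross = {}
        for which, fixed in (
            ("weightings", upt_set.weightings),
            (
                "activations",
                _tile_activations(
                    analysis.cycle_average(upt_set.activations, cfg.n_points),
                    ptb_cat.n_points,
                ),
            ),
        ):
            fit = analysis.fixed_factor_fit(
                ptb_cat,
                fixed,
                which=which,
                iterations=cfg.crossfit_iterations,
                seed=cfg.seed + 3,
                fixed_source="UPT",
            )
            rand = analysis.fixed_factor_fit(
                ptb_cat,
                analysis.random_factor(np.asarray(fixed).shape, seed=cfg.seed + 4),
                which=which,
                iterations=cfg.crossfit_iterations,
                seed=cfg.seed + 5,
                fixed_source="random",
            )
            cross[which] = {
                "vaf_fixed_upt": fit.vaf.global_vaf,
                "vaf_random_baseline": rand.vaf.global_vaf,
            }
        report["cross_reconstruction"] = cross

    # kinetics and epoch-based co-contraction
    if kinetics_upt and kinetics_ptb is not None:
        kin_reports = {"UPT": [], "PTB": []}
        epoch_info = {"UPT": [], "PTB": []}
        for label, traces in (("UPT", kinetics_upt), ("PTB", kinetics_ptb)):
            for trace in traces:
                res = _kinetic_summary(trace, lead_ms=cfg.kin_lead_ms)
                kin_reports[label].append(res["summary"])
                epoch_info[label].append((res["events"], res["power"]))
        report["kinetics"] = {
            lab: _mean_dicts(v) for lab, v in kin_reports.items() if v
        }

        if epoch_info["UPT"] and epoch_info["PTB"] and ptb_n:
            stance_windows = []
            for trials, infos in (
                (upt_n, epoch_info["UPT"]),
                (ptb_n, epoch_info["PTB"]),
            ):
                for t, (events, _) in zip(trials, _cycled(infos, len(trials))):
                    span = events.toe_off - events.left_ic
                    a = int(round((events.ic - events.left_ic) / span * (cfg.n_points - 1)))
                    stance_windows.append((a, cfg.n_points))
            stance_norm = epoch_normalize_amplitude(upt_n + ptb_n, stance_windows)
            cc: dict = {}
            for label, trials, infos in (
                ("UPT", stance_norm[: len(upt_n)], epoch_info["UPT"]),
                ("PTB", stance_norm[len(upt_n) :], epoch_info["PTB"]),
            ):
                per_epoch: dict = {}
                for t, (events, power) in zip(trials, _cycled(infos, len(trials))):
                    epochs = cocontraction.build_epochs(events, power, cfg.n_points)
                    for name, res in cocontraction.cocontraction_by_epoch(t, epochs).items():
                        per_epoch.setdefault(name, []).append(
                            {"ccr": res.ccr, "cci": res.cci}
                        )
                cc[label] = {
                    name: _mean_dicts(vals) for name, vals in per_epoch.items()
                }
            report["cocontraction"] = cc
    return report


def _reorder_by_cycle_peak(
    mset: factorization.MotorModuleSet, n_points: int
) -> factorization.MotorModuleSet:
    """Order a concatenated fit's modules by cycle-averaged peak time."""
    P_cyc = analysis.cycle_average(mset.activations, n_points)
    order = np.argsort(np.argmax(P_cyc, axis=1), kind="stable")
    return factorization.MotorModuleSet(
        weightings=mset.weightings[:, order],
        activations=mset.activations[order],
        n_modules=mset.n_modules,
        fit=mset.fit,
    )


def _tile_activations(P: np.ndarray, k_target: int) -> np.ndarray:
    """Repeat per-cycle activation signals to span a concatenation of cycles."""
    k = P.shape[1]
    if k_target % k:
        raise ValueError("target length is not a whole number of cycles")
    return np.tile(P, (1, k_target // k))


def _cycled(items, n):
    """Pair n trials with len(items) kinetic traces, reusing the last trace
    when fewer traces than trials were recorded."""
    items = list(items)
    while len(items) < n:
        items.append(items[-1])
    return items[:n]


def _mean_dicts(dicts: list[dict]) -> dict:
    keys = dicts[0].keys()
    return {k: float(np.mean([d[k] for d in dicts])) for k in keys}


def run_subject(config: StudyConfig) -> dict:
    """File-based wrapper around :func:`analyze_subject`; writes report.json
    into ``config.out_dir`` and returns the report."""
    upt = [read_emg_csv(p, {"condition": "UPT"}) for p in config.upt_trials]
    ptb = [read_emg_csv(p, {"condition": "PTB"}) for p in config.ptb_trials]
    kin_upt = [read_kinetics_tsv(p, config.body_mass) for p in config.kinetics_upt]
    kin_ptb = [read_kinetics_tsv(p, config.body_mass) for p in config.kinetics_ptb]
    report = analyze_subject(upt, ptb, kin_upt, kin_ptb, config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def simulate_subject(
    out_dir: str | Path,
    seed: int = 0,
    n_upt: int = 10,
    noise_level: float = 0.05,
    stance_ms: float = 330.0,
    body_mass: float = 71.0,
) -> StudyConfig:
    """Emit a full synthetic subject (``n_upt`` UPT + 1 PTB trial) to disk
    and return a ready-to-run :class:`StudyConfig`.

    Writes envelope CSVs, kinetics TSVs, the ground-truth JSON sidecar and a
    ``study.yaml`` config into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = synthetic.cutting_preset_truth(seed=seed, noise_level=noise_level)
    upt = synthetic.synthesize_trials(truth, n_upt, "UPT", seed=seed + 10)
    ptb = synthetic.synthesize_trials(truth, 1, "PTB", seed=seed + 11)
    upt_paths, ptb_paths = [], []
    for i, t in enumerate(upt.trials):
        p = out / f"upt_{i:02d}.csv"
        write_emg_csv(t, p)
        upt_paths.append(str(p))
    p = out / "ptb_00.csv"
    write_emg_csv(ptb.trials[0], p)
    ptb_paths.append(str(p))
    write_truth_json(truth, out / "truth.json")

    kin_paths = {}
    for label, kseed in (("upt", seed + 20), ("ptb", seed + 21)):
        trace, _ = synthetic.synthesize_kinetics(
            stance_ms=stance_ms, body_mass=body_mass, seed=kseed
        )
        kp = out / f"kinetics_{label}.tsv"
        write_kinetics_tsv(trace, kp)
        kin_paths[label] = str(kp)

    cfg = StudyConfig(
        upt_trials=tuple(upt_paths),
        ptb_trials=tuple(ptb_paths),
        kinetics_upt=(kin_paths["upt"],),
        kinetics_ptb=(kin_paths["ptb"],),
        body_mass=body_mass,
        seed=seed,
        out_dir=str(out),
    )
    plain = {
        k: list(v) if isinstance(v := getattr(cfg, k), tuple) else v
        for k in cfg.__dataclass_fields__
    }
    (out / "study.yaml").write_text(yaml.safe_dump(plain))
    return cfg
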