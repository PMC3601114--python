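"""Synthetic EMG-envelope and kinetic data with known ground truth.

The generator emulates the statistical structure the modular-control
analysis assumes: cycle-normalized non-negative envelopes produced by a small
number of motor modules (muscle-weighting columns) driven by unimodal,
cycle-locked activation signals, plus additive non-negative noise.  A
perturbed condition (PTB) is modelled as a gain applied to selected modules'
activation signals inside a window of the cycle — the "reduced recruitment
while the support surface slides" effect — leaving the weightings untouched.

Default conditions
------------------
* 16 muscles, 5 planted modules, 200-point cycle;
* activation peaks at 10, 37, 64, 83 and 95 % of the cycle with an 8 %
  Gaussian width, matching the ordering and rough timing of the five
  modules reported for cutting manoeuvres (foot-descent, load-acceptance
  hamstrings/gluteals, calf propulsion, trunk control, swing preparation);
* ipsilateral initial contact at 30 % of the cycle (the cycle runs from the
  contralateral foot contact to ipsilateral toe-off);
* envelope noise std = 5 % of the clean-mixture RMS, clipped at zero;
* the perturbed condition halves the hamstring/gluteal module's activation
  from initial contact to 62 % of the cycle (a 150 ms surface translation
  occupying the load-acceptance phase).

Noise is truncated additive Gaussian on the envelope: envelopes are
non-negative by construction and no generative noise model is claimed beyond
that constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .muscles import MUSCLES
from .preprocess import EnvelopeMatrix
from .kinetics import CycleKinetics, GaitEvents

__all__ = [
    "PlantedGroundTruth",
    "SyntheticTrialSet",
    "platform_speed_cm_s",
    "generate_module_set",
    "generate_activation_signals",
    "cutting_preset_truth",
    "synthesize_trials",
    "synthesize_kinetics",
    "DEFAULT_PEAK_PCTS",
    "DEFAULT_WIDTH_PCT",
    "DEFAULT_IC_PCT",
    "DEFAULT_PERTURB_SPEC",
    "HAMSTRING_MODULE",
]

#: support-surface translation delivered at initial contact in the
#: perturbed condition: 10 cm over 150 ms
PLATFORM_DISPLACEMENT_CM: float = 10.0
PLATFORM_TRANSLATION_MS: float = 150.0


def platform_speed_cm_s(
    displacement_cm: float = PLATFORM_DISPLACEMENT_CM,
    duration_ms: float = PLATFORM_TRANSLATION_MS,
) -> float:
    """Average speed of the support-surface translation (cm/s)."""
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    return displacement_cm / (duration_ms / 1000.0)


#: default activation-peak placements (% of cycle) for the 5 planted modules
DEFAULT_PEAK_PCTS: tuple[float, ...] = (10.0, 37.0, 64.0, 83.0, 95.0)
#: Gaussian bump width (std, % of cycle)
DEFAULT_WIDTH_PCT: float = 8.0
#: ipsilateral initial contact, % of cycle
DEFAULT_IC_PCT: float = 30.0
#: index of the hamstring/gluteal load-acceptance module in the preset
HAMSTRING_MODULE: int = 1
#: default perturbation: halve module 2's activation from IC to 62 % of cycle
DEFAULT_PERTURB_SPEC: tuple[tuple[int, float, float, float], ...] = (
    (HAMSTRING_MODULE, DEFAULT_IC_PCT, 62.0, 0.5),
)

# dominant muscles per preset module (others receive small background weights)
_PRESET_GROUPS: tuple[tuple[str, ...], ...] = (
    ("TA", "VM", "VL", "RF"),       # M1: pre-contact quadriceps / dorsiflexor
    ("BF", "ST", "GMA", "GME"),     # M2: load-acceptance hamstrings/gluteals
    ("SOL", "GM", "PER"),           # M3: calf propulsion
    ("ESP", "RAB", "EOB"),          # M4: trunk control
    ("TA", "ADD", "TFL"),           # M5: swing preparation
)


@dataclass(frozen=True)
class PlantedGroundTruth:
    """Generative ground truth: weightings S (M x N, unit-norm columns),
    activations P (N x K), noise level and perturbation specification.

    ``perturb_spec`` entries are ``(module_index, start_pct, end_pct, gain)``:
    in the perturbed condition, module ``module_index``'s activation signal
    is multiplied by ``gain`` for cycle percentages in ``[start, end]``.
    ``noise_level`` is the noise std expressed relative to the RMS of the
    clean mixture S @ P.
    """

    weightings: np.ndarray
    activations: np.ndarray
    noise_level: float
    perturb_spec: tuple[tuple[int, float, float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        S = np.asarray(self.weightings, dtype=float)
        P = np.asarray(self.activations, dtype=float)
        if S.ndim != 2 or P.ndim != 2 or S.shape[1] != P.shape[0]:
            raise ValueError("weightings (M x N) and activations (N x K) required")
        if np.any(S < 0) or np.any(P < 0):
            raise ValueError("ground-truth factors must be non-negative")
        norms = np.linalg.norm(S, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("weighting columns must have unit Euclidean norm")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        spec = tuple(tuple(entry) for entry in self.perturb_spec)
        for mod, start, end, gain in spec:
            if not 0 <= mod < S.shape[1]:
                raise ValueError(f"perturbed module index {mod} out of range")
            if not 0 <= start < end <= 100:
                raise ValueError("perturbation window must satisfy 0 <= start < end <= 100")
            if gain < 0:
                raise ValueError("perturbation gain must be >= 0")
        object.__setattr__(self, "weightings", S)
        object.__setattr__(self, "activations", P)
        object.__setattr__(self, "perturb_spec", spec)

    @property
    def n_muscles(self) -> int:
        return self.weightings.shape[0]

    @property
    def n_modules(self) -> int:
        return self.weightings.shape[1]

    @property
    def n_points(self) -> int:
        return self.activations.shape[1]

    def perturbed_activations(self) -> np.ndarray:
        """Activations with the perturbation gains applied inside their windows."""
        P = self.activations.copy()
        pct = np.linspace(0.0, 100.0, self.n_points)
        for mod, start, end, gain in self.perturb_spec:
            mask = (pct >= start) & (pct <= end)
            P[mod, mask] *= gain
        return P


@dataclass(frozen=True)
class SyntheticTrialSet:
    """A batch of synthetic envelope trials with their generative truth."""

    trials: tuple[EnvelopeMatrix, ...]
    condition_labels: tuple[str, ...]
    truth: PlantedGroundTruth

    def __post_init__(self) -> None:
        if len(self.trials) != len(self.condition_labels):
            raise ValueError("one condition label per trial required")
        shapes = {t.values.shape for t in self.trials}
        if len(shapes) > 1:
            raise ValueError("all trials must share muscles and time points")
        object.__setattr__(self, "trials", tuple(self.trials))
        object.__setattr__(self, "condition_labels", tuple(self.condition_labels))


def generate_module_set(
    n_muscles: int, n_modules: int, sparsity: float = 0.4, seed: int = 0
) -> np.ndarray:
    """Random non-negative M x N weighting matrix with unit-norm columns.

    Approximately ``sparsity`` of the entries are zeroed, never producing an
    all-zero column or row.
    """
    if n_modules > n_muscles:
        raise ValueError(f"n_modules ({n_modules}) must be <= n_muscles ({n_muscles})")
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_zero = int(round(sparsity * n_muscles))
    if n_zero >= n_muscles:
        raise ValueError("sparsity leaves no non-zero entry per column")
    W = rng.uniform(0.05, 1.0, size=(n_muscles, n_modules))
    for j in range(n_modules):
        zero_rows = rng.choice(n_muscles, size=n_zero, replace=False)
        W[zero_rows, j] = 0.0
    # repair all-zero rows: every muscle participates in at least one module
    for i in np.flatnonzero(W.sum(axis=1) == 0):
        W[i, rng.integers(n_modules)] = rng.uniform(0.05, 1.0)
    return W / np.linalg.norm(W, axis=0)


def generate_activation_signals(
    n_modules: int,
    n_points: int = 200,
    peak_pcts: Sequence[float] = DEFAULT_PEAK_PCTS,
    width_pct: float = DEFAULT_WIDTH_PCT,
    seed: int = 0,
) -> np.ndarray:
    """N x K matrix of Gaussian activation bumps in cycle-percentage space.

    Row ``i`` peaks (max = 1) at ``peak_pcts[i]`` percent of the cycle with
    std ``width_pct``.  The bumps are deterministic; ``seed`` is accepted for
    interface symmetry with the other generators.
    """
    del seed
    if len(peak_pcts) != n_modules:
        raise ValueError("need one peak percentage per module")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if width_pct <= 0:
        raise ValueError("width_pct must be positive")
    peaks = np.asarray(peak_pcts, dtype=float)
    if np.any((peaks < 0) | (peaks > 100)):
        raise ValueError("activation peaks must lie in [0, 100] % of cycle")
    pct = np.linspace(0.0, 100.0, n_points)
    P = np.exp(-((pct[None, :] - peaks[:, None]) ** 2) / (2 * width_pct**2))
    return P / P.max(axis=1, keepdims=True)


def cutting_preset_truth(
    seed: int = 0,
    noise_level: float = 0.05,
    n_points: int = 200,
    perturb_spec: Sequence[tuple[int, float, float, float]] = DEFAULT_PERTURB_SPEC,
) -> PlantedGroundTruth:
    """Structured 16-muscle, 5-module ground truth for cutting manoeuvres.

    Each module loads strongly on its functional muscle group (quadriceps
    pre-activation, hamstring/gluteal load acceptance, calf propulsion,
    trunk control, swing preparation) with small random background weights
    elsewhere; activation peaks follow :data:`DEFAULT_PEAK_PCTS`.
    """
    rng = np.random.default_rng(seed)
    M, N = len(MUSCLES), len(_PRESET_GROUPS)
    W = rng.uniform(0.0, 0.12, size=(M, N))
    for j, group in enumerate(_PRESET_GROUPS):
        for name in group:
            W[MUSCLES.index(name), j] = rng.uniform(0.6, 1.0)
    W /= np.linalg.norm(W, axis=0)
    P = generate_activation_signals(N, n_points)
    return PlantedGroundTruth(
        weightings=W,
        activations=P,
        noise_level=noise_level,
        perturb_spec=tuple(perturb_spec),
        seed=seed,
    )


def synthesize_trials(
    truth: PlantedGroundTruth,
    n_trials: int,
    condition: str = "UPT",
    seed: int = 0,
    gain_jitter: float = 0.0,
) -> SyntheticTrialSet:
    """Mix the planted factors into ``n_trials`` noisy envelope trials.

    Each trial is ``S @ P_cond + noise`` with the noise std equal to
    ``truth.noise_level`` times the clean mixture's RMS; negative draws are
    clipped to zero so envelopes stay non-negative.  For ``condition='PTB'``
    the perturbation gains are applied to the activations before mixing.
    ``gain_jitter`` optionally scales each module's activation per trial by
    ``1 + gain_jitter * z`` (z standard normal, clipped at 0) to emulate
    inter-trial recruitment variability.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if condition not in ("UPT", "PTB"):
        raise ValueError("condition must be 'UPT' or 'PTB'")
    P = truth.perturbed_activations() if condition == "PTB" else truth.activations
    clean = truth.weightings @ P
    rms = float(np.sqrt(np.mean(clean**2)))
    noise_std = truth.noise_level * rms
    rng = np.random.default_rng(seed)
    trials = []
    for i in range(n_trials):
        Pi = P
        if gain_jitter > 0:
            gains = np.clip(1.0 + gain_jitter * rng.standard_normal(truth.n_modules), 0, None)
            Pi = P * gains[:, None]
        X = truth.weightings @ Pi
        if noise_std > 0:
            X = X + rng.normal(0.0, noise_std, size=X.shape)
        trials.append(
            EnvelopeMatrix(
                values=np.clip(X, 0.0, None),
                labels=MUSCLES[: truth.n_muscles]
                if truth.n_muscles <= len(MUSCLES)
                else tuple(f"CH{i+1}" for i in range(truth.n_muscles)),
                meta={"trial": i, "condition": condition, "synthetic": True},
            )
        )
    return SyntheticTrialSet(
        trials=tuple(trials),
        condition_labels=(condition,) * n_trials,
        truth=truth,
    )


def synthesize_kinetics(
    stance_ms: float = 330.0,
    body_mass: float = 71.0,
    peak_fz: float = 1500.0,
    com_speed: float = 2.67,
    seed: int = 0,
    rate: float = 1024.0,
    ic_pct: float = DEFAULT_IC_PCT,
    power_amp: float = 15.0,
    hf_ap: float = 10.0,
    hf_ml: float = 3.5,
    lead_ms: float = 150.0,
) -> tuple[CycleKinetics, GaitEvents]:
    """Synthetic ground-reaction-force and CoM-velocity traces for one cycle.

    The recording starts ``lead_ms`` before the analyzed cycle; the cycle
    spans contralateral initial contact to ipsilateral toe-off (end of
    trace), with ipsilateral contact at ``ic_pct`` % of the cycle.  Vertical
    force follows a ``sqrt(sin)`` stance profile peaking at ``peak_fz`` (so
    the 20 N contact threshold is crossed within one sample of the planted
    contact).  The CoM power profile over stance is a single-sign-change
    ``-sin(2*pi*s)`` shape scaled to ``power_amp`` W/kg — strictly negative
    during load acceptance, strictly positive during propulsion — realised by
    choosing the CoM velocity along the instantaneous force direction.
    Horizontal forces are single bumps in the first half of stance peaking at
    ``hf_ap`` and ``hf_ml`` N/kg.  Before contact the CoM moves horizontally
    at ``com_speed``.

    Returns the kinetic traces and the planted gait events.
    """
    if stance_ms <= 0:
        raise ValueError("stance_ms must be positive")
    if not 0 < ic_pct < 100:
        raise ValueError("ic_pct must lie in (0, 100)")
    rng = np.random.default_rng(seed)
    del rng  # traces are deterministic; seed kept for interface stability
    cycle_ms = stance_ms / (1.0 - ic_pct / 100.0)
    n_lead = int(round(lead_ms / 1000.0 * rate))
    n_cycle = int(round(cycle_ms / 1000.0 * rate))
    n_total = n_lead + n_cycle
    left_ic = n_lead
    ic = n_lead + int(round(ic_pct / 100.0 * n_cycle))
    n_stance = n_total - ic
    if n_stance < 8:
        raise ValueError("stance too short for the sampling rate")
    t = np.arange(n_total) / rate

    # stance-phase coordinate in (0, 1), excluding the exact endpoints
    s = (np.arange(n_stance) + 1.0) / (n_stance + 1.0)
    fz = np.zeros(n_total)
    fz[ic:] = peak_fz * np.sqrt(np.sin(np.pi * s))
    fy = np.zeros(n_total)
    fx = np.zeros(n_total)
    bump = np.sin(np.pi * np.clip(s / 0.5, 0.0, 1.0))  # single peak at 25 % stance
    fy[ic:] = hf_ap * body_mass * bump
    fx[ic:] = hf_ml * body_mass * bump
    grf = np.vstack([fx, fy, fz])

    # target CoM power (W/kg): one sign change, negative then positive
    p_target = np.zeros(n_total)
    p_target[ic:] = -power_amp * np.sin(2 * np.pi * s)

    com_v = np.zeros((3, n_total))
    com_v[1, :ic] = com_speed  # constant anterior approach velocity
    fmag2 = np.einsum("ij,ij->j", grf[:, ic:], grf[:, ic:])
    scale = p_target[ic:] * body_mass / fmag2
    com_v[:, ic:] = grf[:, ic:] * scale[None, :]

    com_p = np.concatenate(
        [np.zeros((3, 1)), np.cumsum((com_v[:, 1:] + com_v[:, :-1]) / 2, axis=1) / rate],
        axis=1,
    )

    kin = CycleKinetics(
        grf=grf,
        com_velocity=com_v,
        time=t,
        rate=rate,
        body_mass=body_mass,
        com_position=com_p,
        meta={
            "synthetic": True,
            "planted_left_ic": left_ic,
            "planted_ic": ic,
            "planted_toe_off": n_total,
            "planted_neg_peak": ic + int(np.argmin(p_target[ic:])),
            "planted_pos_peak": ic + int(np.argmax(p_target[ic:])),
            "planted_com_speed": com_speed,
            "seed": seed,
        },
    )
    events = GaitEvents(left_ic=left_ic, ic=ic, toe_off=n_total)
    return kin, events
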