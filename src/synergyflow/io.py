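"""Delimited-text readers and writers for the pipeline's data formats.

* EMG CSV: header ``muscle,s0,s1,...``; one row per muscle, columns are
  samples (raw or envelope values).
* Kinetics TSV: named columns ``time_s, Fx, Fy, Fz, CoM_vx, CoM_vy, CoM_vz``
  (optionally ``CoM_px/py/pz``), one row per force sample.
* Ground-truth JSON sidecar: the planted weightings/activations, noise
  level, perturbation spec and seed of a synthetic trial set.
* Module-set JSON: extracted weightings, activations and fit diagnostics.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .factorization import MotorModuleSet
from .kinetics import CycleKinetics
from .preprocess import EnvelopeMatrix
from .synthetic import PlantedGroundTruth

__all__ = [
    "write_emg_csv",
    "read_emg_csv",
    "write_kinetics_tsv",
    "read_kinetics_tsv",
    "write_truth_json",
    "read_truth_json",
    "write_modules_json",
    "read_modules_json",
]


def write_emg_csv(env: EnvelopeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        env.values,
        index=pd.Index(env.labels, name="muscle"),
        columns=[f"s{i}" for i in range(env.n_points)],
    )
    df.to_csv(path, float_format="%.10g")


def read_emg_csv(path: str | Path, meta: dict | None = None) -> EnvelopeMatrix:
    df = pd.read_csv(path, index_col="muscle")
    return EnvelopeMatrix(
        values=df.to_numpy(dtype=float),
        labels=tuple(df.index),
        meta=dict(meta or {}, source=str(path)),
    )


def write_kinetics_tsv(kin: CycleKinetics, path: str | Path) -> None:
    cols = {
        "time_s": kin.time,
        "Fx": kin.grf[0],
        "Fy": kin.grf[1],
        "Fz": kin.grf[2],
        "CoM_vx": kin.com_velocity[0],
        "CoM_vy": kin.com_velocity[1],
        "CoM_vz": kin.com_velocity[2],
    }
    if kin.com_position is not None:
        cols.update(
            CoM_px=kin.com_position[0],
            CoM_py=kin.com_position[1],
            CoM_pz=kin.com_position[2],
        )
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_kinetics_tsv(
    path: str | Path, body_mass: float, meta: dict | None = None
) -> CycleKinetics:
    df = pd.read_csv(path, sep="\t")
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError("kinetics trace needs at least two samples")
    rate = float(round(1.0 / np.median(np.diff(t))))
    pos = None
    if {"CoM_px", "CoM_py", "CoM_pz"}.issubset(df.columns):
        pos = df[["CoM_px", "CoM_py", "CoM_pz"]].to_numpy().T
    return CycleKinetics(
        grf=df[["Fx", "Fy", "Fz"]].to_numpy().T,
        com_velocity=df[["CoM_vx", "CoM_vy", "CoM_vz"]].to_numpy().T,
        time=t,
        rate=rate,
        body_mass=body_mass,
        com_position=pos,
        meta=dict(meta or {}, source=str(path)),
    )


def write_truth_json(truth: PlantedGroundTruth, path: str | Path) -> None:
    payload = {
        "weightings": truth.weightings.tolist(),
        "activations": truth.activations.tolist(),
        "noise_level": truth.noise_level,
        "perturb_spec": [list(entry) for entry in truth.perturb_spec],
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path: str | Path) -> PlantedGroundTruth:
    payload = json.loads(Path(path).read_text())
    return PlantedGroundTruth(
        weightings=np.asarray(payload["weightings"]),
        activations=np.asarray(payload["activations"]),
        noise_level=payload["noise_level"],
        perturb_spec=tuple(tuple(e) for e in payload["perturb_spec"]),
        seed=payload["seed"],
    )


def write_modules_json(mset: MotorModuleSet, path: str | Path) -> None:
    payload = {
        "weightings": mset.weightings.tolist(),
        "activations": mset.activations.tolist(),
        "n_modules": mset.n_modules,
        "fit": {k: v for k, v in mset.fit.items() if not isinstance(v, np.ndarray)},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_modules_json(path: str | Path) -> MotorModuleSet:
    payload = json.loads(Path(path).read_text())
    return MotorModuleSet(
        weightings=np.asarray(payload["weightings"]),
        activations=np.asarray(payload["activations"]),
        n_modules=payload["n_modules"],
        fit=payload.get("fit", {}),
    )
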