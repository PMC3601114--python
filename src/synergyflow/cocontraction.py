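"""Epoch-windowed EMG amplitudes and knee co-contraction ratio/index.

Three analysis epochs around the support phase are used:

* PRE — the 10 ms immediately before initial contact;
* LA  — from initial contact to the negative CoM-power peak (load
  acceptance);
* PRP — a 50 ms window centered on the positive CoM-power peak
  (propulsion).

Average EMG amplitude per muscle and epoch is taken on stance-normalized
envelopes (fraction of the per-muscle stance maximum).  The co-contraction
ratio (CCR) is the mean knee-flexor activity (BF, ST) divided by the mean
knee-extensor activity (VM, VL, RF); the co-contraction index (CCI) is the
grand mean activation of those five muscles times the CCR, so CCR is
invariant to common scaling while CCI scales linearly with it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .kinetics import GaitEvents, PowerSummary
from .muscles import KNEE_EXTENSORS, KNEE_FLEXORS
from .preprocess import EnvelopeMatrix

__all__ = [
    "EpochSet",
    "CocontractionResult",
    "build_epochs",
    "epoch_mean_amplitude",
    "ccr",
    "cci",
    "cocontraction_by_epoch",
]

EPOCHS = ("pre", "la", "prp")


@dataclass(frozen=True)
class EpochSet:
    """Half-open sample windows ``[start, stop)`` on the envelope time axis."""

    pre: tuple[int, int]
    la: tuple[int, int]
    prp: tuple[int, int]

    def __post_init__(self) -> None:
        for name in EPOCHS:
            a, b = getattr(self, name)
            if not 0 <= a < b:
                raise ValueError(f"epoch {name!r} window ({a}, {b}) is empty or negative")
        if not (self.pre[1] <= self.la[0] and self.la[1] <= self.prp[0]):
            raise ValueError("epochs must be ordered PRE < LA < PRP without overlap")

    def items(self):
        return [(name, getattr(self, name)) for name in EPOCHS]


@dataclass(frozen=True)
class CocontractionResult:
    """Knee flexor/extensor co-contraction for one epoch."""

    ccr: float
    cci: float
    flexor_mean: float
    extensor_mean: float
    epoch: str


def build_epochs(
    events: GaitEvents,
    power: PowerSummary,
    n_points: int,
    pre_ms: float = 10.0,
    prp_halfwidth_ms: float = 25.0,
) -> EpochSet:
    """Map the kinetic events onto the normalized envelope time axis.

    The envelope's ``n_points`` samples span the cycle from the
    contralateral contact (``events.left_ic``) to toe-off; kinetic sample
    indices are converted proportionally.  PRE ends at initial contact, LA
    runs from initial contact to the negative power peak, PRP covers
    ``+/- prp_halfwidth_ms`` around the positive power peak.
    """
    span = events.toe_off - events.left_ic
    if span <= 0:
        raise ValueError("degenerate cycle span")

    def to_env(sample: float) -> int:
        frac = (sample - events.left_ic) / span
        return int(round(frac * (n_points - 1)))

    rate = power.rate
    ic_env = to_env(events.ic)
    pre = (to_env(events.ic - pre_ms / 1000.0 * rate), ic_env)
    la = (ic_env, to_env(power.neg_peak_sample) + 1)
    half = prp_halfwidth_ms / 1000.0 * rate
    prp = (to_env(power.pos_peak_sample - half), to_env(power.pos_peak_sample + half) + 1)
    prp = (max(prp[0], la[1]), min(prp[1], n_points))
    if pre[0] < 0:
        raise ValueError("PRE epoch starts before the recording")
    return EpochSet(pre=pre, la=la, prp=prp)


def epoch_mean_amplitude(env: EnvelopeMatrix, epochs: EpochSet) -> pd.DataFrame:
    """Mean amplitude per muscle and epoch (rows: muscles, columns: epochs).

    Expects stance-normalized envelopes so values read as fraction of the
    per-muscle stance maximum.
    """
    data = {}
    for name, (a, b) in epochs.items():
        if b > env.n_points:
            raise ValueError(f"epoch {name!r} extends past the envelope")
        if b <= a:
            raise ValueError(f"epoch {name!r} window is empty")
        data[name] = env.values[:, a:b].mean(axis=1)
    return pd.DataFrame(data, index=list(env.labels))


def _group_means(means: Mapping[str, float] | pd.Series):
    get = means.__getitem__
    flex = float(np.mean([get(m) for m in KNEE_FLEXORS]))
    ext = float(np.mean([get(m) for m in KNEE_EXTENSORS]))
    return flex, ext


def ccr(means: Mapping[str, float] | pd.Series) -> float:
    """Co-contraction ratio: mean(BF, ST) / mean(VM, VL, RF)."""
    flex, ext = _group_means(means)
    if ext <= 0:
        raise ValueError("zero knee-extensor activity: CCR undefined")
    return flex / ext


def cci(means: Mapping[str, float] | pd.Series, mode: str = "mean") -> float:
    """Co-contraction index: overall knee-muscle activation times the CCR.

    ``mode='mean'`` (default) uses the grand mean of the five knee muscles;
    ``mode='sum'`` uses their sum (an alternative scaling of the same
    quantity).
    """
    all_muscles = KNEE_FLEXORS + KNEE_EXTENSORS
    get = means.__getitem__
    vals = [get(m) for m in all_muscles]
    overall = float(np.sum(vals)) if mode == "sum" else float(np.mean(vals))
    if mode not in ("mean", "sum"):
        raise ValueError("mode must be 'mean' or 'sum'")
    return overall * ccr(means)


def cocontraction_by_epoch(
    env: EnvelopeMatrix, epochs: EpochSet, mode: str = "mean"
) -> dict[str, CocontractionResult]:
    """CCR/CCI for every epoch of a stance-normalized envelope trial."""
    table = epoch_mean_amplitude(env, epochs)
    out = {}
    for name in EPOCHS:
        col = table[name]
        flex, ext = _group_means(col)
        out[name] = CocontractionResult(
            ccr=ccr(col),
            cci=cci(col, mode=mode),
            flexor_mean=flex,
            extensor_mean=ext,
            epoch=name,
        )
    return out
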