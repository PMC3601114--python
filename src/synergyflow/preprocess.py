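"""EMG preprocessing: band-pass, rectification/low-pass envelope, cycle
time-normalization and the two amplitude-normalization schemes.

The fixed processing order is band-pass -> segment -> rectify + low-pass ->
time-normalize -> amplitude-normalize.  All filters are second-order
zero-phase (forward-backward) Butterworth, so envelope peak timing is not
shifted by filtering.

Two distinct amplitude normalizations are provided because the downstream
analyses need different references:

* :func:`normalize_amplitude` divides each muscle by its peak over the whole
  pooled trial set (all conditions of one subject); the result feeds the
  non-negative matrix factorization and lies in [0, 1].
* :func:`epoch_normalize_amplitude` divides by the per-muscle maximum taken
  over stance-period samples only; it feeds the epoch-windowed amplitude and
  co-contraction analysis, where activity is expressed as a fraction of the
  stance maximum (swing samples may then exceed 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal

from .muscles import MUSCLES

__all__ = [
    "RawEmgRecording",
    "EnvelopeMatrix",
    "CycleWindow",
    "bandpass",
    "envelope",
    "time_normalize",
    "normalize_amplitude",
    "epoch_normalize_amplitude",
]


@dataclass(frozen=True)
class RawEmgRecording:
    """Multi-channel raw (or band-passed) EMG, one row per muscle."""

    samples: np.ndarray  # (M, T), arbitrary units
    rate: float = 2048.0  # Hz
    labels: tuple[str, ...] = MUSCLES

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2:
            raise ValueError("samples must be a 2-D (muscles x time) array")
        if samples.shape[0] != len(self.labels):
            raise ValueError(
                f"{samples.shape[0]} channels but {len(self.labels)} labels"
            )
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class EnvelopeMatrix:
    """Non-negative muscles x time envelope matrix.

    After :func:`time_normalize` the time axis is the normalized movement
    cycle (``n_points`` equally spaced samples, 200 by default); after
    :func:`normalize_amplitude` values lie in [0, 1] with a per-muscle
    maximum of exactly 1 over the normalization pool.
    """

    values: np.ndarray  # (M, K), >= 0
    labels: tuple[str, ...] = MUSCLES
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be 2-D (muscles x time)")
        if values.shape[0] != len(self.labels):
            raise ValueError(
                f"{values.shape[0]} rows but {len(self.labels)} labels"
            )
        if np.any(values < 0):
            raise ValueError("envelope values must be non-negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_muscles(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CycleWindow:
    """Movement-cycle segment in source samples: contralateral initial
    contact (``start_sample``) to end of ipsilateral stance (``end_sample``)."""

    start_sample: int
    end_sample: int
    rate: float

    def __post_init__(self) -> None:
        if not self.start_sample < self.end_sample:
            raise ValueError("cycle window requires start_sample < end_sample")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


def _butter_filtfilt(
    x: np.ndarray, rate: float, cutoff, btype: str, order: int
) -> np.ndarray:
    sos = signal.butter(order, cutoff, btype=btype, fs=rate, output="sos")
    # forward-backward application doubles the effective order and zeroes
    # the phase; generous even-reflection padding suppresses edge transients
    padlen = min(x.shape[-1] - 1, 12 * order)
    return signal.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def bandpass(
    raw: RawEmgRecording, low: float = 20.0, high: float = 500.0, order: int = 2
) -> RawEmgRecording:
    """Zero-phase Butterworth band-pass applied per channel.

    ``high`` must stay below the Nyquist frequency.
    """
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= raw.rate / 2:
        raise ValueError(
            f"high cutoff {high} Hz >= Nyquist {raw.rate / 2} Hz"
        )
    filtered = _butter_filtfilt(raw.samples, raw.rate, (low, high), "bandpass", order)
    return replace(raw, samples=filtered)


def envelope(raw: RawEmgRecording, lp: float = 10.0, order: int = 2) -> EnvelopeMatrix:
    """Linear envelope: full-wave rectification then zero-phase low-pass.

    Residual filter undershoot below zero is clipped; the clipped magnitude
    is recorded in ``meta['clip_l1']``.
    """
    if not 0 < lp < raw.rate / 2:
        raise ValueError("low-pass cutoff must lie in (0, Nyquist)")
    rectified = np.abs(raw.samples)
    smoothed = _butter_filtfilt(rectified, raw.rate, lp, "lowpass", order)
    clip_l1 = float(np.abs(smoothed[smoothed < 0]).sum())
    smoothed = np.clip(smoothed, 0.0, None)
    return EnvelopeMatrix(
        values=smoothed,
        labels=raw.labels,
        meta={"rate": raw.rate, "clip_l1": clip_l1},
    )


def time_normalize(
    env: EnvelopeMatrix, win: CycleWindow, n_points: int = 200
) -> EnvelopeMatrix:
    """Linearly interpolate each channel onto ``n_points`` equally spaced
    samples spanning the cycle window (endpoints included)."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if win.start_sample < 0 or win.end_sample >= env.n_points:
        raise ValueError("cycle window outside recording")
    if win.end_sample - win.start_sample < 1:
        raise ValueError("cycle window shorter than 2 samples")
    src = np.arange(win.start_sample, win.end_sample + 1, dtype=float)
    dst = np.linspace(win.start_sample, win.end_sample, n_points)
    seg = env.values[:, win.start_sample : win.end_sample + 1]
    out = np.empty((env.n_muscles, n_points))
    for m in range(env.n_muscles):
        out[m] = np.interp(dst, src, seg[m])
    meta = dict(env.meta)
    meta.update(
        cycle_start=win.start_sample,
        cycle_end=win.end_sample,
        source_rate=win.rate,
        n_points=n_points,
    )
    return EnvelopeMatrix(values=out, labels=env.labels, meta=meta)


def _pooled_max(trials: Sequence[EnvelopeMatrix], columns=None) -> np.ndarray:
    labels = trials[0].labels
    for t in trials:
        if t.labels != labels:
            raise ValueError("trials must share muscle ordering")
    maxima = np.zeros(len(labels))
    for t in trials:
        vals = t.values if columns is None else t.values[:, columns(t)]
        if vals.shape[1] == 0:
            raise ValueError("empty normalization window")
        maxima = np.maximum(maxima, vals.max(axis=1))
    return maxima


def _apply_scale(trials, maxima, tag):
    zero = maxima == 0
    if np.any(zero):
        names = [trials[0].labels[i] for i in np.flatnonzero(zero)]
        warnings.warn(
            f"muscle(s) {names} have zero pooled activity; left unscaled",
            stacklevel=3,
        )
    scale = np.where(zero, 1.0, maxima)
    out = []
    for t in trials:
        meta = dict(t.meta)
        meta[tag] = maxima.tolist()
        out.append(
            EnvelopeMatrix(values=t.values / scale[:, None], labels=t.labels, meta=meta)
        )
    return out


def normalize_amplitude(trials: Sequence[EnvelopeMatrix]) -> list[EnvelopeMatrix]:
    """Divide each muscle by its peak over the pooled trial set (all
    conditions of one subject), so the pooled per-muscle maximum becomes 1.

    All-zero channels are flagged with a warning and left at zero.
    """
    if not trials:
        raise ValueError("no trials to normalize")
    maxima = _pooled_max(trials)
    return _apply_scale(trials, maxima, "amplitude_norm_max")


def epoch_normalize_amplitude(
    trials: Sequence[EnvelopeMatrix],
    stance_windows: Sequence[tuple[int, int]],
) -> list[EnvelopeMatrix]:
    """Like :func:`normalize_amplitude` but the per-muscle maximum is taken
    over stance-period samples only.

    ``stance_windows`` gives, per trial, the half-open ``[start, stop)``
    stance span in envelope sample indices.
    """
    if not trials:
        raise ValueError("no trials to normalize")
    if len(stance_windows) != len(trials):
        raise ValueError("one stance window per trial required")
    for (a, b), t in zip(stance_windows, trials):
        if not 0 <= a < b <= t.n_points:
            raise ValueError(f"invalid stance window ({a}, {b})")
    windows = {id(t): w for t, w in zip(trials, stance_windows)}
    maxima = _pooled_max(
        trials, columns=lambda t: slice(windows[id(t)][0], windows[id(t)][1])
    )
    return _apply_scale(trials, maxima, "stance_norm_max")
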