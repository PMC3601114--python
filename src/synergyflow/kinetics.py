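"""Ground-reaction-force and CoM kinetics: stance detection, CoM power and
external work phases, approach speed, horizontal force peaks and generic
peak/timing summaries for joint-level time series.

Sign conventions: CoM power is the dot product of the ground reaction force
with the CoM velocity, normalized per kilogram of body mass (W/kg).  The
load-acceptance (LA) phase is the contiguous span of negative CoM power
after initial contact (energy absorption, external work W_LAC <= 0); the
propulsion (PRP) phase is the positive span that follows (W_PRP >= 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, signal

__all__ = [
    "CycleKinetics",
    "GaitEvents",
    "PowerSummary",
    "detect_stance",
    "com_power",
    "com_speed",
    "horizontal_force_peaks",
    "series_peaks",
    "resample_to_rate",
]

GRAVITY = 9.81  # m/s^2, used only by the per-body-weight power convention


@dataclass(frozen=True)
class CycleKinetics:
    """Force-plate and CoM traces for one recorded cycle.

    ``grf`` rows are (Fx medial-lateral, Fy anterior-posterior, Fz vertical)
    in newtons; ``com_velocity`` rows are the matching CoM velocity
    components in m/s, resampled to the force rate.
    """

    grf: np.ndarray  # (3, T) N
    com_velocity: np.ndarray  # (3, T) m/s
    time: np.ndarray  # (T,) s
    rate: float  # Hz
    body_mass: float  # kg
    com_position: np.ndarray | None = None  # (3, T) m, optional
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grf = np.atleast_2d(np.asarray(self.grf, dtype=float))
        v = np.atleast_2d(np.asarray(self.com_velocity, dtype=float))
        t = np.asarray(self.time, dtype=float)
        if grf.shape != (3, t.size) or v.shape != (3, t.size):
            raise ValueError("grf and com_velocity must be 3 x T matching time")
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        object.__setattr__(self, "grf", grf)
        object.__setattr__(self, "com_velocity", v)
        object.__setattr__(self, "time", t)
        if self.com_position is not None:
            p = np.atleast_2d(np.asarray(self.com_position, dtype=float))
            if p.shape != (3, t.size):
                raise ValueError("com_position must be 3 x T")
            object.__setattr__(self, "com_position", p)

    @property
    def fz(self) -> np.ndarray:
        return self.grf[2]


@dataclass(frozen=True)
class GaitEvents:
    """Cycle events in force-rate samples: contralateral contact (cycle
    start), ipsilateral initial contact and end of ipsilateral stance."""

    ic: int
    toe_off: int
    left_ic: int = 0

    def __post_init__(self) -> None:
        if not self.left_ic <= self.ic < self.toe_off:
            raise ValueError("events must satisfy left_ic <= ic < toe_off")


@dataclass(frozen=True)
class PowerSummary:
    """CoM power trace (W/kg) with phase boundaries and external work."""

    com_power: np.ndarray  # (T,) W/kg
    w_lac: float  # J/kg, <= 0
    w_prp: float  # J/kg, >= 0
    neg_peak_sample: int
    pos_peak_sample: int
    la_span: tuple[int, int]  # half-open, force samples
    prp_span: tuple[int, int]
    rate: float

    def __post_init__(self) -> None:
        if self.w_lac > 1e-12 or self.w_prp < -1e-12:
            raise ValueError("work signs violate phase definition")


def detect_stance(
    fz: np.ndarray,
    rate: float,
    threshold: float = 20.0,
    debounce_ms: float = 5.0,
    left_ic: int = 0,
) -> GaitEvents:
    """Threshold-based stance detection on the vertical force.

    Initial contact is the first sample where ``fz`` exceeds ``threshold``
    (20 N by default) and stays above it for ``debounce_ms``; toe-off is the
    first subsequent sample at or below the threshold sustained for the same
    debounce window.  A recording that ends while still loaded yields
    ``toe_off = len(fz)``.
    """
    fz = np.asarray(fz, dtype=float)
    hold = max(1, int(round(debounce_ms / 1000.0 * rate)))
    above = fz > threshold
    ic = _first_sustained(above, hold)
    if ic is None:
        raise ValueError(f"vertical force never exceeds {threshold} N")
    below = ~above
    off_rel = _first_sustained(below[ic:], hold)
    toe_off = len(fz) if off_rel is None else ic + off_rel
    return GaitEvents(ic=ic, toe_off=toe_off, left_ic=left_ic)


def _first_sustained(mask: np.ndarray, hold: int) -> int | None:
    """First index where ``mask`` is True for ``hold`` consecutive samples."""
    if hold == 1:
        idx = np.flatnonzero(mask)
        return int(idx[0]) if idx.size else None
    window = np.convolve(mask.astype(int), np.ones(hold, dtype=int), mode="valid")
    idx = np.flatnonzero(window == hold)
    return int(idx[0]) if idx.size else None


def com_power(
    grf: np.ndarray,
    com_v: np.ndarray,
    body_mass: float,
    rate: float,
    events: GaitEvents | None = None,
    per: str = "mass",
) -> PowerSummary:
    """CoM power and external work phases.

    ``P(t) = F(t) . v(t) / body_mass`` in W/kg (``per='weight'`` divides by
    ``body_mass * g`` instead).  Within stance, the load-acceptance phase is
    the contiguous negative-power span and propulsion the positive span that
    follows; with multiple sign changes (noisy data) the longest negative
    span preceding the longest positive span is used and a warning is
    emitted.  External work per phase is the trapezoidal time integral of
    the power.
    """
    grf = np.atleast_2d(np.asarray(grf, dtype=float))
    com_v = np.atleast_2d(np.asarray(com_v, dtype=float))
    if grf.shape != com_v.shape or grf.shape[0] != 3:
        raise ValueError("grf and com_v must both be 3 x T")
    if per not in ("mass", "weight"):
        raise ValueError("per must be 'mass' or 'weight'")
    denom = body_mass * (GRAVITY if per == "weight" else 1.0)
    power = np.einsum("ij,ij->j", grf, com_v) / denom

    start = events.ic if events is not None else 0
    stop = events.toe_off if events is not None else power.size
    stance = power[start:stop]
    if stance.size < 2:
        raise ValueError("stance window too short for power phase analysis")

    neg_spans = _sign_spans(stance < 0)
    pos_spans = _sign_spans(stance > 0)
    if not neg_spans or not pos_spans:
        raise ValueError("CoM power lacks a negative or positive phase")
    pos = max(pos_spans, key=lambda s: s[1] - s[0])
    neg_before = [s for s in neg_spans if s[0] < pos[0]]
    if not neg_before:
        raise ValueError("no negative-power span precedes the propulsion phase")
    neg = max(neg_before, key=lambda s: s[1] - s[0])
    if len(neg_spans) > 1 or len(pos_spans) > 1:
        warnings.warn(
            "multiple CoM-power sign changes; using longest negative span "
            "before the longest positive span",
            stacklevel=2,
        )

    la = (start + neg[0], start + neg[1])
    prp = (start + pos[0], start + pos[1])
    w_lac = float(integrate.trapezoid(power[la[0] : la[1]], dx=1.0 / rate))
    w_prp = float(integrate.trapezoid(power[prp[0] : prp[1]], dx=1.0 / rate))
    return PowerSummary(
        com_power=power,
        w_lac=min(w_lac, 0.0),
        w_prp=max(w_prp, 0.0),
        neg_peak_sample=la[0] + int(np.argmin(power[la[0] : la[1]])),
        pos_peak_sample=prp[0] + int(np.argmax(power[prp[0] : prp[1]])),
        la_span=la,
        prp_span=prp,
        rate=rate,
    )


def _sign_spans(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open spans of consecutive True values."""
    spans = []
    diff = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(diff == 1) + 1)
    stops = list(np.flatnonzero(diff == -1) + 1)
    if mask.size and mask[0]:
        starts.insert(0, 0)
    if mask.size and mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def com_speed(
    com_position: np.ndarray,
    rate: float,
    ic: int,
    window_s: tuple[float, float] = (-0.200, -0.100),
    lowpass_hz: float | None = 10.0,
) -> float:
    """Mean CoM speed over a window relative to initial contact.

    Position is optionally low-pass filtered (10 Hz, zero-phase, 2nd order),
    differentiated by second-order central differences, and the mean velocity
    magnitude over ``[ic + window_s[0], ic + window_s[1]]`` is returned.
    """
    pos = np.atleast_2d(np.asarray(com_position, dtype=float))
    if pos.shape[0] != 3:
        raise ValueError("com_position must be 3 x T")
    if lowpass_hz is not None and pos.shape[1] > 24:
        sos = signal.butter(2, lowpass_hz, btype="lowpass", fs=rate, output="sos")
        pos = signal.sosfiltfilt(sos, pos, axis=-1)
    vel = np.gradient(pos, 1.0 / rate, axis=1)
    a = ic + int(round(window_s[0] * rate))
    b = ic + int(round(window_s[1] * rate))
    if not 0 <= a < b <= pos.shape[1]:
        raise ValueError("speed window outside recording")
    speed = np.linalg.norm(vel[:, a:b], axis=0)
    return float(speed.mean())


def horizontal_force_peaks(
    grf: np.ndarray, events: GaitEvents, body_mass: float
) -> tuple[float, float]:
    """Peak horizontal force magnitudes over the first half of stance.

    Returns ``(hf_ap, hf_ml)`` in N per kg body mass: the maxima of |Fy| and
    |Fx| over ``[ic, ic + (toe_off - ic) / 2]``.
    """
    grf = np.atleast_2d(np.asarray(grf, dtype=float))
    half_end = events.ic + (events.toe_off - events.ic) // 2
    if half_end <= events.ic:
        raise ValueError("empty first-half-of-stance window")
    fx = grf[0, events.ic : half_end]
    fy = grf[1, events.ic : half_end]
    return (
        float(np.abs(fy).max() / body_mass),
        float(np.abs(fx).max() / body_mass),
    )


def series_peaks(
    series: np.ndarray,
    phases: PowerSummary,
    events: GaitEvents,
    mode: str = "max",
) -> dict[str, tuple[float, float]]:
    """Per-phase extremum of a stance-aligned series with its timing.

    ``series`` must be sampled on the same axis as the power trace.  For
    each of the load-acceptance and propulsion phases the requested extremum
    (``mode`` in {'max', 'min', 'abs'}) is located and reported as
    ``(value, timing)`` with timing as percent of stance duration.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size != phases.com_power.size:
        raise ValueError("series must be 1-D and aligned with the power trace")
    if mode not in ("max", "min", "abs"):
        raise ValueError("mode must be 'max', 'min' or 'abs'")
    stance_len = events.toe_off - events.ic
    out = {}
    for name, (a, b) in (("la", phases.la_span), ("prp", phases.prp_span)):
        if b <= a:
            raise ValueError(f"empty {name} phase window")
        seg = series[a:b]
        if mode == "max":
            i = int(np.argmax(seg))
        elif mode == "min":
            i = int(np.argmin(seg))
        else:
            i = int(np.argmax(np.abs(seg)))
        idx = a + i
        timing = 100.0 * (idx - events.ic) / max(stance_len - 1, 1)
        out[name] = (float(series[idx]), float(timing))
    return out


def resample_to_rate(
    series: np.ndarray, rate_in: float, rate_out: float
) -> np.ndarray:
    """Linear-interpolation resampling along the last axis (e.g. 256 Hz
    kinematics onto the 1024 Hz force axis)."""
    series = np.asarray(series, dtype=float)
    n_in = series.shape[-1]
    duration = (n_in - 1) / rate_in
    n_out = int(round(duration * rate_out)) + 1
    t_in = np.arange(n_in) / rate_in
    t_out = np.arange(n_out) / rate_out
    return np.apply_along_axis(lambda y: np.interp(t_out, t_in, y), -1, series)
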