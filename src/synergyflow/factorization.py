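"""Motor-module extraction by non-negative matrix factorization.

The envelope matrix X (muscles x time) is approximated as X ~= S @ P with
S >= 0 the muscle-weighting matrix (one column per motor module) and P >= 0
the activation signals (one row per module).  Fitting minimizes the
Frobenius reconstruction error with the classical multiplicative update
rules

    P <- P * (S^T X) / (S^T S P)
    S <- S * (X P^T) / (S P P^T)

which preserve non-negativity and never increase the error.  A small
epsilon guards the denominators.  Because the objective is non-convex the
fit is restarted from several random initializations and the best restart
(lowest final error) is kept.

Reconstruction quality is the variance accounted for,
``VAF = 1 - SSE / SST`` with SSE the summed squared residual and SST the
*uncentered* total sum of squares (sum of X**2) — the dominant convention in
the muscle-synergy literature, under which a zero reconstruction has
VAF = 0.  A centered SST is available behind a flag.

Returned module sets are canonicalized: each weighting column is scaled to
unit Euclidean norm (the scale absorbed into the matching activation row)
and modules are ordered by ascending activation peak time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import EnvelopeMatrix

__all__ = [
    "MotorModuleSet",
    "VafResult",
    "VafCurve",
    "nmf",
    "vaf",
    "vaf_curve",
    "select_dimensionality",
    "concatenate_trials",
    "multiplicative_update",
    "random_init",
]

_EPS = 1e-12


@dataclass(frozen=True)
class VafResult:
    """Variance-accounted-for of a reconstruction."""

    global_vaf: float
    per_muscle_vaf: np.ndarray
    sse: float
    sst: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "per_muscle_vaf", np.asarray(self.per_muscle_vaf, dtype=float)
        )


@dataclass(frozen=True)
class MotorModuleSet:
    """An extracted factorization: weightings S, activations P, diagnostics."""

    weightings: np.ndarray  # (M, N), unit-norm columns after canonicalization
    activations: np.ndarray  # (N, K)
    n_modules: int
    fit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        S = np.asarray(self.weightings, dtype=float)
        P = np.asarray(self.activations, dtype=float)
        if S.shape[1] != P.shape[0] or S.shape[1] != self.n_modules:
            raise ValueError("inconsistent factor shapes")
        if np.any(S < 0) or np.any(P < 0):
            raise ValueError("factors must be non-negative")
        object.__setattr__(self, "weightings", S)
        object.__setattr__(self, "activations", P)

    @property
    def reconstruction(self) -> np.ndarray:
        return self.weightings @ self.activations


def _as_array(X) -> np.ndarray:
    if isinstance(X, EnvelopeMatrix):
        return X.values
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if np.any(X < 0):
        raise ValueError("X must be non-negative")
    return X


def random_init(
    shape: tuple[int, int], scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform (0, 1] initialization scaled to the data magnitude."""
    return scale * (1.0 - rng.random(shape))


def multiplicative_update(
    X: np.ndarray,
    S: np.ndarray,
    P: np.ndarray,
    update: str = "both",
) -> tuple[np.ndarray, np.ndarray]:
    """One multiplicative-update sweep; ``update`` selects which factor(s)
    move ('both', 'weightings' or 'activations')."""
    if update in ("both", "activations"):
        P = P * (S.T @ X) / (S.T @ S @ P + _EPS)
    if update in ("both", "weightings"):
        S = S * (X @ P.T) / (S @ (P @ P.T) + _EPS)
    return S, P


def _canonicalize(S: np.ndarray, P: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-norm weighting columns, scale into activations, sort by peak time."""
    norms = np.linalg.norm(S, axis=0)
    norms = np.where(norms == 0, 1.0, norms)
    S = S / norms
    P = P * norms[:, None]
    order = np.argsort(np.argmax(P, axis=1), kind="stable")
    return S[:, order], P[order], order


def nmf(
    X,
    n_modules: int,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 1000,
    tol: float = 1e-6,
    track_error: bool = False,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> MotorModuleSet:
    """Best-of-restarts multiplicative-update NMF of an envelope matrix.

    Iterations stop when the relative Frobenius-error change drops below
    ``tol`` or after ``max_iter`` sweeps.  ``init`` optionally supplies one
    additional warm-start candidate ``(S0, P0)`` evaluated alongside the
    random restarts.  With ``track_error`` the per-iteration error sequence
    of the winning restart is stored in ``fit['error_history']``.
    """
    Xa = _as_array(X)
    M, K = Xa.shape
    if not 1 <= n_modules <= min(M, K):
        raise ValueError(f"n_modules must lie in [1, {min(M, K)}]")
    if not Xa.any():
        raise ValueError("X is all-zero")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    scale = float(np.sqrt(Xa.mean() / n_modules)) or 1.0
    master = np.random.default_rng(seed)
    candidates: list[tuple[np.ndarray, np.ndarray] | None] = [None] * n_restarts
    if init is not None:
        candidates.append(init)

    best = None
    for r, cand in enumerate(candidates):
        rng = np.random.default_rng(master.integers(2**31))
        if cand is None:
            S = random_init((M, n_modules), scale, rng)
            P = random_init((n_modules, K), scale, rng)
        else:
            S = np.ascontiguousarray(cand[0], dtype=float)
            P = np.ascontiguousarray(cand[1], dtype=float)
        err_prev = np.inf
        history = []
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            S, P = multiplicative_update(Xa, S, P)
            err = float(np.linalg.norm(Xa - S @ P))
            if track_error:
                history.append(err)
            if err_prev < np.inf and err_prev > 0 and (err_prev - err) / err_prev < tol:
                err_prev = err
                break
            err_prev = err
        if best is None or err_prev < best[0]:
            best = (err_prev, S, P, r, n_iter, history)

    err, S, P, restart, n_iter, history = best
    S, P, _ = _canonicalize(S, P)
    fit = {
        "frobenius_error": err,
        "iterations": n_iter,
        "restart_index": restart,
        "seed": seed,
        "n_restarts": len(candidates),
        "tol": tol,
    }
    if track_error:
        fit["error_history"] = history
    return MotorModuleSet(weightings=S, activations=P, n_modules=n_modules, fit=fit)


def vaf(X, Xr, centered: bool = False) -> VafResult:
    """Variance accounted for: ``1 - SSE/SST``.

    SST is uncentered (sum of squares of X) unless ``centered`` is set.
    Per-muscle VAFs use row-wise sums; rows with zero SST yield NaN.
    """
    Xa = np.asarray(X.values if isinstance(X, EnvelopeMatrix) else X, dtype=float)
    Xr = np.asarray(Xr.values if isinstance(Xr, EnvelopeMatrix) else Xr, dtype=float)
    if Xa.shape != Xr.shape:
        raise ValueError("X and reconstruction must have the same shape")
    resid = Xa - Xr
    ref = Xa - Xa.mean(axis=1, keepdims=True) if centered else Xa
    sse = float(np.sum(resid**2))
    sst = float(np.sum(ref**2))
    if sst == 0:
        raise ValueError("SST is zero; VAF undefined")
    row_sse = np.sum(resid**2, axis=1)
    row_sst = np.sum(ref**2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_muscle = np.where(row_sst > 0, 1.0 - row_sse / row_sst, np.nan)
    return VafResult(
        global_vaf=1.0 - sse / sst, per_muscle_vaf=per_muscle, sse=sse, sst=sst
    )


@dataclass(frozen=True)
class VafCurve:
    """Reconstruction quality as a function of the number of modules."""

    n_values: tuple[int, ...]
    vaf_values: tuple[float, ...]
    module_sets: tuple[MotorModuleSet, ...] = ()

    def __post_init__(self) -> None:
        if len(self.n_values) != len(self.vaf_values):
            raise ValueError("n_values and vaf_values must match")
        object.__setattr__(self, "n_values", tuple(self.n_values))
        object.__setattr__(self, "vaf_values", tuple(float(v) for v in self.vaf_values))


def vaf_curve(
    X,
    n_range: Sequence[int],
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 1000,
    tol: float = 1e-6,
    keep_fits: bool = False,
) -> VafCurve:
    """One best-of-restarts fit per module count.

    In addition to its random restarts, each fit at N > min(n_range) warm
    starts from the previous fit augmented with one random module, which
    makes the curve non-decreasing by construction (the multiplicative
    updates never increase the error of that candidate).
    """
    n_range = [int(n) for n in n_range]
    if n_range != sorted(n_range) or len(set(n_range)) != len(n_range):
        raise ValueError("n_range must be strictly increasing")
    Xa = _as_array(X)
    master = np.random.default_rng(seed)
    prev: MotorModuleSet | None = None
    vals, fits = [], []
    for n in n_range:
        sub_seed = int(master.integers(2**31))
        init = None
        if prev is not None and n == prev.n_modules + 1:
            rng = np.random.default_rng(sub_seed ^ 0x5EED)
            scale = float(np.sqrt(Xa.mean() / n)) or 1.0
            S0 = np.hstack([prev.weightings, random_init((Xa.shape[0], 1), scale, rng)])
            P0 = np.vstack([prev.activations, random_init((1, Xa.shape[1]), scale, rng)])
            init = (S0, P0)
        fit = nmf(
            Xa, n, seed=sub_seed, n_restarts=n_restarts, max_iter=max_iter, tol=tol,
            init=init,
        )
        vals.append(vaf(Xa, fit.reconstruction).global_vaf)
        fits.append(fit)
        prev = fit
    return VafCurve(
        n_values=tuple(n_range),
        vaf_values=tuple(vals),
        module_sets=tuple(fits) if keep_fits else (),
    )


def select_dimensionality(
    curve: VafCurve, floor: float = 0.80, gain_eps: float = 3.0
) -> int:
    """Smallest module count meeting the quality floor at a flattened slope.

    Returns the smallest N with ``VAF(N) >= floor`` whose marginal gain to
    N+1 is below ``gain_eps`` percentage points (the slope-change proxy).
    If every floor-satisfying N still gains at least ``gain_eps``, the
    smallest N above the floor is returned with a warning.  A curve that
    never reaches the floor raises ``ValueError``.
    """
    ns, vs = curve.n_values, curve.vaf_values
    if not ns:
        raise ValueError("empty VAF curve")
    above = [i for i, v in enumerate(vs) if v >= floor]
    if not above:
        raise ValueError(
            f"VAF never reaches the {floor:.0%} floor (max {max(vs):.3f}); "
            "insufficient dimensionality range or data quality"
        )
    for i in above:
        if i + 1 < len(vs) and vs[i + 1] - vs[i] < gain_eps / 100.0:
            return ns[i]
        if i + 1 == len(vs) and i > 0 and vs[i] - vs[i - 1] < gain_eps / 100.0:
            # last point: slope already flat coming in
            return ns[i]
    warnings.warn(
        "no module count combines the VAF floor with a flattened slope; "
        "returning the smallest count above the floor",
        stacklevel=2,
    )
    return ns[above[0]]


def concatenate_trials(trials: Sequence[EnvelopeMatrix]) -> EnvelopeMatrix:
    """Horizontal concatenation of trials (M x sum(K)); per-trial boundaries
    are recorded in ``meta['boundaries']``."""
    if not trials:
        raise ValueError("no trials to concatenate")
    labels = trials[0].labels
    for t in trials:
        if t.labels != labels:
            raise ValueError("trials must share muscle ordering")
    values = np.hstack([t.values for t in trials])
    bounds, pos = [], 0
    for t in trials:
        bounds.append((pos, pos + t.n_points))
        pos += t.n_points
    return EnvelopeMatrix(
        values=values,
        labels=labels,
        meta={"boundaries": bounds, "n_trials": len(trials)},
    )
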