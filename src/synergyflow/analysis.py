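"""Cross-condition and cross-subject motor-module comparison.

Module sets are compared with the normalized scalar product (cosine
similarity) between matched factor columns/rows; a pair is considered
"similar" when r > 0.80.  Matching between two sets uses an optimal
one-to-one assignment maximizing total similarity (greedy matching is
available for comparison).  The fixed-factor cross-reconstruction fits one
factor of the model X ~= S @ P while holding the other fixed — e.g.
reconstructing perturbed EMG from fixed unperturbed weightings — by running
the multiplicative update of the free factor for a fixed number of
iterations (1000 by default).
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass, field
from typing import Sequence

from scipy.optimize import linear_sum_assignment

from .factorization import (
    MotorModuleSet,
    VafResult,
    multiplicative_update,
    random_init,
    vaf,
)
from .preprocess import EnvelopeMatrix

__all__ = [
    "SimilarityReport",
    "CrossReconstruction",
    "normalized_scalar_product",
    "similarity_matrix",
    "match_modules",
    "group_similarity",
    "fixed_factor_fit",
    "random_factor",
    "peak_timing",
]

SIMILARITY_THRESHOLD = 0.80


@dataclass(frozen=True)
class SimilarityReport:
    """Matched-pair similarities between module sets.

    ``pair_similarities`` is reported in the first set's module order for a
    two-set comparison; for a group comparison it pools all pairwise matched
    similarities per module index.  ``threshold_flags`` marks pairs
    exceeding the r > 0.80 similarity criterion.
    """

    pair_similarities: np.ndarray
    matching: tuple[int, ...]
    median: np.ndarray
    p25: np.ndarray
    p75: np.ndarray
    threshold_flags: np.ndarray
    threshold: float = SIMILARITY_THRESHOLD

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "pair_similarities", np.asarray(self.pair_similarities, dtype=float)
        )


@dataclass(frozen=True)
class CrossReconstruction:
    """Result of a fixed-factor reconstruction."""

    fixed_factor: str  # 'weightings' | 'activations'
    fixed_source: str  # provenance label, e.g. 'UPT', 'PTB', 'random'
    free_factor_estimate: np.ndarray
    vaf: VafResult
    iterations: int
    seed: int


def normalized_scalar_product(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity ``u.v / (|u||v|)``; errors on zero vectors."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("similarity undefined for zero vectors")
    return float(u @ v / (nu * nv))


def _factor_vectors(mset: MotorModuleSet, on: str) -> np.ndarray:
    """Module vectors as columns: weighting columns or activation rows."""
    if on == "weightings":
        return mset.weightings
    if on == "activations":
        return mset.activations.T
    raise ValueError("on must be 'weightings' or 'activations'")


def similarity_matrix(A: MotorModuleSet, B: MotorModuleSet, on: str = "weightings") -> np.ndarray:
    """All-pairs normalized scalar products between two sets' modules."""
    Va, Vb = _factor_vectors(A, on), _factor_vectors(B, on)
    if Va.shape[0] != Vb.shape[0]:
        raise ValueError("module vectors have incompatible length")
    sims = np.empty((Va.shape[1], Vb.shape[1]))
    for i in range(Va.shape[1]):
        for j in range(Vb.shape[1]):
            sims[i, j] = normalized_scalar_product(Va[:, i], Vb[:, j])
    return sims


def match_modules(
    A: MotorModuleSet,
    B: MotorModuleSet,
    on: str = "weightings",
    method: str = "assignment",
) -> SimilarityReport:
    """Match B's modules one-to-one onto A's and report pair similarities.

    ``method='assignment'`` (default) maximizes the total similarity by
    linear-sum assignment; ``'greedy'`` repeatedly takes the best remaining
    pair.  Both sets must have the same number of modules.
    """
    if A.n_modules != B.n_modules:
        raise ValueError("module sets must have equal dimensionality")
    sims = similarity_matrix(A, B, on)
    n = A.n_modules
    if method == "assignment":
        rows, cols = linear_sum_assignment(sims, maximize=True)
        matching = np.empty(n, dtype=int)
        matching[rows] = cols
    elif method == "greedy":
        matching = np.full(n, -1)
        work = sims.copy()
        for _ in range(n):
            i, j = np.unravel_index(np.argmax(work), work.shape)
            matching[i] = j
            work[i, :] = -np.inf
            work[:, j] = -np.inf
    else:
        raise ValueError("method must be 'assignment' or 'greedy'")
    pair = sims[np.arange(n), matching]
    return SimilarityReport(
        pair_similarities=pair,
        matching=tuple(int(j) for j in matching),
        median=np.median(pair, keepdims=True),
        p25=np.percentile(pair, 25, keepdims=True),
        p75=np.percentile(pair, 75, keepdims=True),
        threshold_flags=pair > SIMILARITY_THRESHOLD,
    )


def group_similarity(
    sets: Sequence[MotorModuleSet], on: str = "weightings"
) -> SimilarityReport:
    """All-pairs matched similarities across a group of module sets.

    Every unordered pair is matched; similarities are pooled per module
    index (in the first set of each pair's order) and summarized by median
    and quartiles per module.
    """
    if len(sets) < 2:
        raise ValueError("need at least two module sets")
    n = sets[0].n_modules
    if any(s.n_modules != n for s in sets):
        raise ValueError("module sets must share dimensionality")
    pooled = [[] for _ in range(n)]
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            rep = match_modules(sets[i], sets[j], on=on)
            for k, s in enumerate(rep.pair_similarities):
                pooled[k].append(s)
    pooled_arr = np.asarray(pooled)  # (n, n_pairs)
    flat = pooled_arr.ravel()
    return SimilarityReport(
        pair_similarities=pooled_arr,
        matching=tuple(range(n)),
        median=np.median(pooled_arr, axis=1),
        p25=np.percentile(pooled_arr, 25, axis=1),
        p75=np.percentile(pooled_arr, 75, axis=1),
        threshold_flags=pooled_arr > SIMILARITY_THRESHOLD,
    )


def random_factor(
    shape: tuple[int, int], seed: int, scale: float = 1.0
) -> np.ndarray:
    """Uniform (0, 1] random matrix — the free-to-vary baseline factor."""
    rng = np.random.default_rng(seed)
    return random_init(shape, scale, rng)


def fixed_factor_fit(
    X,
    fixed: np.ndarray,
    which: str = "weightings",
    iterations: int = 1000,
    seed: int = 0,
    fixed_source: str = "UPT",
) -> CrossReconstruction:
    """Fit the free factor of X ~= S @ P with the other factor held fixed.

    With ``which='weightings'`` the supplied matrix is S (M x N) and the
    activations are estimated; with ``which='activations'`` it is P (N x K)
    and the weightings are estimated.  The free factor starts from a seeded
    uniform random draw and receives exactly ``iterations`` multiplicative
    updates; the fixed factor is never modified.  ``iterations=0`` reports
    the VAF of the random initialization (null reference).
    """
    Xa = np.asarray(X.values if isinstance(X, EnvelopeMatrix) else X, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if np.any(fixed < 0):
        raise ValueError("fixed factor must be non-negative")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    M, K = Xa.shape
    if which == "weightings":
        if fixed.shape[0] != M:
            raise ValueError(f"fixed weightings must have {M} rows")
        n = fixed.shape[1]
        free_shape, update = (n, K), "activations"
    elif which == "activations":
        if fixed.shape[1] != K:
            raise ValueError(f"fixed activations must have {K} columns")
        n = fixed.shape[0]
        free_shape, update = (M, n), "weightings"
    else:
        raise ValueError("which must be 'weightings' or 'activations'")

    rng = np.random.default_rng(seed)
    scale = float(np.sqrt(Xa.mean() / n)) or 1.0
    free = random_init(free_shape, scale, rng)
    fixed_before = fixed.copy()
    for _ in range(iterations):
        if which == "weightings":
            _, free = multiplicative_update(Xa, fixed, free, update=update)
        else:
            free, _ = multiplicative_update(Xa, free, fixed, update=update)
    assert np.array_equal(fixed, fixed_before), "fixed factor was modified"
    Xr = fixed @ free if which == "weightings" else free @ fixed
    return CrossReconstruction(
        fixed_factor=which,
        fixed_source=fixed_source,
        free_factor_estimate=free,
        vaf=vaf(Xa, Xr),
        iterations=iterations,
        seed=seed,
    )


def cycle_average(P: np.ndarray, n_points: int) -> np.ndarray:
    """Average concatenated-trial activation signals back onto one cycle.

    A fit to a concatenation of trials yields activations of length
    ``n_trials * n_points``; this folds them to an (N, n_points) per-cycle
    mean so activation signals from fits with different trial counts can be
    compared on the shared normalized cycle.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if P.shape[1] % n_points:
        raise ValueError("activation length is not a whole number of cycles")
    return P.reshape(P.shape[0], -1, n_points).mean(axis=1)


def peak_timing(P: np.ndarray, flag_ties: bool = True) -> np.ndarray:
    """Activation-signal peak times as percent of the cycle.

    Row-wise argmax converted to ``100 * index / (K - 1)``.  Constant rows
    are a timing tie; the earliest index is returned and a warning emitted.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    K = P.shape[1]
    if K < 2:
        raise ValueError("need at least two time points")
    if flag_ties:
        constant = np.all(P == P[:, :1], axis=1)
        if np.any(constant):
            import warnings

            warnings.warn(
                f"constant activation row(s) {np.flatnonzero(constant).tolist()}: "
                "peak timing is a tie, earliest index used",
                stacklevel=2,
            )
    return 100.0 * np.argmax(P, axis=1) / (K - 1)
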