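"""Tie-aware pair counting and the rank metrics built on it.

Continuous-estimate tasks such as tumor-cellularity (TC) scoring are evaluated
by comparing how an algorithm *ranks* items against how a reference rater
ranks them.  Every metric in this module is a function of the five tallies
over the n(n-1)/2 unordered item pairs:

    C   concordant pairs (both orderings strictly agree)
    D   discordant pairs (both orderings strictly disagree)
    TA  pairs tied in the algorithm scores only
    TR  pairs tied in the reference scores only
    TB  pairs tied in both

From these:

    PK     = (C + TA/2) / (C + D + TA)
    tau-b  = (C - D) / sqrt((C + D + TA) * (C + D + TR))

PK is the probability that the algorithm orders a randomly chosen
reference-distinguished pair the same way as the reference, with half credit
for algorithm ties; it generalizes the trapezoidal ROC AUC to continuous
references.  Unlike tau-b it ignores reference ties entirely, which removes
the incentive to inflate TA by binning continuous outputs (see
:mod:`cellscore.synthetic` for the simulation demonstrating that exploit).

Pairs tied in both vectors (TB) are excluded from TA and TR.  With this
convention tau-b here is algebraically identical to the textbook
tie-corrected Kendall tau-b, and a constant submission scores PK = 0.5
exactly, as concordance semantics require.  Tie detection is exact
floating-point equality — scores arrive as decimal text, and an epsilon
would itself be a gaming surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ._errors import (
    InputValidationError,
    LengthMismatchError,
    NonFiniteError,
    TooFewItemsError,
    UndefinedMetricError,
)

__all__ = [
    "PairCounts",
    "count_pairs",
    "pk_from_counts",
    "tau_b_from_counts",
    "prediction_probability",
    "kendall_tau_b",
    "trapezoidal_auc",
    "average_metric_over_raters",
]

try:  # compiled Fenwick scan; the pure-Python loop below is the fallback
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a standard install here
    _njit = None

# Below this length the O(n^2) vectorized comparison is cheaper than the
# O(n log n) Fenwick-tree scan used for everything larger.
_DENSE_LIMIT = 64


@dataclass(frozen=True)
class PairCounts:
    """Tallies of the five mutually exclusive pair categories.

    Invariant: C + D + TA + TR + TB == n_items*(n_items-1)/2.
    """

    n_items: int
    C: int
    D: int
    TA: int
    TR: int
    TB: int

    def __post_init__(self) -> None:
        for name in ("n_items", "C", "D", "TA", "TR", "TB"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise InputValidationError(
                    f"PairCounts.{name} must be a non-negative integer, got {v!r}"
                )
        if self.C + self.D + self.TA + self.TR + self.TB != self.n_pairs:
            raise InputValidationError(
                "pair tallies do not sum to n_items*(n_items-1)/2"
            )

    @property
    def n_pairs(self) -> int:
        return self.n_items * (self.n_items - 1) // 2


def _paired_vectors(
    ref_scores: Sequence[float], alg_scores: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref_scores, dtype=float)
    alg = np.asarray(alg_scores, dtype=float)
    if ref.ndim != 1 or alg.ndim != 1:
        raise InputValidationError("score inputs must be one-dimensional vectors")
    if ref.shape[0] != alg.shape[0]:
        raise LengthMismatchError(
            f"paired vectors differ in length: {ref.shape[0]} vs {alg.shape[0]}"
        )
    if ref.shape[0] < 2:
        raise TooFewItemsError("need at least 2 items to form a pair")
    if not (np.isfinite(ref).all() and np.isfinite(alg).all()):
        raise NonFiniteError("scores must be finite (no NaN/inf)")
    return ref, alg


def _tie_pair_count(values: np.ndarray) -> int:
    """Number of unordered pairs tied in `values` (includes joint ties)."""
    _, counts = np.unique(values, return_counts=True)
    return int((counts * (counts - 1) // 2).sum())


def _count_dense(ref: np.ndarray, alg: np.ndarray) -> tuple[int, int, int, int, int]:
    i, j = np.triu_indices(ref.shape[0], k=1)
    dr = np.sign(ref[j] - ref[i])
    da = np.sign(alg[j] - alg[i])
    prod = dr * da
    C = int(np.count_nonzero(prod > 0))
    D = int(np.count_nonzero(prod < 0))
    ref_tied = dr == 0
    alg_tied = da == 0
    TB = int(np.count_nonzero(ref_tied & alg_tied))
    TA = int(np.count_nonzero(alg_tied & ~ref_tied))
    TR = int(np.count_nonzero(ref_tied & ~alg_tied))
    return C, D, TA, TR, TB


def _pair_scan_py(ref_codes: np.ndarray, alg_ranks: np.ndarray, n_levels: int):
    """Fenwick scan over items sorted by (ref, alg): returns (C, D, TA).

    Items are inserted reference-group by reference-group, so everything
    already in the tree has a strictly smaller reference score; comparing
    algorithm ranks against the tree classifies each cross-group pair.
    """
    n = ref_codes.shape[0]
    tree = [0] * (n_levels + 1)
    C = D = TA = 0
    inserted = 0
    i = 0
    while i < n:
        j = i
        while j < n and ref_codes[j] == ref_codes[i]:
            j += 1
        for t in range(i, j):
            r = int(alg_ranks[t])
            below = 0
            ii = r
            while ii > 0:
                below += tree[ii]
                ii -= ii & -ii
            at_or_below = 0
            ii = r + 1
            while ii > 0:
                at_or_below += tree[ii]
                ii -= ii & -ii
            C += below
            TA += at_or_below - below
            D += inserted - at_or_below
        for t in range(i, j):
            ii = int(alg_ranks[t]) + 1
            while ii <= n_levels:
                tree[ii] += 1
                ii += ii & -ii
        inserted += j - i
        i = j
    return C, D, TA


if _njit is not None:
    _pair_scan = _njit(cache=False)(_pair_scan_py)
else:  # pragma: no cover
    _pair_scan = _pair_scan_py


def _tie_pairs_from_codes(codes: np.ndarray) -> int:
    _, counts = np.unique(codes, return_counts=True)
    return int((counts * (counts - 1) // 2).sum())


def _count_fenwick(ref: np.ndarray, alg: np.ndarray) -> tuple[int, int, int, int, int]:
    order = np.lexsort((alg, ref))
    ref_levels, ref_codes = np.unique(ref, return_inverse=True)
    alg_levels, alg_codes = np.unique(alg, return_inverse=True)
    ref_codes = ref_codes.astype(np.int64)
    alg_codes = alg_codes.astype(np.int64)
    C, D, TA = _pair_scan(ref_codes[order], alg_codes[order], alg_levels.shape[0])
    joint = ref_codes * alg_levels.shape[0] + alg_codes
    TB = _tie_pairs_from_codes(joint)
    TR = _tie_pairs_from_codes(ref_codes) - TB
    return int(C), int(D), int(TA), TR, TB


def count_pairs(
    ref_scores: Sequence[float], alg_scores: Sequence[float]
) -> PairCounts:
    """Classify every unordered item pair as C, D, TA, TR or TB.

    Uses an exact O(n^2) vectorized comparison for moderate n and an
    O(n log n) Fenwick-tree scan beyond ``_DENSE_LIMIT``; both return counts
    identical to exhaustive enumeration.  Permutation-invariant in item order.

    Raises
    ------
    LengthMismatchError, TooFewItemsError, NonFiniteError
        On malformed input, each distinctly.
    """
    ref, alg = _paired_vectors(ref_scores, alg_scores)
    if ref.shape[0] <= _DENSE_LIMIT:
        C, D, TA, TR, TB = _count_dense(ref, alg)
    else:
        C, D, TA, TR, TB = _count_fenwick(ref, alg)
    return PairCounts(n_items=int(ref.shape[0]), C=C, D=D, TA=TA, TR=TR, TB=TB)


def pk_from_counts(counts: PairCounts) -> float:
    """Prediction probability PK = (C + TA/2) / (C + D + TA).

    Conditions on reference-distinguished pairs only; TR and TB never enter.
    Raises :class:`UndefinedMetricError` when the reference distinguishes no
    pair (C + D + TA == 0, e.g. a constant reference).
    """
    denom = counts.C + counts.D + counts.TA
    if denom == 0:
        raise UndefinedMetricError(
            "PK undefined: the reference distinguishes no pair (C+D+TA == 0)"
        )
    return (counts.C + 0.5 * counts.TA) / denom


def tau_b_from_counts(counts: PairCounts) -> float:
    """Kendall tau-b = (C - D) / sqrt((C + D + TA) * (C + D + TR)).

    With the tied-in-one-side-only convention for TA and TR this equals the
    standard tie-corrected tau-b.  Raises :class:`UndefinedMetricError` when
    either factor of the denominator is zero.
    """
    da = counts.C + counts.D + counts.TA
    dr = counts.C + counts.D + counts.TR
    if da == 0 or dr == 0:
        raise UndefinedMetricError(
            "tau-b undefined: a tie-corrected denominator factor is zero"
        )
    return (counts.C - counts.D) / math.sqrt(da * dr)


def prediction_probability(
    ref_scores: Sequence[float], alg_scores: Sequence[float]
) -> float:
    """PK of `alg_scores` against `ref_scores` (counts + formula)."""
    return pk_from_counts(count_pairs(ref_scores, alg_scores))


def kendall_tau_b(
    ref_scores: Sequence[float], alg_scores: Sequence[float]
) -> float:
    """Kendall tau-b of `alg_scores` against `ref_scores`."""
    return tau_b_from_counts(count_pairs(ref_scores, alg_scores))


def trapezoidal_auc(
    binary_ref: Sequence[float], alg_scores: Sequence[float]
) -> float:
    """Rank-based (Mann-Whitney) AUC with half credit for ties.

    The reference must contain only 0s and 1s with both classes present;
    equals :func:`prediction_probability` on any binary reference.
    """
    ref, alg = _paired_vectors(binary_ref, alg_scores)
    if not np.isin(ref, (0.0, 1.0)).all():
        raise InputValidationError("binary_ref must contain only 0 and 1")
    n_pos = int(np.count_nonzero(ref == 1.0))
    n_neg = ref.shape[0] - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: reference has a single class")
    ranks = stats.rankdata(alg)
    rank_sum_pos = float(ranks[ref == 1.0].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def average_metric_over_raters(per_rater_values: Sequence[float]) -> float:
    """Arithmetic mean of per-rater metric values.

    The challenge-style summary score: compute the metric against each
    reference rater separately, then average.
    """
    vals = np.asarray(list(per_rater_values), dtype=float)
    if vals.size == 0:
        raise InputValidationError("need at least one per-rater value to average")
    if not np.isfinite(vals).all():
        raise NonFiniteError("per-rater metric values must be finite")
    return float(vals.mean())
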