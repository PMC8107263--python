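"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use the dumbest possible algorithms —
exhaustive pair enumeration and explicit sum-of-squares loops — so they
share no code path with the implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from cellscore import ReferenceSet, Submission


def brute_pair_counts(ref, alg) -> tuple[int, int, int, int, int]:
    """(C, D, TA, TR, TB) by exhaustive O(n^2) enumeration."""
    n = len(ref)
    C = D = TA = TR = TB = 0
    for i in range(n):
        for j in range(i + 1, n):
            dr = ref[i] - ref[j]
            da = alg[i] - alg[j]
            if dr == 0 and da == 0:
                TB += 1
            elif dr == 0:
                TR += 1
            elif da == 0:
                TA += 1
            elif (dr > 0) == (da > 0):
                C += 1
            else:
                D += 1
    return C, D, TA, TR, TB


def brute_anova(values) -> tuple[float, float, float]:
    """(ms_rows, ms_cols, ms_err) by explicit loops over the two-way layout."""
    x = np.asarray(values, dtype=float)
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    ss_rows = 0.0
    for i in range(n):
        row_mean = sum(x[i]) / k
        ss_rows += k * (row_mean - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        col_mean = sum(x[i][j] for i in range(n)) / n
        ss_cols += n * (col_mean - grand) ** 2
    ss_tot = sum((x[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def random_tied_vectors(rng, n_max=200):
    """A random paired instance with a heavy chance of duplicated values."""
    n = int(rng.integers(2, n_max + 1))
    kind = rng.integers(0, 3)
    if kind == 0:  # continuous, essentially tie-free
        ref = rng.random(n)
        alg = rng.random(n)
    elif kind == 1:  # coarse grids on both sides -> many ties of all kinds
        ref = rng.integers(0, 5, n) / 4.0
        alg = rng.integers(0, 4, n) / 3.0
    else:  # gridded reference, mixed algorithm
        ref = rng.integers(0, 11, n) / 10.0
        alg = np.where(rng.random(n) < 0.5, rng.integers(0, 3, n) / 2.0, rng.random(n))
    return ref, alg


def toy_reference() -> ReferenceSet:
    """A small deterministic two-rater reference: 12 patches, 4 patients."""
    rng = np.random.default_rng(42)
    n = 12
    r1 = np.round(rng.random(n) * 20) / 20
    r2 = np.clip(np.round((r1 + rng.normal(0, 0.1, n)) * 20) / 20, 0, 1)
    return ReferenceSet.validated(
        patch_ids=[f"p{i:02d}" for i in range(n)],
        slide_ids=[f"c{i // 3}_s0" for i in range(n)],
        case_ids=[f"c{i // 3}" for i in range(n)],
        scores={"path1": r1, "path2": r2},
    )


def submission_from(ref: ReferenceSet, values, entry_id="sub", team="team") -> Submission:
    return Submission(
        team=team,
        entry_id=entry_id,
        scores=dict(zip(map(str, ref.patch_ids), np.asarray(values, float).tolist())),
    )


@pytest.fixture
def small_ref() -> ReferenceSet:
    return toy_reference()
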