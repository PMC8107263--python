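"""Calibration-sensitive agreement: ICC(2,1).

Rank metrics (PK, tau-b) ignore calibration: an algorithm whose scores are a
strictly increasing distortion of a rater's scores gets a perfect PK.  The
two-way random-effects, absolute-agreement, single-rater intraclass
correlation — ICC(2,1) in the Shrout–Fleiss convention — penalizes exactly
such systematic offsets, which is why it complements PK when mean squared
error is the quantity practitioners optimize.

The underlying model is the two-way ANOVA with one observation per cell
(subjects x raters, both random):

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

with MSR the between-subject, MSC the between-rater and MSE the residual
mean square, n subjects and k raters.  Negative values are returned as
computed, not clipped: slight negative ICCs are a legitimate outcome for
near-zero agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._errors import InputValidationError, UndefinedMetricError

__all__ = ["RatingMatrix", "AnovaDecomposition", "anova_mean_squares", "icc_2_1"]


@dataclass(frozen=True)
class RatingMatrix:
    """Complete n_subjects x k_raters grid of scores, no missing cells.

    Rows may repeat (a bootstrap replicate legitimately contains the same
    subject twice); cells may not be NaN — imputation would silently change
    the mean squares, so incomplete grids are rejected.
    """

    values: np.ndarray
    subject_ids: tuple | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise InputValidationError("rating matrix must be 2-dimensional")
        n, k = values.shape
        if n < 2 or k < 2:
            raise InputValidationError(
                f"rating matrix needs >= 2 subjects and >= 2 raters, got {n}x{k}"
            )
        if not np.isfinite(values).all():
            raise InputValidationError(
                "rating matrix has missing or non-finite cells; complete grids only"
            )
        if self.subject_ids is not None and len(self.subject_ids) != n:
            raise InputValidationError("subject_ids length does not match rows")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def k_raters(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AnovaDecomposition:
    """Mean squares of the two-way, one-observation-per-cell layout."""

    ms_rows: float
    ms_cols: float
    ms_err: float
    n: int
    k: int


def anova_mean_squares(m: RatingMatrix) -> AnovaDecomposition:
    """Row (subject), column (rater) and residual mean squares.

    SS_total = SS_rows + SS_cols + SS_err by construction; the residual sum
    of squares is computed cell-wise rather than by subtraction so it cannot
    go negative through cancellation.
    """
    x = m.values
    n, k = x.shape
    # center first: a constant matrix then yields exact zeros everywhere
    xc = x - x.mean()
    grand = xc.mean()
    row_means = xc.mean(axis=1)
    col_means = xc.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    resid = xc - row_means[:, None] - col_means[None, :] + grand
    ss_err = float((resid**2).sum())
    return AnovaDecomposition(
        ms_rows=ss_rows / (n - 1),
        ms_cols=ss_cols / (k - 1),
        ms_err=ss_err / ((n - 1) * (k - 1)),
        n=n,
        k=k,
    )


def icc_2_1(m: RatingMatrix | Sequence[Sequence[float]]) -> float:
    """Two-way random-effects, absolute-agreement, single-rater ICC.

    Accepts a :class:`RatingMatrix` or anything coercible to one.  Raises
    :class:`UndefinedMetricError` when the denominator vanishes (e.g. every
    cell identical), which is distinct from shape/validation errors.
    """
    if not isinstance(m, RatingMatrix):
        m = RatingMatrix(np.asarray(m, dtype=float))
    a = anova_mean_squares(m)
    denom = a.ms_rows + (a.k - 1) * a.ms_err + a.k * (a.ms_cols - a.ms_err) / a.n
    # treat rounding residue of a degenerate grid as zero
    scale = max(1.0, abs(a.ms_rows), abs(a.ms_cols), abs(a.ms_err))
    if abs(denom) <= 1e-12 * scale:
        raise UndefinedMetricError(
            "ICC(2,1) undefined: zero denominator (no variance to apportion)"
        )
    return (a.ms_rows - a.ms_err) / denom
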