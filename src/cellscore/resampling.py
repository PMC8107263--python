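"""Patient-clustered bootstrap CIs and paired algorithm comparison.

Patches cut from one patient's slides are correlated, so a patch-level
bootstrap would understate uncertainty.  Resampling therefore draws whole
patients (clusters) with replacement — a patient drawn twice contributes all
of its patches twice — and recomputes the metric on each replicate; the
confidence interval is the percentile interval of the replicate
distribution.  The point estimate always comes from the full, unresampled
data.

Replicate r uses the RNG stream seeded by ``SeedSequence([seed, r])``, so the
replicate vector is a pure function of (inputs, seed) and independent of
evaluation order.  Replicates on which the metric is undefined (for example
a resample whose reference scores are constant) are dropped and tallied in
``n_dropped`` with a warning rather than aborting the run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping

import numpy as np

from ._errors import InputValidationError, UndefinedMetricError

__all__ = [
    "MetricResult",
    "DifferenceResult",
    "cluster_bootstrap",
    "paired_difference",
    "child_seed",
]

MetricFn = Callable[[Any, Any], float]


def child_seed(root: int, *key: int) -> int:
    """Deterministically derive an independent 31-bit seed from a root seed."""
    ss = np.random.SeedSequence([int(root), *(int(k) for k in key)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class MetricResult:
    """A point estimate with its percentile-bootstrap CI and provenance."""

    value: float
    ci_low: float
    ci_high: float
    level: float
    n_boot: int
    n_dropped: int
    seed: int
    per_rater: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise InputValidationError("ci_low must not exceed ci_high")
        if self.n_dropped > self.n_boot:
            raise InputValidationError("n_dropped cannot exceed n_boot")


@dataclass(frozen=True)
class DifferenceResult:
    """Bootstrap comparison of two algorithms on the same reference.

    ``delta`` is metric(A) - metric(B); ``significant`` holds exactly when
    the CI at level 1 - alpha excludes zero.
    """

    delta: float
    ci_low: float
    ci_high: float
    significant: bool
    alpha: float
    n_boot: int
    seed: int


def _cluster_index_lists(ref: Any) -> list[np.ndarray]:
    case_ids = np.asarray(ref.case_ids)
    if case_ids.size == 0:
        raise InputValidationError("reference has no patches")
    if any(c is None or str(c) == "" for c in case_ids):
        raise InputValidationError("every patch must carry a non-empty cluster id")
    clusters = np.unique(case_ids)
    return [np.flatnonzero(case_ids == c) for c in clusters]


def _replicate_indices(
    clusters: list[np.ndarray], seed: int, r: int
) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(r)]))
    pick = rng.integers(0, len(clusters), size=len(clusters))
    return np.concatenate([clusters[c] for c in pick])


def cluster_bootstrap(
    metric: MetricFn,
    ref: Any,
    sub: Any = None,
    *,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    per_rater: Mapping[str, float] | None = None,
) -> MetricResult:
    """Percentile CI of ``metric(ref, sub)`` under patient resampling.

    ``metric`` is any evaluator over (reference, submission); ``sub`` is
    passed through untouched and may be None for reference-only metrics
    such as interrater concordance.  A replicate raising
    :class:`UndefinedMetricError` is dropped; if every replicate is
    undefined the error propagates.
    """
    if n_boot < 1:
        raise InputValidationError("n_boot must be >= 1")
    if not 0.0 < level < 1.0:
        raise InputValidationError("level must be in (0, 1)")
    point = float(metric(ref, sub))
    clusters = _cluster_index_lists(ref)
    values: list[float] = []
    dropped = 0
    for r in range(n_boot):
        idx = _replicate_indices(clusters, seed, r)
        try:
            values.append(float(metric(ref.take(idx), sub)))
        except UndefinedMetricError:
            dropped += 1
    if not values:
        raise UndefinedMetricError(
            "metric undefined on every bootstrap replicate"
        )
    if dropped:
        warnings.warn(
            f"dropped {dropped}/{n_boot} bootstrap replicates with undefined metric",
            RuntimeWarning,
            stacklevel=2,
        )
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [tail, 1.0 - tail])
    return MetricResult(
        value=point,
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
        n_boot=n_boot,
        n_dropped=dropped,
        seed=int(seed),
        per_rater=dict(per_rater) if per_rater is not None else None,
    )


def paired_difference(
    metric: MetricFn,
    ref: Any,
    sub_a: Any,
    sub_b: Any,
    *,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> DifferenceResult:
    """Paired bootstrap test of metric(A) - metric(B).

    Each replicate applies the *same* resampled patient set to both
    submissions, so the difference distribution reflects only the
    algorithms' disagreement, not resampling noise.  Both submissions must
    cover the same patch set.
    """
    if n_boot < 1:
        raise InputValidationError("n_boot must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise InputValidationError("alpha must be in (0, 1)")
    scores_a = getattr(sub_a, "scores", None)
    scores_b = getattr(sub_b, "scores", None)
    if scores_a is not None and scores_b is not None:
        if set(scores_a) != set(scores_b):
            raise InputValidationError(
                "submissions cover different patch sets; paired comparison impossible"
            )
    delta_point = float(metric(ref, sub_a)) - float(metric(ref, sub_b))
    clusters = _cluster_index_lists(ref)
    deltas: list[float] = []
    dropped = 0
    for r in range(n_boot):
        idx = _replicate_indices(clusters, seed, r)
        rep = ref.take(idx)
        try:
            deltas.append(float(metric(rep, sub_a)) - float(metric(rep, sub_b)))
        except UndefinedMetricError:
            dropped += 1
    if not deltas:
        raise UndefinedMetricError("difference undefined on every replicate")
    if dropped:
        warnings.warn(
            f"dropped {dropped}/{n_boot} bootstrap replicates with undefined metric",
            RuntimeWarning,
            stacklevel=2,
        )
    lo, hi = np.quantile(deltas, [alpha / 2.0, 1.0 - alpha / 2.0])
    return DifferenceResult(
        delta=delta_point,
        ci_low=float(lo),
        ci_high=float(hi),
        significant=bool(lo > 0.0 or hi < 0.0),
        alpha=alpha,
        n_boot=n_boot,
        seed=int(seed),
    )
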