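"""Challenge-facing layer: files, validation, scoring, leaderboards.

A scoring run consumes one reference CSV (patches with patient/slide cluster
ids and one score column per pathologist) and any number of submission CSVs
(one TC score per patch).  Each submission is validated non-destructively,
scored against every rater (PK from :mod:`cellscore.metrics`, ICC(2,1) from
:mod:`cellscore.agreement`), rater-averaged, wrapped with patient-clustered
bootstrap CIs, ranked into a leaderboard, and optionally walked for the
significance frontier — for each entry, the first lower-ranked entry whose
PK difference is statistically significant.

All scores are fractions in [0, 1] internally; percentages exist only at the
I/O boundary (a rater column named ``path1:percent`` is divided by 100 on
read).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import InputValidationError, SubmissionFormatError
from .agreement import RatingMatrix, icc_2_1
from .metrics import average_metric_over_raters, prediction_probability
from .resampling import DifferenceResult, MetricResult, cluster_bootstrap, paired_difference

__all__ = [
    "ReferenceSet",
    "Submission",
    "ValidationReport",
    "ScoredSubmission",
    "LeaderboardRow",
    "PatchError",
    "parse_reference",
    "write_reference",
    "validate_submission",
    "load_submission",
    "score_submission",
    "build_leaderboard",
    "significance_frontier",
    "patch_mse",
    "interrater_avg_pk",
    "interrater_avg_icc",
    "leaderboard_records",
    "write_leaderboard",
]

_ID_COLUMNS = ("patch_id", "slide_id", "case_id")


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class ReferenceSet:
    """Reference standard: patches with cluster ids and per-rater TC scores.

    ``take(indices)`` returns an unvalidated view used by the bootstrap —
    such views intentionally contain duplicated patches, so uniqueness is
    enforced only at construction via :meth:`validated`.
    """

    patch_ids: np.ndarray
    slide_ids: np.ndarray
    case_ids: np.ndarray
    scores: Mapping[str, np.ndarray]
    rater_ids: tuple[str, ...]

    @property
    def n_patches(self) -> int:
        return int(self.patch_ids.shape[0])

    @classmethod
    def validated(
        cls,
        patch_ids: Sequence[str],
        slide_ids: Sequence[str],
        case_ids: Sequence[str],
        scores: Mapping[str, Sequence[float]],
    ) -> "ReferenceSet":
        patch_ids = np.asarray(patch_ids, dtype=object)
        slide_ids = np.asarray(slide_ids, dtype=object)
        case_ids = np.asarray(case_ids, dtype=object)
        n = patch_ids.shape[0]
        if n == 0:
            raise InputValidationError("reference has no patches")
        if slide_ids.shape[0] != n or case_ids.shape[0] != n:
            raise InputValidationError("id columns differ in length")
        seen: set[str] = set()
        for i, pid in enumerate(patch_ids):
            if pid in seen:
                raise InputValidationError(f"duplicate patch_id {pid!r} (row {i + 1})")
            seen.add(pid)
        if any(c is None or str(c) == "" or str(c) == "nan" for c in case_ids):
            raise InputValidationError("every patch needs a non-empty case_id")
        if not scores:
            raise InputValidationError("reference needs at least one rater column")
        clean: dict[str, np.ndarray] = {}
        for rater, vals in scores.items():
            arr = np.asarray(vals, dtype=float)
            if arr.shape[0] != n:
                raise InputValidationError(f"rater {rater!r} column length mismatch")
            if not np.isfinite(arr).all():
                bad = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise InputValidationError(
                    f"rater {rater!r} missing/non-finite score for patch "
                    f"{patch_ids[bad]!r}"
                )
            if (arr < 0).any() or (arr > 1).any():
                bad = int(np.flatnonzero((arr < 0) | (arr > 1))[0])
                raise InputValidationError(
                    f"rater {rater!r} score {arr[bad]} for patch {patch_ids[bad]!r} "
                    "outside [0, 1]"
                )
            clean[rater] = arr
        return cls(
            patch_ids=patch_ids,
            slide_ids=slide_ids,
            case_ids=case_ids,
            scores=clean,
            rater_ids=tuple(scores.keys()),
        )

    def take(self, indices: np.ndarray) -> "ReferenceSet":
        idx = np.asarray(indices)
        return ReferenceSet(
            patch_ids=self.patch_ids[idx],
            slide_ids=self.slide_ids[idx],
            case_ids=self.case_ids[idx],
            scores={r: v[idx] for r, v in self.scores.items()},
            rater_ids=self.rater_ids,
        )


@dataclass(frozen=True)
class Submission:
    """One algorithm's scores: patch_id -> TC fraction."""

    team: str
    entry_id: str
    scores: Mapping[str, float]

    def aligned_to(self, ref: ReferenceSet) -> np.ndarray:
        try:
            return np.array([self.scores[p] for p in ref.patch_ids], dtype=float)
        except KeyError as exc:
            raise SubmissionFormatError(
                f"submission {self.entry_id!r} has no score for patch {exc.args[0]!r}"
            ) from None


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of non-destructive submission validation."""

    missing_patches: tuple[str, ...]
    extra_patches: tuple[str, ...]
    malformed_rows: tuple[tuple[int, str], ...]
    out_of_range: tuple[str, ...]

    @property
    def valid(self) -> bool:
        return not (
            self.missing_patches
            or self.extra_patches
            or self.malformed_rows
            or self.out_of_range
        )

    def summary(self) -> str:
        if self.valid:
            return "valid"
        parts = []
        if self.malformed_rows:
            parts.append(f"{len(self.malformed_rows)} malformed rows")
        if self.missing_patches:
            parts.append(f"{len(self.missing_patches)} missing patches")
        if self.extra_patches:
            parts.append(f"{len(self.extra_patches)} unknown patches")
        if self.out_of_range:
            parts.append(f"{len(self.out_of_range)} out-of-range scores")
        return "invalid: " + ", ".join(parts)


@dataclass(frozen=True)
class ScoredSubmission:
    """One entry's rater-averaged PK and ICC with bootstrap CIs."""

    team: str
    entry_id: str
    avg_pk: MetricResult
    avg_icc: MetricResult


@dataclass(frozen=True)
class LeaderboardRow:
    rank: int
    team: str
    entry_id: str
    avg_pk: MetricResult
    avg_icc: MetricResult
    per_rater_pk: Mapping[str, float]


@dataclass(frozen=True)
class PatchError:
    """Per-patch difficulty: rater-averaged mean squared error across algorithms."""

    patch_id: str
    mse: float
    avg_score: float
    sd_score: float


# ---------------------------------------------------------------------------
# reference I/O


def _split_rater_column(name: str) -> tuple[str, float]:
    """Return (rater_id, divisor) from a header cell; ':percent' scales by 100."""
    if ":" in name:
        rater, unit = name.rsplit(":", 1)
        unit = unit.strip().lower()
        if unit == "percent":
            return rater.strip(), 100.0
        if unit == "fraction":
            return rater.strip(), 1.0
        raise InputValidationError(
            f"unknown unit {unit!r} in reference column {name!r} "
            "(expected 'fraction' or 'percent')"
        )
    return name.strip(), 1.0


def parse_reference(path: str | Path) -> ReferenceSet:
    """Load a reference CSV (patch_id, slide_id, case_id, one column per rater).

    Rater columns may declare their unit as a ``:fraction`` / ``:percent``
    suffix; bare names are fractions.  Percent columns are normalized to
    fractions on read.  Duplicate patch ids, missing cells and out-of-range
    scores raise :class:`InputValidationError`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={c: str for c in _ID_COLUMNS})
    for col in _ID_COLUMNS:
        if col not in df.columns:
            raise InputValidationError(f"reference file missing column {col!r}")
    rater_cols = [c for c in df.columns if c not in _ID_COLUMNS]
    if not rater_cols:
        raise InputValidationError("reference file has no rater score columns")
    dup = df["patch_id"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise InputValidationError(
            f"duplicate patch_id {df['patch_id'].iloc[row]!r} at line {row + 2}"
        )
    scores: dict[str, np.ndarray] = {}
    for col in rater_cols:
        rater, divisor = _split_rater_column(col)
        if rater in scores:
            raise InputValidationError(f"rater {rater!r} appears twice in the header")
        scores[rater] = pd.to_numeric(df[col], errors="coerce").to_numpy() / divisor
    return ReferenceSet.validated(
        patch_ids=df["patch_id"].to_numpy(dtype=object),
        slide_ids=df["slide_id"].fillna("").to_numpy(dtype=object),
        case_ids=df["case_id"].fillna("").to_numpy(dtype=object),
        scores=scores,
    )


def write_reference(ref: ReferenceSet, path: str | Path) -> None:
    """Write a reference CSV (fractions, bare rater column names)."""
    data = {
        "patch_id": ref.patch_ids,
        "slide_id": ref.slide_ids,
        "case_id": ref.case_ids,
    }
    for rater in ref.rater_ids:
        data[rater] = ref.scores[rater]
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# submission validation and loading


def _read_submission_rows(
    path: str | Path,
) -> tuple[dict[str, float], list[tuple[int, str]], list[str]]:
    """Parse a submission CSV leniently; never raises on content errors.

    Returns (scores, malformed_rows, out_of_range_patch_ids).  Out-of-range
    scores are reported but also kept out of the usable score map.
    """
    scores: dict[str, float] = {}
    malformed: list[tuple[int, str]] = []
    out_of_range: list[str] = []
    with open(path, "r", encoding="utf-8-sig", newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and row[0].strip() == ""):
                continue
            if lineno == 1:
                header = [c.strip().lower() for c in row]
                if header != ["patch_id", "score"]:
                    malformed.append(
                        (1, f"header must be 'patch_id,score', got {','.join(row)!r}")
                    )
                continue
            if len(row) != 2:
                malformed.append((lineno, f"expected 2 columns, got {len(row)}"))
                continue
            pid, raw = row[0].strip(), row[1].strip()
            if pid == "":
                malformed.append((lineno, "empty patch_id"))
                continue
            try:
                value = float(raw)
            except ValueError:
                malformed.append((lineno, f"score {raw!r} is not a number"))
                continue
            if not np.isfinite(value):
                malformed.append((lineno, f"score {raw!r} is not finite"))
                continue
            if pid in scores or pid in out_of_range:
                malformed.append((lineno, f"duplicate patch_id {pid!r}"))
                continue
            if value < 0.0 or value > 1.0:
                out_of_range.append(pid)
                continue
            scores[pid] = value
    return scores, malformed, out_of_range


def validate_submission(path: str | Path, ref: ReferenceSet) -> ValidationReport:
    """Check a submission file against the reference patch set.

    Non-destructive: malformed files yield a report, never an exception
    (only an unreadable file raises OSError).
    """
    scores, malformed, out_of_range = _read_submission_rows(path)
    covered = set(scores) | set(out_of_range)
    ref_ids = set(map(str, ref.patch_ids))
    missing = sorted(ref_ids - covered)
    extra = sorted(covered - ref_ids)
    return ValidationReport(
        missing_patches=tuple(missing),
        extra_patches=tuple(extra),
        malformed_rows=tuple(malformed),
        out_of_range=tuple(out_of_range),
    )


def load_submission(
    path: str | Path,
    *,
    team: str,
    entry_id: str,
    ref: ReferenceSet | None = None,
) -> Submission:
    """Strictly load a submission; raises if it fails validation against `ref`."""
    if ref is not None:
        report = validate_submission(path, ref)
        if not report.valid:
            raise SubmissionFormatError(
                f"submission {entry_id!r} failed validation ({report.summary()})"
            )
    scores, malformed, out_of_range = _read_submission_rows(path)
    if malformed or out_of_range:
        raise SubmissionFormatError(
            f"submission {entry_id!r} has malformed or out-of-range rows"
        )
    return Submission(team=team, entry_id=entry_id, scores=scores)


# ---------------------------------------------------------------------------
# scoring


def _avg_pk_metric(ref: ReferenceSet, sub: Submission) -> float:
    alg = sub.aligned_to(ref)
    return average_metric_over_raters(
        [prediction_probability(ref.scores[r], alg) for r in ref.rater_ids]
    )


def _avg_icc_metric(ref: ReferenceSet, sub: Submission) -> float:
    alg = sub.aligned_to(ref)
    vals = [
        icc_2_1(RatingMatrix(np.column_stack([ref.scores[r], alg])))
        for r in ref.rater_ids
    ]
    return average_metric_over_raters(vals)


def interrater_avg_pk(ref: ReferenceSet) -> float:
    """Mean PK over all ordered rater pairs (PK is reference-asymmetric)."""
    raters = ref.rater_ids
    if len(raters) < 2:
        raise InputValidationError("interrater PK needs >= 2 raters")
    vals = [
        prediction_probability(ref.scores[a], ref.scores[b])
        for a in raters
        for b in raters
        if a != b
    ]
    return average_metric_over_raters(vals)


def interrater_avg_icc(ref: ReferenceSet) -> float:
    """Mean ICC(2,1) over all unordered rater pairs."""
    raters = ref.rater_ids
    if len(raters) < 2:
        raise InputValidationError("interrater ICC needs >= 2 raters")
    vals = [
        icc_2_1(RatingMatrix(np.column_stack([ref.scores[a], ref.scores[b]])))
        for i, a in enumerate(raters)
        for b in raters[i + 1 :]
    ]
    return average_metric_over_raters(vals)


def score_submission(
    sub: Submission,
    ref: ReferenceSet,
    *,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> ScoredSubmission:
    """Per-rater PK and ICC, rater-averaged, with cluster-bootstrap CIs.

    The bootstrap resamples patients and recomputes both per-rater values
    inside every replicate before averaging, so the CI reflects the averaged
    metric end to end.
    """
    alg = sub.aligned_to(ref)
    per_pk = {
        r: prediction_probability(ref.scores[r], alg) for r in ref.rater_ids
    }
    per_icc = {
        r: icc_2_1(RatingMatrix(np.column_stack([ref.scores[r], alg])))
        for r in ref.rater_ids
    }
    avg_pk = cluster_bootstrap(
        _avg_pk_metric, ref, sub, n_boot=n_boot, seed=seed, level=level,
        per_rater=per_pk,
    )
    avg_icc = cluster_bootstrap(
        _avg_icc_metric, ref, sub, n_boot=n_boot, seed=seed, level=level,
        per_rater=per_icc,
    )
    return ScoredSubmission(
        team=sub.team, entry_id=sub.entry_id, avg_pk=avg_pk, avg_icc=avg_icc
    )


def build_leaderboard(entries: Iterable[ScoredSubmission]) -> list[LeaderboardRow]:
    """Rank entries by average PK, descending, with competition ranking.

    Entries with exactly equal average PK share the smaller rank and the
    next rank is skipped ([0.9, 0.8, 0.8, 0.7] -> ranks 1, 2, 2, 4).
    Display order among ties is deterministic (entry_id ascending).
    """
    pool = list(entries)
    if not pool:
        raise InputValidationError("leaderboard needs at least one scored entry")
    pool.sort(key=lambda e: (-e.avg_pk.value, e.entry_id))
    rows: list[LeaderboardRow] = []
    rank = 1
    for pos, entry in enumerate(pool):
        if pos > 0 and entry.avg_pk.value != pool[pos - 1].avg_pk.value:
            rank = pos + 1
        rows.append(
            LeaderboardRow(
                rank=rank,
                team=entry.team,
                entry_id=entry.entry_id,
                avg_pk=entry.avg_pk,
                avg_icc=entry.avg_icc,
                per_rater_pk=dict(entry.avg_pk.per_rater or {}),
            )
        )
    return rows


def significance_frontier(
    leaderboard: Sequence[LeaderboardRow],
    ref: ReferenceSet,
    submissions: Mapping[str, Submission],
    *,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
    top: int | None = None,
) -> dict[str, str | None]:
    """First lower-ranked entry significantly below each entry in average PK.

    Walks down the ranking from each entry (optionally only the `top` ranked
    ones) applying the paired patient-bootstrap difference test until it
    finds significance; records that entry id, or None if no lower-ranked
    entry differs significantly.  All pairs share one root seed, i.e. the
    same resampled patient sets, keeping comparisons consistent.
    """
    frontier: dict[str, str | None] = {}
    rows = list(leaderboard)
    limit = len(rows) if top is None else min(top, len(rows))
    cache: dict[tuple[str, str], DifferenceResult] = {}
    for i in range(limit):
        upper = rows[i]
        hit: str | None = None
        for lower in rows[i + 1 :]:
            key = (upper.entry_id, lower.entry_id)
            if key not in cache:
                cache[key] = paired_difference(
                    _avg_pk_metric,
                    ref,
                    submissions[upper.entry_id],
                    submissions[lower.entry_id],
                    n_boot=n_boot,
                    seed=seed,
                    alpha=alpha,
                )
            if cache[key].significant:
                hit = lower.entry_id
                break
        frontier[upper.entry_id] = hit
    return frontier


def patch_mse(
    submissions: Sequence[Submission], ref: ReferenceSet
) -> list[PatchError]:
    """Per-patch error analysis across a pool of algorithms.

    For each patch: the squared difference between a rater's score and each
    algorithm's score, averaged over algorithms, then averaged over raters;
    plus the mean and (population) standard deviation of the algorithm
    scores.  Sorted by MSE descending so the hardest patches come first.
    """
    if not submissions:
        raise InputValidationError("patch_mse needs at least one submission")
    mat = np.column_stack([s.aligned_to(ref) for s in submissions])  # n x m
    sq = np.zeros(ref.n_patches)
    for r in ref.rater_ids:
        sq += ((ref.scores[r][:, None] - mat) ** 2).mean(axis=1)
    sq /= len(ref.rater_ids)
    avg = mat.mean(axis=1)
    sd = mat.std(axis=1)
    out = [
        PatchError(
            patch_id=str(ref.patch_ids[i]),
            mse=float(sq[i]),
            avg_score=float(avg[i]),
            sd_score=float(sd[i]),
        )
        for i in range(ref.n_patches)
    ]
    out.sort(key=lambda p: (-p.mse, p.patch_id))
    return out


# ---------------------------------------------------------------------------
# leaderboard serialization


def _metric_fields(prefix: str, m: MetricResult) -> dict[str, float | int]:
    return {
        f"{prefix}": m.value,
        f"{prefix}_ci_low": m.ci_low,
        f"{prefix}_ci_high": m.ci_high,
        f"{prefix}_n_boot": m.n_boot,
        f"{prefix}_seed": m.seed,
    }


def leaderboard_records(rows: Sequence[LeaderboardRow]) -> list[dict]:
    records = []
    for row in rows:
        rec: dict = {"rank": row.rank, "team": row.team, "entry_id": row.entry_id}
        rec.update(_metric_fields("avg_pk", row.avg_pk))
        rec.update(_metric_fields("avg_icc", row.avg_icc))
        for rater, v in row.per_rater_pk.items():
            rec[f"pk_{rater}"] = v
        records.append(rec)
    return records


def write_leaderboard(
    rows: Sequence[LeaderboardRow], path: str | Path, fmt: str | None = None
) -> None:
    """Write the leaderboard as CSV or JSON (format inferred from suffix)."""
    path = Path(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "csv")
    records = leaderboard_records(rows)
    if fmt == "json":
        path.write_text(json.dumps(records, indent=2) + "\n")
    elif fmt == "csv":
        pd.DataFrame(records).to_csv(path, index=False)
    else:
        raise InputValidationError(f"unknown leaderboard format {fmt!r}")
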