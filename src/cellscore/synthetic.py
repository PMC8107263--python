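"""Seeded generators emulating a TC-scoring challenge, and the tie-gaming study.

Nothing here touches pixels: the generators produce *scores*.  A latent true
tumor-cellularity value is drawn per patch from a zero-inflated two-mode beta
mixture (a spike of tumor-free patches at 0, plus broad low-TC and high-TC
modes, mimicking the U-ish histograms of pathologist scores).  Raters are
simulated by discretizing the latent value to a coarse percentage grid, the
second rater with additive Gaussian noise first; simulated algorithms apply
a monotone miscalibration and additive noise, optionally binning their
output to k equal-width bins.

Binning is the interesting adversary: it inflates the tied-pair count TA,
which *raises* Kendall tau-b (ties shelter would-be discordant pairs from
the numerator more than the denominator) but *lowers* PK, whose denominator
C + D + TA keeps every reference-distinguished pair in play.
:func:`run_gaming_experiment` measures both effects by simulation.

Every generator output is a pure function of (config, seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigError
from .harness import (
    LeaderboardRow,
    PatchError,
    ReferenceSet,
    ScoredSubmission,
    Submission,
    build_leaderboard,
    patch_mse,
    score_submission,
    significance_frontier,
)
from .metrics import count_pairs, pk_from_counts, tau_b_from_counts
from .resampling import child_seed

__all__ = [
    "SyntheticConfig",
    "AlgorithmProfile",
    "LatentReference",
    "VariantStats",
    "GamingResult",
    "ChallengeBundle",
    "generate_reference",
    "generate_algorithm",
    "run_gaming_experiment",
    "run_challenge_simulation",
    "interrater_pk_curve",
    "load_config",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a synthetic challenge reference.

    Defaults mirror a test set of 18 patients contributing ~1100 patches.
    ``tc_low`` / ``tc_high`` are beta-distribution (a, b) shapes for the
    low-TC and high-TC modes of the non-zero mixture; ``tc_weight_low`` is
    the low mode's weight.  ``grid_step`` is the percentage grid raters
    report on (0.05 = steps of 5%).  ``rater_noise_sd`` is the second
    rater's additive score noise before re-gridding; the default 0.11 was
    read off :func:`interrater_pk_curve` so that the simulated raters'
    interrater average PK sits near 0.93, the regime of experienced
    pathologist pairs.  ``zero_fidelity`` is the probability the second
    rater preserves an exact-zero patch as zero.
    """

    n_patients: int = 18
    slides_per_patient: int = 2
    patches_per_slide: int = 31
    zero_inflation: float = 0.2
    tc_weight_low: float = 0.45
    tc_low: tuple[float, float] = (1.2, 3.5)
    tc_high: tuple[float, float] = (4.0, 1.8)
    grid_step: float = 0.05
    rater_noise_sd: float = 0.11
    zero_fidelity: float = 0.9

    def __post_init__(self) -> None:
        for name in ("n_patients", "slides_per_patient", "patches_per_slide"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("zero_inflation", "tc_weight_low", "zero_fidelity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1]")
        for name in ("tc_low", "tc_high"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ConfigError(f"{name} beta shapes must be positive")
        if not 0.0 < self.grid_step <= 1.0:
            raise ConfigError("grid_step must be in (0, 1]")
        if abs(round(1.0 / self.grid_step) * self.grid_step - 1.0) > 1e-9:
            raise ConfigError("grid_step must divide 1 evenly")
        if self.rater_noise_sd < 0:
            raise ConfigError("rater_noise_sd must be >= 0")

    @property
    def n_patches(self) -> int:
        return self.n_patients * self.slides_per_patient * self.patches_per_slide


@dataclass(frozen=True)
class AlgorithmProfile:
    """Behavior of a simulated algorithm.

    ``calibration`` is a strictly increasing map applied to the latent TC
    before noise: ``("id",)``, ``("power", gamma)`` with gamma > 0, or
    ``("affine", a, b)`` with a > 0.  ``n_bins`` = 0 emits continuous
    scores; k >= 2 replaces each score by the midpoint of its bin among k
    equal-width bins — the tau-b gaming move.
    """

    label: str
    noise_sd: float = 0.1
    calibration: tuple = ("id",)
    n_bins: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.n_bins != 0 and self.n_bins < 2:
            raise ConfigError("n_bins must be 0 (continuous) or >= 2")
        kind = self.calibration[0]
        if kind == "id":
            pass
        elif kind == "power":
            if len(self.calibration) != 2 or self.calibration[1] <= 0:
                raise ConfigError("power calibration needs a positive exponent")
        elif kind == "affine":
            if len(self.calibration) != 3 or self.calibration[1] <= 0:
                raise ConfigError("affine calibration needs positive slope a (a, b)")
        else:
            raise ConfigError(f"unknown calibration kind {kind!r}")


@dataclass(frozen=True)
class LatentReference:
    """A generated two-rater reference plus the latent true TC per patch."""

    reference: ReferenceSet
    latent: np.ndarray


@dataclass(frozen=True)
class VariantStats:
    mean_tau_b: float
    mean_pk: float
    mean_C: float
    mean_D: float
    mean_TA: float


@dataclass(frozen=True)
class GamingResult:
    """Replicate-averaged metrics for continuous vs binned output variants."""

    variants: Mapping[str, VariantStats]
    n_reps: int
    seed: int

    def table(self) -> pd.DataFrame:
        rows = [
            {"variant": name, **vars(stats)} for name, stats in self.variants.items()
        ]
        return pd.DataFrame(rows).set_index("variant")


@dataclass(frozen=True)
class ChallengeBundle:
    """Everything a full synthetic challenge run produces."""

    reference: ReferenceSet
    latent: np.ndarray
    submissions: Mapping[str, Submission]
    scored: Sequence[ScoredSubmission]
    leaderboard: Sequence[LeaderboardRow]
    frontier: Mapping[str, str | None]
    patch_errors: Sequence[PatchError]


# ---------------------------------------------------------------------------
# generators


def _grid(x: np.ndarray, step: float) -> np.ndarray:
    return np.clip(np.round(x / step) * step, 0.0, 1.0)


def generate_reference(cfg: SyntheticConfig, seed: int) -> LatentReference:
    """Draw a two-rater reference set with hierarchical patch -> slide -> patient ids.

    Latent TC: zero with probability ``zero_inflation``, else a draw from the
    two-mode beta mixture.  Rater "path1" reports the latent value on the
    percentage grid; "path2" adds Gaussian noise before gridding, preserving
    exact zeros with probability ``zero_fidelity``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    n = cfg.n_patches
    patch_ids, slide_ids, case_ids = [], [], []
    for p in range(cfg.n_patients):
        case = f"case{p:03d}"
        for s in range(cfg.slides_per_patient):
            slide = f"{case}_s{s}"
            for k in range(cfg.patches_per_slide):
                patch_ids.append(f"{slide}_p{k:03d}")
                slide_ids.append(slide)
                case_ids.append(case)

    is_zero = rng.random(n) < cfg.zero_inflation
    low = rng.random(n) < cfg.tc_weight_low
    draws_low = rng.beta(*cfg.tc_low, size=n)
    draws_high = rng.beta(*cfg.tc_high, size=n)
    latent = np.where(low, draws_low, draws_high)
    latent[is_zero] = 0.0

    rater1 = _grid(latent, cfg.grid_step)
    noise = rng.normal(0.0, cfg.rater_noise_sd, size=n) if cfg.rater_noise_sd else 0.0
    rater2 = _grid(np.clip(latent + noise, 0.0, 1.0), cfg.grid_step)
    keep_zero = is_zero & (rng.random(n) < cfg.zero_fidelity)
    rater2[keep_zero] = 0.0

    ref = ReferenceSet.validated(
        patch_ids=patch_ids,
        slide_ids=slide_ids,
        case_ids=case_ids,
        scores={"path1": rater1, "path2": rater2},
    )
    return LatentReference(reference=ref, latent=latent)


def _apply_calibration(x: np.ndarray, calibration: tuple) -> np.ndarray:
    kind = calibration[0]
    if kind == "id":
        return x
    if kind == "power":
        return x ** calibration[1]
    # affine
    _, a, b = calibration
    return a * x + b


def _bin_midpoints(scores: np.ndarray, k: int) -> np.ndarray:
    idx = np.minimum((scores * k).astype(int), k - 1)
    return (idx + 0.5) / k


def generate_algorithm(
    lref: LatentReference, profile: AlgorithmProfile, seed: int
) -> Submission:
    """Simulate one submission: calibrate latent TC, add noise, clamp, maybe bin."""
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    latent = lref.latent
    scores = _apply_calibration(latent, profile.calibration)
    if profile.noise_sd:
        scores = scores + rng.normal(0.0, profile.noise_sd, size=latent.shape[0])
    scores = np.clip(scores, 0.0, 1.0)
    if profile.n_bins:
        scores = _bin_midpoints(scores, profile.n_bins)
    return Submission(
        team=profile.label,
        entry_id=profile.label,
        scores=dict(zip(map(str, lref.reference.patch_ids), scores.tolist())),
    )


# ---------------------------------------------------------------------------
# the tie-gaming experiment


def run_gaming_experiment(
    cfg: SyntheticConfig,
    profile: AlgorithmProfile,
    bin_grid: Sequence[int] = (10,),
    *,
    n_reps: int = 200,
    seed: int = 0,
) -> GamingResult:
    """Measure what output binning does to tau-b vs PK.

    Each replicate draws a fresh reference and one continuous submission
    from `profile` (its ``n_bins`` is ignored), evaluates pair counts, PK
    and tau-b against rater path1 for the continuous scores and for each
    binned variant of the *same* scores, and averages over replicates.
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    for k in bin_grid:
        if k < 2:
            raise ConfigError("bin sizes must be >= 2")
    cont_profile = replace(profile, n_bins=0)
    names = ["continuous"] + [f"binned_{k}" for k in bin_grid]
    acc = {name: np.zeros(5) for name in names}
    for r in range(n_reps):
        lref = generate_reference(cfg, child_seed(seed, r, 0))
        sub = generate_algorithm(lref, cont_profile, child_seed(seed, r, 1))
        ref_scores = lref.reference.scores["path1"]
        cont = np.array(
            [sub.scores[p] for p in map(str, lref.reference.patch_ids)]
        )
        variants = {"continuous": cont}
        for k in bin_grid:
            variants[f"binned_{k}"] = _bin_midpoints(cont, k)
        for name, alg in variants.items():
            counts = count_pairs(ref_scores, alg)
            acc[name] += np.array(
                [
                    tau_b_from_counts(counts),
                    pk_from_counts(counts),
                    counts.C,
                    counts.D,
                    counts.TA,
                ]
            )
    variants_out = {
        name: VariantStats(*(acc[name] / n_reps)) for name in names
    }
    return GamingResult(variants=variants_out, n_reps=n_reps, seed=int(seed))


# ---------------------------------------------------------------------------
# end-to-end challenge simulation


def _profile_behavior_key(profile: AlgorithmProfile) -> int:
    """Stable seed key from a profile's behavior (label excluded), so
    identical behaviors reproduce identical submissions."""
    desc = repr((profile.noise_sd, profile.calibration, profile.n_bins))
    return zlib.crc32(desc.encode())


def run_challenge_simulation(
    cfg: SyntheticConfig,
    roster: Sequence[AlgorithmProfile],
    *,
    n_boot: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    level: float = 0.95,
    frontier_top: int | None = None,
) -> ChallengeBundle:
    """Generate a reference and a roster of submissions, then score everything.

    Deterministic in (cfg, roster, seed).  Submissions from profiles with
    identical behavior (regardless of label) are identical, so duplicated
    profiles tie exactly on the leaderboard.  All entries are scored with
    the same bootstrap seed, i.e. the same resampled patient sets.
    """
    if not roster:
        raise ConfigError("roster must contain at least one profile")
    labels = [p.label for p in roster]
    if len(set(labels)) != len(labels):
        raise ConfigError("profile labels must be unique")
    lref = generate_reference(cfg, child_seed(seed, 0))
    submissions: dict[str, Submission] = {}
    scored: list[ScoredSubmission] = []
    score_seed = child_seed(seed, 2)
    for profile in roster:
        sub = generate_algorithm(
            lref, profile, child_seed(seed, 1, _profile_behavior_key(profile))
        )
        submissions[profile.label] = sub
        scored.append(
            score_submission(
                sub, lref.reference, n_boot=n_boot, seed=score_seed, level=level
            )
        )
    leaderboard = build_leaderboard(scored)
    frontier = significance_frontier(
        leaderboard,
        lref.reference,
        submissions,
        alpha=alpha,
        n_boot=n_boot,
        seed=child_seed(seed, 3),
        top=frontier_top,
    )
    errors = patch_mse(list(submissions.values()), lref.reference)
    return ChallengeBundle(
        reference=lref.reference,
        latent=lref.latent,
        submissions=submissions,
        scored=tuple(scored),
        leaderboard=tuple(leaderboard),
        frontier=frontier,
        patch_errors=tuple(errors),
    )


def interrater_pk_curve(
    cfg: SyntheticConfig,
    noise_sds: Sequence[float],
    *,
    n_reps: int = 200,
    seed: int = 0,
) -> dict[float, float]:
    """Monte-Carlo mean interrater average PK as a function of rater noise.

    The calibration tool behind the default ``rater_noise_sd``: sweep the
    noise level and read off where simulated raters agree like experienced
    pathologists (average PK in the low 0.9s).
    """
    from .harness import interrater_avg_pk

    out: dict[float, float] = {}
    for i, sd in enumerate(noise_sds):
        c = replace(cfg, rater_noise_sd=float(sd))
        vals = [
            interrater_avg_pk(generate_reference(c, child_seed(seed, i, r)).reference)
            for r in range(n_reps)
        ]
        out[float(sd)] = float(np.mean(vals))
    return out


# ---------------------------------------------------------------------------
# config file loading


def _parse_calibration(spec) -> tuple:
    if spec is None or spec == "id":
        return ("id",)
    if isinstance(spec, Mapping):
        if "power" in spec:
            return ("power", float(spec["power"]))
        if "affine" in spec:
            a, b = spec["affine"]
            return ("affine", float(a), float(b))
    raise ConfigError(f"cannot parse calibration {spec!r}")


def load_config(
    path: str | Path,
) -> tuple[SyntheticConfig, list[AlgorithmProfile]]:
    """Read a YAML/JSON simulation config.

    Top-level keys: ``reference`` (SyntheticConfig fields) and ``algorithms``
    (list of AlgorithmProfile entries; ``calibration`` as ``id``,
    ``{power: g}`` or ``{affine: [a, b]}``).
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Mapping):
        raise ConfigError("config must be a mapping")
    ref_kwargs = dict(raw.get("reference", {}))
    for key in ("tc_low", "tc_high"):
        if key in ref_kwargs:
            ref_kwargs[key] = tuple(ref_kwargs[key])
    try:
        cfg = SyntheticConfig(**ref_kwargs)
    except TypeError as exc:
        raise ConfigError(f"bad reference config: {exc}") from None
    profiles = []
    for entry in raw.get("algorithms", []):
        entry = dict(entry)
        entry["calibration"] = _parse_calibration(entry.get("calibration"))
        try:
            profiles.append(AlgorithmProfile(**entry))
        except TypeError as exc:
            raise ConfigError(f"bad algorithm profile: {exc}") from None
    return cfg, profiles
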