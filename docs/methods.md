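# Methods

## The evaluation model

The task being evaluated is continuous estimation: each image patch `i` has
one tumor-cellularity (TC) score per reference rater, a fraction in [0, 1],
and each algorithm submits one score per patch. Evaluation is rank-based
first (is the *ordering* of patches right?) and calibration-based second
(are the *values* right?).

### Pair tallies

Every unordered pair of patches falls into exactly one of five categories
with respect to a (reference, algorithm) score pair: concordant `C`,
discordant `D`, tied only in the algorithm `TA`, tied only in the reference
`TR`, tied in both `TB`. `C + D + TA + TR + TB = n(n−1)/2` always.

A deliberate convention: pairs tied in **both** vectors are counted as `TB`
and excluded from `TA`/`TR`. Under this convention (a) the tau-b formula
below is algebraically the textbook tie-corrected tau-b, and (b) a constant
submission has `C = D = 0` and all reference-distinguished pairs in `TA`,
giving PK exactly ½, which is what "no ranking information" must score.

Ties are exact floating-point equality. Scores arrive as decimal text, so
equality is well defined; an epsilon tolerance would silently reclassify
pairs and would itself be an exploitable surface.

### Metrics

- `PK = (C + ½TA) / (C + D + TA)`. Reference-tied pairs never enter: PK is
  the probability of ordering a randomly chosen reference-distinguished
  pair correctly, with half credit for algorithm ties. On a binary
  reference it equals the trapezoidal (Mann–Whitney) ROC AUC to machine
  precision, which the tests verify.
- `tau-b = (C − D) / sqrt((C + D + TA)(C + D + TR))`.
- `ICC(2,1) = (MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)` from the
  two-way, one-observation-per-cell ANOVA (subjects and raters both
  random, absolute agreement, single rater). Negative values are returned
  as computed; they are meaningful near zero agreement.

Multi-rater summaries average the per-rater metric values arithmetically.
Interrater PK averages both orderings of a rater pair, since PK is
asymmetric in which vector plays the reference.

### Why both PK and tau-b exist here

Binning a continuous output into k bins converts near-ties into exact ties:
`D` collapses much faster than `C` because pairs with similar true TC are
the ones that noise was misordering. In tau-b the reference-tie factor
`(C+D+TR)` barely moves while the numerator loses mostly discordances, so
tau-b **rises** — a submission can game it without any new information. In
PK the denominator `C+D+TA` retains every reference-distinguished pair, so
the same move **lowers** PK. `run_gaming_experiment` reproduces both
directions; the default configuration yields tau-b 0.822 → 0.849 and PK
0.925 → 0.913 for 10-bin binning of a noise-0.1 estimator.

## Uncertainty

Patches cluster within patients, so all CIs come from a per-patient
bootstrap: draw the same number of patients with replacement, carry each
drawn patient's patches (twice if drawn twice), recompute the metric, take
the percentile interval (numpy's default linear-interpolation quantiles) of
the replicates; 1000 replicates and 95% coverage by default. The point
estimate is always computed on the unresampled data. Replicate `r` uses the
RNG stream `SeedSequence([seed, r])`, making the replicate vector a pure
function of (inputs, seed) and independent of evaluation order.

Replicates where a metric is undefined (e.g. a resample whose reference is
constant) are dropped, counted in `n_dropped`, and warned about; only if
*every* replicate is undefined does the run fail. Rater-averaged metrics
are bootstrapped end to end: both per-rater values are recomputed inside
each replicate before averaging.

Two algorithms are compared by the paired version: the same resampled
patient set is applied to both, and the difference is significant at level
α when the percentile CI of the delta excludes zero. The significance
frontier walks each leaderboard entry down the ranking to the first entry
it beats significantly. All pairwise comparisons reuse one root seed — the
same resampled patient sets — so the frontier is internally consistent.
Resampling draws patients, not slides; with multi-slide patients the
patient is the independence unit.

## The synthetic challenge generator

What it emulates: a test set of `n_patients × slides_per_patient ×
patches_per_slide` patches (default 18 × 2 × 31 = 1116, the scale of a
real challenge test phase); a zero-inflated latent TC per patch (tumor-free
patches are true zeros); two raters who report on a coarse percentage grid;
algorithms that distort the latent truth.

- Latent TC: 0 with probability `zero_inflation` (default 0.2), else a
  two-mode beta mixture, `0.45·Beta(1.2, 3.5) + 0.55·Beta(4.0, 1.8)` — a
  broad low-TC mode and a high-TC mode, qualitatively matching the
  U-shaped, zero-spiked histograms pathologists produce. The mixture is a
  shape choice, not a fit to any dataset.
- Rater 1 reports `grid(latent)`; rater 2 reports
  `grid(clip(latent + N(0, rater_noise_sd)))`, preserving exact zeros with
  probability `zero_fidelity` (default 0.9 — a second rater occasionally
  mis-scores a tumor-free patch). Grid step default 0.05 (5% steps).
- `rater_noise_sd` default 0.11: chosen once by sweeping
  `interrater_pk_curve` and selecting the level at which the simulated
  pair's interrater average PK sits near 0.93, the regime reported for
  experienced pathologist pairs; the sweep is itself part of the package.
- Algorithm profiles: `score = clip(calibration(latent) + N(0, noise_sd))`,
  optionally binned to `k` equal-width bins, represented by bin midpoints
  (any within-bin constant gives identical rank metrics; midpoints keep
  MSE and ICC sensible).

Every output is a pure function of (config, seed); child seeds are derived
through `SeedSequence` so components are independent of evaluation order.
In the challenge simulation the algorithm seed is keyed on the profile's
*behavior* (noise, calibration, bins), so duplicated profiles produce
identical submissions and tie exactly — useful for testing tie handling.

What it does **not** emulate: within-patient score correlation beyond
shared membership (latent values are i.i.d. across a patient's patches),
systematic inter-rater calibration offsets (rater noise is symmetric, so
simulated interrater ICC runs higher than real pathologist pairs'),
histology-specific failure modes, or any image content. Passing tests
therefore demonstrate the *evaluation machinery* — counting, formulas,
resampling, ranking — not realism of any particular algorithm's errors.

## Numerical choices

- Pair counting uses an O(n²) vectorized comparison below 65 items and an
  O(n log n) Fenwick-tree scan (numba-compiled, pure-Python fallback)
  above; both are verified exactly against brute-force enumeration.
- The ANOVA centers the matrix on its grand mean before computing sums of
  squares, so a constant matrix yields exact zeros; the ICC denominator is
  treated as zero when below `1e-12 ×` the mean-square scale, raising the
  undefined-metric error instead of returning rounding noise.
- Leaderboard ties require exact float equality of average PK; tied entries
  share the smaller competition rank (1, 2, 2, 4) and are displayed in
  deterministic entry-id order.
- Submission scores outside [0, 1] are validation failures, never clamped:
  TC is a fraction by definition. Validation is non-destructive (a report,
  not an exception), so malformed files can be diagnosed and do not count
  against a submitter.
- Reference CSVs may declare per-rater units with a `:percent` /
  `:fraction` column-name suffix; everything internal is a fraction.
- Per-patch MSE averages squared errors across algorithms and then across
  raters (a mean, not a sum, so values are comparable across pool sizes).
  When both raters give the same score `s`, the identity
  `MSE = (avg_score − s)² + Var(scores)` holds exactly and is tested.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the generator at the default
1116-patch scale for single evaluations, 200-patch references for the
200-trial bootstrap-coverage study (300 replicates per trial, against a
20 000-patch Monte-Carlo truth), 200 replicates per gaming experiment, and
50 seeded repetitions of the 4-algorithm leaderboard-recovery study. These
sizes give Monte-Carlo error well inside every asserted band while keeping
a full run in the minutes range on one core.

## Known limitations

- Percentile CIs only; no BCa or studentized intervals, and no
  multiplicity correction across a leaderboard's many pairwise frontiers.
- ICC forms other than (2,1) are out of scope, as are weighted concordance
  variants and Somers' D.
- The bootstrap resamples patients; if a study's independence unit were
  the slide, the current ReferenceSet would need its cluster column set to
  slide ids instead.
- Real-challenge reference data (e.g. from a public archive) can be scored
  by writing it into the documented reference CSV format; no downloader is
  included.
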