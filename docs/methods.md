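# Methods

## Regional current density and the normative atlas

The unit of analysis is a per-region count of validated neuroelectric
current events from one MEG recording. Counts are normalised to densities

    ρ_r = (c_r / c_total) / (v_r / v_total)

where `c_total` and `v_total` are the whole-brain count and volume. The
normalisation makes ρ = 1 the signature of spatially uniform activity and
removes variation in record length and moment-to-moment data quality (which
scale all counts together). The parcellation partitions the brain into
68 cortical parcels, 68 adjacent white-matter rims (≤ 5 mm thick, one per
parcel, paired bijectively) and 17 subcortical structures; 18 deep
white-matter tracts overlap the white matter and are excluded from the
volume partition but normalised with the same whole-brain totals, since the
density formula needs only `c_total` and `v_total`.

A normative atlas stores each region's mean and standard deviation of
density over a reference cohort (sample SD, n−1 denominator; the choice is a
convention and is configurable). Individual recordings are then expressed
as z-scores `z_r = (ρ_r − mean_r)/sd_r` under a normality assumption for the
reference densities. Because densities are non-negative, each region's z
has a floor `−mean_r/sd_r`, attained exactly when the count is zero; the
floor induces right skew that the z transform does not remove, and no
transformation is applied here either. The atlas refuses regions with zero
reference variance rather than producing unusable entries.

## Empty-room correction

Empty-room recordings yield a non-zero "dark count" whose regional densities
correlate, across subjects, with the densities measured with the subject
present the same day. The correction subtracts the correlation-weighted
empty-room density:

    ρ_corrected_r = ρ_r − corr_r · ρ_empty_r

with `corr_r` the per-region Pearson correlation over same-day pairs. When
subject and empty-room densities have equal variance this is exactly the
least-squares residual, so corrected densities are uncorrelated with the
empty-room densities in expectation; a second pass therefore refits
near-zero correlations and changes densities negligibly. Corrected
densities may be negative — the floor property is asserted only
pre-correction. By default the correlations are estimated within each
cohort separately and the atlas is built on corrected densities; both
choices are flags. A region with zero variance in either vector gets
corr = 0 (no correction) and a warning.

Estimating `corr_r` within a small cohort carries sampling error of order
1/√n, and subtracting a noisily-estimated correlation shifts that entire
cohort coherently. With per-cohort correction and very unequal cohort
sizes this alone can separate the cohorts — a genuine analysis artifact
mirroring scanner/noise-environment confounds in multi-site comparisons.
For this reason the generator's exchangeable-null construction (below)
disables the dark layer entirely.

## Stepwise discriminant classification

Candidate regions (by default the 85 cortical + subcortical regions for
symptom and cohort classifiers; the 18 deep tracts for the tract
classifier) enter a two-group linear discriminant model stepwise. Each
entry step admits the candidate minimising Wilks' Λ (within/total scatter
ratio over the entered set) provided its partial F is at least
`f_to_enter`; entered variables whose partial F falls below `f_to_remove`
are removed; candidates whose tolerance (1 − R² against the entered set, on
the pooled within-group correlation matrix) is below `tolerance` are
skipped as collinear. Defaults are SPSS-style conventions: F-to-enter 3.84,
F-to-remove 2.71, tolerance 0.001, at most 2 × n_regions steps. Λ is
non-increasing along the entry path. The selected set is converted to
Fisher classification functions from the pooled within-group covariance;
priors are equal by default (switchable to proportional), which keeps both
rows of an accuracy report symmetric under unbalanced groups. An empty
selection classifies every subject to the first group label (documented
deterministic tie-break).

**Jackknife.** Accuracy is assessed leave-one-out with the variable set
fixed: only the classification-function coefficients are re-estimated per
fold. This matches the "jackknifed classification" of classical discriminant
packages and is verified, prediction for prediction, against an independent
LDA implementation. It is *not* unbiased when the variable set itself was
selected on the full sample: on exchangeable null data with 85 candidates,
the selection step virtually always admits spurious regions
(P(max partial F > 3.84) ≈ 1 − 0.95⁸⁵ ≈ 0.99) and the fixed-set jackknife
inherits that optimism — measured at ≈ 61–62 % accuracy where an unbiased
procedure would give 50 %. The package reports this honestly rather than
hiding it; genuinely unbiased error estimation would require repeating the
selection inside each fold.

**Significance.** Each confusion row is tested against fair coin flipping
with the exact binomial tail, summed in log space (lgamma + logsumexp) so
extreme tails do not underflow. Two conventions exist: `strict`
(P(X > correct), the default — it reproduces published table p-values, e.g.
42/54 → 0.000007, 23/32 → 0.0035 — but gives 0 for a perfect row) and
`at_least` (P(X ≥ correct), matching the verbal "at least k heads"
description; a perfect row of 63 gives ≈ 10⁻¹⁹). Percentages are rounded
half-away-from-zero to one decimal.

**Second-step reruns** repeat the selection with the first run's regions
excluded, testing whether group information persists in regions correlated
with the first selection. **Discriminant scores** are canonical variate
scores (pooled within-group variance scaled to one, positive group higher);
group differences in scores are tested with Welch's unequal-variance t and
Welch–Satterthwaite degrees of freedom (the conservative choice), one-sided
toward the positive group, alongside Levene's F (mean-centred) for variance
homogeneity. Symptom dependence is summarised by pairwise both-positive
coincidence fractions and Pearson correlations between classifier scores.

Survey screening uses score ≥ cut-off as "positive" (cut-offs 15 for the
insomnia index and 63 for the psychological-distress inventory scales); a
missing score is reported as missing, never silently dropped.

## Test-retest reliability

Per region, reliability is the Pearson correlation across paired subjects
plus the mean difference (second minus first, in z units; usable to adjust
a follow-up measure). Short-term pairs are same-sitting rest vs task;
long-term pairs are baseline vs follow-up rest. Mean differences are tested
per region with a paired two-sided t-test. Swapping sessions negates the
difference and preserves r; r is invariant to common affine rescaling.

## Cortex vs white-matter-rim differentials

For each subject and cortical/rim pair, observed counts are compared with
volume-proportional expectations (`e_ctx = (c_ctx+c_wm)·v_ctx/(v_ctx+v_wm)`)
by a 1-df Pearson χ² without continuity correction — counts are typically in
the thousands, where the correction is immaterial. Tails are computed via
the identity sf(x) = 2Φ(−√x) in log space, representing p-values far below
10⁻³⁰⁰; significance uses p < 10⁻⁸ by default to control false positives
over the tens of thousands of subject × pair tests a cohort produces.
Pairs with fewer than 10 total counts are reported untestable rather than
tested. Raw counts are used (the statistic requires integers); whether
corrected counts should enter is unknowable from densities alone.

## Synthetic cohort generator

The generator emulates the count output of an upstream MEG solver for a
two-cohort study. Study-shaped defaults: 619 normative and 63 clinical
subjects, ~41 % returning for follow-up, ~5 × 10⁵ counts per recording
(CV 0.30), four screened symptoms with clinical prevalences 0.31–0.47,
dark-count share 0.05, and long-term latent stability 0.45.

Per subject, log-activity per partition region is the sum of a baseline
propensity, cohort and symptom effect logs (effects are multiplicative on
activity), and stable subject noise (SD 0.25 in logs); follow-up latents
correlate with baseline at `retest_rho`. A recording draws its total count
log-normally, scaled by a session-quality factor shared with the same-day
empty-room recording, and allocates it multinomially with probabilities
∝ volume × exp(latent) plus a per-recording jitter (SD 0.05). Dark counts
are an added multinomial layer whose regional pattern (SD 0.3 in logs) is
drawn per session and shared with the empty-room recording — this shared
structure, not the totals, is what produces the positive subject ↔
empty-room density correlations, because totals cancel in densities.
Deep-tract counts are binomial thinnings of the rims each tract overlaps
(4–8 same-hemisphere rims, fixed deterministically per table). Survey
scores are integers derived from the same latent that decides symptom
positivity, so prevalence of score ≥ cut-off matches the specified
prevalence exactly in distribution. One root seed feeds independent named
substreams (latents, totals, multinomials, surveys, anatomy), so runs are
bit-reproducible and adding a stream does not perturb the others.

What the generator does *not* emulate: real spatial covariance between
neighbouring regions, age structure, per-sitting state changes (synthetic
same-sitting reliability is ≈ 0.95 rather than the ≈ 0.8 typical of real
recordings — the small per-recording jitter was chosen so that observed
long-term r tracks `retest_rho` with little attenuation), scanner
differences between cohorts, or any time-domain structure. Passing tests
therefore demonstrate correctness of the statistical machinery under a
known generative model, not performance on real recordings.

The exchangeable null (`null_spec`) sets every effect to 1 **and** removes
the dark layer, making the cohort label purely conventional; permuting
labels then provably leaves every downstream statistic's distribution
unchanged, which the suite verifies directly.

## Numerical choices and problem sizes

- Exact binomial tails and χ² tails in log space; χ² p-values below the
  float minimum are reported as 0 with `log10_p` carrying the value.
- Region tables round-trip bit-exactly (floats parsed with round-trip
  precision); all outputs are written atomically (temp file + rename).
- Degenerate inputs: zero `count_total` is an error (density undefined);
  an all-zero empty-room recording is treated as zero density, making the
  correction the identity; zero-variance regions yield corr = 0 (warned) in
  the empty-room model, an error in the atlas, and NaN in reliability.
- Verification sizes (chosen to exercise the asymptotics while keeping the
  suite fast): floor property over 10⁴ recordings of ~3 × 10³ counts;
  oracle equivalence over 10³ χ² instances, all binomial tails to n = 20,
  and 20 jackknife datasets; planted-effect recovery and null
  classification over 20 seeds at 100/group and study size respectively;
  χ² type-I control over ~10⁵ pairs; reliability recovery over 20 seeds of
  80 retested subjects; correction residual at n = 600 pairs × 100 regions.

## Known limitations

- The fixed-set jackknife is optimistic after full-sample selection (see
  above); published-style accuracy tables built this way overstate
  generalisation on null data by ~10 percentage points in our regime.
- The dark-count correction assumes the correlation transfers between
  cohorts only if estimated per cohort; per-cohort estimation in small
  cohorts injects coherent shifts (quantified above).
- The strict binomial convention yields p = 0 for perfect confusion rows;
  use `at_least` when a non-degenerate value is needed.
- Densities, not counts, carry all downstream analyses except the χ²
  differential, which needs raw integers.
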