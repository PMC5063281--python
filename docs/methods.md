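# Methods

This note records the scientific and numerical choices behind `dmdwalk`:
what is modelled, what the synthetic cohort does and does not emulate, and
the conventions that make results reproducible bit for bit.

## Outcome and interval construction

The outcome is the annualized change in six-minute walk distance,
`Δ6MWD = (6MWD_followup − 6MWD_baseline) · 365.25 / elapsed_days` (m/year).
Every ordered same-patient visit pair qualifies as a follow-up interval when

1. baseline 6MWD > 0 (the boy was ambulant at baseline),
2. the follow-up lies 8–16 months later, and
3. every required baseline measure is present.

All qualifying pairs are used; one visit can be the baseline of several
intervals and the follow-up of others. A follow-up 6MWD of 0 (loss of
ambulation) is a valid outcome, not a missing value.

*Month convention.* "Month" is not defined in clinical natural-history
conventions; we use fixed-length months of 30.4375 days with an inclusive
window at both ends. Both bounds and the day count are configurable through
`WindowPolicy`; brute-force enumeration over all ordered pairs is the test
oracle for the builder.

*Required baseline fields* default to every source field of the broad model
(anthropometrics, steroid history, TFT ability flags; a TFT time absent with
`able=False` is a valid, non-missing measurement). Narrower analyses can
relax the list.

## Prognostic models

- **Model 1** — intercept, baseline age, steroid use ≥ 1 year (inclusive
  threshold; the duration is continuous in the descriptive correlations),
  baseline 6MWD.
- **Model 2** — Model 1 plus height, weight, BMI, and the three timed
  function tests. Each TFT contributes an ability indicator and a
  time-in-seconds set to 0 for boys unable to complete (two-part encoding).
  The 10 m walk/run has no ability term: every ambulant boy completes it.
- **Model 3** — Model 2 plus dystrophin genotype class dummies with
  deletion (the largest class) as reference.

Ability or genotype indicator columns that are constant in a given dataset
are dropped with a logged notice (an absent category identifies nothing); a
constant column elsewhere raises a rank-deficiency error instead of being
silently removed.

A separate 30-second cap (unable → 30 s; completed times capped at 30 s)
exists purely for the descriptive Pearson correlation table and is never
used in design matrices. Velocity (`distance/time`), reciprocal-time and
threshold transforms of the TFTs are available as alternative encodings for
sensitivity analyses; `unable` maps to 0 under all of them, continuous with
the two-part convention.

## Estimation: exchangeable GEE

Repeated intervals within a boy are correlated. Estimation solves the
population-averaged estimating equation Σᵢ Xᵢ'Vᵢ⁻¹(yᵢ − Xᵢβ) = 0 with
working covariance `Vᵢ = φ[(1−ρ)I + ρJ]` per patient, alternating

1. a generalized-least-squares update of β (φ cancels; the exchangeable
   inverse has a closed form, so only cluster sums are needed), and
2. moment re-estimation from residuals:
   `φ = Σr²/(N−p)` and
   `ρ = [Σᵢ Σ_{j<k} r_ij r_ik / (Σᵢ nᵢ(nᵢ−1)/2 − p)] / φ`.

Conventions: ρ is floored at 0 (the exchangeable correlation is read as a
variance component) and clamped at 0.99 to keep Vᵢ positive definite;
denominators carry the N−p correction; convergence requires the
column-scaled coefficient step to fall below 1e-8 relative to the outcome
scale, with a 100-iteration cap (non-convergence is a logged warning, never
silent). Zero-residual data short-circuit with φ = 0. Inference uses the
robust sandwich `A⁻¹BA⁻¹` and large-sample normal quantiles
(z = 1.959964 for 95% CIs); no small-sample degrees-of-freedom correction is
applied. The reference implementation in statsmodels uses identical moment
conventions and serves as the independent oracle in the test suite — except
that it permits negative ρ estimates, so oracle comparisons generate data
with clearly positive intraclass correlation.

## Predictive performance

`RMSE` defaults to the standard deviation (denominator n−1) of observed
minus predicted Δ6MWD — the literal "SD of differences" reading — with a
plain root-mean-square option; every result records which was used.
`R² = 1 − (RMSE/SD_observed)²`, where the reference dispersion is the
full-cohort outcome SD (this is the only reading consistent with a
cross-validated RMSE of ~60 m, an outcome SD of ~94 m and a reported R² of
~0.59 appearing together).

Cross-validation splits **patients**, never intervals: each of the repeated
splits samples ⌊0.8·n⌋ boys without replacement for training, fits the GEE,
predicts all held-out intervals, and records that split's evaluation RMSE;
the headline number is the mean over splits (not pooled residuals; pooling
is an option). A split leaving fewer than two evaluation intervals is
skipped and counted. Columns constant in a training subset are dropped for
that split; columns collinear only within the subset (e.g. two ability
indicators that coincide among the sampled boys) are dropped one at a time
until the fit is identified — always with a warning. The disjointness of
training and evaluation patients is asserted on every split.

The bootstrap resamples boys with replacement; a boy drawn k times enters as
k distinct pseudo-patients so the 80/20 split stays well defined. Each draw
reruns the full cross-validation; the CI is the 2.5th–97.5th percentile of
the draws' mean RMSEs, and the point estimate is the CV RMSE of the original
cohort. The published full profile (1000 draws × 200 inner splits) is
configurable; the default reduced profile is 200 × 25, which keeps a full
pipeline run under ten seconds and is the scale used in the coverage tests.

## Quartile stratification

The unit is the interval (one boy can appear in several strata across his
intervals). Thresholds are the 25th/50th/75th percentiles of model-predicted
Δ6MWD, linear interpolation between order statistics; bins are half-open
`[lo, hi)` with the lowest stratum open below and the highest closed above.
Labels run "fast decline", "moderate decline", "stable", "improved".
Per-stratum summaries report mean/SD of observed Δ6MWD, median/IQR with
1.5×IQR whiskers, baseline characteristics, and loss-of-ambulation counts.

## Sample-size translation

`n_per_arm = ⌈2σ²(z_{1−α/2} + z_{power})²/δ²⌉` — the classical two-sided
normal approximation with equal allocation. Defaults: α = 0.05, power = 0.80,
δ = 30 m/year (chosen because reported outcome SDs in this disease typically
exceed twice the targeted treatment effect). Ratios between two residual SDs
are computed before rounding and equal (σ₁/σ₂)² exactly; shrinking σ from
80 to 60 m multiplies the requirement by 0.5625.

## The synthetic cohort

No natural-history dataset of this kind is publicly deposited, so the
generator *states a world* with the published statistical profile rather
than re-creating any real cohort.

Each boy carries a latent ambulatory function in 6MWD metres:
a quadratic rise toward a personal peak (mean 410 m, SD 50) at a peak age
near 7 years, then a quadratic decline with a patient-specific curvature
drawn lognormally (mean 12, SD 14 m/year²) — a minority of fast decliners
produces the heavy left tail of observed Δ6MWD. Ambulation is lost abruptly:
once the declining limb crosses a patient-specific reserve threshold
(uniform 50–300 m) the walk test can no longer be completed and 6MWD is 0
thereafter. This collapse is what generates loss-of-ambulation intervals
with Δ6MWD of −200 to −350 m/year; a trajectory that glides smoothly
through zero cannot reproduce the published outcome SD of ~94 m or the
concentration of losses below baseline ~325 m.

Observed 6MWD adds N(0, 22 m) measurement noise (test-retest correlation
stays above 0.9 at the cohort's cross-sectional SD of ~80 m). Timed-test
times map exponentially from the latent function, anchored at the published
medians, with per-test inability thresholds; the links read the latent
function one year ahead (`tft_lead_years`), making the TFTs leading
indicators of decline — without this, a composite model adds almost nothing
over age + 6MWD + steroids, contradicting the natural-history evidence the
package exists to model. Height and weight follow age-linear growth with
patient-level random slopes; steroid duration is age minus a started age
(~N(6, 1.5) years, all boys eventually treated); genotype classes are drawn
with probabilities (0.733, 0.188, 0.079, 0) for deletion/duplication/point
mutation/other.

Randomness: one root seed; each patient gets a substream derived from
(seed, patient index), so cohorts are bitwise reproducible and insensitive
to patient reordering.

At n ≥ 200 patients the default configuration yields mean Δ6MWD ≈ −41 m/year
(SD ≈ 82), ~10 % loss intervals, baseline 6MWD ≈ 363 ± 80 m, and the
published sign pattern of baseline correlations — inside the stated
calibration windows (−37 ± 15, 93.7 ± 20, 12.6 % ± 7 pp).

**Linear mode** replaces the outcome with `Δ6MWD = x'β + bᵢ + ε` on
mechanistically drawn baselines, with per-patient random effects bᵢ and
interval noise ε of known SDs. Visit pairs are spaced 30 months apart so
each pair forms exactly one qualifying interval. Follow-up walks that would
fall below 0 are floored (and counted); with moderate β and noise this is a
~5σ tail event. This mode is the ground truth for parameter-recovery,
cross-validation and bootstrap-coverage experiments.

*What a green test does not establish.* The generator shares the latent
structure that the models then rediscover; good recovery, CV calibration
and stratification on synthetic cohorts validate the machinery, not the
clinical transportability of any particular coefficient. Real-data features
not emulated: trial-entry truncation beyond a uniform censoring age,
steroid treatment effects (steroid duration here is purely a correlate of
age), inter-assessor TFT variability, and missing visits.

## Known limitations

- Identity link and exchangeable correlation only; no AR(1)/unstructured
  alternatives and no bias-corrected sandwich variants.
- GEE-based in-sample R² can decrease when variables are added (the
  estimator does not minimize the marginal sum of squares); the variable
  ledger therefore makes no monotonicity claim in GEE mode.
- The descriptive correlation p-values are unadjusted for multiplicity.
- Quartile thresholds come from in-sample predictions of the chosen model;
  cross-validated stratification is not implemented.
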