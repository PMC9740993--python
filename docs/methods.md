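# Methods

## The problem

Electronic-nose (eNose) instruments summarize a gas mixture as a vector of
cross-sensitive sensor responses — here 32 conducting-polymer sensors, each
reporting ΔR/R₀, the maximum resistance change during a measurement over the
baseline resistance before it. The joint response vector ("smell-print") of
the headspace above a fecal sample is a candidate non-invasive biomarker for
inflammatory bowel disease (IBD). Polymer sensors, however, drift: ambient
humidity, temperature and surface changes shift the response
characteristics on a time scale of days, so the measurement date becomes a
confounder. When case and control samples are not spread evenly over
measurement days, day drift masquerades as (or masks) a disease signal and
corrupts both per-sensor significance testing and downstream classifiers.

This package implements, tests and stress-tests one complete analysis
chain for that situation: synthetic cohort generation with known ground
truth, drift diagnostics, a control-based per-day correction, per-sensor
case-control testing with sensor selection, and leave-one-out
cross-validated (LOOCV) logistic classification with cut-off optimization
and calibration metrics.

## Generative model (synthetic_data)

One sample i measured on day d(i) yields responses

    x_ij = mu_j (1 + a_j g_d(i)) + beta_j 1[i is case] + lambda_j f_i + eps_ij

- `mu_j > 0` — baseline response of sensor j (default: evenly spread over
  0.5–2.0 response units; ΔR/R₀ is dimensionless).
- `g_d` — shared day drift factor (dimensionless). Default
  g = (−g₀, −g₀, +g₀, +g₀) with g₀ = 0.1 over 4 days: all sensors sit at or
  below their average on the first two days and at or above it on the last
  two, the two-block pattern typical of short-term drift.
- `a_j ≥ 0` — per-sensor drift loading. The common-drift-direction
  assumption behind control-based correction is that most sensors drift
  together; default a_j = 1 except ≈0 (0.05) on three "weak" sensors
  (indices 6, 19, 24, 1-based) that sit outside the correlated block.
- `beta_j` — disease effect, nonzero on six discriminating sensors
  (indices 3, 8, 13, 18, 23, 28). Default 0.12·mu_j, calibrated so that at
  63 cases + 63 controls the corrected per-sensor tests land around
  p ≈ 0.001 — the significance scale such cohorts report.
- `f_i ~ N(0,1)` — per-sample subject factor with loadings
  `lambda_j = 0.2·mu_j` (0 on the weak sensors). This induces the strong
  inter-sensor Spearman correlation (≈0.9 pairwise) characteristic of
  polymer arrays; the weak sensors stay essentially uncorrelated.
- `eps_ij ~ N(0, 0.05·mu_j)` — independent measurement noise. A normal
  family is an assumption of convenience, not an inference about real
  sensor noise.

Day allocation is deterministic given the policy: `balanced` interleaves
each group over all days; `confounded` gives cases 2:1 odds of an
early-half day (early fraction 2/3) while controls stay balanced, so every
day keeps control coverage for the correction fit; custom per-group weights
use largest-remainder apportionment. Matching covariates emulate the 1:1
matched design: each control inherits its case's sex, smoking status and
hospital with a small age offset, so `match_pairs` (greedy over cases in
ascending age, exact categorical match, minimal age difference) recovers a
full pairing on default panels. Subject factors and noise are independent
across samples; there are no within-subject repeats.

Named scenarios freeze the study conditions used by the tests and the
acceptance script: `study_scenario` (defaults above), `null_scenario`
(effect, drift and subject factor off), `confounded_null_scenario` (drift
on, effect off, confounded days, subject factor off) and
`drift_demo_scenario` (defaults with g₀ = 0.25 and confounded days).

## Drift correction (drift_correction)

Controls are assumed exchangeable across days, so any day structure in
their responses is instrument drift. With mu_j the mean over all control
samples and x̄_jd the control mean on day d,

    d_jd = (x̄_jd − mu_j) / mu_j        (mean relative deviation per day)

and every sample on day d is corrected by

    relative mode (default):  x′_ij = x_ij / (1 + d_j,d)
    additive mode:            x′_ij = x_ij − mu_j d_j,d

Both modes equalize the per-day control means exactly (to rounding): in
relative mode x̄_jd/(1+d_jd) = mu_j, in additive mode x̄_jd − mu_j d_jd =
mu_j. The two corrections are related by the identity
rel − add = d·(mu − rel); they agree to first order whenever both the
deviations and the residual spread around the day mean are small. The
estimator is an unconstrained per-sensor per-day table; the rank-1
(common-direction) structure is used only by the simulator and by the
`rank1_share` diagnostic (share of the deviation table's energy on its
first singular direction).

Numerical guards: relative mode requires |mu_j| > 1e-8 × control sd
(scale-aware) and |1 + d| > 1e-6; both raise named errors rather than
producing NaN. A day with no controls is a hard error by default —
silently extrapolating drift is the failure mode the correction exists to
prevent — with an opt-in `pool_adjacent` that borrows the nearest covered
day's deviations. Both cases and controls are corrected by default (a
joint classifier needs all samples on one footing); `restrict_to_cases`
is available. Correction is fitted once on the full control set, not
re-estimated inside cross-validation folds.

### Residual type-I inflation under confounded allocation

The correction is a plug-in estimate. Corrected case and control groups
differ by −mu·Σ_d w_case,d η_d plus case sampling noise, where η_d is the
relative estimation error of the control day-mean and w_case,d the case
day weights; the control group's corrected mean equals the overall control
mean exactly. Under balanced allocation Σ w²_d/n_ctrl,d = 1/n_ctrl and the
correction costs nothing. Under confounded allocation the weights
concentrate where controls are no more numerous, the variance ratio rises
(≈1.09 at severity 2/3 with 63 controls) and the per-sensor level at
nominal 0.05 is ≈0.06 instead of 0.05 — measured at 0.0607 over 1000
simulated replicates. Correction therefore removes essentially all of the
confounding (uncorrected level ≈0.18 at g₀ = 0.1, severity 2/3) but not
exactly all; the residue grows with confound severity. This quantifies,
rather than contradicts, the standing advice to spread cases and controls
evenly over measurement days.

## Diagnostics (diagnostics)

Scaling is the usual per-sensor z-score with sample (n−1) standard
deviation; constant sensors raise a named error. Spearman correlation uses
average ranks for ties. PCA is an SVD of the column-centered scaled matrix
with the sign of each component fixed by making its largest-|loading|
entry positive.

The day-separation score condenses "do samples cluster by measurement
day?" into one number in [−1, 1]: the maximum, over contiguous temporal
bipartitions of the ordered day vocabulary, of the mean silhouette of the
two blocks in PC1/PC2 space. A per-day-label silhouette was considered and
rejected: under two-block drift, adjacent days are distributionally
identical, each day's nearest competing cluster is its coincident
neighbour, and the per-day silhouette is ≈0 both before and after
correction. Scoring temporal bipartitions targets the changepoint
structure that shared drift actually produces (≈0.55 before vs ≈0.1 after
correction on the demo scenario); for two days the definitions coincide.

Heatmap matrices are row-ordered deterministically by (group, day,
sample_id), with optional average-linkage clustering; values are passed
through unchanged.

## Testing and selection (group_stats)

The per-sensor two-group comparison defaults to the two-sided Mann-Whitney
U: exact null distribution for groups of at most 8 (full enumeration when
ties are present), normal approximation with tie and continuity correction
otherwise. Welch's t is available; a fully tied pooled sample yields the
degenerate p = 1, and zero variance in both groups with distinct means is
an error. Selection keeps sensors with p < alpha (default 0.05) on raw
p-values by default, mirroring small-panel practice of reporting a handful
of raw p-values; Benjamini-Hochberg is available behind a flag.

## Classification (classify)

Logistic regression is fitted by iteratively reweighted least squares
(convergence: max coefficient change < 1e-8, at most 100 iterations).
Complete separation is detected (diverging linear predictor with a
perfectly classified training set), flagged, and the last iterate's
probabilities are still returned. The positive class is IBD and
probabilities are oriented as P(IBD).

LOOCV refits the model on each leave-one-out training fold. The default
`fixed` selection policy uses one subset selected on the full data in every
fold — deliberately mirroring common practice, and logged as carrying
selection leakage; the `nested` policy re-runs testing + selection inside
every fold. On null data the fixed policy is measurably optimistic
relative to nested (its out-of-fold accuracy exceeds the nested one on
average), which the test suite asserts as a property.

The cut-off maximizes Youden's J (default) or accuracy over the midpoints
of adjacent sorted unique out-of-fold probabilities plus 0.5, with ties
broken toward 0.5. A probability at the cut-off counts as a positive call.
Reports carry the confusion counts, accuracy, sensitivity, specificity,
PPV, NPV (conventionally rounded to 2 decimals alongside full precision)
and the cut-off-free Brier score, mean (p_i − y_i)².

One LOOCV pathology is worth knowing: with an empty sensor subset the
intercept-only out-of-fold probabilities anti-correlate with the label
(holding out a case lowers the training prevalence), so a degenerate
pipeline can score below chance. This is the honest LOOCV answer for a
model with no predictors, not a bug, and it contributes to the large
corrected-vs-uncorrected accuracy gaps under strong confounded drift.

## Pipeline (cli / pipeline)

`run_pipeline` executes simulate/load → diagnose → correct → test →
classify, writing ten artifacts in fixed order plus a manifest (config
echo, seed, SHA-256 checksums, summary). All artifacts are byte-deterministic
given the configuration, so reruns can be compared checksum-by-checksum and
`compare_runs` reports summary deltas between two runs on the same input
panel. One master seed drives the simulation; LOOCV and all estimators are
deterministic and need none.

## Problem sizes used by the checks

Simulation-based checks run at the study scale (63 + 63 samples, 32
sensors, 4 days). Calibration fractions pool 200 replicates × 32 sensors
with the subject factor off, so the per-sensor tests are independent and a
binomial reference for the pooled rejection fraction is valid. Drift
recovery uses 20 replicates at 50/200/400 controls; paired end-to-end
comparisons use 20 seeds. These sizes give standard errors comfortably
below the asserted margins.

## Known limitations

- The generator's Gaussian noise, single latent subject factor and exact
  rank-1 drift are idealizations; real arrays show heavier-tailed noise,
  several latent factors and partially sensor-specific drift. Passing
  recovery tests show the estimators work under the stated model, not that
  real drift is rank-1.
- Controls are assumed day-exchangeable; any real day structure in control
  biology is absorbed into the "drift" and removed from everyone.
- The plug-in correction's residual type-I inflation under confounded
  allocation (above) is intrinsic to correct-then-test designs.
- Long-term aging drift, blank-sample recalibration and physical sensor
  modelling are out of scope.
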