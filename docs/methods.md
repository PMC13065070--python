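# Methods

This note documents the statistical procedures implemented in
`timeuse_coda`, the choices made where the design was genuinely open, and
what the synthetic-data checks do and do not establish.

## Diary model and validity filters

A diary is one person-day of 144 ten-minute slots covering 04:00–04:00;
slot k covers [04:00 + 10k, 04:00 + 10(k+1)), 0-based (the indexing
convention is ours; nothing downstream depends on it). Each slot carries
one activity code; the code→behaviour-set mapping is configurable via CSV
because instrument codebooks differ, and the shipped default assigns
plausible codes for twelve diary categories to the six sets. Recoding is a
slot count × 10, so recoded parts always sum to 1440 exactly.

A diary is rejected as an unreliable account of a complete day if (in fixed
priority order) any slot is unfilled (`missing_data`), it contains no sleep
(`no_sleep`), or no domestic/personal-care time (`no_domestic`) — the
domestic set includes routine necessities such as dressing and eating, so
its total absence indicates under-reporting rather than true absence.
Complete-case assembly applies filters in the order covariates → diary
validity → outcome and logs the count removed at each step; the order is
part of the contract so removal logs are comparable across runs.

Weekend analyses use the four-part subcomposition {sleep, media, hobbies,
domestic}, re-closed to 1440, because physical activity and school-related
time are too scarce on weekend days to support meaningful reallocations.
Validation is applied before subcomposition; zero replacement is applied
after it, on the composition actually analysed.

## Compositional core

* **Closure** rescales non-negative parts to a fixed total (1440 min);
  conservation is asserted to 1e-6 after every composition-producing
  operation.
* **Multiplicative zero replacement** sets zero parts to δ minutes
  (default δ = 5 — half the slot resolution; any value in (0, 10) is
  accepted) and scales non-zero parts by (1440 − δz)/1440. This preserves
  ratios among non-zero parts exactly (one common factor) and keeps the
  total at 1440. Structural zeros are expected at ten-minute resolution and
  carry no "true zero" meaning; alternative replacement schemes
  (Bayesian-multiplicative, lrEM) are out of scope.
* **Compositional mean**: part-wise geometric mean re-closed to 1440;
  requires strictly positive input.
* **ILR basis**: pivot (sequential binary partition) coordinates, with
  coordinate j contrasting part j of the pivot order against all later
  parts, normalising constant √((D−j)/(D−j+1)). Orthonormality is enforced
  at construction to 1e-10. The pivot order is configurable but immaterial
  for every quantity this package reports: substitution estimates and the
  joint F test are invariant to the choice of orthonormal basis (asserted
  to 1e-9 in tests), so no particular partition tree needs defending.
  Natural logarithms throughout. ILR round-trip accuracy is asserted under
  1e-9 on random compositions.

## Outcome model

OLS of the outcome on [1, ILR coordinates, covariate dummies] with
classical covariance s²(XᵀX)⁻¹. Covariates are treatment-coded with the
modal category as reference (configurable); the reference choice
reparameterises the covariate block only and does not affect ILR
coefficients or substitution estimates. Age is not in the default covariate
set but any extra categorical column can be supplied. Rank deficiency is
detected by pivoted QR and reported with the aliased column names rather
than silently pseudo-inverted. The compositional block is tested with a
nested-model F test against the covariates-only fit (df₁ = D−1) — the
standard choice for a jointly entered coordinate block; single-coordinate
models reduce to the squared t statistic exactly. Included-vs-excluded
comparisons use Welch t-tests for continuous variables and Pearson
chi-square without continuity correction for categoricals.

## Isotemporal substitution

Substitution adds Δ minutes to one part and removes Δ from another at a
base composition, leaving the total fixed. The base defaults to the
analytic sample's compositional mean (overridable). Feasibility requires
all substituted parts strictly positive, since ILR is undefined at zero;
infeasible cells in tables and grids are flagged, not fatal. The point
estimate is the linear ILR contrast; the SE is the delta-method quadratic
form in the ILR block of the coefficient covariance; the 95% CI uses the t
distribution with residual df (the CI method is a choice — bootstrap or
profile intervals would be alternatives — and is labelled as Wald).
Defaults are Δ = 20 min and a ±20-min grid on weekdays, Δ = 30 and ±30 at
weekends, in 5-minute steps. Estimates for (add A, remove B) and (add B,
remove A) are both reported and are genuinely asymmetric on the simplex;
no symmetrisation is applied. Report tables round to 2 decimals; CSVs keep
full precision.

## Synthetic cohort generator

The generator exists to give the pipeline inputs with known ground truth.

* **Composition law**: logistic-normal — Gaussian ILR draws centred at the
  ILR image of a target geometric-mean profile with covariance `ilr_scale`,
  inverted to the simplex and closed to 1440. This matches the analysis
  model, which is what makes the noiseless-recovery check exact; a
  Dirichlet law would not.
* **Defaults**: the weekday target profile is (sleep 897, PA 23, media 143,
  school 50, hobbies 61, domestic 266) min and the weekend profile
  (852, 202, 114, 272) min — realistic adjusted geometric means for a
  mid-adolescent cohort, each summing to 1440. `ilr_scale` defaults to a
  diagonal with per-coordinate SDs (0.15, 0.80, 0.60, 0.70, 0.70) on
  weekdays and (0.15, 0.60, 0.70) at weekends: the sleep-vs-rest balance
  varies little across adolescents while scarce behaviours vary greatly on
  the log scale (their raw means far exceed their geometric means, as heavy
  right-skew requires). Covariate frequencies put 54.2% female, 79.7% White
  British, 7.1% FSM-eligible and 38.3% of mothers at degree level; the
  remaining mass of each distribution is split across the other census /
  NVQ categories with fixed plausible values, since only modal shares are
  typically published. Outcome defaults: intercept 60, residual SD 13 and
  covariate effects of a few attainment points, chosen to give outcome
  spread resembling an Attainment 8 distribution (mean ≈ 56, SD ≈ 16);
  ILR effects (−4, 3, 1, −1.5, 0.5) weekday and (−3, 1, 1.5) weekend give
  20–30-minute substitution effects of order 0.1–6 points.
* **Grid rounding**: continuous compositions are rounded to the 10-minute
  grid by largest-remainder apportionment (floor in grid units, then give
  leftover units to the largest fractional remainders, ties by part order),
  so every generated composition sums to 1440 exactly and zeros arise
  mechanically from the grid — the same way diary zeros arise — rather than
  from an explicit zero-inflation mixture.
* **Outcome**: linear in the ILR coordinates of the *zero-replaced*
  composition plus covariate dummy effects plus Gaussian noise. Clipping to
  [0, 90] is off by default (it would break the linearity that recovery
  tests assert) and warns when enabled.
* **Diary expansion**: each behaviour occupies contiguous blocks; sleep is
  anchored at both ends of the 04:00–04:00 window, other sets are placed in
  random order between. Corruption switches (`missing_slot_rate`,
  `zero_sleep_rate`) blank slots or relabel sleep to exercise the validity
  filters. Expansion followed by recoding reproduces the source composition
  exactly when corruption is off.
* **Determinism**: every stage draws from its own stream derived from
  (seed, stage salt), so identical truth + seed gives byte-identical
  outputs. Weekday and weekend cohorts are generated independently; no
  within-person correlation across day types is modelled.

What the generator does *not* emulate: circadian sequencing and school
timetables, multi-day correlation, reporting biases, or any real-world
deviation from the linear logistic-normal model. Passing recovery and
coverage tests therefore demonstrates the estimator machinery is correct
under its own assumptions, not that those assumptions hold in real diary
data.

## Numerical and validation choices

* Tolerances: closure 1e-6, ILR round-trip 1e-9, basis orthonormality
  1e-10, oracle equivalence 1e-10, noiseless recovery 1e-8.
* `ilr_inverse` subtracts the row-max log before exponentiating to avoid
  overflow; closure removes the shift exactly.
* Simulation-study sizes: noiseless recovery at n = 2000; CI coverage at
  500 replicates of n = 2000; type-I error at 1000 null replicates of
  n = 500. At 500 replicates a coverage estimate carries a Monte-Carlo
  standard error of about 1 percentage point, so individual per-coefficient
  estimates a little beyond ±2% of nominal are compatible with exact
  calibration.
* The imputed zero-replacement value is exposed (`impute_minutes`) rather
  than fixed, so sensitivity over (0, 10) can be examined directly.

## Known limitations

* Single-day diaries per day type; duplicate (participant, day type)
  diaries are a format error, never averaged.
* Complete-case analysis only; no imputation, weighting or mixed effects.
* The default activity mapping is a configurable stand-in, not a validated
  codebook; real analyses should supply their instrument's mapping CSV.
* Wald CIs rely on the homoscedastic Gaussian linear model; no robust or
  bootstrap variants are provided.
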