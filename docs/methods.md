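# Methods

This note documents the models and conventions implemented in
`thermacclim`, the design choices made where the convention was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Respirometry (whole-animal)

Each measurement period is fitted by ordinary least squares of O₂
concentration (µmol l⁻¹) on time; the consumption-positive magnitude of
the per-minute slope is K. A flat trace has undefined R² (zero response
variance); it is reported as NaN and always fails the quality filter
rather than passing vacuously.

* **Quality filter** `min_r_squared = 0.9`: periods disturbed by fish
  activity or bubbles are non-linear and excluded. The retained count is
  non-increasing in the threshold (tested as a property).
* **Background correction** is applied at the slope (K) stage, per
  chamber, before rate conversion. Because MO₂ = K·V is linear in K,
  pre- and post-conversion correction give identical MO₂; correcting
  first lets a physically impossible negative corrected slope be caught
  early — such periods are flagged missing, never clamped to zero.
  Whether the SMR percentile should be taken before or after background
  correction is not standardized in the field; this package corrects
  first (each replicate rate is a corrected rate).
* **MO₂ = K·V** with V = chamber volume − organism volume. Organism
  volume is body mass × (1 ml g⁻¹): fish are close to neutrally
  buoyant, so density 1 is the natural default (configurable).
  O₂ molar mass defaults to 31.998 g mol⁻¹.
* **SMR** is the `smr_percentile = 0.10` quantile of ≥20 replicate MO₂
  values, computed by linear interpolation between order statistics
  (position 1 + (n−1)p of the sorted sample). This convention returns a
  value lying on the empirical CFD curve — the requirement that
  motivated percentile-based SMR in the first place — and is strictly
  order-statistic based, unlike tail averaging which is outlier
  sensitive. Individuals with fewer than `min_replicates = 20`
  surviving rates are excluded with a logged reason.
* Period lengths (12 min at 12 °C, 6 min at 28 °C, reflecting the time
  needed for a ~10% O₂ drawdown) are treated as metadata; no stage
  enforces them.

## Cardiac micro-respirometry

The analysis window is the final 3 of 6 minutes — the first half of a
run is a settling period (temperature equilibration, chamber mixing) and
is ignored. The windowed OLS slope, minus the mean slope of the matching
chamber-day's blank runs, times the chamber volume (default 1 ml),
gives CaM in pmol O₂ s⁻¹ (µmol s⁻¹ × 10⁶).

* Blanks are matched by (chamber, day); when more than three exist, all
  are averaged — "the day's blanks" is the estimator of that chamber's
  leak on that day. Fewer than three is an error naming the chamber-day.
* Negative blank-corrected rates are retained and flagged, not clamped:
  clamping would bias population summaries upward.
* The glycolytic-inhibition chemistry behind the substrate sequence
  (glucose first, then inhibitors, then FA/LKA/END) is represented only
  by the ordered substrate labels; no kinetics are modelled.

## Allometric mass correction

WAM scales as a power law and is fitted log₁₀–log₁₀; CaM and CT_max are
fitted linearly against mass. Fits are per acclimation temperature,
because acclimation itself changes the mass relationship. Corrections
are computed on the fitting scale:

    Y = observed − predicted(mass)
    X_corrected = predicted(reference mass) + Y

with `reference_mass_g = 10.2`. For log-scale traits the corrected value
is also back-transformed to natural units, and both are emitted —
summaries of a lognormal-ish trait differ between scales and neither
alone is complete. Sample SD (n−1) is used throughout. The heart-mass
covariate path is the same code with a different mass column.

CVs are 100 × sample SD / mean; the per-trait ratio CV₁₂/CV₂₈
summarizes where interindividual variation concentrates.

## Plasticity

Per-individual response = log₂(value₂₈/value₁₂), defined only when both
values are positive; the log₂ scale symmetrizes up/down responses and is
approximately normal. Group-level summaries separate two questions:
**fold change** uses mass-corrected means (a size-independent effect
size), while **Q₁₀ = (R₂/R₁)^(10/(T₂−T₁))** uses raw means (the thermal
sensitivity of the measured rates). The "low/mid/high plasticity"
classes use the empirical 10th/90th percentiles of the response
distribution (same quantile convention as SMR) — a distributional
reading of "bottom/top 10% confidence interval"; ties at a cutpoint
fall in "mid". Plasticity-versus-baseline regressions default to mass
residuals for metabolic traits and raw values for CT_max, whose mass
dependence is negligible.

## Trait networks

Partial correlations come from the inverse of the correlation matrix of
complete cases (r_ij·rest = −Ω_ij/√(Ω_iiΩ_jj)); p-values use
t = r√((n−2−k)/(1−r²)) with k = number of controlled traits.
Listwise deletion is used within each temperature: the alternative
(pairwise) produces non-positive-definite matrices. A condition number
above 10¹² is treated as singular and reported with the collinear
pairs. Bonferroni control uses m = 15 (the unique pairs of six traits)
per temperature.

Variance partitioning is a fixed-effects, **sequential (type I)**
decomposition: terms enter in the caller's order (logged), each term's
share is its extra sum of squares as a percentage of the total, and the
percentages plus the residual sum to 100. It is implemented as nested
OLS fits with explicit dummy coding so the entry order is exactly the
caller's; per-term F tests use the full model's residual mean square,
and aliased terms are kept with zero share and NaN p-value. Random
effects are deliberately not implemented: mixed-model variance
statements are reproduced structurally as fixed-effects partitions, a
documented limitation. Partial η² is the obvious alternative estimator;
sequential SS was chosen because it sums to 100% and makes the entry
order explicit rather than hiding it.

## Synthetic-data generator

Defaults are the study conditions: ~160 fish from three populations
(equal shares), lognormal body mass with mean 10.2 g and CV 0.30,
allometric exponent b = 0.8 for WAM, the reference per-trait
mass-corrected means and SDs at both temperatures, ≥25 measurement
periods per respirometry run, and four 6-minute cardiac runs per heart
with three blanks per chamber-day.

Construction, per trait:

1. **12 °C mass-corrected values** are drawn first — lognormal for
   rates (strictly positive), Gaussian for CT_max (SD ≪ mean, roughly
   symmetric). The acclimation-order effect is a symmetric ±δ/2
   additive shift on 12 °C values only (defaults: WAM +0.3 mg O₂ h⁻¹
   higher for fish assayed cold-first; CT_max 0.8 °C higher for fish
   assayed warm-first), with the shift variance budgeted into the draw
   so the configured 12 °C moments still hold.
2. **28 °C values** are value₁₂ × 2^plasticity, with plasticity =
   intercept + slope × z(12 °C performance) + Gaussian noise. The
   intercept and noise SD are calibrated in closed form against the
   realized cohort (matching the expected sample mean and mean square
   over the noise) so the 28 °C moments hit their configured targets
   regardless of the coupling slope. The default slope (per trait)
   exactly cancels the baseline's contribution to the 28 °C spread:
   warm-acclimation values become independent of cold performance,
   which reproduces the observed pattern — no overall 12↔28
   correlation, strongly negative plasticity-versus-12 °C regressions
   (R² ≈ 0.86 for CT_max at study n), and 28 °C CVs below 12 °C CVs.
   Setting the slope to 0 (with an explicit noise SD) gives a null
   cohort for calibration tests; a user-set noise SD takes precedence
   over the SD-matching calibration.
3. **Observed values** add mass dependence: WAM × (mass/10.2)^b;
   CaM + 1.5 pmol s⁻¹ g⁻¹ × (mass − 10.2); CT_max + 0.05 °C g⁻¹ ×
   (mass − 10.2). The linear slopes were chosen to give mass R² in the
   0.1–0.4 range typical of these assays given the default mass spread.
4. **Traces** invert MO₂ = K·V per period. Per-period rates are
   SMR × exp(a) with a ~ N(1.2816σ, σ) (σ = `activity_sigma`, default
   0.12): the population 10th percentile of replicate rates is then
   exactly the true SMR, so the pipeline estimate is centred on truth.
   Background drift (0.02 µmol O₂ min⁻¹ l⁻¹) and Gaussian sensor noise
   (0.3 µmol l⁻¹) are added; contaminated periods (a configurable
   fraction) get a three-cycle sinusoidal excursion with amplitude tied
   to the clean decline, constructed to fail the R² ≥ 0.9 filter even
   at zero noise.
5. **Cardiac runs** decline at 1.3× the true slope during the settling
   half and exactly the true slope in the analysis window; blanks carry
   background leak only (0.002 µmol l⁻¹ s⁻¹). Hearts are larger after
   cold acclimation (cardiosomatic index 0.0035 vs 0.0028), emulating
   cold-induced cardiac remodeling.

All randomness flows from `numpy.random.default_rng` seeded with
(config seed, stage index), so cohort, trace and cardiac generation are
individually and jointly reproducible; identical (seed, config) gives
identical output.

**What the generator does not emulate:** within-individual
repeatability structure for CaM (noise is calibrated only to
cross-sectional SDs), tidal/field temperature regimes, attrition and
survival, population-level trait divergence (population labels carry no
effect by default), and the measurement-order correlation structure of
a real overnight respirometry run (periods are exchangeable given the
activity draw). Passing recovery tests therefore demonstrates that the
estimators invert the assumed measurement model, not that real data
satisfy that model.

## Numerical choices and test calibrations

* Quantiles: linear interpolation between order statistics everywhere
  (SMR, plasticity cutpoints); the convention is configurable in the
  sense that `empirical_quantile` is the single shared implementation.
* Zero-noise recovery is exact (≤1e-9 relative, asserted): the
  generator and pipeline share no code path beyond the unit constants.
* Under study-condition noise, SMR recovery error is dominated by the
  sampling noise of a 10th percentile from ~25 replicates
  (≈4% relative SD at σ_activity = 0.12), not by slope-fit error; the
  recovery test therefore asserts ≥90% of individuals within 7.5% of
  truth, a tolerance fixed from this calibration.
* Moment-matching tests allow 3 standard errors on means and 3.5 on
  SDs — the normal-theory SE of an SD understates the sampling
  variability of a lognormal SD, and the wider band accounts for that
  excess kurtosis without loosening the mean check.
* Problem sizes: oracle-agreement tests use 6 traits × 60 individuals;
  CI-coverage uses 100 cohorts of 500; the type-I-error calibration
  uses 500 single-trait cohorts of 200; group-level summaries in the
  acceptance script use a 5000-fish cohort (cohort-level path) and a
  20-fish cohort for the full trace-level path. These sizes give
  stable statistics while keeping the whole suite fast.

## Known limitations

* Instrument file formats (e.g. PreSens exports) are not parsed; input
  is generic long-format CSV.
* Maximum metabolic rate and aerobic scope are out of scope, as are
  thermal performance curves (only two temperatures are modelled).
* The CT_max reference moments carry an internal oddity in their
  source (mass-corrected means ~10 °C below raw means, which a
  reference-mass correction cannot produce); the generator treats the
  corrected values as the targets and derives raw means through the
  small configured mass slope, so its raw CT_max means sit near the
  corrected ones rather than near the source's raw entries.
* Fixed-effects variance partitions are not mixed models; percentages
  for terms that would be random effects elsewhere are structural
  analogues, not variance components.
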