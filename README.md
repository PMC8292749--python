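# thermacclim

Analysis pipeline for thermal-acclimation physiology in small fish:
from raw oxygen traces to individual metabolic and thermal-tolerance
traits, mass-corrected summaries, acclimation-plasticity metrics and
temperature-specific trait correlation networks.

## The scientific problem

Ectotherms acclimated to different temperatures change their physiology.
Quantifying *how much*, and *which individuals change most*, requires a
chain of standard but fiddly computations:

* **Whole-animal metabolic rate (WAM).** In intermittent-flow
  respirometry a fish sits in a sealed chamber for repeated measurement
  periods; each period's oxygen decline is fitted by OLS, giving a slope
  K (µmol O₂ min⁻¹ l⁻¹). Poor fits (R² < 0.9) are discarded, the
  chamber's background (microbial) respiration is subtracted, and the
  rate is converted by **MO₂ = K·V** (V = chamber volume minus organism
  volume) to mg O₂ h⁻¹. The **standard metabolic rate (SMR)** is the
  10th-percentile value of an individual's ≥20 replicate rates, read off
  the cumulative frequency distribution (interpolated order statistics)
  rather than averaged from the tail.
* **Cardiac metabolic rate (CaM).** Excised ventricles respire in 1 ml
  chambers with four sequential fuels — glucose (GLU), fatty acids (FA),
  lactate+ketones+ethanol (LKA) and endogenous (END) — for 6 minutes
  each; the O₂ slope over the final 3 minutes, minus the mean of that
  chamber-day's ≥3 blank runs, times chamber volume, gives pmol O₂ s⁻¹.
* **Mass correction.** Traits are regressed on body mass (log₁₀–log₁₀
  for WAM, linear for CaM and CT_max) within each acclimation
  temperature, and each individual's value is re-expressed at a
  10.2 g reference: X_corrected = X_mean(10.2 g) + residual.
* **Plasticity.** An individual's acclimation response per trait is
  log₂(value at 28 °C / value at 12 °C); 0 means perfect compensation.
  Group-level sensitivity is the fold change of mass-corrected means and
  **Q₁₀ = (R₂/R₁)^(10/(T₂−T₁))** of raw means. Individuals are classed
  low/mid/high by the 10th/90th percentiles of the response
  distribution, and plasticity is regressed on 12 °C performance.
* **Trait networks.** Within each temperature, partial correlations
  among the six mass-residual traits (inverse-correlation-matrix form,
  t-based p-values, Bonferroni over the 15 pairs) plus a sequential
  fixed-effects variance partition over design terms (mass, temperature,
  order, sex, population).

A seeded synthetic-data generator (`thermacclim.synthetic`) emulates all
of these inputs — cohorts with realistic trait moments, raw respirometry
traces and cardiac runs with known ground truth — so the entire chain is
testable without any external download.

## Worked example

```bash
thermacclim all --seed 1 --n 160 --out runs/demo
```

simulates a 160-fish cohort, re-derives WAM from ~25 measurement periods
per fish per temperature and CaM from blank-corrected cardiac runs, then
mass-corrects, computes plasticity and trait networks. The
`trait_summary.csv` from that run includes (rounded to 2 dp):

```
  trait  acclimation_temp   n  raw_mean  corrected_mean    cv  fold_28_12  q10
    WAM              12.0 158      1.82            1.80 32.11        2.40 1.73
    WAM              28.0 160      4.38            4.31 32.27         NaN  NaN
CaM_END              12.0 160     28.88           28.41 37.52        0.61 0.74
CaM_END              28.0 160     17.97           17.44 39.34         NaN  NaN
 CT_max              12.0 160     26.30           26.28  2.84        1.23 1.14
 CT_max              28.0 160     32.47           32.45  1.03         NaN  NaN
```

Read: warm acclimation raises whole-animal metabolism ~2.4-fold
(Q₁₀ ≈ 1.7, well below the passive expectation of 2–2.5, i.e. an active
but incomplete acclimation response); endogenous cardiac metabolism
*drops* at 28 °C (fold 0.61); thermal tolerance shifts by a factor 1.23
with far less interindividual variation (CV) at the warm acclimation.
`plasticity_regressions.csv` from the same run shows the negative
coupling between 12 °C performance and the log₂ response (slope −0.052,
R² = 0.86 for CT_max): the weakest performers in the cold mount the
largest acclimation responses.

The same stages are available as library functions
(`thermacclim.respirometry.estimate_smr_from_traces`,
`thermacclim.cardiac.compute_cam_table`,
`thermacclim.allometry.mass_correct_trait_table`, …) and as per-stage
CLI subcommands (`simulate`, `wam`, `cam`, `correct`, `plasticity`,
`correlate`) operating on plain CSV files.

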