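# Methods

## The decay model

Layer thickness after occlusion is modelled as
`thickness(d) = plateau + (initial − plateau)·exp(−k·d)`, with
`initial` the day-0 thickness (μm), `plateau` the asymptotic thickness
(μm) and `k` the decay constant (per day).  The model assumes a single
exponential phase; the acute edema peak seen in the first days after a
CRAO is not modelled separately.  For that reason `initial` is *not*
constrained to exceed `plateau` during fitting: an apparently rising fit
(early swelling) is representable and simply flagged by its parameters,
never rejected.  `plateau ≥ 0` and `k ≥ 0` are enforced as bounds.

Observations are pooled across eyes into one population curve per layer
(per-eye curves are available but not the default), with control
(contralateral, non-affected) eyes entering as day-0 baseline points.
Controls are treated as a day-0 cross-section because their thicknesses
are stable over the study horizon; whether to pool them is a switch
(`include_controls`, default on).

## Fitting and inference

The sum of squared residuals is minimised by a bounded trust-region
Levenberg–Marquardt-type solver (`scipy.optimize.least_squares`,
`method="trf"`), multi-started from five deterministic initialisations:
`initial₀` = thickness at the earliest day, `plateau₀` = minimum
observed thickness, and `k₀` from a log-linear regression of
(thickness − 0.9·plateau₀) against day, scaled by {0.2, 0.5, 1, 2, 5}.
The best SSR wins; ties cannot occur in practice because the starts
converge to the same basin or are strictly ordered.  Tolerances are
1e-12 on cost, step and gradient with at most 2000 function
evaluations; non-convergence is reported, never silently ignored.
Fits need at least 4 points spanning at least 2 distinct days.

Reported per fit:

- **R²** = 1 − SS_res/SS_tot about the observed mean.  Undefined (NaN)
  for constant observations, in which case the significance gate fails.
- **RMSE** = √(SS_res/(n − 3)), the regression estimate of the
  experimental error; this σ feeds the power calculations.  The n − 3
  denominator accounts for the three fitted parameters.
- **Significance gate**: R² strictly greater than 0.4.  This is the
  study convention for calling a layer's decay biologically meaningful;
  it is deliberately blunt (residual diagnostics on real data fail, so
  p-values from the fit are not trusted).
- **Covariance / confidence bands**: asymptotic parameter covariance
  s²(JᵀJ)⁻¹; pointwise bands by first-order propagation through the
  model gradient with a t quantile on n − 3 degrees of freedom.

## Residual diagnostics

Normality: the D'Agostino–Pearson omnibus test.  Sample skewness and
kurtosis are transformed to approximate standard-normal deviates
(D'Agostino's skewness transform; Anscombe–Glynn for kurtosis, via
`scipy.stats.skewtest`/`kurtosistest`) and K² = Z₁² + Z₂² is referred to
χ²(2).  The transforms are asymptotic, so the default sample floor is
n ≥ 20 (overridable down to 8, with a warning).  Homoscedasticity: a
Breusch–Pagan score test regressing squared residuals on fitted values,
n·R²_aux against χ²(1) (via statsmodels).  The study's software used an
unnamed built-in homoscedasticity test; Breusch–Pagan on fitted values
was adopted here as a transparent equivalent with the same null.
Diagnostics are attached to every fit but never block the pipeline —
the analysis proceeds on the R² gate regardless, which mirrors how such
cohorts are actually analysed (real residuals fail both tests).

## Trial design

For a trial ending at day *x*: `T_x` is the fitted untreated thickness,
and a drug of efficacy *e* ∈ [0, 1] (fraction of loss prevented) yields
the expected treated thickness `(T0 − T_x)·e + T_x`, where `T0` is the
control-eye baseline.  The detectable difference is δ = e·(T0 − T_x).
Per-group sample size is the smallest integer n such that a two-sided
two-sample t-test (equal arms, common σ) reaches the target power at
true difference δ, computed by walking the exact noncentral-t power
(df = 2n − 2, noncentrality δ/(σ√(2/n))) from the normal-approximation
start 2(z₁₋α/₂ + z_power)²(σ/δ)².  Defaults: α = 0.05, power = 0.8,
σ = the layer's fit RMSE, floor n = 2 (the minimum for a t-test;
configurable).  Noncentral-t iteration was chosen over the bare normal
approximation because the small-n cells of a realistic table (n = 3–9)
differ visibly between the two.  No multiplicity adjustment is applied
across layers, days or efficacies — each cell answers its own planning
question.

Baseline `T0` may be either the control-eye mean or the fitted day-0
intercept; both are supported.  The published endpoint columns this
package uses as worked examples are internally consistent with single
decay curves at days 30–180 (refit residuals ≤ 0.04 μm) but not with
their printed baselines (the implied RNFL intercept is ~30.7 μm against
a 22.5 μm control mean — early swelling inflates the fitted intercept),
which identifies those baselines as control means.  Consequently the
published-column refits used in validation fit the endpoint cells
(days 30–180); the held-out day-60 check additionally includes the
printed day-0 baseline, as its definition prescribes.  Thicknesses are
rendered at one decimal (half-up) and n as integers only at report
time; all internal arithmetic is full precision.

## The synthetic cohort generator

The generator emulates the features the analysis relies on:

- **Cohort shape** (defaults): 19 CRAO patients, 15 control eyes, 1–8
  scans per patient, follow-up capped at 951 days.  Visit days are
  integers sampled without replacement with right-skewed weights
  (∝ (1 − d/D)⁴), reflecting dense acute-phase recall; the true visit
  distribution of real cohorts is unpublished, so this is a modelling
  choice exposed in the config.
- **Curves**: per patient and layer, decay parameters are drawn around
  per-layer population presets — Gaussian between-patient spread (6% of
  the mean) on `initial` and `plateau`, log-normal (log-SD 0.15) on `k`.
  The presets for the inner layers are back-fits of published untreated
  endpoint columns (e.g. GCL ≈ (47.5, 12.3, 0.037)); outer layers are
  stable (k = 0) at normative thicknesses, and central macular thickness
  gets a mild decay.  Presets make defaults *resemble* a real case
  series; they are not patient-level truth.
- **Composites**: INNER = RNFL + GCL + IPL + INL and RETINA = INNER +
  OPL + ONL + OUTER + RPE hold exactly before noise.  Real segmented
  data does not obey these identities (published composite baselines are
  inconsistent with their printed components), so composites are never
  recomputed from components on observed data — they are observed
  layers in their own right.
- **Noise**: additive Gaussian per layer, homoscedastic by default
  (2–8 μm depending on layer scale); a heteroscedastic option scales the
  SD with the predicted thickness for stress tests.  A global
  `noise_sd` override sets all layers at once.
- **QC**: each scan fails segmentation QC independently with
  probability 0.05 by default.
- **Determinism**: every draw derives from `seed` through per-patient
  seed sequences, so cohorts are reproducible field-for-field and visit
  schedules can be regenerated standalone.

What the generator does *not* emulate: the acute edema peak (curves
decay from day 0), informative dropout, cilioretinal-artery sparing
subpopulations, and real segmentation-error structure.  Passing
recovery tests therefore shows the estimator works when its model holds
(plus benign heterogeneity), not that real cohorts are this clean.

## Calibration experiments and problem sizes

The validation suite runs, at sizes chosen to give stable Monte-Carlo
estimates on a single CPU:

- **Power oracle**: 20 000 simulated t-tests per cell on the grid
  δ/σ ∈ {1.2, 2.0, 2.5} × α ∈ {0.01, 0.05, 0.10}.  The grid sits in the
  small-n regime typical of the trial table's stronger-efficacy cells,
  where integer rounding of n leaves a measurable power gap at n − 1;
  at large n the true power at n − 1 approaches 0.8 from below closer
  than Monte-Carlo resolution, and minimality is meaningful only as the
  exact noncentral-t statement.
- **Diagnostics calibration**: K² type-I error over 10 000 normal
  samples of n = 60 (the pooled-fit regime, ~60–90 points per layer);
  Breusch–Pagan over 2 000 replicates of n = 200.  The K² omnibus runs
  slightly hot at n = 60 (true rate ≈ 0.057 against nominal 0.05), a
  known small-sample property of the asymptotic transforms.
- **Parameter recovery**: 100 replicated cohorts of 19 patients with
  4–8 visits and 2 μm noise, fitted and compared to truth; between-
  patient random effects are switched off here because the experiment
  calibrates the fitter against its own iid-noise model (the confidence
  band's coverage statement is defined under that model).  Observed:
  median relative error of k̂ ≈ 3%, band coverage at day 60 ≈ 95%.

## Known limitations

- Single-phase decay only: no edema-then-decay piecewise model, no
  mixed-effects formulation (pooling ignores within-eye correlation, so
  pooled-fit standard errors are optimistic for clustered data).
- Unweighted least squares, per the source analysis, even though real
  residuals are heteroscedastic.
- The sample-size model assumes two independent arms with common SD
  equal to the fit RMSE; repeated-measures designs, dropout inflation
  and unequal allocation are out of scope.
- Published sample-size cells cannot be reproduced exactly because the
  per-layer σ behind them is unpublished; the power machinery is
  validated against a simulation oracle instead.
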