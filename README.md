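# octdecay

Exponential-decay modelling of retinal-layer thinning after central
retinal artery occlusion (CRAO), and the clinical-trial design arithmetic
built on top of it.

## The problem

CRAO cuts off the central retinal artery, the main blood supply of the
inner retina.  The inner layers — retinal nerve fiber layer (RNFL),
ganglion cell layer (GCL), inner plexiform layer (IPL) and inner nuclear
layer (INL) — then thin over weeks to months, while the outer retina,
fed by the separate ciliary circulation, is largely spared.  Segmented
OCT gives layer thicknesses on the ETDRS grid at every clinic visit, so
the thinning can be modelled quantitatively and used as a trial endpoint
for candidate neuroprotective drugs.

`octdecay` is for biostatisticians and ophthalmic researchers planning
such trials.  Given a longitudinal cohort of per-scan layer thicknesses
(affected eyes plus stable contralateral control eyes), it:

1. validates and aggregates the data to the 3-mm ETDRS middle-ring mean,
   applies segmentation-QC exclusions, and pools control eyes as day-0
   baseline points;
2. fits each layer's pooled points to the decay model

   *thickness(d)* = plateau + (initial − plateau) · e^(−k·d)

   with d in days since onset, reporting R² (a fit is treated as
   biologically meaningful only if R² > 0.4), RMSE (with n − 3
   denominator; used as the experimental-error estimate σ), pointwise
   confidence bands, and residual diagnostics (D'Agostino–Pearson K²
   normality, Breusch–Pagan homoscedasticity);
3. projects untreated endpoint thickness T_day at candidate trial
   durations, applies the efficacy adjustment
   *adjusted = (T0 − T_day) · e + T_day* for a drug preventing a
   fraction *e* of the loss, and computes the per-group sample size for
   a two-sided two-sample t-test (α = 0.05, power 0.8, σ = RMSE) by
   noncentral-t iteration;
4. simulates synthetic cohorts with known ground truth (per-patient
   decay curves, irregular visit schedules, measurement noise, QC
   failures) for parameter-recovery and power calibration experiments.

## Worked example

The analysis drivers under `analysis/` run the whole pipeline on a
synthetic cohort shaped like a realistic CRAO case series (19 patients,
1–8 scans each over up to 951 days, 15 control eyes):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_fit_decay_curves.py
python analysis/03_trial_design_table.py
python analysis/04_method_validation.py
```

`02_fit_decay_curves.py` prints, per layer (abridged):

```
    GCL: initial=   46.6  plateau=  12.3  k=0.0401/day  R²=0.94 (PASS)  RMSE=3.2 μm  n=88
   RNFL: initial=   23.1  plateau=  10.6  k=0.0142/day  R²=0.82 (PASS)  RMSE=2.3 μm  n=88
    ONL: initial=   65.8  plateau=  72.3  k=0.0023/day  R²=0.06 (below gate)  RMSE=5.8 μm  n=88
```

The GCL loses ~74% of its thickness toward a ~12 μm plateau with a
~0.04/day decay rate, while outer layers (ONL and friends) show no
meaningful decay and fail the R² gate — the pattern expected of an
inner-retina ischemia.  `03_trial_design_table.py` then reports, for
example:

```
  e.g. GCL, 30-day trial: untreated 22.6 μm (-51.5%), 20% efficacy needs n=9/group
```

i.e. with this cohort's fitted curve and error, a 30-day trial detecting
a drug that prevents 20% of GCL loss needs 9 eyes per arm.  It also
writes a reconstruction of the published endpoint table
(`results/trial_design_published_reconstruction.csv`) from decay curves
re-fitted to the published untreated columns.

Equivalent one-off commands exist on the CLI:
`octdecay simulate | validate | fit | design` (see `--help`).

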