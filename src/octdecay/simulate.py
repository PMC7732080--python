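"""Synthetic longitudinal CRAO cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes:
per-layer exponential thinning of the affected eye with per-patient
random effects, irregular right-skewed visit schedules (acute-phase
visits denser), additive Gaussian measurement noise, stable contralateral
control eyes entering at day 0, and a segmentation-failure QC flag.
Composite layers are exact sums before noise: INNER = RNFL + GCL + IPL +
INL and RETINA = INNER + OPL + ONL + OUTER + RPE, so the composite
baseline of a synthetic cohort follows from its components rather than
from any published composite value.

Per-layer default decay parameters are presets back-fitted from published
untreated endpoint columns (see :mod:`octdecay.datasets`); outer layers,
largely spared by the occlusion, default to stable (k = 0) curves at
normative thicknesses.  These presets make the defaults resemble the
study's curves; they are not ground truth about patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .cohort import Cohort, ScanRecord
from .decay import DecayParams, predict_thickness
from .fitting import confidence_band, fit_layer
from .layers import INNER_COMPONENTS, OUTER_COMPONENTS, LayerName

#: Layers the generator simulates directly (composites are derived sums).
SIMULATED_LAYERS = (*INNER_COMPONENTS, *OUTER_COMPONENTS, LayerName.CMT)

DERIVED_LAYERS = (LayerName.INNER, LayerName.RETINA)


class LayerTruth(BaseModel):
    """True decay-curve population for one layer.

    ``initial``/``plateau``/``k`` are the population means;
    ``initial_sd``/``plateau_sd`` are between-patient Gaussian SDs (μm)
    and ``k_log_sd`` a between-patient log-normal spread of the decay
    rate.  ``noise_sd`` is the additive measurement SD (μm) on the
    middle-ring mean; ``control_sd`` the between-eye SD of stable
    control eyes.
    """

    initial: float = Field(gt=0)
    plateau: float = Field(ge=0)
    k: float = Field(ge=0)
    initial_sd: float = Field(default=0.0, ge=0)
    plateau_sd: float = Field(default=0.0, ge=0)
    k_log_sd: float = Field(default=0.0, ge=0)
    noise_sd: float = Field(default=3.0, ge=0)
    control_sd: float = Field(default=0.0, ge=0)

    def mean_params(self) -> DecayParams:
        return DecayParams(self.initial, self.plateau, self.k)


def _truth(i, p, k, noise=3.0):
    # between-patient spread: 6% Gaussian on levels, 0.15 log-SD on rate
    return LayerTruth(
        initial=i, plateau=p, k=k,
        initial_sd=0.06 * i, plateau_sd=0.06 * p, k_log_sd=0.15 if k > 0 else 0.0,
        noise_sd=noise, control_sd=0.06 * i,
    )


def default_layer_truths() -> dict[LayerName, LayerTruth]:
    """Per-layer presets: inner layers from back-fitted published decay
    columns, outer layers stable at normative thicknesses."""
    return {
        LayerName.RNFL: _truth(22.9, 10.5, 0.016, noise=2.0),
        LayerName.GCL: _truth(47.5, 12.3, 0.037, noise=3.0),
        LayerName.IPL: _truth(39.6, 15.9, 0.029, noise=2.5),
        LayerName.INL: _truth(40.1, 18.1, 0.046, noise=3.0),
        LayerName.OPL: _truth(28.0, 28.0, 0.0, noise=2.5),
        LayerName.ONL: _truth(68.0, 68.0, 0.0, noise=4.0),
        LayerName.OUTER: _truth(85.0, 85.0, 0.0, noise=4.0),
        LayerName.RPE: _truth(15.0, 15.0, 0.0, noise=1.5),
        LayerName.CMT: _truth(280.0, 235.0, 0.020, noise=8.0),
    }


class SyntheticConfig(BaseModel):
    """Cohort-shape and noise parameters of the generator.

    Defaults mirror the study's demographics: 19 CRAO patients, 15
    control eyes, 1–8 scans per patient over at most 951 days.
    ``noise_sd`` (when set) overrides every layer's measurement SD;
    ``random_effects=False`` switches off between-patient heterogeneity
    so the generator matches the fitter's iid-noise model exactly
    (calibration experiments).
    """

    n_crao_patients: int = Field(default=19, ge=0)
    n_control_eyes: int = Field(default=15, ge=0)
    min_scans: int = Field(default=1, ge=1)
    max_scans: int = Field(default=8, ge=1)
    max_followup_days: float = Field(default=951.0, gt=0, le=951.0)
    qc_fail_prob: float = Field(default=0.05, ge=0, le=1)
    noise_sd: float | None = Field(default=None, ge=0)
    random_effects: bool = True
    heteroscedastic: bool = False
    emit_quadrants: bool = False
    seed: int = 0
    layers: dict[LayerName, LayerTruth] = Field(default_factory=default_layer_truths)

    @model_validator(mode="after")
    def _check_scans(self) -> "SyntheticConfig":
        if self.min_scans > self.max_scans:
            raise ValueError(
                f"min_scans ({self.min_scans}) exceeds max_scans ({self.max_scans})"
            )
        return self

    def layer_noise_sd(self, layer: LayerName) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        if layer in self.layers:
            return self.layers[layer].noise_sd
        # derived composites: noise comparable to their largest component
        return max(self.layers[l].noise_sd for l in self.layers)


@dataclass
class GroundTruth:
    """Everything the generator knew: per-patient true curves, pre-noise
    values for every record, noise SDs, and QC-failure assignments."""

    params: dict[tuple[str, LayerName], DecayParams]
    pre_noise: pd.DataFrame  # patient_id, eye, group, days_since_onset, layer, value_um
    noise_sd: dict[LayerName, float]
    qc_failed: set[tuple[str, str, float]]
    config: SyntheticConfig


def _rng(config: SyntheticConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *key])


def generate_visit_schedule(config: SyntheticConfig, patient_index: int) -> list[float]:
    """Visit days for one patient: count uniform on [min, max] scans,
    integer days sampled without replacement with right-skewed weights
    (early, acute-phase visits denser), sorted ascending."""
    rng = _rng(config, 13, patient_index)
    n = int(rng.integers(config.min_scans, config.max_scans + 1))
    grid = np.arange(0.0, np.floor(config.max_followup_days) + 1)
    weights = (1.0 - grid / (grid[-1] + 1.0)) ** 4 + 1e-4
    weights /= weights.sum()
    days = rng.choice(grid, size=min(n, grid.size), replace=False, p=weights)
    return sorted(float(d) for d in days)


def _patient_params(
    truth: LayerTruth, rng: np.random.Generator, random_effects: bool
) -> DecayParams:
    if not random_effects:
        return truth.mean_params()
    initial = truth.initial + rng.normal(0.0, truth.initial_sd)
    plateau = max(truth.plateau + rng.normal(0.0, truth.plateau_sd), 0.0)
    k = truth.k * float(np.exp(rng.normal(0.0, truth.k_log_sd))) if truth.k > 0 else 0.0
    return DecayParams(max(initial, 1e-6), plateau, k)


def _noisy(
    value: float, layer: LayerName, baseline: float,
    config: SyntheticConfig, rng: np.random.Generator,
) -> float:
    sd = config.layer_noise_sd(layer)
    if config.heteroscedastic and baseline > 0:
        sd = sd * value / baseline
    out = value + rng.normal(0.0, sd)
    return float(np.clip(out, 0.5, 999.5))


def _quadrant_values(mean: float, rng: np.random.Generator, spread: float = 1.5):
    """Four quadrant thicknesses with exactly the requested mean."""
    perturb = rng.normal(0.0, spread, size=4)
    perturb -= perturb.mean()
    vals = np.clip(mean + perturb, 0.5, 999.5)
    vals += mean - vals.mean()
    return [float(v) for v in vals]


def generate_cohort(config: SyntheticConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a synthetic cohort and its ground truth.

    Fully reproducible from ``config.seed``; an empty configuration (no
    patients, no controls) yields an empty cohort.
    """
    records: list[ScanRecord] = []
    params: dict[tuple[str, LayerName], DecayParams] = {}
    pre_rows: list[tuple] = []
    qc_failed: set[tuple[str, str, float]] = set()

    def build_record(pid, eye, group, day, pre_noise_values, rng, qc_pass):
        observed = {
            layer: _noisy(v, layer, pre_noise_values.get(layer, v), config, rng)
            for layer, v in pre_noise_values.items()
        }
        if config.emit_quadrants:
            from .cohort import EtdrsSectorGrid
            from .layers import RING3_QUADRANTS

            layers = {}
            for layer, m in observed.items():
                quads = _quadrant_values(m, rng)
                layers[layer] = EtdrsSectorGrid(
                    dict(zip(RING3_QUADRANTS, quads))
                )
            rec = ScanRecord(pid, eye, group, day, layers, qc_pass)
        else:
            rec = ScanRecord.from_middle_ring(pid, eye, group, day, observed, qc_pass)
        records.append(rec)
        for layer, v in pre_noise_values.items():
            pre_rows.append((pid, eye, group, day, layer.value, v))

    # --- CRAO patients: one affected eye, decaying curves -------------
    for idx in range(config.n_crao_patients):
        pid = f"P{idx + 1:03d}"
        rng = _rng(config, 7, idx)
        eye = "OD" if rng.random() < 0.5 else "OS"
        patient_truth = {
            layer: _patient_params(config.layers[layer], rng, config.random_effects)
            for layer in SIMULATED_LAYERS
            if layer in config.layers
        }
        for layer, p in patient_truth.items():
            params[(pid, layer)] = p
        for day in generate_visit_schedule(config, idx):
            values = {
                layer: predict_thickness(p, day) for layer, p in patient_truth.items()
            }
            inner = sum(values[l] for l in INNER_COMPONENTS if l in values)
            if all(l in values for l in INNER_COMPONENTS):
                values[LayerName.INNER] = inner
                if all(l in values for l in OUTER_COMPONENTS):
                    values[LayerName.RETINA] = inner + sum(
                        values[l] for l in OUTER_COMPONENTS
                    )
            qc_pass = not (rng.random() < config.qc_fail_prob)
            if not qc_pass:
                qc_failed.add((pid, eye, day))
            build_record(pid, eye, "CRAO", day, values, rng, qc_pass)

    # --- control eyes: stable at day 0 --------------------------------
    for j in range(config.n_control_eyes):
        pid = f"C{j + 1:03d}"
        rng = _rng(config, 11, j)
        eye = "OD" if rng.random() < 0.5 else "OS"
        values = {}
        for layer in SIMULATED_LAYERS:
            if layer not in config.layers:
                continue
            t = config.layers[layer]
            true_val = t.initial
            if config.random_effects:
                true_val = max(t.initial + rng.normal(0.0, t.control_sd), 1e-6)
            values[layer] = true_val
        if all(l in values for l in INNER_COMPONENTS):
            values[LayerName.INNER] = sum(values[l] for l in INNER_COMPONENTS)
            if all(l in values for l in OUTER_COMPONENTS):
                values[LayerName.RETINA] = values[LayerName.INNER] + sum(
                    values[l] for l in OUTER_COMPONENTS
                )
        qc_pass = not (rng.random() < config.qc_fail_prob)
        if not qc_pass:
            qc_failed.add((pid, eye, 0.0))
        build_record(pid, eye, "CONTROL", 0.0, values, rng, qc_pass)

    if not records:
        import logging

        logging.getLogger(__name__).warning(
            "generate_cohort: degenerate config produced an empty cohort"
        )
        from .cohort import CANONICAL_COLUMNS

        cohort = Cohort(
            pd.DataFrame(columns=list(CANONICAL_COLUMNS)).astype(
                {"days_since_onset": float, "thickness_um": float, "qc_pass": bool}
            ),
            provenance=f"synthetic (seed={config.seed})",
        )
    else:
        cohort = Cohort.from_records(
            records, provenance=f"synthetic (seed={config.seed})"
        )

    pre_noise = pd.DataFrame(
        pre_rows,
        columns=["patient_id", "eye", "group", "days_since_onset", "layer", "value_um"],
    )
    truth = GroundTruth(
        params=params,
        pre_noise=pre_noise,
        noise_sd={
            layer: config.layer_noise_sd(layer)
            for layer in (*SIMULATED_LAYERS, *DERIVED_LAYERS)
        },
        qc_failed=qc_failed,
        config=config,
    )
    return cohort, truth


@dataclass
class RecoveryReport:
    """Outcome of a parameter-recovery experiment on one layer."""

    layer: LayerName
    n_replicates: int
    bias: dict[str, float]
    median_abs_rel_err: dict[str, float]
    band_coverage: float
    eval_day: float


def parameter_recovery_experiment(
    config: SyntheticConfig,
    n_replicates: int,
    seed: int,
    layer: LayerName = LayerName.GCL,
    eval_day: float = 60.0,
) -> RecoveryReport:
    """Generate → fit → compare-to-truth, replicated.

    Per replicate: a fresh cohort from a derived seed, QC exclusions,
    pooled fit of ``layer`` (controls included as day-0 points), then
    parameter errors against the configured population means and
    confidence-band coverage of the true mean curve at ``eval_day``.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    layer = LayerName(layer)
    true = config.layers[layer].mean_params()
    true_at_eval = predict_thickness(true, eval_day)

    rel_err: dict[str, list[float]] = {"initial": [], "plateau": [], "k": []}
    covered = 0
    evaluable = 0
    from .cohort import apply_exclusions

    for r in range(n_replicates):
        child = int(np.random.SeedSequence([seed & 0x7FFFFFFF, r]).generate_state(1)[0] % (2**31))
        cfg = config.model_copy(update={"seed": child})
        cohort, _ = generate_cohort(cfg)
        cohort, _ = apply_exclusions(cohort)
        try:
            fit = fit_layer(cohort, layer, include_controls=True)
        except ValueError:
            continue
        evaluable += 1
        est = fit.params
        rel_err["initial"].append((est.initial - true.initial) / true.initial)
        rel_err["plateau"].append((est.plateau - true.plateau) / true.plateau)
        rel_err["k"].append((est.k - true.k) / true.k)
        if fit.covariance is not None and fit.converged:
            lo, hi = confidence_band(fit, [eval_day])
            if lo[0] <= true_at_eval <= hi[0]:
                covered += 1

    if evaluable < 2:
        raise ValueError("fewer than 2 evaluable replicates; config too sparse")
    return RecoveryReport(
        layer=layer,
        n_replicates=evaluable,
        bias={p: float(np.mean(v)) for p, v in rel_err.items()},
        median_abs_rel_err={p: float(np.median(np.abs(v))) for p, v in rel_err.items()},
        band_coverage=covered / evaluable,
        eval_day=eval_day,
    )
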