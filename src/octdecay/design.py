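"""Trial-design arithmetic: endpoint projection, efficacy adjustment,
and per-group sample sizes for a two-sided two-sample t-test.

A drug of efficacy ``e`` (fraction of CRAO-induced thickness loss
prevented) moves the expected endpoint thickness from the untreated
value ``T_day`` toward the baseline ``T0``:

    adjusted = (T0 - T_day) * e + T_day

The detectable effect is δ = e·(T0 − T_day) μm.  Per-group sample size
is the smallest n such that a two-sample, two-sided t-test with equal
arms and equal SD σ (the layer fit's RMSE) reaches the target power at
true difference δ, computed from the noncentral-t power formula seeded
by the normal approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .decay import percent_change, predict_thickness
from .fitting import FitResult, significance_gate
from .layers import LayerName

MIN_N_PER_GROUP = 2


@dataclass(frozen=True)
class PowerSpec:
    """Significance level, target power, and per-arm SD for sizing.

    ``sigma`` defaults downstream to the layer fit's RMSE — the study's
    experimental-error estimate.
    """

    alpha: float = 0.05
    power: float = 0.8
    sigma: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.power < 1:
            raise ValueError(f"power must be in (0, 1), got {self.power}")
        if self.sigma is not None and not self.sigma > 0:
            raise ValueError(f"sigma must be > 0 μm, got {self.sigma}")


def efficacy_adjusted_thickness(t0: float, t_day: float, efficacy: float) -> float:
    """Expected endpoint thickness under a drug of given efficacy, μm.

    ``adjusted = (t0 - t_day) * efficacy + t_day``; efficacy 0 leaves the
    untreated endpoint, efficacy 1 preserves the baseline.
    """
    if not t0 > 0:
        raise ValueError(f"baseline thickness must be > 0 μm, got {t0}")
    if not t_day > 0:
        raise ValueError(f"endpoint thickness must be > 0 μm, got {t_day}")
    if not 0.0 <= efficacy <= 1.0:
        raise ValueError(f"efficacy must be in [0, 1], got {efficacy}")
    return (t0 - t_day) * efficacy + t_day


def effect_size(t0: float, t_day: float, efficacy: float) -> float:
    """Detectable thickness difference δ = efficacy · (t0 − t_day), μm."""
    return efficacy_adjusted_thickness(t0, t_day, efficacy) - t_day


def power_two_sample_t(n: int, delta: float, sigma: float, alpha: float) -> float:
    """Exact power of the two-sided two-sample t-test, equal arms of n.

    Noncentral-t formulation: df = 2n − 2, noncentrality
    δ / (σ·√(2/n)).
    """
    if n < 2:
        return 0.0
    df = 2 * n - 2
    nc = delta / (sigma * math.sqrt(2.0 / n))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def sample_size_per_group(delta: float, spec: PowerSpec) -> int:
    """Smallest per-arm n reaching the target power at true difference δ.

    Starts from the normal approximation
    n₀ = 2·(z₁₋α/₂ + z_power)²·(σ/δ)² and walks the noncentral-t power
    to the minimal integer; floored at 2 (the minimum for a t-test).
    """
    if spec.sigma is None:
        raise ValueError("PowerSpec.sigma is required for sample-size calculation")
    if not delta > 0:
        raise ValueError("effect size must be positive")
    za = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    zb = stats.norm.ppf(spec.power)
    n = max(MIN_N_PER_GROUP, math.ceil(2.0 * (za + zb) ** 2 * (spec.sigma / delta) ** 2))
    # walk down to minimality, then up to sufficiency
    while n > MIN_N_PER_GROUP and power_two_sample_t(n - 1, delta, spec.sigma, spec.alpha) >= spec.power:
        n -= 1
    while power_two_sample_t(n, delta, spec.sigma, spec.alpha) < spec.power:
        n += 1
    return n


def empirical_power(
    n: int,
    delta: float,
    sigma: float,
    alpha: float = 0.05,
    reps: int = 20000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the two-sample two-sided t-test.

    Simulation oracle for :func:`sample_size_per_group`: both arms are
    Normal with SD ``sigma`` and mean difference ``delta``; returns the
    rejection fraction over ``reps`` replicates.  Reproducible given
    ``seed``.
    """
    if n < 2:
        raise ValueError("need n >= 2 per arm")
    if reps < 1000:
        raise ValueError("need >= 1000 replicates for a stable estimate")
    rng = np.random.default_rng(seed)
    a = rng.normal(delta, sigma, size=(reps, n))
    b = rng.normal(0.0, sigma, size=(reps, n))
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sp = np.sqrt((va + vb) / 2.0)
    t = (a.mean(axis=1) - b.mean(axis=1)) / (sp * math.sqrt(2.0 / n))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, 2 * n - 2)
    return float(np.mean(np.abs(t) > tcrit))


@dataclass
class TrialDesignTable:
    """Projected thicknesses and per-group sample sizes over
    (layer × endpoint day × efficacy).

    ``table`` holds full-precision values; :meth:`to_report` renders the
    publication-style view (thickness at one decimal, half-up; n as
    integers).  ``excluded`` logs layers that failed the R² gate.
    """

    table: pd.DataFrame
    t0_by_layer: dict[LayerName, float]
    sigma_by_layer: dict[LayerName, float]
    excluded: list[str] = field(default_factory=list)

    def to_report(self) -> pd.DataFrame:
        def round1(x: float) -> float:
            # decimal half-up, the convention of printed clinical tables
            return math.floor(x * 10 + 0.5) / 10 if x >= 0 else -math.floor(-x * 10 + 0.5) / 10

        out = self.table.copy()
        for col in out.columns:
            if col.endswith("_um") or col == "pct_change":
                out[col] = out[col].map(round1)
        return out


def build_trial_table(
    fits: dict[LayerName, FitResult],
    t0_by_layer: dict[LayerName, float],
    days,
    efficacies,
    spec: PowerSpec | None = None,
    r2_threshold: float = 0.4,
    force_layers: tuple[LayerName, ...] = (),
) -> TrialDesignTable:
    """Assemble the trial-design grid from per-layer decay fits.

    Layers failing the R² gate are excluded with a log entry unless
    named in ``force_layers``.  Per layer and endpoint day: the
    untreated projection, percent change versus baseline, and for each
    efficacy the adjusted thickness and per-group n with σ = that
    layer's fit RMSE (unless the power spec pins a common σ).
    """
    spec = spec or PowerSpec()
    days = [float(d) for d in days]
    efficacies = [float(e) for e in efficacies]
    if any(d < 0 for d in days):
        raise ValueError("endpoint days must be >= 0")
    if any(not 0 <= e <= 1 for e in efficacies):
        raise ValueError("efficacies must be in [0, 1]")

    excluded: list[str] = []
    rows = []
    sigma_by_layer: dict[LayerName, float] = {}
    for layer, fit in fits.items():
        layer = LayerName(layer)
        if layer not in force_layers and not significance_gate(fit, r2_threshold):
            excluded.append(
                f"{layer.value}: R² = {fit.r_squared if not np.isnan(fit.r_squared) else 'undefined'}"
                f" did not exceed {r2_threshold}; not further analyzed"
            )
            continue
        t0 = float(t0_by_layer[layer])
        sigma = spec.sigma if spec.sigma is not None else fit.rmse
        sigma_by_layer[layer] = sigma
        layer_spec = replace(spec, sigma=sigma)
        for day in days:
            t_day = predict_thickness(fit.params, day)
            row: dict = {
                "layer": layer.value,
                "day": day,
                "t0_um": t0,
                "t_no_drug_um": t_day,
                "pct_change": percent_change(t0, t_day),
            }
            for e in efficacies:
                adj = efficacy_adjusted_thickness(t0, t_day, e)
                delta = adj - t_day
                tag = f"{int(round(e * 100))}"
                row[f"t_eff{tag}_um"] = adj
                row[f"n_eff{tag}"] = (
                    sample_size_per_group(delta, layer_spec) if delta > 0 else np.nan
                )
            rows.append(row)

    table = pd.DataFrame(rows)
    return TrialDesignTable(
        table=table,
        t0_by_layer={LayerName(l): float(v) for l, v in t0_by_layer.items()},
        sigma_by_layer=sigma_by_layer,
        excluded=excluded,
    )
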