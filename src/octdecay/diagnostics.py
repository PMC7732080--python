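"""Residual diagnostics reported alongside every decay fit.

Normality is assessed by the D'Agostino–Pearson omnibus K² test: sample
skewness and kurtosis are each transformed to approximate standard-normal
deviates (D'Agostino's skewness transform, the Anscombe–Glynn kurtosis
transform) and K² = Z₁² + Z₂² is referred to chi-square with 2 degrees of
freedom.  Homoscedasticity is assessed by a Breusch–Pagan score test of
squared residuals against fitted values.

Diagnostics never block fitting or trial design — the analysis proceeds
on the R² gate even when residual assumptions are violated — but they are
attached to every fit for transparency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan

from .fitting import FitResult

#: Below this sample size the moment transforms are unstable.
K2_DEFAULT_FLOOR = 20
K2_HARD_FLOOR = 8

ALPHA = 0.05


@dataclass(frozen=True)
class DiagnosticsReport:
    """Normality and homoscedasticity verdicts for one fit's residuals.

    ``normality_pass`` / ``homosced_pass`` are None when the test was not
    evaluable (too few points, degenerate residuals); the reason is then
    in ``notes``.
    """

    k2_stat: float | None
    k2_p: float | None
    skew_z: float | None
    kurt_z: float | None
    homosced_stat: float | None
    homosced_p: float | None
    normality_pass: bool | None
    homosced_pass: bool | None
    alpha: float = ALPHA
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "k2_stat": self.k2_stat,
            "k2_p": self.k2_p,
            "skew_z": self.skew_z,
            "kurt_z": self.kurt_z,
            "homosced_stat": self.homosced_stat,
            "homosced_p": self.homosced_p,
            "normality_pass": self.normality_pass,
            "homosced_pass": self.homosced_pass,
            "alpha": self.alpha,
            "notes": list(self.notes),
        }


def dagostino_pearson_k2(
    sample, floor: int = K2_DEFAULT_FLOOR
) -> tuple[float, float, float, float]:
    """D'Agostino–Pearson omnibus test → (K², p, skew Z, kurtosis Z).

    ``floor`` may be lowered to 8 (with a warning) for exploratory use;
    the transforms are asymptotic and unreliable in small samples.
    """
    x = np.asarray(sample, dtype=float)
    if floor < K2_HARD_FLOOR:
        raise ValueError(f"sample-size floor cannot be below {K2_HARD_FLOOR}")
    if floor < K2_DEFAULT_FLOOR:
        warnings.warn(
            f"K² floor lowered to {floor}; moment transforms are asymptotic "
            f"and unstable below n = {K2_DEFAULT_FLOOR}",
            stacklevel=2,
        )
    if x.size < floor:
        raise ValueError(f"need at least {floor} values for K², got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance sample; K² undefined")
    skew_z, _ = stats.skewtest(x)
    kurt_z, _ = stats.kurtosistest(x)
    k2 = float(skew_z**2 + kurt_z**2)
    p = float(stats.chi2.sf(k2, df=2))
    return k2, p, float(skew_z), float(kurt_z)


def homoscedasticity_test(residuals, fitted) -> tuple[float, float]:
    """Breusch–Pagan score test of residual variance against fitted values.

    Regresses squared residuals on the fitted values; the LM statistic
    n·R²_aux is referred to chi-square with 1 degree of freedom.
    Returns (statistic, p).
    """
    r = np.asarray(residuals, dtype=float)
    f = np.asarray(fitted, dtype=float)
    if r.size != f.size:
        raise ValueError("residuals and fitted values must have equal length")
    if r.size < 10:
        raise ValueError(f"need at least 10 points, got {r.size}")
    if np.ptp(f) == 0:
        raise ValueError("constant fitted values; no spread to regress on")
    if np.allclose(r, 0):
        raise ValueError("residuals are identically zero; statistic undefined")
    exog = np.column_stack([np.ones_like(f), f])
    lm_stat, lm_p, _, _ = het_breuschpagan(r, exog)
    return float(lm_stat), float(lm_p)


def diagnostics_report(
    fit: FitResult, alpha: float = ALPHA, k2_floor: int = K2_DEFAULT_FLOOR
) -> DiagnosticsReport:
    """Bundle both residual tests for a fit, with α = 0.05 pass flags.

    Component failures (too few residuals, degenerate input) are recorded
    as not-evaluable flags instead of aborting.
    """
    if not fit.converged:
        raise ValueError("diagnostics require a converged fit")
    notes: list[str] = []
    k2 = p = sz = kz = None
    norm_pass: bool | None = None
    if np.allclose(fit.residuals, 0.0, atol=1e-8):
        return DiagnosticsReport(
            k2_stat=None, k2_p=None, skew_z=None, kurt_z=None,
            homosced_stat=None, homosced_p=None,
            normality_pass=None, homosced_pass=None, alpha=alpha,
            notes=(
                "normality not evaluable: residuals are (numerically) zero",
                "homoscedasticity not evaluable: residuals are (numerically) zero",
            ),
        )
    try:
        k2, p, sz, kz = dagostino_pearson_k2(fit.residuals, floor=k2_floor)
        norm_pass = bool(p > alpha)
    except ValueError as e:
        notes.append(f"normality not evaluable: {e}")

    bp = bpp = None
    hom_pass: bool | None = None
    try:
        bp, bpp = homoscedasticity_test(fit.residuals, fit.fitted)
        hom_pass = bool(bpp > alpha)
    except ValueError as e:
        notes.append(f"homoscedasticity not evaluable: {e}")

    return DiagnosticsReport(
        k2_stat=k2,
        k2_p=p,
        skew_z=sz,
        kurt_z=kz,
        homosced_stat=bp,
        homosced_p=bpp,
        normality_pass=norm_pass,
        homosced_pass=hom_pass,
        alpha=alpha,
        notes=tuple(notes),
    )
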