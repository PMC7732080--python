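"""Nonlinear least-squares estimation of the decay model.

Pooled (day, thickness) points for a layer — all CRAO eyes together,
optionally with control eyes as day-0 baseline points — are fitted to
``plateau + (initial - plateau) * exp(-k * days)`` by a bounded
Levenberg–Marquardt-type trust-region optimizer with deterministic
multi-start.  Reported alongside the parameters: R² about the observed
mean, RMSE with n − 3 denominator (the regression error estimate that
feeds the power calculations), residuals, the parameter covariance, and
the study's biological-significance gate R² > 0.4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .cohort import Cohort, baseline_from_controls, collapse_to_middle_ring
from .decay import DecayParams, predict_thickness
from .layers import LayerName

N_PARAMS = 3
R2_THRESHOLD = 0.4


class InsufficientDataError(ValueError):
    """Fewer points than the 3-parameter model can support."""


class UnidentifiableModelError(ValueError):
    """All observations share one day; the decay rate cannot be identified."""


@dataclass(frozen=True)
class FitOptions:
    """Optimizer controls.

    ``k0_scalings`` defines the deterministic multi-start: the log-linear
    heuristic decay rate is multiplied by each scaling and the best SSR
    wins.  ``xtol``/``ftol``/``gtol`` and ``max_nfev`` are passed to the
    trust-region least-squares solver.
    """

    k0_scalings: tuple[float, ...] = (0.2, 0.5, 1.0, 2.0, 5.0)
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-12
    max_nfev: int = 2000


@dataclass
class FitResult:
    """Decay-model fit with goodness-of-fit and inference byproducts.

    ``r_squared`` is NaN when SS_tot = 0 (constant observations); the
    significance gate then fails with a recorded reason.  ``covariance``
    is the asymptotic parameter covariance ``s² (JᵀJ)⁻¹`` ordered
    (initial, plateau, k); None when the Jacobian is singular.
    """

    params: DecayParams
    r_squared: float
    rmse: float
    ssr: float
    residuals: np.ndarray
    n_points: int
    converged: bool
    covariance: np.ndarray | None
    days: np.ndarray = field(repr=False, default=None)
    observed: np.ndarray = field(repr=False, default=None)

    @property
    def fitted(self) -> np.ndarray:
        return self.observed - self.residuals

    @property
    def dof(self) -> int:
        return self.n_points - N_PARAMS

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "r_squared": None if np.isnan(self.r_squared) else float(self.r_squared),
            "rmse_um": float(self.rmse),
            "n_points": int(self.n_points),
            "converged": bool(self.converged),
            "significant": significance_gate(self),
        }


def _as_points(points) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (day, thickness)")
    return arr[:, 0], arr[:, 1]


def _initial_guess(days: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Heuristic start: initial at earliest day, plateau at the observed
    minimum, k from a log-linear regression of (thickness − 0.9·plateau₀)."""
    initial0 = float(y[np.argmin(days)])
    plateau0 = max(float(np.min(y)), 0.0)
    excess = y - 0.9 * plateau0
    mask = excess > 0
    k0 = 0.01
    if mask.sum() >= 2 and np.ptp(days[mask]) > 0:
        slope = np.polyfit(days[mask], np.log(excess[mask]), 1)[0]
        if slope < 0:
            k0 = float(-slope)
    return initial0, plateau0, k0


def fit_decay(points, options: FitOptions | None = None) -> FitResult:
    """Least-squares fit of the decay model to (day, thickness) points.

    Requires at least 4 points with at least 2 distinct days.  Bounds:
    plateau ≥ 0, k ≥ 0, initial free (apparent early thickening is
    permitted and flagged downstream, not forbidden).  Deterministic for
    given points and options; ``converged`` is False when no start meets
    the gradient tolerances.
    """
    options = options or FitOptions()
    days, y = _as_points(points)
    if len(days) < N_PARAMS + 1:
        raise InsufficientDataError(
            f"need >= {N_PARAMS + 1} points to fit {N_PARAMS} parameters, got {len(days)}"
        )
    if np.unique(days).size < 2:
        raise UnidentifiableModelError("all observations share one day; k unidentifiable")
    if np.any(days < 0):
        raise ValueError("days since onset must be >= 0")

    def residual(theta: np.ndarray) -> np.ndarray:
        # observed minus model: the classic regression residual
        i, p, k = theta
        return y - (p + (i - p) * np.exp(-k * days))

    initial0, plateau0, k0 = _initial_guess(days, y)
    lower = np.array([-np.inf, 0.0, 0.0])
    upper = np.array([np.inf, np.inf, np.inf])

    best = None
    for scale in options.k0_scalings:
        x0 = np.array([initial0, plateau0, max(k0 * scale, 1e-8)])
        sol = optimize.least_squares(
            residual, x0, bounds=(lower, upper), method="trf",
            ftol=options.ftol, xtol=options.xtol, gtol=options.gtol,
            max_nfev=options.max_nfev,
        )
        if best is None or sol.cost < best.cost:
            best = sol

    i_hat, p_hat, k_hat = best.x
    # a fit can legitimately land at a tiny positive initial; clamp away from 0
    params = DecayParams(initial=max(i_hat, 1e-9), plateau=p_hat, k=k_hat)
    resid = residual(best.x)
    ssr = float(resid @ resid)
    n = len(days)

    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else float("nan")
    dof = n - N_PARAMS
    rmse = float(np.sqrt(ssr / dof)) if dof > 0 else float("nan")

    cov = None
    jac = best.jac
    jtj = jac.T @ jac
    if np.linalg.matrix_rank(jtj) == N_PARAMS and dof > 0:
        cov = np.linalg.inv(jtj) * (ssr / dof)

    return FitResult(
        params=params,
        r_squared=r2,
        rmse=rmse,
        ssr=ssr,
        residuals=resid,
        n_points=n,
        converged=bool(best.success),
        covariance=cov,
        days=days,
        observed=y,
    )


def goodness_of_fit(fit: FitResult, points=None) -> tuple[float, float]:
    """(R², RMSE) of a fit, recomputed from points when given.

    R² = 1 − SS_res/SS_tot with SS_tot about the observed mean; RMSE uses
    the n − 3 regression denominator.  R² is NaN when the observations
    are constant.
    """
    if points is None:
        days, y = fit.days, fit.observed
    else:
        days, y = _as_points(points)
    resid = y - predict_thickness(fit.params, days)
    ssr = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else float("nan")
    dof = len(y) - N_PARAMS
    rmse = float(np.sqrt(ssr / dof)) if dof > 0 else float("nan")
    return r2, rmse


def significance_gate(fit: FitResult, threshold: float = R2_THRESHOLD) -> bool:
    """The study's biological-significance rule: R² strictly above 0.4.

    An undefined R² (constant observations) fails the gate.
    """
    r2 = fit.r_squared
    if np.isnan(r2):
        return False
    return bool(r2 > threshold)


def confidence_band(
    fit: FitResult, days, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise confidence band for the fitted mean curve.

    First-order error propagation of the parameter covariance through
    the model gradient, with a t quantile on n − 3 degrees of freedom.
    The band always contains the point estimate.
    """
    if fit.covariance is None:
        raise ValueError(
            "singular parameter covariance; collect more data or rescale days"
        )
    if not fit.converged:
        raise ValueError("fit did not converge; no valid covariance")
    d = np.atleast_1d(np.asarray(days, dtype=float))
    i, p, k = fit.params.initial, fit.params.plateau, fit.params.k
    e = np.exp(-k * d)
    grad = np.stack([e, 1.0 - e, -(i - p) * d * e], axis=1)  # d/d(initial, plateau, k)
    var = np.einsum("ij,jk,ik->i", grad, fit.covariance, grad)
    se = np.sqrt(np.maximum(var, 0.0))
    tq = stats.t.ppf(0.5 + level / 2.0, fit.dof)
    pred = np.atleast_1d(predict_thickness(fit.params, d))
    return pred - tq * se, pred + tq * se


def pooled_layer_points(
    cohort: Cohort, layer: LayerName, include_controls: bool = True
) -> np.ndarray:
    """Pooled (day, thickness) points for one layer's population fit.

    Middle-ring means of every CRAO eye at every visit, plus (by
    default) one day-0 point per control eye.
    """
    layer = LayerName(layer)
    df = collapse_to_middle_ring(cohort).df
    crao = df[(df["group"] == "CRAO") & (df["layer"] == layer.value)]
    pts = list(zip(crao["days_since_onset"], crao["thickness_um"]))
    if include_controls:
        pts = baseline_from_controls(cohort, layer) + pts
    return np.array(pts, dtype=float).reshape(-1, 2)


def fit_layer(
    cohort: Cohort,
    layer: LayerName,
    include_controls: bool = True,
    options: FitOptions | None = None,
) -> FitResult:
    """Convenience: pooled points for a layer → :func:`fit_decay`."""
    return fit_decay(pooled_layer_points(cohort, layer, include_controls), options)
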