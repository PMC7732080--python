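"""Published endpoint thicknesses from a retrospective CRAO cohort study.

These small tables are the worked-example inputs used throughout the
package: per-layer baseline thicknesses (control-eye means, μm) and the
projected untreated ("no drug") middle-ring thicknesses at candidate
trial endpoints of 30–180 days after occlusion.  The endpoint cells are
regression outputs of the exponential-decay model and therefore lie on a
single decay curve per layer; the baseline row is a control-eye mean and
does not (for RNFL the implied day-0 intercept of the endpoint curve is
~30.7 μm against a 22.5 μm control mean — acute swelling is part of the
discrepancy).

Everything here is plain published numbers; nothing is fitted at import
time.
"""

from __future__ import annotations

from .layers import LayerName

#: Candidate trial endpoints (days since occlusion) of the published table.
ENDPOINT_DAYS: tuple[float, ...] = (30.0, 60.0, 90.0, 120.0, 180.0)

#: Drug efficacies (fraction of thickness loss prevented) of the published table.
EFFICACIES: tuple[float, ...] = (0.10, 0.20, 0.30, 0.50, 0.75)

#: Baseline (day-0) control-eye mean thickness per layer, μm.
BASELINE_T0: dict[LayerName, float] = {
    LayerName.RETINA: 332.3,
    LayerName.INNER: 253.8,
    LayerName.RNFL: 22.5,
    LayerName.GCL: 47.5,
    LayerName.IPL: 39.5,
    LayerName.INL: 40.1,
}

#: Untreated endpoint thickness (μm) at ENDPOINT_DAYS, per layer.
NO_DRUG_COLUMNS: dict[LayerName, tuple[float, ...]] = {
    LayerName.RETINA: (289.1, 261.9, 245.7, 236.1, 226.9),
    LayerName.INNER: (207.6, 180.4, 164.1, 154.4, 145.1),
    LayerName.RNFL: (19.4, 14.8, 12.9, 12.2, 11.7),
    LayerName.GCL: (23.8, 15.9, 13.4, 12.6, 12.3),
    LayerName.IPL: (26.4, 19.8, 17.5, 16.7, 16.3),
    LayerName.INL: (23.5, 19.6, 18.5, 18.2, 18.0),
}

#: Published pooled-fit coefficients of determination per layer.
REPORTED_R_SQUARED: dict[LayerName, float] = {
    LayerName.GCL: 0.75,
    LayerName.INNER: 0.69,
    LayerName.RETINA: 0.71,
    LayerName.RNFL: 0.38,
    LayerName.INL: 0.32,
}


def no_drug_points(
    layer: LayerName, include_day0: bool = False
) -> list[tuple[float, float]]:
    """(day, thickness) pairs of a layer's untreated endpoint column.

    With ``include_day0`` the control-mean baseline is prepended as a
    day-0 point; by default only the regression-derived endpoint cells
    (days 30–180) are returned.
    """
    pts = list(zip(ENDPOINT_DAYS, NO_DRUG_COLUMNS[layer]))
    if include_day0:
        pts.insert(0, (0.0, BASELINE_T0[layer]))
    return pts
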