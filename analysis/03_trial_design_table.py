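#!/usr/bin/env python
"""Build the trial-design table from the fitted decay curves.

Two tables are produced.  First, the synthetic-cohort table: for every
layer passing the R² gate, the projected untreated thickness at trial
endpoints of 30–180 days, the percent change versus the control-eye
baseline, and — for drug efficacies of 10–75% — the efficacy-adjusted
thickness and the per-group sample size for a two-sided two-sample
t-test (α = 0.05, power 0.8, σ = the layer fit's RMSE).  Second, a
reconstruction of the published endpoint arithmetic: decay curves
re-fitted to the published untreated columns reproduce those columns'
thickness cells, and the footnote formula fills in the efficacy columns.
"""

import pathlib

import octdecay as od
from octdecay.datasets import (
    BASELINE_T0,
    EFFICACIES,
    ENDPOINT_DAYS,
    no_drug_points,
)
from octdecay.layers import LayerName

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"


def synthetic_table() -> None:
    cohort = od.read_cohort_table(str(RESULTS / "cohort.csv"))
    cohort, _ = od.apply_exclusions(cohort)
    fits = {}
    t0 = {}
    baselines = od.control_summary(cohort).set_index("layer")
    for name in sorted(cohort.df["layer"].unique()):
        layer = LayerName(name)
        fits[layer] = od.fit_layer(cohort, layer, include_controls=True)
        t0[layer] = float(baselines.loc[name, "mean_um"])

    table = od.build_trial_table(
        fits, t0, days=list(ENDPOINT_DAYS), efficacies=list(EFFICACIES)
    )
    out = RESULTS / "trial_design_synthetic.csv"
    table.to_report().to_csv(out, index=False)
    for line in table.excluded:
        print(f"  excluded {line}")
    kept = sorted(set(table.table["layer"]))
    print(f"wrote {out} ({len(kept)} layers passed the gate: {', '.join(kept)})")

    gcl = table.table[(table.table["layer"] == "GCL") & (table.table["day"] == 30.0)]
    if not gcl.empty:
        row = gcl.iloc[0]
        print(
            f"  e.g. GCL, 30-day trial: untreated {row['t_no_drug_um']:.1f} μm "
            f"({row['pct_change']:.1f}%), 20% efficacy needs n={int(row['n_eff20'])}/group"
        )


def published_reconstruction() -> None:
    rows = []
    for layer in (LayerName.RETINA, LayerName.INNER, LayerName.RNFL,
                  LayerName.GCL, LayerName.IPL, LayerName.INL):
        fit = od.fit_decay(no_drug_points(layer, include_day0=False))
        t0 = BASELINE_T0[layer]
        for day in ENDPOINT_DAYS:
            t_day = od.predict_thickness(fit.params, day)
            row = {
                "layer": layer.value,
                "day": day,
                "t0_um": t0,
                "t_no_drug_um": round(t_day, 1),
                "pct_change": round(od.percent_change(t0, t_day), 1),
            }
            for e in EFFICACIES:
                row[f"t_eff{int(e * 100)}_um"] = round(
                    od.efficacy_adjusted_thickness(t0, t_day, e), 1
                )
            rows.append(row)
    import pandas as pd

    out = RESULTS / "trial_design_published_reconstruction.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out} (thickness arithmetic only; per-layer σ is not published,")
    print("  so the published sample-size cells are checked via the power oracle instead)")


def main() -> None:
    synthetic_table()
    published_reconstruction()


if __name__ == "__main__":
    main()
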