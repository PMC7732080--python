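"""Efficacy adjustment, sample-size calculation and the trial table."""

import numpy as np
import pytest
from statsmodels.stats.power import TTestIndPower

import octdecay as od
from octdecay.datasets import BASELINE_T0, no_drug_points
from octdecay.design import power_two_sample_t
from octdecay.layers import LayerName


class TestEfficacyAdjustment:
    @pytest.mark.parametrize(
        "t0, t_day, eff, printed",
        [
            (47.5, 23.8, 0.20, 28.5),    # GCL, day 30, 20% efficacy
            (47.5, 15.9, 0.50, 31.7),    # GCL, day 60, 50%
            (253.8, 164.1, 0.75, 231.4), # combined inner layers, day 90, 75%
            (22.5, 19.4, 0.10, 19.7),    # RNFL, day 30, 10%
            (332.3, 289.1, 0.30, 302.1), # whole retina, day 30, 30%
        ],
    )
    def test_published_cells_at_one_decimal(self, t0, t_day, eff, printed):
        assert round(od.efficacy_adjusted_thickness(t0, t_day, eff), 1) == printed

    def test_endpoints(self):
        assert od.efficacy_adjusted_thickness(47.5, 23.8, 0.0) == 23.8
        assert od.efficacy_adjusted_thickness(47.5, 23.8, 1.0) == 47.5

    def test_out_of_range_efficacy(self):
        with pytest.raises(ValueError, match="efficacy"):
            od.efficacy_adjusted_thickness(47.5, 23.8, 1.2)

    @pytest.mark.parametrize("eff", np.linspace(0, 1, 11).tolist())
    def test_linear_monotone_in_efficacy(self, eff):
        lo = od.efficacy_adjusted_thickness(47.5, 23.8, eff)
        assert 23.8 <= lo <= 47.5
        if eff < 1.0:
            assert od.efficacy_adjusted_thickness(47.5, 23.8, eff + 1e-3) > lo


class TestEffectSize:
    def test_arithmetic_from_published_cells(self):
        assert od.effect_size(47.5, 23.8, 0.20) == pytest.approx(4.74)
        assert od.effect_size(47.5, 15.9, 0.50) == pytest.approx(15.8)
        assert od.effect_size(47.5, 23.8, 0.0) == 0.0


class TestSampleSize:
    def test_unit_effect_needs_17(self):
        spec = od.PowerSpec(sigma=1.0)
        assert od.sample_size_per_group(1.0, spec) == 17
        # minimality: one fewer misses the power target
        assert power_two_sample_t(16, 1.0, 1.0, 0.05) < 0.8
        assert power_two_sample_t(17, 1.0, 1.0, 0.05) >= 0.8

    def test_floor_engaged_for_huge_effect(self):
        assert od.sample_size_per_group(10.0, od.PowerSpec(sigma=1.0)) == 2

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            od.sample_size_per_group(0.0, od.PowerSpec(sigma=1.0))

    @pytest.mark.parametrize("ratio", [0.3, 0.5, 0.8, 1.2])
    @pytest.mark.parametrize("alpha", [0.01, 0.05])
    def test_matches_statsmodels_solver(self, ratio, alpha):
        # independent cross-check: statsmodels' noncentral-t power solver
        n = od.sample_size_per_group(ratio, od.PowerSpec(alpha=alpha, sigma=1.0))
        ref = TTestIndPower().solve_power(
            effect_size=ratio, alpha=alpha, power=0.8, alternative="two-sided"
        )
        assert n == int(np.ceil(ref))

    def test_monotonicities(self):
        spec = od.PowerSpec(sigma=5.0)
        ns = [od.sample_size_per_group(od.effect_size(47.5, 23.8, e), spec)
              for e in (0.10, 0.20, 0.30, 0.50, 0.75)]
        assert all(a >= b for a, b in zip(ns, ns[1:]))
        n_lo = od.sample_size_per_group(4.74, od.PowerSpec(sigma=4.0))
        n_hi = od.sample_size_per_group(4.74, od.PowerSpec(sigma=6.0))
        assert n_lo <= n_hi

    def test_normal_approximation_within_two_for_moderate_n(self):
        from scipy import stats

        for ratio in (0.3, 0.4, 0.5, 0.7):
            for alpha in (0.01, 0.05, 0.1):
                n = od.sample_size_per_group(ratio, od.PowerSpec(alpha=alpha, sigma=1.0))
                if n < 15:
                    continue
                za = stats.norm.ppf(1 - alpha / 2)
                zb = stats.norm.ppf(0.8)
                n0 = int(np.ceil(2 * (za + zb) ** 2 / ratio**2))
                assert abs(n - n0) <= 2

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            od.PowerSpec(alpha=0.0)
        with pytest.raises(ValueError):
            od.PowerSpec(power=1.0)
        with pytest.raises(ValueError):
            od.PowerSpec(sigma=-1.0)


class TestEmpiricalPower:
    def test_size_under_null(self):
        prop = od.empirical_power(20, 0.0, 1.0, alpha=0.05, reps=20000, seed=9)
        assert abs(prop - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 20000)

    def test_asymptotic_limit(self):
        assert od.empirical_power(1000, 1.0, 1.0, reps=2000, seed=9) > 0.999

    def test_preconditions(self):
        with pytest.raises(ValueError):
            od.empirical_power(1, 1.0, 1.0)
        with pytest.raises(ValueError):
            od.empirical_power(10, 1.0, 1.0, reps=500)


@pytest.fixture(scope="module")
def gcl_fit():
    return od.fit_decay(no_drug_points(LayerName.GCL, include_day0=True))


class TestBuildTrialTable:
    def test_gcl_thickness_cells_reproduced(self, gcl_fit):
        table = od.build_trial_table(
            {LayerName.GCL: gcl_fit},
            {LayerName.GCL: BASELINE_T0[LayerName.GCL]},
            days=[30, 60, 90, 120, 180],
            efficacies=[0.10, 0.20, 0.30, 0.50, 0.75],
        )
        printed = {
            30: (26.2, 28.5, 30.9, 35.6, 41.6),
            60: (19.0, 22.2, 25.4, 31.7, 39.6),
            90: (16.8, 20.2, 23.6, 30.5, 39.0),
            120: (16.1, 19.6, 23.1, 30.1, 38.8),
            180: (15.8, 19.4, 22.9, 29.9, 38.7),
        }
        got = table.table.set_index("day")
        for day, cells in printed.items():
            for eff, cell in zip((10, 20, 30, 50, 75), cells):
                assert got.loc[day, f"t_eff{eff}_um"] == pytest.approx(cell, abs=0.15)

    def test_empty_efficacies(self, gcl_fit):
        table = od.build_trial_table(
            {LayerName.GCL: gcl_fit}, {LayerName.GCL: 47.5}, days=[30], efficacies=[]
        )
        assert list(table.table.columns) == [
            "layer", "day", "t0_um", "t_no_drug_um", "pct_change"
        ]

    def test_low_r2_layer_excluded_and_logged(self, gcl_fit):
        weak = od.fit_decay(no_drug_points(LayerName.INL, include_day0=True))
        weak.r_squared = 0.32
        table = od.build_trial_table(
            {LayerName.GCL: gcl_fit, LayerName.INL: weak},
            {LayerName.GCL: 47.5, LayerName.INL: 40.1},
            days=[30], efficacies=[0.2],
        )
        assert set(table.table["layer"]) == {"GCL"}
        assert any("INL" in line for line in table.excluded)

    def test_force_layer_overrides_gate(self, gcl_fit):
        weak = od.fit_decay(no_drug_points(LayerName.INL, include_day0=True))
        weak.r_squared = 0.32
        table = od.build_trial_table(
            {LayerName.INL: weak}, {LayerName.INL: 40.1},
            days=[30], efficacies=[0.2], force_layers=(LayerName.INL,),
        )
        assert set(table.table["layer"]) == {"INL"}

    def test_n_non_increasing_in_efficacy(self, gcl_fit):
        table = od.build_trial_table(
            {LayerName.GCL: gcl_fit}, {LayerName.GCL: 47.5},
            days=[30, 90], efficacies=[0.10, 0.20, 0.30, 0.50, 0.75],
        )
        for _, row in table.table.iterrows():
            ns = [row[f"n_eff{e}"] for e in (10, 20, 30, 50, 75)]
            assert all(a >= b for a, b in zip(ns, ns[1:]))
            assert all(n >= 2 for n in ns)

    def test_invalid_days_or_efficacies(self, gcl_fit):
        with pytest.raises(ValueError):
            od.build_trial_table({LayerName.GCL: gcl_fit}, {LayerName.GCL: 47.5},
                                 days=[-1], efficacies=[0.2])
        with pytest.raises(ValueError):
            od.build_trial_table({LayerName.GCL: gcl_fit}, {LayerName.GCL: 47.5},
                                 days=[30], efficacies=[1.5])

    def test_report_rounding_half_up(self, gcl_fit):
        table = od.build_trial_table(
            {LayerName.GCL: gcl_fit}, {LayerName.GCL: 47.5},
            days=[30], efficacies=[0.2],
        )
        report = table.to_report()
        raw = table.table["t_eff20_um"].iloc[0]
        assert report["t_eff20_um"].iloc[0] == pytest.approx(round(raw, 1), abs=0.051)
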