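"""Cohort I/O, ETDRS aggregation, QC exclusions and control baselines."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import octdecay as od
from octdecay.cohort import (
    CohortSchemaError,
    EtdrsSectorGrid,
    RowValidationError,
    cohort_round_trip,
)
from octdecay.layers import RING3_QUADRANTS, LayerName, Sector
from tests.conftest import TIDY_HEADER, tidy_csv


class TestReadCohortTable:
    def test_minimal_two_row_file(self, two_row_csv):
        cohort = od.read_cohort_table(two_row_csv)
        assert len(cohort) == 2
        assert cohort.n_scans == 2
        assert set(cohort.df["group"]) == {"CRAO", "CONTROL"}

    def test_missing_required_column_names_it(self):
        src = io.StringIO("patient_id,eye,group,layer,sector,thickness_um\nP1,OD,CRAO,GCL,RING3_MEAN,30\n")
        with pytest.raises(CohortSchemaError, match="days_since_onset"):
            od.read_cohort_table(src)

    def test_row_errors_carry_line_numbers(self):
        src = tidy_csv(
            [
                "P1,OD,CRAO,38,GCL,RING3_MEAN,31.2,True",
                "P1,OD,CRAO,-5,GCL,RING3_MEAN,30.0,True",
                "P1,OD,CRAO,60,GCL,RING3_MEAN,not_a_number,True",
                "P1,OD,CRAO,90,NOSUCHLAYER,RING3_MEAN,28.0,True",
            ]
        )
        with pytest.raises(RowValidationError) as err:
            od.read_cohort_table(src)
        msgs = "\n".join(err.value.errors)
        assert "line 3" in msgs and "negative" in msgs
        assert "line 4" in msgs and "non-numeric thickness" in msgs
        assert "line 5" in msgs and "NOSUCHLAYER" in msgs

    def test_schema_mapping_for_renamed_columns(self):
        src = io.StringIO(
            "id,side,arm,day,tissue,um\nP1,OD,CRAO,12,GCL,33.5\n"
        )
        schema = od.ColumnSchema(
            patient="id", eye="side", group="arm", day="day",
            layer="tissue", thickness="um", sector=None, qc=None,
        )
        cohort = od.read_cohort_table(src, schema=schema)
        assert cohort.df.loc[0, "sector"] == Sector.RING3_MEAN.value
        assert bool(cohort.df.loc[0, "qc_pass"]) is True

    def test_duplicate_observations_rejected(self):
        src = tidy_csv(
            [
                "P1,OD,CRAO,38,GCL,RING3_MEAN,31.2,True",
                "P1,OD,CRAO,38,GCL,RING3_MEAN,30.0,True",
            ]
        )
        with pytest.raises(RowValidationError, match="duplicate"):
            od.read_cohort_table(src)

    def test_round_trip_is_identity(self, default_cohort):
        cohort, _ = default_cohort
        assert cohort_round_trip(cohort).equals(cohort)

    def test_workbook_reader_matches_csv_reader(self, tmp_path, default_cohort):
        cohort, _ = default_cohort
        xlsx = tmp_path / "cohort.xlsx"
        cohort.df.head(200).to_excel(xlsx, index=False)
        from_xlsx = od.read_cohort_workbook(str(xlsx))
        assert len(from_xlsx) == 200
        assert np.allclose(
            from_xlsx.df["thickness_um"], cohort.df.head(200)["thickness_um"]
        )


class TestMiddleRingMean:
    def test_mean_of_four_quadrants(self):
        grid = EtdrsSectorGrid(dict(zip(RING3_QUADRANTS, (10.0, 20.0, 30.0, 40.0))))
        assert od.middle_ring_mean(grid) == 25.0

    def test_equal_quadrants_identity(self):
        grid = EtdrsSectorGrid({q: 47.5 for q in RING3_QUADRANTS})
        assert od.middle_ring_mean(grid) == 47.5

    def test_missing_quadrant_named(self):
        grid = EtdrsSectorGrid({q: 30.0 for q in RING3_QUADRANTS[:3]})
        with pytest.raises(ValueError, match="RING3_TEMPORAL"):
            od.middle_ring_mean(grid)

    @given(
        st.lists(
            st.floats(min_value=1.0, max_value=900.0, allow_nan=False),
            min_size=4, max_size=4,
        ),
        st.permutations(range(4)),
    )
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant(self, vals, perm):
        a = EtdrsSectorGrid(dict(zip(RING3_QUADRANTS, vals)))
        b = EtdrsSectorGrid(dict(zip(RING3_QUADRANTS, [vals[i] for i in perm])))
        assert od.middle_ring_mean(a) == pytest.approx(od.middle_ring_mean(b))

    def test_out_of_range_thickness_rejected(self):
        with pytest.raises(ValueError, match="must be in"):
            EtdrsSectorGrid({Sector.RING3_NASAL: 1200.0})

    def test_collapse_quadrant_cohort(self):
        cfg = od.SyntheticConfig(
            n_crao_patients=3, n_control_eyes=2, emit_quadrants=True,
            qc_fail_prob=0.0, seed=5,
        )
        cohort, _ = od.generate_cohort(cfg)
        assert set(cohort.df["sector"]) <= {q.value for q in RING3_QUADRANTS}
        collapsed = od.collapse_to_middle_ring(cohort)
        assert set(collapsed.df["sector"]) == {Sector.RING3_MEAN.value}
        # per construction the quadrant mean equals the generated mean value
        one = cohort.df[
            (cohort.df["patient_id"] == "P001") & (cohort.df["layer"] == "GCL")
        ]
        day = one["days_since_onset"].iloc[0]
        quads = one[one["days_since_onset"] == day]["thickness_um"]
        got = collapsed.df[
            (collapsed.df["patient_id"] == "P001")
            & (collapsed.df["layer"] == "GCL")
            & (collapsed.df["days_since_onset"] == day)
        ]["thickness_um"].iloc[0]
        assert got == pytest.approx(quads.mean())


class TestApplyExclusions:
    def _cohort(self, flags):
        rows = [
            f"P{i},OD,CRAO,{10 * i},GCL,RING3_MEAN,30.0,{f}"
            for i, f in enumerate(flags, start=1)
        ]
        return od.read_cohort_table(tidy_csv(rows))

    def test_flagged_scan_removed_and_logged(self):
        cohort = self._cohort(["True", "False", "True"])
        kept, log = od.apply_exclusions(cohort)
        assert len(kept) == 2
        assert log.removed == [
            {"patient_id": "P2", "eye": "OD", "days_since_onset": 20.0}
        ]

    def test_no_flags_identity_empty_log(self):
        cohort = self._cohort(["True", "True"])
        kept, log = od.apply_exclusions(cohort)
        assert kept.equals(cohort)
        assert log.removed == [] and log.warnings == []

    def test_all_flagged_empty_with_warning(self):
        cohort = self._cohort(["False", "False"])
        kept, log = od.apply_exclusions(cohort)
        assert len(kept) == 0
        assert any("all records excluded" in w for w in log.warnings)

    def test_idempotent(self, default_cohort):
        cohort, _ = default_cohort
        once, _ = od.apply_exclusions(cohort)
        twice, _ = od.apply_exclusions(once)
        assert twice.equals(once)


class TestControlBaseline:
    def test_one_point_per_control_eye(self):
        cfg = od.SyntheticConfig(n_control_eyes=15, n_crao_patients=0, qc_fail_prob=0.0, seed=2)
        cohort, _ = od.generate_cohort(cfg)
        points = od.baseline_from_controls(cohort, LayerName.GCL)
        assert len(points) == 15
        assert all(day == 0.0 for day, _ in points)

    def test_control_missing_layer_skipped(self):
        rows = [
            "C1,OD,CONTROL,0,GCL,RING3_MEAN,47.0,True",
            "C2,OS,CONTROL,0,RNFL,RING3_MEAN,22.0,True",
        ]
        cohort = od.read_cohort_table(tidy_csv(rows))
        points = od.baseline_from_controls(cohort, LayerName.GCL)
        assert points == [(0.0, 47.0)]

    def test_zero_controls_empty_list(self):
        rows = ["P1,OD,CRAO,10,GCL,RING3_MEAN,30.0,True"]
        cohort = od.read_cohort_table(tidy_csv(rows))
        assert od.baseline_from_controls(cohort, LayerName.GCL) == []


class TestControlSummary:
    def _controls(self, values, layer="GCL"):
        rows = [
            f"C{i},OD,CONTROL,0,{layer},RING3_MEAN,{v},True"
            for i, v in enumerate(values, start=1)
        ]
        return od.read_cohort_table(tidy_csv(rows))

    def test_constant_values_zero_sd(self):
        s = od.control_summary(self._controls([47.5, 47.5, 47.5]))
        assert s.loc[0, "mean_um"] == pytest.approx(47.5)
        assert s.loc[0, "sd_um"] == pytest.approx(0.0)

    def test_two_point_closed_form(self):
        s = od.control_summary(self._controls([10.0, 20.0]))
        assert s.loc[0, "mean_um"] == pytest.approx(15.0)
        assert s.loc[0, "sd_um"] == pytest.approx(np.sqrt(50.0))
        assert s.loc[0, "n"] == 2

    def test_single_eye_sd_undefined(self):
        s = od.control_summary(self._controls([42.0]))
        assert np.isnan(s.loc[0, "sd_um"])

    def test_mean_within_sampling_bound_of_truth(self):
        # 15 controls around the configured normal mean: |mean - mu| < 4 sigma/sqrt(15)
        cfg = od.SyntheticConfig(n_control_eyes=15, n_crao_patients=0, qc_fail_prob=0.0, seed=77)
        cohort, _ = od.generate_cohort(cfg)
        s = od.control_summary(cohort).set_index("layer")
        truth = cfg.layers[LayerName.GCL]
        sigma = np.hypot(truth.control_sd, truth.noise_sd)
        assert abs(s.loc["GCL", "mean_um"] - truth.initial) < 4 * sigma / np.sqrt(15)

    def test_duplicating_records_preserves_mean(self):
        base = self._controls([40.0, 44.0, 51.0])
        dup_rows = [
            f"C{i},OD,CONTROL,0,GCL,RING3_MEAN,{v},True"
            for i, v in enumerate([40.0, 44.0, 51.0] * 2, start=1)
        ]
        dup = od.read_cohort_table(tidy_csv(dup_rows))
        s1 = od.control_summary(base)
        s2 = od.control_summary(dup)
        assert s2.loc[0, "mean_um"] == pytest.approx(s1.loc[0, "mean_um"])
        assert s2.loc[0, "n"] == 2 * s1.loc[0, "n"]
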