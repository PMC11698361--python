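import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from akistage.data_model import (
    HourlyFrame,
    UMOL_L_PER_MG_DL,
    collapse_hourly,
    convert_creatinine_units,
    grid_span,
    hour_indices,
    validate_inputs,
)


class TestConvertCreatinineUnits:
    @pytest.mark.parametrize(
        "value, unit, expected",
        [
            (1.0, "mg_dl", 1.0),
            (88.42, "umol_l", 1.0),
            (176.84, "umol_l", 2.0),
        ],
    )
    def test_known_conversions(self, value, unit, expected):
        assert convert_creatinine_units(value, unit) == pytest.approx(expected)

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError, match="unknown creatinine unit"):
            convert_creatinine_units(1.0, "mmol_dl")

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            convert_creatinine_units(0.0, "mg_dl")

    @given(st.floats(min_value=0.1, max_value=50.0))
    def test_round_trip(self, mg_dl):
        si = mg_dl * UMOL_L_PER_MG_DL
        back = convert_creatinine_units(si, "umol_l")
        assert back == pytest.approx(mg_dl, rel=1e-9)


class TestValidateInputs:
    def test_all_valid_tables_yield_no_violations(self, toy_tables):
        report = validate_inputs(*toy_tables)
        assert report.violations == []
        assert report.passed

    def test_negative_volume_is_hard_violation(self, toy_tables):
        uo, scr, rrt, demo = toy_tables
        uo = uo.copy()
        uo.loc[0, "volume_ml"] = -5.0
        report = validate_inputs(uo, scr, rrt, demo)
        assert [v.message for v in report.hard_violations] == ["negative volume"]
        assert not report.passed

    def test_missing_demographics_row_is_single_hard_violation(self, toy_tables):
        uo, scr, rrt, demo = toy_tables
        report = validate_inputs(uo, scr, rrt, demo[demo["subject_id"] != "b"])
        assert len(report.hard_violations) == 1
        assert report.hard_violations[0].subject_id == "b"

    def test_missing_weight_is_hard_violation(self, toy_tables):
        uo, scr, rrt, demo = toy_tables
        demo = demo.copy()
        demo.loc[0, "weight_kg"] = np.nan
        report = validate_inputs(uo, scr, rrt, demo)
        assert any("weight" in v.message for v in report.hard_violations)

    def test_paediatric_age_warns_but_passes(self, toy_tables):
        uo, scr, rrt, demo = toy_tables
        demo = demo.copy()
        demo.loc[1, "age_years"] = 12.0
        report = validate_inputs(uo, scr, rrt, demo)
        assert report.passed
        assert any("age" in v.message for v in report.violations)

    def test_idempotent_and_row_order_insensitive(self, toy_tables):
        uo, scr, rrt, demo = toy_tables
        uo = uo.copy()
        uo.loc[0, "volume_ml"] = -1.0
        first = validate_inputs(uo, scr, rrt, demo)
        again = validate_inputs(uo, scr, rrt, demo)
        shuffled = validate_inputs(
            uo.iloc[::-1].reset_index(drop=True), scr, rrt, demo.iloc[::-1]
        )
        assert first.violations == again.violations == shuffled.violations


class TestHourlyCollapse:
    def test_intra_hour_volumes_are_summed(self):
        t0 = pd.Timestamp("2023-01-01 10:05:00")
        df = pd.DataFrame(
            {
                "subject_id": ["a"] * 3,
                "timestamp": [t0, t0 + pd.Timedelta(minutes=30), t0 + pd.Timedelta(hours=2)],
                "volume_ml": [10.0, 20.0, 40.0],
            }
        )
        out = collapse_hourly(df, "volume_ml", "sum")
        assert list(out["volume_ml"]) == [30.0, 40.0]
        assert out["hour"].iloc[0] == pd.Timestamp("2023-01-01 10:00:00")

    def test_last_creatinine_in_hour_wins(self):
        t0 = pd.Timestamp("2023-01-01 10:00:00")
        df = pd.DataFrame(
            {
                "subject_id": ["a", "a"],
                "timestamp": [t0 + pd.Timedelta(minutes=50), t0 + pd.Timedelta(minutes=10)],
                "scr_mg_dl": [2.0, 1.0],
            }
        )
        out = collapse_hourly(df, "scr_mg_dl", "last")
        assert list(out["scr_mg_dl"]) == [2.0]

    def test_dialysis_flags_are_or_ed(self):
        t0 = pd.Timestamp("2023-01-01 10:00:00")
        df = pd.DataFrame(
            {
                "subject_id": ["a", "a"],
                "timestamp": [t0, t0 + pd.Timedelta(minutes=30)],
                "active": [False, True],
            }
        )
        out = collapse_hourly(df, "active", "any")
        assert list(out["active"]) == [True]

    def test_grid_span_and_indices_cover_all_signals(self):
        a = pd.DataFrame({"hour": [pd.Timestamp("2023-01-01 02:00")], "x": [1.0]})
        b = pd.DataFrame({"hour": [pd.Timestamp("2023-01-01 07:00")], "x": [1.0]})
        anchor, n = grid_span({"a": a, "b": b})
        assert anchor == pd.Timestamp("2023-01-01 02:00")
        assert n == 6
        assert list(hour_indices(b, anchor)) == [5]


class TestHourlyFrame:
    def test_rejects_negative_urine_and_bad_weight(self):
        with pytest.raises(ValueError, match=">= 0"):
            HourlyFrame("a", pd.Timestamp("2023-01-01"), [-1.0], [1.0], [False], 70.0)
        with pytest.raises(ValueError, match="weight"):
            HourlyFrame("a", pd.Timestamp("2023-01-01"), [1.0], [1.0], [False], 0.0)

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            HourlyFrame("a", pd.Timestamp("2023-01-01"), [1.0, 2.0], [1.0], [False], 70.0)
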