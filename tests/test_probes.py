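import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from akistage.probes import (
    ProbeConfig,
    absolute_scr_stage_series,
    dialysis_stage_series,
    relative_scr_stage_series,
    uo_stage_series,
)

WEIGHT = 70.0


def _rates(rate_hours):
    """Hourly ml series for a 70 kg adult from (rate, hours) segments."""
    out = []
    for rate, hours in rate_hours:
        out.extend([rate * WEIGHT] * hours)
    return np.array(out)


def _bruteforce_uo(rates_per_kg, cfg=ProbeConfig()):
    """Exhaustive all-window scan, independent of the implementation."""
    eps = cfg.epsilon
    n = len(rates_per_kg)
    out = []
    for t in range(n):
        if np.isnan(rates_per_kg[t]):
            out.append(np.nan)
            continue
        best = 0
        for w in range(1, t + 2):
            window = rates_per_kg[t - w + 1 : t + 1]
            if np.isnan(window).any():
                break
            m = window.mean()
            if w >= 6 and m < 0.5 - eps:
                best = max(best, 1)
            if w >= 12 and m < 0.5 - eps:
                best = max(best, 2)
            if w >= 12 and m <= cfg.anuria_threshold + eps:
                best = max(best, 3)
            if w >= 24 and m < 0.3 - eps:
                best = max(best, 3)
        out.append(best)
    return np.array(out, dtype=float)


class TestUrineOutputProbe:
    @pytest.mark.parametrize(
        "segments, expected_max",
        [
            # sustained 0.4 ml/kg/h: >= 6 h is stage 1, >= 12 h stage 2
            ([(1.0, 6), (0.4, 8), (1.0, 6)], 1),
            ([(1.0, 3), (0.4, 14), (1.0, 3)], 2),
            # 0.2 ml/kg/h over >= 24 h is stage 3
            ([(0.2, 26)], 3),
            # strict anuria for >= 12 h is stage 3
            ([(0.0, 13)], 3),
            # normal output never stages
            ([(1.0, 30)], 0),
        ],
    )
    def test_kdigo_duration_thresholds(self, segments, expected_max):
        stage = uo_stage_series(_rates(segments), WEIGHT)
        assert int(np.nanmax(stage)) == expected_max

    def test_stage_onset_hours(self):
        # low output starting at hour 0: stage 1 from the 6th hour on
        stage = uo_stage_series(_rates([(0.4, 14)]), WEIGHT)
        np.testing.assert_array_equal(stage[:5], 0.0)
        np.testing.assert_array_equal(stage[5:11], 1.0)
        np.testing.assert_array_equal(stage[11:], 2.0)

    def test_missing_hours_break_windows(self):
        uo = _rates([(0.4, 5)]).tolist() + [np.nan] + _rates([(0.4, 5)]).tolist()
        stage = uo_stage_series(np.array(uo), WEIGHT)
        assert np.isnan(stage[5])
        # neither 5-hour run reaches the 6-hour duration criterion
        np.testing.assert_array_equal(stage[:5], 0.0)
        np.testing.assert_array_equal(stage[6:], 0.0)

    def test_exactly_at_flow_threshold_does_not_stage(self):
        # "below 0.5" is strict: 0.5 ml/kg/h exactly is not oliguria
        stage = uo_stage_series(_rates([(0.5, 24)]), WEIGHT)
        np.testing.assert_array_equal(stage, 0.0)

    def test_configurable_anuria_threshold(self):
        stage = uo_stage_series(_rates([(0.08, 12)]), WEIGHT, ProbeConfig(anuria_threshold=0.1))
        assert stage[11] == 3.0

    def test_rejects_non_positive_weight(self):
        with pytest.raises(ValueError):
            uo_stage_series(np.ones(3), 0.0)

    @given(
        rates=hnp.arrays(
            float,
            st.integers(1, 40),
            elements=st.one_of(
                st.sampled_from([0.0, 0.1, 0.25, 0.3, 0.4, 0.5, 0.7, 1.2]),
                st.just(np.nan),
            ),
        )
    )
    def test_matches_all_window_scan(self, rates):
        stage = uo_stage_series(rates * WEIGHT, WEIGHT)
        np.testing.assert_array_equal(stage, _bruteforce_uo(rates))

    @given(
        rates=hnp.arrays(float, st.integers(6, 30), elements=st.floats(0.0, 2.0)),
        data=st.data(),
    )
    def test_lowering_output_never_lowers_a_stage(self, rates, data):
        idx = data.draw(st.integers(0, len(rates) - 1))
        before = uo_stage_series(rates * WEIGHT, WEIGHT)
        lowered = rates.copy()
        lowered[idx] = lowered[idx] / 2
        after = uo_stage_series(lowered * WEIGHT, WEIGHT)
        assert np.all(after >= before)


class TestRelativeCreatinineProbe:
    @pytest.mark.parametrize(
        "scr, expected",
        [(2.5, 2), (1.6, 1), (1.0, 0), (1.49, 0), (1.5, 1), (2.0, 2), (3.0, 3), (3.5, 3)],
    )
    def test_fold_change_bands(self, scr, expected):
        stage = relative_scr_stage_series(np.array([scr]), np.array([1.0]))
        assert stage[0] == expected

    def test_undefined_where_series_missing(self):
        stage = relative_scr_stage_series(
            np.array([np.nan, 2.0]), np.array([1.0, np.nan])
        )
        assert np.isnan(stage).all()

    def test_rejects_non_positive_baseline(self):
        with pytest.raises(ValueError, match="baseline"):
            relative_scr_stage_series(np.array([1.0]), np.array([0.0]))

    @given(
        scr=hnp.arrays(float, 12, elements=st.floats(0.3, 9.0)),
        base=hnp.arrays(float, 12, elements=st.floats(0.3, 3.0)),
        scale=st.floats(0.05, 20.0),
    )
    def test_scale_invariance(self, scr, base, scale):
        plain = relative_scr_stage_series(scr, base)
        scaled = relative_scr_stage_series(scr * scale, base * scale)
        np.testing.assert_array_equal(plain, scaled)

    @given(
        scr=hnp.arrays(float, 8, elements=st.floats(0.3, 9.0)),
        data=st.data(),
    )
    def test_raising_creatinine_never_lowers_a_stage(self, scr, data):
        base = np.ones(8)
        idx = data.draw(st.integers(0, 7))
        before = relative_scr_stage_series(scr, base)
        raised = scr.copy()
        raised[idx] = raised[idx] * 2
        after = relative_scr_stage_series(raised, base)
        assert np.all(after >= before)


class TestAbsoluteCreatinineProbe:
    @pytest.mark.parametrize(
        "scr, base, expected",
        [
            (4.2, 1.0, 3),  # >= 4 mg/dl irrespective of baseline
            (4.2, np.nan, 3),
            (1.35, 1.0, 1),  # rise >= 0.3 mg/dl
            (1.3, 1.0, 1),
            (1.2, 1.0, 0),
        ],
    )
    def test_threshold_semantics(self, scr, base, expected):
        stage = absolute_scr_stage_series(np.array([scr]), np.array([base]))
        assert stage[0] == expected

    def test_undefined_without_baseline_below_stage3_level(self):
        stage = absolute_scr_stage_series(np.array([1.2]), np.array([np.nan]))
        assert np.isnan(stage[0])

    def test_undefined_where_creatinine_missing(self):
        stage = absolute_scr_stage_series(np.array([np.nan]), np.array([1.0]))
        assert np.isnan(stage[0])


class TestDialysisProbe:
    def test_pointwise_map(self):
        stage = dialysis_stage_series(np.array([False, True, False]))
        np.testing.assert_array_equal(stage, [0.0, 3.0, 0.0])


class TestProbeConfig:
    def test_rejects_anuria_threshold_at_stage3_flow(self):
        with pytest.raises(ValueError):
            ProbeConfig(anuria_threshold=0.3)

    def test_rejects_negative_epsilon(self):
        with pytest.raises(ValueError):
            ProbeConfig(epsilon=-1e-9)
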