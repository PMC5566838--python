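"""Injection QC, segment-wise VSMOW calibration, and sample aggregation."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from methatrace import (
    AnalysisRun,
    CalibrationError,
    CalibrationSegment,
    IsotopeStandard,
    QCError,
    R_VSMOW,
    build_calibration_segments,
    calibrate_delta,
    delta_to_ratio,
    qc_exclusions,
    qc_filter,
    ratio_to_delta,
    summarize_sample,
)
from methatrace.lwia import segment_for

from conftest import make_round, make_simple_run


class TestQcFilter:
    @pytest.mark.parametrize("rounds,expected", [(4, 20), (2, 10)])
    def test_last_five_rule_retains_half(self, rounds, expected):
        run = make_simple_run({"s1": -30.0}, rounds=rounds)
        retained = qc_filter(run)
        sample = [r for r in retained if r.sample_id == "s1"]
        assert len(sample) == expected
        assert all(r.injection_index >= 6 for r in sample)

    def test_retention_scales_with_sample_count(self):
        run = make_simple_run({f"s{i}": -30.0 for i in range(3)})
        retained = qc_filter(run)
        sample = [r for r in retained if r.sample_id.startswith("s")]
        assert len([r for r in sample if not r.sample_id.startswith("std")]) == 60

    def test_unstable_temperature_round_fully_excluded(self):
        injections = make_round("a", 1, [-30.0] * 10, 1, temp=0.4)
        injections += make_round("a", 2, [-30.0] * 10, 11)
        run = AnalysisRun(injections=injections)
        retained = qc_filter(run)
        assert {r.round_index for r in retained} == {2}
        assert len(retained) == 5

    def test_rising_pressure_excluded(self):
        injections = make_round("a", 1, [-30.0] * 10, 1, pressure=True)
        injections += make_round("a", 2, [-30.0] * 10, 11)
        retained = qc_filter(AnalysisRun(injections=injections))
        assert all(not r.pressure_rising for r in retained)

    def test_fully_excluded_sample_raises_not_silently_dropped(self):
        injections = make_round("dead", 1, [-30.0] * 10, 1, temp=0.5)
        injections += make_round("ok", 1, [-30.0] * 10, 11)
        with pytest.raises(QCError, match="dead"):
            qc_filter(AnalysisRun(injections=injections))

    def test_short_round_keeps_positional_tail(self):
        # rule is positional, not proportional: 3-injection round keeps all 3
        injections = make_round("a", 1, [-30.0] * 3, 1)
        retained = qc_filter(AnalysisRun(injections=injections))
        assert len(retained) == 3

    def test_missing_diagnostics_treated_as_passing(self):
        from methatrace import InjectionRecord

        injections = [
            InjectionRecord("a", 1, i + 1, -30.0, None, None, i + 1) for i in range(10)
        ]
        assert len(qc_filter(AnalysisRun(injections=injections))) == 5

    def test_exclusions_log_each_injection_once_with_rule(self):
        injections = make_round("a", 1, [-30.0] * 10, 1)
        injections += make_round("a", 2, [-30.0] * 10, 11, temp=0.4)
        run = AnalysisRun(injections=injections)
        exclusions = qc_exclusions(run)
        excluded_ids = [id(i) for i, _ in exclusions]
        assert len(excluded_ids) == len(set(excluded_ids))
        rules = {}
        for inj, rule in exclusions:
            rules.setdefault(rule, 0)
            rules[rule] += 1
        # 5 early per round x2 rounds; 5 temp-flagged in round 2's tail
        assert rules == {"early_injection": 10, "temp_change": 5}
        retained = qc_filter(run)
        assert len(retained) + len(exclusions) == len(run.injections)


class TestCalibration:
    def test_partition_into_segments_of_forty(self):
        run = _segmented_run(n_blocks=3)  # 3 x 40 injections
        segments = build_calibration_segments(run, segment_size=40)
        assert len(segments) == 3
        assert [(s.start_position, s.end_position) for s in segments] == [
            (1, 41),
            (41, 81),
            (81, 121),
        ]

    def test_single_segment_when_run_fits(self):
        run = _segmented_run(n_blocks=1)
        assert len(build_calibration_segments(run, segment_size=40)) == 1

    def test_trailing_segment_missing_standard_is_an_error(self):
        # 40-block plus a 5-injection tail with no standards
        run = _segmented_run(n_blocks=1, tail_sample=5)
        with pytest.raises(CalibrationError, match=r"\[41, 46\)"):
            build_calibration_segments(run, segment_size=40)

    def test_two_point_map_interpolates_between_anchors(self):
        seg = _fit_segment((2.0, 0.5), (-70.0, -73.4))
        assert calibrate_delta(-34.0, seg) == pytest.approx(-36.45, abs=1e-10)

    def test_identity_anchors_give_identity_map(self):
        seg = _fit_segment((0.5, 0.5), (-73.4, -73.4))
        assert calibrate_delta(-10.0, seg) == pytest.approx(-10.0, abs=1e-12)

    def test_anchor_values_reproduced_exactly(self):
        seg = _fit_segment((2.0, 0.5), (-70.0, -73.4))
        assert calibrate_delta(2.0, seg) == pytest.approx(0.5, rel=1e-12)
        assert calibrate_delta(-70.0, seg) == pytest.approx(-73.4, rel=1e-12)

    def test_segment_mean_of_each_standard_maps_to_known_value(self):
        run = _segmented_run(n_blocks=3, jitter=0.05)
        segments = build_calibration_segments(run, segment_size=40)
        retained = qc_filter(run)
        for seg in segments:
            for sid, std in run.standards.items():
                vals = [
                    r.raw_delta_d
                    for r in retained
                    if r.sample_id == sid and seg.covers(r.global_position)
                ]
                mean = sum(vals) / len(vals)
                assert calibrate_delta(mean, seg) == pytest.approx(
                    std.known_delta_d, rel=1e-12, abs=1e-12
                )

    @given(st.floats(-200, 200), st.floats(-200, 200))
    @settings(max_examples=50, deadline=None)
    def test_monotone_increasing_for_positive_slope(self, a, b):
        seg = CalibrationSegment(1, 41, slope=1.03, intercept=-2.0)
        if a + 1e-6 < b:  # gap large enough to survive float rounding
            assert calibrate_delta(a, seg) < calibrate_delta(b, seg)


class TestDeltaRatioConversion:
    @pytest.mark.parametrize(
        "delta,expected",
        [(0.0, 155.76e-6), (0.5, 155.83788e-6), (-73.4, 144.327216e-6)],
    )
    def test_reference_conversions(self, delta, expected):
        assert delta_to_ratio(delta) == pytest.approx(expected, rel=1e-9)

    def test_nonphysical_delta_rejected(self):
        with pytest.raises(ValueError):
            delta_to_ratio(-1000.0)

    @given(st.floats(-999.0, 1000.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_recovers_delta(self, delta):
        assert ratio_to_delta(delta_to_ratio(delta)) == pytest.approx(
            delta, abs=1e-10
        )

    def test_configurable_reference_ratio(self):
        assert delta_to_ratio(0.0, r_vsmow=1.0e-4) == pytest.approx(1.0e-4)


class TestSummarize:
    def test_constant_injections_give_zero_se(self, identity_run):
        retained = qc_filter(identity_run)
        segments = build_calibration_segments(identity_run, segment_size=200)
        m = summarize_sample("s1", retained, segments)
        assert m.n_used == 20
        assert m.se_d_h == pytest.approx(0.0, abs=1e-15)
        assert m.mean_delta_d == pytest.approx(-34.0, abs=1e-9)
        assert m.mean_d_h == pytest.approx(R_VSMOW * (1 - 34.0 / 1000), rel=1e-12)

    def test_mean_and_se_use_n_minus_one_convention(self):
        # injected deltas chosen so calibrated ratios are {2.05,...} x R/(...)
        from methatrace import InjectionRecord

        seg = [CalibrationSegment(1, 100, 1.0, 0.0)]
        vals = [2.05, 2.01, 1.96, 2.08, 1.86]
        recs = [
            InjectionRecord("x", 1, i + 1, v, 0.0, False, i + 1)
            for i, v in enumerate(vals)
        ]
        m = summarize_sample("x", recs, seg)
        # aggregation convention on the calibrated ratios
        ratios = [delta_to_ratio(v) for v in vals]
        mean = sum(ratios) / 5
        sd = math.sqrt(sum((r - mean) ** 2 for r in ratios) / 4)
        assert m.mean_d_h == pytest.approx(mean, rel=1e-12)
        assert m.se_d_h == pytest.approx(sd / math.sqrt(5), rel=1e-12)

    def test_single_injection_warns_and_zero_se(self):
        from methatrace import InjectionRecord

        seg = [CalibrationSegment(1, 10, 1.0, 0.0)]
        recs = [InjectionRecord("x", 1, 1, -10.0, 0.0, False, 1)]
        with pytest.warns(UserWarning, match="single retained injection"):
            m = summarize_sample("x", recs, seg)
        assert m.se_d_h == 0.0
        assert m.mean_delta_d == pytest.approx(-10.0)


def _fit_segment(anchor1, anchor2):
    """Segment fitted from two (measured, known) standard anchors."""
    run = make_simple_run({}, std_values=(anchor1, anchor2))
    return build_calibration_segments(run, segment_size=40)[0]


def _segmented_run(n_blocks, jitter=0.0, tail_sample=0):
    """Blocks of 40: std1 round, std2 round, sample 2 rounds, per block."""
    injections = []
    standards = {
        "std1": IsotopeStandard("std1", 0.5),
        "std2": IsotopeStandard("std2", -73.4),
    }
    pos = 1
    for b in range(n_blocks):
        j = jitter * (b + 1)
        injections += make_round("std1", b + 1, [2.0 + j] * 10, pos)
        pos += 10
        injections += make_round("std2", b + 1, [-70.0 - j] * 10, pos)
        pos += 10
        for r in (1, 2):
            injections += make_round("s1", 2 * b + r, [-34.0] * 10, pos)
            pos += 10
    if tail_sample:
        injections += make_round("s1", 99, [-34.0] * tail_sample, pos)
    return AnalysisRun(injections=injections, standards=standards)


def test_segment_for_rejects_uncovered_position():
    seg = CalibrationSegment(1, 41, 1.0, 0.0)
    assert segment_for([seg], 40) is seg
    with pytest.raises(CalibrationError):
        segment_for([seg], 41)
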