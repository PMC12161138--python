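"""Gap detection, PCHIP reconstruction, removal policy, coverage stats."""

import numpy as np
import pytest

from cgmetrics import (
    GlucoseTrace,
    RunConfig,
    completeness_rate,
    detect_gaps,
    monitoring_days,
    pchip_reconstruct,
    remove_missing_periods,
)

from conftest import START, make_trace
from oracles import fritsch_carlson_eval, oracle_completeness, oracle_gap_indices


def _delete(trace, indices):
    keep = np.ones(len(trace), bool)
    keep[list(indices)] = False
    return GlucoseTrace(
        timestamps=trace.timestamps[keep], values=trace.values[keep], subject_id=trace.subject_id
    )


class TestDetectGaps:
    def test_perfect_grid_no_gaps(self, cfg):
        trace = make_trace(np.full(100, 120.0))
        assert detect_gaps(trace, cfg) == []

    def test_single_deleted_sample(self, cfg):
        trace = _delete(make_trace(np.full(100, 120.0)), [50])
        gaps = detect_gaps(trace, cfg)
        assert len(gaps) == 1
        assert gaps[0].n_missing_expected == 1
        assert gaps[0].duration_min == pytest.approx(10.0)

    def test_k_nonadjacent_deletions_give_k_gaps(self, cfg):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = 200
            trace = make_trace(rng.uniform(60, 300, n))
            candidates = rng.choice(np.arange(2, n - 2, 2), size=8, replace=False)
            degraded = _delete(trace, candidates)
            gaps = detect_gaps(degraded, cfg)
            ts_min = (degraded.timestamps - degraded.timestamps[0]) / np.timedelta64(60, "s")
            expected = oracle_gap_indices(list(ts_min.astype(float)), 5.0, cfg.gap_threshold_min)
            assert len(gaps) == len(expected) == len(candidates)

    def test_fewer_than_two_samples(self, cfg):
        assert detect_gaps(make_trace([100.0]), cfg) == []

    def test_minutes_tolerance_unit(self):
        cfg = RunConfig(sampling_tolerance=2.0, tolerance_unit="minutes")
        assert cfg.gap_threshold_min == pytest.approx(7.0)


class TestPchipReconstruct:
    def test_linear_data_reproduced_exactly(self, cfg):
        values = 100.0 + 0.5 * np.arange(50)
        degraded = _delete(make_trace(values), range(20, 30))
        rt = pchip_reconstruct(degraded, cfg)
        assert len(rt) == 50
        np.testing.assert_allclose(rt.values, values, atol=1e-9)
        assert rt.imputed.sum() == 10
        assert np.all(np.flatnonzero(rt.imputed) == np.arange(20, 30))

    def test_monotone_no_overshoot(self, cfg):
        rng = np.random.default_rng(7)
        for _ in range(50):
            values = np.cumsum(rng.uniform(0, 5, 60)) + 80
            degraded = _delete(make_trace(values), range(25, 35))
            rt = pchip_reconstruct(degraded, cfg)
            filled = rt.values[25:35]
            assert np.all(filled >= values[24] - 1e-12)
            assert np.all(filled <= values[35] + 1e-12)
            assert np.all(np.diff(rt.values) >= -1e-9)

    def test_single_gap_point_matches_independent_fritsch_carlson(self, cfg):
        values = np.array([100.0, 100.0, 100.0, 110.0, 110.0, 110.0])
        # grid slot between the flat shoulders is deleted
        full = np.array([100.0, 100.0, 100.0, 105.0, 110.0, 110.0, 110.0])
        degraded = _delete(make_trace(full), [3])
        rt = pchip_reconstruct(degraded, cfg)
        assert rt.imputed[3]
        assert 100.0 <= rt.values[3] <= 110.0
        x_obs = np.array([0, 5, 10, 20, 25, 30], dtype=float)
        expected = fritsch_carlson_eval(x_obs, values, np.array([15.0]))[0]
        assert rt.values[3] == pytest.approx(expected, rel=1e-9)

    def test_random_gaps_match_independent_fritsch_carlson(self, cfg):
        rng = np.random.default_rng(3)
        for _ in range(20):
            values = rng.uniform(70, 250, 60)
            drop = rng.choice(np.arange(2, 58), size=10, replace=False)
            degraded = _delete(make_trace(values), drop)
            rt = pchip_reconstruct(degraded, cfg)
            x_obs = np.asarray(
                (degraded.timestamps - degraded.timestamps[0]) / np.timedelta64(1, "s"), float
            )
            xq = np.sort(drop) * 300.0
            expected = fritsch_carlson_eval(x_obs, degraded.values, xq)
            np.testing.assert_allclose(rt.values[np.sort(drop)], expected, rtol=1e-8, atol=1e-8)

    def test_observed_points_carry_observations(self, cfg):
        rng = np.random.default_rng(11)
        values = rng.uniform(60, 300, 100)
        degraded = _delete(make_trace(values), [40, 41, 42])
        rt = pchip_reconstruct(degraded, cfg)
        keep = ~rt.imputed
        np.testing.assert_array_equal(rt.values[keep], degraded.values)

    def test_reconstruction_closes_all_gaps(self, cfg):
        rng = np.random.default_rng(13)
        values = rng.uniform(60, 300, 200)
        degraded = _delete(make_trace(values), rng.choice(np.arange(1, 199), 30, replace=False))
        rt = pchip_reconstruct(degraded, cfg)
        as_trace = GlucoseTrace(timestamps=rt.timestamps, values=rt.values, subject_id="rt")
        assert detect_gaps(as_trace, cfg) == []

    def test_identical_timestamps_fatal(self, cfg):
        ts = np.array([START, START], dtype="datetime64[s]")
        trace = GlucoseTrace(timestamps=ts, values=np.array([100.0, 110.0]))
        with pytest.raises(ValueError):
            pchip_reconstruct(trace, cfg)

    def test_max_gap_cap_splits_segments(self):
        cfg = RunConfig(max_gap_min=30.0)
        values = np.full(100, 120.0)
        degraded = _delete(make_trace(values), range(40, 55))  # 80-min gap
        rt = pchip_reconstruct(degraded, cfg)
        assert rt.n_segments == 2
        assert not rt.imputed.any()


class TestRemovePolicy:
    def test_no_gaps_single_segment(self, cfg):
        trace = make_trace(np.full(50, 120.0))
        rt = remove_missing_periods(trace, [], cfg)
        assert rt.n_segments == 1
        assert len(rt) == 50
        assert not rt.imputed.any()

    def test_interior_gap_two_segments(self, cfg):
        trace = _delete(make_trace(np.arange(100.0, 150.0)), range(20, 30))
        gaps = detect_gaps(trace, cfg)
        rt = remove_missing_periods(trace, gaps, cfg)
        assert rt.n_segments == 2
        (s0, e0), (s1, e1) = rt.kept_segments
        assert e0 == trace.timestamps[19]
        assert s1 == trace.timestamps[20]
        assert len(rt) == len(trace)


class TestCoverage:
    def test_full_day_grid(self, cfg):
        assert completeness_rate(make_trace(np.full(288, 120.0)), cfg) == pytest.approx(100.0)

    def test_quarter_deleted(self, cfg):
        trace = _delete(make_trace(np.full(288, 120.0)), range(100, 172))
        assert completeness_rate(trace, cfg) == pytest.approx(75.0)

    def test_random_deletions_match_count_ratio(self, cfg):
        rng = np.random.default_rng(5)
        for _ in range(10):
            trace = _delete(
                make_trace(np.full(288, 120.0)),
                rng.choice(np.arange(1, 287), size=30, replace=False),
            )
            ts_min = (trace.timestamps - trace.timestamps[0]) / np.timedelta64(60, "s")
            assert completeness_rate(trace, cfg) == pytest.approx(
                oracle_completeness(list(ts_min.astype(float)), 5.0)
            )

    def test_single_sample_is_100(self, cfg):
        assert completeness_rate(make_trace([100.0]), cfg) == 100.0

    def test_invariant_under_value_scaling(self, cfg):
        trace = _delete(make_trace(np.full(288, 6.0)), range(10, 20))
        scaled = GlucoseTrace(timestamps=trace.timestamps, values=trace.values * 18.016)
        assert completeness_rate(trace, cfg) == completeness_rate(scaled, cfg)


class TestMonitoringDays:
    def test_midnight_straddle_counts_two(self):
        ts = np.array(
            ["2024-01-01T23:55:00", "2024-01-02T00:05:00"], dtype="datetime64[s]"
        )
        trace = GlucoseTrace(timestamps=ts, values=np.array([100.0, 100.0]))
        assert monitoring_days(trace) == 2

    def test_seven_full_days(self):
        assert monitoring_days(make_trace(np.full(7 * 288, 120.0))) == 7

    def test_matches_distinct_date_count(self):
        rng = np.random.default_rng(2)
        trace = make_trace(rng.uniform(60, 300, 1000))
        expected = len({str(t)[:10] for t in trace.timestamps})
        assert monitoring_days(trace) == expected
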