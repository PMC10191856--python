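"""Binarization, burst records, bootstrap summaries, dwell-bias correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from burstepi.burst_metrics import (
    BinaryTrace,
    binarize,
    cleanup_binary,
    dwell_transition_counts,
    estimate_background_sd,
    estimate_telegraph_parameters,
    estimate_trace_background_width,
    extract_burst_record,
    fit_background_width,
    measure_ring_background,
    summarize_population,
)
from burstepi.synthetic_data import BurstSimParams, simulate_traces


def _binary(states, dt=15.0):
    s = np.asarray(states, dtype=bool)
    return BinaryTrace(state=s, raw_state=s.copy(), frame_interval=dt)


class TestBackgroundWidth:
    def test_cauchy_scale_recovered(self):
        rng = np.random.default_rng(0)
        samples = stats.cauchy.rvs(loc=100, scale=12, size=4000, random_state=rng)
        assert fit_background_width(samples) == pytest.approx(12.0, rel=0.10)

    def test_constant_background_width_zero(self):
        assert fit_background_width(np.full(100, 7.0)) == 0.0

    def test_gaussian_background_documented_width(self):
        # numeric MLE oracle: Cauchy scale fitted to N(0, sigma) settles at
        # ~0.613 sigma (HWHM-comparable, not a true s.d.)
        rng = np.random.default_rng(1)
        w = fit_background_width(rng.normal(0, 10.0, 100000))
        assert w == pytest.approx(6.13, abs=0.3)

    def test_hwhm_sigma_conversion(self):
        rng = np.random.default_rng(2)
        samples = stats.cauchy.rvs(scale=10, size=5000, random_state=rng)
        g = fit_background_width(samples, method="cauchy_scale")
        s = fit_background_width(samples, method="hwhm_sigma")
        assert s == pytest.approx(g / np.sqrt(2 * np.log(2)), rel=1e-9)

    def test_trace_estimate_robust_to_on_frames(self):
        rng = np.random.default_rng(3)
        off = rng.normal(0, 1.0, 8200)
        on = 5 * rng.lognormal(-0.02, 0.2, 1800) + rng.normal(0, 1.0, 1800)
        w = estimate_trace_background_width(np.concatenate([off, on]))
        assert w == pytest.approx(0.613, abs=0.08)


class TestRingBackground:
    def _trace(self, n, y, x):
        from burstepi.trace_quant import IntensityTrace

        return IntensityTrace(
            cell_id=1,
            intensity=np.zeros(n),
            x=np.full(n, float(x)),
            y=np.full(n, float(y)),
            tier=np.array(["primary-6sd"] * n, dtype=object),
            end_frame=n - 1,
        )

    def test_ring_points_sample_background(self):
        rng = np.random.default_rng(4)
        proj = rng.normal(50.0, 1.0, (10, 41, 41))
        samples = measure_ring_background(proj, self._trace(10, 20, 20), ring_distance=5)
        assert samples.size == 40
        # fixed-position photometry of pure background scatters around 0
        assert abs(np.mean(samples)) < 5.0

    def test_too_few_samples_falls_back_to_global_sd(self):
        rng = np.random.default_rng(5)
        proj = rng.normal(0.0, 2.0, (2, 15, 15))
        trace = self._trace(2, 7, 7)
        trace.x[:] = np.nan
        trace.y[:] = np.nan
        with pytest.warns(UserWarning, match="global"):
            w = estimate_background_sd(proj, trace)
        assert w == pytest.approx(2.0, rel=0.2)


class TestBinarize:
    def test_cleanup_rules_hand_traced(self):
        # threshold pattern 0100110110 -> delete singles -> 0000110110
        # -> merge single gaps -> 0000111110
        intensity = np.array([0, 10, 0, 0, 10, 10, 0, 10, 10, 0], dtype=float)
        b = binarize(intensity, bg_width=1.0)
        np.testing.assert_array_equal(
            b.state, np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 0], dtype=bool)
        )

    def test_all_below_threshold_inactive(self):
        b = binarize(np.full(20, 3.0), bg_width=1.0)
        assert not b.state.any()
        rec = extract_burst_record(b, np.full(20, 3.0))
        assert not rec.active and rec.burst_durations == []

    def test_alternating_trace_all_deleted(self):
        # deletion precedes merging, so 1,0,1,0,... vanishes entirely
        intensity = np.tile([10.0, 0.0], 10)
        b = binarize(intensity, bg_width=1.0)
        assert not b.state.any()

    def test_threshold_is_five_times_width(self):
        intensity = np.array([5.01, 5.01, 4.99, 4.99, 5.01, 5.01], dtype=float)
        b = binarize(intensity, bg_width=1.0)
        np.testing.assert_array_equal(b.raw_state, [1, 1, 0, 0, 1, 1])

    def test_negative_width_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.zeros(5), bg_width=-1.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=60))
    def test_cleanup_idempotent(self, bits):
        once = cleanup_binary(np.asarray(bits, dtype=bool))
        twice = cleanup_binary(once)
        np.testing.assert_array_equal(once, twice)


class TestExtractBurstRecord:
    def test_single_burst_arithmetic(self):
        state = np.zeros(24, dtype=bool)
        state[12:20] = True
        rec = extract_burst_record(_binary(state), np.where(state, 100.0, 0.0))
        assert rec.induction_time == pytest.approx(3.0)
        assert rec.burst_durations == [pytest.approx(2.0)]
        assert rec.inter_burst_times == []
        assert rec.burst_intensity == pytest.approx(100.0)

    def test_inter_burst_time(self):
        state = np.zeros(30, dtype=bool)
        state[4:8] = True
        state[16:20] = True
        rec = extract_burst_record(_binary(state), np.ones(30))
        assert rec.inter_burst_times == [pytest.approx(2.0)]

    def test_acquisition_offset_added_to_induction(self):
        state = np.zeros(10, dtype=bool)
        state[4:7] = True
        rec = extract_burst_record(_binary(state), np.ones(10), t_acquisition_offset=5.0)
        assert rec.induction_time == pytest.approx(6.0)

    def test_trailing_burst_censored(self):
        state = np.zeros(10, dtype=bool)
        state[2:4] = True
        state[7:] = True
        rec = extract_burst_record(_binary(state), np.ones(10))
        assert rec.censored_final_burst
        assert rec.burst_durations == [pytest.approx(0.5)]  # censored run excluded


class TestSummarizePopulation:
    def _records(self, inductions):
        return [
            extract_burst_record(_binary(self._state_for(t)), np.ones(240), cell_id=i)
            for i, t in enumerate(inductions)
        ]

    @staticmethod
    def _state_for(induction_min):
        state = np.zeros(240, dtype=bool)
        start = int(induction_min * 4)
        state[start : start + 8] = True
        return state

    def test_identical_values_zero_bootstrap_sd(self):
        summary = summarize_population(self._records([5.0] * 30), seed=0)
        assert summary.params["induction_time"].boot_mean == pytest.approx(5.0)
        assert summary.params["induction_time"].boot_sd == pytest.approx(0.0)

    def test_bootstrap_sd_matches_clt(self):
        rng = np.random.default_rng(6)
        values = rng.exponential(8.0, 200)
        records = self._records(np.clip(values, 0, 50))
        summary = summarize_population(records, n_boot=1000, seed=1)
        got = summary.params["induction_time"].boot_sd
        vals = summary.params["induction_time"].values
        expected = vals.std(ddof=1) / np.sqrt(vals.size)
        assert got == pytest.approx(expected, rel=0.15)

    def test_active_counts_and_errors(self):
        active = self._records([5.0] * 40)
        inactive = [
            extract_burst_record(_binary(np.zeros(240, dtype=bool)), np.ones(240))
            for _ in range(60)
        ]
        summary = summarize_population(active + inactive, seed=2)
        assert summary.n_active == 40 and summary.n_inactive == 60
        assert summary.active_fraction == pytest.approx(0.40)
        assert summary.count_errors == (pytest.approx(np.sqrt(40)), pytest.approx(np.sqrt(60)))

    def test_no_active_cells_reports_counts_only(self):
        records = [
            extract_burst_record(_binary(np.zeros(8, dtype=bool)), np.ones(8))
            for _ in range(5)
        ]
        summary = summarize_population(records, seed=3)
        assert summary.params == {}
        assert summary.active_fraction == 0.0


class TestTelegraphCorrection:
    def test_transition_counts_skip_pre_induction(self):
        state = np.array([0, 0, 1, 1, 1, 0, 0, 1, 1], dtype=bool)
        stops_on, trials_on, stops_off, trials_off = dwell_transition_counts(_binary(state))
        # ON run of 3 complete (3 trials), OFF run of 2 complete, final ON run censored (1 trial)
        assert (stops_on, trials_on) == (1, 4)
        assert (stops_off, trials_off) == (1, 2)

    def test_dwell_means_recovered_within_ten_percent(self):
        params = BurstSimParams(seed=9)
        traces, _ = simulate_traces(params, 400)
        binaries = [
            binarize(traces.intensity[i], 0.63, frame_interval=15.0)
            for i in range(traces.n_cells)
        ]
        est = estimate_telegraph_parameters(binaries, n_boot=300, seed=0)
        assert est["mean_on"][0] == pytest.approx(2.0, rel=0.10)
        assert est["mean_off"][0] == pytest.approx(8.0, rel=0.10)
        assert est["induction_time"][0] == pytest.approx(6.0, rel=0.10)
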