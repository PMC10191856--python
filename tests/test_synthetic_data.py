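"""Generator statistics: telegraph traces, movies, smFISH tables, fragments."""

import numpy as np
import pandas as pd
import pytest

from burstepi.photometry import gaussian_mask_2d
from burstepi.synthetic_data import (
    BurstSimParams,
    NucSimModel,
    TraceSet,
    promoter_array_model,
    render_movie,
    simulate_mnase,
    simulate_smfish,
    simulate_traces,
)


class TestBurstSimParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_steps": 0},
            {"step_rate": -1.0},
            {"mean_on": 0.0},
            {"active_prob": 1.5},
            {"frame_interval": 13.0},  # does not divide 60 min evenly
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BurstSimParams(**kwargs)

    def test_frame_count(self):
        assert BurstSimParams().n_frames == 240


class TestSimulateTraces:
    def test_single_step_induction_mean(self):
        # exponential induction: mean = 1/rate = 2 min
        params = BurstSimParams(n_steps=1, step_rate=0.5, seed=10)
        _, truth = simulate_traces(params, 10000)
        t = truth.induction_time[np.isfinite(truth.induction_time)]
        se = t.std() / np.sqrt(t.size)
        assert abs(t.mean() - 2.0) < 3 * se + 0.05

    def test_induction_matches_gamma_moments(self):
        params = BurstSimParams(n_steps=3, step_rate=0.5, seed=2)
        _, truth = simulate_traces(params, 10000)
        t = truth.induction_time[np.isfinite(truth.induction_time)]
        # Gamma(3, 2): mean 6, var 12, skewness 2/sqrt(3)
        assert abs(t.mean() - 6.0) < 0.15
        assert abs(t.var() - 12.0) < 0.8
        skew = np.mean(((t - t.mean()) / t.std()) ** 3)
        assert abs(skew - 2 / np.sqrt(3)) < 0.15

    def test_dwell_interval_means(self):
        # restrict to intervals starting in the first half of a long movie:
        # those complete with probability ~1, avoiding the length-biased
        # selection that completed intervals near the movie end suffer
        params = BurstSimParams(mean_on=2.0, mean_off=8.0, movie_length=240.0, seed=3)
        _, truth = simulate_traces(params, 450)

        def early(lists):
            return np.array([b - a for c in lists for a, b in c if a < 120.0])

        ons = early(truth.on_intervals)
        offs = early(truth.off_intervals)
        assert ons.size > 5000 and offs.size > 1000
        assert abs(ons.mean() - 2.0) < 0.1
        assert abs(offs.mean() - 8.0) < 0.4

    def test_inactive_population(self):
        params = BurstSimParams(active_prob=0.0, background_sd=1.0, seed=4)
        traces, truth = simulate_traces(params, 50)
        assert not truth.state.any()
        assert np.all(np.isnan(truth.induction_time))
        # traces are pure background
        assert np.abs(traces.intensity).max() < 6.0

    def test_interval_bookkeeping(self):
        params = BurstSimParams(seed=5)
        _, truth = simulate_traces(params, 40)
        dt = params.dt_min
        for i in range(40):
            if not np.isfinite(truth.induction_time[i]):
                continue
            total = truth.induction_time[i]
            total += sum(b - a for a, b in truth.on_intervals[i])
            total += sum(b - a for a, b in truth.off_intervals[i])
            assert total == pytest.approx(truth.movie_length, abs=dt)

    def test_seed_determinism(self):
        params = BurstSimParams(seed=6)
        t1, g1 = simulate_traces(params, 20)
        t2, g2 = simulate_traces(params, 20)
        assert t1.intensity.tobytes() == t2.intensity.tobytes()
        assert np.array_equal(g1.state, g2.state)

    def test_csv_roundtrip(self, tmp_path):
        params = BurstSimParams(seed=7)
        traces, _ = simulate_traces(params, 5)
        path = tmp_path / "traces.csv"
        traces.to_csv(path)
        back = TraceSet.from_csv(path)
        np.testing.assert_allclose(back.intensity, traces.intensity)
        assert back.frame_interval == traces.frame_interval


class TestRenderMovie:
    def test_noiseless_photometry_recovers_trace(self):
        traces = TraceSet(intensity=np.full((1, 5), 1000.0), frame_interval=15.0)
        movie, labels = render_movie(traces, psf_sigma=1.5, noise_sd=0.0)
        cy, cx = np.argwhere(movie[0] == movie[0].max())[0]
        fit = gaussian_mask_2d(movie[0], cy, cx, 1.5)
        assert fit.intensity == pytest.approx(1000.0, rel=0.01)

    def test_two_cells_recovered_independently(self):
        traces = TraceSet(
            intensity=np.vstack([np.full(4, 800.0), np.full(4, 300.0)]),
            frame_interval=15.0,
        )
        movie, labels = render_movie(traces, psf_sigma=1.5, noise_sd=0.0)
        for cid, expected in ((1, 800.0), (2, 300.0)):
            ys, xs = np.nonzero(labels == cid)
            sub_peak = np.argmax(movie[0][ys, xs])
            fit = gaussian_mask_2d(movie[0], ys[sub_peak], xs[sub_peak], 1.5)
            assert fit.intensity == pytest.approx(expected, rel=0.01)

    def test_off_frames_stay_near_background(self):
        traces = TraceSet(intensity=np.zeros((1, 3)), frame_interval=15.0)
        movie, labels = render_movie(traces, noise_sd=1.0, cell_level=5.0, seed=1)
        assert movie.max() < 5.0 + 6.0  # cell body + 6x noise sd

    def test_overlapping_layout_rejected(self):
        traces = TraceSet(intensity=np.zeros((1, 2)), frame_interval=15.0)
        with pytest.raises(ValueError):
            render_movie(traces, spot_offset=(20, 0))


class TestSimulateSmfish:
    def test_uniform_nascent_seven_all_active(self):
        from burstepi.smfish_quant import quantify_cells

        sample = simulate_smfish(50, nascent_counts=7.0, seed=1)
        cells, summary = quantify_cells(sample["spots"])
        assert summary["active_fraction"] == 1.0

    def test_half_active_design(self):
        from burstepi.smfish_quant import quantify_cells

        def nascent(rng, n):
            c = np.full(n, 10.0)
            c[rng.random(n) < 0.5] = 0.0
            return c

        sample = simulate_smfish(1000, nascent_counts=nascent, seed=2)
        _, summary = quantify_cells(sample["spots"])
        truth = float((sample["cells"]["true_nascent"] >= 5).mean())
        assert summary["active_fraction"] == pytest.approx(truth, abs=0.01)

    def test_degenerate_mixture_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            simulate_smfish(20, dapi_means=(1e5, 1e5), seed=3)

    def test_determinism(self):
        s1 = simulate_smfish(100, seed=4)
        s2 = simulate_smfish(100, seed=4)
        pd.testing.assert_frame_equal(s1["cells"], s2["cells"])
        pd.testing.assert_frame_equal(s1["spots"], s2["spots"])


class TestSimulateMnase:
    def test_single_nucleosome_coverage_peak(self):
        from scipy.ndimage import gaussian_filter1d

        from burstepi.mnase import make_coverage

        model = NucSimModel(
            chrom_sizes={"chrI": 5000},
            nucleosomes={"x": pd.DataFrame({"chrom": ["chrI"], "center": [1000.0], "occupancy": [1.0]})},
            fragments_per_condition=10000,
            background_frac=0.0,
            seed=5,
        )
        frags = simulate_mnase(model)["x"]
        cov = make_coverage(frags, {"chrI": 5000})
        peak = int(np.argmax(gaussian_filter1d(cov.raw["chrI"], 17.0)))
        assert abs(peak - 1000) <= 10

    def test_forced_short_fragments_all_filtered(self):
        from burstepi.mnase import filter_fragments

        model = NucSimModel(
            chrom_sizes={"chrI": 5000},
            nucleosomes={"x": pd.DataFrame({"chrom": ["chrI"], "center": [1000.0], "occupancy": [1.0]})},
            fragments_per_condition=500,
            frag_len_mean=80.0,
            frag_len_sd=1e-6,
            background_frac=0.0,
            seed=6,
        )
        frags = simulate_mnase(model)["x"]
        assert ((frags["end"] - frags["start"]) < 95).all()
        assert len(filter_fragments(frags)) == 0

    def test_zero_occupancy_rejected(self):
        model = NucSimModel(
            chrom_sizes={"chrI": 5000},
            nucleosomes={"x": pd.DataFrame({"chrom": ["chrI"], "center": [1000.0], "occupancy": [0.0]})},
            seed=7,
        )
        with pytest.raises(ValueError, match="occupancy"):
            simulate_mnase(model)

    def test_out_of_bounds_center_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            NucSimModel(
                chrom_sizes={"chrI": 5000},
                nucleosomes={"x": pd.DataFrame({"chrom": ["chrI"], "center": [9000.0], "occupancy": [1.0]})},
            )

    def test_determinism(self):
        genes = pd.DataFrame(
            {"name": ["g"], "chrom": ["chrI"], "strand": ["+"], "tss": [5000]}
        )
        model = promoter_array_model(genes, {"chrI": 10000}, fragments_per_condition=2000, seed=8)
        f1 = simulate_mnase(model)["DMSO"]
        f2 = simulate_mnase(model)["DMSO"]
        pd.testing.assert_frame_equal(f1, f2)
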