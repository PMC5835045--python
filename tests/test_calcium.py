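"""Movie summarization, ROI traces and wavelet event detection."""

import numpy as np
import pytest

from neurocult import (
    CalciumMovie,
    CellROI,
    FluorescenceTrace,
    ThresholdSpec,
    WaveletSpec,
    analyze_movie,
    detect_spikes_wavelet,
    extract_trace,
    generate_calcium_movie,
    match_events,
    segment_cells,
    simulate_dff_traces,
    summarize_activity,
    summary_image,
)
from neurocult.synthetic import transient_kernel

FS = 32.0


def trace_from_dff(dff: np.ndarray) -> FluorescenceTrace:
    return FluorescenceTrace(dff + 1.0, dff, FS)


def synthetic_transient(
    t0: float, duration: float = 120.0, amplitude: float = 0.2,
    noise_sd: float = 0.0, seed: int = 0,
) -> np.ndarray:
    T = int(duration * FS)
    dff = np.zeros(T)
    k = amplitude * transient_kernel(FS)
    start = int(np.ceil(t0 * FS))
    dff[start : start + k.size] += k[: T - start]
    if noise_sd:
        dff += np.random.default_rng(seed).normal(0, noise_sd, T)
    return dff


class TestSummaryImage:
    def test_constant_movie_range_is_zero(self):
        movie = CalciumMovie(np.full((10, 8, 8), 50.0), FS)
        assert summary_image(movie, "range").pixels.max() == 0.0

    def test_flashing_pixel_is_maximal(self):
        frames = np.full((40, 8, 8), 10.0)
        frames[::2, 3, 4] = 200.0
        movie = CalciumMovie(frames, FS)
        img = summary_image(movie, "std").pixels
        assert np.unravel_index(img.argmax(), img.shape) == (3, 4)

    def test_single_frame_raises(self):
        with pytest.raises(ValueError):
            summary_image(CalciumMovie(np.zeros((1, 4, 4)), FS))

    def test_summary_elevated_at_truth_footprints(self):
        movie, truth = generate_calcium_movie(6, 0.2, duration=30, seed=4)
        img = summary_image(movie).pixels
        bg = np.median(img)
        for fp in truth.cell_footprints:
            assert img[fp[:, 0], fp[:, 1]].mean() > bg + 0.5 * 0.2 * 100


class TestSegmentCells:
    def test_blank_summary_no_rois(self, default_spec):
        from neurocult.core import Micrograph

        assert segment_cells(Micrograph(np.zeros((16, 16)) + 1, 1.0, "calcium"),
                             ThresholdSpec(mode="absolute", value=10)) == []

    def test_active_cells_recovered_with_good_overlap(self, default_spec):
        # rate 0.3 Hz over 60 s: every cell fires enough for the range
        # summary (cells with only a spike or two are legitimately invisible)
        movie, truth = generate_calcium_movie(20, 0.3, duration=60,
                                              movie_shape=(128, 128), seed=5)
        rois = segment_cells(summary_image(movie), default_spec)
        assert len(rois) == truth.n_cells
        matched = 0
        for fp in truth.cell_footprints:
            a = set(map(tuple, fp))
            best = max(
                len(a & set(map(tuple, r.footprint)))
                / len(a | set(map(tuple, r.footprint)))
                for r in rois
            )
            matched += best > 0.5
        assert matched == truth.n_cells

    def test_silent_cells_invisible_to_range_summary(self, default_spec):
        movie, truth = generate_calcium_movie(8, 0.0, duration=30, seed=6)
        rois = segment_cells(summary_image(movie, "range"), default_spec)
        assert rois == []


class TestExtractTrace:
    def test_constant_movie_dff_zero(self):
        movie = CalciumMovie(np.full((20, 8, 8), 100.0), FS)
        roi = CellROI(1, np.array([[2, 2], [2, 3]]))
        tr = extract_trace(movie, roi)
        assert np.allclose(tr.samples, 100.0)
        assert np.allclose(tr.dff, 0.0)

    def test_single_pixel_roi_matches_pixel_series(self):
        frames = np.random.default_rng(0).uniform(50, 150, (30, 6, 6))
        movie = CalciumMovie(frames, FS)
        tr = extract_trace(movie, CellROI(1, np.array([[4, 5]])))
        assert np.allclose(tr.samples, frames[:, 4, 5])

    def test_out_of_bounds_footprint_raises(self):
        movie = CalciumMovie(np.zeros((5, 6, 6)) + 1, FS)
        with pytest.raises(ValueError):
            extract_trace(movie, CellROI(1, np.array([[7, 2]])))

    def test_single_spike_dff_peak_near_amplitude(self):
        movie, truth = generate_calcium_movie(
            1, 0.0, duration=20, noise_sd=0.005, seed=7
        )
        # inject one known transient into the movie's single cell
        k = 0.2 * transient_kernel(FS)
        fp = truth.cell_footprints[0]
        movie.frames[100 : 100 + k.size, fp[:, 0], fp[:, 1]] += (
            100 * k[:, None]
        ).astype(np.float32)
        tr = extract_trace(movie, CellROI(1, fp))
        assert tr.dff.max() == pytest.approx(0.2, rel=0.2)


class TestDetectSpikes:
    def test_flat_trace_no_events(self):
        train = detect_spikes_wavelet(trace_from_dff(np.zeros(1000)))
        assert train.n_events == 0

    def test_single_transient_detected_once_within_tolerance(self):
        """One clean transient yields exactly one event within 2·tau_rise
        of the true onset, at noise = amplitude / 10."""
        for seed in range(10):
            dff = synthetic_transient(60.33, noise_sd=0.02, seed=seed)
            train = detect_spikes_wavelet(trace_from_dff(dff))
            assert train.n_events == 1
            assert abs(train.event_frames[0] - 60.33 * FS) <= 2 * 0.18 * FS

    def test_threshold_monotonicity_in_k_noise(self):
        dff, spikes = simulate_dff_traces(1, 0.2, 60, FS, seed=8)
        counts = [
            detect_spikes_wavelet(
                trace_from_dff(dff[0]), WaveletSpec(k_noise=k)
            ).n_events
            for k in (2.0, 3.0, 4.0, 6.0, 8.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_time_shift_equivariance(self):
        dff = synthetic_transient(40.0, noise_sd=0.01, seed=1)
        shift = 320  # 10 s, away from boundaries
        t1 = detect_spikes_wavelet(trace_from_dff(dff))
        t2 = detect_spikes_wavelet(trace_from_dff(np.roll(dff, shift)))
        assert np.array_equal(t1.event_frames + shift, t2.event_frames)

    def test_amplitude_invariance(self):
        dff, _ = simulate_dff_traces(1, 0.1, 60, FS, seed=9)
        t1 = detect_spikes_wavelet(trace_from_dff(dff[0]))
        t2 = detect_spikes_wavelet(trace_from_dff(dff[0] * 37.0))
        assert np.array_equal(t1.event_frames, t2.event_frames)

    def test_detected_rate_monotone_in_true_rate(self):
        """Detected event counts increase with the Poisson rate at fixed SNR."""
        means = []
        for rate in (0.02, 0.05, 0.1, 0.2):
            n = 0
            for seed in range(5):
                dff, _ = simulate_dff_traces(4, rate, 120, FS, seed=seed)
                for row in dff:
                    n += detect_spikes_wavelet(trace_from_dff(row)).n_events
            means.append(n)
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_too_short_trace_raises(self):
        with pytest.raises(ValueError, match="too short"):
            detect_spikes_wavelet(
                FluorescenceTrace(np.ones(10), np.zeros(10), FS)
            )


class TestSummarizeActivity:
    def test_pooled_arithmetic(self):
        t1 = __import__("neurocult").SpikeTrain(np.array([1, 50, 99]), FS)
        t2 = __import__("neurocult").SpikeTrain(np.arange(5) * 100, FS)
        s = summarize_activity([t1, t2], n_cells_total=2, duration=120.0)
        assert s.total_spike_frequency == pytest.approx(8 / 120)
        assert s.mean_frequency_per_cell == pytest.approx(4 / 120)

    def test_no_events_zero_frequencies(self):
        s = summarize_activity([], 0, 120.0)
        assert s.total_spike_frequency == 0.0
        assert s.mean_frequency_per_cell == 0.0

    def test_events_without_cells_is_an_error(self):
        from neurocult import SpikeTrain

        with pytest.raises(ValueError):
            summarize_activity([SpikeTrain(np.array([3]), FS)], 0, 120.0)

    def test_conservation_against_train_counts(self):
        from neurocult import SpikeTrain

        trains = [
            SpikeTrain(np.sort(np.random.default_rng(s).choice(
                3000, size=s + 1, replace=False)), FS)
            for s in range(4)
        ]
        s = summarize_activity(trains, 4, 100.0)
        assert s.total_spike_frequency == sum(t.n_events for t in trains) / 100.0


class TestEndToEnd:
    def test_movie_rate_recovery_within_fifteen_percent(self):
        movie, truth = generate_calcium_movie(12, 0.1, duration=60, seed=10)
        rois, trains = analyze_movie(movie)
        s = summarize_activity(rois and trains, len(rois), movie.duration)
        realized = truth.total_spikes / truth.n_cells / movie.duration
        assert s.mean_frequency_per_cell == pytest.approx(realized, rel=0.15)

    def test_match_events_greedy_one_to_one(self):
        m, nt, nd = match_events([1.0, 2.0, 9.0], [1.2, 2.1, 2.4, 30.0])
        assert (m, nt, nd) == (2, 3, 4)
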