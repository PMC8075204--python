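"""Spike detection primitives and the two-round detector."""

import numpy as np
import pytest

import voltspike as vs
from voltspike.detect import _prewhiten
from voltspike.errors import (
    DegenerateTraceError,
    NoTemplateError,
    TooFewPeaksError,
)

from conftest import FRAME_RATE, make_planted_trace, spike_f1


class TestLocalMaxima:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([0, 1, 0, 2, 0], [1, 3]),
            ([0, 1, 2, 3, 4], []),  # monotone ramp
            ([0, 1, 1, 0], [1]),  # plateau: first index
            ([0, 2, 2, 2, 0, 3, 0], [1, 5]),
            ([5, 0, 5], []),  # endpoints never qualify
        ],
    )
    def test_stated_tie_breaks(self, x, expected):
        assert vs.local_maxima(np.array(x, float)).tolist() == expected

    def test_height_filter(self):
        x = np.array([0, 1, 0, 5, 0, 2, 0], float)
        assert vs.local_maxima(x, height=2.0).tolist() == [3, 5]


class TestAdaptiveThreshold:
    def test_planted_delta_peaks_all_detected(self):
        # 20 clear 10-sigma peaks; all must be kept, with few noise extras
        # (the symmetric-reflection noise model underestimates the skewed
        # right tail of noise-peak heights, so a handful may slip through)
        rng = np.random.default_rng(0)
        t = rng.standard_normal(2000)
        pos = np.linspace(50, 1950, 20).astype(int)
        t[pos] += 10.0
        t -= np.median(t)
        s, h = vs.adaptive_threshold(t, 0.5)
        assert set(pos) <= set(s.tolist())
        assert len(s) <= len(pos) + 5
        assert 0 < h < 10

    def test_smaller_p_is_more_stringent(self):
        rng = np.random.default_rng(1)
        t = rng.standard_normal(2000)
        t[np.arange(100, 1900, 90)] += 10.0
        t -= np.median(t)
        _, h25 = vs.adaptive_threshold(t, 0.25)
        _, h50 = vs.adaptive_threshold(t, 0.5)
        assert h25 >= h50

    def test_symmetric_noise_detects_few_maxima(self):
        # no spikes: the max/noise contrast is ~0, detections stay a small
        # fraction of all local maxima (median over seeds)
        fracs = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            t = rng.standard_normal(4000)
            t -= np.median(t)
            s, _ = vs.adaptive_threshold(t, 0.5)
            fracs.append(len(s) / len(vs.local_maxima(t)))
        assert np.median(fracs) < 0.05

    def test_too_few_peaks_raises(self):
        with pytest.raises(TooFewPeaksError):
            vs.adaptive_threshold(np.array([0, 1, 0, 1, 0], float), 0.5)


class TestSimpleThreshold:
    def test_noise_level_estimate_and_monte_carlo_count(self):
        # sigma-hat from the negative half must recover sigma=1 within 3%,
        # and the detected set must equal the brute-force thresholded maxima
        rng = np.random.default_rng(2)
        t = rng.standard_normal(100_000)
        t -= np.median(t)
        s, thr = vs.simple_threshold(t, 3.5)
        sigma_hat = thr / 3.5
        assert 0.97 <= sigma_hat <= 1.03
        oracle = vs.local_maxima(t)
        oracle = oracle[t[oracle] >= thr]
        np.testing.assert_array_equal(s, oracle)
        # expected count of >3.5 sigma local maxima is small but nonzero
        assert 0 < len(s) < 100

    def test_planted_peaks_recovered_exactly(self):
        x, pos = make_planted_trace(3, delta=True, clip=3.0)
        x -= np.median(x)
        s, _ = vs.simple_threshold(x, 3.5)
        assert set(s.tolist()) == set(pos.tolist())

    def test_all_positive_trace_degenerate(self):
        with pytest.raises(DegenerateTraceError):
            vs.simple_threshold(np.abs(np.random.default_rng(0).normal(size=100)) + 1, 3.5)


class TestComputeTemplate:
    def test_single_spike_returns_raw_window(self):
        rng = np.random.default_rng(4)
        t = rng.normal(size=200)
        z = vs.compute_template(t, np.array([100]), tau=8)
        np.testing.assert_array_equal(z, t[92:109])

    def test_two_identical_windows(self):
        t = np.zeros(300)
        w = np.sin(np.linspace(0, np.pi, 17))
        t[50 - 8 : 50 + 9] = w
        t[200 - 8 : 200 + 9] = w
        np.testing.assert_allclose(
            vs.compute_template(t, np.array([50, 200]), 8), w, atol=1e-15
        )

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        t = rng.normal(size=5000)
        s = np.sort(rng.choice(np.arange(10, 4990), 50, replace=False))
        tau = 8
        oracle = np.mean([t[i - tau : i + tau + 1] for i in s], axis=0)
        np.testing.assert_allclose(
            vs.compute_template(t, s, tau), oracle, atol=1e-12
        )

    def test_edge_spikes_trimmed_and_empty_raises(self):
        t = np.arange(100.0)
        z = vs.compute_template(t, np.array([3, 50]), tau=8)  # 3 trimmed
        np.testing.assert_array_equal(z, t[42:59])
        with pytest.raises(NoTemplateError):
            vs.compute_template(t, np.array([3]), tau=8)


class TestWhitenedMatchedFilter:
    def test_planted_template_peaks_enhanced(self):
        # output must peak at the planted times with a better peak/noise
        # ratio than the input
        x, s = make_planted_trace(6, amp=8.0)
        q = np.zeros(x.size)
        q[s] = 1.0
        out = vs.whitened_matched_filter(x, q, s, tau=8)
        peaks = vs.local_maxima(out, height=0.5 * np.median(out[s]))
        assert all(np.min(np.abs(peaks - i)) <= 1 for i in s)

        # peak height over the noise level measured away from spikes
        away = np.convolve(q, np.ones(17), mode="same") < 0.5

        def peak_noise_ratio(trace):
            return np.median(trace[s]) / trace[away].std()

        assert peak_noise_ratio(out) >= peak_noise_ratio(x)

    def test_flat_spectrum_prewhitening_is_near_identity(self):
        rng = np.random.default_rng(7)
        t = rng.standard_normal(20000)
        s = np.arange(100, 19900, 173)
        q = np.zeros(t.size)
        q[s] = 1.0
        tw = _prewhiten(t, q, 8)
        assert np.corrcoef(tw, t)[0, 1] >= 0.99

    def test_empty_spike_set_rejected(self):
        with pytest.raises(NoTemplateError):
            vs.whitened_matched_filter(
                np.zeros(100), np.zeros(100), np.array([], dtype=int), 8
            )


class TestReconstruct:
    def test_zero_train_gives_zero_trace(self):
        assert not vs.reconstruct(np.zeros(50), np.ones(17)).any()

    def test_single_spike_places_template(self):
        z = np.random.default_rng(8).normal(size=17)
        q = np.zeros(300)
        q[100] = 1.0
        rec = vs.reconstruct(q, z)
        np.testing.assert_array_equal(rec[92:109], z)
        assert not rec[:92].any() and not rec[109:].any()

    def test_overlapping_spikes_superpose_linearly(self):
        z = np.random.default_rng(9).normal(size=17)
        q1, q2 = np.zeros(200), np.zeros(200)
        q1[60], q2[65] = 1.0, 1.0
        np.testing.assert_allclose(
            vs.reconstruct(q1 + q2, z),
            vs.reconstruct(q1, z) + vs.reconstruct(q2, z),
            atol=1e-12,
        )

    def test_boundary_spike_truncated(self):
        z = np.arange(17.0)
        q = np.zeros(50)
        q[2] = 1.0
        rec = vs.reconstruct(q, z)
        np.testing.assert_array_equal(rec[:11], z[6:])


class TestDenoiseSpikes:
    @pytest.mark.parametrize("method", ["adaptive", "simple"])
    def test_strong_planted_spikes_recovered(self, method):
        x, s = make_planted_trace(10)
        cfg = vs.PipelineConfig(threshold_method=method)
        r = vs.denoise_spikes(x, FRAME_RATE, cfg)
        assert spike_f1(r.s, s) == 1.0
        assert not r.low_confidence

    def test_pure_noise_yields_little_reconstruction(self):
        # median over seeds: few detections, low reconstructed energy
        counts, energy = [], []
        for seed in range(5):
            t = np.random.default_rng(seed).standard_normal(5000)
            r = vs.denoise_spikes(t, FRAME_RATE)
            counts.append(len(r.s))
            energy.append((r.t_rec**2).sum() / (t**2).sum())
        assert np.median(counts) < 0.02 * 5000
        assert np.median(energy) < 0.10

    def test_deterministic(self):
        x, _ = make_planted_trace(12)
        r1 = vs.denoise_spikes(x, FRAME_RATE)
        r2 = vs.denoise_spikes(x, FRAME_RATE)
        np.testing.assert_array_equal(r1.s, r2.s)
        np.testing.assert_array_equal(r1.t_s, r2.t_s)
        np.testing.assert_array_equal(r1.t_rec, r2.t_rec)

    def test_few_round_one_spikes_falls_back_low_confidence(self):
        # two isolated spikes only: below min_spikes, so whitening is
        # skipped and the result is flagged
        rng = np.random.default_rng(13)
        t = 0.1 * rng.standard_normal(3000)
        t[[1000, 2000]] += 10.0
        r = vs.denoise_spikes(t, FRAME_RATE)
        assert r.low_confidence

    def test_template_length_and_spike_bounds(self):
        x, _ = make_planted_trace(14)
        cfg = vs.PipelineConfig()
        r = vs.denoise_spikes(x, FRAME_RATE, cfg)
        tau = cfg.resolve_tau(FRAME_RATE)
        assert r.z.shape == (2 * tau + 1,)
        assert np.all(np.diff(r.s) > 0)
        assert r.s.min() >= 0 and r.s.max() < x.size
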