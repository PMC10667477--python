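"""Jitter augmentation, GFP anchoring, Hjorth parameters and wavelet
band power, checked against independent time/frequency-domain oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shopeeg.features import (
    DegenerateSignalError,
    JitterWindow,
    Snippet,
    build_feature_table,
    extract_snippet,
    feature_vector,
    find_gfp_peak,
    gfp,
    hjorth_parameters,
    make_jitter_windows,
    minmax_normalize,
    wavelet_band_power,
)
from shopeeg.segment import Episode, LabeledEpisode

from conftest import make_recording


def spectral_moment(x, rate, k):
    """Periodogram spectral moment oracle.

    For sampled data the finite-difference derivative has transfer
    magnitude 2*rate*sin(pi*f/rate) (reducing to 2*pi*f well below
    Nyquist), so the k-th moment uses that discrete frequency mapping;
    Parseval then ties it to the time-domain mean square.
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = len(x)
    spec = np.abs(np.fft.rfft(x)) ** 2
    weights = np.full(len(spec), 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    omega_d = 2.0 * rate * np.sin(np.pi * freqs / rate)
    return float(np.sum(weights * omega_d ** (2 * k) * spec) / n**2)


class TestJitterWindows:
    def test_four_windows_at_stated_offsets(self):
        rec = make_recording(np.zeros((2, 10000)))
        ep = Episode("S1", "P1", 1, 2.0, 10.0)
        wins = make_jitter_windows(ep, rec)
        assert [(w.start, w.end) for w in wins] == [
            (9.8, 9.9), (9.9, 10.0), (10.0, 10.1), (10.1, 10.2),
        ]

    def test_each_window_holds_50_samples_at_500hz(self):
        rec = make_recording(np.zeros((2, 10000)), rate=500.0)
        ep = Episode("S1", "P1", 1, 2.0, 10.0)
        for w in make_jitter_windows(ep, rec):
            i0 = rec.time_to_sample(w.start)
            i1 = rec.time_to_sample(w.end)
            assert i1 - i0 == 50

    def test_episode_near_recording_edge_skipped(self):
        rec = make_recording(np.zeros((2, 500)))  # 1 s
        ep = Episode("S1", "P1", 1, 0.1, 0.95)  # t+200ms beyond end
        assert make_jitter_windows(ep, rec) == []


class TestGfp:
    def test_equal_channels_give_zero(self):
        assert gfp(np.ones((4, 10))).max() == 0.0

    def test_symmetric_pair_gives_one(self):
        sig = np.vstack([np.ones(5), -np.ones(5)])
        np.testing.assert_allclose(gfp(sig), 1.0)

    def test_matches_per_column_std_oracle(self, rng):
        sig = rng.normal(size=(61, 50))
        expected = [np.sqrt(np.mean((sig[:, j] - sig[:, j].mean()) ** 2)) for j in range(50)]
        np.testing.assert_allclose(gfp(sig), expected, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            gfp(np.ones((1, 10)))


class TestGfpPeak:
    def _window(self):
        return JitterWindow("e", 0, 1.0, 1.1)

    def test_planted_spike_found(self, rng):
        data = 0.01 * rng.normal(size=(4, 1000))
        data[:, 517] = [5.0, -5.0, 5.0, -5.0]  # high spatial spread at sample 517
        rec = make_recording(data)
        t = find_gfp_peak(self._window(), rec)
        assert rec.time_to_sample(t) == 517

    def test_flat_trace_ties_resolve_to_first_sample(self):
        rec = make_recording(np.vstack([np.ones(1000), -np.ones(1000)]))
        t = find_gfp_peak(self._window(), rec)
        assert rec.time_to_sample(t) == rec.time_to_sample(1.0)


class TestSnippetExtraction:
    @pytest.mark.parametrize("tau, n", [(1200, 600), (1400, 700), (2000, 1000)])
    def test_sample_counts(self, tau, n):
        rec = make_recording(np.zeros((2, 5000)))
        sig, shifted = extract_snippet(5.0, tau, rec)
        assert sig.shape == (2, n)
        assert not shifted

    def test_early_peak_shifts_window_to_start(self):
        rec = make_recording(np.arange(10000, dtype=float).reshape(2, 5000))
        sig, shifted = extract_snippet(0.1, 1200, rec)
        assert shifted
        np.testing.assert_array_equal(sig[0], rec.data[0, :600])

    def test_recording_shorter_than_tau_skipped(self):
        rec = make_recording(np.zeros((2, 400)))
        assert extract_snippet(0.4, 1200, rec) is None


class TestHjorth:
    def test_pure_sinusoid_analytic_values(self):
        rate = 10000.0
        t = np.arange(int(10 * rate)) / rate
        x = np.sin(2 * np.pi * 10.0 * t)
        activity, mobility, complexity = hjorth_parameters(x, rate)
        assert activity == pytest.approx(0.5, rel=1e-3)
        assert mobility == pytest.approx(2 * np.pi * 10.0, rel=1e-3)
        assert complexity == pytest.approx(1.0, abs=1e-3)

    def test_white_noise_matches_periodogram_moments(self, rng):
        rate = 500.0
        x = rng.normal(size=100_000)
        m0, mob, comp = hjorth_parameters(x, rate)
        s0 = spectral_moment(x, rate, 0)
        s2 = spectral_moment(x, rate, 1)
        s4 = spectral_moment(x, rate, 2)
        assert m0 == pytest.approx(s0, rel=0.01)
        assert mob == pytest.approx(np.sqrt(s2 / s0), rel=0.01)
        assert comp == pytest.approx(np.sqrt(s4 / s2) / np.sqrt(s2 / s0), rel=0.01)

    def test_mixed_sinusoids_match_periodogram_moments(self):
        rate = 500.0
        t = np.arange(20_000) / rate
        x = np.sin(2 * np.pi * 10 * t) + 0.5 * np.sin(2 * np.pi * 23 * t + 0.3)
        m0, mob, comp = hjorth_parameters(x, rate)
        s0 = spectral_moment(x, rate, 0)
        s2 = spectral_moment(x, rate, 1)
        s4 = spectral_moment(x, rate, 2)
        assert m0 == pytest.approx(s0, rel=0.01)
        assert mob == pytest.approx(np.sqrt(s2 / s0), rel=0.01)
        assert comp == pytest.approx(np.sqrt(s4 / s2) / np.sqrt(s2 / s0), rel=0.01)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.1, 50.0), st.integers(0, 2**31 - 1))
    def test_scale_invariance(self, scale, seed):
        x = np.random.default_rng(seed).normal(size=512)
        m0a, moba, compa = hjorth_parameters(x, 500.0)
        m0b, mobb, compb = hjorth_parameters(scale * x, 500.0)
        assert m0b == pytest.approx(scale**2 * m0a, rel=1e-9)
        assert mobb == pytest.approx(moba, rel=1e-9)
        assert compb == pytest.approx(compa, rel=1e-9)

    def test_constant_signal_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            hjorth_parameters(np.full(100, 3.3), 500.0)


class TestFeatureVector:
    def _snippet(self, data, rate=500.0):
        return Snippet("e", 0, 1200, data, rate)

    def test_default_montage_yields_61_values(self, rng):
        snip = self._snippet(rng.normal(size=(61, 600)))
        assert feature_vector(snip, "mobility").shape == (61,)

    def test_reduced_montage_yields_matching_length(self, rng):
        snip = self._snippet(rng.normal(size=(4, 600)))
        assert feature_vector(snip, "complexity").shape == (4,)

    def test_channel_permutation_equivariance(self, rng):
        data = rng.normal(size=(5, 600))
        perm = np.array([3, 0, 4, 1, 2])
        v = feature_vector(self._snippet(data))
        vp = feature_vector(self._snippet(data[perm]))
        np.testing.assert_allclose(vp, v[perm], rtol=1e-12)


class TestMinMax:
    def test_worked_example(self):
        np.testing.assert_allclose(minmax_normalize([2.0, 4.0, 6.0]), [0.0, 0.5, 1.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.01, 100.0), st.floats(-50.0, 50.0), st.integers(0, 2**31 - 1))
    def test_affine_invariance_and_range(self, a, b, seed):
        v = np.random.default_rng(seed).normal(size=8)
        out = minmax_normalize(v)
        np.testing.assert_allclose(minmax_normalize(a * v + b), out, atol=1e-7)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            minmax_normalize(np.ones(5))


class TestWaveletBandPower:
    def _snippet(self, data, rate=500.0, tau=2000):
        return Snippet("e", 0, tau, data, rate)

    def test_10hz_sinusoid_alpha_dominates_theta(self):
        t = np.arange(1000) / 500.0
        data = np.vstack([np.sin(2 * np.pi * 10 * t)] * 3)
        snip = self._snippet(data)
        alpha = wavelet_band_power(snip, "alpha")
        theta = wavelet_band_power(snip, "theta")
        assert np.all(alpha / theta > 10)

    def test_power_scales_quadratically(self, rng):
        data = rng.normal(size=(3, 1000))
        snip1 = self._snippet(data)
        snip2 = self._snippet(2.0 * data)
        ratio = wavelet_band_power(snip2, "alpha") / wavelet_band_power(snip1, "alpha")
        np.testing.assert_allclose(ratio, 4.0, rtol=0.05)

    def test_zero_signal_zero_power(self):
        snip = self._snippet(np.zeros((3, 1000)))
        np.testing.assert_allclose(wavelet_band_power(snip, "alpha"), 0.0, atol=1e-20)

    def test_window_too_short_for_theta_cycles_errors(self):
        snip = self._snippet(np.zeros((3, 600)), tau=1200)  # 1.2 s < 7/5 Hz
        with pytest.raises(ValueError, match="too short"):
            wavelet_band_power(snip, "theta")


class TestAugmentationBookkeeping:
    def test_snippet_count_is_4x_eligible_episodes(self, tiny_cohort):
        bundle = tiny_cohort[0]
        from shopeeg.segment import label_two_class, segment_episodes

        eps = segment_episodes(bundle.events)
        labeled = label_two_class(eps, bundle.events)
        table = build_feature_table(bundle.recording, labeled, taus_ms=(1200,))
        eligible = len(labeled) - table.attrs["n_skipped_episodes"]
        assert len(table) == 4 * eligible
        assert set(table["offset_ms"]) == {-200, -100, 0, 100}
        # every snippet traces back to its source episode
        per_episode = table.groupby("episode_id").size()
        assert (per_episode == 4).all()

    def test_labels_carried_through(self, tiny_cohort):
        bundle = tiny_cohort[0]
        from shopeeg.segment import label_three_class, segment_episodes

        eps = segment_episodes(bundle.events)
        labeled = label_three_class(eps, bundle.events)
        table = build_feature_table(bundle.recording, labeled, taus_ms=(1200,))
        by_ep = dict(zip(table["episode_id"], table["label"]))
        for le in labeled:
            if le.episode.episode_id in by_ep:
                assert by_ep[le.episode.episode_id] == le.label
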