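import numpy as np
import pytest

from conftest import make_epochs
from doceeg.connectivity import (ConnectivityMatrix, coherence_matrix,
                                 laplacian_filter, morlet_tf,
                                 mutual_information_matrix, roi_summarize,
                                 wpli_matrix, wpli_threshold)
from doceeg.core import CHANNELS_1020, ConfigurationError
from doceeg.montage import ADJACENCY, ROI_ELECTRODES, roi_pairs, \
    validate_adjacency
from oracles import (naive_coherence, naive_laplacian, naive_mi,
                     naive_roi_means, naive_wpli)


def lagged_pair_epochs(rng, n_ep=60, sfreq=250.0, n_t=500, freq=10.0,
                       lag_frac=0.25, extra_ch=0, noise=0.05):
    """Two channels: narrowband signal and its quarter-cycle-lagged copy."""
    lag = int(round(sfreq / freq * lag_frac))
    base = rng.standard_normal((n_ep, n_t + lag))
    spec = np.fft.rfft(base, axis=-1)
    f = np.fft.rfftfreq(base.shape[-1], d=1.0 / sfreq)
    spec *= np.exp(-0.5 * ((f - freq) / 0.8) ** 2)
    nb = np.fft.irfft(spec, n=base.shape[-1], axis=-1)
    x = nb[:, lag:]
    y = nb[:, :n_t]
    chans = [x, y] + [rng.standard_normal((n_ep, n_t))
                      for _ in range(extra_ch)]
    data = np.stack(chans, axis=1)
    data += noise * rng.standard_normal(data.shape)
    return make_epochs(data, sfreq=sfreq)


class TestLaplacian:
    def test_adjacency_table_symmetric_and_complete(self):
        validate_adjacency(ADJACENCY)

    def test_common_signal_removed(self, rng):
        wave = rng.standard_normal((5, 1, 200))
        data = np.repeat(wave, 19, axis=1)
        out = laplacian_filter(make_epochs(data, ch_names=CHANNELS_1020))
        assert np.abs(out.data).max() < 1e-12

    def test_single_active_channel(self, rng):
        data = np.zeros((2, 19, 100))
        c3 = CHANNELS_1020.index("C3")
        sig = rng.standard_normal((2, 100))
        data[:, c3, :] = sig
        out = laplacian_filter(make_epochs(data))
        assert np.allclose(out.data[:, c3], sig)
        for nb in ADJACENCY["C3"]:
            i = CHANNELS_1020.index(nb)
            deg = len(ADJACENCY[nb])
            assert np.allclose(out.data[:, i], -sig / deg)

    def test_missing_channel_raises(self, rng):
        ep = make_epochs(rng.standard_normal((2, 3, 50)),
                         ch_names=("a", "b", "c"))
        with pytest.raises(ConfigurationError):
            laplacian_filter(ep, adjacency={"a": ("b",), "b": ("a",)})

    def test_matches_naive_oracle(self, small_tf_fixture):
        adjacency = {"ch0": ("ch1", "ch2"), "ch1": ("ch0", "ch3"),
                     "ch2": ("ch0", "ch3"), "ch3": ("ch1", "ch2")}
        out = laplacian_filter(small_tf_fixture, adjacency=adjacency)
        expected = naive_laplacian(small_tf_fixture.data,
                                   small_tf_fixture.ch_names, adjacency)
        assert np.allclose(out.data, expected, rtol=1e-9, atol=1e-12)

    def test_zero_lag_common_source_discounted_after_laplacian(self, rng):
        """A shared zero-lag source between non-adjacent channels must not
        produce phase-lag connectivity."""
        n_ep, n_t, sfreq = 40, 500, 250.0
        data = 1.0 * rng.standard_normal((n_ep, 19, n_t))
        src = rng.standard_normal((n_ep, n_t))
        spec = np.fft.rfft(src, axis=-1)
        f = np.fft.rfftfreq(n_t, d=1.0 / sfreq)
        spec *= np.exp(-0.5 * ((f - 10.0) / 1.0) ** 2)
        src = np.fft.irfft(spec, n=n_t, axis=-1)
        src /= src.std()
        i, j = CHANNELS_1020.index("F3"), CHANNELS_1020.index("P4")
        data[:, i] += 3.0 * src
        data[:, j] += 3.0 * src
        lap = laplacian_filter(make_epochs(data, sfreq=sfreq))
        w = wpli_matrix(morlet_tf(lap, 10.0))
        assert w.values[i, j] < 0.25


class TestMorlet:
    def test_phase_advances_at_carrier_rate(self):
        sfreq, freq = 250.0, 10.0
        t = np.arange(500) / sfreq
        data = np.tile(np.sin(2 * np.pi * freq * t), (12, 1, 1))
        tf = morlet_tf(make_epochs(data, sfreq=sfreq), freq)
        phase = np.unwrap(np.angle(tf.data[0, 0, tf.valid]))
        rate = np.diff(phase).mean() * sfreq / (2 * np.pi)
        assert rate == pytest.approx(freq, rel=0.01)

    def test_modulus_proportional_to_amplitude(self):
        sfreq, freq = 250.0, 8.0
        t = np.arange(500) / sfreq
        mods = []
        for amp in (1.0, 3.0):
            data = np.tile(amp * np.sin(2 * np.pi * freq * t), (12, 1, 1))
            tf = morlet_tf(make_epochs(data, sfreq=sfreq), freq)
            mods.append(np.abs(tf.data[0, 0, tf.valid]).mean())
        assert mods[1] == pytest.approx(3 * mods[0], rel=0.01)

    def test_off_frequency_attenuation_matches_gaussian_window(self):
        """The wavelet's spectral response is Gaussian with
        sigma_f = f / n_cycles; a tone offset by df is attenuated by
        exp(-df^2 / (2 sigma_f^2))."""
        sfreq, freq, n_cycles, df = 500.0, 15.0, 6, 3.0
        t = np.arange(1000) / sfreq
        on = np.tile(np.sin(2 * np.pi * freq * t), (12, 1, 1))
        off = np.tile(np.sin(2 * np.pi * (freq + df) * t), (12, 1, 1))
        m_on = np.abs(morlet_tf(make_epochs(on, sfreq=sfreq), freq,
                                n_cycles=n_cycles).data).mean()
        m_off = np.abs(morlet_tf(make_epochs(off, sfreq=sfreq), freq,
                                 n_cycles=n_cycles).data).mean()
        sigma_f = freq / n_cycles
        expected = np.exp(-df**2 / (2 * sigma_f**2))
        assert m_off / m_on == pytest.approx(expected, rel=0.10)

    def test_wavelet_longer_than_epoch_raises(self, rng):
        ep = make_epochs(rng.standard_normal((12, 2, 200)), sfreq=250.0)
        with pytest.raises(ConfigurationError):
            morlet_tf(ep, 1.5)


class TestWpli:
    def test_quarter_cycle_lag_gives_unit_wpli(self, rng):
        ep = lagged_pair_epochs(rng)
        w = wpli_matrix(morlet_tf(ep, 10.0))
        assert w.values[0, 1] == pytest.approx(1.0, abs=0.02)

    def test_zero_lag_identical_channels_zero(self, rng):
        sig = rng.standard_normal((12, 1, 500))
        data = np.repeat(sig, 2, axis=1)
        w = wpli_matrix(morlet_tf(make_epochs(data, sfreq=250.0), 10.0))
        assert w.values[0, 1] == 0.0

    def test_matches_naive_oracle(self, small_tf_fixture):
        tf = morlet_tf(small_tf_fixture, 12.0)
        w = wpli_matrix(tf)
        expected = naive_wpli(tf.data, tf.valid)
        assert np.allclose(w.values, expected, rtol=1e-9, atol=1e-12)

    def test_zero_lag_never_beats_lagged(self, rng):
        """Volume-conduction discount: zero-lag mixing yields lower wPLI
        than quarter-cycle-lagged mixing at every coupling strength."""
        for seed in range(3):
            r = np.random.default_rng(seed)
            lag_ep = lagged_pair_epochs(r, n_ep=40, lag_frac=0.25, noise=0.3)
            r = np.random.default_rng(seed)
            zero_ep = lagged_pair_epochs(r, n_ep=40, lag_frac=0.0, noise=0.3)
            w_lag = wpli_matrix(morlet_tf(lag_ep, 10.0)).values[0, 1]
            w_zero = wpli_matrix(morlet_tf(zero_ep, 10.0)).values[0, 1]
            assert w_zero <= w_lag

    def test_too_few_epochs_raises(self, rng):
        ep = make_epochs(rng.standard_normal((4, 2, 500)), sfreq=250.0)
        with pytest.raises(ConfigurationError):
            wpli_matrix(morlet_tf(ep, 10.0))


class TestWpliThreshold:
    def test_independent_channels_mostly_zeroed(self):
        fractions = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ep = make_epochs(rng.standard_normal((12, 6, 400)), sfreq=200.0)
            m = wpli_threshold(ep, 10.0, n_surrogates=40, seed=seed)
            off = ~np.eye(6, dtype=bool)
            fractions.append((m.values[off] > 0).mean())
        assert np.mean(fractions) <= 0.05 + 0.05
        assert m.thresholded

    def test_strong_coupling_survives(self):
        survived = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            ep = lagged_pair_epochs(rng, n_ep=30, extra_ch=2, noise=0.2)
            m = wpli_threshold(ep, 10.0, n_surrogates=40, seed=seed)
            survived += m.values[0, 1] > 0
        assert survived >= 0.95 * n_seeds

    def test_deterministic_given_seed(self, rng):
        ep = make_epochs(rng.standard_normal((12, 4, 400)), sfreq=200.0)
        a = wpli_threshold(ep, 8.0, n_surrogates=25, seed=7)
        b = wpli_threshold(ep, 8.0, n_surrogates=25, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_too_few_surrogates_rejected(self, rng):
        ep = make_epochs(rng.standard_normal((12, 4, 400)), sfreq=200.0)
        for bad in (0, 19):
            with pytest.raises(ConfigurationError):
                wpli_threshold(ep, 8.0, n_surrogates=bad)


class TestCoherence:
    def test_identical_channels_unit_coherence(self, rng):
        sig = rng.standard_normal((20, 1, 250))
        data = np.repeat(sig, 3, axis=1)
        m = coherence_matrix(make_epochs(data, sfreq=250.0), pad_ratio=2)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(m.values[off], 1.0, atol=1e-9)

    def test_independent_noise_bias_floor(self):
        """With K epoch averages, coherence of independent signals is biased
        to roughly 1/K."""
        n_ep = 60
        means = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ep = make_epochs(rng.standard_normal((n_ep, 2, 250)), sfreq=250.0)
            means.append(coherence_matrix(ep, pad_ratio=2).values[0, 1])
        assert np.mean(means) == pytest.approx(1.0 / n_ep, rel=0.5)

    def test_equal_power_signal_plus_noise_half_coherence(self, rng):
        """y = x + independent noise at equal power: per-bin SNR is 1, so
        coherence = SNR / (1 + SNR) = 0.5 at the read-out frequency."""
        sfreq, freq = 250.0, 10.0
        n_ep, n_t = 120, 250
        x = rng.standard_normal((n_ep, n_t))
        y = x + rng.standard_normal((n_ep, n_t))
        data = np.stack([x, y], axis=1)
        m = coherence_matrix(make_epochs(data, sfreq=sfreq),
                             mode="at_frequency", freq_hz=freq, pad_ratio=8)
        assert m.values[0, 1] == pytest.approx(0.5, abs=0.1)

    def test_matches_naive_oracle(self, small_tf_fixture):
        for mode, freq in (("full_band", None), ("at_frequency", 11.0)):
            m = coherence_matrix(small_tf_fixture, mode=mode, freq_hz=freq,
                                 pad_ratio=4)
            expected = naive_coherence(small_tf_fixture.data, 250.0, 4,
                                       mode=mode, freq_hz=freq)
            assert np.allclose(m.values, expected, rtol=1e-9, atol=1e-12)

    def test_at_frequency_requires_freq(self, small_tf_fixture):
        with pytest.raises(ConfigurationError):
            coherence_matrix(small_tf_fixture, mode="at_frequency")


class TestMutualInformation:
    def test_independent_uniform_low_mi(self, rng):
        data = rng.uniform(0, 1, (30, 2, 1000))
        m = mutual_information_matrix(make_epochs(data, sfreq=500.0))
        assert m.values[0, 1] <= 0.02

    def test_identical_uniform_channels_log2_bins(self):
        x = np.linspace(0.0, 1.0, 30000)
        data = np.stack([x, x])[None, :, :]
        ep = make_epochs(data, sfreq=500.0)
        m = mutual_information_matrix(ep, n_bins=10)
        assert m.values[0, 1] == pytest.approx(np.log2(10), abs=0.01)

    def test_six_sample_toy_pair_hand_computed(self):
        x = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
        y = np.array([10.0, 12.0, 11.0, 0.0, 2.0, 1.0])
        data = np.stack([x, y])[None, :, :]
        ep = make_epochs(data, sfreq=6.0)
        m = mutual_information_matrix(ep, n_bins=2, min_samples=1)
        # both channels split 3/3 across the two bins and the joint table is
        # perfectly anti-diagonal: MI = H(X) = H(Y) = 1 bit
        assert m.values[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(m.values, naive_mi(np.stack([x, y]), 2),
                           atol=1e-12)

    def test_constant_channel_zero_with_warning(self, rng):
        data = rng.standard_normal((4, 3, 300))
        data[:, 1, :] = 5.0
        with pytest.warns(RuntimeWarning):
            m = mutual_information_matrix(make_epochs(data), min_samples=100)
        assert (m.values[1, :] == 0).all()

    def test_matches_naive_oracle(self, small_tf_fixture):
        m = mutual_information_matrix(small_tf_fixture, n_bins=10,
                                      min_samples=100)
        x = small_tf_fixture.concatenated()
        assert np.allclose(m.values, naive_mi(x, 10), rtol=1e-9, atol=1e-12)

    def test_min_samples_enforced(self, rng):
        ep = make_epochs(rng.standard_normal((2, 2, 100)))
        with pytest.raises(ConfigurationError):
            mutual_information_matrix(ep)


class TestEstimatorInvariances:
    def test_positive_rescaling_invariance(self, small_tf_fixture):
        scales = np.array([0.5, 2.0, 7.0, 0.1])[None, :, None]
        scaled = make_epochs(small_tf_fixture.data * scales, sfreq=250.0)
        w0 = wpli_matrix(morlet_tf(small_tf_fixture, 12.0)).values
        w1 = wpli_matrix(morlet_tf(scaled, 12.0)).values
        assert np.allclose(w0, w1, atol=1e-9)
        c0 = coherence_matrix(small_tf_fixture, pad_ratio=2).values
        c1 = coherence_matrix(scaled, pad_ratio=2).values
        assert np.allclose(c0, c1, atol=1e-9)
        m0 = mutual_information_matrix(small_tf_fixture, min_samples=100).values
        m1 = mutual_information_matrix(scaled, min_samples=100).values
        assert np.allclose(m0, m1, atol=1e-9)

    def test_channel_permutation_equivariance(self, small_tf_fixture):
        perm = np.array([2, 0, 3, 1])
        permuted = make_epochs(small_tf_fixture.data[:, perm, :], sfreq=250.0)
        m0 = mutual_information_matrix(small_tf_fixture, min_samples=100).values
        m1 = mutual_information_matrix(permuted, min_samples=100).values
        assert np.allclose(m1, m0[np.ix_(perm, perm)], atol=1e-12)
        w0 = wpli_matrix(morlet_tf(small_tf_fixture, 12.0)).values
        w1 = wpli_matrix(morlet_tf(permuted, 12.0)).values
        assert np.allclose(w1, w0[np.ix_(perm, perm)], atol=1e-12)


class TestRoiSummaries:
    def matrix(self, values):
        return ConnectivityMatrix(values=values, estimator="MI",
                                  freq_context="full_band")

    def test_all_ones_matrix(self):
        values = np.ones((19, 19)) - np.eye(19)
        s = roi_summarize(self.matrix(values))
        assert all(v == 1.0 for v in s.as_dict().values())

    def test_two_pair_left_frontoparietal(self):
        values = np.zeros((19, 19))
        for a, b in (("F3", "P3"), ("F7", "T5")):
            i, j = CHANNELS_1020.index(a), CHANNELS_1020.index(b)
            values[i, j] = values[j, i] = 1.0
        s = roi_summarize(self.matrix(values))
        assert s.left_frontoparietal == pytest.approx(2 / 6)
        assert s.right_frontoparietal == 0.0
        assert s.global_mean == pytest.approx((2 / 6) / 5)

    def test_random_matrix_matches_oracle(self, rng):
        sym = rng.random((19, 19))
        sym = (sym + sym.T) / 2
        np.fill_diagonal(sym, 0.0)
        s = roi_summarize(self.matrix(sym))
        expected = naive_roi_means(sym, CHANNELS_1020,
                                   roi_pairs(ROI_ELECTRODES))
        for roi, val in expected.items():
            key = roi if roi != "global_mean" else "global_mean"
            assert s.as_dict()[key] == pytest.approx(val, rel=1e-9)

    def test_empty_roi_rejected(self):
        with pytest.raises(ConfigurationError):
            roi_pairs({"bad": (("F3",), ("F3",))})
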