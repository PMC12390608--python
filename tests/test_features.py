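import numpy as np
import pytest

from erpauth.epoching import EpochSet
from erpauth.features import (DEFAULT_BANDS, N_SPECTRAL, N_TEMPORAL,
                              assemble_feature_vector, band_powers,
                              build_samples, erp_average, feature_matrix,
                              reduce_channels, welch_psd)


def make_epochs(data, sfreq=64.0, labels=None, names=None):
    data = np.asarray(data, float)
    n_ep, n_ch, n_tp = data.shape
    times = -0.1 + np.arange(n_tp) / sfreq
    labels = labels if labels is not None else ["s"] * n_ep
    names = names or [f"c{i}" for i in range(n_ch)]
    return EpochSet(data=data, times=times, labels=np.array(labels, object),
                    sfreq=sfreq, channel_names=names)


class TestErpAverage:
    def test_single_epoch_identity(self, rng):
        ep = make_epochs(rng.standard_normal((1, 2, 20)))
        erp = erp_average(ep)
        np.testing.assert_array_equal(erp.values, ep.data[0].T)

    def test_mean_of_constants(self):
        ep = make_epochs(np.stack([np.full((2, 10), 1.0),
                                   np.full((2, 10), 3.0)]))
        np.testing.assert_allclose(erp_average(ep).values, 2.0)

    def test_variance_shrinks_as_one_over_n(self, rng):
        # variance-of-mean oracle: template + unit white noise, N = 100
        template = rng.standard_normal((2, 50))
        noise = rng.standard_normal((100, 2, 50))
        ep = make_epochs(template[None] + noise)
        resid = erp_average(ep).values.T - template
        assert resid.var() == pytest.approx(1.0 / 100, rel=0.35)

    def test_group_selection_and_permutation_invariance(self, rng):
        ep = make_epochs(rng.standard_normal((6, 2, 12)))
        a = erp_average(ep, [0, 2, 4]).values
        b = erp_average(ep, [4, 0, 2]).values
        np.testing.assert_allclose(a, b, atol=1e-12)  # summation order only

    def test_empty_group_rejected(self, rng):
        ep = make_epochs(rng.standard_normal((3, 2, 12)))
        with pytest.raises(ValueError):
            erp_average(ep, [])


class TestReduceChannels:
    def test_identical_channels_reduce_to_single(self, rng):
        ep = make_epochs(np.repeat(rng.standard_normal((1, 1, 30)), 4,
                                   axis=1))
        erp = erp_average(ep)
        np.testing.assert_allclose(reduce_channels(erp),
                                   erp.values[:, 0])

    def test_opposite_channels_cancel(self, rng):
        v = rng.standard_normal((1, 1, 30))
        ep = make_epochs(np.concatenate([v, -v], axis=1))
        np.testing.assert_allclose(reduce_channels(erp_average(ep)), 0.0,
                                   atol=1e-15)

    def test_matches_hand_computed_row_means(self, rng):
        ep = make_epochs(rng.standard_normal((1, 14, 257)))
        erp = erp_average(ep)
        np.testing.assert_allclose(reduce_channels(erp),
                                   erp.values.mean(axis=1))

    def test_channel_subset(self, rng):
        ep = make_epochs(rng.standard_normal((1, 3, 10)),
                         names=["x", "y", "z"])
        erp = erp_average(ep)
        out = reduce_channels(erp, channels=("x", "z"))
        np.testing.assert_allclose(out, erp.values[:, [0, 2]].mean(axis=1))
        with pytest.raises(ValueError):
            reduce_channels(erp, channels=("nope",))

    def test_per_channel_mode_flattens(self, rng):
        ep = make_epochs(rng.standard_normal((1, 3, 10)))
        erp = erp_average(ep)
        assert reduce_channels(erp, mode="per_channel").shape == (30,)


class TestWelch:
    def test_zero_signal_zero_psd(self):
        ep = make_epochs(np.zeros((2, 2, 300)), sfreq=256.0)
        psd = welch_psd(ep)
        assert np.all(psd.psd == 0)

    def test_white_noise_parseval(self, rng):
        # total power ~ variance for unit white noise (Parseval oracle)
        ep = make_epochs(rng.standard_normal((4, 1, 8192)), sfreq=256.0)
        psd = welch_psd(ep, fmin=0.0, fmax=128.0)
        df = psd.freqs[1] - psd.freqs[0]
        total = psd.psd.sum() * df
        assert total == pytest.approx(1.0, rel=0.05)

    def test_pure_sinusoid_peaks_at_its_frequency(self):
        t = np.arange(2048) / 256.0
        x = np.sin(2 * np.pi * 10.0 * t)
        ep = make_epochs(x[None, None, :], sfreq=256.0)
        psd = welch_psd(ep)
        assert psd.freqs[np.argmax(psd.psd[:, 0])] == pytest.approx(10.0,
                                                                    abs=0.5)

    def test_short_epoch_uses_single_full_segment(self, rng):
        ep = make_epochs(rng.standard_normal((1, 1, 100)), sfreq=256.0)
        psd = welch_psd(ep, seg_len=256)
        assert len(psd.freqs) > 0  # resolution 256/100 Hz, grid still valid

    def test_psd_nonnegative(self, rng):
        ep = make_epochs(rng.standard_normal((3, 2, 257)), sfreq=256.0)
        assert np.all(welch_psd(ep).psd >= 0)


class TestBandPowers:
    def _psd_feature(self, psd_matrix, freqs, names):
        from erpauth.features import PSDFeature

        return PSDFeature(psd=psd_matrix, freqs=freqs, channel_names=names)

    def test_flat_psd_gives_constant_band_powers(self):
        freqs = np.arange(0.5, 45.5, 0.5)
        names = list("abcdef")
        psd = self._psd_feature(np.full((len(freqs), 6), 3.25), freqs, names)
        bp = band_powers(psd, channels6=tuple(names))
        np.testing.assert_allclose(bp, 3.25)
        assert bp.shape == (5, 6)

    def test_power_confined_to_alpha(self):
        freqs = np.arange(0.5, 45.5, 0.5)
        names = list("abcdef")
        mat = np.zeros((len(freqs), 6))
        mat[(freqs >= 8) & (freqs < 13)] = 2.0
        psd = self._psd_feature(mat, freqs, names)
        bp = band_powers(psd, channels6=tuple(names))
        assert np.all(bp[2] > 0)            # alpha row
        assert np.all(bp[[0, 1, 3]] == 0)   # delta, theta, beta

    def test_matches_hand_computed_averages(self):
        freqs = np.arange(1.0, 46.0)   # 1 Hz grid
        names = ["p", "q"]
        mat = np.arange(len(freqs) * 2, dtype=float).reshape(len(freqs), 2)
        psd = self._psd_feature(mat, freqs, names)
        bp = band_powers(psd, channels6=("p", "q"))
        theta_mask = (freqs >= 4) & (freqs < 8)
        np.testing.assert_allclose(bp[1], mat[theta_mask].mean(axis=0))

    def test_flat_vector_is_row_major(self):
        freqs = np.arange(0.5, 45.5, 0.5)
        names = list("abcdef")
        mat = np.tile(freqs[:, None], (1, 6))
        psd = self._psd_feature(mat, freqs, names)
        bp = band_powers(psd, channels6=tuple(names))
        np.testing.assert_array_equal(psd.flat, bp.reshape(-1))

    def test_unknown_channel_rejected(self, rng):
        freqs = np.arange(0.5, 45.5, 0.5)
        psd = self._psd_feature(rng.random((len(freqs), 2)), freqs,
                                ["a", "b"])
        with pytest.raises(ValueError):
            band_powers(psd, channels6=("a", "zz"))

    def test_empty_band_rejected(self, rng):
        freqs = np.arange(10.0, 46.0)  # nothing below 10 Hz
        psd = self._psd_feature(rng.random((len(freqs), 1)), freqs, ["a"])
        with pytest.raises(ValueError):
            band_powers(psd, channels6=("a",))


class TestAssembleAndBuild:
    def test_canonical_lengths_fuse_to_287(self, rng):
        fv = assemble_feature_vector(rng.random(257), rng.random(30), "s")
        assert len(fv.values) == 287 == N_TEMPORAL + N_SPECTRAL

    def test_relaxed_mode_allows_toys(self, rng):
        fv = assemble_feature_vector(rng.random(3), rng.random(2), "s",
                                     strict=False)
        assert len(fv.values) == 5

    def test_strict_mode_rejects_wrong_lengths(self, rng):
        with pytest.raises(ValueError):
            assemble_feature_vector(rng.random(257), rng.random(29), "s")

    def test_layout_temporal_then_spectral(self, rng):
        t, s = np.full(257, 1.0), np.full(30, 2.0)
        fv = assemble_feature_vector(t, s, "s")
        assert np.all(fv.values[:257] == 1.0)
        assert np.all(fv.values[257:] == 2.0)

    def test_grouping_counts_and_leftovers(self, rng):
        # 25 epochs, groups of 10 -> 2 samples, 5 epochs dropped
        ep = make_epochs(rng.standard_normal((25, 2, 257)), sfreq=256.0,
                         labels=["s"] * 25)
        samples = build_samples(ep, epochs_per_sample=10,
                                psd_channels=("c0", "c1"),
                                erp_channels=None)
        assert len(samples) == 2

    def test_group_of_one_degenerates_to_per_epoch(self, rng):
        ep = make_epochs(rng.standard_normal((5, 2, 257)), sfreq=256.0)
        samples = build_samples(ep, epochs_per_sample=1,
                                psd_channels=("c0", "c1"),
                                erp_channels=None)
        assert len(samples) == 5

    def test_36_subjects_with_10_epochs_yield_36_samples(self, rng):
        labels = np.repeat([f"u{i:02d}" for i in range(36)], 10)
        ep = make_epochs(rng.standard_normal((360, 2, 257)), sfreq=256.0,
                         labels=list(labels))
        samples = build_samples(ep, epochs_per_sample=10,
                                psd_channels=("c0", "c1"),
                                erp_channels=None)
        assert len(samples) == 36
        assert sorted({s.label for s in samples}) == sorted(set(labels))

    def test_no_complete_group_is_error(self, rng):
        ep = make_epochs(rng.standard_normal((3, 2, 257)), sfreq=256.0)
        with pytest.raises(ValueError):
            build_samples(ep, epochs_per_sample=10,
                          psd_channels=("c0", "c1"), erp_channels=None)

    def test_feature_matrix_stacking(self, rng):
        ep = make_epochs(rng.standard_normal((4, 2, 257)), sfreq=256.0,
                         labels=["a", "a", "b", "b"])
        samples = build_samples(ep, epochs_per_sample=2,
                                psd_channels=("c0", "c1"),
                                erp_channels=None)
        X, y = feature_matrix(samples)
        assert X.shape == (2, 257 + 5 * 2)   # two PSD channels -> 10 spectral
        assert y == ["a", "b"]
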