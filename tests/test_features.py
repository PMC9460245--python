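"""Feature families: statistics, EMD/HHT, Haar DWT, spectral and packet entropy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from harpipe import (
    FeatureConfig,
    FeatureMatrix,
    Window,
    build_feature_matrix,
    emd,
    extract_all,
    haar_dwt,
    haar_features,
    hht_features,
    minmax_fit_apply,
    spectral_entropy,
    statistical_features,
    wavelet_packet_entropy,
)
from harpipe.features import wpe_features

from conftest import make_feature_matrix

finite_signals = arrays(
    np.float64,
    st.integers(min_value=16, max_value=200),
    elements=st.floats(-100, 100, allow_nan=False),
)


class TestStatisticalFeatures:
    def test_simple_closed_forms(self):
        s = statistical_features([1.0, 2.0, 3.0])
        assert (s.mean, s.sample_std, s.minimum, s.maximum, s.median) == (2, 1, 1, 3, 2)

    def test_constant_input(self):
        s = statistical_features([7.0] * 4)
        assert s.sample_std == 0
        assert s.minimum == s.maximum == s.mode == s.mean == 7

    def test_skewed_input_hand_computed(self):
        s = statistical_features([0.0, 0.0, 0.0, 10.0])
        assert s.median == 0
        assert s.mean == pytest.approx(2.5)
        assert s.sample_std == pytest.approx(5.0)  # sum (I - 2.5)^2 / 3 = 25

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            statistical_features([1.0])

    def test_ordering_invariant(self, rng):
        x = rng.normal(size=64)
        s = statistical_features(x)
        assert s.minimum <= s.median <= s.maximum


class TestEMD:
    def test_constant_signal_has_no_imfs(self):
        d = emd(np.full(32, 2.5))
        assert d.imfs == []
        np.testing.assert_array_equal(d.residue, d.source)

    def test_non_finite_rejected(self):
        x = np.zeros(32)
        x[3] = np.nan
        with pytest.raises(ValueError):
            emd(x)

    def test_single_tone_imf1_matches_input(self):
        t = np.arange(512) / 100.0
        x = np.sin(2 * np.pi * 5.0 * t)
        d = emd(x)
        np.testing.assert_allclose(d.reconstruction(), x, atol=1e-9 * np.abs(x).max())
        corr = np.corrcoef(d.imfs[0], x)[0, 1]
        assert corr > 0.99

    def test_two_tone_separation_by_fft_argmax(self):
        t = np.arange(512) / 100.0
        x = np.sin(2 * np.pi * 1.0 * t) + 0.3 * np.sin(2 * np.pi * 12.0 * t)
        d = emd(x)
        freqs = np.fft.rfftfreq(512, d=0.01)

        def peak(sig):
            return freqs[np.argmax(np.abs(np.fft.rfft(sig))[1:]) + 1]

        assert peak(d.imfs[0]) == pytest.approx(12.0, abs=0.2)
        rest = np.sum(d.imfs[1:], axis=0) + d.residue if d.n_imfs > 1 else d.residue
        assert peak(rest) == pytest.approx(1.0, abs=0.2)

    def test_imf_extrema_zero_crossing_property_on_tones(self):
        t = np.arange(256) / 50.0
        x = np.sin(2 * np.pi * 3.0 * t) + 0.4 * np.sin(2 * np.pi * 9.0 * t)
        for c in emd(x).imfs:
            d = np.diff(c)
            s = np.sign(d)
            s[s == 0] = 1
            extrema = int(np.count_nonzero(np.diff(s)))
            sg = np.sign(c)
            sg = sg[sg != 0]
            crossings = int(np.count_nonzero(np.diff(sg)))
            assert abs(extrema - crossings) <= 1

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(finite_signals)
    def test_reconstruction_identity(self, x):
        d = emd(x)
        scale = max(np.abs(x).max(), 1.0)
        np.testing.assert_allclose(d.reconstruction(), x, atol=1e-9 * scale)


class TestHHTFeatures:
    def test_pure_tone_instantaneous_frequency(self):
        t = np.arange(512) / 100.0
        d = emd(np.sin(2 * np.pi * 5.0 * t))
        feats = hht_features(d, 100.0)
        assert feats["hht_imf1_if_mean"] == pytest.approx(5.0, abs=0.2)

    def test_empty_decomposition_gives_zero_vector(self):
        d = emd(np.full(32, 1.0))
        feats = hht_features(d, 100.0, n_keep=3)
        assert len(feats) == 12
        assert all(v == 0.0 for v in feats.values())

    def test_weak_tone_energy_fraction(self):
        t = np.arange(512) / 100.0
        x = np.sin(2 * np.pi * 1.0 * t) + 0.3 * np.sin(2 * np.pi * 12.0 * t)
        feats = hht_features(emd(x), 100.0)
        # amplitude ratio 0.3 vs 1.0 puts ~0.09/1.09 of the energy in IMF1
        assert feats["hht_imf1_energy_frac"] < 0.2


class TestHaar:
    def test_hand_computed_level_one(self):
        d = haar_dwt([4.0, 2.0, 5.0, 5.0], levels=1)
        np.testing.assert_allclose(d.approximations[0], [6 / np.sqrt(2), 10 / np.sqrt(2)])
        np.testing.assert_allclose(d.details[0], [2 / np.sqrt(2), 0.0])

    def test_constant_signal_zero_details(self):
        d = haar_dwt(np.full(16, 3.0), levels=3)
        for det in d.details:
            np.testing.assert_array_equal(det, 0.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            haar_dwt([1.0, 2.0], levels=3)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(finite_signals)
    def test_energy_conservation(self, x):
        levels = 3
        d = haar_dwt(x, levels=levels)
        n = (len(x) // 2**levels) * 2**levels
        energy_in = float(np.sum(np.asarray(x[:n]) ** 2))
        assert d.coefficient_energy() == pytest.approx(energy_in, rel=1e-9, abs=1e-12)

    def test_detail_energy_example(self):
        feats = haar_features(haar_dwt([4.0, 2.0, 5.0, 5.0], levels=1))
        assert feats["haar_d1_energy"] == pytest.approx(2.0)  # (2/sqrt2)^2 + 0

    def test_energy_features_scale_quadratically(self, rng):
        x = rng.normal(size=64)
        f1 = haar_features(haar_dwt(x, 3))
        f2 = haar_features(haar_dwt(4.0 * x, 3))
        for key in ("haar_d1_energy", "haar_d2_energy", "haar_d3_energy", "haar_a_energy"):
            assert f2[key] == pytest.approx(16.0 * f1[key], rel=1e-9)


class TestSpectralEntropy:
    def test_uniform_spectrum_scores_one(self):
        # build the signal from a flat one-sided spectrum (odd n: no Nyquist bin)
        n = 65
        spec = np.ones(33, dtype=complex)
        spec[0] = 0.0
        x = np.fft.irfft(spec, n=n)
        assert spectral_entropy(x, 50.0).normalized_entropy == pytest.approx(1.0, abs=1e-12)

    def test_bin_aligned_tone_scores_zero(self):
        t = np.arange(64)
        x = np.sin(2 * np.pi * 8 * t / 64)
        assert spectral_entropy(x, 64.0).normalized_entropy == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_bins_give_log2(self):
        n = 64
        spec = np.zeros(33, dtype=complex)
        spec[3] = spec[9] = 1.0
        x = np.fft.irfft(spec, n=n)
        res = spectral_entropy(x, 50.0)
        assert res.entropy == pytest.approx(np.log(2), abs=1e-12)
        assert res.normalized_entropy == pytest.approx(np.log(2) / np.log(res.n_bins), abs=1e-12)

    def test_all_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            spectral_entropy(np.zeros(16), 50.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(finite_signals)
    def test_bounds_and_normalization(self, x):
        x = x - x.mean() + np.sin(np.arange(len(x)))  # guarantee non-DC power
        res = spectral_entropy(x, 50.0)
        assert 0.0 <= res.normalized_entropy <= 1.0 + 1e-12
        assert res.normalized_power.sum() == pytest.approx(1.0, abs=1e-12)
        assert res.entropy == pytest.approx(res.shannon_terms.sum())


class TestWaveletPacket:
    def test_two_levels_give_four_leaves(self, rng):
        tree = wavelet_packet_entropy(rng.normal(size=32), levels=2)
        assert len(tree.leaf_energies()) == 4

    def test_constant_signal_concentrates_in_first_leaf(self):
        tree = wavelet_packet_entropy(np.full(32, 2.0), levels=2)
        leaf = tree.leaf_energies()
        assert leaf[0] > 0
        np.testing.assert_allclose(leaf[1:], 0.0, atol=1e-12)
        assert tree.packet_entropy == 0.0

    def test_all_zero_signal_entropy_zero(self):
        assert wavelet_packet_entropy(np.zeros(32), 2).packet_entropy == 0.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(finite_signals)
    def test_leaf_energy_conservation(self, x):
        levels = 2
        tree = wavelet_packet_entropy(x, levels=levels)
        n = (len(x) // 2**levels) * 2**levels
        energy_in = float(np.sum(np.asarray(x[:n]) ** 2))
        assert tree.leaf_energies().sum() == pytest.approx(energy_in, rel=1e-9, abs=1e-12)
        # per-level conservation as well
        for i in range(1, levels + 1):
            level_energy = sum(tree.node_energies[(i, j)] for j in range(1, 2**i + 1))
            assert level_energy == pytest.approx(energy_in, rel=1e-9, abs=1e-12)


def _window(samples, fs=50.0, subject="s", label="walk"):
    return Window(
        subject_id=subject,
        label=label,
        samples=np.asarray(samples, dtype=float),
        sample_rate_hz=fs,
        start_index=0,
        label_purity=1.0,
    )


class TestExtractAll:
    def test_feature_count_matches_family_widths(self, rng):
        cfg = FeatureConfig()
        win = _window(rng.normal(size=(64, 3)))
        names, values = extract_all(win, cfg)
        per_channel = 7 + 4 * 3 + (2 * 3 + 2) + 2 + (4 + 1)  # 34 under defaults
        assert cfg.features_per_channel() == per_channel
        assert len(names) == len(values) == 3 * per_channel
        assert len(set(names)) == len(names)

    def test_deterministic_bitwise(self, rng):
        win = _window(rng.normal(size=(64, 2)))
        n1, v1 = extract_all(win)
        n2, v2 = extract_all(win)
        assert n1 == n2
        assert (v1 == v2).all()

    def test_metadata_does_not_enter_features(self, rng):
        samples = rng.normal(size=(64, 2))
        _, v1 = extract_all(_window(samples, subject="a", label="x"))
        _, v2 = extract_all(_window(samples, subject="b", label="y"))
        assert (v1 == v2).all()

    def test_zero_variance_window_yields_finite_degenerate_values(self):
        _, values = extract_all(_window(np.full((64, 2), 1.5)))
        assert np.isfinite(values).all()

    def test_entropies_scale_invariant_energies_quadratic(self, rng):
        samples = rng.normal(size=(64, 1))
        n1, v1 = extract_all(_window(samples))
        _, v2 = extract_all(_window(3.0 * samples))
        for name, a, b in zip(n1, v1, v2):
            if name.endswith(("se_normalized", "wpe_entropy")) or "energy_frac" in name:
                assert b == pytest.approx(a, rel=1e-6, abs=1e-9)
            elif name.endswith(("haar_a_energy",)) or "_d" in name and name.endswith("_energy"):
                assert b == pytest.approx(9.0 * a, rel=1e-9)


class TestFeatureMatrix:
    def test_csv_roundtrip_bit_exact(self, tmp_path, rng):
        fm = make_feature_matrix(rng.normal(size=(5, 4)) * 1e-7)
        path = tmp_path / "fm.csv"
        fm.to_csv(path)
        back = FeatureMatrix.from_csv(path)
        assert back.feature_names == fm.feature_names
        assert (back.values == fm.values).all()

    def test_build_from_windows(self, rng):
        wins = [_window(rng.normal(size=(64, 2)), label=l) for l in ("a", "b")]
        fm = build_feature_matrix(wins)
        assert fm.n_rows == 2
        assert list(fm.labels) == ["a", "b"]


class TestMinMax:
    def test_affine_endpoints(self):
        train = make_feature_matrix([[2.0], [4.0], [6.0]])
        norm, _, mins, maxs = minmax_fit_apply(train)
        np.testing.assert_allclose(norm.values[:, 0], [0.0, 0.5, 1.0])
        assert (mins[0], maxs[0]) == (2.0, 6.0)

    def test_constant_column_maps_to_half(self):
        train = make_feature_matrix([[3.0], [3.0]])
        test = make_feature_matrix([[99.0]])
        norm, (norm_test,), _, _ = minmax_fit_apply(train, [test])
        assert (norm.values == 0.5).all()
        assert (norm_test.values == 0.5).all()

    def test_test_values_clipped(self):
        train = make_feature_matrix([[2.0], [6.0]])
        test = make_feature_matrix([[8.0], [0.0]])
        _, (norm_test,), _, _ = minmax_fit_apply(train, [test])
        np.testing.assert_allclose(norm_test.values[:, 0], [1.0, 0.0])

    def test_name_mismatch_rejected(self):
        train = make_feature_matrix([[1.0, 2.0]])
        test = make_feature_matrix([[1.0, 2.0]], names=["g0", "g1"])
        with pytest.raises(ValueError, match="mismatch"):
            minmax_fit_apply(train, [test])

    def test_training_columns_land_in_unit_interval(self, rng):
        train = make_feature_matrix(rng.normal(size=(20, 6)) * 100)
        norm, _, _, _ = minmax_fit_apply(train)
        assert norm.values.min() >= 0.0 and norm.values.max() <= 1.0
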