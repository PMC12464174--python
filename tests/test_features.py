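"""Wavelet decomposition, concatenation and baseline features."""

import numpy as np
import pytest
import pywt
from hypothesis import given
from hypothesis import strategies as st

from seizurekit.features import (
    WaveletConfig,
    coeff_length,
    concat_features,
    dwt_decompose,
    freq_domain_features,
    time_domain_features,
)


class TestCoeffLength:
    @pytest.mark.parametrize(
        "n,f,level,expected",
        [
            (4097, 2, 3, [513, 513, 1025, 2049]),  # total 4100
            (256, 2, 3, [32, 32, 64, 128]),
            (4097, 6, 3, [516, 516, 1028, 2051]),  # db3 total 4111, not 4100
        ],
    )
    def test_known_lengths(self, n, f, level, expected):
        assert coeff_length(n, f, level) == expected

    def test_total_4100_only_for_haar(self):
        assert sum(coeff_length(4097, 2, 3)) == 4100
        assert sum(coeff_length(4097, 6, 3)) == 4111

    def test_signal_shorter_than_filter_rejected(self):
        with pytest.raises(ValueError):
            coeff_length(4, 6, 1)

    @given(
        n=st.integers(min_value=32, max_value=5000),
        wavelet=st.sampled_from(["db1", "db2", "db3", "coif1"]),
        level=st.integers(min_value=1, max_value=3),
    )
    def test_matches_reference_dwt_lengths(self, n, wavelet, level):
        """Closed-form rule equals the reference implementation's output
        lengths for arbitrary (n, wavelet, level)."""
        w = pywt.Wavelet(wavelet)
        expected = coeff_length(n, w.dec_len, level)
        coeffs = pywt.wavedec(np.zeros(n), wavelet, level=level, mode="symmetric")
        assert [len(c) for c in coeffs] == expected


class TestDWTDecompose:
    def test_bonn_length_decomposition(self):
        x = np.random.default_rng(0).standard_normal(4097)
        bands = dwt_decompose(x, WaveletConfig())
        assert [len(bands[k]) for k in ("A3", "D3", "D2", "D1")] == [513, 513, 1025, 2049]

    def test_haar_annihilates_constants(self):
        bands = dwt_decompose(np.full(256, 7.0), WaveletConfig())
        for k in ("D3", "D2", "D1"):
            np.testing.assert_allclose(bands[k], 0.0, atol=1e-12)

    def test_parseval_energy_conservation(self):
        """Orthogonal DWT conserves energy (dyadic length: no border
        extension) to 1e-8 relative."""
        x = np.random.default_rng(1).standard_normal(1024)
        bands = dwt_decompose(x, WaveletConfig())
        e_coeff = sum(float((c**2).sum()) for c in bands.values())
        e_sig = float((x**2).sum())
        assert abs(e_coeff - e_sig) / e_sig < 1e-8

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            dwt_decompose(np.zeros(1), WaveletConfig())

    def test_band_ranges_match_dyadic_halving(self):
        cfg = WaveletConfig()
        ranges = dict(zip(cfg.band_labels(), cfg.band_ranges(256.0)))
        assert ranges["A3"] == (0.0, 16.0)
        assert ranges["D3"] == (16.0, 32.0)
        assert ranges["D2"] == (32.0, 64.0)
        assert ranges["D1"] == (64.0, 128.0)


class TestConcatFeatures:
    def test_bonn_concat_length_4100(self):
        w = np.random.default_rng(2).standard_normal((1, 4097))
        assert len(concat_features(w).concat) == 4100

    def test_multichannel_concat_length(self):
        w = np.random.default_rng(3).standard_normal((22, 256))
        f = concat_features(w)
        assert len(f.concat) == 22 * 256
        assert len(f.per_channel) == 22

    def test_zero_signal_gives_zero_vector(self):
        f = concat_features(np.zeros((1, 256)))
        np.testing.assert_array_equal(f.concat, np.zeros(256))

    def test_band_map_covers_indices_once_in_channel_major_order(self):
        w = np.random.default_rng(4).standard_normal((2, 64))
        f = concat_features(w, fs=256.0)
        assert len(f.band_map) == len(f.concat)
        channels = [c for c, _, _ in f.band_map]
        assert channels == sorted(channels)  # channel-major
        # first block of channel 0 is A3, coarse to fine afterwards
        labels0 = [lab for c, lab, _ in f.band_map if c == 0]
        order = [lab for i, lab in enumerate(labels0) if i == 0 or labels0[i - 1] != lab]
        assert order == ["A3", "D3", "D2", "D1"]

    @given(
        n=st.sampled_from([128, 256, 500, 1024]),
        ch=st.integers(min_value=1, max_value=4),
        wavelet=st.sampled_from(["db1", "db2"]),
    )
    def test_concat_length_equals_channels_times_band_sum(self, n, ch, wavelet):
        cfg = WaveletConfig(wavelet_name=wavelet)
        w = np.random.default_rng(n + ch).standard_normal((ch, n))
        f = concat_features(w, cfg)
        assert len(f.concat) == ch * sum(coeff_length(n, cfg.filter_length, cfg.level))


class TestTimeDomainFeatures:
    def test_constant_channel(self):
        mean, sd, rms = time_domain_features(np.array([[3.0, 3.0, 3.0]]))
        assert (mean, sd, rms) == (3.0, 0.0, 3.0)

    def test_alternating_channel(self):
        mean, sd, rms = time_domain_features(np.array([[1.0, -1.0, 1.0, -1.0]]))
        assert mean == 0.0 and rms == 1.0

    def test_rms_identity(self, rng):
        w = rng.standard_normal((3, 200))
        feats = time_domain_features(w).reshape(3, 3)
        mean, sd, rms = feats[:, 0], feats[:, 1], feats[:, 2]
        np.testing.assert_allclose(rms**2, mean**2 + sd**2, atol=1e-10)


class TestFreqDomainFeatures:
    def test_pure_sine_mean_and_median(self):
        t = np.arange(1024) / 256.0
        w = np.sin(2 * np.pi * 10 * t)[None, :]
        mean_f, median_f = freq_domain_features(w, fs=256.0)
        assert abs(mean_f - 10.0) <= 1.0
        assert abs(median_f - 10.0) <= 1.0

    def test_two_line_spectrum_centroid(self):
        t = np.arange(2048) / 256.0
        w = (np.sin(2 * np.pi * 8 * t) + np.sin(2 * np.pi * 32 * t))[None, :]
        mean_f, _ = freq_domain_features(w, fs=256.0)
        assert abs(mean_f - 20.0) <= 1.0

    def test_white_noise_median_near_nyquist_half(self):
        rng = np.random.default_rng(0)
        medians = []
        for _ in range(100):
            w = rng.standard_normal((1, 2048))
            medians.append(freq_domain_features(w, fs=256.0)[1])
        assert abs(np.mean(medians) - 64.0) < 5.0

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            freq_domain_features(np.zeros((1, 4)), fs=256.0)
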