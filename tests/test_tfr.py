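"""CWT stage: scale formula, windowing, oracle equivalence, localization."""

import numpy as np
import pytest

from eegmvf import CWTConfig, apply_window, build_cdml_tfr, build_sequence, cwt_slice
from eegmvf.tfr import _SUPPORT_SIGMAS, freq_to_scale, morlet_kernel


def oracle_scalogram(x, cfg):
    """Independent brute-force transform: direct time-domain convolution
    of the signal with each sampled scaled wavelet (re-derived here from
    the wavelet formula, not via the FFT bank)."""
    out = np.empty((len(x), cfg.n_freqs))
    for i, f in enumerate(cfg.freqs):
        s = cfg.f_c * cfg.fs / f
        half = int(np.ceil(_SUPPORT_SIGMAS * np.sqrt(cfg.bandwidth) * s))
        u = np.arange(-half, half + 1) / s
        psi = (
            (np.pi * cfg.bandwidth) ** (-0.25)
            * np.exp(2j * np.pi * cfg.f_c * u)
            * np.exp(-0.5 * u**2 / cfg.bandwidth)
            / np.sqrt(s)
        )
        out[:, i] = np.abs(np.convolve(x, psi, mode="full")[half : half + len(x)])
    return out


class TestScaleMapping:
    def test_scale_formula_identity_point(self, cwt_cfg):
        # s = 1 exactly at f = f_c * f_s
        assert freq_to_scale(0.8125 * 250.0, cwt_cfg) == 1.0

    @pytest.mark.parametrize("f,expected", [(4.0, 50.78125), (40.0, 5.078125)])
    def test_scale_formula_band_edges(self, cwt_cfg, f, expected):
        assert freq_to_scale(f, cwt_cfg) == pytest.approx(expected, abs=0)

    def test_nonpositive_frequency_rejected(self, cwt_cfg):
        with pytest.raises(ValueError):
            freq_to_scale(0.0, cwt_cfg)


class TestWindow:
    def test_hamming_endpoints_and_midpoint(self, cwt_cfg):
        w = apply_window(np.ones(125), cwt_cfg)
        assert w[0] == pytest.approx(0.08, abs=1e-12)
        assert w[-1] == pytest.approx(0.08, abs=1e-12)
        assert w[62] == pytest.approx(1.0, abs=1e-12)  # k = (T-1)/2

    def test_zero_input_zero_output(self, cwt_cfg):
        assert np.array_equal(apply_window(np.zeros(125), cwt_cfg), np.zeros(125))

    def test_length_mismatch_rejected(self, cwt_cfg):
        with pytest.raises(ValueError):
            apply_window(np.ones(100), cwt_cfg)


class TestCwtSlice:
    def test_output_shape_125x125(self, cwt_cfg):
        out = cwt_slice(np.random.default_rng(0).normal(size=125), cwt_cfg)
        assert out.shape == (125, 125)

    def test_zero_input_zero_map(self, cwt_cfg):
        assert np.allclose(cwt_slice(np.zeros(125), cwt_cfg), 0.0, atol=1e-14)

    def test_magnitude_scales_linearly(self, cwt_cfg):
        x = np.random.default_rng(1).normal(size=125)
        assert np.allclose(
            cwt_slice(-2.5 * x, cwt_cfg), 2.5 * cwt_slice(x, cwt_cfg), rtol=1e-12
        )

    def test_matches_brute_force_convolution_oracle(self, cwt_cfg):
        rng = np.random.default_rng(7)
        for _ in range(10):
            x = rng.normal(size=125)
            ours = cwt_slice(x, cwt_cfg)
            ref = oracle_scalogram(x, cwt_cfg)
            rel = np.abs(ours - ref).max() / np.abs(ref).max()
            assert rel <= 1e-6

    @pytest.mark.parametrize("f0", [5.0, 10.0, 20.0, 35.0])
    def test_sinusoid_localizes_within_one_bin(self, cwt_cfg, f0):
        t = np.arange(125) / cwt_cfg.fs
        x = np.sin(2 * np.pi * f0 * t)  # unwindowed pure tone
        profile = cwt_slice(x, cwt_cfg).mean(axis=0)
        peak_bin = int(np.argmax(profile))
        true_bin = int(np.argmin(np.abs(cwt_cfg.freqs - f0)))
        assert abs(peak_bin - true_bin) <= 1

    def test_outputs_nonnegative_finite(self, cwt_cfg):
        x = np.random.default_rng(3).normal(size=125) * 100
        out = cwt_slice(x, cwt_cfg)
        assert np.all(out >= 0) and np.all(np.isfinite(out))

    def test_scale_to_frequency_convention_agrees_with_pywavelets(self):
        # independent cross-check of the s = fc*fs/f convention: a long
        # 10 Hz tone analysed by pywt at our scales must peak at ~10 Hz
        pywt = pytest.importorskip("pywt")
        fs = 250.0
        t = np.arange(2000) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        fc = pywt.central_frequency("morl")
        freqs = np.linspace(4, 40, 73)
        scales = fc * fs / freqs
        coef, _ = pywt.cwt(x, scales, "morl")
        profile = np.abs(coef[:, 500:1500]).mean(axis=1)
        assert abs(freqs[np.argmax(profile)] - 10.0) <= 1.0


class TestStacking:
    def test_cdml_shape_and_per_channel_definition(self, cwt_cfg):
        rng = np.random.default_rng(4)
        sl = rng.normal(size=(3, 125))
        out = build_cdml_tfr(sl, cwt_cfg)
        assert out.shape == (3, 125, 125)
        for c in range(3):
            assert np.array_equal(out[c], cwt_slice(apply_window(sl[c], cwt_cfg), cwt_cfg))

    def test_channel_permutation_permutes_planes(self, cwt_cfg):
        rng = np.random.default_rng(5)
        sl = rng.normal(size=(3, 125))
        perm = [2, 0, 1]
        assert np.array_equal(
            build_cdml_tfr(sl[perm], cwt_cfg), build_cdml_tfr(sl, cwt_cfg)[perm]
        )

    def test_wrong_channel_count_rejected(self, cwt_cfg):
        with pytest.raises(ValueError):
            build_cdml_tfr(np.zeros((2, 125)), cwt_cfg)

    def test_sequence_preserves_order_and_count(self, cwt_cfg):
        rng = np.random.default_rng(6)
        slices = rng.normal(size=(8, 3, 125))
        seq = build_sequence(slices, cwt_cfg)
        assert seq.shape == (8, 3, 125, 125)
        rev = build_sequence(slices[::-1], cwt_cfg)
        assert np.array_equal(rev, seq[::-1])
        single = build_sequence(slices[:1], cwt_cfg)
        assert single.shape == (1, 3, 125, 125)
        assert np.array_equal(single[0], seq[0])


def test_plot_scalograms_writes_png(tmp_path, cwt_cfg):
    maps = np.random.default_rng(8).random((2, 3, 125, 125))
    path = tmp_path / "maps.png"
    from eegmvf.tfr import plot_scalograms

    plot_scalograms(maps, str(path), cwt_cfg)
    assert path.stat().st_size > 0
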