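import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgfusion.denoise import (
    ICEEMDANConfig,
    ThresholdParams,
    denoise_metrics,
    denoise_record,
    dominant_frequency,
    emd,
    iceemdan_decompose,
    improved_threshold,
    wavelet_denoise_component,
)
from ecgfusion.synth import NoiseSpec, SynthConfig, add_noise, generate_clean_record

FS = 360.0


class TestImprovedThreshold:
    def test_zero_inside_band(self):
        x = np.array([-0.99, -0.5, 0.0, 0.5, 0.99])
        assert np.all(improved_threshold(x, 1.0) == 0)

    def test_exactly_zero_at_threshold(self):
        # T - 2T/(e^0 + 1) = 0
        assert improved_threshold(1.0, 1.0) == pytest.approx(0.0, abs=1e-15)

    def test_hard_threshold_asymptote_at_10T(self):
        expected = 10.0 - 2.0 / (math.exp(9.0) + 1.0)
        assert improved_threshold(10.0, 1.0) == pytest.approx(expected, abs=1e-3)
        assert improved_threshold(10.0, 1.0) == pytest.approx(9.99975, abs=1e-3)

    def test_soft_threshold_limit_just_above_T(self):
        # f(x) - sign(x)(|x| - T) -> 0 as |x| -> T+
        for eps in (1e-2, 1e-4, 1e-6):
            x = 1.0 + eps
            gap = abs(improved_threshold(x, 1.0) - (x - 1.0))
            assert gap <= eps  # both terms vanish together

    def test_continuity_at_T(self):
        below = improved_threshold(1.0 - 1e-12, 1.0)
        above = improved_threshold(1.0 + 1e-12, 1.0)
        assert abs(above - below) < 1e-9

    def test_identity_when_T_zero(self):
        x = np.array([-3.0, 0.2, 5.0])
        assert np.array_equal(improved_threshold(x, 0.0), x)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            improved_threshold(1.0, -0.1)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        x=st.floats(-1e6, 1e6, allow_nan=False),
        T=st.floats(1e-6, 1e3, allow_nan=False),
    )
    def test_odd_and_contractive(self, x, T):
        fx = improved_threshold(x, T)
        assert improved_threshold(-x, T) == pytest.approx(-fx, rel=1e-12, abs=1e-12)
        assert abs(fx) <= abs(x) + 1e-12

    def test_hard_limit_ratio_tends_to_one(self):
        for scale in (10.0, 100.0, 1000.0):
            assert improved_threshold(scale, 1.0) / scale == pytest.approx(
                1.0, abs=2e-4 / scale * 10
            )


class TestEMD:
    def test_pure_sinusoid_is_single_mode(self):
        t = np.arange(720) / FS
        x = np.sin(2 * np.pi * 10 * t)
        d = emd(x, fs=FS)
        assert np.corrcoef(d.imfs[0], x)[0, 1] > 0.99
        assert np.sum(d.residual**2) < 0.01 * np.sum(x**2)

    def test_imf_property_on_sinusoid(self):
        t = np.arange(720) / FS
        imf = emd(np.sin(2 * np.pi * 10 * t), fs=FS).imfs[0]
        zeros = int(np.sum(np.diff(np.sign(imf)) != 0))
        d = np.sign(np.diff(imf))
        extrema = int(np.sum(np.diff(d[d != 0]) != 0))
        assert abs(extrema - zeros) <= 1

    def test_constant_yields_no_imfs(self):
        x = np.full(100, 3.0)
        d = emd(x)
        assert d.imfs == []
        assert np.array_equal(d.residual, x)

    def test_monotone_yields_no_imfs(self):
        x = np.linspace(0.0, 5.0, 200)
        d = emd(x)
        assert d.imfs == []
        assert np.array_equal(d.residual, x)

    def test_two_tone_first_imf_near_50hz(self):
        t = np.arange(1440) / FS
        x = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 50 * t)
        d = emd(x, fs=FS)
        assert dominant_frequency(d.imfs[0], FS) == pytest.approx(50.0, rel=0.2)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="short"):
            emd(np.ones(4))


class TestICEEMDAN:
    def test_telescoping_reconstruction_exact(self, rng):
        x = rng.standard_normal(600)
        d = iceemdan_decompose(x, ICEEMDANConfig(ensemble_size=4, max_imfs=6, seed=1))
        err = np.max(np.abs(d.reconstruct() - x)) / np.max(np.abs(x))
        assert err < 1e-8

    def test_telescoping_on_ecg(self, noisy_ecg_4s):
        x = noisy_ecg_4s.lead(0)
        d = iceemdan_decompose(
            x, ICEEMDANConfig(ensemble_size=4, max_imfs=8, seed=3), fs=FS
        )
        assert np.max(np.abs(d.reconstruct() - x)) < 1e-8 * np.max(np.abs(x))

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal(400)
        cfg = ICEEMDANConfig(ensemble_size=3, max_imfs=5, seed=11)
        d1 = iceemdan_decompose(x, cfg)
        d2 = iceemdan_decompose(x, cfg)
        assert len(d1.imfs) == len(d2.imfs)
        for a, b in zip(d1.imfs, d2.imfs):
            assert np.array_equal(a, b)
        assert np.array_equal(d1.residual, d2.residual)

    def test_components_ordered_high_to_low_frequency(self, noisy_ecg_4s):
        d = iceemdan_decompose(
            noisy_ecg_4s.lead(0),
            ICEEMDANConfig(ensemble_size=6, max_imfs=10, seed=5),
            fs=FS,
        )
        freqs = d.dominant_freq_hz
        assert freqs[0] > freqs[-1]  # broad trend: first IMF fastest

    def test_small_ensemble_rejected(self):
        with pytest.raises(ValueError, match="ensemble"):
            ICEEMDANConfig(ensemble_size=1)


class TestWaveletDenoiseComponent:
    def test_zero_in_zero_out(self):
        out = wavelet_denoise_component(np.zeros(512))
        assert np.allclose(out, 0.0)

    def test_pure_noise_mostly_removed(self):
        z = np.random.default_rng(0).standard_normal(2048)
        out = wavelet_denoise_component(z)
        assert np.sum(out**2) < 0.2 * np.sum(z**2)

    def test_clean_low_frequency_sinusoid_preserved(self):
        x = np.sin(2 * np.pi * 2 * np.arange(2048) / FS)
        out = wavelet_denoise_component(x)
        ncc = np.sum(out * x) / np.sqrt(np.sum(out**2) * np.sum(x**2))
        assert ncc > 0.99

    def test_explicit_threshold_passthrough_at_zero(self):
        x = np.random.default_rng(1).standard_normal(512)
        out = wavelet_denoise_component(x, ThresholdParams(T=0.0))
        assert np.allclose(out, x, atol=1e-10)

    def test_short_component_rejected(self):
        with pytest.raises(ValueError, match="short"):
            wavelet_denoise_component(np.ones(16), ThresholdParams(levels=5))


class TestDenoiseRecord:
    CFG = ICEEMDANConfig(ensemble_size=50, max_imfs=12, seed=1)

    def test_baseline_wander_removed_5x(self, clean_ecg_4s, noisy_ecg_4s):
        clean, noisy = clean_ecg_4s.lead(0), noisy_ecg_4s.lead(0)
        out = denoise_record(noisy, self.CFG, fs=FS)
        rms_in = np.sqrt(np.mean((noisy - clean) ** 2))
        rms_out = np.sqrt(np.mean((out - clean) ** 2))
        assert rms_in / rms_out >= 5.0

    def test_near_identity_on_clean_input(self, clean_ecg_4s):
        clean = clean_ecg_4s.lead(0)
        out = denoise_record(clean, self.CFG, fs=FS)
        assert denoise_metrics(clean, out).ncc > 0.99

    def test_snr_improves_on_mixed_noise(self):
        rec = generate_clean_record(SynthConfig(FS, 3.0, {"N": 1.0}, 96.0, seed=31))
        noisy = add_noise(
            rec,
            NoiseSpec(baseline_amp=0.25, baseline_freq_hz=0.4,
                      gaussian_snr_db=8.0, powerline_amp=0.05, seed=13),
        )
        out = denoise_record(
            noisy.lead(0), ICEEMDANConfig(ensemble_size=16, max_imfs=10, seed=2), fs=FS
        )
        m = denoise_metrics(rec.lead(0), out, noisy.lead(0))
        assert m.snr_db > m.input_snr_db

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="short"):
            denoise_record(np.ones(200), self.CFG, fs=FS)


class TestDenoiseMetrics:
    def test_identical_signals(self, rng):
        x = rng.standard_normal(100)
        m = denoise_metrics(x, x)
        assert m.snr_db == math.inf and m.rmse == 0.0 and m.ncc == pytest.approx(1.0)

    def test_ncc_scale_invariant(self, rng):
        x = rng.standard_normal(100)
        assert denoise_metrics(x, 2 * x).ncc == pytest.approx(1.0)

    def test_orthogonal_perturbation_snr_closed_form(self):
        t = np.arange(3600) / FS
        clean = np.sin(2 * np.pi * 5 * t)
        denoised = clean + 0.1 * np.cos(2 * np.pi * 5 * t)
        assert denoise_metrics(clean, denoised).snr_db == pytest.approx(20.0, abs=0.01)

    def test_zero_energy_clean_rejected(self):
        with pytest.raises(ValueError, match="zero energy"):
            denoise_metrics(np.zeros(10), np.ones(10))
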