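"""Morlet CWT: mother wavelet identities, oracle equivalence, scalogram/
phasogram definitions, scale grid, image rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgfusion.cwt_features import (CWTResult, MorletParams, cwt, cwt_direct,
                                    default_scales, morlet_mother, phasogram,
                                    pseudo_frequency, scalogram, to_image)

PARAMS = MorletParams()  # omega0 = 6 rad/sample, n = 6 cycles, sigma = 1


class TestMotherWavelet:
    def test_value_at_zero(self):
        v = morlet_mother(0.0, PARAMS)
        expected = 1.0 / np.sqrt(2 * np.pi * PARAMS.sigma ** 2)
        assert v.imag == 0.0
        assert v.real == pytest.approx(expected, rel=1e-12)

    @given(t=st.floats(-5.0, 5.0))
    @settings(max_examples=30, deadline=None)
    def test_even_envelope(self, t):
        assert abs(morlet_mother(t, PARAMS)) == pytest.approx(
            abs(morlet_mother(-t, PARAMS)), rel=1e-9, abs=1e-12)

    def test_gaussian_envelope_ratio(self):
        ratio = abs(morlet_mother(3 * PARAMS.sigma, PARAMS)) / abs(
            morlet_mother(0.0, PARAMS))
        assert ratio == pytest.approx(np.exp(-4.5), rel=1e-9)

    def test_sigma_rule(self):
        p = MorletParams(omega0=5.0, n_cycles=7.0)
        assert p.sigma == 7.0 / 5.0


class TestCWT:
    def test_zero_signal_zero_coefficients(self):
        res = cwt(np.zeros(64), [1.0, 2.0, 4.0], PARAMS)
        assert np.all(res.coefficients == 0)

    def test_impulse_sifting(self):
        n, t0 = 128, 64
        x = np.zeros(n)
        x[t0] = 1.0
        a = 3.0
        res = cwt(x, [a], PARAMS)
        tau = np.arange(n)
        expected = np.abs(morlet_mother((t0 - tau) / a, PARAMS)) / a
        # atol covers the 6-sigma kernel truncation (envelope ~1e-9 there)
        np.testing.assert_allclose(np.abs(res.coefficients[0]), expected,
                                   atol=1e-8)

    def test_oracle_equivalence_interior(self, rng):
        """Convolution implementation vs direct Riemann sum, 20 random
        180-sample signals x 10 scales, interior samples."""
        scales = default_scales(250.0, n_scales=10)
        worst = 0.0
        for _ in range(20):
            x = rng.standard_normal(180)
            fast = cwt(x, scales, PARAMS).coefficients
            slow = cwt_direct(x, scales, PARAMS).coefficients
            interior = slice(80, 100)
            diff = np.abs(fast[:, interior] - slow[:, interior])
            ref = np.abs(slow[:, interior]).max(axis=1, keepdims=True)
            worst = max(worst, float((diff / ref).max()))
        assert worst < 1e-6

    def test_linearity(self, rng):
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        scales = [2.0, 5.0, 11.0]
        wx = cwt(x, scales, PARAMS).coefficients
        wy = cwt(y, scales, PARAMS).coefficients
        wxy = cwt(2.5 * x - 1.5 * y, scales, PARAMS).coefficients
        np.testing.assert_allclose(wxy, 2.5 * wx - 1.5 * wy, atol=1e-10)

    def test_circular_shift_covariance(self, rng):
        x = rng.standard_normal(128)
        k = 17
        scales = [2.0, 4.0]
        a = cwt(np.roll(x, k), scales, PARAMS, mode="circular").coefficients
        b = np.roll(cwt(x, scales, PARAMS, mode="circular").coefficients,
                    k, axis=1)
        np.testing.assert_allclose(a, b, atol=1e-6)

    @pytest.mark.parametrize("freq", [5.0, 10.0, 20.0, 40.0])
    def test_ridge_law(self, freq):
        """Scalogram ridge at a = omega0 * fs / (2 pi f), within one
        scale-grid step."""
        fs, n = 250.0, 800
        x = np.cos(2 * np.pi * freq * np.arange(n) / fs)
        scales = default_scales(fs, n_scales=120)
        res = cwt(x, scales, PARAMS, fs=fs)
        power = scalogram(res)[:, 150:-150].mean(axis=1)
        a_hat = scales[int(np.argmax(power))]
        a_theory = PARAMS.omega0 * fs / (2 * np.pi * freq)
        step = scales[1] / scales[0]
        assert a_theory / step <= a_hat <= a_theory * step

    @pytest.mark.parametrize("bad_scales", [[0.0, 1.0], [-2.0]])
    def test_nonpositive_scale_rejected(self, bad_scales):
        with pytest.raises(ValueError):
            cwt(np.ones(64), bad_scales, PARAMS)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            cwt(np.ones(4), [1.0], PARAMS)


class TestDefaultScales:
    def test_endpoints_invert_to_frequency_band(self):
        fs = 250.0
        scales = default_scales(fs, n_scales=180)
        freqs = pseudo_frequency(scales, fs)
        assert freqs[0] == pytest.approx(0.45 * fs, rel=0.01)
        assert freqs[-1] == pytest.approx(1.0, rel=0.01)

    def test_length_and_log_spacing(self):
        scales = default_scales(250.0, n_scales=180)
        assert len(scales) == 180
        ratios = scales[1:] / scales[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)
        assert np.all(np.diff(scales) > 0)


class TestScalogramPhasogram:
    def test_scalogram_is_squared_magnitude(self):
        res = CWTResult(coefficients=np.array([[3 + 4j]]), scales=[1.0],
                        fs=250.0)
        assert scalogram(res)[0, 0] == pytest.approx(25.0)

    def test_scalogram_homogeneity(self, rng):
        x = rng.standard_normal(64)
        scales = [2.0, 4.0]
        s1 = scalogram(cwt(x, scales, PARAMS))
        s2 = scalogram(cwt(3.0 * x, scales, PARAMS))
        np.testing.assert_allclose(s2, 9.0 * s1, rtol=1e-9)

    def test_phasogram_conventions(self):
        res = CWTResult(
            coefficients=np.array([[1j, 0.0 + 0j, -1.0 + 0j]]),
            scales=[1.0], fs=250.0)
        p = phasogram(res)
        assert p[0, 0] == pytest.approx(np.pi / 2)
        assert p[0, 1] == 0.0          # zero coefficient -> phase 0
        assert p[0, 2] == pytest.approx(np.pi)  # wrapped to (-pi, pi]

    def test_phase_rotation(self, rng):
        x = rng.standard_normal(64)
        res = cwt(x, [3.0], PARAMS)
        theta = 0.7
        rotated = CWTResult(coefficients=res.coefficients * np.exp(1j * theta),
                            scales=res.scales, fs=res.fs)
        d = phasogram(rotated) - phasogram(res)
        d = np.angle(np.exp(1j * d))  # mod 2 pi
        np.testing.assert_allclose(d, theta, atol=1e-9)


class TestToImage:
    def test_constant_scalogram_maps_to_zero(self):
        img = to_image(np.full((50, 50), 7.0), "scalogram")
        assert img.shape == (224, 224)
        assert np.all(img == 0)

    def test_phasogram_fixed_linear_map(self):
        m = np.full((40, 40), np.pi)
        assert np.all(to_image(m, "phasogram") == 255)
        m = np.full((40, 40), -np.pi + 1e-9)
        assert np.all(to_image(m, "phasogram") == 0)

    def test_shape_and_dtype(self, rng):
        img = to_image(rng.standard_normal((180, 180)) ** 2, "scalogram")
        assert img.shape == (224, 224)
        assert img.dtype == np.uint8

    def test_unknown_modality_rejected(self):
        with pytest.raises(ValueError):
            to_image(np.zeros((4, 4)), "spectrogram")
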