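"""Signal-conditioning exactness: every stage checked against an
analytic or independently computed oracle."""

import numpy as np
import pytest

from edasleep.preprocess import (
    PreprocessConfig,
    derive_signals,
    detrend_poly2,
    downsample,
    dwt_denoise,
    fir_derivative,
    make_diff_eda,
    savgol,
)

FS200 = 200.0
FS35 = 35.0


class TestDownsample:
    def test_constant_preserved(self):
        y = downsample(np.full(400, 2.5))
        assert y.shape == (70,)
        assert np.max(np.abs(y - 2.5)) < 1e-9

    def test_in_band_sine_preserved(self):
        t200 = np.arange(0, 60, 1 / FS200)
        y = downsample(np.sin(2 * np.pi * 1.0 * t200))
        t35 = np.arange(len(y)) / FS35
        expected = np.sin(2 * np.pi * 1.0 * t35)
        interior = slice(70, -70)
        assert np.max(np.abs(y[interior] - expected[interior])) < 1e-3

    def test_above_nyquist_sine_attenuated(self):
        t200 = np.arange(0, 60, 1 / FS200)
        y = downsample(np.sin(2 * np.pi * 30.0 * t200))
        assert np.sqrt(np.mean(y**2)) < 0.05

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            downsample(np.array([]))


class TestDetrend:
    def test_quadratic_annihilated(self):
        t = np.arange(2000) / FS35
        x = 3 + 0.1 * t - 0.002 * t**2
        y = detrend_poly2(x)
        assert np.max(np.abs(y)) < 1e-8 * np.max(np.abs(x))

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=3000).cumsum()
        once = detrend_poly2(x)
        assert np.allclose(detrend_poly2(once), once, atol=1e-9)

    def test_matches_normal_equations_oracle(self):
        t = np.arange(4000) / FS35
        x = (1 + 0.5 * t - 0.01 * t**2) + np.sin(2 * np.pi * 0.5 * t)
        # independent oracle: solve the normal equations directly
        A = np.vander(np.linspace(-1, 1, x.size), 3, increasing=True)
        beta = np.linalg.solve(A.T @ A, A.T @ x)
        expected = x - A @ beta
        assert np.allclose(detrend_poly2(x), expected, atol=1e-8)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detrend_poly2(np.array([1.0, 2.0]))


class TestSavitzkyGolay:
    def test_degree7_polynomial_passes_unchanged(self):
        t = np.linspace(0, 1, 1000)
        x = t**3
        y = savgol(x)
        interior = slice(64, -64)
        assert np.max(np.abs(y[interior] - x[interior])) < 1e-8

    def test_constant_unchanged(self):
        assert np.allclose(savgol(np.full(500, 4.2)), 4.2)

    def test_smooths_white_noise(self):
        reduced = 0
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=2000)
            reduced += savgol(x).var() < x.var()
        assert reduced == 20

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(sg_window=128)


class TestWaveletDenoise:
    def test_zero_threshold_reconstructs_perfectly(self):
        x = np.random.default_rng(1).normal(size=4096).cumsum()
        y, _ = dwt_denoise(x, threshold=0.0)
        assert np.max(np.abs(y - x)) < 1e-10

    def test_zero_input_zero_output(self):
        y, details = dwt_denoise(np.zeros(1024))
        assert not y.any()
        assert all(not d.any() for d in details)

    def test_denoising_reduces_mse_against_clean_sine(self):
        t = np.arange(0, 120, 1 / FS35)
        clean = np.sin(2 * np.pi * 0.5 * t)
        wins = 0
        for seed in range(20):
            noise = np.random.default_rng(seed).normal(0, 10 ** (-10 / 20), t.size)
            noisy = clean + noise  # SNR 10 dB
            den, _ = dwt_denoise(noisy)
            wins += np.mean((den - clean) ** 2) < np.mean((noisy - clean) ** 2)
        assert wins == 20

    def test_returns_four_detail_levels(self):
        _, details = dwt_denoise(np.random.default_rng(0).normal(size=2048))
        assert len(details) == 4
        # DL1 is the finest level and therefore the longest
        assert len(details[0]) > len(details[3])


class TestDiffEda:
    def test_identical_inputs_give_zero(self):
        x = np.random.default_rng(0).normal(size=100)
        assert not make_diff_eda(x, x).any()

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(2, 100))
        assert np.allclose(make_diff_eda(a, b), -make_diff_eda(b, a))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            make_diff_eda(np.zeros(10), np.zeros(11))


class TestFirDerivative:
    def test_constant_has_zero_derivative(self):
        y, _ = fir_derivative(np.full(2000, 7.0))
        assert np.max(np.abs(y)) < 1e-6 * 7.0

    def test_first_derivative_of_sine_matches_analytic(self):
        t = np.arange(0, 60, 1 / FS35)
        y, offset = fir_derivative(np.sin(2 * np.pi * t))
        expected = 2 * np.pi * np.cos(2 * np.pi * (np.arange(len(y)) + offset) / FS35)
        interior = slice(100, -100)
        amp_err = np.max(np.abs(y[interior] - expected[interior])) / (2 * np.pi)
        assert amp_err < 0.02

    def test_second_derivative_of_sine_matches_analytic(self):
        t = np.arange(0, 60, 1 / FS35)
        y, offset = fir_derivative(np.sin(2 * np.pi * t), order=2)
        expected = -((2 * np.pi) ** 2) * np.sin(
            2 * np.pi * (np.arange(len(y)) + offset) / FS35
        )
        interior = slice(100, -100)
        amp_err = np.max(np.abs(y[interior] - expected[interior])) / (2 * np.pi) ** 2
        assert amp_err < 0.04

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fir_derivative(np.zeros(80))


@pytest.mark.parametrize(
    "op",
    [
        downsample,
        detrend_poly2,
        savgol,
        lambda x: fir_derivative(x)[0],
    ],
    ids=["downsample", "detrend", "savgol", "fir"],
)
def test_stages_are_linear(op):
    rng = np.random.default_rng(42)
    x, y = rng.normal(size=(2, 1000))
    a, b = 1.7, -0.4
    lhs = op(a * x + b * y)
    rhs = a * op(x) + b * op(y)
    assert np.allclose(lhs, rhs, atol=1e-8)


def test_chain_on_constant_recording_is_null():
    x = np.full(200 * 120, 5.0)
    d = derive_signals(x)
    assert np.max(np.abs(d.det_eda)) < 1e-6
    assert np.max(np.abs(d.diff_eda)) < 1e-6
    assert np.max(np.abs(d.d1_eda)) < 1e-5
    assert np.max(np.abs(d.d2_det)) < 1e-5
    n = len(d.eda)
    for name in ("det_eda", "sg_eda", "dwt_eda", "diff_eda"):
        assert len(getattr(d, name)) == n
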