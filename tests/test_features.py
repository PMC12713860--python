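"""Feature definitions: frozen schema, hand-computable values, and
complexity statistics against known-signal oracles."""

import numpy as np
import pytest

from edasleep.events import detect_events, detect_storms, event_storm_features
from edasleep.features import (
    FEATURE_COLUMNS,
    FeatureNormalizer,
    derivative_features,
    diff_features,
    epoch_slices,
    extract_all,
    freq_features,
    lyapunov_exponent,
    nonlinear_features,
    normalize_features,
    time_features,
    wavelet_features,
)
from edasleep.preprocess import derive_signals

from conftest import make_feature_matrix


class TestSchema:
    def test_column_manifest_is_frozen(self):
        assert len(FEATURE_COLUMNS) == 77
        assert FEATURE_COLUMNS[0] == "eda_mode"
        assert FEATURE_COLUMNS[9] == "deteda_mode"
        assert FEATURE_COLUMNS[18] == "d1eda_mean"
        assert FEATURE_COLUMNS[34] == "eda_psd_max"
        assert FEATURE_COLUMNS[40] == "dl1_max"
        assert FEATURE_COLUMNS[64] == "eda_lyapunov"
        assert FEATURE_COLUMNS[70] == "diffeda_xcorr_sum"
        assert FEATURE_COLUMNS[72:76] == (
            "event_frac",
            "event_norm",
            "storm_frac",
            "storm_norm",
        )
        assert FEATURE_COLUMNS[76] == "sex"
        assert len(set(FEATURE_COLUMNS)) == 77

    def test_epoch_slicing_truncates_partial_epochs(self, night):
        rec, _ = night
        slices = epoch_slices(rec)
        assert len(slices) == 60
        assert slices[3] == (90.0, 120.0)


class TestTimeFeatures:
    def test_constant_epoch_conventions(self):
        vals = time_features(np.full(1050, 3.0))
        mode, median, max_abs, ll, q10, q75, svd_h, nle, sh_h = vals
        assert median == 3.0 and max_abs == 3.0
        assert ll == 0.0 and q10 == 3.0 and q75 == 3.0
        assert svd_h == 0.0 and sh_h == 0.0
        assert mode == pytest.approx(3.0, abs=1e-9)

    def test_line_length_hand_sum(self):
        assert time_features(np.array([0.0, 1.0, 0.0, 1.0, 0.0]))[3] == 4.0

    def test_svd_entropy_orders_sine_below_noise(self):
        t = np.arange(1050) / 35.0
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sine = np.sin(2 * np.pi * 1.0 * t + rng.uniform(0, 2 * np.pi))
            noise = rng.normal(0, sine.std(), t.size)
            wins += time_features(sine)[6] < time_features(noise)[6]
        assert wins == 20


class TestDerivativeFeatures:
    def test_hand_values(self):
        mean, var, median, above = derivative_features(np.array([-1.0, 1.0]))
        assert mean == 0.0
        assert var == 1.0  # population variance (ddof=0), documented convention
        assert median == 0.0
        assert above == 1

    def test_all_negative_has_no_positive_count(self):
        assert derivative_features(-np.ones(50))[3] == 0

    def test_variance_is_sign_invariant(self):
        x = np.random.default_rng(3).normal(size=200)
        assert derivative_features(x)[1] == pytest.approx(derivative_features(-x)[1])


class TestFreqFeatures:
    def test_pure_sine_peak_location_and_concentration(self):
        t = np.arange(1050) / 35.0
        pmax, fmax, g = freq_features(np.sin(2 * np.pi * 1.0 * t))
        assert abs(fmax - 1.0) <= 35.0 / 1050  # within one bin
        assert g > 0.9 and pmax > 0

    def test_white_noise_is_spectrally_flat(self):
        wins = 0
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=1050)
            wins += freq_features(x)[2] < 0.2
        assert wins == 20

    def test_zero_epoch_convention(self):
        assert freq_features(np.zeros(1050)) == (0.0, 0.0, 0.0)


class TestWaveletFeatures:
    def test_zero_coefficients_give_zero_features(self):
        assert wavelet_features(np.zeros(100)) == (0.0,) * 6

    def test_norm_hand_value(self):
        assert wavelet_features(np.array([3.0, 4.0]))[4] == 5.0

    def test_positive_fraction_bounded(self):
        x = np.random.default_rng(0).normal(size=257)
        frac = wavelet_features(x)[5]
        assert 0.0 <= frac <= 1.0


class TestNonlinearFeatures:
    def test_sine_envelope_recovers_amplitude(self):
        t = np.arange(1050) / 35.0
        a = 2.3
        lyap, upper, lower = nonlinear_features(a * np.sin(2 * np.pi * 1.0 * t))
        assert abs(upper - a) / a < 0.02
        assert abs(lower + a) / a < 0.02

    def test_regular_orbit_has_nonpositive_exponent(self):
        t = np.arange(1050) / 35.0
        assert lyapunov_exponent(np.sin(2 * np.pi * 0.7 * t)) <= 0.01

    def test_chaotic_map_has_positive_exponent(self):
        z = np.empty(1050)
        z[0] = 0.3
        for i in range(1049):
            z[i + 1] = 4.0 * z[i] * (1.0 - z[i])
        assert lyapunov_exponent(z, delay=1, theiler=10) > 0

    def test_constant_trace_convention(self):
        assert lyapunov_exponent(np.full(1050, 2.0)) == 0.0


class TestDiffFeatures:
    def test_zero_trace(self):
        assert diff_features(np.zeros(64)) == (0.0, 0.0)

    def test_xcorr_sum_equals_squared_sum(self):
        d = np.random.default_rng(7).normal(size=301)
        assert diff_features(d)[0] == pytest.approx(d.sum() ** 2, rel=1e-9)

    def test_hand_convolution(self):
        assert diff_features(np.array([1.0, 1.0]))[1] == 2.0


class TestExtractAll:
    def test_column_count_and_determinism(self, night, night_features):
        from edasleep.pipeline import extract_night

        rec, _ = night
        assert night_features.features.shape == (60, 77)
        again = extract_night(rec)
        assert again.data.equals(night_features.data)

    def test_event_storm_columns_match_events_module(self, night, night_features):
        rec, _ = night
        derived = derive_signals(rec.signal)
        events = detect_events(derived.eda, amp_threshold=0.5)
        storms = detect_storms(events, duration_s=rec.duration_s)
        k = 7
        expected = event_storm_features(
            events, storms, (30.0 * k, 30.0 * (k + 1)), derived.eda[k * 1050 : (k + 1) * 1050]
        )
        row = night_features.data.iloc[k]
        got = tuple(row[c] for c in ("event_frac", "event_norm", "storm_frac", "storm_norm"))
        assert got == pytest.approx(expected)

    def test_constant_recording_yields_finite_features(self, night):
        rec, _ = night
        flat = type(rec)(
            subject_id="F0",
            signal=np.full_like(rec.signal, 4.0),
            fs=rec.fs,
            hypnogram=rec.hypnogram,
            sex="F",
            ahi=0.0,
            odi=0.0,
        )
        fm = extract_all(flat, derive_signals(flat.signal), [], [])
        assert np.isfinite(fm.features.to_numpy(dtype=float)).all()


class TestNormalization:
    def test_training_columns_standardised_but_test_not(self):
        train = make_feature_matrix(n_subjects=3, seed=1)
        test = make_feature_matrix(n_subjects=2, seed=2)
        train_n, test_n, _ = normalize_features(train, test)
        mu = train_n.data[train_n.numeric_columns].mean()
        sd = train_n.data[train_n.numeric_columns].std(ddof=0)
        assert np.allclose(mu, 0.0, atol=1e-9)
        assert np.allclose(sd, 1.0, atol=1e-9)
        test_mu = test_n.data[test_n.numeric_columns].mean().abs()
        assert (test_mu > 1e-6).any()  # leakage guard: test set not re-centred

    def test_constant_column_left_unscaled_with_warning(self):
        fm = make_feature_matrix(n_subjects=2, seed=3)
        fm.data["eda_mode"] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            norm = FeatureNormalizer().fit(fm)
        out = norm.transform(fm)
        assert (out.data["eda_mode"] == 5.0).all()
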