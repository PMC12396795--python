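"""Tests of the 211-feature representation, against brute-force DFT oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pushglide as pg
from pushglide import features as feat
from pushglide.types import IMU_RATE_HZ

from conftest import make_window


def brute_force_band_powers(x, n_bands, rate=IMU_RATE_HZ):
    """Independent oracle: explicit DFT sums, power per 1-Hz bin, DC excluded."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    n = x.size
    out = np.zeros(n_bands)
    for j in range(n // 2 + 1):
        f = j * rate / n
        re = np.sum(xc * np.cos(-2 * np.pi * j * np.arange(n) / n))
        im = np.sum(xc * np.sin(-2 * np.pi * j * np.arange(n) / n))
        p = re**2 + im**2
        k = int(np.floor(f))
        if 0 < f and k < n_bands:
            out[k] += p
    return out


class TestSchema:
    def test_group_sizes(self):
        sizes = {}
        for e in feat.FEATURE_SCHEMA:
            sizes[e.group] = sizes.get(e.group, 0) + 1
        assert sizes == {
            "accel_time": 29, "accel_rpy": 12, "accel_fft": 71,
            "gyro_time": 30, "gyro_fft": 60, "combined": 8, "baro": 1,
        }
        assert len(feat.FEATURE_SCHEMA) == 211
        assert len(feat.feature_names(("accel",))) == 112

    def test_names_unique_and_order_stable(self):
        names = [e.name for e in feat.FEATURE_SCHEMA]
        assert len(set(names)) == len(names)
        assert names == [e.name for e in feat._build_schema()]

    def test_schema_table_dump(self):
        tbl = feat.schema_table()
        assert list(tbl.columns) == ["name", "group", "definition"]
        assert len(tbl) == 211


class TestAccelTime:
    def test_stationary_gravity_window(self):
        w = make_window()
        out = feat.accel_time_features(w)
        assert len(out) == 29
        assert out["accel_norm_mean"] == pytest.approx(1.0)
        assert out["accel_norm_sd"] == pytest.approx(0.0)
        assert out["accel_norm_skewness"] == 0.0
        assert out["accel_corr_xy"] == 0.0  # constant axes -> 0 by convention

    def test_pure_sine_axis(self, time_grid):
        t = time_grid(20)
        accel = np.zeros((t.size, 3))
        accel[:, 0] = np.sin(2 * np.pi * 2.0 * t)
        out = feat.accel_time_features(make_window(accel=accel))
        assert abs(out["accel_x_mean"]) < 1e-3
        assert out["accel_corr_xy"] == 0.0
        assert out["accel_corr_yz"] == 0.0

    def test_all_finite_on_synthetic_window(self, profile):
        rec = pg.synthesize_activity(profile, "skateboard", "hip", 60, 1)
        w = pg.prepare_windows(rec, 20)[0]
        out = feat.accel_time_features(w)
        assert len(out) == 29
        assert all(np.isfinite(v) for v in out.values())


class TestAccelRPY:
    def test_gravity_aligned(self):
        out = feat.accel_rpy_features(make_window())
        assert len(out) == 12
        assert out["accel_roll_mean"] == pytest.approx(0.0)
        assert out["accel_pitch_mean"] == pytest.approx(0.0)
        assert out["accel_roll_sd"] == pytest.approx(0.0)

    def test_y_axis_gravity_gives_roll_pi_over_2(self, time_grid):
        n = time_grid(20).size
        accel = np.tile([0.0, 1.0, 0.0], (n, 1))
        out = feat.accel_rpy_features(make_window(accel=accel))
        assert out["accel_roll_mean"] == pytest.approx(np.pi / 2)

    def test_zero_sample_convention(self, time_grid):
        n = time_grid(20).size
        accel = np.zeros((n, 3))
        out = feat.accel_rpy_features(make_window(accel=accel))
        assert all(v == 0.0 for v in out.values())


class TestSpectral:
    def test_band_powers_match_brute_force(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)  # 2-s toy window
        freqs, power = feat.power_spectrum(x)
        ours = feat.band_powers(freqs, power, 15)
        oracle = brute_force_band_powers(x, 15)
        np.testing.assert_allclose(ours, oracle, rtol=1e-9, atol=1e-9)

    def test_pure_tone_dominant_frequency(self, time_grid):
        t = time_grid(20)
        accel = np.zeros((t.size, 3))
        accel[:, 0] = np.sin(2 * np.pi * 2.0 * t)
        out = feat.accel_fft_features(make_window(accel=accel))
        assert len(out) == 71
        assert out["accel_fft_x_domfreq"] == pytest.approx(2.0)
        total = sum(out[f"accel_fft_x_band_{k:02d}"] for k in range(15))
        assert out["accel_fft_x_band_02"] >= 0.99 * total

    def test_noise_entropy_exceeds_tone_entropy(self, time_grid):
        t = time_grid(20)
        rng = np.random.default_rng(3)
        tone = np.zeros((t.size, 3))
        tone[:, 2] = 1 + 0.5 * np.sin(2 * np.pi * 2.0 * t)
        noise = np.zeros((t.size, 3))
        noise[:, 2] = 1 + 0.1 * rng.standard_normal(t.size)
        e_tone = feat.accel_fft_features(make_window(accel=tone))["accel_fft_norm_entropy"]
        e_noise = feat.accel_fft_features(make_window(accel=noise))["accel_fft_norm_entropy"]
        assert e_noise > e_tone

    def test_spectral_conservation(self, profile):
        rec = pg.synthesize_activity(profile, "running", "wrist", 60, 2)
        w = pg.prepare_windows(rec, 20)[0]
        norm = np.linalg.norm(w.accel, axis=1)
        freqs, power = feat.power_spectrum(norm)
        bands = feat.band_powers(freqs, power, 15)
        total = power[freqs > 0].sum()
        assert bands.sum() <= total * (1 + 1e-9)

    def test_zero_signal_conventions(self):
        w = make_window(accel=np.zeros((2000, 3)))
        out = feat.accel_fft_features(w)
        assert out["accel_fft_norm_domfreq"] == 0.0
        assert out["accel_fft_norm_maxratio"] == 0.0
        assert all(out[f"accel_fft_norm_band_{k:02d}"] == 0.0 for k in range(15))


class TestGyro:
    def test_zero_angular_velocity(self):
        out = feat.gyro_time_features(make_window())
        assert len(out) == 30
        assert all(v == 0.0 for v in out.values())

    def test_pure_rotation_about_z(self, time_grid):
        """1 Hz rotation about z: the z-axis spectrum peaks at 1 Hz while the
        norm is a rectified wave peaking at the 2 Hz harmonic (verified with
        the brute-force spectrum of |sin|)."""
        t = time_grid(20)
        gyro = np.zeros((t.size, 3))
        gyro[:, 2] = 50 * np.sin(2 * np.pi * 1.0 * t)
        out = feat.gyro_fft_features(make_window(gyro=gyro))
        assert len(out) == 60
        assert out["gyro_fft_z_domfreq"] == pytest.approx(1.0)
        # oracle: argmax of brute-force band powers of the norm
        oracle = brute_force_band_powers(np.abs(gyro[:200, 2]), 12)
        assert np.argmax(oracle) == 2
        assert out["gyro_fft_norm_domfreq"] == pytest.approx(2.0)


class TestCombined:
    def test_self_synchrony(self, time_grid):
        t = time_grid(20)
        sig = np.sin(2 * np.pi * 1.3 * t) + 0.3 * np.sin(2 * np.pi * 2.9 * t)
        accel = np.zeros((t.size, 3))
        accel[:, 0] = sig
        # gyro norm stream exactly equal to the accel norm stream
        gyro = np.zeros((t.size, 3))
        gyro[:, 0] = np.linalg.norm(accel, axis=1)
        w = make_window(accel=accel, gyro=gyro)
        out = feat.combined_features(w)
        assert len(out) == 8
        for k in ("combined_corr", "combined_xcorr_max",
                  "combined_envelope_corr", "combined_rms_corr"):
            assert out[k] == pytest.approx(1.0)
        assert out["combined_xcorr_lag_s"] == 0.0

    def test_shifted_stream_recovers_lag(self, time_grid):
        t = time_grid(20)
        rng = np.random.default_rng(5)
        base = rng.standard_normal(t.size + 100)
        from scipy.ndimage import uniform_filter1d
        base = uniform_filter1d(base, 10)
        accel = np.zeros((t.size, 3))
        accel[:, 0] = base[100:]
        gyro = np.zeros((t.size, 3))
        gyro[:, 0] = np.abs(base[75:-25]) + 1  # gyro = accel delayed 0.25 s
        out = feat.combined_features(make_window(accel=accel, gyro=gyro))
        assert out["combined_xcorr_lag_s"] == pytest.approx(0.25, abs=0.011)

    def test_independent_noise_decorrelated(self, time_grid):
        t = time_grid(20)
        rng = np.random.default_rng(11)
        accel = np.zeros((t.size, 3))
        accel[:, 0] = rng.standard_normal(t.size)
        gyro = np.zeros((t.size, 3))
        gyro[:, 0] = 1 + 0.1 * rng.standard_normal(t.size)
        out = feat.combined_features(make_window(accel=accel, gyro=gyro))
        assert abs(out["combined_corr"]) < 0.1

    def test_zero_variance_convention(self):
        out = feat.combined_features(make_window())
        assert out["combined_corr"] == 0.0
        assert out["combined_xcorr_max"] == 0.0

    def test_lag_matches_brute_force(self, time_grid):
        """The FFT-based lagged correlation equals the per-lag brute force."""
        rng = np.random.default_rng(9)
        a = rng.standard_normal(400)
        g = rng.standard_normal(400)
        best_r, best_lag = feat._xcorr_best(a, g, 100)
        rs = []
        for lag in range(-100, 101):
            if lag >= 0:
                x, y = a[: 400 - lag], g[lag:]
            else:
                x, y = a[-lag:], g[: 400 + lag]
            rs.append(np.corrcoef(x, y)[0, 1])
        rs = np.asarray(rs)
        assert best_r == pytest.approx(rs.max(), abs=1e-10)
        assert best_lag == int(np.arange(-100, 101)[np.argmax(rs)])


class TestBaro:
    def test_exact_linear_slope(self):
        t = np.arange(20.0)
        w = make_window(baro_t=t, baro_p=1000 - 0.035 * t)
        assert feat.baro_slope(w)["baro_slope"] == pytest.approx(-0.035)

    def test_constant_pressure(self):
        t = np.arange(20.0)
        w = make_window(baro_t=t, baro_p=np.full(20, 1000.0))
        assert feat.baro_slope(w)["baro_slope"] == pytest.approx(0.0)

    def test_single_sample_is_missing(self):
        w = make_window(baro_t=[1.0], baro_p=[1000.0])
        assert np.isnan(feat.baro_slope(w)["baro_slope"])


class TestExtract:
    def test_feature_counts(self, profile):
        rec = pg.synthesize_activity(profile, "kickboard", "pocket", 60, 1)
        w = pg.prepare_windows(rec, 20)[0]
        assert len(feat.extract_features(w, ("accel",))) == 112
        assert len(feat.extract_features(w)) == 211

    def test_empty_baro_gives_single_missing(self, profile):
        rec = pg.synthesize_activity(profile, "walking", "hip", 60, 1)
        w = pg.prepare_windows(rec, 20)[0]
        w.baro_t = np.empty(0)
        w.baro_p = np.empty(0)
        out = feat.extract_features(w)
        vals = np.array(list(out.values()))
        assert len(out) == 211
        assert np.isnan(vals).sum() == 1
        assert np.isnan(out["baro_slope"])

    def test_invalid_sensor_sets_rejected(self, profile):
        rec = pg.synthesize_activity(profile, "walking", "hip", 60, 1)
        w = pg.prepare_windows(rec, 20)[0]
        with pytest.raises(ValueError, match="accelerometer"):
            feat.extract_features(w, ("gyro",))
        with pytest.raises(ValueError, match="unknown"):
            feat.extract_features(w, ("accel", "magnetometer"))

    def test_table_layout(self, profile):
        rec = pg.synthesize_activity(profile, "walking", "hip", 60, 1)
        ws = pg.prepare_windows(rec, 20)
        tbl = feat.extract_table(ws)
        assert list(tbl.columns[:5]) == feat.METADATA_COLUMNS
        assert tbl.shape == (len(ws), 5 + 211)


class TestInvariances:
    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(scale=st.floats(min_value=0.1, max_value=10.0),
           shift=st.floats(min_value=-5.0, max_value=5.0))
    def test_scale_equivariance_and_shift_invariance(self, scale, shift, profile):
        rec = pg.synthesize_activity(profile, "walking", "wrist", 60, 4)
        w = pg.prepare_windows(rec, 20)[0]
        base = feat.extract_features(w, ("accel",))

        w2 = make_window(accel=w.accel * scale, gyro=w.gyro,
                         activity=w.activity, placement=w.placement)
        scaled = feat.extract_features(w2, ("accel",))
        for name in ("accel_norm_mean", "accel_norm_sd", "accel_norm_min",
                     "accel_norm_max"):
            assert scaled[name] == pytest.approx(scale * base[name], rel=1e-9)
        for name in ("accel_corr_xy", "accel_corr_xz", "accel_corr_yz",
                     "accel_norm_cv", "accel_fft_norm_maxratio"):
            assert scaled[name] == pytest.approx(base[name], rel=1e-6, abs=1e-9)

        accel3 = w.accel.copy()
        accel3[:, 0] += shift
        w3 = make_window(accel=accel3, gyro=w.gyro,
                         activity=w.activity, placement=w.placement)
        shifted = feat.extract_features(w3, ("accel",))
        for k in range(15):
            assert shifted[f"accel_fft_x_band_{k:02d}"] == pytest.approx(
                base[f"accel_fft_x_band_{k:02d}"], rel=1e-6, abs=1e-9
            )

    def test_baro_shift_invariance(self):
        t = np.arange(20.0)
        p = 1000 + 0.02 * t + 0.001 * np.sin(t)
        s1 = feat.baro_slope(make_window(baro_t=t, baro_p=p))["baro_slope"]
        s2 = feat.baro_slope(make_window(baro_t=t, baro_p=p + 50))["baro_slope"]
        assert s1 == pytest.approx(s2, rel=1e-9)
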