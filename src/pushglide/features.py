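"""The fixed 211-feature representation of one analytic window.

Feature groups and sizes:

* ``accel_time`` (29): general time-domain statistics of the acceleration
  norm and axes;
* ``accel_rpy`` (12): roll/pitch/yaw of the acceleration vector relative
  to gravity, summarized over the window;
* ``accel_fft`` (71): 1-Hz band powers up to 15 Hz, dominant frequency,
  max-to-total power ratio and spectral entropy of the norm and axes;
* ``gyro_time`` (30) and ``gyro_fft`` (60): the gyroscope counterparts
  (bands up to 12 Hz);
* ``combined`` (8): accelerometer/gyroscope synchrony measures aimed at
  the push-to-glide transitions of board riding;
* ``baro`` (1): least-squares pressure slope, a vertical-motion proxy.

Totals: 112 accelerometer-only features, 211 with all sensors.  The
schema (names, groups, order) is fixed and validated at import time.

Spectra use the squared magnitude of the DFT of the mean-removed,
rectangular-windowed signal; band ``[k, k+1)`` sums the power of the
frequency-grid points it covers (DC excluded).  Dominant frequency is the
argmax over ``(0, f_max]`` with ties broken toward the lowest frequency.
Correlations of constant streams are 0 by convention, so downstream
forests never see NaN from IMU features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .types import IMU_RATE_HZ, AnalyticWindow

EPS = 1e-12
ACCEL_FMAX_HZ = 15.0
GYRO_FMAX_HZ = 12.0

_AXES = ("x", "y", "z")
_TIME_STAT_NAMES = (
    "mean", "sd", "cv", "median", "min", "max", "p25", "p75", "iqr",
    "skewness", "kurtosis",
)


# ---------------------------------------------------------------- schema

@dataclass(frozen=True)
class SchemaEntry:
    name: str
    group: str
    definition: str


def _time_names(sensor: str) -> list[str]:
    names = [f"{sensor}_norm_{s}" for s in _TIME_STAT_NAMES]
    for ax in _AXES:
        names += [f"{sensor}_{ax}_{s}" for s in ("mean", "sd", "min", "max")]
    names += [f"{sensor}_corr_{a}{b}" for a, b in (("x", "y"), ("x", "z"), ("y", "z"))]
    names += [f"{sensor}_norm_mad", f"{sensor}_norm_autocorr_1s", f"{sensor}_sma"]
    return names


def _fft_names(sensor: str, n_bands: int, norm_extra: bool) -> list[str]:
    names = [f"{sensor}_fft_norm_band_{k:02d}" for k in range(n_bands)]
    names += [f"{sensor}_fft_norm_domfreq"]
    if norm_extra:
        names += [f"{sensor}_fft_norm_dompow", f"{sensor}_fft_norm_totpow"]
    names += [f"{sensor}_fft_norm_maxratio", f"{sensor}_fft_norm_entropy"]
    for ax in _AXES:
        names += [f"{sensor}_fft_{ax}_band_{k:02d}" for k in range(n_bands)]
        names += [f"{sensor}_fft_{ax}_domfreq", f"{sensor}_fft_{ax}_maxratio"]
        if not norm_extra:
            names += [f"{sensor}_fft_{ax}_entropy"]
    return names


def _build_schema() -> list[SchemaEntry]:
    entries: list[SchemaEntry] = []
    for n in _time_names("accel"):
        entries.append(SchemaEntry(n, "accel_time", "time-domain statistic of acceleration"))
    for ang in ("roll", "pitch", "yaw"):
        for s in ("mean", "sd", "min", "max"):
            entries.append(
                SchemaEntry(f"accel_{ang}_{s}", "accel_rpy",
                            f"{s} of per-sample {ang} of the acceleration vector")
            )
    for n in _fft_names("accel", 15, norm_extra=True):
        entries.append(SchemaEntry(n, "accel_fft", "spectral feature of acceleration"))
    for n in _time_names("gyro"):
        entries.append(SchemaEntry(n, "gyro_time", "time-domain statistic of angular velocity"))
    entries.append(SchemaEntry("gyro_norm_rms", "gyro_time", "RMS of angular-velocity norm"))
    for n in _fft_names("gyro", 12, norm_extra=False):
        entries.append(SchemaEntry(n, "gyro_fft", "spectral feature of angular velocity"))
    combined = [
        ("combined_corr", "Pearson correlation of accel and gyro norms"),
        ("combined_xcorr_max", "max normalized cross-correlation over lags in [-1, 1] s"),
        ("combined_xcorr_lag_s", "lag (s) at the cross-correlation maximum"),
        ("combined_envelope_corr", "correlation of 1-s moving-average envelopes"),
        ("combined_mean_ratio", "mean(accel norm) / mean(gyro norm)"),
        ("combined_sd_ratio", "SD(accel norm) / SD(gyro norm)"),
        ("combined_domfreq_ratio", "dominant-frequency ratio accel/gyro"),
        ("combined_rms_corr", "correlation of per-second RMS series"),
    ]
    for n, d in combined:
        entries.append(SchemaEntry(n, "combined", d))
    entries.append(SchemaEntry("baro_slope", "baro", "OLS pressure slope, hPa/s"))
    return entries


FEATURE_SCHEMA: list[SchemaEntry] = _build_schema()

GROUP_SIZES = {
    "accel_time": 29, "accel_rpy": 12, "accel_fft": 71,
    "gyro_time": 30, "gyro_fft": 60, "combined": 8, "baro": 1,
}

ACCEL_GROUPS = ("accel_time", "accel_rpy", "accel_fft")
GYRO_GROUPS = ("gyro_time", "gyro_fft")


def _validate_schema() -> None:
    counts: dict[str, int] = {}
    names = set()
    for e in FEATURE_SCHEMA:
        counts[e.group] = counts.get(e.group, 0) + 1
        if e.name in names:
            raise AssertionError(f"duplicate feature name {e.name}")
        names.add(e.name)
    if counts != GROUP_SIZES:
        raise AssertionError(f"schema group sizes {counts} != {GROUP_SIZES}")
    if len(FEATURE_SCHEMA) != 211:
        raise AssertionError("schema must contain exactly 211 features")


_validate_schema()


def schema_table() -> pd.DataFrame:
    """The feature schema as a DataFrame (name, group, definition)."""
    return pd.DataFrame([(e.name, e.group, e.definition) for e in FEATURE_SCHEMA],
                        columns=["name", "group", "definition"])


def feature_names(sensor_set=("accel", "gyro", "baro")) -> list[str]:
    """Schema-ordered feature names for a sensor subset (accel mandatory)."""
    groups = _groups_for(frozenset(sensor_set))
    return [e.name for e in FEATURE_SCHEMA if e.group in groups]


def _groups_for(sensor_set: frozenset) -> tuple[str, ...]:
    if "accel" not in sensor_set:
        raise ValueError("every sensor set must include the accelerometer")
    unknown = sensor_set - {"accel", "gyro", "baro"}
    if unknown:
        raise ValueError(f"unknown sensors {sorted(unknown)}")
    groups = list(ACCEL_GROUPS)
    if "gyro" in sensor_set:
        groups += list(GYRO_GROUPS) + ["combined"]
    if "baro" in sensor_set:
        groups += ["baro"]
    return tuple(groups)


# ------------------------------------------------------------ primitives

def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; 0 by convention if either stream is constant."""
    sx, sy = x.std(), y.std()
    if sx < EPS or sy < EPS:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _time_stats(mat: np.ndarray, sensor: str) -> dict[str, float]:
    """The 29 shared time-domain statistics for a 3-axis block."""
    norm = np.linalg.norm(mat, axis=1)
    out: dict[str, float] = {}
    mean = float(norm.mean())
    sd = float(norm.std())
    out[f"{sensor}_norm_mean"] = mean
    out[f"{sensor}_norm_sd"] = sd
    out[f"{sensor}_norm_cv"] = sd / (abs(mean) + EPS)
    out[f"{sensor}_norm_median"] = float(np.median(norm))
    out[f"{sensor}_norm_min"] = float(norm.min())
    out[f"{sensor}_norm_max"] = float(norm.max())
    p25, p75 = np.percentile(norm, [25, 75])
    out[f"{sensor}_norm_p25"] = float(p25)
    out[f"{sensor}_norm_p75"] = float(p75)
    out[f"{sensor}_norm_iqr"] = float(p75 - p25)
    if sd < EPS:
        out[f"{sensor}_norm_skewness"] = 0.0
        out[f"{sensor}_norm_kurtosis"] = 0.0
    else:
        out[f"{sensor}_norm_skewness"] = float(sstats.skew(norm))
        out[f"{sensor}_norm_kurtosis"] = float(sstats.kurtosis(norm))
    for j, ax in enumerate(_AXES):
        col = mat[:, j]
        out[f"{sensor}_{ax}_mean"] = float(col.mean())
        out[f"{sensor}_{ax}_sd"] = float(col.std())
        out[f"{sensor}_{ax}_min"] = float(col.min())
        out[f"{sensor}_{ax}_max"] = float(col.max())
    out[f"{sensor}_corr_xy"] = _safe_corr(mat[:, 0], mat[:, 1])
    out[f"{sensor}_corr_xz"] = _safe_corr(mat[:, 0], mat[:, 2])
    out[f"{sensor}_corr_yz"] = _safe_corr(mat[:, 1], mat[:, 2])
    out[f"{sensor}_norm_mad"] = float(np.abs(norm - mean).mean())
    lag = int(IMU_RATE_HZ)  # 1 s
    if norm.size > lag:
        out[f"{sensor}_norm_autocorr_1s"] = _safe_corr(norm[:-lag], norm[lag:])
    else:
        out[f"{sensor}_norm_autocorr_1s"] = 0.0
    out[f"{sensor}_sma"] = float(np.abs(mat).sum(axis=1).mean())
    return out


def power_spectrum(x: np.ndarray, rate_hz: float = IMU_RATE_HZ):
    """One-sided power spectrum |DFT|^2 of the mean-removed signal.

    Returns (frequencies, power).  Rectangular window, no taper; the
    frequency resolution is ``rate / len(x)``.
    """
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    spec = np.fft.rfft(xc)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / rate_hz)
    return freqs, power


def band_powers(freqs: np.ndarray, power: np.ndarray, n_bands: int) -> np.ndarray:
    """Sum spectral power within 1-Hz bands [k, k+1) Hz, k = 0..n_bands-1.

    DC (f = 0) is excluded so that the band sums never exceed the total
    power over (0, n_bands] Hz.
    """
    out = np.zeros(n_bands)
    for k in range(n_bands):
        mask = (freqs >= k) & (freqs < k + 1) & (freqs > 0)
        out[k] = power[mask].sum()
    return out


def _spectral_summary(x: np.ndarray, fmax: float) -> dict[str, float]:
    """domfreq / dompow / totpow / maxratio / entropy over (0, fmax]."""
    freqs, power = power_spectrum(x)
    mask = (freqs > 0) & (freqs <= fmax)
    p = power[mask]
    f = freqs[mask]
    total = float(p.sum())
    if total < EPS:
        return {"domfreq": 0.0, "dompow": 0.0, "totpow": 0.0,
                "maxratio": 0.0, "entropy": 0.0}
    i = int(np.argmax(p))  # argmax returns the first (lowest-f) maximum
    q = p / total
    nz = q[q > 0]
    entropy = float(-(nz * np.log(nz)).sum() / np.log(len(q))) if len(q) > 1 else 0.0
    return {
        "domfreq": float(f[i]),
        "dompow": float(p[i]),
        "totpow": total,
        "maxratio": float(p[i] / total),
        "entropy": entropy,
    }


def _fft_block(mat: np.ndarray, sensor: str, n_bands: int, fmax: float,
               norm_extra: bool) -> dict[str, float]:
    out: dict[str, float] = {}
    norm = np.linalg.norm(mat, axis=1)
    freqs, power = power_spectrum(norm)
    bp = band_powers(freqs, power, n_bands)
    for k in range(n_bands):
        out[f"{sensor}_fft_norm_band_{k:02d}"] = float(bp[k])
    s = _spectral_summary(norm, fmax)
    out[f"{sensor}_fft_norm_domfreq"] = s["domfreq"]
    if norm_extra:
        out[f"{sensor}_fft_norm_dompow"] = s["dompow"]
        out[f"{sensor}_fft_norm_totpow"] = s["totpow"]
    out[f"{sensor}_fft_norm_maxratio"] = s["maxratio"]
    out[f"{sensor}_fft_norm_entropy"] = s["entropy"]
    for j, ax in enumerate(_AXES):
        freqs, power = power_spectrum(mat[:, j])
        bp = band_powers(freqs, power, n_bands)
        for k in range(n_bands):
            out[f"{sensor}_fft_{ax}_band_{k:02d}"] = float(bp[k])
        s = _spectral_summary(mat[:, j], fmax)
        out[f"{sensor}_fft_{ax}_domfreq"] = s["domfreq"]
        out[f"{sensor}_fft_{ax}_maxratio"] = s["maxratio"]
        if not norm_extra:
            out[f"{sensor}_fft_{ax}_entropy"] = s["entropy"]
    return out


# ------------------------------------------------------- group operations

def accel_time_features(window: AnalyticWindow) -> dict[str, float]:
    """29 general time-domain statistics of the acceleration block."""
    return _time_stats(window.accel, "accel")


def accel_rpy_features(window: AnalyticWindow) -> dict[str, float]:
    """Roll/pitch/yaw of the acceleration vector, 4 stats each (12 values).

    Per-sample convention: roll = atan2(ay, az), pitch = atan2(-ax,
    sqrt(ay^2 + az^2)), yaw = atan2(ay, ax), in radians; an all-zero
    acceleration sample maps to angle 0.
    """
    a = window.accel
    ax, ay, az = a[:, 0], a[:, 1], a[:, 2]
    zero = (np.abs(ax) < EPS) & (np.abs(ay) < EPS) & (np.abs(az) < EPS)
    roll = np.arctan2(ay, az)
    pitch = np.arctan2(-ax, np.hypot(ay, az))
    yaw = np.arctan2(ay, ax)
    out: dict[str, float] = {}
    for name, ang in (("roll", roll), ("pitch", pitch), ("yaw", yaw)):
        ang = np.where(zero, 0.0, ang)
        out[f"accel_{name}_mean"] = float(ang.mean())
        out[f"accel_{name}_sd"] = float(ang.std())
        out[f"accel_{name}_min"] = float(ang.min())
        out[f"accel_{name}_max"] = float(ang.max())
    return out


def accel_fft_features(window: AnalyticWindow) -> dict[str, float]:
    """71 spectral features of the acceleration norm and axes (bands to 15 Hz)."""
    return _fft_block(window.accel, "accel", 15, ACCEL_FMAX_HZ, norm_extra=True)


def gyro_time_features(window: AnalyticWindow) -> dict[str, float]:
    """The 29 shared time-domain statistics on angular velocity, plus norm RMS."""
    out = _time_stats(window.gyro, "gyro")
    norm = np.linalg.norm(window.gyro, axis=1)
    out["gyro_norm_rms"] = float(np.sqrt((norm**2).mean()))
    return out


def gyro_fft_features(window: AnalyticWindow) -> dict[str, float]:
    """60 spectral features of the angular-velocity norm and axes (bands to 12 Hz)."""
    return _fft_block(window.gyro, "gyro", 12, GYRO_FMAX_HZ, norm_extra=False)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def _xcorr_best(a: np.ndarray, g: np.ndarray, max_lag: int) -> tuple[float, int]:
    """(max Pearson correlation, lag) of a[i] vs g[i+lag] over |lag| <= max_lag.

    Each lag's correlation is the exact Pearson correlation over the
    overlapping segments (FFT cross-products + cumulative sums, identical
    to the per-lag brute force).  Ties go to the smallest |lag|, then to
    the negative lag.  Returns (0.0, 0) if either stream is constant.
    """
    from scipy.signal import correlate

    n = a.size
    if a.std() < EPS or g.std() < EPS:
        return 0.0, 0
    lags = np.arange(-max_lag, max_lag + 1)
    m = n - np.abs(lags)  # overlap length per lag
    c = correlate(a, g, mode="full", method="fft")
    dots = c[(n - 1) - lags]
    ca, ca2 = np.cumsum(a), np.cumsum(a * a)
    cg, cg2 = np.cumsum(g), np.cumsum(g * g)

    def head(cs, k):  # sum of first k
        return cs[k - 1]

    def tail(cs, k):  # sum of last (n - k)
        return cs[-1] - (cs[k - 1] if k > 0 else 0.0)

    sx = np.empty_like(dots)
    sxx = np.empty_like(dots)
    sy = np.empty_like(dots)
    syy = np.empty_like(dots)
    for i, L in enumerate(lags):
        if L >= 0:  # a[:n-L] vs g[L:]
            sx[i], sxx[i] = head(ca, n - L), head(ca2, n - L)
            sy[i], syy[i] = tail(cg, L), tail(cg2, L)
        else:  # a[-L:] vs g[:n+L]
            sx[i], sxx[i] = tail(ca, -L), tail(ca2, -L)
            sy[i], syy[i] = head(cg, n + L), head(cg2, n + L)
    vx = sxx - sx * sx / m
    vy = syy - sy * sy / m
    denom = np.sqrt(np.clip(vx, 0, None) * np.clip(vy, 0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > EPS, (dots - sx * sy / m) / denom, 0.0)
    rmax = r.max()
    cand = lags[r >= rmax - 1e-12]
    best = min(cand, key=lambda L: (abs(L), L))
    return float(rmax), int(best)


def combined_features(window: AnalyticWindow) -> dict[str, float]:
    """8 accelerometer/gyroscope synchrony features.

    Built on the two norm streams; aimed at the coupling between push
    acceleration and angular velocity across push-to-glide transitions.
    """
    a_raw = np.linalg.norm(window.accel, axis=1)
    g_raw = np.linalg.norm(window.gyro, axis=1)
    a = a_raw - a_raw.mean()
    g = g_raw - g_raw.mean()
    n = a.size
    max_lag = int(IMU_RATE_HZ)  # 1 s

    out: dict[str, float] = {"combined_corr": _safe_corr(a, g)}

    best_r, best_lag = _xcorr_best(a, g, max_lag)
    out["combined_xcorr_max"] = float(best_r)
    out["combined_xcorr_lag_s"] = float(best_lag) / IMU_RATE_HZ

    w = int(IMU_RATE_HZ)
    out["combined_envelope_corr"] = _safe_corr(
        _moving_average(np.abs(a), w), _moving_average(np.abs(g), w)
    )
    out["combined_mean_ratio"] = float(a_raw.mean() / (g_raw.mean() + EPS))
    out["combined_sd_ratio"] = float(a.std() / (g.std() + EPS))
    fa = _spectral_summary(a_raw, ACCEL_FMAX_HZ)["domfreq"]
    fg = _spectral_summary(g_raw, GYRO_FMAX_HZ)["domfreq"]
    resolution = IMU_RATE_HZ / n
    out["combined_domfreq_ratio"] = float(fa / max(fg, resolution))

    n_sec = n // w
    if n_sec >= 2:
        a_rms = np.sqrt((a[: n_sec * w].reshape(n_sec, w) ** 2).mean(axis=1))
        g_rms = np.sqrt((g[: n_sec * w].reshape(n_sec, w) ** 2).mean(axis=1))
        out["combined_rms_corr"] = _safe_corr(a_rms, g_rms)
    else:
        out["combined_rms_corr"] = 0.0
    return out


def baro_slope(window: AnalyticWindow) -> dict[str, float]:
    """OLS slope of pressure vs time (hPa/s); NaN if fewer than 2 samples."""
    if window.baro_t.size < 2:
        return {"baro_slope": float("nan")}
    slope = np.polyfit(window.baro_t, window.baro_p, 1)[0]
    return {"baro_slope": float(slope)}


_GROUP_FUNCS = {
    "accel_time": accel_time_features,
    "accel_rpy": accel_rpy_features,
    "accel_fft": accel_fft_features,
    "gyro_time": gyro_time_features,
    "gyro_fft": gyro_fft_features,
    "combined": combined_features,
    "baro": baro_slope,
}


def extract_features(window: AnalyticWindow, sensor_set=("accel", "gyro", "baro")) -> dict[str, float]:
    """One window's feature vector, schema-ordered, for a sensor subset.

    ``{accel}`` yields 112 values; the full set yields 211.  A window with
    no barometer samples gets an explicit NaN for the barometer slope
    (imputed only at model-fit time).
    """
    groups = _groups_for(frozenset(sensor_set))
    values: dict[str, float] = {}
    for g in groups:
        values.update(_GROUP_FUNCS[g](window))
    ordered = {e.name: values[e.name] for e in FEATURE_SCHEMA if e.group in groups}
    return ordered


METADATA_COLUMNS = ["subject_id", "activity", "placement", "start_s", "length_s"]


def extract_table(windows, sensor_set=("accel", "gyro", "baro")) -> pd.DataFrame:
    """Feature table: one row per window, metadata then schema-ordered features."""
    rows = []
    for w in windows:
        row = {
            "subject_id": w.subject_id,
            "activity": w.activity.value,
            "placement": w.placement.value,
            "start_s": w.start_s,
            "length_s": w.length_s,
        }
        row.update(extract_features(w, sensor_set))
        rows.append(row)
    cols = METADATA_COLUMNS + feature_names(sensor_set)
    return pd.DataFrame(rows, columns=cols)
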