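"""Reading, writing, trimming, resampling and windowing of recordings.

Each recording is stored as two CSV tables sharing a stem: ``<stem>_imu.csv``
with header ``t,ax,ay,az,gx,gy,gz`` and ``<stem>_baro.csv`` with header
``t,p`` — together the seven independent time series of one bout.  Values
are written with 6-decimal fixed precision, comma-separated, UTF-8.

Windows are half-open ``[start, start + length)`` slices on a uniform
100 Hz grid; the default stride equals the window length, i.e. windows are
non-overlapping, which matches the roughly 30 windows of 20 s obtained
from a 10-minute bout.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import IMU_RATE_HZ, AnalyticWindow, SensorRecording

logger = logging.getLogger(__name__)

IMU_HEADER = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
BARO_HEADER = ["t", "p"]
_FLOAT_FMT = "%.6f"

#: Window lengths supported by the analysis, in seconds.
WINDOW_LENGTHS_S = (10, 20)


def _stem_to_paths(path_stem) -> tuple[Path, Path]:
    stem = Path(path_stem)
    return stem.parent / f"{stem.name}_imu.csv", stem.parent / f"{stem.name}_baro.csv"


def write_recording(recording: SensorRecording, path_stem) -> tuple[Path, Path]:
    """Write one recording as ``<stem>_imu.csv`` and ``<stem>_baro.csv``.

    Lossless to the stated 6-decimal precision; byte-identical on repeated
    calls with identical input.
    """
    imu_path, baro_path = _stem_to_paths(path_stem)
    imu_path.parent.mkdir(parents=True, exist_ok=True)
    imu = pd.DataFrame(
        np.column_stack([recording.imu_t, recording.imu]), columns=IMU_HEADER
    )
    imu.to_csv(imu_path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    baro = pd.DataFrame(
        {"t": recording.baro_t, "p": recording.baro_p}, columns=BARO_HEADER
    )
    baro.to_csv(baro_path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    return imu_path, baro_path


def _validate_time_column(t: np.ndarray, name: str) -> None:
    if np.isnan(t).any():
        row = int(np.flatnonzero(np.isnan(t))[0])
        raise ValueError(f"{name}: NaN timestamp at data row {row}")
    if t.size >= 2:
        d = np.diff(t)
        if (d == 0).any():
            row = int(np.flatnonzero(d == 0)[0]) + 1
            raise ValueError(f"{name}: duplicated timestamp at data row {row}")
        if (d < 0).any():
            row = int(np.flatnonzero(d < 0)[0]) + 1
            raise ValueError(f"{name}: non-monotone timestamp at data row {row}")


def read_recording(
    path_stem, subject_id: str = "", activity=None, placement=None
) -> SensorRecording:
    """Read a recording written by :func:`write_recording`.

    Timestamps are validated (no NaN, strictly increasing, error messages
    name the offending data row).  A missing barometer file is tolerated:
    the recording gets an empty barometer stream and a warning is logged.
    Labels default to values parsed from the stem ``<subject>_<activity>_<placement>``
    unless given explicitly.
    """
    imu_path, baro_path = _stem_to_paths(path_stem)
    imu = pd.read_csv(imu_path)
    if list(imu.columns) != IMU_HEADER:
        raise ValueError(
            f"{imu_path}: malformed header {list(imu.columns)}; expected {IMU_HEADER}"
        )
    t = imu["t"].to_numpy(dtype=float)
    if t.size == 0:
        raise ValueError(f"{imu_path}: empty IMU stream")
    _validate_time_column(t, str(imu_path))
    values = imu[IMU_HEADER[1:]].to_numpy(dtype=float)
    if np.isnan(values).any():
        row = int(np.flatnonzero(np.isnan(values).any(axis=1))[0])
        raise ValueError(f"{imu_path}: NaN sample value at data row {row}")

    if baro_path.exists():
        baro = pd.read_csv(baro_path)
        if list(baro.columns) != BARO_HEADER:
            raise ValueError(
                f"{baro_path}: malformed header {list(baro.columns)}; expected {BARO_HEADER}"
            )
        bt = baro["t"].to_numpy(dtype=float)
        bp = baro["p"].to_numpy(dtype=float)
        _validate_time_column(bt, str(baro_path))
    else:
        logger.warning("%s missing; continuing with empty barometer stream", baro_path)
        bt = np.empty(0)
        bp = np.empty(0)

    if activity is None or placement is None:
        parts = Path(path_stem).name.split("_")
        if len(parts) >= 3:
            subject_id = subject_id or parts[0]
            activity = activity or parts[1]
            placement = placement or parts[2]
        else:
            raise ValueError(
                f"cannot infer labels from stem {path_stem!r}; pass activity/placement"
            )
    duration = float(t[-1]) + 1.0 / IMU_RATE_HZ
    return SensorRecording(
        subject_id=subject_id,
        activity=activity,
        placement=placement,
        imu_t=t,
        imu=values,
        baro_t=bt,
        baro_p=bp,
        duration_s=duration,
    )


def trim_boundaries(recording: SensorRecording, trim_s: float = 5.0) -> SensorRecording:
    """Drop the first and last ``trim_s`` seconds of a bout (boundary effects).

    Samples with ``t < trim_s`` or ``t > duration - trim_s`` are removed and
    timestamps re-zeroed to the new start.
    """
    if trim_s < 0:
        raise ValueError("trim_s must be nonnegative")
    if trim_s == 0:
        return recording
    if recording.duration_s <= 2 * trim_s:
        raise ValueError(
            f"recording of {recording.duration_s:g} s too short to trim {trim_s:g} s "
            "from each end"
        )
    hi = recording.duration_s - trim_s
    keep = (recording.imu_t >= trim_s) & (recording.imu_t <= hi)
    bkeep = (recording.baro_t >= trim_s) & (recording.baro_t <= hi)
    return SensorRecording(
        subject_id=recording.subject_id,
        activity=recording.activity,
        placement=recording.placement,
        imu_t=recording.imu_t[keep] - trim_s,
        imu=recording.imu[keep],
        baro_t=recording.baro_t[bkeep] - trim_s,
        baro_p=recording.baro_p[bkeep],
        duration_s=recording.duration_s - 2 * trim_s,
    )


def resample_uniform(recording: SensorRecording, rate_hz: float = IMU_RATE_HZ) -> SensorRecording:
    """Linearly interpolate the IMU stream onto the exact grid t = k/rate.

    The barometer stream is left untouched (it is summarized by a slope, so
    uniformity is irrelevant there).
    """
    if recording.n_imu < 2:
        raise ValueError("resampling needs at least 2 IMU samples")
    t = recording.imu_t
    grid = np.arange(0.0, t[-1] + 0.5 / rate_hz, 1.0 / rate_hz)
    grid = grid[grid <= t[-1] + 1e-12]
    out = np.column_stack(
        [np.interp(grid, t, recording.imu[:, j]) for j in range(6)]
    )
    return SensorRecording(
        subject_id=recording.subject_id,
        activity=recording.activity,
        placement=recording.placement,
        imu_t=grid,
        imu=out,
        baro_t=recording.baro_t,
        baro_p=recording.baro_p,
        duration_s=recording.duration_s,
    )


def segment(
    recording: SensorRecording,
    length_s: int = 20,
    stride_s: float | None = None,
) -> list[AnalyticWindow]:
    """Cut a uniformly-sampled recording into analytic windows.

    Windows start at 0, stride, 2*stride, ...; only complete windows are
    returned; each carries the barometer samples with t in
    ``[start, start + length)``.  The count obeys
    ``floor((duration - length) / stride) + 1``.
    """
    if length_s not in WINDOW_LENGTHS_S:
        raise ValueError(f"length_s must be one of {WINDOW_LENGTHS_S}; got {length_s}")
    if stride_s is None:
        stride_s = float(length_s)
    if stride_s <= 0:
        raise ValueError("stride_s must be positive")
    t = recording.imu_t
    if t.size < 2:
        return []
    dt = np.diff(t)
    if not np.allclose(dt, 1.0 / IMU_RATE_HZ, atol=1e-6):
        raise ValueError("recording must be resampled to a uniform 100 Hz grid first")

    win_rows = int(round(IMU_RATE_HZ * length_s))
    n = recording.n_imu
    windows: list[AnalyticWindow] = []
    k = 0
    while True:
        start = k * stride_s
        start_row = int(round(start * IMU_RATE_HZ))
        if start_row + win_rows > n:
            break
        bmask = (recording.baro_t >= start) & (recording.baro_t < start + length_s)
        windows.append(
            AnalyticWindow(
                subject_id=recording.subject_id,
                activity=recording.activity,
                placement=recording.placement,
                start_s=float(start),
                length_s=float(length_s),
                imu=recording.imu[start_row : start_row + win_rows],
                baro_t=recording.baro_t[bmask],
                baro_p=recording.baro_p[bmask],
            )
        )
        k += 1
    return windows


def prepare_windows(
    recording: SensorRecording,
    length_s: int = 20,
    stride_s: float | None = None,
    trim_s: float = 5.0,
) -> list[AnalyticWindow]:
    """Standard preprocessing chain: trim -> resample -> segment."""
    rec = trim_boundaries(recording, trim_s)
    rec = resample_uniform(rec)
    return segment(rec, length_s=length_s, stride_s=stride_s)
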