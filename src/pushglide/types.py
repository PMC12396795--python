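"""Core domain types shared across the pipeline.

The pipeline operates on one-bout, one-placement sensor recordings: a
tri-axial accelerometer + tri-axial gyroscope stream at a nominal 100 Hz
and a barometer stream at a nominal 1 Hz.  Units follow consumer-IMU
conventions: acceleration in g, angular velocity in deg/s, pressure in hPa.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

IMU_RATE_HZ = 100.0
IMU_COLUMNS = ("ax", "ay", "az", "gx", "gy", "gz")


class Activity(str, enum.Enum):
    """The nine commuting/sedentary activities under study."""

    SITTING = "sitting"
    STANDING = "standing"
    BICYCLING = "bicycling"
    WALKING = "walking"
    RUNNING = "running"
    KICKBOARD = "kickboard"
    SKATEBOARD = "skateboard"
    UPSTAIRS = "upstairs"
    DOWNSTAIRS = "downstairs"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Activities with the asymmetric push-push-glide motion pattern.
PUSH_PUSH_GLIDE = (Activity.KICKBOARD, Activity.SKATEBOARD)


class Placement(str, enum.Enum):
    """Sensor placement mimicking a commercial device position."""

    WRIST = "wrist"
    HIP = "hip"
    POCKET = "pocket"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Stance(str, enum.Enum):
    """Board stance: regular riders lead with the left foot, goofy with the right.

    A goofy stance mirrors the mediolateral motion of push-push-glide
    activities relative to a regular rider.
    """

    REGULAR = "regular"
    GOOFY = "goofy"


def as_activity(value) -> Activity:
    if isinstance(value, Activity):
        return value
    try:
        return Activity(str(value))
    except ValueError:
        raise ValueError(
            f"unknown activity {value!r}; expected one of "
            f"{[a.value for a in Activity]}"
        ) from None


def as_placement(value) -> Placement:
    if isinstance(value, Placement):
        return value
    try:
        return Placement(str(value))
    except ValueError:
        raise ValueError(
            f"unknown placement {value!r}; expected one of "
            f"{[p.value for p in Placement]}"
        ) from None


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject gait/riding parameters used by the simulator.

    ``step_freq_hz`` is the walking cadence (steps/s); ``push_freq_hz`` the
    push-stroke rate on a board; ``amplitude_scale`` a whole-body motion
    gain and ``noise_scale`` a sensor/placement noise gain, both relative
    to 1.  ``rng_seed`` makes every recording of the subject reproducible.
    """

    subject_id: str
    stance: Stance
    step_freq_hz: float
    push_freq_hz: float
    amplitude_scale: float
    noise_scale: float
    rng_seed: int

    def __post_init__(self) -> None:
        if not (1.2 <= self.step_freq_hz <= 2.6):
            raise ValueError("step_freq_hz must lie in [1.2, 2.6]")
        if not (0.6 <= self.push_freq_hz <= 1.8):
            raise ValueError("push_freq_hz must lie in [0.6, 1.8]")
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")


@dataclass
class SensorRecording:
    """One activity bout for one subject and one placement.

    ``imu_t`` (seconds) and ``imu`` (N x 6: ax, ay, az in g; gx, gy, gz in
    deg/s) hold the 100 Hz inertial stream; ``baro_t`` / ``baro_p`` the
    ~1 Hz pressure stream in hPa.  Timestamps are seconds from bout start.
    """

    subject_id: str
    activity: Activity
    placement: Placement
    imu_t: np.ndarray
    imu: np.ndarray
    baro_t: np.ndarray
    baro_p: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        self.activity = as_activity(self.activity)
        self.placement = as_placement(self.placement)
        self.imu_t = np.asarray(self.imu_t, dtype=float)
        self.imu = np.asarray(self.imu, dtype=float)
        self.baro_t = np.asarray(self.baro_t, dtype=float)
        self.baro_p = np.asarray(self.baro_p, dtype=float)
        if self.imu.ndim != 2 or self.imu.shape[1] != 6:
            raise ValueError("imu must be an (N, 6) array")
        if self.imu_t.shape[0] != self.imu.shape[0]:
            raise ValueError("imu_t and imu must have matching length")
        if self.imu_t.size >= 2 and not np.all(np.diff(self.imu_t) > 0):
            raise ValueError("IMU timestamps must be strictly increasing")
        if self.baro_t.size >= 2 and not np.all(np.diff(self.baro_t) > 0):
            raise ValueError("barometer timestamps must be strictly increasing")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")

    @property
    def n_imu(self) -> int:
        return int(self.imu.shape[0])


@dataclass
class AnalyticWindow:
    """A fixed-duration slice of a recording, aligned across sensors.

    ``imu`` is a uniform 100 Hz block of exactly ``100 * length_s`` rows
    (ax, ay, az, gx, gy, gz); the barometer block carries the samples whose
    timestamp falls in ``[start_s, start_s + length_s)`` and may be empty.
    """

    subject_id: str
    activity: Activity
    placement: Placement
    start_s: float
    length_s: float
    imu: np.ndarray
    baro_t: np.ndarray = field(default_factory=lambda: np.empty(0))
    baro_p: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.activity = as_activity(self.activity)
        self.placement = as_placement(self.placement)
        self.imu = np.asarray(self.imu, dtype=float)
        expected = int(round(IMU_RATE_HZ * self.length_s))
        if self.imu.shape != (expected, 6):
            raise ValueError(
                f"window IMU block must be ({expected}, 6); got {self.imu.shape}"
            )

    @property
    def accel(self) -> np.ndarray:
        return self.imu[:, :3]

    @property
    def gyro(self) -> np.ndarray:
        return self.imu[:, 3:]
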