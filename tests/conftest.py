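import numpy as np
import pytest

import pushglide as pg
from pushglide.types import IMU_RATE_HZ, AnalyticWindow


@pytest.fixture(scope="session")
def cohort():
    return pg.make_cohort(10, 0.3, seed=42)


@pytest.fixture(scope="session")
def profile(cohort):
    return cohort[0]


def make_window(
    accel=None,
    gyro=None,
    length_s=20,
    baro_t=None,
    baro_p=None,
    activity="walking",
    placement="hip",
):
    """Hand-built analytic window for feature unit tests."""
    n = int(IMU_RATE_HZ * length_s)
    if accel is None:
        accel = np.tile([0.0, 0.0, 1.0], (n, 1))
    if gyro is None:
        gyro = np.zeros((n, 3))
    return AnalyticWindow(
        subject_id="T001",
        activity=activity,
        placement=placement,
        start_s=0.0,
        length_s=length_s,
        imu=np.column_stack([accel, gyro]),
        baro_t=np.asarray(baro_t if baro_t is not None else []),
        baro_p=np.asarray(baro_p if baro_p is not None else []),
    )


@pytest.fixture
def time_grid():
    def _grid(length_s=20):
        return np.arange(int(IMU_RATE_HZ * length_s)) / IMU_RATE_HZ

    return _grid
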