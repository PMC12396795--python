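"""Synthetic multi-sensor recordings for the nine study activities.

The generator produces labeled tri-axial accelerometer + gyroscope streams
(100 Hz) and a barometer stream (1 Hz) whose statistical structure carries
the signatures the classifiers exploit:

* sedentary activities: a quasi-static gravity projection plus low noise;
* symmetric gait (walking, running, stairs): a cadence fundamental with up
  to two harmonics, with subject-specific cadence and amplitude; stairs add
  a monotone barometric pressure trend (ascending -> pressure falls);
* bicycling: pedaling periodicity at the hip and pocket, a near-static
  handlebar-constrained wrist;
* kickboard and skateboard: the asymmetric push-push-glide pattern —
  bursts of 2-3 push strokes at the subject's push rate alternating with
  2-5 s glides carrying band-limited 10-15 Hz surface vibration.  At the
  hip and pocket the two activities share the *same* push/glide envelope
  family and differ only in glide vibration amplitude, so they are
  confusable by construction there; at the wrist the kickboard hand is
  handlebar-constrained (stable orientation, little swing) while the
  skateboard arm swings and carves, so the two separate cleanly.

Goofy-stance riders have the mediolateral axis mirrored in the
push-push-glide models only.  Every draw is deterministic given the
subject profile and the call seed.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .types import (
    IMU_RATE_HZ,
    Activity,
    Placement,
    SensorRecording,
    Stance,
    SubjectProfile,
    as_activity,
    as_placement,
)

logger = logging.getLogger(__name__)

BARO_RATE_HZ = 1.0
BARO_BASE_HPA = 1005.0
#: Pressure trend on stairs, hPa/s (~0.3 m/s vertical at ~8.3 m/hPa).
STAIRS_BARO_SLOPE_HPA_S = 0.035

# Cohort parameter distributions (mean, sd) and clip bounds.
STEP_FREQ_DIST = (1.9, 0.15, 1.2, 2.6)
PUSH_FREQ_DIST = (1.2, 0.2, 0.6, 1.8)
RUN_FREQ_DIST = (2.8, 0.2)
STAIR_FREQ_DIST = (1.6, 0.15)
PEDAL_FREQ_DIST = (1.3, 0.15)
GLIDE_DURATION_RANGE_S = (2.0, 5.0)

_ACTIVITY_INDEX = {a: i for i, a in enumerate(Activity)}
_PLACEMENT_INDEX = {p: i for i, p in enumerate(Placement)}


def make_cohort(
    n_subjects: int, goofy_fraction: float = 0.3, seed: int = 0
) -> list[SubjectProfile]:
    """Draw a heterogeneous cohort of subject profiles.

    ``round(goofy_fraction * n_subjects)`` subjects get a goofy stance; all
    parameter draws are independent across subjects and deterministic given
    ``seed``.  At least two subjects are required so that subject-wise
    train/test splitting is possible downstream.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 (subject-wise splits need 2+)")
    if not (0.0 <= goofy_fraction <= 1.0):
        raise ValueError("goofy_fraction must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC040]))
    n_goofy = int(round(goofy_fraction * n_subjects))
    goofy_idx = set(rng.permutation(n_subjects)[:n_goofy].tolist())
    profiles = []
    for i in range(n_subjects):
        m, s, lo, hi = STEP_FREQ_DIST
        step = float(np.clip(rng.normal(m, s), lo, hi))
        m, s, lo, hi = PUSH_FREQ_DIST
        push = float(np.clip(rng.normal(m, s), lo, hi))
        amp = float(np.clip(rng.normal(1.0, 0.15), 0.5, 1.6))
        noise = float(np.clip(rng.normal(1.0, 0.2), 0.5, 1.8))
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i + 1:03d}",
                stance=Stance.GOOFY if i in goofy_idx else Stance.REGULAR,
                step_freq_hz=step,
                push_freq_hz=push,
                amplitude_scale=amp,
                noise_scale=noise,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return profiles


def _subject_latents(profile: SubjectProfile) -> dict:
    """Subject-level latent parameters shared by all of a subject's bouts.

    These random effects (cadences for non-walking gaits, per-placement
    orientation jitter, glide-vibration gain) are what make subject-wise
    generalization non-trivial: train and test subjects differ in them.
    """
    rng = np.random.default_rng(np.random.SeedSequence([profile.rng_seed, 7]))
    lat = {
        "run_freq": float(np.clip(rng.normal(*RUN_FREQ_DIST), 2.2, 3.4)),
        "stair_freq": float(np.clip(rng.normal(*STAIR_FREQ_DIST), 1.2, 2.0)),
        "pedal_freq": float(np.clip(rng.normal(*PEDAL_FREQ_DIST), 0.9, 1.7)),
        # glide vibration gain: the subject-level spread deliberately exceeds
        # the kickboard/skateboard amplitude difference, so hip/pocket models
        # are confusable under subject-wise splits (by construction)
        "vib_gain": float(np.clip(rng.normal(1.0, 0.4), 0.3, 2.2)),
        "orient_jitter": rng.normal(0.0, 0.03, size=(3, 3)),  # placement x axis
        "harmonic2": float(rng.uniform(0.25, 0.5)),
        "phase_bank": rng.uniform(0.0, 2 * np.pi, size=8),
    }
    return lat


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


# Static gravity direction in the sensor frame per (placement, posture).
_GRAVITY = {
    (Placement.HIP, "default"): (0.05, 0.10, 0.99),
    (Placement.HIP, "sitting"): (0.45, 0.15, 0.88),
    (Placement.POCKET, "default"): (0.20, 0.30, 0.93),
    (Placement.POCKET, "sitting"): (0.80, 0.25, 0.50),
    (Placement.WRIST, "default"): (0.10, 0.30, 0.94),
    (Placement.WRIST, "sitting"): (0.60, 0.20, 0.77),
    (Placement.WRIST, "cycling"): (0.85, 0.25, 0.45),
    (Placement.WRIST, "kickboard"): (0.20, 0.25, 0.94),
    (Placement.WRIST, "skateboard"): (0.65, 0.60, 0.30),
}


def _gravity(placement: Placement, posture: str, jitter: np.ndarray) -> np.ndarray:
    base = _GRAVITY.get((placement, posture), _GRAVITY[(placement, "default")])
    return _unit(np.asarray(base) + jitter[_PLACEMENT_INDEX[placement]])


def _bandlimited_vibration(
    n: int, rng: np.random.Generator, lo_hz: float = 10.0, hi_hz: float = 15.0
) -> np.ndarray:
    """Unit-variance band-limited noise emulating surface-roughness vibration."""
    x = rng.standard_normal(n)
    sos = sps.butter(4, [lo_hz, hi_hz], btype="bandpass", fs=IMU_RATE_HZ, output="sos")
    y = sps.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def _push_glide_envelope(
    t: np.ndarray, profile: SubjectProfile, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Push-burst envelope and glide mask for the push-push-glide pattern.

    Cycles of 2-3 push strokes at the subject's push rate, each stroke a
    Gaussian-windowed biphasic pulse, followed by a 2-5 s glide.  Returns
    (push pulse train in [-1, 1]-ish units, glide mask in [0, 1]).
    """
    duration = float(t[-1]) + 1.0 / IMU_RATE_HZ
    stroke_period = 1.0 / profile.push_freq_hz
    centers = []
    cursor = float(rng.uniform(0.3, 1.0))
    while cursor < duration:
        n_push = int(rng.choice([2, 3]))
        for k in range(n_push):
            c = cursor + k * stroke_period
            if c < duration:
                centers.append(c)
        cursor += n_push * stroke_period + float(rng.uniform(*GLIDE_DURATION_RANGE_S))
    pulse = np.zeros_like(t)
    env = np.zeros_like(t)
    sigma = 0.14
    for c in centers:
        w = np.exp(-0.5 * ((t - c) / sigma) ** 2)
        pulse += w * np.sin(2 * np.pi * 2.2 * (t - c))
        env = np.maximum(env, w)
    glide = np.clip(1.0 - env / max(env.max(), 1e-12), 0.0, 1.0) if centers else np.ones_like(t)
    return pulse, glide


def _harmonic(t, freq, amps, phases):
    """Sum of harmonics amps[k] * sin(2*pi*(k+1)*freq*t + phases[k])."""
    out = np.zeros_like(t)
    for k, a in enumerate(amps):
        out += a * np.sin(2 * np.pi * (k + 1) * freq * t + phases[k])
    return out


def synthesize_activity(
    profile: SubjectProfile,
    activity,
    placement,
    duration_s: float,
    seed: int = 0,
) -> SensorRecording:
    """Simulate one activity bout for one subject and placement.

    ``duration_s`` must be at least 40 s so that one 20-s analytic window
    survives the 5-s boundary trims.  Output is deterministic given
    (profile, activity, placement, duration, seed).
    """
    activity = as_activity(activity)
    placement = as_placement(placement)
    if duration_s < 40:
        raise ValueError("duration_s must be >= 40 s (one 20-s window after trims)")

    lat = _subject_latents(profile)
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [profile.rng_seed, int(seed), _ACTIVITY_INDEX[activity],
             _PLACEMENT_INDEX[placement]]
        )
    )
    n = int(round(IMU_RATE_HZ * duration_s))
    t = np.arange(n) / IMU_RATE_HZ
    amp = profile.amplitude_scale
    jit = lat["orient_jitter"]
    ph = rng.uniform(0, 2 * np.pi, size=6)

    accel = np.zeros((n, 3))
    gyro = np.zeros((n, 3))
    baro_slope = 0.0

    def add_gait(freq, a_vert, a_ap, a_ml, g_amp):
        h2 = lat["harmonic2"]
        accel[:, 2] += _harmonic(t, freq, [a_vert, a_vert * h2], ph[:2])
        accel[:, 0] += _harmonic(t, freq, [a_ap, a_ap * h2 * 0.6], ph[2:4])
        accel[:, 1] += a_ml * np.sin(2 * np.pi * freq / 2 * t + ph[4])
        gyro[:, 0] += g_amp * np.sin(2 * np.pi * freq * t + ph[1])
        gyro[:, 1] += 0.6 * g_amp * np.sin(2 * np.pi * freq * t + ph[3])
        gyro[:, 2] += 0.3 * g_amp * np.sin(2 * np.pi * freq / 2 * t + ph[5])

    posture = "default"
    noise_g = 0.010 * profile.noise_scale
    noise_dps = 1.5 * profile.noise_scale

    if activity is Activity.SITTING:
        posture = "sitting"
        noise_g, noise_dps = 0.006 * profile.noise_scale, 0.8 * profile.noise_scale
    elif activity is Activity.STANDING:
        # slow postural sway
        accel[:, 0] += 0.015 * amp * np.sin(2 * np.pi * 0.3 * t + ph[0])
        accel[:, 1] += 0.012 * amp * np.sin(2 * np.pi * 0.25 * t + ph[1])
        gyro[:, 2] += 2.0 * amp * np.sin(2 * np.pi * 0.3 * t + ph[2])
        noise_g, noise_dps = 0.008 * profile.noise_scale, 1.0 * profile.noise_scale
    elif activity is Activity.WALKING:
        if placement is Placement.WRIST:
            # arm swing at stride (half-step) frequency
            add_gait(profile.step_freq_hz, 0.12, 0.22, 0.08, 45.0)
            accel[:, 0] += 0.15 * amp * np.sin(2 * np.pi * profile.step_freq_hz / 2 * t + ph[5])
        else:
            add_gait(profile.step_freq_hz, 0.25 * amp, 0.15 * amp, 0.08 * amp, 30.0 * amp)
    elif activity is Activity.RUNNING:
        f = lat["run_freq"]
        if placement is Placement.WRIST:
            add_gait(f, 0.45 * amp, 0.55 * amp, 0.20 * amp, 110.0 * amp)
        else:
            add_gait(f, 0.80 * amp, 0.45 * amp, 0.20 * amp, 80.0 * amp)
        noise_g *= 2.0
    elif activity in (Activity.UPSTAIRS, Activity.DOWNSTAIRS):
        f = lat["stair_freq"]
        scale = 1.0 if activity is Activity.UPSTAIRS else 0.85
        if placement is Placement.WRIST:
            # hand often on the railing: subdued swing
            add_gait(f, 0.08 * amp * scale, 0.10 * amp * scale, 0.05 * amp, 25.0 * amp)
        else:
            add_gait(f, 0.22 * amp * scale, 0.12 * amp * scale, 0.07 * amp, 28.0 * amp)
        baro_slope = -STAIRS_BARO_SLOPE_HPA_S if activity is Activity.UPSTAIRS else STAIRS_BARO_SLOPE_HPA_S
    elif activity is Activity.BICYCLING:
        f = lat["pedal_freq"]
        if placement is Placement.WRIST:
            posture = "cycling"
            # handlebar: near-static, road buzz at mid frequencies
            buzz = _bandlimited_vibration(n, rng, 5.0, 9.0)
            accel[:, :] += 0.03 * amp * buzz[:, None] * np.array([1.0, 0.7, 0.9])
            gyro[:, :] += 3.0 * buzz[:, None] * np.array([1.0, 0.8, 0.6])
        else:
            a = 0.20 * amp if placement is Placement.POCKET else 0.12 * amp
            accel[:, 2] += a * np.sin(2 * np.pi * f * t + ph[0])
            accel[:, 0] += 0.6 * a * np.sin(2 * np.pi * f * t + ph[1])
            gyro[:, 1] += 35.0 * amp * np.sin(2 * np.pi * f * t + ph[2])
            buzz = _bandlimited_vibration(n, rng, 5.0, 9.0)
            accel[:, :] += 0.02 * amp * buzz[:, None] * np.array([0.8, 0.6, 1.0])
    elif activity in (Activity.KICKBOARD, Activity.SKATEBOARD):
        posture = "kickboard" if activity is Activity.KICKBOARD else "skateboard"
        pulse, glide = _push_glide_envelope(t, profile, rng)
        vib = _bandlimited_vibration(n, rng) * glide * lat["vib_gain"]
        if placement in (Placement.HIP, Placement.POCKET):
            # identical envelope family for both activities; only the glide
            # vibration amplitude differs (board vs kickboard deck/wheels)
            a_vib = 0.050 if activity is Activity.KICKBOARD else 0.070
            accel[:, 0] += 0.40 * amp * pulse
            accel[:, 2] += 0.25 * amp * pulse
            accel[:, 1] += 0.15 * amp * pulse
            accel[:, 1] += 0.04 * amp * glide * np.sin(2 * np.pi * 0.5 * t + ph[0])
            accel[:, :] += a_vib * amp * vib[:, None] * np.array([0.7, 0.6, 1.0])
            gyro[:, 1] += 45.0 * amp * pulse
            gyro[:, 0] += 20.0 * amp * pulse
            gyro[:, :] += 100.0 * a_vib * vib[:, None] * np.array([0.8, 1.0, 0.6])
        elif activity is Activity.KICKBOARD:
            # wrist on handlebar: stable orientation, vibration passes through
            accel[:, 0] += 0.05 * amp * pulse
            accel[:, :] += 0.075 * amp * vib[:, None] * np.array([0.8, 0.7, 1.0])
            gyro[:, :] += 6.0 * vib[:, None] * np.array([1.0, 0.8, 0.7])
            gyro[:, 1] += 8.0 * amp * pulse
        else:
            # skateboard wrist: arm swing plus carving yaw oscillation
            accel[:, 0] += 0.30 * amp * np.sin(2 * np.pi * 0.9 * t + ph[0]) * (0.5 + 0.5 * glide)
            accel[:, 1] += 0.20 * amp * np.sin(2 * np.pi * 0.45 * t + ph[1])
            accel[:, 0] += 0.20 * amp * pulse
            accel[:, :] += 0.045 * amp * vib[:, None] * np.array([0.9, 0.8, 1.0])
            gyro[:, 2] += 45.0 * amp * np.sin(2 * np.pi * 0.45 * t + ph[2])
            gyro[:, 0] += 25.0 * amp * pulse
            gyro[:, :] += 4.0 * vib[:, None] * np.array([0.9, 1.0, 0.8])

    if activity in (Activity.KICKBOARD, Activity.SKATEBOARD) and profile.stance is Stance.GOOFY:
        # mirror the rider: mediolateral acceleration flips; angular velocity
        # is a pseudovector, so the AP and vertical rotation axes flip
        accel[:, 1] *= -1.0
        gyro[:, 0] *= -1.0
        gyro[:, 2] *= -1.0

    g_dir = _gravity(placement, posture, jit)
    accel += g_dir[None, :]
    accel += noise_g * rng.standard_normal((n, 3))
    gyro += noise_dps * rng.standard_normal((n, 3))

    n_baro = int(np.floor(duration_s * BARO_RATE_HZ))
    baro_t = np.arange(n_baro) / BARO_RATE_HZ + 0.5
    baro_t = baro_t[baro_t < duration_s]
    p0 = BARO_BASE_HPA + 5.0 * np.random.default_rng(
        np.random.SeedSequence([profile.rng_seed, 11])
    ).standard_normal()
    baro_p = p0 + baro_slope * baro_t + 0.02 * rng.standard_normal(baro_t.size)

    return SensorRecording(
        subject_id=profile.subject_id,
        activity=activity,
        placement=placement,
        imu_t=t,
        imu=np.column_stack([accel, gyro]),
        baro_t=baro_t,
        baro_p=baro_p,
        duration_s=float(duration_s),
    )


def iter_recordings(
    cohort: Sequence[SubjectProfile],
    duration_s: float,
    seed: int,
    placements: Iterable = tuple(Placement),
    activities: Iterable = tuple(Activity),
):
    """Yield one recording per (subject x activity x placement), deterministically."""
    placements = [as_placement(p) for p in placements]
    activities = [as_activity(a) for a in activities]
    for profile in cohort:
        for activity in activities:
            for placement in placements:
                yield synthesize_activity(profile, activity, placement, duration_s, seed)


def synthesize_dataset(
    cohort: Sequence[SubjectProfile],
    duration_s: float,
    seed: int,
    out_dir,
) -> pd.DataFrame:
    """Write a full cohort dataset as CSV recordings plus a manifest.

    One recording per (subject x 9 activities x 3 placements), in the
    two-file CSV layout of :mod:`pushglide.io_windowing`.  Returns the
    manifest (columns ``file, subject_id, activity, placement``), also
    written to ``out_dir/manifest.csv``.  Byte-identical across calls with
    the same arguments.
    """
    from . import io_windowing  # local import to avoid a cycle

    if not cohort:
        raise ValueError("cohort must be nonempty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in iter_recordings(cohort, duration_s, seed):
        stem = f"{rec.subject_id}_{rec.activity.value}_{rec.placement.value}"
        io_windowing.write_recording(rec, out / stem)
        rows.append(
            {
                "file": stem,
                "subject_id": rec.subject_id,
                "activity": rec.activity.value,
                "placement": rec.placement.value,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    logger.info("wrote %d recordings to %s", len(rows), out)
    return manifest


def dataset_digest(out_dir) -> str:
    """SHA-256 over all CSV bytes in a dataset directory (determinism checks)."""
    h = hashlib.sha256()
    for p in sorted(Path(out_dir).glob("*.csv")):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()
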