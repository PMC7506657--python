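"""Synthetic step-segment generator with controllable class structure.

The generator emulates the data regime of a waist-worn IMU recording five
gait activities at 100 Hz: per-step segments of a few tenths of a second,
accelerometer values within +/-4 g (one axis carrying a ~1 g gravity
offset), gyroscope values within +/-500 deg/s, and class imbalance
defaulting to 13/12/63/6/6 %.

Each axis is a sum of a fundamental sinusoid at the step frequency, one
harmonic, a DC gravity offset on the gravity-aligned accelerometer axis,
a class-signed half-sine pitch pattern on the gyroscope, and white
Gaussian noise.  Class-conditional parameters are expressed as offsets
from the level-walking baseline scaled by a single ``separation`` knob:
at separation 0 all five classes are statistically identical (classifier
accuracy ~ chance), and increasing separation monotonically increases
class discriminability.  Up/down activity pairs differ in the *sign* of
the gyroscope pitch pattern; stairs differ from level mainly in vertical
amplitude and step duration.

The forward (sagittal) axis is randomized per synthetic subject through a
per-subject axis permutation, so forward-direction selection is genuinely
exercised downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from stepgait.signal_model import (
    ACC_RANGE_G,
    GYR_RANGE_DPS,
    GaitActivity,
    StepDataset,
    StepSegment,
)

#: Default class proportions: down incline / up incline / level / down stairs / up stairs.
IMBALANCED_PROPORTIONS = (0.13, 0.12, 0.63, 0.06, 0.06)
UNIFORM_PROPORTIONS = (0.2, 0.2, 0.2, 0.2, 0.2)


@dataclass(frozen=True)
class ClassOffsets:
    """Offsets from the level-walking baseline, applied scaled by separation."""

    vertical_amp: float = 0.0  # [g]
    forward_amp: float = 0.0  # [g]
    step_freq: float = 0.0  # [Hz]
    duration: float = 0.0  # [s]
    pitch_amp: float = 0.0  # [deg/s], signed: + up, - down
    harmonic: float = 0.0  # relative harmonic weight offset


#: Class-conditional offsets at separation 1.  Inclines sit close to level
#: (they are the hard classes); stairs differ strongly in amplitude and
#: duration; up/down variants differ in the sign of the pitch pattern.
CLASS_OFFSETS: dict[GaitActivity, ClassOffsets] = {
    GaitActivity.DOWN_INCLINE: ClassOffsets(
        vertical_amp=0.04, forward_amp=0.03, step_freq=0.08, duration=-0.02, pitch_amp=-35.0
    ),
    GaitActivity.UP_INCLINE: ClassOffsets(
        vertical_amp=0.06, forward_amp=0.02, step_freq=-0.08, duration=0.03, pitch_amp=35.0
    ),
    GaitActivity.LEVEL: ClassOffsets(),
    GaitActivity.DOWN_STAIRS: ClassOffsets(
        vertical_amp=0.28, forward_amp=-0.06, step_freq=0.15, duration=0.08,
        pitch_amp=-110.0, harmonic=0.25,
    ),
    GaitActivity.UP_STAIRS: ClassOffsets(
        vertical_amp=0.34, forward_amp=-0.04, step_freq=-0.15, duration=0.12,
        pitch_amp=100.0, harmonic=0.30,
    ),
}


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable parameters of the synthetic gait generator."""

    sampling_rate: float = 100.0  # [Hz]
    duration_range: tuple[float, float] = (0.4, 0.8)  # [s] per step
    base_vertical_amp: float = 0.35  # [g]
    base_forward_amp: float = 0.45  # [g]
    base_step_freq: float = 1.9  # [Hz]
    base_pitch_amp: float = 60.0  # [deg/s], unsigned common pitch oscillation
    harmonic_weight: float = 0.3  # weight of the first harmonic
    noise_sd_acc: float = 0.05  # [g]
    noise_sd_gyr: float = 8.0  # [deg/s]
    amp_jitter: float = 0.05  # relative step-to-step amplitude variability
    # absolute between-step variability of the class-discriminative
    # parameters (class-independent); comparable to unit-separation offsets
    # so classes genuinely overlap at moderate separation
    vertical_amp_sd: float = 0.08  # [g]
    forward_amp_sd: float = 0.05  # [g]
    step_freq_sd: float = 0.12  # [Hz]
    pitch_sd: float = 45.0  # [deg/s]
    separation: float = 1.0  # scales all class offsets
    class_proportions: tuple[float, ...] = IMBALANCED_PROPORTIONS
    n_subjects: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.duration_range
        if not (0 < lo <= hi <= 2.0):
            raise ValueError("duration_range must lie within (0, 2] s")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if len(self.class_proportions) != len(GaitActivity):
            raise ValueError("need one proportion per activity")
        if any(p < 0 for p in self.class_proportions):
            raise ValueError("proportions must be non-negative")


def _subject_permutations(params: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    """One axis permutation per subject: which physical axis is forward/vertical/lateral."""
    return np.stack([rng.permutation(3) for _ in range(params.n_subjects)])


def generate_step(
    activity: GaitActivity,
    params: GeneratorParams,
    rng: np.random.Generator,
    subject_id: str | None = None,
    axis_permutation: np.ndarray | None = None,
) -> StepSegment:
    """Generate one labeled synthetic step segment.

    ``axis_permutation`` maps the canonical (forward, vertical, lateral)
    channels onto sensor axes (x, y, z); when omitted, a permutation is
    drawn, which models an arbitrary sensor orientation.
    """
    off = CLASS_OFFSETS[activity]
    s = params.separation
    fs = params.sampling_rate

    lo, hi = params.duration_range
    mid = 0.5 * (lo + hi)
    span = 0.5 * (hi - lo)
    # class-shared duration jitter plus a separation-scaled class offset
    duration = float(np.clip(mid + rng.uniform(-0.6, 0.6) * span + s * off.duration, lo, hi))
    n = max(4, int(round(duration * fs)))
    t = np.arange(n) / fs

    jitter = lambda: 1.0 + params.amp_jitter * rng.standard_normal()  # noqa: E731
    freq = max(0.5, params.base_step_freq + s * off.step_freq
               + params.step_freq_sd * rng.standard_normal())
    phase = rng.uniform(-0.3, 0.3)
    harm = params.harmonic_weight + s * off.harmonic

    vert_amp = max(
        0.05,
        (params.base_vertical_amp + s * off.vertical_amp) * jitter()
        + params.vertical_amp_sd * rng.standard_normal(),
    )
    fwd_amp = max(
        0.05,
        (params.base_forward_amp + s * off.forward_amp) * jitter()
        + params.forward_amp_sd * rng.standard_normal(),
    )

    two_pi_ft = 2 * np.pi * freq * t + phase
    half_sine = np.sin(np.pi * t / t[-1]) if n > 1 else np.ones(1)

    acc_forward = fwd_amp * (np.sin(two_pi_ft) + harm * np.sin(2 * two_pi_ft))
    acc_vertical = 1.0 + vert_amp * (np.cos(two_pi_ft) + harm * np.cos(2 * two_pi_ft))
    acc_lateral = 0.1 * jitter() * np.sin(two_pi_ft + 0.5)

    pitch_common = params.base_pitch_amp * jitter() * np.sin(two_pi_ft)
    pitch_class = (
        s * off.pitch_amp * jitter() + params.pitch_sd * rng.standard_normal()
    ) * half_sine
    gyr_pitch = pitch_common + pitch_class
    gyr_roll = 0.3 * params.base_pitch_amp * jitter() * np.sin(two_pi_ft + 1.0)
    gyr_yaw = 0.2 * params.base_pitch_amp * jitter() * np.cos(two_pi_ft)

    if params.noise_sd_acc > 0:
        acc_forward = acc_forward + rng.normal(0, params.noise_sd_acc, n)
        acc_vertical = acc_vertical + rng.normal(0, params.noise_sd_acc, n)
        acc_lateral = acc_lateral + rng.normal(0, params.noise_sd_acc, n)
    if params.noise_sd_gyr > 0:
        gyr_pitch = gyr_pitch + rng.normal(0, params.noise_sd_gyr, n)
        gyr_roll = gyr_roll + rng.normal(0, params.noise_sd_gyr, n)
        gyr_yaw = gyr_yaw + rng.normal(0, params.noise_sd_gyr, n)

    if axis_permutation is None:
        axis_permutation = rng.permutation(3)
    acc_channels = [acc_forward, acc_vertical, acc_lateral]
    gyr_channels = [gyr_pitch, gyr_roll, gyr_yaw]
    acc = [None, None, None]
    gyr = [None, None, None]
    for channel, axis in enumerate(axis_permutation):
        acc[axis] = np.clip(acc_channels[channel], -ACC_RANGE_G, ACC_RANGE_G)
        gyr[axis] = np.clip(gyr_channels[channel], -GYR_RANGE_DPS, GYR_RANGE_DPS)

    return StepSegment(
        acc_x=acc[0], acc_y=acc[1], acc_z=acc[2],
        gyr_x=gyr[0], gyr_y=gyr[1], gyr_z=gyr[2],
        label=activity,
        sampling_rate=fs,
        subject_id=subject_id,
        provenance="synthetic",
    )


def apportion_counts(n_total: int, proportions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n_total over the class proportions."""
    weights = np.asarray(proportions, dtype=float)
    weights = weights / weights.sum()
    quotas = weights * n_total
    counts = np.floor(quotas).astype(int)
    remainder = n_total - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    return counts.tolist()


def generate_dataset(n_total: int, params: GeneratorParams | None = None) -> StepDataset:
    """Generate a labeled dataset with the configured class proportions.

    Deterministic under ``params.seed``; per-class counts follow
    largest-remainder apportionment of the proportions.
    """
    params = params or GeneratorParams()
    if n_total < len(GaitActivity):
        raise ValueError("n_total must be at least the number of classes")
    rng = np.random.default_rng(params.seed)
    perms = _subject_permutations(params, rng)
    counts = apportion_counts(n_total, params.class_proportions)
    segments: list[StepSegment] = []
    step_no = 0
    for activity, count in zip(GaitActivity, counts):
        for _ in range(count):
            subject = int(rng.integers(params.n_subjects))
            seg = generate_step(
                activity, params, rng,
                subject_id=f"S{subject:03d}",
                axis_permutation=perms[subject],
            )
            segments.append(replace(seg, step_id=f"step{step_no:06d}"))
            step_no += 1
    return StepDataset(segments, name="synthetic")


def generate_dataset_with_counts(
    counts: dict[GaitActivity, int], params: GeneratorParams | None = None
) -> StepDataset:
    """Generate a dataset with exact per-class counts (bypassing proportions)."""
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.seed)
    perms = _subject_permutations(params, rng)
    segments: list[StepSegment] = []
    step_no = 0
    for activity in GaitActivity:
        for _ in range(counts.get(activity, 0)):
            subject = int(rng.integers(params.n_subjects))
            seg = generate_step(
                activity, params, rng,
                subject_id=f"S{subject:03d}",
                axis_permutation=perms[subject],
            )
            segments.append(replace(seg, step_id=f"step{step_no:06d}"))
            step_no += 1
    return StepDataset(segments, name="synthetic")
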