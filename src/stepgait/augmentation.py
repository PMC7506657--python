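"""Synthetic-data operators and imbalance treatments for step datasets.

Five augmentation operators act on whole step segments.  Three modify the
magnitude of the signals (DMM) and preserve length:

* **scaling** — one Gaussian factor per signal multiplies every sample;
* **jittering** — an independent Gaussian factor multiplies each sample;
* **smoothing** — moving average with a normalized Hann window whose length
  is (step length / 10) scaled by a Gaussian factor.

Two modify the length/frequency (DMF) and preserve per-sample values:

* **downsampling** — uniform subsampling at one random rate shared by all
  six axes;
* **cutting** — removal of an equal random number of edge frames.

Every Gaussian "variation factor" is drawn from N(mu=1, sigma=0.2) by
default — tight enough that synthetic steps stay within the envelope of
plausible human movement.  Three dataset *treatments* build on these:
leave the data unbalanced, subsample every class to the minority count,
or augment every class up to the majority count.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import hann

from stepgait.signal_model import (
    GaitActivity,
    MIN_SEGMENT_LENGTH,
    SENSOR_COLUMNS,
    StepDataset,
    StepSegment,
    class_histogram,
)

_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class AugmentationConfig:
    """Parameters of the Gaussian variation factor and windowing rule."""

    factor_mean: float = 1.0
    factor_sd: float = 0.2
    window_divisor: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.factor_sd < 0:
            raise ValueError("factor_sd must be >= 0")
        if self.window_divisor < 1:
            raise ValueError("window_divisor must be >= 1")


class Treatment(enum.Enum):
    """The three dataset preparations compared in the study design."""

    UNBALANCED = "unbalanced"
    SAMPLED = "sampled"
    AUGMENTED = "augmented"


class AugmentationTechnique(enum.Enum):
    SCALING = "scaling"
    JITTERING = "jittering"
    SMOOTHING = "smoothing"
    DOWNSAMPLING = "downsampling"
    CUTTING = "cutting"


DMM_TECHNIQUES = (
    AugmentationTechnique.SCALING,
    AugmentationTechnique.JITTERING,
    AugmentationTechnique.SMOOTHING,
)
DMF_TECHNIQUES = (AugmentationTechnique.DOWNSAMPLING, AugmentationTechnique.CUTTING)
ALL_TECHNIQUES = DMM_TECHNIQUES + DMF_TECHNIQUES


def draw_factor(rng: np.random.Generator, config: AugmentationConfig) -> float:
    """One variation factor ~ N(mu, sigma), redrawn if non-positive."""
    for _ in range(_MAX_REDRAWS):
        f = rng.normal(config.factor_mean, config.factor_sd)
        if f > 0:
            return float(f)
    raise RuntimeError("could not draw a positive variation factor")


# ---------------------------------------------------------------------------
# per-signal operators (DMM)
# ---------------------------------------------------------------------------


def scale_signal(series: np.ndarray, factor: float) -> np.ndarray:
    """Multiply every sample by one factor; length unchanged."""
    return np.asarray(series, dtype=float) * float(factor)


def jitter_signal(
    series: np.ndarray, rng: np.random.Generator, config: AugmentationConfig
) -> np.ndarray:
    """Multiply each sample by an independent factor ~ N(mu, sigma)."""
    series = np.asarray(series, dtype=float)
    factors = rng.normal(config.factor_mean, config.factor_sd, size=series.shape)
    return series * factors


def hann_window_length(n: int, config: AugmentationConfig, factor: float) -> int:
    """Window length for smoothing: (n / divisor) * factor, clipped to [1, n]."""
    length = int(round((n / config.window_divisor) * factor))
    return int(np.clip(length, 1, n))


def smooth_signal(
    series: np.ndarray,
    rng: np.random.Generator,
    config: AugmentationConfig,
    factor: float | None = None,
) -> np.ndarray:
    """Moving average with a normalized Hann window of randomized length."""
    series = np.asarray(series, dtype=float)
    if series.size < config.window_divisor:
        raise ValueError(
            f"series length {series.size} shorter than window divisor {config.window_divisor}"
        )
    if factor is None:
        factor = draw_factor(rng, config)
    w = hann_window_length(series.size, config, factor)
    if w < 3:
        return series.copy()  # Hann windows of length 1-2 degenerate to identity
    kernel = hann(w)
    kernel /= kernel.sum()
    half = w // 2
    padded = np.pad(series, (half, w - 1 - half), mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


# ---------------------------------------------------------------------------
# whole-step operators (DMF): the same rate / cut applied to all six axes
# ---------------------------------------------------------------------------


def downsample_signals(
    step_signals: dict[str, np.ndarray],
    rng: np.random.Generator,
    config: AugmentationConfig,
) -> dict[str, np.ndarray]:
    """Uniformly subsample all six axes with one shared retained-index set.

    The reduction rate 1/f (f ~ N(mu, sigma), redrawn until f > 1 so a real
    reduction occurs) fixes the output length L' = round(L / f); retained
    indices are evenly spaced from a random start offset, so every output
    value exists in the corresponding input.
    """
    lengths = {len(v) for v in step_signals.values()}
    if len(lengths) != 1:
        raise ValueError("all six series must have equal length")
    n = lengths.pop()
    if n < 8:
        raise ValueError("downsampling needs segments of at least 8 samples")
    for _ in range(_MAX_REDRAWS):
        f = draw_factor(rng, config)
        if f <= 1.0:
            continue
        n_out = int(round(n / f))
        if MIN_SEGMENT_LENGTH <= n_out < n:
            break
    else:
        raise RuntimeError("could not draw a valid downsampling rate")
    stride = n / n_out
    offset = rng.uniform(0, stride)
    idx = np.floor(offset + np.arange(n_out) * stride).astype(int)
    idx = np.clip(idx, 0, n - 1)
    return {k: np.asarray(v, dtype=float)[idx] for k, v in step_signals.items()}


def cut_signals(
    step_signals: dict[str, np.ndarray],
    rng: np.random.Generator,
    config: AugmentationConfig,
    factor: float | None = None,
) -> dict[str, np.ndarray]:
    """Drop n_remove = round((L / divisor) * factor) frames from the edges.

    Odd removals take the extra frame from the start.  The same contiguous
    block is kept across all six axes.
    """
    lengths = {len(v) for v in step_signals.values()}
    if len(lengths) != 1:
        raise ValueError("all six series must have equal length")
    n = lengths.pop()
    if factor is not None:
        n_remove = int(round((n / config.window_divisor) * factor))
        if n - n_remove < MIN_SEGMENT_LENGTH:
            raise ValueError("cut would leave fewer than 4 samples")
    else:
        for _ in range(_MAX_REDRAWS):
            f = draw_factor(rng, config)
            n_remove = int(round((n / config.window_divisor) * f))
            if n - n_remove >= MIN_SEGMENT_LENGTH:
                break
        else:
            raise RuntimeError("could not draw a valid cut size")
    start = int(np.ceil(n_remove / 2))
    end = n - n_remove // 2
    return {k: np.asarray(v, dtype=float)[start:end] for k, v in step_signals.items()}


# ---------------------------------------------------------------------------
# step-level dispatch and treatments
# ---------------------------------------------------------------------------


def augment_step(
    segment: StepSegment,
    technique: AugmentationTechnique,
    rng: np.random.Generator,
    config: AugmentationConfig | None = None,
) -> StepSegment:
    """Apply one augmentation operator to a step; provenance becomes synthetic.

    DMM operators draw one independent factor per signal; DMF operators
    share a single rate/cut across all six axes.
    """
    config = config or AugmentationConfig()
    signals = {name: getattr(segment, name) for name in SENSOR_COLUMNS}
    if technique is AugmentationTechnique.SCALING:
        out = {k: scale_signal(v, draw_factor(rng, config)) for k, v in signals.items()}
    elif technique is AugmentationTechnique.JITTERING:
        out = {k: jitter_signal(v, rng, config) for k, v in signals.items()}
    elif technique is AugmentationTechnique.SMOOTHING:
        out = {k: smooth_signal(v, rng, config) for k, v in signals.items()}
    elif technique is AugmentationTechnique.DOWNSAMPLING:
        out = downsample_signals(signals, rng, config)
    elif technique is AugmentationTechnique.CUTTING:
        out = cut_signals(signals, rng, config)
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown technique {technique}")
    return segment.with_series(out, provenance="synthetic")


def balance_by_augmentation(
    dataset: StepDataset,
    rng: np.random.Generator,
    config: AugmentationConfig | None = None,
) -> StepDataset:
    """Augment every class up to the majority-class count.

    Synthetic steps are produced by cycling round-robin through the five
    operators, each applied to a source step drawn uniformly (with
    replacement) from the class's *original* instances; synthetic steps
    never seed further synthesis.  Originals are retained unmodified.
    """
    config = config or AugmentationConfig()
    hist = class_histogram(dataset)
    present = {a: c for a, c in hist.items() if c > 0}
    if not present:
        raise ValueError("cannot balance an empty dataset")
    majority = max(present.values())
    by_class: dict[GaitActivity, list[StepSegment]] = {a: [] for a in present}
    for seg in dataset:
        by_class[seg.label].append(seg)

    out = list(dataset.segments)
    for activity in GaitActivity:
        sources = by_class.get(activity)
        if not sources:
            continue  # absent classes cannot be synthesized from nothing
        needed = majority - len(sources)
        for i in range(needed):
            technique = ALL_TECHNIQUES[i % len(ALL_TECHNIQUES)]
            source = sources[rng.integers(len(sources))]
            out.append(augment_step(source, technique, rng, config))
    return StepDataset(out, name=f"{dataset.name}-augmented")


def synthetic_requirements(dataset: StepDataset) -> dict[GaitActivity, int]:
    """Per-class number of synthetic steps balance_by_augmentation will add."""
    hist = class_histogram(dataset)
    present = [c for c in hist.values() if c > 0]
    if not present:
        return {a: 0 for a in GaitActivity}
    majority = max(present)
    return {a: (majority - c if c > 0 else 0) for a, c in hist.items()}


def subsample_to_minority(dataset: StepDataset, rng: np.random.Generator) -> StepDataset:
    """Downsample every class, without replacement, to the minority count."""
    hist = class_histogram(dataset)
    present = {a: c for a, c in hist.items() if c > 0}
    if not present:
        return StepDataset([], name=f"{dataset.name}-sampled")
    minority = min(present.values())
    indices_by_class: dict[GaitActivity, list[int]] = {a: [] for a in present}
    for i, seg in enumerate(dataset):
        indices_by_class[seg.label].append(i)
    keep: list[int] = []
    for activity in GaitActivity:
        idx = indices_by_class.get(activity)
        if not idx:
            continue
        chosen = rng.choice(len(idx), size=minority, replace=False)
        keep.extend(idx[j] for j in sorted(chosen))
    keep.sort()
    return StepDataset([dataset.segments[i] for i in keep], name=f"{dataset.name}-sampled")


def apply_treatment(
    dataset: StepDataset,
    treatment: Treatment,
    rng: np.random.Generator,
    config: AugmentationConfig | None = None,
) -> StepDataset:
    """Dispatch to the identity, minority subsampling, or majority augmentation."""
    if treatment is Treatment.UNBALANCED:
        return dataset
    if treatment is Treatment.SAMPLED:
        return subsample_to_minority(dataset, rng)
    if treatment is Treatment.AUGMENTED:
        return balance_by_augmentation(dataset, rng, config)
    raise ValueError(f"unknown treatment {treatment}")
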