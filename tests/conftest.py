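import numpy as np
import pytest

from stepgait.signal_model import GaitActivity, StepDataset, StepSegment
from stepgait.synthetic_gait import (
    GeneratorParams,
    UNIFORM_PROPORTIONS,
    generate_dataset,
)


def make_segment(
    n: int = 40,
    label: GaitActivity = GaitActivity.LEVEL,
    seed: int = 0,
    provenance: str = "synthetic",
) -> StepSegment:
    """A small deterministic step segment with sinusoid-plus-noise axes."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / 100.0
    series = {}
    for i, name in enumerate(("acc_x", "acc_y", "acc_z")):
        series[name] = 0.3 * np.sin(2 * np.pi * 2 * t + i) + 0.02 * rng.standard_normal(n)
    series["acc_y"] = series["acc_y"] + 1.0  # gravity offset
    for i, name in enumerate(("gyr_x", "gyr_y", "gyr_z")):
        series[name] = 40 * np.sin(2 * np.pi * 2 * t + i) + 2 * rng.standard_normal(n)
    return StepSegment(**series, label=label, provenance=provenance)


@pytest.fixture
def segment() -> StepSegment:
    return make_segment()


@pytest.fixture
def small_dataset() -> StepDataset:
    """Three segments, two classes, deterministic."""
    return StepDataset(
        [
            make_segment(40, GaitActivity.LEVEL, seed=1),
            make_segment(36, GaitActivity.UP_STAIRS, seed=2),
            make_segment(44, GaitActivity.LEVEL, seed=3),
        ],
        name="small",
    )


@pytest.fixture(scope="session")
def balanced_dataset() -> StepDataset:
    """50 steps, 10 per class, default separation."""
    params = GeneratorParams(class_proportions=UNIFORM_PROPORTIONS, seed=42)
    return generate_dataset(50, params)
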