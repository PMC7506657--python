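"""Domain types and delimited-text I/O for step-segmented inertial data.

A *step segment* is one labeled gait step: six synchronized sensor series
(triaxial accelerometer in g, triaxial gyroscope in deg/s) sampled at a
common rate (100 Hz by default).  Datasets are stored as long-format CSV,
one row per sample, grouped into segments by a step id column.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Accelerometer dynamic range of the sensing hardware, in g.
ACC_RANGE_G = 4.0
#: Gyroscope dynamic range of the sensing hardware, in deg/s.
GYR_RANGE_DPS = 500.0

SENSOR_COLUMNS = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")

#: Minimum number of samples for a step segment to be usable downstream.
MIN_SEGMENT_LENGTH = 4


class GaitActivity(enum.IntEnum):
    """The five gait activities, with stable integer codes 0..4."""

    DOWN_INCLINE = 0
    UP_INCLINE = 1
    LEVEL = 2
    DOWN_STAIRS = 3
    UP_STAIRS = 4

    @classmethod
    def from_text(cls, text: str) -> "GaitActivity":
        """Map free label text onto an activity, case-insensitively.

        Accepts the canonical names plus a small alias table so exports from
        third-party tools ("walk", "slope-up", ...) ingest without edits.
        """
        key = str(text).strip().lower().replace("-", "_").replace(" ", "_")
        try:
            return _LABEL_ALIASES[key]
        except KeyError:
            valid = sorted(set(_LABEL_ALIASES))
            raise ValueError(
                f"unknown gait activity label {text!r}; valid labels: {valid}"
            ) from None


_LABEL_ALIASES: dict[str, GaitActivity] = {
    "down_incline": GaitActivity.DOWN_INCLINE,
    "incline_down": GaitActivity.DOWN_INCLINE,
    "down_slope": GaitActivity.DOWN_INCLINE,
    "slope_down": GaitActivity.DOWN_INCLINE,
    "downhill": GaitActivity.DOWN_INCLINE,
    "up_incline": GaitActivity.UP_INCLINE,
    "incline_up": GaitActivity.UP_INCLINE,
    "up_slope": GaitActivity.UP_INCLINE,
    "slope_up": GaitActivity.UP_INCLINE,
    "uphill": GaitActivity.UP_INCLINE,
    "level": GaitActivity.LEVEL,
    "walk": GaitActivity.LEVEL,
    "walking": GaitActivity.LEVEL,
    "level_walking": GaitActivity.LEVEL,
    "flat": GaitActivity.LEVEL,
    "down_stairs": GaitActivity.DOWN_STAIRS,
    "stairs_down": GaitActivity.DOWN_STAIRS,
    "step_down": GaitActivity.DOWN_STAIRS,
    "up_stairs": GaitActivity.UP_STAIRS,
    "stairs_up": GaitActivity.UP_STAIRS,
    "step_up": GaitActivity.UP_STAIRS,
}
# canonical enum names resolve too
for _a in GaitActivity:
    _LABEL_ALIASES[_a.name.lower()] = _a


PROVENANCE_VALUES = ("real", "synthetic", "augmented")


@dataclass(frozen=True)
class StepSegment:
    """One labeled gait step: six equal-length sensor series plus metadata."""

    acc_x: np.ndarray
    acc_y: np.ndarray
    acc_z: np.ndarray
    gyr_x: np.ndarray
    gyr_y: np.ndarray
    gyr_z: np.ndarray
    label: GaitActivity
    sampling_rate: float = 100.0
    subject_id: str | None = None
    provenance: str = "real"
    step_id: str | None = None

    def __post_init__(self) -> None:
        for name in SENSOR_COLUMNS:
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        lengths = {len(getattr(self, name)) for name in SENSOR_COLUMNS}
        if len(lengths) != 1:
            raise ValueError(f"sensor series have unequal lengths: {sorted(lengths)}")
        n = lengths.pop()
        if n < MIN_SEGMENT_LENGTH:
            raise ValueError(f"step segment needs >= {MIN_SEGMENT_LENGTH} samples, got {n}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.provenance not in PROVENANCE_VALUES:
            raise ValueError(f"provenance must be one of {PROVENANCE_VALUES}")
        if self.provenance == "real":
            # soft range check against the hardware's dynamic range
            acc_max = max(np.abs(getattr(self, a)).max() for a in SENSOR_COLUMNS[:3])
            gyr_max = max(np.abs(getattr(self, g)).max() for g in SENSOR_COLUMNS[3:])
            if acc_max > ACC_RANGE_G or gyr_max > GYR_RANGE_DPS:
                warnings.warn(
                    f"step segment exceeds sensor dynamic range "
                    f"(|acc| max {acc_max:.3g} g, |gyr| max {gyr_max:.3g} deg/s)",
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return len(self.acc_x)

    @property
    def acc(self) -> np.ndarray:
        """Accelerometer triad as a (3, n) array."""
        return np.stack([self.acc_x, self.acc_y, self.acc_z])

    @property
    def gyr(self) -> np.ndarray:
        """Gyroscope triad as a (3, n) array."""
        return np.stack([self.gyr_x, self.gyr_y, self.gyr_z])

    def with_series(
        self, series: Mapping[str, np.ndarray], provenance: str | None = None
    ) -> "StepSegment":
        """Copy of this segment with some sensor series (and provenance) replaced."""
        kwargs = dict(series)
        if provenance is not None:
            kwargs["provenance"] = provenance
        return replace(self, **kwargs)


@dataclass
class StepDataset:
    """An ordered collection of step segments."""

    segments: list[StepSegment] = field(default_factory=list)
    name: str = "dataset"

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[StepSegment]:
        return iter(self.segments)

    def __getitem__(self, idx):
        return self.segments[idx]

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.segments], dtype=int)


def class_histogram(dataset: StepDataset) -> dict[GaitActivity, int]:
    """Count segments per activity; absent classes are reported as 0."""
    counts = {a: 0 for a in GaitActivity}
    for seg in dataset:
        counts[seg.label] += 1
    return counts


@dataclass(frozen=True)
class CsvDialect:
    """Column mapping for long-format step CSV files."""

    step_id: str = "step_id"
    label: str = "label"
    sensor_columns: tuple[str, ...] = SENSOR_COLUMNS
    subject_id: str | None = "subject_id"
    provenance: str | None = "provenance"
    time_index: str | None = "t_index"
    sampling_rate: float = 100.0


def read_steps(path: str | Path, dialect: CsvDialect | None = None) -> StepDataset:
    """Read a long-format CSV of step samples into a :class:`StepDataset`.

    One row per sample; rows are grouped into segments by the step-id column
    with row order preserved.  Steps shorter than four samples are dropped
    with a logged warning; unknown label text raises.
    """
    dialect = dialect or CsvDialect()
    path = Path(path)
    df = pd.read_csv(path)

    required = [dialect.step_id, dialect.label, *dialect.sensor_columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"input file {path} is missing required column(s): {missing}")

    segments: list[StepSegment] = []
    if len(df) == 0:
        return StepDataset(segments, name=path.stem)

    for step_id, group in df.groupby(dialect.step_id, sort=False):
        if len(group) < MIN_SEGMENT_LENGTH:
            logger.warning(
                "dropping step %r: only %d rows (< %d)", step_id, len(group), MIN_SEGMENT_LENGTH
            )
            continue
        label = GaitActivity.from_text(group[dialect.label].iloc[0])
        subject = None
        if dialect.subject_id and dialect.subject_id in group.columns:
            value = group[dialect.subject_id].iloc[0]
            subject = None if pd.isna(value) else str(value)
        provenance = "real"
        if dialect.provenance and dialect.provenance in group.columns:
            provenance = str(group[dialect.provenance].iloc[0])
        series = {
            ours: group[theirs].to_numpy(dtype=float)
            for ours, theirs in zip(SENSOR_COLUMNS, dialect.sensor_columns)
        }
        segments.append(
            StepSegment(
                **series,
                label=label,
                sampling_rate=dialect.sampling_rate,
                subject_id=subject,
                provenance=provenance,
                step_id=str(step_id),
            )
        )
    return StepDataset(segments, name=path.stem)


def write_steps(dataset: StepDataset, path: str | Path, dialect: CsvDialect | None = None) -> Path:
    """Write a dataset as long-format CSV; inverse of :func:`read_steps`."""
    dialect = dialect or CsvDialect()
    path = Path(path)
    frames = []
    for i, seg in enumerate(dataset):
        n = len(seg)
        frame = {
            dialect.step_id: [seg.step_id if seg.step_id is not None else f"step{i:06d}"] * n,
        }
        if dialect.time_index:
            frame[dialect.time_index] = np.arange(n)
        for ours, theirs in zip(SENSOR_COLUMNS, dialect.sensor_columns):
            frame[theirs] = getattr(seg, ours)
        frame[dialect.label] = [seg.label.name.lower()] * n
        if dialect.subject_id:
            frame[dialect.subject_id] = [seg.subject_id or ""] * n
        if dialect.provenance:
            frame[dialect.provenance] = [seg.provenance] * n
        frames.append(pd.DataFrame(frame))
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        columns = [dialect.step_id]
        if dialect.time_index:
            columns.append(dialect.time_index)
        columns += list(dialect.sensor_columns) + [dialect.label]
        if dialect.subject_id:
            columns.append(dialect.subject_id)
        if dialect.provenance:
            columns.append(dialect.provenance)
        out = pd.DataFrame(columns=columns)
    out.to_csv(path, index=False, float_format="%.12g")
    return path


def concat_datasets(datasets: Iterable[StepDataset], name: str = "dataset") -> StepDataset:
    segs: list[StepSegment] = []
    for d in datasets:
        segs.extend(d.segments)
    return StepDataset(segs, name=name)
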