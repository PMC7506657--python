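"""Signal conditioning for step segments.

Each raw segment is low-pass filtered and smoothed on all six axes, then
reduced to the four canonical signals used downstream:

* ``acc_fd`` / ``gyr_fd`` — the *forward-direction* axis, i.e. the axis with
  the greatest mean-removed power within the step, taken as aligned with the
  sagittal plane;
* ``acc_xyz`` / ``gyr_xyz`` — the per-sample Euclidean magnitude of the
  triad, invariant to device rotation.

Mean-removed power is used for axis selection because the gravity-aligned
accelerometer axis carries a ~1 g DC offset that would otherwise dominate
regardless of movement content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from stepgait.signal_model import GaitActivity, StepSegment

#: Default low-pass cutoff [Hz]; gait energy is concentrated well below this.
DEFAULT_CUTOFF_HZ = 10.0
#: Default pseudo-Gaussian smoothing width [samples].
DEFAULT_SMOOTH_WIDTH = 5


@dataclass(frozen=True)
class ProcessedStep:
    """The four derived signals of one step, plus which axes were selected."""

    acc_fd: np.ndarray
    acc_xyz: np.ndarray
    gyr_fd: np.ndarray
    gyr_xyz: np.ndarray
    fd_axis_acc: int
    fd_axis_gyr: int
    label: GaitActivity
    source: StepSegment | None = None

    def __len__(self) -> int:
        return len(self.acc_fd)


def lowpass_filter(series: np.ndarray, sampling_rate: float, cutoff: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass filter.

    Applied forward-backward (``filtfilt``) so dominant peaks are not
    time-shifted, which matters for the width/height step descriptors.
    """
    series = np.asarray(series, dtype=float)
    if not 0 < cutoff < sampling_rate / 2:
        raise ValueError(
            f"cutoff must lie in (0, {sampling_rate / 2}) Hz, got {cutoff}"
        )
    if series.size < 4:
        raise ValueError("series too short to filter (need >= 4 samples)")
    b, a = sps.butter(4, cutoff / (sampling_rate / 2), btype="low")
    # Gustafsson's method chooses initial conditions that minimize edge
    # transients, which matters on step segments only a few dozen samples long
    return sps.filtfilt(b, a, series, method="gust")


def pseudo_gaussian_smooth(series: np.ndarray, width: int = DEFAULT_SMOOTH_WIDTH) -> np.ndarray:
    """Smooth with a normalized discrete Gaussian kernel.

    The kernel has sigma = width/4, is truncated at +/- width/2, and sums to
    one; boundaries are handled by reflection so the output length equals the
    input length.  ``width=1`` is the identity.
    """
    series = np.asarray(series, dtype=float)
    if width < 1:
        raise ValueError("width must be >= 1")
    if width > series.size:
        raise ValueError(f"width {width} exceeds series length {series.size}")
    if width == 1:
        return series.copy()
    half = width // 2
    offsets = np.arange(-half, half + 1)
    sigma = width / 4.0
    kernel = np.exp(-0.5 * (offsets / sigma) ** 2)
    kernel /= kernel.sum()
    padded = np.pad(series, half, mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


def _mean_removed_power(series: np.ndarray) -> float:
    series = np.asarray(series, dtype=float)
    return float(np.mean((series - series.mean()) ** 2))


def select_forward_direction(triad: np.ndarray) -> tuple[int, np.ndarray]:
    """Pick the axis with maximal mean-removed power (ties -> lowest index)."""
    triad = np.asarray(triad, dtype=float)
    if triad.ndim != 2 or triad.shape[0] != 3:
        raise ValueError(f"expected a (3, n) triad, got shape {triad.shape}")
    powers = [_mean_removed_power(axis) for axis in triad]
    idx = int(np.argmax(powers))  # argmax takes the first maximum: lowest index on ties
    return idx, triad[idx]


def magnitude_vector(triad: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm sqrt(x^2 + y^2 + z^2) of the triad."""
    triad = np.asarray(triad, dtype=float)
    if triad.ndim != 2 or triad.shape[0] != 3:
        raise ValueError(f"expected a (3, n) triad, got shape {triad.shape}")
    return np.sqrt(np.sum(triad**2, axis=0))


def preprocess_step(
    segment: StepSegment,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    smooth_width: int = DEFAULT_SMOOTH_WIDTH,
) -> ProcessedStep:
    """Filter and smooth all six axes, then derive the four canonical signals.

    The forward-direction axis is selected independently for the
    accelerometer and the gyroscope; magnitudes are computed from the
    filtered-and-smoothed triads.
    """
    width = min(smooth_width, len(segment))

    def condition(triad: np.ndarray) -> np.ndarray:
        return np.stack(
            [
                pseudo_gaussian_smooth(
                    lowpass_filter(axis, segment.sampling_rate, cutoff), width
                )
                for axis in triad
            ]
        )

    acc = condition(segment.acc)
    gyr = condition(segment.gyr)
    fd_axis_acc, acc_fd = select_forward_direction(acc)
    fd_axis_gyr, gyr_fd = select_forward_direction(gyr)
    return ProcessedStep(
        acc_fd=acc_fd,
        acc_xyz=magnitude_vector(acc),
        gyr_fd=gyr_fd,
        gyr_xyz=magnitude_vector(gyr),
        fd_axis_acc=fd_axis_acc,
        fd_axis_gyr=fd_axis_gyr,
        label=segment.label,
        source=segment,
    )
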