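"""Gramian Angular Field (GAF) encoding of step signals as feature images.

A series X = {x_1..x_N} is rescaled into [-1, 1] by

    x~_i = ((x_i - max X) + (x_i - min X)) / (max X - min X),

mapped to polar angles phi_i = arccos(x~_i) (with radii r_i = t_i / N for
the polar plot), and encoded as the summation-form Gramian matrix
G_ij = cos(phi_i + phi_j).  Because the rescaling removes offset and
scale, the encoding is invariant to positive affine transforms of the
input signal.

A step becomes an N x N x 3 8-bit feature image with a fixed channel map:
red = GAF(acc magnitude), green = GAF(gyro magnitude),
blue = GAF(forward-direction acceleration).  Signals are first resampled
to the image side length (piecewise aggregate approximation when
shrinking, linear interpolation when stretching).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from stepgait.preprocessing import ProcessedStep
from stepgait.signal_model import GaitActivity

#: Default image side length; steps at 100 Hz span ~40-120 samples.
DEFAULT_SIDE = 64


@dataclass(frozen=True)
class GAFImage:
    """N x N x 3 8-bit feature image of one step."""

    pixels: np.ndarray  # uint8, (N, N, 3)
    label: GaitActivity
    step_id: str | None = None

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 3 or p.shape[0] != p.shape[1] or p.shape[2] != 3:
            raise ValueError(f"expected a square (N, N, 3) image, got shape {p.shape}")
        if p.dtype != np.uint8:
            raise ValueError("pixel intensities must be 8-bit")

    @property
    def side(self) -> int:
        return self.pixels.shape[0]

    def to_png(self, path: str | Path) -> Path:
        path = Path(path)
        Image.fromarray(self.pixels, mode="RGB").save(path)
        return path


def rescale_unit(series: np.ndarray) -> np.ndarray:
    """Rescale into [-1, 1]; the maximum maps to 1 and the minimum to -1.

    A constant series (max = min) maps to all zeros by convention — the
    neutral angle pi/2.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 1:
        raise ValueError("series must be non-empty")
    hi, lo = series.max(), series.min()
    if hi == lo:
        return np.zeros_like(series)
    scaled = ((series - hi) + (series - lo)) / (hi - lo)
    return np.clip(scaled, -1.0, 1.0)


def to_polar(rescaled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Angles phi = arccos(x~) in [0, pi] and radii r_i = t_i / N, t_i = 1..N.

    The radii are used for polar plots only; the Gramian needs the angles.
    """
    rescaled = np.asarray(rescaled, dtype=float)
    phi = np.arccos(np.clip(rescaled, -1.0, 1.0))
    n = rescaled.size
    r = np.arange(1, n + 1) / n
    return phi, r


def gaf_matrix(rescaled: np.ndarray) -> np.ndarray:
    """Summation-form Gramian G_ij = cos(phi_i + phi_j); symmetric, in [-1, 1]."""
    phi, _ = to_polar(rescaled)
    return np.cos(phi[:, None] + phi[None, :])


def resample_fixed(series: np.ndarray, target_length: int) -> np.ndarray:
    """Resample to a fixed length.

    Shrinking uses piecewise aggregate approximation (mean per bin);
    stretching uses linear interpolation.  Output values stay within the
    input's [min, max].
    """
    series = np.asarray(series, dtype=float)
    if target_length < 2:
        raise ValueError("target_length must be >= 2")
    if series.size < 2:
        raise ValueError("series must have at least 2 samples")
    n = series.size
    if target_length == n:
        return series.copy()
    if target_length < n:
        edges = np.linspace(0, n, target_length + 1)
        return np.array(
            [series[int(edges[i]) : max(int(edges[i]) + 1, int(np.ceil(edges[i + 1])))].mean()
             for i in range(target_length)]
        )
    x_old = np.linspace(0.0, 1.0, n)
    x_new = np.linspace(0.0, 1.0, target_length)
    return np.interp(x_new, x_old, series)


def quantize_unit(values: np.ndarray) -> np.ndarray:
    """Linear quantization from [-1, 1] to 8-bit intensities [0, 255]."""
    scaled = np.rint((np.clip(values, -1.0, 1.0) + 1.0) * 127.5)
    return scaled.astype(np.uint8)


def encode_channel(series: np.ndarray, side: int) -> np.ndarray:
    """One signal -> one quantized GAF channel of shape (side, side)."""
    resampled = resample_fixed(series, side)
    return quantize_unit(gaf_matrix(rescale_unit(resampled)))


#: Fixed channel -> signal mapping of the feature image.
CHANNEL_SIGNALS = ("acc_xyz", "gyr_xyz", "acc_fd")  # R, G, B


def compose_feature_image(step: ProcessedStep, side: int = DEFAULT_SIDE) -> GAFImage:
    """Encode a processed step as an N x N x 3 feature image.

    Red carries the acceleration magnitude, green the angular-velocity
    magnitude, blue the forward-direction acceleration.
    """
    channels = [encode_channel(getattr(step, name), side) for name in CHANNEL_SIGNALS]
    pixels = np.stack(channels, axis=-1)
    step_id = step.source.step_id if step.source is not None else None
    return GAFImage(pixels=pixels, label=step.label, step_id=step_id)


def export_png(
    image: GAFImage, directory: str | Path, prefix: str = "step"
) -> Path:
    """Write the RGB image (filename encodes label and step id)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    step_part = image.step_id or "unknown"
    return image.to_png(directory / f"{prefix}_{image.label.name.lower()}_{step_part}.png")
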