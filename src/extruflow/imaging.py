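"""Filament length measurement from grayscale video frames.

Stand-in for the manual workflow of extracting frames from a video of the
hanging filament and measuring its length in an image tool.  Conventions:
frames are grayscale with intensities in [0, 1], a bright filament on a dark
background, row index increasing downward (row 0 at the top), and the nozzle
tip at a known row.  Pixel size comes from the needle itself: its physical
length divided by its apparent length in pixels.

Length is vertical extent only — the hanging filament is assumed plumb.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .errors import CalibrationError, InvalidInputError
from .traces import FilamentTrace, segment_trace

__all__ = [
    "FrameImage",
    "calibrate_pixels",
    "filament_length",
    "trace_from_frames",
    "load_frame",
    "save_frame",
    "DEFAULT_THRESHOLD",
    "DEFAULT_FRAME_INTERVAL",
]

DEFAULT_THRESHOLD = 0.5
DEFAULT_FRAME_INTERVAL = 0.25  # s between extracted frames


@dataclass(frozen=True)
class FrameImage:
    """One grayscale frame: pixel grid, optional calibration, nozzle tip row."""

    pixels: np.ndarray
    tip_row: int
    pixel_size: float | None = None  # meters per pixel; None until calibrated

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", pixels)
        if pixels.ndim != 2:
            raise InvalidInputError("pixels must be a 2-D grayscale array")
        if pixels.min() < 0 or pixels.max() > 1:
            raise InvalidInputError("intensities must lie in [0, 1]")
        if not (0 <= self.tip_row < pixels.shape[0]):
            raise InvalidInputError(
                f"tip_row {self.tip_row} outside image of height {pixels.shape[0]}"
            )
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise InvalidInputError("pixel_size must be > 0")

    def calibrated(self, pixel_size: float) -> "FrameImage":
        return FrameImage(pixels=self.pixels, tip_row=self.tip_row, pixel_size=pixel_size)


def calibrate_pixels(needle_pixel_length: float, needle_physical_length: float) -> float:
    """Meters per pixel from the needle's known length and its length in pixels."""
    if needle_pixel_length <= 0 or needle_physical_length <= 0:
        raise InvalidInputError("needle lengths must be > 0")
    return needle_physical_length / needle_pixel_length


def filament_length(
    frame: FrameImage,
    threshold: float = DEFAULT_THRESHOLD,
    column_band: tuple[int, int] | None = None,
) -> float:
    """Filament length (m): how far the bright filament extends below the tip.

    Binarizes at ``threshold``, restricts to ``column_band`` (half-open column
    range; the whole width if None), and measures from the nozzle tip row to
    the lowest foreground row.  A frame with no foreground below the tip has
    length 0.  Thanks to the fixed threshold, the result is invariant to any
    intensity rescaling that keeps foreground above and background below it.
    """
    if frame.pixel_size is None:
        raise CalibrationError("frame is not calibrated; set pixel_size first")
    if not (0 < threshold < 1):
        raise InvalidInputError(f"threshold must be in (0, 1), got {threshold!r}")
    band = frame.pixels if column_band is None else frame.pixels[:, slice(*column_band)]
    below_tip = band[frame.tip_row :, :] > threshold
    rows = np.nonzero(below_tip.any(axis=1))[0]
    if rows.size == 0:
        return 0.0
    return float(rows[-1]) * frame.pixel_size


def trace_from_frames(
    frames: Sequence[FrameImage],
    pressure: float,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    threshold: float = DEFAULT_THRESHOLD,
) -> FilamentTrace:
    """Measure every frame, assemble a uniformly sampled trace, and segment it.

    Frame order defines time order; all frames must share one calibration.
    """
    if len(frames) < 2:
        raise InvalidInputError("need >= 2 frames to build a trace")
    sizes = {f.pixel_size for f in frames}
    if None in sizes or len(sizes) != 1:
        raise InvalidInputError(
            f"frames must share a single calibration, got pixel sizes {sizes}"
        )
    lengths = np.array([filament_length(f, threshold=threshold) for f in frames])
    times = np.arange(len(frames)) * frame_interval
    return segment_trace(FilamentTrace(pressure=pressure, times=times, lengths=lengths))


def load_frame(path: str | Path, tip_row: int, pixel_size: float | None = None) -> FrameImage:
    """Read a PNG/TIFF grayscale image into a frame, intensities scaled to [0, 1]."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("F"), dtype=float)
    if arr.max() > 1.0:  # 8/16-bit files arrive in [0, 255] / [0, 65535]
        arr = arr / (255.0 if arr.max() <= 255.0 else 65535.0)
    return FrameImage(pixels=np.clip(arr, 0.0, 1.0), tip_row=tip_row, pixel_size=pixel_size)


def save_frame(frame: FrameImage, path: str | Path) -> None:
    """Write a frame as an 8-bit grayscale PNG/TIFF (format from the suffix)."""
    img = Image.fromarray((np.clip(frame.pixels, 0, 1) * 255).astype(np.uint8), mode="L")
    img.save(path)
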