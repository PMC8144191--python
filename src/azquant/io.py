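"""Image container and TIFF round-trip with physical calibration.

Images are kept as ``frames × rows × cols × channels`` float arrays with
the calibration (nm per pixel, seconds per frame) attached, so every
downstream measurement can be reported in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile


class CalibrationError(ValueError):
    """Raised when an image lacks pixel-size / frame-interval calibration."""


class ImageReadError(IOError):
    """Raised when a file cannot be read as a TIFF stack."""


@dataclass
class ImageStack:
    """A calibrated image stack, axes = (frame, row, col, channel)."""

    data: np.ndarray
    pixel_size_nm: float
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:  # single frame, single channel
            self.data = self.data[None, :, :, None]
        elif self.data.ndim == 3:  # frames × rows × cols
            self.data = self.data[:, :, :, None]
        if self.data.ndim != 4:
            raise ValueError(f"expected 2–4 dimensional image data, got {self.data.ndim}")
        if not (self.pixel_size_nm > 0):
            raise CalibrationError("pixel_size_nm must be positive")
        if not (self.frame_interval_s > 0):
            raise CalibrationError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[3]

    @property
    def shape_rc(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def frame(self, index: int, channel: int = 0) -> np.ndarray:
        """Single 2D frame (rows × cols) for one channel."""
        return self.data[index, :, :, channel]

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def with_data(self, data: np.ndarray) -> "ImageStack":
        return replace(self, data=data)


def write_image_stack(path: str | Path, stack: ImageStack) -> Path:
    """Write a multi-page TIFF (axes TCYX) with calibration in the metadata."""
    path = Path(path)
    data = np.moveaxis(stack.data, 3, 1)  # T, C, Y, X
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        metadata={
            "axes": "TCYX",
            "pixel_size_nm": float(stack.pixel_size_nm),
            "frame_interval_s": float(stack.frame_interval_s),
        },
    )
    return path


def read_image_stack(
    path: str | Path,
    pixel_size_nm: float | None = None,
    frame_interval_s: float | None = None,
) -> ImageStack:
    """Read a TIFF stack, normalising axes to frames × rows × cols × channels.

    Calibration is taken from the file's metadata; explicit arguments
    override it.  A file without calibration and without overrides raises
    :class:`CalibrationError`.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes
            meta = {}
            if tif.shaped_metadata:
                meta = dict(tif.shaped_metadata[0])
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise ImageReadError(f"cannot read {path} as TIFF: {exc}") from exc

    # normalise axis order to TCYX then move channel last
    axes = axes.replace("S", "C").replace("Q", "T").replace("Z", "T").replace("I", "T")
    if "Y" not in axes or "X" not in axes:
        raise ImageReadError(f"unsupported TIFF axes {series.axes!r} in {path}")
    for missing in ("T", "C"):
        if missing not in axes:
            data = data[None]
            axes = missing + axes
    order = [axes.index(ax) for ax in "TCYX"]
    data = np.transpose(data, order)
    data = np.moveaxis(data, 1, 3)

    px = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
    dt = frame_interval_s if frame_interval_s is not None else meta.get("frame_interval_s", 1.0)
    if px is None:
        raise CalibrationError(f"{path} carries no pixel-size metadata and no override was given")
    return ImageStack(data=data, pixel_size_nm=float(px), frame_interval_s=float(dt))
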