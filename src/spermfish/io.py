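"""Calibrated multi-channel image I/O and pixel/micron unit conversion.

Images are stored as multi-page TIFF (one page per channel, 16-bit) with a
JSON sidecar carrying the physical calibration.  The acquisition setup this
package targets resolves 12 pixels per micron (x100 oil-immersion objective),
so the default pixel size is 1/12 um.

Coordinate conventions: 0-based (row, col) pixel indices; a point is the
center of its pixel; all physical distances are computed in microns after
calibration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

#: Default calibration: 12 px correspond to 1 um.
DEFAULT_PIXEL_SIZE_UM = 1.0 / 12.0

DEFAULT_CHANNEL_NAMES = ("counterstain", "telomere", "paint")


class ImageFormatError(ValueError):
    """Raised when a file cannot be interpreted as a calibrated image."""


@dataclass
class CalibratedImage:
    """A multi-channel 2D image with physical pixel-size calibration.

    Parameters
    ----------
    pixels
        Array of shape ``(n_channels, height, width)``, non-negative
        integer intensities.
    pixel_size_um
        Microns per pixel (isotropic); must be positive.
    channel_names
        One name per channel.
    """

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    channel_names: tuple[str, ...] = DEFAULT_CHANNEL_NAMES
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 3:
            raise ImageFormatError(
                f"expected (channels, height, width) array, got shape {self.pixels.shape}"
            )
        if self.pixels.size == 0:
            raise ImageFormatError("empty pixel array")
        if np.issubdtype(self.pixels.dtype, np.integer) and self.pixels.min() < 0:
            raise ImageFormatError("negative intensities")
        if not self.pixel_size_um > 0:
            raise ImageFormatError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        self.channel_names = tuple(self.channel_names)[: self.pixels.shape[0]]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of each channel."""
        return self.pixels.shape[1:]

    def channel(self, name_or_index: str | int) -> np.ndarray:
        if isinstance(name_or_index, str):
            name_or_index = self.channel_names.index(name_or_index)
        return self.pixels[name_or_index]


def px_to_um(length_px: float, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> float:
    """Convert a pixel length to microns (exact product)."""
    if length_px < 0:
        raise ValueError("length_px must be >= 0")
    return float(length_px) * float(pixel_size_um)


def um_to_px(length_um: float, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> float:
    """Inverse of :func:`px_to_um`."""
    if length_um < 0:
        raise ValueError("length_um must be >= 0")
    return float(length_um) / float(pixel_size_um)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_image(image: CalibratedImage, path: str | Path) -> Path:
    """Write a multi-page TIFF plus JSON sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, image.pixels, photometric="minisblack")
    sidecar = {
        "pixel_size_um": image.pixel_size_um,
        "channels": list(image.channel_names),
        **image.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_image(path: str | Path) -> CalibratedImage:
    """Read a 1-4 page TIFF with optional JSON sidecar.

    Without a sidecar the default calibration (1/12 um/px) is applied and a
    warning is logged.  Round-trips :func:`write_image` exactly.
    """
    path = Path(path)
    try:
        pixels = tifffile.imread(path)
    except (tifffile.TiffFileError, FileNotFoundError, ValueError) as exc:
        raise ImageFormatError(f"cannot read TIFF {path}: {exc}") from exc
    pixels = np.asarray(pixels)
    if pixels.ndim == 2:
        pixels = pixels[None]
    if pixels.ndim != 3 or not 1 <= pixels.shape[0] <= 4:
        raise ImageFormatError(
            f"{path}: expected 1-4 equally shaped pages, got shape {pixels.shape}"
        )
    sidecar = _sidecar_path(path)
    pixel_size = DEFAULT_PIXEL_SIZE_UM
    channels = DEFAULT_CHANNEL_NAMES
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_size = float(meta.pop("pixel_size_um", DEFAULT_PIXEL_SIZE_UM))
        channels = tuple(meta.pop("channels", DEFAULT_CHANNEL_NAMES))
    else:
        logger.warning(
            "%s: no calibration sidecar; assuming %.6f um/px (12 px per um)",
            path, DEFAULT_PIXEL_SIZE_UM,
        )
    return CalibratedImage(pixels, pixel_size_um=pixel_size, channel_names=channels, meta=meta)
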