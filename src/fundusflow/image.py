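"""Fundus image container and raster I/O.

All pixel data are kept as float arrays in [0, 1] internally; loaders rescale
8/16-bit input. Coordinates are (row, col), 0-based, row increasing downward.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

__all__ = ["FundusImage", "load_fundus_image", "save_fundus_image"]

VALID_LATERALITIES = ("OD", "OS")


@dataclass
class FundusImage:
    """A single fundus photograph with laterality and timepoint metadata.

    Parameters
    ----------
    pixels
        ``(H, W)`` or ``(H, W, 3)`` float array, intensities in [0, 1].
    laterality
        ``"OD"`` (right eye) or ``"OS"`` (left eye).
    timepoint_label
        Free-form ordered label, e.g. ``"pre"``, ``"m01"``.
    frame_id
        Identifier of the pixel grid the image lives in.
    flipped
        Whether the image has already been horizontally mirrored into the
        common left-eye orientation (guards against double flipping).
    validity_mask
        Boolean in-field mask; ``None`` means the full frame is valid.
    """

    pixels: np.ndarray
    laterality: str = "OS"
    timepoint_label: str = ""
    frame_id: str = ""
    flipped: bool = False
    validity_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError(f"pixels must be 2-D or 3-D, got shape {self.pixels.shape}")
        h, w = self.pixels.shape[:2]
        if h < 64 or w < 64:
            raise ValueError(f"image too small ({h}x{w}); need at least 64x64")
        if self.laterality not in VALID_LATERALITIES:
            raise ValueError(f"laterality must be one of {VALID_LATERALITIES}, got {self.laterality!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def green(self) -> np.ndarray:
        """Single-channel view: the green channel of RGB input (highest vessel
        contrast), or the image itself when already single-channel."""
        if self.pixels.ndim == 3:
            return np.ascontiguousarray(self.pixels[..., 1])
        return self.pixels

    def mask(self) -> np.ndarray:
        if self.validity_mask is not None:
            return self.validity_mask
        return np.ones(self.shape, dtype=bool)

    def with_(self, **kwargs) -> "FundusImage":
        return replace(self, **kwargs)


def _to_float01(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def load_fundus_image(
    path: str | Path,
    laterality: str = "OS",
    timepoint_label: str = "",
    frame_id: str | None = None,
) -> FundusImage:
    """Read a PNG/TIFF/JPEG raster into a :class:`FundusImage`."""
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    return FundusImage(
        pixels=_to_float01(arr),
        laterality=laterality,
        timepoint_label=timepoint_label,
        frame_id=frame_id if frame_id is not None else path.stem,
    )


def save_fundus_image(image: FundusImage, path: str | Path) -> None:
    """Write as TIFF (float32) or 8-bit PNG/JPEG depending on the extension."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels.astype(np.float32))
    else:
        iio.imwrite(path, (np.clip(image.pixels, 0, 1) * 255).round().astype(np.uint8))
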