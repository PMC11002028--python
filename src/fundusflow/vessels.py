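"""Per-pixel vessel probability maps.

The registration substrate is a per-pixel vessel likelihood in [0, 1]. Maps
are produced here with a classical multiscale Hessian vesselness (Frangi)
filter on the green channel — dark vessels on bright background — or loaded
from an external segmenter (e.g. a CNN) that honours the same contract.
Downstream code consumes only the probability map, so the two sources are
interchangeable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from skimage.filters import frangi

from .errors import ShapeMismatchError
from .image import FundusImage

__all__ = [
    "VesselProbabilityMap",
    "vesselness_map",
    "binarize",
    "load_probability_map",
    "save_probability_map",
    "DEFAULT_SCALES",
]

logger = logging.getLogger(__name__)

#: default Gaussian scales (sigma, px) tuned for images whose fovea-disc
#: distance is about 1000 px; scaled proportionally when the FDD is known
DEFAULT_SCALES = (1.5, 2.5, 4.0)


@dataclass
class VesselProbabilityMap:
    """Per-pixel vessel likelihood in [0, 1] on a named frame."""

    values: np.ndarray
    frame_id: str = ""
    validity_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"map must be 2-D, got {self.values.shape}")
        if self.validity_mask is None:
            self.validity_mask = np.ones(self.values.shape, dtype=bool)
        if self.validity_mask.shape != self.values.shape:
            raise ShapeMismatchError(
                f"validity mask {self.validity_mask.shape} vs map {self.values.shape}"
            )
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("probability values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def scales_for_fdd(fdd: float, base: tuple[float, ...] = DEFAULT_SCALES) -> tuple[float, ...]:
    """Rescale the default sigmas to the image's fovea-disc distance.

    Sigmas grow proportionally for higher-resolution images (FDD > 1000 px)
    but are never reduced below the base values: on lower-resolution frames
    vessels occupy the same few pixels regardless of FDD, and sub-pixel
    sigmas only amplify noise.
    """
    return tuple(max(s, s * fdd / 1000.0) for s in base)


def vesselness_map(
    image: FundusImage,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    dark_vessels: bool = True,
    pct: tuple[float, float] = (1.0, 99.0),
) -> VesselProbabilityMap:
    """Multiscale Hessian (Frangi) vesselness of a fundus image.

    The tubularity response is computed on the green channel at each Gaussian
    scale, maximized over scales, and rescaled to [0, 1] by robust
    percentile normalization (clipping at the ``pct`` percentiles, which is
    stable against isolated hot pixels). ``dark_vessels`` selects the dark-on-
    bright polarity of color fundus photographs; external maps with inverted
    polarity can set it False and obtain the identical response.

    Deterministic: no randomness is involved.
    """
    scales = tuple(float(s) for s in scales)
    if len(scales) == 0:
        raise ValueError("at least one scale is required")
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be positive")
    chan = image.green().astype(np.float64)
    if not np.all(np.isfinite(chan)):
        raise ValueError("image contains non-finite pixels")
    if not dark_vessels:
        chan = chan.max() - chan  # bring bright ridges to the dark polarity

    mask = image.mask()
    if chan.max() - chan.min() == 0:
        return VesselProbabilityMap(np.zeros_like(chan), image.frame_id, mask.copy())

    resp = frangi(chan, sigmas=scales, black_ridges=True)
    resp[~mask] = 0.0

    inside = resp[mask]
    lo, hi = np.percentile(inside, pct)
    if hi <= lo:
        values = np.zeros_like(resp)
    else:
        values = np.clip((resp - lo) / (hi - lo), 0.0, 1.0)
    values[~mask] = 0.0
    return VesselProbabilityMap(values=values, frame_id=image.frame_id, validity_mask=mask.copy())


def binarize(pmap: VesselProbabilityMap, threshold: float = 0.5) -> np.ndarray:
    """Boolean vessel mask: ``map >= threshold`` within the validity mask.

    Used for alignment diagnostics (Dice); the registration similarity itself
    operates on the continuous maps.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return (pmap.values >= threshold) & pmap.validity_mask


def save_probability_map(pmap: VesselProbabilityMap, path: str | Path) -> None:
    """Write as single-channel 32-bit float TIFF."""
    tifffile.imwrite(Path(path), pmap.values.astype(np.float32))


def load_probability_map(
    path: str | Path,
    expected_shape: tuple[int, int] | None = None,
    frame_id: str = "",
) -> VesselProbabilityMap:
    """Load an externally computed probability map (e.g. CNN output).

    Values outside [0, 1] are clipped with a logged warning; a shape mismatch
    against ``expected_shape`` is an error.
    """
    arr = tifffile.imread(Path(path))
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 2:
        raise ShapeMismatchError(f"expected single-channel raster, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-numeric data in {path}")
    if expected_shape is not None and tuple(arr.shape) != tuple(expected_shape):
        raise ShapeMismatchError(
            f"probability map shape {tuple(arr.shape)} does not match expected {tuple(expected_shape)}"
        )
    if arr.min() < 0 or arr.max() > 1:
        logger.warning("clipping probability values outside [0, 1] in %s", path)
        arr = np.clip(arr, 0.0, 1.0)
    return VesselProbabilityMap(values=arr, frame_id=frame_id)
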