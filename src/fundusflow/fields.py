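"""Dense per-pixel displacement fields on the reference grid.

The field assigns every reference-grid pixel a 2-vector ``(d_row, d_col)`` in
pixels, pointing from the earlier position of the tissue toward its later
(reference) position.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import tifffile

from .errors import ShapeMismatchError

__all__ = ["DisplacementField", "save_field", "load_field"]


@dataclass
class DisplacementField:
    """Per-pixel retinal displacement vector field.

    Attributes
    ----------
    vectors
        ``(H, W, 2)`` float array of (row, col) displacement components in
        pixels, earlier -> later convention, living on the reference grid.
    reference_frame_id
        Frame identifier of the reference (fixed, latest) image.
    validity_mask
        ``(H, W)`` booleans; ``False`` marks pixels with no valid estimate
        (e.g. outside the globally warped moving image footprint).
    provenance
        Free-form record of the pair of frames and transforms applied.
    """

    vectors: np.ndarray
    reference_frame_id: str = ""
    validity_mask: np.ndarray | None = None
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 3 or self.vectors.shape[2] != 2:
            raise ValueError(f"vectors must be (H, W, 2), got {self.vectors.shape}")
        if self.validity_mask is None:
            self.validity_mask = np.ones(self.vectors.shape[:2], dtype=bool)
        if self.validity_mask.shape != self.vectors.shape[:2]:
            raise ShapeMismatchError(
                f"validity mask {self.validity_mask.shape} vs field {self.vectors.shape[:2]}"
            )
        if not np.all(np.isfinite(self.vectors[self.validity_mask])):
            raise ValueError("non-finite displacement inside validity mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.vectors.shape[:2]

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.vectors[..., 0], self.vectors[..., 1])


def save_field(fld: DisplacementField, path: str | Path) -> None:
    """Write as 2-channel 32-bit float TIFF, channel order (row-disp, col-disp)."""
    tifffile.imwrite(
        Path(path),
        fld.vectors.astype(np.float32),
        metadata={"channels": "row_disp,col_disp", "frame": fld.reference_frame_id},
    )


def load_field(path: str | Path, reference_frame_id: str = "") -> DisplacementField:
    arr = tifffile.imread(Path(path)).astype(np.float64)
    if arr.ndim != 3 or arr.shape[-1] != 2:
        raise ShapeMismatchError(f"expected (H, W, 2) field, got {arr.shape}")
    return DisplacementField(vectors=arr, reference_frame_id=reference_frame_id)
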