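"""Landmark-anchored conventions: fovea-disc axis, direction angles,
standardized magnitude, and laterality normalization.

Every directional quantity in the pipeline is defined through the fovea-disc
axis of the reference image, never through raw image axes:

* the **nasal** unit vector ``n`` points from the fovea center toward the
  optic-disc center (0 degrees);
* the **superior** unit vector ``s`` is the 90-degree rotation of ``n`` whose
  row component is non-positive (pointing up in erect fundus presentation);
* a displacement of one fovea-disc distance (FDD) has **standardized
  magnitude** 1000, making magnitudes comparable across devices and patients.

Right-eye (OD) images are horizontally mirrored into the common left-eye
orientation before any of this applies, so nasal always means "toward the
disc side" in the normalized frame.

Coordinates are (row, col), 0-based, row increasing downward.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import (
    DegenerateLandmarksError,
    ImplausibleLandmarksError,
    LateralityError,
)
from .fields import DisplacementField
from .image import FundusImage

__all__ = [
    "Landmarks",
    "NasalAxis",
    "PolarVector",
    "fovea_disc_distance",
    "nasal_axis",
    "vector_direction",
    "standardize_magnitude",
    "normalize_laterality",
    "flip_landmarks",
    "flip_field",
    "load_landmarks",
    "save_landmarks",
]

#: axes tilted more than this many degrees from horizontal trigger a warning
VERTICAL_AXIS_WARN_DEG = 75.0


@dataclass(frozen=True)
class Landmarks:
    """Fovea and optic-disc centers in a named pixel frame.

    ``fovea_center`` and ``disc_center`` are (row, col) tuples; sub-pixel
    positions are allowed.
    """

    fovea_center: tuple[float, float]
    disc_center: tuple[float, float]
    frame_id: str = ""
    laterality: str = "OS"

    def __post_init__(self) -> None:
        if tuple(self.fovea_center) == tuple(self.disc_center):
            raise DegenerateLandmarksError("fovea and disc centers coincide")

    @property
    def fdd(self) -> float:
        return fovea_disc_distance(self)


@dataclass(frozen=True)
class NasalAxis:
    """Orthonormal (nasal, superior) frame anchored at the fovea."""

    n: tuple[float, float]  # unit vector, fovea -> disc (nasal direction)
    s: tuple[float, float]  # unit vector, superior (row component <= 0)

    def __post_init__(self) -> None:
        n = np.asarray(self.n, dtype=float)
        s = np.asarray(self.s, dtype=float)
        if abs(np.linalg.norm(n) - 1) > 1e-9 or abs(np.linalg.norm(s) - 1) > 1e-9:
            raise ValueError("axis vectors must be unit length")
        if abs(float(n @ s)) > 1e-9:
            raise ValueError("axis vectors must be orthogonal")
        if s[0] > 1e-12:
            raise ValueError("superior vector must have non-positive row component")


@dataclass(frozen=True)
class PolarVector:
    """A displacement expressed in the field's polar conventions.

    ``magnitude`` is in pixels, ``standardized_magnitude`` in per-mille of
    the fovea-disc distance, ``direction_deg`` in [0, 360) with nasal = 0 and
    temporal = 180. A zero vector has direction 0 by convention.
    """

    magnitude: float
    standardized_magnitude: float
    direction_deg: float

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("magnitude must be non-negative")
        if not (0.0 <= self.direction_deg < 360.0):
            raise ValueError("direction must lie in [0, 360)")


def fovea_disc_distance(landmarks: Landmarks) -> float:
    """Euclidean pixel distance between fovea and disc centers (FDD)."""
    fr, fc = landmarks.fovea_center
    dr, dc = landmarks.disc_center
    d = math.hypot(dr - fr, dc - fc)
    if d <= 0:
        raise DegenerateLandmarksError("fovea-disc distance must be positive")
    return d


def nasal_axis(landmarks: Landmarks, *, strict: bool = False) -> NasalAxis:
    """Build the (nasal, superior) frame from left-eye-normalized landmarks.

    ``n`` points fovea -> disc; ``s`` is the perpendicular with row component
    <= 0. An exactly vertical fovea-disc axis has no superior-pointing
    perpendicular and raises; axes within 15 degrees of vertical warn (or
    raise when ``strict``) because they almost certainly indicate swapped or
    mistyped landmarks.
    """
    fdd = fovea_disc_distance(landmarks)
    fr, fc = landmarks.fovea_center
    dr, dc = landmarks.disc_center
    n = ((dr - fr) / fdd, (dc - fc) / fdd)

    tilt = math.degrees(math.atan2(abs(n[0]), abs(n[1])))  # angle from horizontal
    if abs(n[1]) < 1e-12:
        raise ImplausibleLandmarksError("fovea-disc axis is exactly vertical; superior direction undefined")
    if tilt > VERTICAL_AXIS_WARN_DEG:
        msg = f"fovea-disc axis is {tilt:.1f} deg from horizontal; landmarks look implausible"
        if strict:
            raise ImplausibleLandmarksError(msg)
        warnings.warn(msg, stacklevel=2)

    cand = (-n[1], n[0])
    if cand[0] > 0:
        cand = (n[1], -n[0])
    return NasalAxis(n=n, s=cand)


def vector_direction(v, axis: NasalAxis) -> float:
    """Angle of ``v`` in degrees within [0, 360), measured from nasal (= 0)
    through superior (= 90). Total function: the zero vector maps to 0."""
    v = np.asarray(v, dtype=float)
    comp_n = float(v @ np.asarray(axis.n))
    comp_s = float(v @ np.asarray(axis.s))
    if comp_n == 0.0 and comp_s == 0.0:
        return 0.0
    theta = math.degrees(math.atan2(comp_s, comp_n)) % 360.0
    return theta if theta < 360.0 else 0.0


def standardize_magnitude(magnitude: float, fdd: float) -> float:
    """Rescale a pixel magnitude so that one fovea-disc distance equals 1000."""
    if fdd <= 0:
        raise DegenerateLandmarksError("fovea-disc distance must be positive")
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    return magnitude * 1000.0 / fdd


def flip_landmarks(landmarks: Landmarks, width: int) -> Landmarks:
    """Mirror landmark columns about the vertical image midline."""
    fr, fc = landmarks.fovea_center
    dr, dc = landmarks.disc_center
    return replace(
        landmarks,
        fovea_center=(fr, width - 1 - fc),
        disc_center=(dr, width - 1 - dc),
    )


def flip_field(fld: DisplacementField) -> DisplacementField:
    """Mirror a displacement field: positions column-mirrored, column
    components negated."""
    vec = fld.vectors[:, ::-1].copy()
    vec[..., 1] *= -1.0
    mask = fld.validity_mask[:, ::-1].copy()
    prov = dict(fld.provenance)
    prov["flipped"] = True
    return DisplacementField(
        vectors=vec,
        reference_frame_id=fld.reference_frame_id,
        validity_mask=mask,
        provenance=prov,
    )


def normalize_laterality(
    image: FundusImage,
    landmarks: Landmarks | None = None,
    field: DisplacementField | None = None,
):
    """Bring an image (and optional landmarks / field) into the common
    left-eye orientation.

    OS inputs are returned unchanged. OD inputs are horizontally mirrored:
    pixel (r, c) -> (r, W-1-c), landmark columns likewise, and displacement
    fields column-mirrored with negated column components. A ``flipped``
    metadata flag forbids double application.

    Returns ``(image, landmarks, field)`` with ``None`` passed through.
    """
    if image.laterality not in ("OD", "OS"):
        raise LateralityError(f"unknown laterality {image.laterality!r}")
    if image.laterality == "OS":
        return image, landmarks, field
    if image.flipped:
        raise LateralityError(f"image {image.frame_id!r} was already flipped")

    w = image.shape[1]
    pixels = image.pixels[:, ::-1].copy()
    vmask = None if image.validity_mask is None else image.validity_mask[:, ::-1].copy()
    out_image = image.with_(pixels=pixels, validity_mask=vmask, flipped=True)
    out_landmarks = None if landmarks is None else flip_landmarks(landmarks, w)
    out_field = None if field is None else flip_field(field)
    return out_image, out_landmarks, out_field


# -- landmark JSON I/O --------------------------------------------------------

def save_landmarks(landmarks: Landmarks, path: str | Path) -> None:
    payload = {
        "frame_id": landmarks.frame_id,
        "laterality": landmarks.laterality,
        "fovea": list(landmarks.fovea_center),
        "disc": list(landmarks.disc_center),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_landmarks(path: str | Path) -> Landmarks:
    payload = json.loads(Path(path).read_text())
    return Landmarks(
        fovea_center=tuple(float(x) for x in payload["fovea"]),
        disc_center=tuple(float(x) for x in payload["disc"]),
        frame_id=str(payload.get("frame_id", "")),
        laterality=str(payload.get("laterality", "OS")),
    )
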