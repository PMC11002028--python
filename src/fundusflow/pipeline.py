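"""End-to-end displacement-field computation for an image pair.

Stages: laterality normalization -> global feature-based alignment ->
vessel probability maps -> b-spline non-rigid registration on the maps ->
densification and sign flip into the tissue-motion (earlier -> later)
convention. The field lives on the reference (latest) image grid; only that
image needs fovea/disc landmarks.

The global transform aligns the *viewing* geometry (camera pose,
magnification) and is deliberately excluded from the reported field, which
captures only the residual non-rigid tissue motion.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .bspline import RegistrationConfig, RegistrationReport, densify, register_bspline
from .errors import FundusFlowError
from .fields import DisplacementField
from .geometry import (
    Landmarks,
    NasalAxis,
    PolarVector,
    fovea_disc_distance,
    nasal_axis,
    normalize_laterality,
    standardize_magnitude,
    vector_direction,
)
from .image import FundusImage
from .rigid import GlobalTransform, RigidConfig, detect_and_match, estimate_global_transform, warp_to_reference
from .vessels import DEFAULT_SCALES, scales_for_fdd, vesselness_map

__all__ = ["PairConfig", "PairResult", "compute_pair_field", "polar_at"]


@dataclass
class PairConfig:
    """All stage settings for one pair registration."""

    rigid: RigidConfig = dc_field(default_factory=RigidConfig)
    nonrigid: RegistrationConfig = dc_field(default_factory=RegistrationConfig)
    vessel_scales: tuple[float, ...] = DEFAULT_SCALES
    fdd_relative: bool = True  # scale vessel sigmas and grid spacings to the FDD
    transform_kind: str = "similarity"
    #: canonical working resolution: images are resampled so the fovea-disc
    #: distance equals this many pixels before registration (None = native).
    #: Fixing the anatomical sampling density makes filter scales and grid
    #: spacings mean the same thing for every camera/resolution, and makes
    #: standardized outputs nearly independent of input scale.
    working_fdd: float | None = 170.0
    #: skip resampling when the scale change would be below this fraction
    working_fdd_slack: float = 0.05


@dataclass
class PairResult:
    """Displacement field plus per-stage diagnostics."""

    field: DisplacementField
    landmarks: Landmarks
    axis: NasalAxis
    fdd: float
    global_transform: GlobalTransform
    nonrigid_report: RegistrationReport

    def report_dict(self) -> dict:
        return {
            "moving_frame": self.field.provenance.get("moving_frame"),
            "fixed_frame": self.field.reference_frame_id,
            "fdd_px": self.fdd,
            "global": {
                "kind": self.global_transform.kind,
                "matrix": self.global_transform.matrix.tolist(),
                "inlier_count": self.global_transform.inlier_count,
                "inlier_rms": self.global_transform.inlier_rms,
            },
            "nonrigid": {
                "initial_ncc": self.nonrigid_report.initial_ncc,
                "final_ncc": self.nonrigid_report.final_ncc,
                "final_dice": self.nonrigid_report.final_dice,
                "rounds": self.nonrigid_report.rounds,
                "warnings": list(self.nonrigid_report.warnings),
            },
        }


def _rescale_image(image: FundusImage, c: float) -> FundusImage:
    """Resample an image (and its validity mask) by scale factor ``c``."""
    from skimage.transform import rescale

    if image.pixels.ndim == 3:
        pixels = rescale(image.pixels, c, order=1, channel_axis=-1)
    else:
        pixels = rescale(image.pixels, c, order=1)
    mask = rescale(image.mask().astype(np.float64), c, order=0) > 0.5
    return image.with_(pixels=pixels, validity_mask=mask)


def _field_to_native(
    vectors: np.ndarray,
    validity: np.ndarray,
    native_shape: tuple[int, int],
    c: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Map a working-resolution field back onto the native reference grid:
    ``u_native(x) = u_work(c x) / c``."""
    from scipy import ndimage

    rows, cols = np.mgrid[0 : native_shape[0], 0 : native_shape[1]].astype(np.float64)
    coords = [rows * c, cols * c]
    out = np.stack(
        [
            ndimage.map_coordinates(vectors[..., 0], coords, order=1, mode="nearest") / c,
            ndimage.map_coordinates(vectors[..., 1], coords, order=1, mode="nearest") / c,
        ],
        axis=-1,
    )
    native_valid = (
        ndimage.map_coordinates(validity.astype(np.float64), coords, order=0, mode="constant", cval=0.0)
        > 0.5
    )
    return out, native_valid


def _stage(name: str):
    """Re-raise pipeline errors with a stage label."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, FundusFlowError):
                exc.args = (f"[{name}] {exc.args[0] if exc.args else ''}",) + exc.args[1:]
            return False

    return _Ctx()


def compute_pair_field(
    moving: FundusImage,
    fixed: FundusImage,
    landmarks_fixed: Landmarks,
    config: PairConfig | None = None,
) -> PairResult:
    """Compute the retinal displacement vector field moving -> fixed.

    ``fixed`` is the later/reference image of the same eye and
    ``landmarks_fixed`` its fovea/disc centers. Returns the field on the
    reference grid in the earlier->later tissue-motion convention, with a
    validity mask excluding pixels outside the globally warped moving
    footprint.
    """
    config = config or PairConfig()
    if moving.laterality != fixed.laterality:
        raise FundusFlowError(
            f"[input] pair mixes lateralities {moving.laterality}/{fixed.laterality}"
        )

    with _stage("laterality"):
        moving, _, _ = normalize_laterality(moving)
        fixed, landmarks_fixed, _ = normalize_laterality(fixed, landmarks_fixed)

    from dataclasses import replace as dc_replace

    landmarks_fixed = dc_replace(landmarks_fixed, frame_id=fixed.frame_id)
    fdd = fovea_disc_distance(landmarks_fixed)
    axis = nasal_axis(landmarks_fixed)

    native_shape = fixed.shape
    native_fdd = fdd
    native_landmarks = landmarks_fixed
    work_scale = 1.0
    if config.working_fdd is not None:
        c = config.working_fdd / fdd
        if abs(c - 1.0) > config.working_fdd_slack:
            work_scale = c
            moving = _rescale_image(moving, c)
            fixed = _rescale_image(fixed, c)
            landmarks_fixed = dc_replace(
                landmarks_fixed,
                fovea_center=tuple(v * c for v in landmarks_fixed.fovea_center),
                disc_center=tuple(v * c for v in landmarks_fixed.disc_center),
            )
            fdd = fovea_disc_distance(landmarks_fixed)

    with _stage("rigid"):
        matches = detect_and_match(moving, fixed, config.rigid)
        gtf = estimate_global_transform(matches, config.transform_kind, config.rigid)
        moving_warped = warp_to_reference(moving, gtf, fixed.shape)

    with _stage("vessels"):
        scales = scales_for_fdd(fdd, config.vessel_scales) if config.fdd_relative else config.vessel_scales
        vmap_moving = vesselness_map(moving_warped, scales)
        vmap_fixed = vesselness_map(fixed, scales)

    with _stage("nonrigid"):
        nr_config = config.nonrigid.scaled_to_fdd(fdd) if config.fdd_relative else config.nonrigid
        transform, report = register_bspline(vmap_moving, vmap_fixed, nr_config)

    pullback = densify(transform, reference_frame_id=fixed.frame_id)
    vectors = -pullback.vectors  # pull-back -> tissue motion (earlier -> later)
    validity = moving_warped.mask() & fixed.mask()
    if work_scale != 1.0:
        vectors, validity = _field_to_native(vectors, validity, native_shape, work_scale)
    field = DisplacementField(
        vectors=vectors,
        reference_frame_id=fixed.frame_id,
        validity_mask=validity,
        provenance={
            "moving_frame": moving.frame_id,
            "fixed_frame": fixed.frame_id,
            "global_kind": gtf.kind,
            "nonrigid_rounds": report.rounds,
            "flipped": fixed.flipped,
            "working_scale": work_scale,
        },
    )
    return PairResult(
        field=field,
        landmarks=native_landmarks,
        axis=axis,
        fdd=native_fdd,
        global_transform=gtf,
        nonrigid_report=report,
    )


def polar_at(
    field: DisplacementField,
    pixel: tuple[int, int],
    axis: NasalAxis,
    fdd: float,
) -> PolarVector:
    """Polar decomposition of the field at one pixel: magnitude (px),
    standardized magnitude (per-mille of FDD) and direction (degrees, nasal
    = 0). The pixel must lie inside the validity mask."""
    r, c = int(pixel[0]), int(pixel[1])
    if not (0 <= r < field.shape[0] and 0 <= c < field.shape[1]):
        raise ValueError(f"pixel {pixel} outside field {field.shape}")
    if not field.validity_mask[r, c]:
        raise ValueError(f"pixel {pixel} outside validity mask")
    u = field.vectors[r, c]
    mag = float(np.hypot(u[0], u[1]))
    return PolarVector(
        magnitude=mag,
        standardized_magnitude=standardize_magnitude(mag, fdd),
        direction_deg=vector_direction(u, axis),
    )
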