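"""Global (similarity/affine) alignment of a fundus image pair.

The earlier (moving) image is aligned onto the latest (fixed, reference)
image by sparse feature matching on the green channel followed by robust
RANSAC estimation of a similarity transform — rotation, isotropic scale and
translation. Scale is included because the viewing magnification can change
between visits (e.g. after cataract surgery); the transform family is
configurable to affine.

The detector is pluggable (SIFT by default; any detector producing keypoints
plus descriptors satisfies the contract) since the alignment contract is
robust feature matching, not a particular descriptor.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from skimage.feature import SIFT, match_descriptors
from skimage.measure import ransac
from skimage.transform import AffineTransform, SimilarityTransform

from .errors import InsufficientFeaturesError, RegistrationFailureError
from .image import FundusImage

__all__ = [
    "RigidConfig",
    "MatchedFeatures",
    "GlobalTransform",
    "detect_and_match",
    "estimate_global_transform",
    "warp_to_reference",
]


@dataclass
class RigidConfig:
    """Settings of the sparse matching and robust estimation stage."""

    ratio: float = 0.8             # Lowe-style ratio test threshold
    residual_threshold: float = 3.0  # RANSAC inlier distance, px
    min_matches: int = 3
    min_inlier_fraction: float = 0.25
    scale_band: tuple[float, float] = (0.5, 2.0)  # plausible similarity scales
    max_trials: int = 1000
    seed: int = 17
    #: the final refit re-admits matches within this multiple of
    #: ``residual_threshold`` of the consensus model. Pairs awaiting non-rigid
    #: registration are smoothly deformed, so a tight consensus set tends to
    #: describe one locally-rigid patch; the broad least-squares refit averages
    #: the deformation out while RANSAC still rejects gross mismatches.
    refit_threshold_factor: float = 5.0


@dataclass
class MatchedFeatures:
    """Putative correspondences between the moving and fixed images."""

    src_points: np.ndarray  # (N, 2) (row, col) in the moving image
    dst_points: np.ndarray  # (N, 2) (row, col) in the fixed image
    scores: np.ndarray      # per-match descriptor distances
    moving_frame_id: str = ""
    fixed_frame_id: str = ""

    def __post_init__(self) -> None:
        self.src_points = np.atleast_2d(np.asarray(self.src_points, dtype=np.float64))
        self.dst_points = np.atleast_2d(np.asarray(self.dst_points, dtype=np.float64))
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.src_points) != len(self.dst_points):
            raise ValueError("src/dst point lists must have equal length")

    def __len__(self) -> int:
        return len(self.src_points)


@dataclass
class GlobalTransform:
    """2x3 matrix mapping moving (row, col, 1) -> fixed (row, col)."""

    kind: str
    matrix: np.ndarray
    inlier_count: int = 0
    inlier_rms: float = 0.0
    extras: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(2, 3)
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise ValueError("transform matrix is singular")

    @classmethod
    def identity(cls, kind: str = "similarity") -> "GlobalTransform":
        return cls(kind=kind, matrix=np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @property
    def scale(self) -> float:
        return float(np.sqrt(abs(np.linalg.det(self.matrix[:, :2]))))

    @property
    def rotation_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.matrix[1, 0], self.matrix[1, 1])))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def full_matrix(self) -> np.ndarray:
        return np.vstack([self.matrix, [0.0, 0.0, 1.0]])

    def inverse_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.full_matrix())


def _rc_matrix_from_xy(tform) -> np.ndarray:
    """Convert a skimage (x, y) transform to our (row, col) 2x3 matrix."""
    m = np.asarray(tform.params, dtype=np.float64)
    a, b, tx = m[0]
    c, d, ty = m[1]
    return np.array([[d, c, ty], [b, a, tx]])


def detect_and_match(
    moving: FundusImage,
    fixed: FundusImage,
    config: RigidConfig | None = None,
) -> MatchedFeatures:
    """Detect keypoints on both green channels and match descriptors.

    Matches are mutual nearest neighbours that pass the ratio test
    (``config.ratio``); deterministic for fixed inputs and config.
    """
    if config is None:
        config = RigidConfig()

    def _extract(img: FundusImage):
        det = SIFT()
        try:
            det.detect_and_extract(img.green())
        except RuntimeError:
            return None, None
        if det.keypoints is None or len(det.keypoints) == 0:
            return None, None
        return det.keypoints.astype(np.float64), det.descriptors

    kp_m, des_m = _extract(moving)
    kp_f, des_f = _extract(fixed)
    if kp_m is None or kp_f is None or len(kp_m) < config.min_matches or len(kp_f) < config.min_matches:
        raise InsufficientFeaturesError(
            f"too few keypoints in pair ({moving.frame_id!r}, {fixed.frame_id!r})"
        )

    idx = match_descriptors(des_m, des_f, cross_check=True, max_ratio=config.ratio)
    if len(idx) < config.min_matches:
        raise InsufficientFeaturesError(
            f"only {len(idx)} matches between {moving.frame_id!r} and {fixed.frame_id!r}; "
            f"need at least {config.min_matches}"
        )
    d1 = des_m[idx[:, 0]].astype(np.float64)
    d2 = des_f[idx[:, 1]].astype(np.float64)
    scores = np.linalg.norm(d1 - d2, axis=1)
    return MatchedFeatures(
        src_points=kp_m[idx[:, 0]],
        dst_points=kp_f[idx[:, 1]],
        scores=scores,
        moving_frame_id=moving.frame_id,
        fixed_frame_id=fixed.frame_id,
    )


def estimate_global_transform(
    matches: MatchedFeatures,
    kind: str = "similarity",
    config: RigidConfig | None = None,
) -> GlobalTransform:
    """Robust (RANSAC) global transform from putative matches.

    The consensus model is refit on its inliers by least squares. Estimates
    with an inlier fraction below ``config.min_inlier_fraction`` or a scale
    outside the plausibility band are rejected as registration failures.
    """
    if config is None:
        config = RigidConfig()
    if kind not in ("similarity", "affine"):
        raise ValueError(f"unknown transform kind {kind!r}")
    model_cls = SimilarityTransform if kind == "similarity" else AffineTransform
    min_samples = 3 if kind == "similarity" else 4
    if len(matches) < min_samples:
        raise RegistrationFailureError(
            f"{len(matches)} matches; {kind} estimation needs at least {min_samples}"
        )

    src_xy = matches.src_points[:, ::-1]
    dst_xy = matches.dst_points[:, ::-1]
    # collinear points leave the transform family underdetermined
    sv = np.linalg.svd(src_xy - src_xy.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-6 * max(sv[0], 1.0):
        raise RegistrationFailureError("degenerate (collinear) point geometry")
    try:
        model, inliers = ransac(
            (src_xy, dst_xy),
            model_cls,
            min_samples=min_samples,
            residual_threshold=config.residual_threshold,
            max_trials=config.max_trials,
            rng=config.seed,
        )
    except Exception as exc:  # degenerate geometry inside skimage
        raise RegistrationFailureError(f"robust estimation failed: {exc}") from exc
    if model is None or inliers is None or not np.any(inliers):
        raise RegistrationFailureError("no consensus set found")

    inlier_count = int(inliers.sum())
    if inlier_count < min_samples or inlier_count / len(matches) < config.min_inlier_fraction:
        raise RegistrationFailureError(
            f"inlier fraction {inlier_count}/{len(matches)} below "
            f"{config.min_inlier_fraction:.0%}"
        )

    keep = inliers
    refined = None
    for _ in range(3):  # refit, re-admit, refit: converges in 2-3 passes
        candidate = model_cls.from_estimate(src_xy[keep], dst_xy[keep])
        if not candidate:
            raise RegistrationFailureError("least-squares refit on inliers failed")
        refined = candidate
        resid = np.linalg.norm(refined(src_xy) - dst_xy, axis=1)
        expanded = resid <= config.refit_threshold_factor * config.residual_threshold
        if np.array_equal(expanded, keep) or expanded.sum() < min_samples:
            break
        keep = expanded
    inliers = keep
    inlier_count = int(inliers.sum())
    params = np.asarray(refined.params)
    if not np.all(np.isfinite(params)):
        raise RegistrationFailureError("non-finite transform (degenerate point geometry)")

    matrix = _rc_matrix_from_xy(refined)
    scale = float(np.sqrt(abs(np.linalg.det(matrix[:, :2]))))
    lo, hi = config.scale_band
    if not (lo <= scale <= hi):
        raise RegistrationFailureError(f"estimated scale {scale:.3f} outside [{lo}, {hi}]")

    residuals = refined.residuals(src_xy[inliers], dst_xy[inliers])
    return GlobalTransform(
        kind=kind,
        matrix=matrix,
        inlier_count=inlier_count,
        inlier_rms=float(np.sqrt(np.mean(residuals**2))),
        extras={"n_matches": len(matches)},
    )


def warp_to_reference(
    moving: FundusImage,
    transform: GlobalTransform,
    reference_shape: tuple[int, int] | None = None,
) -> FundusImage:
    """Resample the moving image onto the reference grid.

    Inverse mapping with bilinear interpolation; out-of-field pixels are 0
    and excluded by the validity mask carried in the result's metadata.
    An exact identity transform returns the pixels unchanged.
    """
    if reference_shape is None:
        reference_shape = moving.shape
    h, w = reference_shape

    if np.array_equal(transform.matrix, np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])) and (
        reference_shape == moving.shape
    ):
        return moving.with_(
            pixels=moving.pixels.copy(),
            validity_mask=moving.mask().copy(),
            frame_id=moving.frame_id,
        )

    minv = transform.inverse_matrix()
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    src_r = minv[0, 0] * rows + minv[0, 1] * cols + minv[0, 2]
    src_c = minv[1, 0] * rows + minv[1, 1] * cols + minv[1, 2]
    coords = np.stack([src_r, src_c])

    if moving.pixels.ndim == 3:
        warped = np.stack(
            [
                ndimage.map_coordinates(moving.pixels[..., k], coords, order=1, mode="constant", cval=0.0)
                for k in range(moving.pixels.shape[2])
            ],
            axis=-1,
        )
    else:
        warped = ndimage.map_coordinates(moving.pixels, coords, order=1, mode="constant", cval=0.0)

    mh, mw = moving.shape
    in_bounds = (src_r >= 0) & (src_r <= mh - 1) & (src_c >= 0) & (src_c <= mw - 1)
    src_mask = ndimage.map_coordinates(
        moving.mask().astype(np.float64), coords, order=0, mode="constant", cval=0.0
    )
    validity = in_bounds & (src_mask > 0.5)
    warped[~validity] = 0.0
    return moving.with_(pixels=warped, validity_mask=validity)
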