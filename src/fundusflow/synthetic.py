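"""Seeded synthetic fundus pairs and series with ground truth.

The study's clinical images are unavailable, so every pipeline stage is
exercised on generated data instead: a random branching vessel tree grown
from the optic disc and arcing around the fovea, drawn dark on a bright,
radially shaded, textured background inside a circular 45-degree-style field
of view. Pairs are produced by warping the reference image with a known
smooth b-spline field (optionally biased centripetally toward a contraction
center, emulating epiretinal-membrane traction and its postoperative
release) plus a known similarity jitter (camera pose/magnification change)
and noise. The generator returns the exact dense correspondence field, the
global transform, the vessel mask and the landmarks, so recovery errors are
measurable everywhere.

All randomness flows from one ``numpy`` generator seeded per case, so cases
are bit-reproducible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy import ndimage

from .bspline import BSplineLevel, BSplineTransform, control_grid_size
from .fields import DisplacementField
from .geometry import Landmarks, flip_landmarks
from .image import FundusImage
from .rigid import GlobalTransform

__all__ = [
    "VesselTreeParams",
    "WarpParams",
    "SeriesParams",
    "SyntheticCase",
    "SyntheticSeries",
    "generate_vessel_tree",
    "random_warp",
    "make_pair",
    "make_longitudinal_series",
]


@dataclass(frozen=True)
class VesselTreeParams:
    """Geometry of the generated eye and vessel tree.

    Defaults mimic a 45-degree-field photograph: circular validity mask and
    a fovea-disc distance of one third of the image width.
    """

    image_shape: tuple[int, int] = (512, 512)
    fdd_px: float | None = None          # default: image width / 3
    n_arcades: int = 7
    branching_depth: int = 3
    width_range_px: tuple[float, float] = (1.6, 4.2)
    tortuosity: float = 0.12
    noise_sigma: float = 0.01
    vessel_contrast: float = 0.55
    step_px: float = 3.0

    def resolved_fdd(self) -> float:
        return self.fdd_px if self.fdd_px is not None else self.image_shape[1] / 3.0


@dataclass(frozen=True)
class WarpParams:
    """Smooth ground-truth deformation settings."""

    amplitude_px: float = 12.0
    warp_spacing_px: float = 64.0
    center_bias: float = 0.5  # 0 = isotropic random, 1 = purely centripetal


@dataclass(frozen=True)
class SeriesParams:
    """Longitudinal study emulation: one reference (latest) image, earlier
    timepoints deformed by a shared contraction pattern of decaying amplitude
    (structural change concentrates early after surgery)."""

    n_timepoints: int = 5
    amplitudes_px: tuple[float, ...] | None = None  # one per earlier timepoint
    laterality: str = "OS"
    jitter: bool = True

    def resolved_amplitudes(self) -> tuple[float, ...]:
        if self.amplitudes_px is not None:
            return tuple(float(a) for a in self.amplitudes_px)
        base = (1.0, 0.5, 0.25, 0.1)
        n = self.n_timepoints - 1
        if n <= 4:
            return tuple(12.0 * b for b in base[:n])
        extra = tuple(12.0 * 0.1 * (0.5 ** (i + 1)) for i in range(n - 4))
        return tuple(12.0 * b for b in base) + extra


@dataclass
class SyntheticCase:
    """One moving/fixed pair with full ground truth on the fixed grid."""

    fixed_image: FundusImage
    moving_image: FundusImage
    truth_global: GlobalTransform
    truth_field: DisplacementField          # earlier -> later, on fixed grid
    truth_vessel_mask: np.ndarray
    landmarks: Landmarks
    seed: int
    params: dict = dc_field(default_factory=dict)


@dataclass
class SyntheticSeries:
    """Ordered timepoints sharing one reference (the last image)."""

    reference: FundusImage
    landmarks: Landmarks
    cases: list[SyntheticCase]              # earliest -> latest-but-one
    amplitudes_px: tuple[float, ...]
    timepoint_labels: tuple[str, ...]

    def truth_to_reference(self, i: int) -> DisplacementField:
        return self.cases[i].truth_field

    def stage_truth(self, i: int) -> np.ndarray:
        """Dense truth for the epoch timepoint i -> timepoint i+1."""
        u_a = self.cases[i].truth_field.vectors
        if i + 1 < len(self.cases):
            u_b = self.cases[i + 1].truth_field.vectors
        else:
            u_b = np.zeros_like(u_a)
        return u_a - u_b


# ---------------------------------------------------------------------------
# vessel tree image
# ---------------------------------------------------------------------------

def _rot(v: np.ndarray, ang: float) -> np.ndarray:
    ca, sa = math.cos(ang), math.sin(ang)
    return np.array([ca * v[0] - sa * v[1], sa * v[0] + ca * v[1]])


def _grow_tree(rng: np.random.Generator, params: VesselTreeParams, fovea, disc, fov_radius, center):
    """Random branching polylines from the disc arcing around the fovea.

    Returns a list of (points, width) with points an (N, 2) float array.
    """
    h, w = params.image_shape
    wmin, wmax = params.width_range_px
    branches = []
    stack = []
    for k in range(params.n_arcades):
        # arcades leave the disc fanned over all directions, thicker trunks
        ang = 2 * math.pi * (k + rng.uniform(-0.25, 0.25)) / params.n_arcades
        heading = np.array([math.sin(ang), math.cos(ang)])
        start = np.asarray(disc, dtype=float) + heading * rng.uniform(2.0, 6.0)
        sign = 1.0 if heading[0] * 1.0 >= 0 else -1.0  # keep arcing to its own side
        width = rng.uniform(0.8 * wmax, wmax)
        stack.append((start, heading, width, 0, sign))

    max_steps = int(3.2 * fov_radius / params.step_px)
    faz_radius = 0.12 * np.linalg.norm(np.asarray(disc, float) - np.asarray(fovea, float))
    macular_radius = (2.0 / 3.0) * faz_radius / 0.12  # = (2/3) FDD
    while stack:
        pos, heading, width, depth, sign = stack.pop()
        pts = [pos.copy()]
        children = 0
        macular_twig_spawned = False
        steps = int(max_steps * rng.uniform(0.45, 1.0) * (0.75**depth))
        # trunks arc firmly around the macula; deeper branches wander inward,
        # stopping at the foveal avascular zone
        arc_weight = 0.12 if depth == 0 else 0.04
        for _ in range(steps):
            radial = pos - np.asarray(fovea, dtype=float)
            rnorm = np.linalg.norm(radial)
            if rnorm < faz_radius:
                break
            if rnorm > 1e-6:
                tangent = sign * np.array([radial[1], -radial[0]]) / rnorm
                # blend: follow current heading, arc around the fovea
                heading = (1.0 - arc_weight) * heading + arc_weight * tangent
                heading /= np.linalg.norm(heading)
            heading = _rot(heading, rng.normal(0.0, params.tortuosity))
            pos = pos + heading * params.step_px
            if np.linalg.norm(pos - center) > 0.97 * fov_radius:
                break
            if not (0 <= pos[0] < h and 0 <= pos[1] < w):
                break
            pts.append(pos.copy())
            # every trunk skirting the macula sends one twig inward: real
            # maculae are vascularized up to the foveal avascular zone
            if (
                depth == 0
                and not macular_twig_spawned
                and len(pts) > 10
                and macular_radius < rnorm < 1.8 * macular_radius
                and rng.uniform() < 0.12
            ):
                macular_twig_spawned = True
                inward = -radial / max(rnorm, 1e-9)
                stack.append(
                    (
                        pos.copy(),
                        _rot(inward, rng.normal(0.0, 0.3)),
                        max(wmin, width * rng.uniform(0.5, 0.7)),
                        params.branching_depth,  # twigs do not branch further
                        sign,
                    )
                )
            if (
                depth < params.branching_depth
                and children < 2
                and len(pts) > 15
                and rng.uniform() < 0.015
            ):
                children += 1
                macular_zone = rnorm < 8.3 * faz_radius  # within ~1.5 macular radii
                if macular_zone and rng.uniform() < 0.6:
                    # macular twig: head toward the fovea (real maculae are
                    # vascularized up to the foveal avascular zone)
                    inward = -radial / max(rnorm, 1e-9)
                    child_heading = _rot(inward, rng.normal(0.0, 0.35))
                else:
                    child_heading = _rot(heading, rng.choice([-1.0, 1.0]) * rng.uniform(0.4, 0.9))
                child_width = max(wmin, width * rng.uniform(0.6, 0.8))
                stack.append((pos.copy(), child_heading, child_width, depth + 1, sign))
        if len(pts) > 2:
            branches.append((np.asarray(pts), max(wmin, width)))
    return branches


def generate_vessel_tree(
    seed: int,
    params: VesselTreeParams | None = None,
    laterality: str = "OS",
    timepoint_label: str = "ref",
    frame_id: str | None = None,
):
    """Generate one fundus-like image, its true vessel mask and landmarks.

    Vessels are dark with a Gaussian cross-profile and width decreasing with
    branching depth; the background is bright with radial illumination
    falloff, a brighter disc, a darker macula, low-frequency texture and
    additive Gaussian noise. Deterministic per seed.
    """
    params = params or VesselTreeParams()
    h, w = params.image_shape
    if h < 256 or w < 256:
        raise ValueError("image must be at least 256x256")
    fdd = params.resolved_fdd()
    if fdd < min(h, w) / 4:
        raise ValueError("fovea-disc distance too small for the frame")
    if params.width_range_px[1] >= params.step_px * 4:
        raise ValueError("vessel width incompatible with centerline step")
    rng = np.random.default_rng(seed)

    center = np.array([h / 2.0, w / 2.0])
    fov_radius = 0.495 * min(h, w)
    tilt = math.radians(rng.uniform(-8.0, 8.0))
    fovea = (h / 2.0 + rng.uniform(-6, 6), w / 2.0 - 0.45 * fdd)
    disc = (fovea[0] - fdd * math.sin(tilt), fovea[1] + fdd * math.cos(tilt))
    landmarks = Landmarks(
        fovea_center=fovea, disc_center=disc,
        frame_id=frame_id or f"synthetic-{seed}", laterality=laterality,
    )

    branches = _grow_tree(rng, params, fovea, disc, fov_radius, center)

    # rasterize centerlines, remembering the local width
    width_map = np.zeros((h, w), dtype=np.float64)
    for pts, width in branches:
        # densify the polyline so centerline pixels are contiguous
        seg = np.diff(pts, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        n_sub = np.maximum(1, np.ceil(seglen).astype(int))
        dense_pts = [pts[0]]
        for p0, d, n in zip(pts[:-1], seg, n_sub):
            for t in range(1, n + 1):
                dense_pts.append(p0 + d * t / n)
        dp = np.asarray(dense_pts)
        rr = np.clip(np.round(dp[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.round(dp[:, 1]).astype(int), 0, w - 1)
        width_map[rr, cc] = np.maximum(width_map[rr, cc], width)

    on_center = width_map > 0
    dist, (ir, ic) = ndimage.distance_transform_edt(~on_center, return_indices=True)
    local_width = width_map[ir, ic]
    truth_mask = dist <= local_width / 2.0
    sigma = np.maximum(local_width / 2.0, 1e-6)
    soft = np.exp(-0.5 * (dist / sigma) ** 2)
    soft[dist > 3.0 * local_width] = 0.0

    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    rho = np.hypot(rows - center[0], cols - center[1])
    background = 0.85 - 0.25 * (rho / fov_radius) ** 2
    d_disc = np.hypot(rows - disc[0], cols - disc[1])
    background += 0.12 * np.exp(-((d_disc / (0.35 * fdd)) ** 2))
    d_fov = np.hypot(rows - fovea[0], cols - fovea[1])
    background -= 0.08 * np.exp(-((d_fov / (0.5 * fdd)) ** 2))
    texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), 18.0)
    tex_scale = texture.std()
    if tex_scale > 0:
        background += 0.03 * texture / tex_scale

    img = background * (1.0 - params.vessel_contrast * soft)
    img += rng.normal(0.0, params.noise_sigma, size=(h, w))
    fov_mask = rho <= fov_radius
    img[~fov_mask] = 0.0
    truth_mask &= fov_mask
    img = np.clip(img, 0.0, 1.0)

    image = FundusImage(
        pixels=img,
        laterality=laterality,
        timepoint_label=timepoint_label,
        frame_id=landmarks.frame_id,
        validity_mask=fov_mask,
    )
    return image, truth_mask, landmarks


# ---------------------------------------------------------------------------
# ground-truth warps
# ---------------------------------------------------------------------------

def random_warp(
    seed: int,
    shape: tuple[int, int],
    params: WarpParams | None = None,
    contraction_center: tuple[float, float] | None = None,
    weight_mask: "np.ndarray | None" = None,
):
    """Random fold-free b-spline deformation with known dense field.

    Smooth random control-point displacements are blended with a centripetal
    component toward ``contraction_center`` (``center_bias`` sets the mix)
    and rescaled so the dense field's maximum magnitude equals
    ``amplitude_px`` exactly. Returns ``(transform, dense_field)`` where the
    dense field is the resampling displacement ``w`` in
    ``moving(y) = fixed(y + w(y))``.
    """
    params = params or WarpParams()
    h, w = shape
    spacing = float(params.warp_spacing_px)
    amp = float(params.amplitude_px)
    if amp >= spacing / 2.0:
        raise ValueError(
            f"amplitude {amp} too large for spacing {spacing} (fold risk); need amplitude < spacing/2"
        )
    rng = np.random.default_rng(seed)
    gr = control_grid_size(h, spacing)
    gc = control_grid_size(w, spacing)

    coeffs = ndimage.gaussian_filter(rng.standard_normal((gr, gc, 2)), sigma=(1.0, 1.0, 0.0))
    if contraction_center is None:
        contraction_center = (h / 2.0, w / 2.0)
    ctr = np.asarray(contraction_center, dtype=float)
    pr = (np.arange(gr) - 1.0) * spacing
    pc = (np.arange(gc) - 1.0) * spacing
    pos = np.stack(np.meshgrid(pr, pc, indexing="ij"), axis=-1)
    radial = ctr[None, None, :] - pos
    rnorm = np.linalg.norm(radial, axis=-1, keepdims=True)
    envelope = np.exp(-((rnorm / (0.45 * min(h, w))) ** 2))
    centripetal = np.where(rnorm > 1e-9, radial / np.maximum(rnorm, 1e-9), 0.0) * envelope
    rms = np.sqrt((coeffs**2).mean()) or 1.0
    coeffs = (1.0 - params.center_bias) * coeffs / rms + params.center_bias * centripetal

    if amp == 0.0:
        zero = BSplineTransform(
            levels=[BSplineLevel(spacing, np.zeros((gr, gc, 2)))], domain_shape=(h, w)
        )
        return zero, np.zeros((h, w, 2))

    # remove the warp's net similarity component so the split between global
    # (similarity) and non-rigid motion is canonical: any rigid-like content
    # here would be absorbed by the pipeline's global stage and show up as a
    # spurious mismatch against this ground truth. Cubic b-splines reproduce
    # affine fields exactly, so the projection is exact at coefficient level.
    transform = BSplineTransform(levels=[BSplineLevel(spacing, coeffs)], domain_shape=(h, w))
    dense = transform.dense_displacement()
    a, b = _fit_similarity_component(dense, weight_mask)
    zi = pos[..., 0] + 1j * pos[..., 1]
    sim = (a - 1.0) * zi + b
    coeffs = coeffs - np.stack([sim.real, sim.imag], axis=-1)

    transform = BSplineTransform(levels=[BSplineLevel(spacing, coeffs)], domain_shape=(h, w))
    dense = transform.dense_displacement()
    peak = np.hypot(dense[..., 0], dense[..., 1]).max()
    if peak <= 0:
        raise ValueError("degenerate random warp (zero field)")
    scale = amp / peak
    coeffs = coeffs * scale
    dense = dense * scale
    transform = BSplineTransform(levels=[BSplineLevel(spacing, coeffs)], domain_shape=(h, w))

    _check_fold_free(dense)
    return transform, dense


def _fit_similarity_component(dense: np.ndarray, weight_mask: np.ndarray | None = None, step: int = 4):
    """Least-squares similarity content of a dense field.

    With pixels as complex numbers z = row + i col, a similarity map is
    ``z -> a z + b``; returns (a, b) minimizing |w(z) - ((a - 1) z + b)|^2
    over a subsampled grid (restricted to ``weight_mask`` when given, e.g.
    the vessel pixels that drive feature matching).
    """
    h, w = dense.shape[:2]
    rows, cols = np.mgrid[0:h:step, 0:w:step].astype(np.float64)
    z = (rows + 1j * cols).ravel()
    wz = (dense[::step, ::step, 0] + 1j * dense[::step, ::step, 1]).ravel()
    if weight_mask is not None:
        sel = weight_mask[::step, ::step].ravel()
        if np.count_nonzero(sel) >= 16:
            z = z[sel]
            wz = wz[sel]
    # normal equations for [a-1, b]
    n = z.size
    szz = np.vdot(z, z)
    sz = z.sum()
    rhs1 = np.vdot(z, wz)
    rhs2 = wz.sum()
    det = szz * n - np.conj(sz) * sz
    am1 = (rhs1 * n - np.conj(sz) * rhs2) / det
    b = (szz * rhs2 - sz * rhs1) / det
    return am1 + 1.0, b


def _check_fold_free(dense: np.ndarray, n_samples: int = 100) -> None:
    """Verify det(I + grad w) > 0 on a subsampled grid."""
    h, w = dense.shape[:2]
    g00, g01 = np.gradient(dense[..., 0])
    g10, g11 = np.gradient(dense[..., 1])
    det = (1.0 + g00) * (1.0 + g11) - g01 * g10
    rs = np.linspace(0, h - 1, n_samples).astype(int)
    cs = np.linspace(0, w - 1, n_samples).astype(int)
    sub = det[np.ix_(rs, cs)]
    if sub.min() <= 0:
        raise ValueError(f"warp folds (min Jacobian determinant {sub.min():.3f})")


def invert_resampling_warp(dense_w: np.ndarray, n_iter: int = 15) -> np.ndarray:
    """Dense tissue-motion field from the resampling warp.

    With ``moving(y) = fixed(y + w(y))``, tissue visible at fixed-grid pixel
    ``x`` sat at moving position ``y = phi^{-1}(x)`` where
    ``phi(y) = y + w(y)``. The earlier->later displacement stored at ``x`` is
    ``u(x) = x - phi^{-1}(x)``; the inverse is found by the fixed-point
    iteration ``y <- x - w(y)`` (contractive because |grad w| < 1 for
    fold-free warps).
    """
    h, w = dense_w.shape[:2]
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    yr, yc = rows.copy(), cols.copy()
    for _ in range(n_iter):
        wr = ndimage.map_coordinates(dense_w[..., 0], [yr, yc], order=1, mode="nearest")
        wc = ndimage.map_coordinates(dense_w[..., 1], [yr, yc], order=1, mode="nearest")
        yr = rows - wr
        yc = cols - wc
    return np.stack([rows - yr, cols - yc], axis=-1)


def _random_similarity(rng: np.random.Generator, shape: tuple[int, int]) -> GlobalTransform:
    """Similarity jitter: rotation <= 3 deg, scale 0.95-1.05, translation <= 15 px,
    about the image center. Matrix maps moving coords -> fixed coords."""
    h, w = shape
    ang = math.radians(rng.uniform(-3.0, 3.0))
    s = rng.uniform(0.95, 1.05)
    t = rng.uniform(-15.0, 15.0, size=2)
    ctr = np.array([h / 2.0, w / 2.0])
    rot = s * np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
    offset = ctr + t - rot @ ctr
    return GlobalTransform(kind="similarity", matrix=np.column_stack([rot, offset]))


def _resample(img: np.ndarray, coords_r: np.ndarray, coords_c: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(img, [coords_r, coords_c], order=1, mode="constant", cval=0.0)


def make_pair(
    seed: int,
    tree_params: VesselTreeParams | None = None,
    warp_params: WarpParams | None = None,
    laterality: str = "OS",
    jitter: bool = True,
    check: bool = True,
) -> SyntheticCase:
    """One moving/fixed pair: the fixed (reference, later) image plus an
    earlier image deformed by a known b-spline warp and similarity jitter."""
    tree_params = tree_params or VesselTreeParams()
    warp_params = warp_params or WarpParams()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9151]))

    fixed, truth_mask, landmarks = generate_vessel_tree(
        seed, tree_params, laterality="OS", timepoint_label="ref"
    )
    h, w = fixed.shape
    fdd = landmarks.fdd
    # membrane center within the macular circle (radius 2/3 FDD): surgical
    # traction is a macular phenomenon, so displacement concentrates there
    ctr_offset = rng.uniform(-0.2, 0.2, size=2) * fdd
    contraction_center = (landmarks.fovea_center[0] + ctr_offset[0], landmarks.fovea_center[1] + ctr_offset[1])
    from scipy.ndimage import binary_dilation
    feature_zone = binary_dilation(truth_mask, iterations=4)
    _, dense_w = random_warp(seed + 1, (h, w), warp_params, contraction_center, weight_mask=feature_zone)

    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    mov_aligned = _resample(fixed.pixels, rows + dense_w[..., 0], cols + dense_w[..., 1])
    mov_mask = _resample(fixed.mask().astype(float), rows + dense_w[..., 0], cols + dense_w[..., 1]) > 0.5

    truth_global = _random_similarity(rng, (h, w)) if jitter else GlobalTransform.identity()
    m = truth_global.matrix
    tr = m[0, 0] * rows + m[0, 1] * cols + m[0, 2]
    tc = m[1, 0] * rows + m[1, 1] * cols + m[1, 2]
    mov = _resample(mov_aligned, tr, tc)
    mov_mask = _resample(mov_mask.astype(float), tr, tc) > 0.5
    mov = np.clip(mov + rng.normal(0.0, tree_params.noise_sigma / 2.0, size=mov.shape), 0.0, 1.0)
    mov[~mov_mask] = 0.0

    truth_field = DisplacementField(
        vectors=invert_resampling_warp(dense_w),
        reference_frame_id=fixed.frame_id,
        validity_mask=fixed.mask().copy(),
        provenance={"kind": "synthetic_truth", "seed": seed},
    )

    moving = FundusImage(
        pixels=mov,
        laterality="OS",
        timepoint_label="pre",
        frame_id=f"{fixed.frame_id}-moving",
        validity_mask=mov_mask,
    )
    case_landmarks = landmarks

    if laterality == "OD":
        fixed, case_landmarks, truth_field = _mirror_case(fixed, case_landmarks, truth_field)
        moving = moving.with_(
            pixels=moving.pixels[:, ::-1].copy(),
            validity_mask=moving.mask()[:, ::-1].copy(),
            laterality="OD",
        )
        fixed = fixed.with_(laterality="OD")
        truth_mask = truth_mask[:, ::-1].copy()
        mm = truth_global.matrix
        f = np.array([[1.0, 0.0, 0.0], [0.0, -1.0, w - 1.0]])
        finv_full = np.vstack([f, [0, 0, 1]])
        full = np.vstack([mm, [0, 0, 1]])
        mirrored = finv_full @ full @ np.linalg.inv(finv_full)
        truth_global = GlobalTransform(kind=truth_global.kind, matrix=mirrored[:2])

    case = SyntheticCase(
        fixed_image=fixed,
        moving_image=moving,
        truth_global=truth_global,
        truth_field=truth_field,
        truth_vessel_mask=truth_mask,
        landmarks=case_landmarks,
        seed=seed,
        params={"tree": tree_params, "warp": warp_params, "jitter": jitter},
    )
    if check:
        _check_case(case, dense_w if laterality == "OS" else None)
    return case


def _mirror_case(fixed: FundusImage, landmarks: Landmarks, field: DisplacementField):
    w = fixed.shape[1]
    fixed2 = fixed.with_(
        pixels=fixed.pixels[:, ::-1].copy(),
        validity_mask=fixed.mask()[:, ::-1].copy(),
        laterality="OD",
    )
    lm2 = replace(flip_landmarks(landmarks, w), laterality="OD")
    vec = field.vectors[:, ::-1].copy()
    vec[..., 1] *= -1.0
    field2 = DisplacementField(
        vectors=vec,
        reference_frame_id=field.reference_frame_id,
        validity_mask=field.validity_mask[:, ::-1].copy(),
        provenance=dict(field.provenance),
    )
    return fixed2, lm2, field2


def _check_case(case: SyntheticCase, dense_w: np.ndarray | None) -> None:
    """Generation-time invariant: pushing the fixed image through the truth
    transforms reproduces the moving image up to interpolation + noise."""
    if dense_w is None:
        return
    fixed = case.fixed_image
    h, w = fixed.shape
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    m = case.truth_global.matrix
    tr = m[0, 0] * rows + m[0, 1] * cols + m[0, 2]
    tc = m[1, 0] * rows + m[1, 1] * cols + m[1, 2]
    wr = _resample(dense_w[..., 0], tr, tc)
    wc = _resample(dense_w[..., 1], tr, tc)
    pred = _resample(fixed.pixels, tr + wr, tc + wc)
    both = case.moving_image.mask() & (_resample(fixed.mask().astype(float), tr + wr, tc + wc) > 0.5)
    both = ndimage.binary_erosion(both, iterations=3)
    err = np.abs(pred[both] - case.moving_image.pixels[both]).mean()
    if err >= 0.02:
        raise AssertionError(f"synthetic case self-check failed (mean abs err {err:.4f})")


def make_longitudinal_series(
    seed: int,
    params: SeriesParams | None = None,
    tree_params: VesselTreeParams | None = None,
    warp_params: WarpParams | None = None,
) -> SyntheticSeries:
    """Series of ``n_timepoints`` images sharing the last one as reference.

    Earlier timepoints are the reference deformed by one shared b-spline
    contraction pattern scaled by non-increasing amplitudes (largest for the
    earliest image), each with its own similarity jitter and noise.
    """
    params = params or SeriesParams()
    tree_params = tree_params or VesselTreeParams()
    warp_params = warp_params or WarpParams()
    if params.n_timepoints < 2:
        raise ValueError("a series needs at least 2 timepoints")
    amplitudes = params.resolved_amplitudes()
    if len(amplitudes) != params.n_timepoints - 1:
        raise ValueError("need one amplitude per earlier timepoint")
    if any(b > a for a, b in zip(amplitudes, amplitudes[1:])):
        raise ValueError("amplitudes must be non-increasing toward the reference")

    fixed, truth_mask, landmarks = generate_vessel_tree(
        seed, tree_params, laterality="OS", timepoint_label="ref"
    )
    h, w = fixed.shape
    rng = np.random.default_rng(np.random.SeedSequence([seed, 40427]))
    fdd = landmarks.fdd
    ctr_offset = rng.uniform(-0.2, 0.2, size=2) * fdd
    contraction_center = (landmarks.fovea_center[0] + ctr_offset[0], landmarks.fovea_center[1] + ctr_offset[1])

    amax = amplitudes[0]
    if amax > 0:
        from scipy.ndimage import binary_dilation
        _, dense_unit = random_warp(
            seed + 1,
            (h, w),
            WarpParams(amplitude_px=amax, warp_spacing_px=warp_params.warp_spacing_px,
                       center_bias=warp_params.center_bias),
            contraction_center,
            weight_mask=binary_dilation(truth_mask, iterations=4),
        )
        dense_unit = dense_unit / amax
    else:
        dense_unit = np.zeros((h, w, 2))

    labels_default = ("pre", "m01", "m04", "m10", "m22")
    if params.n_timepoints <= 5:
        labels = labels_default[5 - params.n_timepoints :]
    else:
        labels = tuple(f"t{i:02d}" for i in range(params.n_timepoints))

    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    cases = []
    for i, amp in enumerate(amplitudes):
        dense_w = dense_unit * amp
        mov_aligned = _resample(fixed.pixels, rows + dense_w[..., 0], cols + dense_w[..., 1])
        mov_mask = _resample(fixed.mask().astype(float), rows + dense_w[..., 0], cols + dense_w[..., 1]) > 0.5
        g = _random_similarity(rng, (h, w)) if params.jitter else GlobalTransform.identity()
        m = g.matrix
        tr = m[0, 0] * rows + m[0, 1] * cols + m[0, 2]
        tc = m[1, 0] * rows + m[1, 1] * cols + m[1, 2]
        mov = _resample(mov_aligned, tr, tc)
        mov_mask = _resample(mov_mask.astype(float), tr, tc) > 0.5
        mov = np.clip(mov + rng.normal(0.0, tree_params.noise_sigma / 2.0, size=mov.shape), 0.0, 1.0)
        mov[~mov_mask] = 0.0
        truth_field = DisplacementField(
            vectors=invert_resampling_warp(dense_w) if amp > 0 else np.zeros((h, w, 2)),
            reference_frame_id=fixed.frame_id,
            validity_mask=fixed.mask().copy(),
            provenance={"kind": "synthetic_truth", "seed": seed, "timepoint": labels[i]},
        )
        cases.append(
            SyntheticCase(
                fixed_image=fixed,
                moving_image=FundusImage(
                    pixels=mov,
                    laterality=params.laterality if params.laterality == "OS" else "OS",
                    timepoint_label=labels[i],
                    frame_id=f"{fixed.frame_id}-{labels[i]}",
                    validity_mask=mov_mask,
                ),
                truth_global=g,
                truth_field=truth_field,
                truth_vessel_mask=truth_mask,
                landmarks=landmarks,
                seed=seed,
                params={"amplitude_px": amp},
            )
        )

    series = SyntheticSeries(
        reference=fixed,
        landmarks=landmarks,
        cases=cases,
        amplitudes_px=amplitudes,
        timepoint_labels=labels,
    )
    if params.laterality == "OD":
        series = _mirror_series(series)
    return series


def _mirror_series(series: SyntheticSeries) -> SyntheticSeries:
    w = series.reference.shape[1]
    ref2, lm2, _ = _mirror_case(
        series.reference, series.landmarks,
        DisplacementField(np.zeros((*series.reference.shape, 2)), series.reference.frame_id),
    )
    cases2 = []
    for case in series.cases:
        fixed2, clm2, tf2 = _mirror_case(case.fixed_image, case.landmarks, case.truth_field)
        mov2 = case.moving_image.with_(
            pixels=case.moving_image.pixels[:, ::-1].copy(),
            validity_mask=case.moving_image.mask()[:, ::-1].copy(),
            laterality="OD",
        )
        mm = np.vstack([case.truth_global.matrix, [0, 0, 1]])
        f = np.vstack([[1.0, 0.0, 0.0], [0.0, -1.0, w - 1.0], [0, 0, 1]])
        g2 = GlobalTransform(case.truth_global.kind, (f @ mm @ np.linalg.inv(f))[:2])
        cases2.append(
            SyntheticCase(
                fixed_image=fixed2,
                moving_image=mov2,
                truth_global=g2,
                truth_field=tf2,
                truth_vessel_mask=case.truth_vessel_mask[:, ::-1].copy(),
                landmarks=clm2,
                seed=case.seed,
                params=case.params,
            )
        )
    return SyntheticSeries(
        reference=ref2,
        landmarks=lm2,
        cases=cases2,
        amplitudes_px=series.amplitudes_px,
        timepoint_labels=series.timepoint_labels,
    )
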