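"""B-spline FFD transform, NCC similarity, registration and densification."""
import numpy as np
import pytest

import fundusflow as ff
from fundusflow.bspline import (
    BSplineLevel,
    BSplineTransform,
    RegistrationConfig,
    basis_matrix,
    control_grid_size,
    densify,
    ncc,
    register_bspline,
)
from fundusflow.errors import NoSignalError, ShapeMismatchError
from fundusflow.synthetic import invert_resampling_warp
from fundusflow.vessels import VesselProbabilityMap, vesselness_map
from scipy import ndimage


class TestNcc:
    def test_self_correlation_is_one(self):
        a = np.random.default_rng(0).uniform(size=(50, 50))
        assert ncc(a, a) == pytest.approx(1.0)

    def test_anticorrelation_is_minus_one(self):
        a = np.random.default_rng(1).uniform(size=(50, 50))
        assert ncc(a, 1.0 - a) == pytest.approx(-1.0)

    def test_independent_noise_nearly_uncorrelated(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(size=(100, 100))
        b = rng.uniform(size=(100, 100))
        assert abs(ncc(a, b)) < 0.05

    def test_constant_inputs_zero_by_convention(self):
        a = np.full((20, 20), 0.5)
        assert ncc(a, a) == 0.0

    def test_empty_support_rejected(self):
        a = np.zeros((10, 10))
        with pytest.raises(ValueError):
            ncc(a, a, support_mask=np.zeros((10, 10), dtype=bool))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeMismatchError):
            ncc(np.zeros((10, 10)), np.zeros((10, 11)))


class TestTransform:
    def test_partition_of_unity(self):
        for n, h in [(128, 16.0), (200, 37.5)]:
            b = basis_matrix(n, h)
            assert np.allclose(b.sum(axis=0), 1.0, atol=1e-12)

    def test_constant_coefficients_give_constant_field(self):
        shape = (100, 120)
        spacing = 24.0
        gr = control_grid_size(shape[0], spacing)
        gc = control_grid_size(shape[1], spacing)
        coeffs = np.zeros((gr, gc, 2))
        coeffs[..., 1] = 5.0
        t = BSplineTransform([BSplineLevel(spacing, coeffs)], shape)
        u = t.dense_displacement()
        assert np.allclose(u[..., 1], 5.0, atol=1e-6)
        assert np.allclose(u[..., 0], 0.0, atol=1e-6)

    def test_zero_coefficients_are_identity(self):
        t = BSplineTransform.identity((64, 64), 16.0)
        fld = densify(t)
        assert np.all(fld.vectors == 0.0)

    def test_levels_combine_additively(self):
        shape = (80, 80)
        t1 = BSplineTransform.identity(shape, 40.0)
        t1.levels[0].coefficients[..., 0] = 2.0
        t2 = BSplineTransform.identity(shape, 20.0)
        t2.levels[0].coefficients[..., 0] = 1.0
        both = BSplineTransform(levels=t1.levels + t2.levels, domain_shape=shape)
        assert np.allclose(both.dense_displacement()[..., 0], 3.0, atol=1e-6)


def test_ffd_evaluation_matches_simpleitk():
    """Independent oracle: our tensor-product cubic FFD must agree with
    SimpleITK's BSplineTransform for identical coefficients."""
    import SimpleITK as sitk

    shape = (96, 80)
    spacing = 20.0
    gr, gc = control_grid_size(shape[0], spacing), control_grid_size(shape[1], spacing)
    coeffs = np.random.default_rng(0).normal(0, 3, (gr, gc, 2))
    u = BSplineTransform([BSplineLevel(spacing, coeffs)], shape).dense_displacement()

    bs = sitk.BSplineTransform(2, 3)
    bs.SetTransformDomainOrigin((0.0, 0.0))
    bs.SetTransformDomainPhysicalDimensions(((gc - 3) * spacing, (gr - 3) * spacing))
    bs.SetTransformDomainMeshSize((gc - 3, gr - 3))
    bs.SetParameters(
        np.concatenate([coeffs[..., 1].ravel(), coeffs[..., 0].ravel()]).tolist()
    )
    for r in range(0, shape[0], 7):
        for c in range(0, shape[1], 7):
            x, y = bs.TransformPoint((float(c), float(r)))
            assert abs((y - r) - u[r, c, 0]) < 1e-10
            assert abs((x - c) - u[r, c, 1]) < 1e-10


@pytest.fixture(scope="module")
def vessel_map_pair():
    """Fixed vesselness map plus a copy warped by a known smooth field."""
    img, truth_mask, lm = ff.generate_vessel_tree(
        42, ff.VesselTreeParams(image_shape=(384, 384))
    )
    fixed = vesselness_map(img)
    _, dense_w = ff.random_warp(
        7, img.shape, ff.WarpParams(amplitude_px=12.0, warp_spacing_px=64.0),
        contraction_center=lm.fovea_center,
    )
    rows, cols = np.mgrid[0 : img.shape[0], 0 : img.shape[1]].astype(float)
    mov_values = ndimage.map_coordinates(
        fixed.values, [rows + dense_w[..., 0], cols + dense_w[..., 1]], order=1
    )
    moving = VesselProbabilityMap(np.clip(mov_values, 0, 1), "warped", fixed.validity_mask)
    truth_u = invert_resampling_warp(dense_w)
    return moving, fixed, truth_u, truth_mask, lm


class TestRegisterBspline:
    def test_identity_pair_stays_near_identity(self, vessel_map_pair):
        _, fixed, _, _, _ = vessel_map_pair
        t, report = register_bspline(fixed, fixed)
        u = t.dense_displacement()
        assert np.hypot(u[..., 0], u[..., 1]).mean() < 0.1
        assert report.final_ncc >= 0.999

    def test_known_warp_recovery(self, vessel_map_pair):
        moving, fixed, truth_u, truth_mask, lm = vessel_map_pair
        config = RegistrationConfig(level_spacings=(lm.fdd / 2, lm.fdd / 4, lm.fdd / 8))
        t, report = register_bspline(moving, fixed, config)
        recovered = -densify(t).vectors  # pull-back -> tissue motion
        err = np.hypot(*(recovered - truth_u).transpose(2, 0, 1))
        assert err[truth_mask].mean() <= 2.5
        assert report.final_ncc >= report.initial_ncc  # similarity monotonicity

    def test_no_signal_rejected(self):
        zero = VesselProbabilityMap(np.zeros((96, 96)), "z")
        with pytest.raises(NoSignalError):
            register_bspline(zero, zero)

    def test_inverse_consistency(self, vessel_map_pair):
        """A->B then B->A should roughly cancel (weak inverse consistency)."""
        moving, fixed, truth_u, truth_mask, lm = vessel_map_pair
        config = RegistrationConfig(level_spacings=(lm.fdd / 2, lm.fdd / 4, lm.fdd / 8))
        t_ab, _ = register_bspline(moving, fixed, config)
        t_ba, _ = register_bspline(fixed, moving, config)
        u_ab = t_ab.dense_displacement()
        u_ba = t_ba.dense_displacement()
        h, w = fixed.shape
        rows, cols = np.mgrid[0:h, 0:w].astype(float)
        comp_r = u_ab[..., 0] + ndimage.map_coordinates(
            u_ba[..., 0], [rows + u_ab[..., 0], cols + u_ab[..., 1]], order=1
        )
        comp_c = u_ab[..., 1] + ndimage.map_coordinates(
            u_ba[..., 1], [rows + u_ab[..., 0], cols + u_ab[..., 1]], order=1
        )
        amp = np.hypot(*truth_u.transpose(2, 0, 1)).max()
        assert np.hypot(comp_r, comp_c)[truth_mask].mean() < 0.2 * amp

    def test_config_requires_decreasing_spacings(self):
        with pytest.raises(ValueError):
            RegistrationConfig(level_spacings=(16.0, 32.0))
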