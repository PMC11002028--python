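"""Macular 24-sector grid, summaries, quadrants, longitudinal arithmetic."""
import math

import numpy as np
import pytest

import fundusflow as ff
from fundusflow.errors import FrameMismatchError
from fundusflow.fields import DisplacementField
from fundusflow.sectors import (
    QUADRANT_SCHEMES,
    RING_NAMES,
    WEDGE_NAMES,
    between_timepoints,
    build_sector_grid,
    group_quadrants,
    summarize_field,
)

LM = ff.Landmarks(fovea_center=(256.0, 200.0), disc_center=(256.0, 500.0), frame_id="g")
SHAPE = (512, 512)


@pytest.fixture(scope="module")
def grid():
    return build_sector_grid(LM, SHAPE)


def brute_force_labels(landmarks, shape):
    """Independent straight-line reimplementation of the two rules (ring by
    radius, wedge by angle from the nasal axis), scalar math throughout."""
    fr, fc = landmarks.fovea_center
    dr_, dc_ = landmarks.disc_center
    fdd = math.hypot(dr_ - fr, dc_ - fc)
    radius = 2.0 * fdd / 3.0
    nr, nc = (dr_ - fr) / fdd, (dc_ - fc) / fdd
    sr, sc = -nc, nr
    if sr > 0:
        sr, sc = nc, -nr
    out = np.zeros(shape, dtype=int)
    for r in range(shape[0]):
        for c in range(shape[1]):
            dr = r - fr
            dc = c - fc
            dist = math.hypot(dr, dc)
            if dist > radius:
                continue
            if dist < radius / 3.0:
                ring = 0
            elif dist < 2.0 * radius / 3.0:
                ring = 1
            else:
                ring = 2
            theta = math.degrees(math.atan2(dr * sr + dc * sc, dr * nr + dc * nc)) % 360.0
            wedge = min(int(theta // 45.0), 7)
            out[r, c] = ring * 8 + wedge + 1
    return out


class TestGrid:
    def test_exactly_24_labels(self, grid):
        labels = np.unique(grid.label_map)
        assert set(labels) == set(range(25))

    def test_radius_is_two_thirds_fdd(self, grid):
        assert grid.radius == pytest.approx(2.0 * LM.fdd / 3.0, abs=1e-9)

    def test_fovea_pixel_in_central_snn(self, grid):
        sid = grid.label_map[256, 200]
        assert grid.ring_of(sid) == "central_fovea"
        assert grid.wedge_of(sid) == "SNN"  # angle 0 boundary convention

    def test_brute_force_oracle_equivalence(self, grid):
        oracle = brute_force_labels(LM, SHAPE)
        assert np.array_equal(oracle, grid.label_map)

    def test_partition_and_ring_area_ratio(self, grid):
        counts = np.bincount(grid.label_map.ravel(), minlength=25)[1:]
        assert counts.sum() == np.count_nonzero(grid.label_map)
        ring_areas = [counts[i * 8 : (i + 1) * 8].sum() for i in range(3)]
        total = sum(ring_areas)
        for area, frac in zip(ring_areas, (1 / 9, 3 / 9, 5 / 9)):  # annuli 1:3:5
            assert area / total == pytest.approx(frac, rel=0.02)

    def test_clipped_circle_warns(self):
        lm = ff.Landmarks((40.0, 100.0), (40.0, 400.0), frame_id="c")
        with pytest.warns(UserWarning, match="clipped"):
            build_sector_grid(lm, (512, 512))

    def test_rigid_rotation_leaves_magnitudes_invariant(self):
        """Rotating landmarks and field together must not change standardized
        magnitudes, and only boundary pixels may change sector."""
        ang = math.radians(30.0)
        ctr = (256.0, 256.0)

        def rot_pt(p):
            dr, dc = p[0] - ctr[0], p[1] - ctr[1]
            return (
                ctr[0] + math.cos(ang) * dr - math.sin(ang) * dc,
                ctr[1] + math.sin(ang) * dr + math.cos(ang) * dc,
            )

        lm2 = ff.Landmarks(rot_pt(LM.fovea_center), rot_pt(LM.disc_center), frame_id="g")
        grid1 = build_sector_grid(LM, SHAPE)
        grid2 = build_sector_grid(lm2, SHAPE)

        rng = np.random.default_rng(5)
        const = rng.normal(size=2)
        vec1 = np.broadcast_to(const, (*SHAPE, 2)).copy()
        rot = np.array(
            [[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]]
        )
        vec2 = np.broadcast_to(rot @ const, (*SHAPE, 2)).copy()
        s1 = summarize_field(DisplacementField(vec1, "g"), grid1)
        s2 = summarize_field(DisplacementField(vec2, "g"), grid2)
        for sid in range(1, 25):
            assert s1.std_magnitude(sid) == pytest.approx(s2.std_magnitude(sid), abs=1e-6)
            assert s1.direction_deg(sid) == pytest.approx(s2.direction_deg(sid), abs=1e-6)


class TestSummaries:
    def test_uniform_field_conservation(self, grid):
        c = np.array([2.5, -1.0])
        fld = DisplacementField(np.broadcast_to(c, (*SHAPE, 2)).copy(), "g")
        s = summarize_field(fld, grid)
        expected_std = np.hypot(*c) * 1000.0 / LM.fdd
        expected_dir = ff.vector_direction(c, grid.axis)
        for sid in range(1, 25):
            assert np.allclose(s.mean_vectors[sid - 1], c)
            assert s.std_magnitude(sid) == pytest.approx(expected_std)
            assert s.direction_deg(sid) == pytest.approx(expected_dir)

    def test_zero_field(self, grid):
        s = summarize_field(DisplacementField(np.zeros((*SHAPE, 2)), "g"), grid)
        assert all(s.std_magnitude(sid) == 0.0 for sid in range(1, 25))

    def test_radial_contraction_matches_discrete_integration(self, grid):
        center = np.array([250.0, 230.0])
        rows, cols = np.mgrid[0 : SHAPE[0], 0 : SHAPE[1]].astype(float)
        vec = np.stack([-0.03 * (rows - center[0]), -0.03 * (cols - center[1])], axis=-1)
        s = summarize_field(DisplacementField(vec, "g"), grid)
        for sid in range(1, 25):
            mask = grid.label_map == sid
            expected = vec[mask].mean(axis=0)
            assert np.allclose(s.mean_vectors[sid - 1], expected, atol=1e-6)

    def test_mean_vs_sum_consistency(self, grid):
        rng = np.random.default_rng(11)
        fld = DisplacementField(rng.normal(size=(*SHAPE, 2)), "g")
        s = summarize_field(fld, grid)
        np.testing.assert_array_equal(
            s.sum_vectors / np.maximum(s.pixel_counts, 1)[:, None], s.mean_vectors
        )

    def test_pixel_mean_magnitude_mode(self, grid):
        rng = np.random.default_rng(12)
        fld = DisplacementField(rng.normal(size=(*SHAPE, 2)), "g")
        s = summarize_field(fld, grid, magnitude_mode="pixel_mean")
        mags = fld.magnitude() * 1000.0 / LM.fdd
        sid = 9
        assert s.std_magnitude(sid) == pytest.approx(mags[grid.label_map == sid].mean())

    def test_frame_mismatch_rejected(self, grid):
        fld = DisplacementField(np.zeros((*SHAPE, 2)), "other-frame")
        with pytest.raises(FrameMismatchError):
            summarize_field(fld, grid)


class TestQuadrants:
    def test_each_quadrant_has_six_sectors(self, grid):
        fld = DisplacementField(np.zeros((*SHAPE, 2)), "g")
        s = summarize_field(fld, grid)
        for scheme in QUADRANT_SCHEMES:
            quads = group_quadrants(s, scheme)
            assert len(quads) == 4
            for q in quads.values():
                assert len(q["sector_ids"]) == 6

    def test_uniform_field_identical_quadrants(self, grid):
        c = np.array([0.0, 3.0])
        fld = DisplacementField(np.broadcast_to(c, (*SHAPE, 2)).copy(), "g")
        s = summarize_field(fld, grid)
        quads = group_quadrants(s, "cardinal")
        vals = [(q["std_magnitude"], q["direction_deg"]) for q in quads.values()]
        for v in vals[1:]:
            assert v[0] == pytest.approx(vals[0][0])
            assert v[1] == pytest.approx(vals[0][1])

    def test_weighted_mean_matches_hand_computation(self, grid):
        rng = np.random.default_rng(21)
        fld = DisplacementField(rng.normal(size=(*SHAPE, 2)), "g")
        s = summarize_field(fld, grid)
        quads = group_quadrants(s, "diagonal")
        for q in quads.values():
            idx = [sid - 1 for sid in q["sector_ids"]]
            w = s.pixel_counts[idx]
            expected = (s.mean_vectors[idx] * w[:, None]).sum(axis=0) / w.sum()
            assert np.allclose([q["vec_row"], q["vec_col"]], expected)


class TestBetweenTimepoints:
    def _summary(self, grid, vec):
        return summarize_field(DisplacementField(vec, "g"), grid)

    def test_zero_reference_returns_input(self, grid):
        rng = np.random.default_rng(31)
        a = self._summary(grid, rng.normal(size=(*SHAPE, 2)))
        zero = self._summary(grid, np.zeros((*SHAPE, 2)))
        diff = between_timepoints(a, zero)
        assert np.allclose(diff.mean_vectors, a.mean_vectors)
        assert np.array_equal(diff.pixel_counts, a.pixel_counts)

    def test_telescoping_identity(self, grid):
        rng = np.random.default_rng(32)
        a = self._summary(grid, rng.normal(size=(*SHAPE, 2)))
        b = self._summary(grid, rng.normal(size=(*SHAPE, 2)))
        c = self._summary(grid, rng.normal(size=(*SHAPE, 2)))
        ab = between_timepoints(a, b)
        bc = between_timepoints(b, c)
        ac = between_timepoints(a, c)
        assert np.allclose(ab.mean_vectors + bc.mean_vectors, ac.mean_vectors, atol=1e-9)

    def test_difference_equals_summary_of_difference_field(self, grid):
        """Summarization is linear, so per-sector vector arithmetic must agree
        exactly with summarizing the dense stage field."""
        rng = np.random.default_rng(33)
        ua = rng.normal(size=(*SHAPE, 2))
        ub = rng.normal(size=(*SHAPE, 2))
        diff = between_timepoints(self._summary(grid, ua), self._summary(grid, ub))
        direct = self._summary(grid, ua - ub)
        assert np.allclose(diff.mean_vectors, direct.mean_vectors, atol=1e-9)

    def test_mismatched_frames_rejected(self, grid):
        a = self._summary(grid, np.zeros((*SHAPE, 2)))
        other = summarize_field(
            DisplacementField(np.zeros((*SHAPE, 2)), "h"),
            build_sector_grid(ff.Landmarks((256.0, 200.0), (256.0, 500.0), frame_id="h"), SHAPE),
        )
        with pytest.raises(FrameMismatchError):
            between_timepoints(a, other)


def test_ring_and_wedge_name_tables():
    assert RING_NAMES == ("central_fovea", "inner_macula", "outer_macula")
    assert WEDGE_NAMES == ("SNN", "SSN", "SST", "STT", "ITT", "IIT", "IIN", "INN")
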