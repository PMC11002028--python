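"""Shared fixtures: synthetic scenes and registered results.

Heavy artifacts (generated scenes, full pipeline runs) are session-scoped so
many tests can share one computation.
"""
from __future__ import annotations

import numpy as np
import pytest

import fundusflow as ff
from fundusflow.sectors import build_sector_grid, summarize_field


@pytest.fixture(scope="session")
def tree():
    """A mid-size synthetic eye: (image, truth vessel mask, landmarks)."""
    return ff.generate_vessel_tree(0, ff.VesselTreeParams(image_shape=(384, 384)))


@pytest.fixture(scope="session")
def pair_case():
    """Default synthetic pair: known global jitter + 12 px b-spline warp."""
    return ff.make_pair(1)


@pytest.fixture(scope="session")
def pair_result(pair_case):
    """Full pipeline output for the default pair."""
    return ff.compute_pair_field(
        pair_case.moving_image, pair_case.fixed_image, pair_case.landmarks
    )


@pytest.fixture(scope="session")
def series11():
    """Canonical 5-timepoint longitudinal series (decaying contraction)."""
    return ff.make_longitudinal_series(11)


@pytest.fixture(scope="session")
def series11_summaries(series11):
    """To-reference sector summaries for every earlier timepoint of the
    canonical series, sharing one sector grid."""
    grid = build_sector_grid(series11.landmarks, series11.reference.shape)
    summaries = []
    for case in series11.cases:
        res = ff.compute_pair_field(case.moving_image, case.fixed_image, case.landmarks)
        summaries.append(summarize_field(res.field, grid))
    return grid, summaries


@pytest.fixture()
def horizontal_landmarks():
    return ff.Landmarks(fovea_center=(100.0, 100.0), disc_center=(100.0, 400.0), frame_id="t")


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
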