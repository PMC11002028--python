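"""Macular 24-sector grid and displacement summarization.

The macular region is the disc of radius ``R = (2/3) * FDD`` centered on the
fovea, split into 3 concentric rings (central fovea, inner macula, outer
macula; boundaries at R/3 and 2R/3) and 8 half-open 45-degree wedges counted
counter-clockwise from the nasal axis:

    [0, 45) SNN | [45, 90) SSN | [90, 135) SST | [135, 180) STT |
    [180, 225) ITT | [225, 270) IIT | [270, 315) IIN | [315, 360) INN

giving 24 sectors. Each sector's representative vector is the sum of its
per-pixel displacement vectors; reported polar values (standardized
magnitude, direction) are computed from the **mean** vector (sum / pixel
count) so that sectors of different areas are directly comparable. Ring and
quadrant aggregates are pixel-count-weighted means of their member sectors.

Longitudinal arithmetic: with every timepoint registered to one reference
image, the displacement between two earlier timepoints a and b is the
per-sector vector difference v(a->ref) - v(b->ref).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import FrameMismatchError
from .fields import DisplacementField
from .geometry import Landmarks, NasalAxis, fovea_disc_distance, nasal_axis, vector_direction

__all__ = [
    "RING_NAMES",
    "WEDGE_NAMES",
    "QUADRANT_SCHEMES",
    "SectorGrid",
    "SectorSummary",
    "build_sector_grid",
    "summarize_field",
    "group_quadrants",
    "between_timepoints",
]

RING_NAMES = ("central_fovea", "inner_macula", "outer_macula")
WEDGE_NAMES = ("SNN", "SSN", "SST", "STT", "ITT", "IIT", "IIN", "INN")

#: quadrant groupings; each quadrant collects 2 wedges x 3 rings = 6 sectors
QUADRANT_SCHEMES = {
    "cardinal": {
        "nasal": ("SNN", "INN"),
        "superior": ("SSN", "SST"),
        "temporal": ("STT", "ITT"),
        "inferior": ("IIT", "IIN"),
    },
    "diagonal": {
        "superonasal": ("SNN", "SSN"),
        "superotemporal": ("SST", "STT"),
        "inferotemporal": ("ITT", "IIT"),
        "inferonasal": ("IIN", "INN"),
    },
}


def _sector_id(ring_idx: int, wedge_idx: int) -> int:
    """Sector ids 1..24, ring-major (1..8 central fovea, 9..16 inner, 17..24 outer)."""
    return ring_idx * 8 + wedge_idx + 1


@dataclass
class SectorGrid:
    """Pixel labelling of the macular region into 24 sectors (0 = outside)."""

    label_map: np.ndarray
    radius: float
    landmarks: Landmarks
    axis: NasalAxis

    @property
    def fdd(self) -> float:
        return fovea_disc_distance(self.landmarks)

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape

    @staticmethod
    def ring_of(sector_id: int) -> str:
        return RING_NAMES[(sector_id - 1) // 8]

    @staticmethod
    def wedge_of(sector_id: int) -> str:
        return WEDGE_NAMES[(sector_id - 1) % 8]

    def sector_mask(self, sector_id: int) -> np.ndarray:
        return self.label_map == sector_id

    def centroid(self, sector_id: int) -> tuple[float, float]:
        rows, cols = np.nonzero(self.label_map == sector_id)
        return float(rows.mean()), float(cols.mean())


def build_sector_grid(landmarks: Landmarks, shape: tuple[int, int]) -> SectorGrid:
    """Label every pixel of ``shape`` with its macular sector.

    Rings by distance from the fovea center (boundaries R/3 and 2R/3, outer
    circle closed at R), wedges by the angle of ``pixel - fovea`` in the
    nasal/superior frame, half-open and lower-inclusive. Landmarks must be in
    normalized (left-eye) orientation.
    """
    h, w = shape
    fr, fc = landmarks.fovea_center
    if not (0 <= fr < h and 0 <= fc < w):
        raise ValueError(f"fovea {landmarks.fovea_center} outside image {shape}")
    axis = nasal_axis(landmarks)
    fdd = fovea_disc_distance(landmarks)
    radius = 2.0 * fdd / 3.0

    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    dr = rows - fr
    dcl = cols - fc
    r = np.hypot(dr, dcl)
    comp_n = dr * axis.n[0] + dcl * axis.n[1]
    comp_s = dr * axis.s[0] + dcl * axis.s[1]
    theta = np.degrees(np.arctan2(comp_s, comp_n)) % 360.0
    theta[theta >= 360.0] = 0.0

    wedge = np.clip((theta // 45.0).astype(np.int64), 0, 7)
    ring = np.full(shape, -1, dtype=np.int64)
    ring[r < radius / 3.0] = 0
    ring[(r >= radius / 3.0) & (r < 2.0 * radius / 3.0)] = 1
    ring[(r >= 2.0 * radius / 3.0) & (r <= radius)] = 2

    labels = np.zeros(shape, dtype=np.int64)
    inside = ring >= 0
    labels[inside] = ring[inside] * 8 + wedge[inside] + 1

    if fr - radius < 0 or fr + radius > h - 1 or fc - radius < 0 or fc + radius > w - 1:
        area = np.count_nonzero(labels)
        expected = np.pi * radius**2
        warnings.warn(
            f"macular circle exceeds image bounds; {1 - area / expected:.1%} of its area is clipped",
            stacklevel=2,
        )
    return SectorGrid(label_map=labels, radius=radius, landmarks=landmarks, axis=axis)


@dataclass
class SectorSummary:
    """Per-sector representative vectors and polar statistics.

    ``sum_vectors[i]`` is the raw vector sum over sector ``i+1``;
    ``mean_vectors`` the sums divided by pixel counts. Polar columns are
    derived from the mean vectors via the grid's axis and FDD.
    """

    sum_vectors: np.ndarray        # (24, 2)
    pixel_counts: np.ndarray       # (24,)
    fdd: float
    axis: NasalAxis
    reference_frame_id: str = ""
    empty_sectors: tuple[int, ...] = ()
    magnitude_mode: str = "mean_vector"
    mean_pixel_std_magnitudes: np.ndarray | None = dc_field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sum_vectors = np.asarray(self.sum_vectors, dtype=np.float64).reshape(24, 2)
        self.pixel_counts = np.asarray(self.pixel_counts, dtype=np.int64).reshape(24)

    @property
    def mean_vectors(self) -> np.ndarray:
        counts = np.maximum(self.pixel_counts, 1)
        return self.sum_vectors / counts[:, None]

    def _polar(self, vec: np.ndarray) -> tuple[float, float]:
        mag = float(np.hypot(vec[0], vec[1]))
        return mag * 1000.0 / self.fdd, vector_direction(vec, self.axis)

    def std_magnitude(self, sector_id: int) -> float:
        if self.magnitude_mode == "pixel_mean" and self.mean_pixel_std_magnitudes is not None:
            return float(self.mean_pixel_std_magnitudes[sector_id - 1])
        return self._polar(self.mean_vectors[sector_id - 1])[0]

    def direction_deg(self, sector_id: int) -> float:
        return self._polar(self.mean_vectors[sector_id - 1])[1]

    def ring_aggregate(self, ring: str) -> dict:
        idx = [i for i in range(24) if RING_NAMES[i // 8] == ring]
        return self._aggregate(idx, ring)

    def macular_aggregate(self) -> dict:
        return self._aggregate(list(range(24)), "macula")

    def mean_sector_std_magnitude(self) -> float:
        """Mean over the 24 sectors of per-sector standardized magnitudes —
        the whole-macula displacement summary. (Unlike the magnitude of the
        macula-wide mean vector, this does not cancel for centripetal
        patterns.)"""
        return float(np.mean([self.std_magnitude(sid) for sid in range(1, 25)]))

    def _aggregate(self, idx: list[int], name: str) -> dict:
        count = int(self.pixel_counts[idx].sum())
        vec = self.sum_vectors[idx].sum(axis=0) / max(count, 1)
        std, direc = self._polar(vec)
        return {
            "name": name,
            "pixel_count": count,
            "vec_row": float(vec[0]),
            "vec_col": float(vec[1]),
            "std_magnitude": std,
            "direction_deg": direc,
        }

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: one row per sector, then per ring, then the whole
        macula (columns: id, ring, wedge, pixel_count, std_magnitude,
        direction_deg, vec_row, vec_col)."""
        rows = []
        for sid in range(1, 25):
            vec = self.mean_vectors[sid - 1]
            std, direc = self._polar(vec)
            rows.append(
                {
                    "id": str(sid),
                    "ring": SectorGrid.ring_of(sid),
                    "wedge": SectorGrid.wedge_of(sid),
                    "pixel_count": int(self.pixel_counts[sid - 1]),
                    "std_magnitude": self.std_magnitude(sid) if self.magnitude_mode == "pixel_mean" else std,
                    "direction_deg": direc,
                    "vec_row": float(vec[0]),
                    "vec_col": float(vec[1]),
                }
            )
        for ring in RING_NAMES:
            agg = self.ring_aggregate(ring)
            rows.append(
                {
                    "id": ring,
                    "ring": ring,
                    "wedge": "all",
                    "pixel_count": agg["pixel_count"],
                    "std_magnitude": agg["std_magnitude"],
                    "direction_deg": agg["direction_deg"],
                    "vec_row": agg["vec_row"],
                    "vec_col": agg["vec_col"],
                }
            )
        agg = self.macular_aggregate()
        rows.append(
            {
                "id": "macula",
                "ring": "all",
                "wedge": "all",
                "pixel_count": agg["pixel_count"],
                "std_magnitude": agg["std_magnitude"],
                "direction_deg": agg["direction_deg"],
                "vec_row": agg["vec_row"],
                "vec_col": agg["vec_col"],
            }
        )
        return pd.DataFrame(rows)


def summarize_field(
    field: DisplacementField,
    grid: SectorGrid,
    magnitude_mode: str = "mean_vector",
) -> SectorSummary:
    """Aggregate a displacement field over the 24 sectors.

    ``magnitude_mode='mean_vector'`` (default) reports the standardized
    magnitude of each sector's mean vector; ``'pixel_mean'`` reports the mean
    of per-pixel standardized magnitudes instead (sensitivity alternative).
    Sectors fully covered by validity-mask holes are flagged in
    ``empty_sectors``.
    """
    if magnitude_mode not in ("mean_vector", "pixel_mean"):
        raise ValueError(f"unknown magnitude_mode {magnitude_mode!r}")
    if field.shape != grid.shape:
        raise FrameMismatchError(f"field {field.shape} vs grid {grid.shape}")
    gframe = grid.landmarks.frame_id
    fframe = field.reference_frame_id
    if gframe and fframe and gframe != fframe:
        raise FrameMismatchError(f"field frame {fframe!r} vs grid frame {gframe!r}")

    labels = grid.label_map.copy()
    labels[~field.validity_mask] = 0
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=25)[1:25]
    sums = np.stack(
        [
            np.bincount(flat, weights=field.vectors[..., 0].ravel(), minlength=25)[1:25],
            np.bincount(flat, weights=field.vectors[..., 1].ravel(), minlength=25)[1:25],
        ],
        axis=-1,
    )
    fdd = grid.fdd
    pixel_std = None
    if magnitude_mode == "pixel_mean":
        mags = field.magnitude().ravel() * 1000.0 / fdd
        sums_mag = np.bincount(flat, weights=mags, minlength=25)[1:25]
        pixel_std = sums_mag / np.maximum(counts, 1)

    empty = tuple(int(i + 1) for i in range(24) if counts[i] == 0)
    if empty:
        warnings.warn(f"sectors with no valid pixels: {empty}", stacklevel=2)
    return SectorSummary(
        sum_vectors=sums,
        pixel_counts=counts,
        fdd=fdd,
        axis=grid.axis,
        reference_frame_id=fframe or gframe,
        empty_sectors=empty,
        magnitude_mode=magnitude_mode,
        mean_pixel_std_magnitudes=pixel_std,
    )


def group_quadrants(summary: SectorSummary, scheme: str = "cardinal") -> dict[str, dict]:
    """Aggregate the 24 sectors into four 6-sector quadrants.

    ``scheme='cardinal'`` gives nasal/superior/temporal/inferior;
    ``'diagonal'`` gives superonasal/superotemporal/inferotemporal/
    inferonasal. Aggregates are pixel-count-weighted mean vectors.
    """
    if scheme not in QUADRANT_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(QUADRANT_SCHEMES)}")
    out = {}
    for name, wedges in QUADRANT_SCHEMES[scheme].items():
        idx = [i for i in range(24) if WEDGE_NAMES[i % 8] in wedges]
        if len(idx) != 6:
            raise ValueError("quadrant must collect exactly 6 sectors")
        out[name] = summary._aggregate(idx, name)
        out[name]["sector_ids"] = [i + 1 for i in idx]
    return out


def between_timepoints(summary_a_ref: SectorSummary, summary_b_ref: SectorSummary) -> SectorSummary:
    """Displacement summary for epoch a -> b from the two to-reference
    summaries: per-sector mean vector ``v(a->b) = v(a->ref) - v(b->ref)``.

    Both summaries must live on the same reference grid (same frame, FDD and
    axis). Pixel counts are combined conservatively (elementwise minimum)
    when validity holes differ between the two registrations.
    """
    a, b = summary_a_ref, summary_b_ref
    if a.reference_frame_id != b.reference_frame_id:
        raise FrameMismatchError(
            f"reference frames differ: {a.reference_frame_id!r} vs {b.reference_frame_id!r}"
        )
    if abs(a.fdd - b.fdd) > 1e-9 or not np.allclose(a.axis.n, b.axis.n):
        raise FrameMismatchError("summaries use different landmarks")
    counts = np.minimum(a.pixel_counts, b.pixel_counts)
    diff_mean = a.mean_vectors - b.mean_vectors
    return SectorSummary(
        sum_vectors=diff_mean * counts[:, None],
        pixel_counts=counts,
        fdd=a.fdd,
        axis=a.axis,
        reference_frame_id=a.reference_frame_id,
        empty_sectors=tuple(sorted(set(a.empty_sectors) | set(b.empty_sectors))),
    )
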