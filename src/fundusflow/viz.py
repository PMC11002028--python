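"""Rendering of the two figure products: the pixel-wise quiver overlay and
the 24-sector arrow overlay.

Arrows are magnified by a documented scale factor (default 3x) because
true-scale displacement arrows are invisible for small motions; a legend
states the factor. Rendering is deterministic.
"""
from __future__ import annotations

import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .fields import DisplacementField
from .sectors import SectorGrid, SectorSummary

__all__ = ["quiver_anchors", "quiver_overlay", "sector_arrow_overlay", "DEFAULT_STRIDE"]

#: pixel stride between displayed vectors
DEFAULT_STRIDE = 25

#: arrow length magnification in both overlays
DEFAULT_ARROW_SCALE = 3.0


def quiver_anchors(shape: tuple[int, int], stride_px: int = DEFAULT_STRIDE):
    """Anchor coordinates of the quiver display: every ``stride_px``-th pixel
    in both axes, starting at 0. Returns (rows, cols) 1-D arrays."""
    if stride_px < 1:
        raise ValueError(f"stride must be >= 1, got {stride_px}")
    return np.arange(0, shape[0], stride_px), np.arange(0, shape[1], stride_px)


def _figure_for(image: np.ndarray):
    h, w = image.shape[:2]
    dpi = 100.0
    fig = Figure(figsize=(w / dpi, h / dpi), dpi=dpi)
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_axis_off()
    if image.ndim == 2:
        ax.imshow(image, cmap="gray", vmin=0, vmax=1, interpolation="nearest")
    else:
        ax.imshow(np.clip(image, 0, 1), interpolation="nearest")
    ax.set_xlim(-0.5, w - 0.5)
    ax.set_ylim(h - 0.5, -0.5)
    return fig, ax


def _render(fig: Figure) -> np.ndarray:
    canvas = FigureCanvasAgg(fig)
    canvas.draw()
    return np.asarray(canvas.buffer_rgba())[..., :3].copy()


def quiver_overlay(
    image,
    field: DisplacementField,
    stride_px: int = DEFAULT_STRIDE,
    arrow_scale: float = DEFAULT_ARROW_SCALE,
) -> np.ndarray:
    """Render the displacement field as arrows every ``stride_px`` pixels.

    ``image`` is a FundusImage or a bare array on the field's grid. Returns
    an (H, W, 3) uint8 rendering.
    """
    pixels = getattr(image, "pixels", image)
    pixels = np.asarray(pixels)
    if pixels.shape[:2] != field.shape:
        raise ValueError(f"image {pixels.shape[:2]} vs field {field.shape}")
    rows, cols = quiver_anchors(field.shape, stride_px)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    u = field.vectors[rr, cc]

    fig, ax = _figure_for(pixels)
    ax.quiver(
        cc.ravel(),
        rr.ravel(),
        u[..., 1].ravel() * arrow_scale,
        u[..., 0].ravel() * arrow_scale,
        angles="xy",
        scale_units="xy",
        scale=1.0,
        color="yellow",
        width=0.002,
    )
    ax.text(
        0.02, 0.02, f"arrows x{arrow_scale:g}",
        transform=ax.transAxes, color="yellow", fontsize=8, va="bottom",
    )
    return _render(fig)


def sector_arrow_overlay(
    image,
    grid: SectorGrid,
    summary: SectorSummary,
    arrow_scale: float = DEFAULT_ARROW_SCALE,
) -> np.ndarray:
    """Render one arrow per sector (anchored at the sector's area centroid,
    mean vector scaled by ``arrow_scale``) plus the ring circles and wedge
    spokes of the macular grid."""
    pixels = getattr(image, "pixels", image)
    pixels = np.asarray(pixels)
    if pixels.shape[:2] != grid.shape:
        raise ValueError(f"image {pixels.shape[:2]} vs grid {grid.shape}")
    if np.any(summary.pixel_counts == 0) and len(summary.empty_sectors) == 24:
        raise ValueError("summary covers no sectors")

    fig, ax = _figure_for(pixels)
    fr, fc = grid.landmarks.fovea_center
    theta = np.linspace(0, 2 * np.pi, 256)
    for frac in (1.0 / 3.0, 2.0 / 3.0, 1.0):
        r = grid.radius * frac
        ax.plot(fc + r * np.cos(theta), fr + r * np.sin(theta), color="cyan", lw=0.8)
    n = np.asarray(grid.axis.n)
    s = np.asarray(grid.axis.s)
    for k in range(8):
        ang = np.radians(45.0 * k)
        d = np.cos(ang) * n + np.sin(ang) * s
        ax.plot(
            [fc + grid.radius / 3.0 * d[1], fc + grid.radius * d[1]],
            [fr + grid.radius / 3.0 * d[0], fr + grid.radius * d[0]],
            color="cyan", lw=0.8,
        )

    mean = summary.mean_vectors
    for sid in range(1, 25):
        if summary.pixel_counts[sid - 1] == 0:
            continue
        cr, cc_ = grid.centroid(sid)
        ax.annotate(
            "",
            xy=(cc_ + mean[sid - 1, 1] * arrow_scale, cr + mean[sid - 1, 0] * arrow_scale),
            xytext=(cc_, cr),
            arrowprops={"arrowstyle": "-|>", "color": "red", "lw": 1.4},
        )
    ax.text(
        0.02, 0.02, f"arrows x{arrow_scale:g}",
        transform=ax.transAxes, color="red", fontsize=8, va="bottom",
    )
    return _render(fig)
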