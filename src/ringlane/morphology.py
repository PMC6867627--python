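"""Cell/nuclear shape factors and relative staining intensity from masks.

The shape factor quantifies elongation as the ratio of the narrowest to the
widest spread of a binary mask: min over orientations of the Feret diameter
(projection extent) divided by the maximum Feret diameter (largest distance
between two boundary points).  Round cells score near 1, spindle-shaped
mesenchymal cells score low.

Masks are consumed, not produced — thresholding/segmentation of the raw
fluorescence images is upstream.  Synthetic parametric masks (discs,
ellipses, spindles) are provided for testing and demonstration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .errors import InputError

#: orientation grid step for the minimum Feret diameter, degrees
FERET_ANGLE_STEP_DEG = 1.0


@dataclass
class CellMask:
    """A single-cell binary raster with physical pixel size (um/px)."""

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise InputError("mask must be a 2-D raster")
        if not self.pixels.any():
            raise InputError("empty mask (no foreground pixels)")
        if not self.pixel_size > 0:
            raise InputError("pixel size must be > 0")

    def n_components(self) -> int:
        return int(measure.label(self.pixels, connectivity=2).max())


@dataclass
class ShapeResult:
    """Feret spreads (um) and their ratio, the shape factor in (0, 1]."""

    max_spread: float
    min_spread: float

    @property
    def shape_factor(self) -> float:
        return self.min_spread / self.max_spread


def _hull_points(mask: np.ndarray) -> np.ndarray:
    coords = np.argwhere(mask).astype(float)
    if len(coords) < 3:
        return coords
    try:
        hull = ConvexHull(coords)
    except QhullError:  # collinear pixels
        return coords
    return coords[hull.vertices]


def shape_factor(mask: CellMask) -> ShapeResult:
    """Min/max Feret diameter and their ratio for a single connected mask.

    The maximum spread is the largest pairwise distance between convex-hull
    vertices; the minimum spread is the smallest projection extent over a 1
    degree orientation grid.  Extents use pixel centers.

    Raises
    ------
    InputError
        If the mask has more than one connected component (label/split
        upstream first) or no foreground.
    """
    n_comp = mask.n_components()
    if n_comp > 1:
        raise InputError(f"mask has {n_comp} connected components; expected one")
    pts = _hull_points(mask.pixels)
    if len(pts) == 1:
        raise InputError("single-pixel mask has no measurable spread")
    diff = pts[:, None, :] - pts[None, :, :]
    max_spread = float(np.sqrt((diff**2).sum(-1)).max())
    angles = np.deg2rad(np.arange(0.0, 180.0, FERET_ANGLE_STEP_DEG))
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    proj = pts @ dirs.T  # (n_pts, n_angles)
    widths = proj.max(axis=0) - proj.min(axis=0)
    min_spread = float(widths.min())
    if min_spread == 0.0:  # degenerate 1-pixel-wide line: count the pixel footprint
        min_spread = 1.0
    return ShapeResult(
        max_spread=max_spread * mask.pixel_size,
        min_spread=min_spread * mask.pixel_size,
    )


def relative_intensity(image: np.ndarray, mask: CellMask, reference: float) -> float:
    """Total intensity over the mask, normalized by a reference value.

    With ``reference`` set to e.g. the control-condition mean total
    intensity, the control normalizes to 1 and other conditions are read as
    fold changes.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != mask.pixels.shape:
        raise InputError(
            f"image shape {image.shape} does not match mask shape {mask.pixels.shape}"
        )
    if not reference > 0:
        raise InputError("reference must be > 0")
    return float(image[mask.pixels].sum() / reference)


# ---------------------------------------------------------------------------
# synthetic parametric masks (for tests and demos; not measured data)
# ---------------------------------------------------------------------------

def make_disc(radius: float, pad: int = 4) -> np.ndarray:
    """Synthetic filled disc mask of the given pixel radius."""
    size = int(2 * radius) + 2 * pad + 1
    c = size // 2
    yy, xx = np.mgrid[:size, :size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def make_ellipse(a: float, b: float, angle_deg: float = 0.0, pad: int = 4) -> np.ndarray:
    """Synthetic filled ellipse mask with semi-axes `a`, `b` (px), rotated."""
    size = int(2 * max(a, b)) + 2 * pad + 1
    c = size // 2
    yy, xx = np.mgrid[:size, :size]
    th = np.deg2rad(angle_deg)
    u = (xx - c) * np.cos(th) + (yy - c) * np.sin(th)
    w = -(xx - c) * np.sin(th) + (yy - c) * np.cos(th)
    return (u / a) ** 2 + (w / b) ** 2 <= 1.0


def make_spindle(length: float, width: float, angle_deg: float = 0.0, pad: int = 4) -> np.ndarray:
    """Synthetic spindle (lens-shaped) mask: pointed ends, widest at center."""
    size = int(2 * length) + 2 * pad + 1
    c = size // 2
    yy, xx = np.mgrid[:size, :size]
    th = np.deg2rad(angle_deg)
    u = (xx - c) * np.cos(th) + (yy - c) * np.sin(th)
    w = -(xx - c) * np.sin(th) + (yy - c) * np.cos(th)
    half = length
    envelope = (width / 2.0) * (1.0 - (u / half) ** 2)
    return (np.abs(u) <= half) & (np.abs(w) <= envelope)
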