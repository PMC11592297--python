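"""Entry-echo shape descriptors: surface roughness, PAR and ACR.

All three quantify the jaggedness of the bright superficial band (entry
echo) of a skin B-mode scan.  They are defined for any layer mask but are
clinically reported for the entry echo.

Conventions
-----------
* Surface roughness (SR) is the sample standard deviation of the
  rasterized upper-edge row values, in pixels.  A millimetre accessor is
  provided, but the pixel value is the reported one.
* The mask is treated as a union of closed unit pixel squares.  Perimeter
  is the total length of exposed square edges (no diagonal corner
  cutting), so a 10x100 solid rectangle has perimeter 220 and
  PAR = 220/1000 = 0.22 exactly.
* The convex hull is the hull of the same pixel-square union (hull of all
  square corners), giving exact rational ACR values on small shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from .layers import LayerAnnotation, UltrasoundFrame, rasterize_edge

__all__ = [
    "MorphologyFeatures",
    "surface_roughness",
    "surface_roughness_mm",
    "perimeter_area_ratio",
    "area_convexhull_ratio",
]


@dataclass
class MorphologyFeatures:
    thickness_mm: float
    tvi_mm: float
    sr_px: float
    par_per_px: float
    acr: float


def surface_roughness(ann: LayerAnnotation) -> float:
    """Height variability along the layer's upper edge, in pixels.

    Sample SD (n-1) of the rasterized upper-edge rows.  Undefined for a
    single-column annotation.
    """
    rows = rasterize_edge(ann.upper_edge, ann.column_range)
    if rows.size < 2:
        raise ValueError("surface roughness undefined for a single-column annotation")
    return float(np.std(rows.astype(float), ddof=1))


def surface_roughness_mm(ann: LayerAnnotation, frame: UltrasoundFrame) -> float:
    """SR converted to millimetres via the axial spacing."""
    return surface_roughness(ann) * frame.axial_spacing_mm_per_px


def mask_perimeter_px(mask: np.ndarray) -> float:
    """Length of the boundary of the pixel-square union, in pixel units."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    n = int(m.sum())
    pairs = int((m[1:, :] & m[:-1, :]).sum()) + int((m[:, 1:] & m[:, :-1]).sum())
    return float(4 * n - 2 * pairs)


def perimeter_area_ratio(mask: np.ndarray) -> float:
    """Perimeter of the mask region divided by its pixel count (PAR).

    Lower values indicate a smoother, more regular layer outline.
    """
    m = np.asarray(mask, dtype=bool)
    area = int(m.sum())
    return mask_perimeter_px(m) / area


def area_convexhull_ratio(mask: np.ndarray) -> float:
    """Mask area over the area of its convex hull (ACR), capped at 1.

    The hull is taken over the corners of the unit squares of all mask
    pixels, so a convex pixel region (any solid rectangle) scores exactly
    1.  Lower values indicate a more irregular, concave shape.  A
    degenerate hull (zero area, impossible for unit squares but kept for
    API robustness) is defined as 1.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    rr, cc = np.nonzero(m)
    # Four corners of each pixel square (x=column, y=row).
    x = np.concatenate([cc - 0.5, cc + 0.5, cc - 0.5, cc + 0.5])
    y = np.concatenate([rr - 0.5, rr - 0.5, rr + 0.5, rr + 0.5])
    pts = np.column_stack([x, y])
    try:
        hull_area = float(ConvexHull(pts).volume)  # 2-D: volume == area
    except Exception:
        return 1.0
    if hull_area <= 0:
        return 1.0
    return min(1.0, float(m.sum()) / hull_area)
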