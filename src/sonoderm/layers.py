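"""Skin-layer geometry: frames, contour annotations, masks and thickness profiles.

Coordinate convention (fixed throughout the package): pixels are indexed
``(row, column)`` with row 0 at the skin surface and depth increasing with
the row index.  Layer boundaries are polylines that are functions of the
column; a layer occupies the half-open depth band ``upper(c) <= row <
lower(c)``, so vertically adjacent layers partition the image with no
double-counted pixels.  Edge rasterization interpolates linearly between
polyline vertices and rounds half up, which makes every derived quantity
bit-stable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LAYER_NAMES",
    "UltrasoundFrame",
    "LayerAnnotation",
    "ThicknessProfile",
    "read_contours",
    "write_contours",
    "rasterize_edge",
    "rasterize_mask",
    "thickness_profile",
]

#: Layers in order of increasing depth.  SLEB (subepidermal low-echogenic
#: band) may be absent in a given frame.
LAYER_NAMES = ("entry_echo", "sleb", "dermis")


class ContourError(ValueError):
    """Raised for geometrically invalid layer annotations."""


@dataclass
class UltrasoundFrame:
    """One 8-bit grayscale B-mode frame with physical pixel spacing.

    Parameters
    ----------
    pixels
        2-D ``uint8`` array, shape ``(rows, columns)``; row 0 is the most
        superficial scan line.
    axial_spacing_mm_per_px, lateral_spacing_mm_per_px
        Physical size of one pixel along depth and along the probe face.
    frame_id
        Stable identifier used in feature tables and manifests.
    """

    pixels: np.ndarray
    axial_spacing_mm_per_px: float
    lateral_spacing_mm_per_px: float = 0.05
    frame_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("frame pixels must be a 2-D array")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.axial_spacing_mm_per_px <= 0 or self.lateral_spacing_mm_per_px <= 0:
            raise ValueError("pixel spacings must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LayerAnnotation:
    """Upper/lower boundary polylines for one named layer.

    ``upper_edge`` and ``lower_edge`` are sequences of ``(column, row)``
    vertices spanning ``column_range`` (half-open ``[c0, c1)``); both edges
    must rasterize with ``upper < lower`` at every column.
    """

    layer_name: str
    upper_edge: list[tuple[float, float]]
    lower_edge: list[tuple[float, float]]
    column_range: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.layer_name not in LAYER_NAMES:
            raise ValueError(
                f"unknown layer {self.layer_name!r}; expected one of {LAYER_NAMES}"
            )
        if self.column_range is None:
            c0 = int(np.ceil(min(c for c, _ in self.upper_edge)))
            c1 = int(np.floor(max(c for c, _ in self.upper_edge))) + 1
            self.column_range = (c0, c1)
        c0, c1 = self.column_range
        if c1 <= c0:
            raise ContourError(f"empty column range {self.column_range}")
        rows_up = rasterize_edge(self.upper_edge, self.column_range)
        rows_lo = rasterize_edge(self.lower_edge, self.column_range)
        bad = np.nonzero(rows_up >= rows_lo)[0]
        if bad.size:
            col = c0 + int(bad[0])
            raise ContourError(
                f"layer {self.layer_name!r}: upper edge not above lower edge "
                f"at column {col}"
            )

    @property
    def n_columns(self) -> int:
        return self.column_range[1] - self.column_range[0]

    def translated(self, d_col: int = 0, d_row: int = 0) -> "LayerAnnotation":
        """Whole-pixel translation (used by shift-invariance checks)."""
        return LayerAnnotation(
            self.layer_name,
            [(c + d_col, r + d_row) for c, r in self.upper_edge],
            [(c + d_col, r + d_row) for c, r in self.lower_edge],
            (self.column_range[0] + d_col, self.column_range[1] + d_col),
        )


@dataclass
class ThicknessProfile:
    """Per-column layer thickness in mm with its mean and sample SD."""

    per_column_thickness_mm: np.ndarray
    mean_mm: float
    sd_mm: float


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def rasterize_edge(
    vertices: list[tuple[float, float]], column_range: tuple[int, int]
) -> np.ndarray:
    """Rasterize a boundary polyline to one integer row per column.

    Rows are obtained by linear interpolation between vertices at integer
    column positions, then rounded half up.  Columns outside the vertex
    span take the nearest endpoint's row (flat extrapolation).
    """
    if len(vertices) == 0:
        raise ContourError("polyline has no vertices")
    pts = sorted(vertices)
    cols = np.array([c for c, _ in pts], dtype=float)
    rows = np.array([r for _, r in pts], dtype=float)
    c0, c1 = column_range
    grid = np.arange(c0, c1, dtype=float)
    return _round_half_up(np.interp(grid, cols, rows))


def rasterize_mask(ann: LayerAnnotation, frame: UltrasoundFrame) -> np.ndarray:
    """Boolean region mask: true exactly where ``upper(c) <= row < lower(c)``."""
    n_rows, n_cols = frame.shape
    c0, c1 = ann.column_range
    if c0 < 0 or c1 > n_cols:
        raise ContourError(
            f"annotation columns [{c0}, {c1}) outside frame width {n_cols}"
        )
    up = rasterize_edge(ann.upper_edge, ann.column_range)
    lo = rasterize_edge(ann.lower_edge, ann.column_range)
    if up.min() < 0 or lo.max() > n_rows:
        raise ContourError(
            f"annotation rows [{up.min()}, {lo.max()}) outside frame height {n_rows}"
        )
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    rr = np.arange(n_rows)[:, None]
    mask[:, c0:c1] = (rr >= up[None, :]) & (rr < lo[None, :])
    return mask


def thickness_profile(ann: LayerAnnotation, frame: UltrasoundFrame) -> ThicknessProfile:
    """Per-column thickness of a layer in mm.

    Thickness at column ``c`` is ``(lower(c) - upper(c))`` pixels times the
    axial spacing.  ``mean_mm`` is the layer's reported thickness; ``sd_mm``
    (sample SD, n-1 denominator) of the entry-echo profile is the thickness
    variation index (TVI).  A single-column profile reports ``sd_mm = 0``
    by convention.
    """
    up = rasterize_edge(ann.upper_edge, ann.column_range)
    lo = rasterize_edge(ann.lower_edge, ann.column_range)
    t_px = lo - up
    ax = frame.axial_spacing_mm_per_px
    # statistics on integer pixel counts, scaled afterwards: a constant
    # profile reports exactly zero SD
    sd = float(np.std(t_px, ddof=1)) * ax if t_px.size > 1 else 0.0
    return ThicknessProfile(t_px * ax, float(np.mean(t_px)) * ax, sd)


# ---------------------------------------------------------------------------
# Contour CSV dialect: columns layer,edge(upper|lower),x_px,y_px
# ---------------------------------------------------------------------------

def write_contours(annotations: list[LayerAnnotation], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["layer", "edge", "x_px", "y_px"])
        for ann in annotations:
            for edge_name, edge in (("upper", ann.upper_edge), ("lower", ann.lower_edge)):
                for c, r in edge:
                    w.writerow([ann.layer_name, edge_name, repr(float(c)), repr(float(r))])
    return path


def read_contours(path: str | Path) -> list[LayerAnnotation]:
    """Read layer annotations from the contour CSV dialect.

    One annotation per layer present in the file; an absent SLEB is a legal
    outcome.  Geometric validation (upper above lower at every column) runs
    on construction and raises :class:`ContourError` naming the first
    offending column.
    """
    edges: dict[str, dict[str, list[tuple[float, float]]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"layer", "edge", "x_px", "y_px"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ContourError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            layer = row["layer"]
            edge = row["edge"]
            if edge not in ("upper", "lower"):
                raise ContourError(f"{path}: bad edge label {edge!r}")
            edges.setdefault(layer, {"upper": [], "lower": []})
            edges[layer][edge].append((float(row["x_px"]), float(row["y_px"])))
    out = []
    for layer in LAYER_NAMES:
        if layer in edges:
            out.append(
                LayerAnnotation(layer, edges[layer]["upper"], edges[layer]["lower"])
            )
    return out
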