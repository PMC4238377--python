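"""Neighbor maps, normalized (superimposed) maps, isodensity grids and radial profiles.

Two complementary density representations are used, matching field practice
for whole-mount topography:

* sparse populations (melanopsin-positive cells, ~1000 per retina) are shown
  as *neighbor maps*: each cell is coloured by the number of other cells of
  the same population within a fixed radius (default 0.165 mm, inclusive);
* dense populations (Brn3a-positive RGCs, ~40 000 per retina) are shown as
  *isodensity maps*: square bins (default area = the 0.2161 mm² acquisition
  frame subdivided 6x6) coloured by cells/mm².

*Normalized maps* superimpose several same-orientation retinas centred on
the optic nerve and recompute neighbor counts on the pooled point set with a
rescaled colour scale.  *Radial profiles* histogram distance from the ON,
overall and per quadrant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree

from .errors import DomainError, FrameError
from .geometry import QUADRANT_ORDER, CellTable, assign_quadrants

#: Fixed study radius for neighbor counting (mm).
DEFAULT_NEIGHBOR_RADIUS_MM = 0.165
#: Area of one acquisition frame (mm²) and the default 6x6 subdivision.
FRAME_AREA_MM2 = 0.2161
DEFAULT_BIN_AREA_MM2 = FRAME_AREA_MM2 / 36.0
DEFAULT_RADIAL_BIN_MM = 0.165


@dataclass(frozen=True)
class ColorScale:
    """Discrete colour scale for neighbor counts.

    Counts at or below ``low_label`` take the lowest class (purple); counts
    at or above ``high_label`` take the highest (red); the integers strictly
    between are split into ``n_classes - 2`` equal-width, lower-inclusive
    intervals.
    """

    n_classes: int
    low_label: int
    high_label: int

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise DomainError("a colour scale needs at least 2 classes")
        if not self.low_label < self.high_label:
            raise DomainError("low_label must be below high_label")


#: Published endpoint pairs: single retinas run purple(0-1) -> red(>=11);
#: three-retina normalized maps run purple(0-3) -> red(>=28).
COLOR_SCALES: dict[str, ColorScale] = {
    "single": ColorScale(n_classes=11, low_label=1, high_label=11),
    "normalized3": ColorScale(n_classes=14, low_label=3, high_label=28),
}


def bin_color(count, scale: ColorScale) -> np.ndarray | int:
    """Colour-class index for a neighbor count (vectorised)."""
    c = np.asarray(count)
    if (c < 0).any():
        raise DomainError("neighbor counts cannot be negative")
    k = scale.n_classes - 2
    span = scale.high_label - scale.low_label - 1
    if span > 0 and k > 0:
        inner = 1 + ((c - scale.low_label - 1) * k) // span
        inner = np.clip(inner, 1, max(k, 1))
    else:
        inner = np.ones_like(c)
    out = np.where(
        c <= scale.low_label, 0, np.where(c >= scale.high_label, scale.n_classes - 1, inner)
    )
    return out if out.ndim else int(out)


@dataclass
class NeighborMap:
    """Per-cell neighbor counts at a fixed radius, with colour classes."""

    radius: float
    cells: pd.DataFrame  # cell_id, x_mm, y_mm, neighbor_count, color_bin
    scale: ColorScale

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def class_histogram(self) -> np.ndarray:
        return np.bincount(self.cells["color_bin"], minlength=self.scale.n_classes)


def _neighbor_counts_points(points: np.ndarray, radius: float) -> np.ndarray:
    """Number of *other* points within ``radius`` (inclusive) of each point."""
    if radius <= 0:
        raise DomainError("neighbor radius must be positive")
    if len(points) == 0:
        return np.zeros(0, dtype=int)
    tree = cKDTree(points)
    counts = tree.query_ball_point(points, r=radius, return_length=True)
    return np.asarray(counts, dtype=int) - 1  # exclude the cell itself


def neighbor_counts(
    table: CellTable,
    mask=None,
    radius: float = DEFAULT_NEIGHBOR_RADIUS_MM,
    scale: ColorScale | str = "single",
) -> NeighborMap:
    """Fixed-radius neighbor map for the filtered population of one retina.

    Distances are Euclidean and the radius comparison is inclusive; the
    result depends only on inter-cell distances, so it is invariant under
    canonicalisation.
    """
    if isinstance(scale, str):
        scale = COLOR_SCALES[scale]
    sub = table.cells if mask is None else table.cells.loc[np.asarray(mask, dtype=bool)]
    pts = sub[["x_mm", "y_mm"]].to_numpy()
    counts = _neighbor_counts_points(pts, radius)
    df = pd.DataFrame(
        {
            "cell_id": sub["cell_id"].to_numpy(),
            "x_mm": pts[:, 0] if len(pts) else np.array([]),
            "y_mm": pts[:, 1] if len(pts) else np.array([]),
            "neighbor_count": counts,
        }
    )
    df["color_bin"] = bin_color(counts, scale) if len(df) else np.array([], dtype=int)
    return NeighborMap(radius=radius, cells=df, scale=scale)


def normalized_map(
    tables: list[CellTable],
    masks=None,
    radius: float = DEFAULT_NEIGHBOR_RADIUS_MM,
    scale: ColorScale | str = "normalized3",
) -> NeighborMap:
    """Neighbor map of several superimposed canonical retinas.

    All tables must already be in the canonical frame (ON at origin, same
    side convention); their filtered cells are pooled into one point set and
    neighbor counts are recomputed on the pool, so the map total equals the
    sum of the input totals.
    """
    if isinstance(scale, str):
        scale = COLOR_SCALES[scale]
    if masks is None:
        masks = [None] * len(tables)
    frames = []
    for i, (t, m) in enumerate(zip(tables, masks)):
        if not t.canonical:
            raise FrameError("normalized maps require canonicalized tables")
        sub = t.cells if m is None else t.cells.loc[np.asarray(m, dtype=bool)]
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": [f"r{i}:{cid}" for cid in sub["cell_id"]],
                    "x_mm": sub["x_mm"].to_numpy(),
                    "y_mm": sub["y_mm"].to_numpy(),
                }
            )
        )
    pooled = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["cell_id", "x_mm", "y_mm"]
    )
    counts = _neighbor_counts_points(pooled[["x_mm", "y_mm"]].to_numpy(), radius)
    pooled["neighbor_count"] = counts
    pooled["color_bin"] = bin_color(counts, scale) if len(pooled) else np.array([], dtype=int)
    return NeighborMap(radius=radius, cells=pooled, scale=scale)


@dataclass
class DensityGrid:
    """Square-binned cell density over the retina (cells/mm²)."""

    bin_area: float
    bins: pd.DataFrame  # bin_x, bin_y (lower-left corners, mm), count, density
    max_class_density: float | None = None

    @property
    def total_count(self) -> int:
        return int(self.bins["count"].sum())

    def density_class(self, n_classes: int = 12) -> np.ndarray:
        """Colour class per bin, saturating at ``max_class_density``."""
        top = self.max_class_density or max(float(self.bins["density"].max()), 1.0)
        cls = np.floor(self.bins["density"].to_numpy() / top * n_classes).astype(int)
        return np.clip(cls, 0, n_classes - 1)


def isodensity_grid(
    table: CellTable,
    mask=None,
    bin_area: float = DEFAULT_BIN_AREA_MM2,
    max_class_density: float | None = None,
) -> DensityGrid:
    """Isodensity grid: square bins of ``bin_area`` tiling the contour's bounding box.

    Bins that do not touch the contour are omitted; per-bin density is
    count / bin_area.  Bin counts sum to the number of filtered cells.
    """
    if bin_area <= 0:
        raise DomainError("bin_area must be positive")
    side = float(np.sqrt(bin_area))
    xmin, ymin, xmax, ymax = table.retina.polygon.bounds
    nx = max(int(np.ceil((xmax - xmin) / side)), 1)
    ny = max(int(np.ceil((ymax - ymin) / side)), 1)

    sub = table.cells if mask is None else table.cells.loc[np.asarray(mask, dtype=bool)]
    pts = sub[["x_mm", "y_mm"]].to_numpy()
    counts = np.zeros((nx, ny), dtype=int)
    if len(pts):
        ix = np.clip(((pts[:, 0] - xmin) // side).astype(int), 0, nx - 1)
        iy = np.clip(((pts[:, 1] - ymin) // side).astype(int), 0, ny - 1)
        np.add.at(counts, (ix, iy), 1)

    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    x0 = xmin + gx.ravel() * side
    y0 = ymin + gy.ravel() * side
    boxes = shapely.box(x0, y0, x0 + side, y0 + side)
    keep = shapely.intersects(table.retina.polygon, boxes)
    df = pd.DataFrame(
        {
            "bin_x": x0[keep],
            "bin_y": y0[keep],
            "count": counts.ravel()[keep],
            "density": counts.ravel()[keep] / bin_area,
        }
    )
    return DensityGrid(bin_area=bin_area, bins=df, max_class_density=max_class_density)


@dataclass
class RadialProfile:
    """Cell counts against distance from the optic nerve, overall and per quadrant."""

    bin_edges: np.ndarray  # mm, len = n_bins + 1
    total: np.ndarray  # counts, len = n_bins
    per_quadrant: pd.DataFrame  # columns SN, ST, IN, IT

    def to_frame(self) -> pd.DataFrame:
        df = self.per_quadrant.copy()
        df.insert(0, "bin_start_mm", self.bin_edges[:-1])
        df.insert(1, "bin_end_mm", self.bin_edges[1:])
        df["total"] = self.total
        return df


def radial_profile(
    table: CellTable, mask=None, bin_width: float = DEFAULT_RADIAL_BIN_MM
) -> RadialProfile:
    """Histogram of distance-from-ON in half-open bins [k·w, (k+1)·w).

    Requires the canonical frame (ON at the origin).  Per-quadrant counts sum
    to the overall counts bin-wise.
    """
    if bin_width <= 0:
        raise DomainError("bin_width must be positive")
    if not table.canonical:
        raise FrameError("radial profiles require a canonicalized table")
    sub = table.cells if mask is None else table.cells.loc[np.asarray(mask, dtype=bool)]
    pts = sub[["x_mm", "y_mm"]].to_numpy()
    r = np.hypot(pts[:, 0], pts[:, 1]) if len(pts) else np.zeros(0)
    n_bins = max(int(np.floor(r.max() / bin_width)) + 1, 1) if len(r) else 1
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.minimum((r // bin_width).astype(int), n_bins - 1) if len(r) else np.array([], int)

    quad = assign_quadrants(pts) if len(pts) else np.array([], dtype=object)
    per = {}
    for q in QUADRANT_ORDER:
        sel = idx[quad == q.value] if len(pts) else np.array([], int)
        per[q.value] = np.bincount(sel, minlength=n_bins)
    per_df = pd.DataFrame(per)
    total = per_df.sum(axis=1).to_numpy()
    return RadialProfile(bin_edges=edges, total=total, per_quadrant=per_df)
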