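"""Retinal coordinate frame, orientation, and compartment geometry.

A flat-mounted retina is digitised as a simple closed contour polygon (mm),
the optic-nerve (ON) head position, and a table of labelled cells.  All
downstream analyses share one *canonical frame*: the ON at the origin,
superior along +y and nasal along +x.  Right-eye retinas are translated into
this frame; left-eye retinas are additionally mirrored about the vertical
axis so that nasal maps to +x, which makes maps from both eyes directly
superimposable.

The module also provides the compartment predicates the analyses rely on:
axis-aligned quadrants through the ON (supero-nasal SN, supero-temporal ST,
infero-nasal IN, infero-temporal IT), the nasal/temporal hemiretina split,
and membership in the ciliary marginal zone (CMZ), defined as the band
within 0.100 mm of the retinal edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

from .errors import ConfigurationError, DataError, DomainError, GeometryError

logger = logging.getLogger(__name__)

#: Width of the ciliary-marginal-zone band, measured inward from the retinal
#: edge (mm).  Boundary inclusive.
DEFAULT_CMZ_BAND_MM = 0.100


class Layer(str, Enum):
    """Retinal layer holding a cell body."""

    GCL = "GCL"  # ganglion cell layer (orthotopic RGCs / ipRGCs)
    INL = "INL"  # inner nuclear layer (displaced ipRGCs)
    IPL = "IPL"  # inner plexiform layer (rare; grouped with INL in accounting)


class EyeSide(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class Quadrant(str, Enum):
    """Axis-aligned retinal quadrants in the canonical frame."""

    SN = "SN"  # supero-nasal
    ST = "ST"  # supero-temporal
    IN = "IN"  # infero-nasal
    IT = "IT"  # infero-temporal


class Hemiretina(str, Enum):
    NASAL = "nasal"
    TEMPORAL = "temporal"


QUADRANT_ORDER: tuple[Quadrant, ...] = (
    Quadrant.SN,
    Quadrant.ST,
    Quadrant.IN,
    Quadrant.IT,
)

#: Columns every cell table carries.  ``soma`` holds an (n, 2) float array of
#: outline vertices in a local µm frame, or ``None``.
CELL_COLUMNS = ["cell_id", "x_mm", "y_mm", "layer", "melanopsin", "brn3a", "ohst", "soma"]


def _as_contour(vertices) -> np.ndarray:
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise GeometryError("contour must be an (n, 2) array of vertices")
    # tolerate an explicitly repeated closing vertex
    if len(arr) > 1 and np.allclose(arr[0], arr[-1]):
        arr = arr[:-1]
    if len(arr) < 3:
        raise GeometryError("contour needs at least 3 distinct vertices")
    return arr


@dataclass
class RetinaGeometry:
    """Spatial frame of one flat-mounted retina.

    Parameters
    ----------
    contour:
        Ordered vertices of the retinal outline (mm).  Must form a simple
        (non-self-intersecting) closed polygon.
    on_center:
        Position of the optic-nerve head (mm), strictly inside ``contour``.
    eye_side:
        ``"left"`` or ``"right"``; required before canonicalisation.
    strain:
        Free-text animal/strain label (e.g. ``"pigmented"``).
    """

    contour: np.ndarray
    on_center: np.ndarray
    eye_side: str | None = None
    strain: str = ""

    def __post_init__(self) -> None:
        self.contour = _as_contour(self.contour)
        self.on_center = np.asarray(self.on_center, dtype=float).reshape(2)
        poly = Polygon(self.contour)
        if not (poly.is_valid and poly.is_simple):
            raise GeometryError("contour is not a simple polygon")
        if self.eye_side is not None:
            self.eye_side = EyeSide(self.eye_side).value
        self._polygon = poly
        if not poly.contains(Point(self.on_center)):
            raise GeometryError("optic-nerve center must lie strictly inside the contour")

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    @property
    def area_mm2(self) -> float:
        """Planimetric retinal area (mm²)."""
        return float(self._polygon.area)

    # -- vectorised point queries ------------------------------------------

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Boolean mask: which points lie inside or on the contour."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        geoms = shapely.points(pts)
        inside = shapely.covers(self._polygon, geoms)
        if not inside.all() and tol > 0:
            # re-test near-misses against a hair-thin buffer (float round-trip)
            miss = ~inside
            inside[miss] = shapely.covers(self._polygon.buffer(tol), geoms[miss])
        return inside

    def edge_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance (mm) from each point to the nearest contour edge."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return shapely.distance(shapely.points(pts), self._polygon.exterior)


def distance_to_contour(p, geometry: RetinaGeometry) -> float:
    """Minimum Euclidean distance (mm) from a point to the retinal edge.

    Raises :class:`DomainError` when ``p`` lies outside the contour.
    """
    p = np.asarray(p, dtype=float).reshape(2)
    if not geometry.contains(p)[0]:
        raise DomainError(f"point {tuple(p)} lies outside the retinal contour")
    return float(geometry.edge_distance(p)[0])


def in_cmz(p, geometry: RetinaGeometry, band: float = DEFAULT_CMZ_BAND_MM) -> bool:
    """True when ``p`` lies within ``band`` mm of the retinal edge (inclusive)."""
    return distance_to_contour(p, geometry) <= band


def assign_quadrant(p) -> Quadrant:
    """Quadrant of a canonical-frame point.

    Nasal is +x and superior is +y; points on a boundary axis are assigned to
    the nasal / superior side respectively.
    """
    x, y = float(p[0]), float(p[1])
    if y >= 0:
        return Quadrant.SN if x >= 0 else Quadrant.ST
    return Quadrant.IN if x >= 0 else Quadrant.IT


def assign_quadrants(points: np.ndarray) -> np.ndarray:
    """Vectorised :func:`assign_quadrant`; returns an array of quadrant labels."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    nasal = pts[:, 0] >= 0
    superior = pts[:, 1] >= 0
    out = np.empty(len(pts), dtype="U2")
    out[nasal & superior] = Quadrant.SN.value
    out[~nasal & superior] = Quadrant.ST.value
    out[nasal & ~superior] = Quadrant.IN.value
    out[~nasal & ~superior] = Quadrant.IT.value
    return out


def hemiretina(p) -> Hemiretina:
    """Nasal (x >= 0) or temporal (x < 0) half, canonical frame."""
    return Hemiretina.NASAL if float(p[0]) >= 0 else Hemiretina.TEMPORAL


def hemiretinas(points: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.empty(len(pts), dtype="U8")
    nasal = pts[:, 0] >= 0
    out[nasal] = Hemiretina.NASAL.value
    out[~nasal] = Hemiretina.TEMPORAL.value
    return out


@dataclass
class CellTable:
    """All labelled cells of one retina, bound to its geometry.

    ``cells`` is a DataFrame with columns ``cell_id, x_mm, y_mm, layer,
    melanopsin, brn3a, ohst, soma`` (see :data:`CELL_COLUMNS`).  Positions are
    mm in the same frame as ``retina``; ``canonical`` records whether that
    frame is the canonical one (ON at origin, nasal +x, superior +y).
    """

    retina: RetinaGeometry
    cells: pd.DataFrame
    canonical: bool = False

    def __post_init__(self) -> None:
        df = self.cells
        missing = [c for c in CELL_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"cell table missing columns: {missing}")
        df = df[CELL_COLUMNS].reset_index(drop=True)
        if df["cell_id"].duplicated().any():
            dups = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()
            raise DataError(f"duplicate cell_id values: {dups[:5]}")
        bad_layer = ~df["layer"].isin([l.value for l in Layer])
        if bad_layer.any():
            raise DataError(
                f"invalid layer values: {sorted(df.loc[bad_layer, 'layer'].unique())}"
            )
        for col in ("melanopsin", "brn3a", "ohst"):
            df[col] = df[col].astype(bool)
        if len(df):
            inside = self.retina.contains(df[["x_mm", "y_mm"]].to_numpy(), tol=1e-6)
            if not inside.all():
                ids = df.loc[~inside, "cell_id"].tolist()
                raise DataError(f"cells outside the retinal contour: {ids[:10]}")
        self.cells = df

    # -- basic views --------------------------------------------------------

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of cell positions (mm)."""
        return self.cells[["x_mm", "y_mm"]].to_numpy()

    def subset(self, mask: np.ndarray) -> "CellTable":
        sub = self.cells.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True)
        return CellTable(self.retina, sub, canonical=self.canonical)

    def mask(
        self,
        *,
        layer=None,
        melanopsin: bool | None = None,
        brn3a: bool | None = None,
        ohst: bool | None = None,
        cmz: bool | None = None,
        band: float = DEFAULT_CMZ_BAND_MM,
    ) -> np.ndarray:
        """Boolean population filter over the cells.

        ``layer`` may be a single layer or an iterable of layers; ``cmz``
        selects (or excludes) cells within ``band`` mm of the retinal edge.
        Omitted criteria do not constrain.
        """
        df = self.cells
        m = np.ones(len(df), dtype=bool)
        if layer is not None:
            layers = [layer] if isinstance(layer, (str, Layer)) else list(layer)
            layers = [Layer(l).value for l in layers]
            m &= df["layer"].isin(layers).to_numpy()
        for col, want in (("melanopsin", melanopsin), ("brn3a", brn3a), ("ohst", ohst)):
            if want is not None:
                m &= df[col].to_numpy() == want
        if cmz is not None and len(df):
            rim = self.retina.edge_distance(self.positions) <= band
            m &= rim if cmz else ~rim
        return m


def canonicalize(table: CellTable) -> CellTable:
    """Bring a cell table into the canonical frame.

    The ON is translated to the origin.  Right-eye retinas are translated
    only; left-eye retinas are additionally mirrored about the vertical axis
    (x -> -x) so that nasal maps to +x.  Both operations are isometries, so
    all pairwise inter-cell distances are preserved.  Soma outlines live in
    per-cell local frames and are left untouched (chord statistics are
    reflection-invariant).
    """
    if table.canonical:
        return table
    g = table.retina
    if g.eye_side is None:
        raise ConfigurationError("eye_side must be set before canonicalisation")
    mirror = -1.0 if g.eye_side == EyeSide.LEFT.value else 1.0

    contour = (g.contour - g.on_center) * np.array([mirror, 1.0])
    if mirror < 0:
        contour = contour[::-1]  # keep vertex orientation after reflection
    geom = RetinaGeometry(contour, (0.0, 0.0), eye_side=g.eye_side, strain=g.strain)

    df = table.cells.copy()
    df["x_mm"] = (df["x_mm"] - g.on_center[0]) * mirror
    df["y_mm"] = df["y_mm"] - g.on_center[1]
    logger.info(
        "canonicalized %s-eye retina (%d cells, mirrored=%s)",
        g.eye_side, len(df), mirror < 0,
    )
    return CellTable(geom, df, canonical=True)
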