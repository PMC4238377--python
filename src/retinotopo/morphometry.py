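"""Chord-based soma morphometry.

Soma size is summarised the way the microscopy routine measured it: the
soma outline is a small closed polygon (µm, local frame), and the diameter
is the mean length of the chords through the area centroid taken at 2°
angular intervals.  A chord at angle θ and θ+180° is the same segment, so
the default sweep covers [0°, 180°) — 90 chords.

For non-convex outlines a centroid line can cross the boundary more than
twice; the chord is then read calliper-style as the outermost span (distance
between the two extreme boundary intersections), and the condition is
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .errors import DataError, GeometryError

DEFAULT_ANGLE_STEP_DEG = 2.0


def _polygon(outline) -> tuple[np.ndarray, Polygon]:
    verts = np.asarray(outline, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise GeometryError("soma outline must be an (n>=3, 2) vertex array")
    if np.allclose(verts[0], verts[-1]) and len(verts) > 3:
        verts = verts[:-1]
    poly = Polygon(verts)
    if not (poly.is_valid and poly.is_simple) or poly.area <= 0:
        raise GeometryError("soma outline is degenerate (self-intersecting or zero area)")
    return verts, poly


def _area_centroid(verts: np.ndarray) -> np.ndarray:
    """Shoelace area centroid of a closed polygon given as open vertex list."""
    x, y = verts[:, 0], verts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area6 = 3.0 * cross.sum()  # 6 * signed area
    if area6 == 0:
        raise GeometryError("zero-area outline has no centroid")
    return np.array([((x + x1) * cross).sum() / area6, ((y + y1) * cross).sum() / area6])


def soma_centroid(outline) -> np.ndarray:
    """Area centroid (not vertex mean) of a soma outline polygon."""
    verts, _ = _polygon(outline)
    return _area_centroid(verts)


def _chord_spans(verts: np.ndarray, c: np.ndarray, ang_rad: np.ndarray):
    """Outermost chord span through ``c`` for each direction, pure numpy.

    Returns ``(lengths, multi)``; ``multi[i]`` marks lines crossing the
    boundary more than twice (non-convex outline, outermost span reported).
    """
    d = np.stack([np.cos(ang_rad), np.sin(ang_rad)], axis=1)  # (A, 2)
    v0 = verts                                                # (E, 2)
    e = np.roll(verts, -1, axis=0) - verts                    # (E, 2)
    w = v0 - c                                                # (E, 2)

    # Solve c + t*d = v0 + s*e per (angle, edge) via 2-D cross products.
    denom = d[:, None, 0] * e[None, :, 1] - d[:, None, 1] * e[None, :, 0]   # (A, E)
    wxe = w[None, :, 0] * e[None, :, 1] - w[None, :, 1] * e[None, :, 0]
    wxd = w[None, :, 0] * d[:, None, 1] - w[None, :, 1] * d[:, None, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = wxe / denom
        s = wxd / denom
    valid = (np.abs(denom) > 1e-12) & (s >= -1e-9) & (s <= 1 + 1e-9)
    t = np.where(valid, t, np.nan)

    t_min = np.nanmin(t, axis=1)
    t_max = np.nanmax(t, axis=1)
    bad = ~np.isfinite(t_min) | ~np.isfinite(t_max) | (t_min > 0) | (t_max < 0)
    if bad.any():
        theta = float(np.rad2deg(ang_rad[np.argmax(bad)]))
        raise GeometryError(f"no two-sided boundary crossing at angle {theta:.1f} deg")

    # distinct crossings per angle (shared edge endpoints duplicate t values):
    # sort, then count adjacent gaps larger than tolerance.
    t_sorted = np.sort(t, axis=1)  # NaNs sort to the end
    finite = np.isfinite(t_sorted)
    gaps = (np.diff(t_sorted, axis=1) > 1e-9) & finite[:, 1:]
    n_crossings = 1 + gaps.sum(axis=1)
    return t_max - t_min, n_crossings > 2


def chord_lengths(outline, angles_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lengths of centroid chords at the given angles (validated input).

    Returns ``(lengths, multi)`` where ``multi[i]`` is True when the line at
    ``angles_deg[i]`` crossed the boundary more than twice (non-convex
    outline; outermost span reported).
    """
    verts, poly = _polygon(outline)
    c = _area_centroid(verts)
    if not poly.contains(Point(c)):
        raise GeometryError("centroid lies outside the outline; chord diameters undefined")
    return _chord_spans(verts, c, np.deg2rad(np.asarray(angles_deg, dtype=float)))


def soma_diameter(
    outline, step_deg: float = DEFAULT_ANGLE_STEP_DEG, with_flags: bool = False
):
    """Mean centroid-chord diameter (µm) over angles 0°, step, ..., <180°."""
    angles = np.arange(0.0, 180.0, step_deg)
    lengths, multi = chord_lengths(outline, angles)
    mean = float(lengths.mean())
    if with_flags:
        return mean, bool(multi.any())
    return mean


@dataclass
class SomaMetrics:
    """Population soma-diameter summary (µm)."""

    n: int
    mean_um: float
    sd_um: float
    min_um: float
    max_um: float
    diameters: pd.Series  # per-cell mean diameter, indexed by cell_id
    n_multi_interval: int = 0  # cells where a non-convex outermost span was used

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_um": self.mean_um,
            "sd_um": self.sd_um,
            "min_um": self.min_um,
            "max_um": self.max_um,
            "n_multi_interval": self.n_multi_interval,
        }


def population_soma_stats(table, mask=None, step_deg: float = DEFAULT_ANGLE_STEP_DEG) -> SomaMetrics:
    """Mean / SD (n-1) / min / max of per-cell chord diameters for a population.

    Every filtered cell must carry a soma outline; offenders are listed in the
    raised :class:`DataError`.
    """
    df = table.cells if mask is None else table.cells.loc[np.asarray(mask, dtype=bool)]
    missing = [cid for cid, soma in zip(df["cell_id"], df["soma"]) if soma is None]
    if missing:
        raise DataError(f"cells missing soma outlines: {missing[:10]}")
    values, flags = [], 0
    for soma in df["soma"]:
        mean, multi = soma_diameter(soma, step_deg=step_deg, with_flags=True)
        values.append(mean)
        flags += int(multi)
    diam = pd.Series(values, index=df["cell_id"].to_numpy(), name="diameter_um")
    n = len(diam)
    if n == 0:
        return SomaMetrics(0, float("nan"), float("nan"), float("nan"), float("nan"), diam)
    sd = float(diam.std(ddof=1)) if n > 1 else 0.0
    return SomaMetrics(
        n, float(diam.mean()), sd, float(diam.min()), float(diam.max()), diam, flags
    )
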