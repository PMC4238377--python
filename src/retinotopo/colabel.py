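"""Marker colocalization accounting.

Covers the three count-derived analyses of the study design:

* whole-retina tracing/expression percentages (fraction of a reference
  population positive for a second marker, e.g. melanopsin cells that are
  OHSt-traced, or that express Brn3a);
* ciliary-marginal-zone accounting (traced vs untraced melanopsin cells per
  nasal/temporal hemiretina within the rim band);
* displaced-cell accounting (melanopsin cells in the INL/IPL: traced vs
  untraced, inside vs outside the CMZ, and their share of the total
  melanopsin population).

Printed percentages in the companion tables are truncated (not rounded) at
the reported precision; :func:`truncate_percent` reproduces that display
convention while raw counts are always carried alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import DomainError, FrameError
from .geometry import DEFAULT_CMZ_BAND_MM, CellTable, Layer

#: Default mutual-nearest-neighbor pairing tolerance (mm) for point sets
#: digitised from separate channels (10 µm ~ one soma radius).
DEFAULT_MATCH_TOLERANCE_MM = 0.010


def truncate_percent(value: float, decimals: int = 1) -> float:
    """Truncate a percentage toward zero at the given number of decimals."""
    scale = 10 ** decimals
    return math.floor(value * scale + 1e-9) / scale


def percent(n_double: int, n_reference: int) -> float:
    """100 * n_double / n_reference; NaN when the denominator is empty."""
    if n_reference == 0:
        return float("nan")
    return 100.0 * n_double / n_reference


def match_points(set_a: np.ndarray, set_b: np.ndarray, tolerance: float = DEFAULT_MATCH_TOLERANCE_MM):
    """Pair two point sets by mutual nearest neighbors within a tolerance.

    Returns ``(pairs, distances)`` where ``pairs`` is an (m, 2) integer array
    of (index in A, index in B).  Pairs are accepted greedily by ascending
    distance and each point enters at most one pair.  Intended for users
    whose marker channels arrive as separate coordinate lists; the native
    cell-table format carries per-cell boolean flags instead.
    """
    if tolerance <= 0:
        raise DomainError("matching tolerance must be positive")
    a = np.atleast_2d(np.asarray(set_a, dtype=float)) if len(set_a) else np.zeros((0, 2))
    b = np.atleast_2d(np.asarray(set_b, dtype=float)) if len(set_b) else np.zeros((0, 2))
    if len(a) == 0 or len(b) == 0:
        return np.zeros((0, 2), dtype=int), np.zeros(0)
    tree_a, tree_b = cKDTree(a), cKDTree(b)
    d_ab, j_ab = tree_b.query(a)
    _, j_ba = tree_a.query(b)
    cand = [(d_ab[i], i, j_ab[i]) for i in range(len(a)) if j_ba[j_ab[i]] == i and d_ab[i] <= tolerance]
    cand.sort()
    used_a, used_b, pairs, dists = set(), set(), [], []
    for d, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
        dists.append(d)
    return np.array(pairs, dtype=int).reshape(-1, 2), np.array(dists)


@dataclass
class ColocalizationTable:
    """Fraction of a reference population positive for a second marker."""

    compartment: str
    second_marker: str
    n_reference: int
    n_double: int

    def __post_init__(self) -> None:
        if self.n_double > self.n_reference:
            raise DomainError("n_double cannot exceed n_reference")

    @property
    def percent(self) -> float:
        return percent(self.n_double, self.n_reference)

    @property
    def defined(self) -> bool:
        """False when the reference population is empty (percent is NaN)."""
        return self.n_reference > 0

    def display_percent(self, decimals: int = 1) -> float:
        return truncate_percent(self.percent, decimals) if self.defined else float("nan")

    def to_dict(self) -> dict:
        return {
            "compartment": self.compartment,
            "second_marker": self.second_marker,
            "n_reference": self.n_reference,
            "n_double": self.n_double,
            "percent": self.percent if self.defined else None,
        }


def coloc_percent(
    table: CellTable, reference_mask, second_marker: str, compartment: str = ""
) -> ColocalizationTable:
    """Colocalization fraction: reference cells whose ``second_marker`` flag is true."""
    if second_marker not in ("melanopsin", "brn3a", "ohst"):
        raise DomainError(f"unknown marker {second_marker!r}")
    m = np.asarray(reference_mask, dtype=bool)
    flags = table.cells[second_marker].to_numpy()
    return ColocalizationTable(
        compartment=compartment,
        second_marker=second_marker,
        n_reference=int(m.sum()),
        n_double=int((m & flags).sum()),
    )


@dataclass
class CmzAccount:
    """Traced/untraced melanopsin cells in the CMZ rim, per hemiretina."""

    band_mm: float
    nasal_traced: int
    nasal_untraced: int
    temporal_traced: int
    temporal_untraced: int

    @property
    def nasal_total(self) -> int:
        return self.nasal_traced + self.nasal_untraced

    @property
    def temporal_total(self) -> int:
        return self.temporal_traced + self.temporal_untraced

    @property
    def total(self) -> int:
        return self.nasal_total + self.temporal_total

    @property
    def nasal_share_percent(self) -> float:
        return percent(self.nasal_total, self.total)

    def traced_percent(self, hemi: str) -> float:
        if hemi == "nasal":
            return percent(self.nasal_traced, self.nasal_total)
        if hemi == "temporal":
            return percent(self.temporal_traced, self.temporal_total)
        raise DomainError(f"unknown hemiretina {hemi!r}")

    @property
    def untraced_percent(self) -> float:
        return percent(self.nasal_untraced + self.temporal_untraced, self.total)

    def to_dict(self) -> dict:
        return {
            "band_mm": self.band_mm,
            "nasal": {"traced": self.nasal_traced, "untraced": self.nasal_untraced},
            "temporal": {"traced": self.temporal_traced, "untraced": self.temporal_untraced},
            "total": self.total,
            "nasal_share_percent": self.nasal_share_percent if self.total else None,
            "untraced_percent": self.untraced_percent if self.total else None,
        }


def cmz_account(table: CellTable, band: float = DEFAULT_CMZ_BAND_MM) -> CmzAccount:
    """Account of melanopsin cells within the CMZ band, split by hemiretina.

    Requires the canonical frame (nasal = x >= 0).  Traced means OHSt-positive.
    """
    if not table.canonical:
        raise FrameError("cmz_account requires a canonicalized table")
    mel_rim = table.mask(melanopsin=True, cmz=True, band=band)
    df = table.cells.loc[mel_rim]
    nasal = df["x_mm"].to_numpy() >= 0
    traced = df["ohst"].to_numpy()
    return CmzAccount(
        band_mm=band,
        nasal_traced=int((nasal & traced).sum()),
        nasal_untraced=int((nasal & ~traced).sum()),
        temporal_traced=int((~nasal & traced).sum()),
        temporal_untraced=int((~nasal & ~traced).sum()),
    )


@dataclass
class DisplacedAccount:
    """Displaced melanopsin cells (INL, plus rare IPL), traced vs untraced, in/out of CMZ."""

    n_total: int
    n_traced_cmz: int
    n_traced_outside: int
    n_untraced_cmz: int
    n_untraced_outside: int
    total_iprgc: int

    @property
    def n_traced(self) -> int:
        return self.n_traced_cmz + self.n_traced_outside

    @property
    def n_untraced(self) -> int:
        return self.n_untraced_cmz + self.n_untraced_outside

    @property
    def percent_of_total(self) -> float:
        """Displaced cells as a percentage of the total melanopsin population."""
        return percent(self.n_total, self.total_iprgc)

    @property
    def untraced_percent(self) -> float:
        return percent(self.n_untraced, self.n_total)

    @property
    def untraced_cmz_share_percent(self) -> float:
        """Share of the untraced displaced cells residing in the CMZ."""
        return percent(self.n_untraced_cmz, self.n_untraced)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "traced": {"cmz": self.n_traced_cmz, "outside": self.n_traced_outside},
            "untraced": {"cmz": self.n_untraced_cmz, "outside": self.n_untraced_outside},
            "total_iprgc": self.total_iprgc,
            "percent_of_total": self.percent_of_total if self.total_iprgc else None,
            "untraced_percent": self.untraced_percent if self.n_total else None,
        }


def displaced_account(
    table: CellTable, total_iprgc: int, band: float = DEFAULT_CMZ_BAND_MM
) -> DisplacedAccount:
    """Account of displaced melanopsin cells (soma in the INL; IPL grouped with INL).

    ``total_iprgc`` is the denominator for the population share and must be at
    least the number of displaced cells found.
    """
    mel_displaced = table.mask(melanopsin=True, layer=(Layer.INL, Layer.IPL))
    n_total = int(mel_displaced.sum())
    if total_iprgc < n_total:
        raise DomainError(
            f"total_iprgc ({total_iprgc}) is below the displaced-cell count ({n_total})"
        )
    df = table.cells.loc[mel_displaced]
    if n_total:
        rim = table.retina.edge_distance(df[["x_mm", "y_mm"]].to_numpy()) <= band
    else:
        rim = np.zeros(0, dtype=bool)
    traced = df["ohst"].to_numpy()
    return DisplacedAccount(
        n_total=n_total,
        n_traced_cmz=int((traced & rim).sum()),
        n_traced_outside=int((traced & ~rim).sum()),
        n_untraced_cmz=int((~traced & rim).sum()),
        n_untraced_outside=int((~traced & ~rim).sum()),
        total_iprgc=total_iprgc,
    )
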