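"""End-to-end per-retina and cross-retina analysis.

``analyze`` strings the stages together the way the study reports them:
canonicalise every retina, then per retina build the melanopsin neighbor
map, the Brn3a isodensity grid, the radial profile, the colocalization
tables (tracing and Brn3a co-expression, by compartment), the CMZ account,
the displaced-cell account and the soma statistics; then pool same-strain
retinas into a normalized map and, when two strains are present, run the
between-strain comparisons.  The machine-readable JSON summary is the single
source of truth; CSV/PNG outputs are derived views carrying the config as a
provenance header.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import colabel, topography
from .colabel import cmz_account, coloc_percent, displaced_account
from .errors import ConfigurationError
from .geometry import (
    DEFAULT_CMZ_BAND_MM,
    QUADRANT_ORDER,
    CellTable,
    Layer,
    assign_quadrants,
    canonicalize,
)
from .morphometry import population_soma_stats
from .groupstats import mann_whitney, t_test
from .io import write_csv_with_provenance

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable constants of the pipeline (mm / mm² where dimensional)."""

    neighbor_radius_mm: float = topography.DEFAULT_NEIGHBOR_RADIUS_MM
    cmz_band_mm: float = DEFAULT_CMZ_BAND_MM
    radial_bin_mm: float = topography.DEFAULT_RADIAL_BIN_MM
    isodensity_bin_area_mm2: float = topography.DEFAULT_BIN_AREA_MM2
    color_scale: str = "single"
    normalized_scale: str = "normalized3"
    match_tolerance_mm: float = colabel.DEFAULT_MATCH_TOLERANCE_MM
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("neighbor_radius_mm", "cmz_band_mm", "radial_bin_mm",
                     "isodensity_bin_area_mm2", "match_tolerance_mm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def analyze_retina(table: CellTable, config: AnalysisConfig, name: str = "") -> dict:
    """All per-retina quantifications; ``table`` must be canonical."""
    band = config.cmz_band_mm
    mel_gcl = table.mask(melanopsin=True, layer=Layer.GCL)
    mel_gcl_interior = table.mask(melanopsin=True, layer=Layer.GCL, cmz=False, band=band)
    mel_cmz_gcl = table.mask(melanopsin=True, layer=Layer.GCL, cmz=True, band=band)
    mel_inl = table.mask(melanopsin=True, layer=(Layer.INL, Layer.IPL))
    mel_all = table.mask(melanopsin=True)
    brn3a_gcl = table.mask(brn3a=True, melanopsin=False, layer=Layer.GCL)
    n_mel_gcl = int(mel_gcl.sum())
    logger.info(
        "%s: %d cells (mel GCL %d, mel INL %d, Brn3a %d)",
        name or "retina", len(table), n_mel_gcl, int(mel_inl.sum()), int(brn3a_gcl.sum()),
    )

    nmap = topography.neighbor_counts(
        table, mel_gcl, radius=config.neighbor_radius_mm, scale=config.color_scale
    )
    grid = topography.isodensity_grid(table, brn3a_gcl, bin_area=config.isodensity_bin_area_mm2)
    profile = topography.radial_profile(table, mel_gcl, bin_width=config.radial_bin_mm)

    quad = assign_quadrants(table.positions[mel_gcl_interior]) if mel_gcl_interior.any() \
        else np.array([], dtype=object)
    quadrant_counts = {q.value: int((quad == q.value).sum()) for q in QUADRANT_ORDER}

    coloc = {
        "ohst_in_mel_gcl_interior": coloc_percent(table, mel_gcl_interior, "ohst",
                                                  "GCL outside CMZ").to_dict(),
        "ohst_in_mel_cmz_gcl": coloc_percent(table, mel_cmz_gcl, "ohst", "CMZ (GCL)").to_dict(),
        "ohst_in_mel_inl": coloc_percent(table, mel_inl, "ohst", "INL (displaced)").to_dict(),
        "brn3a_in_mel_all": coloc_percent(table, mel_all, "brn3a", "whole retina").to_dict(),
    }

    soma = {}
    sub = table.cells
    if mel_gcl.any() and all(s is not None for s in sub.loc[mel_gcl, "soma"]):
        soma["mel_gcl"] = population_soma_stats(table, mel_gcl).to_dict()
    if mel_inl.any() and all(s is not None for s in sub.loc[mel_inl, "soma"]):
        soma["mel_inl"] = population_soma_stats(table, mel_inl).to_dict()

    return {
        "name": name,
        "strain": table.retina.strain,
        "eye_side": table.retina.eye_side,
        "area_mm2": table.retina.area_mm2,
        "counts": {
            "total": len(table),
            "brn3a_gcl": int(brn3a_gcl.sum()),
            "mel_gcl": n_mel_gcl,
            "mel_gcl_interior": int(mel_gcl_interior.sum()),
            "mel_cmz_all_layers": int(table.mask(melanopsin=True, cmz=True, band=band).sum()),
            "mel_inl": int(mel_inl.sum()),
        },
        "quadrant_counts_mel_gcl_interior": quadrant_counts,
        "neighbor_map": {
            "radius_mm": nmap.radius,
            "n_cells": nmap.n_cells,
            "class_histogram": nmap.class_histogram().tolist(),
        },
        "isodensity": {
            "bin_area_mm2": grid.bin_area,
            "n_bins": len(grid.bins),
            "total_count": grid.total_count,
            "mean_density": float(grid.bins["density"].mean()) if len(grid.bins) else 0.0,
            "max_density": float(grid.bins["density"].max()) if len(grid.bins) else 0.0,
        },
        "radial_profile": {
            "bin_width_mm": config.radial_bin_mm,
            "total": profile.total.tolist(),
            "per_quadrant": {c: profile.per_quadrant[c].tolist() for c in profile.per_quadrant},
        },
        "cmz": cmz_account(table, band=band).to_dict(),
        "displaced": displaced_account(table, total_iprgc=n_mel_gcl, band=band).to_dict()
        if n_mel_gcl >= int(mel_inl.sum()) else None,
        "colocalization": coloc,
        "soma": soma,
    }


def analyze(tables: list[CellTable], config: AnalysisConfig | None = None,
            outdir=None, names=None) -> dict:
    """Run the full pipeline over one or more retinas.

    Returns the JSON-serialisable summary; when ``outdir`` is given, the
    summary and flat CSV views are written there (with provenance headers).
    Deterministic for fixed inputs, config and seed.
    """
    if not tables:
        raise ConfigurationError("analyze requires at least one cell table")
    config = config or AnalysisConfig()
    names = names or [f"retina_{i}" for i in range(len(tables))]
    canonical = [canonicalize(t) for t in tables]

    summary = {
        "config": config.to_dict(),
        "retinas": [analyze_retina(t, config, name=n) for t, n in zip(canonical, names)],
    }

    # cross-retina normalized maps, per strain
    strains = sorted({t.retina.strain for t in canonical})
    normalized = {}
    for strain in strains:
        group = [t for t in canonical if t.retina.strain == strain]
        masks = [t.mask(melanopsin=True, layer=Layer.GCL) for t in group]
        nmap = topography.normalized_map(
            group, masks, radius=config.neighbor_radius_mm, scale=config.normalized_scale
        )
        normalized[strain or "all"] = {
            "n_retinas": len(group),
            "n_cells": nmap.n_cells,
            "class_histogram": nmap.class_histogram().tolist(),
        }
    summary["normalized_maps"] = normalized

    # between-strain comparisons when exactly two strains are present
    if len(strains) == 2:
        summary["group_stats"] = _strain_comparisons(canonical, strains)

    summary = _round_floats(summary)
    if outdir is not None:
        _write_bundle(summary, canonical, config, Path(outdir))
    return summary


def _strain_comparisons(tables: list[CellTable], strains: list[str]) -> dict:
    """Soma-diameter t test and hemiretina-share rank tests between strains."""
    out: dict = {}
    diam = {s: [] for s in strains}
    temporal_share = {s: [] for s in strains}
    superior_share = {s: [] for s in strains}
    for t in tables:
        s = t.retina.strain
        mel_gcl = t.mask(melanopsin=True, layer=Layer.GCL)
        if mel_gcl.any() and all(x is not None for x in t.cells.loc[mel_gcl, "soma"]):
            diam[s].extend(population_soma_stats(t, mel_gcl).diameters.tolist())
        pts = t.positions[mel_gcl]
        if len(pts):
            temporal_share[s].append(float((pts[:, 0] < 0).mean()))
            superior_share[s].append(float((pts[:, 1] >= 0).mean()))
    a, b = strains
    if len(diam[a]) >= 2 and len(diam[b]) >= 2:
        out["soma_diameter_t_test"] = t_test(diam[a], diam[b]).to_dict()
    if temporal_share[a] and temporal_share[b]:
        out["temporal_share_mann_whitney"] = mann_whitney(
            temporal_share[a], temporal_share[b]).to_dict()
        out["superior_share_mann_whitney"] = mann_whitney(
            superior_share[a], superior_share[b]).to_dict()
    out["order"] = [a, b]
    return out


def _write_bundle(summary: dict, tables: list[CellTable], config: AnalysisConfig,
                  outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    prov = {f"config.{k}": v for k, v in config.to_dict().items()}
    rows = []
    for block in summary["retinas"]:
        for key, c in block["colocalization"].items():
            rows.append({
                "retina": block["name"], "strain": block["strain"], "analysis": key,
                "compartment": c["compartment"], "n_reference": c["n_reference"],
                "n_double": c["n_double"], "percent": c["percent"],
            })
    write_csv_with_provenance(pd.DataFrame(rows), outdir / "colocalization.csv", prov)
    cmz_rows = []
    for block in summary["retinas"]:
        for hemi in ("nasal", "temporal"):
            cmz_rows.append({
                "retina": block["name"], "strain": block["strain"], "hemiretina": hemi,
                "traced": block["cmz"][hemi]["traced"],
                "untraced": block["cmz"][hemi]["untraced"],
            })
    write_csv_with_provenance(pd.DataFrame(cmz_rows), outdir / "cmz.csv", prov)
    logger.info("analysis bundle written to %s", outdir)
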