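"""Shared fixtures: small synthetic retinas and hand-built cell tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from retinotopo.geometry import CellTable, RetinaGeometry
from retinotopo.synthetic import Brn3aGradient, SyntheticConfig, generate


def disc_geometry(radius=2.2, n_vertices=256, center=(0.0, 0.0), eye_side="right",
                  strain="") -> RetinaGeometry:
    ang = (np.arange(n_vertices) + 0.5) / n_vertices * 2.0 * np.pi
    contour = np.column_stack([
        center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)
    ])
    return RetinaGeometry(contour, center, eye_side=eye_side, strain=strain)


def make_table(geometry: RetinaGeometry, positions, layer="GCL", melanopsin=True,
               brn3a=False, ohst=False, soma=None, canonical=True,
               id_prefix="x") -> CellTable:
    """Build a CellTable from positions, broadcasting scalar attributes."""
    pts = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(pts)

    def _col(v):
        return list(v) if np.iterable(v) and not isinstance(v, str) else [v] * n

    df = pd.DataFrame({
        "cell_id": [f"{id_prefix}{i:05d}" for i in range(n)],
        "x_mm": pts[:, 0],
        "y_mm": pts[:, 1],
        "layer": _col(layer),
        "melanopsin": _col(melanopsin),
        "brn3a": _col(brn3a),
        "ohst": _col(ohst),
        "soma": list(soma) if soma is not None else [None] * n,
    })
    return CellTable(geometry, df, canonical=canonical)


def random_points_in_disc(rng, n, radius=2.0, center=(0.0, 0.0)) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)])


def small_config(seed=0, **overrides) -> SyntheticConfig:
    """Down-scaled generator config for fast unit/property tests."""
    base = SyntheticConfig(
        n_brn3a=800,
        n_iprgc_gcl=200,
        n_diprgc=30,
        n_cmz_nasal=12,
        n_cmz_temporal=5,
        seed=seed,
    )
    return replace(base, **overrides)


@pytest.fixture(scope="session")
def small_retina():
    """One small synthetic retina (raw frame) shared across read-only tests."""
    return generate(small_config(seed=7))


def regular_polygon(radius, n, center=(0.0, 0.0)) -> np.ndarray:
    ang = np.arange(n) / n * 2.0 * np.pi
    return np.column_stack([center[0] + radius * np.cos(ang),
                            center[1] + radius * np.sin(ang)])
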