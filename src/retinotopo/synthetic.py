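"""Seeded generator of synthetic flat-mounted mouse retinas.

The generator emulates the statistical structure the downstream analyses
assume, so that every stage is testable without microscopy data:

* a ~15 mm² circular retina (fine polygonal disc, radius 2.2 mm);
* a dense Brn3a-positive RGC population (~38 500 pigmented / ~45 900 albino)
  whose density decays with eccentricity, with an elevated streak just
  dorsal to the optic nerve;
* a sparse melanopsin-positive (ipRGC) population in the ganglion cell
  layer with quadrant biases (temporal-heavy in pigmented, superior-heavy in
  albino) and a peripheral radial bias;
* displaced melanopsin cells (d-ipRGCs) in the inner nuclear layer, dorsally
  biased;
* a nasal-biased melanopsin plexus inside the 0.100 mm ciliary-marginal-zone
  rim band;
* per-compartment retrograde-labeling (OHSt) probabilities and a small
  probability of Brn3a co-expression in melanopsin cells;
* noisy-ellipse soma outlines whose chord-mean diameter follows the
  configured per-compartment normal distribution (µm).

Placement counts are exact (each compartment realises its configured count);
marker labeling is Bernoulli per cell.  Everything is driven by a single
seeded pseudo-random stream, so a given config and seed reproduce the same
retina byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely

from .errors import ConfigurationError
from .geometry import DEFAULT_CMZ_BAND_MM, CellTable, RetinaGeometry
from .morphometry import _area_centroid, _chord_spans

_QUADRANT_SECTORS = {  # canonical-frame angular sectors (radians), order SN, ST, IN, IT
    "SN": (0.0, 0.5 * np.pi),
    "ST": (0.5 * np.pi, np.pi),
    "IN": (-0.5 * np.pi, 0.0),
    "IT": (-np.pi, -0.5 * np.pi),
}


@dataclass(frozen=True)
class Brn3aGradient:
    """Density field of the general RGC population.

    Density decays exponentially with distance from the optic nerve
    (``radial_scale_mm``) and is boosted inside a horizontal streak centred
    ``streak_y_mm`` dorsal to the ON — the rodent high-density visual streak.
    """

    radial_scale_mm: float = 1.1
    streak_boost: float = 1.0
    streak_y_mm: float = 0.30
    streak_sigma_mm: float = 0.25

    def weight(self, xy: np.ndarray) -> np.ndarray:
        r = np.hypot(xy[:, 0], xy[:, 1])
        w = np.exp(-r / self.radial_scale_mm)
        w *= 1.0 + self.streak_boost * np.exp(
            -((xy[:, 1] - self.streak_y_mm) ** 2) / (2.0 * self.streak_sigma_mm**2)
        )
        return w

    @property
    def max_weight(self) -> float:
        return 1.0 + self.streak_boost


@dataclass(frozen=True)
class SyntheticConfig:
    """All generative parameters of one synthetic retina.

    Quadrant weights are ordered (SN, ST, IN, IT) and must sum to 1.  The
    radial bias exponent beta places melanopsin cells with radial density
    proportional to r^(1+beta) (beta = 0 is uniform over area; larger beta is
    more peripheral).  Soma means/SDs are µm.
    """

    radius_mm: float = 2.2
    contour_vertices: int = 256
    n_brn3a: int = 38500
    brn3a_gradient: Brn3aGradient = field(default_factory=Brn3aGradient)
    n_iprgc_gcl: int = 1020
    iprgc_quadrant_weights: tuple[float, float, float, float] = (0.21, 0.31, 0.19, 0.29)
    iprgc_radial_bias: float = 2.0
    n_diprgc: int = 147
    diprgc_quadrant_weights: tuple[float, float, float, float] = (0.30, 0.30, 0.20, 0.20)
    n_cmz_nasal: int = 34
    n_cmz_temporal: int = 14
    cmz_band_mm: float = DEFAULT_CMZ_BAND_MM
    p_ohst_gcl: float = 0.997
    p_ohst_diprgc: float = 0.857
    p_ohst_cmz: float = 0.792
    p_ohst_brn3a: float = 0.96
    p_brn3a_in_iprgc: float = 0.0193
    soma_mu_gcl: float = 13.5
    soma_sd_gcl: float = 1.8
    soma_mu_inl: float = 11.8
    soma_sd_inl: float = 1.6
    soma_vertices: int = 32
    soma_noise: float = 0.03
    eye_side: str = "right"
    strain: str = "pigmented"
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_ohst_gcl", "p_ohst_diprgc", "p_ohst_cmz", "p_ohst_brn3a",
                     "p_brn3a_in_iprgc"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} is not a probability")
        for name in ("n_brn3a", "n_iprgc_gcl", "n_diprgc", "n_cmz_nasal", "n_cmz_temporal"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for w in (self.iprgc_quadrant_weights, self.diprgc_quadrant_weights):
            if len(w) != 4 or any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
                raise ConfigurationError("quadrant weights must be 4 nonnegative values summing to 1")
        if self.radius_mm <= 0 and (self.n_brn3a or self.n_iprgc_gcl or self.n_diprgc
                                    or self.n_cmz_nasal or self.n_cmz_temporal):
            raise ConfigurationError("cannot place cells on a zero-area retina")
        if self.radius_mm <= 0 or self.contour_vertices < 3:
            raise ConfigurationError("infeasible retina geometry")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["brn3a_gradient"] = dataclasses.asdict(self.brn3a_gradient)
        return d


def strain_preset(strain: str) -> SyntheticConfig:
    """Preset whose expected counts and probabilities match the published
    strain means (totals, per-compartment tracing fractions, soma sizes,
    quadrant biases).

    ``strain`` is ``"pigmented"`` (C57BL/6-like) or ``"albino"`` (Swiss-like).
    """
    if strain == "pigmented":
        return SyntheticConfig()
    if strain == "albino":
        return SyntheticConfig(
            n_brn3a=45880,
            n_iprgc_gcl=960,
            iprgc_quadrant_weights=(0.31, 0.31, 0.19, 0.19),
            n_diprgc=46,
            n_cmz_nasal=56,
            n_cmz_temporal=26,
            p_ohst_gcl=0.989,
            p_ohst_diprgc=0.717,
            p_ohst_cmz=0.744,
            p_brn3a_in_iprgc=0.0078,
            soma_mu_gcl=14.8,
            soma_sd_gcl=2.2,
            soma_mu_inl=12.9,
            soma_sd_inl=2.3,
            strain="albino",
        )
    raise ConfigurationError(f"unknown strain {strain!r}; expected 'pigmented' or 'albino'")


# ---------------------------------------------------------------------------
# samplers


def _disc_contour(radius: float, n_vertices: int) -> np.ndarray:
    ang = (np.arange(n_vertices) + 0.5) / n_vertices * 2.0 * np.pi
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])


def _sample_brn3a(rng, n, polygon, radius, gradient: Brn3aGradient) -> np.ndarray:
    """Rejection-sample n points from the inhomogeneous Brn3a density."""
    out = np.zeros((0, 2))
    wmax = gradient.max_weight
    while len(out) < n:
        m = max(4 * (n - len(out)), 1000)
        xy = rng.uniform(-radius, radius, size=(m, 2))
        keep = shapely.covers(polygon, shapely.points(xy))
        xy = xy[keep]
        accept = rng.uniform(0.0, 1.0, size=len(xy)) < gradient.weight(xy) / wmax
        out = np.vstack([out, xy[accept]])
    return out[:n]


def _sample_sector(rng, n, polygon, exterior, radius, theta_lo, theta_hi, beta,
                   min_edge=None, max_edge=None) -> np.ndarray:
    """Sample n points in an angular sector with radial density ~ r^(1+beta).

    ``min_edge`` / ``max_edge`` optionally constrain distance to the contour
    (used to keep GCL cells out of the rim band and to confine CMZ cells to it).
    """
    out = np.zeros((0, 2))
    while len(out) < n:
        m = max(4 * (n - len(out)), 64)
        theta = rng.uniform(theta_lo, theta_hi, size=m)
        r = radius * rng.uniform(0.0, 1.0, size=m) ** (1.0 / (2.0 + beta))
        xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        keep = shapely.covers(polygon, shapely.points(xy))
        xy = xy[keep]
        if len(xy) and (min_edge is not None or max_edge is not None):
            d = shapely.distance(shapely.points(xy), exterior)
            ok = np.ones(len(xy), dtype=bool)
            if min_edge is not None:
                ok &= d > min_edge
            if max_edge is not None:
                ok &= d <= max_edge
            xy = xy[ok]
        out = np.vstack([out, xy])
    return out[:n]


def _sample_quadrants(rng, counts_per_quadrant, polygon, exterior, radius, beta,
                      min_edge=None) -> np.ndarray:
    parts = []
    for q, n_q in zip(("SN", "ST", "IN", "IT"), counts_per_quadrant):
        lo, hi = _QUADRANT_SECTORS[q]
        if n_q:
            parts.append(
                _sample_sector(rng, n_q, polygon, exterior, radius, lo, hi, beta,
                               min_edge=min_edge)
            )
    return np.vstack(parts) if parts else np.zeros((0, 2))


def _soma_outline(rng, target_diameter_um, n_vertices, noise) -> np.ndarray:
    """Noisy-ellipse outline whose chord-mean diameter equals the target.

    A unit ellipse (random aspect ratio 0.70-0.95) gets multiplicative radial
    vertex noise, then the polygon is rescaled so its fine-step chord-mean
    diameter matches ``target_diameter_um`` exactly.
    """
    q = rng.uniform(0.70, 0.95)
    phi = np.arange(n_vertices) / n_vertices * 2.0 * np.pi
    r0 = q / np.sqrt((q * np.cos(phi)) ** 2 + np.sin(phi) ** 2)  # ellipse a=1, b=q
    r = r0 * np.clip(1.0 + noise * rng.standard_normal(n_vertices), 0.5, 1.5)
    poly = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    # star-shaped by construction (positive radii), so skip polygon validation
    angles = np.deg2rad(np.arange(0.0, 180.0, 1.0))
    mean_chord = _chord_spans(poly, _area_centroid(poly), angles)[0].mean()
    return poly * (target_diameter_um / mean_chord)


def generate(config: SyntheticConfig) -> tuple[RetinaGeometry, CellTable]:
    """Generate one synthetic retina and its cell table (raw image frame).

    Deterministic given ``config.seed``.  The returned table is in a raw
    frame (ON offset from the origin; left eyes mirrored), exactly as a
    digitised whole-mount would arrive, so the pipeline's canonicalisation
    step is exercised.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    R = config.radius_mm
    contour = _disc_contour(R, config.contour_vertices)
    polygon = shapely.polygons(contour)
    exterior = shapely.get_exterior_ring(polygon)
    band = config.cmz_band_mm

    # --- placement (canonical frame) --------------------------------------
    xy_brn3a = _sample_brn3a(rng, config.n_brn3a, polygon, R, config.brn3a_gradient)

    quad_mel = rng.multinomial(config.n_iprgc_gcl, config.iprgc_quadrant_weights)
    xy_mel = _sample_quadrants(
        rng, quad_mel, polygon, exterior, R, config.iprgc_radial_bias, min_edge=band
    )
    # shuffle so row order does not encode the quadrant
    xy_mel = xy_mel[rng.permutation(len(xy_mel))]

    xy_cmz_n = _sample_sector(rng, config.n_cmz_nasal, polygon, exterior, R,
                              -0.5 * np.pi, 0.5 * np.pi, 6.0, max_edge=band)
    xy_cmz_t = _sample_sector(rng, config.n_cmz_temporal, polygon, exterior, R,
                              0.5 * np.pi, 1.5 * np.pi, 6.0, max_edge=band)
    xy_cmz = np.vstack([xy_cmz_n, xy_cmz_t])

    quad_d = rng.multinomial(config.n_diprgc, config.diprgc_quadrant_weights)
    xy_d = _sample_quadrants(rng, quad_d, polygon, exterior, R, config.iprgc_radial_bias)
    xy_d = xy_d[rng.permutation(len(xy_d))]

    # --- assemble records ---------------------------------------------------
    blocks = []
    blocks.append(pd.DataFrame({
        "cell_id": [f"b{i:06d}" for i in range(len(xy_brn3a))],
        "x_mm": xy_brn3a[:, 0], "y_mm": xy_brn3a[:, 1],
        "layer": "GCL", "melanopsin": False, "brn3a": True,
        "ohst": rng.uniform(size=len(xy_brn3a)) < config.p_ohst_brn3a,
    }))
    blocks.append(pd.DataFrame({
        "cell_id": [f"m{i:05d}" for i in range(len(xy_mel))],
        "x_mm": xy_mel[:, 0], "y_mm": xy_mel[:, 1],
        "layer": "GCL", "melanopsin": True,
        "brn3a": rng.uniform(size=len(xy_mel)) < config.p_brn3a_in_iprgc,
        "ohst": rng.uniform(size=len(xy_mel)) < config.p_ohst_gcl,
    }))
    blocks.append(pd.DataFrame({
        "cell_id": [f"c{i:05d}" for i in range(len(xy_cmz))],
        "x_mm": xy_cmz[:, 0], "y_mm": xy_cmz[:, 1],
        "layer": "GCL", "melanopsin": True,
        "brn3a": rng.uniform(size=len(xy_cmz)) < config.p_brn3a_in_iprgc,
        "ohst": rng.uniform(size=len(xy_cmz)) < config.p_ohst_cmz,
    }))
    blocks.append(pd.DataFrame({
        "cell_id": [f"d{i:05d}" for i in range(len(xy_d))],
        "x_mm": xy_d[:, 0], "y_mm": xy_d[:, 1],
        "layer": "INL", "melanopsin": True,
        "brn3a": rng.uniform(size=len(xy_d)) < config.p_brn3a_in_iprgc,
        "ohst": rng.uniform(size=len(xy_d)) < config.p_ohst_diprgc,
    }))
    df = pd.concat(blocks, ignore_index=True)

    # soma outlines for melanopsin cells (GCL params for GCL/CMZ, INL for displaced)
    somas: list = [None] * len(df)
    mel_idx = np.flatnonzero(df["melanopsin"].to_numpy())
    layers = df["layer"].to_numpy()
    for i in mel_idx:
        mu, sd = ((config.soma_mu_inl, config.soma_sd_inl) if layers[i] == "INL"
                  else (config.soma_mu_gcl, config.soma_sd_gcl))
        target = max(float(rng.normal(mu, sd)), 6.0)
        somas[i] = _soma_outline(rng, target, config.soma_vertices, config.soma_noise)
    df["soma"] = somas

    # --- raw image frame ----------------------------------------------------
    mirror = -1.0 if config.eye_side == "left" else 1.0
    offset = np.array([R + 0.3, R + 0.3])
    raw_contour = contour * np.array([mirror, 1.0]) + offset
    if mirror < 0:
        raw_contour = raw_contour[::-1]
    df["x_mm"] = df["x_mm"] * mirror + offset[0]
    df["y_mm"] = df["y_mm"] + offset[1]

    geometry = RetinaGeometry(
        raw_contour, offset, eye_side=config.eye_side, strain=config.strain
    )
    return geometry, CellTable(geometry, df, canonical=False)
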