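"""Neighbor maps, colour binning, normalized maps, isodensity grids, radial profiles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from retinotopo.errors import DomainError, FrameError
from retinotopo.geometry import canonicalize
from retinotopo.topography import (
    COLOR_SCALES,
    ColorScale,
    bin_color,
    isodensity_grid,
    neighbor_counts,
    normalized_map,
    radial_profile,
)

from conftest import disc_geometry, make_table, random_points_in_disc


def brute_force_counts(points: np.ndarray, radius: float) -> np.ndarray:
    """O(n²) all-pairs oracle: number of other points within radius (inclusive)."""
    if len(points) == 0:
        return np.zeros(0, dtype=int)
    d = cdist(points, points)
    return (d <= radius).sum(axis=1) - 1


class TestNeighborCounts:
    def test_single_cell_has_no_neighbors(self):
        t = make_table(disc_geometry(), [(0.0, 0.0)])
        assert neighbor_counts(t).cells["neighbor_count"].tolist() == [0]

    def test_collinear_chain_counts_immediate_neighbors_only(self):
        # 5 cells 0.1 mm apart: radius 0.165 reaches one step but not two
        pts = [(0.1 * i, 0.0) for i in range(5)]
        t = make_table(disc_geometry(), pts)
        counts = neighbor_counts(t, radius=0.165).cells["neighbor_count"]
        assert counts.tolist() == [1, 2, 2, 2, 1]

    def test_matches_brute_force_on_random_points(self):
        rng = np.random.default_rng(21)
        pts = random_points_in_disc(rng, 500, radius=2.1)
        t = make_table(disc_geometry(), pts)
        nmap = neighbor_counts(t, radius=0.165)
        np.testing.assert_array_equal(
            nmap.cells["neighbor_count"].to_numpy(), brute_force_counts(pts, 0.165)
        )

    def test_invariant_under_canonicalize(self):
        rng = np.random.default_rng(5)
        pts = random_points_in_disc(rng, 300, radius=1.8, center=(3.0, 2.0))
        g = disc_geometry(center=(3.0, 2.0), eye_side="left")
        t = make_table(g, pts, canonical=False)
        raw = neighbor_counts(t).cells["neighbor_count"].to_numpy()
        canon = neighbor_counts(canonicalize(t)).cells["neighbor_count"].to_numpy()
        np.testing.assert_array_equal(raw, canon)

    def test_rejects_nonpositive_radius(self):
        t = make_table(disc_geometry(), [(0.0, 0.0)])
        with pytest.raises(DomainError):
            neighbor_counts(t, radius=0.0)

    def test_symmetry_of_neighbor_relation(self):
        rng = np.random.default_rng(8)
        pts = random_points_in_disc(rng, 100)
        d = cdist(pts, pts)
        within = d <= 0.165
        assert (within == within.T).all()  # i counts j iff j counts i


class TestColorScale:
    def test_single_retina_scale_endpoints(self):
        scale = COLOR_SCALES["single"]  # purple 0-1 ... red >= 11
        assert bin_color(0, scale) == 0
        assert bin_color(1, scale) == 0
        assert bin_color(11, scale) == scale.n_classes - 1
        assert bin_color(2, scale) == 1

    def test_normalized_scale_endpoints(self):
        scale = COLOR_SCALES["normalized3"]  # purple 0-3 ... red >= 28
        assert bin_color(30, scale) == scale.n_classes - 1
        assert bin_color(3, scale) == 0
        assert bin_color(28, scale) == scale.n_classes - 1  # boundary inclusive

    def test_monotone_nondecreasing_and_in_range(self):
        for scale in COLOR_SCALES.values():
            classes = bin_color(np.arange(60), scale)
            assert (np.diff(classes) >= 0).all()
            assert classes.min() == 0 and classes.max() == scale.n_classes - 1

    def test_invalid_scales_rejected(self):
        with pytest.raises(DomainError):
            ColorScale(1, 0, 5)
        with pytest.raises(DomainError):
            ColorScale(5, 7, 7)


class TestNormalizedMap:
    def test_triple_superposition_brute_force(self):
        # pooling the same table 3x: each position holds 3 coincident cells,
        # so a cell's pooled count is 3 * single + 2 (its own two copies)
        rng = np.random.default_rng(17)
        pts = random_points_in_disc(rng, 20, radius=1.5)
        t = make_table(disc_geometry(), pts)
        single = neighbor_counts(t).cells["neighbor_count"].to_numpy()
        pooled = normalized_map([t, t, t]).cells["neighbor_count"].to_numpy()
        expected = np.concatenate([3 * single + 2] * 3)
        np.testing.assert_array_equal(np.sort(pooled), np.sort(expected))

    def test_one_table_reduces_to_neighbor_counts(self):
        rng = np.random.default_rng(2)
        t = make_table(disc_geometry(), random_points_in_disc(rng, 50))
        a = neighbor_counts(t, scale="normalized3").cells["neighbor_count"]
        b = normalized_map([t]).cells["neighbor_count"]
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_pooled_total_is_additive(self):
        rng = np.random.default_rng(4)
        sizes = [1069, 992, 1000]
        tables = [make_table(disc_geometry(), random_points_in_disc(rng, n)) for n in sizes]
        assert normalized_map(tables).n_cells == sum(sizes)

    def test_requires_canonical_frame(self):
        t = make_table(disc_geometry(eye_side="right"), [(0.0, 0.0)], canonical=False)
        with pytest.raises(FrameError):
            normalized_map([t])


class TestIsodensityGrid:
    def test_empty_population_all_zero(self):
        t = make_table(disc_geometry(), np.zeros((0, 2)))
        grid = isodensity_grid(t)
        assert grid.total_count == 0
        assert (grid.bins["density"] == 0).all()

    def test_single_cell_density_from_frame_constant(self):
        t = make_table(disc_geometry(), [(0.0, 0.0)])
        grid = isodensity_grid(t)  # default bin area = 0.2161/36 mm²
        occupied = grid.bins.loc[grid.bins["count"] > 0]
        assert len(occupied) == 1
        assert occupied["density"].iloc[0] == pytest.approx(1 / (0.2161 / 36), rel=1e-12)
        assert occupied["density"].iloc[0] == pytest.approx(166.6, abs=0.1)

    def test_uniform_density_recovered(self):
        # 10 000 uniform cells in a ~15 mm² disc -> ~666.7 cells/mm² expected
        rng = np.random.default_rng(9)
        radius = np.sqrt(15.0 / np.pi)
        g = disc_geometry(radius=radius, n_vertices=720)
        pts = random_points_in_disc(rng, 10_000, radius=radius * 0.9999)
        grid = isodensity_grid(make_table(g, pts))
        # interior bins only: fully covered by the contour
        side = np.sqrt(grid.bin_area)
        centers = grid.bins[["bin_x", "bin_y"]].to_numpy() + side / 2
        interior = np.hypot(centers[:, 0], centers[:, 1]) < radius - side
        mean_density = grid.bins.loc[interior, "density"].mean()
        expected = 10_000 / 15.0
        se = np.sqrt(expected / grid.bin_area) / np.sqrt(interior.sum())  # Poisson
        assert abs(mean_density - expected) < 3 * se

    def test_counts_conserved(self):
        rng = np.random.default_rng(14)
        pts = random_points_in_disc(rng, 2000, radius=2.1)
        grid = isodensity_grid(make_table(disc_geometry(), pts))
        assert grid.total_count == 2000

    def test_rejects_nonpositive_bin_area(self):
        t = make_table(disc_geometry(), [(0.0, 0.0)])
        with pytest.raises(DomainError):
            isodensity_grid(t, bin_area=-1.0)


class TestRadialProfile:
    def test_half_open_binning(self):
        pts = [(0.1, 0.0), (0.0, 0.2), (0.4, 0.0)]
        prof = radial_profile(make_table(disc_geometry(), pts), bin_width=0.25)
        assert prof.total.tolist() == [2, 1]

    def test_empty_filter_gives_zero_profile(self):
        t = make_table(disc_geometry(), [(0.5, 0.5)])
        prof = radial_profile(t, mask=np.array([False]))
        assert prof.total.sum() == 0

    def test_quadrant_counts_sum_to_total_binwise(self):
        rng = np.random.default_rng(31)
        pts = random_points_in_disc(rng, 1000, radius=2.1)
        prof = radial_profile(make_table(disc_geometry(), pts))
        np.testing.assert_array_equal(
            prof.per_quadrant.sum(axis=1).to_numpy(), prof.total
        )
        # brute-force check of the overall histogram
        r = np.hypot(pts[:, 0], pts[:, 1])
        brute = [((r >= lo) & (r < hi)).sum()
                 for lo, hi in zip(prof.bin_edges[:-1], prof.bin_edges[1:])]
        assert prof.total.tolist() == brute

    def test_requires_canonical_frame(self):
        t = make_table(disc_geometry(eye_side="right"), [(0.1, 0.1)], canonical=False)
        with pytest.raises(FrameError):
            radial_profile(t)
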