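"""Colocalization percentages, CMZ and displaced-cell accounting, point matching."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from retinotopo.colabel import (
    cmz_account,
    coloc_percent,
    displaced_account,
    match_points,
    truncate_percent,
)
from retinotopo.errors import DomainError
from retinotopo.geometry import canonicalize

from conftest import disc_geometry, make_table, random_points_in_disc


def flags(n_true: int, n_total: int) -> np.ndarray:
    return np.arange(n_total) < n_true


class TestMatchPoints:
    def test_identical_sets_pair_perfectly(self):
        rng = np.random.default_rng(0)
        pts = random_points_in_disc(rng, 80)
        pairs, dists = match_points(pts, pts)
        assert len(pairs) == 80
        assert (dists == 0).all()
        assert (pairs[:, 0] == pairs[:, 1]).all()

    def test_large_offset_yields_no_pairs(self):
        rng = np.random.default_rng(1)
        pts = random_points_in_disc(rng, 30)
        pairs, _ = match_points(pts, pts + np.array([0.05, 0.0]), tolerance=0.010)
        assert len(pairs) == 0

    def test_jittered_copy_matches_optimal_assignment(self):
        # 2 µm jitter on a 200-point set: mutual-NN greedy should recover
        # essentially all pairs and agree with the exhaustive optimum
        rng = np.random.default_rng(2)
        a = random_points_in_disc(rng, 200, radius=1.9)
        b = a + rng.normal(0.0, 0.002, size=a.shape)
        perm = rng.permutation(200)
        pairs, _ = match_points(a, b[perm], tolerance=0.010)
        assert len(pairs) >= 0.99 * 200
        # exhaustive optimal assignment oracle on the same instance
        cost = np.linalg.norm(a[:, None, :] - b[perm][None, :, :], axis=2)
        ri, ci = linear_sum_assignment(cost)
        optimal = {(i, j) for i, j in zip(ri, ci) if cost[i, j] <= 0.010}
        assert set(map(tuple, pairs)) <= optimal
        assert len(pairs) == len(optimal)

    def test_empty_sets_allowed(self):
        pairs, dists = match_points(np.zeros((0, 2)), np.zeros((3, 2)))
        assert len(pairs) == 0 and len(dists) == 0


class TestColocPercent:
    def test_published_tracing_fraction_reproduced(self):
        # 1423 melanopsin GCL cells of which 1401 traced -> printed as 98.4%
        rng = np.random.default_rng(3)
        t = make_table(disc_geometry(), random_points_in_disc(rng, 1423),
                       melanopsin=True, ohst=flags(1401, 1423))
        res = coloc_percent(t, t.mask(melanopsin=True, layer="GCL"), "ohst")
        assert res.n_reference == 1423 and res.n_double == 1401
        assert res.display_percent(1) == 98.4

    def test_all_double_labeled_is_100(self):
        rng = np.random.default_rng(4)
        t = make_table(disc_geometry(), random_points_in_disc(rng, 10), ohst=True)
        assert coloc_percent(t, t.mask(melanopsin=True), "ohst").percent == 100.0

    def test_brn3a_expression_fraction_two_decimals(self):
        # 17 of 2179 melanopsin cells Brn3a-positive -> printed as 0.78%
        rng = np.random.default_rng(5)
        t = make_table(disc_geometry(), random_points_in_disc(rng, 2179),
                       brn3a=flags(17, 2179))
        res = coloc_percent(t, t.mask(melanopsin=True), "brn3a")
        assert res.display_percent(2) == 0.78

    def test_empty_reference_flagged_not_zero(self):
        t = make_table(disc_geometry(), [(0.0, 0.0)], melanopsin=False)
        res = coloc_percent(t, t.mask(melanopsin=True), "ohst")
        assert not res.defined
        assert np.isnan(res.percent)

    def test_invariant_under_canonicalize_and_permutation(self):
        rng = np.random.default_rng(6)
        pts = random_points_in_disc(rng, 100, center=(3.0, 3.0))
        g = disc_geometry(center=(3.0, 3.0), eye_side="left")
        t = make_table(g, pts, ohst=flags(37, 100), canonical=False)
        raw = coloc_percent(t, t.mask(melanopsin=True), "ohst")
        canon = coloc_percent(*(lambda c: (c, c.mask(melanopsin=True)))(canonicalize(t)),
                              "ohst")
        shuffled = t.subset(np.ones(100, bool)).cells.sample(frac=1, random_state=0)
        t2 = make_table(g, shuffled[["x_mm", "y_mm"]].to_numpy(),
                        ohst=shuffled["ohst"].tolist(), canonical=False)
        assert raw.percent == canon.percent == 37.0
        assert coloc_percent(t2, t2.mask(melanopsin=True), "ohst").percent == 37.0


def cmz_fixture(n_nasal_traced, n_nasal_untraced, n_temporal_traced, n_temporal_untraced,
                seed=0):
    """Melanopsin cells placed in the rim band of a 2.2 mm disc, per hemiretina."""
    rng = np.random.default_rng(seed)
    g = disc_geometry(radius=2.2, n_vertices=720)
    apothem = 2.2 * np.cos(np.pi / 720)
    rows, ohst = [], []
    specs = [(1, True, n_nasal_traced), (1, False, n_nasal_untraced),
             (-1, True, n_temporal_traced), (-1, False, n_temporal_untraced)]
    for side, traced, n in specs:
        theta = rng.uniform(-0.45 * np.pi, 0.45 * np.pi, size=n)
        if side < 0:
            theta += np.pi
        r = rng.uniform(apothem - 0.095, apothem - 0.005, size=n)
        for th, rr in zip(theta, r):
            rows.append((rr * np.cos(th), rr * np.sin(th)))
            ohst.append(traced)
    return make_table(g, rows, melanopsin=True, ohst=ohst)


class TestCmzAccount:
    def test_published_hemiretinal_counts(self):
        # nasal 26 traced / 8 untraced, temporal 12 / 2 (pigmented, ON tracing)
        t = cmz_fixture(26, 8, 12, 2)
        acc = cmz_account(t)
        assert (acc.nasal_traced, acc.nasal_untraced) == (26, 8)
        assert (acc.temporal_traced, acc.temporal_untraced) == (12, 2)
        assert acc.nasal_share_percent == pytest.approx(100 * 34 / 48)

    def test_no_cmz_cells_gives_zero_account(self):
        t = make_table(disc_geometry(), [(0.0, 0.0)], melanopsin=True)
        acc = cmz_account(t)
        assert acc.total == 0

    def test_all_traced(self):
        t = cmz_fixture(5, 0, 3, 0)
        acc = cmz_account(t)
        assert acc.untraced_percent == 0.0
        assert acc.traced_percent("nasal") == 100.0

    def test_conservation_per_hemiretina(self):
        t = cmz_fixture(7, 3, 4, 6, seed=5)
        acc = cmz_account(t)
        assert acc.nasal_traced + acc.nasal_untraced == acc.nasal_total
        assert acc.nasal_total + acc.temporal_total == acc.total == 20


def displaced_fixture(n_traced_out, n_untraced_out, n_traced_cmz, n_untraced_cmz, seed=0):
    rng = np.random.default_rng(seed)
    g = disc_geometry(radius=2.2, n_vertices=720)
    apothem = 2.2 * np.cos(np.pi / 720)
    rows, ohst = [], []
    for in_cmz_band, traced, n in [(False, True, n_traced_out), (False, False, n_untraced_out),
                                   (True, True, n_traced_cmz), (True, False, n_untraced_cmz)]:
        theta = rng.uniform(0, 2 * np.pi, size=n)
        r = (rng.uniform(apothem - 0.09, apothem - 0.01, size=n) if in_cmz_band
             else rng.uniform(0.2, 1.8, size=n))
        rows.extend(zip(r * np.cos(theta), r * np.sin(theta)))
        ohst.extend([traced] * n)
    return make_table(g, rows, layer="INL", melanopsin=True, ohst=ohst)


class TestDisplacedAccount:
    def test_pigmented_population_shares(self):
        # 147 displaced cells, 21 untraced (half of those in the CMZ), total 1021
        t = displaced_fixture(116, 10, 10, 11)
        acc = displaced_account(t, total_iprgc=1021)
        assert acc.n_total == 147 and acc.n_untraced == 21
        assert round(acc.percent_of_total) == 14
        assert round(acc.untraced_percent) == 14

    def test_albino_untraced_share(self):
        t = displaced_fixture(30, 9, 3, 4)
        acc = displaced_account(t, total_iprgc=962)
        assert acc.n_total == 46 and acc.n_untraced == 13
        assert round(acc.untraced_percent) == 28
        assert round(acc.percent_of_total) == 5

    def test_zero_displaced_cells(self):
        t = make_table(disc_geometry(), [(0.0, 0.0)], layer="GCL", melanopsin=True)
        acc = displaced_account(t, total_iprgc=10)
        assert acc.n_total == 0 and acc.percent_of_total == 0.0

    def test_violated_total_precondition(self):
        t = displaced_fixture(5, 0, 0, 0)
        with pytest.raises(DomainError):
            displaced_account(t, total_iprgc=3)

    def test_inside_outside_conservation(self):
        t = displaced_fixture(8, 3, 5, 2, seed=9)
        acc = displaced_account(t, total_iprgc=100)
        assert acc.n_traced_cmz + acc.n_traced_outside == acc.n_traced == 13
        assert acc.n_untraced_cmz + acc.n_untraced_outside == acc.n_untraced == 5
        assert acc.n_traced + acc.n_untraced == acc.n_total


class TestTruncatePercent:
    @pytest.mark.parametrize("value,decimals,expected", [
        (100 * 1401 / 1423, 1, 98.4),   # would round to 98.5
        (100 * 1398 / 1438, 1, 97.2),
        (100 * 1052 / 1055, 1, 99.7),
        (100 * 733 / 741, 1, 98.9),
        (100 * 17 / 2179, 2, 0.78),
        (100 * 48 / 2478, 2, 1.93),     # would round to 1.94
    ])
    def test_reproduces_printed_table_style(self, value, decimals, expected):
        assert truncate_percent(value, decimals) == expected
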