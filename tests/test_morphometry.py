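import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from morphotree.morphometry import (
    branch_length,
    dm_tortuosity,
    measure_branch,
    soam_angles,
    soam_tortuosity,
    soma_distances,
    tapering,
)
from morphotree.swc import parse_swc
from morphotree.topology import build_forest

from conftest import make_branch
from oracles import ols_slope


def random_branch(rng, n=10, scale=5.0):
    pts = np.cumsum(rng.normal(scale=scale, size=(n, 3)), axis=0)
    return make_branch(pts, radii=rng.uniform(0.2, 1.5, size=n))


class TestBranchLength:
    def test_three_four_five_triangle(self):
        assert branch_length(make_branch([(0, 0, 0), (3, 4, 0)])) == 5.0

    def test_unit_step_staircase(self):
        b = make_branch([(0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0), (2, 2, 0)])
        assert branch_length(b) == pytest.approx(4.0)

    def test_matches_per_segment_brute_force(self):
        rng = np.random.default_rng(3)
        b = random_branch(rng)
        brute = sum(
            math.dist(tuple(b.points[i]), tuple(b.points[i + 1]))
            for i in range(len(b.points) - 1)
        )
        assert branch_length(b) == pytest.approx(brute, rel=1e-12)


class TestDmTortuosity:
    def test_collinear_is_exactly_one(self):
        b = make_branch([(0, 0, 0), (1, 1, 1), (2, 2, 2), (3, 3, 3)])
        assert dm_tortuosity(b) == pytest.approx(1.0)

    def test_l_shape(self):
        b = make_branch([(0, 0, 0), (1, 0, 0), (1, 1, 0)])
        assert dm_tortuosity(b) == pytest.approx(2 / math.sqrt(2))

    def test_coincident_endpoints_reported_missing(self):
        b = make_branch([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 0, 0)])
        with pytest.warns(UserWarning, match="coincident endpoints"):
            assert math.isnan(dm_tortuosity(b))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_dm_at_least_one_always(self, seed):
        rng = np.random.default_rng(seed)
        b = random_branch(rng, n=int(rng.integers(2, 15)))
        assert dm_tortuosity(b) >= 1.0 - 1e-12


class TestSoamTortuosity:
    def test_collinear_branch_is_zero(self):
        b = make_branch([(i, 0, 0) for i in range(8)])
        assert soam_tortuosity(b) == 0.0

    def test_planar_u_turn_hand_value(self):
        # single triple: IP = pi/2, TP = 0, path length 3 -> pi/6
        b = make_branch([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)])
        assert soam_tortuosity(b) == pytest.approx(math.pi / 6, abs=1e-12)

    def test_halves_under_double_scaling(self):
        rng = np.random.default_rng(4)
        b = random_branch(rng)
        doubled = make_branch(2.0 * b.points, radii=b.radii)
        assert soam_tortuosity(doubled) == pytest.approx(soam_tortuosity(b) / 2, rel=1e-9)

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(5)
        b = random_branch(rng)
        # random rotation via QR, plus a translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = make_branch(b.points @ q.T + np.array([10.0, -3.0, 7.0]), radii=b.radii)
        assert soam_tortuosity(moved) == pytest.approx(soam_tortuosity(b), rel=1e-9)

    def test_angles_within_zero_pi(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            b = random_branch(rng, n=int(rng.integers(4, 20)))
            ips, tps = soam_angles(b.points)
            assert np.all(ips >= 0) and np.all(ips <= math.pi)
            assert np.all(tps >= 0) and np.all(tps <= math.pi)

    def test_short_branch_has_empty_angle_sum(self):
        b = make_branch([(0, 0, 0), (1, 0, 0), (1, 1, 0)])
        assert soam_tortuosity(b) == 0.0

    def test_sum_variant_at_least_euclidean(self):
        rng = np.random.default_rng(7)
        b = random_branch(rng)
        assert soam_tortuosity(b, combine="sum") >= soam_tortuosity(b) - 1e-12


class TestTapering:
    def test_constant_diameter(self):
        b = make_branch([(i, 0, 0) for i in range(5)], radii=[0.5] * 5)
        slope, mean, sem = tapering(b)
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert mean == pytest.approx(1.0)
        assert sem == pytest.approx(0.0)

    def test_linear_taper_recovered_exactly(self):
        # diameter 2.0 -> 1.0 over 10 um at 11 uniform points
        pts = [(i, 0, 0) for i in range(11)]
        radii = [(2.0 - 0.1 * i) / 2 for i in range(11)]
        slope, mean, _ = tapering(make_branch(pts, radii=radii))
        assert slope == pytest.approx(-0.1, rel=1e-10)
        assert mean == pytest.approx(1.5)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            b = random_branch(rng, n=int(rng.integers(3, 12)))
            slope, _, _ = tapering(b)
            s = np.concatenate(
                [[0.0], np.cumsum(np.linalg.norm(np.diff(b.points, axis=0), axis=1))]
            )
            assert slope == pytest.approx(ols_slope(s, 2 * b.radii), rel=1e-10, abs=1e-12)

    def test_degenerate_abscissa_gives_missing_slope(self):
        b = make_branch([(0, 0, 0)], radii=[0.5])
        slope, _, _ = tapering(b)
        assert math.isnan(slope)


class TestSomaDistances:
    def test_root_branch_starting_at_soma(self, ytree_forest):
        root = ytree_forest[ytree_forest.roots[0]]
        euclid, path = soma_distances(root, ytree_forest)
        assert euclid == 0.0 and path == 0.0

    def test_straight_cable_euclid_equals_path(self):
        rec = parse_swc(
            "1 3 0 0 0 1 -1\n2 3 0 3 0 1 1\n3 3 0 6 0 1 2\n"
            "4 3 1 7 0 1 3\n5 3 -1 7 0 1 3\n"
        )
        forest = build_forest(rec)
        stem = forest[forest.roots[0]]
        for d in forest.daughters(stem):
            euclid, path = soma_distances(d, forest)
            assert path == pytest.approx(6.0)  # the straight stem
            assert euclid == pytest.approx(6.0)

    def test_ytree_hand_summed_reference(self, ytree_forest):
        stem = ytree_forest[ytree_forest.roots[0]]
        for d in ytree_forest.daughters(stem):
            euclid, path = soma_distances(d, ytree_forest)
            # stem runs (0,0,0)->(0,2,0): both distances are 2
            assert path == pytest.approx(2.0)
            assert euclid == pytest.approx(2.0)

    def test_path_at_least_euclidean_on_random_trees(self):
        from conftest import random_reconstruction

        rng = np.random.default_rng(9)
        for _ in range(20):
            forest = build_forest(random_reconstruction(rng, int(rng.integers(5, 60))))
            for b in forest:
                euclid, path = soma_distances(b, forest)
                assert path >= euclid - 1e-9


def test_measure_branch_bundles_all_metrics(ytree_forest):
    stem = ytree_forest[ytree_forest.roots[0]]
    m = measure_branch(stem, ytree_forest)
    assert m.length == pytest.approx(2.0)
    assert m.dm == pytest.approx(1.0)
    assert m.soam == 0.0
    assert m.soam_too_short  # 3 points only
    assert m.path_to_soma == 0.0
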