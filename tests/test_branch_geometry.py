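import math

import numpy as np
import pytest

from morphotree.branch_geometry import (
    GeometryError,
    bifurcation_angle,
    directional_vector,
    find_bifurcations,
    rall_exponent,
)
from morphotree.generator import FixtureSpec, make_fixture
from morphotree.swc import parse_swc
from morphotree.topology import build_forest

from conftest import make_branch
from oracles import grid_search_rall


class TestDirectionalVector:
    def test_collinear_points_recover_axis_exactly(self):
        b = make_branch([(i, 0, 0) for i in range(7)])
        for end in ("start", "finish"):
            v = directional_vector(b, end)
            assert np.allclose(v.direction, [1, 0, 0], atol=1e-12)

    def test_two_point_branch_uses_single_chord(self):
        b = make_branch([(0, 0, 0), (1, 1, 0)])
        v = directional_vector(b, "start", m=5)
        assert v.n_segments_used == 1
        assert np.allclose(v.direction, np.array([1, 1, 0]) / math.sqrt(2))

    def test_unit_norm_always(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            pts = np.cumsum(rng.normal(size=(8, 3)), axis=0)
            v = directional_vector(make_branch(pts), "finish")
            assert np.linalg.norm(v.direction) == pytest.approx(1.0)

    def test_noisy_line_mean_recovery_error_below_two_degrees(self):
        # simulation with a known axis: noise sigma = 5% of the extent
        rng = np.random.default_rng(3)
        axis = np.array([1.0, 2.0, -0.5])
        axis /= np.linalg.norm(axis)
        extent, npts = 20.0, 50
        errors = []
        for _ in range(100):
            t = np.linspace(0, extent, npts)[:, None]
            noise = rng.normal(scale=0.05 * extent, size=(npts, 3))
            b = make_branch(t * axis + noise)
            v = directional_vector(b, "start", m=npts)
            angle = math.acos(min(1.0, abs(float(np.dot(v.direction, axis)))))
            errors.append(math.degrees(angle))
        assert np.mean(errors) < 2.0

    def test_coincident_points_raise(self):
        b = make_branch([(0, 0, 0), (0, 0, 0)])
        with pytest.raises(GeometryError):
            directional_vector(b, "start")


class TestBifurcationAngle:
    @staticmethod
    def _forest(swc_text):
        return build_forest(parse_swc(swc_text))

    def test_straight_continuation_is_zero(self):
        forest = self._forest(
            "1 3 0 0 0 1 -1\n2 3 0 1 0 1 1\n"
            "3 3 0 2 0 1 2\n"  # daughter A continues straight
            "4 3 1 1.5 0 1 2\n"  # daughter B veers off
        )
        stem = forest[forest.roots[0]]
        straight = next(d for d in forest.daughters(stem) if d.points[-1][0] == 0)
        assert bifurcation_angle(stem, straight) == pytest.approx(0.0, abs=1e-8)

    def test_orthogonal_daughter_is_half_pi(self):
        forest = self._forest(
            "1 3 0 0 0 1 -1\n2 3 0 1 0 1 1\n"
            "3 3 1 1 0 1 2\n"  # +x daughter, orthogonal to the +y stem
            "4 3 0 2 0 1 2\n"
        )
        stem = forest[forest.roots[0]]
        ortho = next(d for d in forest.daughters(stem) if d.points[-1][0] == 1)
        assert bifurcation_angle(stem, ortho) == pytest.approx(math.pi / 2, abs=1e-8)

    def test_symmetric_y_recovers_planned_angles(self):
        forest = build_forest(make_fixture(FixtureSpec(template="ytree", daughter_angle_deg=60)))
        stem = forest[forest.roots[0]]
        for d in forest.daughters(stem):
            assert bifurcation_angle(stem, d) == pytest.approx(math.pi / 3, abs=1e-6)

    def test_angles_invariant_under_rotation_and_scale(self):
        rec = make_fixture(FixtureSpec(template="ytree", daughter_angle_deg=47.0))
        forest = build_forest(rec)
        stem = forest[forest.roots[0]]
        base = [bifurcation_angle(stem, d) for d in forest.daughters(stem)]

        rng = np.random.default_rng(11)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        for b in forest:
            b.points = 2.5 * (b.points @ q.T)
        rotated = [bifurcation_angle(stem, d) for d in forest.daughters(stem)]
        assert rotated == pytest.approx(base, abs=1e-9)

    def test_non_daughter_rejected(self, ytree_forest):
        stem = ytree_forest[ytree_forest.roots[0]]
        d1, d2 = ytree_forest.daughters(stem)
        with pytest.raises(ValueError, match="not a daughter"):
            bifurcation_angle(d1, d2)


class TestRallExponent:
    @pytest.mark.parametrize(
        "d_eq, expected",
        [(2 ** (2 / 3), 1.5), (2.0, 1.0), (math.sqrt(2), 2.0)],
    )
    def test_closed_form_symmetric_bifurcations(self, d_eq, expected):
        e, reason = rall_exponent(d_eq, [1.0, 1.0])
        assert reason is None
        assert e == pytest.approx(expected, abs=1e-6)

    def test_parent_not_larger_than_daughter_is_missing(self):
        e, reason = rall_exponent(1.0, [1.0, 0.5])
        assert math.isnan(e)
        assert "not larger" in reason

    def test_parent_exceeding_daughter_sum_can_lack_root(self):
        # d_eq far above even the E->0 norm limit inside the bracket
        e, reason = rall_exponent(1e9, [1.0, 1.0])
        assert math.isnan(e)
        assert reason == "no sign change in bracket"

    def test_single_daughter_is_missing(self):
        e, reason = rall_exponent(2.0, [1.0])
        assert math.isnan(e) and "fewer than 2" in reason

    def test_agrees_with_grid_search_on_random_triples(self):
        rng = np.random.default_rng(13)
        checked = 0
        while checked < 100:
            d1, d2 = rng.uniform(0.3, 2.0, size=2)
            # place the parent strictly between the E=20 and E=0.3 norms
            e_true = rng.uniform(0.3, 5.0)
            d_eq = (d1 ** e_true + d2 ** e_true) ** (1 / e_true)
            e, reason = rall_exponent(d_eq, [d1, d2])
            assert reason is None
            assert e == pytest.approx(e_true, abs=1e-6)
            assert e == pytest.approx(grid_search_rall(d_eq, [d1, d2]), abs=2e-4)
            checked += 1

    def test_fixture_trees_recover_planned_exponent(self):
        for planned in (1.0, 1.5, 2.0):
            rec = make_fixture(FixtureSpec(template="binary", depth=3, rall_exponent=planned))
            forest = build_forest(rec)
            exps = [b.rall_exponent for b in find_bifurcations(forest)]
            assert len(exps) == 3  # internal branches of a depth-3 tree
            assert np.median(exps) == pytest.approx(planned, abs=1e-6)
            assert exps == pytest.approx([planned] * 3, abs=1e-6)


class TestFindBifurcations:
    def test_ytree_single_bifurcation_geometry(self, ytree_forest):
        bifs = find_bifurcations(ytree_forest)
        assert len(bifs) == 1
        bif = bifs[0]
        assert np.allclose(bif.location, [0, 2, 0])
        assert len(bif.daughter_names) == 2
        assert bif.parent_diameter == pytest.approx(2.0)
        assert bif.daughter_diameters == pytest.approx([1.0, 1.0])

    def test_terminal_branches_produce_no_bifurcation(self):
        forest = build_forest(make_fixture(FixtureSpec(template="chain")))
        assert find_bifurcations(forest) == []
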