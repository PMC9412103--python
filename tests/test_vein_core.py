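"""Direction encoding, adjacency codec and graph invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bionicvein.errors import DomainError, StructureError
from bionicvein.fixtures import random_vein_tree
from bionicvein.vein_core import (
    AdjacencyPair,
    Direction,
    HeadBranch,
    VeinEdge,
    VeinGraph,
    VeinGrade,
    VeinPoint,
    alpha_to_gamma,
    build_adjacency,
    canonical_numbering,
    gamma_to_angle,
    gamma_to_direction,
    graph_from_adjacency,
    graph_from_json,
    graph_to_json,
    layout_graph,
    validate_graph,
)


class TestAlphaToGamma:
    @pytest.mark.parametrize(
        "alpha, branch, expected",
        [
            (90.0, HeadBranch.LEFT_HEAD, 1.0),
            (90.0, HeadBranch.RIGHT_HEAD_OBTUSE, 0.0),
            (45.0, HeadBranch.RIGHT_HEAD_ACUTE, 1.75),
            (180.0, HeadBranch.LEFT_HEAD, 0.5),
            (0.0, HeadBranch.LEFT_HEAD, 1.5),
            (180.0, HeadBranch.RIGHT_HEAD_OBTUSE, 0.5),
        ],
    )
    def test_printed_relation(self, alpha, branch, expected):
        assert alpha_to_gamma(alpha, branch) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "alpha, branch",
        [
            (-1.0, HeadBranch.LEFT_HEAD),
            (181.0, HeadBranch.LEFT_HEAD),
            (89.0, HeadBranch.RIGHT_HEAD_OBTUSE),
            (90.0, HeadBranch.RIGHT_HEAD_ACUTE),
        ],
    )
    def test_domain_errors_name_the_branch(self, alpha, branch):
        with pytest.raises(DomainError, match=branch.name):
            alpha_to_gamma(alpha, branch)

    def test_monotone_and_in_range_on_each_branch(self):
        """On the left branch gamma decreases with alpha; on both right
        branches it increases; all angles land inside [0, 360)."""
        specs = [
            (HeadBranch.LEFT_HEAD, range(0, 181), -1),
            (HeadBranch.RIGHT_HEAD_OBTUSE, range(90, 181), +1),
            (HeadBranch.RIGHT_HEAD_ACUTE, range(0, 90), +1),
        ]
        for branch, domain, sign in specs:
            gammas = [alpha_to_gamma(float(a), branch) for a in domain]
            for g in gammas:
                assert 0.0 <= gamma_to_angle(g) < 360.0
            diffs = np.diff(gammas)
            assert (np.sign(diffs) == sign).all(), branch

    def test_angular_resolution_is_0_9_degrees(self):
        """A gamma discrepancy of 0.005 corresponds to exactly 0.9 deg
        (gamma scales as 180 deg per unit), which is within one degree."""
        base = alpha_to_gamma(120.0, HeadBranch.LEFT_HEAD)
        assert abs(alpha_to_gamma(120.9, HeadBranch.LEFT_HEAD) - base) == pytest.approx(
            0.005, abs=1e-12
        )
        assert abs(alpha_to_gamma(121.0, HeadBranch.LEFT_HEAD) - base) > 0.005
        admitted = 0.005 * 180.0
        assert admitted == pytest.approx(0.9) and admitted <= 1.0


class TestGammaMaps:
    @pytest.mark.parametrize(
        "gamma, expected",
        [
            (0.25, Direction.UPPER_RIGHT),
            (0.75, Direction.UPPER_LEFT),
            (1.2, Direction.LOWER_LEFT),
            (1.9, Direction.LOWER_RIGHT),
            (0.0, Direction.RIGHT),
            (0.5, Direction.UP),
            (1.0, Direction.LEFT),
            (1.5, Direction.DOWN),
        ],
    )
    def test_quadrants_and_axes(self, gamma, expected):
        assert gamma_to_direction(gamma) is expected

    @pytest.mark.parametrize("bad", [-0.1, 2.0, 2.5])
    def test_out_of_range(self, bad):
        with pytest.raises(DomainError):
            gamma_to_direction(bad)
        with pytest.raises(DomainError):
            gamma_to_angle(bad)

    def test_angle_is_linear(self):
        assert gamma_to_angle(0.0) == 0.0
        assert gamma_to_angle(0.5) == 90.0
        assert gamma_to_angle(1.75) == 315.0

    @given(st.floats(min_value=0.0, max_value=2.0, exclude_max=True,
                     allow_nan=False, allow_infinity=False))
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_angle_gamma_round_trip(self, gamma):
        from bionicvein.vein_core import angle_to_gamma

        assert angle_to_gamma(gamma_to_angle(gamma)) == pytest.approx(gamma, abs=1e-12)

    @given(st.floats(min_value=0.0, max_value=180.0, allow_nan=False))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_left_branch_always_yields_legal_direction(self, alpha):
        g = alpha_to_gamma(alpha, HeadBranch.LEFT_HEAD)
        assert 0.0 <= g < 2.0
        assert gamma_to_direction(g) is not None


def _two_point_graph() -> VeinGraph:
    return VeinGraph(
        points=[
            VeinPoint(id=0, grade=VeinGrade.MAIN, label="O1"),
            VeinPoint(id=1, grade=VeinGrade.MAIN, label="O2"),
        ],
        edges=[VeinEdge(src=0, dst=1, gamma=0.5, length=50.0)],
    )


class TestAdjacencyCodec:
    def test_single_edge_matrices(self):
        pair = build_adjacency(_two_point_graph())
        assert pair.n == 2
        assert pair.m1[0, 1] == 0.5 and pair.m2[0, 1] == 50.0
        assert pair.edge_mask.sum() == 1
        assert pair.m1.sum() == 0.5 and pair.m2.sum() == 50.0

    def test_non_canonical_edge_rejected(self):
        g = _two_point_graph()
        g.edges = [VeinEdge(src=1, dst=0, gamma=0.5, length=50.0)]
        with pytest.raises(StructureError, match="canonical"):
            build_adjacency(g)

    def test_matrices_strictly_upper_triangular(self):
        for seed in range(20):
            g = random_vein_tree(12, seed=seed)
            pair = build_adjacency(g)
            lower = np.tril_indices(pair.n)
            assert not pair.m1[lower].any()
            assert not pair.m2[lower].any()
            assert not pair.edge_mask[lower].any()

    def test_trivial_1x1_pair_is_isolated_root(self):
        pair = AdjacencyPair(
            n=1, m1=np.zeros((1, 1)), m2=np.zeros((1, 1)),
            edge_mask=np.zeros((1, 1), dtype=bool),
        )
        g = graph_from_adjacency(pair, [VeinGrade.MAIN])
        assert g.n_points == 1 and g.n_edges == 0

    @pytest.mark.parametrize("seed", range(100))
    def test_round_trip_identity(self, seed):
        """graph -> (M1, M2, mask) -> graph is lossless for random trees."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 26))
        g = random_vein_tree(n, seed=seed)
        pair = build_adjacency(g)
        back = graph_from_adjacency(
            pair, [p.grade for p in g.points], [p.label for p in g.points]
        )
        assert back.structurally_equal(g, tol=1e-9)
        assert build_adjacency(back).equal(pair, tol=0.0)

    def test_inconsistent_mask_rejected(self):
        m1 = np.zeros((3, 3)); m2 = np.zeros((3, 3))
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 1] = True  # edge in the mask but zero length in M2
        with pytest.raises(StructureError):
            AdjacencyPair(n=3, m1=m1, m2=m2, edge_mask=mask)

    def test_multi_parent_rejected(self):
        m1 = np.zeros((3, 3)); m2 = np.zeros((3, 3))
        mask = np.zeros((3, 3), dtype=bool)
        for i in (0, 1):
            mask[i, 2] = True
            m1[i, 2] = 0.5
            m2[i, 2] = 10.0
        pair = AdjacencyPair(n=3, m1=m1, m2=m2, edge_mask=mask)
        with pytest.raises(StructureError, match="incoming"):
            graph_from_adjacency(pair, [VeinGrade.MAIN] * 3)


class TestLayoutAndNumbering:
    def test_straight_up_and_reference_direction(self):
        g = layout_graph(_two_point_graph())
        assert g.point(1).position == pytest.approx((0.0, 50.0))
        g2 = _two_point_graph()
        g2.edges = [VeinEdge(src=0, dst=1, gamma=0.0, length=10.0)]
        g2 = layout_graph(g2)
        assert g2.point(1).position == pytest.approx((10.0, 0.0))

    def test_left_head_lateral_lands_up_and_left(self):
        """With 90 < alpha1 < 180 the left head lateral endpoint sits left
        of and above the head junction."""
        gamma = alpha_to_gamma(120.0, HeadBranch.LEFT_HEAD)
        g = VeinGraph(
            points=[
                VeinPoint(0, VeinGrade.MAIN, "O2"),
                VeinPoint(1, VeinGrade.LATERAL, "A2"),
            ],
            edges=[VeinEdge(0, 1, gamma, 12.0)],
        )
        x, y = layout_graph(g).point(1).position
        assert x < 0.0 and y > 0.0

    def test_numbering_idempotent(self):
        g = canonical_numbering(layout_graph(random_vein_tree(15, seed=3)))
        again = canonical_numbering(g)
        assert again.structurally_equal(g, tol=0.0)

    def test_single_point_unchanged(self):
        g = VeinGraph(points=[VeinPoint(0, VeinGrade.MAIN, "O1", (0.0, 0.0))])
        out = canonical_numbering(g)
        assert out.n_points == 1 and out.point(0).label == "O1"

    def test_requires_positions(self):
        with pytest.raises(StructureError, match="position"):
            canonical_numbering(_two_point_graph())

    def test_parents_always_precede_children(self):
        for seed in range(25):
            g = random_vein_tree(20, seed=seed)
            assert all(e.src < e.dst for e in g.edges)

    def test_bottom_to_top_when_unconstrained(self):
        """Among mutually unrelated points the numbering follows ascending
        y, ties broken left to right."""
        g = VeinGraph(
            points=[
                VeinPoint(0, VeinGrade.MAIN, "root"),
                VeinPoint(1, VeinGrade.LATERAL, "high"),
                VeinPoint(2, VeinGrade.LATERAL, "low-right"),
                VeinPoint(3, VeinGrade.LATERAL, "low-left"),
            ],
            edges=[
                VeinEdge(0, 1, 0.5, 30.0),
                VeinEdge(0, 2, 0.0, 10.0),
                VeinEdge(0, 3, 1.0, 10.0),
            ],
        )
        out = canonical_numbering(layout_graph(g))
        assert [p.label for p in out.points] == ["root", "low-left", "low-right", "high"]
        # children of the (renumbered) root keep src < dst
        assert all(e.src < e.dst for e in out.edges)


class TestValidateGraph:
    def test_valid_tree_is_clean(self):
        assert validate_graph(random_vein_tree(10, seed=1)) == []

    def test_each_violation_reported(self):
        g = random_vein_tree(6, seed=2)
        # corrupt: gamma out of range (bypassing the edge constructor)
        object.__setattr__(g.edges[0], "gamma", 2.3)
        codes = {d.code for d in validate_graph(g)}
        assert "gamma-range" in codes

    def test_grade_inversion_detected(self):
        g = VeinGraph(
            points=[
                VeinPoint(0, VeinGrade.MINOR, "x"),
                VeinPoint(1, VeinGrade.LATERAL, "y"),
            ],
            edges=[VeinEdge(0, 1, 0.5, 5.0)],
        )
        codes = [d.code for d in validate_graph(g)]
        assert codes == ["grade-order"]

    def test_multi_parent_and_root_count(self):
        g = VeinGraph(
            points=[VeinPoint(i, VeinGrade.MAIN) for i in range(3)],
            edges=[
                VeinEdge(0, 2, 0.5, 5.0),
                VeinEdge(1, 2, 0.25, 5.0),
            ],
        )
        codes = {d.code for d in validate_graph(g)}
        assert "multi-parent" in codes and "root-count" in codes


class TestJsonInterchange:
    def test_round_trip(self):
        g = random_vein_tree(12, seed=9)
        back = graph_from_json(graph_to_json(g))
        assert back.structurally_equal(g, tol=0.0)
        assert [p.position for p in back.points] == [p.position for p in g.points]

    def test_grades_serialized_as_names(self):
        obj = graph_to_json(random_vein_tree(5, seed=0))
        assert {p["grade"] for p in obj["points"]} <= {"MAIN", "LATERAL", "MINOR"}
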