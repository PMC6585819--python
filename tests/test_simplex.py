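import itertools

import numpy as np
import pytest

from gridsimplex.pareto import ParetoSet
from gridsimplex.simplex import (
    SearchOptions,
    classify_outcome,
    initialize_simplex,
    propose_move,
    run_search,
)


def separable_concave(cstar, coef=None):
    coef = coef or [1.0] * len(cstar)
    return lambda p: -sum(a * (c - cs) ** 2 for a, c, cs in zip(coef, p, cstar))


def all_points(shape):
    return list(itertools.product(*[range(1, L + 1) for L in shape]))


class TestInitializeSimplex:
    def test_six_dimensional_lattice_gives_seven_vertices(self):
        bounds = [(1, 4), (1, 3), (1, 4), (1, 3), (1, 3), (1, 3)]
        verts = initialize_simplex((2, 2, 2, 2, 2, 2), bounds)
        assert len(verts) == 7
        assert len(set(verts)) == 7

    def test_upper_corner_flips_all_steps_inward(self):
        bounds = [(1, 4), (1, 3), (1, 4)]
        verts = initialize_simplex((4, 3, 4), bounds)
        assert len(set(verts)) == 4
        assert verts[0] == (4, 3, 4)
        for v in verts[1:]:
            assert all(1 <= c <= hi for c, (lo, hi) in zip(v, bounds))
            assert sum(abs(a - b) for a, b in zip(v, (4, 3, 4))) == 1

    def test_two_d_example(self):
        assert initialize_simplex((1, 1), [(1, 3), (1, 3)]) == [
            (1, 1),
            (2, 1),
            (1, 2),
        ]

    def test_single_level_dimension_rejected(self):
        with pytest.raises(ValueError, match="single level"):
            initialize_simplex((1, 1), [(1, 3), (1, 1)])


class TestProposeMove:
    def test_reflection_through_centroid(self):
        vertices = [(1, 1), (3, 1), (1, 3)]
        values = [0.0, 1.0, 2.0]  # worst is (1,1)
        cand, label = propose_move(vertices, values, [(1, 5), (1, 5)])
        assert (cand, label) == ((3, 3), "reflection")

    def test_reflection_clamped_to_bounds(self):
        vertices = [(1, 1), (3, 1), (1, 3)]
        values = [0.0, 1.0, 2.0]
        cand, label = propose_move(vertices, values, [(1, 2), (1, 2)])
        assert cand == (2, 2)

    def test_duplicate_reflection_triggers_contraction(self):
        # reflection of (1,1) through centroid of (2,1),(1,2) is (2,2) — force
        # a duplicate by including (2,2) as a vertex of a 3-vertex simplex
        vertices = [(1, 1), (3, 3), (2, 2)]
        values = [0.0, 2.0, 1.0]
        # worst (1,1); centroid (2.5, 2.5); reflection -> (4,4)
        cand, label = propose_move(vertices, values, [(1, 4), (1, 4)])
        assert (cand, label) == ((4, 4), "reflection")
        # shrink bounds so the reflection clamps onto vertex (2,2)
        cand, label = propose_move(vertices, values, [(1, 2), (1, 2)])
        assert label in ("contraction", "shrink")
        assert cand not in ((4, 4),)


class TestRunSearch:
    @pytest.mark.parametrize("cstar", [(3, 2, 2), (1, 1, 1), (4, 3, 4), (2, 3, 1)])
    def test_all_starts_reach_global_argmax_on_unimodal_lattice(self, cstar):
        shape = (4, 3, 4)
        bounds = [(1, L) for L in shape]
        obj = separable_concave(cstar)
        for start in all_points(shape):
            res = run_search(start, obj, bounds)
            assert res.best_point == cstar, f"start {start} ended at {res.best_point}"

    def test_start_simplex_containing_argmax_keeps_it(self):
        cstar = (2, 2)
        res = run_search((2, 2), separable_concave(cstar), [(1, 4), (1, 4)])
        assert res.best_point == cstar
        assert res.best_value == 0.0

    def test_constant_objective_returns_start_vertex(self):
        bounds = [(1, 4), (1, 3)]
        res = run_search((2, 2), lambda p: 0.5, bounds)
        assert res.best_point in initialize_simplex((2, 2), bounds)
        assert res.terminated_reason in ("stalled", "collapsed")

    def test_cache_uniqueness_no_point_evaluated_twice(self):
        calls = []

        def obj(p):
            calls.append(p)
            return -sum((c - 2) ** 2 for c in p)

        res = run_search((1, 1, 1), obj, [(1, 4)] * 3)
        assert len(calls) == len(set(calls))
        assert res.n_evaluations == len(res.trajectory) == len(set(res.trajectory))
        assert len(calls) == res.n_evaluations

    def test_best_so_far_monotone_nondecreasing(self):
        res = run_search(
            (1, 1, 1, 1), separable_concave((3, 2, 4, 1)), [(1, 4)] * 4
        )
        bsf = res.best_so_far()
        assert (np.diff(bsf) >= 0).all()
        assert res.best_value == bsf[-1]

    def test_unique_x_projection_counts(self):
        res = run_search(
            (1, 1, 1, 1), separable_concave((2, 2, 2, 2)), [(1, 3)] * 4, n_x=2
        )
        assert res.n_unique_x == len({p[:2] for p in res.trajectory})
        assert res.n_unique_x <= res.n_evaluations

    def test_mapping_objective_accepted(self):
        shape = (3, 3)
        obj = {p: separable_concave((2, 2))(p) for p in all_points(shape)}
        res = run_search((1, 1), obj, [(1, 3), (1, 3)])
        assert res.best_point == (2, 2)

    def test_poll_disabled_may_stall_early_but_terminates(self):
        opts = SearchOptions(poll_on_stall=False)
        res = run_search(
            (1, 2, 4), separable_concave((3, 2, 2)), [(1, 4), (1, 3), (1, 4)], opts
        )
        assert res.terminated_reason in ("stalled", "collapsed", "max_iterations")


class TestClassifyOutcome:
    def _result(self, point, value):
        from gridsimplex.simplex import SearchResult

        return SearchResult(
            best_point=point,
            best_value=value,
            trajectory=[point],
            values=[value],
            n_evaluations=1,
            n_unique_x=1,
            terminated_reason="stalled",
        )

    def test_exact_optimum_is_converged(self):
        front = ParetoSet(members=frozenset({(1, 1)}))
        res = self._result((1, 1, 2, 2), 0.9)
        assert (
            classify_outcome(res, (1, 1, 2, 2), 0.9, front, n_x=2) == "converged"
        )

    def test_pareto_member_within_tolerance_is_near_optimal(self):
        front = ParetoSet(members=frozenset({(2, 2)}))
        res = self._result((2, 2, 1, 1), 0.995 * 0.9)
        assert (
            classify_outcome(res, (1, 1, 2, 2), 0.9, front, n_x=2, tol=0.01)
            == "near_optimal"
        )

    def test_non_pareto_point_fails_even_when_close(self):
        front = ParetoSet(members=frozenset({(1, 1)}))
        res = self._result((2, 2, 1, 1), 0.999 * 0.9)
        assert (
            classify_outcome(res, (1, 1, 2, 2), 0.9, front, n_x=2, tol=0.01) == "fail"
        )

    def test_pareto_member_below_tolerance_fails(self):
        front = ParetoSet(members=frozenset({(2, 2)}))
        res = self._result((2, 2, 1, 1), 0.9 * 0.9)
        assert (
            classify_outcome(res, (1, 1, 2, 2), 0.9, front, n_x=2, tol=0.01) == "fail"
        )
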