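import numpy as np
import pytest

import screenopt as so
from conftest import make_regimens, random_instance, random_separable_instance


class TestBuildProblem:
    def test_default_costs_and_budget(self, params):
        regs = make_regimens([1, 3])
        q = so.RiskQuantiles(np.full(100, 0.01))
        assert [r.cost for r in regs] == pytest.approx([6.0, 2.0])
        assert so.triennial_equivalent_budget(100, regs) == pytest.approx(200.0)
        prob = so.build_problem(q, regs, params, budget=200.0)
        assert prob.p.shape == (100, 2)

    def test_four_year_cost(self):
        assert so.RegimenSpec.from_interval(4).cost == pytest.approx(1.5)

    def test_p_is_risk_times_adjustment(self, params):
        q = so.RiskQuantiles(np.array([0.01, 0.03]))
        regs = make_regimens([2])
        prob = so.build_problem(q, regs, params, budget=10.0)
        s = so.screen_detected_fraction(params, 2.0)
        adj = so.advanced_fraction(params, s)
        assert prob.p == pytest.approx(np.array([[0.01 * adj], [0.03 * adj]]))

    def test_empty_regimens_rejected(self, params):
        q = so.RiskQuantiles(np.array([0.01]))
        with pytest.raises(ValueError):
            so.build_problem(q, [], params, budget=1.0)

    def test_single_regimen_feasibility(self, params):
        q = so.RiskQuantiles(np.array([0.01, 0.02]))
        regs = make_regimens([3])
        feasible = so.solve_lp(so.build_problem(q, regs, params, budget=4.0))
        assert feasible.is_optimal
        infeasible = so.solve_lp(so.build_problem(q, regs, params, budget=3.9))
        assert infeasible.status == "infeasible"


class TestProblemType:
    def test_validation(self):
        with pytest.raises(ValueError):
            so.Problem(np.array([[-0.1]]), np.array([1.0]), 1.0, ["a"])
        with pytest.raises(ValueError):
            so.Problem(np.array([[0.1]]), np.array([0.0]), 1.0, ["a"])
        with pytest.raises(ValueError):
            so.Problem(np.array([[0.1]]), np.array([1.0]), 0.0, ["a"])
        with pytest.raises(ValueError):
            so.Problem(np.array([[0.1]]), np.array([1.0, 2.0]), 1.0, ["a"])

    def test_per_quantile_costs_accepted(self):
        p = np.array([[0.1, 0.2], [0.3, 0.4]])
        h = np.array([[1.0, 2.0], [1.5, 2.5]])
        prob = so.Problem(p, h, 10.0, ["a", "b"])
        assert prob.cost_matrix == pytest.approx(h)

    def test_json_round_trip(self, tmp_path):
        prob = so.Problem(np.array([[0.1, 0.2]]), np.array([1.0, 2.0]), 3.0, ["a", "b"])
        path = tmp_path / "p.json"
        prob.to_json(path)
        prob2 = so.Problem.from_json(path)
        assert prob2.p == pytest.approx(prob.p)
        assert prob2.labels == prob.labels


class TestSolveLP:
    def test_unconstrained_picks_rowwise_best(self, rng):
        prob = random_instance(rng)
        big = so.Problem(prob.p, prob.costs, 1e9, prob.labels)
        sol = so.solve_lp(big)
        expected = prob.p.min(axis=1).sum()
        assert sol.objective == pytest.approx(expected, rel=1e-8)

    def test_three_quantile_frozen_instance(self, params):
        # frozen from the grid brute-force oracle on this instance
        q = so.RiskQuantiles(np.array([0.001, 0.01, 0.05]))
        regs = make_regimens([1, 3, 6])
        prob = so.build_problem(q, regs, params, budget=6.0)
        sol = so.solve_lp(prob)
        assert sol.objective == pytest.approx(0.0187348709, abs=1e-8)
        oracle = so.brute_force(prob, grid_step=0.01, mode="lp")
        assert sol.objective == pytest.approx(oracle.objective, abs=1e-4)

    def test_equal_risk_objective_unique(self, params):
        q = so.RiskQuantiles(np.full(4, 0.02))
        regs = make_regimens([1, 3])
        prob = so.build_problem(q, regs, params, budget=4 * 3.0)
        sol = so.solve_lp(prob)
        # symmetric instance: any optimum attains the same objective
        oracle = so.brute_force(prob, grid_step=0.01, mode="lp")
        assert sol.objective == pytest.approx(oracle.objective, abs=1e-4)
        assert np.allclose(sol.x.sum(axis=1), 1.0)

    def test_feasible_solution_invariants(self, rng):
        for _ in range(10):
            prob = random_instance(rng)
            sol = so.solve_lp(prob)
            if not sol.is_optimal:
                continue
            assert np.all(sol.x >= 0) and np.all(sol.x <= 1)
            assert np.allclose(sol.x.sum(axis=1), 1.0, atol=1e-7)
            assert sol.total_cost(prob) <= prob.budget + 1e-6

    def test_infeasible_status(self):
        prob = so.Problem(np.array([[0.1], [0.1]]), np.array([2.0]), 1.0, ["a"])
        assert so.solve_lp(prob).status == "infeasible"


class TestSolveIP:
    def test_two_by_two_enumeration(self):
        p = np.array([[0.05, 0.02], [0.30, 0.10]])
        costs = np.array([2.0, 1.0])
        prob = so.Problem(p, costs, 3.0, ["hi", "lo"])
        sol = so.solve_ip(prob)
        # all four binary assignments: feasible are (hi,lo)=0.15, (lo,hi)=0.32,
        # (lo,lo)=0.12; (hi,hi) costs 4 > 3. best is 0.12
        assert sol.objective == pytest.approx(0.12)
        assert sol.x == pytest.approx(np.array([[0, 1], [0, 1]]))

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(15):
            prob = random_instance(rng)
            ip = so.solve_ip(prob)
            oracle = so.brute_force(prob, mode="ip")
            assert ip.status == oracle.status
            if ip.is_optimal:
                assert ip.objective == pytest.approx(oracle.objective, abs=1e-9)

    def test_relaxation_bound(self, rng):
        for _ in range(15):
            prob = random_instance(rng)
            lp, ip = so.solve_lp(prob), so.solve_ip(prob)
            if lp.is_optimal and ip.is_optimal:
                assert lp.objective <= ip.objective + 1e-9

    def test_loose_budget_matches_lp(self, rng):
        prob = random_instance(rng)
        big = so.Problem(prob.p, prob.costs, 1e9, prob.labels)
        assert so.solve_ip(big).objective == pytest.approx(
            so.solve_lp(big).objective, rel=1e-8
        )


class TestBruteForce:
    def test_refuses_large_instances(self):
        p = np.full((9, 2), 0.1)
        prob = so.Problem(p, np.array([1.0, 2.0]), 100.0, ["a", "b"])
        with pytest.raises(ValueError, match="limited"):
            so.brute_force(prob)

    def test_k1_picks_affordable_argmin(self):
        prob = so.Problem(
            np.array([[0.01, 0.05, 0.2]]), np.array([5.0, 2.0, 1.0]), 2.0, list("abc")
        )
        sol = so.brute_force(prob, mode="ip")
        assert sol.objective == pytest.approx(0.05)  # cheapest-best is unaffordable

    def test_never_beats_lp_beyond_tolerance(self, rng):
        for _ in range(8):
            prob = random_instance(rng)
            lp = so.brute_force(prob, 0.05, "lp")
            exact = so.solve_lp(prob)
            if lp.is_optimal and exact.is_optimal:
                assert lp.objective >= exact.objective - 1e-9


class TestCanonicalize:
    def test_contiguous_input_unchanged(self, rng):
        quantiles, _, _, problem = random_separable_instance(rng)
        sol = so.solve_lp(problem)
        canon = so.canonicalize(sol, quantiles, problem)
        canon2 = so.canonicalize(canon, quantiles, problem)
        assert np.allclose(canon.x, canon2.x, atol=1e-9)

    def test_swapped_equal_risk_rows_reordered(self):
        q = so.RiskQuantiles(np.array([0.02, 0.02]))
        x = np.array([[0.0, 1.0], [1.0, 0.0]])  # intensive regimen on first row
        p = np.outer(q.mean_risk, [0.3, 0.2])
        prob = so.Problem(p, np.array([1.0, 3.0]), 4.0, ["lo", "hi"])
        a = so.Assignment(x=x, objective=float((p * x).sum()), mode="lp",
                          status="optimal", labels=["lo", "hi"], costs=prob.costs)
        canon = so.canonicalize(a, q, prob)
        # equal risks: canonical deals the intensive regimen to the first
        # quantile in stable descending-risk order; objective unchanged
        assert canon.objective == pytest.approx(a.objective)
        assert np.allclose(canon.x.sum(axis=0), x.sum(axis=0))
        costs_per_row = canon.x @ prob.costs
        risk_order = np.argsort(-q.mean_risk, kind="stable")
        assert np.all(np.diff(costs_per_row[risk_order]) <= 1e-9)

    def test_objective_preserved_and_cost_monotone(self, rng):
        for _ in range(10):
            quantiles, _, _, problem = random_separable_instance(rng)
            sol = so.solve_lp(problem)
            if not sol.is_optimal:
                continue
            canon = so.canonicalize(sol, quantiles, problem)
            assert canon.objective == pytest.approx(sol.objective, abs=1e-8)
            assert canon.total_cost(problem) <= problem.budget + 1e-6
            costs_per_row = canon.x @ problem.cost_matrix[0]
            risk_order = np.argsort(-quantiles.mean_risk, kind="stable")
            assert np.all(np.diff(costs_per_row[risk_order]) <= 1e-7)

    def test_infeasible_passthrough(self):
        prob = so.Problem(np.array([[0.1]]), np.array([2.0]), 1.0, ["a"])
        sol = so.solve_lp(prob)
        q = so.RiskQuantiles(np.array([0.1]))
        assert so.canonicalize(sol, q, prob).status == "infeasible"


class TestInvariants:
    def test_scale_invariance(self, rng):
        for _ in range(5):
            quantiles, regimens, params, problem = random_separable_instance(rng)
            base = so.canonicalize(so.solve_lp(problem), quantiles, problem)
            if not base.is_optimal:
                continue
            for M in (0.5, 1.0, 2.0):
                scaled_p = so.Problem(problem.p * M, problem.costs,
                                      problem.budget, problem.labels)
                sol = so.canonicalize(so.solve_lp(scaled_p), quantiles, scaled_p)
                assert np.allclose(sol.x, base.x, atol=1e-6)
                assert sol.objective == pytest.approx(M * base.objective, rel=1e-6)

    def test_objective_non_increasing_in_budget(self, rng):
        quantiles, regimens, params, problem = random_separable_instance(rng)
        budgets = np.linspace(problem.budget, 3 * problem.budget, 8)
        objs = []
        for H in budgets:
            sol = so.solve_lp(so.Problem(problem.p, problem.costs, H, problem.labels))
            assert sol.is_optimal
            objs.append(sol.objective)
        assert np.all(np.diff(objs) <= 1e-10)

    def test_at_most_m_minus_1_fractional_rows(self, rng):
        for _ in range(10):
            quantiles, _, _, problem = random_separable_instance(rng)
            sol = so.solve_lp(problem)
            if not sol.is_optimal:
                continue
            canon = so.canonicalize(sol, quantiles, problem)
            frac_rows = np.sum(np.any((canon.x > 1e-7) & (canon.x < 1 - 1e-7), axis=1))
            assert frac_rows <= problem.m - 1

    def test_monotone_assignment_under_effectiveness_ordering(self, rng):
        # costlier regimens are more effective (shorter interval); in the
        # canonical optimum higher-risk quantiles never get cheaper regimens
        quantiles, regimens, params, problem = random_separable_instance(rng, K=6)
        sol = so.canonicalize(so.solve_lp(problem), quantiles, problem)
        if sol.is_optimal:
            costs_per_row = sol.x @ problem.cost_matrix[0]
            order = np.argsort(-quantiles.mean_risk, kind="stable")
            assert np.all(np.diff(costs_per_row[order]) <= 1e-7)


class TestAssignmentIO:
    def test_summary_and_json(self, tmp_path, params):
        q = so.RiskQuantiles(np.array([0.01, 0.05]))
        prob = so.build_problem(q, make_regimens([1, 3]), params, budget=20.0)
        sol = so.solve_lp(prob)
        df = sol.summary_frame()
        assert set(df.columns) == {"k", "regimen_label", "x"}
        sol.to_json(tmp_path / "a.json")
        import json

        with open(tmp_path / "a.json") as fh:
            obj = json.load(fh)
        assert obj["status"] == "optimal"
        assert np.asarray(obj["x"]).shape == (2, 2)
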