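"""Budget-constrained assignment of screening regimens to risk quantiles.

Minimize expected advanced-cancer incidence ``sum_kj x_kj p_kj`` subject to
one regimen per quantile (row sums 1), bounds ``0 <= x <= 1`` (binary in ip
mode) and a resource constraint ``sum_kj h_kj x_kj <= H``. Instances are tiny
(at most ~100 x 5), so exact LP/MILP solvers are used, with an independent
brute-force oracle for verification.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .natural_history import NaturalHistoryParams, RegimenSpec, advanced_risk
from .risk_distribution import RiskQuantiles

__all__ = [
    "Problem",
    "Assignment",
    "build_problem",
    "triennial_equivalent_budget",
    "solve_lp",
    "solve_ip",
    "brute_force",
    "canonicalize",
]

logger = logging.getLogger(__name__)

FEASIBILITY_TOL = 1e-9
OBJECTIVE_RTOL = 1e-8


@dataclass(frozen=True)
class Problem:
    """The K x m advanced-risk matrix with regimen costs and a budget."""

    p: np.ndarray
    costs: np.ndarray  # length m, or K x m
    budget: float
    labels: list[str]

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.p, dtype=float))
        costs = np.asarray(self.costs, dtype=float)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "costs", costs)
        object.__setattr__(self, "labels", list(self.labels))
        K, m = p.shape
        if K < 1 or m < 1:
            raise ValueError("need at least one quantile and one regimen")
        if np.any(p < 0):
            raise ValueError("advanced risks p must be non-negative")
        if costs.shape not in ((m,), (K, m)):
            raise ValueError(f"costs must have shape ({m},) or ({K}, {m})")
        if np.any(costs <= 0):
            raise ValueError("costs must be positive")
        if not self.budget > 0:
            raise ValueError("budget must be positive")
        if len(self.labels) != m:
            raise ValueError("labels must match the number of regimens")

    @property
    def K(self) -> int:
        return self.p.shape[0]

    @property
    def m(self) -> int:
        return self.p.shape[1]

    @property
    def cost_matrix(self) -> np.ndarray:
        """Costs broadcast to K x m."""
        if self.costs.ndim == 1:
            return np.broadcast_to(self.costs, self.p.shape)
        return self.costs

    def to_json(self, path) -> None:
        obj = {
            "labels": self.labels,
            "budget": self.budget,
            "p": self.p.tolist(),
            "costs": self.costs.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Problem":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            np.asarray(obj["p"]), np.asarray(obj["costs"]), obj["budget"], obj["labels"]
        )


@dataclass(frozen=True)
class Assignment:
    """A (possibly fractional) K x m decision matrix with its objective value."""

    x: np.ndarray | None
    objective: float
    mode: str  # "lp" | "ip"
    status: str  # "optimal" | "infeasible"
    labels: list[str] = field(default_factory=list)
    costs: np.ndarray | None = None

    @property
    def is_optimal(self) -> bool:
        return self.status == "optimal"

    def total_cost(self, problem: Problem) -> float:
        if self.x is None:
            return float("nan")
        return float(np.sum(problem.cost_matrix * self.x))

    def shares_pct(self) -> np.ndarray:
        """Population percentage per regimen."""
        if self.x is None:
            raise ValueError("no solution available")
        return 100.0 * self.x.sum(axis=0) / self.x.shape[0]

    def summary_frame(self) -> pd.DataFrame:
        if self.x is None:
            raise ValueError("no solution available")
        K, m = self.x.shape
        rows = [
            {"k": k + 1, "regimen_label": self.labels[j], "x": self.x[k, j]}
            for k in range(K)
            for j in range(m)
            if self.x[k, j] > 1e-12
        ]
        return pd.DataFrame(rows, columns=["k", "regimen_label", "x"])

    def to_json(self, path) -> None:
        obj = {
            "mode": self.mode,
            "status": self.status,
            "objective": self.objective,
            "labels": self.labels,
            "x": self.x.tolist() if self.x is not None else None,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def triennial_equivalent_budget(
    K: int, regimens: Sequence[RegimenSpec], baseline_label: str = "3y"
) -> float:
    """Budget equal to giving every quantile the baseline regimen."""
    for reg in regimens:
        if reg.label == baseline_label:
            return K * reg.cost
    raise ValueError(f"baseline regimen {baseline_label!r} not among regimens")


def build_problem(
    quantiles: RiskQuantiles,
    regimens: Sequence[RegimenSpec],
    params: NaturalHistoryParams,
    budget: float,
) -> Problem:
    """Assemble the K x m advanced-risk matrix p_kj = r_k * adj(u_j)."""
    regimens = list(regimens)
    if not regimens:
        raise ValueError("regimen list must be non-empty")
    p = np.array(
        [[advanced_risk(r, params, reg) for reg in regimens] for r in quantiles.mean_risk]
    )
    costs = np.array([reg.cost for reg in regimens])
    labels = [reg.label for reg in regimens]
    return Problem(p, costs, budget, labels)


def _infeasible(problem: Problem, mode: str) -> Assignment:
    return Assignment(
        x=None,
        objective=float("nan"),
        mode=mode,
        status="infeasible",
        labels=problem.labels,
        costs=np.asarray(problem.costs, dtype=float),
    )


def solve_lp(problem: Problem) -> Assignment:
    """Exact LP solution (fractional assignment) via HiGHS."""
    K, m = problem.K, problem.m
    h = problem.cost_matrix
    if problem.budget < h.min(axis=1).sum() - FEASIBILITY_TOL:
        return _infeasible(problem, "lp")
    c = problem.p.ravel()
    A_eq = np.zeros((K, K * m))
    for k in range(K):
        A_eq[k, k * m : (k + 1) * m] = 1.0
    A_ub = h.reshape(1, -1)
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=[problem.budget],
        A_eq=A_eq,
        b_eq=np.ones(K),
        bounds=(0.0, 1.0),
        method="highs",
    )
    if res.status == 2:
        return _infeasible(problem, "lp")
    if not res.success:
        raise RuntimeError(f"LP solver failed: status={res.status} message={res.message}")
    x = np.clip(res.x.reshape(K, m), 0.0, 1.0)
    logger.info("LP solved: objective=%.8g cost=%.6g/%g", res.fun, float((h * x).sum()), problem.budget)
    return Assignment(
        x=x,
        objective=float(res.fun),
        mode="lp",
        status="optimal",
        labels=problem.labels,
        costs=np.asarray(problem.costs, dtype=float),
    )


def solve_ip(problem: Problem) -> Assignment:
    """Exact binary solution via MILP (branch and bound)."""
    K, m = problem.K, problem.m
    h = problem.cost_matrix
    if problem.budget < h.min(axis=1).sum() - FEASIBILITY_TOL:
        return _infeasible(problem, "ip")
    c = problem.p.ravel()
    A_eq = np.zeros((K, K * m))
    for k in range(K):
        A_eq[k, k * m : (k + 1) * m] = 1.0
    constraints = [
        LinearConstraint(A_eq, 1.0, 1.0),
        LinearConstraint(h.reshape(1, -1), -np.inf, problem.budget),
    ]
    res = milp(
        c,
        constraints=constraints,
        integrality=np.ones(K * m),
        bounds=Bounds(0.0, 1.0),
    )
    if res.status == 2:
        return _infeasible(problem, "ip")
    if not res.success:
        raise RuntimeError(f"MILP solver failed: status={res.status} message={res.message}")
    x = np.rint(res.x.reshape(K, m))
    return Assignment(
        x=x,
        objective=float(res.fun),
        mode="ip",
        status="optimal",
        labels=problem.labels,
        costs=np.asarray(problem.costs, dtype=float),
    )


def _simplex_grid(m: int, steps: int) -> np.ndarray:
    """All points of the m-simplex with coordinates i/steps."""
    pts = []
    for comb in itertools.combinations_with_replacement(range(m), steps):
        counts = np.bincount(np.asarray(comb), minlength=m)
        pts.append(counts / steps)
    return np.asarray(pts)


def brute_force(problem: Problem, grid_step: float = 0.01, mode: str = "lp") -> Assignment:
    """Exhaustive-search oracle for tiny instances.

    ip mode enumerates all m**K binary assignments. lp mode restricts each row
    to the simplex grid with the given step and searches all grid combinations
    exhaustively via dynamic programming over a quantized budget axis; row
    costs are rounded *up* to the quantization grid, so the search is
    conservative and its optimum can exceed the true LP optimum by at most the
    grid resolution.
    """
    K, m = problem.K, problem.m
    if K > 8 or m > 3:
        raise ValueError(f"brute force limited to K <= 8, m <= 3 (got {K}, {m})")
    h = problem.cost_matrix
    if mode == "ip":
        best_obj, best_choice = np.inf, None
        for choice in itertools.product(range(m), repeat=K):
            idx = np.arange(K), np.asarray(choice)
            cost = float(h[idx].sum())
            if cost > problem.budget + FEASIBILITY_TOL:
                continue
            obj = float(problem.p[idx].sum())
            if obj < best_obj:
                best_obj, best_choice = obj, choice
        if best_choice is None:
            return _infeasible(problem, "ip")
        x = np.zeros((K, m))
        x[np.arange(K), np.asarray(best_choice)] = 1.0
        return Assignment(
            x=x, objective=best_obj, mode="ip", status="optimal",
            labels=problem.labels, costs=np.asarray(problem.costs, dtype=float),
        )
    if mode != "lp":
        raise ValueError("mode must be 'lp' or 'ip'")

    steps = int(round(1.0 / grid_step))
    grid = _simplex_grid(m, steps)  # G x m
    q = grid_step * float(h.min())  # cost quantum
    n_bins = int(np.floor(problem.budget / q + FEASIBILITY_TOL)) + 1

    # per row: cost bin (rounded up => conservative) and objective per grid point
    row_tables = []
    for k in range(K):
        costs_k = grid @ h[k]
        bins_k = np.ceil(costs_k / q - FEASIBILITY_TOL).astype(int)
        objs_k = grid @ problem.p[k]
        # keep only the best grid point per cost bin
        order = np.lexsort((objs_k, bins_k))
        bins_s, objs_s, idx_s = bins_k[order], objs_k[order], order
        keep = np.concatenate([[True], bins_s[1:] != bins_s[:-1]])
        row_tables.append((bins_s[keep], objs_s[keep], idx_s[keep]))

    INF = np.inf
    dp = np.full(n_bins, INF)
    dp[0] = 0.0
    back: list[np.ndarray] = []
    for bins_k, objs_k, idx_k in row_tables:
        new_dp = np.full(n_bins, INF)
        choice = np.full(n_bins, -1, dtype=int)
        for b, o, gi in zip(bins_k, objs_k, idx_k):
            if b >= n_bins:
                continue
            cand = np.full(n_bins, INF)
            cand[b:] = dp[: n_bins - b] + o
            better = cand < new_dp
            new_dp[better] = cand[better]
            choice[better] = gi
        dp = new_dp
        back.append(choice)
    if not np.isfinite(dp.min()):
        return _infeasible(problem, "lp")
    b_end = int(np.argmin(dp))
    x = np.zeros((K, m))
    b_cur = b_end
    for k in range(K - 1, -1, -1):
        gi = back[k][b_cur]
        x[k] = grid[gi]
        bins_k, _, idx_k = row_tables[k]
        b_cur -= int(bins_k[np.where(idx_k == gi)[0][0]])
    return Assignment(
        x=x, objective=float(dp[b_end]), mode="lp", status="optimal",
        labels=problem.labels, costs=np.asarray(problem.costs, dtype=float),
    )


def canonicalize(
    assignment: Assignment, quantiles: RiskQuantiles, problem: Problem | None = None
) -> Assignment:
    """Tie-break an optimal assignment into risk-sorted, cost-monotone form.

    Per-regimen total mass is preserved and re-dealt so that, with quantiles
    sorted by descending risk, regimen cost is non-increasing in quantile rank.
    Row sums and total cost are unchanged, and for a separable advanced-risk
    matrix (risk times regimen factor) the rearrangement cannot increase the
    objective, so an optimum stays optimal. When ``problem`` is supplied the
    objective is recomputed and, if the rearrangement would worsen it beyond
    tolerance (possible only for non-separable matrices), the input is
    returned unchanged.
    """
    if assignment.x is None:
        return assignment
    x = np.asarray(assignment.x, dtype=float)
    K, m = x.shape
    if K != quantiles.K:
        raise ValueError("assignment and quantiles have inconsistent K")
    costs = np.asarray(assignment.costs, dtype=float)
    if costs.ndim != 1:
        return assignment  # per-quantile costs: mass reallocation not cost-preserving
    mass = x.sum(axis=0)  # total quantile-mass per regimen, sums to K
    # stable orders: risk descending, cost descending
    risk_order = np.argsort(-quantiles.mean_risk, kind="stable")
    cost_order = np.argsort(-costs, kind="stable")
    x_new = np.zeros_like(x)
    remaining = mass.copy()
    ji = 0
    for k in risk_order:
        room = 1.0
        while room > 1e-12 and ji < m:
            j = cost_order[ji]
            take = min(room, remaining[j])
            if take > 0:
                x_new[k, j] += take
                remaining[j] -= take
                room -= take
            if remaining[j] <= 1e-12:
                ji += 1
    objective = assignment.objective
    if problem is not None:
        obj_new = float(np.sum(problem.p * x_new))
        scale = max(abs(assignment.objective), 1.0)
        if obj_new > assignment.objective + OBJECTIVE_RTOL * scale:
            logger.warning(
                "canonicalize would worsen objective (%.10g -> %.10g); keeping input",
                assignment.objective, obj_new,
            )
            return assignment
        objective = obj_new
    return Assignment(
        x=x_new,
        objective=objective,
        mode=assignment.mode,
        status=assignment.status,
        labels=assignment.labels,
        costs=costs,
    )
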