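"""Relative benefit versus a baseline regimen, resource sweeps, sensitivity runs.

All results are expressed relative to giving every quantile the baseline
regimen: the headline number is advanced cancers averted per 1000 advanced
cancers expected under baseline-for-all, which is invariant to rescaling all
quantile risks by a common factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .natural_history import (
    NaturalHistoryParams,
    RegimenSpec,
    advanced_fraction,
    screen_detected_fraction,
)
from .optimizer import (
    Assignment,
    Problem,
    build_problem,
    canonicalize,
    solve_lp,
    triennial_equivalent_budget,
)
from .risk_distribution import GroupThresholds, RiskQuantiles, thresholds_from_assignment

__all__ = [
    "BenefitResult",
    "SweepResult",
    "SensitivityScenario",
    "relative_benefit",
    "resource_sweep",
    "run_sensitivity",
    "default_sensitivity_scenarios",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BenefitResult:
    """Objective under baseline-for-all vs the optimized assignment."""

    baseline_objective: float
    optimized_objective: float

    @property
    def reduction_per_1000(self) -> float:
        return 1000.0 * (self.baseline_objective - self.optimized_objective) / self.baseline_objective

    def to_dict(self) -> dict:
        return {
            "baseline_objective": self.baseline_objective,
            "optimized_objective": self.optimized_objective,
            "reduction_per_1000": self.reduction_per_1000,
        }


@dataclass(frozen=True)
class SweepResult:
    """Reduction and per-regimen population shares over a budget grid."""

    budget_multiples: np.ndarray
    reductions: np.ndarray  # NaN at infeasible points
    shares_pct: np.ndarray  # n_points x m, NaN rows at infeasible points
    labels: list[str]
    feasible: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Tidy form: one row per budget point x regimen."""
        rows = []
        for i, c in enumerate(self.budget_multiples):
            for j, lab in enumerate(self.labels):
                rows.append(
                    {
                        "budget_multiple": c,
                        "feasible": bool(self.feasible[i]),
                        "reduction_per_1000": self.reductions[i],
                        "regimen": lab,
                        "share_pct": self.shares_pct[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SensitivityScenario:
    """Absolute perturbations of the stage-mix and detection parameters.

    ``d_screen_detected`` shifts the screen-detected fraction s (after the
    closed-form model) for the regimens named in ``regimen_labels`` (all
    regimens when None). Perturbed probabilities are clipped to [0, 1].
    """

    name: str
    d_adv_screen: float = 0.0
    d_adv_interval: float = 0.0
    d_screen_detected: float = 0.0
    regimen_labels: tuple[str, ...] | None = None


def default_sensitivity_scenarios(
    intensive_label: str = "1y", lax_label: str = "4y"
) -> list[SensitivityScenario]:
    """The stage-mix and detection perturbations explored in the analysis."""
    return [
        SensitivityScenario("adv_screen+10", d_adv_screen=0.10),
        SensitivityScenario("adv_screen-10", d_adv_screen=-0.10),
        SensitivityScenario("adv_interval+10", d_adv_interval=0.10),
        SensitivityScenario("adv_interval-10", d_adv_interval=-0.10),
        SensitivityScenario("screen_detected+5_all", d_screen_detected=0.05),
        SensitivityScenario("screen_detected-5_all", d_screen_detected=-0.05),
        SensitivityScenario(
            "screen_detected-5_nonbaseline",
            d_screen_detected=-0.05,
            regimen_labels=(intensive_label, lax_label),
        ),
    ]


def relative_benefit(
    problem: Problem, assignment: Assignment, baseline_label: str
) -> BenefitResult:
    """Benefit of ``assignment`` over baseline-for-all, from the same p matrix."""
    if baseline_label not in problem.labels:
        raise ValueError(f"baseline regimen {baseline_label!r} not in problem")
    if assignment.x is None:
        raise ValueError("assignment has no solution")
    j = problem.labels.index(baseline_label)
    baseline_obj = float(problem.p[:, j].sum())
    return BenefitResult(baseline_objective=baseline_obj, optimized_objective=assignment.objective)


def _perturbed_problem(
    quantiles: RiskQuantiles,
    regimens: Sequence[RegimenSpec],
    params: NaturalHistoryParams,
    budget: float,
    scenario: SensitivityScenario,
) -> Problem:
    """Rebuild p under a scenario: s-deltas applied after the closed form, clipped."""
    a = float(np.clip(params.adv_frac_screen + scenario.d_adv_screen, 0.0, 1.0))
    b = float(np.clip(params.adv_frac_interval + scenario.d_adv_interval, 0.0, 1.0))
    if a != params.adv_frac_screen + scenario.d_adv_screen:
        logger.warning("scenario %s: adv_frac_screen clipped to %.3f", scenario.name, a)
    if b != params.adv_frac_interval + scenario.d_adv_interval:
        logger.warning("scenario %s: adv_frac_interval clipped to %.3f", scenario.name, b)
    pert = params.with_updates(adv_frac_screen=a, adv_frac_interval=b)
    factors = []
    for reg in regimens:
        s = screen_detected_fraction(params, reg.interval_years)
        if scenario.regimen_labels is None or reg.label in scenario.regimen_labels:
            s_new = float(np.clip(s + scenario.d_screen_detected, 0.0, 1.0))
            if s_new != s + scenario.d_screen_detected:
                logger.warning(
                    "scenario %s: screen-detected fraction for %s clipped to %.3f",
                    scenario.name, reg.label, s_new,
                )
            s = s_new
        factors.append(advanced_fraction(pert, s))
    p = np.outer(quantiles.mean_risk, np.asarray(factors))
    costs = np.array([reg.cost for reg in regimens])
    return Problem(p, costs, budget, [reg.label for reg in regimens])


def resource_sweep(
    quantiles: RiskQuantiles,
    regimens: Sequence[RegimenSpec],
    params: NaturalHistoryParams,
    budget_multiples: Sequence[float] | None = None,
    baseline_label: str = "3y",
) -> SweepResult:
    """Solve at H = c * K * h_baseline for each multiple c on the grid."""
    if budget_multiples is None:
        budget_multiples = np.arange(0.60, 1.6001, 0.05)
    budget_multiples = np.asarray(list(budget_multiples), dtype=float)
    if np.any(budget_multiples <= 0):
        raise ValueError("budget multiples must be positive")
    regimens = list(regimens)
    base_budget = triennial_equivalent_budget(quantiles.K, regimens, baseline_label)
    m = len(regimens)
    n = budget_multiples.size
    reductions = np.full(n, np.nan)
    shares = np.full((n, m), np.nan)
    feasible = np.zeros(n, dtype=bool)
    for i, c in enumerate(budget_multiples):
        problem = build_problem(quantiles, regimens, params, budget=c * base_budget)
        sol = solve_lp(problem)
        if not sol.is_optimal:
            logger.info("budget multiple %.3g infeasible", c)
            continue
        sol = canonicalize(sol, quantiles, problem)
        feasible[i] = True
        reductions[i] = relative_benefit(problem, sol, baseline_label).reduction_per_1000
        shares[i] = sol.shares_pct()
    return SweepResult(
        budget_multiples=budget_multiples,
        reductions=reductions,
        shares_pct=shares,
        labels=[r.label for r in regimens],
        feasible=feasible,
    )


def run_sensitivity(
    scenarios: Sequence[SensitivityScenario],
    quantiles: RiskQuantiles,
    regimens: Sequence[RegimenSpec],
    params: NaturalHistoryParams,
    budget: float | None = None,
    baseline_label: str = "3y",
) -> pd.DataFrame:
    """Re-optimize under each scenario; report thresholds and relative benefit.

    The baseline objective is recomputed under the same perturbed model, so
    the reported reduction isolates the effect of the assumption change.
    """
    regimens = list(regimens)
    if budget is None:
        budget = triennial_equivalent_budget(quantiles.K, regimens, baseline_label)
    rows = []
    for sc in scenarios:
        problem = _perturbed_problem(quantiles, regimens, params, budget, sc)
        sol = solve_lp(problem)
        if not sol.is_optimal:
            rows.append(
                {"scenario": sc.name, "status": "infeasible",
                 "reduction_per_1000": np.nan, "thresholds": None}
            )
            continue
        sol = canonicalize(sol, quantiles, problem)
        benefit = relative_benefit(problem, sol, baseline_label)
        thresholds = thresholds_from_assignment(quantiles, sol)
        rows.append(
            {
                "scenario": sc.name,
                "status": "optimal",
                "reduction_per_1000": benefit.reduction_per_1000,
                "thresholds": thresholds,
            }
        )
    return pd.DataFrame(rows, columns=["scenario", "status", "reduction_per_1000", "thresholds"])


def sensitivity_frame_for_csv(results: pd.DataFrame) -> pd.DataFrame:
    """Flatten a run_sensitivity frame for CSV output (one row per scenario x regimen)."""
    rows = []
    for _, rec in results.iterrows():
        th: GroupThresholds | None = rec["thresholds"]
        if th is None:
            rows.append(
                {"scenario": rec["scenario"], "status": rec["status"],
                 "reduction_per_1000": rec["reduction_per_1000"],
                 "regimen": None, "share_pct": np.nan,
                 "lower_bound": np.nan, "upper_bound": np.nan}
            )
            continue
        for i, lab in enumerate(th.labels):
            rows.append(
                {
                    "scenario": rec["scenario"],
                    "status": rec["status"],
                    "reduction_per_1000": rec["reduction_per_1000"],
                    "regimen": lab,
                    "share_pct": th.share_pct[i],
                    "lower_bound": th.lower[i] if th.lower is not None else np.nan,
                    "upper_bound": th.upper[i] if th.upper is not None else np.nan,
                }
            )
    cols = ["scenario", "status", "reduction_per_1000", "regimen",
            "share_pct", "lower_bound", "upper_bound"]
    return pd.DataFrame(rows, columns=cols)
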