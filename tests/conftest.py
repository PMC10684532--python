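import numpy as np
import pytest

import screenopt as so


@pytest.fixture
def params():
    return so.NaturalHistoryParams()  # lambda=0.25, D=0.92, a=0.22, b=0.53


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


@pytest.fixture
def quantiles20():
    """Deterministic 20-quantile distribution from a fixed synthetic sample."""
    sample = so.synthesize_case_control(400, 2000, seed=11)
    return so.quantiles_from_scores(sample, 20)


def make_regimens(intervals, horizon_years=6.0):
    return so.default_regimens(intervals, so.Horizon(horizon_years))


def random_instance(rng, K_max=6, m_max=3, grid_friendly=True):
    """Random small Problem with costs on a 0.5 grid (oracle-friendly)."""
    K = int(rng.integers(2, K_max + 1))
    m = int(rng.integers(2, m_max + 1))
    p = rng.random((K, m)) * 0.05
    if grid_friendly:
        costs = rng.choice([0.5, 1.0, 1.5, 2.0, 3.0, 6.0], size=m, replace=False)
    else:
        costs = rng.uniform(0.5, 6.0, size=m)
    budget = float(K * rng.uniform(costs.min(), costs.max() * 1.1))
    labels = [f"r{j}" for j in range(m)]
    return so.Problem(p, costs, budget, labels)


def random_separable_instance(rng, K=8, intervals=(1.0, 3.0, 6.0), budget_mult=None):
    """Risk-quantile instance with separable p (risk x regimen factor)."""
    risks = np.sort(rng.uniform(0.0005, 0.08, size=K))
    quantiles = so.RiskQuantiles(risks)
    regimens = make_regimens(intervals)
    params = so.NaturalHistoryParams()
    costs = np.array([r.cost for r in regimens])
    if budget_mult is None:
        budget_mult = rng.uniform(1.0, 1.3)
    budget = float(budget_mult * K * costs.min())
    problem = so.build_problem(quantiles, regimens, params, budget)
    return quantiles, regimens, params, problem
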