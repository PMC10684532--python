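"""Population risk distribution by quantiles, score thresholds, synthetic samples.

The population distribution of projected invasive-cancer risk is summarised by
``K`` equal-count quantiles of the (control) score distribution; the optimizer
works on quantile mean risks, and optimized assignments are mapped back to
risk-score thresholds here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .optimizer import Assignment

__all__ = [
    "RiskQuantiles",
    "ScoreSample",
    "GroupThresholds",
    "quantiles_from_scores",
    "thresholds_from_assignment",
    "synthesize_case_control",
]


@dataclass(frozen=True)
class RiskQuantiles:
    """K equal-weight risk quantiles: mean risks and score boundaries.

    ``boundaries`` has length K+1; ``boundaries[k-1]``/``boundaries[k]`` bracket
    quantile ``k`` on the risk-score scale. Each quantile carries population
    weight 1/K.
    """

    mean_risk: np.ndarray
    boundaries: np.ndarray | None = None

    def __post_init__(self) -> None:
        mr = np.asarray(self.mean_risk, dtype=float)
        object.__setattr__(self, "mean_risk", mr)
        if mr.ndim != 1 or mr.size < 1:
            raise ValueError("mean_risk must be a non-empty 1-D vector")
        if np.any(mr < 0) or np.any(mr > 1):
            raise ValueError("mean risks must be probabilities in [0, 1]")
        if np.any(np.diff(mr) < 0):
            raise ValueError("mean risks must be non-decreasing in quantile index")
        if self.boundaries is not None:
            b = np.asarray(self.boundaries, dtype=float)
            object.__setattr__(self, "boundaries", b)
            if b.shape != (mr.size + 1,):
                raise ValueError("boundaries must have length K + 1")
            if np.any(np.diff(b) < 0):
                raise ValueError("boundaries must be non-decreasing")

    @property
    def K(self) -> int:
        return int(self.mean_risk.size)

    @property
    def weight(self) -> float:
        return 1.0 / self.K

    def scaled(self, factor: float) -> "RiskQuantiles":
        """Multiply all mean risks by ``factor`` (clipped at 1)."""
        return RiskQuantiles(np.clip(self.mean_risk * factor, 0.0, 1.0), self.boundaries)

    def to_frame(self) -> pd.DataFrame:
        b = self.boundaries
        return pd.DataFrame(
            {
                "k": np.arange(1, self.K + 1),
                "mean_risk": self.mean_risk,
                "lower_bound": b[:-1] if b is not None else np.nan,
                "upper_bound": b[1:] if b is not None else np.nan,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RiskQuantiles":
        df = pd.read_csv(path).sort_values("k")
        boundaries = None
        if "lower_bound" in df.columns and df["lower_bound"].notna().all():
            boundaries = np.concatenate(
                [df["lower_bound"].to_numpy(), [df["upper_bound"].iloc[-1]]]
            )
        return cls(df["mean_risk"].to_numpy(), boundaries)


@dataclass(frozen=True)
class ScoreSample:
    """Case-control risk-score records."""

    ids: np.ndarray
    status: np.ndarray  # "case" | "control"
    risk: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids)
        status = np.asarray(self.status)
        risk = np.asarray(self.risk, dtype=float)
        if not (ids.shape == status.shape == risk.shape) or risk.ndim != 1:
            raise ValueError("ids, status and risk must be 1-D arrays of equal length")
        bad = set(np.unique(status)) - {"case", "control"}
        if bad:
            raise ValueError(f"status values must be 'case' or 'control', got {bad}")
        if np.any(risk < 0) or np.any(risk > 1):
            raise ValueError("risk scores must lie in [0, 1]")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "status", status)
        object.__setattr__(self, "risk", risk)

    def __len__(self) -> int:
        return int(self.risk.size)

    def control_risks(self) -> np.ndarray:
        return self.risk[self.status == "control"]

    def case_risks(self) -> np.ndarray:
        return self.risk[self.status == "case"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "status": self.status, "risk": self.risk})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScoreSample":
        df = pd.read_csv(path)
        return cls(
            df["id"].to_numpy(), df["status"].to_numpy(), df["risk"].to_numpy(float)
        )


@dataclass(frozen=True)
class GroupThresholds:
    """Per-regimen population shares and risk-score bounds."""

    labels: list[str]
    share_pct: np.ndarray
    lower: np.ndarray | None  # None when the assignment is non-contiguous
    upper: np.ndarray | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "regimen": self.labels,
                "share_pct": self.share_pct,
                "lower_bound": self.lower if self.lower is not None else np.nan,
                "upper_bound": self.upper if self.upper is not None else np.nan,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_dict(self) -> dict:
        out = {}
        for i, lab in enumerate(self.labels):
            entry = {"share_pct": float(self.share_pct[i])}
            if self.lower is not None:
                entry["lower_bound"] = float(self.lower[i])
                entry["upper_bound"] = float(self.upper[i])
            out[lab] = entry
        return out


def quantiles_from_scores(
    sample: ScoreSample | np.ndarray,
    K: int,
    use_controls_only: bool = True,
) -> RiskQuantiles:
    """Equal-count quantiles of the empirical score distribution.

    Quantile ``k`` (1-based) holds sorted ranks ``ceil((k-1) n / K) + 1`` to
    ``ceil(k n / K)``; its mean score is the quantile mean risk. Boundary
    ``q_k`` is the score at rank ``ceil(k n / K)``; ties are therefore placed
    in the lower quantile. By default only controls define the distribution.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    if isinstance(sample, ScoreSample):
        scores = sample.control_risks() if use_controls_only else sample.risk
    else:
        scores = np.asarray(sample, dtype=float)
    n = scores.size
    if n < K:
        raise ValueError(f"need at least K={K} usable records, got {n}")
    s = np.sort(scores, kind="stable")
    upper_idx = np.ceil(np.arange(1, K + 1) * n / K).astype(int)  # 1-based ranks
    lower_idx = np.concatenate([[0], upper_idx[:-1]])
    means = np.array([s[lo:hi].mean() for lo, hi in zip(lower_idx, upper_idx)])
    boundaries = np.concatenate([[s[0]], s[upper_idx - 1]])
    return RiskQuantiles(means, boundaries)


def thresholds_from_assignment(
    quantiles: RiskQuantiles, assignment: "Assignment"
) -> GroupThresholds:
    """Map an optimized quantile assignment to population shares and score bounds.

    Shares are ``sum_k x_kj / K`` as percentages. Score bounds sit at quantile
    boundaries; a fractional split within a quantile is interpolated linearly
    in rank between that quantile's boundary scores. If a regimen's assigned
    mass is not contiguous (quantiles in risk order, regimens in cost order),
    shares are still reported but bounds are omitted with a warning.
    """
    x = np.asarray(assignment.x, dtype=float)
    K, m = x.shape
    if K != quantiles.K:
        raise ValueError("assignment and quantiles have inconsistent K")
    if not np.allclose(x.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("assignment rows must sum to 1")
    labels = list(assignment.labels)
    shares = 100.0 * x.sum(axis=0) / K

    # walk quantiles in ascending risk; within a quantile, cheaper (less
    # intensive) regimens occupy the lower-risk portion
    costs = np.asarray(assignment.costs, dtype=float)
    order = np.argsort(costs, kind="stable")
    segments: dict[int, list[tuple[float, float]]] = {j: [] for j in range(m)}
    for k in range(K):
        pos = float(k)
        for j in order:
            f = x[k, j]
            if f > 1e-9:
                segments[j].append((pos, pos + f))
                pos += f

    tol = 1e-6
    lower = np.full(m, np.nan)
    upper = np.full(m, np.nan)
    contiguous = True
    for j in range(m):
        segs = segments[j]
        if not segs:
            continue
        for (a0, a1), (b0, b1) in zip(segs, segs[1:]):
            if b0 - a1 > tol:
                contiguous = False
        lower[j], upper[j] = segs[0][0], segs[-1][1]
    if not contiguous:
        warnings.warn(
            "assignment is not contiguous in risk order; score bounds omitted",
            stacklevel=2,
        )
        return GroupThresholds(labels, shares, None, None)

    if quantiles.boundaries is None:
        return GroupThresholds(labels, shares, None, None)

    b = quantiles.boundaries

    def pos_to_score(t: float) -> float:
        k = min(int(np.floor(t)), K - 1)
        frac = t - k
        return float(b[k] + frac * (b[k + 1] - b[k]))

    lo_scores = np.array(
        [pos_to_score(lower[j]) if not np.isnan(lower[j]) else np.nan for j in range(m)]
    )
    hi_scores = np.array(
        [pos_to_score(upper[j]) if not np.isnan(upper[j]) else np.nan for j in range(m)]
    )
    return GroupThresholds(labels, shares, lo_scores, hi_scores)


def synthesize_case_control(
    n_cases: int,
    n_controls: int,
    mu: float = float(np.log(0.02)),
    sigma: float = 0.8,
    seed: int | None = None,
) -> ScoreSample:
    """Synthetic case-control risk scores with cases enriched at high risk.

    Control scores follow a log-normal(mu, sigma) truncated to [0, 1]. Case
    scores follow the risk-tilted control law, density proportional to
    ``r * f(r)``, drawn by rejection with acceptance probability ``r``. A
    warning is raised if the un-truncated law puts more than 5% mass above 1.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("counts must be positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    trunc_mass = float(stats.lognorm(s=sigma, scale=np.exp(mu)).sf(1.0))
    if trunc_mass > 0.05:
        warnings.warn(
            f"log-normal(mu={mu:.3g}, sigma={sigma:.3g}) places "
            f"{100 * trunc_mass:.1f}% mass above 1 (truncated)",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)

    def draw_controls(n: int) -> np.ndarray:
        out = np.empty(0)
        while out.size < n:
            batch = rng.lognormal(mu, sigma, size=max(n, 1024))
            out = np.concatenate([out, batch[batch <= 1.0]])
        return out[:n]

    controls = draw_controls(n_controls)

    cases = np.empty(0)
    while cases.size < n_cases:
        cand = draw_controls(max(n_cases, 4096))
        accept = rng.random(cand.size) < cand
        cases = np.concatenate([cases, cand[accept]])
    cases = cases[:n_cases]

    ids = np.array(
        [f"case-{i + 1}" for i in range(n_cases)]
        + [f"control-{i + 1}" for i in range(n_controls)]
    )
    status = np.array(["case"] * n_cases + ["control"] * n_controls)
    risk = np.concatenate([cases, controls])
    return ScoreSample(ids, status, risk)
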