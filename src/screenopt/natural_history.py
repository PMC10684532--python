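"""Two-state natural-history model for screen-detected versus interval cancer.

The model assumes preclinical (asymptomatic, screen-detectable) disease
becomes symptomatic at a constant exponential rate, screens recur every
``u`` years with per-screen sensitivity ``D``, and the probability a
diagnosed cancer is advanced (node-positive) differs by detection mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NaturalHistoryParams",
    "RegimenSpec",
    "Horizon",
    "screen_detected_fraction",
    "advanced_fraction",
    "advanced_risk",
    "node_positive_table",
    "simulate_screen_detected_fraction",
    "default_regimens",
]


@dataclass(frozen=True)
class NaturalHistoryParams:
    """Parameters governing detection mode and stage mixing.

    Attributes
    ----------
    lambda_rate : float
        Transition rate per year from asymptomatic to symptomatic disease.
    sensitivity : float
        Per-screen probability of detecting preclinical disease; ``0`` is
        accepted as a continuity boundary (nothing is screen-detected).
    adv_frac_screen : float
        Probability a screen-detected cancer is advanced (node-positive).
    adv_frac_interval : float
        Probability an interval cancer is advanced.
    """

    lambda_rate: float = 0.25
    sensitivity: float = 0.92
    adv_frac_screen: float = 0.22
    adv_frac_interval: float = 0.53

    def __post_init__(self) -> None:
        if not self.lambda_rate > 0:
            raise ValueError(f"lambda_rate must be > 0, got {self.lambda_rate}")
        if not 0 <= self.sensitivity <= 1:
            raise ValueError(f"sensitivity must be in [0, 1], got {self.sensitivity}")
        for name in ("adv_frac_screen", "adv_frac_interval"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def with_updates(self, **kwargs) -> "NaturalHistoryParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Horizon:
    """Planning period over which per-person screening costs are counted."""

    horizon_years: float = 6.0

    def __post_init__(self) -> None:
        if not self.horizon_years > 0:
            raise ValueError("horizon_years must be > 0")


@dataclass(frozen=True)
class RegimenSpec:
    """A screening regimen: interval ``u`` with cost ``h`` screens per horizon."""

    label: str
    interval_years: float
    cost: float

    def __post_init__(self) -> None:
        if not self.interval_years > 0:
            raise ValueError("interval_years must be > 0")
        if not self.cost > 0:
            raise ValueError("cost must be > 0")

    @classmethod
    def from_interval(
        cls,
        interval_years: float,
        horizon: Horizon | float = Horizon(),
        label: str | None = None,
    ) -> "RegimenSpec":
        """Build a regimen with the default costing rule h = horizon / interval."""
        h = horizon.horizon_years if isinstance(horizon, Horizon) else float(horizon)
        if label is None:
            iv = interval_years
            label = f"{iv:g}y"
        return cls(label=label, interval_years=float(interval_years), cost=h / interval_years)


def default_regimens(
    intervals: Sequence[float], horizon: Horizon | float = Horizon()
) -> list[RegimenSpec]:
    """Regimens for each interval with cost = horizon / interval."""
    return [RegimenSpec.from_interval(u, horizon) for u in intervals]


def screen_detected_fraction(
    params: NaturalHistoryParams, interval_years: float
) -> float:
    """Probability a cancer is screen-detected (vs interval) under regular screening.

    Closed form for exponential sojourn with rate ``lambda_rate``, screens
    every ``interval_years``, per-screen sensitivity ``sensitivity``:

        s = D (1 - exp(-lam u)) / (lam u (1 - (1 - D) exp(-lam u)))

    ``sensitivity == 0`` returns 0 by continuity.
    """
    if not interval_years > 0:
        raise ValueError(f"interval_years must be > 0, got {interval_years}")
    lam = params.lambda_rate
    d = params.sensitivity
    if d == 0:
        return 0.0
    lu = lam * interval_years
    e = math.exp(-lu)
    return d * (1.0 - e) / (lu * (1.0 - (1.0 - d) * e))


def advanced_fraction(params: NaturalHistoryParams, s: float) -> float:
    """Probability a diagnosed cancer is advanced, mixing over detection mode.

    Returns ``a*s + b*(1-s)`` where ``a``/``b`` are the advanced fractions
    for screen-detected and interval cancers.
    """
    if not 0 <= s <= 1:
        raise ValueError(f"screen-detected fraction s must be in [0, 1], got {s}")
    return params.adv_frac_screen * s + params.adv_frac_interval * (1.0 - s)


def advanced_risk(
    invasive_risk: float, params: NaturalHistoryParams, regimen: RegimenSpec
) -> float:
    """Advanced-cancer risk: invasive risk times the regimen's stage adjustment."""
    if not 0 <= invasive_risk <= 1:
        raise ValueError(f"invasive_risk must be in [0, 1], got {invasive_risk}")
    s = screen_detected_fraction(params, regimen.interval_years)
    return invasive_risk * advanced_fraction(params, s)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def node_positive_table(
    params: NaturalHistoryParams, intervals: Iterable[float]
) -> pd.DataFrame:
    """Screen-detected and advanced (node-positive) percentages per interval.

    Percentages are rounded to the nearest integer, half away from zero.
    """
    intervals = list(intervals)
    if not intervals:
        raise ValueError("intervals must be non-empty")
    rows = []
    for u in intervals:
        s = screen_detected_fraction(params, u)
        adv = advanced_fraction(params, s)
        rows.append(
            {
                "interval_years": u,
                "screen_detected_pct": _round_half_away(100.0 * s),
                "advanced_pct": _round_half_away(100.0 * adv),
            }
        )
    return pd.DataFrame(rows, columns=["interval_years", "screen_detected_pct", "advanced_pct"])


def simulate_screen_detected_fraction(
    params: NaturalHistoryParams,
    interval_years: float,
    n: int = 100_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Event-level Monte-Carlo estimate of the screen-detected fraction.

    Simulates, per cancer: preclinical onset uniform within a screening round,
    an exponential sojourn time, and independent Bernoulli detection at each
    screen falling inside the preclinical window. Used as an independent check
    on :func:`screen_detected_fraction`.

    Returns
    -------
    (estimate, standard_error)
    """
    if not interval_years > 0:
        raise ValueError("interval_years must be > 0")
    if rng is None:
        rng = np.random.default_rng()
    u = interval_years
    lam = params.lambda_rate
    d = params.sensitivity
    onset = rng.uniform(0.0, u, size=n)
    sojourn = rng.exponential(1.0 / lam, size=n)
    # screens at u, 2u, 3u, ... ; count those strictly before symptom onset
    n_screens = np.ceil((onset + sojourn) / u).astype(np.int64) - 1
    if d == 0:
        detected = np.zeros(n, dtype=bool)
    else:
        # geometric number of screens needed for first detection
        trials_needed = rng.geometric(d, size=n)
        detected = trials_needed <= n_screens
    est = float(detected.mean())
    se = float(np.sqrt(est * (1.0 - est) / n))
    return est, se
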