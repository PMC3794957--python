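"""Daily food demand: goals from food-insecurity prevalence, stochastic draws.

Aggregate demand is sized from hunger statistics: a regional population, the
fraction of individuals needing food assistance, per-capita daily food
consumption (2.85 lbs for a typical American), and the share of intake the
food bank covers (one third by default).  Day-to-day demand is either a fixed
goal or a Gaussian around it, truncated at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "DemandSpec",
    "weekly_individuals",
    "demand_goal",
    "mean_daily_distribution",
    "draw_daily_demand",
]


@dataclass(frozen=True)
class DemandSpec:
    """Daily demand distribution: mean (lbs/day), coefficient of variation, mode."""

    mean: float
    cv: float = 0.1
    mode: Literal["constant", "gaussian"] = "constant"

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError("mean must be >= 0")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.mode not in ("constant", "gaussian"):
            raise ValueError(f"unknown mode {self.mode!r}")


def weekly_individuals(population: float, prevalence: float) -> int:
    """People needing weekly food assistance: round(population * prevalence)."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    if population < 0:
        raise ValueError("population must be >= 0")
    return round(population * prevalence)


def demand_goal(individuals: float, per_capita: float, share: float) -> int:
    """Daily demand goal in whole pounds: floor(individuals * per_capita * share).

    ``per_capita`` is pounds of food per person-day; ``share`` the fraction of
    that intake the food bank supplies.  Floored to whole pounds.
    """
    if individuals < 0 or per_capita < 0:
        raise ValueError("arguments must be >= 0")
    if not 0.0 <= share <= 1.0:
        raise ValueError("share must be in [0, 1]")
    return math.floor(individuals * per_capita * share)


def mean_daily_distribution(total: float, days: int) -> int:
    """Mean pounds distributed per day: floor(total / days)."""
    if days < 1:
        raise ValueError("days must be >= 1")
    if total < 0:
        raise ValueError("total must be >= 0")
    return math.floor(total / days)


def draw_daily_demand(spec: DemandSpec, rng: np.random.Generator) -> float:
    """One day's demand; Gaussian mode is truncated below at zero."""
    if spec.mode == "constant":
        return spec.mean
    draw = rng.normal(spec.mean, spec.cv * spec.mean)
    return max(0.0, draw)
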