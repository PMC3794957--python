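"""Monte Carlo experiments over the full supply/demand/scheduling model.

A simulation fixes a donor roster and runs one day at a time: draw each
donor's donation, decay yesterday's leftovers, draw demand, choose the
cheapest cluster selection covering it, collect, and settle the warehouse.
Runs are repeated-measures experiments: sweeps over the overnight survival
fraction or the participating-donor fraction reuse common random numbers
(per-donor substreams keyed by donor id), so curves differ only through the
parameter being varied, not through sampling noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .demand_model import DemandSpec, draw_daily_demand
from .scheduler import (
    LedgerState,
    PickupDecision,
    accrue_supply,
    apply_pickups,
    solve_day,
    update_warehouse,
)
from .spatial_cost import DonorProfile, cluster_donors, exclude_distant
from .supply_model import donations_from_uniforms

__all__ = [
    "SimConfig",
    "SimulationSummary",
    "donor_uniforms",
    "run_simulation",
    "summarize",
    "sweep_epsilon",
    "sweep_participation",
]

_DEMAND_TAG = 0xDE3A9D
_SUBSET_TAG = 0x5B5E7


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    ``survival`` is the fraction of un-recovered food remaining after one
    night (the expiry dial: 0.5 means half expires overnight, 0.8 means 20%
    expires).  ``max_donor_km`` drops donors beyond that driving distance;
    ``warehouse_capacity`` caps stored excess.  Both default to unlimited.
    """

    n_days: int = 365
    survival: float = 0.5
    demand: DemandSpec = DemandSpec(mean=10_260.0)
    radius_km: float = 10.0
    circuity: float = 1.3
    max_donor_km: float = np.inf
    warehouse_capacity: float = np.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if not 0.0 <= self.survival <= 1.0:
            raise ValueError("survival must be in [0, 1]")


@dataclass(frozen=True)
class SimulationSummary:
    """Arithmetic per-day means and counts over a simulated horizon."""

    mean_excess: float
    mean_shortage: float
    underrun_days: int
    mean_cost: float
    total_picked: float


def donor_uniforms(donor_id: str, seed: int, n_days: int) -> np.ndarray:
    """The (n_days, 2) uniform pairs driving one donor's daily draws.

    Each donor owns a Philox substream keyed by (seed, crc32(donor id)), so a
    donor's draws are identical whichever other donors share the run — the
    common-random-numbers contract behind comparable sweeps.
    """
    key = zlib.crc32(donor_id.encode("utf-8"))
    rng = np.random.Generator(np.random.Philox(key=[seed, key]))
    return rng.random((n_days, 2))


def run_simulation(
    donors: Sequence[DonorProfile], config: SimConfig
) -> list[PickupDecision]:
    """Simulate ``config.n_days`` days over the roster; one record per day.

    Donors beyond ``max_donor_km`` are excluded up front; clusters are built
    once from geometry and held fixed.  Bit-identical output for identical
    (donors, config) including the seed.
    """
    if np.isfinite(config.max_donor_km):
        donors = exclude_distant(donors, config.max_donor_km)
    if not donors:
        raise ValueError("no donors remain after distance filtering")

    clusters = cluster_donors(donors, config.radius_km)
    cluster_costs = {c.id: c.cost_km for c in clusters}
    member_of = {d: c.id for c in clusters for d in c.member_ids}

    per_donor = []
    for d in donors:
        u = donor_uniforms(d.id, config.seed, config.n_days)
        per_donor.append(donations_from_uniforms(u[:, 0], u[:, 1], d.params))
    draws = np.stack(per_donor, axis=0)  # (n_donors, n_days)
    donor_ids = [d.id for d in donors]

    demand_rng = np.random.Generator(
        np.random.Philox(key=[config.seed, _DEMAND_TAG])
    )

    ledger = LedgerState(available={d: 0.0 for d in donor_ids})
    records: list[PickupDecision] = []
    for day in range(config.n_days):
        ledger = accrue_supply(
            ledger, dict(zip(donor_ids, draws[:, day])), config.survival
        )
        demand = draw_daily_demand(config.demand, demand_rng)

        cluster_supply = {c.id: 0.0 for c in clusters}
        for did, avail in ledger.available.items():
            cluster_supply[member_of[did]] += avail
        carryover = config.survival * ledger.warehouse

        selected = solve_day(cluster_supply, cluster_costs, carryover, demand)
        picked, ledger = apply_pickups(ledger, selected, clusters)
        cost = sum(cluster_costs[c] for c in selected)
        warehouse, shortage, excess = update_warehouse(
            ledger.warehouse,
            picked,
            demand,
            config.survival,
            config.warehouse_capacity,
        )
        ledger = LedgerState(available=ledger.available, warehouse=warehouse)
        records.append(
            PickupDecision(
                day=day,
                selected=selected,
                picked_lbs=picked,
                cost_km=cost,
                shortage_lbs=shortage,
                excess_lbs=excess,
                demand_lbs=demand,
                warehouse_lbs=warehouse,
            )
        )
    return records


def summarize(records: Sequence[PickupDecision], n_days: int) -> SimulationSummary:
    """Per-day means of excess, shortage and cost, and the underrun-day count."""
    if len(records) != n_days:
        raise ValueError("records must cover exactly n_days")
    return SimulationSummary(
        mean_excess=sum(r.excess_lbs for r in records) / n_days,
        mean_shortage=sum(r.shortage_lbs for r in records) / n_days,
        underrun_days=sum(1 for r in records if r.shortage_lbs > 0),
        mean_cost=sum(r.cost_km for r in records) / n_days,
        total_picked=sum(r.picked_lbs for r in records),
    )


def sweep_epsilon(
    donors: Sequence[DonorProfile],
    config: SimConfig,
    survival_grid: Sequence[float],
) -> pd.DataFrame:
    """One simulation per overnight-survival value, common random numbers.

    Returns columns ``survival, underrun_days, mean_cost, mean_excess,
    mean_shortage``.
    """
    rows = []
    for s in survival_grid:
        if not 0.0 <= s <= 1.0:
            raise ValueError("survival grid values must be in [0, 1]")
        recs = run_simulation(donors, replace(config, survival=s))
        summ = summarize(recs, config.n_days)
        rows.append(
            {
                "survival": s,
                "underrun_days": summ.underrun_days,
                "mean_cost": summ.mean_cost,
                "mean_excess": summ.mean_excess,
                "mean_shortage": summ.mean_shortage,
            }
        )
    return pd.DataFrame(rows)


def sweep_participation(
    donors: Sequence[DonorProfile],
    config: SimConfig,
    fractions: Sequence[float],
    demand_goals: Sequence[float],
    draws: int = 10,
) -> pd.DataFrame:
    """Simulate random donor subsets of increasing size for each demand goal.

    For every replicate a seeded permutation of the roster defines nested
    subsets (the donors at fraction f are a subset of those at f' > f), so
    participation curves are comparable point to point.  Summaries are
    averaged over ``draws`` replicates.  Returns columns ``fraction, demand,
    mean_cost, underrun_days, mean_shortage, total_picked``.
    """
    if draws < 1:
        raise ValueError("draws must be >= 1")
    if any(not 0.0 < f <= 1.0 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    n = len(donors)
    rows = []
    for rep in range(draws):
        perm_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, _SUBSET_TAG, rep])
        )
        order = perm_rng.permutation(n)
        for frac in fractions:
            size = max(1, int(np.ceil(frac * n)))
            subset = [donors[i] for i in sorted(order[:size])]
            for goal in demand_goals:
                cfg = replace(config, demand=replace(config.demand, mean=goal))
                summ = summarize(run_simulation(subset, cfg), config.n_days)
                rows.append(
                    {
                        "replicate": rep,
                        "fraction": frac,
                        "demand": goal,
                        "mean_cost": summ.mean_cost,
                        "underrun_days": summ.underrun_days,
                        "mean_shortage": summ.mean_shortage,
                        "total_picked": summ.total_picked,
                    }
                )
    out = (
        pd.DataFrame(rows)
        .groupby(["fraction", "demand"], as_index=False)[
            ["mean_cost", "underrun_days", "mean_shortage", "total_picked"]
        ]
        .mean()
    )
    return out
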