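"""Perishable-inventory ledger and the per-day minimum-cost pickup selection.

Un-picked-up food at a donor decays overnight: a fraction ``survival`` of it
remains each morning, so the recoverable stock is a geometric sum of recent
daily draws.  Food brought to the warehouse decays at the same rate.  Each
day a set of donor clusters is chosen to pick up; the selection minimises,
lexicographically, (1) the shortfall against demand, (2) total driving cost,
(3) the number of clusters visited, (4) the sorted tuple of cluster ids.
The selection problem is a 0/1 integer program (fractional pickups are
meaningless) solved with HiGHS via :func:`scipy.optimize.milp`; a brute-force
enumerator with identical tie-breaking serves as a verification oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .spatial_cost import Cluster

__all__ = [
    "LedgerState",
    "PickupDecision",
    "SchedulingError",
    "accrue_supply",
    "apply_pickups",
    "update_warehouse",
    "solve_day",
    "brute_force_day",
]

_MILP_TOL = 1e-7
BRUTE_FORCE_MAX = 20


class SchedulingError(RuntimeError):
    """MILP failure, with the day's inputs attached for diagnosis."""


@dataclass
class LedgerState:
    """Recoverable food currently sitting at each donor, plus warehouse stock."""

    available: dict[str, float] = field(default_factory=dict)
    warehouse: float = 0.0

    def __post_init__(self) -> None:
        if self.warehouse < 0 or any(v < 0 for v in self.available.values()):
            raise ValueError("inventory quantities must be >= 0")


@dataclass(frozen=True)
class PickupDecision:
    """One simulated day's outcome."""

    day: int
    selected: frozenset[str]
    picked_lbs: float
    cost_km: float
    shortage_lbs: float
    excess_lbs: float
    demand_lbs: float = 0.0
    warehouse_lbs: float = 0.0


def accrue_supply(
    ledger: LedgerState, draws: Mapping[str, float], survival: float
) -> LedgerState:
    """Overnight decay then today's draws: available' = draw + survival * available.

    Equivalent, between pickups, to the closed-form geometric sum
    sum_j survival^(d-j) * draw_j over days since the last pickup.
    """
    if not 0.0 <= survival <= 1.0:
        raise ValueError("survival must be in [0, 1]")
    if any(v < 0 for v in draws.values()):
        raise ValueError("draws must be >= 0")
    new = {
        donor: draws.get(donor, 0.0) + survival * ledger.available.get(donor, 0.0)
        for donor in set(ledger.available) | set(draws)
    }
    return LedgerState(available=new, warehouse=ledger.warehouse)


def apply_pickups(
    ledger: LedgerState,
    selected: Sequence[str] | frozenset[str],
    clusters: Sequence[Cluster],
) -> tuple[float, LedgerState]:
    """Collect everything at every member of each selected cluster.

    Returns the total pounds picked up and the ledger with those donors'
    stocks zeroed; visiting any cluster member visits all of them.
    """
    by_id = {c.id: c for c in clusters}
    unknown = set(selected) - set(by_id)
    if unknown:
        raise KeyError(f"unknown cluster ids: {sorted(unknown)}")
    visited: set[str] = set()
    for cid in selected:
        visited |= by_id[cid].member_ids
    picked = sum(ledger.available.get(d, 0.0) for d in visited)
    new_avail = {
        d: (0.0 if d in visited else v) for d, v in ledger.available.items()
    }
    return picked, LedgerState(available=new_avail, warehouse=ledger.warehouse)


def update_warehouse(
    warehouse: float,
    picked: float,
    demand: float,
    survival: float,
    capacity: float = np.inf,
) -> tuple[float, float, float]:
    """Serve today's demand from pickups plus surviving warehouse stock.

    Returns ``(warehouse', shortage, excess)``.  Stock decays overnight at the
    same rate as donor-held food; leftover beyond demand is stored up to
    ``capacity``; shortfall is reported, never carried as a deficit.
    """
    if min(warehouse, picked, demand) < 0 or capacity < 0:
        raise ValueError("quantities must be >= 0")
    if not 0.0 <= survival <= 1.0:
        raise ValueError("survival must be in [0, 1]")
    supply_today = picked + survival * warehouse
    shortage = max(0.0, demand - supply_today)
    excess = max(0.0, supply_today - demand)
    return min(excess, capacity), shortage, excess


def _rank_key(
    sel: tuple[str, ...],
    supply: Mapping[str, float],
    cost: Mapping[str, float],
    need: float,
):
    got = sum(supply[c] for c in sel)
    return (
        max(0.0, need - got),
        sum(cost[c] for c in sel),
        len(sel),
        tuple(sorted(sel)),
    )


def brute_force_day(
    cluster_supply: Mapping[str, float],
    cluster_cost: Mapping[str, float],
    carryover: float,
    demand: float,
) -> frozenset[str]:
    """Exhaustive reference selection over all 2^C subsets (tests only)."""
    ids = sorted(cluster_supply)
    if set(ids) != set(cluster_cost):
        raise ValueError("supply and cost key sets differ")
    if len(ids) > BRUTE_FORCE_MAX:
        raise ValueError(f"brute force limited to {BRUTE_FORCE_MAX} clusters")
    need = demand - carryover
    if need <= 0:
        return frozenset()
    best: tuple[str, ...] | None = None
    best_key = None
    for r in range(len(ids) + 1):
        for sel in combinations(ids, r):
            key = _rank_key(sel, cluster_supply, cluster_cost, need)
            if best_key is None or key < best_key:
                best, best_key = sel, key
    return frozenset(best or ())


def solve_day(
    cluster_supply: Mapping[str, float],
    cluster_cost: Mapping[str, float],
    carryover: float,
    demand: float,
) -> frozenset[str]:
    """Choose today's clusters: minimise shortfall, then cost, then count, then
    the lexicographic order of the sorted selected-id tuple.

    ``carryover`` is warehouse stock already surviving into today.  Demand
    already met by carryover yields the empty selection.  Zero-supply clusters
    can never help and are pruned (the cost/count tie-breaks would exclude
    them regardless).
    """
    ids = sorted(cluster_supply)
    if set(ids) != set(cluster_cost):
        raise ValueError("supply and cost key sets differ")
    if any(cluster_supply[c] < 0 or cluster_cost[c] < 0 for c in ids):
        raise ValueError("supplies and costs must be >= 0")
    need = demand - carryover
    if need <= 0:
        return frozenset()

    ids = [c for c in ids if cluster_supply[c] > 0]
    if not ids:
        return frozenset()
    supply = np.array([cluster_supply[c] for c in ids])
    cost = np.array([cluster_cost[c] for c in ids])
    total = float(supply.sum())

    if total <= need:
        # demand unreachable: shortfall minimisation forces every productive
        # cluster; tie-breaks cannot drop any (each removal adds shortfall)
        return frozenset(ids)

    # stage 1 implicit: shortfall 0 is attainable. stage 2: cheapest cover.
    x = _milp_min(cost, supply, need, ids, fixed={})
    best_cost = float(cost @ x)
    sel = frozenset(np.array(ids)[x > 0.5].tolist())

    # uniqueness probe: re-optimise with the found selection excluded; if the
    # optimum worsens, the selection is unique and tie-breaks are moot
    alt = _milp_min(cost, supply, need, ids, fixed={}, exclude=x)
    if alt is None or float(cost @ alt) > best_cost + _MILP_TOL * (1 + best_cost):
        return sel

    # ties exist: stage 3 minimises cluster count at optimal cost
    ones = np.ones_like(cost)
    x = _milp_min(ones, supply, need, ids, fixed={}, cost_cap=(cost, best_cost))
    best_count = int(round(float(ones @ x)))

    # stage 4: lexicographically smallest sorted id tuple among optima, built
    # greedily: force each id in, keep it if an optimal completion still exists
    fixed: dict[int, int] = {}
    chosen: list[str] = []
    for i, cid in enumerate(ids):
        if len(chosen) == best_count:
            break
        trial = dict(fixed)
        trial[i] = 1
        x = _milp_feasible(
            supply, need, ids, trial, cost, best_cost, best_count
        )
        if x is not None:
            fixed[i] = 1
            chosen.append(cid)
        else:
            fixed[i] = 0
    return frozenset(chosen)


def _milp_min(
    objective: np.ndarray,
    supply: np.ndarray,
    need: float,
    ids: Sequence[str],
    fixed: Mapping[int, int],
    exclude: np.ndarray | None = None,
    cost_cap: tuple[np.ndarray, float] | None = None,
) -> np.ndarray | None:
    n = len(ids)
    lb = np.zeros(n)
    ub = np.ones(n)
    for i, v in fixed.items():
        lb[i] = ub[i] = v
    constraints = [LinearConstraint(supply, lb=need)]
    if cost_cap is not None:
        cvec, cbound = cost_cap
        constraints.append(
            LinearConstraint(cvec, ub=cbound + _MILP_TOL * (1 + cbound))
        )
    if exclude is not None:
        # no-good cut: any feasible point must differ from `exclude` somewhere
        coeff = np.where(exclude > 0.5, -1.0, 1.0)
        constraints.append(
            LinearConstraint(coeff, lb=1.0 - float(np.sum(exclude > 0.5)))
        )
    res = milp(
        c=objective,
        constraints=constraints,
        integrality=np.ones(n),
        bounds=Bounds(lb, ub),
    )
    if res.status == 2:  # infeasible
        return None
    if not res.success:
        raise SchedulingError(
            f"MILP failed (status {res.status}): ids={list(ids)}, need={need}"
        )
    return np.round(res.x)


def _milp_feasible(
    supply: np.ndarray,
    need: float,
    ids: Sequence[str],
    fixed: Mapping[int, int],
    cost: np.ndarray,
    best_cost: float,
    best_count: int,
) -> np.ndarray | None:
    n = len(ids)
    lb = np.zeros(n)
    ub = np.ones(n)
    for i, v in fixed.items():
        lb[i] = ub[i] = v
    constraints = [
        LinearConstraint(supply, lb=need),
        LinearConstraint(cost, ub=best_cost + _MILP_TOL * (1 + best_cost)),
        LinearConstraint(np.ones(n), lb=best_count, ub=best_count),
    ]
    res = milp(
        c=np.zeros(n),
        constraints=constraints,
        integrality=np.ones(n),
        bounds=Bounds(lb, ub),
    )
    if res.status == 2 or res.x is None:
        return None
    if not res.success:
        raise SchedulingError(f"MILP feasibility probe failed: status {res.status}")
    return np.round(res.x)
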