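"""Synthetic donor regions: rosters, coordinates, and donation logs.

Generates a mixed rural/urban service area around a central warehouse: town
centers scattered over a square extent, donors placed normally around towns,
categories allocated by a fixed mix, store sizes lognormal per category, and
each donor's supply process taken from its category's fitted parameters with
the scale re-tuned through the size-scaling power law so bigger stores waste
more.  The defaults are fixtures producing a region of food-bank-like scale
(order 100-150 retail donors, donations dominated by grocers), not estimates
of any real county.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .spatial_cost import DonorProfile
from .supply_model import (
    DEFAULT_CATEGORY_PARAMS,
    DonationEvent,
    GpdSupplyParams,
    SizeScalingModel,
    donations_from_uniforms,
    gpd_conditional_mean,
    predict_mean_supply,
    rescale_to_mean,
)

__all__ = [
    "RegionConfig",
    "DEFAULT_CATEGORY_MIX",
    "DEFAULT_SIZE_LOG_PARAMS",
    "default_size_scaling",
    "allocate_counts",
    "generate_donors",
    "generate_donation_log",
]

#: Retail mix: grocer-dominated, as in food-bank donation records.
DEFAULT_CATEGORY_MIX: dict[str, float] = {
    "grocers": 0.7,
    "manufacturers": 0.2,
    "bakeries": 0.1,
}

#: log10 square-feet (mean, sd) per category: supermarkets around 30k ft^2,
#: manufacturers around 20k, bakeries small storefronts around 3k.
DEFAULT_SIZE_LOG_PARAMS: dict[str, tuple[float, float]] = {
    "grocers": (4.5, 0.30),
    "manufacturers": (4.3, 0.35),
    "bakeries": (3.5, 0.25),
}

# bakeries have no fitted category of their own; they inherit the pooled
# all-donor supply parameters
_CATEGORY_PARAMS: dict[str, GpdSupplyParams] = {
    "grocers": DEFAULT_CATEGORY_PARAMS["grocers"],
    "manufacturers": DEFAULT_CATEGORY_PARAMS["manufacturers"],
    "bakeries": GpdSupplyParams(
        "bakeries",
        DEFAULT_CATEGORY_PARAMS["all"].threshold,
        DEFAULT_CATEGORY_PARAMS["all"].rate,
        DEFAULT_CATEGORY_PARAMS["all"].scale,
        DEFAULT_CATEGORY_PARAMS["all"].shape,
    ),
}


@dataclass(frozen=True)
class RegionConfig:
    """Knobs for the synthetic region (distances in km, sizes in log10 ft^2)."""

    n_donors: int = 156
    category_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    size_log_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_LOG_PARAMS)
    )
    n_towns: int = 6
    town_sd_km: float = 3.0
    extent_km: float = 60.0
    circuity: float = 1.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")
        total = sum(self.category_mix.values())
        if total <= 0:
            raise ValueError("category mix must have positive total weight")
        if abs(total - 1.0) > 1e-6:
            raise ValueError("category mix fractions must sum to 1")


def default_size_scaling(
    slope: float = 0.8,
    size_log_params: Mapping[str, tuple[float, float]] | None = None,
) -> SizeScalingModel:
    """Power-law size model calibrated so a category-median store has its
    category's fitted conditional mean donation.

    With one shared slope, each category offset is pinned by
    ``offset = log10(category mean) - slope * median log10 size``.
    """
    sizes = dict(size_log_params or DEFAULT_SIZE_LOG_PARAMS)
    offsets = {}
    for cat, (mu, _sd) in sizes.items():
        cat_mean = gpd_conditional_mean(_CATEGORY_PARAMS[cat])
        offsets[cat] = math.log10(cat_mean) - slope * mu
    return SizeScalingModel(
        intercept=0.0, slope=slope, category_offsets=offsets, residual_sd=0.0
    )


def allocate_counts(n: int, mix: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of ``n`` donors to categories.

    Quotas are floored, then leftover units go to the categories with the
    largest fractional remainders (ties broken alphabetically), so the counts
    sum exactly to ``n``.
    """
    cats = sorted(mix)
    quotas = {c: n * mix[c] for c in cats}
    counts = {c: int(math.floor(quotas[c])) for c in cats}
    leftover = n - sum(counts.values())
    by_remainder = sorted(cats, key=lambda c: (-(quotas[c] - counts[c]), c))
    for c in by_remainder[:leftover]:
        counts[c] += 1
    return counts


def generate_donors(config: RegionConfig) -> list[DonorProfile]:
    """Draw a seed-deterministic donor roster around a central warehouse.

    The warehouse sits at the region center; town centers are uniform over
    the extent; each donor picks a town uniformly and scatters normally
    around it.  Warehouse driving distance is straight-line x circuity.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7E9104]))
    counts = allocate_counts(config.n_donors, config.category_mix)
    scaling = default_size_scaling(size_log_params=config.size_log_params)
    warehouse = np.array([config.extent_km / 2.0, config.extent_km / 2.0])
    towns = rng.uniform(0.0, config.extent_km, size=(config.n_towns, 2))

    donors: list[DonorProfile] = []
    idx = 0
    for cat in sorted(counts):
        base = _CATEGORY_PARAMS[cat]
        mu, sd = config.size_log_params[cat]
        for _ in range(counts[cat]):
            town = towns[rng.integers(config.n_towns)]
            loc = town + rng.normal(0.0, config.town_sd_km, size=2)
            sqft = 10.0 ** rng.normal(mu, sd)
            target = predict_mean_supply(sqft, cat, scaling)
            params = rescale_to_mean(base, target)
            donors.append(
                DonorProfile(
                    id=f"d{idx:04d}",
                    category=cat,
                    square_feet=sqft,
                    location=(float(loc[0]), float(loc[1])),
                    warehouse_km=float(
                        np.linalg.norm(loc - warehouse) * config.circuity
                    ),
                    params=params,
                )
            )
            idx += 1
    return donors


def generate_donation_log(
    donors: Sequence[DonorProfile], n_days: int, seed: int
) -> list[DonationEvent]:
    """Per-donor, per-day zero-inflated GPD draws as a flat event log.

    Zero days are omitted; output sorted by (day, donor id).  Suitable as
    input for rate estimation and GPD refitting round trips.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    events: list[DonationEvent] = []
    for d in donors:
        key = np.random.SeedSequence([seed, zlib.crc32(d.id.encode("utf-8"))])
        rng = np.random.default_rng(key)
        u = rng.random((n_days, 2))
        pounds = donations_from_uniforms(u[:, 0], u[:, 1], d.params)
        for day in np.flatnonzero(pounds > 0):
            events.append(DonationEvent(d.id, int(day), float(pounds[day])))
    events.sort(key=lambda e: (e.day, e.donor_id))
    return events
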