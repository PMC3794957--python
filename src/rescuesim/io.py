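"""Tabular interchange: rosters, donation logs, fitted parameters, schedules.

All formats are plain CSV/YAML.  Rosters carry planar coordinates in km
(``x_km, y_km``); donation logs are long-form ``donor_id, day, pounds`` with
0-based integer days; fitted parameter tables mirror the supply-model
columns ``category, threshold, rate, scale, shape, scale_se, shape_se,
mean``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .scheduler import PickupDecision
from .spatial_cost import DonorProfile
from .supply_model import (
    DonationEvent,
    GpdSupplyParams,
    gpd_conditional_mean,
    gpd_quantile,
)

__all__ = [
    "write_roster",
    "read_roster",
    "write_donation_log",
    "read_donation_log",
    "write_params_table",
    "read_params_table",
    "write_schedule",
    "write_day_summary",
    "qq_table",
    "load_config",
]


def write_roster(donors: Sequence[DonorProfile], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [d.id for d in donors],
            "category": [d.category for d in donors],
            "square_feet": [d.square_feet for d in donors],
            "x_km": [d.location[0] for d in donors],
            "y_km": [d.location[1] for d in donors],
            "warehouse_km": [d.warehouse_km for d in donors],
            "rate": [d.params.rate for d in donors],
            "scale": [d.params.scale for d in donors],
            "shape": [d.params.shape for d in donors],
        }
    ).to_csv(path, index=False)


def read_roster(path: str | Path) -> list[DonorProfile]:
    df = pd.read_csv(path, float_precision="round_trip")
    donors = []
    for row in df.itertuples(index=False):
        donors.append(
            DonorProfile(
                id=str(row.id),
                category=row.category,
                square_feet=float(row.square_feet),
                location=(float(row.x_km), float(row.y_km)),
                warehouse_km=float(row.warehouse_km),
                params=GpdSupplyParams(
                    category=row.category,
                    threshold=0.0,
                    rate=float(row.rate),
                    scale=float(row.scale),
                    shape=float(row.shape),
                ),
            )
        )
    return donors


def write_donation_log(events: Sequence[DonationEvent], path: str | Path) -> None:
    pd.DataFrame(
        {
            "donor_id": [e.donor_id for e in events],
            "day": [e.day for e in events],
            "pounds": [e.pounds for e in events],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_donation_log(path: str | Path) -> list[DonationEvent]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        DonationEvent(str(r.donor_id), int(r.day), float(r.pounds))
        for r in df.itertuples(index=False)
    ]


def write_params_table(
    params: Mapping[str, GpdSupplyParams], path: str | Path
) -> None:
    rows = []
    for cat, p in params.items():
        rows.append(
            {
                "category": cat,
                "threshold": p.threshold,
                "rate": p.rate,
                "scale": p.scale,
                "shape": p.shape,
                "scale_se": p.scale_se,
                "shape_se": p.shape_se,
                "mean": gpd_conditional_mean(p) if p.shape < 1 else np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_params_table(path: str | Path) -> dict[str, GpdSupplyParams]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = {}
    for r in df.itertuples(index=False):
        out[str(r.category)] = GpdSupplyParams(
            category=str(r.category),
            threshold=float(r.threshold),
            rate=float(r.rate),
            scale=float(r.scale),
            shape=float(r.shape),
            scale_se=None if pd.isna(r.scale_se) else float(r.scale_se),
            shape_se=None if pd.isna(r.shape_se) else float(r.shape_se),
        )
    return out


def write_schedule(records: Sequence[PickupDecision], path: str | Path) -> None:
    """Long-form pickup schedule: one row per (day, selected cluster)."""
    rows = [
        {"day": r.day, "cluster_id": cid}
        for r in records
        for cid in sorted(r.selected)
    ]
    pd.DataFrame(rows, columns=["day", "cluster_id"]).to_csv(path, index=False)


def write_day_summary(records: Sequence[PickupDecision], path: str | Path) -> None:
    pd.DataFrame(
        {
            "day": [r.day for r in records],
            "demand": [r.demand_lbs for r in records],
            "picked": [r.picked_lbs for r in records],
            "shortage": [r.shortage_lbs for r in records],
            "excess": [r.excess_lbs for r in records],
            "cost_km": [r.cost_km for r in records],
            "warehouse": [r.warehouse_lbs for r in records],
        }
    ).to_csv(path, index=False)


def qq_table(
    positive_samples: Sequence[float], params: GpdSupplyParams
) -> pd.DataFrame:
    """(empirical quantile, model quantile) pairs for QQ diagnostics."""
    x = np.sort(np.asarray(positive_samples, dtype=float))
    n = x.size
    probs = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame(
        {"empirical": x, "model": gpd_quantile(probs, params)}
    )


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
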