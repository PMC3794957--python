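"""Distance matrices, radius-limited donor clustering, and visit costs.

Pickups at nearby donors are batched: k-means partitions donor locations with
the smallest k whose clusters all fit inside a centroid-radius constraint
(10 km by default).  Visiting any member of a cluster visits all of them, so
a cluster has a single visit cost: twice the mean warehouse distance of its
members (out and back) plus the minimum spanning tree weight of the
intra-cluster distance graph, a lower-bound surrogate for the route driven
between members.  Driving distances are synthesised as straight-line distance
times a circuity factor standing in for road routing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .supply_model import GpdSupplyParams

__all__ = [
    "DonorProfile",
    "Cluster",
    "distance_matrix",
    "haversine_matrix",
    "cluster_donors",
    "mst_length",
    "cluster_cost",
    "exclude_distant",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class DonorProfile:
    """A supplier: category, size, planar location (km), and supply process."""

    id: str
    category: str
    square_feet: float
    location: tuple[float, float]
    warehouse_km: float
    params: GpdSupplyParams

    def __post_init__(self) -> None:
        if self.square_feet <= 0:
            raise ValueError("square_feet must be positive")
        if self.warehouse_km < 0:
            raise ValueError("warehouse_km must be >= 0")


@dataclass(frozen=True)
class Cluster:
    """A batch of nearby donors sharing one visit cost (km per visit)."""

    id: str
    member_ids: frozenset[str]
    cost_km: float

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("cluster must be non-empty")


def distance_matrix(
    locations: Sequence[tuple[float, float]], circuity: float = 1.0
) -> np.ndarray:
    """Pairwise synthetic driving distances for planar (x_km, y_km) points.

    Euclidean distance scaled by ``circuity`` (>= 1), the detour ratio of road
    routes over straight lines.  Symmetric with zero diagonal.
    """
    if len(locations) < 1:
        raise ValueError("need at least one location")
    if circuity < 1.0:
        raise ValueError("circuity must be >= 1")
    pts = np.asarray(locations, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or not np.all(np.isfinite(pts)):
        raise ValueError("locations must be finite (x, y) pairs")
    return cdist(pts, pts) * circuity


def haversine_matrix(
    latlon: Sequence[tuple[float, float]], circuity: float = 1.0
) -> np.ndarray:
    """Great-circle pairwise distances (km) for (lat, lon) degrees, x circuity."""
    if circuity < 1.0:
        raise ValueError("circuity must be >= 1")
    arr = np.radians(np.asarray(latlon, dtype=float))
    if arr.ndim != 2 or arr.shape[1] != 2 or not np.all(np.isfinite(arr)):
        raise ValueError("latlon must be finite (lat, lon) pairs")
    lat, lon = arr[:, 0], arr[:, 1]
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat[:, None]) * np.cos(lat[None, :]) * (
        np.sin(dlon / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1))) * circuity


def _farthest_point_centers(points: np.ndarray, k: int) -> np.ndarray:
    """Deterministic k-center seeding: start nearest the grand centroid, then
    repeatedly add the point farthest from the chosen centers."""
    centroid = points.mean(axis=0)
    first = int(np.argmin(np.linalg.norm(points - centroid, axis=1)))
    chosen = [first]
    dmin = np.linalg.norm(points - points[first], axis=1)
    while len(chosen) < k:
        nxt = int(np.argmax(dmin))
        chosen.append(nxt)
        dmin = np.minimum(dmin, np.linalg.norm(points - points[nxt], axis=1))
    return points[chosen]


def cluster_donors(
    donors: Sequence[DonorProfile], radius_km: float = 10.0
) -> list[Cluster]:
    """Partition donors into the fewest k-means clusters satisfying the radius.

    k is searched incrementally from 1; the first k whose clusters all lie
    within ``radius_km`` of their centroid wins.  Deterministic: k-means is
    seeded with farthest-point centers, no random restarts.  Cluster costs are
    computed afterwards by :func:`cluster_cost`; here ``cost_km`` is filled
    with the Eq.-style visit cost from member geometry.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    if not donors:
        raise ValueError("need at least one donor")
    points = np.array([d.location for d in donors], dtype=float)
    n = len(donors)
    labels = np.zeros(n, dtype=int)
    for k in range(1, n + 1):
        if k == 1:
            centers = points.mean(axis=0, keepdims=True)
            trial = np.zeros(n, dtype=int)
        else:
            km = KMeans(
                n_clusters=k,
                init=_farthest_point_centers(points, k),
                n_init=1,
                random_state=0,
            ).fit(points)
            trial = km.labels_
            centers = km.cluster_centers_
        dists = np.linalg.norm(points - centers[trial], axis=1)
        if np.max(dists) <= radius_km:
            labels = trial
            break
    else:  # pragma: no cover - singletons always satisfy any positive radius
        labels = np.arange(n)

    clusters: list[Cluster] = []
    for lbl in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == lbl)
        members = [donors[i] for i in idx]
        intra = distance_matrix([m.location for m in members], circuity=1.0)
        wkm = np.array([m.warehouse_km for m in members])
        cost = cluster_cost_from_parts(wkm, intra)
        clusters.append(
            Cluster(
                id=f"c{len(clusters)}",
                member_ids=frozenset(m.id for m in members),
                cost_km=cost,
            )
        )
    return clusters


def mst_length(intra_km: np.ndarray) -> float:
    """Minimum-spanning-tree weight of a complete intra-cluster distance graph."""
    intra_km = np.asarray(intra_km, dtype=float)
    if intra_km.shape[0] == 0:
        raise ValueError("members must be non-empty")
    if intra_km.shape[0] == 1:
        return 0.0
    return float(minimum_spanning_tree(intra_km).sum())


def cluster_cost_from_parts(warehouse_km: np.ndarray, intra_km: np.ndarray) -> float:
    """Visit cost: 2 x mean member-to-warehouse distance + intra-cluster MST."""
    return 2.0 * float(np.mean(warehouse_km)) + mst_length(intra_km)


def cluster_cost(
    cluster: Cluster,
    warehouse_km: dict[str, float],
    intra_km: np.ndarray,
) -> float:
    """Visit cost of ``cluster`` given member warehouse distances and the
    intra-member distance matrix (rows/cols in sorted member-id order)."""
    members = sorted(cluster.member_ids)
    wkm = np.array([warehouse_km[m] for m in members])
    return cluster_cost_from_parts(wkm, np.asarray(intra_km))


def exclude_distant(
    donors: Sequence[DonorProfile], max_km: float
) -> list[DonorProfile]:
    """Drop donors farther than ``max_km`` driving distance from the warehouse."""
    if max_km <= 0:
        raise ValueError("max_km must be positive")
    return [d for d in donors if d.warehouse_km <= max_km]
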