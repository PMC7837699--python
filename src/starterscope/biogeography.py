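"""Geographic distances, distance-decay testing, and k-means regioning."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import DistanceMatrix
from .multivariate import MantelResult, mantel

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "GeoCoordinates",
    "RegionClustering",
    "haversine_matrix",
    "distance_decay",
    "kmeans_regions",
]


@dataclass
class GeoCoordinates:
    sample_ids: list
    latitude: np.ndarray
    longitude: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.latitude = np.asarray(self.latitude, dtype=float)
        self.longitude = np.asarray(self.longitude, dtype=float)
        n = len(self.sample_ids)
        if self.latitude.shape != (n,) or self.longitude.shape != (n,):
            raise ValueError("one coordinate pair required per sample")
        if (np.abs(self.latitude) > 90).any():
            bad = [self.sample_ids[i] for i in np.flatnonzero(np.abs(self.latitude) > 90)]
            raise ValueError(f"latitude out of [-90, 90] for: {bad}")
        if (np.abs(self.longitude) > 180).any():
            bad = [self.sample_ids[i] for i in np.flatnonzero(np.abs(self.longitude) > 180)]
            raise ValueError(f"longitude out of [-180, 180] for: {bad}")

    def subset(self, sample_ids) -> "GeoCoordinates":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return GeoCoordinates(list(sample_ids), self.latitude[idx], self.longitude[idx])


@dataclass
class RegionClustering:
    k: int
    labels: np.ndarray
    centroids: np.ndarray  # (k, 2) lat/lon
    inertia: float
    sample_ids: list
    inertia_history: list


def haversine_matrix(coords: GeoCoordinates, radius_km: float = EARTH_RADIUS_KM) -> DistanceMatrix:
    """Great-circle distance matrix (km) via the haversine formula."""
    lat = np.radians(coords.latitude)
    lon = np.radians(coords.longitude)
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2 * radius_km * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(coords.sample_ids, d, "haversine_km")


def distance_decay(
    comm: DistanceMatrix,
    geo: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Test whether community dissimilarity increases with geographic distance.

    A Spearman Mantel test of the community distances against geographic
    distances, one-sided for positive association.
    """
    return mantel(comm, geo, method="spearman", n_perm=n_perm, seed=seed, alternative="greater")


def _lloyd(points: np.ndarray, centers: np.ndarray, max_iter: int = 300):
    k = centers.shape[0]
    history = []
    labels = None
    for _ in range(max_iter):
        d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(len(points)), new_labels].sum())
        history.append(inertia)
        for c in range(k):
            mask = new_labels == c
            if mask.any():
                centers[c] = points[mask].mean(axis=0)
            else:
                # re-seed an empty cluster at the farthest point
                far = int(d2[np.arange(len(points)), new_labels].argmax())
                centers[c] = points[far]
                new_labels[far] = c
        if labels is not None and np.array_equal(labels, new_labels):
            break
        labels = new_labels
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(len(points)), labels].sum())
    history.append(inertia)
    return labels, centers, inertia, history


def kmeans_regions(
    coords: GeoCoordinates,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    project: bool = False,
) -> RegionClustering:
    """Group samples into k geographic regions with Lloyd's algorithm.

    Operates on raw (lat, lon) degrees by default; ``project=True``
    switches to a local equirectangular projection (longitude scaled by
    the cosine of the mean latitude) before clustering. Best of
    ``n_restarts`` random initializations by within-cluster sum of
    squares; deterministic for a given seed.
    """
    points = np.column_stack([coords.latitude, coords.longitude])
    if project:
        points = points.copy()
        points[:, 1] *= np.cos(np.radians(coords.latitude.mean()))
    distinct = np.unique(points, axis=0)
    if k > len(distinct):
        raise ValueError(f"k={k} exceeds number of distinct points ({len(distinct)})")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        init_idx = rng.choice(len(distinct), size=k, replace=False)
        labels, centers, inertia, history = _lloyd(points, distinct[init_idx].copy())
        if best is None or inertia < best[2]:
            best = (labels, centers, inertia, history)
    labels, centers, inertia, history = best
    return RegionClustering(k, labels, centers, inertia, coords.sample_ids, history)
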