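"""Spatial neighborhood structures for areal statistics.

Two weighting schemes are used downstream: inverse-distance weights within a
fixed distance band (Moran statistics) and binary adjacency on the same band
(the CAR prior of the BYM model).  Neighborhoods are defined on planar
centroid coordinates in km: ``j`` is a neighbor of ``i`` iff
``0 < d(i, j) <= radius_km`` (inclusive at the band radius, 120 km by
default).  The relation is symmetric and isolated areas are permitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

DEFAULT_RADIUS_KM = 120.0


@dataclass(frozen=True)
class WeightMatrix:
    """Neighbor lists with aligned positive weights.

    Attributes
    ----------
    neighbors:
        tuple of int arrays; ``neighbors[i]`` lists the neighbor indices of
        area ``i`` (no self-neighbors; symmetric as a relation).
    weights:
        tuple of float arrays aligned with ``neighbors``.
    scheme:
        ``"inverse_distance"`` or ``"binary"``.
    row_standardized:
        True if each nonempty row has been scaled to sum to 1.
    """

    neighbors: tuple
    weights: tuple
    scheme: str
    row_standardized: bool = False

    def __post_init__(self) -> None:
        for i, (nb, wt) in enumerate(zip(self.neighbors, self.weights)):
            if len(nb) != len(wt):
                raise ValueError(f"row {i}: neighbors and weights misaligned")
            if np.any(np.asarray(nb) == i):
                raise ValueError(f"row {i}: self-neighbor")
            if len(wt) and np.any(np.asarray(wt) <= 0):
                raise ValueError(f"row {i}: non-positive weight")

    @property
    def n(self) -> int:
        return len(self.neighbors)

    @property
    def s0(self) -> float:
        """Sum of all weights (the S0 normalizer of Moran's I)."""
        return float(sum(np.sum(w) for w in self.weights))

    @property
    def cardinalities(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors], dtype=int)

    def isolated(self) -> np.ndarray:
        """Boolean mask of areas with no neighbors."""
        return self.cardinalities == 0

    def to_sparse(self) -> sparse.csr_matrix:
        rows = np.repeat(np.arange(self.n), self.cardinalities)
        cols = np.concatenate([np.asarray(nb, dtype=int) for nb in self.neighbors]) if self.n else np.array([], int)
        data = np.concatenate([np.asarray(w, dtype=float) for w in self.weights]) if self.n else np.array([], float)
        return sparse.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def to_dense(self) -> np.ndarray:
        return self.to_sparse().toarray()

    def pairs(self) -> np.ndarray:
        """(m, 2) array of unique undirected neighbor pairs (i < j)."""
        out = []
        for i, nb in enumerate(self.neighbors):
            for j in nb:
                if i < j:
                    out.append((i, j))
        return np.array(out, dtype=int).reshape(-1, 2)

    def export_adjacency_list(self, path: str | Path, area_ids: Sequence[str]) -> None:
        """Write one 'area_id neighbor_id weight' line per directed edge."""
        with open(path, "w") as fh:
            for i, (nb, wt) in enumerate(zip(self.neighbors, self.weights)):
                for j, w in zip(nb, wt):
                    fh.write(f"{area_ids[i]},{area_ids[int(j)]},{w:.10g}\n")


def _check_duplicates(dist: np.ndarray) -> None:
    dup = np.argwhere((dist == 0) & ~np.eye(dist.shape[0], dtype=bool))
    if dup.size:
        i, j = dup[0]
        raise ValueError(f"duplicate centroids: areas {i} and {j} coincide")


def distance_band_neighbors(centroids, radius_km: float = DEFAULT_RADIUS_KM) -> tuple:
    """Neighbor lists under the inclusive distance band ``0 < d <= radius_km``."""
    centroids = np.asarray(centroids, dtype=float)
    if centroids.ndim != 2 or centroids.shape[0] < 2:
        raise ValueError("need >= 2 areas with planar (x, y) centroids")
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    dist = cdist(centroids, centroids)
    _check_duplicates(dist)
    within = (dist > 0) & (dist <= radius_km)
    return tuple(np.flatnonzero(within[i]) for i in range(centroids.shape[0]))


def inverse_distance_weights(neighbors, centroids) -> WeightMatrix:
    """Weights ``w_ij = 1 / d(i, j)`` on an existing neighbor relation."""
    centroids = np.asarray(centroids, dtype=float)
    dist = cdist(centroids, centroids)
    _check_duplicates(dist)
    weights = tuple(1.0 / dist[i, np.asarray(nb, dtype=int)] if len(nb) else np.array([], float)
                    for i, nb in enumerate(neighbors))
    return WeightMatrix(neighbors=tuple(np.asarray(nb, int) for nb in neighbors),
                        weights=weights, scheme="inverse_distance")


def row_standardize(W: WeightMatrix) -> WeightMatrix:
    """Scale each nonempty row to sum to 1 (idempotent; empty rows unchanged)."""
    new = []
    for wt in W.weights:
        s = np.sum(wt)
        new.append(wt / s if s > 0 else wt)
    return replace(W, weights=tuple(new), row_standardized=True)


def binary_adjacency(W: WeightMatrix) -> WeightMatrix:
    """Same neighbor relation with all weights 1 (CAR-prior adjacency)."""
    ones = tuple(np.ones(len(nb)) for nb in W.neighbors)
    return replace(W, weights=ones, scheme="binary", row_standardized=False)


def build_weights(centroids, radius_km: float = DEFAULT_RADIUS_KM,
                  standardize: bool = True) -> WeightMatrix:
    """Distance-band inverse-distance weights, row-standardized by default."""
    nb = distance_band_neighbors(centroids, radius_km)
    W = inverse_distance_weights(nb, centroids)
    return row_standardize(W) if standardize else W


def nearest_centre(centroids, centre_a, centre_b) -> np.ndarray:
    """Label each area 'A' or 'B' by the closer assessment centre.

    Exact ties go to centre A with a logged warning.
    """
    centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
    a = np.asarray(centre_a, dtype=float)
    b = np.asarray(centre_b, dtype=float)
    da = np.linalg.norm(centroids - a, axis=1)
    db = np.linalg.norm(centroids - b, axis=1)
    ties = np.flatnonzero(da == db)
    if ties.size:
        logger.warning("areas %s equidistant from both centres; assigned to A", ties.tolist())
    return np.where(da <= db, "A", "B")


def connected_components(neighbors) -> np.ndarray:
    """Component label per area of the neighbor graph (0-based)."""
    n = len(neighbors)
    labels = np.full(n, -1, dtype=int)
    comp = 0
    for start in range(n):
        if labels[start] != -1:
            continue
        stack = [start]
        labels[start] = comp
        while stack:
            i = stack.pop()
            for j in neighbors[i]:
                j = int(j)
                if labels[j] == -1:
                    labels[j] = comp
                    stack.append(j)
        comp += 1
    return labels
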