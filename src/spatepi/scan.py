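"""Kulldorff's purely spatial scan statistic under the conditional Poisson model.

Candidate zones are circles centred on area centroids, grown one
distance-rank at a time until the zone population exceeds a cap (a fraction
of the total population).  Each zone is scored by the Poisson log-likelihood
ratio

    LLR = O ln(O/E) + (T - O) ln((T - O)/(T - E)),

with O the observed and E the expected count inside the zone and T the total
observed count (indirect standardization guarantees total expected = T).
Zones with O > E are high-rate candidates, O < E low-rate.  Inference
conditions on T: replicates redistribute the T cases multinomially with
probabilities E_i / sum(E), and each cluster's Monte-Carlo p-value is ranked
against the replicate-wide maximum LLR of its direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class Window:
    """A candidate circular zone."""

    center: int
    radius_km: float
    members: tuple  # sorted area indices


@dataclass
class ScanCluster:
    center_area: str
    radius_km: float
    member_areas: list
    observed: int
    expected: float
    relative_risk_inside: float
    llr: float
    direction: str  # "high" | "low"
    p_value: float = np.nan
    rank: int = 0


def enumerate_windows(centroids, populations, max_pop_fraction: float = 0.25) -> list:
    """All circular candidate zones with population <= cap.

    For each center, areas are added in increasing centroid distance
    (distance ties enter together, so members are exactly the areas within
    the zone radius); every prefix whose population respects the cap is a
    zone.  Duplicate member-sets are removed.
    """
    if not (0 < max_pop_fraction <= 0.5):
        raise ValueError("max_pop_fraction must be in (0, 0.5]")
    centroids = np.asarray(centroids, dtype=float)
    populations = np.asarray(populations, dtype=float)
    n = centroids.shape[0]
    cap = max_pop_fraction * populations.sum()
    dist = cdist(centroids, centroids)

    windows: list[Window] = []
    seen: set = set()
    for c in range(n):
        order = np.argsort(dist[c], kind="stable")
        d_sorted = dist[c][order]
        cum_pop = 0.0
        k = 0
        while k < n:
            # absorb the whole tie-group at this radius
            k_end = k + 1
            while k_end < n and d_sorted[k_end] == d_sorted[k]:
                k_end += 1
            cum_pop += populations[order[k:k_end]].sum()
            if cum_pop > cap:
                break
            members = tuple(sorted(int(a) for a in order[:k_end]))
            if members not in seen:
                seen.add(members)
                windows.append(Window(center=c, radius_km=float(d_sorted[k_end - 1]),
                                      members=members))
            k = k_end
    return windows


def poisson_llr(obs_in: float, exp_in: float, obs_total: float) -> tuple:
    """(LLR, direction) of a zone under the conditional Poisson model.

    Terms with O = 0 or T - O = 0 evaluate to 0; LLR >= 0 always, and
    LLR = 0 iff O = E.
    """
    O, E, T = float(obs_in), float(exp_in), float(obs_total)
    if not (0 < E < T):
        raise ValueError("need 0 < exp_in < obs_total")
    if not (0 <= O <= T):
        raise ValueError("obs_in must lie in [0, obs_total]")
    llr = 0.0
    if O > 0:
        llr += O * np.log(O / E)
    if T - O > 0:
        llr += (T - O) * np.log((T - O) / (T - E))
    direction = "high" if O > E else "low"
    return max(float(llr), 0.0), direction


def _llr_vector(obs_in: np.ndarray, exp_in: np.ndarray, T: float) -> np.ndarray:
    """Vectorized LLR over zones (same convention as :func:`poisson_llr`)."""
    O = obs_in.astype(float)
    E = exp_in
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(O > 0, O * np.log(O / E), 0.0)
        rem = T - O
        t2 = np.where(rem > 0, rem * np.log(rem / (T - E)), 0.0)
    return np.maximum(t1 + t2, 0.0)


def _membership(windows: list, n_areas: int) -> np.ndarray:
    Z = np.zeros((len(windows), n_areas), dtype=bool)
    for k, w in enumerate(windows):
        Z[k, list(w.members)] = True
    return Z


def scan(obs, expected, windows: list, directions=("high", "low"),
         area_ids=None, populations=None) -> list:
    """Rank clusters: most-likely per direction, then greedy non-overlapping.

    Secondary clusters are reported in decreasing LLR order, skipping any
    zone that shares a member area with an already-reported cluster.  Ties in
    LLR break toward the smaller zone population, then the lexicographically
    smaller center id.
    """
    obs = np.asarray(obs, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if not np.isclose(obs.sum(), expected.sum(), rtol=1e-6):
        raise ValueError("sum(expected) must equal sum(observed): indirect standardization")
    if not windows:
        return []
    n = obs.size
    T = obs.sum()
    ids = np.asarray(area_ids) if area_ids is not None else np.array([str(i) for i in range(n)])
    pops = np.asarray(populations, dtype=float) if populations is not None else np.ones(n)

    Z = _membership(windows, n)
    obs_in = Z @ obs
    exp_in = Z @ expected
    valid = exp_in > 0
    llr = np.where(valid & (exp_in < T), _llr_vector(obs_in, exp_in, T), 0.0)
    llr[~valid] = -np.inf
    is_high = obs_in > exp_in

    def _emit(k: int, direction: str, rank: int) -> ScanCluster:
        w = windows[k]
        if T - exp_in[k] > 0 and T - obs_in[k] >= 0 and exp_in[k] > 0:
            rr_out = (T - obs_in[k]) / (T - exp_in[k])
            rr = (obs_in[k] / exp_in[k]) / rr_out if rr_out > 0 else np.inf
        else:
            rr = obs_in[k] / exp_in[k]
        return ScanCluster(
            center_area=str(ids[w.center]),
            radius_km=w.radius_km,
            member_areas=[str(ids[m]) for m in w.members],
            observed=int(obs_in[k]),
            expected=float(exp_in[k]),
            relative_risk_inside=float(rr),
            llr=float(llr[k]),
            direction=direction,
            rank=rank,
        )

    clusters: list[ScanCluster] = []
    for direction in directions:
        mask = is_high if direction == "high" else (obs_in < exp_in)
        cand = np.flatnonzero(mask & valid & (llr > 0))
        if cand.size == 0:
            continue
        zone_pop = Z[cand] @ pops
        center_id = ids[[windows[k].center for k in cand]]
        order = sorted(range(cand.size),
                       key=lambda r: (-llr[cand[r]], zone_pop[r], center_id[r]))
        used: set = set()
        rank = 1
        for r in order:
            k = int(cand[r])
            if used & set(windows[k].members):
                continue
            clusters.append(_emit(k, direction, rank))
            used |= set(windows[k].members)
            rank += 1
    if not clusters and np.any(valid):
        # perfectly flat surface (every zone has O == E): report the single
        # best (zero-LLR) zone so callers always see the most-likely window
        k = int(np.flatnonzero(valid)[np.argmax(llr[valid])])
        clusters.append(_emit(k, "high", 1))
    return clusters


def monte_carlo_p(obs_total: float, expected, windows: list, clusters: list,
                  n_reps: int = 999, seed: int = 0) -> list:
    """Attach Monte-Carlo p-values to reported clusters (in place and returned).

    p = (1 + #{replicate max LLR of the cluster's direction >= cluster LLR})
        / (n_reps + 1).
    """
    expected = np.asarray(expected, dtype=float)
    T = int(round(float(obs_total)))
    probs = expected / expected.sum()
    n = expected.size
    Z = _membership(windows, n)
    exp_in = Z @ expected
    valid = (exp_in > 0) & (exp_in < T)

    rng = np.random.default_rng(seed)
    reps = rng.multinomial(T, probs, size=n_reps)  # (n_reps, n)
    obs_in = reps @ Z.T  # (n_reps, n_zones)
    with np.errstate(divide="ignore", invalid="ignore"):
        O = obs_in.astype(float)
        t1 = np.where(O > 0, O * np.log(O / exp_in), 0.0)
        rem = T - O
        t2 = np.where(rem > 0, rem * np.log(rem / (T - exp_in)), 0.0)
        llr_rep = np.maximum(t1 + t2, 0.0)
    llr_rep[:, ~valid] = 0.0
    high = obs_in > exp_in
    max_high = np.max(np.where(high, llr_rep, 0.0), axis=1)
    max_low = np.max(np.where(~high, llr_rep, 0.0), axis=1)

    for cl in clusters:
        ref = max_high if cl.direction == "high" else max_low
        cl.p_value = float((1 + np.sum(ref >= cl.llr)) / (n_reps + 1))
    return clusters


def clusters_to_frame(clusters: list) -> pd.DataFrame:
    rows = []
    for cl in clusters:
        rows.append({
            "rank": cl.rank,
            "direction": cl.direction,
            "center_area": cl.center_area,
            "radius_km": cl.radius_km,
            "members": ";".join(cl.member_areas),
            "observed": cl.observed,
            "expected": cl.expected,
            "relative_risk": cl.relative_risk_inside,
            "llr": cl.llr,
            "p_value": cl.p_value,
        })
    return pd.DataFrame(rows)


def clusters_to_geojson(clusters: list, centroids, area_ids) -> dict:
    """Circle features (centre + radius in km) for reported clusters."""
    id_to_xy = {str(a): (float(x), float(y)) for a, (x, y) in
                zip(area_ids, np.asarray(centroids, float))}
    feats = []
    for cl in clusters:
        x, y = id_to_xy[cl.center_area]
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [x, y]},
            "properties": {
                "rank": cl.rank,
                "direction": cl.direction,
                "radius_km": cl.radius_km,
                "members": cl.member_areas,
                "observed": cl.observed,
                "expected": cl.expected,
                "llr": cl.llr,
                "p_value": cl.p_value,
            },
        })
    return {"type": "FeatureCollection", "features": feats}


class KulldorffScan:
    """Estimator-style wrapper for the full scan analysis.

    ``KulldorffScan(max_pop_fraction=0.25, n_reps=999, seed=0).fit(obs,
    expected, centroids, populations)`` enumerates windows, ranks clusters in
    both directions and attaches Monte-Carlo p-values.  Fitted attributes:
    ``clusters_`` (list of :class:`ScanCluster`), ``windows_``.
    """

    def __init__(self, max_pop_fraction: float = 0.25, n_reps: int = 999,
                 directions=("high", "low"), seed: int = 0):
        self.max_pop_fraction = max_pop_fraction
        self.n_reps = n_reps
        self.directions = directions
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"max_pop_fraction": self.max_pop_fraction, "n_reps": self.n_reps,
                "directions": self.directions, "seed": self.seed}

    def set_params(self, **params) -> "KulldorffScan":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, obs, expected, centroids, populations, area_ids=None) -> "KulldorffScan":
        self.windows_ = enumerate_windows(centroids, populations, self.max_pop_fraction)
        self.clusters_ = scan(obs, expected, self.windows_, directions=self.directions,
                              area_ids=area_ids, populations=populations)
        monte_carlo_p(np.sum(obs), expected, self.windows_, self.clusters_,
                      n_reps=self.n_reps, seed=self.seed)
        return self
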