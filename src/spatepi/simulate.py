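"""Synthetic areal study regions with the statistical structure the chain assumes.

A scenario lays ~82 geographic areas on a jittered grid (default 60-km
spacing, so a 120-km distance band yields a well-connected neighbor graph),
draws log-normal male populations, a physician-density-like covariate, a
spatially structured relative-risk surface

    log(theta_i) = c + beta * x_i + u_i + v_i

with ``u`` an intrinsic-CAR draw on the adjacency graph and ``v`` i.i.d.
normal noise, and finally Poisson case counts ``O_i ~ Poisson(E_i theta_i)``
around the indirectly standardized expectations.  Optional planted circular
clusters multiply theta inside their radius before sampling — the ground
truth for scan-recovery checks.

Default magnitudes emulate the Saskatchewan study setting: 82 areas, a few
thousand men aged >= 35 per area, per-level case totals of the order of the
registry's five-year counts, covariate median near 1 physician per 1000.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .region import RISK_LEVELS, StudyRegion, build_region
from .weights import WeightMatrix, connected_components


@dataclass
class PlantedCluster:
    """A circular excess-risk zone: every area whose centroid lies within
    ``radius_km`` of the centroid of ``center`` has theta multiplied by
    ``risk_multiplier``."""

    center: int
    radius_km: float
    risk_multiplier: float


@dataclass
class SyntheticScenario:
    n_areas: int = 82
    grid_spacing_km: float = 60.0
    jitter_km: float = 10.0
    pop_median: float = 2500.0
    pop_sigma: float = 0.8
    c: float = 0.0
    beta: float = 0.0
    sd_u: float = 0.3
    sd_v: float = 0.1
    covariate_median: float = 1.0
    covariate_sigma: float = 0.4
    covariate_smooth: bool = False
    overall_rate: float = 0.0035  # cases per man >= 35 over the study period
    planted_clusters: Sequence[PlantedCluster] = field(default_factory=tuple)
    seed: int = 0


def _grid_centroids(n: int, spacing: float, jitter: float, rng) -> np.ndarray:
    n_cols = int(np.ceil(np.sqrt(n)))
    rows, cols = np.divmod(np.arange(n), n_cols)
    xy = np.column_stack([cols * spacing, rows * spacing]).astype(float)
    xy += rng.uniform(-jitter, jitter, size=xy.shape)
    return xy


def generate_region(scenario: SyntheticScenario) -> StudyRegion:
    """Geometry, populations and covariate for a scenario (counts all zero).

    Deterministic given ``scenario.seed``: re-running writes a byte-identical
    CSV.  Case counts are filled in by :func:`simulate_cases` (or the
    convenience :func:`generate_dataset`).
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_areas
    xy = _grid_centroids(n, scenario.grid_spacing_km, scenario.jitter_km, rng)
    pop = np.maximum(
        np.round(rng.lognormal(np.log(scenario.pop_median), scenario.pop_sigma, n)), 1
    ).astype(int)
    x = rng.lognormal(np.log(scenario.covariate_median), scenario.covariate_sigma, n)
    if scenario.covariate_smooth:
        # average with neighbors within 1.5 grid spacings for spatial smoothness
        d = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
        k = (d <= 1.5 * scenario.grid_spacing_km).astype(float)
        x = (k @ x) / k.sum(axis=1)
    remoteness = rng.normal(0.3, 0.1, n)
    ids = [f"GA{idx + 1:03d}" for idx in range(n)]
    return build_region(ids, xy, pop, phys_density=x, remoteness=remoteness)


def icar_scale(adjacency: WeightMatrix) -> float:
    """Geometric-mean marginal variance of the unit-precision intrinsic CAR.

    Computed from the graph Laplacian's pseudo-inverse over active (non
    isolated) areas.  Scaling a unit-precision iCAR draw by
    ``sd_u / sqrt(icar_scale)`` gives a field whose typical marginal standard
    deviation is ``sd_u``; equivalently it is an iCAR draw with precision
    ``tau_u = icar_scale / sd_u**2``.
    """
    A = (adjacency.to_dense() > 0).astype(float)
    Q = np.diag(A.sum(axis=1)) - A
    vals, vecs = np.linalg.eigh(Q)
    pos = vals > 1e-9 * max(vals.max(), 1.0)
    marg = (vecs[:, pos] ** 2 / vals[pos]).sum(axis=1)
    active = adjacency.cardinalities > 0
    if not active.any():
        return 1.0
    return float(np.exp(np.mean(np.log(marg[active]))))


def icar_draw(adjacency: WeightMatrix, sd_u: float, rng) -> np.ndarray:
    """Draw a structured field with typical marginal scale ``sd_u``.

    The draw lives on the subspace orthogonal to each connected component's
    constant vector (the centered subspace the sum-to-zero constraint picks
    out): eigen-decompose the graph Laplacian Q = D - A, sample each
    positive-eigenvalue mode with variance ``1 / lambda`` and leave the null
    modes at zero, then rescale so the geometric-mean marginal variance is
    ``sd_u^2`` (the draw is then exactly intrinsic-CAR with precision
    ``icar_scale / sd_u^2``).  Isolated areas get u_i = 0.
    """
    n = adjacency.n
    if sd_u == 0:
        return np.zeros(n)
    A = (adjacency.to_dense() > 0).astype(float)
    Q = np.diag(A.sum(axis=1)) - A
    vals, vecs = np.linalg.eigh(Q)
    pos = vals > 1e-9 * max(vals.max(), 1.0)
    z = rng.standard_normal(int(pos.sum()))
    u = vecs[:, pos] @ (z / np.sqrt(vals[pos]))
    u *= sd_u / np.sqrt(icar_scale(adjacency))
    # exact sum-to-zero per connected component of the active subgraph
    labels = connected_components(adjacency.neighbors)
    active = adjacency.cardinalities > 0
    for comp in np.unique(labels[active]):
        m = active & (labels == comp)
        u[m] -= u[m].mean()
    u[~active] = 0.0
    return u


def simulate_risk_surface(region: StudyRegion, adjacency: WeightMatrix,
                          c: float, beta: float, sd_u: float, sd_v: float,
                          seed: int = 0) -> dict:
    """True relative-risk surface theta_i = exp(c + beta x_i + u_i + v_i).

    Returns a dict with ``theta``, ``u``, ``v`` (the ground truth used by
    recovery tests).
    """
    rng = np.random.default_rng(seed)
    u = icar_draw(adjacency, sd_u, rng)
    v = rng.normal(0.0, sd_v, region.n_areas) if sd_v > 0 else np.zeros(region.n_areas)
    x = region.phys_density
    theta = np.exp(c + beta * x + u + v)
    tau_u = icar_scale(adjacency) / sd_u**2 if sd_u > 0 else np.inf
    tau_v = 1.0 / sd_v**2 if sd_v > 0 else np.inf
    return {"theta": theta, "u": u, "v": v, "tau_u": tau_u, "tau_v": tau_v}


def simulate_cases(region: StudyRegion, theta, overall_rate: float, seed: int = 0,
                   planted_clusters: Sequence[PlantedCluster] = ()) -> np.ndarray:
    """Poisson counts O_i ~ Poisson(E_i * theta_i) with optional planted zones.

    Baseline expectations are ``E_i = overall_rate * n_i``; planted clusters
    multiply theta inside their circles before sampling.
    """
    rng = np.random.default_rng(seed)
    theta = np.asarray(theta, dtype=float).copy()
    xy = region.centroids
    for pc in planted_clusters:
        d = np.linalg.norm(xy - xy[pc.center], axis=1)
        theta[d <= pc.radius_km] *= pc.risk_multiplier
    base_e = overall_rate * region.population.astype(float)
    return rng.poisson(base_e * theta).astype(int)


def generate_dataset(scenario: SyntheticScenario):
    """Full synthetic dataset: region with counts for all four risk levels.

    Every risk level shares the scenario's risk-surface parameters but gets
    an independent surface and counts; level rates are scaled so per-level
    totals are in realistic proportion (high and intermediate levels each
    about 2.5x the metastatic and low levels, echoing registry case mixes).

    Returns ``(region, truth)`` where ``truth[level]`` holds theta/u/v.
    """
    region = generate_region(scenario)
    from .weights import binary_adjacency, build_weights  # local import to avoid cycle
    W = build_weights(region.centroids, standardize=False)
    adj = binary_adjacency(W)
    level_share = {"metastatic": 0.135, "high": 0.365, "intermediate": 0.355, "low": 0.145}
    truth = {}
    ss = np.random.SeedSequence(scenario.seed).spawn(2 * len(RISK_LEVELS))
    for k, lvl in enumerate(RISK_LEVELS):
        surf_seed = int(ss[2 * k].generate_state(1)[0] % (2**31 - 1))
        case_seed = int(ss[2 * k + 1].generate_state(1)[0] % (2**31 - 1))
        surf = simulate_risk_surface(region, adj, scenario.c, scenario.beta,
                                     scenario.sd_u, scenario.sd_v, seed=surf_seed)
        rate = scenario.overall_rate * level_share[lvl] / 0.25
        obs = simulate_cases(region, surf["theta"], rate, seed=case_seed,
                             planted_clusters=scenario.planted_clusters)
        region.counts[lvl] = obs
        truth[lvl] = surf
    return region, truth
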