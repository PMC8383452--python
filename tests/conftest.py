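"""Shared fixtures: frozen synthetic study regions and their weight matrices.

Three fixed-seed scenarios cover the regimes the chain must handle: a null
region (no spatial structure), a clustered region (strong structured risk
surface at registry-scale counts), and a covariate-effect region (log-linear
physician-density effect beta = -0.07).  Expensive BYM fits are session
scoped so several tests can share one posterior.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spatepi as sp
from spatepi.simulate import (
    SyntheticScenario,
    generate_region,
    simulate_cases,
    simulate_risk_surface,
)
from spatepi.weights import binary_adjacency, build_weights

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# frozen study conditions -------------------------------------------------
NULL_SCENARIO = SyntheticScenario(seed=11, sd_u=0.0, sd_v=0.15, overall_rate=0.0035)
CLUSTERED_SCENARIO = SyntheticScenario(seed=17, sd_u=0.6, sd_v=0.05, overall_rate=0.01)
COVARIATE_SCENARIO = SyntheticScenario(seed=23, sd_u=0.3, sd_v=0.1, beta=-0.07,
                                       overall_rate=0.0035)
# metastatic-scale counts: ~500 cases over 82 areas, so small areas can have
# zero observed cases (the regime where crude SIR minima hit 0)
METASTATIC_SCENARIO = SyntheticScenario(seed=29, sd_u=0.6, sd_v=0.05,
                                        overall_rate=0.0012)


def make_region_and_counts(scenario, surf_seed, case_seed, risk_level="metastatic"):
    region = generate_region(scenario)
    adj = binary_adjacency(build_weights(region.centroids, standardize=False))
    surf = simulate_risk_surface(region, adj, scenario.c, scenario.beta,
                                 scenario.sd_u, scenario.sd_v, seed=surf_seed)
    obs = simulate_cases(region, surf["theta"], scenario.overall_rate, seed=case_seed,
                         planted_clusters=scenario.planted_clusters)
    region.counts[risk_level] = obs
    return region, adj, surf, obs


@pytest.fixture(scope="session")
def null_scenario():
    return NULL_SCENARIO


@pytest.fixture(scope="session")
def null_region():
    return make_region_and_counts(NULL_SCENARIO, surf_seed=111, case_seed=112)


@pytest.fixture(scope="session")
def clustered_region():
    return make_region_and_counts(CLUSTERED_SCENARIO, surf_seed=171, case_seed=172)


@pytest.fixture(scope="session")
def covariate_region():
    return make_region_and_counts(COVARIATE_SCENARIO, surf_seed=231, case_seed=232)


@pytest.fixture(scope="session")
def metastatic_region():
    return make_region_and_counts(METASTATIC_SCENARIO, surf_seed=291, case_seed=292)


@pytest.fixture(scope="session")
def metastatic_fit(metastatic_region):
    """BYM null-model fit at metastatic-scale counts (zero-count areas)."""
    region, adj, _surf, obs = metastatic_region
    exp = sp.expected_counts(region.population, obs)
    model = sp.BYMModel(adjacency=adj, seed=9).fit(obs, exp)
    return region, obs, exp, model


@pytest.fixture(scope="session")
def clustered_fit(clustered_region):
    """BYM null-model fit on the clustered fixture (shared across tests)."""
    region, adj, _surf, obs = clustered_region
    exp = sp.expected_counts(region.population, obs)
    model = sp.BYMModel(adjacency=adj, seed=7).fit(obs, exp)
    return region, obs, exp, model


@pytest.fixture(scope="session")
def null_fit_30():
    """Null-data BYM fit: O_i = round(E_i) on a 30-area region."""
    rng = np.random.default_rng(2)
    xy = np.array([(60.0 * (i % 6) + rng.uniform(-5, 5),
                    60.0 * (i // 6) + rng.uniform(-5, 5)) for i in range(30)])
    pop = rng.integers(1000, 4000, 30)
    obs = np.round(pop * 0.005).astype(int)
    exp = sp.expected_counts(pop, obs)
    adj = binary_adjacency(build_weights(xy, standardize=False))
    return sp.BYMModel(adjacency=adj, seed=3).fit(obs.astype(float), exp)


@pytest.fixture(scope="session")
def small_region():
    """10-area region for brute-force oracle comparisons."""
    rng = np.random.default_rng(5)
    xy = rng.uniform(0, 300, size=(10, 2))
    pop = rng.integers(500, 5000, size=10)
    obs = rng.poisson(pop * 0.004)
    return xy, pop.astype(int), obs.astype(int)
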