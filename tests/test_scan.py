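"""Kulldorff scan: window enumeration, Poisson LLR, ranking and Monte-Carlo p."""

import numpy as np
import pytest

import spatepi as sp
from spatepi.simulate import PlantedCluster, simulate_cases


def independent_llr(obs_in, exp_in, total):
    """Closed-form Poisson LLR written independently of the implementation."""
    val = 0.0
    if obs_in > 0:
        val += obs_in * np.log(obs_in / exp_in)
    if total - obs_in > 0:
        val += (total - obs_in) * np.log((total - obs_in) / (total - exp_in))
    return max(val, 0.0)


def brute_force_zones(xy, pop, frac):
    """All (center, radius) circles respecting the population cap, by exhaustion."""
    xy = np.asarray(xy, float)
    n = len(xy)
    cap = frac * pop.sum()
    zones = set()
    d = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
    for c in range(n):
        for r in np.unique(d[c]):
            members = tuple(sorted(np.flatnonzero(d[c] <= r)))
            if pop[list(members)].sum() <= cap:
                zones.add(members)
    return zones


class TestPoissonLlr:
    def test_spot_values_match_closed_form(self):
        llr, direction = sp.poisson_llr(10, 5, 100)
        assert llr == pytest.approx(10 * np.log(2) + 90 * np.log(90 / 95), abs=1e-3)
        assert direction == "high"
        llr0, d0 = sp.poisson_llr(0, 5, 100)
        assert llr0 == pytest.approx(100 * np.log(100 / 95), abs=1e-3)
        assert llr0 == pytest.approx(5.129, abs=1e-3)
        assert d0 == "low"

    def test_zero_when_observed_equals_expected(self):
        llr, _ = sp.poisson_llr(5, 5.0, 100)
        assert llr == 0.0

    def test_monotone_in_excess(self):
        vals = [sp.poisson_llr(o, 5.0, 100)[0] for o in range(6, 30)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_precondition_errors(self):
        with pytest.raises(ValueError):
            sp.poisson_llr(5, 0.0, 100)
        with pytest.raises(ValueError):
            sp.poisson_llr(5, 100.0, 100)


class TestEnumerateWindows:
    def test_collinear_equal_pop_singletons_only(self):
        xy = [[0, 0], [100, 0], [200, 0]]
        pop = np.array([100, 100, 100])
        wins = sp.enumerate_windows(xy, pop, 0.34)
        assert sorted(w.members for w in wins) == [(0,), (1,), (2,)]

    def test_pairs_enter_with_unequal_populations(self):
        # centre area is small: its pair with a neighbor respects the cap
        xy = [[0, 0], [100, 0], [200, 0]]
        pop = np.array([50, 50, 400])
        wins = sp.enumerate_windows(xy, pop, 0.25)
        members = sorted(w.members for w in wins)
        assert (0, 1) in members and (0,) in members and (1,) in members
        assert all(pop[list(m)].sum() <= 0.25 * 500 for m in members)

    def test_invalid_fraction(self):
        for bad in (0.0, 0.51, -0.1, 1.0):
            with pytest.raises(ValueError):
                sp.enumerate_windows([[0, 0], [1, 1]], np.array([1, 1]), bad)

    def test_matches_brute_force_enumeration(self, small_region):
        xy, pop, _ = small_region
        wins = sp.enumerate_windows(xy, pop, 0.25)
        got = {w.members for w in wins}
        assert got == brute_force_zones(xy, pop, 0.25)

    def test_members_are_exactly_areas_within_radius(self, small_region):
        xy, pop, _ = small_region
        for w in sp.enumerate_windows(xy, pop, 0.3):
            d = np.sqrt(((xy - xy[w.center]) ** 2).sum(-1))
            assert set(w.members) == set(np.flatnonzero(d <= w.radius_km))


class TestScan:
    def test_most_likely_matches_exhaustive_search(self, small_region):
        xy, pop, obs = small_region
        if obs.sum() == 0:
            pytest.skip("degenerate draw")
        exp = sp.expected_counts(pop, obs)
        wins = sp.enumerate_windows(xy, pop, 0.4)
        clusters = sp.scan(obs, exp, wins, populations=pop)
        top_high = [c for c in clusters if c.direction == "high" and c.rank == 1][0]
        # exhaustive search scored with the independent LLR
        best = max(
            (independent_llr(obs[list(m)].sum(), exp[list(m)].sum(), obs.sum())
             for m in (w.members for w in wins)
             if 0 < exp[list(m)].sum() < obs.sum()
             and obs[list(m)].sum() > exp[list(m)].sum()),
        )
        assert top_high.llr == pytest.approx(best, abs=1e-10)

    def test_llr_invariant_to_outside_relabeling(self, small_region):
        xy, pop, obs = small_region
        exp = sp.expected_counts(pop, obs)
        wins = sp.enumerate_windows(xy, pop, 0.25)
        base = sp.scan(obs, exp, wins, populations=pop)
        # permute observed counts among areas outside the top cluster
        top = base[0]
        inside = {int(m) for m in top.member_areas}
        outside = [i for i in range(len(obs)) if i not in inside]
        obs2 = obs.copy()
        obs2[outside] = obs[list(np.roll(outside, 1))]
        exp2 = sp.expected_counts(pop, obs2)
        # expected depends only on totals, unchanged by the permutation
        np.testing.assert_allclose(exp2, exp)
        again = sp.scan(obs2, exp2, wins, populations=pop)
        match = [c for c in again if set(c.member_areas) == set(top.member_areas)]
        assert match and match[0].llr == pytest.approx(top.llr)

    def test_secondary_clusters_do_not_overlap(self, clustered_region):
        region, _adj, _surf, obs = clustered_region
        exp = sp.expected_counts(region.population, obs)
        wins = sp.enumerate_windows(region.centroids, region.population, 0.25)
        clusters = sp.scan(obs, exp, wins, populations=region.population,
                           area_ids=region.area_ids)
        for direction in ("high", "low"):
            seen = set()
            for c in [c for c in clusters if c.direction == direction]:
                assert not (seen & set(c.member_areas))
                seen |= set(c.member_areas)

    def test_single_zone_region_returned(self):
        # a hand-built whole-region window (O == E == T): still reported
        from spatepi.scan import Window
        wins = [Window(center=0, radius_km=0.0, members=(0,))]
        clusters = sp.scan(np.array([7]), np.array([7.0]), wins)
        assert len(clusters) == 1 and clusters[0].llr == 0.0

    def test_planted_cluster_recovered(self, clustered_region):
        """A 2.5x planted circle is mostly inside the top high cluster."""
        region, _adj, _surf, _obs = clustered_region
        pc = PlantedCluster(center=30, radius_km=100, risk_multiplier=2.5)
        wins = sp.enumerate_windows(region.centroids, region.population, 0.25)
        d = np.linalg.norm(region.centroids - region.centroids[30], axis=1)
        planted = set(np.flatnonzero(d <= 100))
        theta = np.ones(region.n_areas)
        hits = 0
        for s in range(10):
            obs = simulate_cases(region, theta, 0.0035, seed=800 + s,
                                 planted_clusters=[pc])
            exp = sp.expected_counts(region.population, obs)
            cl = sp.scan(obs, exp, wins, directions=("high",),
                         populations=region.population)
            top = [c for c in cl if c.rank == 1][0]
            got = {int(m) for m in top.member_areas}
            hits += len(got & planted) >= len(planted) / 2
        assert hits >= 9


class TestMonteCarloP:
    def test_minimum_p_with_few_replicates(self, small_region):
        xy, pop, obs = small_region
        obs = obs + 1  # ensure nonzero totals
        exp = sp.expected_counts(pop, obs)
        wins = sp.enumerate_windows(xy, pop, 0.4)
        clusters = sp.scan(obs, exp, wins, populations=pop)
        # force an untouchable llr so every replicate max is below it
        clusters[0].llr = 1e6
        sp.monte_carlo_p(obs.sum(), exp, wins, clusters[:1], n_reps=9, seed=0)
        assert clusters[0].p_value == pytest.approx(0.1)

    def test_planted_cluster_attains_floor_p(self, clustered_region):
        region, _adj, _surf, _obs = clustered_region
        pc = PlantedCluster(center=30, radius_km=100, risk_multiplier=2.5)
        wins = sp.enumerate_windows(region.centroids, region.population, 0.25)
        theta = np.ones(region.n_areas)
        floor_hits = 0
        for s in range(5):
            obs = simulate_cases(region, theta, 0.0035, seed=900 + s,
                                 planted_clusters=[pc])
            exp = sp.expected_counts(region.population, obs)
            cl = sp.scan(obs, exp, wins, directions=("high",),
                         populations=region.population)
            top = [c for c in cl if c.rank == 1]
            sp.monte_carlo_p(obs.sum(), exp, wins, top, n_reps=199, seed=950 + s)
            floor_hits += top[0].p_value == pytest.approx(1 / 200)
        assert floor_hits >= 4

    def test_estimator_wrapper(self, small_region):
        xy, pop, obs = small_region
        obs = obs + 1
        exp = sp.expected_counts(pop, obs)
        ks = sp.KulldorffScan(max_pop_fraction=0.4, n_reps=99, seed=1)
        ks.fit(obs, exp, xy, pop)
        assert ks.clusters_ and all(np.isfinite(c.p_value) for c in ks.clusters_)
        assert ks.get_params()["n_reps"] == 99
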