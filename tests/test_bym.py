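"""BYM model: posterior density, sampler correctness, smoothing and IRR."""

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm, poisson

import spatepi as sp
from spatepi.bym import BYMModelSpec, MCMCConfig, gamma_full_conditionals
from spatepi.weights import WeightMatrix, binary_adjacency, build_weights


def single_area_adjacency():
    return WeightMatrix(neighbors=(np.array([], int),), weights=(np.array([]),),
                        scheme="binary")


def chain_adjacency(n):
    """Path graph 0-1-2-...-(n-1) as binary adjacency."""
    nbs = []
    for i in range(n):
        nb = [j for j in (i - 1, i + 1) if 0 <= j < n]
        nbs.append(np.array(nb, int))
    return WeightMatrix(neighbors=tuple(nbs),
                        weights=tuple(np.ones(len(nb)) for nb in nbs),
                        scheme="binary")


class TestLogPosterior:
    def test_zero_u_contributes_no_pairwise_penalty(self):
        adj = chain_adjacency(4)
        spec = BYMModelSpec(adjacency=adj)
        obs = np.array([2.0, 3, 1, 4])
        exp = np.full(4, 2.5)
        base = dict(c=0.1, u=np.zeros(4), v=np.zeros(4), tau_u=3.0, tau_v=2.0)
        other = dict(base, tau_u=30.0)
        # with u = 0 the only tau_u dependence left is prior + rank term
        rank = 3
        a, b = 0.5, 0.0005
        delta = (0.5 * rank * np.log(30 / 3)
                 + (a - 1) * np.log(30 / 3) - b * (30 - 3))
        got = sp.log_posterior(other, spec, obs, exp) - sp.log_posterior(base, spec, obs, exp)
        assert got == pytest.approx(delta, abs=1e-10)

    def test_tau_linearity_of_pairwise_penalty(self):
        adj = chain_adjacency(3)
        spec = BYMModelSpec(adjacency=adj)
        obs = np.array([1.0, 2, 3])
        exp = np.ones(3)
        u = np.array([0.2, -0.1, -0.1])
        ssq = (0.3) ** 2 + 0.0
        s1 = dict(c=0.0, u=u, v=np.zeros(3), tau_u=1.0, tau_v=1.0)
        s2 = dict(s1, tau_u=2.0)
        s1z = dict(s1, u=np.zeros(3))
        s2z = dict(s2, u=np.zeros(3))
        pen1 = (sp.log_posterior(s1, spec, obs, exp) - sp.log_posterior(s1z, spec, obs, exp))
        pen2 = (sp.log_posterior(s2, spec, obs, exp) - sp.log_posterior(s2z, spec, obs, exp))
        # likelihood change from u is identical; prior penalty doubles with tau
        lik = float(np.sum(obs * u - exp * (np.exp(u) - 1)))
        assert pen1 - lik == pytest.approx(-0.5 * 1.0 * ssq, abs=1e-10)
        assert pen2 - lik == pytest.approx(-0.5 * 2.0 * ssq, abs=1e-10)

    def test_single_area_matches_hand_density(self):
        """No neighbors: the model is Poisson-lognormal; compare to a density
        written with scipy building blocks."""
        spec = BYMModelSpec(adjacency=single_area_adjacency())
        obs, exp = np.array([4.0]), np.array([2.0])
        state = dict(c=0.3, u=np.zeros(1), v=np.array([0.2]), tau_u=5.0, tau_v=1.5)
        lam = exp[0] * np.exp(state["c"] + state["v"][0])
        hand = (poisson.logpmf(4, lam)
                + norm.logpdf(state["v"][0], 0, 1 / np.sqrt(1.5))
                + gamma_dist.logpdf(5.0, 0.5, scale=1 / 0.0005)
                + gamma_dist.logpdf(1.5, 0.5, scale=1 / 0.0005))
        assert sp.log_posterior(state, spec, obs, exp) == pytest.approx(hand, abs=1e-9)

    def test_non_finite_state_errors(self):
        spec = BYMModelSpec(adjacency=chain_adjacency(2))
        with pytest.raises(ValueError, match="non-finite"):
            sp.log_posterior(dict(c=np.nan, u=np.zeros(2), v=np.zeros(2),
                                  tau_u=1.0, tau_v=1.0), spec,
                             np.array([1.0, 1]), np.array([1.0, 1]))


class TestConjugateUpdates:
    def test_gamma_full_conditionals_match_hand_derivation(self):
        # path 0-1-2 plus an isolated area 3: rank = 3 active - 1 component = 2
        nbs = (np.array([1]), np.array([0, 2]), np.array([1]), np.array([], int))
        adj = WeightMatrix(neighbors=nbs,
                           weights=tuple(np.ones(len(nb)) for nb in nbs),
                           scheme="binary")
        spec = BYMModelSpec(adjacency=adj)
        u = np.array([0.5, -0.2, -0.3, 0.0])
        v = np.array([0.1, 0.0, -0.1, 0.2])
        fc = gamma_full_conditionals(spec, u, v)
        ssq_pair = (0.5 - -0.2) ** 2 + (-0.2 - -0.3) ** 2
        assert fc["tau_u"] == pytest.approx((0.5 + 1.0, 0.0005 + ssq_pair / 2))
        assert fc["tau_v"] == pytest.approx((0.5 + 2.0, 0.0005 + float(v @ v) / 2))


class TestSampler:
    def test_null_data_smoothed_sirs_near_one(self, null_fit_30):
        smoothed = null_fit_30.smoothed_sir_
        assert np.all(smoothed > 0.8) and np.all(smoothed < 1.2)

    def test_sum_to_zero_in_every_retained_draw(self, null_fit_30):
        u = null_fit_30.posterior_.u
        np.testing.assert_allclose(u.sum(axis=2), 0.0, atol=1e-8)

    def test_positive_precisions(self, null_fit_30):
        po = null_fit_30.posterior_
        assert np.all(po.tau_u > 0) and np.all(po.tau_v > 0)

    def test_seed_contract(self, clustered_fit):
        """Different seeds: different draws, same summaries within MC error."""
        region, obs, exp, model = clustered_fit
        other = sp.BYMModel(adjacency=model.adjacency, seed=8).fit(obs, exp)
        assert not np.allclose(other.posterior_.c, model.posterior_.c)
        np.testing.assert_allclose(other.smoothed_sir_, model.smoothed_sir_,
                                   rtol=0.05, atol=0.03)
        same = sp.BYMModel(adjacency=model.adjacency, seed=7).fit(obs, exp)
        np.testing.assert_allclose(same.posterior_.c, model.posterior_.c)

    def test_shrinkage_on_clustered_fixture(self, clustered_fit):
        """Smoothed SIR range strictly inside the crude range (crude min 0
        becomes a positive smoothed minimum)."""
        region, obs, exp, model = clustered_fit
        crude = sp.crude_sir(obs, exp)
        smoothed = model.smoothed_sir_
        assert smoothed.min() > crude.min() or crude.min() > 0
        assert smoothed.max() < crude.max()
        assert smoothed.min() > 0

    def test_empty_adjacency_reduces_to_poisson_lognormal(self):
        """With no neighbors anywhere the model is exchangeable; posterior
        means must agree with an independent random-walk sampler of the
        reduced model written here from scratch."""
        rng = np.random.default_rng(9)
        n = 12
        pop = rng.integers(2000, 6000, n)
        theta_true = np.exp(rng.normal(0, 0.25, n))
        obs = rng.poisson(pop * 0.004 * theta_true).astype(float)
        exp = sp.expected_counts(pop, obs)
        nbs = tuple(np.array([], int) for _ in range(n))
        adj = WeightMatrix(neighbors=nbs, weights=tuple(np.array([]) for _ in range(n)),
                           scheme="binary")
        model = sp.BYMModel(adjacency=adj, n_iterations=40_000, burn_in=10_000,
                            seed=4).fit(obs, exp)

        # --- independent reduced-model sampler (plain numpy, no reuse) ---
        def reduced_logpost(c, v, tau):
            lam = exp * np.exp(c + v)
            ll = np.sum(obs * np.log(lam) - lam - gammaln(obs + 1))
            lp = np.sum(norm.logpdf(v, 0, 1 / np.sqrt(tau)))
            lp += gamma_dist.logpdf(tau, 0.5, scale=1 / 0.0005)
            return ll + lp

        rng2 = np.random.default_rng(77)
        c, v, tau = 0.0, np.zeros(n), 10.0
        keep_theta = []
        cur = reduced_logpost(c, v, tau)
        for it in range(60_000):
            c_p = c + 0.05 * rng2.standard_normal()
            cand = reduced_logpost(c_p, v, tau)
            if np.log(rng2.random()) < cand - cur:
                c, cur = c_p, cand
            v_p = v.copy()
            i = it % n
            v_p[i] += 0.3 * rng2.standard_normal()
            cand = reduced_logpost(c, v_p, tau)
            if np.log(rng2.random()) < cand - cur:
                v, cur = v_p, cand
            tau = rng2.gamma(0.5 + n / 2, 1.0 / (0.0005 + 0.5 * v @ v))
            cur = reduced_logpost(c, v, tau)
            if it > 20_000 and it % 10 == 0:
                keep_theta.append(np.exp(c + v))
        ref = np.mean(keep_theta, axis=0)
        np.testing.assert_allclose(model.smoothed_sir_, ref, rtol=0.06, atol=0.04)

    def test_prior_sanity_zero_counts(self):
        """All O = 0 with tiny E: posterior is prior-driven but proper."""
        adj = chain_adjacency(6)
        obs = np.zeros(6)
        exp = np.full(6, 0.01)
        model = sp.BYMModel(adjacency=adj, n_iterations=6000, burn_in=2000,
                            thin=4, seed=5).fit(obs, exp)
        assert np.all(np.isfinite(model.smoothed_sir_))
        assert np.all(np.isfinite(model.smoothed_sir_cri_))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_chains=1)
        with pytest.raises(ValueError):
            MCMCConfig(burn_in=50_000, n_iterations=30_000)
        with pytest.raises(ValueError):
            MCMCConfig(thin=0)
        with pytest.raises(ValueError):
            BYMModelSpec(adjacency=build_weights([[0, 0], [50, 0]]))  # not binary


class TestIrrAndPercentChange:
    def test_percent_change_values(self):
        assert round(sp.percent_change(-0.067), 1) == 6.5
        assert round(sp.percent_change(-0.076), 1) == 7.3
        assert sp.percent_change(0.0) == 0.0

    def test_irr_from_posterior_mean(self, covariate_region):
        region, adj, _surf, obs = covariate_region
        exp = sp.expected_counts(region.population, obs)
        model = sp.BYMModel(adjacency=adj, covariate=region.phys_density,
                            seed=6).fit(obs, exp)
        s = sp.irr_summary(model.posterior_)
        assert s["irr"] == pytest.approx(np.exp(s["beta_mean"]), rel=1e-12)
        assert s["irr_cri"][0] < s["irr"] < s["irr_cri"][1]
        assert s["significant"] == (not (s["irr_cri"][0] <= 1 <= s["irr_cri"][1]))

    def test_null_posterior_has_no_beta(self, null_fit_30):
        with pytest.raises(ValueError):
            sp.irr_summary(null_fit_30.posterior_)
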