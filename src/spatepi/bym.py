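"""Bayesian BYM (Besag-York-Mollié) disease mapping with ecological covariates.

The observed count in area *i* is modeled as Poisson with mean
``E_i * theta_i`` and

    log(theta_i) = c + beta * x_i + u_i + v_i,

where ``u`` is a spatially structured intrinsic-CAR effect on the binary
adjacency graph, ``v`` an exchangeable normal effect, ``c`` the intercept
(flat prior over the real line) and ``beta`` the optional log-linear
coefficient of an ecological covariate (flat prior).  Both random-effect
precisions get Gamma(shape, rate) hyper-priors, (0.5, 0.0005) by default.
The intrinsic CAR is made identifiable by a sum-to-zero constraint on ``u``;
isolated areas have ``u_i`` fixed at 0 and do not enter the pairwise term or
its rank.

The posterior mean of ``theta_i`` is the *smoothed SIR*: the crude SIR
shrunk toward its neighborhood and the regional level.  With a covariate,
``exp(posterior mean of beta)`` is the incidence rate ratio (IRR) per unit
covariate, significant when its 95% credible interval excludes 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._bym_kernels import run_chain
from .weights import WeightMatrix, connected_components

logger = logging.getLogger(__name__)


@dataclass
class BYMModelSpec:
    """Model structure: adjacency, optional covariate, precision hyper-priors."""

    adjacency: WeightMatrix
    covariate: Optional[np.ndarray] = None
    hyper_shape: float = 0.5
    hyper_rate: float = 0.0005
    standardize_covariate: bool = False

    def __post_init__(self):
        if self.adjacency.scheme != "binary":
            raise ValueError("BYM adjacency must be a binary weight matrix")
        if self.covariate is not None:
            self.covariate = np.asarray(self.covariate, dtype=float)
            if self.covariate.size != self.adjacency.n:
                raise ValueError("covariate length must match the number of areas")


@dataclass
class MCMCConfig:
    """Desk-scale default schedule: 3 chains x 30,000 iterations, burn-in
    10,000, thin 10 (2,000 retained draws per chain)."""

    n_iterations: int = 30_000
    burn_in: int = 10_000
    thin: int = 10
    n_chains: int = 3
    seed: int = 0
    step_u: float = 0.5
    step_v: float = 0.5
    step_c: float = 0.1
    step_beta: float = 0.1

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for the scale-reduction diagnostic")
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("burn_in must lie in [0, n_iterations)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class BYMPosterior:
    """Retained MCMC draws, stacked per chain."""

    c: np.ndarray        # (n_chains, n_keep)
    beta: Optional[np.ndarray]
    tau_u: np.ndarray
    tau_v: np.ndarray
    u: np.ndarray        # (n_chains, n_keep, n)
    v: np.ndarray
    covariate: Optional[np.ndarray]
    acceptance: np.ndarray  # (n_chains, 4) post-burn-in rates [u, v, c, beta]
    config: MCMCConfig = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def n_chains(self) -> int:
        return self.c.shape[0]

    @property
    def n_areas(self) -> int:
        return self.u.shape[2]

    def theta(self) -> np.ndarray:
        """Per-draw relative risks, shape (n_chains, n_keep, n)."""
        eta = self.c[..., None] + self.u + self.v
        if self.beta is not None:
            eta = eta + self.beta[..., None] * self.covariate[None, None, :]
        return np.exp(eta)

    def stacked(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        if arr is None:
            raise ValueError(f"parameter '{name}' not present in this model")
        return arr.reshape(-1, *arr.shape[2:])

    def scalar_chains(self) -> dict:
        """Chains of the monitored scalar parameters (for diagnostics)."""
        out = {"c": self.c, "tau_u": self.tau_u, "tau_v": self.tau_v}
        if self.beta is not None:
            out["beta"] = self.beta
        return out


def _active_structure(adjacency: WeightMatrix):
    W = adjacency
    card = W.cardinalities
    active = card > 0
    # rank of the iCAR precision: active areas minus connected components
    # among active areas (isolated areas are excluded entirely)
    if active.any():
        labels = connected_components(W.neighbors)
        n_comp_active = len(np.unique(labels[active]))
        rank = int(active.sum() - n_comp_active)
    else:
        rank = 0
    sp = W.to_sparse()
    return active, rank, sp.indptr.astype(np.int64), sp.indices.astype(np.int64)


def log_posterior(state: dict, spec: BYMModelSpec, obs, expected) -> float:
    """Unnormalized log posterior density at a given state.

    ``state`` holds ``c``, ``u``, ``v``, ``tau_u``, ``tau_v`` and optionally
    ``beta``.  The iCAR factor is the pairwise-difference form with the
    rank/2 power of tau_u; c and beta carry flat priors.
    """
    obs = np.asarray(obs, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive for all modeled areas")
    c = float(state["c"])
    u = np.asarray(state["u"], dtype=float)
    v = np.asarray(state["v"], dtype=float)
    tau_u = float(state["tau_u"])
    tau_v = float(state["tau_v"])
    beta = float(state.get("beta", 0.0))
    if not np.all(np.isfinite(u)) or not np.all(np.isfinite(v)) or not np.isfinite(c):
        raise ValueError("non-finite state")
    if tau_u <= 0 or tau_v <= 0:
        return -np.inf

    x = spec.covariate if spec.covariate is not None else np.zeros_like(u)
    eta = c + beta * x + u + v
    lam = expected * np.exp(eta)
    lp = float(np.sum(obs * np.log(lam) - lam - gammaln(obs + 1)))

    active, rank, indptr, indices = _active_structure(spec.adjacency)
    pairs = spec.adjacency.pairs()
    ssq_pair = float(np.sum((u[pairs[:, 0]] - u[pairs[:, 1]]) ** 2)) if len(pairs) else 0.0
    lp += 0.5 * rank * np.log(tau_u) - 0.5 * tau_u * ssq_pair

    n = u.size
    lp += 0.5 * n * np.log(tau_v / (2 * np.pi)) - 0.5 * tau_v * float(v @ v)

    a, b = spec.hyper_shape, spec.hyper_rate
    for tau in (tau_u, tau_v):
        lp += a * np.log(b) - gammaln(a) + (a - 1) * np.log(tau) - b * tau
    return lp


def gamma_full_conditionals(spec: BYMModelSpec, u, v) -> dict:
    """Parameters of the conjugate Gamma full conditionals at a given state.

    tau_u ~ Gamma(shape = a + rank/2, rate = b + pairwise-SSQ(u)/2) with rank
    the active-area count minus the number of connected components;
    tau_v ~ Gamma(shape = a + n/2, rate = b + SSQ(v)/2).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    _active, rank, _p, _i = _active_structure(spec.adjacency)
    pairs = spec.adjacency.pairs()
    ssq_pair = float(np.sum((u[pairs[:, 0]] - u[pairs[:, 1]]) ** 2)) if len(pairs) else 0.0
    a, b = spec.hyper_shape, spec.hyper_rate
    return {
        "tau_u": (a + 0.5 * rank, b + 0.5 * ssq_pair),
        "tau_v": (a + 0.5 * u.size, b + 0.5 * float(v @ v)),
    }


def run_mcmc(spec: BYMModelSpec, obs, expected, config: MCMCConfig) -> BYMPosterior:
    """Sample the BYM posterior with Metropolis-within-Gibbs chains.

    Conjugate Gamma draws update the precisions; every other coordinate gets
    a random-walk Metropolis step with burn-in-only adaptation.  Chains use
    seeds derived deterministically from ``config.seed``.
    """
    obs = np.asarray(obs, dtype=np.float64)
    expected = np.asarray(expected, dtype=np.float64)
    if obs.shape != expected.shape or obs.ndim != 1:
        raise ValueError("obs and expected must be 1-d arrays of equal length")
    if obs.size != spec.adjacency.n:
        raise ValueError("data length must match adjacency size")
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive for all modeled areas")

    has_cov = spec.covariate is not None
    x = np.zeros(obs.size) if not has_cov else spec.covariate.astype(np.float64).copy()
    if has_cov and spec.standardize_covariate:
        x = (x - x.mean()) / x.std(ddof=0)

    active, rank, indptr, indices = _active_structure(spec.adjacency)

    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_chains) % (2**31 - 1)
    chains_c, chains_b, chains_tu, chains_tv, chains_u, chains_v, rates = [], [], [], [], [], [], []
    for ch in range(config.n_chains):
        c_d, b_d, tu_d, tv_d, u_d, v_d, rate, _steps = run_chain(
            obs, expected, x, has_cov,
            indptr, indices, active, rank,
            float(spec.hyper_shape), float(spec.hyper_rate),
            int(config.n_iterations), int(config.burn_in), int(config.thin),
            int(seeds[ch]),
            float(config.step_u), float(config.step_v),
            float(config.step_c), float(config.step_beta),
        )
        chains_c.append(c_d)
        chains_b.append(b_d)
        chains_tu.append(tu_d)
        chains_tv.append(tv_d)
        chains_u.append(u_d)
        chains_v.append(v_d)
        rates.append(rate)
        watched = rate[:4] if has_cov else rate[:3]
        bad = watched[np.isfinite(watched)]
        if np.any(bad < 0.05) or np.any(bad > 0.95):
            logger.warning("chain %d acceptance rates outside [0.05, 0.95]: %s",
                           ch, np.round(rate, 3).tolist())

    return BYMPosterior(
        c=np.stack(chains_c),
        beta=np.stack(chains_b) if has_cov else None,
        tau_u=np.stack(chains_tu),
        tau_v=np.stack(chains_tv),
        u=np.stack(chains_u),
        v=np.stack(chains_v),
        covariate=x if has_cov else None,
        acceptance=np.stack(rates),
        config=config,
    )


def smoothed_sir(posterior: BYMPosterior) -> np.ndarray:
    """Posterior mean of theta_i per area (the smoothed SIR)."""
    return posterior.theta().reshape(-1, posterior.n_areas).mean(axis=0)


def smoothed_sir_ci(posterior: BYMPosterior, level: float = 0.95) -> np.ndarray:
    """(n, 2) central credible-interval bounds for theta_i."""
    q = (1 - level) / 2
    th = posterior.theta().reshape(-1, posterior.n_areas)
    return np.quantile(th, [q, 1 - q], axis=0).T


def irr_summary(posterior: BYMPosterior, level: float = 0.95) -> dict:
    """IRR = exp(posterior mean of beta); CrI = exp of beta's quantiles.

    The covariate effect is 'significant' when the CrI excludes 1.
    """
    if posterior.beta is None:
        raise ValueError("posterior has no covariate coefficient")
    b = posterior.stacked("beta")
    q = (1 - level) / 2
    lo, hi = np.quantile(b, [q, 1 - q])
    irr = float(np.exp(b.mean()))
    cri = (float(np.exp(lo)), float(np.exp(hi)))
    significant = not (cri[0] <= 1.0 <= cri[1])
    return {
        "beta_mean": float(b.mean()),
        "beta_cri": (float(lo), float(hi)),
        "irr": irr,
        "irr_cri": cri,
        "significant": significant,
    }


def percent_change(beta_mean: float) -> float:
    """Average percent decrease in SIR per unit covariate: 100*(1 - exp(beta))."""
    return float(100.0 * (1.0 - np.exp(beta_mean)))


class BYMModel:
    """Estimator-style interface to the BYM sampler.

    Parameters mirror :class:`BYMModelSpec` and :class:`MCMCConfig`; call
    ``fit(obs, expected)`` to sample.  Fitted attributes:

    - ``posterior_`` — the :class:`BYMPosterior`;
    - ``smoothed_sir_`` — posterior mean relative risk per area;
    - ``smoothed_sir_cri_`` — 95% credible bounds per area;
    - ``irr_`` / ``irr_cri_`` / ``significant_`` — covariate models only.
    """

    def __init__(self, adjacency: WeightMatrix, covariate=None,
                 hyper_shape: float = 0.5, hyper_rate: float = 0.0005,
                 n_iterations: int = 30_000, burn_in: int = 10_000,
                 thin: int = 10, n_chains: int = 3, seed: int = 0):
        self.adjacency = adjacency
        self.covariate = covariate
        self.hyper_shape = hyper_shape
        self.hyper_rate = hyper_rate
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.thin = thin
        self.n_chains = n_chains
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "adjacency", "covariate", "hyper_shape", "hyper_rate",
            "n_iterations", "burn_in", "thin", "n_chains", "seed")}

    def set_params(self, **params) -> "BYMModel":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, obs, expected) -> "BYMModel":
        spec = BYMModelSpec(adjacency=self.adjacency, covariate=self.covariate,
                            hyper_shape=self.hyper_shape, hyper_rate=self.hyper_rate)
        config = MCMCConfig(n_iterations=self.n_iterations, burn_in=self.burn_in,
                            thin=self.thin, n_chains=self.n_chains, seed=self.seed)
        self.posterior_ = run_mcmc(spec, obs, expected, config)
        self.smoothed_sir_ = smoothed_sir(self.posterior_)
        self.smoothed_sir_cri_ = smoothed_sir_ci(self.posterior_)
        if self.covariate is not None:
            s = irr_summary(self.posterior_)
            self.beta_mean_ = s["beta_mean"]
            self.irr_ = s["irr"]
            self.irr_cri_ = s["irr_cri"]
            self.significant_ = s["significant"]
        return self

    def summary_frame(self, area_ids=None, crude=None) -> pd.DataFrame:
        df = pd.DataFrame({
            "smoothed_sir": self.smoothed_sir_,
            "cri_low": self.smoothed_sir_cri_[:, 0],
            "cri_high": self.smoothed_sir_cri_[:, 1],
        })
        if crude is not None:
            df.insert(0, "crude_sir", np.asarray(crude, float))
        if area_ids is not None:
            df.insert(0, "area_id", np.asarray(area_ids))
        return df
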