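"""Numba-compiled Metropolis-within-Gibbs sweeps for the BYM sampler.

One chain is a sequence of sweeps over the state
(c, beta, u, v, tau_u, tau_v):

* each active u_i (area with >= 1 CAR neighbor) gets a random-walk
  Metropolis update against the Poisson likelihood plus the intrinsic-CAR
  pairwise-difference prior; after the sweep u is recentred to sum to zero
  over active areas (isolated areas keep u_i = 0);
* each v_i gets a random-walk update against the likelihood plus the
  exchangeable normal prior;
* c (and beta when a covariate is present) get scalar random-walk updates
  against the likelihood alone (flat priors);
* tau_u and tau_v are conjugate Gamma draws — shape
  ``hyper_shape + rank/2`` (rank = active areas minus connected components)
  and ``hyper_shape + n/2``, rates ``hyper_rate + pairwise-SSQ/2`` and
  ``hyper_rate + SSQ(v)/2``.

Scalar proposal scales adapt toward 30-45% acceptance during burn-in only
and are frozen afterwards, preserving detailed balance for retained draws.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def run_chain(obs, expected, x, has_cov,
              indptr, indices, active, rank,
              hyper_shape, hyper_rate,
              n_iter, burn_in, thin, seed,
              step_u0, step_v0, step_c0, step_b0):
    np.random.seed(seed)
    n = obs.shape[0]
    n_active = 0
    for i in range(n):
        if active[i]:
            n_active += 1

    c = np.log(max(np.sum(obs), 1.0) / np.sum(expected))
    beta = 0.0
    u = np.zeros(n)
    v = np.zeros(n)
    tau_u = 10.0
    tau_v = 10.0

    step_u = step_u0
    step_v = step_v0
    step_c = step_c0
    step_b = step_b0

    n_keep = (n_iter - burn_in + thin - 1) // thin
    c_out = np.empty(n_keep)
    b_out = np.empty(n_keep)
    tu_out = np.empty(n_keep)
    tv_out = np.empty(n_keep)
    u_out = np.empty((n_keep, n))
    v_out = np.empty((n_keep, n))

    acc_u = 0.0
    try_u = 0.0
    acc_v = 0.0
    try_v = 0.0
    acc_c = 0.0
    try_c = 0.0
    acc_b = 0.0
    try_b = 0.0
    # post-burn-in acceptance bookkeeping
    pacc = np.zeros(4)
    ptry = np.zeros(4)

    kept = 0
    for it in range(n_iter):
        # ---- structured effects u ----
        for i in range(n):
            if not active[i]:
                continue
            prop = u[i] + step_u * np.random.normal()
            eta = c + beta * x[i] + v[i]
            lam_old = expected[i] * np.exp(eta + u[i])
            lam_new = expected[i] * np.exp(eta + prop)
            d = obs[i] * (prop - u[i]) - (lam_new - lam_old)
            s = 0.0
            for jj in range(indptr[i], indptr[i + 1]):
                j = indices[jj]
                s += (prop - u[j]) ** 2 - (u[i] - u[j]) ** 2
            d -= 0.5 * tau_u * s
            try_u += 1.0
            if it >= burn_in:
                ptry[0] += 1.0
            if np.log(np.random.random()) < d:
                u[i] = prop
                acc_u += 1.0
                if it >= burn_in:
                    pacc[0] += 1.0
        # sum-to-zero recentring over active areas
        if n_active > 0:
            m = 0.0
            for i in range(n):
                if active[i]:
                    m += u[i]
            m /= n_active
            for i in range(n):
                if active[i]:
                    u[i] -= m

        # ---- unstructured effects v ----
        for i in range(n):
            prop = v[i] + step_v * np.random.normal()
            eta = c + beta * x[i] + u[i]
            lam_old = expected[i] * np.exp(eta + v[i])
            lam_new = expected[i] * np.exp(eta + prop)
            d = obs[i] * (prop - v[i]) - (lam_new - lam_old)
            d -= 0.5 * tau_v * (prop * prop - v[i] * v[i])
            try_v += 1.0
            if it >= burn_in:
                ptry[1] += 1.0
            if np.log(np.random.random()) < d:
                v[i] = prop
                acc_v += 1.0
                if it >= burn_in:
                    pacc[1] += 1.0

        # ---- intercept c (flat prior) ----
        prop = c + step_c * np.random.normal()
        d = 0.0
        for i in range(n):
            rest = beta * x[i] + u[i] + v[i]
            d += obs[i] * (prop - c) - expected[i] * (np.exp(prop + rest) - np.exp(c + rest))
        try_c += 1.0
        if it >= burn_in:
            ptry[2] += 1.0
        if np.log(np.random.random()) < d:
            c = prop
            acc_c += 1.0
            if it >= burn_in:
                pacc[2] += 1.0

        # ---- covariate coefficient beta (flat prior) ----
        if has_cov:
            prop = beta + step_b * np.random.normal()
            d = 0.0
            for i in range(n):
                rest = c + u[i] + v[i]
                d += obs[i] * (prop - beta) * x[i] \
                    - expected[i] * (np.exp(rest + prop * x[i]) - np.exp(rest + beta * x[i]))
            try_b += 1.0
            if it >= burn_in:
                ptry[3] += 1.0
            if np.log(np.random.random()) < d:
                beta = prop
                acc_b += 1.0
                if it >= burn_in:
                    pacc[3] += 1.0

        # ---- conjugate precision draws ----
        ssq_pair = 0.0
        for i in range(n):
            for jj in range(indptr[i], indptr[i + 1]):
                j = indices[jj]
                if j > i:
                    ssq_pair += (u[i] - u[j]) ** 2
        if rank > 0:
            tau_u = np.random.gamma(hyper_shape + 0.5 * rank,
                                    1.0 / (hyper_rate + 0.5 * ssq_pair))
        ssq_v = 0.0
        for i in range(n):
            ssq_v += v[i] * v[i]
        tau_v = np.random.gamma(hyper_shape + 0.5 * n,
                                1.0 / (hyper_rate + 0.5 * ssq_v))

        # ---- burn-in-only step adaptation (target 30-45% acceptance) ----
        if it < burn_in and (it + 1) % 200 == 0:
            if try_u > 0:
                r = acc_u / try_u
                if r > 0.45:
                    step_u *= 1.2
                elif r < 0.30:
                    step_u /= 1.2
            if try_v > 0:
                r = acc_v / try_v
                if r > 0.45:
                    step_v *= 1.2
                elif r < 0.30:
                    step_v /= 1.2
            r = acc_c / try_c
            if r > 0.45:
                step_c *= 1.2
            elif r < 0.30:
                step_c /= 1.2
            if has_cov:
                r = acc_b / try_b
                if r > 0.45:
                    step_b *= 1.2
                elif r < 0.30:
                    step_b /= 1.2
            acc_u = try_u = acc_v = try_v = 0.0
            acc_c = try_c = acc_b = try_b = 0.0

        if it >= burn_in and (it - burn_in) % thin == 0:
            c_out[kept] = c
            b_out[kept] = beta
            tu_out[kept] = tau_u
            tv_out[kept] = tau_v
            for i in range(n):
                u_out[kept, i] = u[i]
                v_out[kept, i] = v[i]
            kept += 1

    rates = np.full(4, np.nan)
    for k in range(4):
        if ptry[k] > 0:
            rates[k] = pacc[k] / ptry[k]
    steps = np.array([step_u, step_v, step_c, step_b])
    return c_out, b_out, tu_out, tv_out, u_out, v_out, rates, steps
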