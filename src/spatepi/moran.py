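"""Global and Local Moran's I with permutation inference.

Global Moran's I measures region-wide spatial autocorrelation of an areal
variable; its null expectation under random relabeling is ``-1/(n-1)``.
Inference is by pseudo p-value over uniform permutations of the values across
areas, one-sided in the direction of the observed statistic.  Local Moran's I
(LISA) decomposes the global statistic per area; areas significant under
conditional permutation (the area's own value held fixed) are classified
High-High, Low-Low, Low-High or High-Low by the signs of the centered value
and its spatial lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .weights import WeightMatrix

#: LISA class labels, spelled as in registry reports.
CLUSTER_LABELS = {
    "HH": "High-High",
    "LL": "Low-Low",
    "LH": "Low-High",
    "HL": "High-Low",
    "NS": "Not Significant",
}


@dataclass(frozen=True)
class GlobalMoranResult:
    I: float
    expected_I: float
    pseudo_p: float
    n_perm: int
    seed: int

    def __post_init__(self):
        assert self.pseudo_p >= 1.0 / (self.n_perm + 1)


@dataclass
class LisaResult:
    I_i: np.ndarray
    pseudo_p: np.ndarray
    cluster: np.ndarray  # codes in {HH, LL, LH, HL, NS}
    alpha: float
    n_perm: int
    seed: int

    def labels(self) -> np.ndarray:
        return np.array([CLUSTER_LABELS[c] for c in self.cluster])

    def counts(self) -> dict:
        return {CLUSTER_LABELS[c]: int(np.sum(self.cluster == c)) for c in ("HH", "LL", "LH", "HL", "NS")}

    def to_frame(self, area_ids=None) -> pd.DataFrame:
        df = pd.DataFrame({
            "I_i": self.I_i,
            "pseudo_p": self.pseudo_p,
            "cluster": self.labels(),
        })
        if area_ids is not None:
            df.insert(0, "area_id", np.asarray(area_ids))
        return df


def _validate(values, W: WeightMatrix) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size != W.n:
        raise ValueError(f"values length {x.size} does not match weight matrix n={W.n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: constant value vector")
    if W.s0 <= 0:
        raise ValueError("weight matrix has S0 = 0")
    return x


def global_moran(values, W: WeightMatrix) -> float:
    """Moran's I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2."""
    x = _validate(values, W)
    z = x - x.mean()
    lag = W.to_sparse() @ z
    return float(x.size / W.s0 * (z @ lag) / (z @ z))


def global_moran_test(values, W: WeightMatrix, n_perm: int = 999, seed: int = 0) -> GlobalMoranResult:
    """Permutation test for Global Moran's I.

    pseudo_p = (1 + #{permuted I at least as extreme as observed}) / (n_perm + 1),
    one-sided toward the observed side of the null expectation -1/(n-1).
    """
    x = _validate(values, W)
    n = x.size
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Wsp = W.to_sparse()
    s0 = W.s0
    z = x - x.mean()
    denom = z @ z
    I_obs = float(n / s0 * (z @ Wsp @ z) / denom)

    rng = np.random.default_rng(seed)
    # Permuting z permutes x up to the (permutation-invariant) mean shift.
    perms = np.empty((n_perm, n))
    for k in range(n_perm):
        perms[k] = rng.permutation(z)
    I_perm = n / s0 * np.sum(perms * (Wsp @ perms.T).T, axis=1) / denom

    e_I = -1.0 / (n - 1)
    if I_obs >= e_I:
        count = int(np.sum(I_perm >= I_obs))
    else:
        count = int(np.sum(I_perm <= I_obs))
    p = (1 + count) / (n_perm + 1)
    return GlobalMoranResult(I=I_obs, expected_I=e_I, pseudo_p=p, n_perm=n_perm, seed=seed)


def local_moran(values, W: WeightMatrix) -> np.ndarray:
    """Local Moran's I_i = z_i * (W z)_i / m2 with m2 = sum(z^2)/n.

    Isolated areas (empty neighbor row) get I_i = 0.
    """
    x = _validate(values, W)
    z = x - x.mean()
    m2 = (z @ z) / x.size
    lag = W.to_sparse() @ z
    return z * lag / m2


def lisa_classify(values, W: WeightMatrix, n_perm: int = 999, alpha: float = 0.05,
                  seed: int = 0) -> LisaResult:
    """Local Moran significance by conditional permutation + quadrant labels.

    For each area i, the remaining n-1 values are permuted among the other
    areas while z_i stays in place; the pseudo p is one-sided toward the
    observed sign of I_i.  Significant areas (p <= alpha) are labeled by the
    signs of (z_i, spatial lag of z_i); all others are Not Significant.
    Per-area RNG substreams are derived from the master seed so results do
    not depend on iteration order.
    """
    x = _validate(values, W)
    n = x.size
    z = x - x.mean()
    m2 = (z @ z) / n
    I_obs = local_moran(values, W)

    p = np.ones(n)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    for i in range(n):
        nb = np.asarray(W.neighbors[i], dtype=int)
        if nb.size == 0:
            p[i] = 1.0
            continue
        wt = np.asarray(W.weights[i], dtype=float)
        others = np.delete(z, i)
        rng = np.random.default_rng(children[i])
        # draw n_perm random neighbor-sets from the other n-1 values
        idx = np.empty((n_perm, nb.size), dtype=int)
        for k in range(n_perm):
            idx[k] = rng.choice(others.size, size=nb.size, replace=False)
        lag_perm = others[idx] @ wt
        I_perm = z[i] * lag_perm / m2
        if I_obs[i] >= 0:
            count = int(np.sum(I_perm >= I_obs[i]))
        else:
            count = int(np.sum(I_perm <= I_obs[i]))
        p[i] = (1 + count) / (n_perm + 1)

    lag = W.to_sparse() @ z
    cluster = np.full(n, "NS", dtype=object)
    sig = p <= alpha
    for i in np.flatnonzero(sig):
        if z[i] > 0:
            cluster[i] = "HH" if lag[i] > 0 else "HL"
        elif z[i] < 0:
            cluster[i] = "LL" if lag[i] < 0 else "LH"
        # z_i == 0 stays NS: no quadrant
    return LisaResult(I_i=I_obs, pseudo_p=p, cluster=cluster, alpha=alpha,
                      n_perm=n_perm, seed=seed)


class GlobalMoran:
    """Estimator-style wrapper: ``GlobalMoran(n_perm=999, seed=0).fit(x, W)``.

    Fitted attributes: ``I_``, ``expected_I_``, ``pseudo_p_``.
    """

    def __init__(self, n_perm: int = 999, seed: int = 0):
        self.n_perm = n_perm
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"n_perm": self.n_perm, "seed": self.seed}

    def set_params(self, **params) -> "GlobalMoran":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, values, W: WeightMatrix) -> "GlobalMoran":
        res = global_moran_test(values, W, n_perm=self.n_perm, seed=self.seed)
        self.result_ = res
        self.I_ = res.I
        self.expected_I_ = res.expected_I
        self.pseudo_p_ = res.pseudo_p
        return self


class LocalMoran:
    """Estimator-style wrapper around :func:`lisa_classify`.

    Fitted attributes: ``I_i_``, ``pseudo_p_``, ``cluster_`` (verbal labels).
    """

    def __init__(self, n_perm: int = 999, alpha: float = 0.05, seed: int = 0):
        self.n_perm = n_perm
        self.alpha = alpha
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"n_perm": self.n_perm, "alpha": self.alpha, "seed": self.seed}

    def set_params(self, **params) -> "LocalMoran":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, values, W: WeightMatrix) -> "LocalMoran":
        res = lisa_classify(values, W, n_perm=self.n_perm, alpha=self.alpha, seed=self.seed)
        self.result_ = res
        self.I_i_ = res.I_i
        self.pseudo_p_ = res.pseudo_p
        self.cluster_ = res.labels()
        return self
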