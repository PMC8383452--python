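"""Indirect standardization and crude SIRs.

The expected count for area *i* applies the region-wide rate to the area's
population: ``E_i = n_i * (sum(O) / sum(n))``, so ``sum(E) == sum(O)`` by
construction.  The crude standardized incidence ratio is ``O_i / E_i``; it is
undefined where ``E_i == 0`` (zero-population areas are retained in the data
model but drop out of SIR and clustering vectors).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .region import RISK_LEVELS, StudyRegion

#: Verbal SIR bins mirroring how registry reports tabulate crude SIRs.
#: Boundary convention: the central "within 10%" bin is closed, [0.9, 1.1];
#: bins above parity are half-open on the left, (1.1, 1.5], (1.5, 2.0],
#: (2.0, inf); mirrored below parity: [0.5, 0.9), [0, 0.5).
BIN_LABELS: tuple[str, ...] = (
    "> 50% less than expected",
    "10 to 50% less than expected",
    "within 10% expected",
    "10 to 50% more than expected",
    "50 to 100% more than expected",
    "> 100% more than expected",
)

NO_EXPECTED_LABEL = "no-expected-cases"


def expected_counts(pop, obs) -> np.ndarray:
    """Indirectly standardized expected counts ``E_i = n_i * sum(O)/sum(n)``.

    Parameters
    ----------
    pop : array-like of non-negative int
        Area populations ``n_i``.
    obs : array-like of non-negative int
        Observed case counts ``O_i``, same length as ``pop``.
    """
    pop = np.asarray(pop, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pop.ndim != 1 or pop.shape != obs.shape or pop.size < 1:
        raise ValueError("pop and obs must be 1-d arrays of equal length >= 1")
    if (pop < 0).any() or (obs < 0).any():
        raise ValueError("populations and counts must be non-negative")
    total_pop = pop.sum()
    if total_pop <= 0:
        raise ValueError("degenerate region: total population is zero")
    return pop * (obs.sum() / total_pop)


def crude_sir(obs, expected) -> np.ndarray:
    """Crude SIR ``O_i / E_i``; NaN marks areas with ``E_i == 0`` (undefined)."""
    obs = np.asarray(obs, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if obs.shape != expected.shape:
        raise ValueError("obs and expected must have equal length")
    if (obs < 0).any() or (expected < 0).any():
        raise ValueError("observed and expected counts must be non-negative")
    out = np.full(obs.shape, np.nan)
    pos = expected > 0
    out[pos] = obs[pos] / expected[pos]
    return out


def classify_sir_bins(sir) -> np.ndarray:
    """Map each SIR to one of the six verbal bins (NaN -> 'no-expected-cases').

    The six bins partition [0, inf): [0, 0.5), [0.5, 0.9), [0.9, 1.1],
    (1.1, 1.5], (1.5, 2.0], (2.0, inf).
    """
    sir = np.asarray(sir, dtype=float)
    if (sir[~np.isnan(sir)] < 0).any():
        raise ValueError("SIR values must be non-negative")
    out = np.empty(sir.shape, dtype=object)
    for i, s in np.ndenumerate(sir):
        if np.isnan(s):
            out[i] = NO_EXPECTED_LABEL
        elif s < 0.5:
            out[i] = BIN_LABELS[0]
        elif s < 0.9:
            out[i] = BIN_LABELS[1]
        elif s <= 1.1:
            out[i] = BIN_LABELS[2]
        elif s <= 1.5:
            out[i] = BIN_LABELS[3]
        elif s <= 2.0:
            out[i] = BIN_LABELS[4]
        else:
            out[i] = BIN_LABELS[5]
    return out


def annual_cv(yearly_counts) -> float:
    """Coefficient of variation (%) of annual counts: 100 * sample SD / mean.

    Uses the sample (n-1 denominator) standard deviation.
    """
    y = np.asarray(yearly_counts, dtype=float)
    if y.size < 2:
        raise ValueError("need at least two yearly counts")
    mean = y.mean()
    if mean == 0:
        raise ValueError("zero mean annual count")
    return float(100.0 * y.std(ddof=1) / mean)


def risk_level_proportions(counts_by_level: dict) -> dict:
    """Percentage of cases per risk level, rounded to one decimal place."""
    total = sum(counts_by_level.values())
    if total <= 0:
        raise ValueError("total case count must be positive")
    return {lvl: round(100.0 * c / total, 1) for lvl, c in counts_by_level.items()}


def sir_table(region: StudyRegion, risk_level: str | None = None) -> pd.DataFrame:
    """Long-form SIR table: area_id, risk_level, observed, expected, crude_sir, bin.

    Zero-population areas appear with expected 0 and bin 'no-expected-cases'.
    """
    levels = RISK_LEVELS if risk_level is None else (risk_level,)
    rows = []
    for lvl in levels:
        obs = region.observed(lvl)
        exp = expected_counts(region.population, obs)
        sirs = crude_sir(obs, exp)
        bins = classify_sir_bins(sirs)
        for aid, o, e, s, b in zip(region.area_ids, obs, exp, sirs, bins):
            rows.append(
                {
                    "area_id": aid,
                    "risk_level": lvl,
                    "observed": int(o),
                    "expected": float(e),
                    "crude_sir": float(s) if not np.isnan(s) else np.nan,
                    "bin": b,
                }
            )
    return pd.DataFrame(rows)
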