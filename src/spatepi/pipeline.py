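"""End-to-end per-risk-level workflow.

For each requested risk level: compute the SIR table; test Global Moran's I
on the crude SIRs of populated areas; when the pseudo p-value clears the
gate (it applies to the clustering stage jointly), run the LISA
classification and the Kulldorff scan; always fit the BYM null model and one
single-covariate ecological model per configured covariate, each with a
convergence-diagnostics report.  The gate never suppresses SIR or BYM
outputs.  A manifest records configuration and seeds so a rerun with the
same config reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bym import BYMModel, percent_change
from .diagnostics import diagnose_posterior
from .moran import GlobalMoran, LocalMoran
from .region import RISK_LEVELS, StudyRegion, ValidationError
from .scan import KulldorffScan, clusters_to_frame, clusters_to_geojson
from .sir import BIN_LABELS, classify_sir_bins, crude_sir, expected_counts, sir_table
from .weights import binary_adjacency, build_weights

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = {"phys_density", "remoteness"}


@dataclass
class RunConfig:
    input_csv: Optional[str] = None
    output_dir: str = "spatepi_run"
    risk_levels: Sequence[str] = RISK_LEVELS
    weights_radius_km: float = 120.0
    moran_permutations: int = 999
    moran_alpha: float = 0.05
    scan_max_fraction: float = 0.25
    scan_replicates: int = 999
    mcmc_iterations: int = 30_000
    mcmc_burn_in: int = 10_000
    mcmc_thin: int = 10
    mcmc_chains: int = 3
    covariates: Sequence[str] = ("phys_density",)
    force_clustering: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not self.risk_levels:
            raise ValidationError("config lists zero risk levels")
        unknown = [lvl for lvl in self.risk_levels if lvl not in RISK_LEVELS]
        if unknown:
            raise ValidationError(f"unknown risk levels: {unknown}")
        bad = [c for c in self.covariates if c not in COVARIATE_COLUMNS]
        if bad:
            raise ValidationError(f"unknown covariate columns: {bad}")


def _stage_seed(master: int, *tags: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    h = np.random.SeedSequence([master] + [zlib.crc32(t.encode()) for t in tags])
    return int(h.generate_state(1)[0] % (2**31 - 1))


def run(config: RunConfig, region: Optional[StudyRegion] = None) -> Path:
    """Execute the workflow; returns the run directory."""
    config.validate()
    if region is None:
        if config.input_csv is None:
            raise ValidationError("no input: provide input_csv or a StudyRegion")
        region = StudyRegion.from_csv(config.input_csv)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    pop_mask = region.populated_mask()
    sub_idx = np.flatnonzero(pop_mask)
    centroids = region.centroids[pop_mask]
    W_moran = build_weights(centroids, config.weights_radius_km, standardize=True)
    adjacency = binary_adjacency(
        build_weights(centroids, config.weights_radius_km, standardize=False))

    from . import __version__ as pkg_version

    manifest = {
        "version": pkg_version,
        "config": {k: (list(v) if isinstance(v, (tuple, list)) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "n_areas": int(region.n_areas),
        "n_populated": int(pop_mask.sum()),
        "stages": {},
    }

    for lvl in config.risk_levels:
        obs_all = region.observed(lvl)
        tab = sir_table(region, lvl)
        tab.to_csv(out / f"sir_{lvl}.csv", index=False, float_format="%.6f")

        obs = obs_all[pop_mask]
        exp = expected_counts(region.population[pop_mask], obs)
        sirs = crude_sir(obs, exp)

        moran_seed = _stage_seed(config.seed, "moran", lvl)
        gm = GlobalMoran(n_perm=config.moran_permutations, seed=moran_seed).fit(sirs, W_moran)
        # the gate asks for evidence of *positive* spatial autocorrelation
        gate_open = (gm.pseudo_p_ <= config.moran_alpha and gm.I_ > gm.expected_I_) \
            or config.force_clustering
        manifest["stages"][f"moran_{lvl}"] = {
            "I": gm.I_, "expected_I": gm.expected_I_, "pseudo_p": gm.pseudo_p_,
            "seed": moran_seed, "gate_open": bool(gate_open),
        }

        if gate_open:
            lm = LocalMoran(n_perm=config.moran_permutations, alpha=config.moran_alpha,
                            seed=_stage_seed(config.seed, "lisa", lvl)).fit(sirs, W_moran)
            lisa_df = lm.result_.to_frame(area_ids=region.area_ids[pop_mask])
            lisa_df.to_csv(out / f"lisa_{lvl}.csv", index=False, float_format="%.6f")

            ks = KulldorffScan(max_pop_fraction=config.scan_max_fraction,
                               n_reps=config.scan_replicates,
                               seed=_stage_seed(config.seed, "scan", lvl))
            ks.fit(obs, exp, centroids, region.population[pop_mask],
                   area_ids=region.area_ids[pop_mask])
            clusters_to_frame(ks.clusters_).to_csv(out / f"scan_{lvl}.csv", index=False,
                                                   float_format="%.6f")
            gj = clusters_to_geojson(ks.clusters_, centroids, region.area_ids[pop_mask])
            (out / f"scan_{lvl}.geojson").write_text(json.dumps(gj, indent=1))
        else:
            logger.info("Moran gate closed for %s (p=%.3f): skipping LISA and scan",
                        lvl, gm.pseudo_p_)

        # BYM null model (always)
        model_rows = []
        null_model = BYMModel(
            adjacency=adjacency,
            n_iterations=config.mcmc_iterations, burn_in=config.mcmc_burn_in,
            thin=config.mcmc_thin, n_chains=config.mcmc_chains,
            seed=_stage_seed(config.seed, "bym-null", lvl),
        ).fit(obs, exp)
        area_df = null_model.summary_frame(area_ids=region.area_ids[pop_mask], crude=sirs)
        area_df.to_csv(out / f"bym_{lvl}_areas.csv", index=False, float_format="%.6f")
        diag = diagnose_posterior(null_model.posterior_)
        diag.to_frame().to_csv(out / f"diagnostics_{lvl}_null.csv", index=False)
        model_rows.append({
            "model": "null", "parameter": "c",
            "mean": float(null_model.posterior_.stacked("c").mean()),
            "verdict": diag.overall(),
        })

        # one single-covariate ecological model per configured covariate
        for cov in config.covariates:
            x = region.areas.loc[pop_mask, cov].to_numpy(dtype=float)
            eco = BYMModel(
                adjacency=adjacency, covariate=x,
                n_iterations=config.mcmc_iterations, burn_in=config.mcmc_burn_in,
                thin=config.mcmc_thin, n_chains=config.mcmc_chains,
                seed=_stage_seed(config.seed, "bym-eco", lvl, cov),
            ).fit(obs, exp)
            dg = diagnose_posterior(eco.posterior_)
            dg.to_frame().to_csv(out / f"diagnostics_{lvl}_{cov}.csv", index=False)
            model_rows.append({
                "model": cov, "parameter": "beta",
                "mean": eco.beta_mean_,
                "cri_low": float(np.log(eco.irr_cri_[0])),
                "cri_high": float(np.log(eco.irr_cri_[1])),
                "irr": eco.irr_,
                "irr_cri_low": eco.irr_cri_[0],
                "irr_cri_high": eco.irr_cri_[1],
                "significant": eco.significant_,
                "percent_change": percent_change(eco.beta_mean_),
                "verdict": dg.overall(),
            })
        pd.DataFrame(model_rows).to_csv(out / f"bym_{lvl}_models.csv", index=False,
                                        float_format="%.6f")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    summarize_tables(out)
    return out


def summarize_tables(run_dir: str | Path) -> dict:
    """Build the four summary CSVs from a run directory's per-level outputs.

    Shapes mirror the registry report: SIR bin counts per level, Moran/LISA
    counts, crude-vs-smoothed SIR ranges, and the ecological coefficient /
    IRR / CrI table.
    """
    run_dir = Path(run_dir)
    manifest = json.loads((run_dir / "manifest.json").read_text())
    levels = [lvl for lvl in manifest["config"]["risk_levels"]]

    # SIR bin counts (Table-2 shape)
    bins = {}
    for lvl in levels:
        df = pd.read_csv(run_dir / f"sir_{lvl}.csv")
        defined = df[df["bin"] != "no-expected-cases"]
        counts = defined["bin"].value_counts()
        bins[lvl] = [int(counts.get(b, 0)) for b in BIN_LABELS]
    t2 = pd.DataFrame(bins, index=list(BIN_LABELS))
    t2.index.name = "crude_sir_bin"
    t2.to_csv(run_dir / "table_sir_bins.csv")

    # Moran / LISA counts (Table-3 shape)
    rows = {}
    lisa_cats = ["High-High", "Low-Low", "Low-High", "High-Low", "Not Significant"]
    for lvl in levels:
        st = manifest["stages"][f"moran_{lvl}"]
        col = {"Global Moran's I": round(st["I"], 3),
               "pseudo p": st["pseudo_p"]}
        lisa_path = run_dir / f"lisa_{lvl}.csv"
        if lisa_path.exists():
            ldf = pd.read_csv(lisa_path)
            vc = ldf["cluster"].value_counts()
            for cat in lisa_cats:
                col[cat] = int(vc.get(cat, 0))
        else:
            for cat in lisa_cats:
                col[cat] = np.nan
        rows[lvl] = col
    t3 = pd.DataFrame(rows)
    t3.index.name = "statistic"
    t3.to_csv(run_dir / "table_moran_lisa.csv")

    # crude vs smoothed ranges (Table-4 shape)
    rec = []
    for lvl in levels:
        adf = pd.read_csv(run_dir / f"bym_{lvl}_areas.csv")
        rec.append({
            "risk_level": lvl,
            "crude_min": adf["crude_sir"].min(),
            "crude_max": adf["crude_sir"].max(),
            "smoothed_min": adf["smoothed_sir"].min(),
            "smoothed_max": adf["smoothed_sir"].max(),
        })
    t4 = pd.DataFrame(rec)
    t4.to_csv(run_dir / "table_sir_ranges.csv", index=False, float_format="%.3f")

    # ecological analysis (Table-5 shape)
    rec = []
    for lvl in levels:
        mdf = pd.read_csv(run_dir / f"bym_{lvl}_models.csv")
        for _, r in mdf[mdf["parameter"] == "beta"].iterrows():
            rec.append({
                "risk_level": lvl,
                "covariate": r["model"],
                "mean": round(float(r["mean"]), 3),
                "cri": f"{r['cri_low']:.3f} to {r['cri_high']:.3f}",
                "irr": round(float(r["irr"]), 3),
                "irr_cri": (f"{r['irr_cri_low']:.3f} to {r['irr_cri_high']:.3f}"
                            if bool(r["significant"]) else "Not significant"),
            })
    t5 = pd.DataFrame(rec)
    t5.to_csv(run_dir / "table_ecological.csv", index=False)
    return {"table_sir_bins": t2, "table_moran_lisa": t3,
            "table_sir_ranges": t4, "table_ecological": t5}
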