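"""End-to-end study runner: simulate -> kinship -> heritability -> CV -> reduction.

Driven by a YAML study configuration with sections ``sim`` (SimConfig
fields), ``model`` (WGRConfig fields), ``cv`` (n_folds), ``kinship``
(n_snps, n_bootstrap) and ``reduce`` (step, max_markers, r2_cutoff, window,
threshold, top_n, plot_n), plus a global ``seed``.  Writes a consolidated
report (TSV tables, JSON summaries, PNG plots) and a manifest with the
resolved configuration.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from . import plotting
from .evaluate import make_cv_plan, run_cv, selection_response
from .herit import heritability_report
from .kinship import kinship_matrix
from .reduce import optimal_density, rrblup_b_curve
from .simulate import SimConfig, simulate_population
from .wgr import METHODS, WGRConfig

log = logging.getLogger("palmgs")

DEFAULTS = {
    "seed": 0,
    "sim": {},
    "model": {"n_iter": 20000, "burn_in": 2500},
    "cv": {"n_folds": 5},
    "kinship": {"n_snps": 15000, "n_bootstrap": 100},
    "reduce": {
        "enabled": True,
        "step": 10,
        "max_markers": 20000,
        "r2_cutoff": 0.6,
        "window": 100,
        "threshold": 0.05,
        "top_n": 300,
        "plot_n": 600,
    },
    "methods": list(METHODS),
}


def load_study_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    merged = {}
    for key, val in DEFAULTS.items():
        if isinstance(val, dict):
            merged[key] = {**val, **cfg.get(key, {})}
        else:
            merged[key] = cfg.get(key, val)
    return merged


def run_pipeline(config: dict, outdir) -> Path:
    """Run the full study on a simulated population; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    sim_cfg = SimConfig(**{**config.get("sim", {}), "seed": seed})
    G, traits, truth = simulate_population(sim_cfg)
    log.info("simulated %d individuals x %d markers", G.n_individuals, G.n_markers)
    pio.write_genotypes(G, outdir / "population", fmt="plink-bed")
    pio.write_genotypes(G, outdir / "population", fmt="dosage-tsv")
    pio.write_phenotypes(traits, outdir / "phenotypes.tsv")
    pio.write_truth(truth, outdir / "truth.json")

    kin_cfg = config["kinship"]
    kin = kinship_matrix(
        G, n_snps=int(kin_cfg["n_snps"]), n_bootstrap=int(kin_cfg["n_bootstrap"]),
        seed=seed,
    )
    kin_summary = {
        "mean": kin.summary[0], "min": kin.summary[1], "max": kin.summary[2],
        "n_snps": int(len(kin.snps_used)),
    }

    estimates, h2_corr = heritability_report(G, traits)
    herit_df = pd.DataFrame(
        {
            "trait": [e.trait for e in estimates],
            "h2_full": [e.h2_full for e in estimates],
            "h2_subset": [e.h2_subset for e in estimates],
            "n_markers_subset": [e.n_markers_subset for e in estimates],
            "class": [e.classification for e in estimates],
        }
    )

    model_cfg = WGRConfig(**{**config["model"], "seed": seed})
    plan = make_cv_plan(G.n_individuals, n_folds=int(config["cv"]["n_folds"]), seed=seed)
    methods = config["methods"]
    cv_rows, sel_rows = [], []
    for trait in traits.trait_names:
        y = traits.values(trait, individual_ids=G.individual_ids)
        cv = run_cv(G, y, methods, plan, config=model_cfg, trait=trait)
        for method, res in cv.items():
            cv_rows.append(
                {
                    "trait": trait,
                    "method": method,
                    "mean_accuracy": res.mean_accuracy,
                    "sd_accuracy": res.sd_accuracy,
                }
            )
        rep = selection_response(y, individual_ids=G.individual_ids, trait=trait)
        sel_rows.append(
            {"trait": trait, "top_fraction": rep.top_fraction, "response": rep.response}
        )
        plotting.plot_pred_obs(
            cv[methods[0]].gebv_table, outdir / f"pred_obs_{trait}.png", trait=trait
        )
    cv_df = pd.DataFrame(cv_rows)

    red_cfg = config["reduce"]
    curves = []
    reduce_summary = {}
    if red_cfg.get("enabled", True):
        for trait in traits.trait_names:
            y = traits.values(trait, individual_ids=G.individual_ids)
            curve = rrblup_b_curve(
                G, y, plan,
                step=int(red_cfg["step"]),
                max_markers=int(red_cfg["max_markers"]),
                trait=trait,
            )
            curves.append(curve)
            try:
                opt = optimal_density(
                    curve, window=int(red_cfg["window"]),
                    threshold=float(red_cfg["threshold"]),
                )
            except ValueError:
                opt = None
            reduce_summary[trait] = {"optimal_density": opt}
        plotting.plot_accuracy_curves(curves, outdir / "rrblup_b_curves.png")

    tables = {
        "kinship_summary": kin_summary,
        "heritability": herit_df,
        "cv_accuracy": cv_df,
        "selection_response": pd.DataFrame(sel_rows),
        "reduce_summary": {
            **reduce_summary,
            "h2_full_vs_subset_correlation": h2_corr,
        },
    }
    if curves:
        tables["rrblup_b_curves"] = pd.concat(
            [
                pd.DataFrame(
                    {
                        "trait": c.trait,
                        "strategy": c.strategy,
                        "k": c.marker_counts,
                        "mean": c.mean_accuracy,
                        "sd": c.sd_accuracy,
                    }
                )
                for c in curves
            ],
            ignore_index=True,
        )
    resolved = {**config, "sim": dataclasses.asdict(sim_cfg),
                "model": dataclasses.asdict(model_cfg)}
    return pio.write_results(tables, outdir, config=resolved)
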