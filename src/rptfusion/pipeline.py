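"""End-to-end pipeline: simulate/load -> features -> regressions ->
overlap -> heatmaps -> feature selection -> kNN.

Every stage reads its inputs from the previous stage's in-memory outputs
and writes tidy CSV/JSON (plus heatmap images) under the configured output
directory; no stage mutates its inputs, and all randomness flows from the
single configured seed.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, classify, features, heatmaps, simulate
from .io import PipelineConfig, read_cohort_tables, write_table
from .labels import DEMOGRAPHICS, GROUPS

log = logging.getLogger("rptfusion")

__all__ = ["build_cohort_table", "run_pipeline"]


def build_cohort_table(
    responses: pd.DataFrame,
    participants: pd.DataFrame,
    *,
    include_zeros: bool = False,
    value_form: str = "log",
) -> pd.DataFrame:
    """Merge computed keypress-metric profiles onto the participant table."""
    prof = features.profiles_from_responses(
        responses, include_zeros=include_zeros, value_form=value_form
    )
    return participants.merge(prof, on="participant_id", validate="1:1")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the in-memory report bundle.

    Stages: (optional) cohort simulation, RPT feature extraction, the
    per-group regression grids with and without covariates, cross-group
    overlap accounting, heatmap construction/comparison/rendering, feature
    selection, and pairwise kNN over the six feature combinations.  Writes
    a run manifest with the config hash and seed alongside the outputs.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate or config.responses_path is None:
        log.info("simulating cohort (seed=%d)", config.seed)
        ds = simulate.generate_cohort(simulate.SimulationConfig(seed=config.seed))
        responses, participants = ds.responses, ds.participants
        ds.save(outdir / "cohort")
    else:
        responses, participants = read_cohort_tables(
            config.responses_path, config.participants_path,
            volumes=config.volumes,
        )

    cohort = build_cohort_table(
        responses, participants,
        include_zeros=config.include_zeros, value_form=config.value_form,
    )
    write_table(cohort, outdir / "cohort_table.csv")

    bundle: dict = {"cohort": cohort}
    grids_cov, grids_nocov, mats = {}, {}, {}
    for g in GROUPS:
        if (cohort["group"] == g).sum() == 0:
            continue
        grids_cov[g] = association.run_grid(
            cohort, g, with_covariates=True,
            volumes=config.volumes, metrics=config.metrics,
            alpha=config.alpha, cooks=config.cooks,
            cooks_rule=config.cooks_rule, bh_method=config.bh_method,
        )
        grids_nocov[g] = association.run_grid(
            cohort, g, with_covariates=False,
            volumes=config.volumes, metrics=config.metrics,
            alpha=config.alpha, cooks=config.cooks,
            cooks_rule=config.cooks_rule, bh_method=config.bh_method,
        )
        write_table(grids_cov[g], outdir / f"grid_{g}_covariates.csv")
        write_table(grids_nocov[g], outdir / f"grid_{g}_no_covariates.csv")
        mats[g] = heatmaps.beta_matrix(
            cohort, g, volumes=config.volumes, metrics=config.metrics,
            grid=grids_nocov[g],
        )
        mats[g].beta.to_csv(outdir / f"beta_matrix_{g}.csv")
    bundle["grids_covariates"] = grids_cov
    bundle["grids_no_covariates"] = grids_nocov
    bundle["beta_matrices"] = mats

    overlap = association.overlap_analysis(grids_cov, rule="p", alpha=config.alpha)
    bundle["overlap"] = overlap

    comparisons = {}
    render_set = {f"beta_{g}": m.beta for g, m in mats.items()}
    limits = {k: (-1.0, 1.0) for k in render_set}
    for a, b in itertools.combinations(mats.keys(), 2):
        mc = heatmaps.compare(
            mats[a], mats[b], exact_proportion=config.exact_proportion_test
        )
        comparisons[(a, b)] = mc
        render_set[f"valence_{a}_vs_{b}"] = mc.valence
        render_set[f"intensity_{a}_vs_{b}"] = mc.intensity
        render_set[f"agreement_{a}_vs_{b}"] = mc.agreement
        limits[f"valence_{a}_vs_{b}"] = (-1.0, 1.0)
        limits[f"intensity_{a}_vs_{b}"] = (0.0, 2.0)
        limits[f"agreement_{a}_vs_{b}"] = (-1.0, 1.0)
    heatmaps.render_heatmaps(render_set, outdir / "heatmaps", limits=limits)
    bundle["comparisons"] = comparisons
    comp_json = {
        f"{a}_vs_{b}": {
            "t_p": mc.t_p, "wilcoxon_p": mc.wilcoxon_p,
            "wilcoxon_median": mc.wilcoxon_median,
            "proportion_p": mc.proportion_p,
            "agree_fraction": mc.agree_fraction, "n_cells": mc.n_cells,
        }
        for (a, b), mc in comparisons.items()
    }
    (outdir / "heatmap_tests.json").write_text(json.dumps(comp_json, indent=2))

    valid = cohort[cohort["valid"].astype(bool)] if "valid" in cohort.columns else cohort
    sel_metrics = classify.select_features(valid, config.metrics, alpha=config.alpha)
    sel_volumes = classify.select_features(valid, config.volumes, alpha=config.alpha)
    write_table(sel_metrics, outdir / "selection_metrics.csv")
    write_table(sel_volumes, outdir / "selection_volumes.csv")
    bundle["selection_metrics"] = sel_metrics
    bundle["selection_volumes"] = sel_volumes

    knn_cfg = classify.KNNConfig(
        k=config.knn_k, refit_transform=config.knn_refit_transform
    )
    report = classify.run_combinations(
        cohort,
        sel_metrics.loc[sel_metrics["selected"], "feature"].tolist(),
        sel_volumes.loc[sel_volumes["selected"], "feature"].tolist(),
        demographics=DEMOGRAPHICS,
        config=knn_cfg,
    )
    write_table(report, outdir / "knn_report.csv")
    bundle["knn_report"] = report

    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_participants": int(len(participants)),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return bundle
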