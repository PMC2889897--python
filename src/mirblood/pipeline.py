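"""End-to-end pipeline: simulate -> preprocess -> markers -> structure ->
classification -> concordance, with a manifest recording seed and versions.
"""
from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import crossvalidate_signature, permutation_test
from .concordance import (
    ddct_fold_change,
    log_fold_correlation,
    per_set_fold_quotients,
    platform_correlation,
)
from .config import CvConfig, PipelineConfig, reseed
from .io import (
    write_annotation_csv,
    write_expression_tsv,
    write_json,
    write_marker_table,
)
from .markers import apply_marker_filters, build_marker_table, significance_sets
from .preprocess import preprocess
from .simulate import generate_cohort, generate_qpcr_panel, write_probe_tsv, write_truth_tsv
from .unsupervised import hierarchical_cluster, pca, select_top_variance, two_cut_fisher

log = logging.getLogger("mirblood")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage on a freshly simulated cohort and write all artifacts.

    Returns a summary dict mirroring the written report. All randomness
    derives from ``config.seed``; a repeated run with the same config writes
    an identical bundle.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "version": __version__}

    # -- simulate ----------------------------------------------------------
    sim_cfg = config.simulation
    if sim_cfg.seed != config.seed:
        sim_cfg = type(sim_cfg)(**{**asdict(sim_cfg), "seed": reseed(config.seed, 10)})
    log.info("simulating cohort: %d features x %d samples",
             sim_cfg.n_features, sim_cfg.n_control + sim_cfg.n_test + sim_cfg.n_validation)
    probe, ann, truth = generate_cohort(sim_cfg)
    write_probe_tsv(probe, out / "probe_level.tsv")
    write_annotation_csv(ann, out / "annotation.csv")
    write_truth_tsv(truth, out / "truth.tsv")

    # -- preprocess --------------------------------------------------------
    m = preprocess(probe)
    write_expression_tsv(m, out / "expression.tsv")

    # -- single-marker statistics -----------------------------------------
    table = build_marker_table(m, ann)
    _, venn = significance_sets(
        {"t": table["adj_t"], "wmw": table["adj_wmw"], "limma": table["adj_limma"]},
        alpha=config.filters.alpha,
    )
    markers = apply_marker_filters(table, config.filters)
    write_marker_table(markers, out / "marker_table.tsv")
    write_json(venn.to_dict(), out / "venn.json")
    planted = set(truth.planted_ids)
    recovered = len(planted & set(markers.index))
    summary["markers"] = {
        "n_significant_union": venn.union_total,
        "n_filtered": int(len(markers)),
        "n_planted_recovered": recovered,
        "n_false_positive": int(len(set(markers.index) - planted)),
    }
    log.info("markers: %d pass filters (%d/%d planted recovered)",
             len(markers), recovered, len(planted))

    # -- unsupervised structure -------------------------------------------
    top = select_top_variance(m, min(config.top_variance_k, m.shape[0]))
    tree = hierarchical_cluster(top)
    (out / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
    two_cut = two_cut_fisher(tree, ann)
    pca_result = pca(top)
    pca_result.scores.to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample_id")
    summary["unsupervised"] = {
        "fisher_p": two_cut.fisher_p,
        "contingency": two_cut.table.tolist(),
        "explained_fraction": pca_result.explained_fraction.tolist(),
    }
    write_json(summary["unsupervised"], out / "two_cut_fisher.json")
    log.info("two-cluster Fisher p = %.3g", two_cut.fisher_p)

    # -- classification ----------------------------------------------------
    cv_cfg = config.cv
    if cv_cfg.seed != config.seed:
        cv_cfg = CvConfig(**{**cv_cfg.__dict__, "seed": reseed(config.seed, 11)})
    cv = crossvalidate_signature(m, ann, cv_cfg)
    perm = permutation_test(m, ann, cv_cfg, n_permutations=config.n_permutations)
    rates = cv.rates_at_best()
    summary["classification"] = {
        "best_subset_size": cv.best_size,
        "accuracy": rates["accuracy"],
        "sensitivity": rates["sensitivity"],
        "specificity": rates["specificity"],
        "signature": list(cv.signature),
        "null_mean_accuracy": perm.mean_accuracy,
    }
    write_json(summary["classification"], out / "cv_result.json")
    cv.summary.to_csv(out / "cv_summary.tsv", sep="\t")
    perm.per_permutation.to_csv(out / "permutation_null.tsv", sep="\t", index=False)
    log.info("CV: accuracy %.3f at s=%d (null %.3f)",
             rates["accuracy"], cv.best_size, perm.mean_accuracy)

    # -- concordance -------------------------------------------------------
    controls = ann.loc[ann["group"] == "C", "sample_id"]
    test_ids = ann.loc[ann["group"] == "M", "sample_id"]
    val_ids = ann.loc[ann["group"] == "N", "sample_id"]
    fq_test = per_set_fold_quotients(m[list(test_ids)], m[list(controls)], label="test")
    fq_val = per_set_fold_quotients(m[list(val_ids)], m[list(controls)], label="validation")
    r_sets = log_fold_correlation(fq_test, fq_val)

    picked = list(truth.planted_ids[: config.qpcr_panel_size])
    panel = generate_qpcr_panel(
        truth, picked, n_per_group=config.qpcr_n_per_group,
        ct_sd=config.qpcr_ct_sd, seed=reseed(config.seed, 12),
    )
    qpcr_folds = ddct_fold_change(panel)
    case_med, ctrl_med = (
        m.loc[picked, list(test_ids)].median(axis=1),
        m.loc[picked, list(controls)].median(axis=1),
    )
    array_folds = case_med / ctrl_med
    r_platform = platform_correlation(qpcr_folds, array_folds)
    summary["concordance"] = {
        "test_validation_log_fold_r": r_sets,
        "qpcr_array_r": r_platform,
    }
    write_json(summary["concordance"], out / "concordance.json")
    log.info("concordance: test/validation r=%.3f, qPCR/array r=%.3f", r_sets, r_platform)

    manifest = {
        "seed": config.seed,
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": config.to_dict(),
    }
    write_json(manifest, out / "manifest.json")
    write_json(summary, out / "report.json")
    return summary
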