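"""End-to-end orchestration of the staged biomarker analysis.

``run_pipeline`` chains every stage — preprocessing, CV filtering,
per-phase differential expression, per-phase co-expression and networks,
enrichment, deviation scoring with permutation calibration, the
pathway-level ANOVA screen, and the RFE+SVM diagnostic model — and
returns a run summary dict mirroring every count a report would quote.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as clf_mod
from . import coexpression as coexpr
from . import network as net_mod
from . import pathway_scoring as scoring
from . import preprocess as prep
from . import stage_genes as sg
from .io_formats import (PHASES, GeneSet, RunConfig, phase_samples,
                         write_edges, write_expression, write_run_summary)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _sub_seed(seed: int | None, offset: int) -> int | None:
    if seed is None:
        return None
    return int(np.random.SeedSequence(seed).generate_state(offset + 1)[offset]
               % (2 ** 31))


def run_pipeline(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    collection: dict[str, GeneSet],
    config: RunConfig | None = None,
    *,
    raw_scale: bool = True,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full analysis and return the machine-readable summary.

    ``raw_scale=False`` declares the input already control-standardized
    (preprocessing is then skipped apart from validation).  When
    ``out_dir`` is given, every stage writes its tables there.
    """
    cfg = config or RunConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": cfg.to_dict(), "stages": {}}

    metadata = metadata.loc[[s for s in metadata.index
                             if s in expression.columns]]
    case_samples = (phase_samples(metadata, "early")
                    + phase_samples(metadata, "late"))

    # -- preprocessing -----------------------------------------------------
    if raw_scale:
        raw = expression
        norm = prep.preprocess_pipeline(raw, metadata, cfg.max_missing)
        # CV is computed on the raw intensity scale, where a small mean
        # signals a quiet gene; on the z-scale the ratio is uninformative
        cv_source = prep.impute_missing(
            prep.filter_missing(raw, cfg.max_missing)).loc[norm.data.index]
    else:
        if expression.isna().any().any():
            raise ValueError("pre-normalized input must have no missing cells")
        norm = prep.zscore_to_control(expression, metadata)
        cv_source = norm.data
    data = norm.data
    metadata = metadata.loc[[s for s in metadata.index if s in data.columns]]
    case_samples = [s for s in case_samples if s in data.columns]
    summary["stages"]["preprocess"] = {
        "n_genes": int(data.shape[0]),
        "n_samples": int(data.shape[1]),
        "imputed_before_zscore": True,
    }

    # -- CV filter + differential expression -------------------------------
    stats_table = sg.compute_cv(cv_source, case_samples)
    kept = sg.cv_filter(stats_table, cfg.cv_quantile)
    controls = phase_samples(metadata, "control")
    de_early = sg.differential_expression(
        data, phase_samples(metadata, "early"), controls, kept,
        method=cfg.de_method)
    de_late = sg.differential_expression(
        data, phase_samples(metadata, "late"), controls, kept,
        method=cfg.de_method)
    sets = sg.extract_stage_sets(de_early, de_late, cfg.de_p, cfg.de_lfc)
    summary["stages"]["stage_genes"] = {
        "cv_kept": len(kept), **sets.counts()}

    # -- co-expression -----------------------------------------------------
    specific_universe = sorted(set(sets.delta0) | set(sets.delta1))
    pair_tables: dict[str, pd.DataFrame] = {}
    table1: dict[str, dict[str, int]] = {}
    if len(specific_universe) >= 2:
        for ph in PHASES:
            corr = coexpr.pairwise_correlation(
                data, specific_universe, phase_samples(metadata, ph))
            pair_tables[ph] = coexpr.classify_pairs(corr, ph,
                                                    cfg.corr_threshold)
            table1[ph] = coexpr.pair_counts(pair_tables[ph])
        stable, stable_genes = coexpr.stable_pairs(pair_tables.values())
        table1["overlap"] = coexpr.pair_counts(
            stable.rename(columns={"class": "class"}))
    else:
        stable, stable_genes = pd.DataFrame(
            columns=["gene_a", "gene_b", "class"]), set()
    summary["stages"]["coexpression"] = {
        "pair_counts": table1,
        "stable_pairs": int(len(stable)),
        "stable_genes": len(stable_genes),
    }

    # -- networks ----------------------------------------------------------
    topology: dict[str, dict] = {}
    for ph, tab in pair_tables.items():
        g = net_mod.build_network(tab, ph, specific_universe)
        t = net_mod.topology_metrics(g)
        topology[ph] = {
            "n_nodes": t.n_nodes, "n_edges": t.n_edges,
            "avg_shortest_path": t.avg_shortest_path,
            "mean_degree": float(np.mean(list(t.degree.values()))),
            "mean_closeness": float(np.mean(list(t.closeness.values()))),
            "mean_clustering": float(np.mean(list(t.clustering.values()))),
        }
        if out is not None:
            write_edges(net_mod.network_edges(g), out / f"network_{ph}.edges.tsv")
    delta2_genes = sorted(sets.delta2)
    weights_map: dict[str, float] = {}
    if len(delta2_genes) >= 2:
        corr_all = coexpr.pairwise_correlation(data, delta2_genes,
                                               list(data.columns))
        nonspec_pairs = coexpr.classify_pairs(corr_all, "nonspecific",
                                              cfg.corr_threshold)
        nonspec = net_mod.build_network(nonspec_pairs, "nonspecific",
                                        delta2_genes)
        t = net_mod.topology_metrics(nonspec)
        topology["nonspecific"] = {
            "n_nodes": t.n_nodes, "n_edges": t.n_edges,
            "avg_shortest_path": t.avg_shortest_path,
            "mean_degree": float(np.mean(list(t.degree.values()))),
        }
        wdf = net_mod.degree_weights(nonspec, kept)
        weights_map = dict(wdf["weight"])
        if out is not None:
            write_edges(net_mod.network_edges(nonspec),
                        out / "network_nonspecific.edges.tsv")
            wdf.to_csv(out / "weights.tsv", sep="\t")
    summary["stages"]["network"] = topology

    # -- enrichment + deviation scoring ------------------------------------
    universe = set(kept)
    enrichment = scoring.fisher_enrichment(set(delta2_genes), collection,
                                           universe, cfg.enrich_p)
    enriched = list(enrichment.loc[enrichment["significant"], "pathway"])
    anova_p = scoring.gene_anova(data, metadata, kept)
    gene_z = {g: z for g, z in zip(
        anova_p.index,
        scoring.p_to_z(anova_p.to_numpy(),
                       np.array([weights_map.get(g, 0.5)
                                 for g in anova_p.index])))}
    pathway_members = {
        name: sorted(set(collection[name].genes) & set(delta2_genes))
        for name in enriched}
    pathway_members = {k: v for k, v in pathway_members.items() if v}
    scores = scoring.score_pathways(pathway_members, gene_z,
                                    n_perm=cfg.n_perm,
                                    seed=_sub_seed(cfg.seed, 1))
    profiles = scoring.sample_score_matrix(data, pathway_members, weights_map)
    screen = (scoring.pathway_anova(profiles, metadata, cfg.anova_p)
              if len(profiles) else
              pd.DataFrame(columns=["pathway", "p_value", "significant"]))
    summary["stages"]["pathways"] = {
        "enriched": len(enriched),
        "scored": int(len(scores)),
        "anova_significant": int(screen["significant"].sum())
        if len(screen) else 0,
    }

    # -- diagnostic model --------------------------------------------------
    clf_summary: dict = {"scheme": cfg.label_scheme}
    try:
        labels = clf_mod.make_labels(metadata, cfg.label_scheme)
    except ValueError as exc:
        logger.warning("classifier skipped: %s", exc)
        labels = None
        clf_summary["skipped"] = str(exc)
    if labels is not None and delta2_genes:
        X = data.loc[delta2_genes, labels.index].T
        trace = clf_mod.rfe_select(X, labels.to_numpy(),
                                   folds=cfg.cv_folds,
                                   seed=_sub_seed(cfg.seed, 2))
        model = clf_mod.train_svm(
            X, labels.to_numpy(), trace.selected,
            {"C": cfg.svm_costs, "gamma": cfg.svm_gammas},
            folds=cfg.cv_folds, seed=_sub_seed(cfg.seed, 3))
        report = clf_mod.evaluate_cv(
            X, labels.to_numpy(), model.features, C=model.C,
            gamma=model.gamma, folds=cfg.cv_folds,
            seed=_sub_seed(cfg.seed, 4))
        clf_summary.update({
            "n_candidates": len(delta2_genes),
            "n_selected": len(trace.selected),
            "selected": trace.selected,
            "cv_accuracy": report.accuracy,
            "auroc": report.auroc,
            "C": model.C, "gamma": str(model.gamma),
        })
        if out is not None:
            trace.to_frame().to_csv(out / "selection_trace.tsv", sep="\t",
                                    index=False)
    summary["stages"]["classifier"] = clf_summary

    # -- exports -----------------------------------------------------------
    if out is not None:
        write_expression(data, out / "normalized.tsv")
        pd.DataFrame({"control_mean": norm.control_mean,
                      "control_sd": norm.control_sd}) \
            .to_csv(out / "control_parameters.tsv", sep="\t",
                    index_label="gene")
        de_early.to_csv(out / "de_early.tsv", sep="\t", index_label="gene")
        de_late.to_csv(out / "de_late.tsv", sep="\t", index_label="gene")
        stable.to_csv(out / "stable_pairs.tsv", sep="\t", index=False)
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        scores.to_csv(out / "pathway_scores.tsv", sep="\t", index=False)
        if len(profiles):
            profiles.to_csv(out / "sample_scores.tsv", sep="\t",
                            index_label="pathway")
        screen.to_csv(out / "pathway_anova.tsv", sep="\t", index=False)
        write_run_summary(summary, out / "run_summary.json")
    return summary
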