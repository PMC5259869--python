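"""End-to-end orchestration: preprocess -> networks -> tune -> detect -> merge -> enrich.

``run_pipeline`` executes the whole study workflow on a pair of expression
TSVs plus a known-interaction table, writing every intermediate artifact
and a machine-readable manifest into the output directory. All randomness
flows from the single configured seed, fanned out deterministically to the
stages; rerunning with the same inputs and config reproduces the outputs
byte for byte.
"""

from __future__ import annotations

import logging
from importlib.metadata import version as pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import sklearn

from . import io, netbuild, preprocess, tuning
from .config import PipelineConfig
from .enrichment import annotate_cancer_mirnas, set_enrichment
from .spectral import IntegratedNetwork, detect_modules, merge_module_runs

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _prepare_expression(
    path: Path, probe_map_path: Path | None, top_n, min_var, impute_first: bool
) -> pd.DataFrame:
    expr = io.read_expression(path)
    if impute_first:
        expr = preprocess.impute_missing(expr)
    if probe_map_path is not None:
        expr = preprocess.collapse_duplicates(expr, io.read_probe_map(probe_map_path))
    expr = preprocess.impute_missing(expr)
    if top_n is not None or min_var is not None:
        expr = preprocess.filter_by_variance(expr, top_n=top_n, min_var=min_var)
    return expr


def run_pipeline(
    config: PipelineConfig,
    gene_expr: str | Path,
    mirna_expr: str | Path,
    known_pairs: str | Path,
    out_dir: str | Path,
    gene_probe_map: str | Path | None = None,
    clusters: str | Path | None = None,
    cancer_mirnas: str | Path | None = None,
) -> Path:
    """Run the full detection workflow; returns the output directory.

    Stages: expression cleaning and variance filtering, sample alignment,
    within-type network construction at the configured cutoff, gene-miRNA
    cutoff tuning by rank AUC (skipped when ``config.gm_tau`` is fixed),
    module detection for every K in the grid, cross-K merging, and (when
    reference files are given) hypergeometric enrichment. Any stage failure
    halts the run; artifacts written so far stay in place.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in (gene_expr, mirna_expr, known_pairs, gene_probe_map, clusters, cancer_mirnas):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"input not found: {p}")

    seeds = config.spawn_seeds(4)
    tune_seed, detect_seed = seeds[0], seeds[1]

    logger.info("stage preprocess")
    expr_g = _prepare_expression(
        Path(gene_expr), Path(gene_probe_map) if gene_probe_map else None,
        config.gene_top_n, config.gene_min_var, config.impute_first,
    )
    expr_m = _prepare_expression(
        Path(mirna_expr), None, config.mirna_top_n, None, config.impute_first
    )
    expr_g, expr_m = preprocess.align_samples(expr_g, expr_m)
    io.write_expression(expr_g, out / "gene_expression.clean.tsv")
    io.write_expression(expr_m, out / "mirna_expression.clean.tsv")

    logger.info("stage netbuild")
    pairs = io.read_interaction_pairs(known_pairs)
    corr_g = netbuild.correlation_matrix(expr_g)
    corr_m = netbuild.correlation_matrix(expr_m)
    corr_gm = netbuild.correlation_matrix(expr_g, expr_m)
    gene_ids, mirna_ids = list(expr_g.index), list(expr_m.index)
    a_g = netbuild.threshold_adjacency(corr_g, config.coexpr_tau, gene_ids)
    a_m = netbuild.threshold_adjacency(corr_m, config.coexpr_tau, mirna_ids)
    fit_g = _try_fit(a_g, config.coexpr_tau)
    fit_m = _try_fit(a_m, config.coexpr_tau)
    io.write_edge_list(a_g, out / "gene_network.edges.tsv")
    io.write_edge_list(a_m, out / "mirna_network.edges.tsv")

    logger.info("stage tune")
    if config.gm_tau is not None:
        gm_tau = config.gm_tau
        auc_table = None
    else:
        gm_tau, _, auc_table = tuning.select_gm_threshold(
            expr_g, expr_m, pairs,
            tau_grid=config.gm_tau_grid, k_grid=config.k_grid,
            lam=config.lam, coexpr_tau=config.coexpr_tau,
            seed=tune_seed, subsample=config.auc_subsample,
        )
        auc_table.to_csv(out / "auc_table.tsv", sep="\t", index=False)
    logger.info("gene-miRNA threshold: %.3g", gm_tau)

    coexpr_c = netbuild.threshold_cross_adjacency(corr_gm, gm_tau, gene_ids, mirna_ids)
    c = netbuild.combine_cross_network(coexpr_c, pairs)
    io.write_edge_list(c, out / "cross_network.edges.tsv")
    net = IntegratedNetwork(a_g=a_g, a_m=a_m, c=c, lam=config.lam)

    logger.info("stage detect")
    runs = []
    max_k = max(2, net.n_nodes - 1)
    for k in config.k_grid:
        if k > max_k:
            logger.warning("K=%d exceeds usable node count; capped to %d", k, max_k)
            k = max_k
        _, modules = detect_modules(
            net, k, seed=detect_seed,
            normalize_rows=config.normalize_embedding,
            n_init=config.kmeans_restarts,
        )
        runs.append(modules)

    logger.info("stage merge")
    merged = merge_module_runs(
        runs, overlap_frac=config.merge_overlap, metric=config.overlap_metric
    )
    io.write_modules_json(merged, out / "modules.json")
    io.write_modules_tsv(merged, out / "modules.tsv")
    logger.info("%d merged co-modules", len(merged))

    enrichment_summary: dict = {}
    if clusters is not None:
        logger.info("stage enrich")
        cluster_sets = io.read_mirna_clusters(clusters)
        background = set(mirna_ids)
        module_sets = {
            f"module_{i + 1}": m.mirnas for i, m in enumerate(merged)
        }
        by_cluster = set_enrichment(
            module_sets, cluster_sets, background,
            min_overlap=config.min_overlap, alpha=config.alpha,
        )
        by_module = set_enrichment(
            cluster_sets, module_sets, background,
            min_overlap=config.min_overlap, alpha=config.alpha,
        )
        _write_enrichment(by_cluster, out / "modules_enriched_by_clusters.tsv")
        _write_enrichment(by_module, out / "clusters_enriched_by_modules.tsv")
        enrichment_summary = {
            "modules_enriched_by_clusters": sum(r.significant for r in by_cluster),
            "clusters_enriched_by_modules": sum(r.significant for r in by_module),
        }
    if cancer_mirnas is not None:
        cancer = io.read_node_list(cancer_mirnas)
        global_res, table = annotate_cancer_mirnas(merged, cancer, set(mirna_ids))
        table.to_csv(out / "cancer_mirna_table.tsv", sep="\t", index=False)
        enrichment_summary["cancer_mirna_global_p"] = global_res.p_raw

    manifest = {
        "config": config.to_dict(),
        "inputs": {
            "gene_expr": str(gene_expr),
            "mirna_expr": str(mirna_expr),
            "known_pairs": str(known_pairs),
            "gene_probe_map": str(gene_probe_map) if gene_probe_map else None,
            "clusters": str(clusters) if clusters else None,
            "cancer_mirnas": str(cancer_mirnas) if cancer_mirnas else None,
        },
        "derived": {
            "n_genes": len(gene_ids),
            "n_mirnas": len(mirna_ids),
            "n_samples": expr_g.shape[1],
            "gene_net_avg_degree": float(a_g.degrees.mean()),
            "mirna_net_avg_degree": float(a_m.degrees.mean()),
            "gene_net_scale_free_r2": fit_g,
            "mirna_net_scale_free_r2": fit_m,
            "n_known_pairs_in_network": int((c.provenance >= netbuild.PROV_KNOWN).sum()),
            "gm_tau": gm_tau,
            "n_modules": len(merged),
            **enrichment_summary,
        },
        "stage_seeds": {"tune": tune_seed, "detect": detect_seed},
        "versions": {
            "comodule": pkg_version("comodule"),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    io.write_manifest(manifest, out / "manifest.json")
    return out


def _try_fit(adj, tau) -> float | None:
    try:
        return netbuild.scale_free_fit(adj, threshold=tau).r_squared
    except ValueError:
        return None


def _write_enrichment(results, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "module_id\tset_id\toverlap\tmodule_size\tset_size\t"
            "background_size\tp_raw\tp_adj\tsignificant\n"
        )
        for r in results:
            fh.write(
                f"{r.module_id}\t{r.set_id}\t{r.overlap}\t{r.module_size}\t"
                f"{r.set_size}\t{r.background_size}\t{r.p_raw:.6g}\t"
                f"{r.p_adj:.6g}\t{int(r.significant)}\n"
            )
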