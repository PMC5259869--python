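"""Threshold tuning by rank AUC over known gene-miRNA interactions.

The gene-miRNA coexpression cutoff cannot be picked by scale-free topology
(the cross network is bipartite), so it is chosen by how well the method's
same-module scores rank the experimentally known interactions: for a
candidate cutoff, build C from the thresholded gene-miRNA coexpression
alone, embed the integrated network for each K in a grid, score every
gene-miRNA pair with the row-normalized eigenvector similarity, and compute
the Mann-Whitney AUC

    AUC = (sum_i R_i - q(q+1)/2) / (p q)

where R_i are the (ascending, tie-averaged) ranks of the q known interacting
pairs among all scored pairs and p counts the non-interacting pairs. The
cutoff with the highest K-averaged AUC wins; the coupling weight lambda can
be co-tuned by coordinate ascent on the same statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import netbuild
from .netbuild import threshold_adjacency, threshold_cross_adjacency
from .spectral import IntegratedNetwork, comodule_scores, connected_components, embed_network

logger = logging.getLogger(__name__)

__all__ = [
    "AUCResult",
    "auc_rank",
    "mean_auc_over_K",
    "select_gm_threshold",
    "alternate_lambda_threshold",
]


@dataclass
class AUCResult:
    """Rank-AUC of known interactions, optionally averaged over a K grid."""

    auc: float
    q: int
    p: int
    k_values: list = field(default_factory=list)
    per_k_auc: list = field(default_factory=list)


def auc_rank(scores, is_known) -> AUCResult:
    """Mann-Whitney rank AUC of the known pairs' scores.

    ``scores`` are the same-module scores of every gene-miRNA pair under
    consideration, ``is_known`` flags the known interacting pairs. Ranks are
    ascending (rank 1 = smallest score) with ties receiving average ranks,
    making the statistic exactly the normalized Mann-Whitney U: the fraction
    of (known, non-known) pairs in which the known pair scores higher, ties
    counting one half.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    known = np.asarray(is_known).astype(bool).ravel()
    if scores.shape != known.shape:
        raise ValueError("scores and is_known must have equal length")
    q = int(known.sum())
    p = int((~known).sum())
    if q == 0 or p == 0:
        raise ValueError(
            f"AUC undefined: need >=1 known and >=1 non-known pair (q={q}, p={p})"
        )
    ranks = rankdata(scores, method="average")
    auc = (ranks[known].sum() - q * (q + 1) / 2.0) / (p * q)
    return AUCResult(auc=float(auc), q=q, p=p)


def _known_mask(net: IntegratedNetwork, known_pairs) -> np.ndarray:
    gi = {g: i for i, g in enumerate(net.a_g.node_ids)}
    mi = {m: j for j, m in enumerate(net.a_m.node_ids)}
    w = np.zeros((net.n_genes, net.n_mirnas), dtype=bool)
    dropped = 0
    for g, m in known_pairs:
        i, j = gi.get(g), mi.get(m)
        if i is None or j is None:
            dropped += 1
            continue
        w[i, j] = True
    if dropped:
        logger.info("%d known pair(s) outside the network ignored", dropped)
    return w


def mean_auc_over_K(
    net: IntegratedNetwork,
    known_pairs,
    k_grid,
    seed: int = 0,
    subsample: int | None = None,
) -> AUCResult:
    """Average rank AUC of the known interactions over a grid of module counts.

    For each K the integrated network is spectrally embedded, every
    gene-miRNA pair is scored with the row-normalized eigenvector similarity,
    and the AUC of the known pairs is computed. Pairs are restricted to nodes
    lying in a non-trivial connected component (isolated nodes carry no
    embedding signal); the excluded count is logged. ``subsample`` caps the
    number of non-known pairs (seeded), as a scale escape hatch; off by
    default.
    """
    k_grid = [int(k) for k in k_grid]
    if not k_grid:
        raise ValueError("K grid must be non-empty")
    if max(k_grid) > net.n_nodes:
        raise ValueError("K exceeds the node count")
    w = _known_mask(net, known_pairs)
    _, comp_labels = connected_components(net)
    sizes = np.bincount(comp_labels)
    in_comp = sizes[comp_labels] >= 2
    universe = np.outer(in_comp[: net.n_genes], in_comp[net.n_genes :])
    n_excluded = int(w.size - universe.sum())
    if n_excluded:
        logger.info(
            "%d gene-miRNA pair(s) with an isolated endpoint excluded from AUC",
            n_excluded,
        )
    labels = w[universe]
    keep = slice(None)
    if subsample is not None and (~labels).sum() > subsample:
        rng = np.random.default_rng(seed)
        neg = np.flatnonzero(~labels)
        keep = np.sort(
            np.concatenate([np.flatnonzero(labels), rng.choice(neg, subsample, False)])
        )
    per_k = []
    for k in k_grid:
        emb = embed_network(net, k)
        s = comodule_scores(emb)
        pair_scores = s[: net.n_genes, net.n_genes :][universe]
        res = auc_rank(pair_scores[keep], labels[keep])
        per_k.append(res.auc)
        logger.info("K=%d: AUC=%.4f (q=%d, p=%d)", k, res.auc, res.q, res.p)
    return AUCResult(
        auc=float(np.mean(per_k)),
        q=res.q,
        p=res.p,
        k_values=k_grid,
        per_k_auc=per_k,
    )


def _networks_for_tau(
    corr_g, corr_m, corr_gm, gene_ids, mirna_ids, coexpr_tau, tau, lam
) -> IntegratedNetwork:
    a_g = threshold_adjacency(corr_g, coexpr_tau, gene_ids)
    a_m = threshold_adjacency(corr_m, coexpr_tau, mirna_ids)
    c = threshold_cross_adjacency(corr_gm, tau, gene_ids, mirna_ids)
    return IntegratedNetwork(a_g=a_g, a_m=a_m, c=c, lam=lam)


def select_gm_threshold(
    expr_g: pd.DataFrame,
    expr_m: pd.DataFrame,
    known_pairs,
    tau_grid,
    k_grid,
    lam: float = 1.0,
    coexpr_tau: float = 0.6,
    seed: int = 0,
    subsample: int | None = None,
) -> tuple[float, AUCResult, pd.DataFrame]:
    """Grid search of the gene-miRNA coexpression cutoff by mean rank AUC.

    For each tau in ``tau_grid`` the cross network C is rebuilt from the
    tau-thresholded gene-miRNA coexpression (known interactions are *not*
    injected here, to keep the evaluation honest), and the K-averaged AUC of
    the known pairs is computed. Returns the winning tau (ties broken toward
    the smaller tau), its AUCResult, and the full (tau, K, auc) table.
    """
    taus = sorted(float(t) for t in tau_grid)
    if not taus:
        raise ValueError("tau grid must be non-empty")
    corr_g = netbuild.correlation_matrix(expr_g)
    corr_m = netbuild.correlation_matrix(expr_m)
    corr_gm = netbuild.correlation_matrix(expr_g, expr_m)
    gene_ids = list(expr_g.index)
    mirna_ids = list(expr_m.index)
    rows = []
    best: tuple[float, AUCResult] | None = None
    for tau in taus:
        net = _networks_for_tau(
            corr_g, corr_m, corr_gm, gene_ids, mirna_ids, coexpr_tau, tau, lam
        )
        res = mean_auc_over_K(net, known_pairs, k_grid, seed=seed, subsample=subsample)
        for k, a in zip(res.k_values, res.per_k_auc):
            rows.append({"tau": tau, "K": k, "auc": a})
        logger.info("tau=%.3g: mean AUC=%.4f", tau, res.auc)
        if best is None or res.auc > best[1].auc:  # strict: ties keep smaller tau
            best = (tau, res)
    table = pd.DataFrame(rows, columns=["tau", "K", "auc"])
    return best[0], best[1], table


def alternate_lambda_threshold(
    expr_g: pd.DataFrame,
    expr_m: pd.DataFrame,
    known_pairs,
    tau_grid,
    lambda_grid,
    k_grid,
    max_rounds: int = 5,
    coexpr_tau: float = 0.6,
    seed: int = 0,
    subsample: int | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Coordinate ascent over (tau, lambda) on the K-averaged AUC.

    Alternately fixes lambda and picks the best tau, then fixes tau and picks
    the best lambda, until neither changes or ``max_rounds`` is reached. Ties
    go to the smaller grid value; the accepted-step mean AUC sequence is
    non-decreasing by construction. Returns the selected (tau, lambda) and a
    history table of accepted steps.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    taus = sorted(float(t) for t in tau_grid)
    lams = sorted(float(v) for v in lambda_grid)
    if not taus or not lams:
        raise ValueError("grids must be non-empty")
    corr_g = netbuild.correlation_matrix(expr_g)
    corr_m = netbuild.correlation_matrix(expr_m)
    corr_gm = netbuild.correlation_matrix(expr_g, expr_m)
    gene_ids = list(expr_g.index)
    mirna_ids = list(expr_m.index)

    def score(tau: float, lam: float) -> float:
        net = _networks_for_tau(
            corr_g, corr_m, corr_gm, gene_ids, mirna_ids, coexpr_tau, tau, lam
        )
        return mean_auc_over_K(net, known_pairs, k_grid, seed=seed, subsample=subsample).auc

    lam = lams[0]
    tau = taus[0]
    history = []
    best_auc = -np.inf
    for rnd in range(1, max_rounds + 1):
        new_tau = tau
        for t in taus:
            a = score(t, lam)
            if a > best_auc:
                best_auc, new_tau = a, t
        new_lam = lam
        for v in lams:
            a = score(new_tau, v)
            if a > best_auc:
                best_auc, new_lam = a, v
        history.append({"round": rnd, "tau": new_tau, "lambda": new_lam, "auc": best_auc})
        if new_tau == tau and new_lam == lam and rnd > 1:
            break
        if (new_tau, new_lam) == (tau, lam):
            tau, lam = new_tau, new_lam
            break
        tau, lam = new_tau, new_lam
    return tau, lam, pd.DataFrame(history, columns=["round", "tau", "lambda", "auc"])
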