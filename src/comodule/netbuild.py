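"""Coexpression-network construction.

Binary networks are built by hard thresholding: two features are joined by an
edge when the absolute Pearson correlation of their expression profiles is
strictly greater than a cutoff tau. Within-type networks (gene-gene,
miRNA-miRNA) are symmetric with a zero diagonal; the gene-miRNA cross network
is a rectangular binary matrix that may additionally absorb experimentally
known interactions. The within-type cutoff is chosen so that the degree
distribution is approximately scale free, judged by the R^2 of an ordinary
least-squares fit of log10 f(d) on log10 d, where f(d) is the number of nodes
with degree exactly d.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "Adjacency",
    "CrossAdjacency",
    "ScaleFreeFit",
    "correlation_matrix",
    "threshold_adjacency",
    "threshold_cross_adjacency",
    "degree_frequencies",
    "scale_free_fit",
    "scale_free_fit_from_frequencies",
    "select_scale_free_threshold",
    "combine_cross_network",
]

# provenance codes for cross edges
PROV_NONE, PROV_COEXPR, PROV_KNOWN, PROV_BOTH = 0, 1, 2, 3


@dataclass
class Adjacency:
    """Binary symmetric within-type network with a zero diagonal."""

    node_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.matrix)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if a.shape[0] != len(self.node_ids):
            raise ValueError("adjacency size does not match node id list")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency matrix must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        self.matrix = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def degrees(self) -> np.ndarray:
        return self.matrix.sum(axis=1).astype(np.int64)

    @property
    def n_edges(self) -> int:
        return int(self.matrix.sum()) // 2


@dataclass
class CrossAdjacency:
    """Binary gene x miRNA connection matrix with per-edge provenance.

    ``provenance`` uses codes 0 (no edge), 1 (coexpression), 2 (known
    interaction), 3 (both).
    """

    gene_ids: list[str]
    mirna_ids: list[str]
    matrix: np.ndarray
    provenance: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.matrix)
        if c.shape != (len(self.gene_ids), len(self.mirna_ids)):
            raise ValueError("cross matrix shape does not match id lists")
        if not np.isin(c, (0, 1)).all():
            raise ValueError("cross matrix entries must be 0/1")
        self.matrix = c.astype(np.uint8)
        if self.provenance is None:
            self.provenance = self.matrix.astype(np.int8) * PROV_COEXPR
        else:
            p = np.asarray(self.provenance, dtype=np.int8)
            if p.shape != c.shape:
                raise ValueError("provenance shape does not match cross matrix")
            if np.any((p > 0) != (c > 0)):
                raise ValueError("provenance must mark exactly the edges")
            self.provenance = p

    @property
    def n_edges(self) -> int:
        return int(self.matrix.sum())


@dataclass
class ScaleFreeFit:
    """OLS fit of log10 degree frequency against log10 degree."""

    threshold: float
    slope: float
    r_squared: float
    n_points: int
    fallback: bool = False


def correlation_matrix(
    x, y=None, *, return_constant_mask: bool = False
) -> np.ndarray:
    """Pearson correlations between the rows of ``x`` and the rows of ``y``.

    With ``y`` omitted the correlation of ``x`` with itself is returned.
    Inputs may be DataFrames (features x samples) or 2-d arrays; samples must
    already be aligned column-for-column. Constant rows have undefined
    correlation: their entries are set to 0 and the rows are reported in the
    log (and returned when ``return_constant_mask`` is set).
    """
    a = np.asarray(x, dtype=float)
    self_corr = y is None
    b = a if self_corr else np.asarray(y, dtype=float)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("expression inputs must be 2-dimensional")
    if a.shape[1] != b.shape[1]:
        raise ValueError("x and y must have the same number of samples")
    if a.shape[1] < 3:
        raise ValueError("need at least 3 samples for Pearson correlation")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing values present; impute before correlating")

    def standardize(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        centered = m - m.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        const = norms == 0
        norms[const] = 1.0
        return centered / norms[:, None], const

    za, const_a = standardize(a)
    zb, const_b = (za, const_a) if self_corr else standardize(b)
    corr = np.clip(za @ zb.T, -1.0, 1.0)
    corr[const_a, :] = 0.0
    corr[:, const_b] = 0.0
    n_const = int(const_a.sum() + (0 if self_corr else const_b.sum()))
    if n_const:
        logger.warning(
            "%d constant feature row(s): correlations set to 0", n_const
        )
    if self_corr:
        np.fill_diagonal(corr, np.where(const_a, 0.0, 1.0))
        corr = (corr + corr.T) / 2.0
    if return_constant_mask:
        return corr, const_a if self_corr else (const_a, const_b)
    return corr


def _check_tau(tau: float) -> float:
    tau = float(tau)
    if not 0.0 <= tau < 1.0:
        raise ValueError(f"threshold tau must lie in [0, 1), got {tau}")
    return tau


def threshold_adjacency(corr: np.ndarray, tau: float, node_ids: list[str]) -> Adjacency:
    """Within-type network: edge iff |r| > tau (strictly); zero diagonal."""
    tau = _check_tau(tau)
    corr = np.asarray(corr, dtype=float)
    if corr.shape[0] != corr.shape[1]:
        raise ValueError("within-type correlation matrix must be square")
    a = (np.abs(corr) > tau).astype(np.uint8)
    a = np.maximum(a, a.T)  # guard against asymmetric float input
    np.fill_diagonal(a, 0)
    return Adjacency(node_ids=list(node_ids), matrix=a)


def threshold_cross_adjacency(
    corr: np.ndarray, tau: float, gene_ids: list[str], mirna_ids: list[str]
) -> CrossAdjacency:
    """Gene-miRNA coexpression network: C(i,j)=1 iff |r_ij| > tau."""
    tau = _check_tau(tau)
    c = (np.abs(np.asarray(corr, dtype=float)) > tau).astype(np.uint8)
    return CrossAdjacency(gene_ids=list(gene_ids), mirna_ids=list(mirna_ids), matrix=c)


def degree_frequencies(adj: Adjacency) -> tuple[np.ndarray, np.ndarray]:
    """Distinct positive degrees d and their raw node counts f(d)."""
    deg = adj.degrees
    deg = deg[deg >= 1]
    d, f = np.unique(deg, return_counts=True)
    return d.astype(float), f.astype(float)


def scale_free_fit_from_frequencies(
    d: np.ndarray, f: np.ndarray, threshold: float = math.nan
) -> ScaleFreeFit:
    """OLS of log10 f(d) on log10 d over degrees d >= 1 with f(d) > 0."""
    d = np.asarray(d, dtype=float)
    f = np.asarray(f, dtype=float)
    keep = (d >= 1) & (f > 0)
    d, f = d[keep], f[keep]
    if len(np.unique(d)) < 3:
        raise ValueError(
            f"scale-free fit needs >=3 distinct positive degrees, got {len(d)}"
        )
    res = stats.linregress(np.log10(d), np.log10(f))
    return ScaleFreeFit(
        threshold=float(threshold),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
        n_points=int(len(d)),
    )


def scale_free_fit(adj: Adjacency, threshold: float = math.nan) -> ScaleFreeFit:
    """Fit the degree distribution of a network to a power law on log-log axes."""
    d, f = degree_frequencies(adj)
    return scale_free_fit_from_frequencies(d, f, threshold=threshold)


def select_scale_free_threshold(
    corr: np.ndarray,
    tau_grid,
    min_r2: float = 0.8,
    node_ids: list[str] | None = None,
) -> ScaleFreeFit:
    """Pick the smallest tau whose thresholded network fits a power law.

    Scans ``tau_grid`` in increasing order and returns the fit for the
    smallest tau with R^2 >= ``min_r2``. If no tau qualifies the fit with
    maximal R^2 is returned with ``fallback=True``. Thresholds at which the
    fit is undefined (fewer than 3 distinct degrees) are skipped.
    """
    taus = sorted(_check_tau(t) for t in tau_grid)
    if not taus:
        raise ValueError("tau grid must be non-empty")
    corr = np.asarray(corr, dtype=float)
    if node_ids is None:
        node_ids = [str(i) for i in range(corr.shape[0])]
    fits: list[ScaleFreeFit] = []
    for tau in taus:
        try:
            fit = scale_free_fit(threshold_adjacency(corr, tau, node_ids), threshold=tau)
        except ValueError as exc:
            logger.info("tau=%.3g: scale-free fit undefined (%s)", tau, exc)
            continue
        avg_deg = threshold_adjacency(corr, tau, node_ids).degrees.mean()
        logger.info(
            "tau=%.3g: slope=%.3f R2=%.3f avg_degree=%.2f",
            tau, fit.slope, fit.r_squared, avg_deg,
        )
        fits.append(fit)
        if fit.r_squared >= min_r2:
            return fit
    if not fits:
        raise ValueError("scale-free fit undefined at every threshold in the grid")
    best = max(fits, key=lambda ft: ft.r_squared)
    best.fallback = True
    logger.warning(
        "no threshold reached R2 >= %.3g; falling back to tau=%.3g (R2=%.3f)",
        min_r2, best.threshold, best.r_squared,
    )
    return best


def combine_cross_network(coexpr: CrossAdjacency, known_pairs) -> CrossAdjacency:
    """Union of the gene-miRNA coexpression network and known interactions.

    ``known_pairs`` is an iterable of (gene_id, mirna_id). Pairs whose ids do
    not resolve against the network's id lists are dropped, with a count
    logged. Edge provenance distinguishes coexpression-only, known-only and
    both.
    """
    gi = {g: i for i, g in enumerate(coexpr.gene_ids)}
    mi = {m: j for j, m in enumerate(coexpr.mirna_ids)}
    known = np.zeros_like(coexpr.matrix)
    dropped = 0
    for g, m in known_pairs:
        i, j = gi.get(g), mi.get(m)
        if i is None or j is None:
            dropped += 1
            continue
        known[i, j] = 1
    if dropped:
        logger.info("dropped %d known pair(s) not resolvable in the network", dropped)
    logger.info(
        "known interactions among network nodes: %d", int(known.sum())
    )
    combined = np.maximum(coexpr.matrix, known)
    prov = (coexpr.matrix.astype(np.int8) * PROV_COEXPR) | (
        known.astype(np.int8) * PROV_KNOWN
    )
    return CrossAdjacency(
        gene_ids=list(coexpr.gene_ids),
        mirna_ids=list(coexpr.mirna_ids),
        matrix=combined,
        provenance=prov,
    )
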