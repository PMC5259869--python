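"""Spectral co-module detection in an integrated gene-miRNA network.

The integrated network stacks a gene coexpression network A_g, a miRNA
coexpression network A_m and a gene-miRNA connection matrix C (genes first,
then miRNAs). Module quality of a hard assignment (S_g, S_m) into K modules
is the sum of within-type Rayleigh terms built on 2A - D plus a coupling
term::

    Psi = sum_k s_gk'(2A_g-D_g)s_gk / s_gk's_gk
        + sum_k s_mk'(2A_m-D_m)s_mk / s_mk's_mk
        + lambda * sum_k s_gk' C s_mk / (||s_gk|| ||s_mk||)

where s_gk is the k-th indicator column. Maximizing Psi over hard
assignments is combinatorial; relaxing the normalized indicators to an
orthonormal frame turns the problem into trace maximization of
L = diag(2A_g-D_g, 2A_m-D_m) + lambda * [[0, C], [C', 0]], solved by the top-K
eigenvectors. Hard modules are then recovered by k-means on the (row
normalized) eigenvector embedding, filtered down to clusters that contain
both node types and all three edge types, and de-duplicated across runs with
different K by merging heavily overlapping modules.

lambda trades within-network modularity against cross-network connectivity;
the study default is 1.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, sparse
from scipy.sparse import csgraph
from sklearn.cluster import KMeans

from .netbuild import Adjacency, CrossAdjacency

logger = logging.getLogger(__name__)

__all__ = [
    "IntegratedNetwork",
    "Embedding",
    "ModuleAssignment",
    "Module",
    "build_integrated_matrix",
    "connected_components",
    "spectral_embedding",
    "embed_network",
    "cluster_embedding",
    "detect_modules",
    "discrete_objective",
    "normalized_discrete_objective",
    "bruteforce_max_normalized_objective",
    "comodule_scores",
    "filter_candidate_modules",
    "merge_module_runs",
]


@dataclass
class IntegratedNetwork:
    """A_g, A_m and C plus the coupling weight lambda (genes first, then miRNAs)."""

    a_g: Adjacency
    a_m: Adjacency
    c: CrossAdjacency
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.c.matrix.shape != (self.a_g.n_nodes, self.a_m.n_nodes):
            raise ValueError("cross matrix shape does not match A_g / A_m")
        if list(self.c.gene_ids) != list(self.a_g.node_ids):
            raise ValueError("cross gene ids disagree with A_g node ids")
        if list(self.c.mirna_ids) != list(self.a_m.node_ids):
            raise ValueError("cross miRNA ids disagree with A_m node ids")

    @property
    def n_genes(self) -> int:
        return self.a_g.n_nodes

    @property
    def n_mirnas(self) -> int:
        return self.a_m.n_nodes

    @property
    def n_nodes(self) -> int:
        return self.n_genes + self.n_mirnas

    @property
    def node_ids(self) -> list[str]:
        return list(self.a_g.node_ids) + list(self.a_m.node_ids)

    def union_adjacency(self) -> sparse.csr_matrix:
        """Binary adjacency of the union graph on all N_g + N_m nodes."""
        ng, nm = self.n_genes, self.n_mirnas
        u = np.zeros((ng + nm, ng + nm), dtype=np.uint8)
        u[:ng, :ng] = self.a_g.matrix
        u[ng:, ng:] = self.a_m.matrix
        u[:ng, ng:] = self.c.matrix
        u[ng:, :ng] = self.c.matrix.T
        return sparse.csr_matrix(u)


@dataclass
class Embedding:
    """Columns of T are orthonormal eigenvectors; eigenvalues non-increasing."""

    T: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.T.shape[0]

    @property
    def k(self) -> int:
        return self.T.shape[1]


@dataclass
class ModuleAssignment:
    """One cluster label per node; labels run from 0 to n_clusters - 1."""

    gene_labels: np.ndarray
    mirna_labels: np.ndarray
    n_clusters: int
    seed: int = 0

    def __post_init__(self) -> None:
        self.gene_labels = np.asarray(self.gene_labels, dtype=np.int64)
        self.mirna_labels = np.asarray(self.mirna_labels, dtype=np.int64)
        labels = np.concatenate([self.gene_labels, self.mirna_labels])
        if labels.size and (labels.min() < 0 or labels.max() >= self.n_clusters):
            raise ValueError("labels out of range for n_clusters")

    @property
    def s_g(self) -> np.ndarray:
        s = np.zeros((len(self.gene_labels), self.n_clusters), dtype=np.uint8)
        s[np.arange(len(self.gene_labels)), self.gene_labels] = 1
        return s

    @property
    def s_m(self) -> np.ndarray:
        s = np.zeros((len(self.mirna_labels), self.n_clusters), dtype=np.uint8)
        s[np.arange(len(self.mirna_labels)), self.mirna_labels] = 1
        return s


@dataclass
class Module:
    """A gene set + miRNA set with provenance and a validity flag."""

    genes: set
    mirnas: set
    source_runs: list = field(default_factory=list)
    valid: bool = False
    edge_counts: dict = field(default_factory=dict)

    @property
    def nodes(self) -> frozenset:
        return frozenset(("g", g) for g in self.genes) | frozenset(
            ("m", m) for m in self.mirnas
        )


def _modularity_matrix(adj: Adjacency) -> np.ndarray:
    a = adj.matrix.astype(float)
    return 2.0 * a - np.diag(adj.degrees.astype(float))


def connected_components(net: IntegratedNetwork) -> tuple[int, np.ndarray]:
    """Connected components of the union graph (count, per-node labels)."""
    return csgraph.connected_components(net.union_adjacency(), directed=False)


def build_integrated_matrix(
    net: IntegratedNetwork, check_connected: bool = True
) -> np.ndarray:
    """Assemble L = diag(2A_g - D_g, 2A_m - D_m) + lambda * [[0,C],[C',0]].

    The relaxation's norm constant is absorbed into the orthonormality of the
    eigenvectors, so L itself carries no extra factor. By default a
    disconnected union graph is refused with advice to run per connected
    component (``detect_modules`` and ``embed_network`` do exactly that).
    """
    if check_connected:
        n_comp, _ = connected_components(net)
        if n_comp > 1:
            raise ValueError(
                f"integrated network has {n_comp} connected components; "
                "run the method per component (detect_modules does this) "
                "or pass check_connected=False"
            )
    ng, nm = net.n_genes, net.n_mirnas
    L = np.zeros((ng + nm, ng + nm), dtype=float)
    L[:ng, :ng] = _modularity_matrix(net.a_g)
    L[ng:, ng:] = _modularity_matrix(net.a_m)
    c = net.c.matrix.astype(float)
    L[:ng, ng:] = net.lam * c
    L[ng:, :ng] = net.lam * c.T
    return L


def _canonicalize_signs(v: np.ndarray) -> np.ndarray:
    """Flip eigenvector signs so each column's largest-|entry| is positive."""
    idx = np.argmax(np.abs(v), axis=0)
    signs = np.sign(v[idx, np.arange(v.shape[1])])
    signs[signs == 0] = 1.0
    return v * signs


def spectral_embedding(L: np.ndarray, k: int) -> Embedding:
    """Orthonormal eigenvectors of the K algebraically largest eigenvalues."""
    L = np.asarray(L, dtype=float)
    n = L.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"K={k} out of range for {n} nodes")
    try:
        w, v = linalg.eigh(L, subset_by_index=[n - k, n - 1])
    except linalg.LinAlgError as exc:  # pragma: no cover - solver failure
        raise RuntimeError(f"eigensolver failed on {n}x{n} matrix: {exc}") from exc
    order = np.argsort(w)[::-1]
    return Embedding(T=_canonicalize_signs(v[:, order]), eigenvalues=w[order])


def _component_plan(
    net: IntegratedNetwork, k: int
) -> tuple[list[np.ndarray], list[int], np.ndarray]:
    """Split nodes into components and allocate embedding columns.

    Components of size >= 2 are clusterable and receive at least one of the K
    columns each, allocated proportionally to component size (largest
    remainder, capped at component size). Isolated nodes are returned
    separately and end up in a single shared unassigned cluster.
    """
    _, comp = connected_components(net)
    components = [np.flatnonzero(comp == c) for c in range(comp.max() + 1)]
    clusterable = [ix for ix in components if len(ix) >= 2]
    isolated = np.concatenate(
        [ix for ix in components if len(ix) < 2] or [np.array([], dtype=int)]
    )
    if not clusterable:
        raise ValueError("integrated network has no component with an edge")
    total = sum(len(ix) for ix in clusterable)
    shares = [k * len(ix) / total for ix in clusterable]
    alloc = [min(len(ix), max(1, int(s))) for ix, s in zip(clusterable, shares)]
    # distribute any remaining columns by largest fractional remainder
    remaining = k - sum(alloc)
    if remaining > 0:
        order = np.argsort([-(s - int(s)) for s in shares], kind="stable")
        for idx in itertools.cycle(order):
            if remaining <= 0:
                break
            if alloc[idx] < len(clusterable[idx]):
                alloc[idx] += 1
                remaining -= 1
    if sum(alloc) != k:
        logger.info(
            "K adjusted from %d to %d to give every connected component "
            "at least one cluster", k, sum(alloc),
        )
    return clusterable, alloc, isolated


def embed_network(net: IntegratedNetwork, k: int) -> Embedding:
    """Spectral embedding of a possibly disconnected integrated network.

    Connected networks get the plain top-K embedding of L. Otherwise each
    clusterable component is embedded on its own block of L with its share of
    the K columns, and the per-component eigenvectors are stacked into one
    block-orthonormal T; isolated nodes get all-zero rows.
    """
    n_comp, _ = connected_components(net)
    L = build_integrated_matrix(net, check_connected=False)
    if n_comp == 1:
        return spectral_embedding(L, k)
    components, alloc, _ = _component_plan(net, k)
    k_total = sum(alloc)
    T = np.zeros((net.n_nodes, k_total), dtype=float)
    vals = np.zeros(k_total, dtype=float)
    col = 0
    for ix, kc in zip(components, alloc):
        sub = spectral_embedding(L[np.ix_(ix, ix)], kc)
        T[ix, col : col + kc] = sub.T
        vals[col : col + kc] = sub.eigenvalues
        col += kc
    order = np.argsort(vals)[::-1]
    return Embedding(T=T[:, order], eigenvalues=vals[order])


def _row_normalize(t: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(t, axis=1)
    zero = norms == 0
    if zero.any():
        logger.info("%d all-zero embedding row(s) left at zero", int(zero.sum()))
    norms[zero] = 1.0
    return t / norms[:, None]


def cluster_embedding(
    emb: Embedding,
    k: int,
    seed: int,
    normalize_rows: bool = True,
    n_init: int = 50,
) -> np.ndarray:
    """K-means labels for the embedding rows (row-normalized by default).

    Deterministic given the seed: k-means++ seeding with a fixed number of
    restarts and tolerance.
    """
    if emb.n_nodes < k:
        raise ValueError(f"cannot form {k} clusters from {emb.n_nodes} rows")
    rows = _row_normalize(emb.T) if normalize_rows else emb.T
    km = KMeans(
        n_clusters=k, n_init=n_init, random_state=int(seed), tol=1e-6
    ).fit(rows)
    return km.labels_.astype(np.int64)


def detect_modules(
    net: IntegratedNetwork,
    k: int,
    seed: int,
    normalize_rows: bool = True,
    n_init: int = 50,
) -> tuple[ModuleAssignment, list[Module]]:
    """Full detection pass: embed, cluster per component, filter clusters.

    Each clusterable connected component is embedded and k-means clustered
    with its allocation of the K clusters; isolated nodes are pooled into one
    trailing unassigned cluster (it never survives filtering). Returns the
    hard assignment and the candidate modules with validity flags.
    """
    L = build_integrated_matrix(net, check_connected=False)
    components, alloc, isolated = _component_plan(net, k)
    labels = np.full(net.n_nodes, -1, dtype=np.int64)
    next_label = 0
    for ix, kc in zip(components, alloc):
        sub = spectral_embedding(L[np.ix_(ix, ix)], kc)
        sub_labels = cluster_embedding(
            sub, kc, seed=seed, normalize_rows=normalize_rows, n_init=n_init
        )
        labels[ix] = next_label + sub_labels
        next_label += kc
    n_clusters = next_label
    if isolated.size:
        labels[isolated] = n_clusters
        n_clusters += 1
    assign = ModuleAssignment(
        gene_labels=labels[: net.n_genes],
        mirna_labels=labels[net.n_genes :],
        n_clusters=n_clusters,
        seed=seed,
    )
    return assign, filter_candidate_modules(assign, net)


def discrete_objective(assign: ModuleAssignment, net: IntegratedNetwork) -> float:
    """The hard-assignment objective Psi = Psi_g + Psi_m + lambda * cross.

    Per-type terms are Rayleigh quotients on 2A - D; the cross term for each
    module is s_g' C s_m / (||s_g|| ||s_m||). A module that is empty on one
    side contributes 0 to the cross term (the limit of the normalized term).
    """
    sg = assign.s_g.astype(float)
    sm = assign.s_m.astype(float)
    if sg.shape[0] != net.n_genes or sm.shape[0] != net.n_mirnas:
        raise ValueError("assignment dimensions do not match the network")
    lg = _modularity_matrix(net.a_g)
    lm = _modularity_matrix(net.a_m)
    c = net.c.matrix.astype(float)
    ng = sg.sum(axis=0)
    nm = sm.sum(axis=0)
    qg = np.einsum("ik,ij,jk->k", sg, lg, sg)
    qm = np.einsum("ik,ij,jk->k", sm, lm, sm)
    qc = np.einsum("ik,ij,jk->k", sg, c, sm)
    with np.errstate(invalid="ignore", divide="ignore"):
        psi_g = np.where(ng > 0, qg / np.where(ng > 0, ng, 1), 0.0)
        psi_m = np.where(nm > 0, qm / np.where(nm > 0, nm, 1), 0.0)
        both = (ng > 0) & (nm > 0)
        cross = np.where(both, qc / np.sqrt(np.where(both, ng * nm, 1)), 0.0)
    return float(psi_g.sum() + psi_m.sum() + net.lam * cross.sum())


def _batch_normalized_objective(
    lg: np.ndarray, lm: np.ndarray, c: np.ndarray, lam: float, labels: np.ndarray, k: int
) -> np.ndarray:
    """Normalized objective for a batch of labelings (rows of ``labels``)."""
    ngenes = lg.shape[0]
    total = np.zeros(labels.shape[0], dtype=float)
    for kk in range(k):
        x = labels == kk
        xg = x[:, :ngenes].astype(float)
        xm = x[:, ngenes:].astype(float)
        sg = xg.sum(axis=1)
        sm = xm.sum(axis=1)
        qg = np.einsum("mi,ij,mj->m", xg, lg, xg)
        qm = np.einsum("mi,ij,mj->m", xm, lm, xm)
        qc = np.einsum("mi,ij,mj->m", xg, c, xm)
        val = np.zeros_like(total)
        both = (sg > 0) & (sm > 0)
        gonly = (sg > 0) & ~both
        monly = (sm > 0) & ~both
        val[both] = 0.5 * (qg[both] / sg[both] + qm[both] / sm[both]) + lam * qc[
            both
        ] / np.sqrt(sg[both] * sm[both])
        val[gonly] = qg[gonly] / sg[gonly]
        val[monly] = qm[monly] / sm[monly]
        total += val
    return total


def normalized_discrete_objective(
    assign: ModuleAssignment, net: IntegratedNetwork
) -> float:
    """Objective of the discrete point mapped into the relaxed feasible set.

    Each module's indicator pair becomes the unit vector
    u_k = [s_g/||s_g||; s_m/||s_m||]/sqrt(2) (one-sided modules use the
    non-empty normalized side alone), so the value is
    sum_k u_k' L u_k = (Psi_g + Psi_m)/2 + lambda * cross for two-sided
    assignments. Since the u_k are orthonormal, this never exceeds the
    relaxed optimum Tr(T'LT) at the spectral embedding.
    """
    labels = np.concatenate([assign.gene_labels, assign.mirna_labels])[None, :]
    return float(
        _batch_normalized_objective(
            _modularity_matrix(net.a_g),
            _modularity_matrix(net.a_m),
            net.c.matrix.astype(float),
            net.lam,
            labels,
            assign.n_clusters,
        )[0]
    )


def bruteforce_max_normalized_objective(
    net: IntegratedNetwork, k: int, chunk: int = 65536
) -> float:
    """Exact maximum of the normalized discrete objective by full enumeration.

    Enumerates all K^N assignments (vectorized, in chunks), keeping those in
    which every one of the K modules is non-empty: an assignment with an
    empty module has no normalized counterpart in the relaxed feasible set
    (its indicator column cannot be scaled to unit norm), so only surjective
    assignments are dominated by the spectral optimum. Feasible for small
    networks only; serves as the combinatorial side of the relaxation-bound
    check.
    """
    n = net.n_nodes
    m = k**n
    if m > 5_000_000:
        raise ValueError(f"enumeration of {m} assignments is too large")
    lg = _modularity_matrix(net.a_g)
    lm = _modularity_matrix(net.a_m)
    c = net.c.matrix.astype(float)
    powers = k ** np.arange(n)
    best = -np.inf
    for start in range(0, m, chunk):
        codes = np.arange(start, min(start + chunk, m))[:, None]
        labels = (codes // powers[None, :]) % k
        surjective = np.ones(labels.shape[0], dtype=bool)
        for kk in range(k):
            surjective &= (labels == kk).any(axis=1)
        if not surjective.any():
            continue
        vals = _batch_normalized_objective(lg, lm, c, net.lam, labels[surjective], k)
        best = max(best, float(vals.max()))
    return best


def comodule_scores(emb_or_t) -> np.ndarray:
    """Pairwise same-module scores S = T_rownorm @ T_rownorm'.

    Rows of T are scaled to unit norm (all-zero rows stay zero and are
    logged); the i,j entry then measures how likely nodes i and j share a
    module. S is symmetric with unit diagonal on non-degenerate rows and
    entries in [-1, 1].
    """
    t = emb_or_t.T if isinstance(emb_or_t, Embedding) else np.asarray(emb_or_t, float)
    tn = _row_normalize(t)
    s = np.clip(tn @ tn.T, -1.0, 1.0)
    nonzero = np.linalg.norm(t, axis=1) > 0
    diag = np.where(nonzero, 1.0, 0.0)
    np.fill_diagonal(s, diag)
    return (s + s.T) / 2.0


def filter_candidate_modules(
    assign: ModuleAssignment, net: IntegratedNetwork
) -> list[Module]:
    """Mark clusters that qualify as co-modules.

    A cluster is a valid module when, within the cluster, there is at least
    one gene, one miRNA, one gene-gene edge, one miRNA-miRNA edge and one
    gene-miRNA edge. All clusters are returned, invalid ones flagged.
    """
    gene_ids = np.asarray(net.a_g.node_ids, dtype=object)
    mirna_ids = np.asarray(net.a_m.node_ids, dtype=object)
    ag, am, c = net.a_g.matrix, net.a_m.matrix, net.c.matrix
    modules: list[Module] = []
    for k in range(assign.n_clusters):
        gix = np.flatnonzero(assign.gene_labels == k)
        mix = np.flatnonzero(assign.mirna_labels == k)
        gg = int(ag[np.ix_(gix, gix)].sum()) // 2
        mm = int(am[np.ix_(mix, mix)].sum()) // 2
        gm = int(c[np.ix_(gix, mix)].sum())
        valid = len(gix) >= 1 and len(mix) >= 1 and gg >= 1 and mm >= 1 and gm >= 1
        modules.append(
            Module(
                genes=set(gene_ids[gix]),
                mirnas=set(mirna_ids[mix]),
                source_runs=[(assign.n_clusters, k)],
                valid=valid,
                edge_counts={"gene_gene": gg, "mirna_mirna": mm, "gene_mirna": gm},
            )
        )
    logger.info(
        "%d of %d clusters qualify as co-modules",
        sum(m.valid for m in modules), len(modules),
    )
    return modules


def _overlap_fraction(a: Module, b: Module, metric: str) -> float:
    na, nb = a.nodes, b.nodes
    inter = len(na & nb)
    if metric == "min":
        denom = min(len(na), len(nb))
    elif metric == "jaccard":
        denom = len(na | nb)
    else:
        raise ValueError(f"unknown overlap metric {metric!r}")
    return inter / denom if denom else 0.0


def _module_sort_key(m: Module):
    return min(m.nodes) if m.nodes else ("", "")


def merge_module_runs(
    runs: list[list[Module]],
    overlap_frac: float = 0.9,
    metric: str = "min",
    valid_only: bool = True,
) -> list[Module]:
    """Merge modules from multiple K-runs that overlap more than ``overlap_frac``.

    The overlap percentage of two modules is |intersection| / min(|A|, |B|)
    over their combined gene+miRNA node sets (Jaccard available via
    ``metric``). Any pair strictly above ``overlap_frac`` is replaced by its
    union, iterated to a fixed point; the rule is therefore idempotent.
    Output is ordered by each module's smallest contained node id.
    """
    if not 0.0 < overlap_frac <= 1.0:
        raise ValueError("overlap_frac must lie in (0, 1]")
    pool = [
        Module(
            genes=set(m.genes),
            mirnas=set(m.mirnas),
            source_runs=list(m.source_runs),
            valid=m.valid,
            edge_counts=dict(m.edge_counts),
        )
        for run in runs
        for m in run
        if m.valid or not valid_only
    ]
    merged = True
    while merged:
        merged = False
        pool.sort(key=_module_sort_key)
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                if _overlap_fraction(pool[i], pool[j], metric) > overlap_frac:
                    a, b = pool[i], pool[j]
                    union = Module(
                        genes=a.genes | b.genes,
                        mirnas=a.mirnas | b.mirnas,
                        source_runs=a.source_runs + b.source_runs,
                        valid=a.valid or b.valid,
                    )
                    pool = [m for p, m in enumerate(pool) if p not in (i, j)]
                    pool.append(union)
                    merged = True
                    break
            if merged:
                break
    pool.sort(key=_module_sort_key)
    return pool
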