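"""Synthetic planted-module data with the structure the method assumes.

The generator emulates what the detection model expects of real paired
expression data: per module, genes and miRNAs load on a shared latent factor
across samples (giving block-wise gene-gene, miRNA-miRNA and gene-miRNA
coexpression), background features are independent noise, and "known"
interactions are sparse and concentrated within modules. Everything is
reproducible from a single seed. A second generator produces graphs with
heavy-tailed (preferential attachment) or Poisson-like (uniform random)
degree distributions for exercising the scale-free fit.

For module members the expression is ``loading * factor + N(0, noise_sd)``,
so the expected within-module correlation is loading^2/(loading^2 +
noise_sd^2) (about 0.74 at the defaults). Background features are
unit-variance noise so that variance filtering is not a trivial separator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .netbuild import Adjacency

__all__ = [
    "PlantedParams",
    "PlantedDataset",
    "generate_planted_dataset",
    "generate_degree_test_graphs",
    "write_dataset",
]


@dataclass(frozen=True)
class PlantedParams:
    """Generator settings; the defaults define the standard study conditions."""

    n_modules: int = 6
    genes_per_module: int = 30
    mirnas_per_module: int = 5
    n_background_genes: int = 50
    n_background_mirnas: int = 20
    n_samples: int = 200
    loading: float = 0.85
    noise_sd: float = 0.5
    known_within_rate: float = 0.3
    known_background_rate: float = 0.005
    seed: int = 11

    def __post_init__(self) -> None:
        for name in ("n_modules", "genes_per_module", "mirnas_per_module", "n_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_background_genes", "n_background_mirnas"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.loading <= 1.0:
            raise ValueError("loading must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("known_within_rate", "known_background_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class PlantedDataset:
    """Paired expression matrices with ground-truth module labels."""

    expr_g: pd.DataFrame
    expr_m: pd.DataFrame
    known_pairs: set
    true_gene_labels: np.ndarray  # module index per gene, 0 = background
    true_mirna_labels: np.ndarray
    params: PlantedParams

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expr_g.index)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.expr_m.index)


def generate_planted_dataset(params: PlantedParams | None = None, **overrides) -> PlantedDataset:
    """Draw one planted dataset; bitwise reproducible from the seed."""
    if params is None:
        params = PlantedParams(**overrides)
    elif overrides:
        raise TypeError("pass either a PlantedParams or keyword overrides, not both")
    p = params
    rng = np.random.default_rng(p.seed)

    n_genes = p.n_modules * p.genes_per_module + p.n_background_genes
    n_mirnas = p.n_modules * p.mirnas_per_module + p.n_background_mirnas
    gene_labels = np.concatenate(
        [
            np.repeat(np.arange(1, p.n_modules + 1), p.genes_per_module),
            np.zeros(p.n_background_genes, dtype=int),
        ]
    )
    mirna_labels = np.concatenate(
        [
            np.repeat(np.arange(1, p.n_modules + 1), p.mirnas_per_module),
            np.zeros(p.n_background_mirnas, dtype=int),
        ]
    )

    factors = rng.standard_normal((p.n_modules, p.n_samples))
    expr_g = np.empty((n_genes, p.n_samples))
    expr_m = np.empty((n_mirnas, p.n_samples))
    for arr, labels in ((expr_g, gene_labels), (expr_m, mirna_labels)):
        member = labels > 0
        arr[member] = p.loading * factors[labels[member] - 1] + rng.normal(
            0.0, p.noise_sd, size=(int(member.sum()), p.n_samples)
        )
        arr[~member] = rng.standard_normal((int((~member).sum()), p.n_samples))

    gene_ids = [f"g{i + 1:04d}" for i in range(n_genes)]
    mirna_ids = [f"mir{j + 1:04d}" for j in range(n_mirnas)]
    sample_ids = [f"s{t + 1:03d}" for t in range(p.n_samples)]

    same_module = (gene_labels[:, None] == mirna_labels[None, :]) & (
        gene_labels[:, None] > 0
    )
    rates = np.where(same_module, p.known_within_rate, p.known_background_rate)
    drawn = rng.random((n_genes, n_mirnas)) < rates
    known_pairs = {
        (gene_ids[i], mirna_ids[j]) for i, j in zip(*np.nonzero(drawn))
    }

    return PlantedDataset(
        expr_g=pd.DataFrame(expr_g, index=pd.Index(gene_ids, name="feature_id"), columns=sample_ids),
        expr_m=pd.DataFrame(expr_m, index=pd.Index(mirna_ids, name="feature_id"), columns=sample_ids),
        known_pairs=known_pairs,
        true_gene_labels=gene_labels,
        true_mirna_labels=mirna_labels,
        params=p,
    )


def generate_degree_test_graphs(
    kind: str, n: int, param: int | float, seed: int
) -> Adjacency:
    """Reproducible graphs for exercising the scale-free topology fit.

    ``kind="preferential-attachment"`` grows a Barabasi-Albert graph with
    ``param`` edges per new node (heavy-tailed degrees); ``kind="uniform-
    random"`` draws a G(n, M) graph with mean degree ``param`` (Poisson-like
    degrees, a poor power-law fit).
    """
    if n < 10:
        raise ValueError("need n >= 10 nodes")
    if kind == "preferential-attachment":
        g = nx.barabasi_albert_graph(n, int(param), seed=int(seed))
    elif kind == "uniform-random":
        m_edges = int(round(n * float(param) / 2.0))
        g = nx.gnm_random_graph(n, m_edges, seed=int(seed))
    else:
        raise ValueError(f"unknown graph kind {kind!r}")
    a = nx.to_numpy_array(g, nodelist=range(n), dtype=np.uint8)
    return Adjacency(node_ids=[f"n{i}" for i in range(n)], matrix=a)


def write_dataset(ds: PlantedDataset, out_dir: str | Path) -> dict:
    """Write the dataset as plain TSVs; returns the path map.

    Files: gene/miRNA expression, known interaction pairs, a cluster table
    assigning each planted module's miRNAs to one cluster, and the ground
    truth labels.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr_g": out / "gene_expression.tsv",
        "expr_m": out / "mirna_expression.tsv",
        "known_pairs": out / "known_pairs.tsv",
        "clusters": out / "mirna_clusters.tsv",
        "labels": out / "true_labels.tsv",
        "params": out / "generator_params.tsv",
    }
    ds.expr_g.to_csv(paths["expr_g"], sep="\t", na_rep="NA")
    ds.expr_m.to_csv(paths["expr_m"], sep="\t", na_rep="NA")
    with open(paths["known_pairs"], "w") as fh:
        fh.write("gene_id\tmirna_id\n")
        for g, m in sorted(ds.known_pairs):
            fh.write(f"{g}\t{m}\n")
    with open(paths["clusters"], "w") as fh:
        fh.write("cluster_id\tmirna_id\n")
        for mid, lab in zip(ds.mirna_ids, ds.true_mirna_labels):
            if lab > 0:
                fh.write(f"cluster_{lab}\t{mid}\n")
    with open(paths["labels"], "w") as fh:
        fh.write("node_id\tnode_type\tmodule\n")
        for gid, lab in zip(ds.gene_ids, ds.true_gene_labels):
            fh.write(f"{gid}\tgene\t{lab}\n")
        for mid, lab in zip(ds.mirna_ids, ds.true_mirna_labels):
            fh.write(f"{mid}\tmirna\t{lab}\n")
    with open(paths["params"], "w") as fh:
        fh.write("param\tvalue\n")
        for key, val in asdict(ds.params).items():
            fh.write(f"{key}\t{val}\n")
    return {k: str(v) for k, v in paths.items()}
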