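"""Readers and writers for the pipeline's external formats.

All tabular formats are TSV; annotation collections use GMT; networks export
as edge lists or GraphML; module lists and run manifests are JSON. Every
writer's output round-trips through the matching reader.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .netbuild import Adjacency, CrossAdjacency
from .spectral import Module

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_probe_map",
    "read_interaction_pairs",
    "read_gmt",
    "read_mirna_clusters",
    "read_node_list",
    "write_modules_json",
    "read_modules_json",
    "write_modules_tsv",
    "write_edge_list",
    "write_graphml",
    "write_manifest",
]

_MISSING = {"", "NA"}


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample expression TSV.

    First column holds feature ids, the header row holds sample ids; empty
    fields and "NA" parse as missing. Ragged rows and duplicate ids raise
    with the offending line/id.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip("\r\n") != ""]
    if len(lines) < 2:
        raise ValueError(f"{path}: expected a header row and at least one feature row")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dup = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample id(s) {dup[:5]}")
    feature_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ValueError(
                f"{path}:{lineno}: ragged row ({len(fields)} fields, "
                f"expected {len(header)})"
            )
        fid = fields[0]
        if fid in seen:
            raise ValueError(f"{path}:{lineno}: duplicate feature id {fid!r}")
        seen.add(fid)
        feature_ids.append(fid)
        rows.append(
            [np.nan if f in _MISSING else float(f) for f in fields[1:]]
        )
    return pd.DataFrame(
        np.asarray(rows, dtype=float),
        index=pd.Index(feature_ids, name=header[0] or "feature_id"),
        columns=sample_ids,
    )


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(
        Path(path), sep="\t", na_rep="NA",
        index_label=expr.index.name or "feature_id",
    )


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (probe_id, feature_id) -> dict."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and fields[0].lower() in {"probe", "probe_id"}:
                continue
            mapping[fields[0]] = fields[1]
    if not mapping:
        raise ValueError(f"{path}: empty probe map")
    return mapping


_PAIR_HEADER_TOKENS = {
    "gene", "gene_id", "genes", "target", "target_gene", "mrna",
    "mirna", "mirna_id", "mir", "mirnas",
}


def read_interaction_pairs(
    path: str | Path, has_header: bool | None = None
) -> set[tuple[str, str]]:
    """Read known (gene, miRNA) interaction pairs from a two-column TSV.

    Duplicated pairs are collapsed with the count logged. With
    ``has_header=None`` the first row is treated as a header when its fields
    look like column names (e.g. "gene_id", "mirna"); pass True/False to
    override.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty interaction file")
    first = lines[0].split("\t")
    if has_header is None:
        has_header = any(f.strip().lower() in _PAIR_HEADER_TOKENS for f in first[:2])
    for lineno, line in enumerate(lines, start=1):
        if lineno == 1 and has_header:
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected >=2 columns")
        pairs.append((fields[0], fields[1]))
    unique = set(pairs)
    n_dup = len(pairs) - len(unique)
    if n_dup:
        logger.info("%s: %d duplicate pair(s) collapsed", path, n_dup)
    logger.info("%s: %d interaction pair(s)", path, len(unique))
    return unique


def read_gmt(path: str | Path) -> dict[str, set]:
    """GMT annotation collection: name <TAB> description <TAB> member..."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT rows need name, description, >=1 member"
                )
            sets[fields[0]] = set(fields[2:])
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return sets


def read_mirna_clusters(path: str | Path) -> dict[str, set]:
    """Cluster TSV (cluster_id, mirna_id[, chromosome, start, end]) -> dict."""
    clusters: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 columns")
            if lineno == 1 and fields[0].lower() in {"cluster", "cluster_id"}:
                continue
            clusters.setdefault(fields[0], set()).add(fields[1])
    if not clusters:
        raise ValueError(f"{path}: empty cluster file")
    return clusters


def read_node_list(path: str | Path) -> set[str]:
    """One id per line (a cancer-miRNA list, for example)."""
    with open(path) as fh:
        ids = {ln.strip() for ln in fh if ln.strip()}
    if not ids:
        raise ValueError(f"{path}: empty id list")
    return ids


def _module_record(idx: int, m: Module) -> dict:
    return {
        "id": f"module_{idx + 1}",
        "genes": sorted(m.genes),
        "mirnas": sorted(m.mirnas),
        "source_runs": [[int(k), int(c)] for k, c in m.source_runs],
        "valid": bool(m.valid),
        "edge_counts": {k: int(v) for k, v in sorted(m.edge_counts.items())},
    }


def write_modules_json(modules: list[Module], path: str | Path) -> None:
    records = [_module_record(i, m) for i, m in enumerate(modules)]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_modules_json(path: str | Path) -> list[Module]:
    with open(path) as fh:
        records = json.load(fh)
    return [
        Module(
            genes=set(r["genes"]),
            mirnas=set(r["mirnas"]),
            source_runs=[tuple(sr) for sr in r.get("source_runs", [])],
            valid=bool(r.get("valid", True)),
            edge_counts=dict(r.get("edge_counts", {})),
        )
        for r in records
    ]


def write_modules_tsv(modules: list[Module], path: str | Path) -> None:
    """Long format: module_id, node_id, node_type."""
    with open(path, "w") as fh:
        fh.write("module_id\tnode_id\tnode_type\n")
        for i, m in enumerate(modules):
            mid = f"module_{i + 1}"
            for g in sorted(m.genes):
                fh.write(f"{mid}\t{g}\tgene\n")
            for mr in sorted(m.mirnas):
                fh.write(f"{mid}\t{mr}\tmirna\n")


def _as_graph(adj: Adjacency | CrossAdjacency) -> nx.Graph:
    g = nx.Graph()
    if isinstance(adj, Adjacency):
        g.add_nodes_from(adj.node_ids)
        ii, jj = np.nonzero(np.triu(adj.matrix))
        g.add_edges_from(
            (adj.node_ids[i], adj.node_ids[j]) for i, j in zip(ii, jj)
        )
    else:
        g.add_nodes_from(adj.gene_ids, node_type="gene")
        g.add_nodes_from(adj.mirna_ids, node_type="mirna")
        ii, jj = np.nonzero(adj.matrix)
        g.add_edges_from(
            (adj.gene_ids[i], adj.mirna_ids[j]) for i, j in zip(ii, jj)
        )
    return g


def write_edge_list(adj: Adjacency | CrossAdjacency, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in _as_graph(adj).edges():
            fh.write(f"{u}\t{v}\n")


def write_graphml(adj: Adjacency | CrossAdjacency, path: str | Path) -> None:
    nx.write_graphml(_as_graph(adj), str(path))


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
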