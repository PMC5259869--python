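"""Pipeline configuration with validated defaults.

Defaults mirror the study settings: keep the 3200 most variable genes,
within-type coexpression cutoff 0.60, gene-miRNA cutoff tuned over
0.1..0.9 (step 0.1) by rank AUC averaged over K = 100..200 (step 10),
coupling weight lambda = 1, modules merged above 90% overlap, enrichment
with minimum overlap 3 at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = ["PipelineConfig", "parse_grid"]


def parse_grid(spec) -> list[float]:
    """Parse a grid given as a list or as an inclusive "start:stop:step" string."""
    if isinstance(spec, str):
        parts = spec.split(":")
        if len(parts) != 3:
            raise ValueError(f"grid string must be start:stop:step, got {spec!r}")
        start, stop, step = (float(p) for p in parts)
        if step <= 0:
            raise ValueError("grid step must be positive")
        n = int(round((stop - start) / step))
        grid = [round(start + i * step, 10) for i in range(n + 1)]
        return [g for g in grid if g <= stop + 1e-9]
    return [float(v) for v in spec]


@dataclass
class PipelineConfig:
    """All pipeline tunables; unknown keys in a config file are rejected."""

    gene_top_n: int | None = 3200        # most-variable genes kept
    gene_min_var: float | None = None    # alternative to gene_top_n
    mirna_top_n: int | None = None       # miRNAs are kept unfiltered by default
    coexpr_tau: float = 0.6              # within-type |r| cutoff
    gm_tau: float | None = None          # fixed gene-miRNA cutoff; None = tune
    gm_tau_grid: list = field(default_factory=lambda: parse_grid("0.1:0.9:0.1"))
    k_grid: list = field(default_factory=lambda: parse_grid("100:200:10"))
    lam: float = 1.0                     # coupling weight lambda
    merge_overlap: float = 0.9           # strict overlap fraction for merging
    overlap_metric: str = "min"          # "min" or "jaccard"
    min_overlap: int = 3                 # enrichment minimum overlap
    alpha: float = 0.05                  # Bonferroni-adjusted significance level
    min_r2: float = 0.8                  # scale-free acceptance R^2
    seed: int = 0
    normalize_embedding: bool = True     # k-means on row-normalized T
    kmeans_restarts: int = 50
    impute_first: bool = False           # impute before probe collapsing
    auc_subsample: int | None = None     # cap on non-known AUC pairs (off)

    def __post_init__(self) -> None:
        self.gm_tau_grid = parse_grid(self.gm_tau_grid)
        self.k_grid = [int(k) for k in parse_grid(self.k_grid)]
        if (self.gene_top_n is None) == (self.gene_min_var is None):
            raise ValueError("set exactly one of gene_top_n / gene_min_var")
        if not 0.0 <= self.coexpr_tau < 1.0:
            raise ValueError("coexpr_tau must lie in [0, 1)")
        for tau in self.gm_tau_grid + ([self.gm_tau] if self.gm_tau is not None else []):
            if not 0.0 <= tau < 1.0:
                raise ValueError(f"gene-miRNA tau {tau} outside [0, 1)")
        if not self.k_grid or min(self.k_grid) < 1:
            raise ValueError("k_grid must contain positive module counts")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if not 0.0 < self.merge_overlap <= 1.0:
            raise ValueError("merge_overlap must lie in (0, 1]")
        if self.overlap_metric not in ("min", "jaccard"):
            raise ValueError("overlap_metric must be 'min' or 'jaccard'")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0.0 <= self.min_r2 <= 1.0:
            raise ValueError("min_r2 must lie in [0, 1]")
        if self.kmeans_restarts < 1:
            raise ValueError("kmeans_restarts must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        allowed = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - allowed)
        if unknown:
            raise ValueError(f"{path}: unknown config key(s): {unknown}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def spawn_seeds(self, n: int) -> list[int]:
        """Fan the top-level seed out into per-stage seeds (all < 2**31)."""
        ss = np.random.SeedSequence(self.seed)
        return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
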