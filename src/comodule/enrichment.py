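"""Hypergeometric set enrichment with Bonferroni correction.

Modules are tested against reference collections (miRNA genomic clusters,
cancer-miRNA lists, arbitrary GMT gene sets) in either direction: are the
modules enriched by the reference sets, and are the reference sets enriched
by the modules. The test is the upper hypergeometric tail P(X >= observed)
on the overlap, over a user-supplied background universe, with Bonferroni
correction across the tests actually performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "hypergeom_tail",
    "bonferroni_adjust",
    "set_enrichment",
    "annotate_cancer_mirnas",
    "normalize_mirna_id",
]


@dataclass
class EnrichmentResult:
    """One tested (module, reference-set) overlap."""

    module_id: str
    set_id: str
    overlap: int
    module_size: int
    set_size: int
    background_size: int
    p_raw: float
    p_adj: float
    significant: bool = False


def hypergeom_tail(background: int, successes: int, draws: int, observed: int) -> float:
    """Upper tail P(X >= observed), X ~ Hypergeometric(background, successes, draws).

    ``background`` is the universe size, ``successes`` the number of marked
    items in the universe, ``draws`` the sample size, ``observed`` the marked
    items seen in the sample.
    """
    background, successes, draws, observed = (
        int(background), int(successes), int(draws), int(observed),
    )
    if background < 1:
        raise ValueError("background must be >= 1")
    if not 0 <= successes <= background or not 0 <= draws <= background:
        raise ValueError("successes and draws must lie in [0, background]")
    if observed < 0 or observed > min(successes, draws):
        raise ValueError(
            f"observed={observed} inconsistent with successes={successes}, "
            f"draws={draws}"
        )
    if observed == 0:
        return 1.0
    # sf(k) = P(X > k); survival evaluated at observed-1 gives P(X >= observed)
    return float(hypergeom.sf(observed - 1, background, successes, draws))


def bonferroni_adjust(pvals) -> list[float]:
    """Multiply each p-value by the number of tests, capping at 1."""
    pvals = list(pvals)
    if not pvals:
        return []
    arr = np.asarray(pvals, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(arr, method="bonferroni")
    return [float(p) for p in adj]


def set_enrichment(
    collections_a: dict,
    collections_b: dict,
    background: set,
    min_overlap: int = 3,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every (a, b) pair of sets for over-represented overlap.

    Both collections are dicts mapping set id -> node set; all sets are
    restricted to the background universe before testing. A pair is tested
    when the overlap is at least ``min_overlap`` (study default 3), with
    p = P(X >= |a n b|) for X ~ Hypergeometric(|background|, |b|, |a|).
    Bonferroni correction runs over the tests actually performed;
    ``significant`` means adjusted p < ``alpha``. Swap the two arguments to
    test the opposite direction.
    """
    if not background:
        raise ValueError("background universe must be non-empty")
    bg = set(background)
    results: list[EnrichmentResult] = []
    for a_id, a_raw in collections_a.items():
        a = set(a_raw) & bg
        for b_id, b_raw in collections_b.items():
            b = set(b_raw) & bg
            overlap = len(a & b)
            if overlap < min_overlap:
                continue
            p = hypergeom_tail(len(bg), len(b), len(a), overlap)
            results.append(
                EnrichmentResult(
                    module_id=str(a_id),
                    set_id=str(b_id),
                    overlap=overlap,
                    module_size=len(a),
                    set_size=len(b),
                    background_size=len(bg),
                    p_raw=p,
                    p_adj=p,
                )
            )
    if results:
        adj = bonferroni_adjust([r.p_raw for r in results])
        for r, pa in zip(results, adj):
            r.p_adj = pa
            r.significant = pa < alpha
    logger.info(
        "tested %d set pairs; %d significant at alpha=%g (Bonferroni over %d tests)",
        len(results), sum(r.significant for r in results), alpha, len(results),
    )
    return results


def normalize_mirna_id(raw: str, known_ids: set | None = None) -> str:
    """Harmonize a miRNA identifier: lower-case, strip the species prefix.

    If a ``known_ids`` universe is supplied and the harmonized id is not in
    it, the -5p/-3p arm suffix is additionally collapsed; the fallback is
    logged.
    """
    mid = raw.strip().lower()
    if mid.startswith("hsa-"):
        mid = mid[4:]
    if known_ids is not None and mid not in known_ids:
        for suffix in ("-5p", "-3p"):
            if mid.endswith(suffix) and mid[: -len(suffix)] in known_ids:
                logger.info("miRNA id %r matched as %r", raw, mid[: -len(suffix)])
                return mid[: -len(suffix)]
    return mid


def annotate_cancer_mirnas(
    modules,
    cancer_list: set,
    background: set,
) -> tuple[EnrichmentResult, pd.DataFrame]:
    """Cancer-annotation of module miRNAs: one global test plus a per-module table.

    The global test asks whether the miRNAs appearing in any module are
    over-represented in the cancer list relative to the background universe
    of miRNAs; the table gives, per module, its miRNA count, cancer-miRNA
    count, and the hypergeometric p (Bonferroni-adjusted across modules).
    """
    if not background:
        raise ValueError("background universe must be non-empty")
    bg = {normalize_mirna_id(m) for m in background}
    cancer = {normalize_mirna_id(m, bg) for m in cancer_list} & bg
    module_sets = []
    for idx, mod in enumerate(modules):
        mirnas = {normalize_mirna_id(m, bg) for m in mod.mirnas} & bg
        module_sets.append((f"module_{idx + 1}", mirnas))
    covered = set().union(*(s for _, s in module_sets)) if module_sets else set()
    global_p = hypergeom_tail(len(bg), len(cancer), len(covered), len(covered & cancer))
    global_res = EnrichmentResult(
        module_id="all_modules",
        set_id="cancer_mirnas",
        overlap=len(covered & cancer),
        module_size=len(covered),
        set_size=len(cancer),
        background_size=len(bg),
        p_raw=global_p,
        p_adj=global_p,
    )
    rows = []
    for mod_id, mirnas in module_sets:
        n_cancer = len(mirnas & cancer)
        p = hypergeom_tail(len(bg), len(cancer), len(mirnas), n_cancer) if mirnas else 1.0
        rows.append(
            {
                "module_id": mod_id,
                "n_mirnas": len(mirnas),
                "n_cancer_mirnas": n_cancer,
                "p_raw": p,
            }
        )
    table = pd.DataFrame(rows, columns=["module_id", "n_mirnas", "n_cancer_mirnas", "p_raw"])
    if len(table):
        table["p_adj"] = bonferroni_adjust(table["p_raw"].tolist())
    else:
        table["p_adj"] = []
    return global_res, table
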