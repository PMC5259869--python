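"""Expression-matrix preprocessing.

Expression matrices are pandas DataFrames with one row per feature (gene or
miRNA), one column per sample, and ``NaN`` marking missing measurements.
The functions here turn raw platform-level tables into the clean,
variance-filtered, sample-aligned matrices the network-construction step
expects: probe-level rows are averaged into feature-level rows, remaining
missing entries are imputed with the feature's own mean across samples, low
variance features are dropped, and the two matrices are restricted to their
common samples in a single shared order.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "collapse_duplicates",
    "impute_missing",
    "filter_by_variance",
    "align_samples",
]


def _check_expression(expr: pd.DataFrame, name: str = "expression") -> None:
    if not isinstance(expr, pd.DataFrame):
        raise TypeError(f"{name} must be a pandas DataFrame (features x samples)")
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"{name} has duplicate feature ids: {dups[:5]}")
    if expr.columns.has_duplicates:
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"{name} has duplicate sample ids: {dups[:5]}")


def collapse_duplicates(expr: pd.DataFrame, id_of: Mapping[str, str]) -> pd.DataFrame:
    """Average probe-level rows that map to the same feature.

    Parameters
    ----------
    expr
        Probe-level expression (probes x samples).
    id_of
        Mapping from probe id to feature id. Every probe in ``expr`` must be
        present.

    Returns
    -------
    Feature-level expression with one row per distinct feature, each row the
    per-sample mean over the feature's probes, ignoring missing values.
    Features appear in order of first occurrence of their probes.
    """
    _check_expression(expr)
    missing = [p for p in expr.index if p not in id_of]
    if missing:
        raise KeyError(
            f"{len(missing)} probe(s) missing from the probe->feature map, "
            f"e.g. {missing[:5]}"
        )
    features = [id_of[p] for p in expr.index]
    # groupby(..., sort=False) keeps first-occurrence order of feature ids;
    # DataFrame.mean is missing-aware (skipna) by default.
    collapsed = expr.groupby(pd.Index(features, name=expr.index.name), sort=False).mean()
    return collapsed


def impute_missing(expr: pd.DataFrame) -> pd.DataFrame:
    """Replace each missing entry by its feature's mean over observed samples.

    A feature with no observed value at all cannot be imputed and raises a
    ``ValueError`` naming it.
    """
    _check_expression(expr)
    values = expr.to_numpy(dtype=float)
    observed = ~np.isnan(values)
    dead = ~observed.any(axis=1)
    if dead.any():
        names = expr.index[dead].tolist()
        raise ValueError(f"feature(s) with all values missing: {names[:5]}")
    if observed.all():
        return expr.copy()
    row_means = np.nanmean(values, axis=1)
    filled = np.where(observed, values, row_means[:, None])
    n_imputed = int((~observed).sum())
    logger.info("imputed %d missing entries in %d features", n_imputed, len(expr))
    return pd.DataFrame(filled, index=expr.index.copy(), columns=expr.columns.copy())


def filter_by_variance(
    expr: pd.DataFrame,
    top_n: int | None = None,
    min_var: float | None = None,
) -> pd.DataFrame:
    """Keep the most variable features.

    Exactly one of ``top_n`` (keep the ``top_n`` features with the largest
    sample variance) or ``min_var`` (keep features with variance strictly
    greater than ``min_var``) must be given. Variance is the unbiased sample
    variance (``ddof=1``), ignoring missing values. The result is ordered by
    decreasing variance with ties broken by input order; the kept features'
    original input order is stashed in ``result.attrs["input_order"]``.
    """
    _check_expression(expr)
    if (top_n is None) == (min_var is None):
        raise ValueError("give exactly one of top_n or min_var")
    variances = expr.var(axis=1, ddof=1, skipna=True).to_numpy(dtype=float)
    if top_n is not None:
        if not 1 <= top_n <= len(expr):
            raise ValueError(
                f"top_n={top_n} out of range for {len(expr)} features"
            )
        order = np.argsort(-variances, kind="stable")
        keep = order[:top_n]
    else:
        mask = variances > float(min_var)
        keep = np.argsort(-variances[mask], kind="stable")
        keep = np.flatnonzero(mask)[keep]
    out = expr.iloc[keep].copy()
    out.attrs["input_order"] = expr.index[np.sort(keep)].tolist()
    logger.info("variance filter kept %d of %d features", len(out), len(expr))
    return out


def align_samples(
    expr_a: pd.DataFrame, expr_b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both matrices to their common samples, in a shared order.

    The shared order is the order the common samples appear in ``expr_a``.
    Pearson correlation needs at least three points, so fewer than three
    shared samples is an error.
    """
    _check_expression(expr_a, "expr_a")
    _check_expression(expr_b, "expr_b")
    common = [s for s in expr_a.columns if s in set(expr_b.columns)]
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} shared sample(s); need at least 3 for "
            "correlation-based network construction"
        )
    logger.info(
        "aligned to %d common samples (of %d and %d)",
        len(common), expr_a.shape[1], expr_b.shape[1],
    )
    return expr_a.loc[:, common].copy(), expr_b.loc[:, common].copy()
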