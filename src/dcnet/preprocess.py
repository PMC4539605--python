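"""Five-step expression preprocessing.

Order is fixed: quantile normalisation -> missing-fraction filter -> KNN
imputation -> probe collapse -> variance filter.  Each step returns a new
:class:`~dcnet.expression.ExpressionMatrix`; :func:`preprocess_pipeline`
chains them and logs the surviving row count after every step.

Conventions (chosen once, documented in the methods note):

* quantile normalisation is applied per condition by default — the two
  conditions are separate array series;
* the variance filter keeps a gene if its standard deviation is in the top
  quartile in *either* condition (a gene is dropped only when it is
  low-variance in both), with ties at the cut kept;
* KNN imputation uses plain Euclidean distance over mutually non-missing
  columns and the unweighted mean of the k nearest rows.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, ProbeAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "quantile_normalize",
    "filter_missing_probes",
    "knn_impute",
    "collapse_probes",
    "variance_filter",
    "preprocess_pipeline",
]


def _quantile_normalize_block(X: np.ndarray) -> np.ndarray:
    """Rank-mean quantile normalisation of one column pool (NaN-aware).

    Each column's non-missing values are replaced by the reference
    distribution (the across-column mean of sorted values, interpolated onto
    a common quantile grid); ties within a column get the average reference
    value.  Missing entries stay missing.
    """
    n_rows, n_cols = X.shape
    grid = (np.arange(n_rows) + 0.5) / n_rows
    ref = np.zeros(n_rows)
    for j in range(n_cols):
        col = X[:, j]
        vals = np.sort(col[~np.isnan(col)])
        if vals.size == 0:
            raise ValueError(f"column {j} is entirely missing")
        q = (np.arange(vals.size) + 0.5) / vals.size
        ref += np.interp(grid, q, vals)
    ref /= n_cols

    out = np.full_like(X, np.nan)
    for j in range(n_cols):
        col = X[:, j]
        mask = ~np.isnan(col)
        vals = col[mask]
        order = np.argsort(vals, kind="mergesort")
        ranks = np.empty(vals.size)
        ranks[order] = np.arange(vals.size)
        q = (ranks + 0.5) / vals.size
        new = np.interp(q, grid, ref)
        # average reference value over ties
        uniq, inv = np.unique(vals, return_inverse=True)
        if uniq.size < vals.size:
            sums = np.bincount(inv, weights=new)
            counts = np.bincount(inv)
            new = (sums / counts)[inv]
        out[mask, j] = new
    return out


def quantile_normalize(
    m: ExpressionMatrix, pool_conditions: bool = False
) -> ExpressionMatrix:
    """Quantile-normalise so every array shares one empirical distribution.

    By default each condition's columns form their own quantile pool; set
    ``pool_conditions=True`` to normalise all columns together.
    """
    X = m.values.to_numpy(dtype=float).copy()
    if pool_conditions or len(m.conditions) == 1:
        if X.shape[1] < 2:
            raise ValueError("nothing to normalize against: need >=2 columns")
        X = _quantile_normalize_block(X)
    else:
        for cond in m.conditions:
            idx = np.flatnonzero(m.condition == cond)
            if idx.size < 2:
                raise ValueError(
                    f"nothing to normalize against in condition {cond!r}"
                )
            X[:, idx] = _quantile_normalize_block(X[:, idx])
    return m.with_values(pd.DataFrame(X, index=m.values.index,
                                      columns=m.values.columns))


def filter_missing_probes(
    m: ExpressionMatrix, max_missing_frac: float = 0.20
) -> ExpressionMatrix:
    """Drop rows with more than ``max_missing_frac`` missing timepoints in
    any single condition (default: more than 20%)."""
    if not (0 <= max_missing_frac < 1):
        raise ValueError("max_missing_frac must be in [0, 1)")
    keep = np.ones(m.n_genes, dtype=bool)
    for cond in m.conditions:
        sub = m.values.loc[:, m.condition == cond]
        frac = sub.isna().mean(axis=1).to_numpy()
        keep &= frac <= max_missing_frac
    return m.with_values(m.values.loc[keep])


def knn_impute(m: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Fill missing entries with the unweighted mean of the k nearest rows.

    Distance is Euclidean over mutually non-missing columns; only neighbours
    observed at the target column contribute.  Rows with no missing values
    are untouched.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = m.values.to_numpy(dtype=float).copy()
    miss = np.isnan(X)
    if not miss.any():
        return m
    obs = ~miss
    n = X.shape[0]
    for i in np.flatnonzero(miss.any(axis=1)):
        shared = obs & obs[i]  # (n, n_cols) columns usable against row i
        diff = X - X[i]
        diff[~shared] = 0.0
        n_shared = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt((diff ** 2).sum(axis=1))
        dist[i] = np.inf
        dist[n_shared == 0] = np.inf
        for j in np.flatnonzero(miss[i]):
            cand = np.flatnonzero(obs[:, j] & np.isfinite(dist))
            if cand.size == 0:
                raise ValueError(f"no neighbour observed at column {j}")
            if cand.size < k:
                logger.warning(
                    "knn_impute: only %d candidate neighbours (< k=%d) "
                    "for row %d column %d; using all", cand.size, k, i, j,
                )
            chosen = cand[np.argsort(dist[cand], kind="mergesort")[:k]]
            X[i, j] = X[chosen, j].mean()
    assert not np.isnan(X).any()
    return m.with_values(pd.DataFrame(X, index=m.values.index,
                                      columns=m.values.columns))


def collapse_probes(m: ExpressionMatrix, ann: ProbeAnnotation) -> ExpressionMatrix:
    """Drop non-annotated probes and average multi-probe genes row-wise."""
    if len(ann) == 0:
        raise ValueError("empty probe annotation map")
    genes = m.values.index.map(ann.mapping.get)
    keep = genes.notna()
    vals = m.values.loc[keep].groupby(genes[keep].to_numpy()).mean()
    vals = vals.sort_index()
    return m.with_values(vals)


def _sd_cutoff(sds: np.ndarray, top_frac: float) -> float:
    """SD value of the top ceil(top_frac * n)-th gene; ties at the cut kept."""
    n_top = math.ceil(top_frac * sds.size)
    return float(np.sort(sds)[::-1][n_top - 1])


def variance_filter(
    m_a: ExpressionMatrix, m_b: ExpressionMatrix, top_frac: float = 0.25
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Remove genes whose SD is outside the top quartile in both conditions.

    A gene survives iff its sample standard deviation ranks in the top
    ``top_frac`` in condition a OR condition b (drop only when low in both).
    """
    if not m_a.values.index.equals(m_b.values.index):
        raise ValueError("variance_filter requires identical gene sets")
    sd_a = m_a.values.std(axis=1, ddof=1).to_numpy()
    sd_b = m_b.values.std(axis=1, ddof=1).to_numpy()
    keep = (sd_a >= _sd_cutoff(sd_a, top_frac)) | (sd_b >= _sd_cutoff(sd_b, top_frac))
    return (
        m_a.with_values(m_a.values.loc[keep]),
        m_b.with_values(m_b.values.loc[keep]),
    )


def preprocess_pipeline(
    m: ExpressionMatrix,
    ann: ProbeAnnotation | None = None,
    max_missing_frac: float = 0.20,
    k: int = 10,
    top_frac: float = 0.25,
    pool_conditions: bool = False,
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[tuple[str, int]]]:
    """Run the full five-step pipeline on a two-condition matrix.

    Returns the two single-condition matrices after the variance filter plus
    a ``[(step, n_rows), ...]`` log of remaining rows after each step.
    If ``ann`` is None the probe-collapse step is skipped (rows are already
    gene-level).
    """
    conds = m.conditions
    if len(conds) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {conds}")
    log: list[tuple[str, int]] = [("input", m.n_genes)]
    m = quantile_normalize(m, pool_conditions=pool_conditions)
    log.append(("quantile_normalize", m.n_genes))
    m = filter_missing_probes(m, max_missing_frac)
    log.append(("filter_missing_probes", m.n_genes))
    m = knn_impute(m, k=k)
    log.append(("knn_impute", m.n_genes))
    if ann is not None:
        m = collapse_probes(m, ann)
        log.append(("collapse_probes", m.n_genes))
    m_a, m_b = m.subset_condition(conds[0]), m.subset_condition(conds[1])
    m_a, m_b = variance_filter(m_a, m_b, top_frac)
    log.append(("variance_filter", m_a.n_genes))
    for step, n in log:
        logger.info("preprocess %-24s rows=%d", step, n)
    return m_a, m_b, log
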