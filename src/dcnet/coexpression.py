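"""Differential coexpression: scoring, permutation testing, network assembly.

The analysis compares Spearman correlations of every gene pair between two
conditions.  The per-pair statistic is

    score(u, v) = Delta * (1 + w * (|r_a| + |r_b|) / 2),   Delta = r_b - r_a

where ``r_a``/``r_b`` are the within-condition Spearman correlations and the
second factor breaks ties between pairs sharing the same correlation
difference: among pairs with equal Delta, the pair involving stronger
absolute correlations scores higher in magnitude (a drop from 1.0 to 0.5 is
more informative than a drop from 0.5 to 0.0).  ``sign(score) == sign(Delta)``,
so positive scores mark pairs whose correlation is higher in condition b
(positively differentially coexpressed links) and negative scores the
converse.

Significance is assessed by a permutation test on the condition labels of the
sample columns: a single shared pool of ``n_perm`` column reassignments is
applied to all pairs and the two-sided empirical p-value of a pair is the
fraction of permutations whose |score| meets or exceeds the observed |score|.
Empirical p-values are Benjamini-Hochberg adjusted; pairs below the
significance threshold (default adjusted p < 1e-4) become differentially
coexpressed links (DCELs).  Pairs with Spearman correlation above a high
floor (default > 0.95) in *both* conditions are constitutively coexpressed
links (CCELs).

Usage follows the model/results idiom::

    model = DifferentialCoexpression(expr_a, expr_b)
    res = model.fit(n_perm=10_000, seed=1)
    print(res.summary())
    res.dcen   # SignedNetwork of DCELs
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix
from .network import SignedNetwork, assemble_network, connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "spearman_matrix",
    "differential_score",
    "permutation_pvalues",
    "bh_adjust",
    "call_dcels",
    "call_ccels",
    "DifferentialCoexpression",
    "DifferentialCoexpressionResults",
]


# ---------------------------------------------------------------------------
# correlation machinery
# ---------------------------------------------------------------------------

def _spearman_from_values(X: np.ndarray) -> np.ndarray:
    """Pairwise Spearman matrix of the rows of X (average ranks for ties).

    Rows with zero rank variance get NaN correlations.
    """
    R = rankdata(X, axis=1).astype(float)
    R -= R.mean(axis=1, keepdims=True)
    norm = np.sqrt((R ** 2).sum(axis=1))
    valid = norm > 0
    R[valid] /= norm[valid, None]
    C = R @ R.T
    np.clip(C, -1.0, 1.0, out=C)
    C[~valid, :] = np.nan
    C[:, ~valid] = np.nan
    np.fill_diagonal(C, 1.0)
    C[np.ix_(~valid, ~valid)] = np.nan
    return C


def spearman_matrix(m: ExpressionMatrix) -> pd.DataFrame:
    """All-pairs Spearman correlation of a single-condition matrix.

    Requires >= 4 samples; zero-variance genes yield NaN rows/columns (their
    pairs are excluded downstream, with a logged count).
    """
    if m.n_samples < 4:
        raise ValueError("need >= 4 samples per condition for Spearman")
    if m.values.isna().any().any():
        raise ValueError("missing values present; impute first")
    C = _spearman_from_values(m.values.to_numpy(dtype=float))
    n_bad = int(np.isnan(np.diag(C)).sum())
    if n_bad:
        logger.warning("spearman_matrix: %d zero-variance genes", n_bad)
    return pd.DataFrame(C, index=m.row_ids, columns=m.row_ids)


def differential_score(r_a, r_b, tie_weight: float = 1.0):
    """Aggregated differential-coexpression score (vectorised).

    ``Delta * (1 + tie_weight * (|r_a| + |r_b|) / 2)`` with
    ``Delta = r_b - r_a``.
    """
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    delta = r_b - r_a
    return delta * (1.0 + tie_weight * (np.abs(r_a) + np.abs(r_b)) / 2.0)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def _aligned_values(m_a: ExpressionMatrix, m_b: ExpressionMatrix):
    common = m_a.row_ids.intersection(m_b.row_ids)
    if len(common) == 0:
        raise ValueError("no shared genes between conditions")
    if len(common) < len(m_a.row_ids) or len(common) < len(m_b.row_ids):
        logger.warning("restricting to %d shared genes", len(common))
    genes = list(common)
    return (genes,
            m_a.values.loc[genes].to_numpy(dtype=float),
            m_b.values.loc[genes].to_numpy(dtype=float))


def permutation_pvalues(
    m_a: ExpressionMatrix,
    m_b: ExpressionMatrix,
    n_perm: int = 100_000,
    scheme: str = "pooled",
    seed: int | np.random.Generator | None = None,
    tie_weight: float = 1.0,
    plus_one: bool = False,
) -> pd.DataFrame:
    """Per-pair empirical p-values from a shared permutation pool.

    ``scheme="pooled"`` reassigns sample columns to conditions at random
    (per-condition sample counts preserved); ``scheme="paired"`` swaps the
    condition labels independently per shared timepoint and requires equal
    time grids.  Pairs involving a zero-variance gene are dropped (logged).

    Returns a DataFrame with one row per retained unordered pair:
    gene_u, gene_v, r_a, r_b, delta, score, p_emp.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if scheme not in ("pooled", "paired"):
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    genes, A, B = _aligned_values(m_a, m_b)
    n_a, n_b = A.shape[1], B.shape[1]
    if scheme == "paired" and n_a != n_b:
        raise ValueError("paired scheme requires matching timepoints")

    Ca = _spearman_from_values(A)
    Cb = _spearman_from_values(B)
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    r_a, r_b = Ca[iu, ju], Cb[iu, ju]
    keep = ~(np.isnan(r_a) | np.isnan(r_b))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d pairs with undefined correlations", n_dropped)
    iu, ju, r_a, r_b = iu[keep], ju[keep], r_a[keep], r_b[keep]
    s_obs = differential_score(r_a, r_b, tie_weight)
    abs_obs = np.abs(s_obs)

    X = np.concatenate([A, B], axis=1)
    counts = np.zeros(abs_obs.size, dtype=np.int64)
    for _ in range(n_perm):
        if scheme == "pooled":
            perm = rng.permutation(n_a + n_b)
            idx_a, idx_b = perm[:n_a], perm[n_a:]
        else:
            swap = rng.random(n_a) < 0.5
            idx_a = np.where(swap, np.arange(n_a) + n_a, np.arange(n_a))
            idx_b = np.where(swap, np.arange(n_a), np.arange(n_a) + n_a)
        Pa = _spearman_from_values(X[:, idx_a])
        Pb = _spearman_from_values(X[:, idx_b])
        s_perm = differential_score(Pa[iu, ju], Pb[iu, ju], tie_weight)
        # tolerance absorbs float dust so an exactly-tied score counts as >=
        counts += np.abs(s_perm) >= abs_obs - 1e-12
    if plus_one:
        p = (counts + 1) / (n_perm + 1)
    else:
        p = counts / n_perm
    return pd.DataFrame({
        "gene_u": np.asarray(genes, dtype=object)[iu],
        "gene_v": np.asarray(genes, dtype=object)[ju],
        "r_a": r_a, "r_b": r_b, "delta": r_b - r_a,
        "score": s_obs, "p_emp": p,
    })


# ---------------------------------------------------------------------------
# link calling
# ---------------------------------------------------------------------------

def call_dcels(links: pd.DataFrame, alpha: float = 1e-4,
               adjust: bool = True, n_perm: int | None = None) -> pd.DataFrame:
    """Select differentially coexpressed links at strict p < alpha.

    ``adjust=True`` thresholds the BH-adjusted p (column ``q``, added here if
    absent); otherwise the raw empirical p.  ``sign`` is set from the score.
    """
    links = links.copy()
    if "q" not in links.columns:
        links["q"] = bh_adjust(links["p_emp"].to_numpy())
    if n_perm is not None and alpha < 1.0 / n_perm:
        logger.warning(
            "alpha=%g is below the permutation resolution 1/%d; calls depend "
            "on zero-count p-values", alpha, n_perm)
    crit = links["q"] if adjust else links["p_emp"]
    out = links.loc[crit < alpha].copy()
    out["sign"] = np.where(out["score"] > 0, 1, -1)
    return out.reset_index(drop=True)


def call_ccels(corr_a: pd.DataFrame, corr_b: pd.DataFrame,
               r_min: float = 0.95) -> pd.DataFrame:
    """Constitutively coexpressed links: Spearman r strictly > ``r_min`` in
    both conditions."""
    genes = corr_a.index
    if not genes.equals(corr_b.index):
        raise ValueError("correlation matrices must share the gene set")
    Ca, Cb = corr_a.to_numpy(), corr_b.to_numpy()
    iu, ju = np.triu_indices(len(genes), k=1)
    with np.errstate(invalid="ignore"):
        keep = (Ca[iu, ju] > r_min) & (Cb[iu, ju] > r_min)
    return pd.DataFrame({
        "gene_u": genes.to_numpy(dtype=object)[iu[keep]],
        "gene_v": genes.to_numpy(dtype=object)[ju[keep]],
        "r_a": Ca[iu, ju][keep], "r_b": Cb[iu, ju][keep],
    })


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class DifferentialCoexpression:
    """Two-condition differential coexpression model.

    Parameters
    ----------
    expr_a, expr_b : ExpressionMatrix
        Preprocessed single-condition matrices over a shared gene set
        (no missing values).
    tie_weight : float
        Weight ``w`` of the magnitude tie-break term in the score.
    """

    def __init__(self, expr_a: ExpressionMatrix, expr_b: ExpressionMatrix,
                 tie_weight: float = 1.0):
        self.expr_a = expr_a
        self.expr_b = expr_b
        self.tie_weight = float(tie_weight)

    def fit(self, n_perm: int = 100_000, scheme: str = "pooled",
            alpha: float = 1e-4, adjust: bool = True,
            ccel_min_r: float = 0.95, seed=None,
            plus_one: bool = False) -> "DifferentialCoexpressionResults":
        links = permutation_pvalues(
            self.expr_a, self.expr_b, n_perm=n_perm, scheme=scheme,
            seed=seed, tie_weight=self.tie_weight, plus_one=plus_one)
        links["q"] = bh_adjust(links["p_emp"].to_numpy())
        dcels = call_dcels(links, alpha=alpha, adjust=adjust, n_perm=n_perm)
        ccels = call_ccels(spearman_matrix(self.expr_a),
                           spearman_matrix(self.expr_b), r_min=ccel_min_r)
        params = dict(n_perm=n_perm, scheme=scheme, alpha=alpha,
                      adjust=adjust, ccel_min_r=ccel_min_r,
                      tie_weight=self.tie_weight, plus_one=plus_one)
        return DifferentialCoexpressionResults(links, dcels, ccels, params)


class DifferentialCoexpressionResults:
    """Fitted differential-coexpression results.

    Attributes
    ----------
    links : DataFrame of every tested pair (r_a, r_b, delta, score, p_emp, q).
    dcels : called differential links (subset of ``links`` with ``sign``).
    ccels : constitutively coexpressed links.
    dcen, ccen : the assembled :class:`SignedNetwork` objects.
    """

    def __init__(self, links: pd.DataFrame, dcels: pd.DataFrame,
                 ccels: pd.DataFrame, params: dict):
        self.links = links
        self.dcels = dcels
        self.ccels = ccels
        self.params = params
        self.dcen: SignedNetwork = assemble_network(
            ((r.gene_u, r.gene_v, r.sign, abs(r.score))
             for r in dcels.itertuples(index=False)), edge_type="DCEL")
        self.ccen: SignedNetwork = assemble_network(
            ((r.gene_u, r.gene_v, 1, min(r.r_a, r.r_b))
             for r in ccels.itertuples(index=False)), edge_type="CCEL")

    def largest_component(self) -> SignedNetwork:
        comps = connected_components(self.dcen)
        if not comps:
            return SignedNetwork()
        return self.dcen.subgraph(comps[0])

    def summary(self) -> str:
        d, c = self.dcen, self.ccen
        lines = [
            "Differential coexpression results",
            "=================================",
            f"pairs tested        {len(self.links):>8d}",
            f"permutations        {self.params['n_perm']:>8d}  "
            f"(scheme={self.params['scheme']})",
            f"DCEL threshold      {'adj. ' if self.params['adjust'] else ''}"
            f"p < {self.params['alpha']:g}",
            f"DCEN genes          {d.n_nodes:>8d}",
            f"DCELs               {d.n_edges:>8d}  "
            f"({d.n_positive} positive, {d.n_negative} negative)",
            f"CCEL floor          r > {self.params['ccel_min_r']:g} (both conditions)",
            f"CCEN genes          {c.n_nodes:>8d}",
            f"CCELs               {c.n_edges:>8d}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path, which: str = "dcels") -> None:
        {"links": self.links, "dcels": self.dcels,
         "ccels": self.ccels}[which].to_csv(path, sep="\t", index=False)
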