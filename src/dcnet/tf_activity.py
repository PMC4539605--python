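"""Transcription-factor differential-activation inference from a DCEN.

A TF whose targets appear on both ends of differentially coexpressed links
far more often than chance is a candidate for gained or lost activity
between the two conditions.  The observed statistic per TF is the
co-occurrence count: the number of DCEN edges whose two endpoints are both
targets of that TF.  The null preserves the regulatory "degree" of every
network gene: each DCEN node is replaced by a random gene regulated by the
same (or, when the matching bin is sparse, a similar) number of TFs, edge
topology fixed, and the co-occurrence is recounted; repeating this gives
per-TF empirical p-values, BH-corrected across TFs.  TFs with p < 0.05 are
called differentially activated.

The module also provides the common-TF index of a gene pair (mean of the
Jaccard and overlap coefficients of the two regulator sets) and the per-TF
comparison of target-target correlation distributions between conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .coexpression import bh_adjust
from .network import SignedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "TFRegulationTable",
    "TFActivation",
    "TFActivationResults",
    "tf_cooccurrence",
    "degree_matched_null",
    "tf_activation_pvalues",
    "common_tf_index",
    "target_correlation_shift",
]


@dataclass
class TFRegulationTable:
    """TF -> target-gene sets plus the per-gene regulator count.

    ``universe`` is the pool replacement genes are drawn from; it defaults
    to every gene appearing as a target but may be widened explicitly.
    """

    targets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for tf, t in self.targets.items():
            if not t:
                raise ValueError(f"TF {tf!r} has an empty target set")
        covered = set().union(*self.targets.values()) if self.targets else set()
        self.universe = set(self.universe) | covered
        counts = {g: 0 for g in self.universe}
        for t in self.targets.values():
            for g in t:
                counts[g] += 1
        self.tf_count: dict[str, int] = counts

    @classmethod
    def from_tsv(cls, path: str | Path, universe=None) -> "TFRegulationTable":
        """Two-column TSV (TF, target) — the flat regulation-export dialect."""
        df = pd.read_csv(path, sep="\t", header=None, names=["tf", "target"],
                         dtype=str, comment="#").dropna()
        targets: dict[str, set[str]] = {}
        for row in df.itertuples(index=False):
            targets.setdefault(row.tf, set()).add(row.target)
        return cls(targets, set(universe) if universe else set())

    def to_tsv(self, path: str | Path) -> None:
        rows = [(tf, g) for tf in sorted(self.targets)
                for g in sorted(self.targets[tf])]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)

    @property
    def tfs(self) -> list[str]:
        return sorted(self.targets)

    def regulators_of(self, gene: str) -> set[str]:
        return {tf for tf, t in self.targets.items() if gene in t}


# ---------------------------------------------------------------------------
# co-occurrence and null
# ---------------------------------------------------------------------------

def tf_cooccurrence(dcen: SignedNetwork, tf_table: TFRegulationTable) -> pd.Series:
    """Per-TF count of network edges with both endpoints in the TF's
    target set."""
    if dcen.n_edges == 0:
        raise ValueError("network has no edges")
    edges = [(u, v) for u, v, _ in dcen.edges()]
    out = {}
    for tf in tf_table.tfs:
        t = tf_table.targets[tf]
        out[tf] = sum(1 for u, v in edges if u in t and v in t)
    return pd.Series(out, name="co_occurrence")


def _matching_pools(nodes, tf_table: TFRegulationTable,
                    min_pool: int = 50) -> dict:
    """Replacement pool per node: universe genes whose TF-count equals the
    node's, widened symmetrically (+-1, +-2, ...) until >= ``min_pool``
    genes (or the whole universe)."""
    by_count: dict[int, list[str]] = {}
    for g, c in tf_table.tf_count.items():
        by_count.setdefault(c, []).append(g)
    max_c = max(by_count) if by_count else 0
    pools: dict[int, np.ndarray] = {}
    pool_of: dict = {}
    for node in nodes:
        c = tf_table.tf_count.get(node, 0)
        if c not in pools:
            pool: list[str] = []
            w = 0
            while len(pool) < min_pool and (c - w >= 0 or c + w <= max_c):
                lo, hi = c - w, c + w
                extra = []
                if lo >= 0:
                    extra += by_count.get(lo, [])
                if hi != lo:
                    extra += by_count.get(hi, [])
                pool += extra
                w += 1
            if len(pool) < min_pool:
                logger.info("matching pool for TF-count %d holds only %d "
                            "genes after widening to the whole universe",
                            c, len(pool))
            pools[c] = np.asarray(sorted(set(pool)), dtype=object)
        pool_of[node] = pools[c]
    return pool_of


def degree_matched_null(
    dcen: SignedNetwork, tf_table: TFRegulationTable,
    n_perm: int = 100_000, seed=None, min_pool: int = 50,
) -> pd.DataFrame:
    """Null co-occurrence samples per TF under degree-matched gene
    replacement.

    Per permutation every network node is replaced (without repetition
    within the permutation; a node may draw itself) by a gene with a
    matching regulator count, topology fixed, and co-occurrence is
    recounted for every TF.  Returns an ``n_perm x n_tfs`` DataFrame.
    """
    nodes = list(dcen.graph.nodes)
    node_idx = {u: i for i, u in enumerate(nodes)}
    edges = np.asarray([(node_idx[u], node_idx[v])
                        for u, v, _ in dcen.edges()], dtype=int)
    pool_of = _matching_pools(nodes, tf_table, min_pool)

    tfs = tf_table.tfs
    uni = sorted(tf_table.universe)
    uni_idx = {g: i for i, g in enumerate(uni)}
    member = np.zeros((len(tfs), len(uni)), dtype=bool)
    for i, tf in enumerate(tfs):
        for g in tf_table.targets[tf]:
            member[i, uni_idx[g]] = True

    pools_idx = {u: np.asarray([uni_idx[g] for g in pool_of[u]
                                if g in uni_idx], dtype=int)
                 for u in nodes}
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    order = np.arange(len(nodes))
    out = np.zeros((n_perm, len(tfs)), dtype=np.int64)
    for r in range(n_perm):
        rng.shuffle(order)
        used: set[int] = set()
        repl = np.empty(len(nodes), dtype=int)
        for i in order:
            pool = pools_idx[nodes[i]]
            # rejection-sample, then fall back to the unused remainder
            for _ in range(8):
                cand = int(pool[rng.integers(pool.size)])
                if cand not in used:
                    break
            else:
                free = np.setdiff1d(pool, np.fromiter(used, int, len(used)))
                if free.size == 0:
                    # pool exhausted: draw from the whole universe
                    free = np.setdiff1d(np.arange(len(uni)),
                                        np.fromiter(used, int, len(used)))
                cand = int(free[rng.integers(free.size)])
            used.add(cand)
            repl[i] = cand
        gu, gv = repl[edges[:, 0]], repl[edges[:, 1]]
        out[r] = (member[:, gu] & member[:, gv]).sum(axis=1)
    return pd.DataFrame(out, columns=tfs)


def tf_activation_pvalues(observed: pd.Series, null_samples: pd.DataFrame,
                          alpha: float = 0.05,
                          call_on: str = "p") -> pd.DataFrame:
    """Per-TF empirical p (fraction of null counts >= observed), BH q and
    the activation call (``call_on`` selects the thresholded column)."""
    if len(null_samples) < 100:
        raise ValueError("need >= 100 permutations")
    if call_on not in ("p", "q"):
        raise ValueError("call_on must be 'p' or 'q'")
    tfs = list(observed.index)
    null = null_samples[tfs].to_numpy()
    obs = observed.to_numpy()
    p = (null >= obs[None, :]).mean(axis=0)
    q = bh_adjust(p)
    crit = p if call_on == "p" else q
    return pd.DataFrame({
        "co_occurrence": obs,
        "null_mean": null.mean(axis=0),
        "null_sd": null.std(axis=0),
        "p_emp": p,
        "q": q,
        "activated": crit < alpha,
    }, index=pd.Index(tfs, name="tf")).sort_values(["p_emp", "q", "tf"])


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class TFActivation:
    """Degree-matched randomisation model for TF differential activation."""

    def __init__(self, dcen: SignedNetwork, tf_table: TFRegulationTable):
        self.dcen = dcen
        self.tf_table = tf_table

    def fit(self, n_perm: int = 100_000, seed=None, alpha: float = 0.05,
            call_on: str = "p", min_pool: int = 50) -> "TFActivationResults":
        observed = tf_cooccurrence(self.dcen, self.tf_table)
        null = degree_matched_null(self.dcen, self.tf_table, n_perm=n_perm,
                                   seed=seed, min_pool=min_pool)
        table = tf_activation_pvalues(observed, null, alpha=alpha,
                                      call_on=call_on)
        comp = set(self.dcen.graph.nodes)
        table["in_dcen"] = [tf in comp for tf in table.index]
        return TFActivationResults(table, dict(n_perm=n_perm, alpha=alpha,
                                               call_on=call_on))


class TFActivationResults:
    """Per-TF activation table (sorted by empirical p) plus run parameters."""

    def __init__(self, table: pd.DataFrame, params: dict):
        self.table = table
        self.params = params

    @property
    def activated(self) -> pd.DataFrame:
        return self.table.loc[self.table["activated"]]

    def rank_of(self, tf: str) -> int:
        """1-based rank of ``tf`` by empirical p (ties share the better
        rank order position by table order)."""
        return int(np.flatnonzero(self.table.index == tf)[0]) + 1

    def summary(self, top: int = 10) -> str:
        n_act = int(self.table["activated"].sum())
        lines = [
            "TF differential activation",
            "==========================",
            f"TFs tested          {len(self.table):>6d}",
            f"permutations        {self.params['n_perm']:>6d}",
            f"activated (p<{self.params['alpha']:g})  {n_act:>6d}",
            "",
            self.table.head(top).to_string(
                float_format=lambda x: f"{x:.4g}"),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# auxiliary statistics
# ---------------------------------------------------------------------------

def common_tf_index(gene_u: str, gene_v: str,
                    tf_table: TFRegulationTable) -> float:
    """Mean of the Jaccard and overlap coefficients of the two genes'
    regulator sets; 0 when either gene has no regulator."""
    A = tf_table.regulators_of(gene_u)
    B = tf_table.regulators_of(gene_v)
    if not A or not B:
        logger.info("common_tf_index: %r has no regulators",
                    gene_u if not A else gene_v)
        return 0.0
    inter = len(A & B)
    jaccard = inter / len(A | B)
    overlap = inter / max(len(A), len(B))
    return 0.5 * (jaccard + overlap)


def target_correlation_shift(tf: str, tf_table: TFRegulationTable,
                             corr_a: pd.DataFrame,
                             corr_b: pd.DataFrame) -> dict:
    """Compare a TF's target-target correlation distributions between
    conditions (two-sample Kolmogorov-Smirnov)."""
    targets = sorted(tf_table.targets.get(tf, set())
                     & set(corr_a.index) & set(corr_b.index))
    if len(targets) < 2:
        raise ValueError(f"TF {tf!r} has < 2 targets in the expression data")
    sub_a = corr_a.loc[targets, targets].to_numpy()
    sub_b = corr_b.loc[targets, targets].to_numpy()
    iu, ju = np.triu_indices(len(targets), k=1)
    ra, rb = sub_a[iu, ju], sub_b[iu, ju]
    if np.array_equal(ra, rb):
        stat, p = 0.0, 1.0
    else:
        stat, p = ks_2samp(ra, rb)
    return {
        "tf": tf, "n_targets": len(targets), "n_pairs": len(ra),
        "corr_a": ra, "corr_b": rb,
        "mean_a": float(ra.mean()), "mean_b": float(rb.mean()),
        "ks_stat": float(stat), "ks_p": float(p),
    }
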