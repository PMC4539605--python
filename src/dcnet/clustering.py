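"""Functional clustering of network components and link-density statistics.

Genes are clustered on their rows of the functional-similarity matrix
(hierarchical agglomerative average linkage, distance = 1 - Pearson
correlation of profiles).  Within/between-cluster DCEL connectivity is
expressed as a density

    D_ij = I_ij / (n_i * n_j)          for i != j
    D_ii = I_ii / C(n_i, 2)

(I = link count, n = cluster size; the pair-count normalisation is the one
that makes D a density in [0, 1]) and standardised against a
cluster-label-shuffling null: z_ij = (D_ij - mu_ij) / rho_ij, with z > 1.5
flagging cluster pairs linked more densely than chance.  The same null
yields an empirical p-value for the between/within link-count ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .network import SignedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "DensityMatrix",
    "cluster_profiles",
    "link_density",
    "density_zscores",
    "between_within_ratio_test",
    "linkage_to_newick",
]


@dataclass
class ClusterAssignment:
    """gene -> contiguous integer cluster label (1..n_clusters)."""

    labels: pd.Series
    linkage: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())

    def members(self, label: int) -> list:
        return list(self.labels.index[self.labels == label])

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def cluster_profiles(sim: pd.DataFrame, n_clusters: int | None = None,
                     cut_height: float | None = None) -> ClusterAssignment:
    """Average-linkage clustering of similarity profiles.

    Distance between two genes is 1 minus the Pearson correlation of their
    rows of the similarity matrix.  Exactly one of ``n_clusters`` /
    ``cut_height`` selects the tree cut.  Genes with constant profiles
    (undefined correlation) become singleton clusters (logged).
    """
    if (n_clusters is None) == (cut_height is None):
        raise ValueError("give exactly one of n_clusters or cut_height")
    if sim.shape[0] < 3:
        raise ValueError("need >= 3 genes to cluster")
    if not np.allclose(sim.values, sim.values.T):
        raise ValueError("similarity matrix must be symmetric")
    X = sim.to_numpy(dtype=float)
    sd = X.std(axis=1)
    ok = sd > 0
    constant = list(sim.index[~ok])
    if constant:
        logger.warning("cluster_profiles: %d constant profiles become "
                       "singletons", len(constant))
    idx = sim.index[ok]
    Xo = X[ok]
    corr = np.corrcoef(Xo)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    if n_clusters is not None:
        want = max(1, n_clusters - len(constant))
        raw = fcluster(Z, t=want, criterion="maxclust")
    else:
        raw = fcluster(Z, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=idx, dtype=int)
    # contiguous relabel in order of first appearance, singletons appended
    remap = {old: new for new, old in
             enumerate(dict.fromkeys(labels), start=1)}
    labels = labels.map(remap)
    nxt = labels.max() + 1 if len(labels) else 1
    for g in constant:
        labels.loc[g] = nxt
        nxt += 1
    return ClusterAssignment(labels.astype(int), Z)


def linkage_to_newick(Z: np.ndarray, leaf_names) -> str:
    """Serialise a scipy linkage matrix as a newick string (branch lengths =
    merge-height differences)."""
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(Z)
    names = list(leaf_names)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

@dataclass
class DensityMatrix:
    """Observed link densities and (optionally) their z-scores."""

    D: pd.DataFrame
    counts: pd.DataFrame
    sizes: pd.Series
    Z: pd.DataFrame | None = None
    undefined: list[tuple[int, int]] = field(default_factory=list)

    @property
    def total_links(self) -> int:
        c = self.counts.to_numpy()
        return int(np.triu(c).sum())

    def significant_pairs(self, z_min: float = 1.5) -> list[tuple[int, int]]:
        """Cluster pairs (i <= j) with z >= ``z_min`` — the edges of the
        cluster-interaction map."""
        if self.Z is None:
            raise ValueError("z-scores not computed")
        out = []
        z = self.Z.to_numpy()
        labs = list(self.Z.index)
        for a in range(len(labs)):
            for b in range(a, len(labs)):
                if np.isfinite(z[a, b]) and z[a, b] >= z_min:
                    out.append((labs[a], labs[b]))
        return out


def _edge_label_arrays(net: SignedNetwork, clusters: ClusterAssignment):
    lab = clusters.labels
    pairs = [(lab[u], lab[v]) for u, v, _ in net.edges()
             if u in lab.index and v in lab.index]
    n_skipped = net.n_edges - len(pairs)
    if n_skipped:
        logger.info("%d edges touch unclustered genes and are excluded",
                    n_skipped)
    if not pairs:
        return np.empty(0, int), np.empty(0, int)
    arr = np.asarray(pairs, dtype=int)
    return arr[:, 0], arr[:, 1]


def _density_from_counts(I: np.ndarray, sizes: np.ndarray):
    k = len(sizes)
    denom = np.outer(sizes, sizes).astype(float)
    diag = sizes * (sizes - 1) / 2.0
    np.fill_diagonal(denom, diag)
    undefined = [(i, i) for i in range(k) if diag[i] == 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        D = np.where(denom > 0, I / denom, 0.0)
    return D, undefined


def _count_matrix(eu: np.ndarray, ev: np.ndarray, k: int) -> np.ndarray:
    """Symmetric cluster-pair link counts from edge label arrays (labels 1..k)."""
    I = np.zeros((k, k), dtype=np.int64)
    np.add.at(I, (eu - 1, ev - 1), 1)
    I = I + I.T
    np.fill_diagonal(I, np.diag(I) // 2)
    return I


def link_density(net: SignedNetwork, clusters: ClusterAssignment) -> DensityMatrix:
    """Observed within/between-cluster DCEL densities.

    Counts are conserved: the upper triangle plus diagonal of the count
    matrix sums to the number of edges with both endpoints clustered.
    Singleton clusters have an undefined within-density, reported as 0 and
    flagged.
    """
    labs = sorted(clusters.labels.unique())
    k = len(labs)
    if labs != list(range(1, k + 1)):
        raise ValueError("cluster labels must be contiguous from 1")
    sizes = clusters.sizes().to_numpy()
    eu, ev = _edge_label_arrays(net, clusters)
    I = _count_matrix(eu, ev, k)
    D, undefined = _density_from_counts(I, sizes)
    index = pd.Index(labs, name="cluster")
    return DensityMatrix(
        D=pd.DataFrame(D, index=index, columns=index),
        counts=pd.DataFrame(I, index=index, columns=index),
        sizes=pd.Series(sizes, index=index),
        undefined=[(labs[i], labs[j]) for i, j in undefined],
    )


def _shuffled_label_edges(lab_values: np.ndarray, pos_u: np.ndarray,
                          pos_v: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(lab_values)
    return perm[pos_u], perm[pos_v]


def _edge_positions(net: SignedNetwork, clusters: ClusterAssignment):
    gene_pos = {g: i for i, g in enumerate(clusters.labels.index)}
    pairs = [(gene_pos[u], gene_pos[v]) for u, v, _ in net.edges()
             if u in gene_pos and v in gene_pos]
    arr = np.asarray(pairs, dtype=int) if pairs else np.empty((0, 2), int)
    return arr[:, 0] if len(arr) else np.empty(0, int), \
        arr[:, 1] if len(arr) else np.empty(0, int)


def density_zscores(net: SignedNetwork, clusters: ClusterAssignment,
                    n_perm: int = 100_000, seed=None) -> DensityMatrix:
    """Densities standardised against the gene-cluster label-shuffling null.

    Per permutation, cluster labels are shuffled over the clustered genes
    (cluster sizes preserved) and all densities recomputed; z = (D - mu)/rho.
    Cells with zero null standard deviation get z = NaN and are flagged.
    """
    if clusters.n_clusters < 2:
        raise ValueError("need >= 2 clusters")
    dm = link_density(net, clusters)
    sizes = dm.sizes.to_numpy()
    k = len(sizes)
    lab_values = clusters.labels.to_numpy()
    pos_u, pos_v = _edge_positions(net, clusters)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    acc = np.zeros((k, k))
    acc2 = np.zeros((k, k))
    for _ in range(n_perm):
        eu, ev = _shuffled_label_edges(lab_values, pos_u, pos_v, rng)
        I = _count_matrix(eu, ev, k)
        Dp, _ = _density_from_counts(I, sizes)
        acc += Dp
        acc2 += Dp ** 2
    mu = acc / n_perm
    var = np.maximum(acc2 / n_perm - mu ** 2, 0.0)
    rho = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = np.where(rho > 0, (dm.D.to_numpy() - mu) / rho, np.nan)
    for i in range(k):
        for j in range(i, k):
            if rho[i, j] == 0:
                dm.undefined.append((int(dm.D.index[i]), int(dm.D.index[j])))
    dm.Z = pd.DataFrame(Z, index=dm.D.index, columns=dm.D.columns)
    return dm


def between_within_ratio_test(net: SignedNetwork, clusters: ClusterAssignment,
                              n_perm: int = 100_000, seed=None
                              ) -> tuple[int, int, float]:
    """Empirical p-value of the between/within-cluster link-count ratio.

    p = fraction of label shuffles whose ratio meets or exceeds the observed
    ratio.  When the observed network has no within-cluster link, the ratio
    is infinite and the test falls back to comparing between-link counts
    (logged).
    """
    lab_values = clusters.labels.to_numpy()
    pos_u, pos_v = _edge_positions(net, clusters)
    eu, ev = lab_values[pos_u], lab_values[pos_v]
    n_within_obs = int((eu == ev).sum())
    n_between_obs = int((eu != ev).sum())
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    use_counts = n_within_obs == 0
    if use_counts:
        logger.warning("no within-cluster edges: p computed on the "
                       "between-cluster count instead of the ratio")
        obs = n_between_obs
    else:
        obs = n_between_obs / n_within_obs
    hits = 0
    for _ in range(n_perm):
        pu, pv = _shuffled_label_edges(lab_values, pos_u, pos_v, rng)
        nb = int((pu != pv).sum())
        nw = len(pu) - nb
        if use_counts:
            stat = nb
        else:
            stat = np.inf if nw == 0 else nb / nw
        hits += stat >= obs
    return n_between_obs, n_within_obs, hits / n_perm
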