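"""Structural characterisation of signed networks and tree-likeness nulls.

Differential coexpression networks are expected to be scale-free but
tree-like: low average clustering and long shortest paths, because the sign
transitivity of coexpression (triangles carry an odd number of positive
edges) suppresses triads in the *difference* of two coexpression networks.
This module quantifies the standard topology statistics and provides the two
null models used to test tree-likeness:

* a degree-preserving double-edge-swap null for the average clustering
  coefficient, and
* a data-randomisation null that rebuilds a size-matched network from
  condition-shuffled expression data and counts its triads.

Edge signs are ignored by the unsigned metrics (degree, clustering, paths);
they matter only to the triad census.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .coexpression import _spearman_from_values, differential_score
from .expression import ExpressionMatrix
from .network import SignedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "TopologySummary",
    "TriadCensus",
    "degree_stats",
    "powerlaw_gamma",
    "clustering_stats",
    "path_stats",
    "degree_preserving_null_C",
    "triad_census",
    "random_dcen_triad_null",
    "coexpression_transitivity_check",
    "summarize_topology",
]


# ---------------------------------------------------------------------------
# basic statistics
# ---------------------------------------------------------------------------

def degree_stats(net: SignedNetwork) -> tuple[float, int, dict[int, float]]:
    """Average degree (2E/N), maximum degree and degree distribution P(k)."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    degrees = [d for _, d in g.degree()]
    avg_k = 2.0 * g.number_of_edges() / g.number_of_nodes()
    ks, counts = np.unique(degrees, return_counts=True)
    pk = {int(k): float(c) / len(degrees) for k, c in zip(ks, counts)}
    return avg_k, int(max(degrees)), pk


def _discrete_pl_nll(gamma: float, log_sum: float, n: int, xmin: int) -> float:
    return n * np.log(zeta(gamma, xmin)) + gamma * log_sum


def powerlaw_gamma(degrees, xmin: int | None = None) -> tuple[float, int]:
    """Discrete maximum-likelihood power-law exponent with KS-selected xmin.

    Fits P(k) ~ k^-gamma for k >= xmin by maximising the discrete power-law
    likelihood (Hurwitz-zeta normalisation); when ``xmin`` is None every
    observed degree is tried as a candidate cutoff and the one minimising the
    Kolmogorov-Smirnov distance between the tail's empirical CDF and the
    fitted model is kept.
    """
    d = np.sort(np.asarray([k for k in degrees if k >= 1], dtype=int))
    if d.size < 10:
        raise ValueError("need >= 10 nodes with degree >= 1")
    if np.unique(d).size == 1:
        raise ValueError("degenerate degree sequence")

    def fit_tail(xm: int) -> tuple[float, float, int]:
        tail = d[d >= xm]
        log_sum = float(np.log(tail).sum())
        res = minimize_scalar(
            _discrete_pl_nll, bounds=(1.01, 8.0), method="bounded",
            args=(log_sum, tail.size, xm))
        g = float(res.x)
        # KS distance between tail ECDF and model CDF
        ks_vals = np.unique(tail)
        z_xm = zeta(g, xm)
        model_cdf = 1.0 - zeta(g, ks_vals + 1) / z_xm
        ecdf = np.searchsorted(np.sort(tail), ks_vals, side="right") / tail.size
        return g, float(np.abs(ecdf - model_cdf).max()), tail.size

    if xmin is not None:
        g, _, _ = fit_tail(int(xmin))
        return g, int(xmin)

    best: tuple[float, float, int] | None = None  # (ks, gamma, xmin)
    for xm in np.unique(d):
        tail_n = int((d >= xm).sum())
        if tail_n < 10:
            break
        g, ks, _ = fit_tail(int(xm))
        if best is None or ks < best[0]:
            best = (ks, g, int(xm))
    assert best is not None
    return best[1], best[2]


def clustering_stats(net: SignedNetwork) -> tuple[float, dict[int, float]]:
    """Average clustering coefficient C and degree-dependent C(k).

    Nodes of degree < 2 have c_i = 0 and are included in the averages.
    """
    g = net.graph
    ci = nx.clustering(g)
    if len(ci) == 0:
        return 0.0, {}
    C = float(np.mean(list(ci.values())))
    by_k: dict[int, list[float]] = {}
    for node, k in g.degree():
        by_k.setdefault(int(k), []).append(ci[node])
    ck = {k: float(np.mean(v)) for k, v in sorted(by_k.items())}
    return C, ck


def path_stats(net: SignedNetwork) -> tuple[float, int, dict[int, int]]:
    """Average shortest path length L, diameter D and distance histogram
    over all unordered node pairs of a connected network."""
    g = net.graph
    if g.number_of_nodes() < 2:
        raise ValueError("need >= 2 nodes")
    if not nx.is_connected(g):
        raise ValueError("pass a connected component")
    hist: dict[int, int] = {}
    total = 0
    count = 0
    # distances are symmetric: accumulate ordered pairs, then halve
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for dd in dists.values():
            if dd == 0:
                continue
            hist[dd] = hist.get(dd, 0) + 1
            total += dd
            count += 1
    L = total / count
    D = max(hist)
    hist = {k: v // 2 for k, v in sorted(hist.items())}
    return float(L), int(D), hist


# ---------------------------------------------------------------------------
# triads
# ---------------------------------------------------------------------------

@dataclass
class TriadCensus:
    """Triangle count partitioned by the number of positive edges (0-3)."""

    n_triads: int
    sign_pattern_counts: dict[int, int] = field(default_factory=dict)

    @property
    def odd_positive_fraction(self) -> float | None:
        """Fraction of triads with an odd number of positive edges (the
        sign patterns compatible with correlation transitivity); None if the
        network has no triads."""
        if self.n_triads == 0:
            return None
        odd = self.sign_pattern_counts.get(1, 0) + self.sign_pattern_counts.get(3, 0)
        return odd / self.n_triads


def triad_census(net: SignedNetwork) -> TriadCensus:
    """Exact triangle enumeration with sign-pattern classification."""
    g = net.graph
    index = {u: i for i, u in enumerate(g.nodes)}
    counts = {0: 0, 1: 0, 2: 0, 3: 0}
    n = 0
    for u, v, duv in g.edges(data=True):
        if index[u] > index[v]:
            u, v = v, u
            # sign unchanged
        for w in set(g[u]) & set(g[v]):
            if index[w] > index[v]:
                n += 1
                npos = sum(1 for s in (duv["sign"], g[u][w]["sign"],
                                       g[v][w]["sign"]) if s > 0)
                counts[npos] += 1
    return TriadCensus(n, {k: v for k, v in counts.items() if v})


def coexpression_transitivity_check(net: SignedNetwork) -> float | None:
    """Fraction of triads with an odd number of positive edges; None when
    the network is triangle-free (reported as undefined)."""
    return triad_census(net).odd_positive_fraction


# ---------------------------------------------------------------------------
# null models
# ---------------------------------------------------------------------------

def degree_preserving_null_C(
    net: SignedNetwork, n_samples: int = 100_000,
    swaps_per_edge: int = 10, seed=None,
) -> tuple[np.ndarray, float]:
    """Null distribution of average clustering under degree-preserving
    rewiring (double-edge-swap Markov chain), plus the empirical p-value of
    the observed C being as low or lower.
    """
    g = net.graph
    E = g.number_of_edges()
    if E < 2:
        raise ValueError("need >= 2 edges to swap")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    C_obs = float(np.mean(list(nx.clustering(g).values())))
    nswap = swaps_per_edge * E
    samples = np.empty(n_samples)
    for i in range(n_samples):
        h = g.copy()
        nx.double_edge_swap(h, nswap=nswap, max_tries=nswap * 100,
                            seed=int(rng.integers(2 ** 31)))
        samples[i] = np.mean(list(nx.clustering(h).values()))
    p = float(np.mean(samples <= C_obs))
    return samples, p


def _score_matrix_pairs(X: np.ndarray, idx_a, idx_b, iu, ju,
                        tie_weight: float) -> np.ndarray:
    Ca = _spearman_from_values(X[:, idx_a])
    Cb = _spearman_from_values(X[:, idx_b])
    return differential_score(Ca[iu, ju], Cb[iu, ju], tie_weight)


def random_dcen_triad_null(
    m_a: ExpressionMatrix, m_b: ExpressionMatrix,
    observed_edge_count: int, n_reps: int = 1000, seed=None,
    tie_weight: float = 1.0, observed_triad_prop: float | None = None,
) -> tuple[np.ndarray, float | None]:
    """Triad proportion (triangles per edge) of size-matched networks built
    from condition-randomised data.

    Per replicate the condition labels of the pooled sample columns are
    shuffled, pairwise scores are recomputed, and the
    ``observed_edge_count`` top-|score| pairs form a random network whose
    triads-per-edge proportion is recorded.  The empirical p-value is the
    fraction of replicates whose proportion is <= the observed one (None if
    no observed proportion is supplied).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    genes = list(m_a.row_ids)
    A = m_a.values.to_numpy(dtype=float)
    B = m_b.values.loc[genes].to_numpy(dtype=float)
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    if observed_edge_count > iu.size:
        raise ValueError("observed_edge_count exceeds the number of gene pairs")
    X = np.concatenate([A, B], axis=1)
    n_a = A.shape[1]
    props = np.empty(n_reps)
    for r in range(n_reps):
        perm = rng.permutation(X.shape[1])
        s = _score_matrix_pairs(X, perm[:n_a], perm[n_a:], iu, ju, tie_weight)
        s = np.where(np.isnan(s), -np.inf, np.abs(s))
        top = np.argpartition(s, -observed_edge_count)[-observed_edge_count:]
        g = nx.Graph()
        g.add_edges_from(zip(iu[top], ju[top]))
        n_tri = sum(nx.triangles(g).values()) // 3
        props[r] = n_tri / observed_edge_count
    p = None
    if observed_triad_prop is not None:
        p = float(np.mean(props <= observed_triad_prop))
    return props, p


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

@dataclass
class TopologySummary:
    """Flat record of the standard network statistics."""

    n_nodes: int
    n_edges: int
    n_pos: int
    n_neg: int
    avg_degree: float
    max_degree: int
    gamma: float | None
    xmin: int | None
    avg_clustering: float
    diameter: int | None
    avg_shortest_path: float | None
    degree_distribution: dict[int, float]
    ck_curve: dict[int, float]

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["degree_distribution"] = {str(k): v for k, v
                                    in self.degree_distribution.items()}
        d["ck_curve"] = {str(k): v for k, v in self.ck_curve.items()}
        return d


def summarize_topology(net: SignedNetwork, fit_gamma: bool = True) -> TopologySummary:
    """Compute the full statistics table for one network.

    Path statistics are computed only when the network is connected (callers
    normally pass the largest component); gamma fitting is skipped on
    degenerate degree sequences.
    """
    avg_k, max_k, pk = degree_stats(net)
    C, ck = clustering_stats(net)
    gamma = xmin = None
    if fit_gamma:
        try:
            gamma, xmin = powerlaw_gamma([d for _, d in net.graph.degree()])
        except ValueError as exc:
            logger.warning("gamma fit skipped: %s", exc)
    L = D = None
    if net.n_nodes >= 2 and nx.is_connected(net.graph):
        L, D, _ = path_stats(net)
    return TopologySummary(
        n_nodes=net.n_nodes, n_edges=net.n_edges,
        n_pos=net.n_positive, n_neg=net.n_negative,
        avg_degree=avg_k, max_degree=max_k, gamma=gamma, xmin=xmin,
        avg_clustering=C, diameter=D, avg_shortest_path=L,
        degree_distribution=pk, ck_curve=ck,
    )
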