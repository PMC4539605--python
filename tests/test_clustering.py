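"""Functional clustering and link-density randomisation statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dcnet.clustering import (
    ClusterAssignment,
    between_within_ratio_test,
    cluster_profiles,
    density_zscores,
    link_density,
    linkage_to_newick,
)
from dcnet.network import assemble_network


def brute_force_average_linkage(dist, n_clusters):
    """Independent O(n^3) agglomerative average-linkage oracle."""
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    while len(clusters) > n_clusters:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([dist[i, j] for i in clusters[a]
                         for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return {frozenset(c) for c in clusters}


def partition_of(assign: ClusterAssignment, index):
    pos = {g: i for i, g in enumerate(index)}
    out = {}
    for g, lab in assign.labels.items():
        out.setdefault(lab, set()).add(pos[g])
    return {frozenset(v) for v in out.values()}


class TestClusterProfiles:
    def test_two_block_matrix(self):
        M = np.full((6, 6), 0.1)
        M[:3, :3] = 0.9
        M[3:, 3:] = 0.9
        np.fill_diagonal(M, 1.0)
        sim = pd.DataFrame(M, index=list("abcdef"), columns=list("abcdef"))
        assign = cluster_profiles(sim, n_clusters=2)
        assert partition_of(assign, sim.index) == {
            frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_all_singletons(self, rng):
        M = rng.uniform(size=(4, 4))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        sim = pd.DataFrame(M, index=list("abcd"), columns=list("abcd"))
        assign = cluster_profiles(sim, n_clusters=4)
        assert assign.n_clusters == 4

    def test_agrees_with_brute_force_oracle(self, rng):
        """Average-linkage on the profile-correlation distance matches an
        independent O(n^3) agglomeration on 7-gene instances."""
        n = 7
        for trial in range(100):
            M = rng.uniform(size=(n, n))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 1.0)
            sim = pd.DataFrame(M, index=[f"g{i}" for i in range(n)],
                               columns=[f"g{i}" for i in range(n)])
            corr = np.corrcoef(M)
            dist = 1 - corr
            np.fill_diagonal(dist, 0.0)
            for k in (2, 3):
                got = partition_of(cluster_profiles(sim, n_clusters=k),
                                   sim.index)
                want = brute_force_average_linkage(dist, k)
                assert got == want, f"trial {trial}, k={k}"

    def test_exactly_one_cut_parameter(self):
        sim = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError):
            cluster_profiles(sim)
        with pytest.raises(ValueError):
            cluster_profiles(sim, n_clusters=2, cut_height=0.5)

    def test_newick_export_contains_all_leaves(self, rng):
        M = rng.uniform(size=(5, 5))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        sim = pd.DataFrame(M, index=list("abcde"), columns=list("abcde"))
        assign = cluster_profiles(sim, n_clusters=2)
        nwk = linkage_to_newick(assign.linkage, sim.index)
        assert nwk.endswith(";")
        for leaf in "abcde":
            assert leaf in nwk


def two_cluster_setup(all_between=True):
    """Clusters of sizes 3 and 4; 6 between-cluster links."""
    xs = [f"x{i}" for i in range(3)]
    ys = [f"y{i}" for i in range(4)]
    pairs = [(0, 0), (0, 1), (1, 0), (1, 2), (2, 3), (2, 2)]
    edges = [(xs[i], ys[j], 1) for i, j in pairs]
    if not all_between:
        edges.append((xs[0], xs[1], 1))
    net = assemble_network(edges)
    labels = pd.Series({**{g: 1 for g in xs}, **{g: 2 for g in ys}})
    return net, ClusterAssignment(labels)


class TestLinkDensity:
    def test_hand_between_density(self):
        net, clusters = two_cluster_setup()
        dm = link_density(net, clusters)
        assert dm.D.loc[1, 2] == pytest.approx(6 / 12)
        assert dm.total_links == 6

    def test_complete_triangle_within(self):
        net = assemble_network([("a", "b", 1), ("b", "c", 1), ("a", "c", 1),
                                ("a", "d", 1)])
        labels = pd.Series({"a": 1, "b": 1, "c": 1, "d": 2})
        dm = link_density(net, ClusterAssignment(labels))
        assert dm.D.loc[1, 1] == pytest.approx(1.0)
        assert (1, 2) not in dm.undefined  # only singleton diagonal flagged
        assert (2, 2) in dm.undefined

    def test_counts_conserved(self):
        net, clusters = two_cluster_setup(all_between=False)
        dm = link_density(net, clusters)
        assert dm.total_links == net.n_edges

    def test_no_edges(self):
        net = assemble_network([])
        net.add_isolate("a")
        net.add_isolate("b")
        net.add_isolate("c")
        labels = pd.Series({"a": 1, "b": 1, "c": 2})
        dm = link_density(net, ClusterAssignment(labels))
        assert (dm.D.to_numpy() == 0).all()


class TestDensityZ:
    def test_planted_between_direction(self):
        net, clusters = two_cluster_setup()
        dm = density_zscores(net, clusters, n_perm=1000, seed=1)
        assert dm.Z.loc[1, 2] > 1.5
        assert dm.Z.loc[1, 1] < 0
        assert dm.Z.loc[2, 2] < 0

    def test_reproducible(self):
        net, clusters = two_cluster_setup(all_between=False)
        d1 = density_zscores(net, clusters, n_perm=300, seed=9)
        d2 = density_zscores(net, clusters, n_perm=300, seed=9)
        pd.testing.assert_frame_equal(d1.Z, d2.Z)

    def test_invariant_to_cluster_relabeling(self):
        net, clusters = two_cluster_setup(all_between=False)
        swapped = ClusterAssignment(clusters.labels.map({1: 2, 2: 1}))
        d1 = density_zscores(net, clusters, n_perm=400, seed=3)
        d2 = density_zscores(net, swapped, n_perm=400, seed=3)
        assert d1.Z.loc[1, 2] == pytest.approx(d2.Z.loc[1, 2])
        assert d1.Z.loc[1, 1] == pytest.approx(d2.Z.loc[2, 2])


class TestRatioTest:
    def test_all_between_gives_small_p(self):
        net, clusters = two_cluster_setup()
        nb, nw, p = between_within_ratio_test(net, clusters, n_perm=500,
                                              seed=2)
        assert (nb, nw) == (6, 0)
        assert p < 0.1

    def test_ratio_statistic_reported(self):
        net, clusters = two_cluster_setup(all_between=False)
        nb, nw, p = between_within_ratio_test(net, clusters, n_perm=500,
                                              seed=2)
        assert (nb, nw) == (6, 1)
        assert 0 <= p <= 1

    def test_calibration_on_random_graph(self, rng):
        """Random clustering of a random graph: p is approximately uniform
        over replicates."""
        import networkx as nx

        from dcnet.network import SignedNetwork

        ps = []
        for rep in range(60):
            g = nx.gnm_random_graph(16, 28, seed=100 + rep)
            net = SignedNetwork()
            for u, v in g.edges():
                net.add_edge(u, v, 1)
            labels = pd.Series(
                rng.permutation([1] * 8 + [2] * 8), index=range(16))
            _, _, p = between_within_ratio_test(
                net, ClusterAssignment(labels), n_perm=200,
                seed=int(rng.integers(2 ** 31)))
            ps.append(p)
        ps = np.asarray(ps)
        # discrete & conservative, but far from degenerate
        assert 0.2 < ps.mean() < 0.8
        assert (ps < 0.05).mean() < 0.2
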