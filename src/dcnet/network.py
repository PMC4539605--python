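"""Signed undirected networks and their standard-format exports.

A :class:`SignedNetwork` wraps a :class:`networkx.Graph` whose edges carry a
``sign`` (+1/-1), an ``etype`` (``"DCEL"``, ``"CCEL"`` or ``"generic"``) and a
``weight``.  It is the unit every topology operation consumes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "SignedNetwork",
    "assemble_network",
    "connected_components",
    "edge_overlap",
    "export_network",
    "load_network",
]

_SIF_REL = {1: "pos", -1: "neg"}
_SIF_REL_INV = {v: k for k, v in _SIF_REL.items()}


class SignedNetwork:
    """Undirected signed graph: no self-loops, no duplicate edges."""

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    # -- construction ---------------------------------------------------
    def add_edge(self, u, v, sign: int = 1, etype: str = "generic",
                 weight: float = 1.0) -> None:
        if u == v:
            raise ValueError(f"self-loop on {u!r} not allowed")
        if sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")
        if self.graph.has_edge(u, v):
            if self.graph[u][v]["sign"] != sign:
                raise ValueError(f"duplicate edge ({u},{v}) with conflicting signs")
            return
        self.graph.add_edge(u, v, sign=sign, etype=etype, weight=float(weight))

    def add_isolate(self, u) -> None:
        self.graph.add_node(u)

    # -- counts ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_positive(self) -> int:
        return sum(1 for *_, d in self.graph.edges(data=True) if d["sign"] > 0)

    @property
    def n_negative(self) -> int:
        return self.n_edges - self.n_positive

    def edges(self):
        return self.graph.edges(data=True)

    def subgraph(self, nodes) -> "SignedNetwork":
        return SignedNetwork(self.graph.subgraph(nodes).copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, SignedNetwork):
            return NotImplemented
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        a = {frozenset(e): (d["sign"], d["etype"]) for *e, d in self.edges()}
        b = {frozenset(e): (d["sign"], d["etype"]) for *e, d in other.edges()}
        return a == b

    def __repr__(self) -> str:
        return (f"SignedNetwork(nodes={self.n_nodes}, edges={self.n_edges}, "
                f"pos={self.n_positive}, neg={self.n_negative})")


def assemble_network(
    edges: Iterable[tuple], edge_type: str = "DCEL",
    isolates: Sequence | None = None,
) -> SignedNetwork:
    """Build a SignedNetwork from ``(u, v, sign[, weight])`` tuples.

    Duplicate pairs with conflicting signs raise; consistent duplicates are
    merged silently.
    """
    net = SignedNetwork()
    for edge in edges:
        u, v, sign = edge[0], edge[1], edge[2]
        weight = edge[3] if len(edge) > 3 else 1.0
        net.add_edge(u, v, sign=int(sign), etype=edge_type, weight=weight)
    for u in isolates or ():
        net.add_isolate(u)
    return net


def connected_components(net: SignedNetwork) -> list[list]:
    """Components as node lists, largest first; ties broken by the
    lexicographically smallest member id."""
    comps = [sorted(c, key=str) for c in nx.connected_components(net.graph)]
    comps.sort(key=lambda c: (-len(c), str(c[0])))
    return comps


def edge_overlap(net: SignedNetwork, reference_edges: Iterable[tuple]) -> tuple[int, list]:
    """Count unordered-pair overlap between the network and a reference
    edge list (e.g. a protein-protein interaction export)."""
    ref = {frozenset((u, v)) for u, v in reference_edges}
    hits = [tuple(sorted(e, key=str)) for e in
            ({frozenset((u, v)) for u, v, _ in net.graph.edges(data=True)} & ref)]
    hits.sort()
    return len(hits), hits


# -- serialisation ------------------------------------------------------

def export_network(net: SignedNetwork, path: str | Path, fmt: str = "tsv") -> None:
    """Write the network as ``tsv``, ``sif`` or ``graphml`` (round-trip safe)."""
    path = Path(path)
    if fmt == "tsv":
        rows = [(u, v, d["sign"], d["etype"], d["weight"])
                for u, v, d in net.edges()]
        df = pd.DataFrame(rows, columns=["gene_u", "gene_v", "sign", "etype", "weight"])
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, d in net.edges():
                fh.write(f"{u}\t{_SIF_REL[d['sign']]}\t{v}\n")
    elif fmt == "graphml":
        nx.write_graphml(net.graph, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_network(path: str | Path, fmt: str = "tsv") -> SignedNetwork:
    path = Path(path)
    net = SignedNetwork()
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"gene_u": str, "gene_v": str})
        for row in df.itertuples(index=False):
            net.add_edge(row.gene_u, row.gene_v, sign=int(row.sign),
                         etype=str(row.etype), weight=float(row.weight))
    elif fmt == "sif":
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                u, rel, v = line.rstrip("\n").split("\t")
                net.add_edge(u, v, sign=_SIF_REL_INV[rel])
    elif fmt == "graphml":
        g = nx.read_graphml(path)
        for u, v, d in g.edges(data=True):
            net.add_edge(u, v, sign=int(d.get("sign", 1)),
                         etype=str(d.get("etype", "generic")),
                         weight=float(d.get("weight", 1.0)))
        for u in g.nodes:
            net.graph.add_node(u)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return net
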