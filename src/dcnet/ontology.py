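"""GO loading, information content, semantic similarity and enrichment.

Similarity follows the relevance measure: for terms t1, t2 with annotation
probabilities p(t) (term frequency after propagating gene annotations to all
is_a ancestors),

    s(t1, t2) = max over common ancestors c of
                [2 ln p(c) / (ln p(t1) + ln p(t2))] * (1 - p(c))

i.e. Lin's ratio weighted by (1 - p) of the most informative common
ancestor, so similarity through the root (p = 1) is zero.  Gene-level
similarity (funSim) is the best-match average over the two genes' term sets.
Enrichment is the upper-tail hypergeometric test with BH correction.

Only the biological_process namespace is used; annotations inferred from
expression pattern (IEP) or genetic interaction (IGI) are excluded by
default because they are circular evidence for coexpression analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from scipy.stats import hypergeom

from .coexpression import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyDAG",
    "AnnotationTable",
    "OntologyBundle",
    "load_obo",
    "read_annotations",
    "filter_annotations",
    "information_content",
    "sim_rel",
    "funsim_bma",
    "similarity_matrix",
    "hypergeom_enrich",
]

DEFAULT_EXCLUDED_CODES = frozenset({"IEP", "IGI"})


class OntologyDAG:
    """Rooted is_a DAG of ontology terms (one namespace)."""

    def __init__(self, parents: dict[str, set[str]],
                 names: dict[str, str] | None = None,
                 namespace: str = "biological_process"):
        self.parents = {t: set(p) for t, p in parents.items()}
        self.names = names or {}
        self.namespace = namespace
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for t, ps in self.parents.items():
            for p in ps:
                if p not in self.parents:
                    raise ValueError(f"parent {p!r} of {t!r} is not a term")
                g.add_edge(t, p)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology contains a cycle")
        roots = [t for t, ps in self.parents.items() if not ps]
        if len(roots) != 1:
            raise ValueError(f"expected one root, found {roots}")
        self.root = roots[0]
        self._graph = g
        self._anc_cache: dict[str, frozenset[str]] = {}

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def __len__(self) -> int:
        return len(self.parents)

    @property
    def terms(self) -> list[str]:
        return list(self.parents)

    def ancestors(self, term: str) -> frozenset[str]:
        """Proper is_a ancestors of ``term`` (excludes ``term`` itself)."""
        if term not in self._anc_cache:
            self._anc_cache[term] = frozenset(nx.descendants(self._graph, term))
        return self._anc_cache[term]

    def common_ancestors(self, t1: str, t2: str) -> frozenset[str]:
        """Shared ancestors, each term counted as its own ancestor."""
        return (self.ancestors(t1) | {t1}) & (self.ancestors(t2) | {t2})

    def write_obo(self, path: str | Path) -> None:
        """Minimal OBO 1.2 writer (round-trips through :func:`load_obo`)."""
        lines = ["format-version: 1.2", ""]
        for t in self.terms:
            lines += [
                "[Term]",
                f"id: {t}",
                f"name: {self.names.get(t, t)}",
                f"namespace: {self.namespace}",
            ]
            lines += [f"is_a: {p} ! {self.names.get(p, p)}"
                      for p in sorted(self.parents[t])]
            lines.append("")
        Path(path).write_text("\n".join(lines))


def load_obo(path: str | Path, namespace: str = "biological_process",
             include_part_of: bool = False) -> OntologyDAG:
    """Parse an OBO 1.2 file, keeping one namespace; obsolete terms dropped.

    is_a links define the DAG; ``include_part_of=True`` additionally treats
    part_of relationships as parent links.
    """
    g = obonet.read_obo(str(path))
    keep = {t for t, d in g.nodes(data=True)
            if d.get("namespace", namespace) == namespace
            and not d.get("is_obsolete", False)}
    parents: dict[str, set[str]] = {t: set() for t in keep}
    names = {t: g.nodes[t].get("name", t) for t in keep}
    for t in keep:
        for p in g.nodes[t].get("is_a", []):
            if p in keep:
                parents[t].add(p)
        if include_part_of:
            for rel in g.nodes[t].get("relationship", []):
                kind, _, target = rel.partition(" ")
                if kind == "part_of" and target in keep:
                    parents[t].add(target)
    return OntologyDAG(parents, names, namespace)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTable:
    """gene -> set of (term, evidence_code)."""

    annotations: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.annotations)

    def terms_of(self, gene: str) -> set[str]:
        return {t for t, _ in self.annotations.get(gene, ())}

    def __len__(self) -> int:
        return sum(len(v) for v in self.annotations.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, t, e) for g, anns in self.annotations.items()
                for t, e in sorted(anns)]
        return pd.DataFrame(rows, columns=["gene", "term", "evidence"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, header=False)


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read the reduced 3-column annotation dialect (gene, term, evidence)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["gene", "term", "evidence"], dtype=str, comment="!")
    ann: dict[str, set[tuple[str, str]]] = {}
    for row in df.itertuples(index=False):
        ann.setdefault(row.gene, set()).add((row.term, row.evidence))
    return AnnotationTable(ann)


def filter_annotations(
    ann: AnnotationTable,
    excluded_codes: frozenset[str] | set[str] = DEFAULT_EXCLUDED_CODES,
) -> AnnotationTable:
    """Drop annotations carrying excluded evidence codes; genes left with no
    annotation are removed (count logged)."""
    out: dict[str, set[tuple[str, str]]] = {}
    n_emptied = 0
    for gene, anns in ann.annotations.items():
        kept = {(t, e) for t, e in anns if e not in excluded_codes}
        if kept:
            out[gene] = kept
        else:
            n_emptied += 1
    if n_emptied:
        logger.info("filter_annotations: %d genes left without annotations",
                    n_emptied)
    return AnnotationTable(out)


# ---------------------------------------------------------------------------
# information content and similarity
# ---------------------------------------------------------------------------

def information_content(dag: OntologyDAG, ann: AnnotationTable) -> dict[str, float]:
    """Term probability p(t): fraction of annotated genes annotated to t or
    any of its descendants (annotation propagation to ancestors)."""
    term_genes: dict[str, set[str]] = {t: set() for t in dag.terms}
    annotated_genes = set()
    for gene in ann.genes:
        terms = {t for t in ann.terms_of(gene) if t in dag}
        if not terms:
            continue
        annotated_genes.add(gene)
        for t in terms:
            term_genes[t].add(gene)
            for a in dag.ancestors(t):
                term_genes[a].add(gene)
    n = len(annotated_genes)
    if n == 0:
        raise ValueError("no usable annotations in the DAG's namespace")
    return {t: len(gs) / n for t, gs in term_genes.items() if gs}


def sim_rel(t1: str, t2: str, ic: dict[str, float], dag: OntologyDAG) -> float:
    """Relevance similarity of two terms in [0, 1] (symmetric)."""
    p1, p2 = ic.get(t1), ic.get(t2)
    if p1 is None or p2 is None:
        raise ValueError("both terms need a defined annotation probability")
    denom = np.log(p1) + np.log(p2)
    best = 0.0
    for c in dag.common_ancestors(t1, t2):
        pc = ic.get(c)
        if pc is None:
            continue
        if denom == 0.0:
            # both terms at p=1: no information to share
            s = 0.0
        else:
            s = (2.0 * np.log(pc) / denom) * (1.0 - pc)
        best = max(best, s)
    return float(min(best, 1.0))


def funsim_bma(gene_a: str, gene_b: str, ann: AnnotationTable,
               ic: dict[str, float], dag: OntologyDAG) -> float:
    """Gene functional similarity: best-match average of the term-pair
    similarity matrix of the two genes' (direct) annotation sets."""
    ta = sorted(t for t in ann.terms_of(gene_a) if t in ic)
    tb = sorted(t for t in ann.terms_of(gene_b) if t in ic)
    if not ta or not tb:
        raise ValueError(
            f"no usable annotations for {gene_a if not ta else gene_b!r}")
    S = np.array([[sim_rel(i, j, ic, dag) for j in tb] for i in ta])
    return float(0.5 * (S.max(axis=1).mean() + S.max(axis=0).mean()))


def similarity_matrix(genes, ann: AnnotationTable, ic: dict[str, float],
                      dag: OntologyDAG) -> pd.DataFrame:
    """Symmetric funSim matrix over the annotated subset of ``genes``.

    Genes without usable annotations are excluded (count logged); duplicate
    ids raise.
    """
    genes = list(genes)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids")
    usable = [g for g in genes
              if any(t in ic for t in ann.terms_of(g))]
    n_skip = len(genes) - len(usable)
    if n_skip:
        logger.info("similarity_matrix: %d genes lack annotations", n_skip)
    n = len(usable)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            M[i, j] = M[j, i] = funsim_bma(usable[i], usable[j], ann, ic, dag)
    return pd.DataFrame(M, index=usable, columns=usable)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def _propagated_gene_terms(genes, ann: AnnotationTable,
                           dag: OntologyDAG) -> dict[str, set[str]]:
    out = {}
    for g in genes:
        direct = {t for t in ann.terms_of(g) if t in dag}
        full = set(direct)
        for t in direct:
            full |= dag.ancestors(t)
        out[g] = full
    return out


def hypergeom_enrich(test_set, reference_set, ann: AnnotationTable,
                     dag: OntologyDAG) -> pd.DataFrame:
    """Per-term upper-tail hypergeometric enrichment with BH correction.

    For a test set of n genes, k annotated to term g, inside a reference set
    of N genes with M annotated to g, p = P(X >= k) under
    Hypergeometric(N, M, n).  Only terms with M >= 1 and k >= 1 are tested.
    """
    test = set(test_set)
    ref = set(reference_set)
    if not test:
        raise ValueError("empty test set")
    if not test <= ref:
        raise ValueError("test set must be a subset of the reference set")
    terms_by_gene = _propagated_gene_terms(ref, ann, dag)
    M_count: dict[str, int] = {}
    k_count: dict[str, int] = {}
    for g, terms in terms_by_gene.items():
        for t in terms:
            M_count[t] = M_count.get(t, 0) + 1
            if g in test:
                k_count[t] = k_count.get(t, 0) + 1
    N, n = len(ref), len(test)
    rows = []
    for t, k in sorted(k_count.items()):
        M = M_count[t]
        p = float(hypergeom.sf(k - 1, N, M, n))
        rows.append((t, k, n, M, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "k", "n", "M", "N", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values(["q", "p", "term"]).reset_index(drop=True)


@dataclass
class OntologyBundle:
    """DAG + filtered annotations + information-content map, loaded once."""

    dag: OntologyDAG
    annotations: AnnotationTable
    ic: dict[str, float]

    @classmethod
    def load(cls, obo_path, annotation_path,
             excluded_codes=DEFAULT_EXCLUDED_CODES,
             namespace: str = "biological_process") -> "OntologyBundle":
        dag = load_obo(obo_path, namespace=namespace)
        ann = filter_annotations(read_annotations(annotation_path),
                                 excluded_codes)
        return cls(dag, ann, information_content(dag, ann))
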