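"""GO loading, information content, semantic similarity, enrichment."""

import math
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from dcnet.ontology import (
    AnnotationTable,
    OntologyDAG,
    filter_annotations,
    funsim_bma,
    hypergeom_enrich,
    information_content,
    load_obo,
    read_annotations,
    sim_rel,
    similarity_matrix,
)
from dcnet.synthetic import generate_toy_ontology


def hypergeom_tail_oracle(k, N, M, n):
    """Exhaustive upper-tail enumeration, P(X >= k)."""
    total = math.comb(N, n)
    return sum(math.comb(M, i) * math.comb(N - M, n - i)
               for i in range(k, min(M, n) + 1)) / total


class TestDagAndObo:
    def test_obo_round_trip(self, tmp_path):
        dag = OntologyDAG({"GO:1": set(), "GO:2": {"GO:1"},
                           "GO:3": {"GO:1", "GO:2"}})
        path = tmp_path / "toy.obo"
        dag.write_obo(path)
        back = load_obo(path)
        assert set(back.terms) == set(dag.terms)
        assert back.parents == dag.parents
        assert back.root == "GO:1"

    def test_other_namespace_excluded(self, tmp_path):
        text = """format-version: 1.2

[Term]
id: GO:1
name: root
namespace: biological_process

[Term]
id: GO:2
name: child
namespace: biological_process
is_a: GO:1 ! root

[Term]
id: GO:9
name: mf term
namespace: molecular_function
"""
        p = tmp_path / "ns.obo"
        p.write_text(text)
        dag = load_obo(p)
        assert "GO:9" not in dag
        assert len(dag) == 2

    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            OntologyDAG({"A": {"B"}, "B": {"A"}, "R": set()})


class TestAnnotationFilter:
    def test_excluded_codes_removed(self):
        ann = AnnotationTable({"g1": {("T", "IEP")},
                               "g2": {("T", "IEP"), ("U", "EXP")}})
        out = filter_annotations(ann)
        assert "g1" not in out.annotations
        assert out.annotations["g2"] == {("U", "EXP")}

    def test_empty_exclusion_is_identity(self):
        ann = AnnotationTable({"g": {("T", "IEP")}})
        assert filter_annotations(ann, set()).annotations == ann.annotations

    def test_filter_never_adds(self, rng):
        dag, ann = generate_toy_ontology(12, 20, seed=3)
        out = filter_annotations(ann)
        for g, anns in out.annotations.items():
            assert anns <= ann.annotations[g]


class TestInformationContent:
    def test_chain_propagation(self):
        dag = OntologyDAG({"R": set(), "A": {"R"}, "B": {"A"}})
        ann = AnnotationTable({
            "g1": {("B", "EXP")}, "g2": {("A", "EXP")},
            "g3": {("R", "EXP")}, "g4": {("R", "EXP")},
        })
        ic = information_content(dag, ann)
        assert ic["R"] == 1.0
        assert ic["A"] == 0.5
        assert ic["B"] == 0.25

    def test_monotone_towards_root(self):
        dag, ann = generate_toy_ontology(15, 25, seed=7)
        ic = information_content(dag, filter_annotations(ann))
        for t, p in ic.items():
            for a in dag.ancestors(t):
                assert ic[a] >= p - 1e-12


class TestSimRel:
    def test_self_similarity(self, chain_dag):
        dag, ic = chain_dag
        assert sim_rel("B", "B", ic, dag) == pytest.approx(0.75)

    def test_chain_mica(self, chain_dag):
        dag, ic = chain_dag
        assert sim_rel("A", "B", ic, dag) == pytest.approx(1 / 3)

    def test_root_only_ancestry_is_zero(self):
        dag = OntologyDAG({"R": set(), "A": {"R"}, "B": {"R"}})
        ic = {"R": 1.0, "A": 0.5, "B": 0.5}
        assert sim_rel("A", "B", ic, dag) == 0.0
        assert sim_rel("R", "R", ic, dag) == 0.0

    def test_bounded_and_symmetric_on_random_dags(self):
        dag, ann = generate_toy_ontology(20, 30, seed=5)
        ic = information_content(dag, filter_annotations(ann))
        terms = [t for t in dag.terms if t in ic][:10]
        for t1, t2 in itertools.combinations(terms, 2):
            s12 = sim_rel(t1, t2, ic, dag)
            assert 0.0 <= s12 <= 1.0
            assert s12 == pytest.approx(sim_rel(t2, t1, ic, dag))


class TestFunSim:
    def test_identical_single_term(self, chain_dag):
        dag, ic = chain_dag
        ann = AnnotationTable({"x": {("B", "EXP")}, "y": {("B", "EXP")}})
        assert funsim_bma("x", "y", ann, ic, dag) == pytest.approx(0.75)

    def test_root_level_only_gives_zero(self):
        dag = OntologyDAG({"R": set(), "A": {"R"}, "B": {"R"}})
        ic = {"R": 1.0, "A": 0.5, "B": 0.5}
        ann = AnnotationTable({"x": {("A", "EXP")}, "y": {("B", "EXP")}})
        assert funsim_bma("x", "y", ann, ic, dag) == 0.0

    def test_unannotated_gene_errors(self, chain_dag):
        dag, ic = chain_dag
        ann = AnnotationTable({"x": {("B", "EXP")}})
        with pytest.raises(ValueError, match="no usable annotations"):
            funsim_bma("x", "nobody", ann, ic, dag)

    def test_matrix_consistent_with_pairwise_calls(self):
        dag, ann0 = generate_toy_ontology(15, 8, seed=9)
        ann = filter_annotations(ann0)
        ic = information_content(dag, ann)
        genes = ann.genes[:5]
        M = similarity_matrix(genes, ann, ic, dag)
        assert np.allclose(M, M.T)
        for g1 in M.index:
            for g2 in M.columns:
                assert M.loc[g1, g2] == pytest.approx(
                    funsim_bma(g1, g2, ann, ic, dag))

    def test_duplicate_ids_rejected(self, chain_dag):
        dag, ic = chain_dag
        ann = AnnotationTable({"x": {("B", "EXP")}})
        with pytest.raises(ValueError, match="duplicate"):
            similarity_matrix(["x", "x"], ann, ic, dag)


class TestEnrichment:
    def _setup(self):
        dag = OntologyDAG({"R": set(), "T": {"R"}})
        ann = AnnotationTable(
            {f"g{i}": {("T", "EXP")} for i in range(5)}
            | {f"g{i}": {("R", "EXP")} for i in range(5, 10)})
        return dag, ann

    def test_hand_tail_value(self):
        dag, ann = self._setup()
        out = hypergeom_enrich({"g0", "g1"}, {f"g{i}" for i in range(10)},
                               ann, dag)
        row = out.set_index("term").loc["T"]
        assert row["p"] == pytest.approx(10 / 45)

    def test_test_equals_reference_gives_p_one(self):
        dag, ann = self._setup()
        ref = {f"g{i}" for i in range(10)}
        out = hypergeom_enrich(ref, ref, ann, dag)
        assert (out["p"] == 1.0).all()

    def test_empty_test_set_errors(self):
        dag, ann = self._setup()
        with pytest.raises(ValueError, match="empty test set"):
            hypergeom_enrich(set(), {"g0"}, ann, dag)

    @given(st.integers(1, 12), st.data())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_tail_matches_exhaustive_enumeration(self, N, data):
        M = data.draw(st.integers(0, N))
        n = data.draw(st.integers(1, N))
        k = data.draw(st.integers(0, min(M, n)))
        assert float(hypergeom.sf(k - 1, N, M, n)) == pytest.approx(
            hypergeom_tail_oracle(k, N, M, n), abs=1e-12)


class TestRoundTripAnnotations:
    def test_tsv_round_trip(self, tmp_path):
        ann = AnnotationTable({"g1": {("GO:2", "EXP"), ("GO:3", "IEP")},
                               "g2": {("GO:2", "IDA")}})
        p = tmp_path / "ann.tsv"
        ann.to_tsv(p)
        back = read_annotations(p)
        assert back.annotations == ann.annotations
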