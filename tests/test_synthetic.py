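"""Synthetic generator: planted truth enumeration, determinism, fidelity."""

from itertools import combinations

import numpy as np
import pytest

from dcnet.coexpression import spearman_matrix
from dcnet.synthetic import (
    ModuleSpec,
    SyntheticSpec,
    SyntheticTruth,
    generate_expression_pair,
    generate_tf_table,
    generate_toy_ontology,
    standard_modules,
    write_bundle,
)


def spec_with(modules, n_genes=30, **kw):
    return SyntheticSpec(n_genes=n_genes, modules=modules, **kw)


class TestExpressionPair:
    def test_same_seed_bit_identical(self):
        spec = spec_with(standard_modules(30, module_size=6,
                                          n_rewired_pos=1, n_rewired_neg=1,
                                          n_ccel=1), seed=3)
        a1, b1, _ = generate_expression_pair(spec)
        a2, b2, _ = generate_expression_pair(spec)
        assert a1.values.equals(a2.values)
        assert b1.values.equals(b2.values)

    def test_one_condition_module_pair_count(self):
        mod = ModuleSpec(tuple(f"G{i:04d}" for i in range(1, 6)),
                         coexpr_a=True, coexpr_b=False)
        _, _, truth = generate_expression_pair(spec_with([mod], n_genes=10))
        assert len(truth.planted_dcels) == 10  # C(5,2)
        assert all(s == -1 for s in truth.dcel_signs.values())

    def test_rewired_module_truth_partition(self):
        genes = tuple(f"G{i:04d}" for i in range(1, 9))
        mod = ModuleSpec(genes, True, True, flip_half_in="b")
        _, _, truth = generate_expression_pair(spec_with([mod], n_genes=12))
        # cross-half pairs are differential, same-half pairs constitutive
        assert len(truth.planted_dcels) == 16
        assert len(truth.planted_ccels) == 12
        assert truth.planted_dcels.isdisjoint(truth.planted_ccels)
        assert all(s == -1 for s in truth.dcel_signs.values())

    def test_near_zero_noise_gives_perfect_coexpression(self):
        mod = ModuleSpec(tuple(f"G{i:04d}" for i in range(1, 6)), True, True)
        spec = spec_with([mod], n_genes=8, noise_sd=1e-9, seed=2)
        m_a, m_b, truth = generate_expression_pair(spec)
        Ca, Cb = spearman_matrix(m_a), spearman_matrix(m_b)
        for pair in truth.planted_ccels:
            u, v = sorted(pair)
            assert Ca.loc[u, v] == pytest.approx(1.0)
            assert Cb.loc[u, v] == pytest.approx(1.0)

    def test_strong_signal_high_within_condition_correlation(self):
        """At SNR 10 and >= 12 timepoints, planted coexpressed pairs have
        within-condition Spearman > 0.9 almost surely."""
        mods = standard_modules(40, module_size=8, n_rewired_pos=1,
                                n_rewired_neg=1, n_ccel=1)
        spec = spec_with(mods, n_genes=40, noise_sd=0.1, seed=6)
        m_a, m_b, truth = generate_expression_pair(spec)
        Ca, Cb = spearman_matrix(m_a), spearman_matrix(m_b)
        vals = []
        for mod in mods:
            for cond, C in (("a", Ca), ("b", Cb)):
                if not getattr(mod, f"coexpr_{cond}"):
                    continue
                for g, h in combinations(mod.genes, 2):
                    vals.append(C.loc[g, h] * mod.sign_of(g, cond)
                                * mod.sign_of(h, cond))
        assert np.mean(np.asarray(vals) > 0.9) >= 0.95

    def test_unequal_time_grids(self):
        spec = spec_with([], n_genes=5, n_times_a=12, n_times_b=14)
        m_a, m_b, _ = generate_expression_pair(spec)
        assert m_a.n_samples == 12 and m_b.n_samples == 14

    def test_overlapping_modules_rejected(self):
        g = tuple(f"G{i:04d}" for i in range(1, 5))
        with pytest.raises(ValueError, match="overlap"):
            spec_with([ModuleSpec(g, True, False),
                       ModuleSpec(g[:2] + ("G0009", "G0010"), False, True)])

    def test_modules_exceeding_genes_rejected(self):
        g = tuple(f"G{i:04d}" for i in range(1, 12))
        with pytest.raises(ValueError, match="exceed"):
            spec_with([ModuleSpec(g, True, False)], n_genes=10)

    def test_truth_classes_disjoint_by_construction(self):
        with pytest.raises(ValueError):
            SyntheticTruth({frozenset(("a", "b"))}, {}, {frozenset(("a", "b"))},
                           ["a", "b"])


class TestToyOntology:
    def test_same_seed_identical(self):
        d1, a1 = generate_toy_ontology(12, 15, seed=4)
        d2, a2 = generate_toy_ontology(12, 15, seed=4)
        assert d1.parents == d2.parents
        assert a1.annotations == a2.annotations

    def test_every_gene_annotated_and_rooted(self):
        dag, ann = generate_toy_ontology(10, 20, seed=1)
        assert len(ann.genes) == 20
        for t in dag.terms:
            if t != dag.root:
                assert dag.root in dag.ancestors(t)

    def test_excluded_evidence_codes_present(self):
        _, ann = generate_toy_ontology(10, 60, seed=0)
        codes = {e for anns in ann.annotations.values() for _, e in anns}
        assert codes & {"IEP", "IGI"}


class TestTfTable:
    def _truth(self, seed=0):
        spec = spec_with(standard_modules(60, module_size=8,
                                          n_rewired_pos=1, n_rewired_neg=1,
                                          n_ccel=1), n_genes=60, seed=seed)
        return generate_expression_pair(spec)[2]

    def test_designated_tf_covers_endpoints(self):
        truth = self._truth()
        table, tf = generate_tf_table(10, truth, seed=5)
        covered = len(table.targets[tf] & truth.dcel_endpoints)
        assert covered >= 0.8 * len(truth.dcel_endpoints)
        assert truth.planted_tf_changes[tf] == "deactivated"

    def test_same_seed_identical(self):
        truth = self._truth()
        t1, _ = generate_tf_table(10, truth, seed=7)
        t2, _ = generate_tf_table(10, truth, seed=7)
        assert t1.targets == t2.targets

    def test_non_designated_overlap_near_uniform_expectation(self):
        truth = self._truth()
        table, tf = generate_tf_table(40, truth, seed=9)
        n_uni = len(table.universe)
        frac_endpoint = len(truth.dcel_endpoints) / n_uni
        overlaps = []
        for other in table.tfs:
            if other == tf:
                continue
            t = table.targets[other]
            overlaps.append(len(t & truth.dcel_endpoints) / len(t))
        # hypergeometric mean: endpoint share of the universe
        assert np.mean(overlaps) == pytest.approx(frac_endpoint, abs=0.05)


class TestBundle:
    def test_bundle_files_written_and_readable(self, tmp_path):
        from dcnet.expression import read_expression_tsv
        from dcnet.ontology import load_obo, read_annotations
        from dcnet.tf_activity import TFRegulationTable

        spec = spec_with(standard_modules(30, module_size=6,
                                          n_rewired_pos=1, n_rewired_neg=1,
                                          n_ccel=1), n_genes=30, seed=8)
        truth = write_bundle(tmp_path, spec, n_terms=12, n_tfs=6)
        m_a = read_expression_tsv(tmp_path / "expr_a.tsv",
                                  tmp_path / "expr_a.samples.yaml")
        assert m_a.n_genes == 30
        dag = load_obo(tmp_path / "toy_go.obo")
        assert len(dag) == 12
        ann = read_annotations(tmp_path / "annotations.tsv")
        assert set(ann.genes) <= set(truth.gene_ids)
        table = TFRegulationTable.from_tsv(tmp_path / "tf_table.tsv")
        assert len(table.tfs) == 6
        assert (tmp_path / "truth.json").exists()
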