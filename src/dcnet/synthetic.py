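"""Synthetic two-condition time courses with planted coexpression structure.

The generator emulates the study conditions every downstream stage needs:

* two conditions with (possibly unequal) timepoint counts — defaults 12 and
  14, echoing a glucose-pulse experiment design;
* gene modules sharing a latent time course per condition plus iid Gaussian
  noise.  The default latent is an iid Gaussian sequence ("white"), which
  makes distinct modules exactly independent; a shared-period sinusoid with
  random phase is available (``latent_kind="sine"``) but couples modules
  whose phases happen to align, planting unlabelled structure.  Every
  statistic downstream (Spearman, the label permutation) is invariant to
  within-condition time ordering, so latent smoothness is irrelevant to what
  the tests measure.  A module may be coexpressed in one condition only
  (every within-module pair is a planted differential link of contrast
  |Delta| ~ 1), in both (planted constitutive links), or "rewired":
  coexpressed in both conditions but with half the module anti-correlated in
  exactly one of them, so cross-half pairs flip correlation sign between
  conditions (contrast |Delta| ~ 2) — a planted differential link of the
  corresponding sign — while same-half pairs stay constitutive.  Rewired
  modules are the calibrated differential condition: their full-contrast
  links are detectable at the strict production threshold, and they produce
  complete-bipartite (triangle-free) differential blocks, the designed
  analogue of the sign-transitivity argument for tree-like differential
  networks;
* a toy rooted biological-process-style ontology with gene annotations,
  including a tagged subset carrying excluded evidence codes (IEP/IGI);
* a TF-regulation table with one designated "deactivated" TF whose targets
  cover the planted differential-link endpoints.

Everything is driven by one seeded generator; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .ontology import AnnotationTable, OntologyDAG
from .tf_activity import TFRegulationTable

__all__ = [
    "ModuleSpec",
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_expression_pair",
    "generate_toy_ontology",
    "generate_tf_table",
    "standard_modules",
    "tree_likeness_spec",
    "write_bundle",
]


@dataclass(frozen=True)
class ModuleSpec:
    """A planted gene module.

    ``flip_half_in`` ('a' or 'b') anti-correlates the second half of the
    module in exactly that condition; it requires the module to be
    coexpressed there.
    """

    genes: tuple[str, ...]
    coexpr_a: bool
    coexpr_b: bool
    flip_half_in: str | None = None

    def __post_init__(self):
        if len(self.genes) < 2:
            raise ValueError("module needs >= 2 genes")
        if self.flip_half_in not in (None, "a", "b"):
            raise ValueError("flip_half_in must be None, 'a' or 'b'")
        if self.flip_half_in == "a" and not self.coexpr_a:
            raise ValueError("cannot flip in a condition without coexpression")
        if self.flip_half_in == "b" and not self.coexpr_b:
            raise ValueError("cannot flip in a condition without coexpression")

    def sign_of(self, gene: str, cond: str) -> int:
        half = len(self.genes) // 2
        flipped = self.flip_half_in == cond and gene in self.genes[half:]
        return -1 if flipped else 1


@dataclass
class SyntheticSpec:
    """Generator parameters; defaults mirror the emulated study design."""

    n_genes: int = 200
    n_times_a: int = 12
    n_times_b: int = 14
    modules: list[ModuleSpec] = field(default_factory=list)
    latent_amplitude: float = 1.0
    noise_sd: float = 0.2
    latent_kind: str = "white"
    seed: int = 0

    def __post_init__(self):
        if self.latent_kind not in ("white", "sine"):
            raise ValueError("latent_kind must be 'white' or 'sine'")
        if self.n_times_a < 8 or self.n_times_b < 8:
            raise ValueError("need >= 8 timepoints per condition")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        used: set[str] = set()
        for mod in self.modules:
            overlap = used & set(mod.genes)
            if overlap:
                raise ValueError(f"module gene sets overlap: {sorted(overlap)}")
            used |= set(mod.genes)
        if len(used) > self.n_genes:
            raise ValueError("modules exceed n_genes")

    @property
    def gene_ids(self) -> list[str]:
        module_genes = [g for m in self.modules for g in m.genes]
        fillers = [f"G{i:04d}" for i in range(1, self.n_genes + 1)]
        fillers = [g for g in fillers if g not in set(module_genes)]
        return (module_genes + fillers)[: self.n_genes]


@dataclass
class SyntheticTruth:
    """Ground truth of the planted structure."""

    planted_dcels: set[frozenset]
    dcel_signs: dict[frozenset, int]
    planted_ccels: set[frozenset]
    gene_ids: list[str]
    planted_tf_changes: dict[str, str] = field(default_factory=dict)
    toy_dag: OntologyDAG | None = None
    toy_annotations: AnnotationTable | None = None
    toy_tf_table: TFRegulationTable | None = None

    def __post_init__(self):
        if self.planted_dcels & self.planted_ccels:
            raise ValueError("a pair cannot be both DCEL and CCEL")

    @property
    def dcel_endpoints(self) -> set[str]:
        return {g for pair in self.planted_dcels for g in pair}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_dcels": [sorted(p) for p in sorted(self.planted_dcels,
                                                        key=sorted)],
            "dcel_signs": {"|".join(sorted(p)): s
                           for p, s in self.dcel_signs.items()},
            "planted_ccels": [sorted(p) for p in sorted(self.planted_ccels,
                                                        key=sorted)],
            "planted_tf_changes": self.planted_tf_changes,
            "gene_ids": self.gene_ids,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _classify_pairs(modules: list[ModuleSpec]):
    dcels: set[frozenset] = set()
    signs: dict[frozenset, int] = {}
    ccels: set[frozenset] = set()
    for mod in modules:
        for g, h in combinations(mod.genes, 2):
            pair = frozenset((g, h))
            rho_a = mod.sign_of(g, "a") * mod.sign_of(h, "a") if mod.coexpr_a else 0
            rho_b = mod.sign_of(g, "b") * mod.sign_of(h, "b") if mod.coexpr_b else 0
            if rho_a != rho_b:
                dcels.add(pair)
                signs[pair] = 1 if rho_b > rho_a else -1
            elif rho_a == rho_b == 1:
                ccels.add(pair)
            # rho_a == rho_b in {0, -1}: neither planted class
    return dcels, signs, ccels


def generate_expression_pair(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Simulate the two condition matrices and enumerate the planted truth."""
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    grids = {
        "a": np.arange(spec.n_times_a) * 10.0,
        "b": np.arange(spec.n_times_b) * 10.0,
    }
    # baseline: independent trajectories with variance matching a module gene
    lat_var = (spec.latent_amplitude ** 2 / 2 if spec.latent_kind == "sine"
               else spec.latent_amplitude ** 2)
    base_sd = np.sqrt(lat_var + spec.noise_sd ** 2)
    X = {c: rng.normal(0.0, base_sd, size=(len(genes), t.size))
         for c, t in grids.items()}
    for mod in spec.modules:
        for cond in ("a", "b"):
            if not getattr(mod, f"coexpr_{cond}"):
                continue
            t = grids[cond]
            if spec.latent_kind == "sine":
                phase = rng.uniform(0, 2 * np.pi)
                latent = spec.latent_amplitude * np.sin(
                    2 * np.pi * t / (t[-1] - t[0] + 10.0) + phase)
            else:
                # white latent scaled to sample sd == latent_amplitude, so
                # latent_amplitude / noise_sd is exactly the per-gene SNR
                z = rng.standard_normal(t.size)
                latent = spec.latent_amplitude * (z - z.mean()) / z.std()
            for g in mod.genes:
                X[cond][gene_pos[g]] = (
                    mod.sign_of(g, cond) * latent
                    + rng.normal(0.0, spec.noise_sd, size=t.size))
    dcels, signs, ccels = _classify_pairs(spec.modules)
    truth = SyntheticTruth(dcels, signs, ccels, list(genes))
    mats = {
        c: ExpressionMatrix(
            pd.DataFrame(X[c], index=genes,
                         columns=[f"{c}_t{int(tt):03d}" for tt in grids[c]]),
            np.full(grids[c].size, c, dtype=object), grids[c])
        for c in ("a", "b")
    }
    return mats["a"], mats["b"], truth


def standard_modules(n_genes: int = 200, module_size: int = 10,
                     n_rewired_pos: int = 2, n_rewired_neg: int = 2,
                     n_ccel: int = 2, n_one_condition: int = 0
                     ) -> list[ModuleSpec]:
    """Default module layout: rewired (sign-flip) differential modules of
    both sign classes, constitutive modules, and optionally weaker
    one-condition-only differential modules."""
    specs: list[ModuleSpec] = []
    idx = 1

    def take(k):
        nonlocal idx
        ids = tuple(f"G{i:04d}" for i in range(idx, idx + k))
        idx += k
        return ids

    for _ in range(n_rewired_pos):
        specs.append(ModuleSpec(take(module_size), True, True,
                                flip_half_in="a"))
    for _ in range(n_rewired_neg):
        specs.append(ModuleSpec(take(module_size), True, True,
                                flip_half_in="b"))
    for _ in range(n_ccel):
        specs.append(ModuleSpec(take(module_size), True, True))
    for _ in range(n_one_condition):
        specs.append(ModuleSpec(take(module_size), True, False))
    if idx - 1 > n_genes:
        raise ValueError("modules exceed n_genes")
    return specs


def tree_likeness_spec(seed: int = 11) -> SyntheticSpec:
    """Fixture for topology nulls: two rewired 20-gene modules (one per sign
    class) plus 30 unstructured genes.  The resulting differential network
    is a pair of complete-bipartite blocks — triangle-free by the
    sign-transitivity argument — while condition-shuffled rebuilds of the
    same data pick up fluctuation-driven edge sets that do form triads."""
    mods = [
        ModuleSpec(tuple(f"G{j:04d}" for j in range(1, 21)), True, True,
                   flip_half_in="b"),
        ModuleSpec(tuple(f"G{j:04d}" for j in range(21, 41)), True, True,
                   flip_half_in="a"),
    ]
    return SyntheticSpec(n_genes=70, n_times_a=14, n_times_b=14,
                         modules=mods, seed=seed)


# ---------------------------------------------------------------------------
# toy ontology
# ---------------------------------------------------------------------------

def generate_toy_ontology(
    n_terms: int, n_genes: int, seed: int,
    gene_ids: list[str] | None = None,
    frac_excluded_evidence: float = 0.15,
) -> tuple[OntologyDAG, AnnotationTable]:
    """Random rooted DAG plus gene annotations.

    Every gene is annotated to at least one non-root term with a reliable
    evidence code; a fraction of extra annotations carry the excluded codes
    (IEP/IGI) to exercise evidence filtering.
    """
    if n_terms < 3:
        raise ValueError("need >= 3 terms")
    rng = np.random.default_rng(seed)
    terms = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    root = terms[0]
    parents: dict[str, set[str]] = {root: set()}
    for i, t in enumerate(terms[1:], start=1):
        n_par = 1 if i < 3 or rng.random() < 0.7 else 2
        choices = rng.choice(i, size=min(n_par, i), replace=False)
        parents[t] = {terms[int(c)] for c in choices}
    dag = OntologyDAG(parents, {t: f"toy process {k}" for k, t in
                                enumerate(terms)})
    genes = gene_ids or [f"G{i:04d}" for i in range(1, n_genes + 1)]
    genes = list(genes)[:n_genes]
    reliable = ["EXP", "IDA", "IMP"]
    excluded = ["IEP", "IGI"]
    non_root = terms[1:]
    ann: dict[str, set[tuple[str, str]]] = {}
    for g in genes:
        k = int(rng.integers(1, 4))
        chosen = rng.choice(len(non_root), size=min(k, len(non_root)),
                            replace=False)
        ann[g] = {(non_root[int(c)], reliable[int(rng.integers(3))])
                  for c in chosen}
        if rng.random() < frac_excluded_evidence:
            extra = non_root[int(rng.integers(len(non_root)))]
            ann[g].add((extra, excluded[int(rng.integers(2))]))
    return dag, AnnotationTable(ann)


# ---------------------------------------------------------------------------
# TF table
# ---------------------------------------------------------------------------

def generate_tf_table(
    n_tfs: int, expr_truth: SyntheticTruth, seed: int,
    coverage: float = 0.9, target_frac: float = 0.15,
) -> tuple[TFRegulationTable, str]:
    """Random TF-target table with one designated "deactivated" TF.

    The designated TF's targets cover ``coverage`` of the planted
    differential-link endpoint genes (plus random padding); the remaining
    TFs draw uniformly random target sets of comparable size from the full
    gene universe.  The designated TF id is recorded on the truth object.
    """
    rng = np.random.default_rng(seed)
    universe = list(expr_truth.gene_ids)
    endpoints = sorted(expr_truth.dcel_endpoints)
    designated = "TF001"
    n_cover = max(2, int(round(coverage * len(endpoints))))
    covered = [endpoints[int(i)] for i in
               rng.choice(len(endpoints), size=min(n_cover, len(endpoints)),
                          replace=False)] if endpoints else []
    size = max(len(covered), int(round(target_frac * len(universe))))
    pad_pool = [g for g in universe if g not in set(covered)]
    n_pad = min(max(0, size - len(covered)), len(pad_pool))
    pad = [pad_pool[int(i)] for i in
           rng.choice(len(pad_pool), size=n_pad, replace=False)]
    targets: dict[str, set[str]] = {designated: set(covered) | set(pad)}
    for i in range(2, n_tfs + 1):
        k = max(2, int(rng.normal(size, size * 0.2)))
        k = min(k, len(universe))
        picks = rng.choice(len(universe), size=k, replace=False)
        targets[f"TF{i:03d}"] = {universe[int(j)] for j in picks}
    table = TFRegulationTable(targets, set(universe))
    expr_truth.planted_tf_changes[designated] = "deactivated"
    expr_truth.toy_tf_table = table
    return table, designated


# ---------------------------------------------------------------------------
# on-disk bundle
# ---------------------------------------------------------------------------

def write_bundle(out_dir: str | Path, spec: SyntheticSpec,
                 n_terms: int = 30, n_tfs: int = 20) -> SyntheticTruth:
    """Generate the full fixture bundle (expression TSVs + sidecars, OBO,
    annotations, TF table, truth JSON) in the formats the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m_a, m_b, truth = generate_expression_pair(spec)
    m_a.to_tsv(out / "expr_a.tsv", out / "expr_a.samples.yaml")
    m_b.to_tsv(out / "expr_b.tsv", out / "expr_b.samples.yaml")
    dag, ann = generate_toy_ontology(n_terms, spec.n_genes, spec.seed + 1,
                                     gene_ids=truth.gene_ids)
    truth.toy_dag, truth.toy_annotations = dag, ann
    dag.write_obo(out / "toy_go.obo")
    ann.to_tsv(out / "annotations.tsv")
    table, _ = generate_tf_table(n_tfs, truth, spec.seed + 2)
    table.to_tsv(out / "tf_table.tsv")
    truth.to_json(out / "truth.json")
    return truth
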