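"""Configuration-driven orchestration of the full analysis.

``run_pipeline`` executes preprocess -> differential/constitutive network
construction -> topology -> GO clustering -> TF activation, skipping stages
whose inputs are absent, and records a :class:`RunManifest` (parameters, row
counts, wall-clock, seeds, output hashes) alongside the outputs.

Determinism: one master seed; each stage's sub-seed is derived by hashing
``(master_seed, stage_name)`` so adding a stage never shifts another stage's
randomness.  All the analysis thresholds live in one config block with the
production defaults (20% missing cutoff, k = 10 imputation, top-25%
variance filter, CCEL floor 0.95, DCEL threshold 1e-4, density z 1.5,
TF activation p 0.05).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .clustering import cluster_profiles, density_zscores
from .coexpression import DifferentialCoexpression
from .expression import ProbeAnnotation, read_expression_tsv
from .network import connected_components, export_network
from .ontology import OntologyBundle, similarity_matrix
from .preprocess import preprocess_pipeline
from .tf_activity import TFActivation, TFRegulationTable
from .topology import summarize_topology

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "stage_seed"]

DEFAULT_PARAMS = dict(
    max_missing_frac=0.20,
    knn_k=10,
    variance_top_frac=0.25,
    n_perm=100_000,
    scheme="pooled",
    alpha=1e-4,
    adjust=True,
    ccel_min_r=0.95,
    tie_weight=1.0,
    n_clusters=7,
    density_n_perm=100_000,
    z_min=1.5,
    tf_n_perm=100_000,
    tf_alpha=0.05,
)


def stage_seed(master_seed: int, stage: str) -> int:
    """Sub-seed for one stage, stable under pipeline growth (< 2^31)."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    """Input paths + stage parameters + master seed + output directory."""

    expression_tsv: str | None = None
    expression_sidecar: str | None = None
    probe_annotation: str | None = None
    obo: str | None = None
    go_annotations: str | None = None
    tf_table: str | None = None
    reference_edges: str | None = None
    out_dir: str = "dcnet_out"
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        merged = dict(DEFAULT_PARAMS)
        unknown = set(self.params) - set(merged)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        merged.update(self.params)
        self.params = merged
        for name in ("expression_tsv", "expression_sidecar", "probe_annotation",
                     "obo", "go_annotations", "tf_table", "reference_edges"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)


@dataclass
class RunManifest:
    """Append-only per-stage record of one pipeline run."""

    seed: int
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, started: float, seed: int | None = None,
               **info) -> None:
        entry = {"stage": stage, "wall_clock_s": round(time.time() - started, 3),
                 "seed": seed}
        entry.update(info)
        self.stages.append(entry)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"seed": self.seed, "stages": self.stages}, indent=1))


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute every stage whose inputs are available.

    A stage failure aborts the run with the failing stage named; outputs of
    completed stages are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=cfg.seed)
    p = cfg.params

    def fail(stage: str, exc: Exception):
        manifest.record(stage, time.time(), status="failed", error=str(exc))
        manifest.to_json(out / "manifest.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if cfg.expression_tsv is None:
        raise ValueError("expression_tsv is required")

    # -- preprocess -----------------------------------------------------
    t0 = time.time()
    try:
        m = read_expression_tsv(cfg.expression_tsv, cfg.expression_sidecar)
        ann = (ProbeAnnotation.from_tsv(cfg.probe_annotation)
               if cfg.probe_annotation else None)
        m_a, m_b, steplog = preprocess_pipeline(
            m, ann, max_missing_frac=p["max_missing_frac"], k=p["knn_k"],
            top_frac=p["variance_top_frac"])
        m_a.to_tsv(out / "clean_a.tsv", out / "clean_a.samples.yaml")
        m_b.to_tsv(out / "clean_b.tsv", out / "clean_b.samples.yaml")
    except Exception as exc:  # noqa: BLE001 - abort with stage named
        fail("preprocess", exc)
    manifest.record("preprocess", t0, row_counts=dict(steplog),
                    outputs={f.name: _file_hash(f) for f in
                             (out / "clean_a.tsv", out / "clean_b.tsv")})

    # -- differential coexpression --------------------------------------
    t0 = time.time()
    seed = stage_seed(cfg.seed, "dcen")
    try:
        model = DifferentialCoexpression(m_a, m_b, tie_weight=p["tie_weight"])
        res = model.fit(n_perm=p["n_perm"], scheme=p["scheme"],
                        alpha=p["alpha"], adjust=p["adjust"],
                        ccel_min_r=p["ccel_min_r"], seed=seed)
        res.to_tsv(out / "dcels.tsv", "dcels")
        res.to_tsv(out / "ccels.tsv", "ccels")
        export_network(res.dcen, out / "dcen.graphml", "graphml")
        export_network(res.dcen, out / "dcen.sif", "sif")
    except Exception as exc:  # noqa: BLE001
        fail("dcen", exc)
    manifest.record("dcen", t0, seed=seed,
                    n_pairs=len(res.links), n_dcels=res.dcen.n_edges,
                    n_dcen_genes=res.dcen.n_nodes, n_ccels=res.ccen.n_edges,
                    outputs={f.name: _file_hash(f) for f in
                             (out / "dcels.tsv", out / "ccels.tsv")})

    # -- topology --------------------------------------------------------
    t0 = time.time()
    try:
        comps = connected_components(res.dcen)
        if comps:
            lcc = res.dcen.subgraph(comps[0])
            summ = summarize_topology(lcc)
            (out / "topology.json").write_text(
                json.dumps(summ.to_dict(), indent=1))
            manifest.record("topology", t0, n_components=len(comps),
                            largest=summ.n_nodes,
                            outputs={"topology.json":
                                     _file_hash(out / "topology.json")})
        else:
            manifest.record("topology", t0, status="skipped (empty DCEN)")
    except Exception as exc:  # noqa: BLE001
        fail("topology", exc)

    # -- GO clustering ----------------------------------------------------
    t0 = time.time()
    if cfg.obo and cfg.go_annotations and res.dcen.n_nodes >= 3:
        seed = stage_seed(cfg.seed, "cluster")
        try:
            bundle = OntologyBundle.load(cfg.obo, cfg.go_annotations)
            genes = sorted(res.dcen.graph.nodes, key=str)
            sim = similarity_matrix(genes, bundle.annotations, bundle.ic,
                                    bundle.dag)
            sim.to_csv(out / "funsim.tsv", sep="\t")
            n_clust = min(p["n_clusters"], max(2, sim.shape[0] - 1))
            assign = cluster_profiles(sim, n_clusters=n_clust)
            assign.labels.rename("cluster").to_csv(out / "clusters.tsv",
                                                   sep="\t")
            dm = density_zscores(res.dcen, assign,
                                 n_perm=p["density_n_perm"], seed=seed)
            dm.Z.to_csv(out / "density_z.tsv", sep="\t")
            sig = dm.significant_pairs(p["z_min"])
            manifest.record("cluster", t0, seed=seed,
                            n_clustered=sim.shape[0],
                            n_clusters=assign.n_clusters,
                            significant_cluster_pairs=len(sig))
        except Exception as exc:  # noqa: BLE001
            fail("cluster", exc)
    else:
        manifest.record("cluster", t0, status="skipped (missing GO inputs)")

    # -- TF activation -----------------------------------------------------
    t0 = time.time()
    if cfg.tf_table and res.dcen.n_edges > 0:
        seed = stage_seed(cfg.seed, "tf")
        try:
            table = TFRegulationTable.from_tsv(cfg.tf_table)
            tf_res = TFActivation(res.dcen, table).fit(
                n_perm=p["tf_n_perm"], seed=seed, alpha=p["tf_alpha"])
            tf_res.to_tsv(out / "tf_activation.tsv")
            manifest.record("tf", t0, seed=seed,
                            n_tfs=len(tf_res.table),
                            n_activated=int(tf_res.table["activated"].sum()))
        except Exception as exc:  # noqa: BLE001
            fail("tf", exc)
    else:
        manifest.record("tf", t0, status="skipped (no TF table)")

    manifest.to_json(out / "manifest.json")
    return manifest
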