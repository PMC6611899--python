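"""Config-driven end-to-end runner: markers -> metabolomics -> subnetwork ->
enrichment -> export, with a manifest so every artifact is regenerable.

Inputs may be files (graph TSV, seeds TSV, event-map TSV, clinical long
TSV, feature-table TSV, GMT annotation) or, when a path is omitted,
generated by the synthetic module under the configured seed.  The summary
is always recomputed from the exported artifacts, never from in-memory
state, so `summarize(out_dir)` on a finished directory reproduces it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clinical as cm
from . import enrichment as en
from . import knowledge_graph as kgm
from . import metabolomics as mb
from . import subnetwork as sn
from . import synthetic as syn

logger = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.json"


@dataclass
class PipelineConfig:
    seed: int = 0
    # input paths; None -> synthesize with the seed
    graph: str | None = None
    seeds: str | None = None
    event_map: str | None = None
    clinical: str | None = None
    features: str | None = None
    annotation: str | None = None
    # stage toggles
    run_markers: bool = True
    run_metabolomics: bool = True
    run_subnetwork: bool = True
    run_enrichment: bool = True
    # thresholds
    max_len: int = 4
    q_threshold: float = 0.01
    vip_threshold: float = 1.0
    alpha: float = 0.05
    n_permutations: int = 2000
    normalization: str = "ratio"
    scaling: str = "unit_variance"
    n_components: int = 2

    def __post_init__(self) -> None:
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")
        for name in ("q_threshold", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.vip_threshold < 0:
            raise ValueError("vip_threshold must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class SummaryReport:
    layered_nodes: int = 0
    layered_edges: int = 0
    target_pathway_nodes: int = 0
    target_pathway_edges: int = 0
    n_enriched_pathways: int = 0
    n_differential_metabolites: int = 0
    n_increased: int = 0
    n_decreased: int = 0
    unmapped_seeds: list[str] = field(default_factory=list)
    top_compound_degrees: dict[str, int] = field(default_factory=dict)
    top_target_degrees: dict[str, int] = field(default_factory=dict)
    markers_compared: list[str] = field(default_factory=list)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _load_or_generate(config: PipelineConfig):
    """Resolve all inputs, generating any that lack a path."""
    spec = syn.SyntheticSpec(seed=config.seed)
    if config.graph:
        graph = kgm.load_edge_list(config.graph)
        chains = None
    else:
        graph, chains = syn.generate_kg(spec)
    if config.seeds:
        compound_labels, marker_labels = sn.load_seeds(config.seeds)
    elif chains is not None:
        compound_labels = sorted({c[0].split(":", 1)[1] for c in chains})
        marker_labels = sorted({c[-1].split(":", 1)[1] for c in chains})
    else:
        raise StageError("subnetwork: seeds file required with an external graph")
    event_map = sn.load_event_map(config.event_map) if config.event_map else None
    if config.clinical:
        clin_table = pd.read_csv(config.clinical, sep="\t")
    else:
        clin_table, _ = syn.generate_clinical(spec)
    if config.features:
        features = mb.FeatureTable.from_tsv(config.features)
    else:
        features, _ = syn.generate_metabolomics(spec)
    if config.annotation:
        annotation = en.PathwayAnnotation.from_gmt_dict(kgm.read_gmt(config.annotation))
    else:
        annotation = _annotation_from_graph(graph)
    return graph, compound_labels, marker_labels, event_map, clin_table, features, annotation


def _annotation_from_graph(graph: kgm.KnowledgeGraph) -> en.PathwayAnnotation:
    """Derive pathway membership sets from the graph's member_of_pathway edges."""
    pathways: dict[str, set[str]] = {}
    for edge in graph.edges:
        if edge.relation == "member_of_pathway":
            pathways.setdefault(edge.target, set()).add(edge.source)
    return en.PathwayAnnotation.from_gmt_dict(pathways)


def run_pipeline(config: PipelineConfig, out_dir) -> SummaryReport:
    """Execute all enabled stages, write artifacts + manifest, return summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    (
        graph,
        compound_labels,
        marker_labels,
        event_map,
        clin_table,
        features,
        annotation,
    ) = _load_or_generate(config)

    def record(name: str, path: Path) -> None:
        artifacts[name] = path.name

    try:
        if config.run_markers:
            logger.info("stage markers: %d rows", len(clin_table))
            responses = cm.marker_responses(clin_table, normalization=config.normalization)
            aucs = cm.auc_table(responses)
            aucs.to_csv(out / "auc.tsv", sep="\t", index=False)
            record("auc", out / "auc.tsv")
            comparisons = [
                cm.compare_arms(
                    aucs, m, n_permutations=config.n_permutations,
                    seed=config.seed, alpha=config.alpha,
                )
                for m in sorted(aucs["marker"].unique())
            ]
            cm.comparison_table(comparisons).to_csv(
                out / "arm_comparison.tsv", sep="\t", index=False
            )
            record("arm_comparison", out / "arm_comparison.tsv")
    except Exception as exc:  # noqa: BLE001 — re-raise with stage name
        _fail(out, artifacts, "markers", exc)

    try:
        if config.run_metabolomics:
            logger.info("stage metabolomics: %d x %d", features.n_samples, features.n_metabolites)
            prep = mb.preprocess(features, scaling=config.scaling)
            model = mb.plsda(prep, n_components=config.n_components)
            selected = mb.select_differential(
                features, model, vip_threshold=config.vip_threshold, alpha=config.alpha
            )
            selected.to_csv(out / "differential_metabolites.tsv", sep="\t", index=False)
            record("differential_metabolites", out / "differential_metabolites.tsv")
            vip_df = pd.DataFrame({"metabolite": model.feature_ids, "vip": model.vip_})
            vip_df.to_csv(out / "vip.tsv", sep="\t", index=False)
            record("vip", out / "vip.tsv")
    except Exception as exc:  # noqa: BLE001
        _fail(out, artifacts, "metabolomics", exc)

    net = None
    try:
        if config.run_subnetwork:
            logger.info(
                "stage subnetwork: %d compounds x %d markers",
                len(compound_labels),
                len(marker_labels),
            )
            seeds = sn.map_seeds(graph, compound_labels, marker_labels)
            net = sn.build_layered_network(
                graph, seeds, max_len=config.max_len, event_map=event_map
            )
            kgm.write_sif(net.graph, out / "layered_network.sif")
            record("layered_network_sif", out / "layered_network.sif")
            kgm.write_graphml(net.graph, out / "layered_network.graphml")
            record("layered_network_graphml", out / "layered_network.graphml")
            layers = pd.DataFrame(
                sorted(net.layer_of.items()), columns=["node_id", "layer"]
            )
            layers.to_csv(out / "layers.tsv", sep="\t", index=False)
            record("layers", out / "layers.tsv")
            sn.degree_table(net).to_csv(out / "degree_table.tsv", sep="\t", index=False)
            record("degree_table", out / "degree_table.tsv")
            pd.DataFrame({"unmapped": seeds.unmapped}).to_csv(
                out / "unmapped_seeds.tsv", sep="\t", index=False
            )
            record("unmapped_seeds", out / "unmapped_seeds.tsv")
    except Exception as exc:  # noqa: BLE001
        _fail(out, artifacts, "subnetwork", exc)

    try:
        if config.run_enrichment and net is not None:
            members = {
                nid
                for nid in net.graph.node_ids
                if net.graph.node(nid).node_type in ("protein", "metabolite")
            }
            query = members & annotation.universe
            if query:
                results = en.enrich(query, annotation, q_threshold=config.q_threshold)
                en.results_table(results).to_csv(out / "enrichment.tsv", sep="\t", index=False)
                record("enrichment", out / "enrichment.tsv")
                tp = en.build_target_pathway_network(net, results, annotation)
                kgm.write_sif(tp, out / "target_pathway.sif")
                record("target_pathway_sif", out / "target_pathway.sif")
            else:
                logger.warning("enrichment skipped: no subnetwork member annotated")
    except Exception as exc:  # noqa: BLE001
        _fail(out, artifacts, "enrichment", exc)

    manifest = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "artifacts": artifacts,
        "complete": True,
    }
    (out / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    report = summarize(out)
    (out / "summary.json").write_text(json.dumps(asdict(report), indent=2, sort_keys=True))
    return report


def _fail(out: Path, artifacts: dict[str, str], stage: str, exc: Exception):
    manifest = {"artifacts": artifacts, "complete": False, "failed_stage": stage}
    (out / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    raise StageError(f"stage {stage!r} failed: {exc}") from exc


def summarize(artifact_dir) -> SummaryReport:
    """Recompute the summary purely from exported artifacts."""
    out = Path(artifact_dir)
    manifest_path = out / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {out}")
    manifest = json.loads(manifest_path.read_text())
    artifacts = manifest["artifacts"]
    report = SummaryReport()

    def path_of(name: str) -> Path | None:
        if name not in artifacts:
            return None
        p = out / artifacts[name]
        if not p.exists():
            raise FileNotFoundError(f"artifact {name!r} missing: {p}")
        return p

    sif = path_of("layered_network_sif")
    if sif is not None:
        graph = kgm.read_sif(sif)
        report.layered_nodes = len(graph)
        report.layered_edges = graph.n_edges
    layers_path = path_of("layers")
    degree_path = path_of("degree_table")
    if layers_path is not None and degree_path is not None:
        degrees = pd.read_csv(degree_path, sep="\t")
        for layer, slot in (("component", "top_compound_degrees"), ("target", "top_target_degrees")):
            top = degrees[degrees["layer"] == layer].head(5)
            getattr(report, slot).update(
                {r.node_id: int(r.degree) for r in top.itertuples(index=False)}
            )
    unmapped_path = path_of("unmapped_seeds")
    if unmapped_path is not None:
        df = pd.read_csv(unmapped_path, sep="\t")
        report.unmapped_seeds = [] if df.empty else df["unmapped"].astype(str).tolist()
    enr = path_of("enrichment")
    if enr is not None:
        df = pd.read_csv(enr, sep="\t")
        report.n_enriched_pathways = int(df["significant"].sum())
    tp = path_of("target_pathway_sif")
    if tp is not None:
        g = kgm.read_sif(tp)
        report.target_pathway_nodes = len(g)
        report.target_pathway_edges = g.n_edges
    diff = path_of("differential_metabolites")
    if diff is not None:
        df = pd.read_csv(diff, sep="\t")
        report.n_differential_metabolites = int(len(df))
        if len(df):
            report.n_increased = int((df["direction"] == "increased").sum())
            report.n_decreased = int((df["direction"] == "decreased").sum())
    cmp_path = path_of("arm_comparison")
    if cmp_path is not None:
        df = pd.read_csv(cmp_path, sep="\t")
        report.markers_compared = sorted(df["marker"].unique().tolist())
    return report


def load_supplementary_counts(
    network_sif=None, pathway_table=None, seed_target_table=None
) -> dict[str, float | None]:
    """Counts conditional on the study's supplementary tables being supplied.

    The original supplementary network/pathway tables are not distributed
    with the package; when a path is absent or missing the corresponding
    count is None rather than an error, so callers can skip gracefully.
    Returns keys: network_nodes, network_edges, n_pathways,
    n_compounds_with_target.
    """
    counts: dict[str, float | None] = {
        "network_nodes": None,
        "network_edges": None,
        "n_pathways": None,
        "n_compounds_with_target": None,
    }
    if network_sif and Path(network_sif).exists():
        g = kgm.read_sif(network_sif)
        counts["network_nodes"] = len(g)
        counts["network_edges"] = g.n_edges
        compounds = [n.id for n in g.nodes if n.node_type == "compound"]
        counts["n_compounds_with_target"] = sum(
            1 for c in compounds if g.degree(c, "protein") >= 1
        )
    if pathway_table and Path(pathway_table).exists():
        df = pd.read_csv(pathway_table, sep="\t")
        counts["n_pathways"] = int(df["pathway"].nunique())
    return counts
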