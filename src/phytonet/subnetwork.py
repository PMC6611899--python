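"""Shortest-path extraction of the layered component–target–phenotype network.

Seed phytochemicals and differential clinical markers are mapped onto the
knowledge graph; every shortest path between each (compound, marker) pair
is unioned into a four-layered network (component / target / intermediate
/ marker, with phenotypes attached through curated marker_of_phenotype
edges).  All shortest paths — not one arbitrary path — are retained,
because multi-target fan-outs of a single compound are the object of
interest and a single-path choice would drop them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .knowledge_graph import (
    KGEdge,
    KnowledgeGraph,
    NodeNotFoundError,
    make_node_id,
)

logger = logging.getLogger(__name__)

LAYERS = ("component", "target", "intermediate", "marker", "phenotype")

#: sentinel hop count for a disconnected pair
NO_PATH = -1


class SeedMappingError(ValueError):
    """No input label could be resolved to a graph node."""


@dataclass
class SeedSet:
    """Resolved seed node ids plus the labels that failed to map."""

    compounds: list[str]
    markers: list[str]
    unmapped: list[str] = field(default_factory=list)


@dataclass
class PathResult:
    """All minimal-hop paths between one compound and one marker."""

    compound: str
    marker: str
    paths: list[list[str]]
    length: int  # NO_PATH when disconnected within max_len


@dataclass
class LayeredNetwork:
    graph: KnowledgeGraph
    layer_of: dict[str, str]
    event_of: dict[str, str] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.graph)

    @property
    def n_edges(self) -> int:
        return self.graph.n_edges

    def nodes_in_layer(self, layer: str) -> list[str]:
        return sorted(n for n, l in self.layer_of.items() if l == layer)


def map_seeds(
    graph: KnowledgeGraph,
    compound_labels: list[str],
    marker_labels: list[str],
    synonyms: dict[str, str] | None = None,
) -> SeedSet:
    """Resolve raw compound/marker labels to graph node ids.

    Labels go through identifier normalization and an optional synonym
    table (raw label -> canonical label).  Unmapped labels are reported in
    the result, never silently dropped; if *nothing* maps the function
    raises, since there is nothing to analyze.
    """
    if not compound_labels or not marker_labels:
        raise SeedMappingError("compound and marker label lists must be non-empty")
    synonyms = synonyms or {}

    def resolve(labels: list[str], node_type: str, mapped: list[str], unmapped: list[str]):
        for label in labels:
            canonical = synonyms.get(label, label)
            node_id = make_node_id(canonical, node_type)
            if node_id in graph:
                if node_id not in mapped:
                    mapped.append(node_id)
            else:
                unmapped.append(label)

    compounds: list[str] = []
    markers: list[str] = []
    unmapped: list[str] = []
    resolve(compound_labels, "compound", compounds, unmapped)
    resolve(marker_labels, "marker", markers, unmapped)
    if not compounds and not markers:
        raise SeedMappingError(f"no seed label mapped onto the graph: {unmapped}")
    if unmapped:
        logger.warning("unmapped seed labels: %s", unmapped)
    return SeedSet(compounds=compounds, markers=markers, unmapped=unmapped)


def _pair_shortest_paths(g: nx.Graph, source: str, target: str, max_len: int):
    """All minimal-hop paths on a prepared networkx view; ([], NO_PATH) if none."""
    try:
        length = nx.shortest_path_length(g, source, target)
    except nx.NetworkXNoPath:
        return [], NO_PATH
    if length > max_len:
        return [], NO_PATH
    return sorted(nx.all_shortest_paths(g, source, target)), length


def shortest_paths(
    graph: KnowledgeGraph,
    compound: str,
    marker: str,
    max_len: int = 4,
    respect_direction: bool = False,
) -> PathResult:
    """All shortest paths between two nodes, capped at ``max_len`` hops.

    Breadth-first over the undirected view by default.  An empty path list
    (length ``NO_PATH``) means the pair is disconnected within the cap.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    for endpoint in (compound, marker):
        if endpoint not in graph:
            raise NodeNotFoundError(endpoint)
    g = graph.to_networkx(respect_direction=respect_direction)
    paths, length = _pair_shortest_paths(g, compound, marker, max_len)
    return PathResult(compound, marker, paths, length)


def _node_type(graph: KnowledgeGraph, node_id: str) -> str:
    return graph.node(node_id).node_type


def build_layered_network(
    graph: KnowledgeGraph,
    seeds: SeedSet,
    max_len: int = 4,
    event_map: pd.DataFrame | None = None,
    respect_direction: bool = False,
) -> LayeredNetwork:
    """Union every (compound, marker) shortest-path set into a layered network.

    Layer assignment: seed compounds -> component; proteins adjacent to a
    component -> target (this wins when a protein is also mid-path);
    markers and phenotypes -> their own layers; every remaining path node
    -> intermediate.  Curated marker_of_phenotype edges incident to
    included markers are appended, pulling in their phenotypes.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    kept_nodes: set[str] = set()
    kept_pairs: set[tuple[str, str]] = set()
    g = graph.to_networkx(respect_direction=respect_direction)
    for compound in seeds.compounds:
        for marker in seeds.markers:
            paths, _ = _pair_shortest_paths(g, compound, marker, max_len)
            for path in paths:
                kept_nodes.update(path)
                for a, b in zip(path, path[1:]):
                    kept_pairs.add((a, b))
    if not kept_nodes:
        logger.warning("no (compound, marker) pair connected within %d hops", max_len)

    # curated marker->phenotype edges for included markers
    for edge in graph.edges:
        if edge.relation == "marker_of_phenotype" and edge.source in kept_nodes:
            kept_nodes.add(edge.target)
            kept_pairs.add((edge.source, edge.target))

    sub = KnowledgeGraph()
    for nid in sorted(kept_nodes):
        sub.add_node(graph.node(nid))
    pair_lookup = kept_pairs | {(b, a) for a, b in kept_pairs}
    for edge in graph.edges:
        if (edge.source, edge.target) in pair_lookup:
            sub.add_edge(edge)

    component = set(seeds.compounds) & kept_nodes
    layer_of: dict[str, str] = {}
    for nid in sorted(kept_nodes):
        ntype = _node_type(graph, nid)
        if nid in component:
            layer_of[nid] = "component"
        elif ntype == "marker":
            layer_of[nid] = "marker"
        elif ntype == "phenotype":
            layer_of[nid] = "phenotype"
        elif ntype == "protein" and any(n in component for n in g.neighbors(nid)):
            layer_of[nid] = "target"
        else:
            layer_of[nid] = "intermediate"

    event_of: dict[str, str] = {}
    if event_map is not None and len(event_map):
        for row in event_map.itertuples(index=False):
            if layer_of.get(row.target_id) == "target":
                event_of[row.target_id] = row.event

    return LayeredNetwork(graph=sub, layer_of=layer_of, event_of=event_of)


def load_event_map(path) -> pd.DataFrame:
    """Read the curated target -> functional event TSV (target_id, event)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"target_id", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"event map must have columns {sorted(required)}")
    return df


_PAIRED_LAYER = {"component": "target", "target": "component", "marker": "phenotype",
                 "phenotype": "marker"}


def degree_table(net: LayeredNetwork) -> pd.DataFrame:
    """Cross-layer degrees, sorted descending (ties broken lexicographically).

    Component nodes count distinct target-layer neighbors; target nodes
    count component-layer neighbors (the compound fan-in the degree
    analysis reports); marker/phenotype nodes count each other; every
    other node counts neighbors outside its own layer.
    """
    rows = []
    for nid in net.graph.node_ids:
        layer = net.layer_of[nid]
        paired = _PAIRED_LAYER.get(layer)
        nbrs = net.graph.neighbors(nid)
        if paired is not None:
            deg = sum(1 for n in nbrs if net.layer_of[n] == paired)
        else:
            deg = sum(1 for n in nbrs if net.layer_of[n] != layer)
        rows.append((nid, layer, deg))
    df = pd.DataFrame(rows, columns=["node_id", "layer", "degree"])
    return df.sort_values(
        ["degree", "node_id"], ascending=[False, True], ignore_index=True
    )


def load_seeds(path) -> tuple[list[str], list[str]]:
    """Read a seeds TSV (columns: label, role in {compound, marker})."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"label", "role"}.issubset(df.columns):
        raise ValueError("seeds file must have columns label, role")
    bad = set(df["role"]) - {"compound", "marker"}
    if bad:
        raise ValueError(f"unknown seed role(s): {sorted(bad)}")
    compounds = df.loc[df["role"] == "compound", "label"].tolist()
    markers = df.loc[df["role"] == "marker", "label"].tolist()
    return compounds, markers
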