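"""Typed heterogeneous knowledge graph for component–target–phenotype analysis.

The graph holds six node categories (compounds, proteins, metabolites,
pathways, phenotypes, clinical markers) connected by a closed set of
relations.  It is the in-memory substrate onto which phytochemicals and
differential markers are mapped before shortest-path subnetwork extraction.

The graph is *simple per relation*: at most one edge per
(source, target, relation) triple, while parallel edges of different
relations are allowed.  Every edge carries a ``directed`` flag, but path
search elsewhere in the package treats the graph as undirected by default.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import networkx as nx

logger = logging.getLogger(__name__)

NODE_TYPES = frozenset(
    {"compound", "protein", "metabolite", "pathway", "phenotype", "marker"}
)
RELATIONS = frozenset(
    {"targets", "regulates", "interacts", "member_of_pathway", "marker_of_phenotype"}
)

#: relations constrained to specific endpoint types: relation -> (source types, target types)
_RELATION_ENDPOINTS = {
    "member_of_pathway": (frozenset({"protein", "metabolite"}), frozenset({"pathway"})),
    "marker_of_phenotype": (frozenset({"marker"}), frozenset({"phenotype"})),
}

_EDGE_LIST_COLUMNS = ("source_id", "source_type", "relation", "target_id", "target_type")


class GraphFormatError(ValueError):
    """Malformed input file (missing columns, bad tokens)."""


class GraphValidationError(ValueError):
    """Content violates a graph invariant (unknown type, bad endpoint)."""


class NodeNotFoundError(KeyError):
    """Lookup of a node id absent from the graph."""


def normalize_label(label: str, node_type: str) -> str:
    """Normalize a raw label into the canonical un-prefixed identifier.

    Gene/protein style symbols ("VCAM-1" vs "VCAM1") are uppercased with
    hyphens and whitespace removed; all other categories are lowercased
    with whitespace collapsed, which reconciles mixed-case compound names.
    """
    label = label.strip()
    if node_type in ("protein", "marker"):
        return re.sub(r"[\s\-]+", "", label).upper()
    return re.sub(r"\s+", " ", label).lower()


def make_node_id(label: str, node_type: str) -> str:
    """Build the namespace-prefixed internal id, e.g. ``protein:CASP3``."""
    if node_type not in NODE_TYPES:
        raise GraphValidationError(f"unknown node_type {node_type!r}")
    return f"{node_type}:{normalize_label(label, node_type)}"


def split_node_id(node_id: str) -> tuple[str, str]:
    """Split ``protein:CASP3`` into ``("protein", "CASP3")``."""
    node_type, _, label = node_id.partition(":")
    if not label or node_type not in NODE_TYPES:
        raise GraphValidationError(f"malformed node id {node_id!r}")
    return node_type, label


@dataclass(frozen=True)
class KGNode:
    id: str
    label: str
    node_type: str
    attributes: dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise GraphValidationError("node id must be non-empty")
        if self.node_type not in NODE_TYPES:
            raise GraphValidationError(
                f"unknown node_type {self.node_type!r} for node {self.id!r}"
            )


@dataclass(frozen=True)
class KGEdge:
    source: str
    target: str
    relation: str
    directed: bool = True
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise GraphValidationError(
                f"unknown relation {self.relation!r} on edge {self.source}->{self.target}"
            )

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.relation)


class KnowledgeGraph:
    """Simple-per-relation typed graph with an undirected adjacency index."""

    def __init__(self) -> None:
        self._nodes: dict[str, KGNode] = {}
        self._edges: dict[tuple[str, str, str], KGEdge] = {}
        self._adjacency: dict[str, set[str]] = {}

    # -- construction -------------------------------------------------

    def add_node(self, node: KGNode) -> KGNode:
        existing = self._nodes.get(node.id)
        if existing is not None:
            if existing.node_type != node.node_type:
                raise GraphValidationError(
                    f"node {node.id!r} re-added with conflicting type "
                    f"{node.node_type!r} (was {existing.node_type!r})"
                )
            return existing
        self._nodes[node.id] = node
        self._adjacency[node.id] = set()
        return node

    def ensure_node(self, label: str, node_type: str) -> KGNode:
        """Add (or fetch) a node from a raw label, normalizing the id."""
        node_id = make_node_id(label, node_type)
        if node_id in self._nodes:
            return self._nodes[node_id]
        return self.add_node(KGNode(id=node_id, label=label.strip(), node_type=node_type))

    def add_edge(self, edge: KGEdge, warn_duplicate: bool = False) -> bool:
        """Add an edge; returns False (dropping it) if the triple already exists."""
        for endpoint in (edge.source, edge.target):
            if endpoint not in self._nodes:
                raise GraphValidationError(
                    f"edge endpoint {endpoint!r} not in graph"
                )
        constraint = _RELATION_ENDPOINTS.get(edge.relation)
        if constraint is not None:
            src_ok = self._nodes[edge.source].node_type in constraint[0]
            tgt_ok = self._nodes[edge.target].node_type in constraint[1]
            if not (src_ok and tgt_ok):
                raise GraphValidationError(
                    f"relation {edge.relation!r} cannot connect "
                    f"{self._nodes[edge.source].node_type} -> "
                    f"{self._nodes[edge.target].node_type}"
                )
        if edge.triple in self._edges:
            if warn_duplicate:
                logger.warning("duplicate edge collapsed: %s", edge.triple)
            return False
        self._edges[edge.triple] = edge
        self._adjacency[edge.source].add(edge.target)
        self._adjacency[edge.target].add(edge.source)
        return True

    # -- queries ------------------------------------------------------

    @property
    def nodes(self) -> list[KGNode]:
        return [self._nodes[i] for i in sorted(self._nodes)]

    @property
    def edges(self) -> list[KGEdge]:
        return [self._edges[t] for t in sorted(self._edges)]

    @property
    def node_ids(self) -> list[str]:
        return sorted(self._nodes)

    def __len__(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def node(self, node_id: str) -> KGNode:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise NodeNotFoundError(node_id) from None

    def neighbors(self, node_id: str) -> set[str]:
        if node_id not in self._adjacency:
            raise NodeNotFoundError(node_id)
        return set(self._adjacency[node_id])

    def degree(self, node_id: str, neighbor_type: str | None = None) -> int:
        """Distinct-neighbor degree, ignoring direction.

        When ``neighbor_type`` is given, only neighbors of that category
        count — e.g. the number of phytochemicals connected to a protein.
        """
        nbrs = self.neighbors(node_id)
        if neighbor_type is None:
            return len(nbrs)
        if neighbor_type not in NODE_TYPES:
            raise GraphValidationError(f"unknown node_type {neighbor_type!r}")
        return sum(1 for n in nbrs if self._nodes[n].node_type == neighbor_type)

    def induced_subgraph(self, node_ids) -> "KnowledgeGraph":
        """Subgraph on ``node_ids`` with exactly the edges internal to the set."""
        keep = set(node_ids)
        missing = keep - self._nodes.keys()
        if missing:
            raise NodeNotFoundError(sorted(missing)[0])
        sub = KnowledgeGraph()
        for nid in keep:
            sub.add_node(self._nodes[nid])
        for edge in self._edges.values():
            if edge.source in keep and edge.target in keep:
                sub.add_edge(edge)
        return sub

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return (
            self._nodes == other._nodes
            and set(self._edges) == set(other._edges)
        )

    def to_networkx(self, respect_direction: bool = False) -> nx.Graph:
        """Export to networkx for path algorithms.

        Multiple relations between the same pair collapse onto one
        networkx edge (hop counts are relation-agnostic).
        """
        g: nx.Graph = nx.DiGraph() if respect_direction else nx.Graph()
        for node in self._nodes.values():
            g.add_node(node.id, node_type=node.node_type, label=node.label)
        for edge in self._edges.values():
            g.add_edge(edge.source, edge.target, relation=edge.relation)
            if respect_direction and not edge.directed:
                g.add_edge(edge.target, edge.source, relation=edge.relation)
        return g


# -- readers / writers ------------------------------------------------


def load_edge_list(path, directed_default: bool = True) -> KnowledgeGraph:
    """Load a TSV edge list into a :class:`KnowledgeGraph`.

    Required header columns: source_id, source_type, relation, target_id,
    target_type.  Optional: directed (true/false), provenance.  Nodes are
    auto-created from the endpoint columns with identifier normalization;
    duplicate (source, target, relation) triples collapse with a warning.
    """
    graph = KnowledgeGraph()
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise GraphFormatError(f"{path}: empty file, expected header")
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in _EDGE_LIST_COLUMNS if c not in header]
        if missing:
            raise GraphFormatError(f"{path}: missing required column(s) {missing}")
        col = {name: header.index(name) for name in header}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(_EDGE_LIST_COLUMNS):
                raise GraphFormatError(f"{path}:{lineno}: expected at least "
                                       f"{len(_EDGE_LIST_COLUMNS)} fields")
            try:
                # a row with empty relation and target declares an isolated node
                if not fields[col["relation"]] and not fields[col["target_id"]]:
                    graph.ensure_node(fields[col["source_id"]], fields[col["source_type"]])
                    continue
                src = graph.ensure_node(fields[col["source_id"]], fields[col["source_type"]])
                tgt = graph.ensure_node(fields[col["target_id"]], fields[col["target_type"]])
                directed = directed_default
                if "directed" in col and len(fields) > col["directed"] and fields[col["directed"]]:
                    directed = fields[col["directed"]].strip().lower() in ("true", "1", "yes")
                provenance = ""
                if "provenance" in col and len(fields) > col["provenance"]:
                    provenance = fields[col["provenance"]]
                graph.add_edge(
                    KGEdge(
                        source=src.id,
                        target=tgt.id,
                        relation=fields[col["relation"]].strip(),
                        directed=directed,
                        provenance=provenance,
                    ),
                    warn_duplicate=True,
                )
            except GraphValidationError as exc:
                raise GraphValidationError(f"{path}:{lineno}: {exc}") from None
    return graph


def write_edge_list(graph: KnowledgeGraph, path) -> None:
    """Write the TSV edge list (inverse of :func:`load_edge_list`).

    Isolated nodes are preserved as declaration rows with empty relation
    and target columns, so the round trip is lossless.
    """
    connected = {e.source for e in graph.edges} | {e.target for e in graph.edges}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source_id\tsource_type\trelation\ttarget_id\ttarget_type\tdirected\tprovenance\n")
        for node in graph.nodes:
            if node.id not in connected:
                n_type, n_label = split_node_id(node.id)
                fh.write(f"{n_label}\t{n_type}\t\t\t\t\t\n")
        for edge in graph.edges:
            s_type, s_label = split_node_id(edge.source)
            t_type, t_label = split_node_id(edge.target)
            fh.write(
                f"{s_label}\t{s_type}\t{edge.relation}\t{t_label}\t{t_type}\t"
                f"{str(edge.directed).lower()}\t{edge.provenance}\n"
            )


def write_sif(graph: KnowledgeGraph, path) -> None:
    """Write the Cytoscape SIF (3-column tab) export, lexicographic line order."""
    lines = sorted(f"{e.source}\t{e.relation}\t{e.target}" for e in graph.edges)
    with open(path, "w", encoding="utf-8") as fh:
        for line in lines:
            fh.write(line + "\n")


def read_sif(path) -> KnowledgeGraph:
    """Read a SIF file written by :func:`write_sif` (ids carry the namespace)."""
    graph = KnowledgeGraph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise GraphFormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
            src, relation, tgt = fields
            for nid in (src, tgt):
                node_type, label = split_node_id(nid)
                if nid not in graph:
                    graph.add_node(KGNode(id=nid, label=label, node_type=node_type))
            graph.add_edge(KGEdge(source=src, target=tgt, relation=relation))
    return graph


def write_graphml(graph: KnowledgeGraph, path) -> None:
    g = nx.DiGraph()
    for node in graph.nodes:
        g.add_node(node.id, label=node.label, node_type=node.node_type)
    for edge in graph.edges:
        g.add_edge(
            edge.source,
            edge.target,
            relation=edge.relation,
            directed_flag=edge.directed,
            provenance=edge.provenance,
        )
    nx.write_graphml(g, path)


def read_graphml(path) -> KnowledgeGraph:
    g = nx.read_graphml(path)
    graph = KnowledgeGraph()
    for nid, data in g.nodes(data=True):
        node_type, label = split_node_id(nid)
        graph.add_node(
            KGNode(id=nid, label=data.get("label", label), node_type=data["node_type"])
        )
    for src, tgt, data in g.edges(data=True):
        graph.add_edge(
            KGEdge(
                source=src,
                target=tgt,
                relation=data["relation"],
                directed=bool(data.get("directed_flag", True)),
                provenance=data.get("provenance", ""),
            )
        )
    return graph


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: ``name<TAB>description<TAB>member...``.

    Returns pathway name -> member-id set; empty sets are dropped.
    """
    annotation: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise GraphFormatError(f"{path}:{lineno}: expected name, description, members")
            name, members = fields[0], [m for m in fields[2:] if m]
            if members:
                annotation[name] = set(members)
    return annotation


def write_gmt(annotation: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(annotation):
            members = "\t".join(sorted(annotation[name]))
            fh.write(f"{name}\t{description}\t{members}\n")
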