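"""Curated study inputs for the Sanghuang–Danshen (SD) vascular trial.

Small literature-curated tables used as worked examples and defaults:
the twelve signature phytochemicals of the SD supplement, the
compound–target associations enumerated for the three functional events
(adhesion molecule production, platelet activation, endothelial
inflammation), and the thirteen plasma metabolites reported as
differential between the placebo and high-dose arms.
"""

from __future__ import annotations

import pandas as pd

from .knowledge_graph import KGEdge, KnowledgeGraph

#: the 12 signature phytochemicals (label, botanical source)
SIGNATURE_PHYTOCHEMICALS: list[tuple[str, str]] = [
    ("caffeic acid", "sanghuang"),
    ("ellagic acid", "sanghuang"),
    ("fumaric acid", "sanghuang"),
    ("hispidin", "sanghuang"),
    ("protocatechuic acid", "sanghuang"),
    ("cryptotanshinone", "danshen"),
    ("danshensu", "danshen"),
    ("rosmarinic acid", "danshen"),
    ("salvianolic acid A", "danshen"),
    ("salvianolic acid B", "danshen"),
    ("tanshinone I", "danshen"),
    ("tanshinone IIA", "danshen"),
]

#: compound -> protein target associations enumerated per functional event
CURATED_ASSOCIATIONS: list[tuple[str, str, str]] = [
    # adhesion molecule production
    ("fumaric acid", "VCAM-1", "adhesion_molecule_production"),
    ("fumaric acid", "ICAM-1", "adhesion_molecule_production"),
    ("cryptotanshinone", "VCAM-1", "adhesion_molecule_production"),
    ("cryptotanshinone", "ICAM-1", "adhesion_molecule_production"),
    ("ellagic acid", "PLA2G2A", "adhesion_molecule_production"),
    # platelet activation
    ("protocatechuic acid", "VEGFA", "platelet_activation"),
    ("ellagic acid", "APAF1", "platelet_activation"),
    ("tanshinone IIA", "APAF1", "platelet_activation"),
    # endothelial inflammation: the six phytochemicals connected to CASP3
    ("ellagic acid", "CASP3", "endothelial_inflammation"),
    ("caffeic acid", "CASP3", "endothelial_inflammation"),
    ("protocatechuic acid", "CASP3", "endothelial_inflammation"),
    ("salvianolic acid A", "CASP3", "endothelial_inflammation"),
    ("salvianolic acid B", "CASP3", "endothelial_inflammation"),
    ("tanshinone IIA", "CASP3", "endothelial_inflammation"),
]

#: plasma metabolites reported differential between placebo and high-dose SD
INCREASED_METABOLITES: list[str] = [
    "oleamide",
    "cholesterol",
    "oleonitrile",
    "stearic acid",
    "pyrophosphate",
    "tryptophan",
    "proline",
]
DECREASED_METABOLITES: list[str] = [
    "aspartic acid",
    "9,12-octadecadienoic acid",
    "glucose",
    "glycine",
    "arachidonic acid",
    "5-oxoproline",
]


def curated_mini_network() -> KnowledgeGraph:
    """Build the compound–target layer from the curated associations.

    The returned graph is the small worked example used throughout the
    docs: ``degree("protein:CASP3", "compound") == 6`` and
    ``degree("compound:cryptotanshinone", "protein") == 2``.
    """
    graph = KnowledgeGraph()
    for compound, protein, event in CURATED_ASSOCIATIONS:
        c = graph.ensure_node(compound, "compound")
        p = graph.ensure_node(protein, "protein")
        graph.add_edge(
            KGEdge(source=c.id, target=p.id, relation="targets", provenance="curated")
        )
        # the event annotation lives on the protein node's attribute map
        graph.node(p.id).attributes.setdefault("event", event)
    return graph


def curated_event_map() -> pd.DataFrame:
    """Target -> functional event table (columns: target_id, event)."""
    rows = {}
    for _, protein, event in CURATED_ASSOCIATIONS:
        graph_id = "protein:" + protein.replace("-", "").upper()
        rows[graph_id] = event
    return pd.DataFrame(
        sorted(rows.items()), columns=["target_id", "event"]
    )


def differential_marker_table() -> pd.DataFrame:
    """The reported differential plasma metabolites as a pre-flagged table.

    Columns: metabolite, direction (increased/decreased in treatment).
    """
    rows = [(m, "increased") for m in INCREASED_METABOLITES]
    rows += [(m, "decreased") for m in DECREASED_METABOLITES]
    return pd.DataFrame(rows, columns=["metabolite", "direction"])
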