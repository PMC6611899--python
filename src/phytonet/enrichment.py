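"""Pathway over-representation analysis and the target–pathway network.

Each candidate pathway is tested with the one-sided hypergeometric tail
(equivalently a one-sided Fisher's exact test on the 2x2 table) against a
background universe of every id annotated to at least one pathway — the
standard ORA convention, overridable.  P-values are Benjamini–Hochberg
adjusted; by default the BH family includes pathways with zero query hits
(m = all annotated pathways), switchable via ``family``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .knowledge_graph import KGEdge, KGNode, KnowledgeGraph
from .subnetwork import LayeredNetwork


@dataclass
class PathwayAnnotation:
    """Pathway id -> member set, with the background universe."""

    pathways: dict[str, set[str]]
    universe: set[str]

    @classmethod
    def from_gmt_dict(
        cls, pathways: dict[str, set[str]], universe: set[str] | None = None
    ) -> "PathwayAnnotation":
        pathways = {p: set(m) for p, m in pathways.items() if m}
        if universe is None:
            universe = set().union(*pathways.values()) if pathways else set()
        else:
            universe = set(universe)
            pathways = {p: m & universe for p, m in pathways.items()}
            pathways = {p: m for p, m in pathways.items() if m}
        return cls(pathways=pathways, universe=universe)


@dataclass
class EnrichmentResult:
    pathway: str
    k: int  # query hits in the pathway
    K: int  # pathway size
    n: int  # effective query size
    N: int  # universe size
    p: float
    q: float
    significant: bool


def hypergeom_overrep(k: int, K: int, n: int, N: int) -> float:
    """One-sided over-representation tail P[X >= k], X ~ Hypergeom(N, K, n)."""
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise ValueError(f"invalid hypergeometric configuration k={k} K={K} n={n} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query,
    annotation: PathwayAnnotation,
    q_threshold: float = 0.01,
    family: str = "all",
) -> list[EnrichmentResult]:
    """Over-representation of ``query`` against every annotated pathway.

    ``family`` controls the BH family size: "all" adjusts over every
    annotated pathway (zero-hit pathways included); "hit" restricts the
    family to pathways with at least one query hit.  Results only include
    hit pathways either way, sorted by q then pathway id.
    """
    query = set(query) & annotation.universe
    if not query:
        raise ValueError("query has no overlap with the annotation universe")
    if family not in ("all", "hit"):
        raise ValueError("family must be 'all' or 'hit'")

    N = len(annotation.universe)
    n = len(query)
    names = sorted(annotation.pathways)
    ks = {name: len(annotation.pathways[name] & query) for name in names}
    tested = names if family == "all" else [nm for nm in names if ks[nm] > 0]
    pvals = [
        hypergeom_overrep(ks[nm], len(annotation.pathways[nm]), n, N) for nm in tested
    ]
    qvals = bh_fdr(pvals)

    results = [
        EnrichmentResult(
            pathway=nm,
            k=ks[nm],
            K=len(annotation.pathways[nm]),
            n=n,
            N=N,
            p=pvals[i],
            q=float(qvals[i]),
            significant=bool(qvals[i] < q_threshold),
        )
        for i, nm in enumerate(tested)
        if ks[nm] > 0
    ]
    results.sort(key=lambda r: (r.q, r.pathway))
    return results


def build_target_pathway_network(
    net: LayeredNetwork,
    results: list[EnrichmentResult],
    annotation: PathwayAnnotation,
) -> KnowledgeGraph:
    """Bipartite target/metabolite <-> significant-pathway membership graph.

    An edge is present iff the subnetwork member belongs to the pathway;
    only significant pathways appear.
    """
    members = {
        nid
        for nid in net.graph.node_ids
        if net.graph.node(nid).node_type in ("protein", "metabolite")
    }
    graph = KnowledgeGraph()
    for res in results:
        if not res.significant:
            continue
        hits = sorted(annotation.pathways[res.pathway] & members)
        if not hits:
            continue
        pw = graph.ensure_node(res.pathway.removeprefix("pathway:"), "pathway")
        for nid in hits:
            graph.add_node(net.graph.node(nid))
            graph.add_edge(
                KGEdge(source=nid, target=pw.id, relation="member_of_pathway")
            )
    return graph


def results_table(results: list[EnrichmentResult]):
    """Results as a DataFrame ready for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            (r.pathway, r.k, r.K, r.n, r.N, r.p, r.q, r.significant)
            for r in results
        ],
        columns=["pathway", "k", "K", "n", "N", "p", "q", "significant"],
    )
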