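"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators emulate the study's data sources so every stage is
testable without external databases:

* a typed knowledge graph with planted compound -> protein [-> protein]
  -> phenotype chains, marker_of_phenotype edges, pathway memberships and
  Erdős–Rényi distractor edges;
* a four-arm crossover trial table (placebo / 300 / 600 / 900 mg) whose
  markers spike at 3 h over a log-normal baseline, with dose-proportional
  suppression (or elongation, for closure-time-like markers) and
  multiplicative noise;
* a two-group metabolite feature table with a chosen number of planted
  differential metabolites shifted by a stated effect size in log space.

Each generator returns its ground truth alongside the data, and a fixed
seed reproduces outputs byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .knowledge_graph import KGEdge, KnowledgeGraph
from .metabolomics import FeatureTable


@dataclass
class KGSpec:
    n_compounds: int = 12
    n_proteins: int = 40
    n_metabolites: int = 15
    n_pathways: int = 12
    n_phenotypes: int = 4
    n_markers: int = 6
    n_planted_chains: int = 10
    chain_has_intermediate_prob: float = 0.5
    distractor_edge_prob: float = 0.02
    pathway_membership_prob: float = 0.15


@dataclass
class ClinicalSpec:
    n_subjects: int = 50
    arms: tuple[str, ...] = ("placebo", "dose300", "dose600", "dose900")
    markers: tuple[str, ...] = ("TG", "insulin", "closure_time")
    #: fractional suppression of the postprandial excursion at the top dose
    effect_top_dose: float = 0.3
    #: markers whose response is elongated (not suppressed) by treatment
    elongated_markers: tuple[str, ...] = ("closure_time",)
    excursion_amplitude: float = 1.0
    late_fraction: float = 0.3  # residual excursion at 6 h relative to the 3-h peak
    noise_cv: float = 0.15
    baseline_sigma: float = 0.3


@dataclass
class MetabolomicsSpec:
    n_per_group: int = 25
    n_metabolites: int = 120
    n_differential: int = 13
    effect_sd: float = 2.0
    lognormal_sigma: float = 0.5
    groups: tuple[str, str] = ("placebo", "treatment")


@dataclass
class SyntheticSpec:
    seed: int = 0
    kg: KGSpec = field(default_factory=KGSpec)
    clinical: ClinicalSpec = field(default_factory=ClinicalSpec)
    metabolomics: MetabolomicsSpec = field(default_factory=MetabolomicsSpec)


# -- knowledge graph --------------------------------------------------


def generate_kg(spec: SyntheticSpec) -> tuple[KnowledgeGraph, list[list[str]]]:
    """Typed graph with planted chains; returns (graph, planted chains).

    Each planted chain is compound -> protein [-> protein] -> phenotype,
    recorded as the full node-id list including the marker attached to the
    phenotype, so chain recovery can be checked exactly.  Chain proteins
    are drawn without replacement across chains, which makes every planted
    chain the unique shortest compound–marker route when
    ``distractor_edge_prob`` is 0.
    """
    kg = spec.kg
    rng = np.random.default_rng(spec.seed)
    n_chain_proteins = 2 * kg.n_planted_chains
    if n_chain_proteins > kg.n_proteins:
        raise ValueError(
            f"{kg.n_planted_chains} chains need up to {n_chain_proteins} proteins, "
            f"only {kg.n_proteins} available"
        )
    if kg.n_planted_chains > kg.n_compounds * kg.n_phenotypes:
        raise ValueError("more chains than compound-phenotype pairs")

    graph = KnowledgeGraph()
    compounds = [graph.ensure_node(f"cmpd{i:03d}", "compound").id for i in range(kg.n_compounds)]
    proteins = [graph.ensure_node(f"P{i:03d}", "protein").id for i in range(kg.n_proteins)]
    metabolites = [graph.ensure_node(f"met{i:03d}", "metabolite").id for i in range(kg.n_metabolites)]
    pathways = [graph.ensure_node(f"pw{i:03d}", "pathway").id for i in range(kg.n_pathways)]
    phenotypes = [graph.ensure_node(f"pheno{i:02d}", "phenotype").id for i in range(kg.n_phenotypes)]
    markers = [graph.ensure_node(f"MK{i:02d}", "marker").id for i in range(kg.n_markers)]

    # every phenotype gets one curated marker (cycled if markers run short)
    for i, pheno in enumerate(phenotypes):
        marker = markers[i % len(markers)]
        graph.add_edge(
            KGEdge(marker, pheno, "marker_of_phenotype", provenance="curated")
        )
    marker_of = {pheno: markers[i % len(markers)] for i, pheno in enumerate(phenotypes)}

    free_proteins = list(proteins)
    rng.shuffle(free_proteins)
    chains: list[list[str]] = []
    for c in range(kg.n_planted_chains):
        compound = compounds[c % kg.n_compounds]
        phenotype = phenotypes[(c // kg.n_compounds) % kg.n_phenotypes]
        first = free_proteins.pop()
        chain = [compound, first]
        if rng.random() < kg.chain_has_intermediate_prob:
            chain.append(free_proteins.pop())
        chain.append(phenotype)
        graph.add_edge(KGEdge(chain[0], chain[1], "targets", provenance="planted"))
        for a, b in zip(chain[1:], chain[2:]):
            graph.add_edge(KGEdge(a, b, "regulates", provenance="planted"))
        chains.append(chain + [marker_of[phenotype]])

    # pathway membership over proteins and metabolites
    for member in proteins + metabolites:
        for pw in pathways:
            if rng.random() < kg.pathway_membership_prob:
                graph.add_edge(KGEdge(member, pw, "member_of_pathway", provenance="synthetic"))

    # Erdős–Rényi distractors among proteins (and protein-metabolite links)
    if kg.distractor_edge_prob > 0:
        others = proteins + metabolites
        for i, a in enumerate(others):
            for b in others[i + 1:]:
                if rng.random() < kg.distractor_edge_prob:
                    graph.add_edge(KGEdge(a, b, "interacts", provenance="distractor"))
    return graph, chains


# -- clinical trial ---------------------------------------------------


def _dose_fraction(arm: str) -> float:
    return {"placebo": 0.0, "dose300": 1 / 3, "dose600": 2 / 3, "dose900": 1.0}[arm]


def generate_clinical(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format crossover table plus the ground-truth arm effects.

    Returns (table, truth).  ``table`` has columns subject, arm, marker,
    time_h, value sampled at 0/3/6 h; ``truth`` records per (marker, arm)
    the noise-free excursion multiplier so recovery checks know the
    planted ordering.
    """
    cl = spec.clinical
    rng = np.random.default_rng(spec.seed + 1)
    shape = {0.0: 0.0, 3.0: 1.0, 6.0: cl.late_fraction}
    rows = []
    truth_rows = []
    subjects = [f"S{i:03d}" for i in range(cl.n_subjects)]
    baselines = {
        (s, m): float(np.exp(rng.normal(np.log(100.0), cl.baseline_sigma)))
        for s in subjects
        for m in cl.markers
    }
    sigma_noise = np.sqrt(np.log(1 + cl.noise_cv**2))
    for marker in cl.markers:
        elongated = marker in cl.elongated_markers
        for arm in cl.arms:
            frac = _dose_fraction(arm)
            effect = cl.effect_top_dose * frac
            # suppressed markers shrink the excursion; elongated markers grow it
            multiplier = (1 + effect) if elongated else (1 - effect)
            truth_rows.append((marker, arm, multiplier))
            for s in subjects:
                base = baselines[(s, marker)]
                for t in (0.0, 3.0, 6.0):
                    clean = base * (1 + cl.excursion_amplitude * shape[t] * multiplier)
                    noise = np.exp(rng.normal(-0.5 * sigma_noise**2, sigma_noise)) if t > 0 else 1.0
                    rows.append((s, arm, marker, t, clean * noise))
    table = pd.DataFrame(rows, columns=["subject", "arm", "marker", "time_h", "value"])
    truth = pd.DataFrame(truth_rows, columns=["marker", "arm", "excursion_multiplier"])
    return table, truth


# -- metabolomics -----------------------------------------------------


def generate_metabolomics(spec: SyntheticSpec) -> tuple[FeatureTable, pd.DataFrame]:
    """Two-group log-normal feature table with planted shifts.

    ``n_differential`` metabolites are shifted by ``effect_sd`` log-scale
    standard deviations in the treatment group, half up / half down (odd
    remainder up).  Returns (table, truth) where truth lists each planted
    metabolite and its direction.
    """
    mb = spec.metabolomics
    if mb.n_differential > mb.n_metabolites:
        raise ValueError("n_differential exceeds n_metabolites")
    rng = np.random.default_rng(spec.seed + 2)
    control, treatment = mb.groups
    mets = [f"m{i:04d}" for i in range(mb.n_metabolites)]
    samples = [f"{g}_{i:03d}" for g in (control, treatment) for i in range(mb.n_per_group)]
    groups = pd.Series(
        [control] * mb.n_per_group + [treatment] * mb.n_per_group, index=samples, name="group"
    )
    mu = rng.normal(np.log(1000.0), 1.0, size=mb.n_metabolites)
    log_x = rng.normal(0.0, mb.lognormal_sigma, size=(len(samples), mb.n_metabolites)) + mu

    planted = rng.choice(mb.n_metabolites, size=mb.n_differential, replace=False)
    n_up = (mb.n_differential + 1) // 2
    directions = ["increased"] * n_up + ["decreased"] * (mb.n_differential - n_up)
    is_treatment = (groups == treatment).to_numpy()
    for idx, direction in zip(planted, directions):
        shift = mb.effect_sd * mb.lognormal_sigma * (1 if direction == "increased" else -1)
        log_x[is_treatment, idx] += shift
    intensities = pd.DataFrame(np.exp(log_x), index=samples, columns=mets)
    truth = pd.DataFrame(
        {"metabolite": [mets[i] for i in planted], "direction": directions}
    ).sort_values("metabolite", ignore_index=True)
    return FeatureTable(intensities=intensities, groups=groups), truth


# -- annotation (for enrichment tests) --------------------------------


def generate_annotation(
    n_pathways: int = 20,
    universe_size: int = 200,
    pathway_size: int = 10,
    planted_pathway_size: int = 10,
    seed: int = 0,
) -> tuple[dict[str, set[str]], str]:
    """Random pathway annotation with one designated 'planted' pathway.

    Returns (pathways dict, planted pathway name).  A query equal to the
    planted pathway's member set is fully enriched there by construction.
    """
    rng = np.random.default_rng(seed)
    universe = [f"g{i:04d}" for i in range(universe_size)]
    pathways: dict[str, set[str]] = {}
    planted_members = set(rng.choice(universe, size=planted_pathway_size, replace=False))
    pathways["pw_planted"] = planted_members
    for i in range(n_pathways - 1):
        pathways[f"pw{i:03d}"] = set(rng.choice(universe, size=pathway_size, replace=False))
    # keep the universe complete so background = all annotated ids
    annotated = set().union(*pathways.values())
    leftovers = [g for g in universe if g not in annotated]
    for j, g in enumerate(leftovers):
        pathways[f"pw{(j % (n_pathways - 1)):03d}"].add(g)
    return pathways, "pw_planted"
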