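# phytonet

Network-biology toolkit for asking how the many phytochemicals in a
botanical supplement act together on a clinical phenotype. It was built
around the Sanghuang–Danshen (SD) vascular-protection setting — a
four-arm postprandial crossover trial plus a heterogeneous biological
knowledge graph — but every stage is generic:

1. **Clinical markers** — per-subject 0/3/6-h time series are normalized
   to their own *t* = 0 baseline, summarized as trapezoidal AUCs
   (AUC = Σᵢ (tᵢ₊₁−tᵢ)(vᵢ+vᵢ₊₁)/2), and arms are compared with a
   repeated-measures one-way ANOVA whose p-value comes from permuting arm
   labels within subjects. qPCR expression uses the comparative-Ct method
   (fold change = 2^−ΔΔCt).
2. **Metabolomics** — a two-group feature table is autoscaled and fitted
   with a NIPALS PLS-DA model; metabolites are ranked by variable
   importance in projection, VIPⱼ = √(p·Σₐ SSYₐ(w_{ja}/‖wₐ‖)² / Σₐ SSYₐ),
   and called differential when VIP > 1 **and** a BH-adjusted rank-sum
   test passes α.
3. **Subnetwork extraction** — seed compounds and differential markers
   are mapped onto a typed knowledge graph (compounds, proteins,
   metabolites, pathways, phenotypes, markers) and *all* shortest paths
   between every (compound, marker) pair are unioned into a four-layered
   component → target → intermediate → marker network, with curated
   marker→phenotype edges attached and cross-layer degrees reported.
4. **Enrichment** — subnetwork proteins/metabolites are tested per
   pathway with the one-sided hypergeometric tail P[X ≥ k] (one-sided
   Fisher) against the all-annotated universe, BH-FDR adjusted
   (default q < 0.01), and exported as a bipartite target–pathway graph.

A synthetic-data module generates every input with known ground truth
(planted graph chains, dose-responsive trial arms, shifted metabolites),
so the whole pipeline is testable end to end without external databases.

## Worked example

`examples/subnetwork_extraction.py` builds the curated SD compound–target
layer, attaches a vascular-dysfunction phenotype with a triglyceride
marker, and extracts the layered network:

```
8 of 12 phytochemicals mapped; unmapped: hispidin, danshensu, rosmarinic acid, tanshinone I
layered network: 16 nodes, 21 edges
                     node_id     layer  degree
               protein:CASP3    target       6
       compound:ellagic acid component       3
   compound:cryptotanshinone component       2
```

A target's degree counts the distinct phytochemicals hitting it — the
apoptosis executioner CASP3 is reached by six of the eight mapped
compounds, the strongest synergy signal in this layer — while a
component's degree is its target scope (here ellagic acid is broadest).
Cryptotanshinone touches exactly the two adhesion molecules VCAM-1 and
ICAM-1.

The other scripts in `examples/` demonstrate one capability each
(clinical AUC comparison, PLS-DA/VIP selection, enrichment, the
config-driven pipeline with its audit-ready manifest). The
`phytonet` CLI wraps the same functions
(`phytonet simulate|markers|metabolomics|subnet|enrich|run|summarize`).

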