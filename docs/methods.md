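# Methods

## Knowledge graph model

The graph is typed and *simple per relation*: nodes carry one of six
categories (compound, protein, metabolite, pathway, phenotype, marker)
and edges one of five relations (targets, regulates, interacts,
member_of_pathway, marker_of_phenotype), with at most one edge per
(source, target, relation) triple. Two relations are endpoint-checked:
member_of_pathway only links proteins/metabolites to pathways, and
marker_of_phenotype only links clinical markers to phenotypes (that
layer is curated by hand, not inferred). Every edge stores a `directed`
flag and a free-text provenance string; the model carries no weights or
signs, since the mapping substrate it emulates provides none.

Identifiers are namespace-prefixed (`protein:CASP3`) and normalized on
entry: protein/marker symbols are uppercased with hyphens and whitespace
removed (reconciling "VCAM-1"/"VCAM1" styles), other labels are
lowercased with whitespace collapsed. Duplicate triples collapse on load
with a warning. All exports (TSV edge list, SIF, GraphML) are written in
lexicographic order so re-runs are byte-identical; the TSV edge list
preserves isolated nodes through declaration rows with empty
relation/target columns, making the load/write round trip lossless.

## Layered subnetwork extraction

Seed compounds and markers are resolved through the same normalization
plus an optional synonym table; unmapped labels are reported, never
dropped. For every (compound, marker) pair, **all** minimal-hop paths up
to `max_len` hops (default 4, spanning component → target → intermediate
→ marker) are found by breadth-first search and unioned. Traversal is
undirected by default — the direction semantics of heterogeneous
biological associations are rarely uniform — with a `respect_direction`
switch. Unioning every shortest path rather than one arbitrary path is
deliberate: a compound's multi-target fan-out is the quantity of
interest, and single-path extraction would hide it.

Layers are assigned after the union: seed compounds → component;
proteins adjacent to any component → target (this wins when a protein is
also mid-path, matching how compound-adjacent proteins are read as
targets); markers and phenotypes → their own layers; everything else →
intermediate. Curated marker_of_phenotype edges incident to included
markers are appended. Cross-layer degree counts distinct neighbors in
the paired layer (component↔target, marker↔phenotype), sorted descending
with lexicographic tie-break. Functional-event annotations
(adhesion-molecule production, platelet activation, endothelial
inflammation) come from a user-supplied TSV because that grouping is an
editorial judgement, not a graph property.

## Over-representation analysis

Per pathway, p = P[X ≥ k] for X ~ Hypergeometric(N, K, n) via
`scipy.stats.hypergeom.sf` — identical to a one-sided Fisher's exact
test on the 2×2 table (verified exhaustively in the tests against exact
integer pmf sums and `fisher_exact`). The universe defaults to every id
annotated to at least one pathway, the standard ORA background
convention, and proteins and metabolites share it when both are
annotated. BH adjustment (statsmodels `fdr_bh`) runs by default over the
full annotated family including zero-hit pathways (`family="all"`); the
`family="hit"` flag restricts the family, since conventions differ
between tools. Significance is q < 0.01 by default. The target–pathway
export is the bipartite membership graph restricted to significant
pathways.

## Clinical markers

Normalization is ratio-to-baseline by default (each subject's series
divided by its *t* = 0 value), with a difference mode available; the
AUC integrates the normalized series over the actual 0–3–6-h spacing by
the trapezoidal rule, total area by default with an incremental
(above-baseline) flag. Ratio-then-AUC is the assumed order of
operations. Subjects with a zero baseline in ratio mode are excluded
with a log entry.

Arm comparison computes the classical repeated-measures one-way F from
the within-subject decomposition (SS_treat/(k−1)) / (SS_error/((n−1)(k−1))),
but takes its p-value from permuting arm labels independently within
each subject (10,000 permutations by default, seeded) — under the null
of no arm effect the labels are exchangeable within subject, and the
permutation reference is valid without the sphericity/normality
assumptions the parametric lookup needs; the F statistic is still
reported. Pairwise paired sign-flip permutation tests at α feed a
compact-letter display in place of parametric studentized-range
p-values. Unbalanced subjects are dropped listwise with a warning.
Comparative-Ct expression is 2^−ΔΔCt with ΔCt = Ct_target − Ct_reference
and ΔΔCt against the control condition's mean ΔCt per gene; fold changes
are invariant to constant Ct shifts (tested).

## Metabolomics

Preprocessing imputes missing cells with half the metabolite minimum
(below-detection convention), optionally logs, mean-centres and scales
(unit-variance default, Pareto and none available). The n−1 variance
convention is used everywhere. PCA is a plain SVD with a deterministic
sign convention (largest-magnitude loading positive). PLS-DA encodes the
two groups as −1/+1 and runs NIPALS per component (w = X′u/‖X′u‖,
t = Xw, q = y′t/t′t, u = yq until the score change < 1e−10 or 500
iterations — one pass suffices for a univariate response, the general
loop is kept), deflating X by tp′ and y by tq. PLS-DA substitutes for
OPLS-DA deliberately: with two classes the predictive subspace is
identical and the orthogonal-variation split is a visualization aid.

VIP is computed from the weights and per-component explained response
sums of squares; Σ VIP² = p holds to 1e−10 by construction and is
asserted on every fitted model. Differential calling uses the dual
criterion VIP > 1 (the community default; no standard cutoff exists) AND
a BH-adjusted two-sided Wilcoxon rank-sum test on raw intensities at
α = 0.05 (rank-sum rather than t because intensity distributions are
heavy-tailed; a Welch-t flag exists). The heat-map matrix z-scores each
metabolite across samples and orders rows by average-linkage
hierarchical clustering on Euclidean distances, columns by group then
sample id; both orders are deterministic.

## Synthetic data

The generators reproduce the *statistical structure* the analysis
assumes, not any real measurement distributions.

* **Graph**: planted compound → protein [→ protein] → phenotype chains
  (intermediate present with probability 0.5), one curated marker per
  phenotype, pathway-membership edges at rate 0.15, and Erdős–Rényi
  "interacts" distractors among proteins/metabolites. Chain proteins are
  drawn without replacement, so at distractor probability 0 each planted
  chain is the unique shortest compound–marker route and recovery can be
  checked exactly. Defaults: 12 compounds, 40 proteins, 10 chains.
* **Clinical**: a four-arm crossover (placebo/300/600/900 mg labels) of
  50 subjects; per-subject log-normal baselines (σ = 0.3 around 100
  units), a postprandial excursion peaking at 3 h with 30% residual at
  6 h, a dose-proportional fractional modification of the excursion
  (suppression 0.3 at the top dose for TG/insulin-like markers,
  elongation for the closure-time-like marker), and mean-corrected
  multiplicative log-normal noise at CV 0.15 — values chosen once as
  typical of postprandial biomarker studies.
* **Metabolomics**: 25 samples per group over 120 metabolites (a
  realistic single-platform GC–MS panel), log-normal with σ = 0.5;
  13 planted metabolites shifted by 2 log-SD in the treatment group,
  7 up and 6 down (odd remainder up).

Because the generators are log-normal, homogeneous and free of batch
effects, missingness structure, drift or correlated metabolite blocks,
passing recovery tests demonstrates correctness of the algorithms under
their stated assumptions — not performance on real cohort data.

## Numerical and design notes

* Determinism: a single integer seed drives every generator and every
  permutation test; all file exports are sorted; re-running a pipeline
  config reproduces the summary exactly (tested byte-wise on SIF).
* The pipeline manifest records the config hash, seed and artifact list;
  `summarize` recomputes every count from the exported files so reports
  are auditable from disk alone.
* Degenerate inputs: zero-variance metabolites are dropped (scaling) or
  z-zeroed (heat map) with warnings; disconnected seed pairs yield an
  empty-network warning, not an error; an all-identical arm matrix gives
  F = 0 with p ≈ 1.
* Monte-Carlo problem sizes in the test suite (100 seeds for chain
  recovery and metabolite-selection operating characteristics, 200
  replicates at 400 permutations for null-p uniformity, 20 replicates
  for the null selection rate) were chosen as the package's own balance
  between statistical resolution and a fast default test run.
* Known limitations: no path weighting or diffusion-based alternatives
  to shortest paths; no mixed-effects or carryover modelling for the
  crossover; no GSEA-style rank enrichment; no raw instrument-data
  ingestion; OPLS orthogonal filtering intentionally absent.
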