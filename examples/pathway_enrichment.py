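"""Hypergeometric over-representation with BH-FDR control.

Builds a synthetic annotation of 20 pathways over a 200-id universe with
one fully-hit planted pathway, then tests a query equal to that
pathway's member set.
"""

from phytonet import PathwayAnnotation, enrich, generate_annotation

pathways, planted = generate_annotation(seed=0)
annotation = PathwayAnnotation.from_gmt_dict(pathways)
query = pathways[planted]

results = enrich(query, annotation, q_threshold=0.01)
print(f"universe N = {len(annotation.universe)}, query n = {len(query)}, "
      f"{len(results)} pathways with hits")
for r in results[:5]:
    flag = "*" if r.significant else " "
    print(f"{flag} {r.pathway:12s} k/K = {r.k:2d}/{r.K:2d}  p = {r.p:.2e}  q = {r.q:.2e}")
# p is the one-sided hypergeometric tail P[X >= k] (one-sided Fisher);
# q is the Benjamini-Hochberg adjustment over all 20 pathways. Only the
# planted pathway survives q < 0.01.
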