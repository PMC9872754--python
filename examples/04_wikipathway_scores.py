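"""Pathway-level statistics: harmonic-mean-p, Gene_percent, ratios.

A WikiPathway is scored by intersecting its genes with a DEG list and
combining the significances of the map terms its DEGs highlight with the
harmonic mean p-value (valid under dependence). The up/down enrichment
ratio compares how strongly one pathway is driven by up- versus
down-regulated genes, and the pro/anti ratio summarizes its inflammatory
leaning on the BP map.
"""

from enscompare import (
    combine_hmp,
    enrichment_ratio,
    gene_percent,
    pro_anti_ratio,
    similarity_matrix,
    pathway_correlation,
)

# per-DEG significances of the highlighted map terms for one pathway
term_qs = [0.001, 0.02, 0.04, 0.01]
hmp = combine_hmp(term_qs)
print(f"harmonic-mean p over {term_qs} = {hmp:.5f} "
      f"(bounded by [{min(term_qs)}, {max(term_qs)}])")

print(f"Gene_percent: 6 pathway DEGs of 48 total = {gene_percent(6, 48):.3f}")

r = enrichment_ratio(1e-4, 1e-2)
print(f"up/down enrichment ratio (-log10 scale), q_up=1e-4 vs q_down=1e-2: {r:.1f}")
print(f"reciprocal check: {r * enrichment_ratio(1e-2, 1e-4):.3f}")

ratio = pro_anti_ratio({"n1", "n2", "n3", "n4", "n5"}, {"n1", "n2", "n3"}, {"n4", "n5"})
print(f"pro/anti shared-BP ratio, 3 pro vs 2 anti nodes: {ratio:.2f}")

sim = similarity_matrix({"GJA1": {"gap_junction", "contraction"},
                         "ACTA2": {"contraction", "cytoskeleton"},
                         "IL6": {"inflammation"}})
print("gene-gene functional similarity (shared-annotation Jaccard):")
print(sim.round(2).to_string())

r, p = pathway_correlation([1.2, 2.5, 3.1, 4.0], [1.0, 2.4, 3.3, 3.9])
print(f"between-pathway Pearson r={r:.3f} (p={p:.3f})")
print("-> ratios above 1 lean pro-inflammatory / up-regulated; the HMP is"
      " the pathway's combined evidence across its dependent member DEGs.")
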