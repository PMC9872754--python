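"""Enrichment maps and cross-species functional-linkage coverage.

Builds a term-overlap network from the terms enriched in a DEG list, then
asks how much of that network's linkage structure a *different* (foreign
species) DEG list recovers once projected through the ortholog bijection:
the linkage-coverage statistic. Also shows the involvement fraction, the
share of network nodes directly containing a DEG from the subset.
"""

import pandas as pd

from enscompare import (
    GeneSet,
    GeneSetDB,
    build_enrichment_map,
    cross_species_match,
    enrich_fisher,
    filter_high_quality,
    highlight_terms,
    involvement_fraction,
)
from enscompare.orthologs import ORTHOLOG_COLUMNS, OrthologTable

background = {f"g{i}" for i in range(60)}
native_degs = {f"g{i}" for i in range(12)}
terms = [
    GeneSet("axon_guidance", genes={"g0", "g1", "g2", "g20", "g21"}),
    GeneSet("synapse_assembly", genes={"g1", "g2", "g3", "g20", "g22"}),
    GeneSet("smooth_muscle", genes={"g4", "g5", "g23", "g24"}),
    GeneSet("ion_transport", genes={"g5", "g6", "g23", "g25"}),
]
res = enrich_fisher(native_degs, background, GeneSetDB(terms))
emap = build_enrichment_map(terms, overlap_cutoff=0.25, deg_genes=native_degs,
                            term_q=res["q"].to_dict())
print(f"map: {emap.graph.number_of_nodes()} terms, "
      f"{emap.graph.number_of_edges()} functional linkages")

# a small orthologous DEG set from the other species (h0<->g0, ...)
rows = [(f"g{i}", f"h{i}", "one2one", 90, 90) for i in range(60)]
ortho = filter_high_quality(OrthologTable(pd.DataFrame(rows, columns=ORTHOLOG_COLUMNS)))
foreign = {"h1", "h5"}  # just two driver genes
rep = cross_species_match(emap, foreign, ortho, native_degs, direction="b_to_a")
print(f"foreign DEGs {sorted(foreign)} highlight "
      f"{rep.highlighted_node_count}/{rep.total_node_count} terms and cover "
      f"{rep.covered_linkage_weight:.0f}/{rep.total_linkage_weight:.0f} "
      f"linkage weight -> coverage {rep.linkage_coverage:.2f}")

up_nodes = highlight_terms(emap, {"g1"})
print(f"involvement fraction for one up/one down highlighted node of 2+2: "
      f"{involvement_fraction(1, 2, 1, 2):.0f}%")
print("-> a handful of orthologous driver genes can recover the full linkage"
      " structure of the native network even though they are a small subset"
      " of the native DEG list.")
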