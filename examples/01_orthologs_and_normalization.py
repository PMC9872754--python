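"""Ortholog filtering and cross-species normalization.

Simulates a small two-species bulk study, keeps the high-quality strict
1:1 orthologs (GOC and WGA scores above 75), joins the two species in one
gene space, and applies RPKM + median-anchored scaling so every sample's
conserved-gene median hits the common value.
"""

import pandas as pd

from enscompare import (
    BulkConfig,
    cross_species_scale,
    filter_high_quality,
    generate_bulk,
    map_gene_space,
    rpkm,
)
from enscompare.normalize import ExpressionMatrix

matrices, ortho_raw, truth = generate_bulk(
    BulkConfig(n_genes=800, n_deg_region=40, n_deg_plexus=20, n_deg_vns=20), seed=1
)
ortho = filter_high_quality(ortho_raw)
print(f"orthologs: {len(ortho_raw)} raw records -> {len(ortho)} strict 1:1 pairs")

pig = rpkm(matrices["pig"])
human = rpkm(matrices["human"])
human_in_pig, dropped = map_gene_space(human.values, ortho, "b_to_a")
shared = pig.values.index.intersection(human_in_pig.index)
joint = ExpressionMatrix(
    pd.concat([pig.values.loc[shared], human_in_pig.loc[shared]], axis=1), "rpkm"
)
print(f"joint matrix: {joint.values.shape[0]} orthologous genes x "
      f"{joint.values.shape[1]} samples ({dropped} human genes unmappable)")

scaled, res = cross_species_scale(joint, list(shared))
print(f"common median after scaling: {res.common_value:.3f}")
print("per-sample scaling factors (first 5):")
print(res.factor.head().round(4).to_string())
print("-> factors above 1 boost shallow libraries, below 1 shrink deep ones;"
      " after scaling every sample's median over the anchor genes is equal.")
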