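"""Gene overlap of consensus regions and Fisher/EASE enrichment.

Maps breed-specific regions onto a gene annotation, then tests a gene
set for over-representation among the region genes with the one-sided
Fisher exact test and its conservative EASE variant (one success
removed from the overlap).
"""

import pandas as pd

from rohtrace.annotate import enrichment, genes_in_regions
from rohtrace.consensus import ConsensusRegion

regions = [ConsensusRegion("1", 100_000, 400_000, 9, breed_specific=True),
           ConsensusRegion("1", 900_000, 1_200_000, 9, breed_specific=True)]

# toy annotation: 40 genes every 50 kb; g2..g7 and g18..g23 overlap
genes = pd.DataFrame({
    "gene_id": [f"g{i}" for i in range(40)],
    "chrom": "1",
    "start": [i * 50_000 + 1 for i in range(40)],
    "end": [i * 50_000 + 30_000 for i in range(40)],
})

table, region_genes = genes_in_regions(regions, genes)
print(f"{len(region_genes)} genes overlap the regions: {region_genes}")

gene_sets = {
    "hair_follicle": [f"g{i}" for i in range(2, 10)],   # overlaps regions
    "unrelated": [f"g{i}" for i in range(30, 38)],      # mostly outside
}
result = enrichment(region_genes, list(genes["gene_id"]), gene_sets,
                    ease_threshold=0.1)
print(result.to_string(index=False))
# fisher_p is P(X >= k) under the hypergeometric null; ease_p >= fisher_p
# by construction.  Sets with ease_p <= 0.1 are flagged enriched.
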