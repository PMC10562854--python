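"""Co-expression partners of a disease lncRNA and gene-set enrichment.

Ranks cluster genes by Spearman correlation with the lncRNA, reports the
co-detection ratio for top partners, and tests the partner list against a
module-aligned gene-set collection with the hypergeometric test.
"""

from crossatlas import (
    SyntheticConfig, coexpression_ratio, concat_cells, correlated_genes,
    hypergeom_enrich, simulate_atlas, synthetic_gene_sets,
)

config = SyntheticConfig(seed=0)
datasets, truth = simulate_atlas(config)
combined = concat_cells(datasets)

lncrna, cluster = "LNC0002", "EpD_KRT2_Basalinflammatory"  # planted disease lncRNA
ranked = correlated_genes(combined, lncrna, cluster, top_n=combined.n_genes)
print(f"top correlated genes with {lncrna} in {cluster}:")
print(ranked.head(5).to_string(index=False))

for gene in ranked["gene"].head(3):
    rec = coexpression_ratio(combined, None, lncrna, gene, cluster)
    print(f"co-detection ratio {lncrna}~{gene}: {rec.ratio:.2f} "
          f"({rec.n_lncrna_detected} lncRNA+ cells of {rec.n_cells})")

sets = synthetic_gene_sets(config)
enrichment = hypergeom_enrich(
    list(ranked["gene"].head(50)), sets, universe=list(ranked["gene"])
)
print("\nmost enriched terms for the top-50 partner list:")
print(enrichment.head(3)[["term_id", "overlap_k", "set_K", "pval", "padj"]]
      .to_string(index=False))
# The generator plants no real co-regulation, so enrichment stays flat here;
# the statistics themselves are exercised against exact oracles in the tests.
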