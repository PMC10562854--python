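"""Generate the default synthetic skin atlas and inspect what was planted.

Three datasets with batch effects, 21 cell subtypes defined by marker genes,
healthy and psoriatic donors, and six lncRNAs shifted under the psoriatic
condition in designated cell types.
"""

from crossatlas import SyntheticConfig, simulate_atlas

config = SyntheticConfig(seed=0)
datasets, truth = simulate_atlas(config)

for ds in datasets:
    name = ds.cell_meta["dataset"].iloc[0]
    print(f"{name}: {ds.n_cells} cells x {ds.n_genes} genes, "
          f"{ds.cell_meta['label'].nunique()} cell types, "
          f"{(ds.gene_meta['biotype'] == 'lncRNA').sum()} lncRNAs")

print(f"\nplanted marker genes: {len(truth.true_marker)} (gene, type) pairs")
print("planted condition-shifted lncRNAs:")
for (gene, cell_type), log_fold in sorted(truth.de_log_folds.items()):
    print(f"  {gene} in {cell_type}: log2 fold {log_fold:+.1f} (psoriatic vs healthy)")

# Each dataset is one synthetic "study"; the cell counts, marker structure and
# the planted fold changes are the ground truth every later stage is scored on.
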