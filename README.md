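# crossatlas

Cross-dataset single-cell RNA-seq integration through **classifier
probability latent spaces**, attribution-based expression recovery, and
per-cell-type long non-coding RNA (lncRNA) analysis — exercised end to end on
a synthetic multi-study skin atlas with healthy and psoriatic conditions.

The package is aimed at computational biologists who want to project several
scRNA-seq datasets into a common space without correcting expression values
directly, transfer cell-type labels across studies, and then ask which
lncRNAs shift per cell subtype between disease and health.

## The method

1. **Per-dataset classifier.** For each dataset *d* with cell-type labels, a
   small interpretable softmax network *f_d* (one ReLU hidden layer over
   log-normalized expression `ln(1 + 10⁴·x/libsize)`) is trained. For any
   cell *x*, `f_d(x)` is a probability vector over dataset *d*'s cell types —
   its *probabilistic score*.
2. **Latent space.** Every model scores every cell of every dataset; the
   horizontal concatenation of the score blocks, `Z = [f_1(X) | f_2(X) | …]`,
   is the latent space. Batch effects act on expression, not on a trained
   model's opinion of a cell, so neighbor structure in `Z` is batch-robust.
3. **Label transfer.** Query cells take the majority label of their *k* = 15
   Euclidean nearest reference cells in `Z` (ties: smaller mean distance,
   then lexicographic), with the vote fraction reported.
4. **Expression recovery.** Per model, DeepLift (rescale rule, zero-expression
   baseline) attributions of each gene to each class logit, averaged over the
   model's training cells of that class, give a feature-weight matrix
   `W (genes × types)`. A denoised expression matrix is `E = W·Pᵀ`, and
   matrices from several models are merged by averaging non-empty values per
   gene, with support counts.
5. **Downstream statistics.** Per cell type: two-sided Wilcoxon rank-sum DE
   between conditions with Benjamini–Hochberg adjustment within type and
   log2 fold changes (pseudocount 1); lncRNA filtering; co-detection ratios
   and Spearman partner screens around candidate lncRNAs; upper-tail
   hypergeometric gene-set enrichment; the `2^-ΔΔCT` qPCR helper; and the
   atlas-export downsampler (≤ 300 cells per cell type × condition × donor).

Because the real multi-study atlas cannot ship with a package, `crossatlas`
includes a first-class synthetic-data module: a negative-binomial generator
with marker-defined cell subtypes (the 21 skin subtype labels of the
integrated atlas), lognormal batch factors, dropout, and planted
condition-specific lncRNA fold changes — with full ground truth, so every
stage is scored against what was actually simulated.

## Worked example

```python
from crossatlas import (SyntheticConfig, TrainConfig, simulate_atlas,
                        train_classifier, build_latent, transfer_labels)

datasets, truth = simulate_atlas(SyntheticConfig(seed=0))
models = [train_classifier(ds, config=TrainConfig(seed=i))
          for i, ds in enumerate(datasets)]
latent = build_latent(models, datasets)
query = [c for ds in datasets[1:] for c in ds.cell_ids]
result = transfer_labels(latent, datasets[0].cell_meta["label"], query, k=15)
print((result.labels() == truth.true_label.loc[query]).mean())
```

Running the bundled examples prints, among others:

```
final held-out accuracy: 0.937            # self-classification of 21 subtypes
latent space: 7560 cells x 63 score columns
label-transfer accuracy on 5040 query cells: 0.995
distinct labels assigned: 21 of 21
markers peaking in their own type after recovery: 210/210
   LNC0002   up in EpD_KRT2_Basalinflammatory   log2FC +0.95, padj 8.76e-15  [planted]
```

Held-out accuracy above 0.9 means the classifier assigns the 21 subtypes at
the quality level the approach targets; transfer accuracy 0.995 with all 21
labels present shows score-space neighbors see through the simulated batch
effect; and all six planted lncRNA condition shifts — and nothing else —
reach significance in their designated cell types.

See `examples/` for one short script per capability and `docs/methods.md`
for model details and limitations. A thin CLI mirrors the library
(`crossatlas simulate|train|predict|integrate|transfer|de|coexpr|enrich|run`).

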