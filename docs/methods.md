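# Methods

## Synthetic atlas generator

The generator produces one sparse count matrix per "study", with cell
metadata (dataset, donor, condition ∈ {healthy, psoriatic}, true label) and
gene biotypes (protein_coding / lncRNA). The mean model for cell *c* of type
*t*, condition *v*, dataset *d* and gene *g* is

```
mu = base_mean · 2^(marker_log_fold·[g marker of t]) · 2^(fold_{g,t}·[v = psoriatic]) · B_{d,g} · s_c
```

with counts drawn negative-binomially (variance `mu + φ·mu²`) and then
zeroed by independent Bernoulli dropout. All folds are log2.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| datasets × donors | 3 × 2 per condition | a minimal multi-study design with donor structure |
| cell types | the 21 skin subtype labels | the atlas label set the analysis is built around |
| cells/type/donor/condition | 30 | full pipeline in ~1 min on one core |
| genes / lncRNAs | 2,000 / 200 | desk-scale stand-in for a full transcriptome |
| markers per type | 10, disjoint, protein-coding | distinct defining markers per subtype; lncRNAs reserved for condition effects |
| `marker_log_fold` | 5.0 (32×) | canonical subtype markers (keratins, collagens, PTPRC-class genes) run tens of counts in their own type against a sub-count background; with `base_mean` 0.3 this puts marker means near 10 counts |
| `base_mean` | 0.3 counts | typical non-marker gene detection level in UMI data |
| dispersion φ | 0.3 | common scRNA-seq overdispersion |
| `dropout_rate` | 0.2 | stresses detection-fraction statistics without dominating |
| `batch_scale` | 0.3 | per-dataset per-gene lognormal factor; strong enough that raw-expression neighbors degrade while score-space neighbors do not |
| size factor | lognormal(0, 0.25) | cell-to-cell library variation |
| planted lncRNA effects | 6 pairs, log2 folds ±2–3 | epidermal/perivascular up-shifts plus one immune down-shift under the psoriatic condition |

What it does **not** emulate: transcriptome-wide correlation structure
(genes are conditionally independent given type/condition/batch), doublets,
donor-level random effects beyond the size factor, ambient RNA, or realistic
gene-length/GC biases. Passing tests therefore certify the statistical
machinery on data satisfying the model's own assumptions — not robustness to
every artifact of real atlases. Co-regulated gene modules, needed to
exercise the correlation screen positively, are constructed directly in the
tests rather than by the generator.

Label note: the atlas label list fixes 21 subtype names (nine epidermal
zonation types including the inflammatory basal branch and a
hair-follicle-like group, six mesenchymal, two endothelial, two immune,
Schwann/melanocyte, mixed erythrocytes). "EpD_KRT7_Corneum" and
"Endo_Vascular" complete the zonation and endothelial pairs.

## Classifier

One hidden ReLU layer (64 units) + softmax, trained with mini-batch Adam
(lr 1e-3, batch 64, 100 epochs) on `ln(1 + 10⁴·x/libsize)` features over the
full gene set (no HVG selection — recovery should cover every gene). Adam
rather than plain SGD because at this learning rate plain SGD does not
converge within the epoch budget on log-normalized inputs; the piecewise-
linear architecture is what keeps DeepLift exact. A pure multinomial-
logistic architecture is available (`architecture="logistic"`), useful as a
closed-form attribution oracle. A stratified 20% held-out split (at least
one cell per class) is scored after every epoch; the recorded curve feeds
the learning-curve report with its default 80%-accuracy threshold.
Numerical choices: label set sorted lexicographically so argmax ties break
toward the smallest label; missing query genes are zero-imputed after
normalization; zero-library query cells get all-zero feature rows (bias-only
softmax) and a log warning rather than an error — projection must tolerate
degenerate cells, while `io.normalize` itself still rejects them.

## Latent space, transfer, embedding

The latent space concatenates every model's score block in model order; each
block is row-stochastic by construction. Transfer uses Euclidean k-NN
(k = 15) with majority vote; tie-break: more votes, then smaller mean
neighbor distance, then lexicographic label. k, the metric and uniform block
weighting are free choices fixed here; scores live on bounded simplices, so
unweighted Euclidean distance is well-scaled. The 2-D UMAP embedding is a
visualization convenience — only shape, finiteness and seeded
reproducibility are contractual.

## Attribution and recovery

DeepLift rescale rule against the all-zero expression baseline ("gene
absent"): for each unit the multiplier is Δactivation/Δpre-activation,
falling back to the derivative where the difference vanishes (|Δ| ≤ 1e-12).
Per-class weights are the mean attribution over the model's training cells
of that class; aggregation over cells (rather than a class prototype) keeps
the completeness identity exact in mean form: per class,
`Σ_g W[g,c] = mean over class cells of [logit_c(x) − logit_c(baseline)]`.
For the logistic architecture this collapses to
`weight × (class mean − baseline)`. Recovery is the exact product
`E = W·Pᵀ` with no clipping — negative recovered values are meaningful
(evidence against expression); consumers needing non-negativity must clip
explicitly. Merging across models averages values gene-wise over the models
whose feature set covers the gene, masking uncovered entries (support 0).
The pipeline writes the recovered matrix restricted to marker genes and
lncRNAs — the genes downstream stages consume — since the full dense
genes × cells text artifact is disproportionate at atlas scale; the full
matrix remains available through the API.

## Differential expression and enrichment

Wilcoxon rank-sum per (cell type, gene) on normalized expression, two-sided;
scipy's exact method applies automatically to tiny tie-free groups, the
tie-corrected normal approximation otherwise. BH adjustment within each cell
type (the per-type tables are the reporting unit). Effect size:
`log2((mean_psor + 1)/(mean_healthy + 1))`. Types with fewer than
`min_cells = 20` cells in either condition are skipped and logged. The
lncRNA filter keeps biotype = lncRNA rows with padj ≤ α (inclusive, so α = 1
degenerates to "all lncRNA rows") and annotates up/down by fold sign.

Co-expression ratio = co-detection conditional on lncRNA detection — a
deliberate, normalization-free definition recorded in output metadata;
partner screens use Spearman correlation with constant genes excluded and
rho ties broken lexicographically. Enrichment is the upper-tail
hypergeometric test with the universe restricted to genes tested in the
cluster (conditioning away detection bias), BH across terms.

## Pipeline and reproducibility

`run_pipeline` chains simulate → train (per dataset) → latent → transfer
(+ crosstab, radar) → attribution/recovery/merge → DE → lncRNA filter →
co-expression → enrichment → capped atlas export (≤ 300 cells per
type × condition × donor). Each per-dataset model trains with seed
`train.seed + dataset index`. Every artifact is plain text (TSV/MTX/JSON/
GMT); the manifest stores per-stage counts and SHA-256 hashes, and a rerun
with the same config reproduces every byte. Default problem sizes (2,520
cells × 2,000 genes per dataset; 42,000 DE tests) keep a full run near one
minute on a single core while leaving every stage statistically non-trivial.

## Known limitations

- Self-dataset scores come from resubstitution of the fitted model, not
  cross-validation; scores on training data are mildly optimistic.
- Probabilities are uncalibrated; they are coordinates, not posterior
  guarantees.
- DE treats cells as exchangeable within condition (no donor-level mixed
  model); with two donors per condition, donor effects fold into the
  condition contrast.
- Enrichment ignores gene-set topology (no GO DAG propagation).
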