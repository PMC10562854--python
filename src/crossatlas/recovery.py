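"""Attribution-based expression recovery.

Feature weights per reference cell type are DeepLift (rescale rule)
contributions of each gene to the class logit, averaged over the model's
training cells of that class, relative to a zero-expression baseline. A
denoised genes x cells matrix is then the plain matrix product of those
weights with the cells' probabilistic scores, E = W · Pᵀ; matrices recovered
under several per-dataset models are merged by averaging non-empty values.

For the piecewise-linear networks used here the rescale rule is exact: per
cell, attributions sum to logit(x) − logit(baseline) (completeness), and for
the purely linear architecture W reduces to weight x (mean input − baseline).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import ProbScoreMatrix, ReferenceModel, _design_matrix
from .io import CellDataset


@dataclass
class FeatureWeightMatrix:
    """Genes x cell-types attribution weights for one reference model."""

    W: pd.DataFrame  # index = feature_list, columns = label_set
    model_id: str
    baseline: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.W.to_numpy()).all():
            raise ValueError("feature weights must be finite")


@dataclass
class RecoveredExpression:
    """Merged genes x cells expression with per-entry support counts.

    ``values`` holds NaN wherever no model's feature set covered the gene
    (support 0); defined entries carry support >= 1.
    """

    values: pd.DataFrame  # genes x cells, NaN where masked
    support: pd.DataFrame  # genes x cells, int


def _deeplift_rescale(model: ReferenceModel, X: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Per-cell rescale-rule attributions, shape (n_cells, n_genes, n_classes)."""
    dx = X - baseline[None, :]
    if model.config.architecture == "logistic":
        return dx[:, :, None] * model.params["W"][None, :, :]
    W1, b1, W2 = model.params["W1"], model.params["b1"], model.params["W2"]
    z1 = X @ W1 + b1
    z0 = baseline @ W1 + b1
    a1 = np.maximum(z1, 0.0)
    a0 = np.maximum(z0, 0.0)
    dz = z1 - z0[None, :]
    # rescale multiplier (Δactivation / Δpre-activation); where Δ vanishes the
    # unit is inactive w.r.t. the baseline and the derivative is used instead
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(np.abs(dz) > 1e-12, (a1 - a0[None, :]) / dz, (z1 > 0).astype(float))
    # attr[n,g,c] = dx[n,g] * sum_h W1[g,h] * m[n,h] * W2[h,c]
    M = np.einsum("gh,nh,hc->ngc", W1, m, W2, optimize=True)
    return dx[:, :, None] * M


def attribute_features(
    model: ReferenceModel,
    dataset: CellDataset | None = None,
    labels: pd.Series | None = None,
    baseline: np.ndarray | None = None,
    chunk_size: int = 256,
) -> FeatureWeightMatrix:
    """Class-mean DeepLift feature weights relative to a baseline expression.

    By default attributions are averaged over the model's cached training
    cells per class; pass ``dataset`` (and optionally ``labels``) to attribute
    over other labeled cells. The default baseline is the all-zero expression
    vector (the "absent gene" reference).
    """
    if dataset is not None:
        X = _design_matrix(dataset, model.feature_list)
        labs = labels if labels is not None else dataset.cell_meta["label"]
        labs = labs.reindex(dataset.cell_ids)
        if labs.isna().any():
            raise ValueError("every attributed cell must be labeled")
        unknown = set(labs.unique()) - set(model.label_set)
        if unknown:
            raise ValueError(f"labels outside the model label set: {sorted(unknown)}")
        y = np.searchsorted(model.label_set, labs.to_numpy())
    else:
        if model._train_X is None:
            raise ValueError(
                "model has no cached training data; pass the training dataset explicitly"
            )
        X, y = model._train_X, model._train_y
    baseline = (
        np.zeros(len(model.feature_list)) if baseline is None else np.asarray(baseline, float)
    )
    if baseline.shape != (len(model.feature_list),):
        raise ValueError("baseline must be one expression value per model feature")

    n_classes = len(model.label_set)
    class_counts = np.bincount(y, minlength=n_classes)
    missing = [model.label_set[c] for c in np.flatnonzero(class_counts == 0)]
    if missing:
        raise ValueError(f"class(es) with no cells to attribute over: {missing}")

    sums = np.zeros((len(model.feature_list), n_classes))
    for start in range(0, X.shape[0], chunk_size):
        sl = slice(start, start + chunk_size)
        attr = _deeplift_rescale(model, X[sl], baseline)  # (n, g, c)
        for c in np.unique(y[sl]):
            sums[:, c] += attr[y[sl] == c, :, c].sum(axis=0)
    W = sums / class_counts[None, :]
    return FeatureWeightMatrix(
        W=pd.DataFrame(W, index=pd.Index(model.feature_list, name="gene_id"),
                       columns=list(model.label_set)),
        model_id=model.model_id,
        baseline=baseline,
    )


def recover_expression(W: FeatureWeightMatrix, P: ProbScoreMatrix) -> pd.DataFrame:
    """Denoised expression E = W · Pᵀ (genes x cells), exact linear algebra."""
    if set(W.W.columns) != set(P.labels):
        raise ValueError(
            f"label sets differ: weights {sorted(W.W.columns)} vs scores {sorted(P.labels)}"
        )
    Wm = W.W[list(P.labels)].to_numpy()  # align column order to the score labels
    E = Wm @ P.scores.T
    return pd.DataFrame(E, index=W.W.index, columns=P.cell_ids)


def merge_recovered(
    E_list: Sequence[pd.DataFrame],
    feature_masks: Sequence[Sequence[str]] | None = None,
) -> RecoveredExpression:
    """Average non-empty recovered values across models, gene by gene.

    Each matrix contributes only on its model's feature set (by default its
    own row index); entries no model covers are masked (NaN) with support 0.
    """
    if not E_list:
        raise ValueError("nothing to merge")
    if feature_masks is None:
        feature_masks = [list(E.index) for E in E_list]
    if len(feature_masks) != len(E_list):
        raise ValueError("one feature mask per recovered matrix is required")
    cells = E_list[0].columns
    for E in E_list[1:]:
        if not cells.equals(E.columns):
            if set(cells) != set(E.columns):
                raise ValueError("recovered matrices must share the same cell axis")
            E_list = [e[cells] for e in E_list]
            break
    all_genes = pd.Index(sorted(set().union(*[set(m) for m in feature_masks])), name="gene_id")
    total = np.zeros((len(all_genes), len(cells)))
    support = np.zeros((len(all_genes), len(cells)), dtype=int)
    for E, mask in zip(E_list, feature_masks):
        genes = pd.Index(mask).intersection(E.index)
        pos = all_genes.get_indexer(genes)
        total[pos] += E.loc[genes, cells].to_numpy()
        support[pos] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(support > 0, total / np.maximum(support, 1), np.nan)
    return RecoveredExpression(
        values=pd.DataFrame(values, index=all_genes, columns=cells),
        support=pd.DataFrame(support, index=all_genes, columns=cells),
    )
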