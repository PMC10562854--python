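"""Cross-prediction latent space, KNN label transfer, and comparison summaries.

Every trained per-dataset model scores every cell of every dataset; the
horizontal concatenation of those probability blocks is the latent space in
which label transfer and embedding operate. Batch effects act on expression,
not on a model's opinion of a cell, which is why neighbor search in score
space outperforms neighbor search in expression space across datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .classifier import ProbScoreMatrix, ReferenceModel, predict_scores
from .io import CellDataset

logger = logging.getLogger(__name__)


@dataclass
class LatentSpace:
    """Cells x (sum of model label sets) probabilistic-score coordinates."""

    matrix: np.ndarray
    cell_ids: pd.Index
    columns: list[tuple[str, str]]  # (model_id, label)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (len(self.cell_ids), len(self.columns)):
            raise ValueError("latent matrix shape does not match cell_ids/columns")

    def to_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(self.columns, names=["model", "label"])
        return pd.DataFrame(self.matrix, index=self.cell_ids, columns=cols)

    def block(self, model_id: str) -> np.ndarray:
        idx = [j for j, (m, _) in enumerate(self.columns) if m == model_id]
        if not idx:
            raise KeyError(f"no columns for model {model_id!r}")
        return self.matrix[:, idx]


def build_latent(
    models: Sequence[ReferenceModel], datasets: Sequence[CellDataset]
) -> LatentSpace:
    """Score every cell with every model and concatenate the blocks in model order."""
    if not models:
        raise ValueError("need at least one trained model")
    all_ids = pd.Index(np.concatenate([np.asarray(ds.cell_ids) for ds in datasets]))
    if all_ids.has_duplicates:
        raise ValueError("cell ids must be unique across datasets")
    blocks: list[np.ndarray] = []
    columns: list[tuple[str, str]] = []
    for model in models:
        per_ds = []
        for ds in datasets:
            try:
                per_ds.append(predict_scores(model, ds).scores)
            except Exception as exc:  # annotate with (model, dataset) context
                ds_name = ds.cell_meta["dataset"].iloc[0] if "dataset" in ds.cell_meta else "?"
                raise RuntimeError(
                    f"predict_scores failed for model {model.model_id!r} on dataset "
                    f"{ds_name!r}: {exc}"
                ) from exc
        blocks.append(np.vstack(per_ds))
        columns.extend((model.model_id, lab) for lab in model.label_set)
    return LatentSpace(matrix=np.hstack(blocks), cell_ids=all_ids, columns=columns)


@dataclass
class TransferResult:
    """KNN label-transfer assignments for the query cells."""

    assignments: pd.DataFrame  # index cell_id; columns label, vote_fraction, k

    def labels(self) -> pd.Series:
        return self.assignments["label"]


def transfer_labels(
    latent: LatentSpace,
    reference_labels: pd.Series,
    query_cells: Sequence[str],
    k: int = 15,
) -> TransferResult:
    """Majority-vote KNN label transfer in the latent space (Euclidean metric).

    Ties between labels with equal votes are broken by the smaller mean
    distance of their voting neighbors, then lexicographically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ref_ids = pd.Index(reference_labels.index)
    query_ids = pd.Index(query_cells)
    for name, ids in (("reference", ref_ids), ("query", query_ids)):
        missing = ids.difference(latent.cell_ids)
        if len(missing):
            raise KeyError(f"{name} cells not present in latent space: {list(missing[:5])}")
    if k > len(ref_ids):
        raise ValueError(f"k={k} exceeds the {len(ref_ids)} reference cells")

    ref_pos = latent.cell_ids.get_indexer(ref_ids)
    query_pos = latent.cell_ids.get_indexer(query_ids)
    nn = NearestNeighbors(n_neighbors=k, metric="euclidean")
    nn.fit(latent.matrix[ref_pos])
    dist, nbr = nn.kneighbors(latent.matrix[query_pos])
    ref_label_arr = reference_labels.to_numpy()

    assigned, votes = [], []
    for d_row, n_row in zip(dist, nbr):
        labs = ref_label_arr[n_row]
        tally: dict[str, list[float]] = {}
        for lab, d in zip(labs, d_row):
            tally.setdefault(str(lab), []).append(float(d))
        # rank: most votes, then smaller mean distance, then lexicographic
        best = min(tally.items(), key=lambda kv: (-len(kv[1]), float(np.mean(kv[1])), kv[0]))
        assigned.append(best[0])
        votes.append(len(best[1]) / k)
    table = pd.DataFrame(
        {"label": assigned, "vote_fraction": votes, "k": k}, index=query_ids
    )
    table.index.name = "cell_id"
    return TransferResult(assignments=table)


def assignment_crosstab(labels_a: pd.Series, labels_b: pd.Series) -> pd.DataFrame:
    """Contingency counts between two labelings of the same cells, long format.

    Returns columns (source, target, count), Sankey-ready; total count equals
    the number of cells and marginals equal class sizes.
    """
    if set(labels_a.index) != set(labels_b.index):
        raise ValueError("the two labelings must cover the same cell set")
    labels_b = labels_b.reindex(labels_a.index)
    long = (
        pd.crosstab(labels_a.rename("source"), labels_b.rename("target"))
        .stack()
        .rename("count")
        .reset_index()
    )
    long = long[long["count"] > 0].reset_index(drop=True)
    return long.sort_values(["source", "target"]).reset_index(drop=True)


def radar_scores(scores: ProbScoreMatrix, query_labels: pd.Series) -> pd.DataFrame:
    """Mean probabilistic score of each query cell type against each reference type.

    Rows (query types) are means over probability vectors, hence themselves sum
    to 1. Label categories with no cells are dropped with a warning.
    """
    query_labels = query_labels.reindex(scores.cell_ids)
    if query_labels.isna().any():
        raise ValueError("every query cell must be labeled")
    frame = scores.to_frame()
    out = frame.groupby(query_labels.to_numpy(), observed=True).mean()
    observed = set(out.index)
    declared = set(query_labels.unique())
    empty = declared - observed
    if empty:
        logger.warning("dropping empty query type(s): %s", sorted(empty))
    out.index.name = "query_type"
    return out.sort_index()


def embed(latent: LatentSpace, seed: int = 0, n_neighbors: int = 15, min_dist: float = 0.1) -> pd.DataFrame:
    """2-D UMAP of the latent space, deterministic given the seed.

    The layout is a visualization convenience; only shape, finiteness and
    reproducibility are contractual.
    """
    n = len(latent.cell_ids)
    if n < 10:
        raise ValueError(f"embedding needs at least 10 cells, got {n}")
    n_neighbors = min(n_neighbors, n - 1)
    import umap  # deferred: heavy import

    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
    )
    coords = reducer.fit_transform(latent.matrix)
    return pd.DataFrame(coords, index=latent.cell_ids, columns=["umap1", "umap2"])
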