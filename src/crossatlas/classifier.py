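"""Per-dataset cell-type classifier emitting probabilistic scores.

The reference model is a deliberately small, interpretable softmax network:
one ReLU hidden layer (or a pure multinomial-logistic variant) trained on
log-normalized expression with mini-batch Adam. Its piecewise-linear form is
what keeps the downstream attribution (recovery module) exact. Each trained
model turns any cell — from its own dataset or a projected one — into a
probability vector over its cell-type labels; those vectors are the latent
coordinates used for integration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CellDataset, normalize

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults favour small desk-scale references."""

    architecture: str = "mlp"  # "mlp" (one ReLU hidden layer) or "logistic"
    hidden_units: int = 64
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 64
    val_fraction: float = 0.2
    min_cells_per_class: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.architecture not in ("mlp", "logistic"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must lie in (0, 1)")
        for name in ("hidden_units", "epochs", "batch_size", "min_cells_per_class"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ProbScoreMatrix:
    """Cells x labels probabilistic scores; each row is a probability vector."""

    scores: np.ndarray
    cell_ids: pd.Index
    labels: list[str]
    model_id: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (len(self.cell_ids), len(self.labels)):
            raise ValueError("score matrix shape does not match cell_ids/labels")
        if not np.allclose(self.scores.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("score rows must sum to 1")
        if self.scores.min() < -1e-12 or self.scores.max() > 1 + 1e-12:
            raise ValueError("scores must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.cell_ids, columns=self.labels)

    def argmax_labels(self) -> pd.Series:
        # label_set is kept sorted, so argmax's first-index rule breaks ties
        # toward the lexicographically smallest label
        return pd.Series(
            np.asarray(self.labels)[np.argmax(self.scores, axis=1)], index=self.cell_ids
        )


@dataclass
class ReferenceModel:
    """A trained per-dataset classifier plus its training record."""

    model_id: str
    feature_list: np.ndarray  # ordered gene ids
    label_set: list[str]  # sorted cell-type labels
    params: dict[str, np.ndarray]
    config: TrainConfig
    learning_curve_: list[float] = field(default_factory=list)
    train_cell_ids: list[str] = field(default_factory=list)
    # cached normalized training design matrix / labels (not serialized)
    _train_X: np.ndarray | None = None
    _train_y: np.ndarray | None = None

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Logits for a dense design matrix aligned to ``feature_list``."""
        if self.config.architecture == "logistic":
            return X @ self.params["W"] + self.params["b"]
        h = np.maximum(X @ self.params["W1"] + self.params["b1"], 0.0)
        return h @ self.params["W2"] + self.params["b2"]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _softmax(self.forward(X))

    def save(self, path) -> Path:
        """Single-archive serialization: weight arrays + JSON header."""
        path = Path(path)
        meta = {
            "model_id": self.model_id,
            "label_set": self.label_set,
            "config": asdict(self.config),
            "learning_curve": self.learning_curve_,
            "train_cell_ids": self.train_cell_ids,
        }
        np.savez(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            feature_list=self.feature_list.astype(str),
            **self.params,
        )
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path) -> "ReferenceModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(z["meta"].tobytes().decode())
            params = {
                k: z[k] for k in z.files if k not in ("meta", "feature_list")
            }
            return cls(
                model_id=meta["model_id"],
                feature_list=z["feature_list"].astype(str),
                label_set=list(meta["label_set"]),
                params=params,
                config=TrainConfig(**meta["config"]),
                learning_curve_=list(meta["learning_curve"]),
                train_cell_ids=list(meta["train_cell_ids"]),
            )


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _design_matrix(
    dataset: CellDataset, feature_list: np.ndarray, scale: float = 1e4
) -> np.ndarray:
    """Normalize and align genes to the model feature list (missing genes -> 0).

    Applies the same ln(1 + scale x / libsize) transform as io.normalize but
    tolerates zero-library cells (their row stays all-zero), so projection of
    degenerate query cells yields a defined — if uninformative — score.
    """
    pos = dataset.gene_ids.get_indexer(pd.Index(feature_list))
    if (pos >= 0).sum() == 0:
        raise ValueError("query dataset shares no genes with the model feature list")
    counts = dataset.counts.astype(np.float64).tocsr()
    lib = np.asarray(counts.sum(axis=1)).ravel()
    row_scale = np.divide(scale, lib, out=np.zeros_like(lib), where=lib > 0)
    norm = counts.copy()
    norm.data *= np.repeat(row_scale, np.diff(norm.indptr))
    np.log1p(norm.data, out=norm.data)
    X = np.zeros((dataset.n_cells, len(feature_list)))
    present = pos >= 0
    X[:, present] = norm[:, pos[present]].toarray()
    return X


def train_classifier(
    dataset: CellDataset,
    labels: pd.Series | None = None,
    config: TrainConfig | None = None,
    model_id: str | None = None,
) -> ReferenceModel:
    """Train the softmax network on one labeled dataset.

    Holds out ``val_fraction`` of cells (stratified) and records held-out
    accuracy after every epoch as the learning curve. Deterministic for fixed
    (dataset, labels, config).
    """
    config = config or TrainConfig()
    config.validate()
    if labels is None:
        if "label" not in dataset.cell_meta.columns:
            raise ValueError("no labels given and cell_meta has no 'label' column")
        labels = dataset.cell_meta["label"]
    labels = labels.reindex(dataset.cell_ids)
    if labels.isna().any():
        raise ValueError("every cell must be labeled for training")
    label_set = sorted(labels.unique())
    if len(label_set) < 2:
        raise ValueError("training needs at least 2 cell-type labels")
    counts = labels.value_counts()
    small = counts[counts < config.min_cells_per_class]
    if len(small):
        raise ValueError(
            f"class(es) below min_cells_per_class={config.min_cells_per_class}: "
            f"{dict(small)}"
        )

    rng = np.random.default_rng(config.seed)
    feature_list = np.asarray(dataset.gene_ids, dtype=str)
    X = _design_matrix(dataset, feature_list)
    y = np.searchsorted(label_set, labels.to_numpy())

    # stratified split: per class, at least one held-out cell
    val_mask = np.zeros(len(y), dtype=bool)
    for k in range(len(label_set)):
        idx = np.flatnonzero(y == k)
        n_val = max(1, int(round(config.val_fraction * len(idx))))
        val_mask[rng.choice(idx, size=n_val, replace=False)] = True
    Xtr, ytr = X[~val_mask], y[~val_mask]
    Xva, yva = X[val_mask], y[val_mask]

    params = _init_params(config, n_features=X.shape[1], n_classes=len(label_set), rng=rng)
    if model_id is None:
        model_id = (
            str(dataset.cell_meta["dataset"].iloc[0])
            if "dataset" in dataset.cell_meta.columns
            else "model"
        )
    model = ReferenceModel(
        model_id=model_id,
        feature_list=feature_list,
        label_set=label_set,
        params=params,
        config=config,
    )

    opt_state = {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in params.items()}
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(ytr))
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            grads = _grad_cross_entropy(model, Xtr[batch], ytr[batch])
            step += 1
            _adam_update(params, grads, opt_state, lr=config.learning_rate, t=step)
        val_acc = float(np.mean(model.predict_proba(Xva).argmax(axis=1) == yva))
        model.learning_curve_.append(val_acc)

    model.train_cell_ids = list(dataset.cell_ids)
    model._train_X = X
    model._train_y = y
    return model


def _init_params(config: TrainConfig, n_features: int, n_classes: int, rng) -> dict[str, np.ndarray]:
    if config.architecture == "logistic":
        return {
            "W": rng.normal(0.0, 1.0 / np.sqrt(n_features), size=(n_features, n_classes)),
            "b": np.zeros(n_classes),
        }
    h = config.hidden_units
    return {
        "W1": rng.normal(0.0, np.sqrt(2.0 / n_features), size=(n_features, h)),
        "b1": np.zeros(h),
        "W2": rng.normal(0.0, np.sqrt(2.0 / h), size=(h, n_classes)),
        "b2": np.zeros(n_classes),
    }


def _grad_cross_entropy(model: ReferenceModel, X: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
    n = len(y)
    if model.config.architecture == "logistic":
        p = _softmax(X @ model.params["W"] + model.params["b"])
        p[np.arange(n), y] -= 1.0
        p /= n
        return {"W": X.T @ p, "b": p.sum(axis=0)}
    z1 = X @ model.params["W1"] + model.params["b1"]
    h = np.maximum(z1, 0.0)
    p = _softmax(h @ model.params["W2"] + model.params["b2"])
    p[np.arange(n), y] -= 1.0
    p /= n
    dh = p @ model.params["W2"].T
    dh[z1 <= 0] = 0.0
    return {
        "W1": X.T @ dh,
        "b1": dh.sum(axis=0),
        "W2": h.T @ p,
        "b2": p.sum(axis=0),
    }


def _adam_update(params, grads, state, lr, t, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
    for k, g in grads.items():
        m, v = state[k]
        m *= beta1
        m += (1 - beta1) * g
        v *= beta2
        v += (1 - beta2) * g * g
        mhat = m / (1 - beta1**t)
        vhat = v / (1 - beta2**t)
        params[k] -= lr * mhat / (np.sqrt(vhat) + eps)


def predict_scores(model: ReferenceModel, dataset: CellDataset) -> ProbScoreMatrix:
    """Probabilistic scores of every cell against the model's cell types.

    The dataset is log-normalized and gene-aligned to the model's feature list
    (genes absent from the query are imputed as 0). All-zero expression cells
    get the baseline softmax vector and are flagged in the log.
    """
    X = _design_matrix(dataset, model.feature_list)
    zero_cells = np.flatnonzero(~X.any(axis=1))
    if zero_cells.size:
        logger.warning(
            "%d cell(s) have zero expression on the model feature list, e.g. %s",
            zero_cells.size,
            list(dataset.cell_ids[zero_cells[:5]]),
        )
    return ProbScoreMatrix(
        scores=model.predict_proba(X),
        cell_ids=dataset.cell_ids,
        labels=list(model.label_set),
        model_id=model.model_id,
    )


@dataclass
class AccuracyReport:
    overall: float
    per_class: dict[str, float]
    n_cells: int


def evaluate_accuracy(
    model: ReferenceModel, dataset: CellDataset, labels: pd.Series | None = None
) -> AccuracyReport:
    """Overall and per-class argmax assignment accuracy against given labels."""
    if labels is None:
        labels = dataset.cell_meta["label"]
    labels = labels.reindex(dataset.cell_ids)
    if labels.isna().any():
        raise ValueError("labels must cover every cell in the dataset")
    pred = predict_scores(model, dataset).argmax_labels()
    correct = (pred == labels).to_numpy()
    per_class = {
        str(ct): float(correct[(labels == ct).to_numpy()].mean())
        for ct in sorted(labels.unique())
    }
    return AccuracyReport(
        overall=float(correct.mean()), per_class=per_class, n_cells=len(labels)
    )


@dataclass
class LearningCurve:
    table: pd.DataFrame  # columns: epoch (1-based), accuracy
    threshold: float
    first_epoch_at_threshold: int | None  # None means "never"

    def __str__(self) -> str:
        hit = self.first_epoch_at_threshold
        return (
            f"learning curve over {len(self.table)} epochs; "
            f"{self.threshold:.0%} threshold first reached at epoch "
            f"{hit if hit is not None else 'never'}"
        )


def learning_curve(model: ReferenceModel, threshold: float = 0.8) -> LearningCurve:
    """Per-epoch held-out accuracy with the first crossing of ``threshold``."""
    if not model.learning_curve_:
        raise ValueError("model was trained without learning-curve recording")
    acc = np.asarray(model.learning_curve_, dtype=float)
    table = pd.DataFrame({"epoch": np.arange(1, len(acc) + 1), "accuracy": acc})
    above = np.flatnonzero(acc >= threshold)
    first = int(above[0]) + 1 if above.size else None
    return LearningCurve(table=table, threshold=threshold, first_epoch_at_threshold=first)
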