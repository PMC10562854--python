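"""Latent-space construction, KNN label transfer, crosstab, radar, embedding."""

import numpy as np
import pandas as pd
import pytest

from crossatlas import (
    LatentSpace,
    ProbScoreMatrix,
    TrainConfig,
    assignment_crosstab,
    build_latent,
    embed,
    normalize,
    radar_scores,
    train_classifier,
    transfer_labels,
)

from conftest import build_dataset, separable_dataset


def toy_latent(points, ids=None):
    points = np.asarray(points, float)
    ids = ids or [f"c{i}" for i in range(len(points))]
    cols = [("m", f"L{j}") for j in range(points.shape[1])]
    return LatentSpace(points, pd.Index(ids), cols)


class TestBuildLatent:
    def test_column_block_bookkeeping(self):
        ds = separable_dataset(seed=1)
        m1 = train_classifier(ds, config=TrainConfig(seed=0, epochs=5), model_id="m1")
        # a second model with 3 labels
        labels3 = ds.cell_meta["label"].copy()
        labels3.iloc[:20] = "TypeC"
        m2 = train_classifier(ds, labels=labels3, config=TrainConfig(seed=0, epochs=5), model_id="m2")
        other = separable_dataset(n_per_type=10, seed=2)
        other.cell_meta.index = pd.Index([f"q{i}" for i in range(other.n_cells)], name="cell_id")
        latent = build_latent([m1, m2], [ds, other])
        assert latent.matrix.shape == (ds.n_cells + other.n_cells, 2 + 3)
        assert latent.columns[:2] == [("m1", "TypeA"), ("m1", "TypeB")]
        # each model block is row-stochastic
        assert np.allclose(latent.block("m1").sum(axis=1), 1.0, atol=1e-6)
        assert np.allclose(latent.block("m2").sum(axis=1), 1.0, atol=1e-6)

    def test_identical_cells_get_identical_latent_rows(self):
        ds = separable_dataset(seed=1)
        model = train_classifier(ds, config=TrainConfig(seed=0, epochs=5))
        dup = build_dataset(
            ds.counts.toarray(), labels=ds.cell_meta["label"],
            cell_ids=[f"dup_{c}" for c in ds.cell_ids],
        )
        latent = build_latent([model], [ds, dup])
        n = ds.n_cells
        assert np.allclose(latent.matrix[:n], latent.matrix[n:])

    def test_duplicate_ids_rejected(self):
        ds = separable_dataset(seed=1)
        model = train_classifier(ds, config=TrainConfig(seed=0, epochs=5))
        with pytest.raises(ValueError, match="unique"):
            build_latent([model], [ds, ds])


class TestTransferLabels:
    def test_exact_match_single_neighbor(self):
        latent = toy_latent([[1, 0], [0, 1], [1, 0]])
        ref = pd.Series(["A", "B"], index=["c0", "c1"])
        res = transfer_labels(latent, ref, ["c2"], k=1)
        assert res.labels()["c2"] == "A"
        assert res.assignments.loc["c2", "vote_fraction"] == 1.0

    def test_majority_vote_two_thirds(self):
        latent = toy_latent([[0, 0], [0.1, 0], [5, 5], [0.05, 0]])
        ref = pd.Series(["A", "A", "B"], index=["c0", "c1", "c2"])
        res = transfer_labels(latent, ref, ["c3"], k=3)
        assert res.labels()["c3"] == "A"
        assert res.assignments.loc["c3", "vote_fraction"] == pytest.approx(2 / 3)

    def test_vote_tie_broken_by_mean_distance_then_label(self):
        # two A's and two B's; B neighbors are closer on average
        latent = toy_latent([[0, 1], [0, -1], [0, 0.5], [0, -0.4], [0, 0]])
        ref = pd.Series(["A", "A", "B", "B"], index=["c0", "c1", "c2", "c3"])
        res = transfer_labels(latent, ref, ["c4"], k=4)
        assert res.labels()["c4"] == "B"
        # perfectly symmetric tie falls back to the lexicographically smaller label
        sym = toy_latent([[0, 1], [0, -1], [1, 0], [-1, 0], [0, 0]])
        res2 = transfer_labels(sym, pd.Series(["B", "B", "A", "A"], index=["c0", "c1", "c2", "c3"]), ["c4"], k=4)
        assert res2.labels()["c4"] == "A"

    def test_reference_as_its_own_query_with_k1_is_identity(self, ref_model, default_atlas):
        _, datasets, _ = default_atlas
        latent = build_latent([ref_model], [datasets[0]])
        ref = datasets[0].cell_meta["label"]
        res = transfer_labels(latent, ref, list(datasets[0].cell_ids), k=1)
        assert (res.labels() == ref).all()

    def test_k_larger_than_reference_rejected(self):
        latent = toy_latent([[0, 0], [1, 1], [2, 2]])
        ref = pd.Series(["A", "B"], index=["c0", "c1"])
        with pytest.raises(ValueError, match="exceeds"):
            transfer_labels(latent, ref, ["c2"], k=3)

    def test_latent_transfer_beats_raw_expression_1nn(self, default_atlas):
        """Score-space neighbors overcome the batch effect better than raw
        normalized-expression neighbors (cross-dataset, fixed seeds)."""
        from sklearn.neighbors import KNeighborsClassifier

        _, datasets, truth = default_atlas
        model = train_classifier(datasets[0], config=TrainConfig(seed=0))
        latent = build_latent([model], datasets)
        query = [c for ds in datasets[1:] for c in ds.cell_ids]
        res = transfer_labels(latent, datasets[0].cell_meta["label"], query, k=15)
        latent_acc = (res.labels() == truth.true_label.loc[query]).mean()

        Xref = normalize(datasets[0]).toarray()
        knn = KNeighborsClassifier(n_neighbors=1).fit(Xref, datasets[0].cell_meta["label"])
        raw_acc = np.mean(
            [
                (knn.predict(normalize(ds).toarray()) == ds.cell_meta["label"]).mean()
                for ds in datasets[1:]
            ]
        )
        assert latent_acc > raw_acc


class TestCrosstab:
    def test_identical_labelings_are_diagonal(self):
        a = pd.Series(["X"] * 6 + ["Y"] * 4, index=[f"c{i}" for i in range(10)])
        tab = assignment_crosstab(a, a)
        assert set(map(tuple, tab.to_numpy())) == {("X", "X", 6), ("Y", "Y", 4)}

    def test_conservation_and_marginals(self):
        rng = np.random.default_rng(0)
        idx = [f"c{i}" for i in range(50)]
        a = pd.Series(rng.choice(["A", "B", "C"], 50), index=idx)
        b = pd.Series(rng.choice(["P", "Q"], 50), index=idx)
        tab = assignment_crosstab(a, b)
        assert tab["count"].sum() == 50
        assert tab.groupby("source")["count"].sum().to_dict() == a.value_counts().to_dict()
        assert tab.groupby("target")["count"].sum().to_dict() == b.value_counts().to_dict()

    def test_three_cell_enumeration(self):
        a = pd.Series({"x": "A", "y": "A", "z": "B"})
        b = pd.Series({"x": "P", "y": "Q", "z": "Q"})
        tab = assignment_crosstab(a, b)
        assert {
            (s, t): c for s, t, c in zip(tab["source"], tab["target"], tab["count"])
        } == {
            ("A", "P"): 1, ("A", "Q"): 1, ("B", "Q"): 1,
        }

    def test_cell_set_mismatch_rejected(self):
        a = pd.Series({"x": "A"})
        b = pd.Series({"y": "A"})
        with pytest.raises(ValueError, match="same cell set"):
            assignment_crosstab(a, b)


class TestRadarScores:
    def test_one_hot_scores_give_identity(self):
        scores = ProbScoreMatrix(np.eye(3), pd.Index(["c0", "c1", "c2"]), ["A", "B", "C"])
        labels = pd.Series(["A", "B", "C"], index=["c0", "c1", "c2"])
        radar = radar_scores(scores, labels)
        assert np.allclose(radar.loc[["A", "B", "C"], ["A", "B", "C"]], np.eye(3))

    def test_hand_mean(self):
        scores = ProbScoreMatrix(
            np.array([[0.6, 0.4], [0.2, 0.8]]), pd.Index(["c0", "c1"]), ["A", "B"]
        )
        labels = pd.Series(["q", "q"], index=["c0", "c1"])
        radar = radar_scores(scores, labels)
        assert radar.loc["q"].to_list() == pytest.approx([0.4, 0.6])

    def test_rows_sum_to_one(self, ref_model, default_atlas):
        _, datasets, truth = default_atlas
        from crossatlas import predict_scores

        scores = predict_scores(ref_model, datasets[1])
        radar = radar_scores(scores, truth.true_label.loc[scores.cell_ids])
        assert np.allclose(radar.sum(axis=1), 1.0, atol=1e-6)


class TestEmbed:
    def test_shape_finiteness_reproducibility_and_separation(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.05, (50, 3)), rng.normal(1, 0.05, (50, 3))])
        latent = toy_latent(pts)
        coords = embed(latent, seed=42)
        assert coords.shape == (100, 2)
        assert np.isfinite(coords.to_numpy()).all()
        again = embed(latent, seed=42)
        assert np.allclose(coords.to_numpy(), again.to_numpy())
        xy = coords.to_numpy()
        c1, c2 = xy[:50].mean(axis=0), xy[50:].mean(axis=0)
        intra = np.linalg.norm(xy[:50] - c1, axis=1).mean() + np.linalg.norm(xy[50:] - c2, axis=1).mean()
        assert np.linalg.norm(c1 - c2) > intra / 2

    def test_too_few_cells_rejected(self):
        latent = toy_latent(np.zeros((5, 2)))
        with pytest.raises(ValueError, match="at least 10"):
            embed(latent, seed=0)
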