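"""Differential-expression contracts: exact rank-sum oracle, null behaviour,
planted-effect recovery, lncRNA filtering, dot-plot stats and 2^-ddCT."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from crossatlas import (
    SyntheticConfig,
    concat_cells,
    ddct,
    de_by_celltype,
    filter_lncRNA,
    marker_stats,
    simulate_atlas,
)

from conftest import build_dataset


def exact_ranksum_two_sided_p(x, y):
    """Enumeration oracle: exact two-sided rank-sum p over all group splits."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    observed = ranks[:n].sum()
    mean = ranks.sum() * n / len(pooled)
    stats = [
        abs(sum(ranks[list(c)]) - mean)
        for c in combinations(range(len(pooled)), n)
    ]
    obs = abs(observed - mean)
    return sum(s >= obs - 1e-12 for s in stats) / len(stats)


class TestMarkerStats:
    def test_zero_gene_and_detection_fraction(self):
        counts = np.array([[0, 0], [0, 0], [0, 2], [0, 2]])
        ds = build_dataset(counts, labels=["T"] * 4, gene_ids=["gz", "gd"])
        stats = marker_stats(ds.subset_cells(np.array([False, False, True, True])),
                            genes=["gz", "gd"])
        gz = stats[stats["gene"] == "gz"].iloc[0]
        assert gz["mean_norm"] == 0.0 and gz["frac_detected"] == 0.0
        # 4 cells with counts (0,0,2,2) -> fraction 0.5 by the count>0 rule
        stats_all = marker_stats(
            build_dataset([[0, 1], [0, 1], [2, 1], [2, 1]], labels=["T"] * 4,
                          gene_ids=["g", "lib"]),
            genes=["g"],
        )
        assert stats_all.iloc[0]["frac_detected"] == 0.5

    def test_unknown_gene_rejected(self):
        ds = build_dataset([[1, 2]], labels=["T"])
        with pytest.raises(KeyError, match="nope"):
            marker_stats(ds, genes=["nope"])

    def test_simulated_marker_mean_is_maximal_in_own_type(self, default_atlas):
        cfg, datasets, truth = default_atlas
        ds = datasets[0]
        markers = sorted({g for g, _ in truth.true_marker})
        stats = marker_stats(ds, genes=markers)
        pivot = stats.pivot(index="gene", columns="cell_type", values="mean_norm")
        hits = sum(pivot.loc[g].idxmax() == ct for g, ct in sorted(truth.true_marker))
        assert hits / len(truth.true_marker) > 0.95


class TestDeByCelltype:
    def six_cell_dataset(self):
        # gene "goi" ordered 1..6 against a constant library gene: healthy
        # (1,2,3), psoriatic (4,5,6); normalized values keep that order
        counts = np.column_stack([np.arange(1, 7), np.full(6, 100)])
        return build_dataset(
            counts,
            labels=["T"] * 6,
            condition=["healthy"] * 3 + ["psoriatic"] * 3,
            gene_ids=["goi", "lib"],
        )

    def test_exact_p_on_three_vs_three(self):
        ds = self.six_cell_dataset()
        table = de_by_celltype(ds, min_cells=3, genes=["goi"])
        oracle = exact_ranksum_two_sided_p(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert oracle == pytest.approx(0.1)
        assert table.iloc[0]["pval"] == pytest.approx(0.1)
        assert table.iloc[0]["log2fc"] > 0

    def test_exact_p_matches_enumeration_on_interleaved_values(self):
        counts = np.column_stack([[1, 4, 2, 6, 3, 5], np.full(6, 100)])
        ds = build_dataset(counts, labels=["T"] * 6,
                           condition=["healthy", "psoriatic"] * 3,
                           gene_ids=["goi", "lib"])
        table = de_by_celltype(ds, min_cells=3, genes=["goi"])
        h = np.array([1.0, 2, 3])
        p = np.array([4.0, 6, 5])
        assert table.iloc[0]["pval"] == pytest.approx(
            exact_ranksum_two_sided_p(h, p)
        )

    def test_identical_distributions_are_null(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(5, size=(50, 30))
        counts = np.vstack([base, base])  # both conditions identical
        ds = build_dataset(
            counts, labels=["T"] * 100,
            condition=["healthy"] * 50 + ["psoriatic"] * 50,
        )
        table = de_by_celltype(ds, min_cells=20)
        assert (table["pval"] > 0.99).all()
        assert np.allclose(table["log2fc"], 0.0, atol=1e-9)

    def test_small_groups_skipped_and_logged(self, caplog):
        ds = self.six_cell_dataset()
        with caplog.at_level("INFO", logger="crossatlas.diffexpr"):
            table = de_by_celltype(ds, min_cells=20)
        assert table.empty
        assert "skipping" in caplog.text

    def test_missing_condition_column_rejected(self):
        ds = build_dataset([[1, 2]], labels=["T"])
        ds.cell_meta.drop(columns="condition", inplace=True)
        with pytest.raises(KeyError, match="condition"):
            de_by_celltype(ds)

    def test_bh_is_monotone_within_cell_type(self, default_atlas):
        _, datasets, _ = default_atlas
        table = de_by_celltype(concat_cells(datasets))
        for _, grp in table.groupby("cell_type"):
            g = grp.sort_values("pval")
            assert (g["padj"].diff().dropna() >= -1e-12).all()
            assert (g["padj"] >= g["pval"] - 1e-12).all()

    def test_planted_lncrna_recovered_in_correct_type_only(self):
        """Planted |log2 fold| >= 2 effects at 200 cells/side are significant
        in their own type and nowhere else."""
        cfg = SyntheticConfig(
            n_datasets=1,
            n_donors_per_condition=2,
            cell_types=["TypeA", "TypeB", "TypeC", "TypeD"],
            cells_per_type_per_donor=100,
            n_genes=300,
            n_lncRNAs=30,
            marker_genes_per_type=5,
            de_lncRNAs=[
                ("LNC0001", "TypeA", 2.0),
                ("LNC0002", "TypeB", -2.0),
                ("LNC0003", "TypeC", 3.0),
            ],
            seed=21,
        )
        datasets, truth = simulate_atlas(cfg)
        table = de_by_celltype(datasets[0]).set_index(["cell_type", "gene"])
        for gene, ct in sorted(truth.true_de):
            assert table.loc[(ct, gene), "padj"] < 0.05
            sign = np.sign(truth.de_log_folds[(gene, ct)])
            assert np.sign(table.loc[(ct, gene), "log2fc"]) == sign
            others = table.xs(gene, level="gene").drop(ct)
            assert (others["padj"] >= 0.05).all()

    def test_type_one_error_control_on_null_simulation(self):
        """With no planted effects, ~5% of raw p-values fall below 0.05
        (1,000 gene tests, 100 cells/side, tie-light counts)."""
        cfg = SyntheticConfig(
            n_datasets=1,
            n_donors_per_condition=1,
            cell_types=["TypeA", "TypeB"],
            cells_per_type_per_donor=100,
            n_genes=1000,
            n_lncRNAs=100,
            marker_genes_per_type=5,
            de_lncRNAs=[],
            dropout_rate=0.0,
            base_mean=2.0,
            seed=5,
        )
        datasets, _ = simulate_atlas(cfg)
        table = de_by_celltype(datasets[0])
        frac = (
            table[table["cell_type"] == "TypeA"]["pval"] < 0.05
        ).mean()
        assert frac == pytest.approx(0.05, abs=0.02)


class TestFilterLncRNA:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["cell_type", "gene", "biotype", "log2fc", "padj"])

    def test_empty_when_no_lncrna(self):
        t = self.table([("T", "g1", "protein_coding", 1.0, 0.001)])
        assert filter_lncRNA(t).empty

    def test_split_up_down_and_biotype_filter(self):
        t = self.table(
            [
                ("T", "l1", "lncRNA", 1.0, 0.01),
                ("T", "l2", "lncRNA", -0.5, 0.02),
                ("T", "l3", "lncRNA", 2.0, 0.2),
                ("T", "g1", "protein_coding", 3.0, 0.001),
            ]
        )
        out = filter_lncRNA(t, alpha=0.05)
        assert set(out["gene"]) == {"l1", "l2"}
        assert dict(zip(out["gene"], out["direction"])) == {"l1": "up", "l2": "down"}

    def test_alpha_one_keeps_all_lncrna_rows(self):
        t = self.table(
            [("T", "l1", "lncRNA", 1.0, 0.9), ("T", "g1", "protein_coding", 1.0, 0.9)]
        )
        out = filter_lncRNA(t, alpha=1.0)
        assert list(out["gene"]) == ["l1"]


class TestDdct:
    def test_identity_and_hand_arithmetic(self):
        assert ddct(20, 15, 22, 17) == 1.0  # ddCT = 0
        # case (25,20), ctrl (26,20): ddCT = (25-20)-(26-20) = -1 -> 2.0
        assert ddct(25, 20, 26, 20) == 2.0

    @given(
        st.floats(10, 35), st.floats(10, 35), st.floats(10, 35), st.floats(10, 35)
    )
    def test_swapping_case_and_control_inverts(self, a, b, c, d):
        r = ddct(a, b, c, d)
        assert ddct(c, d, a, b) == pytest.approx(1.0 / r)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            ddct(np.nan, 20, 26, 20)
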