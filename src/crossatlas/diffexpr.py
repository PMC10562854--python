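"""Per-cell-type differential expression, lncRNA filtering and dot-plot statistics.

DE between conditions (psoriatic vs healthy) is computed independently within
each cell type with the two-sided Wilcoxon rank-sum test on log-normalized
expression — exact for tiny tie-free groups, normal approximation with tie
correction otherwise — with Benjamini–Hochberg adjustment across genes within
each cell type. Effect size is the log2 fold change of mean normalized
expression with pseudocount 1. The 2^-ΔΔCT helper mirrors the qPCR
quantification used for bench validation of candidates.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CellDataset, normalize

logger = logging.getLogger(__name__)

DE_COLUMNS = [
    "cell_type", "gene", "biotype", "log2fc", "stat", "pval", "padj",
    "mean_healthy", "mean_psoriatic", "frac_healthy", "frac_psoriatic",
]


def marker_stats(
    dataset: CellDataset,
    labels: pd.Series | None = None,
    genes: Sequence[str] | None = None,
    by_condition: bool = False,
) -> pd.DataFrame:
    """Dot-plot statistics: per-group mean normalized expression and detection fraction.

    Detection fraction is the fraction of cells with raw count > 0, the
    dot-size statistic of atlas marker plots.
    """
    if labels is None:
        labels = dataset.cell_meta["label"]
    labels = labels.reindex(dataset.cell_ids)
    if labels.isna().any():
        raise ValueError("every cell must be labeled")
    if genes is None:
        genes = list(dataset.gene_ids)
    unknown = pd.Index(genes).difference(dataset.gene_ids)
    if len(unknown):
        raise KeyError(f"unknown gene(s): {list(unknown)}")
    gpos = dataset.gene_ids.get_indexer(pd.Index(genes))
    norm = normalize(dataset)[:, gpos]
    detected = (dataset.counts[:, gpos] > 0).astype(np.float64)

    keys = pd.DataFrame({"cell_type": labels.to_numpy()})
    names = ["cell_type"]
    if by_condition:
        keys["condition"] = dataset.cell_meta["condition"].to_numpy()
        names.append("condition")
    records = []
    for group, idx in sorted(keys.groupby(names, observed=True).indices.items(), key=lambda kv: str(kv[0])):
        rows = np.sort(idx)
        mean = np.asarray(norm[rows].mean(axis=0)).ravel()
        frac = np.asarray(detected[rows].mean(axis=0)).ravel()
        base = dict(zip(names, group if isinstance(group, tuple) else (group,)))
        for g, m, f in zip(genes, mean, frac):
            records.append({**base, "gene": g, "mean_norm": float(m), "frac_detected": float(f)})
    return pd.DataFrame.from_records(records)


def de_by_celltype(
    dataset: CellDataset,
    labels: pd.Series | None = None,
    condition_col: str = "condition",
    min_cells: int = 20,
    pseudocount: float = 1.0,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Psoriatic-vs-healthy Wilcoxon rank-sum DE within each cell type.

    Cell types lacking ``min_cells`` cells in either condition are skipped and
    logged. Returns one row per (cell_type, gene) with log2FC, the rank-sum
    statistic, raw and BH-adjusted p (adjusted within cell type), per-condition
    means and detection fractions, and the gene biotype.
    """
    if condition_col not in dataset.cell_meta.columns:
        raise KeyError(f"cell_meta has no condition column {condition_col!r}")
    if labels is None:
        labels = dataset.cell_meta["label"]
    labels = labels.reindex(dataset.cell_ids)
    cond = dataset.cell_meta[condition_col]
    if genes is None:
        genes = list(dataset.gene_ids)
    gpos = dataset.gene_ids.get_indexer(pd.Index(genes))
    if (gpos < 0).any():
        raise KeyError(f"unknown gene(s): {list(pd.Index(genes)[gpos < 0])}")
    norm = normalize(dataset)[:, gpos].toarray()
    detected = (dataset.counts[:, gpos] > 0).toarray()
    biotype = dataset.gene_meta["biotype"].to_numpy()[gpos]

    frames = []
    for ct in sorted(pd.unique(labels.dropna())):
        in_ct = (labels == ct).to_numpy()
        h = in_ct & (cond == "healthy").to_numpy()
        p = in_ct & (cond == "psoriatic").to_numpy()
        if h.sum() < min_cells or p.sum() < min_cells:
            logger.info(
                "skipping cell type %s: %d healthy / %d psoriatic cells (< %d)",
                ct, h.sum(), p.sum(), min_cells,
            )
            continue
        Xh, Xp = norm[h], norm[p]
        res = stats.mannwhitneyu(Xp, Xh, axis=0, alternative="two-sided", method="auto")
        mean_h, mean_p = Xh.mean(axis=0), Xp.mean(axis=0)
        padj = multipletests(res.pvalue, method="fdr_bh")[1]
        frames.append(
            pd.DataFrame(
                {
                    "cell_type": ct,
                    "gene": genes,
                    "biotype": biotype,
                    "log2fc": np.log2((mean_p + pseudocount) / (mean_h + pseudocount)),
                    "stat": res.statistic,
                    "pval": res.pvalue,
                    "padj": padj,
                    "mean_healthy": mean_h,
                    "mean_psoriatic": mean_p,
                    "frac_healthy": detected[h].mean(axis=0),
                    "frac_psoriatic": detected[p].mean(axis=0),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=DE_COLUMNS)
    return pd.concat(frames, ignore_index=True)[DE_COLUMNS]


def filter_lncRNA(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Significant lncRNA rows of a DE table, annotated up/down by fold sign.

    Retains rows with adjusted p at or below ``alpha`` (inclusive, so the
    degenerate ``alpha=1.0`` keeps every lncRNA row).
    """
    if "biotype" not in table.columns:
        raise KeyError("DE table lacks a biotype column")
    out = table[(table["biotype"] == "lncRNA") & (table["padj"] <= alpha)].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out.sort_values(["cell_type", "padj", "gene"]).reset_index(drop=True)


def ddct(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ΔΔCT method.

    ΔΔCT = (CT_target,case − CT_ref,case) − (CT_target,ctrl − CT_ref,ctrl);
    the returned value is the case expression relative to control, normalized
    to the reference gene.
    """
    vals = [ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl]
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"CT values must be finite, got {vals}")
    ddct_val = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct_val))
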