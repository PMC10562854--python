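"""lncRNA co-expression and hypergeometric gene-set enrichment.

The co-expression ratio of (lncRNA, partner gene) in a cell cluster is the
fraction of lncRNA-detecting cells that also detect the partner — co-detection
conditional on lncRNA detection, a normalization-free statistic. Correlation
screens use Spearman's rho on log-normalized expression. Enrichment of a gene
list against a gene-set collection uses the upper-tail hypergeometric test
with the cluster's tested genes as the universe, BH-adjusted across terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CellDataset, GeneSetCollection, normalize


@dataclass
class CoexprRecord:
    """Co-detection ratio and rank correlation of one (lncRNA, gene, cluster)."""

    lncrna: str
    gene: str
    cluster: str
    ratio: float  # NaN when the lncRNA is detected in no cell (flagged below)
    spearman_rho: float
    n_cells: int
    n_lncrna_detected: int
    defined: bool = True


def _cluster_cells(dataset: CellDataset, labels: pd.Series | None, cluster: str) -> np.ndarray:
    if labels is None:
        labels = dataset.cell_meta["label"]
    labels = labels.reindex(dataset.cell_ids)
    known = set(labels.dropna().unique())
    if cluster not in known:
        raise KeyError(f"unknown cluster {cluster!r}; known: {sorted(known)[:8]}...")
    return np.flatnonzero((labels == cluster).to_numpy())


def coexpression_ratio(
    dataset: CellDataset,
    labels: pd.Series | None,
    lncrna: str,
    gene: str,
    cluster: str,
    min_cells: int = 20,
) -> CoexprRecord:
    """Co-detection of ``gene`` among cells of ``cluster`` detecting ``lncrna``.

    ratio = #(cells with both counts > 0) / #(cells with lncRNA count > 0),
    with Spearman correlation of the two genes' normalized expression over all
    cluster cells reported alongside.
    """
    rows = _cluster_cells(dataset, labels, cluster)
    if len(rows) < min_cells:
        raise ValueError(f"cluster {cluster!r} has {len(rows)} cells < min_cells={min_cells}")
    for g in (lncrna, gene):
        if g not in dataset.gene_ids:
            raise KeyError(f"unknown gene {g!r}")
    gi = dataset.gene_ids.get_indexer([lncrna, gene])
    counts = dataset.counts[rows][:, gi].toarray()
    lnc_on = counts[:, 0] > 0
    both_on = lnc_on & (counts[:, 1] > 0)
    n_lnc = int(lnc_on.sum())
    if n_lnc == 0:
        ratio, defined = float("nan"), False
    else:
        ratio, defined = float(both_on.sum() / n_lnc), True
    norm = normalize(dataset.subset_cells(np.isin(np.arange(dataset.n_cells), rows)))
    x = np.asarray(norm[:, gi[0]].todense()).ravel()
    y = np.asarray(norm[:, gi[1]].todense()).ravel()
    if lncrna == gene:
        rho = 1.0
    elif np.ptp(x) == 0 or np.ptp(y) == 0:
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(x, y).statistic)
    return CoexprRecord(
        lncrna=lncrna, gene=gene, cluster=cluster, ratio=ratio,
        spearman_rho=rho, n_cells=len(rows), n_lncrna_detected=n_lnc, defined=defined,
    )


def correlated_genes(
    dataset: CellDataset,
    lncrna: str,
    cluster: str,
    labels: pd.Series | None = None,
    top_n: int = 100,
) -> pd.DataFrame:
    """Genes ranked by descending Spearman correlation with the lncRNA in a cluster.

    Constant genes are excluded (their correlation is undefined); exact rho
    ties break lexicographically by gene id. Errors if the lncRNA itself is
    constant in the cluster.
    """
    rows = _cluster_cells(dataset, labels, cluster)
    if lncrna not in dataset.gene_ids:
        raise KeyError(f"unknown gene {lncrna!r}")
    norm = normalize(dataset.subset_cells(np.isin(np.arange(dataset.n_cells), rows))).toarray()
    li = dataset.gene_ids.get_loc(lncrna)
    x = norm[:, li]
    if np.ptp(x) == 0:
        raise ValueError(f"{lncrna!r} is constant in cluster {cluster!r}; correlation undefined")
    keep = np.flatnonzero(np.ptp(norm, axis=0) > 0)
    keep = keep[keep != li]
    # rank-transform once, then correlate against all genes in one matrix op
    rx = stats.rankdata(x)
    rm = np.apply_along_axis(stats.rankdata, 0, norm[:, keep])
    rx_c = rx - rx.mean()
    rm_c = rm - rm.mean(axis=0)
    rho = (rm_c.T @ rx_c) / (
        np.sqrt((rm_c**2).sum(axis=0)) * np.sqrt((rx_c**2).sum())
    )
    table = pd.DataFrame({"gene": np.asarray(dataset.gene_ids)[keep], "spearman_rho": rho})
    table = table.sort_values(
        ["spearman_rho", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table.head(top_n)


def hypergeom_enrich(
    gene_list: Sequence[str],
    gene_sets: GeneSetCollection,
    universe: Sequence[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a gene list against each term.

    For each term: universe size N, set size K (after intersecting the term
    with the universe), list size n, overlap k, p = P(X >= k), BH across
    terms; rows sorted by adjusted p then term id.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    genes = set(gene_list)
    if not genes:
        raise ValueError("empty gene list")
    stray = genes - universe_set
    if stray:
        raise ValueError(f"gene list members outside the universe: {sorted(stray)[:5]}")
    N, n = len(universe_set), len(genes)
    records = []
    for term, members in sorted(gene_sets.items()):
        in_universe = members & universe_set
        K = len(in_universe)
        overlap = sorted(genes & in_universe)
        k = len(overlap)
        pval = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        records.append(
            {
                "term_id": term,
                "term_name": gene_sets.names.get(term, term),
                "overlap_k": k,
                "list_n": n,
                "set_K": K,
                "universe_N": N,
                "pval": pval,
                "genes": ",".join(overlap),
            }
        )
    table = pd.DataFrame.from_records(records)
    table["padj"] = multipletests(table["pval"], method="fdr_bh")[1]
    table = table.sort_values(["padj", "term_id"], kind="mergesort").reset_index(drop=True)
    return table[
        ["term_id", "term_name", "overlap_k", "set_K", "list_n", "universe_N", "pval", "padj", "genes"]
    ]
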