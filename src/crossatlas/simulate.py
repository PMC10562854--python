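"""Synthetic multi-dataset skin atlas generator with full ground truth.

Emulates, at desk scale, the statistical structure of a multi-study psoriasis
skin atlas: several datasets with multiplicative batch effects, several donors
per condition (healthy / psoriatic), 21 skin cell subtypes defined by marker
genes, a protein-coding + lncRNA gene complement, and a handful of lncRNAs
whose expression shifts under the psoriatic condition in designated cell types
only. Counts follow a negative-binomial model with lognormal cell size factors
and independent Bernoulli dropout.

Every random draw flows through one ``numpy.random.default_rng(seed)``, so a
(config, seed) pair reproduces bit-identical atlases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CellDataset, GeneSetCollection, write_counts


def default_atlas_labels() -> list[str]:
    """The 21 skin cell subtype labels of the integrated atlas.

    Nine epidermal zonation types (stem/cycling through cornified, plus the
    inflammatory basal branch and a hair-follicle-like group), six mesenchymal
    types (four fibroblast, two perivascular mural), two endothelial, two
    immune, a Schwann/melanocyte group and a mixed erythrocyte group.
    """
    return [
        "EpD_KRT0_StemCyclingKeratinocyte",
        "EpD_KRT1_Basal",
        "EpD_KRT2_Basalinflammatory",
        "EpD_KRT3_earlySpinous",
        "EpD_KRT4_diffSpinous",
        "EpD_KRT5_Granular",
        "EpD_KRT6_BasalGranular",
        "EpD_KRT7_Corneum",
        "EpD_HF_HairFollicle",
        "Mes_FibroDS",
        "Mes_FibroInflammatory",
        "Mes_FibroPapillary",
        "Mes_FibroReticular",
        "Mes_PeriV",
        "Mes_PeriVInflammatory",
        "Imm_Lymphocyte",
        "Imm_MyeloidCell",
        "Endo_Vascular",
        "Endo_Endo-Lymph",
        "Schwann_Melano",
        "Mixed_Erythrocytes",
    ]


def _default_de_lncrnas() -> list[tuple[str, str, float]]:
    # lncRNAs shifted in the psoriatic condition, each in one designated cell
    # type: epidermal and perivascular up-regulation plus one immune
    # down-regulation, mirroring localized-inflammation biology.
    return [
        ("LNC0001", "EpD_KRT1_Basal", 2.0),
        ("LNC0002", "EpD_KRT2_Basalinflammatory", 2.5),
        ("LNC0003", "EpD_KRT3_earlySpinous", 2.0),
        ("LNC0004", "Mes_PeriVInflammatory", 2.0),
        ("LNC0005", "Mes_PeriV", 2.0),
        ("LNC0006", "Imm_Lymphocyte", -2.0),
    ]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic atlas.

    Fold parameters are log2 folds. ``batch_scale`` is the standard deviation
    of the per-dataset per-gene lognormal batch factor (0 disables batch
    effects). ``dispersion`` is the negative-binomial overdispersion
    (variance = mu + dispersion * mu^2); 0 falls back to Poisson.
    """

    n_datasets: int = 3
    n_donors_per_condition: int = 2
    cell_types: list[str] = field(default_factory=default_atlas_labels)
    cells_per_type_per_donor: int = 30
    n_genes: int = 2000
    n_lncRNAs: int = 200
    marker_genes_per_type: int = 10
    marker_log_fold: float = 5.0
    de_lncRNAs: list[tuple[str, str, float]] = field(default_factory=_default_de_lncrnas)
    batch_scale: float = 0.3
    dropout_rate: float = 0.2
    base_mean: float = 0.3
    dispersion: float = 0.3
    size_factor_sigma: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        positive = {
            "n_datasets": self.n_datasets,
            "n_donors_per_condition": self.n_donors_per_condition,
            "cells_per_type_per_donor": self.cells_per_type_per_donor,
            "n_genes": self.n_genes,
            "marker_genes_per_type": self.marker_genes_per_type,
            "base_mean": self.base_mean,
            "marker_log_fold": self.marker_log_fold,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not self.cell_types:
            raise ValueError("cell_types must be non-empty")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ValueError("cell_types contains duplicates")
        if self.n_lncRNAs < 0 or self.n_lncRNAs > self.n_genes:
            raise ValueError(f"n_lncRNAs={self.n_lncRNAs} must lie in [0, n_genes={self.n_genes}]")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.batch_scale < 0:
            raise ValueError("batch_scale must be non-negative")
        n_pc = self.n_genes - self.n_lncRNAs
        if self.marker_genes_per_type * len(self.cell_types) > n_pc:
            raise ValueError(
                "not enough protein-coding genes for "
                f"{len(self.cell_types)} x {self.marker_genes_per_type} markers"
            )
        lnc_ids = set(self.lncrna_ids())
        for gene, cell_type, _fold in self.de_lncRNAs:
            if gene not in lnc_ids:
                raise ValueError(f"de_lncRNA gene {gene!r} is not a simulated lncRNA")
            if cell_type not in self.cell_types:
                raise ValueError(f"de_lncRNA cell type {cell_type!r} not in cell_types")

    # gene naming: protein-coding block first, lncRNA block after
    def gene_ids(self) -> list[str]:
        n_pc = self.n_genes - self.n_lncRNAs
        return [f"PC{i + 1:04d}" for i in range(n_pc)] + self.lncrna_ids()

    def lncrna_ids(self) -> list[str]:
        return [f"LNC{i + 1:04d}" for i in range(self.n_lncRNAs)]

    def marker_map(self) -> dict[str, list[str]]:
        """Disjoint marker blocks, one per cell type, drawn from protein-coding genes."""
        m = self.marker_genes_per_type
        return {
            ct: [f"PC{i + 1:04d}" for i in range(t * m, (t + 1) * m)]
            for t, ct in enumerate(self.cell_types)
        }


@dataclass
class GroundTruth:
    """What the generator actually planted, keyed for downstream scoring."""

    true_label: pd.Series  # cell_id -> cell type
    batch: pd.Series  # cell_id -> dataset id
    true_marker: set[tuple[str, str]]  # (gene, cell_type)
    true_de: set[tuple[str, str]]  # (gene, cell_type), psoriatic-vs-healthy shift
    de_log_folds: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "true_label": self.true_label.to_dict(),
            "batch": self.batch.to_dict(),
            "true_marker": sorted(map(list, self.true_marker)),
            "true_de": sorted(map(list, self.true_de)),
            "de_log_folds": {f"{g}|{ct}": lf for (g, ct), lf in sorted(self.de_log_folds.items())},
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def simulate_atlas(config: SyntheticConfig) -> tuple[list[CellDataset], GroundTruth]:
    """Draw the synthetic atlas: one :class:`CellDataset` per dataset + ground truth.

    Mean model per cell c (type t, condition v, dataset d) and gene g::

        mu = base_mean * 2^(marker_log_fold * [g marker of t])
                       * 2^(fold_{g,t} * [v == psoriatic])
                       * B_{d,g} * s_c

    with B lognormal(0, batch_scale), s lognormal(0, size_factor_sigma),
    counts ~ NB(mu, dispersion), then independent Bernoulli dropout.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    gene_index = {g: i for i, g in enumerate(genes)}
    n_pc = config.n_genes - config.n_lncRNAs
    biotype = np.array(["protein_coding"] * n_pc + ["lncRNA"] * config.n_lncRNAs)
    gene_meta = pd.DataFrame({"biotype": biotype}, index=pd.Index(genes, name="gene_id"))

    markers = config.marker_map()
    type_factor = np.ones((len(config.cell_types), config.n_genes))
    for t, ct in enumerate(config.cell_types):
        idx = [gene_index[g] for g in markers[ct]]
        type_factor[t, idx] = 2.0 ** config.marker_log_fold
    cond_factor = np.ones((len(config.cell_types), config.n_genes))  # psoriatic multiplier
    for gene, ct, log_fold in config.de_lncRNAs:
        cond_factor[config.cell_types.index(ct), gene_index[gene]] = 2.0 ** log_fold

    datasets: list[CellDataset] = []
    labels_all: list[pd.Series] = []
    batch_all: list[pd.Series] = []
    for d in range(config.n_datasets):
        ds_id = f"DS{d + 1}"
        batch = (
            np.exp(rng.normal(0.0, config.batch_scale, size=config.n_genes))
            if config.batch_scale > 0
            else np.ones(config.n_genes)
        )
        rows, metas = [], []
        for cond in ("healthy", "psoriatic"):
            for donor_i in range(config.n_donors_per_condition):
                donor = f"{ds_id}_{cond[0].upper()}{donor_i + 1}"
                for t, ct in enumerate(config.cell_types):
                    n = config.cells_per_type_per_donor
                    mu = config.base_mean * type_factor[t] * batch
                    if cond == "psoriatic":
                        mu = mu * cond_factor[t]
                    size = np.exp(rng.normal(0.0, config.size_factor_sigma, size=n))
                    mu_cells = size[:, None] * mu[None, :]
                    if config.dispersion > 0:
                        shape = 1.0 / config.dispersion
                        lam = rng.gamma(shape, mu_cells / shape)
                        counts = rng.poisson(lam)
                    else:
                        counts = rng.poisson(mu_cells)
                    if config.dropout_rate > 0:
                        counts = counts * (rng.random(counts.shape) >= config.dropout_rate)
                    rows.append(sp.csr_matrix(counts))
                    metas.append(
                        pd.DataFrame(
                            {
                                "dataset": ds_id,
                                "donor": donor,
                                "condition": cond,
                                "label": ct,
                            },
                            index=[f"{donor}_{ct}_{i + 1:03d}" for i in range(n)],
                        )
                    )
        cell_meta = pd.concat(metas)
        cell_meta.index.name = "cell_id"
        ds = CellDataset(sp.vstack(rows, format="csr").astype(np.int64), cell_meta, gene_meta.copy())
        datasets.append(ds)
        labels_all.append(cell_meta["label"])
        batch_all.append(pd.Series(ds_id, index=cell_meta.index))

    true_label = pd.concat(labels_all)
    truth = GroundTruth(
        true_label=true_label,
        batch=pd.concat(batch_all),
        true_marker={(g, ct) for ct, gs in markers.items() for g in gs},
        true_de={(g, ct) for g, ct, _lf in config.de_lncRNAs},
        de_log_folds={(g, ct): lf for g, ct, lf in config.de_lncRNAs},
    )
    return datasets, truth


def synthetic_gene_sets(config: SyntheticConfig, n_random: int = 5) -> GeneSetCollection:
    """A GO-like gene-set collection aligned with the simulated marker modules.

    One term per cell type containing its marker genes, plus ``n_random``
    size-matched random background terms, so enrichment of a marker-derived
    gene list is verifiable without external annotation downloads.
    """
    rng = np.random.default_rng(config.seed + 101)
    genes = np.array(config.gene_ids())
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for ct, members in config.marker_map().items():
        term = f"MODULE_{ct}"
        sets[term] = set(members)
        names[term] = f"marker program of {ct}"
    for j in range(n_random):
        term = f"RANDOM_{j + 1:02d}"
        sets[term] = set(rng.choice(genes, size=config.marker_genes_per_type, replace=False))
        names[term] = "size-matched random background set"
    return GeneSetCollection(sets=sets, names=names)


def write_atlas(datasets: Sequence[CellDataset], truth: GroundTruth, out_dir) -> Path:
    """Write each dataset as an MTX triple plus ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ds in datasets:
        ds_id = ds.cell_meta["dataset"].iloc[0]
        write_counts(ds, out / ds_id)
    (out / "ground_truth.json").write_text(truth.to_json())
    return out
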