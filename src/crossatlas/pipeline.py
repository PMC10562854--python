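"""End-to-end driver: simulate -> train -> integrate -> transfer -> recover ->
DE -> lncRNA filter -> co-expression -> enrichment -> atlas export.

Every stage writes a plain-text artifact into the run directory and records
entering/surviving counts in ``manifest.json``; the whole run is a pure
function of (config, seeds), so reruns reproduce byte-identical artifacts and
manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import yaml

from . import __version__
from .classifier import (
    ProbScoreMatrix,
    TrainConfig,
    learning_curve,
    train_classifier,
)
from .coexpr import coexpression_ratio, correlated_genes, hypergeom_enrich
from .diffexpr import de_by_celltype, filter_lncRNA
from .integration import assignment_crosstab, build_latent, radar_scores, transfer_labels
from .io import concat_cells, downsample, read_gmt, write_counts, write_gmt
from .recovery import attribute_features, merge_recovered, recover_expression
from .simulate import SyntheticConfig, simulate_atlas, synthetic_gene_sets, write_atlas

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-atlas run; all randomness is seeded."""

    out_dir: str = "crossatlas_run"
    seed: int = 0
    sim: SyntheticConfig = field(default_factory=SyntheticConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    transfer_k: int = 15
    de_alpha: float = 0.05
    de_min_cells: int = 20
    downsample_cap: int = 300
    gmt_path: str | None = None  # None -> synthetic module-aligned gene sets
    n_coexpr_lncrnas: int = 5
    n_correlated_genes: int = 50

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SyntheticConfig(**raw.pop("sim", {}))
        train = TrainConfig(**raw.pop("train", {}))
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown pipeline config key(s): {sorted(unknown)}")
        cfg = cls(sim=sim, train=train, **raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        self.sim.validate()
        self.train.validate()
        if self.transfer_k < 1:
            raise ValueError("transfer_k must be >= 1")
        if not (0 < self.de_alpha <= 1):
            raise ValueError("de_alpha must lie in (0, 1]")
        if self.gmt_path is not None and not Path(self.gmt_path).exists():
            raise FileNotFoundError(self.gmt_path)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["de_lncRNAs"] = [list(t) for t in self.sim.de_lncRNAs]
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage, returning the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "artifacts": {},
    }

    def record(stage: str, artifact: Path | None = None, **counts) -> None:
        manifest["stages"].setdefault(stage, {}).update(counts)
        if artifact is not None:
            rel = str(artifact.relative_to(out))
            if artifact.is_dir():
                manifest["artifacts"][rel] = {
                    str(p.relative_to(out)): _sha256(p) for p in sorted(artifact.rglob("*")) if p.is_file()
                }
            else:
                manifest["artifacts"][rel] = _sha256(artifact)
        logger.info("stage %s done: %s", stage, counts)

    # 1. simulate ----------------------------------------------------------
    datasets, truth = simulate_atlas(config.sim)
    data_dir = write_atlas(datasets, truth, out / "datasets")
    record(
        "simulate", data_dir,
        n_datasets=len(datasets),
        n_cells=int(sum(ds.n_cells for ds in datasets)),
        n_genes=int(datasets[0].n_genes),
    )

    # 2. train one reference model per dataset -----------------------------
    models = []
    model_dir = out / "models"
    model_dir.mkdir(exist_ok=True)
    curves = []
    for i, ds in enumerate(datasets):
        tc = dataclasses.replace(config.train, seed=config.train.seed + i)
        model = train_classifier(ds, config=tc)
        model.save(model_dir / f"{model.model_id}.npz")
        models.append(model)
        lc = learning_curve(model)
        tab = lc.table.assign(model=model.model_id)
        curves.append(tab)
    curve_path = out / "learning_curves.tsv"
    pd.concat(curves, ignore_index=True).to_csv(curve_path, sep="\t", index=False)
    record(
        "train", curve_path,
        final_heldout_accuracy={m.model_id: m.learning_curve_[-1] for m in models},
    )

    # 3. latent space ------------------------------------------------------
    latent = build_latent(models, datasets)
    latent_path = out / "latent.tsv"
    frame = latent.to_frame()
    frame.columns = [f"{m}:{lab}" for m, lab in latent.columns]
    frame.rename_axis("cell_id").to_csv(latent_path, sep="\t", float_format="%.6g")
    record("latent", latent_path, n_cells=int(frame.shape[0]), n_columns=int(frame.shape[1]))

    # 4. label transfer + comparison summaries -----------------------------
    ref_ds = datasets[0]
    ref_labels = ref_ds.cell_meta["label"]
    query_ids = [cid for ds in datasets[1:] for cid in ds.cell_ids]
    transferred = transfer_labels(latent, ref_labels, query_ids, k=config.transfer_k)
    transfer_path = out / "transfer.tsv"
    transferred.assignments.to_csv(transfer_path, sep="\t", float_format="%.6g")
    truth_query = truth.true_label.loc[query_ids]
    transfer_acc = float((transferred.labels() == truth_query).mean())
    crosstab = assignment_crosstab(truth_query, transferred.labels())
    crosstab.to_csv(out / "crosstab.tsv", sep="\t", index=False)
    radar = radar_scores(
        # scores of all cells under the reference model, summarized per true type
        _ref_scores(models[0], datasets),
        truth.true_label,
    )
    radar.to_csv(out / "radar.tsv", sep="\t", float_format="%.6g")
    record(
        "transfer", transfer_path,
        n_query=len(query_ids), transfer_accuracy=transfer_acc,
        n_labels_assigned=int(transferred.labels().nunique()),
    )
    record("crosstab", out / "crosstab.tsv", n_pairs=int(len(crosstab)))
    record("radar", out / "radar.tsv", n_query_types=int(radar.shape[0]))

    # 5. attribution + recovery + merge ------------------------------------
    combined = concat_cells(datasets)
    export_genes = sorted(
        {g for g, _ in truth.true_marker} | {g for g, _ in truth.true_de}
    )
    E_list, masks = [], []
    for model, ds in zip(models, datasets):
        W = attribute_features(model)
        P = _ref_scores(model, datasets)
        E_list.append(recover_expression(W, P).loc[export_genes])
        masks.append(export_genes)
    merged = merge_recovered(E_list, masks)
    rec_path = out / "recovered.mtx"
    scipy.io.mmwrite(str(rec_path), np.asarray(merged.values.fillna(0.0)))
    pd.DataFrame(
        {"gene_id": merged.values.index, "support": merged.support.min(axis=1).to_numpy()}
    ).to_csv(out / "recovered_mask.tsv", sep="\t", index=False)
    pd.Series(merged.values.columns, name="cell_id").to_csv(
        out / "recovered_cells.tsv", sep="\t", index=False
    )
    record(
        "recover", rec_path,
        n_genes_exported=len(export_genes), n_models=len(models),
        n_cells=int(merged.values.shape[1]),
    )
    record("recover_mask", out / "recovered_mask.tsv")

    # 6-7. differential expression + lncRNA filter -------------------------
    de_table = de_by_celltype(combined, min_cells=config.de_min_cells)
    de_path = out / "de_table.tsv"
    de_table.to_csv(de_path, sep="\t", index=False, float_format="%.6g")
    lnc = filter_lncRNA(de_table, alpha=config.de_alpha)
    lnc_path = out / "lncrna_de.tsv"
    lnc.to_csv(lnc_path, sep="\t", index=False, float_format="%.6g")
    record(
        "de", de_path,
        n_tests=int(len(de_table)),
        n_cell_types=int(de_table["cell_type"].nunique()) if len(de_table) else 0,
    )
    record("lncrna_filter", lnc_path, n_significant=int(len(lnc)))

    # 8. co-expression around the top DE lncRNAs ---------------------------
    gene_sets = (
        read_gmt(config.gmt_path) if config.gmt_path else synthetic_gene_sets(config.sim)
    )
    if config.gmt_path is None:
        write_gmt(gene_sets, out / "gene_sets.gmt")
    top = lnc.sort_values(["padj", "cell_type", "gene"]).head(config.n_coexpr_lncrnas)
    coexpr_rows, enrich_frames = [], []
    for _, row in top.iterrows():
        corr_all = correlated_genes(
            combined, row["gene"], row["cell_type"], top_n=combined.n_genes
        )
        partners = corr_all.head(config.n_correlated_genes)
        for partner in partners["gene"].head(10):
            rec = coexpression_ratio(
                combined, None, row["gene"], partner, row["cell_type"],
                min_cells=config.de_min_cells,
            )
            coexpr_rows.append(dataclasses.asdict(rec))
        enr = hypergeom_enrich(
            list(partners["gene"]), gene_sets, universe=list(corr_all["gene"])
        )
        enr.insert(0, "lncrna", row["gene"])
        enr.insert(1, "cluster", row["cell_type"])
        enrich_frames.append(enr)
    coexpr_path = out / "coexpr.tsv"
    pd.DataFrame(coexpr_rows).to_csv(coexpr_path, sep="\t", index=False, float_format="%.6g")
    record("coexpr", coexpr_path, n_pairs=len(coexpr_rows))

    # 9. enrichment --------------------------------------------------------
    enrich_path = out / "enrichment.tsv"
    enrich_table = (
        pd.concat(enrich_frames, ignore_index=True)
        if enrich_frames
        else pd.DataFrame()
    )
    enrich_table.to_csv(enrich_path, sep="\t", index=False, float_format="%.6g")
    record("enrich", enrich_path, n_terms=int(len(enrich_table)))

    # 10. atlas export: final labels + downsampling cap --------------------
    final_labels = pd.concat([ref_labels, transferred.labels()])
    export = combined.subset_cells(list(final_labels.index))
    export.cell_meta["label"] = final_labels.reindex(export.cell_ids)
    capped = downsample(
        export, cap=config.downsample_cap, keys=("label", "condition", "donor"),
        seed=config.seed,
    )
    export_dir = write_counts(capped, out / "atlas_export")
    record(
        "export", export_dir,
        n_cells_in=int(export.n_cells), n_cells_out=int(capped.n_cells),
        cap=config.downsample_cap,
    )

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def _ref_scores(model, datasets) -> ProbScoreMatrix:
    """Score every cell of every dataset under one model."""
    block = build_latent([model], datasets)
    return ProbScoreMatrix(
        scores=block.matrix, cell_ids=block.cell_ids,
        labels=[lab for _, lab in block.columns], model_id=model.model_id,
    )
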