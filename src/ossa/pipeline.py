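"""Pipeline orchestration: simulate → qc → normalize → divergence / DE / LR
with a resolved-config run manifest and structured logging.

A single global seed is expanded into independent per-stage streams (the
stage name is hashed into the seed-sequence spawn key), so toggling one
stage never perturbs another stage's randomness; two runs with the same
config produce byte-identical result tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import file_sha256, logger, stage_seed
from .diffexpr import (
    ANTI_INFLAMMATORY_GENES,
    PRO_INFLAMMATORY_GENES,
    DEThresholds,
    GapSplitDE,
    gene_set_score,
)
from .divergence import PCDivergence, region_dendrogram
from .io import CellMatrix, ResultTable, read_cohort, write_cohort, write_result
from .lr import LRDatabase, LRPermutationModel
from .qc import (
    QCThresholds,
    apply_qc,
    cluster_for_size_factors,
    compute_pca,
    compute_size_factors,
    log_normalize,
    select_hvgs,
)
from .simulate import (
    PlantedEffect,
    PlantedLRPair,
    SimulationConfig,
    design_from_paper,
    simulate_cohort,
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class RunConfig:
    """Resolved pipeline configuration with the study defaults."""

    out_dir: str = "ossa_run"
    seed: int = 0
    # stage toggles
    run_simulate: bool = True
    run_qc: bool = True
    run_divergence: bool = True
    run_de: bool = True
    run_lr: bool = True
    # inputs when not simulating
    input_dir: str | None = None
    # simulation
    sim: SimulationConfig | None = None
    planted_effects: list = dataclasses.field(default_factory=list)
    planted_lr: list = dataclasses.field(default_factory=list)
    # qc / normalization
    qc_thresholds: QCThresholds = dataclasses.field(default_factory=QCThresholds)
    hvg_per_sample: int = 4000
    n_components: int = 50
    # divergence
    n_perm: int = 1000
    min_cells_divergence: int = 20
    # DE
    de_thresholds: DEThresholds = dataclasses.field(default_factory=DEThresholds)
    # LR
    lr_db_path: str | None = None
    lr_target_n: int = 400
    lr_min_cells: int = 10
    lr_delta_min: float = 0.95
    # which regions carry the bone-level statistics
    analysis_tissue_class: str = "bone"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("sim", None)
        qc_t = raw.pop("qc_thresholds", None)
        de_t = raw.pop("de_thresholds", None)
        effects = raw.pop("planted_effects", [])
        lr_pairs = raw.pop("planted_lr", [])
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = SimulationConfig(**sim) if isinstance(sim, dict) else sim
        if qc_t is not None:
            cfg.qc_thresholds = QCThresholds(**qc_t) if isinstance(qc_t, dict) else qc_t
        if de_t is not None:
            cfg.de_thresholds = DEThresholds(**de_t) if isinstance(de_t, dict) else de_t
        cfg.planted_effects = [
            PlantedEffect(**e) if isinstance(e, dict) else e for e in effects
        ]
        cfg.planted_lr = [
            PlantedLRPair(**e) if isinstance(e, dict) else e for e in lr_pairs
        ]
        return cfg


def _setup_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s\t%(name)s\t%(levelname)s\t%(message)s")
    )
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and return the run manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out_dir)
    outputs: dict[str, str] = {}  # file -> stage
    try:
        cohort = _stage_input(config, out_dir, outputs)
        layer = hvgs = None
        if config.run_qc:
            cohort, layer, hvgs = _stage_qc(config, cohort, out_dir, outputs)
        if config.run_divergence or config.run_de or config.run_lr:
            if layer is None:
                raise StageError(
                    "divergence", ValueError("qc stage disabled but no layer available")
                )
        analysis_mask = (
            cohort.cells["tissue_class"].astype(str) == config.analysis_tissue_class
        ).to_numpy()
        if config.run_divergence:
            _stage_divergence(config, cohort, layer, hvgs, analysis_mask, out_dir, outputs)
        if config.run_de:
            _stage_de(config, cohort, layer, analysis_mask, out_dir, outputs)
        if config.run_lr:
            _stage_lr(config, cohort, layer, analysis_mask, out_dir, outputs)
        manifest = {
            "version": __version__,
            "config": _jsonable(config.to_dict()),
            "files": [
                {"file": name, "stage": stage, "sha256": file_sha256(out_dir / name)}
                for name, stage in sorted(outputs.items())
            ],
        }
        with open(out_dir / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _stage_input(config: RunConfig, out_dir: Path, outputs: dict) -> CellMatrix:
    stage = "simulate" if config.run_simulate else "load"
    try:
        if config.run_simulate:
            sim = config.sim or design_from_paper()
            sim = dataclasses.replace(sim, seed=stage_seed(config.seed, "simulate"))
            logger.info("simulate: %d regions x %d conditions x %d cells/sample",
                        sim.n_regions, sim.n_conditions, sim.cells_per_sample)
            cohort, _truth = simulate_cohort(
                sim, config.planted_effects, config.planted_lr
            )
            cdir = out_dir / "cohort"
            write_cohort(cohort, cdir)
            for f in ("matrix.mtx", "cells.tsv", "genes.tsv", "manifest.tsv"):
                outputs[f"cohort/{f}"] = "simulate"
            return cohort
        if not config.input_dir:
            raise ValueError("input_dir required when simulation is disabled")
        d = Path(config.input_dir)
        return read_cohort(d / "matrix.mtx", d / "cells.tsv", d / "genes.tsv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc


def _stage_qc(config: RunConfig, cohort: CellMatrix, out_dir: Path, outputs: dict):
    try:
        filtered, report = apply_qc(cohort, config.qc_thresholds)
        logger.info("qc: %d -> %d cells, %d -> %d genes",
                    report.cells_in, report.cells_out, report.genes_in, report.genes_out)
        write_result(ResultTable(report.to_frame()), out_dir / "qc_report.tsv")
        outputs["qc_report.tsv"] = "qc"
        clusters = cluster_for_size_factors(filtered, seed=stage_seed(config.seed, "qc"))
        sf = compute_size_factors(filtered, clusters)
        layer = log_normalize(filtered, sf)
        hvgs = select_hvgs(
            layer, filtered.cells["sample_id"], n_per_sample=config.hvg_per_sample
        )
        write_result(
            ResultTable(hvgs.combined, key_columns=("gene_id",)),
            out_dir / "hvg_combined.tsv",
        )
        outputs["hvg_combined.tsv"] = "qc"
        return filtered, layer, hvgs
    except Exception as exc:
        raise StageError("qc", exc) from exc


def _stage_divergence(config, cohort, layer, hvgs, analysis_mask, out_dir, outputs):
    try:
        idx = np.flatnonzero(analysis_mask)
        model = PCDivergence(
            _sub_layer(layer, idx),
            cohort.cells["region"].to_numpy()[idx],
            cohort.cells["cell_type"].to_numpy()[idx],
            genes=hvgs.genes if hvgs is not None else None,
            n_components=config.n_components,
            min_cells=config.min_cells_divergence,
        )
        res = model.fit(n_perm=config.n_perm, seed=stage_seed(config.seed, "divergence"))
        write_result(res.to_result_table(), out_dir / "divergence.tsv")
        outputs["divergence.tsv"] = "divergence"
        # dendrogram over all regions on the full-cohort PCA
        pca = compute_pca(
            layer, genes=hvgs.genes if hvgs is not None else None,
            n_components=config.n_components,
        )
        dend = region_dendrogram(pca, cohort.cells["region"])
        (out_dir / "region_dendrogram.nwk").write_text(dend.newick + "\n")
        dend.correlation.rename_axis("region").reset_index().pipe(
            lambda df: write_result(ResultTable(df, key_columns=("region",)),
                                    out_dir / "region_correlation.tsv")
        )
        outputs["region_dendrogram.nwk"] = "divergence"
        outputs["region_correlation.tsv"] = "divergence"
    except Exception as exc:
        raise StageError("divergence", exc) from exc


def _sub_layer(layer, idx):
    from .io import NormalizedLayer

    return NormalizedLayer(
        values=layer.values[idx],
        size_factors=layer.size_factors[idx],
        gene_ids=layer.gene_ids,
    )


def _stage_de(config, cohort, layer, analysis_mask, out_dir, outputs):
    try:
        idx = np.flatnonzero(analysis_mask)
        model = GapSplitDE(
            _sub_layer(layer, idx),
            cohort.cells["region"].to_numpy()[idx],
            cohort.cells["cell_type"].to_numpy()[idx],
            thresholds=config.de_thresholds,
        )
        res = model.fit()
        write_result(res.result_table, out_dir / "de_combinatorial.tsv")
        outputs["de_combinatorial.tsv"] = "de"
        counts = res.region_counts()
        write_result(ResultTable(counts, key_columns=("region",)),
                     out_dir / "de_region_counts.tsv")
        outputs["de_region_counts.tsv"] = "de"
        # inflammation gene-set scores per (region, condition)
        groups = (
            cohort.cells["region"].astype(str) + ":" + cohort.cells["condition"].astype(str)
        ).to_numpy()
        frames = []
        for name, genes in (
            ("pro_inflammatory", PRO_INFLAMMATORY_GENES),
            ("anti_inflammatory", ANTI_INFLAMMATORY_GENES),
        ):
            try:
                score = gene_set_score(layer, name, genes, groups)
            except ValueError:
                logger.warning("gene set %s entirely absent; skipped", name)
                continue
            stats = score.group_stats.copy()
            stats.insert(0, "set_name", name)
            frames.append(stats)
        if frames:
            write_result(
                ResultTable(pd.concat(frames, ignore_index=True),
                            key_columns=("set_name", "group")),
                out_dir / "geneset_scores.tsv",
            )
            outputs["geneset_scores.tsv"] = "de"
    except Exception as exc:
        raise StageError("de", exc) from exc


def _stage_lr(config, cohort, layer, analysis_mask, out_dir, outputs):
    try:
        idx = np.flatnonzero(analysis_mask)
        sub = cohort.subset(cell_idx=idx)
        db = (
            LRDatabase.from_tsv(config.lr_db_path)
            if config.lr_db_path
            else LRDatabase.bundled_toy()
        )
        model = LRPermutationModel(
            sub, _sub_layer(layer, idx), db=db,
            min_cells=config.lr_min_cells, target_n=config.lr_target_n,
            delta_min=config.lr_delta_min,
        )
        res = model.fit(n_perm=config.n_perm, seed=stage_seed(config.seed, "lr"))
        write_result(res.to_result_table(), out_dir / "lr_interactions.tsv")
        write_result(
            ResultTable(res.common, key_columns=("interaction_id", "sender", "receiver")),
            out_dir / "lr_common.tsv",
        )
        write_result(
            ResultTable(
                res.unique,
                key_columns=("unique_region", "interaction_id", "sender", "receiver"),
            ),
            out_dir / "lr_unique.tsv",
        )
        for f in ("lr_interactions.tsv", "lr_common.tsv", "lr_unique.tsv"):
            outputs[f] = "lr"
    except Exception as exc:
        raise StageError("lr", exc) from exc
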