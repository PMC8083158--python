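"""Configuration-driven orchestration of the full analysis.

A single config (YAML or dict) drives: cohort acquisition (simulation or
TSV input) -> mapped-reads QC -> exploratory clustering/PCA -> size-factor
normalization -> LOO core-marker selection -> LOO classification with all
five methods, with and without FloWPS -> threshold-sweep metric tables ->
NB differential expression -> optional multi-dataset overlap analysis.
Every run writes a manifest recording the config hash and the global seed;
one global seed fans out to per-stage seeds by stable hashing so a stage is
reproducible independently of execution order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import classify, degsets, io_qc, markers, simdata
from .flowps import FlowpsParams

logger = logging.getLogger(__name__)

COHORTS = ("full", "VCD")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def derive_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed from the global seed via a stable hash; < 2**31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    simulate: dict[str, Any] | None = None
    counts_path: str | None = None
    annotation_path: str | None = None
    cohort: str = "full"
    qc_threshold: int = io_qc.QC_READ_THRESHOLD
    top_k: int = 30
    methods: tuple[str, ...] = classify.METHODS
    flowps: dict[str, list[int]] | None = None  # explicit k_grid/m_grid override
    b_grid: list[float] | None = None
    de_padj: float = degsets.PADJ_CUTOFF
    de_lfc: float = degsets.LFC_CUTOFF
    n_perm: int = 1000
    overlap: dict[str, Any] | None = None  # simulated multi-dataset DEG scenario
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        has_paths = self.counts_path is not None or self.annotation_path is not None
        if (self.simulate is not None) == has_paths:
            raise ValueError(
                "config must contain exactly one of a 'simulate' block or "
                "counts/annotation input paths"
            )
        if has_paths and (self.counts_path is None or self.annotation_path is None):
            raise ValueError("both counts_path and annotation_path are required")
        if self.cohort not in COHORTS:
            raise ValueError(f"cohort must be one of {COHORTS}")
        unknown = set(self.methods) - set(classify.METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "methods" in raw:
            raw = {**raw, "methods": tuple(raw["methods"])}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise StageError(f"[{name}] {exc}") from exc

        return wrapped

    return deco


def select_cohort(annot: pd.DataFrame, cohort: str) -> pd.Index:
    """Pretreatment, response-labelled samples of the requested cohort.

    ``full`` keeps every labelled pretreatment sample; ``VCD`` keeps samples
    whose regimen includes VCD (VCD-only or PAD+VCD) and drops PAD-only.
    """
    mask = (annot["timepoint"] == "pretreatment") & annot["binary_label"].isin(
        ["R", "NR"]
    )
    if cohort == "VCD":
        mask &= annot["regimen"].isin(["VCD", "PAD+VCD"])
    return annot.index[mask]


def run(config: PipelineConfig, output_dir: str | Path | None = None) -> dict[str, Any]:
    """Execute the full pipeline; artifacts land under ``output_dir``.

    Returns a result bundle with the in-memory key objects (core marker set,
    per-method evaluation table, DE result, overlap stats when configured).
    """
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {}

    counts, annot = _acquire(config, out)
    counts, annot, removed = _qc(config, counts, annot)
    results["qc_removed"] = removed
    logger.info("QC removed %d sample(s): %s", len(removed), removed)

    _explore(config, counts, annot, out)

    cohort_samples = select_cohort(annot, config.cohort)
    cohort_counts = counts.loc[:, cohort_samples]
    cohort_labels = annot.loc[cohort_samples, "binary_label"]

    norm, core = _markers(config, cohort_counts, cohort_labels, out)
    results["core_markers"] = core

    table5, curves = _classify(config, norm, core, cohort_labels, out)
    results["evaluation"] = table5
    results["curves"] = curves

    deg, overlap = _degsets(config, cohort_counts, cohort_labels, norm, out)
    results["de"] = deg
    results["overlap"] = overlap

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "cohort": config.cohort,
        "n_samples_analyzed": int(len(cohort_samples)),
        "qc_removed": removed,
        "n_core_markers": len(core.genes),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results


@_stage("acquire")
def _acquire(config: PipelineConfig, out: Path):
    if config.simulate is not None:
        sim_cfg = simdata.SimConfig(
            **{**config.simulate, "seed": derive_seed(config.seed, "simulate")}
        )
        counts, annot, truth = simdata.simulate_cohort(sim_cfg)
        simdata.write_counts(counts, out / "counts.tsv")
        simdata.write_annotation(annot, out / "annotation.tsv")
        truth.to_json(out / "truth.json")
        return counts, annot
    counts = io_qc.read_counts(config.counts_path)
    annot = io_qc.read_annotation(config.annotation_path)
    return io_qc.align(counts, annot)


@_stage("qc")
def _qc(config: PipelineConfig, counts, annot):
    return io_qc.filter_by_mapped_reads(counts, annot, config.qc_threshold)


@_stage("explore")
def _explore(config: PipelineConfig, counts, annot, out: Path):
    qnorm = io_qc.quantile_normalize_with_pseudocount(counts)
    dendro = io_qc.hierarchical_cluster(qnorm)
    dendro.to_newick(out / "dendrogram.nwk")
    coords, evr = io_qc.pca_embed(qnorm)
    coords.to_csv(out / "pca.tsv", sep="\t")
    pd.Series(evr, name="explained_variance_ratio").to_csv(
        out / "pca_variance.tsv", sep="\t", index_label="component"
    )


@_stage("markers")
def _markers(config: PipelineConfig, counts, labels, out: Path):
    norm = markers.size_factor_normalize(counts)
    core = markers.loo_core_markers(norm, labels, top_k=config.top_k)
    core.to_tsv(out / "core_markers.tsv")
    core.ranking.to_csv(out / "marker_ranking.tsv", sep="\t")
    if not core.genes:
        raise ValueError(
            "core marker set is empty; the cohort carries no stable signal "
            "at this top_k"
        )
    return norm, core


@_stage("classify")
def _classify(config: PipelineConfig, norm, core, labels, out: Path):
    features = norm.expression.loc[core.genes].T  # samples x core genes
    if config.flowps is not None:
        params = FlowpsParams(**config.flowps)
    else:
        params = FlowpsParams.default_grid(
            n_train=features.shape[0] - 1, n_features=features.shape[1]
        )
    seed = derive_seed(config.seed, "classify")
    table5 = classify.evaluate_all_methods(
        features, labels, seed=seed, flowps_params=params, methods=config.methods
    )
    table5.to_csv(out / "classifier_metrics.tsv", sep="\t")

    b_grid = (
        np.asarray(config.b_grid, dtype=float)
        if config.b_grid is not None
        else classify.DEFAULT_B_GRID
    )
    curve_frames = []
    for method in config.methods:
        cfg = classify.ClassifierConfig(method=method, random_seed=seed)
        ev = classify.loo_evaluate(features, labels, cfg, params)
        cur = classify.metrics_vs_balance(ev, b_grid)
        cur.insert(0, "method", method)
        curve_frames.append(cur)
    curves = pd.concat(curve_frames, ignore_index=True)
    curves.to_csv(out / "balance_curves.tsv", sep="\t", index=False)
    return table5, curves


@_stage("degsets")
def _degsets(config: PipelineConfig, counts, labels, norm, out: Path):
    deg = degsets.nb_wald_de(
        counts,
        labels,
        norm.size_factors,
        padj_cutoff=config.de_padj,
        lfc_cutoff=config.de_lfc,
    )
    deg.table.to_csv(out / "de_table.tsv", sep="\t")
    overlap = None
    if config.overlap is not None:
        sets, truth = simdata.simulate_deg_universe(
            **{**config.overlap, "seed": derive_seed(config.seed, "overlap")}
        )
        overlap = degsets.pairwise_overlap_stats(
            sets,
            truth["universe"],
            n_perm=config.n_perm,
            seed=derive_seed(config.seed, "overlap_perm"),
        )
        overlap.to_tsv(out / "overlap_stats.tsv")
        overlap.upset.to_csv(out / "upset_counts.tsv", sep="\t", index=False)
    return deg, overlap
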