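"""End-to-end orchestration: ingest -> FDR -> align -> recalibrate ->
cluster -> roll-up -> normalize -> test -> presence -> regions.

The stage order and every threshold live in :class:`PipelineConfig`; a run
writes all stage outputs plus a ``summary.json`` recording the counts at
each stage and the thresholds used, so a run is reproducible from config +
seed alone.
"""

from __future__ import annotations

import glob as _glob
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .align import align_retention_times, recalibrate_masses
from .cluster import (DEFAULT_PPM_TOL, DEFAULT_RT_TOL_MIN,
                      build_quant_matrix, cluster_observations, QuantMatrix)
from .core import SampleDesign, completeness_summary
from .ingest import evalue_ceiling, fdr_filter, read_psm_table, decode_mod_shifts
from .masses import theoretical_mass, load_mod_table, annotate_shift
from .regions import load_region_map, RegionMap
from .stats import (annotate_results_regions, bh_adjust, median_polish,
                    moderated_t, paired_log2fc, presence_screen,
                    volcano_classify, regional_trend)
from .synth import load_precursors

logger = logging.getLogger("proformquant")

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All inputs and thresholds of a pipeline run."""

    psm_paths: list = field(default_factory=list)
    design_path: str = ""
    region_map_path: str | None = None     # packaged default when None
    mod_table_path: str | None = None
    column_map: dict = field(default_factory=dict)
    out_dir: str = "run"
    seed: int = 1
    # thresholds (printed into the run summary)
    evalue_max: float = 0.05
    fdr: float = 0.01
    fdr_per_dataset: bool = False
    span: float = 0.5
    min_anchors: int = 10
    global_recal: bool = False
    ppm_tol: float = DEFAULT_PPM_TOL
    rt_tol_min: float = DEFAULT_RT_TOL_MIN
    mod_match_tol_da: float = 0.1
    min_pairs: int = 2
    p_cut: float = 0.05
    p_adj_cut: float = 0.05
    lfc_cut: float = 1.0
    presence_cut: float = 0.01
    schema_version: int = SCHEMA_VERSION

    def validate(self) -> None:
        for name in ("evalue_max", "fdr", "span", "ppm_tol", "rt_tol_min",
                     "mod_match_tol_da", "p_cut", "lfc_cut", "presence_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class PipelineResult:
    frame: pd.DataFrame            # clustered, aligned, recalibrated PSMs
    quant: QuantMatrix
    normalized: pd.DataFrame
    results: pd.DataFrame          # differential testing table
    presence_results: pd.DataFrame
    eb_params: object
    summary: dict


def _theoretical_masses(frame: pd.DataFrame, sequences: dict) -> pd.Series:
    """Theoretical mass (base + reported shifts) per identified record."""
    out = np.full(len(frame), np.nan)
    cache: dict = {}
    genes = frame["gene"].to_numpy()
    firsts = frame["first_aa"].to_numpy()
    lasts = frame["last_aa"].to_numpy()
    shifts = frame["mod_shifts"].to_numpy()
    decoy = frame["is_decoy"].to_numpy()
    for i in range(len(frame)):
        if decoy[i]:
            continue
        gene = genes[i]
        seq = sequences.get(gene)
        if seq is None or not (1 <= firsts[i] <= lasts[i] <= len(seq)):
            continue
        base_key = (gene, firsts[i], lasts[i])
        base = cache.get(base_key)
        if base is None:
            base = theoretical_mass(seq[firsts[i] - 1:lasts[i]])
            cache[base_key] = base
        out[i] = base + sum(d for d, _ in decode_mod_shifts(shifts[i]))
    return pd.Series(out, index=frame.index)


def process_psms(frames, config: PipelineConfig, sequences: dict | None = None):
    """Identification-level stages: ceiling -> FDR -> align -> recal -> cluster.

    ``frames`` is an iterable of canonical PSM frames (one per acquisition).
    Returns ``(clustered_frame, stage_counts, models)``.
    """
    t0 = time.time()
    if sequences is None:
        sequences = load_precursors()
    combined = pd.concat(list(frames), ignore_index=True)
    counts = {"records_read": int(len(combined))}
    combined = evalue_ceiling(combined, config.evalue_max)
    counts["post_evalue_ceiling"] = int(len(combined))
    filtered, fdr_info = fdr_filter(combined, config.fdr,
                                    per_dataset=config.fdr_per_dataset)
    counts["post_fdr"] = int(len(filtered))
    aligned, align_model = align_retention_times(
        filtered, span=config.span, min_anchors=config.min_anchors)
    theo = _theoretical_masses(aligned, sequences)
    recal, recal_model = recalibrate_masses(aligned, theo,
                                            global_median=config.global_recal)
    clustered = cluster_observations(recal, ppm_tol=config.ppm_tol,
                                     rt_tol_min=config.rt_tol_min)
    counts["clusters"] = int(clustered["cluster_id"].nunique())
    logger.info("identification stages done in %.1fs", time.time() - t0)
    models = {"alignment": align_model, "recalibration": recal_model,
              "fdr": fdr_info}
    return clustered, counts, models


def quantify(quant: QuantMatrix, config: PipelineConfig,
             region_map: RegionMap):
    """Statistical stages: normalize -> paired test -> BH -> presence -> regions."""
    polish = median_polish(quant.abundance)
    normalized = polish.normalized
    diffs, n_excluded = paired_log2fc(normalized, quant.design,
                                      min_pairs=config.min_pairs)
    eb, results = moderated_t(diffs)
    results["p_adj"] = bh_adjust(results["p"].to_numpy())
    info = quant.row_info.loc[results.index]
    results = results.join(info[["gene", "accession", "first_aa", "last_aa",
                                 "modified"]])
    results["region"] = annotate_results_regions(results, region_map)
    results["class"] = volcano_classify(results, p_cut=config.p_cut,
                                        lfc_cut=config.lfc_cut)
    results["significant_adj"] = results["p_adj"] < config.p_adj_cut
    presence = quant.presence()
    pres_results = presence_screen(presence, quant.design,
                                   alpha=config.presence_cut)
    return normalized, results, pres_results, eb, polish


def run_pipeline(config: PipelineConfig, frames=None,
                 design: SampleDesign | None = None,
                 write: bool = True) -> PipelineResult:
    """Execute every stage; optionally write outputs under ``config.out_dir``."""
    config.validate()
    if design is None:
        design = SampleDesign.read_csv(config.design_path)
    if frames is None:
        paths: list = []
        for pattern in config.psm_paths:
            matched = sorted(_glob.glob(str(pattern)))
            paths.extend(matched if matched else [pattern])
        frames = [read_psm_table(p, column_map=config.column_map or None).frame
                  for p in paths]
    region_map = load_region_map(config.region_map_path)

    clustered, counts, models = process_psms(frames, config)
    quant = build_quant_matrix(clustered, design)
    counts["identified_proteoforms"] = int(len(quant.labels))
    frac, bins = (completeness_summary(quant.presence())
                  if len(quant.labels) else (pd.Series(dtype=float), None))
    normalized, results, pres_results, eb, polish = quantify(
        quant, config, region_map)
    counts["quantifiable"] = int(len(results))
    cls = results["class"].value_counts()
    counts["increased"] = int(cls.get("increased", 0))
    counts["decreased"] = int(cls.get("decreased", 0))
    counts["presence_significant"] = int(pres_results["significant"].sum()) \
        if len(pres_results) else 0

    trends = []
    for gene in region_map.genes():
        for reg in region_map.regions_of(gene):
            tr = regional_trend(results, region_map, gene, reg.name)
            if tr["n_total"]:
                trends.append(tr)

    summary = {
        "schema_version": config.schema_version,
        "thresholds": {k: v for k, v in asdict(config).items()
                       if k not in ("psm_paths", "column_map")},
        "counts": counts,
        "eb_params": {"d0": eb.d0, "s0_sq": eb.s0_sq},
        "median_ppm": models["recalibration"].median_ppm,
        "reference_dataset": models["alignment"].reference_id,
        "completeness_ge_50pct": int((frac >= 0.5).sum()) if len(frac) else 0,
        "regional_trends": trends,
    }
    result = PipelineResult(frame=clustered, quant=quant,
                            normalized=normalized, results=results,
                            presence_results=pres_results, eb_params=eb,
                            summary=summary)
    if write:
        _write_outputs(result, models, config)
    return result


def _write_outputs(result: PipelineResult, models: dict,
                   config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.quant.abundance.rename_axis("label").to_csv(out / "quant_matrix.csv")
    result.quant.spectral_counts.rename_axis("label").to_csv(
        out / "spectral_counts.csv")
    result.normalized.rename_axis("label").to_csv(
        out / "quant_matrix_normalized.csv")
    long = (result.quant.abundance.rename_axis("label").reset_index()
            .melt(id_vars="label", var_name="sample_id", value_name="log2_intensity"))
    long.to_csv(out / "quant_long.tsv", sep="\t", index=False)
    cols = ["gene", "accession", "first_aa", "last_aa", "region", "n_pairs",
            "log2fc", "t", "p", "p_adj", "class", "significant_adj"]
    result.results[cols].rename_axis("label").to_csv(
        out / "differential_results.tsv", sep="\t")
    result.presence_results.to_csv(out / "presence_results.tsv", sep="\t",
                                   index=False)
    diag = models["alignment"].diagnostics()
    diag = diag.merge(models["recalibration"].diagnostics(), on="dataset_id",
                      how="outer")
    diag.to_csv(out / "alignment_diagnostics.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(
        json.dumps(result.summary, indent=2, sort_keys=True, default=float))


def annotate_unknown_shifts(results_frame: pd.DataFrame,
                            mod_table=None, tol_da: float = 0.1) -> pd.Series:
    """Tentative names for reported mass shifts (``;``-joined per row)."""
    table = mod_table if mod_table is not None else load_mod_table()
    names = []
    for shifts in results_frame.get("mod_shifts", pd.Series(dtype=str)):
        hits = []
        for delta, _ in decode_mod_shifts(shifts):
            m = annotate_shift(delta, table, tol_da=tol_da)
            hits.append(m.name if m else "unknown")
        names.append(";".join(hits))
    return pd.Series(names, index=results_frame.index, name="mod_annotation")
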