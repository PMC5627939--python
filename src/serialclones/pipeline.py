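"""End-to-end orchestration: from a sample manifest to a consolidated case report.

The pipeline chains the stages in dependency order — variant reading and
somatic filtering, cross-sample harmonization, clone partitioning and
replacement detection, copy-number segmentation with focal-amplification and
fusion-concordance analysis, optional catalog analytics, and optional
expression prioritization. Every stage's output is persisted under the output
directory, and the report contains only numbers copied from those stage
outputs (no report-local computation).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import gene_summary_table, read_catalog, filter_catalog
from .clones import call_presence, detect_replacement, partition_clones
from .copynumber import (
    breakpoint_concordance,
    call_focal_amplifications,
    compute_log2_ratios,
    estimate_absolute_copies,
    locus_log2,
    read_fusion_tsv,
    read_seg,
    write_seg,
)
from .expression import fold_change, prioritize_candidates, rpkm_table
from .variants import (
    VafMatrix,
    filter_somatic,
    harmonize_across_samples,
    read_variant_table,
    write_filter_report,
)


@dataclass
class PipelineConfig:
    """Declarative run description: sample manifest, inputs, and thresholds.

    ``samples`` lists sample ids in chronological order; ``variant_tables``
    maps each id to its MAF-like TSV. Copy-number input is either per-bin
    counts (``cn_bins`` TSV with sample, chrom, start, end, tumor_count,
    normal_count) or precomputed segments (``segments`` SEG file). The
    expression and catalog stages are optional and are skipped (flagged) when
    their inputs are absent.
    """

    samples: list[str]
    variant_tables: dict[str, str]
    out_dir: str
    cn_bins: str | None = None
    segments: str | None = None
    fusions: str | None = None
    expression: str | None = None
    expression_reference: str | None = None
    gene_regions: str | None = None
    catalog: str | None = None
    purity: dict[str, float] = field(default_factory=dict)  # per-sample; default 1.0
    min_depth: int = 20
    min_vaf: float = 0.20
    max_normal_vaf: float = 0.0
    min_depth_all: int = 20
    support_metric: str = "depth"
    presence_vaf: float = 0.10
    min_clone_size: int = 2
    merge_hamming: int = 1
    smooth_window: int = 5
    merge_tolerance: float = 0.3
    min_log2: float = 0.5
    max_span_bp: float = 10e6
    min_fold: int = 5
    seed: int = 0

    def validate(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique and chronologically ordered")
        for sid in self.samples:
            if sid not in self.variant_tables:
                raise ValueError(f"no variant table for sample {sid}")
        for name in ("cn_bins", "segments", "fusions", "expression",
                     "expression_reference", "gene_regions", "catalog"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name} path does not exist: {p}")
        for sid, p in self.variant_tables.items():
            if not Path(p).exists():
                raise ValueError(f"variant table for {sid} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CaseReport:
    """Consolidated per-case result; serializable as deterministic JSON."""

    filter_counts: dict
    clone_sizes: dict
    exclusivity_index: float
    replacement_events: list
    focal_amplifications: dict  # sample -> list of regions
    fusion: dict | None
    gene_summaries: list | None
    candidates: list | None
    skipped_stages: list
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=str)


def _stage(name: str):
    """Wrap a stage so failures name the stage and its offending input."""
    def deco(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return inner
    return deco


def run_pipeline(config: PipelineConfig) -> CaseReport:
    """Execute all stages on the configured inputs and write the case report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    skipped: list[str] = []

    # --- variants: read, somatic-filter, harmonize -----------------------
    matrix, filter_counts = _variant_stage(config, out)

    # --- clone tracking ---------------------------------------------------
    presence = call_presence(matrix, presence_vaf=config.presence_vaf)
    partition = partition_clones(
        presence, min_clone_size=config.min_clone_size, merge_hamming=config.merge_hamming
    )
    events = detect_replacement(partition, config.samples)
    partition.replacement_events = events
    partition.write_tsv(out / "clone_assignments.tsv")
    matrix.write_tsv(out / "vaf_matrix.tsv")

    # --- copy number ------------------------------------------------------
    segments_by_sample = _cn_stage(config, out)
    amps = {
        sid: [
            dict(chrom=s.chrom, start=s.start, end=s.end,
                 log2=round(s.log2_ratio, 4), n_bins=s.n_bins)
            for s in call_focal_amplifications(
                segs, min_log2=config.min_log2, max_span_bp=config.max_span_bp
            )
        ]
        for sid, segs in segments_by_sample.items()
    }

    fusion_report = None
    if config.fusions:
        fusion_report = _fusion_stage(config, segments_by_sample, out)
    else:
        skipped.append("fusions")

    # --- catalog (optional) ----------------------------------------------
    gene_summaries = None
    if config.catalog:
        records = read_catalog(config.catalog)
        kept, cat_report = filter_catalog(records, support_metric=config.support_metric)
        genes = sorted({r.gene for r in kept})
        table = gene_summary_table(kept, genes)
        table.to_csv(out / "gene_summaries.tsv", sep="\t", index=False)
        gene_summaries = table.to_dict(orient="records")
        filter_counts["catalog"] = cat_report
    else:
        skipped.append("catalog")

    # --- expression (optional) ---------------------------------------------
    candidates = None
    if config.expression and config.expression_reference and config.gene_regions:
        candidates = _expression_stage(config, amps, out)
    else:
        skipped.append("expression")

    report = CaseReport(
        filter_counts=filter_counts,
        clone_sizes=partition.clone_sizes(),
        exclusivity_index=partition.exclusivity_index,
        replacement_events=[dataclasses.asdict(e) for e in events],
        focal_amplifications=amps,
        fusion=fusion_report,
        gene_summaries=gene_summaries,
        candidates=candidates,
        skipped_stages=skipped,
        provenance={
            "config_hash": config.content_hash(),
            "package_version": __version__,
            "seed": config.seed,
        },
    )
    (out / "case_report.json").write_text(report.to_json())
    return report


@_stage("variants")
def _variant_stage(config: PipelineConfig, out: Path):
    full_tables = {
        sid: read_variant_table(config.variant_tables[sid], "maf_tsv", sample_id=sid)
        for sid in config.samples
    }
    filter_counts: dict = {}
    somatic_keys: set[str] = set()
    reports = {}
    for sid, calls in full_tables.items():
        kept, rep = filter_somatic(
            calls,
            min_depth=config.min_depth,
            min_vaf=config.min_vaf,
            max_normal_vaf=config.max_normal_vaf,
        )
        somatic_keys |= {c.key for c in kept}
        reports[sid] = rep
        filter_counts[sid] = rep.as_dict()
    write_filter_report(reports, out / "filter_report.json")

    matrix = harmonize_across_samples(
        full_tables,
        min_depth_all=config.min_depth_all,
        support_metric=config.support_metric,
    )
    keep = [k for k in matrix.vaf.index if k in somatic_keys]
    return (
        VafMatrix(
            vaf=matrix.vaf.loc[keep],
            depth=matrix.depth.loc[keep],
            variants=matrix.variants.loc[keep],
        ),
        filter_counts,
    )


@_stage("copy-number")
def _cn_stage(config: PipelineConfig, out: Path):
    segments_by_sample: dict[str, list] = {sid: [] for sid in config.samples}
    if config.segments:
        for seg in read_seg(config.segments):
            segments_by_sample.setdefault(seg.sample_id, []).append(seg)
    elif config.cn_bins:
        bins = pd.read_csv(config.cn_bins, sep="\t")
        for sid in config.samples:
            sub = bins[bins["sample"].astype(str) == str(sid)]
            if sub.empty:
                continue
            tumor = sub[["chrom", "start", "end", "tumor_count"]].rename(
                columns={"tumor_count": "count"}
            )
            normal = sub[["chrom", "start", "end", "normal_count"]].rename(
                columns={"normal_count": "count"}
            )
            segments_by_sample[sid] = compute_log2_ratios(
                tumor, normal, sample_id=sid,
                smooth_window=config.smooth_window,
                merge_tolerance=config.merge_tolerance,
            )
        all_segs = [s for segs in segments_by_sample.values() for s in segs]
        write_seg(all_segs, out / "segments.seg")
    return segments_by_sample


@_stage("fusion")
def _fusion_stage(config: PipelineConfig, segments_by_sample, out: Path):
    events = read_fusion_tsv(config.fusions)
    for e in events:
        segs = segments_by_sample.get(e.sample_id, [])
        log2 = locus_log2(segs, e.chrom3, e.breakpoint3)
        if np.isfinite(log2):
            e.copy_estimate = estimate_absolute_copies(
                log2, purity=float(config.purity.get(e.sample_id, 1.0))
            )
    report = breakpoint_concordance(events)
    report.per_sample.to_csv(out / "fusion_concordance.tsv", sep="\t", index=False)
    return {
        "gene5": report.gene5,
        "gene3": report.gene3,
        "concordant": report.concordant,
        "common_founder": report.common_founder,
        "copy_estimates": {
            str(r["sample"]): (None if pd.isna(r["copy_estimate"]) else int(r["copy_estimate"]))
            for _, r in report.per_sample.iterrows()
        },
    }


@_stage("expression")
def _expression_stage(config: PipelineConfig, amps: Mapping[str, list], out: Path):
    expr = rpkm_table(pd.read_csv(config.expression, sep="\t"))
    ref = pd.read_csv(config.expression_reference, sep="\t", index_col="gene")
    regions = pd.read_csv(config.gene_regions, sep="\t")
    folds = {}
    for _, row in expr.iterrows():
        gene = str(row["gene"])
        if gene in ref.index:
            folds[gene] = fold_change(row["rpkm"], ref.loc[gene].to_numpy(), gene=gene)
    amp_tuples = [
        (a["chrom"], a["start"], a["end"])
        for regions_ in amps.values()
        for a in regions_
    ]
    ranked = prioritize_candidates(
        amp_tuples, regions, folds, min_fold=config.min_fold
    )
    ranked.to_csv(out / "candidates.tsv", sep="\t", index=False)
    return ranked.to_dict(orient="records")
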