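"""Somatic variant tables: reading, somatic filtering, cross-sample harmonization.

The variant substrate of serial-sample clone tracking is a tumor/normal call
set per time point. This module reads MAF-like TSV tables and VCF files into
:class:`VariantCall` records, applies the somatic competence filter (tumor
depth, tumor allele fraction, zero evidence in the matched normal), and
harmonizes per-sample call sets into a variants x samples VAF matrix in which
absent-but-covered loci are explicit zeros and uncovered loci are missing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import normalize_chrom

#: closed vocabulary of variant classes used throughout the package
VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "insertion",
    "deletion",
    "silent",
    "splice",
    "UTR",
    "RNA",
    "other",
)

#: classes counted as protein-coding for catalog analytics
CODING_CLASSES = frozenset({"missense", "nonsense", "insertion", "deletion", "silent"})

# MAF Variant_Classification -> package vocabulary
_MAF_CLASS_MAP = {
    "missense_mutation": "missense",
    "nonsense_mutation": "nonsense",
    "nonstop_mutation": "nonsense",
    "silent": "silent",
    "frame_shift_ins": "insertion",
    "in_frame_ins": "insertion",
    "frame_shift_del": "deletion",
    "in_frame_del": "deletion",
    "splice_site": "splice",
    "splice_region": "splice",
    "3'utr": "UTR",
    "5'utr": "UTR",
    "rna": "RNA",
}

_MAF_COLUMNS = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "t_depth",
    "t_alt_count",
    "n_depth",
    "n_alt_count",
]


def normalize_variant_class(raw: str) -> str:
    """Map a MAF-style Variant_Classification onto the package vocabulary."""
    s = str(raw).strip()
    if s in VARIANT_CLASSES:
        return s
    return _MAF_CLASS_MAP.get(s.lower(), "other")


@dataclass(frozen=True)
class VariantCall:
    """One somatic variant observation in one sample.

    Indels follow the MAF dash convention: a deletion has ``alt == "-"`` and
    ``ref`` holding the deleted bases; an insertion has ``ref == "-"``.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    aa_change: str = ""
    variant_class: str = "other"
    t_depth: int = 0
    t_alt: int = 0
    n_depth: int = 0
    n_alt: int = 0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for name, total, alt in (
            ("tumor", self.t_depth, self.t_alt),
            ("normal", self.n_depth, self.n_alt),
        ):
            if total < 0 or alt < 0:
                raise ValueError(f"negative {name} read counts for {self.key}")
            if alt > total:
                raise ValueError(
                    f"{name} alt reads ({alt}) exceed depth ({total}) for {self.key}"
                )
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.variant_class!r}")

    @property
    def vaf(self) -> float:
        """Tumor variant allele fraction (alternative allele ratio)."""
        return self.t_alt / self.t_depth if self.t_depth > 0 else 0.0

    @property
    def normal_vaf(self) -> float | None:
        """Allele fraction in the matched normal; None when unevaluable."""
        return self.n_alt / self.n_depth if self.n_depth > 0 else None

    @property
    def key(self) -> str:
        """Cross-sample variant identity: chrom:pos:ref>alt (chrom normalized)."""
        return f"{normalize_chrom(self.chrom)}:{self.pos}:{self.ref}>{self.alt}"


def _normalize_indel(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Convert a left-anchored VCF indel into the MAF dash convention."""
    if len(ref) == len(alt):
        return pos, ref, alt
    # strip the shared left anchor
    shared = 0
    while shared < min(len(ref), len(alt)) and ref[shared] == alt[shared]:
        shared += 1
    if len(ref) > len(alt):  # deletion
        return pos + shared, ref[shared:], alt[shared:] or "-"
    return pos + shared - 1, ref[shared:] or "-", alt[shared:]  # insertion


def read_variant_table(
    path: str | Path,
    format: str = "maf_tsv",
    sample_id: str | None = None,
    tumor_sample: str | None = None,
    normal_sample: str | None = None,
) -> list[VariantCall]:
    """Read a per-sample somatic variant table.

    Parameters
    ----------
    path
        MAF-like TSV or VCF file.
    format
        ``"maf_tsv"`` (tab-separated, MAF column names) or ``"vcf"``.
    sample_id
        Sample identifier to stamp on the records; defaults to the
        ``Tumor_Sample_Barcode`` column (MAF) or the tumor sample name (VCF),
        falling back to the file stem.
    tumor_sample, normal_sample
        VCF genotype-column names. Default: first column is the tumor;
        the normal is optional.
    """
    path = Path(path)
    if format == "maf_tsv":
        return _read_maf_tsv(path, sample_id)
    if format == "vcf":
        return _read_vcf(path, sample_id, tumor_sample, normal_sample)
    raise ValueError(f"unknown format {format!r}; expected 'maf_tsv' or 'vcf'")


def _read_maf_tsv(path: Path, sample_id: str | None) -> list[VariantCall]:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"malformed table {path}: {exc}") from exc
    missing = [c for c in _MAF_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"malformed header in {path}: missing columns {missing}")
    calls: list[VariantCall] = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        sid = sample_id or rec.get("Tumor_Sample_Barcode") or path.stem
        counts = {}
        for col in ("t_depth", "t_alt_count", "n_depth", "n_alt_count"):
            val = int(float(rec.get(col, 0) or 0))
            if val < 0:
                raise ValueError(f"negative count in column {col} of {path}")
            counts[col] = val
        calls.append(
            VariantCall(
                sample_id=str(sid),
                chrom=str(rec["Chromosome"]),
                pos=int(float(rec["Start_Position"])),
                ref=str(rec["Reference_Allele"]),
                alt=str(rec["Tumor_Seq_Allele2"]),
                gene=str(rec.get("Hugo_Symbol", "") or ""),
                aa_change=str(rec.get("HGVSp_Short", rec.get("AA_Change", "")) or ""),
                variant_class=normalize_variant_class(rec["Variant_Classification"]),
                t_depth=counts["t_depth"],
                t_alt=counts["t_alt_count"],
                n_depth=counts["n_depth"],
                n_alt=counts["n_alt_count"],
            )
        )
    return calls


def _read_vcf(
    path: Path,
    sample_id: str | None,
    tumor_sample: str | None,
    normal_sample: str | None,
) -> list[VariantCall]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path} carries no genotype columns")
    tumor = tumor_sample or samples[0]
    if tumor not in samples:
        raise ValueError(f"tumor sample {tumor!r} not in {path}")
    t_idx = samples.index(tumor)
    n_idx = samples.index(normal_sample) if normal_sample else None

    calls: list[VariantCall] = []
    for rec in vcf:
        ad = rec.format("AD")
        dp = rec.format("DP")
        for alt_i, alt in enumerate(rec.ALT):
            t_alt = int(ad[t_idx][alt_i + 1]) if ad is not None else 0
            if dp is not None:
                t_depth = int(np.atleast_1d(dp[t_idx])[0])
            elif ad is not None:
                t_depth = int(sum(max(v, 0) for v in ad[t_idx]))
            else:
                t_depth = 0
            n_depth = n_alt = 0
            if n_idx is not None:
                if dp is not None:
                    n_depth = int(np.atleast_1d(dp[n_idx])[0])
                elif ad is not None:
                    n_depth = int(sum(max(v, 0) for v in ad[n_idx]))
                if ad is not None:
                    n_alt = int(ad[n_idx][alt_i + 1])
            pos, ref, alt_n = _normalize_indel(rec.POS, rec.REF, alt)
            if len(ref) > 1 and alt_n != "-" and len(alt_n) == len(ref):
                vclass = "missense"
            elif alt_n == "-":
                vclass = "deletion"
            elif ref == "-":
                vclass = "insertion"
            else:
                vclass = "other"
            calls.append(
                VariantCall(
                    sample_id=sample_id or tumor,
                    chrom=rec.CHROM,
                    pos=pos,
                    ref=ref,
                    alt=alt_n,
                    gene=str(rec.INFO.get("GENE", "") or ""),
                    variant_class=vclass,
                    t_depth=max(t_depth, t_alt),
                    t_alt=t_alt,
                    n_depth=max(n_depth, n_alt),
                    n_alt=n_alt,
                )
            )
    return calls


def calls_to_frame(calls: Iterable[VariantCall]) -> pd.DataFrame:
    """MAF-like DataFrame view of a call list (column order is the MAF layout)."""
    rows = [
        {
            "Hugo_Symbol": c.gene,
            "Chromosome": c.chrom,
            "Start_Position": c.pos,
            "Reference_Allele": c.ref,
            "Tumor_Seq_Allele2": c.alt,
            "Variant_Classification": c.variant_class,
            "AA_Change": c.aa_change,
            "t_depth": c.t_depth,
            "t_alt_count": c.t_alt,
            "n_depth": c.n_depth,
            "n_alt_count": c.n_alt,
            "Tumor_Sample_Barcode": c.sample_id,
        }
        for c in calls
    ]
    cols = _MAF_COLUMNS[:6] + ["AA_Change"] + _MAF_COLUMNS[6:] + ["Tumor_Sample_Barcode"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class FilterReport:
    """Bookkeeping for the somatic filter: how many calls each rule removed."""

    n_input: int = 0
    n_pass: int = 0
    n_low_depth: int = 0
    n_low_vaf: int = 0
    n_normal_evidence: int = 0
    n_normal_unevaluable: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def filter_somatic(
    calls: Sequence[VariantCall],
    min_depth: int = 20,
    min_vaf: float = 0.20,
    max_normal_vaf: float = 0.0,
) -> tuple[list[VariantCall], FilterReport]:
    """Apply the somatic competence filter to one sample's calls.

    A call is retained when tumor depth >= ``min_depth`` (inclusive), tumor
    VAF >= ``min_vaf`` (inclusive), and the matched-normal allele fraction is
    <= ``max_normal_vaf`` (0 by default: no variant evidence in blood).
    Calls whose normal depth is 0 cannot be evaluated against a strict
    normal cutoff; they are excluded and counted separately in the report.
    """
    report = FilterReport(n_input=len(calls))
    kept: list[VariantCall] = []
    for c in calls:
        if c.t_depth < min_depth:
            report.n_low_depth += 1
            continue
        if c.vaf < min_vaf:
            report.n_low_vaf += 1
            continue
        nv = c.normal_vaf
        if nv is None:
            report.n_normal_unevaluable += 1
            continue
        if nv > max_normal_vaf:
            report.n_normal_evidence += 1
            continue
        kept.append(c)
    report.n_pass = len(kept)
    return kept, report


@dataclass
class VafMatrix:
    """Variants x serial samples grid of VAF and depth.

    ``vaf`` and ``depth`` share the same index (variant keys, see
    :attr:`VariantCall.key`) and columns (sample ids in chronological order).
    Missing cells (locus not covered in that sample's table) are NaN and are
    distinct from an observed VAF of 0 at a covered locus.
    """

    vaf: pd.DataFrame
    depth: pd.DataFrame
    variants: pd.DataFrame  # key -> chrom,pos,ref,alt,gene,variant_class

    @property
    def samples(self) -> list[str]:
        return list(self.vaf.columns)

    def __post_init__(self) -> None:
        if not self.vaf.index.equals(self.depth.index) or list(self.vaf.columns) != list(
            self.depth.columns
        ):
            raise ValueError("vaf and depth grids must share index and columns")
        observed = self.vaf.to_numpy(dtype=float)
        obs = observed[~np.isnan(observed)]
        if obs.size and (obs.min() < 0 or obs.max() > 1):
            raise ValueError("observed VAF outside [0, 1]")

    def write_tsv(self, path: str | Path) -> None:
        out = self.variants.join(self.vaf)
        out.to_csv(path, sep="\t", index_label="variant_key")


def harmonize_across_samples(
    per_sample_calls: Mapping[str, Sequence[VariantCall]],
    min_depth_all: int = 20,
    support_metric: str = "depth",
) -> VafMatrix:
    """Build the cross-sample VAF matrix from per-sample call tables.

    Variants are keyed by (chrom, pos, ref, alt); the union across samples is
    taken, then a variant is retained only when it is competent in *every*
    sample: with ``support_metric="depth"`` (default) the locus must carry at
    least ``min_depth_all`` total reads in each sample; ``"alt"`` demands
    that many variant-supporting reads instead. Loci with no record in some
    sample are not evaluable there and are dropped under ``min_depth_all > 0``
    (kept as NaN cells when the competence filter is disabled).
    """
    if len(per_sample_calls) < 2:
        raise ValueError("harmonization needs at least two samples")
    if support_metric not in ("depth", "alt"):
        raise ValueError("support_metric must be 'depth' or 'alt'")

    sample_ids = list(per_sample_calls)
    records: dict[str, dict[str, VariantCall]] = {}
    meta: dict[str, VariantCall] = {}
    for sid in sample_ids:
        seen: set[str] = set()
        for c in per_sample_calls[sid]:
            if c.key in seen:
                raise ValueError(f"duplicate variant key {c.key} in sample {sid}")
            seen.add(c.key)
            records.setdefault(c.key, {})[sid] = c
            meta.setdefault(c.key, c)

    keys = sorted(
        records,
        key=lambda k: (normalize_chrom(meta[k].chrom), meta[k].pos, meta[k].ref, meta[k].alt),
    )
    vaf = pd.DataFrame(np.nan, index=keys, columns=sample_ids, dtype=float)
    depth = pd.DataFrame(np.nan, index=keys, columns=sample_ids, dtype=float)
    for key in keys:
        for sid, c in records[key].items():
            vaf.at[key, sid] = c.vaf
            depth.at[key, sid] = c.t_depth

    if min_depth_all > 0:
        support = depth if support_metric == "depth" else vaf * depth
        ok = (support >= min_depth_all).all(axis=1) & support.notna().all(axis=1)
        vaf, depth = vaf.loc[ok], depth.loc[ok]
        keys = list(vaf.index)

    variants = pd.DataFrame(
        {
            "chrom": [meta[k].chrom for k in keys],
            "pos": [meta[k].pos for k in keys],
            "ref": [meta[k].ref for k in keys],
            "alt": [meta[k].alt for k in keys],
            "gene": [meta[k].gene for k in keys],
            "variant_class": [meta[k].variant_class for k in keys],
        },
        index=pd.Index(keys, name="variant_key"),
    )
    return VafMatrix(vaf=vaf, depth=depth, variants=variants)


def write_filter_report(reports: Mapping[str, FilterReport], path: str | Path) -> None:
    """Persist per-sample filter counts as JSON."""
    Path(path).write_text(
        json.dumps({sid: r.as_dict() for sid, r in reports.items()}, indent=2, sort_keys=True)
    )
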