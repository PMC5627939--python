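"""Reference mutation-catalog analytics: competence filtering, per-gene
silent-mutation fractions, recurrence lookup, driver/passenger classification.

The guiding statistic: in a large pan-cancer mutation catalog, genes under
positive selection (drivers) show very low fractions of silent (synonymous)
mutations (~2-4%), because their observed mutations are enriched for
protein-altering events; genes mutated only as passengers show silent
fractions near the neutral expectation (~20-30%). A gene's silent fraction
over its catalog mutations, together with the recurrence of specific
variants, therefore separates driver-like from passenger-like mutation sets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import normalize_chrom, round_half_away
from .variants import CODING_CLASSES, VARIANT_CLASSES, normalize_variant_class


@dataclass(frozen=True)
class CatalogRecord:
    """One mutation record from a reference catalog (MAF-style)."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    depth: int | None = None  # supporting reads; None when the catalog lacks counts
    alt_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.variant_class!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Normalized variant identity used for recurrence matching."""
    return (normalize_chrom(chrom), int(pos), str(ref).upper(), str(alt).upper())


def read_catalog(path: str | Path) -> list[CatalogRecord]:
    """Read a MAF-format catalog (standard TCGA-style columns)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, low_memory=False)
    needed = ["Hugo_Symbol", "Chromosome", "Start_Position", "Reference_Allele",
              "Tumor_Seq_Allele2", "Variant_Classification"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"catalog {path} missing MAF columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        depth = rec.get("t_depth")
        alt_n = rec.get("t_alt_count")
        depth_i = int(float(depth)) if depth not in (None, "", "nan") else None
        ratio = (
            int(float(alt_n)) / depth_i
            if depth_i and alt_n not in (None, "", "nan")
            else None
        )
        records.append(
            CatalogRecord(
                gene=str(rec["Hugo_Symbol"]),
                chrom=str(rec["Chromosome"]),
                pos=int(float(rec["Start_Position"])),
                ref=str(rec["Reference_Allele"]),
                alt=str(rec["Tumor_Seq_Allele2"]),
                variant_class=normalize_variant_class(rec["Variant_Classification"]),
                depth=depth_i,
                alt_ratio=ratio,
            )
        )
    return records


def filter_catalog(
    records: Sequence[CatalogRecord],
    min_reads: int = 20,
    min_aaf: float = 0.2,
    support_metric: str = "depth",
) -> tuple[list[CatalogRecord], dict[str, int]]:
    """Competence-filter a catalog.

    Retains records with read support >= ``min_reads`` (inclusive), alt
    allele ratio >= ``min_aaf`` (inclusive), and a protein-coding variant
    class (missense, nonsense, insertion, deletion, silent); splice/UTR/RNA
    and other classes are excluded. Records without read-count support are
    not evaluable and are excluded, counted under ``n_no_support``.

    ``support_metric`` selects whether ``min_reads`` is judged on total locus
    depth ("depth", default) or on variant-supporting reads ("alt").
    """
    if support_metric not in ("depth", "alt"):
        raise ValueError("support_metric must be 'depth' or 'alt'")
    report = {
        "n_input": len(records),
        "n_no_support": 0,
        "n_low_reads": 0,
        "n_low_ratio": 0,
        "n_noncoding": 0,
        "n_pass": 0,
    }
    kept: list[CatalogRecord] = []
    for r in records:
        if r.depth is None or r.alt_ratio is None:
            report["n_no_support"] += 1
            continue
        reads = r.depth if support_metric == "depth" else r.alt_ratio * r.depth
        if reads < min_reads:
            report["n_low_reads"] += 1
            continue
        if r.alt_ratio < min_aaf:
            report["n_low_ratio"] += 1
            continue
        if r.variant_class not in CODING_CLASSES:
            report["n_noncoding"] += 1
            continue
        kept.append(r)
    report["n_pass"] = len(kept)
    return kept, report


@dataclass
class GeneMutationSummary:
    """Per-gene silent-mutation statistic over a filtered catalog."""

    gene: str
    total_mutations: int
    silent_count: int

    def __post_init__(self) -> None:
        if self.silent_count > self.total_mutations:
            raise ValueError("silent count exceeds total")

    @property
    def silent_fraction(self) -> float | None:
        """silent/total; None (undefined) when the gene has no mutations."""
        if self.total_mutations == 0:
            return None
        return self.silent_count / self.total_mutations

    @property
    def percent_display(self) -> str:
        """Integer-percent display, e.g. '24% (599)'; distinct from 0% when
        the gene is absent from the catalog."""
        f = self.silent_fraction
        if f is None:
            return "NA (0)"
        return f"{round_half_away(100 * f)}% ({self.total_mutations})"


def silent_fraction(
    records: Sequence[CatalogRecord], gene: str
) -> GeneMutationSummary:
    """Silent-mutation summary of one gene over (already filtered) records."""
    mine = [r for r in records if r.gene == gene]
    return GeneMutationSummary(
        gene=gene,
        total_mutations=len(mine),
        silent_count=sum(r.variant_class == "silent" for r in mine),
    )


def recurrence_lookup(
    records: Sequence[CatalogRecord],
    variants: Iterable[tuple[str, int, str, str]],
) -> dict[tuple[str, int, str, str], int]:
    """Exact-key recurrence count of each queried variant in the catalog.

    Keys are normalized (chromosome prefix stripped, alleles uppercased)
    identically on both sides; absent variants count 0.
    """
    counts = Counter(r.key for r in records)
    return {
        variant_key(*v): counts.get(variant_key(*v), 0) for v in variants
    }


def classify_driver_like(
    summary: GeneMutationSummary,
    driver_max_fraction: float = 0.05,
    min_total: int = 30,
    passenger_min_fraction: float = 0.15,
) -> str:
    """Advisory driver/passenger call from the silent fraction.

    driver-like: fraction <= ``driver_max_fraction`` with at least
    ``min_total`` catalog mutations (guards small denominators);
    passenger-like: fraction >= ``passenger_min_fraction``; otherwise
    indeterminate. The bands bracket the empirical extremes (drivers a few
    percent, neutral genes ~20-30%) but known exceptions exist, so the call
    is a flag, not a verdict.
    """
    f = summary.silent_fraction
    if f is None:
        raise ValueError(f"silent fraction undefined for {summary.gene} (0 mutations)")
    if f <= driver_max_fraction and summary.total_mutations >= min_total:
        return "driver-like"
    if f >= passenger_min_fraction:
        return "passenger-like"
    return "indeterminate"


def gene_summary_table(
    records: Sequence[CatalogRecord],
    genes: Sequence[str],
    queries: Mapping[str, tuple[str, int, str, str]] | None = None,
    **classify_kwargs,
) -> pd.DataFrame:
    """Per-gene table (gene, recurrence, silent %, total, classification)."""
    recur = (
        recurrence_lookup(records, list(queries.values())) if queries else {}
    )
    rows = []
    for gene in genes:
        s = silent_fraction(records, gene)
        rows.append(
            {
                "gene": gene,
                "recurrence": (
                    recur.get(variant_key(*queries[gene]), 0) if queries and gene in queries else None
                ),
                "silent_fraction": s.silent_fraction,
                "display": s.percent_display,
                "total": s.total_mutations,
                "classification": (
                    classify_driver_like(s, **classify_kwargs)
                    if s.total_mutations
                    else "indeterminate"
                ),
            }
        )
    return pd.DataFrame(rows)
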