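"""RPKM normalization, fold change vs a reference cohort, and candidate
prioritization inside amplified regions.

A focal DNA amplification only matters therapeutically if it drives
expression, so amplified-region genes are ranked by their expression fold
change over the median of a reference tumor cohort: fold = case RPKM /
reference-median RPKM. Genes above a fold cutoff are candidates; everything
in-region is reported either way so the cutoff stays transparent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_away


def compute_rpkm(count: float, length_bp: int, total_mapped: float) -> float:
    """Reads per kilobase of transcript per million mapped reads.

    rpkm = count / ((length_bp / 1000) * (total_mapped / 1e6)). Counts are
    assumed to be unique (high mapping quality) reads.
    """
    if length_bp <= 0:
        raise ValueError("gene length must be positive")
    if total_mapped < 1:
        raise ValueError("total mapped reads must be >= 1")
    if count < 0:
        raise ValueError("read count must be >= 0")
    return count / ((length_bp / 1000.0) * (total_mapped / 1e6))


def rpkm_table(
    expression: pd.DataFrame, total_mapped: float | None = None
) -> pd.DataFrame:
    """Add an ``rpkm`` column to a (gene, length_bp, count) table.

    ``total_mapped`` defaults to the table's ``total_mapped`` column when
    present (the library size recorded alongside a gene-subset table), else
    to the count sum — appropriate only when the table covers the library.
    """
    for col in ("gene", "length_bp", "count"):
        if col not in expression.columns:
            raise ValueError(f"expression table needs a {col!r} column")
    if total_mapped is not None:
        total = float(total_mapped)
    elif "total_mapped" in expression.columns:
        total = float(expression["total_mapped"].iloc[0])
    else:
        total = float(expression["count"].sum())
    out = expression.copy()
    out["rpkm"] = [
        compute_rpkm(c, l, total) for c, l in zip(out["count"], out["length_bp"])
    ]
    return out


@dataclass
class FoldChangeResult:
    """Case-vs-reference expression ratio for one gene."""

    gene: str
    case_value: float  # median RPKM over the case sample(s)
    reference_median: float
    infinite: bool = False

    @property
    def fold_change_raw(self) -> float:
        if self.infinite:
            return float("inf")
        return self.case_value / self.reference_median

    @property
    def fold_change_display(self) -> str:
        """Nearest-integer display with a multiplication prefix, e.g. '×98'."""
        if self.infinite:
            return "×inf"
        return f"×{round_half_away(self.fold_change_raw)}"

    @property
    def fold_display_int(self) -> int | None:
        return None if self.infinite else round_half_away(self.fold_change_raw)


def fold_change(
    case_rpkm: float | Sequence[float],
    reference_rpkms: Sequence[float],
    gene: str = "",
) -> FoldChangeResult:
    """Fold change of case expression over the reference cohort median.

    ``case_rpkm`` may be a single value or several case samples (their median
    is used, so one sample is just its own median). A zero reference median
    yields an infinite-fold flag rather than a number.
    """
    ref = np.asarray(list(reference_rpkms), dtype=float)
    if ref.size == 0:
        raise ValueError("reference RPKM list is empty")
    case = float(np.median(np.atleast_1d(np.asarray(case_rpkm, dtype=float))))
    ref_median = float(np.median(ref))
    if ref_median == 0:
        return FoldChangeResult(gene=gene, case_value=case, reference_median=0.0, infinite=True)
    return FoldChangeResult(gene=gene, case_value=case, reference_median=ref_median)


def read_bed_regions(path: str | Path) -> pd.DataFrame:
    """Gene regions from BED (0-based half-open) as 1-based inclusive."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene"], usecols=[0, 1, 2, 3],
    )
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df[["gene", "chrom", "start", "end"]]


def _overlaps(gene_row, regions) -> bool:
    for r in regions:
        chrom = r.chrom if hasattr(r, "chrom") else r[0]
        start = r.start if hasattr(r, "start") else r[1]
        end = r.end if hasattr(r, "end") else r[2]
        if (
            str(gene_row["chrom"]) == str(chrom)
            and int(gene_row["start"]) <= int(end)
            and int(gene_row["end"]) >= int(start)
        ):
            return True
    return False


def prioritize_candidates(
    amplified_regions: Sequence,
    gene_regions: pd.DataFrame,
    fold_results: Mapping[str, FoldChangeResult],
    min_fold: int = 5,
) -> pd.DataFrame:
    """Rank amplified-region genes by expression fold change.

    ``amplified_regions`` is any sequence of segments or (chrom, start, end)
    tuples (1-based inclusive); ``gene_regions`` maps genes to intervals.
    Genes inside an amplified region with display fold >= ``min_fold`` are
    candidates, ranked by raw fold descending (alphabetical on ties); genes
    below threshold are kept in the table as non-candidates, and in-region
    genes without an expression record are flagged "unquantified".
    """
    rows = []
    for _, g in gene_regions.iterrows():
        if not _overlaps(g, amplified_regions):
            continue
        gene = str(g["gene"])
        fc = fold_results.get(gene)
        if fc is None:
            rows.append(
                dict(gene=gene, fold_raw=np.nan, fold_display=None,
                     status="unquantified")
            )
            continue
        disp = fc.fold_display_int
        status = (
            "candidate"
            if fc.infinite or (disp is not None and disp >= min_fold)
            else "non-candidate"
        )
        rows.append(
            dict(gene=gene, fold_raw=fc.fold_change_raw,
                 fold_display=fc.fold_change_display, status=status)
        )
    if not rows:
        return pd.DataFrame(columns=["gene", "fold_raw", "fold_display", "status", "rank"])
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["fold_raw", "gene"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    is_cand = df["status"] == "candidate"
    df["rank"] = np.where(is_cand, is_cand.cumsum(), 0)
    df["rank"] = df["rank"].where(is_cand, other=pd.NA)
    return df
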