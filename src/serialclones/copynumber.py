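"""Copy-number log2 ratios, focal amplifications, and fusion concordance.

Tumor/normal read-count bins are normalized by library size, smoothed with a
running median, log2-transformed, and merged into segments. Segments feed
three analyses: focal-amplification calling (high log2 over a short span),
absolute copy estimation from the log2 ratio under a purity/ploidy model, and
a concordance test over gene-fusion breakpoints across serial samples — an
identical breakpoint in every sample implies the subclones descend from a
single founder cell in which the rearrangement occurred.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import round_half_away


@dataclass
class CnSegment:
    """A constant-copy-number genomic segment (1-based inclusive coords)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float
    n_bins: int = 1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.n_bins < 1:
            raise ValueError("a segment needs at least one supporting bin")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class FusionEvent:
    """A gene-fusion call: 5'/3' partners with genomic breakpoints."""

    sample_id: str
    gene5: str
    gene3: str
    chrom5: str
    breakpoint5: int
    chrom3: str
    breakpoint3: int
    supporting_reads: int = 0
    copy_estimate: int | None = None

    def __post_init__(self) -> None:
        if self.supporting_reads < 0:
            raise ValueError("supporting_reads must be >= 0")
        if self.copy_estimate is not None and self.copy_estimate < 0:
            raise ValueError("copy_estimate must be >= 0")


def compute_log2_ratios(
    tumor_bins: pd.DataFrame,
    normal_bins: pd.DataFrame,
    sample_id: str = "",
    smooth_window: int = 5,
    merge_tolerance: float = 0.3,
    normalize: bool = True,
) -> list[CnSegment]:
    """Segment library-normalized tumor/normal bin ratios.

    Both frames need columns (chrom, start, end, count) on an identical bin
    grid. Per-bin ratios are (tumor/tumor_total)/(normal/normal_total),
    median-smoothed over ``smooth_window`` bins within each chromosome, then
    log2-transformed; adjacent bins join the current segment while their
    smoothed log2 stays within ``merge_tolerance`` of the segment's running
    mean. Bins with zero normal count are masked (segment boundaries), never
    infinite. Invariant to rescaling either library's total depth.

    ``normalize=False`` skips the library-size division and takes raw
    tumor/normal count ratios — for inputs that are already depth-matched.
    """
    for col in ("chrom", "start", "end", "count"):
        if col not in tumor_bins.columns or col not in normal_bins.columns:
            raise ValueError(f"bin tables need a {col!r} column")
    t = tumor_bins.sort_values(["chrom", "start"]).reset_index(drop=True)
    n = normal_bins.sort_values(["chrom", "start"]).reset_index(drop=True)
    if not (
        t[["chrom", "start", "end"]].equals(n[["chrom", "start", "end"]])
    ):
        raise ValueError("tumor and normal bins must share an identical grid")
    t_total = float(t["count"].sum()) if normalize else 1.0
    n_total = float(n["count"].sum()) if normalize else 1.0
    if t_total <= 0 or n_total <= 0:
        raise ValueError("bin counts sum to zero")

    segments: list[CnSegment] = []
    for chrom, tg in t.groupby("chrom", sort=False):
        ng = n.loc[tg.index]
        tc = tg["count"].to_numpy(dtype=float)
        nc = ng["count"].to_numpy(dtype=float)
        valid = nc > 0
        ratio = np.full(len(tc), np.nan)
        ratio[valid] = (tc[valid] / t_total) / (nc[valid] / n_total)
        smoothed = (
            pd.Series(ratio)
            .rolling(smooth_window, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        smoothed[~valid] = np.nan  # masked bins stay masked after smoothing
        log2 = np.log2(np.where(smoothed > 0, smoothed, np.nan))
        starts = tg["start"].to_numpy()
        ends = tg["end"].to_numpy()

        cur: list[int] = []
        for i in range(len(log2)):
            if not np.isfinite(log2[i]):
                if cur:
                    segments.append(_flush(sample_id, chrom, starts, ends, log2, cur))
                    cur = []
                continue
            if cur and abs(log2[i] - np.mean(log2[cur])) >= merge_tolerance:
                segments.append(_flush(sample_id, chrom, starts, ends, log2, cur))
                cur = []
            cur.append(i)
        if cur:
            segments.append(_flush(sample_id, chrom, starts, ends, log2, cur))
    return segments


def _flush(sample_id, chrom, starts, ends, log2, idx) -> CnSegment:
    return CnSegment(
        sample_id=sample_id,
        chrom=str(chrom),
        start=int(starts[idx[0]]),
        end=int(ends[idx[-1]]),
        log2_ratio=float(np.mean(log2[idx])),
        n_bins=len(idx),
    )


def call_focal_amplifications(
    segments: Sequence[CnSegment],
    min_log2: float = 0.5,
    max_span_bp: float = 10e6,
    merge_gap_bp: int = 1,
) -> list[CnSegment]:
    """Focal amplified regions: log2 >= ``min_log2`` (inclusive) over a span
    of at most ``max_span_bp``.

    Adjacent qualifying segments (same sample and chromosome, separated by at
    most ``merge_gap_bp``) are merged into one region first — segmentation
    noise can split a contiguous amplification — with an n_bins-weighted mean
    log2. The span rule applies to the merged region, so broad gains are
    excluded even when reported piecewise.
    """
    amplified = sorted(
        (s for s in segments if s.log2_ratio >= min_log2),
        key=lambda s: (s.sample_id, s.chrom, s.start),
    )
    merged: list[CnSegment] = []
    for s in amplified:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and (s.sample_id, s.chrom) == (prev.sample_id, prev.chrom)
            and s.start - prev.end <= merge_gap_bp
        ):
            total = prev.n_bins + s.n_bins
            merged[-1] = CnSegment(
                sample_id=prev.sample_id,
                chrom=prev.chrom,
                start=prev.start,
                end=s.end,
                log2_ratio=(prev.log2_ratio * prev.n_bins + s.log2_ratio * s.n_bins)
                / total,
                n_bins=total,
            )
        else:
            merged.append(s)
    return [s for s in merged if s.span <= max_span_bp]


def estimate_absolute_copies(
    log2_ratio: float,
    purity: float = 1.0,
    normal_ploidy: int = 2,
) -> int:
    """Convert a log2 tumor/normal ratio to an integer copy number.

    The observed ratio mixes tumor cells at fraction ``purity`` with diploid
    normal cells, so the tumor-cell copy number is

        copies = (normal_ploidy * 2**L - (1 - purity) * normal_ploidy) / purity

    rounded half away from zero. At purity 1 this is round(2 * 2**L):
    L = 1.4 -> 5 copies, L = 0.5 -> 3, L = 0 -> 2.
    """
    if not np.isfinite(log2_ratio):
        raise ValueError("log2 ratio must be finite")
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    raw = (normal_ploidy * 2.0**log2_ratio - (1.0 - purity) * normal_ploidy) / purity
    return max(round_half_away(raw), 0)


def locus_log2(
    segments: Sequence[CnSegment], chrom: str, pos: int
) -> float:
    """log2 ratio of the segment containing a locus (NaN when uncovered)."""
    for s in segments:
        if s.chrom == chrom and s.start <= pos <= s.end:
            return s.log2_ratio
    return float("nan")


@dataclass
class ConcordanceReport:
    """Cross-sample fusion-breakpoint comparison.

    A concordant breakpoint across serial samples (all pairwise distances
    within tolerance on both partners) flags a common founder cell: the
    rearrangement predates the divergence of the subclones.
    """

    gene5: str
    gene3: str
    concordant: bool
    common_founder: bool
    max_distance5: int
    max_distance3: int
    per_sample: pd.DataFrame  # sample, chrom5, pos5, chrom3, pos3, copy_estimate

    @property
    def copy_estimates(self) -> list[int | None]:
        return list(self.per_sample["copy_estimate"])


def breakpoint_concordance(
    events: Sequence[FusionEvent], tolerance_bp: int = 0
) -> ConcordanceReport:
    """Test whether fusion breakpoints agree across samples.

    All events must describe the same 5'/3' gene pair (mixed pairs raise).
    Concordance requires, for every pair of events, the same chromosomes and
    breakpoint distances <= ``tolerance_bp`` on both partners; at tolerance 0
    this is exact coordinate identity (and hence transitive).
    """
    if len(events) < 2:
        raise ValueError("concordance needs at least two fusion events")
    pairs = {(e.gene5, e.gene3) for e in events}
    if len(pairs) > 1:
        raise ValueError(f"mixed gene pairs in concordance test: {sorted(pairs)}")
    gene5, gene3 = next(iter(pairs))

    d5 = d3 = 0
    concordant = True
    for a, b in itertools.combinations(events, 2):
        if a.chrom5 != b.chrom5 or a.chrom3 != b.chrom3:
            concordant = False
            continue
        d5 = max(d5, abs(a.breakpoint5 - b.breakpoint5))
        d3 = max(d3, abs(a.breakpoint3 - b.breakpoint3))
    concordant = concordant and d5 <= tolerance_bp and d3 <= tolerance_bp

    per_sample = pd.DataFrame(
        {
            "sample": [e.sample_id for e in events],
            "chrom5": [e.chrom5 for e in events],
            "pos5": [e.breakpoint5 for e in events],
            "chrom3": [e.chrom3 for e in events],
            "pos3": [e.breakpoint3 for e in events],
            "supporting_reads": [e.supporting_reads for e in events],
            "copy_estimate": [e.copy_estimate for e in events],
        }
    )
    return ConcordanceReport(
        gene5=gene5,
        gene3=gene3,
        concordant=concordant,
        common_founder=concordant,
        max_distance5=d5,
        max_distance3=d3,
        per_sample=per_sample,
    )


# ---------------------------------------------------------------------------
# plain-text IO


def read_seg(path: str | Path) -> list[CnSegment]:
    """Read a SEG-style TSV (sample, chrom, start, end, log2[, n_bins])."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "chrom", "start", "end", "log2"}
    if not required.issubset(df.columns):
        raise ValueError(f"SEG file {path} missing columns {required - set(df.columns)}")
    return [
        CnSegment(
            sample_id=str(r["sample"]),
            chrom=str(r["chrom"]),
            start=int(r["start"]),
            end=int(r["end"]),
            log2_ratio=float(r["log2"]),
            n_bins=1 if pd.isna(r.get("n_bins", 1)) else int(r.get("n_bins", 1)),
        )
        for _, r in df.iterrows()
    ]


def write_seg(segments: Sequence[CnSegment], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample": [s.sample_id for s in segments],
            "chrom": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "log2": [s.log2_ratio for s in segments],
            "n_bins": [s.n_bins for s in segments],
        }
    ).to_csv(path, sep="\t", index=False)


def read_fusion_tsv(path: str | Path) -> list[FusionEvent]:
    """Read fusion calls from TSV (sample, gene5, gene3, chrom5, pos5, chrom3,
    pos3, supporting_reads)."""
    df = pd.read_csv(path, sep="\t")
    return [
        FusionEvent(
            sample_id=str(r["sample"]),
            gene5=str(r["gene5"]),
            gene3=str(r["gene3"]),
            chrom5=str(r["chrom5"]),
            breakpoint5=int(r["pos5"]),
            chrom3=str(r["chrom3"]),
            breakpoint3=int(r["pos3"]),
            supporting_reads=int(r.get("supporting_reads", 0) or 0),
        )
        for _, r in df.iterrows()
    ]
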