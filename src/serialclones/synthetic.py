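"""Synthetic serial-tumor cohorts with known clonal truth.

The generator encodes the clonal-evolution scenario that motivates this
package: a founder cell acquires a gene fusion, daughter lineages inherit
different fusion copy numbers, and two subclones then accumulate disjoint
somatic mutation sets. Across an ordered series of samples the primary
subclone (A) is replaced by the secondary subclone (B), which additionally
carries focal amplifications and drives overexpression of genes inside them.

Every downstream stage (variant filtering, clone partitioning, copy-number
segmentation, fusion concordance, expression prioritization) can therefore be
tested against exact truth without any external sequencing data.

The read model is deliberately shallow: per-locus depths are Poisson, variant
reads are Binomial(depth, expected VAF), and copy-number bins are Poisson
counts proportional to the local tumor copy state. No read-level artifacts
(mapping error, FFPE damage, GC bias) are simulated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import VariantCall, calls_to_frame

_BASES = ("A", "C", "G", "T")

# default class mix for simulated coding variants
_CLASS_PROBS = {
    "missense": 0.62,
    "silent": 0.22,
    "nonsense": 0.06,
    "insertion": 0.05,
    "deletion": 0.05,
}

#: default focal amplification regions carried only by clone B: three short
#: pericentromeric segments on a chr1-like arm, log2 = 1 (4 copies per cell).
DEFAULT_AMP_REGIONS = (
    ("chr1", 88_000_001, 90_000_000, 1.0),
    ("chr1", 110_000_001, 111_500_000, 1.0),
    ("chr1", 118_000_001, 119_000_000, 1.0),
)

#: amplified-region genes with their expression fold over the reference
#: cohort; one candidate is ~100-fold overexpressed, others graded down to
#: unremarkable, mirroring a focal amplification whose expression effect is
#: concentrated in a handful of genes.
DEFAULT_AMP_GENES = (
    # (gene, chrom, start, end, length_bp, reference_median_rpkm, fold)
    # coordinates lie inside DEFAULT_AMP_REGIONS so the genes are amplified
    ("TBX15", "chr1", 118_100_001, 118_207_000, 3_495, 2.80, 98.0),
    ("NOTCH2", "chr1", 110_400_001, 110_558_000, 11_466, 21.22, 8.0),
    ("PTGFRN", "chr1", 111_000_001, 111_080_000, 6_160, 28.72, 8.0),
    ("CNN3", "chr1", 88_400_001, 88_431_000, 2_112, 133.00, 5.0),
    ("PHGDH", "chr1", 118_600_001, 118_684_000, 2_015, 67.87, 2.0),
    ("OLFM3", "chr1", 89_200_001, 89_468_000, 2_800, 12.00, 1.0),
    ("MAN1A2", "chr1", 110_800_001, 110_968_000, 5_100, 40.00, 2.0),
    ("WDR3", "chr1", 118_850_001, 118_899_000, 4_200, 30.00, 1.0),
)

#: library size of the simulated case transcriptome (uniquely mapped reads)
CASE_LIBRARY_SIZE = 2_000_000


@dataclass
class CohortConfig:
    """Parameters of a simulated serial cohort.

    ``clone_fractions`` maps clone label -> per-sample cell fractions; per
    sample the fractions must lie in [0, 1] and sum to <= 1, the remainder
    being normal contamination. Defaults describe four serial samples in
    which clone A (37 private variants, 5 fusion copies) dominates the first
    sample at 80% purity and clone B (21 private variants, 3 fusion copies,
    plus focal amplifications) dominates the rest, each clone persisting at a
    2% trace outside its era.
    """

    sample_labels: tuple[str, ...] = ("2007", "2009", "2010", "2013")
    clone_fractions: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "A": (0.80, 0.02, 0.02, 0.02),
            "B": (0.02, 0.80, 0.80, 0.80),
        }
    )
    n_variants_per_clone: Mapping[str, int] = field(
        default_factory=lambda: {"A": 37, "B": 21}
    )
    n_shared_variants: int = 3
    depth_mean: float = 100.0
    fusion_genes: tuple[str, str] = ("COL1A1", "PDGFB")
    fusion_breakpoint: tuple[tuple[str, int], tuple[str, int]] = (
        ("chr17", 48_262_000),
        ("chr22", 39_625_000),
    )
    fusion_copies_per_clone: Mapping[str, int] = field(
        default_factory=lambda: {"A": 5, "B": 3}
    )
    amp_regions: tuple[tuple[str, int, int, float], ...] = DEFAULT_AMP_REGIONS
    amp_clone: str = "B"
    normal_contamination_vaf: float = 0.0
    cn_bin_size: int = 100_000
    cn_window: tuple[str, int, int] = ("chr1", 85_000_001, 125_000_000)
    n_reference_expression_samples: int = 20
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.sample_labels)

    def validate(self) -> None:
        if len(set(self.sample_labels)) != len(self.sample_labels):
            raise ValueError("sample labels must be unique")
        lens = {len(f) for f in self.clone_fractions.values()}
        if lens != {self.n_samples}:
            raise ValueError("each clone needs one fraction per sample")
        fracs = np.array([list(f) for f in self.clone_fractions.values()], dtype=float)
        if (fracs < 0).any() or (fracs > 1).any():
            raise ValueError("clone fractions must lie in [0, 1]")
        sums = fracs.sum(axis=0)
        bad = np.nonzero(sums > 1 + 1e-9)[0]
        if bad.size:
            raise ValueError(
                f"clone fractions sum to {sums[bad[0]]:.3f} > 1 in sample "
                f"{self.sample_labels[bad[0]]!r}; the remainder must be normal tissue"
            )
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        if any(c < 0 for c in self.fusion_copies_per_clone.values()):
            raise ValueError("fusion copies must be >= 0")


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort.

    ``expected_vaf`` is the noise-free allele fraction of each variant in
    each sample under the local copy state: with one mutated copy on ``c_t``
    tumor copies at clone fraction ``f``,
    ``VAF = f * m / (f * c_t + (1 - f) * 2)``, which reduces to ``f / 2``
    for a heterozygous variant in a diploid region.
    """

    sample_labels: tuple[str, ...]
    clone_of_variant: dict[str, str]  # variant key -> clone label or "shared"
    clone_fractions: dict[str, tuple[float, ...]]
    purity: tuple[float, ...]  # per-sample total tumor cell fraction
    region_copies: dict[str, dict[str, float]]  # region id -> sample -> mean copies
    fusion_breakpoint: tuple[tuple[str, int], tuple[str, int]]
    fusion_copies_per_clone: dict[str, int]
    expected_vaf: pd.DataFrame  # variants x samples
    expected_fusion_log2: dict[str, float]  # sample -> mixture log2 at fusion locus

    def membership(self, presence_vaf: float = 0.10) -> pd.DataFrame:
        """Boolean truth matrix: is the variant detectable (expected VAF above
        the presence threshold) in each sample?"""
        return self.expected_vaf > presence_vaf

    def to_json(self) -> str:
        d = {
            "sample_labels": list(self.sample_labels),
            "clone_of_variant": self.clone_of_variant,
            "clone_fractions": {k: list(v) for k, v in self.clone_fractions.items()},
            "purity": list(self.purity),
            "region_copies": self.region_copies,
            "fusion_breakpoint": [list(bp) for bp in self.fusion_breakpoint],
            "fusion_copies_per_clone": self.fusion_copies_per_clone,
            "variant_order": list(self.expected_vaf.index),
            "expected_vaf": self.expected_vaf.round(10).to_dict(orient="index"),
            "expected_fusion_log2": self.expected_fusion_log2,
        }
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortTruth":
        d = json.loads(text)
        ev = pd.DataFrame.from_dict(d["expected_vaf"], orient="index")
        ev = ev.reindex(d.get("variant_order", ev.index))[d["sample_labels"]]
        return cls(
            sample_labels=tuple(d["sample_labels"]),
            clone_of_variant=d["clone_of_variant"],
            clone_fractions={k: tuple(v) for k, v in d["clone_fractions"].items()},
            purity=tuple(d["purity"]),
            region_copies=d["region_copies"],
            fusion_breakpoint=tuple(
                (c, int(p)) for c, p in d["fusion_breakpoint"]
            ),
            fusion_copies_per_clone={
                k: int(v) for k, v in d["fusion_copies_per_clone"].items()
            },
            expected_vaf=ev,
            expected_fusion_log2=d["expected_fusion_log2"],
        )


@dataclass
class SyntheticCohort:
    """Bundle of generator outputs: truth plus per-stage input tables."""

    config: CohortConfig
    truth: CohortTruth
    variant_tables: dict[str, list[VariantCall]]
    cn_bins: pd.DataFrame  # sample, chrom, start, end, tumor_count, normal_count
    fusions: pd.DataFrame  # sample, gene5, gene3, chrom5, pos5, chrom3, pos3, supporting_reads
    expression: pd.DataFrame  # gene, length_bp, count (the case sample)
    expression_reference: pd.DataFrame  # genes x reference samples, RPKM
    gene_regions: pd.DataFrame  # gene, chrom, start, end (1-based inclusive)


def _truncated_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Poisson(mean) conditioned on >= 1 (resampled, not clipped)."""
    out = rng.poisson(mean, size=size)
    while (zero := out == 0).any():
        out[zero] = rng.poisson(mean, size=int(zero.sum()))
    return out


def _expected_vaf(f: float, c_t: float = 2.0, m: float = 1.0) -> float:
    """Allele fraction of m mutated copies at clone fraction f on c_t tumor copies."""
    denom = f * c_t + (1.0 - f) * 2.0
    return f * m / denom if denom > 0 else 0.0


def _in_regions(chrom: str, pos: int, regions) -> float | None:
    for rchrom, start, end, log2 in regions:
        if chrom == rchrom and start <= pos <= end:
            return 2.0 * 2.0**log2
    return None


def simulate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Draw a full serial cohort (variants, CN bins, fusions, expression).

    Deterministic under a fixed ``config.seed``. Raises ``ValueError`` for
    configs whose clone fractions exceed 1 in any sample.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = config.sample_labels
    clones = list(config.clone_fractions)

    # --- variant truth ------------------------------------------------
    variant_meta: list[dict] = []
    clone_of: dict[str, str] = {}
    classes = list(_CLASS_PROBS)
    probs = np.array([_CLASS_PROBS[c] for c in classes])
    groups = [(cl, config.n_variants_per_clone.get(cl, 0)) for cl in clones]
    groups.append(("shared", config.n_shared_variants))
    counter = 0
    for label, n in groups:
        for _ in range(n):
            counter += 1
            chrom = f"chr{int(rng.integers(2, 20))}"  # avoid the CN window on chr1
            pos = int(rng.integers(1_000_000, 200_000_000))
            while f"{chrom[3:]}:{pos}" in {k.rsplit(":", 1)[0] for k in clone_of}:
                pos = int(rng.integers(1_000_000, 200_000_000))
            vclass = classes[int(rng.choice(len(classes), p=probs))]
            ref = _BASES[int(rng.integers(4))]
            if vclass == "deletion":
                ref, alt = ref + _BASES[int(rng.integers(4))], "-"
            elif vclass == "insertion":
                ref, alt = "-", _BASES[int(rng.integers(4))]
            else:
                alt = _BASES[int((_BASES.index(ref) + 1 + rng.integers(3)) % 4)]
            gene = f"G{counter:03d}{label if label != 'shared' else 'S'}"
            key = f"{chrom[3:]}:{pos}:{ref}>{alt}"
            variant_meta.append(
                dict(chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene, vclass=vclass, key=key)
            )
            clone_of[key] = label

    # expected VAF per variant per sample
    frac = {cl: np.asarray(config.clone_fractions[cl], dtype=float) for cl in clones}
    purity = tuple(float(sum(frac[cl][j] for cl in clones)) for j in range(len(samples)))
    exp_vaf = np.zeros((len(variant_meta), len(samples)))
    for i, v in enumerate(variant_meta):
        label = clone_of[v["key"]]
        for j in range(len(samples)):
            f = purity[j] if label == "shared" else float(frac[label][j])
            c_t = _in_regions(v["chrom"], v["pos"], config.amp_regions) if label == config.amp_clone else None
            exp_vaf[i, j] = _expected_vaf(f, c_t if c_t is not None else 2.0)
    expected_vaf = pd.DataFrame(
        exp_vaf, index=[v["key"] for v in variant_meta], columns=list(samples)
    )

    # --- read sampling -------------------------------------------------
    variant_tables: dict[str, list[VariantCall]] = {}
    for j, sid in enumerate(samples):
        depths = _truncated_poisson(rng, config.depth_mean, len(variant_meta))
        alts = rng.binomial(depths, exp_vaf[:, j])
        n_depths = _truncated_poisson(rng, config.depth_mean, len(variant_meta))
        n_alts = rng.binomial(n_depths, config.normal_contamination_vaf)
        table = [
            VariantCall(
                sample_id=sid,
                chrom=v["chrom"],
                pos=v["pos"],
                ref=v["ref"],
                alt=v["alt"],
                gene=v["gene"],
                variant_class=v["vclass"],
                t_depth=int(depths[i]),
                t_alt=int(alts[i]),
                n_depth=int(n_depths[i]),
                n_alt=int(n_alts[i]),
            )
            for i, v in enumerate(variant_meta)
        ]
        variant_tables[sid] = table

    # --- copy-number bins ----------------------------------------------
    amp_copies = {f"{c}:{s}-{e}": 2.0 * 2.0**l for c, s, e, l in config.amp_regions}
    region_copies: dict[str, dict[str, float]] = {rid: {} for rid in amp_copies}
    fus_chrom, fus_pos = config.fusion_breakpoint[1]  # 3' partner carries the gain
    fusion_window = (fus_chrom, fus_pos - 1_000_000 + 1, fus_pos + 1_000_000)

    windows = [config.cn_window, fusion_window]
    rows = []
    fusion_log2: dict[str, float] = {}
    for j, sid in enumerate(samples):
        f_amp = float(frac[config.amp_clone][j])
        # mean tumor copy number at a locus given the clone mixture
        def mix_copies(chrom: str, mid: int) -> float:
            c = 2.0 * (1.0 - purity[j])  # normal cells
            for cl in clones:
                cc = 2.0
                if cl == config.amp_clone:
                    amp = _in_regions(chrom, mid, config.amp_regions)
                    if amp is not None:
                        cc = amp
                if chrom == fus_chrom and fusion_window[1] <= mid <= fusion_window[2]:
                    cc = float(config.fusion_copies_per_clone.get(cl, 2))
                c += float(frac[cl][j]) * cc
            return c

        for wchrom, wstart, wend in windows:
            starts = np.arange(wstart, wend, config.cn_bin_size)
            for s in starts:
                e = min(int(s) + config.cn_bin_size - 1, wend)
                mid = (int(s) + e) // 2
                copies = mix_copies(wchrom, mid)
                normal_count = int(rng.poisson(config.depth_mean))
                tumor_count = int(rng.poisson(config.depth_mean * copies / 2.0))
                rows.append(
                    dict(sample=sid, chrom=wchrom, start=int(s), end=e,
                         tumor_count=tumor_count, normal_count=normal_count)
                )
        for rid, (rchrom, rstart, rend, _l) in zip(amp_copies, config.amp_regions):
            region_copies[rid][sid] = mix_copies(rchrom, (rstart + rend) // 2)
        fusion_log2[sid] = float(np.log2(mix_copies(fus_chrom, fus_pos) / 2.0))
    cn_bins = pd.DataFrame(rows)

    # --- fusion records --------------------------------------------------
    (g5chrom, g5pos), (g3chrom, g3pos) = config.fusion_breakpoint
    fusions = pd.DataFrame(
        {
            "sample": list(samples),
            "gene5": config.fusion_genes[0],
            "gene3": config.fusion_genes[1],
            "chrom5": g5chrom,
            "pos5": g5pos,
            "chrom3": g3chrom,
            "pos3": g3pos,
            "supporting_reads": [
                int(rng.poisson(config.depth_mean * 2.0 ** fusion_log2[s] / 4.0)) + 1
                for s in samples
            ],
        }
    )

    # --- expression ------------------------------------------------------
    total_case = CASE_LIBRARY_SIZE
    genes, exp_rows, ref_rows, region_rows = [], [], [], []
    for gene, chrom, start, end, length, ref_median, fold in DEFAULT_AMP_GENES:
        genes.append(gene)
        case_rpkm = ref_median * fold
        lam = case_rpkm * (length / 1000.0) * (total_case / 1e6)
        exp_rows.append(
            dict(gene=gene, length_bp=length, count=int(rng.poisson(lam)),
                 total_mapped=total_case)
        )
        ref = rng.gamma(shape=100.0, scale=ref_median / 100.0,
                        size=config.n_reference_expression_samples)
        ref_rows.append(ref)
        region_rows.append(dict(gene=gene, chrom=chrom, start=start, end=end))
    expression = pd.DataFrame(exp_rows)
    expression_reference = pd.DataFrame(
        np.array(ref_rows),
        index=genes,
        columns=[f"REF{i + 1:02d}" for i in range(config.n_reference_expression_samples)],
    )
    gene_regions = pd.DataFrame(region_rows)

    truth = CohortTruth(
        sample_labels=tuple(samples),
        clone_of_variant=clone_of,
        clone_fractions={cl: tuple(map(float, frac[cl])) for cl in clones},
        purity=purity,
        region_copies=region_copies,
        fusion_breakpoint=config.fusion_breakpoint,
        fusion_copies_per_clone=dict(config.fusion_copies_per_clone),
        expected_vaf=expected_vaf,
        expected_fusion_log2=fusion_log2,
    )
    return SyntheticCohort(
        config=config,
        truth=truth,
        variant_tables=variant_tables,
        cn_bins=cn_bins,
        fusions=fusions,
        expression=expression,
        expression_reference=expression_reference,
        gene_regions=gene_regions,
    )


def simulate_catalog(
    n_records: int,
    n_genes: int = 40,
    seed: int = 0,
    missing_support_rate: float = 0.05,
):
    """Random reference-catalog records for exercising catalog analytics.

    Classes span the full vocabulary (coding and excluded types), read
    support is uniform over 0-60 so roughly half the records fail the
    20-read competence cut, and a small fraction lack support fields
    entirely. Returns a list of :class:`~serialclones.catalog.CatalogRecord`.
    """
    from .catalog import CatalogRecord

    rng = np.random.default_rng(seed)
    classes = list(_CLASS_PROBS) + ["splice", "UTR", "RNA", "other"]
    genes = [f"CG{i:03d}" for i in range(n_genes)]
    records = []
    for _ in range(n_records):
        no_support = rng.random() < missing_support_rate
        depth = None if no_support else int(rng.integers(0, 61))
        ratio = None if no_support else float(np.round(rng.random(), 3))
        records.append(
            CatalogRecord(
                gene=genes[int(rng.integers(n_genes))],
                chrom=f"chr{int(rng.integers(1, 23))}",
                pos=int(rng.integers(1, 5_000_000)),
                ref=_BASES[int(rng.integers(4))],
                alt=_BASES[int(rng.integers(4))],
                variant_class=classes[int(rng.integers(len(classes)))],
                depth=depth,
                alt_ratio=ratio,
            )
        )
    return records


def write_fixtures(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort to disk in the plain-text formats the readers consume.

    Emits one MAF-like TSV per sample, the CN bin table, a SEG file of the
    truth-expected log2 per amplified region (usable as a precomputed-segment
    bypass), the fusion TSV, expression tables, gene regions, and the truth
    JSON. Returns the path of each artifact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sid, calls in cohort.variant_tables.items():
        p = out / f"variants_{sid}.maf.tsv"
        calls_to_frame(calls).to_csv(p, sep="\t", index=False)
        paths[f"variants_{sid}"] = p

    p = out / "cn_bins.tsv"
    cohort.cn_bins.to_csv(p, sep="\t", index=False)
    paths["cn_bins"] = p

    seg_rows = []
    for rid, per_sample in cohort.truth.region_copies.items():
        chrom, span = rid.split(":")
        start, end = (int(x) for x in span.split("-"))
        for sid, copies in per_sample.items():
            seg_rows.append(
                dict(sample=sid, chrom=chrom, start=start, end=end,
                     log2=float(np.log2(copies / 2.0)))
            )
    p = out / "truth_segments.seg"
    pd.DataFrame(seg_rows).to_csv(p, sep="\t", index=False)
    paths["truth_segments"] = p

    for name, df in (
        ("fusions", cohort.fusions),
        ("expression", cohort.expression),
        ("gene_regions", cohort.gene_regions),
    ):
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p

    p = out / "expression_reference.tsv"
    cohort.expression_reference.to_csv(p, sep="\t", index_label="gene")
    paths["expression_reference"] = p

    p = out / "truth.json"
    p.write_text(cohort.truth.to_json())
    paths["truth"] = p
    return paths
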