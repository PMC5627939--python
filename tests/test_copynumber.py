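"""Log2 segmentation, focal amplification calling, copy estimation,
and fusion-breakpoint concordance."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import serialclones as sc
from serialclones.copynumber import CnSegment, FusionEvent


def _bins(counts, bin_size=100_000, chrom="chr1"):
    starts = np.arange(1, len(counts) * bin_size, bin_size)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + bin_size - 1,
            "count": list(counts),
        }
    )


class TestLog2Segmentation:
    def test_identical_coverage_is_flat_zero(self):
        normal = _bins([100] * 50)
        segs = sc.compute_log2_ratios(normal, normal)
        assert len(segs) == 1
        assert segs[0].log2_ratio == pytest.approx(0.0, abs=1e-9)

    def test_uniform_doubling_without_normalization(self):
        normal = _bins([100] * 30)
        tumor = _bins([200] * 30)
        (seg,) = sc.compute_log2_ratios(tumor, normal, normalize=False)
        assert seg.log2_ratio == pytest.approx(1.0, abs=1e-9)

    def test_global_library_scaling_invariance(self):
        rng = np.random.default_rng(3)
        normal = _bins(rng.poisson(100, 80))
        tumor = _bins(rng.poisson(100, 80))
        tumor.loc[30:45, "count"] *= 2
        a = sc.compute_log2_ratios(tumor, normal)
        scaled = tumor.assign(count=tumor["count"] * 7)
        b = sc.compute_log2_ratios(scaled, normal)
        assert [(s.start, s.end) for s in a] == [(s.start, s.end) for s in b]
        assert all(
            x.log2_ratio == pytest.approx(y.log2_ratio, abs=1e-9) for x, y in zip(a, b)
        )

    def test_zero_normal_bins_masked_not_infinite(self):
        normal = _bins([100] * 10 + [0] * 3 + [100] * 10)
        tumor = _bins([100] * 23)
        segs = sc.compute_log2_ratios(tumor, normal)
        assert all(np.isfinite(s.log2_ratio) for s in segs)
        assert sum(s.n_bins for s in segs) == 20  # masked bins excluded

    def test_amp_region_recovered_within_tenth(self):
        """A clone-private 2 Mb amplification simulated at log2 = 1 is
        recovered by segmentation within +-0.1 in the fully clonal sample."""
        cfg = sc.CohortConfig(
            sample_labels=("t1", "t2"),
            clone_fractions={"A": (1.0, 0.0), "B": (0.0, 1.0)},
            amp_regions=(("chr1", 100_000_001, 102_000_000, 1.0),),
            n_shared_variants=0,
            seed=13,
        )
        cohort = sc.simulate_cohort(cfg)
        bins = cohort.cn_bins
        sub = bins[(bins["sample"] == "t2") & (bins["chrom"] == "chr1")]
        tumor = sub[["chrom", "start", "end", "tumor_count"]].rename(
            columns={"tumor_count": "count"}
        )
        normal = sub[["chrom", "start", "end", "normal_count"]].rename(
            columns={"normal_count": "count"}
        )
        segs = sc.compute_log2_ratios(tumor, normal, sample_id="t2")
        hits = [
            s for s in segs
            if s.start <= 101_000_000 <= s.end and s.log2_ratio > 0.5
        ]
        assert len(hits) == 1
        assert hits[0].log2_ratio == pytest.approx(1.0, abs=0.1)


class TestFocalAmplifications:
    def test_flat_genome_yields_nothing(self):
        segs = [CnSegment("s", "chr1", 1, 10_000_000, 0.0, 100)]
        assert sc.call_focal_amplifications(segs) == []

    def test_broad_gain_excluded_by_span(self):
        segs = [CnSegment("s", "chr1", 1, 50_000_000, 0.6, 500)]
        assert sc.call_focal_amplifications(segs) == []

    def test_threshold_inclusive(self):
        segs = [CnSegment("s", "chr1", 1, 2_000_000, 0.5, 20)]
        assert len(sc.call_focal_amplifications(segs)) == 1

    def test_clone_private_amp_detected_only_after_replacement(self, case_report):
        """The amplifications carried only by the incoming clone appear in the
        post-replacement samples and never in the first sample."""
        amps = case_report.focal_amplifications
        samples = list(amps)
        chr1 = {s: [a for a in amps[s] if a["chrom"] == "chr1"] for s in samples}
        assert chr1[samples[0]] == []
        for s in samples[1:]:
            assert len(chr1[s]) == 3


class TestAbsoluteCopies:
    @pytest.mark.parametrize(
        "log2,copies", [(1.4, 5), (0.5, 3), (0.0, 2), (1.0, 4), (-1.0, 1)]
    )
    def test_pure_tumor_conversions(self, log2, copies):
        assert sc.estimate_absolute_copies(log2) == copies

    def test_purity_correction(self):
        # 82% tumor mixing 5 copies with diploid normal: log2((0.82*5+0.36)/2)
        log2 = np.log2((0.82 * 5 + 0.18 * 2) / 2)
        assert sc.estimate_absolute_copies(log2, purity=0.82) == 5

    def test_invalid_purity_rejected(self):
        with pytest.raises(ValueError, match="purity"):
            sc.estimate_absolute_copies(1.0, purity=0.0)

    @given(st.floats(min_value=-2, max_value=4))
    @settings(max_examples=80, deadline=None)
    def test_monotone_in_log2(self, l):
        assert sc.estimate_absolute_copies(l + 0.25) >= sc.estimate_absolute_copies(l)

    @given(st.integers(min_value=1, max_value=64))
    @settings(max_examples=40, deadline=None)
    def test_inverse_round_trip_at_full_purity(self, copies):
        l = np.log2(copies / 2)
        assert sc.estimate_absolute_copies(l) == copies


def _event(sample, pos5=48_262_000, pos3=39_625_000, genes=("COL1A1", "PDGFB"), copy=None):
    return FusionEvent(
        sample_id=sample, gene5=genes[0], gene3=genes[1],
        chrom5="chr17", breakpoint5=pos5, chrom3="chr22", breakpoint3=pos3,
        supporting_reads=10, copy_estimate=copy,
    )


class TestBreakpointConcordance:
    def test_identical_coordinates_concordant(self):
        rep = sc.breakpoint_concordance([_event(f"s{i}") for i in range(4)])
        assert rep.concordant and rep.common_founder

    def test_offset_beyond_tolerance_discordant(self):
        rep = sc.breakpoint_concordance([_event("a"), _event("b", pos3=39_625_100)])
        assert not rep.concordant

    def test_tolerance_window_allows_small_offsets(self):
        rep = sc.breakpoint_concordance(
            [_event("a"), _event("b", pos3=39_625_050)], tolerance_bp=100
        )
        assert rep.concordant

    def test_mixed_gene_pairs_rejected(self):
        with pytest.raises(ValueError, match="mixed gene pairs"):
            sc.breakpoint_concordance(
                [_event("a"), _event("b", genes=("COL1A2", "PDGFB"))]
            )

    def test_concordant_with_heterogeneous_copies(self):
        """Identical breakpoints with per-sample copies derived from log2
        ratios {1.4, 0.5, 0.5, 0.5} report concordance alongside the copy
        heterogeneity 5,3,3,3."""
        copies = [sc.estimate_absolute_copies(l) for l in (1.4, 0.5, 0.5, 0.5)]
        events = [_event(f"s{i}", copy=c) for i, c in enumerate(copies)]
        rep = sc.breakpoint_concordance(events)
        assert rep.concordant
        assert rep.copy_estimates == [5, 3, 3, 3]

    def test_transitive_at_zero_tolerance(self):
        """If A~B and B~C pairwise at tolerance 0 then {A,B,C} is concordant."""
        a, b, c = _event("a"), _event("b"), _event("c")
        for pair in itertools.combinations([a, b, c], 2):
            assert sc.breakpoint_concordance(list(pair)).concordant
        assert sc.breakpoint_concordance([a, b, c]).concordant


class TestSegIO:
    def test_round_trip(self, tmp_path):
        segs = [
            CnSegment("s1", "chr1", 1, 100, 0.5, 3),
            CnSegment("s2", "chr2", 50, 99, -0.3, 1),
        ]
        p = tmp_path / "t.seg"
        sc.write_seg(segs, p)
        back = sc.read_seg(p)
        assert [(s.sample_id, s.chrom, s.start, s.end, s.n_bins) for s in back] == [
            ("s1", "chr1", 1, 100, 3), ("s2", "chr2", 50, 99, 1)
        ]
        assert back[0].log2_ratio == pytest.approx(0.5)
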