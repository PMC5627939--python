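"""Variant reading, somatic filtering, and cross-sample harmonization."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import serialclones as sc
from serialclones.variants import VariantCall

MAF_HEADER = (
    "Hugo_Symbol\tChromosome\tStart_Position\tReference_Allele\t"
    "Tumor_Seq_Allele2\tVariant_Classification\tAA_Change\t"
    "t_depth\tt_alt_count\tn_depth\tn_alt_count\n"
)


def _call(t_depth=100, t_alt=40, n_depth=100, n_alt=0, pos=100, **kw):
    base = dict(
        sample_id="s1", chrom="chr1", pos=pos, ref="T", alt="A",
        gene="GX", variant_class="missense",
        t_depth=t_depth, t_alt=t_alt, n_depth=n_depth, n_alt=n_alt,
    )
    base.update(kw)
    return VariantCall(**base)


class TestReadMaf:
    def test_tsv_row_yields_call_with_vaf(self, tmp_path):
        """A missense row at chr1:158644387 T>A with 30/100 reads reads back
        with VAF 0.30 and the dash-free key."""
        p = tmp_path / "t.maf.tsv"
        p.write_text(
            MAF_HEADER
            + "SPTA1\tchr1\t158644387\tT\tA\tmissense\tE397V\t100\t30\t80\t0\n"
        )
        (call,) = sc.read_variant_table(p, "maf_tsv")
        assert (call.gene, call.chrom, call.pos) == ("SPTA1", "chr1", 158644387)
        assert (call.ref, call.alt, call.aa_change) == ("T", "A", "E397V")
        assert call.vaf == pytest.approx(0.30)

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "empty.maf.tsv"
        p.write_text(MAF_HEADER)
        assert sc.read_variant_table(p, "maf_tsv") == []

    def test_missing_columns_name_the_problem(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("Hugo_Symbol\tChromosome\nA\tchr1\n")
        with pytest.raises(ValueError, match="missing columns"):
            sc.read_variant_table(p, "maf_tsv")

    def test_negative_counts_rejected(self, tmp_path):
        p = tmp_path / "neg.maf.tsv"
        p.write_text(
            MAF_HEADER + "GX\tchr1\t100\tT\tA\tmissense\t.\t-5\t0\t10\t0\n"
        )
        with pytest.raises(ValueError, match="negative"):
            sc.read_variant_table(p, "maf_tsv")


class TestReadVcf:
    def test_ad_dp_mapping(self, tmp_path):
        """DP=50 with AD=35,15 maps to t_depth 50, t_alt 15, VAF 0.30."""
        p = tmp_path / "t.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="depth">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="allele depths">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\n"
            "chr2\t500\t.\tG\tC\t.\tPASS\t.\tDP:AD\t50:35,15\n"
        )
        (call,) = sc.read_variant_table(p, "vcf")
        assert (call.t_depth, call.t_alt) == (50, 15)
        assert call.vaf == pytest.approx(0.30)

    def test_deletion_normalized_to_dash(self, tmp_path):
        p = tmp_path / "d.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\n"
            "chr14\t58831339\t.\tCAA\tC\t.\tPASS\t.\tDP:AD\t60:40,20\n"
        )
        (call,) = sc.read_variant_table(p, "vcf")
        assert (call.pos, call.ref, call.alt) == (58831340, "AA", "-")
        assert call.variant_class == "deletion"


class TestFilterSomatic:
    @pytest.mark.parametrize(
        "t_depth,t_alt,n_depth,n_alt,kept",
        [
            (19, 10, 100, 0, False),   # one read short of 20x coverage
            (20, 4, 100, 0, True),     # both thresholds inclusive (>=)
            (100, 40, 50, 1, False),   # any variant evidence in blood
            (100, 40, 100, 0, True),
            (100, 19, 100, 0, False),  # VAF 0.19 below 20%
        ],
    )
    def test_threshold_boundaries(self, t_depth, t_alt, n_depth, n_alt, kept):
        calls = [_call(t_depth=t_depth, t_alt=t_alt, n_depth=n_depth, n_alt=n_alt)]
        out, _ = sc.filter_somatic(calls)
        assert (len(out) == 1) is kept

    def test_normal_unevaluable_excluded_and_counted(self):
        out, report = sc.filter_somatic([_call(n_depth=0, n_alt=0)])
        assert out == []
        assert report.n_normal_unevaluable == 1

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 60), st.floats(0, 1), st.integers(0, 60), st.booleans()
            ),
            max_size=40,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_idempotent_and_monotone(self, raw):
        calls = [
            _call(
                t_depth=d, t_alt=int(round(d * f)), n_depth=nd,
                n_alt=1 if (evid and nd > 0) else 0, pos=i + 1,
            )
            for i, (d, f, nd, evid) in enumerate(raw)
        ]
        once, _ = sc.filter_somatic(calls)
        twice, _ = sc.filter_somatic(once)
        assert twice == once
        stricter, _ = sc.filter_somatic(calls, min_depth=30)
        assert set(c.key for c in stricter) <= set(c.key for c in once)


class TestHarmonize:
    def _tables(self, rows):
        """rows: dict key->list of (depth, alt) per sample (None = no record)."""
        tables = {}
        n_samples = len(next(iter(rows.values())))
        for j in range(n_samples):
            sid = f"s{j + 1}"
            calls = []
            for i, (key, cells) in enumerate(rows.items()):
                if cells[j] is None:
                    continue
                d, a = cells[j]
                calls.append(_call(t_depth=d, t_alt=a, pos=1000 + i, sample_id=sid))
            tables[sid] = calls
        return tables

    def test_depth_failure_in_one_sample_drops_variant(self):
        tables = self._tables({"v1": [(25, 10), (25, 10), (19, 10), (25, 10)]})
        m = sc.harmonize_across_samples(tables)
        assert len(m.vaf) == 0

    def test_private_variant_keeps_zero_cells(self):
        tables = self._tables({"v1": [(50, 20), (50, 0), (50, 0), (50, 0)]})
        m = sc.harmonize_across_samples(tables)
        assert list(m.vaf.iloc[0]) == pytest.approx([0.4, 0.0, 0.0, 0.0])

    def test_missing_record_distinct_from_zero_when_filter_off(self):
        tables = self._tables({"v1": [(50, 20), None]})
        m = sc.harmonize_across_samples(tables, min_depth_all=0)
        assert np.isnan(m.vaf.iloc[0, 1]) and m.vaf.iloc[0, 0] == pytest.approx(0.4)

    def test_duplicate_key_in_sample_raises(self):
        dup = [_call(pos=5), _call(pos=5)]
        with pytest.raises(ValueError, match="duplicate variant key"):
            sc.harmonize_across_samples({"s1": dup, "s2": []})

    def test_sample_order_invariance(self, default_cohort):
        tables = default_cohort.variant_tables
        fwd = sc.harmonize_across_samples(tables)
        rev = sc.harmonize_across_samples(dict(reversed(list(tables.items()))))
        assert list(fwd.vaf.index) == list(rev.vaf.index)
        assert fwd.vaf.equals(rev.vaf[fwd.vaf.columns])

    def test_retained_set_matches_bruteforce_on_cohort(self, default_cohort):
        """Competence retention equals an independent scan over per-sample depths."""
        tables = default_cohort.variant_tables
        m = sc.harmonize_across_samples(tables, min_depth_all=20)
        expected = set.intersection(
            *[
                {c.key for c in calls if c.t_depth >= 20}
                for calls in tables.values()
            ]
        )
        assert set(m.vaf.index) == expected
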