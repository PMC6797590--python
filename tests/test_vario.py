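from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from offtarget_burden.cohortsim import SimConfig, build_cohort, simulate_founders
from offtarget_burden.vario import (
    Cohort,
    GenomicInterval,
    IntervalSet,
    Sample,
    VariantCall,
    VariantKey,
    left_normalize,
    read_bed,
    read_sample_sheet,
    read_vcf,
    write_bed,
    write_sample_sheet,
    write_vcf,
)


# ---------------------------------------------------------------------------
# Domain-type invariants
# ---------------------------------------------------------------------------


class TestDomainTypes:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="", start=0, end=1),
            dict(chrom="chr1", start=-1, end=5),
            dict(chrom="chr1", start=5, end=5),
            dict(chrom="chr1", start=8, end=5),
        ],
    )
    def test_interval_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            GenomicInterval(**kwargs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="chr1", pos=3, ref="A", alt="A"),
            dict(chrom="chr1", pos=3, ref="", alt="A"),
            dict(chrom="chr1", pos=3, ref="AN", alt="A"),
            dict(chrom="chr1", pos=-1, ref="A", alt="G"),
        ],
    )
    def test_variant_key_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            VariantKey(**kwargs)

    def test_call_strand_consistency(self):
        key = VariantKey("chr1", 5, "A", "G")
        with pytest.raises(ValueError):
            VariantCall(key, "s", "c", depth=10, alt_depth=4, af=0.4,
                        alt_fwd=3, alt_rev=2)
        call = VariantCall(key, "s", "c", depth=10, alt_depth=4, af=0.4)
        assert call.both_strands is None  # unknown strand -> rules abstain


# ---------------------------------------------------------------------------
# Left-normalization
# ---------------------------------------------------------------------------


class TestLeftNormalize:
    def test_deletion_shifts_to_leftmost_equivalent_placement(self):
        # deleting one C of the CCC run: valid placements of (CC -> C) are
        # pos 1 and pos 2; the leftmost (enumerated by hand) is pos 1
        key = left_normalize("GCCCA", 2, "CC", "C", chrom="chr1")
        assert (key.pos, key.ref, key.alt) == (1, "CC", "C")

    def test_snv_unchanged(self):
        key = left_normalize("GCCCAT", 5, "T", "A", chrom="chr1")
        assert (key.pos, key.ref, key.alt) == (5, "T", "A")

    def test_shared_prefix_trimmed(self):
        key = left_normalize("GCATGG", 2, "AT", "AG", chrom="chr1")
        assert (key.pos, key.ref, key.alt) == (3, "T", "G")

    def test_ref_mismatch_fails(self):
        with pytest.raises(ValueError, match="does not match"):
            left_normalize("GCCCA", 0, "TT", "T", chrom="chr1")

    def test_insertion_in_repeat_run_shifts_left(self):
        #      0123456789
        ctx = "GATATATACC"
        key = left_normalize(ctx, 7, "A", "ATA", chrom="chr1")
        assert (key.pos, key.ref, key.alt) == (1, "A", "ATA")

    @given(
        ctx=st.text(alphabet="ACGT", min_size=8, max_size=40),
        pos=st.integers(min_value=0, max_value=35),
        ref_len=st.integers(min_value=1, max_value=3),
        alt=st.text(alphabet="ACGT", min_size=1, max_size=3),
    )
    def test_idempotent(self, ctx, pos, ref_len, alt):
        if pos + ref_len > len(ctx):
            return
        ref = ctx[pos : pos + ref_len]
        if ref == alt:
            return
        key = left_normalize(ctx, pos, ref, alt, chrom="chr1")
        again = left_normalize(ctx, key.pos, key.ref, key.alt, chrom="chr1")
        assert again == key


# ---------------------------------------------------------------------------
# IntervalSet
# ---------------------------------------------------------------------------


class TestIntervalSet:
    def test_merge_overlapping_and_abutting(self):
        s = IntervalSet([
            GenomicInterval("chr1", 10, 20),
            GenomicInterval("chr1", 15, 30),
            GenomicInterval("chr1", 30, 35),
            GenomicInterval("chr2", 5, 8),
        ])
        assert s.intervals() == [
            GenomicInterval("chr1", 10, 35),
            GenomicInterval("chr2", 5, 8),
        ]
        assert s.total_bp == 28

    @given(
        raw=st.lists(
            st.tuples(st.integers(0, 1990), st.integers(1, 60)),
            min_size=0, max_size=25,
        ),
        probes=st.lists(st.integers(0, 2100), min_size=1, max_size=30),
    )
    def test_membership_matches_per_base_scan(self, raw, probes):
        intervals = [GenomicInterval("c", a, a + w) for a, w in raw]
        s = IntervalSet(intervals)
        covered = set()
        for iv in intervals:
            covered.update(range(iv.start, iv.end))
        for p in probes:
            assert s.overlaps("c", p) == (p in covered)
        assert s.total_bp == len(covered)

    def test_expand_clips_at_bounds(self):
        s = IntervalSet([GenomicInterval("chr1", 5, 10)])
        e = s.expand(20, {"chr1": 25})
        assert e.intervals() == [GenomicInterval("chr1", 0, 25)]

    def test_intersection(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 100)])
        b = IntervalSet([GenomicInterval("chr1", 50, 150),
                         GenomicInterval("chr2", 0, 10)])
        assert a.intersection(b).intervals() == [GenomicInterval("chr1", 50, 100)]


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------


class TestBed:
    def test_merge_on_read(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\nchr1\t15\t30\n")
        s = read_bed(p)
        assert s.intervals() == [GenomicInterval("chr1", 10, 30)]
        assert s.total_bp == 20

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        s = read_bed(p)
        assert s.total_bp == 0 and len(s) == 0

    def test_inverted_interval_names_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t20\t10\n")
        with pytest.raises(ValueError, match="line 1"):
            read_bed(p)

    def test_round_trip(self, tmp_path):
        s = IntervalSet([
            GenomicInterval("chr1", 3, 9),
            GenomicInterval("chr1", 40, 55),
            GenomicInterval("chr2", 0, 7),
        ])
        write_bed(s, tmp_path / "rt.bed")
        assert read_bed(tmp_path / "rt.bed") == s

    def test_extra_columns_preserved(self, tmp_path):
        p = tmp_path / "b6.bed"
        p.write_text("chr1\t10\t33\tguideA:crispor\t520\t+\n")
        s = read_bed(p)
        rec = s.records[0]
        assert rec.name == "guideA:crispor"
        assert rec.score == 520.0


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


class TestVcf:
    def test_coordinate_shift_and_af(self, tmp_path):
        p = tmp_path / "one.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tDP:AD\t50:30,20\n"
        )
        calls = read_vcf(p, caller_id="c")
        assert len(calls) == 1
        c = calls[0]
        assert (c.key.pos, c.key.ref, c.key.alt) == (99, "A", "G")
        assert (c.depth, c.alt_depth) == (50, 20)
        assert c.af == pytest.approx(0.4)
        assert not c.strand_known

    def test_multiallelic_split(self, tmp_path):
        p = tmp_path / "ma.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chr1\t100\t.\tA\tG,T\t.\tPASS\t.\tDP:AD\t60:30,20,10\n"
        )
        calls = read_vcf(p)
        assert [(c.key.alt, c.alt_depth) for c in calls] == [("G", 20), ("T", 10)]
        assert len({(c.key.chrom, c.key.pos) for c in calls}) == 1

    def test_zero_depth_rejected(self, tmp_path, caplog):
        p = tmp_path / "dp0.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tDP:AD\t0:0,0\n"
        )
        with caplog.at_level("WARNING"):
            calls = read_vcf(p)
        assert calls == []
        assert "zero depth" in caplog.text

    def test_write_read_round_trip(self, tmp_path):
        calls = [
            VariantCall(VariantKey("chr1", 42, "A", "G"), "s1", "c",
                        depth=80, alt_depth=40, af=0.5, alt_fwd=22, alt_rev=18),
            VariantCall(VariantKey("chr1", 99, "CC", "C"), "s1", "c",
                        depth=60, alt_depth=12, af=0.2),
            VariantCall(VariantKey("chr2", 7, "T", "A"), "s1", "c",
                        depth=30, alt_depth=9, af=0.3, alt_fwd=4, alt_rev=5),
        ]
        path = tmp_path / "s1.c.vcf"
        write_vcf(calls, path, contigs={"chr1": 1000, "chr2": 500})
        back = read_vcf(path, sample_id="s1", caller_id="c")
        assert {(c.key, c.depth, c.alt_depth, c.alt_fwd, c.alt_rev)
                for c in back} == {
            (c.key, c.depth, c.alt_depth, c.alt_fwd, c.alt_rev) for c in calls
        }


# ---------------------------------------------------------------------------
# Sample sheet / cohort
# ---------------------------------------------------------------------------


class TestSampleSheet:
    def test_default_cohort_has_study_arm_sizes(self, tmp_path):
        config = SimConfig(seed=0, capture_bp=10_000, founder_het_density=0.0)
        founders = simulate_founders(config)
        cohort = build_cohort(config, founders.guides)
        assert len(cohort) == 70  # 2 parents + 52 F0 + 16 F1
        assert len(cohort.generation("F0")) == 52
        assert len(cohort.generation("F1")) == 16
        write_sample_sheet(cohort, tmp_path / "sheet.tsv")
        again = read_sample_sheet(tmp_path / "sheet.tsv")
        assert again.samples == cohort.samples

    def test_edited_requires_guide(self):
        with pytest.raises(ValueError, match="guide_id"):
            Cohort([Sample("x", "F0", "edited", "")])

    def test_duplicate_sample_id(self):
        with pytest.raises(ValueError, match="duplicate"):
            Cohort([Sample("x", "parent", "uninjected"),
                    Sample("x", "parent", "uninjected")])

    def test_dangling_parent_reference(self):
        with pytest.raises(ValueError, match="dangling"):
            Cohort([Sample("kid", "F0", "uninjected", "", ("ghost",))])

    def test_unknown_condition(self):
        with pytest.raises(ValueError, match="condition"):
            Cohort([Sample("x", "F0", "mock_injected")])
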