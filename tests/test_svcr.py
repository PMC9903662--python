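"""Sparse representation: conversion, merging, densification, round trips."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from svcrkit.gvcf_io import (
    NON_REF,
    GQ_BINS,
    GvcfRecord,
    bin_and_merge_blocks,
    bin_reference_gq,
    render_gvcf,
)
from svcrkit.svcr import (
    Locus,
    SvcrDataset,
    SvcrEntry,
    SvcrRow,
    densify,
    export_pvcf,
    genotype_index,
    genotype_tuples,
    gvcf_to_svcr,
    hierarchical_merge,
    merge_alleles,
    merge_rounds,
    merge_svcr,
    project_pl_to_local,
    read_pvcf,
    svcr_to_gvcf,
    _expand_call,
)

CONTIGS = [("chr1", 1000)]


def block(pos, end, gq=45, dp=30, contig="chr1"):
    return GvcfRecord(contig, pos, "A", (), (0, 0), gq, dp, end=end)


def variant(pos, alts=("T",), gt=(0, 1), ad=None, pl=None, gq=99, dp=30, contig="chr1"):
    alts = tuple(alts) + (NON_REF,)
    n = len(alts) + 1
    ad = ad or tuple([15] * 2 + [0] * (n - 2))
    if pl is None:
        pl = tuple(range(0, 10 * (n * (n + 1) // 2), 10))
    return GvcfRecord(contig, pos, "A", alts, gt, gq, dp, ad=ad, pl=pl)


class TestGqBinning:
    @pytest.mark.parametrize(
        "gq,expected", [(37, 30), (99, 60), (0, 0), (9, 0), (10, 10), (60, 60), (61, 60)]
    )
    def test_floor_to_bin_with_cap(self, gq, expected):
        assert bin_reference_gq(gq) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            bin_reference_gq(-1)

    @given(st.integers(min_value=0, max_value=500))
    def test_result_is_largest_bin_at_or_below(self, gq):
        b = bin_reference_gq(gq)
        assert b in GQ_BINS
        assert b <= gq
        assert all(other <= b or other > gq for other in GQ_BINS)

    def test_adjacent_same_bin_blocks_coalesce(self):
        merged = bin_and_merge_blocks([block(0, 50, gq=41), block(50, 90, gq=47)])
        assert merged == [block(0, 90, gq=40)]

    def test_different_bin_blocks_stay_separate(self):
        merged = bin_and_merge_blocks([block(0, 50, gq=41), block(50, 90, gq=52)])
        assert [b.gq for b in merged] == [40, 50]
        assert len(merged) == 2


class TestGvcfToSvcr:
    def test_record_count_preserved(self):
        records = [
            block(0, 100, gq=30),
            variant(100),
            block(101, 200, gq=45),
            variant(200, gt=(1, 1)),
            block(201, 300, gq=55),
        ]
        ds = gvcf_to_svcr("S1", records, CONTIGS)
        assert len(ds.rows) == 5
        assert ds.samples == ["S1"]
        assert all(len(r.entries) == 1 for r in ds.rows)

    def test_identity_relabeling_of_variant_fields(self):
        rec = variant(10, alts=("T",), gt=(0, 1), ad=(7, 5, 0), pl=(99, 0, 88, 120, 130, 140))
        ds = gvcf_to_svcr("S1", [rec], CONTIGS)
        entry = ds.rows[0].entries["S1"]
        assert entry.la == (0, 1, 2)
        assert entry.lgt == (0, 1)
        assert entry.lad == (7, 5, 0)
        assert entry.lpl == (99, 0, 88, 120, 130, 140)
        assert ds.rows[0].alts == ("T", NON_REF)

    def test_unsorted_input_names_offending_locus(self):
        with pytest.raises(ValueError, match="chr1:51"):
            gvcf_to_svcr("S1", [variant(100), variant(50)], CONTIGS)

    def test_overlapping_variant_records_rejected(self):
        ins = GvcfRecord(
            "chr1", 10, "AC", ("A", NON_REF), (0, 1), 50, 30, ad=(9, 9, 0),
            pl=(50, 0, 60, 70, 80, 90),
        )
        with pytest.raises(ValueError, match="overlapping"):
            gvcf_to_svcr("S1", [ins, variant(11)], CONTIGS)


class TestMergeAlleles:
    def test_lexicographic_union_with_maps(self):
        (ref, alts), maps = merge_alleles([("A", ("T",)), ("A", ("C",))])
        assert (ref, alts) == ("A", ("C", "T"))
        assert maps == [(0, 2), (0, 1)]

    def test_single_input_identity(self):
        (ref, alts), maps = merge_alleles([("A", ("G", "T"))])
        assert alts == ("G", "T")
        assert maps == [(0, 1, 2)]

    def test_idempotent_on_equal_inputs(self):
        sets = [("A", ("T", NON_REF)), ("A", ("T", NON_REF))]
        (ref, alts), maps = merge_alleles(sets)
        assert alts == ("T", NON_REF)
        assert maps == [(0, 1, 2), (0, 1, 2)]

    def test_symbolic_alleles_sort_last(self):
        (_, alts), _ = merge_alleles([("A", (NON_REF, "T")), ("A", ("*", "C"))])
        assert alts == ("C", "T", "*", NON_REF)

    def test_conflicting_reference_rejected(self):
        with pytest.raises(ValueError, match="conflicting reference"):
            merge_alleles([("A", ("T",)), ("AC", ("A",))])


class TestMergeSvcr:
    def test_disjoint_loci_outer_join(self):
        d1 = gvcf_to_svcr("S1", [variant(10)], CONTIGS)
        d2 = gvcf_to_svcr("S2", [variant(20)], CONTIGS)
        m = merge_svcr([d1, d2])
        assert len(m.rows) == 2
        assert [len(r.entries) for r in m.rows] == [1, 1]
        assert m.samples == ["S1", "S2"]

    def test_shared_variant_single_row_two_entries(self):
        d1 = gvcf_to_svcr("S1", [variant(10)], CONTIGS)
        d2 = gvcf_to_svcr("S2", [variant(10)], CONTIGS)
        m = merge_svcr([d1, d2])
        assert len(m.rows) == 1
        row = m.rows[0]
        assert set(row.entries) == {"S1", "S2"}
        assert row.entries["S1"].la == row.entries["S2"].la == (0, 1, 2)

    def test_sparse_entry_where_sample_has_no_record(self):
        d1 = gvcf_to_svcr("S1", [block(0, 100)], CONTIGS)
        d2 = gvcf_to_svcr("S2", [variant(50)], CONTIGS)
        m = merge_svcr([d1, d2])
        row_at_50 = [r for r in m.rows if r.locus.position == 50][0]
        assert "S1" not in row_at_50.entries
        assert "S2" in row_at_50.entries

    def test_duplicate_sample_rejected(self):
        d1 = gvcf_to_svcr("S1", [variant(10)], CONTIGS)
        d2 = gvcf_to_svcr("S1", [variant(20)], CONTIGS)
        with pytest.raises(ValueError, match="duplicate sample"):
            merge_svcr([d1, d2])

    def test_storage_linear_in_input_records(self, small_cohort):
        c = small_cohort
        singles = [gvcf_to_svcr(s, c.gvcfs[s], c.contigs) for s in c.samples]
        merged = merge_svcr(singles)
        assert merged.n_entries == sum(d.n_entries for d in singles)


def _dataset_equal(a: SvcrDataset, b: SvcrDataset) -> bool:
    if a.samples != b.samples or len(a.rows) != len(b.rows):
        return False
    return all(
        (r1.locus, r1.ref, r1.alts, r1.entries) == (r2.locus, r2.ref, r2.alts, r2.entries)
        for r1, r2 in zip(a.rows, b.rows)
    )


class TestHierarchicalMerge:
    @pytest.mark.parametrize(
        "s,n,expected",
        [(1_000_000, 100, 3), (100, 100, 1), (1, 100, 0), (101, 100, 2), (7, 2, 3)],
    )
    def test_round_count_formula(self, s, n, expected):
        assert merge_rounds(s, n) == expected

    def test_round_count_matches_ceil_log(self):
        import math

        for n in (2, 10, 100):
            for s in list(range(1, 1200)) + [10**4, 10**5, 10**6]:
                expected = 0 if s == 1 else math.ceil(math.log(s) / math.log(n) - 1e-12)
                # integer recurrence avoids float edge cases at exact powers
                width, r = 1, 0
                while width < s:
                    width *= n
                    r += 1
                assert merge_rounds(s, n) == r
                assert abs(r - expected) <= 0

    def test_branch_factor_below_two_rejected(self):
        with pytest.raises(ValueError, match="branch factor"):
            merge_rounds(10, 1)

    def test_grouping_invariance_vs_flat_merge(self, small_cohort):
        c = small_cohort
        singles = [gvcf_to_svcr(s, c.gvcfs[s], c.contigs) for s in c.samples]
        flat = merge_svcr(singles)
        for bf in (2, 3, 100):
            hier, rounds = hierarchical_merge(singles, bf)
            assert rounds == merge_rounds(len(singles), bf)
            assert _dataset_equal(hier, flat)

    def test_seven_inputs_branch_two_bit_identical_to_flat(self):
        singles = [
            gvcf_to_svcr(f"S{i}", [variant(10 * i), block(10 * i + 1, 10 * i + 5)], CONTIGS)
            for i in range(7)
        ]
        hier, rounds = hierarchical_merge(singles, 2)
        assert rounds == 3
        assert _dataset_equal(hier, merge_svcr(singles))


class TestDensify:
    def test_block_fills_homref_when_spanning(self):
        da = gvcf_to_svcr("A", [block(100, 200, gq=33)], CONTIGS)
        db = gvcf_to_svcr("B", [variant(150)], CONTIGS)
        dm = densify(merge_svcr([da, db]))
        assert len(dm.rows) == 1
        call_a = dm.rows[0].calls[0]
        assert call_a.gt == (0, 0)
        assert call_a.gq == 30  # block GQ is stored binned
        assert call_a.filled

    def test_missing_beyond_block_end(self):
        da = gvcf_to_svcr("A", [block(100, 200)], CONTIGS)
        db = gvcf_to_svcr("B", [variant(250)], CONTIGS)
        dm = densify(merge_svcr([da, db]))
        assert dm.rows[0].calls[0] is None

    def test_no_carry_across_contigs(self):
        contigs = [("chr1", 1000), ("chr2", 1000)]
        da = gvcf_to_svcr("A", [block(0, 900, contig="chr1")], contigs)
        db = gvcf_to_svcr("B", [variant(10, contig="chr2")], contigs)
        dm = densify(merge_svcr([da, db]))
        assert dm.rows[0].calls[0] is None

    def test_single_sample_identity_on_own_variant_rows(self):
        records = [block(0, 50), variant(50), block(51, 100), variant(100, gt=(1, 1))]
        ds = gvcf_to_svcr("S1", records, CONTIGS)
        dm = densify(ds)
        assert [r.locus.position for r in dm.rows] == [50, 100]
        assert dm.rows[0].calls[0].gt == (0, 1)
        assert dm.rows[1].calls[0].gt == (1, 1)
        assert dm.rows[0].calls[0].ad == (15, 15, 0)


class TestJointMatrixOracle:
    def test_densified_merge_equals_bruteforce_joint_matrix(self, small_cohort):
        """Cross-check densification against a direct read of the gVCF texts."""
        c = small_cohort
        singles = [gvcf_to_svcr(s, c.gvcfs[s], c.contigs) for s in c.samples]
        merged, _ = hierarchical_merge(singles, 3)
        dm = densify(merged)

        binned = {s: bin_and_merge_blocks(c.gvcfs[s]) for s in c.samples}
        for row in dm.rows:
            contig, pos = row.locus.contig, row.locus.position
            for s_idx, sample in enumerate(c.samples):
                at_locus = [
                    r for r in binned[sample] if r.contig == contig and r.pos == pos
                ]
                call = row.calls[s_idx]
                if at_locus and not at_locus[0].is_block:
                    rec = at_locus[0]
                    expected_gt = tuple(
                        0 if a == 0 else row.alts.index(rec.alts[a - 1]) + 1
                        for a in rec.gt
                    )
                    assert call.gt == expected_gt
                    assert call.dp == rec.dp and call.gq == rec.gq
                else:
                    spanning = [
                        r
                        for r in binned[sample]
                        if r.is_block and r.contig == contig and r.pos <= pos < r.end
                    ]
                    if spanning:
                        assert call is not None and call.gt == (0, 0)
                        assert call.gq == spanning[0].gq
                    else:
                        assert call is None


class TestLosslessRoundTrip:
    def test_roundtrip_through_merge_is_byte_identical(self, small_cohort):
        c = small_cohort
        singles = [gvcf_to_svcr(s, c.gvcfs[s], c.contigs) for s in c.samples]
        merged, _ = hierarchical_merge(singles, 4)
        for s in c.samples:
            expected = bin_and_merge_blocks(c.gvcfs[s])
            restored = svcr_to_gvcf(merged, s)
            assert restored == expected
            assert render_gvcf(s, restored, c.contigs) == render_gvcf(
                s, expected, c.contigs
            )

    def test_empty_column_yields_no_records(self):
        ds = SvcrDataset(
            samples=["S1", "S2"],
            rows=[
                SvcrRow(
                    Locus("chr1", 5),
                    "A",
                    ("T", NON_REF),
                    {
                        "S1": SvcrEntry(
                            "variant_call", (0, 1, 2), (0, 1), 50, 30,
                            lad=(9, 9, 0),
                        )
                    },
                )
            ],
            contigs=CONTIGS,
        )
        assert svcr_to_gvcf(ds, "S2") == []

    def test_corrupt_la_reference_raises(self):
        entry = SvcrEntry("variant_call", (0, 3), (0, 1), 50, 30)
        ds = SvcrDataset(
            ["S1"],
            [SvcrRow(Locus("chr1", 5), "A", ("T",), {"S1": entry})],
            CONTIGS,
        )
        with pytest.raises(ValueError, match="corrupt"):
            svcr_to_gvcf(ds, "S1")


class TestPlProjection:
    @pytest.mark.parametrize("la", [(0, 1), (0, 2), (0, 1, 3), (0, 2, 4)])
    def test_local_global_local_identity_diploid(self, la):
        n_local = len(la)
        lpl = tuple(range(0, 7 * (n_local * (n_local + 1) // 2), 7))
        entry = SvcrEntry(
            "variant_call", la, (0, 1), 50, 30,
            lad=tuple([10] * n_local), lpl=lpl,
        )
        n_global = max(la) + 1
        call = _expand_call(entry, n_global)
        assert project_pl_to_local(call.pl, la, 2) == lpl

    def test_vcf_genotype_index_formula(self):
        order = genotype_tuples(3, 2)
        assert order == [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)]
        for i, gt in enumerate(order):
            assert genotype_index(gt) == i


class TestPvcfExport:
    def test_two_samples_one_shared_variant_one_line(self):
        d1 = gvcf_to_svcr("S1", [variant(10)], CONTIGS)
        d2 = gvcf_to_svcr("S2", [variant(10)], CONTIGS)
        text = export_pvcf(densify(merge_svcr([d1, d2])))
        data = [l for l in text.splitlines() if not l.startswith("#")]
        assert len(data) == 1
        assert len(data[0].split("\t")) == 11  # 9 fixed + 2 genotype columns

    def test_missing_call_rendered_as_dots(self):
        d1 = gvcf_to_svcr("S1", [block(0, 20)], CONTIGS)
        d2 = gvcf_to_svcr("S2", [variant(50)], CONTIGS)
        text = export_pvcf(densify(merge_svcr([d1, d2])))
        data = [l for l in text.splitlines() if not l.startswith("#")][0]
        assert data.split("\t")[9] == "./."

    def test_parse_back_reproduces_dense_matrix(self, small_cohort, tmp_path):
        c = small_cohort
        singles = [gvcf_to_svcr(s, c.gvcfs[s], c.contigs) for s in c.samples]
        dm = densify(merge_svcr(singles))
        path = tmp_path / "joint.vcf"
        path.write_text(export_pvcf(dm))
        back = read_pvcf(path)
        assert back.samples == dm.samples
        assert len(back.rows) == len(dm.rows)
        for r1, r2 in zip(dm.rows, back.rows):
            assert (r1.locus, r1.ref, r1.alts) == (r2.locus, r2.ref, r2.alts)
            for a, b in zip(r1.calls, r2.calls):
                if a is None:
                    assert b is None
                else:
                    assert (a.gt, a.gq, a.dp, a.ad, a.pl) == (b.gt, b.gq, b.dp, b.ad, b.pl)
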