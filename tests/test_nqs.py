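"""NQS qualification, pileups, SNP/DIP calling, merging and rates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from felsnp.io import AlignedRead
from felsnp.nqs import (
    Discrepancy,
    NqsParams,
    UndefinedRateError,
    build_pileup,
    call_dips,
    call_snps,
    merge_sites,
    per_individual_site_counts,
    qualify_base,
    qualify_read,
    qualified_base_count,
    snp_rate,
)
from felsnp.simulate import PopulationModel, ReadModel, simulate_population, simulate_reads

from conftest import make_reference, perfect_read
from oracles import oracle_depths, oracle_merge, oracle_qualify


def mutate(read, offset, base=None, q=None):
    """Return a copy of the read with one base and/or quality changed."""
    seq = list(read.seq)
    if base is not None:
        seq[offset] = base
    quals = read.quals.copy()
    if q is not None:
        quals[offset] = q
    return AlignedRead(
        read_id=read.read_id,
        individual=read.individual,
        chrom=read.chrom,
        start=read.start,
        strand=read.strand,
        seq="".join(seq),
        quals=quals,
        cigar=list(read.cigar),
    )


def other_base(b):
    return {"A": "C", "C": "G", "G": "T", "T": "A"}[b]


class TestQualifyBase:
    def test_exact_threshold_boundary_qualifies(self, params):
        asm = make_reference(1)
        read = perfect_read(asm, q=15)
        read = mutate(read, 30, q=23)  # center 23, all ten flanks 15, all match
        assert qualify_base(read, 30, asm, params)

    def test_center_quality_22_fails(self, params):
        asm = make_reference(1)
        read = mutate(perfect_read(asm, q=40), 30, q=22)
        assert not qualify_base(read, 30, asm, params)

    def test_eight_of_ten_flank_matches_fails(self, params):
        asm = make_reference(1)
        read = perfect_read(asm, q=40)
        # center mismatch does not count against the flanks
        read = mutate(read, 30, base=other_base(read.seq[30]))
        read = mutate(read, 27, base=other_base(read.seq[27]))
        assert qualify_base(read, 30, asm, params)  # 9/10 still passes
        read = mutate(read, 33, base=other_base(read.seq[33]))
        assert not qualify_base(read, 30, asm, params)  # 8/10 fails

    def test_incomplete_neighborhood_never_qualifies(self, params):
        asm = make_reference(1)
        read = perfect_read(asm, q=60)
        assert not qualify_base(read, 3, asm, params)
        assert not qualify_base(read, len(read) - 2, asm, params)

    def test_flank_quality_14_fails(self, params):
        asm = make_reference(1)
        read = mutate(perfect_read(asm, q=40), 28, q=14)
        assert not qualify_base(read, 30, asm, params)
        assert qualify_base(read, 40, asm, params)

    def test_gap_crossing_neighborhood_disqualifies(self, params):
        asm = make_reference(1)
        ref = asm.sequences["chr1"]
        # 30M 2D 30M: the deletion splits the alignment at read offset 30
        seq = ref[100:130] + ref[132:162]
        read = AlignedRead(
            read_id="r",
            individual="Pixel",
            chrom="chr1",
            start=100,
            strand="+",
            seq=seq,
            quals=np.full(60, 40, dtype=np.uint8),
            cigar=[("M", 30), ("D", 2), ("M", 30)],
        )
        q = qualify_read(read, asm, params)
        # bases within flank_width of the junction are unqualified
        assert not q[26:35].any()
        assert q[15] and q[45]

    def test_offset_out_of_range(self, params):
        asm = make_reference(1)
        read = perfect_read(asm)
        with pytest.raises(IndexError):
            qualify_base(read, len(read), asm, params)

    def test_matches_exhaustive_oracle_on_simulated_reads(self, small_truth, small_reads, params):
        """Vectorized rule equals an independent per-base walk on 150+ reads."""
        rng = np.random.default_rng(1)
        idx = rng.choice(len(small_reads), size=150, replace=False)
        checked = 0
        for i in idx:
            read = small_reads[int(i)]
            got = qualify_read(read, small_truth.reference, params)
            want = oracle_qualify(read, small_truth.reference, params)
            assert got.tolist() == want
            checked += 1
        assert checked >= 100

    @given(
        center_q=st.integers(15, 40),
        flank_q=st.integers(5, 25),
        min_matches=st.integers(5, 10),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_oracle_under_varied_thresholds(self, center_q, flank_q, min_matches):
        asm = make_reference(9, length=400)
        rng = np.random.default_rng(center_q * 1000 + flank_q * 10 + min_matches)
        params = NqsParams(
            center_min_q=center_q, flank_min_q=flank_q, min_flank_matches=min_matches
        )
        ref = asm.sequences["chr1"]
        start, L = 50, 80
        seq = list(ref[start : start + L])
        for j in rng.integers(0, L, size=6):
            seq[j] = other_base(seq[j])
        read = AlignedRead(
            read_id="r",
            individual="x",
            chrom="chr1",
            start=start,
            strand="+",
            seq="".join(seq),
            quals=rng.integers(2, 45, size=L).astype(np.uint8),
            cigar=[("M", L)],
        )
        assert qualify_read(read, asm, params).tolist() == oracle_qualify(
            read, asm, params
        )


class TestPileup:
    def test_empty(self, params):
        asm = make_reference(1)
        pileup = build_pileup([], asm, params)
        assert list(pileup.columns("chr1")) == []

    def test_two_overlapping_reads_depth_two(self, params):
        asm = make_reference(1)
        r1 = perfect_read(asm, start=100, length=50, read_id="a")
        r2 = perfect_read(asm, start=130, length=50, read_id="b")
        pileup = build_pileup([r1, r2], asm, params)
        depth = pileup.depth("chr1")
        assert depth[140] == 2 and depth[100] == 1 and depth[190] == 0
        assert len(pileup.column("chr1", 140)) == 2

    def test_depths_match_interval_stabbing_oracle(self, params):
        asm = make_reference(4, length=3_000)
        rng = np.random.default_rng(4)
        reads = [
            perfect_read(
                asm,
                start=int(rng.integers(0, 2_800)),
                length=int(rng.integers(30, 150)),
                read_id=f"r{i}",
            )
            for i in range(50)
        ]
        pileup = build_pileup(reads, asm, params)
        assert pileup.depth("chr1").tolist() == oracle_depths(reads, "chr1", 3_000)

    def test_unknown_chromosome_rejected(self, params):
        asm = make_reference(1)
        read = perfect_read(asm)
        read.chrom = "chrZ"
        with pytest.raises(ValueError, match="unknown chromosome"):
            build_pileup([read], asm, params)


class TestCallSnps:
    def _mismatch_reads(self, asm, n, offset=30):
        reads = []
        for i in range(n):
            r = perfect_read(asm, q=40, read_id=f"r{i}", individual="Pixel")
            reads.append(mutate(r, offset, base=other_base(r.seq[offset])))
        return reads

    def test_qualified_mismatch_emits_one_record_per_read(self, params):
        asm = make_reference(1)
        reads = self._mismatch_reads(asm, 3)
        records = call_snps(build_pileup(reads, asm, params))
        assert len(records) == 3
        assert {r.pos for r in records} == {130}
        assert all(r.individual == "Pixel" for r in records)

    def test_depth_above_cap_emits_nothing(self):
        asm = make_reference(1)
        params = NqsParams(max_depth=2)
        reads = self._mismatch_reads(asm, 3)
        assert call_snps(build_pileup(reads, asm, params)) == []

    def test_unqualified_mismatch_emits_nothing(self, params):
        asm = make_reference(1)
        (read,) = self._mismatch_reads(asm, 1)
        read = mutate(read, 28, q=14)  # flank below threshold
        assert call_snps(build_pileup([read], asm, params)) == []

    def test_reference_n_and_gap_adjacent_columns_excluded(self, params):
        asm = make_reference(2, length=2_000, n_run=(150, 160))
        ref = asm.sequences["chr1"]
        read = AlignedRead(
            read_id="r",
            individual="Pixel",
            chrom="chr1",
            start=100,
            strand="+",
            seq=ref[100:180],
            quals=np.full(80, 40, dtype=np.uint8),
            cigar=[("M", 80)],
        )
        # mismatch within flank_width of the N-run: excluded column
        read = mutate(read, 62, base=other_base(ref[162]))  # pos 162, N-run ends 160
        assert call_snps(build_pileup([read], asm, params)) == []

    def test_lowering_center_threshold_never_reduces_calls(self, small_truth, small_reads):
        counts = []
        for q in (23, 20, 15):
            params = NqsParams(center_min_q=q)
            pileup = build_pileup(list(small_reads[:400]), small_truth.reference, params)
            counts.append(len(call_snps(pileup)))
        assert counts[0] <= counts[1] <= counts[2]


class TestCallDips:
    def _del_read(self, asm, del_len=1, q=40):
        ref = asm.sequences["chr1"]
        seq = ref[100:130] + ref[130 + del_len : 160 + del_len]
        return AlignedRead(
            read_id="rd",
            individual="Pixel",
            chrom="chr1",
            start=100,
            strand="+",
            seq=seq,
            quals=np.full(60, q, dtype=np.uint8),
            cigar=[("M", 30), ("D", del_len), ("M", 30)],
        )

    def test_one_base_deletion_with_qualified_flanks(self, params):
        asm = make_reference(3)
        records = call_dips([self._del_read(asm)], asm, params)
        assert len(records) == 1
        rec = records[0]
        assert (rec.vtype, rec.pos, rec.ref, rec.alt) == (
            "DIP",
            129,
            asm.sequences["chr1"][130],
            "",
        )

    def test_low_quality_flank_blocks_dip(self, params):
        asm = make_reference(3)
        read = mutate(self._del_read(asm), 30, q=14)  # right flank base
        assert call_dips([read], asm, params) == []

    def test_gap_longer_than_cap_ignored(self, params):
        asm = make_reference(3)
        assert call_dips([self._del_read(asm, del_len=11)], asm, params) == []
        assert len(call_dips([self._del_read(asm, del_len=10)], asm, params)) == 1

    def test_insertion_recorded_with_anchor(self, params):
        asm = make_reference(3)
        ref = asm.sequences["chr1"]
        seq = ref[100:130] + "TT" + ref[130:160]
        read = AlignedRead(
            read_id="ri",
            individual="Pixel",
            chrom="chr1",
            start=100,
            strand="+",
            seq=seq,
            quals=np.full(62, 40, dtype=np.uint8),
            cigar=[("M", 30), ("I", 2), ("M", 30)],
        )
        (rec,) = call_dips([read], asm, params)
        assert (rec.vtype, rec.pos, rec.ref, rec.alt) == ("DIP", 129, "", "TT")


class TestMergeAndRates:
    def test_two_individuals_one_site(self):
        recs = [
            Discrepancy("chr1", 10, "SNP", "A", "G", "Pixel", "r1"),
            Discrepancy("chr1", 10, "SNP", "A", "G", "Nancy", "r2"),
        ]
        (site,) = merge_sites(recs)
        assert site.discoverers == {"Pixel", "Nancy"}
        assert site.support == {"Pixel": 1, "Nancy": 1}

    def test_different_alts_stay_separate(self):
        recs = [
            Discrepancy("chr1", 10, "SNP", "A", "G", "Pixel", "r1"),
            Discrepancy("chr1", 10, "SNP", "A", "T", "Pixel", "r2"),
        ]
        assert len(merge_sites(recs)) == 2

    @given(st.lists(
        st.tuples(
            st.integers(0, 30),            # position
            st.sampled_from("ACGT"),       # alt
            st.sampled_from(["Pixel", "Nancy", "Cinnamon", "Cocoa"]),
        ),
        max_size=60,
    ))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_merge_matches_grouping_oracle(self, raw):
        recs = [
            Discrepancy("chr1", pos, "SNP", "A", alt, ind, f"r{i}")
            for i, (pos, alt, ind) in enumerate(raw)
        ]
        sites = merge_sites(recs)
        want = oracle_merge(recs)
        assert len(sites) == len(want)
        for site in sites:
            assert site.support == want[site.key]
        # merge conservation: per-cat sums never below the non-redundant total
        per_cat = per_individual_site_counts(sites)
        assert sum(per_cat.values()) >= len(sites)

    def test_snp_rate_arithmetic(self, params):
        asm = make_reference(6, length=3_000)
        # two reads, uniform q=40, fully matching: qualified = len - 2*flank each
        reads = [
            perfect_read(asm, start=100, length=510, read_id="a", individual="Pixel"),
            perfect_read(asm, start=700, length=510, read_id="b", individual="Pixel"),
        ]
        recs = [
            Discrepancy("chr1", 150, "SNP", "A", "G", "Pixel", "a"),
            Discrepancy("chr1", 800, "SNP", "C", "T", "Pixel", "b"),
        ]
        rate = snp_rate("Pixel", recs, reads, asm, params)
        assert rate == (2 * 500) / 2  # one SNP per 500 qualified bases

    def test_zero_snps_is_undefined(self, params):
        asm = make_reference(6)
        reads = [perfect_read(asm, individual="Pixel")]
        with pytest.raises(UndefinedRateError):
            snp_rate("Pixel", [], reads, asm, params)

    def test_qualified_denominator_matches_per_base_oracle(self, small_truth, small_reads, params):
        for read in small_reads[:40]:
            want = sum(oracle_qualify(read, small_truth.reference, params))
            assert qualified_base_count(read, small_truth.reference, params) == want


class TestAgainstTruth:
    def test_error_free_calls_are_truth_subset_and_recall_grows(self):
        model = PopulationModel(chromosome_plan=[("chr1", 400_000, False)])
        truth = simulate_population(model, 13)
        truth_keys = truth.alt_site_keys(vtype="SNP")
        params = NqsParams()
        recalls = []
        for cov in (0.2, 0.6):
            rm = ReadModel(coverage=cov, q_plateau=60, q_floor=60, inject_errors=False)
            reads = simulate_reads(truth, rm, 13)
            sites = merge_sites(call_snps(build_pileup(reads, truth.reference, params)))
            called = {s.key for s in sites}
            assert called <= truth_keys  # zero false positives
            recalls.append(len(called) / len(truth_keys))
        assert recalls[1] > recalls[0]
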