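import gzip

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bisukit.align import MODE_CT, MODE_GA, ReadAlignment, write_sam
from bisukit.methcall import (
    BLOCK_LEN,
    CompressedCounters,
    TargetSet,
    beta,
    build_cg_bitvector,
    build_record_frame,
    call_status,
    classify_context,
    coverage_from_sam,
    emit,
    process_alignments,
    target_stats,
)

from conftest import make_reference, random_dna


def _aln(read_id, seq, pos, mode=MODE_CT, contig="c1", status="unique"):
    return ReadAlignment(read_id, contig, pos, mode, 0, status, len(seq),
                         seq, "I" * len(seq))


class TestRankBitVector:
    def test_marking_example(self):
        bv = build_cg_bitvector(make_reference("AACGT"))
        assert list(bv.bits) == [0, 0, 1, 1, 0]
        assert bv.rank(5) == 2

    def test_rank_zero(self):
        bv = build_cg_bitvector(make_reference("GCGC"))
        assert bv.rank(0) == 0

    def test_rank_against_naive_prefix(self):
        rng = np.random.default_rng(1)
        text = random_dna(rng, 50_000)
        bv = build_cg_bitvector(make_reference(text))
        naive = np.cumsum(bv.bits)
        for i in rng.integers(0, 50_001, size=1000).tolist():
            want = 0 if i == 0 else int(naive[i - 1])
            assert bv.rank(i) == want

    def test_out_of_range(self):
        bv = build_cg_bitvector(make_reference("ACGT"))
        with pytest.raises(IndexError):
            bv.rank(5)


class TestCompressedCounters:
    def test_capacity_growth_trace(self):
        c = CompressedCounters(10)
        for _ in range(3):
            c.increment(4, "primary")
        assert c.get(4, "primary") == 3
        assert c.primary.capacity[0] == 2  # 3 needs 2 bits
        assert c.get(4, "converted") == 0

    def test_isolation(self):
        c = CompressedCounters(600)
        c.increment(0, "primary")
        c.increment(599, "primary")
        c.increment(0, "converted")
        assert c.get(0, "primary") == 1
        assert c.get(599, "primary") == 1
        assert c.get(1, "primary") == 0
        assert c.get(599, "converted") == 0

    def test_out_of_range(self):
        c = CompressedCounters(8)
        with pytest.raises(IndexError):
            c.increment(8, "primary")
        with pytest.raises(ValueError):
            c.increment(0, "sideways")

    def test_random_ops_match_naive_array(self):
        rng = np.random.default_rng(2)
        n = 4 * BLOCK_LEN
        c = CompressedCounters(n)
        naive = {"primary": np.zeros(n, int), "converted": np.zeros(n, int)}
        for _ in range(5000):
            which = "primary" if rng.random() < 0.5 else "converted"
            i = int(rng.integers(0, n))
            c.increment(i, which)
            naive[which][i] += 1
        got_p, got_c = c.to_arrays()
        assert np.array_equal(got_p, naive["primary"])
        assert np.array_equal(got_c, naive["converted"])

    def test_bulk_matches_naive(self):
        rng = np.random.default_rng(3)
        n = 3 * BLOCK_LEN
        c = CompressedCounters(n)
        naive = np.zeros(n, int)
        for _ in range(200):
            idxs = rng.integers(0, n, size=int(rng.integers(1, 120)))
            c.add_many(idxs, "primary")
            np.add.at(naive, idxs, 1)
        assert np.array_equal(c.to_arrays()[0], naive)

    def test_rebuilds_bounded_by_reads(self):
        """With block length >= read length, a read rebuilds at most the
        blocks it touches, so total rebuilds stay below the read count."""
        rng = np.random.default_rng(4)
        n = 8 * BLOCK_LEN
        c = CompressedCounters(n)
        n_reads = 2000
        read_len = 100  # < BLOCK_LEN
        for _ in range(n_reads):
            start = int(rng.integers(0, n - read_len))
            c.add_many(np.arange(start, start + read_len), "primary")
        assert c.rebuilds <= n_reads

    @given(st.lists(st.integers(0, 63), min_size=0, max_size=300))
    @settings(max_examples=30, deadline=None)
    def test_property_exactness(self, idxs):
        c = CompressedCounters(64)
        naive = np.zeros(64, int)
        for i in idxs:
            c.increment(i, "primary")
            naive[i] += 1
        assert np.array_equal(c.to_arrays()[0], naive)


class TestBeta:
    def test_examples(self):
        assert beta(3, 1) == 0.75
        assert beta(0, 5) == 0.0
        assert beta(0, 0) is None

    def test_call_status_strict(self):
        assert call_status(0.5) is False
        assert call_status(0.5000001) is True
        assert call_status(0.0) is False

    def test_call_status_undefined(self):
        with pytest.raises(ValueError):
            call_status(None)


class TestClassifyContext:
    def test_plus_strand(self):
        assert classify_context(make_reference("ACGT"), 1, "+") == "CpG"
        assert classify_context(make_reference("ACAGT"), 1, "+") == "CHG"
        assert classify_context(make_reference("ACAAT"), 1, "+") == "CHH"

    def test_minus_strand_mirrored(self):
        assert classify_context(make_reference("ACGT"), 2, "-") == "CpG"
        assert classify_context(make_reference("ACTGA"), 3, "-") == "CHG"
        assert classify_context(make_reference("ATTGA"), 3, "-") == "CHH"

    def test_contig_end_falls_back_to_chh(self):
        assert classify_context(make_reference("AAAC"), 3, "+") == "CHH"

    def test_wrong_base(self):
        with pytest.raises(ValueError):
            classify_context(make_reference("ACGT"), 0, "+")


def _counted(ref, alns, tmp_path, **opts):
    sam = tmp_path / "in.sam"
    write_sam(alns, ref, sam)
    bv = build_cg_bitvector(ref)
    counters = process_alignments(sam, ref, rank_bv=bv, **opts)
    return bv, counters


class TestProcessAlignments:
    def test_forward_read_counts_under_c(self, tmp_path):
        ref = make_reference("AACGT")
        bv, c = _counted(ref, [_aln("r", "ACG", 1)], tmp_path)
        # rank 0 is the C at position 2: read C -> primary
        assert c.get(0, "primary") == 1
        assert c.get(0, "converted") == 0
        # the G at position 3 is only informed by GA-rule reads
        assert c.get(1, "primary") == 0

    def test_converted_base_counts_as_converted(self, tmp_path):
        ref = make_reference("AACGT")
        bv, c = _counted(ref, [_aln("r", "ATG", 1)], tmp_path)
        assert c.get(0, "primary") == 0
        assert c.get(0, "converted") == 1

    def test_reverse_read_counts_under_g(self, tmp_path):
        ref = make_reference("AACGT")
        # original read ACG; written to SAM as its revcomp CGT (reverse flag)
        bv, c = _counted(ref, [_aln("r", "ACG", 2, mode=MODE_GA)], tmp_path)
        assert c.get(1, "primary") == 1  # G at position 3
        assert c.get(0, "primary") == 0  # C not informed by a GA read

    def test_read_over_at_positions_changes_nothing(self, tmp_path):
        ref = make_reference("TTAAATTT")
        bv, c = _counted(ref, [_aln("r", "AAA", 2)], tmp_path)
        assert bv.total == 0 or np.all(c.to_arrays()[0] == 0)

    def test_multiple_discarded_by_default(self, tmp_path):
        ref = make_reference("AACGT")
        alns = [_aln("r", "ACG", 1, status="multiple")]
        _, c = _counted(ref, alns, tmp_path)
        assert c.get(0, "primary") == 0
        _, c = _counted(ref, alns, tmp_path, discard_multiple=False)
        assert c.get(0, "primary") == 1

    def test_conservation(self, tmp_path):
        """primary+converted equals the number of kept {C,T} read bases
        over forward cytosines (mirrored for reverse)."""
        rng = np.random.default_rng(5)
        text = random_dna(rng, 400)
        ref = make_reference(text)
        alns = []
        for i in range(30):
            pos = int(rng.integers(0, 350))
            seq = text[pos : pos + 50]
            alns.append(_aln(f"r{i}", seq, pos))
        bv, c = _counted(ref, alns, tmp_path)
        prim, conv = c.to_arrays()
        naive = np.zeros(bv.total, int)
        cpos = {p: r for r, p in enumerate(np.flatnonzero(bv.bits).tolist())}
        for a in alns:
            for j, b in enumerate(a.seq):
                p = a.position + j
                if text[p] == "C" and b in "CT":
                    naive[cpos[p]] += 1
        assert np.array_equal(prim + conv, naive)

    def test_off_target_reads_skipped(self, tmp_path):
        text = "AACGT" * 40
        ref = make_reference(text)
        bed = tmp_path / "t.bed"
        bed.write_text("c1\t0\t10\n")
        targets = TargetSet.from_bed(bed, ref)
        alns = [_aln("in", "ACG", 1), _aln("out", "ACG", 101)]
        _, c = _counted(ref, alns, tmp_path, targets=targets,
                        discard_off_target=True)
        prim, _ = c.to_arrays()
        assert prim.sum() == 1


class TestEmit:
    def _frame(self):
        ref = make_reference("TACGT")
        bv = build_cg_bitvector(ref)
        counters = CompressedCounters(bv.total)
        for _ in range(3):
            counters.increment(0, "primary")
        counters.increment(0, "converted")
        return build_record_frame(ref, bv, counters)

    def test_cov_line_format(self, tmp_path):
        out = tmp_path / "o.cov"
        emit(self._frame(), out, format="cov")
        assert out.read_text() == "c1\t3\t3\t75\t3\t1\n"

    def test_zero_coverage_absent_from_cov(self, tmp_path):
        out = tmp_path / "o.cov"
        emit(self._frame(), out, format="cov")
        # the G at position 3 has no coverage -> only one line
        assert len(out.read_text().splitlines()) == 1

    def test_bed_includes_uncovered(self, tmp_path):
        out = tmp_path / "o.bed"
        emit(self._frame(), out, format="bed")
        lines = out.read_text().splitlines()
        assert len(lines) == 2
        assert lines[0].split("\t") == [
            "c1", "2", "3", "+", "CpG", "3", "1", "0.75"]
        assert lines[1].split("\t")[-1] == "NA"

    def test_cov_round_trip(self, tmp_path):
        out = tmp_path / "o.cov"
        frame = self._frame()
        emit(frame, out, format="cov")
        back = pd.read_csv(out, sep="\t", header=None,
                           names=["chrom", "p1", "p2", "pct", "prim", "conv"])
        covered = frame[frame["coverage"] > 0]
        assert list(back["prim"]) == list(covered["count_primary"])
        assert list(back["conv"]) == list(covered["count_converted"])
        assert list(back["p1"]) == [p + 1 for p in covered["position"]]

    def test_gzip_round_trip(self, tmp_path):
        plain, zipped = tmp_path / "a.cov", tmp_path / "a.cov.gz"
        frame = self._frame()
        emit(frame, plain, format="cov")
        emit(frame, zipped, format="cov", compress="gzip")
        assert gzip.open(zipped, "rb").read() == plain.read_bytes()

    def test_epp_dialect(self, tmp_path):
        out = tmp_path / "o.epp"
        emit(self._frame(), out, format="epp")
        assert out.read_text() == "c1\t3\t+\tCpG\t3\t4\t0.75\n"

    def test_on_target_only(self, tmp_path):
        ref = make_reference("TACGT")
        bed = tmp_path / "t.bed"
        bed.write_text("c1\t3\t4\n")  # covers only the G
        targets = TargetSet.from_bed(bed, ref)
        out = tmp_path / "o.bed"
        emit(self._frame(), out, format="bed", on_target_only=True,
             targets=targets)
        lines = out.read_text().splitlines()
        assert len(lines) == 1 and lines[0].split("\t")[1] == "3"

    def test_on_target_requires_targets(self, tmp_path):
        with pytest.raises(ValueError):
            emit(self._frame(), tmp_path / "x", on_target_only=True)


class TestTargetSet:
    def test_merge_and_flank(self, tmp_path):
        ref = make_reference("A" * 100)
        bed = tmp_path / "t.bed"
        bed.write_text("c1\t10\t20\nc1\t22\t30\nc1\t50\t60\n")
        t = TargetSet.from_bed(bed, ref, flank=2)
        assert list(t.starts) == [8, 48]
        assert list(t.ends) == [32, 62]

    def test_clip_at_contig_bounds(self, tmp_path):
        ref = make_reference("A" * 50)
        bed = tmp_path / "t.bed"
        bed.write_text("c1\t0\t5\nc1\t45\t50\n")
        t = TargetSet.from_bed(bed, ref, flank=10)
        assert t.starts[0] == 0
        assert t.ends[-1] == 50

    def test_unknown_contig(self, tmp_path):
        ref = make_reference("A" * 50)
        bed = tmp_path / "t.bed"
        bed.write_text("nope\t0\t5\n")
        with pytest.raises(ValueError):
            TargetSet.from_bed(bed, ref)


class TestTargetStats:
    def test_all_reads_on_target(self, tmp_path):
        ref = make_reference("ACGT" * 50)
        bed = tmp_path / "t.bed"
        bed.write_text("c1\t0\t200\n")
        t = TargetSet.from_bed(bed, ref)
        cov = np.zeros(200)
        cov[0:100] = 2
        stats = target_stats([(0, 50), (10, 60)], cov, t)
        assert stats["on_target_fraction"] == 1.0
        assert stats["mean_target_coverage"] == 1.0

    def test_uniform_coverage_mean(self, tmp_path):
        ref = make_reference("ACGT" * 50)
        bed = tmp_path / "t.bed"
        bed.write_text("c1\t50\t150\n")
        t = TargetSet.from_bed(bed, ref)
        cov = np.full(200, 7.0)
        stats = target_stats([(50, 150)], cov, t)
        assert stats["mean_target_coverage"] == 7.0

    def test_flank_profile_decays(self, tmp_path):
        """Reads only on the target: flank coverage hits 0 past read reach."""
        ref = make_reference("ACGT" * 100)
        bed = tmp_path / "t.bed"
        bed.write_text("c1\t150\t250\n")
        t = TargetSet.from_bed(bed, ref)
        cov = np.zeros(400)
        cov[140:260] = 3  # 10 bp of spill on each side
        stats = target_stats([(140, 260)], cov, t, max_distance=50)
        profile = stats["coverage_by_distance"]
        assert profile[0] == 3.0  # distance 1
        assert profile[30] == 0.0  # beyond the spill

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            target_stats([], np.zeros(10), TargetSet(
                np.array([], dtype=np.int64), np.array([], dtype=np.int64)))
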