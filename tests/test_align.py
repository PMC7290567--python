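"""Trimming semantics, k-mer index, aligner vs Smith-Waterman oracle,
duplicate removal and the NUMT score filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scmito import simulate as sim
from scmito.align import (
    AlignmentIndex,
    Scoring,
    TrimConfig,
    align_read,
    align_readset,
    filter_numts,
    remove_duplicates,
    trim_read,
    trim_reads,
)
from scmito.simulate import ReadRecord, ReadSet, revcomp

ADAPTER = "AGATCGGAAGAGC"
CFG = TrimConfig(adapter=ADAPTER, min_overlap=3, quality_cutoff=20, min_length=10)


def q(n, phred=35):
    return chr(33 + phred) * n


class TestTrim:
    def test_full_adapter_removed(self):
        seq = "ACGTACGTACGTACGT" + ADAPTER
        out, oq = trim_read(seq, q(len(seq)), CFG)
        assert out == "ACGTACGTACGTACGT"

    def test_three_base_adapter_prefix_removed(self):
        seq = "ACGTACGTACGTACGT" + ADAPTER[:3]
        out, _ = trim_read(seq, q(len(seq)), CFG)
        assert out == "ACGTACGTACGTACGT"

    def test_two_base_overlap_not_trimmed(self):
        # stringency demands >= 3 matching bases; take 2 adapter bases that do
        # not extend to a 3-base match
        seq = "ACGTACGTACGTACGT" + ADAPTER[:2]
        out, _ = trim_read(seq, q(len(seq)), CFG)
        assert out == seq

    def test_low_quality_tail_removed(self):
        seq = "ACGTACGTGG"
        qual = q(8) + chr(33 + 5) * 2
        out, oq = trim_read(seq, qual, CFG)
        assert out == "ACGTACGT"
        assert len(out) == len(oq)

    def test_short_reads_dropped(self):
        rs = ReadSet([ReadRecord("r1", "ACGTAC", q(6), "mt", ("?", 0, 0, "+"))])
        assert len(trim_reads(rs, CFG)) == 0

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        seq=st.text(alphabet="ACGT", min_size=1, max_size=60),
        quals=st.lists(st.integers(0, 41), min_size=60, max_size=60),
    )
    def test_never_lengthens_and_stays_in_register(self, seq, quals):
        qual = "".join(chr(33 + x) for x in quals[: len(seq)])
        out, oq = trim_read(seq, qual, CFG)
        assert len(out) <= len(seq)
        assert len(out) == len(oq)
        assert seq.startswith(out)
        assert qual.startswith(oq)


class TestIndex:
    def test_repeated_kmer_positions(self):
        idx = AlignmentIndex(None, [("r", "ACGTACGTACGT")], k=8)
        hits = idx.lookup("ACGTACGT")
        assert {(n, p + 1) for n, p in hits} == {("r", 1), ("r", 5)}

    def test_origin_spanning_kmer_indexed(self, ref2k, idx2k):
        L = ref2k.length
        kmer = ref2k.sequence[-14:] + ref2k.sequence[0]
        hits = idx2k.lookup(kmer)
        assert ("chrM", L - 14) in hits
        # brute-force oracle over the doubled sequence
        doubled = ref2k.sequence * 2
        oracle = {i % L for i in range(L) if doubled[i : i + 15] == kmer}
        assert {p for _n, p in hits} == oracle

    def test_absent_kmer_empty(self, idx2k):
        assert idx2k.lookup("X" * 15) == []

    def test_k_bounds(self, ref2k):
        with pytest.raises(ValueError):
            AlignmentIndex(ref2k, [], k=5)


class TestAlignRead:
    def test_exact_read_perfect_score(self, ref2k, idx2k):
        read = ref2k.sequence[100:150]  # positions 101..150
        (a,) = align_read(("r", read, q(50)), idx2k)
        assert (a.start, a.strand, a.score) == (101, "+", 50)
        assert a.cigar == [("M", 50)]

    def test_read_across_origin(self, ref2k, idx2k):
        L = ref2k.length
        read = (ref2k.sequence * 2)[L - 11 : L + 39]  # positions L-10 .. L+39
        (a,) = align_read(("r", read, q(50)), idx2k)
        assert a.start == L - 10
        assert a.score == 50
        assert a.end == L + 39  # unwrapped: consumes across the origin

    def test_single_mismatch_score(self, ref2k, idx2k, other):
        read = list(ref2k.sequence[200:260])
        read[30] = other(read[30])
        (a,) = align_read(("r", "".join(read), q(60)), idx2k)
        assert a.score == 60 - 2

    def test_reverse_strand(self, ref2k, idx2k):
        read = revcomp(ref2k.sequence[300:360])
        (a,) = align_read(("r", read, q(60)), idx2k)
        assert (a.start, a.strand, a.score) == (301, "-", 60)

    def test_unmapped_read(self, idx2k):
        rng = np.random.default_rng(0)
        read = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        # random 60-mer almost surely lacks any exact 15-mer hit in 2 kb
        assert align_read(("r", read, q(60)), AlignmentIndex(None, [("d", "A" * 100)], k=15)) == []

    def test_too_short_read(self, idx2k):
        assert align_read(("r", "ACGT", q(4)), idx2k) == []


@pytest.fixture(scope="module")
def sw_oracle():
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-1,
    )
    return aligner


class TestOracleEquivalence:
    @pytest.mark.parametrize("case_seed", range(8))
    def test_best_score_matches_full_smith_waterman(
        self, ref2k, idx2k, sw_oracle, case_seed
    ):
        """Seed-and-extend best score equals exhaustive DP over both strands
        and the doubled circular reference, for reads with substitutions and
        small indels."""
        rng = np.random.default_rng(1000 + case_seed)
        doubled = ref2k.sequence * 2
        for t in range(25):
            start = int(rng.integers(0, ref2k.length))
            frag = list(doubled[start : start + 80])
            for _ in range(int(rng.integers(0, 4))):
                i = int(rng.integers(0, len(frag)))
                r = rng.random()
                if r < 0.6:
                    frag[i] = "ACGT"[int(rng.integers(0, 4))]
                elif r < 0.8:
                    frag.insert(i, "ACGT"[int(rng.integers(0, 4))])
                elif len(frag) > 20:
                    frag.pop(i)
            read = "".join(frag)
            if rng.integers(0, 2):
                read = revcomp(read)
            alns = align_read(("t", read, q(len(read))), idx2k)
            mine = max((a.score for a in alns), default=0)
            expected = max(
                sw_oracle.score(doubled, read), sw_oracle.score(doubled, revcomp(read))
            )
            assert mine == expected

    def test_cigar_consumes_read_exactly(self, ref2k, idx2k):
        rng = np.random.default_rng(77)
        doubled = ref2k.sequence * 2
        for t in range(20):
            start = int(rng.integers(0, ref2k.length))
            frag = list(doubled[start : start + 70])
            i = int(rng.integers(1, 69))
            frag.insert(i, "ACGT"[int(rng.integers(0, 4))])
            read = "".join(frag)
            for a in align_read(("t", read, q(len(read))), idx2k):
                assert a.read_consumed() == len(read)


class TestDuplicates:
    def _aln(self, aln_factory, rid, start, seq, phred):
        return aln_factory(start, seq, qual=chr(33 + phred) * len(seq), read_id=rid)

    def test_identical_coordinates_collapse(self, aln_factory):
        a = self._aln(aln_factory, "a", 10, "ACGTACGT", 30)
        b = self._aln(aln_factory, "b", 10, "ACGTACGT", 30)
        assert len(remove_duplicates([a, b])) == 1

    def test_opposite_strands_kept(self, aln_factory):
        a = aln_factory(10, "ACGTACGT", strand="+", read_id="a")
        b = aln_factory(10, "ACGTACGT", strand="-", read_id="b")
        assert len(remove_duplicates([a, b])) == 2

    def test_quality_then_id_tie_break(self, aln_factory):
        trip = [
            self._aln(aln_factory, "a", 5, "ACGTACGTAC", 30),  # qual sum 300
            self._aln(aln_factory, "b", 5, "ACGTACGTAC", 31),  # 310
            self._aln(aln_factory, "c", 5, "ACGTACGTAC", 31),  # 310
        ]
        (kept,) = remove_duplicates(trip)
        assert kept.read_id == "b"

    def test_idempotent(self, ref2k, idx2k):
        reads = sim.generate_reads(
            ref2k.sequence, sim.get_protocol("ATAC"), 20, seed=4
        )
        kept, _ = filter_numts(align_readset(reads, idx2k))
        once = remove_duplicates(kept)
        twice = remove_duplicates(once)
        assert [a.read_id for a in once] == [a.read_id for a in twice]
        assert len(once) < len(kept)  # ATAC's heavy duplication visibly collapses


class TestNumtFilter:
    def test_equal_scores_discarded(self, aln_factory):
        mt = aln_factory(1, "A" * 50, score=50, ref_class="mt")
        nuc = aln_factory(1, "A" * 50, score=50, ref_class="nuclear")
        kept, report = filter_numts([[mt, nuc]])
        assert kept == []
        assert report[0].kept is False

    def test_strictly_better_mt_kept(self, aln_factory):
        mt = aln_factory(1, "A" * 50, score=50, ref_class="mt")
        nuc = aln_factory(1, "A" * 50, score=40, ref_class="nuclear")
        kept, _ = filter_numts([[mt, nuc]])
        assert [a.ref_class for a in kept] == ["mt"]

    def test_nuclear_only_discarded(self, aln_factory):
        nuc = aln_factory(1, "A" * 50, score=50, ref_class="nuclear")
        kept, report = filter_numts([[nuc]])
        assert kept == []
        assert report[0].mt_score is None

    def test_mt_only_kept(self, aln_factory):
        mt = aln_factory(1, "A" * 50, score=30, ref_class="mt")
        kept, _ = filter_numts([[mt]])
        assert len(kept) == 1
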