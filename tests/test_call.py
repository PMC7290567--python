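"""Pileup quality filtering, variant-call thresholds, consensus, VCF I/O."""

import numpy as np
import pytest

from scmito import call as vc
from scmito import simulate as sim
from scmito.align import AlignmentIndex
from scmito.pipeline import reconstruct_cell
from scmito.simulate import CellGenotype


def qstr(phreds):
    return "".join(chr(33 + p) for p in phreds)


class TestPileup:
    def test_low_quality_base_excluded(self, ref2k, aln_factory):
        seq = ref2k.sequence[0:10]
        a = aln_factory(1, seq, qual=qstr([29] + [35] * 9))
        p = vc.build_pileup([a], ref2k)
        assert p.filtered_depth[0] == 0
        assert p.raw_depth[0] == 1
        assert p.filtered_depth[1] == 1

    def test_uncovered_position_zero(self, ref2k, aln_factory):
        a = aln_factory(1, ref2k.sequence[0:10])
        p = vc.build_pileup([a], ref2k)
        assert p.filtered_depth[500] == 0

    def test_allele_counts_sum_to_depth(self, ref2k, aln_factory, other):
        base = ref2k.base(50)
        alns = []
        for i in range(10):
            b = other(base) if i < 3 else base
            alns.append(aln_factory(50, b, read_id=f"r{i}"))
        p = vc.build_pileup(alns, ref2k)
        counts = p.counts_at(50)
        assert counts == {base: 7, other(base): 3}
        assert sum(counts.values()) == p.filtered_depth[49] == 10

    def test_non_mt_alignment_rejected(self, ref2k, aln_factory):
        a = aln_factory(1, "ACGT", ref_class="nuclear")
        with pytest.raises(ValueError, match="not on the mtDNA"):
            vc.build_pileup([a], ref2k)


def _snp_pileup(ref, aln_factory, pos, alt, n_alt, n_ref):
    alns = []
    for i in range(n_alt):
        alns.append(aln_factory(pos, alt, read_id=f"a{i}"))
    for i in range(n_ref):
        alns.append(aln_factory(pos, ref.base(pos), read_id=f"r{i}"))
    return vc.build_pileup(alns, ref)


class TestCallVariants:
    def test_support_below_threshold_not_called(self, ref2k, aln_factory, other):
        alt = other(ref2k.base(100))
        p = _snp_pileup(ref2k, aln_factory, 100, alt, n_alt=4, n_ref=96)
        assert vc.call_variants(p, ref2k, min_support=5) == []

    def test_af_is_support_over_total(self, ref2k, aln_factory, other):
        alt = other(ref2k.base(100))
        p = _snp_pileup(ref2k, aln_factory, 100, alt, n_alt=5, n_ref=95)
        (c,) = vc.call_variants(p, ref2k, min_support=5)
        assert (c.support, c.total, c.af) == (5, 100, 0.05)
        p = _snp_pileup(ref2k, aln_factory, 100, alt, n_alt=20, n_ref=30)
        (c,) = vc.call_variants(p, ref2k, min_support=5)
        assert c.af == 0.4

    def test_min_support_monotone(self, ref2k):
        reads = sim.generate_reads(
            ref2k.sequence, sim.get_protocol("MDA", error_rate=0.02), 30, seed=3
        )
        idx = AlignmentIndex(ref2k, [])
        res = reconstruct_cell(reads, idx, ref2k, min_support=1)
        previous = None
        for ms in range(1, 8):
            n = len(vc.call_variants(res.pileup, ref2k, min_support=ms))
            if previous is not None:
                assert n <= previous
            previous = n

    def test_indel_near_read_end_dropped(self, ref2k, aln_factory):
        # insertion 3 bases from the end on every supporting read
        alns = []
        for i in range(6):
            seq = ref2k.sequence[0:7] + "A" + ref2k.sequence[7:10]
            cigar = [("M", 7), ("I", 1), ("M", 3)]
            alns.append(aln_factory(1, seq, cigar=cigar, read_id=f"i{i}"))
        p = vc.build_pileup(alns, ref2k)
        assert vc.call_variants(p, ref2k, indel_end_distance=5) == []
        assert len(vc.call_variants(p, ref2k, indel_end_distance=3)) == 1

    def test_deletion_call_and_vcf_anchoring(self, ref_full, aln_factory, tmp_path):
        # deletion of 2 bases following position 3106
        anchor = 3106
        alns = []
        for i in range(6):
            seq = ref_full.fetch(anchor - 9, 10) + ref_full.fetch(anchor + 3, 10)
            cigar = [("M", 10), ("D", 2), ("M", 10)]
            alns.append(aln_factory(anchor - 9, seq, cigar=cigar, read_id=f"d{i}"))
        p = vc.build_pileup(alns, ref_full)
        (c,) = vc.call_variants(p, ref_full)
        assert c.vtype == "del"
        assert c.pos == anchor
        assert c.ref == ref_full.base(anchor) + ref_full.fetch(anchor + 1, 2)
        assert c.alt == ref_full.base(anchor)
        vc.write_vcf([c], ref_full, "cell", tmp_path / "x.vcf")
        line = [
            l for l in (tmp_path / "x.vcf").read_text().splitlines()
            if not l.startswith("#")
        ][0]
        chrom, pos, _id, ref_f, alt_f = line.split("\t")[:5]
        assert (chrom, pos) == ("chrM", "3106")
        assert len(ref_f) == 3 and alt_f == ref_f[0]


class TestConsensus:
    def _uniform_pileup(self, ref, aln_factory, depth=10, alt_at=None):
        alns = []
        L = ref.length
        rl = 50
        for d in range(depth):
            for s in range(0, L, rl):
                n = min(rl, L - s)
                seq = ref.sequence[s : s + n]
                if alt_at:
                    pos, alt, frac = alt_at
                    if s < pos <= s + n and d < round(frac * depth):
                        off = pos - 1 - s
                        seq = seq[:off] + alt + seq[off + 1 :]
                alns.append(aln_factory(s + 1, seq, read_id=f"u{d}.{s}"))
        return vc.build_pileup(alns, ref)

    def test_alt_above_threshold_written(self, ref2k, aln_factory, other):
        pos, alt = 400, other(ref2k.base(400))
        p = self._uniform_pileup(ref2k, aln_factory, depth=20, alt_at=(pos, alt, 0.85))
        calls = vc.call_variants(p, ref2k)
        cons = vc.build_consensus(p, calls, ref2k)
        assert cons.n_contigs == 1
        assert cons.contigs[0][2][pos - 1] == alt

    def test_alt_below_threshold_keeps_reference(self, ref2k, aln_factory, other):
        pos, alt = 400, other(ref2k.base(400))
        p = self._uniform_pileup(ref2k, aln_factory, depth=20, alt_at=(pos, alt, 0.5))
        calls = vc.call_variants(p, ref2k)
        assert any(c.pos == pos for c in calls)  # called, but not consensus-worthy
        cons = vc.build_consensus(p, calls, ref2k)
        assert cons.contigs[0][2][pos - 1] == ref2k.base(pos)

    def test_full_coverage_single_contig(self, ref2k, aln_factory):
        p = self._uniform_pileup(ref2k, aln_factory, depth=6)
        cons = vc.build_consensus(p, [], ref2k)
        assert cons.n_contigs == 1
        assert cons.breadth_pct == 100.0
        assert cons.contigs[0][2] == ref2k.sequence

    def test_internal_gap_splits_contigs(self, ref2k, aln_factory):
        p = self._uniform_pileup(ref2k, aln_factory, depth=6)
        p.base_counts[:, 1000:1100] = 0  # knock out 100 internal sites
        cons = vc.build_consensus(p, [], ref2k)
        assert cons.n_contigs == 2
        assert cons.breadth_pct == pytest.approx((ref2k.length - 100) / ref2k.length * 100)

    def test_consensus_equals_simulated_haplotype(self, ref2k, other):
        # error-free, uniform, well-covered: exact genome recovery, one contig
        pos = 777
        g = CellGenotype(
            "c", extra_homoplasmic=frozenset({(pos, ref2k.base(pos), other(ref2k.base(pos)))})
        )
        hap = sim.apply_genotype(ref2k, None, g)
        proto = sim.get_protocol("BULK", error_rate=0.0)
        reads = sim.generate_reads(hap, proto, 30, seed=8)
        res = reconstruct_cell(reads, AlignmentIndex(ref2k, []), ref2k)
        assert res.consensus.n_contigs == 1
        assert res.consensus.contigs[0][2] == hap.sequence


class TestVcfRoundTrip:
    def test_round_trip_preserves_calls(self, ref2k, aln_factory, other, tmp_path):
        alt1 = other(ref2k.base(100))
        p = _snp_pileup(ref2k, aln_factory, 100, alt1, n_alt=7, n_ref=13)
        calls = vc.call_variants(p, ref2k)
        vc.write_vcf(calls, ref2k, "cell", tmp_path / "c.vcf")
        back = vc.read_vcf(tmp_path / "c.vcf")
        assert [(c.pos, c.ref, c.alt, c.total, c.af) for c in back] == [
            (c.pos, c.ref, c.alt, c.total, c.af) for c in calls
        ]

    def test_empty_calls_header_only(self, ref2k, tmp_path):
        vc.write_vcf([], ref2k, "cell", tmp_path / "e.vcf")
        lines = (tmp_path / "e.vcf").read_text().splitlines()
        assert all(l.startswith("#") for l in lines)
        assert vc.read_vcf(tmp_path / "e.vcf") == []

    def test_unsorted_rejected(self, ref2k, tmp_path):
        calls = [
            vc.VariantCall(200, "A", "G", "snp", 5, 10, 0.5),
            vc.VariantCall(100, "A", "G", "snp", 5, 10, 0.5),
        ]
        with pytest.raises(ValueError, match="sorted"):
            vc.write_vcf(calls, ref2k, "cell", tmp_path / "u.vcf")
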