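"""Quality-filtered pileup, heteroplasmy-aware variant calls, consensus.

The pileup counts only aligned, non-clipped bases with Phred quality at or
above a threshold (default 30). Variants (mismatches, insertions, deletions)
are reported when supported by at least ``min_support`` reads (default 5),
with the heteroplasmy fraction estimated as the plain ratio of supporting to
total quality-filtered depth. An indel is retained only if on at least one
supporting read it lies ``indel_end_distance`` or more bases from both read
ends. The consensus writes an alternate allele only when its fraction reaches
``hf_threshold`` (default 0.8) and splits into contigs wherever the filtered
depth falls below ``min_depth`` (default 5).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import Alignment
from .reference import MitoReference

_B2I = {"A": 0, "C": 1, "G": 2, "T": 3}
_I2B = "ACGT"


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

class Pileup:
    """Per-position allele tallies over a circular genome.

    ``base_counts`` is a 4 x L array (A/C/G/T) of quality-filtered counts;
    ``indels`` maps a 1-based left-anchor position to {allele: count} where an
    allele is ("I", inserted sequence) or ("D", deleted length).
    """

    def __init__(self, length: int, min_base_quality: int = 30) -> None:
        self.length = length
        self.min_base_quality = min_base_quality
        self.base_counts = np.zeros((4, length), dtype=np.int64)
        self.raw_depth = np.zeros(length, dtype=np.int64)
        self.indels: dict[int, dict[tuple[str, object], int]] = {}
        # (anchor pos, allele) -> largest min-distance-from-read-end seen
        self.indel_end_distance: dict[tuple[int, tuple[str, object]], int] = {}

    @property
    def filtered_depth(self) -> np.ndarray:
        return self.base_counts.sum(axis=0)

    def counts_at(self, pos: int) -> dict[str, int]:
        col = self.base_counts[:, pos - 1]
        return {_I2B[i]: int(col[i]) for i in range(4) if col[i]}


def build_pileup(
    alignments: list[Alignment],
    ref: MitoReference,
    min_base_quality: int = 30,
) -> Pileup:
    """Tally quality-filtered alleles from deduplicated, NUMT-filtered reads."""
    L = ref.length
    p = Pileup(L, min_base_quality)
    for a in alignments:
        if a.ref_class != "mt":
            raise ValueError(f"alignment {a.read_id} is not on the mtDNA reference")
        if not 1 <= a.start <= L:
            raise ValueError(f"alignment start {a.start} outside [1, {L}]")
        _add_alignment(p, a)
    return p


def _add_alignment(p: Pileup, a: Alignment) -> None:
    L = p.length
    minq = p.min_base_quality
    quals = np.frombuffer(a.quality.encode(), dtype=np.uint8).astype(np.int32) - 33
    seq = np.frombuffer(a.sequence.encode(), dtype=np.uint8)
    read_len = seq.size
    ref_cur = a.start - 1  # 0-based
    read_cur = 0
    for op, n in a.cigar:
        if op == "S":
            read_cur += n
        elif op == "M":
            pos = (ref_cur + np.arange(n)) % L
            bases = seq[read_cur : read_cur + n]
            q = quals[read_cur : read_cur + n]
            np.add.at(p.raw_depth, pos, 1)
            ok = q >= minq
            code = np.searchsorted(
                np.frombuffer(b"ACGT", dtype=np.uint8), bases
            )
            valid = ok & (bases != ord("N"))
            np.add.at(p.base_counts, (code[valid], pos[valid]), 1)
            ref_cur += n
            read_cur += n
        elif op == "I":
            anchor = (ref_cur - 1) % L + 1
            ins = a.sequence[read_cur : read_cur + n]
            if int(quals[read_cur : read_cur + n].min()) >= minq:
                allele = ("I", ins)
                p.indels.setdefault(anchor, {})
                p.indels[anchor][allele] = p.indels[anchor].get(allele, 0) + 1
                dist = min(read_cur, read_len - (read_cur + n))
                key = (anchor, allele)
                p.indel_end_distance[key] = max(p.indel_end_distance.get(key, 0), dist)
            read_cur += n
        elif op == "D":
            anchor = (ref_cur - 1) % L + 1
            allele = ("D", n)
            p.indels.setdefault(anchor, {})
            p.indels[anchor][allele] = p.indels[anchor].get(allele, 0) + 1
            dist = min(read_cur, read_len - read_cur)
            key = (anchor, allele)
            p.indel_end_distance[key] = max(p.indel_end_distance.get(key, 0), dist)
            ref_cur += n
        else:
            raise ValueError(f"unsupported CIGAR op {op!r}")


# ---------------------------------------------------------------------------
# variant calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantCall:
    pos: int  # 1-based; anchor position for indels
    ref: str
    alt: str
    vtype: str  # "snp" | "ins" | "del"
    support: int
    total: int
    af: float

    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)


def call_variants(
    pileup: Pileup,
    ref: MitoReference,
    min_support: int = 5,
    indel_end_distance: int = 5,
) -> list[VariantCall]:
    """Report every non-reference allele with supporting depth >= min_support."""
    calls: list[VariantCall] = []
    depth = pileup.filtered_depth
    nz = np.flatnonzero(pileup.base_counts.sum(axis=0))
    for pos0 in nz:
        pos = int(pos0) + 1
        rbase = ref.base(pos)
        col = pileup.base_counts[:, pos0]
        total = int(depth[pos0])
        for i in range(4):
            allele = _I2B[i]
            support = int(col[i])
            if allele != rbase and support >= min_support:
                calls.append(
                    VariantCall(pos, rbase, allele, "snp", support, total, support / total)
                )
    for anchor, alleles in pileup.indels.items():
        total = int(depth[anchor - 1])
        if total == 0:
            continue
        for allele, support in alleles.items():
            if support < min_support:
                continue
            if pileup.indel_end_distance.get((anchor, allele), 0) < indel_end_distance:
                continue
            anchor_base = ref.base(anchor)
            if allele[0] == "I":
                calls.append(
                    VariantCall(
                        anchor,
                        anchor_base,
                        anchor_base + str(allele[1]),
                        "ins",
                        support,
                        total,
                        min(1.0, support / total),
                    )
                )
            else:
                dlen = int(allele[1])
                calls.append(
                    VariantCall(
                        anchor,
                        anchor_base + ref.fetch(anchor + 1, dlen),
                        anchor_base,
                        "del",
                        support,
                        total,
                        min(1.0, support / total),
                    )
                )
    calls.sort(key=lambda c: (c.pos, c.ref, c.alt))
    return calls


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

@dataclass
class ConsensusAssembly:
    contigs: list[tuple[int, int, str]]  # (1-based start, end, sequence)
    breadth_pct: float
    mean_depth: float

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    def callable_intervals(self) -> list[tuple[int, int]]:
        return [(s, e) for s, e, _seq in self.contigs]

    def to_fasta(self, cell_id: str, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, (s, e, seq) in enumerate(self.contigs, start=1):
                fh.write(f">{cell_id}|contig_{i}|{s}-{e}\n")
                for j in range(0, len(seq), 70):
                    fh.write(seq[j : j + 70] + "\n")

    def to_bed(self, path: str | Path, chrom: str = "chrM") -> None:
        with open(path, "w") as fh:
            for s, e, _seq in self.contigs:
                fh.write(f"{chrom}\t{s - 1}\t{e}\n")  # BED half-open, 0-based

    def stats(self) -> dict:
        return {
            "breadth_pct": round(self.breadth_pct, 2),
            "mean_depth": round(self.mean_depth, 2),
            "n_contigs": self.n_contigs,
        }


def build_consensus(
    pileup: Pileup,
    calls: list[VariantCall],
    ref: MitoReference,
    hf_threshold: float = 0.8,
    min_depth: int = 5,
) -> ConsensusAssembly:
    """Assemble callable contigs, writing alternates at AF >= hf_threshold.

    Positions with quality-filtered depth below ``min_depth`` are non-callable
    and split contigs (they are omitted, not written as N). At a multiallelic
    site the single most frequent alternate is applied only if it alone
    reaches the threshold. Indel calls passing the threshold are applied
    (deleted bases omitted, insertions appended after their anchor).
    """
    depth = pileup.filtered_depth
    callable_mask = depth >= min_depth
    L = ref.length

    snp_at: dict[int, VariantCall] = {}
    ins_at: dict[int, VariantCall] = {}
    del_span: dict[int, int] = {}  # first deleted position -> length
    for c in calls:
        if c.af < hf_threshold:
            continue
        if c.vtype == "snp":
            cur = snp_at.get(c.pos)
            if cur is None or c.support > cur.support:
                snp_at[c.pos] = c
        elif c.vtype == "ins":
            ins_at[c.pos] = c
        elif c.vtype == "del":
            del_span[c.pos + 1] = len(c.ref) - 1

    contigs: list[tuple[int, int, str]] = []
    pos = 1
    while pos <= L:
        if not callable_mask[pos - 1]:
            pos += 1
            continue
        start = pos
        parts: list[str] = []
        skip_until = 0
        while pos <= L and callable_mask[pos - 1]:
            if pos >= skip_until:
                if pos in del_span:
                    skip_until = pos + del_span[pos]
                else:
                    c = snp_at.get(pos)
                    parts.append(c.alt if c else ref.base(pos))
                    ic = ins_at.get(pos)
                    if ic:
                        parts.append(ic.alt[1:])
            pos += 1
        contigs.append((start, pos - 1, "".join(parts)))

    breadth = 100.0 * int(callable_mask.sum()) / L
    mean_depth = float(depth.sum()) / L
    return ConsensusAssembly(contigs=contigs, breadth_pct=breadth, mean_depth=mean_depth)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(
    calls: list[VariantCall],
    ref: MitoReference,
    sample_id: str,
    path: str | Path,
    chrom: str = "chrM",
) -> None:
    """Write calls as VCF v4.2 with DP/AF/TYPE INFO fields."""
    positions = [c.pos for c in calls]
    if positions != sorted(positions):
        raise ValueError("calls must be sorted by position")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=scmito\n##sample={sample_id}\n")
        fh.write(f"##contig=<ID={chrom},length={ref.length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Quality-filtered depth">\n')
        fh.write('##INFO=<ID=SUP,Number=A,Type=Integer,Description="Supporting depth">\n')
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Heteroplasmy fraction">\n')
        fh.write('##INFO=<ID=TYPE,Number=A,Type=String,Description="snp, ins or del">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            info = f"DP={c.total};SUP={c.support};AF={c.af:.10g};TYPE={c.vtype}"
            fh.write(f"{chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\n")


def read_vcf(path: str | Path) -> list[VariantCall]:
    """Read a VCF written by :func:`write_vcf` back into calls (via pysam)."""
    import pysam

    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alt = rec.alts[0]
            vtype = rec.info.get("TYPE", ("snp",))
            vtype = vtype[0] if isinstance(vtype, tuple) else vtype
            af = rec.info["AF"]
            af = af[0] if isinstance(af, tuple) else af
            total = int(rec.info["DP"])
            sup = rec.info.get("SUP")
            if sup is not None:
                support = int(sup[0] if isinstance(sup, tuple) else sup)
            else:
                support = int(round(total * af))
            calls.append(
                VariantCall(
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    vtype=str(vtype),
                    support=support,
                    total=total,
                    af=support / total if total else float(af),
                )
            )
    return calls
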