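"""Synthetic single-cell mtDNA sequencing data generator.

Emulates the statistical structure of single-cell whole-genome-amplified
(scWGA) mtDNA libraries so the downstream reconstruction pipeline can be
exercised and evaluated against known truth, without any external data:

* protocol-specific positional coverage bias over the circular genome
  (uniform bulk; smooth lognormal amplification fields for MDA/eWGA;
  window-concentrated amplicon bias for DOP-PCR; window bias plus genome
  dropout for MALBAC; uniform with heavy PCR duplication for ATAC-like
  libraries),
* heteroplasmy as independent Bernoulli(h) draws per read at each
  heteroplasmic site,
* PCR duplicates (fragment-coordinate copies) at a protocol duplicate rate,
* per-base substitution sequencing error with Phred+33 qualities drawn so
  erroneous bases are low-quality (Q 2-20) and correct bases high-quality
  (Q 25-40), giving the downstream Q>=30 pileup filter real work,
* NumtS decoys: diverged contiguous mtDNA segments embedded at recorded
  coordinates in random nuclear background contigs.

Every operation is a pure function of its inputs and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .phylotree import ToyPhylotree, Variant
from .reference import MitoReference

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_B2I = {b: i for i, b in enumerate("ACGT")}

MIN_REFERENCE_LENGTH = 1000


# ---------------------------------------------------------------------------
# reference and genotypes
# ---------------------------------------------------------------------------

def build_reference(length: int, seed: int, name: str = "chrM") -> MitoReference:
    """Random circular reference with roughly uniform base composition."""
    if length < MIN_REFERENCE_LENGTH:
        raise ValueError(
            f"reference length {length} below minimum {MIN_REFERENCE_LENGTH}"
        )
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length).tobytes().decode()
    return MitoReference(name=name, sequence=seq)


@dataclass(frozen=True)
class CellGenotype:
    """True mtDNA state of one simulated cell.

    ``haplogroup`` names a node of a :class:`ToyPhylotree`; its cumulative
    defining variants are homoplasmic. ``extra_homoplasmic`` adds private
    fixed variants; ``heteroplasmic`` holds (pos, ref, alt, fraction) with
    fraction strictly inside (0, 1).
    """

    cell_id: str
    haplogroup: str | None = None
    extra_homoplasmic: frozenset[Variant] = frozenset()
    heteroplasmic: frozenset[tuple[int, str, str, float]] = frozenset()

    def __post_init__(self) -> None:
        hom_pos = {v[0] for v in self.extra_homoplasmic}
        for pos, _ref, _alt, h in self.heteroplasmic:
            if not 0.0 < h < 1.0:
                raise ValueError(f"heteroplasmic fraction {h} at {pos} not in (0,1)")
            if pos in hom_pos:
                raise ValueError(f"position {pos} is both homoplasmic and heteroplasmic")


@dataclass(frozen=True)
class Haplotype:
    """Realized cell genome: homoplasmic variants applied to the sequence.

    ``truth`` lists every simulated variant in reference coordinates with its
    fraction (1.0 for homoplasmic). ``het_sites`` are mixture instructions in
    *haplotype* coordinates, consumed by read generation.
    """

    sequence: str
    truth: tuple[tuple[int, str, str, float], ...]
    het_sites: tuple[tuple[int, str, str, float], ...]  # (hap pos, ref, alt, h)


def apply_genotype(
    ref: MitoReference, tree: ToyPhylotree | None, genotype: CellGenotype
) -> Haplotype:
    """Apply a genotype to the reference, returning haplotype + truth list.

    Homoplasmic variants (haplogroup path plus extras) are written into the
    sequence; heteroplasmic variants (SNPs only) are kept as per-read mixture
    instructions. Indels among the homoplasmic variants shift downstream
    haplotype coordinates; the returned het instructions account for that.
    """
    hom: set[Variant] = set(genotype.extra_homoplasmic)
    if genotype.haplogroup is not None:
        if tree is None:
            raise ValueError("genotype names a haplogroup but no tree was given")
        hom |= tree.cumulative_variants(genotype.haplogroup)

    for pos, vref, valt in sorted(hom):
        if ref.fetch(pos, len(vref)) != vref:
            raise ValueError(
                f"reference allele mismatch at position {pos}: "
                f"expected {vref!r}, reference has {ref.fetch(pos, len(vref))!r}"
            )
    for pos, vref, valt, _h in genotype.heteroplasmic:
        if len(vref) != 1 or len(valt) != 1:
            raise ValueError("heteroplasmic variants must be single-base substitutions")
        if ref.base(pos) != vref:
            raise ValueError(
                f"reference allele mismatch at position {pos}: "
                f"expected {vref!r}, reference has {ref.base(pos)!r}"
            )

    # apply homoplasmic edits right-to-left so positions stay valid
    seq = ref.sequence
    for pos, vref, valt in sorted(hom, reverse=True):
        seq = seq[: pos - 1] + valt + seq[pos - 1 + len(vref) :]

    # haplotype coordinate of each het site = ref pos + net indel shift upstream
    shifts = sorted((pos, len(valt) - len(vref)) for pos, vref, valt in hom)
    het_sites = []
    for pos, vref, valt, h in sorted(genotype.heteroplasmic):
        off = sum(d for p, d in shifts if p < pos)
        het_sites.append((pos + off, vref, valt, h))

    truth = [(pos, vref, valt, 1.0) for pos, vref, valt in sorted(hom)]
    truth += [(pos, vref, valt, h) for pos, vref, valt, h in sorted(genotype.heteroplasmic)]
    truth.sort()
    return Haplotype(sequence=seq, truth=tuple(truth), het_sites=tuple(het_sites))


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtocolModel:
    """Positional-bias and noise model of one library preparation protocol.

    The bias is expressed as a positional weight function over the circular
    genome from which read start positions are drawn:

    * ``lognormal_sigma`` > 0 turns on a smoothed lognormal amplification
      field (MDA-like; eWGA uses a smaller sigma than MDA),
    * ``n_windows`` > 0 concentrates weight in randomly placed windows of
      ``window_length`` bases (DOP-PCR amplicon-like), the rest of the genome
      keeping ``background_weight``,
    * ``dropout_fraction`` zeroes that expected fraction of the genome in
      contiguous blocks (MALBAC-like fragmentation/dropout).
    """

    name: str
    lognormal_sigma: float = 0.0
    smooth_window: int = 300
    n_windows: int = 0
    window_length: int = 600
    background_weight: float = 0.05
    dropout_fraction: float = 0.0
    dropout_block: int = 200
    duplicate_rate: float = 0.02
    error_rate: float = 0.001
    read_length: int = 100
    length_jitter: int = 10  # fragment lengths drawn from [rl - jitter, rl]
    paired: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_fraction < 1.0:
            raise ValueError("dropout fraction must be in [0, 1)")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error rate must be in [0, 0.1]")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ValueError("duplicate rate must be in [0, 1)")


#: Default protocol models. The field-reported ordering of coverage bias
#: (MALBAC, DOP-PCR most uneven; MDA/eWGA mildly uneven; bulk uniform) emerges
#: from these settings; magnitudes are package choices, not published fits.
PROTOCOLS: dict[str, ProtocolModel] = {
    "BULK": ProtocolModel("BULK", duplicate_rate=0.02),
    "MDA": ProtocolModel("MDA", lognormal_sigma=0.8, duplicate_rate=0.05),
    "eWGA": ProtocolModel("eWGA", lognormal_sigma=0.5, duplicate_rate=0.05),
    "DOP": ProtocolModel("DOP", n_windows=8, window_length=600, duplicate_rate=0.10),
    "MALBAC": ProtocolModel(
        "MALBAC",
        n_windows=6,
        window_length=500,
        background_weight=0.02,
        dropout_fraction=0.5,
        duplicate_rate=0.10,
    ),
    "ATAC": ProtocolModel("ATAC", duplicate_rate=0.30),
}


def get_protocol(name: str, **overrides) -> ProtocolModel:
    model = PROTOCOLS[name.upper() if name.upper() in PROTOCOLS else name]
    return replace(model, **overrides) if overrides else model


def positional_weights(model: ProtocolModel, length: int, rng: np.random.Generator) -> np.ndarray:
    """Normalized read-start weight per position of the circular genome."""
    w = np.ones(length)
    if model.lognormal_sigma > 0:
        z = rng.standard_normal(length)
        k = min(model.smooth_window, length)
        kernel = np.ones(k) / k
        # circular smoothing via FFT-free wrap-around convolution
        z = np.convolve(np.concatenate([z, z[: k - 1]]), kernel, mode="valid")
        z = (z - z.mean()) / max(z.std(), 1e-12)
        w *= np.exp(model.lognormal_sigma * z)
    if model.n_windows > 0:
        mask = np.full(length, model.background_weight)
        starts = rng.integers(0, length, size=model.n_windows)
        idx = (starts[:, None] + np.arange(model.window_length)[None, :]) % length
        mask[idx.ravel()] = 1.0
        w *= mask
    if model.dropout_fraction > 0:
        n_blocks = int(np.ceil(length / model.dropout_block))
        drop = rng.random(n_blocks) < model.dropout_fraction
        block_of = np.arange(length) // model.dropout_block
        w[drop[block_of]] = 0.0
        if not w.any():  # keep at least one block alive
            keep = int(rng.integers(0, n_blocks)) * model.dropout_block
            w[keep : keep + model.dropout_block] = 1.0
    return w / w.sum()


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

_COMP = bytes.maketrans(b"ACGT", b"TGCA")


def revcomp(seq: str) -> str:
    return seq.encode().translate(_COMP)[::-1].decode()


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    quality: str  # Phred+33
    origin: str  # "mt" | "numts" | "nuclear"
    source: tuple[str, int, int, str]  # (contig, 1-based start, end, strand)

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError("sequence and quality lengths differ")


@dataclass
class ReadSet:
    reads: list[ReadRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def to_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")

    @classmethod
    def from_fastq(cls, path: str | Path, origin: str = "mt") -> "ReadSet":
        reads = []
        with open(path) as fh:
            while True:
                head = fh.readline().rstrip()
                if not head:
                    break
                seq = fh.readline().rstrip()
                fh.readline()
                qual = fh.readline().rstrip()
                reads.append(
                    ReadRecord(head[1:].split()[0], seq, qual, origin, ("?", 0, 0, "+"))
                )
        return cls(reads)


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _apply_errors_and_quals(
    frag: np.ndarray, error_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Substitution errors at ``error_rate``; Q 2-20 for errors, 25-40 else."""
    n = frag.size
    err = rng.random(n) < error_rate
    out = frag.copy()
    if err.any():
        idx = np.flatnonzero(err)
        # pick one of the three non-identical bases
        shift = rng.integers(1, 4, size=idx.size)
        cur = np.searchsorted(_BASES, out[idx])
        out[idx] = _BASES[(cur + shift) % 4]
    q = rng.integers(25, 41, size=n)
    if err.any():
        q[err] = rng.integers(2, 21, size=int(err.sum()))
    return out, q


def _qual_string(q: np.ndarray) -> str:
    return (q.astype(np.uint8) + 33).tobytes().decode()


def generate_reads(
    haplotype: Haplotype | str,
    protocol: ProtocolModel,
    target_depth: float,
    seed: int,
    cell_id: str = "cell",
    contig_name: str = "chrM",
) -> ReadSet:
    """Sample reads from a circular haplotype under a protocol bias model.

    Emits exactly ``round(target_depth * L / read_length)`` reads, a
    ``duplicate_rate`` fraction of which are fragment-coordinate copies of
    other emitted fragments (PCR duplicates re-sequenced independently, i.e.
    with fresh errors/qualities). At heteroplasmic sites each non-duplicate
    fragment draws the alternate allele independently with probability h;
    duplicates inherit their template's allele, as PCR amplifies molecules.
    """
    if target_depth <= 0:
        raise ValueError("target_depth must be positive")
    hap = haplotype if isinstance(haplotype, Haplotype) else Haplotype(haplotype, (), ())
    rng = np.random.default_rng(seed)
    seq = _seq_to_array(hap.sequence)
    L = seq.size
    rl = min(protocol.read_length, L)
    jitter = min(protocol.length_jitter, max(0, rl - 2 * 15))
    mean_len = rl - jitter / 2
    n_total = max(1, int(round(target_depth * L / mean_len)))
    n_dup = int(round(n_total * protocol.duplicate_rate))
    n_unique = max(1, n_total - n_dup)
    n_dup = n_total - n_unique

    weights = positional_weights(protocol, L, rng)
    starts = rng.choice(L, size=n_unique, p=weights)
    strands = rng.random(n_unique) < 0.5
    lengths = rl - rng.integers(0, jitter + 1, size=n_unique)

    het = [(p - 1, ord(r), ord(a), h) for p, r, a, h in hap.het_sites]

    fragments: list[tuple[int, bool, np.ndarray]] = []
    offs = np.arange(rl)
    for s, minus, flen in zip(starts, strands, lengths):
        frag = seq[(s + offs[:flen]) % L].copy()
        for hp, _rb, ab, h in het:
            rel = (hp - s) % L
            if rel < flen and rng.random() < h:
                frag[rel] = ab
        fragments.append((int(s), bool(minus), frag))

    if n_dup:
        for i in rng.integers(0, n_unique, size=n_dup):
            fragments.append(fragments[int(i)])

    reads = []
    for i, (s, minus, frag) in enumerate(fragments):
        obs, q = _apply_errors_and_quals(frag, protocol.error_rate, rng)
        if minus:
            obs = obs[::-1]
            obs = np.frombuffer(obs.tobytes().translate(_COMP), dtype=np.uint8)
            q = q[::-1]
        reads.append(
            ReadRecord(
                read_id=f"{cell_id}|r{i:06d}",
                sequence=obs.tobytes().decode(),
                quality=_qual_string(q),
                origin="mt",
                source=(contig_name, s + 1, s + frag.size, "-" if minus else "+"),
            )
        )
    return ReadSet(reads)


def true_depth_profile(readset: ReadSet, length: int, origin: str = "mt") -> np.ndarray:
    """Per-base depth implied by the truth source intervals (circular)."""
    diff = np.zeros(length + 1, dtype=np.int64)
    for r in readset:
        if r.origin != origin:
            continue
        _c, start, end, _s = r.source
        s = (start - 1) % length
        e = s + (end - start + 1)
        if e <= length:
            diff[s] += 1
            diff[e] -= 1
        else:  # wraps through the origin
            diff[s] += 1
            diff[length] -= 1
            diff[0] += 1
            diff[e - length] -= 1
    return np.cumsum(diff[:length])


# ---------------------------------------------------------------------------
# NumtS decoys
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NumtSModel:
    """Nuclear-embedded mitochondrial segment (NumtS) decoy model."""

    n_insertions: int = 3
    min_length: int = 300
    max_length: int = 1500
    divergence: float = 0.03
    contig_length: int = 30000

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 0.2:
            raise ValueError("divergence must be in [0, 0.2]")
        if self.min_length > self.max_length:
            raise ValueError("min_length > max_length")


@dataclass(frozen=True)
class NumtSInterval:
    contig: str
    start: int  # 1-based inclusive, on the decoy contig
    end: int
    mt_start: int  # 1-based start of the source segment on the mt haplotype
    mt_length: int


def insert_numts(
    mt_sequence: str,
    model: NumtSModel,
    seed: int,
    contig_name: str = "decoy1",
) -> tuple[list[tuple[str, str]], list[NumtSInterval]]:
    """Embed diverged mtDNA segments in a random nuclear background contig.

    Each NumtS is a contiguous (circular) substring of the mt haplotype with
    i.i.d. substitutions at the divergence rate, overwriting the background at
    a recorded, non-overlapping interval.
    """
    rng = np.random.default_rng(seed)
    slot = model.contig_length // max(model.n_insertions, 1)
    if model.max_length > slot:
        raise ValueError(
            f"contig of {model.contig_length} bp cannot host {model.n_insertions} "
            f"insertions of up to {model.max_length} bp without overlap"
        )
    background = rng.choice(_BASES, size=model.contig_length)
    mt = _seq_to_array(mt_sequence)
    L = mt.size
    intervals = []
    for i in range(model.n_insertions):
        seg_len = int(rng.integers(model.min_length, model.max_length + 1))
        src = int(rng.integers(0, L))
        seg = mt[(src + np.arange(seg_len)) % L].copy()
        if model.divergence > 0:
            mut = rng.random(seg_len) < model.divergence
            if mut.any():
                idx = np.flatnonzero(mut)
                shift = rng.integers(1, 4, size=idx.size)
                cur = np.searchsorted(_BASES, seg[idx])
                seg[idx] = _BASES[(cur + shift) % 4]
        offset = i * slot + int(rng.integers(0, slot - seg_len + 1))
        background[offset : offset + seg_len] = seg
        intervals.append(
            NumtSInterval(contig_name, offset + 1, offset + seg_len, src + 1, seg_len)
        )
    return [(contig_name, background.tobytes().decode())], intervals


def generate_decoy_reads(
    contigs: list[tuple[str, str]],
    intervals: list[NumtSInterval],
    n_reads: int,
    seed: int,
    read_length: int = 100,
    error_rate: float = 0.001,
    cell_id: str = "decoy",
) -> ReadSet:
    """Uniform reads from the (linear) decoy contigs, truth-labelled.

    A read is labelled ``numts`` when at least half of it lies inside an
    embedded NumtS interval, ``nuclear`` otherwise.
    """
    rng = np.random.default_rng(seed)
    reads = []
    by_contig: dict[str, list[NumtSInterval]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append(iv)
    names = [c[0] for c in contigs]
    seqs = {name: _seq_to_array(s) for name, s in contigs}
    sizes = np.array([len(s) - read_length + 1 for _n, s in contigs])
    probs = sizes / sizes.sum()
    for i in range(n_reads):
        ci = int(rng.choice(len(names), p=probs))
        name = names[ci]
        s = int(rng.integers(0, sizes[ci]))
        frag = seqs[name][s : s + read_length]
        obs, q = _apply_errors_and_quals(frag, error_rate, rng)
        minus = rng.random() < 0.5
        if minus:
            obs = np.frombuffer(obs[::-1].tobytes().translate(_COMP), dtype=np.uint8)
            q = q[::-1]
        overlap = 0
        for iv in by_contig.get(name, []):
            overlap = max(overlap, min(iv.end, s + read_length) - max(iv.start - 1, s))
        origin = "numts" if overlap >= read_length / 2 else "nuclear"
        reads.append(
            ReadRecord(
                read_id=f"{cell_id}|d{i:06d}",
                sequence=obs.tobytes().decode(),
                quality=_qual_string(q),
                origin=origin,
                source=(name, s + 1, s + read_length, "-" if minus else "+"),
            )
        )
    return ReadSet(reads)


def merge_readsets(*readsets: ReadSet) -> ReadSet:
    out: list[ReadRecord] = []
    for rs in readsets:
        out.extend(rs.reads)
    return ReadSet(out)


# ---------------------------------------------------------------------------
# toy tree generation
# ---------------------------------------------------------------------------

#: (name, parent, number of branch-defining variants) — a small clade layout
#: echoing the macrohaplogroup L -> M/N structure of the human mtDNA phylogeny.
_TOY_TOPOLOGY = [
    ("L3", None, 3),
    ("M", "L3", 2),
    ("N", "L3", 2),
    ("M7", "M", 2),
    ("M7b1", "M7", 2),
    ("M7c1", "M7", 2),
    ("R", "N", 2),
    ("F4a", "R", 3),
    ("K", "R", 2),
    ("K1a", "K", 2),
]


def make_toy_tree(ref: MitoReference, seed: int) -> ToyPhylotree:
    """Random toy haplogroup tree consistent with ``ref`` (SNPs only)."""
    rng = np.random.default_rng(seed)
    total = sum(n for _a, _b, n in _TOY_TOPOLOGY)
    positions = rng.choice(
        np.arange(100, ref.length - 100), size=total, replace=False
    )
    positions = iter(positions.tolist())
    nodes: dict[str, tuple[str | None, list[Variant]]] = {}
    for name, parent, n_vars in _TOY_TOPOLOGY:
        variants = []
        for _ in range(n_vars):
            pos = int(next(positions))
            rbase = ref.base(pos)
            alt = "ACGT"[(_B2I[rbase] + int(rng.integers(1, 4))) % 4]
            variants.append((pos, rbase, alt))
        nodes[name] = (parent, sorted(variants))
    return ToyPhylotree(nodes)


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records],
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_truth_tsv(
    path: str | Path, cell_truths: dict[str, tuple[tuple[int, str, str, float], ...]]
) -> None:
    with open(path, "w") as fh:
        fh.write("cell_id\tpos\tref\talt\tfraction\n")
        for cell, truth in cell_truths.items():
            for pos, ref, alt, frac in truth:
                fh.write(f"{cell}\t{pos}\t{ref}\t{alt}\t{frac:g}\n")
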