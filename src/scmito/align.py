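"""Read trimming, seed-and-extend alignment, duplicate removal, NUMT filter.

One internal aligner serves both selective rounds of the mtDNA read-rescue
strategy: reads are aligned against a combined index holding the circular
mtDNA (stored doubled, so seeds and alignments may span the origin) and
nuclear decoy contigs. A read is accepted as genuine mtDNA only when its best
mtDNA alignment score is strictly greater than its best nuclear score — reads
scoring equally on both (the NumtS signature) are discarded.

Scoring is local (Smith-Waterman style) with affine gaps; defaults are
match +1, mismatch -1, first gap base -2, each further gap base -1.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .reference import MitoReference
from .simulate import ReadRecord, ReadSet, revcomp

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGT")


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrimConfig:
    """Adapter / quality trimming parameters (3' end only)."""

    adapter: str = "AGATCGGAAGAGC"
    min_overlap: int = 3
    quality_cutoff: int = 20
    min_length: int = 30

    def __post_init__(self) -> None:
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0 <= self.quality_cutoff <= 41:
            raise ValueError("quality_cutoff must be in [0, 41]")


def trim_read(seq: str, qual: str, cfg: TrimConfig) -> tuple[str, str]:
    """Trim one read: adapter-prefix suffix match, then low-quality 3' bases."""
    n = len(seq)
    for ell in range(min(len(cfg.adapter), n), cfg.min_overlap - 1, -1):
        if seq.endswith(cfg.adapter[:ell]):
            seq, qual = seq[: n - ell], qual[: n - ell]
            break
    while seq and ord(qual[-1]) - 33 < cfg.quality_cutoff:
        seq, qual = seq[:-1], qual[:-1]
    return seq, qual


def trim_reads(reads: ReadSet, cfg: TrimConfig) -> ReadSet:
    out = []
    for r in reads:
        seq, qual = trim_read(r.sequence, r.quality, cfg)
        if len(seq) >= cfg.min_length:
            out.append(ReadRecord(r.read_id, seq, qual, r.origin, r.source))
    return ReadSet(out)


# ---------------------------------------------------------------------------
# index
# ---------------------------------------------------------------------------

@dataclass
class IndexedReference:
    name: str
    sequence: str
    ref_class: str  # "mt" | "nuclear"
    circular: bool

    @property
    def length(self) -> int:
        return len(self.sequence)


class AlignmentIndex:
    """Exact k-mer index over the doubled mtDNA plus nuclear decoy contigs.

    mtDNA k-mer hits are canonicalized modulo the genome length, so a k-mer
    spanning the origin is indexed at its true circular start.
    """

    def __init__(
        self,
        mt: MitoReference | None,
        decoys: list[tuple[str, str]] | None = None,
        k: int = 15,
    ) -> None:
        if not 8 <= k <= 31:
            raise ValueError("k must be in [8, 31]")
        self.k = k
        self.refs: dict[str, IndexedReference] = {}
        self._kmers: dict[str, list[tuple[str, int]]] = defaultdict(list)
        if mt is not None:
            self.refs[mt.name] = IndexedReference(mt.name, mt.sequence, "mt", True)
            self._index(mt.name, mt.sequence + mt.sequence, n_positions=mt.length)
        for name, seq in decoys or []:
            self.refs[name] = IndexedReference(name, seq, "nuclear", False)
            self._index(name, seq, n_positions=len(seq) - k + 1)

    def _index(self, name: str, seq: str, n_positions: int) -> None:
        k = self.k
        if n_positions < 1:
            raise ValueError(f"reference {name!r} shorter than k={k}")
        skipped = 0
        for p in range(n_positions):
            kmer = seq[p : p + k]
            if set(kmer) <= _VALID:
                self._kmers[kmer].append((name, p))
            else:
                skipped += 1
        if skipped:
            logger.info("index %s: skipped %d positions with degenerate bases", name, skipped)

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """All (reference name, 0-based canonical position) occurrences."""
        return self._kmers.get(kmer, [])


# ---------------------------------------------------------------------------
# alignment record
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap_open: int = -2   # cost of the first base of a gap
    gap_extend: int = -1


@dataclass
class Alignment:
    """Local alignment of one read against one reference.

    ``start`` is the 1-based reference position of the first aligned base
    (canonical, in [1, L] for the circular mtDNA; the alignment may extend
    past L, wrapping). ``cigar`` uses ops S/M/I/D and consumes exactly the
    read; ``sequence``/``quality`` are stored reference-strand oriented.
    """

    read_id: str
    ref_name: str
    ref_class: str
    start: int
    strand: str
    score: int
    cigar: list[tuple[str, int]]
    sequence: str
    quality: str
    origin: str = "mt"
    ambiguous: bool = False

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def end(self) -> int:
        """1-based end, unwrapped (may exceed L for origin-spanning hits)."""
        return self.start + self.ref_span - 1

    @property
    def quality_sum(self) -> int:
        return sum(ord(c) - 33 for c in self.quality)

    def read_consumed(self) -> int:
        return sum(n for op, n in self.cigar if op in "SMI")


# ---------------------------------------------------------------------------
# gapped extension (Gotoh, local, with traceback)
# ---------------------------------------------------------------------------

def _gotoh_local(q: np.ndarray, t: np.ndarray, sc: Scoring):
    """Full local DP of query q vs target t; returns (score, cigar-core,
    query start offset, query end, target start offset, target end).

    Row recurrences are vectorized; the in-row horizontal-gap dependency is
    resolved in closed form (running maximum of H[j'] - ext*j').
    """
    m, n = q.size, t.size
    NEG = -(10**6)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in query (consumes target)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in target (consumes query)
    go, ge, ma, mi = sc.gap_open, sc.gap_extend, sc.match, sc.mismatch
    jj = np.arange(1, n + 1)
    for i in range(1, m + 1):
        sub = np.where(t == q[i - 1], ma, mi)
        F[i, 1:] = np.maximum(F[i - 1, 1:] + ge, H[i - 1, 1:] + go)
        diag = H[i - 1, :-1] + sub
        # E[i,j] = max(E[i,j-1]+ge, H[i,j-1]+go) depends on H within the row;
        # closed form: E[i,j] = ge*(j-1) + go + max_{j'<j}(H[i,j'] - ge*j').
        # Compute H without E first, then fold E in with one accumulate pass.
        h_no_e = np.maximum(0, np.maximum(diag, F[i, 1:]))
        base = np.maximum.accumulate(
            np.concatenate(([H[i, 0]], h_no_e[:-1])) - ge * np.arange(n)
        )
        E[i, 1:] = ge * (jj - 1) + go + base
        # one more pass: H with E may feed later E cells; iterate to fixpoint
        # (two passes suffice because E only increases H, and the accumulate
        # already majorizes chains of extensions through increased cells)
        h_final = np.maximum(h_no_e, E[i, 1:])
        base2 = np.maximum.accumulate(
            np.concatenate(([H[i, 0]], h_final[:-1])) - ge * np.arange(n)
        )
        E[i, 1:] = ge * (jj - 1) + go + base2
        H[i, 1:] = np.maximum(h_no_e, E[i, 1:])
    best = int(H.max())
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    # traceback
    ops: list[str] = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            sub = ma if q[i - 1] == t[j - 1] else mi
            if H[i, j] == H[i - 1, j - 1] + sub:
                ops.append("M")
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = "E"
            elif H[i, j] == F[i, j]:
                state = "F"
            else:  # numerical impossibility guard
                break
        elif state == "E":
            ops.append("D")
            if E[i, j] == H[i, j - 1] + go:
                state = "H"
            j -= 1
        else:  # F
            ops.append("I")
            if F[i, j] == H[i - 1, j] + go:
                state = "H"
            i -= 1
    ops.reverse()
    q0, t0 = i, j
    qe, te = np.unravel_index(int(H.argmax()), H.shape)
    return best, ops, q0, int(qe), t0, int(te)


def _compress_cigar(ops: list[tuple[str, int] | str]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for item in ops:
        op, n = item if isinstance(item, tuple) else (item, 1)
        if n == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def _kadane(scores: np.ndarray) -> tuple[int, int, int]:
    """Best contiguous segment sum with bounds [start, end)."""
    best, best_s, best_e = 0, 0, 0
    cur, cur_s = 0, 0
    for i, v in enumerate(scores):
        cur += int(v)
        if cur <= 0:
            cur, cur_s = 0, i + 1
        elif cur > best:
            best, best_s, best_e = cur, cur_s, i + 1
    return best, best_s, best_e


# ---------------------------------------------------------------------------
# align_read
# ---------------------------------------------------------------------------

def _window(ref: IndexedReference, start0: int, length: int) -> tuple[np.ndarray, int]:
    """Reference window as uint8 array; pads with 'N' beyond linear contigs.

    Returns (array, actual 0-based start of the first array element).
    """
    if ref.circular:
        L = ref.length
        s = start0 % L
        seq = ref.sequence + ref.sequence + ref.sequence[: length]
        return np.frombuffer(seq[s : s + length].encode(), dtype=np.uint8), s
    lo = max(0, start0)
    hi = min(ref.length, start0 + length)
    core = ref.sequence[lo:hi] if hi > lo else ""
    pad_l = lo - start0
    pad_r = length - pad_l - len(core)
    arr = np.frombuffer(
        ("N" * pad_l + core + "N" * max(0, pad_r)).encode(), dtype=np.uint8
    )
    return arr, start0


def align_read(
    read: ReadRecord | tuple[str, str, str],
    index: AlignmentIndex,
    scoring: Scoring = Scoring(),
    band: int = 15,
    seed_stride: int | None = None,
    max_candidates: int = 8,
) -> list[Alignment]:
    """Best local alignment of a read per reference class (mt, nuclear).

    Seeds are exact k-mer hits sampled along the read on both strands; each
    candidate diagonal is scored first by an ungapped pass (best-scoring
    contiguous segment) and, when a gap could possibly improve on that, by a
    full local Gotoh DP over a banded window around the diagonal.
    """
    if isinstance(read, ReadRecord):
        rid, seq, qual, origin = read.read_id, read.sequence, read.quality, read.origin
    else:
        rid, seq, qual = read
        origin = "mt"
    k = index.k
    m = len(seq)
    if m < k:
        return []
    stride = seed_stride or k
    sc = scoring

    best_by_class: dict[str, Alignment] = {}

    for strand in "+-":
        if strand == "+":
            q_str, q_qual = seq, qual
        else:
            q_str, q_qual = revcomp(seq), qual[::-1]
        q = np.frombuffer(q_str.encode(), dtype=np.uint8)

        votes: dict[tuple[str, int], int] = defaultdict(int)
        offsets = list(range(0, m - k + 1, stride))
        if offsets[-1] != m - k:
            offsets.append(m - k)
        for off in offsets:
            for name, p in index.lookup(q_str[off : off + k]):
                ref = index.refs[name]
                d = (p - off) % ref.length if ref.circular else p - off
                votes[(name, d)] += 1

        by_ref: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for (name, d), v in votes.items():
            by_ref[name].append((v, d))

        for name, cand in by_ref.items():
            ref = index.refs[name]
            cand.sort(reverse=True)
            for _v, d in cand[:max_candidates]:
                t, win_start = _window(ref, d, m)
                per_base = np.where(t == q, sc.match, sc.mismatch)
                per_base[t == ord("N")] = sc.mismatch
                u_score, u_s, u_e = _kadane(per_base)
                aln = None
                if u_score > 0:
                    cigar = _compress_cigar(
                        [("S", u_s), ("M", u_e - u_s), ("S", m - u_e)]
                    )
                    aln = (u_score, win_start + u_s, cigar)
                if u_score < m * sc.match - 2:
                    # a gap could beat the ungapped reading; run banded DP
                    t2, w2 = _window(ref, d - band, m + 2 * band)
                    g_score, ops, q0, qe, t0, te = _gotoh_local(q, t2, sc)
                    if g_score > (aln[0] if aln else 0):
                        cigar = _compress_cigar(
                            [("S", q0)] + [(op, 1) for op in ops] + [("S", m - qe)]
                        )
                        aln = (g_score, w2 + t0, cigar)
                if aln is None:
                    continue
                score, start0, cigar = aln
                start = start0 % ref.length + 1 if ref.circular else start0 + 1
                oriented_seq = q_str
                oriented_qual = q_qual
                new = Alignment(
                    read_id=rid,
                    ref_name=name,
                    ref_class=ref.ref_class,
                    start=start,
                    strand=strand,
                    score=score,
                    cigar=cigar,
                    sequence=oriented_seq,
                    quality=oriented_qual,
                    origin=origin,
                )
                cur = best_by_class.get(ref.ref_class)
                if cur is None or new.score > cur.score:
                    best_by_class[ref.ref_class] = new
                elif new.score == cur.score and (
                    new.start, new.ref_name, new.strand
                ) != (cur.start, cur.ref_name, cur.strand):
                    # equal-best placements: keep the lowest coordinate, flag
                    keep = min((cur, new), key=lambda a: (a.ref_name, a.start))
                    keep.ambiguous = True
                    best_by_class[ref.ref_class] = keep
    return list(best_by_class.values())


# ---------------------------------------------------------------------------
# duplicate removal & NUMT filter
# ---------------------------------------------------------------------------

def remove_duplicates(alignments: list[Alignment]) -> list[Alignment]:
    """Keep one alignment per (start, end, strand): highest base-quality sum,
    ties broken by lexicographically smallest read id. Idempotent."""
    best: dict[tuple[int, int, str], Alignment] = {}
    for a in alignments:
        key = (a.start, a.end, a.strand)
        cur = best.get(key)
        if (
            cur is None
            or a.quality_sum > cur.quality_sum
            or (a.quality_sum == cur.quality_sum and a.read_id < cur.read_id)
        ):
            best[key] = a
    return sorted(best.values(), key=lambda a: (a.start, a.end, a.strand, a.read_id))


@dataclass
class FilterDecision:
    read_id: str
    mt_score: int | None
    nuclear_score: int | None
    kept: bool


def filter_numts(
    per_read_alignments: list[list[Alignment]],
) -> tuple[list[Alignment], list[FilterDecision]]:
    """Retain reads whose mtDNA score strictly exceeds their nuclear score.

    Equal scores (the NumtS signature) and nuclear-only reads are discarded;
    an absent nuclear hit counts as minus infinity.
    """
    kept: list[Alignment] = []
    report: list[FilterDecision] = []
    for alns in per_read_alignments:
        mt = next((a for a in alns if a.ref_class == "mt"), None)
        nuc = next((a for a in alns if a.ref_class == "nuclear"), None)
        decision = False
        if mt is not None and (nuc is None or mt.score > nuc.score):
            kept.append(mt)
            decision = True
        rid = (mt or nuc).read_id if (mt or nuc) else "?"
        report.append(
            FilterDecision(
                rid,
                mt.score if mt else None,
                nuc.score if nuc else None,
                decision,
            )
        )
    return kept, report


def align_readset(
    reads: ReadSet,
    index: AlignmentIndex,
    scoring: Scoring = Scoring(),
    band: int = 15,
) -> list[list[Alignment]]:
    """Align every read; returns per-read best-per-class alignment lists."""
    return [align_read(r, index, scoring=scoring, band=band) for r in reads]
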