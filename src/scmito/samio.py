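"""SAM import/export for internal alignments (text SAM via pysam).

Alignments that wrap through the circular origin cannot be expressed as one
record on a linear reference, so they are split at the boundary into a
primary record and a supplementary record, each soft-clipping the bases the
other carries. Reading a SAM therefore yields the two halves as independent
alignments, which is exactly what the pileup needs.
"""

from __future__ import annotations

from pathlib import Path

import pysam

from .align import Alignment, FilterDecision
from .reference import MitoReference

_OP2CODE = {"M": 0, "I": 1, "D": 2, "S": 4}
_CODE2OP = {0: "M", 1: "I", 2: "D", 4: "S", 7: "M", 8: "M"}


def _split_at_origin(a: Alignment, L: int) -> list[Alignment]:
    """Split an origin-wrapping alignment into two linear pieces."""
    if a.end <= L:
        return [a]
    boundary = L - a.start + 1  # reference bases before the origin
    first_ops: list[tuple[str, int]] = []
    second_ops: list[tuple[str, int]] = []
    ref_used = 0
    read_used = 0
    second_read_start = None
    for op, n in a.cigar:
        consumes_ref = op in "MD"
        consumes_read = op in "SMI"
        if second_read_start is not None or (consumes_ref and ref_used >= boundary):
            if second_read_start is None:
                second_read_start = read_used
            second_ops.append((op, n))
            if consumes_read:
                read_used += n
            continue
        if consumes_ref and ref_used + n > boundary:
            take = boundary - ref_used
            first_ops.append((op, take))
            if consumes_read:
                read_used += take
            second_read_start = read_used
            second_ops.append((op, n - take))
            if consumes_read:
                read_used += n - take
            ref_used += n
            continue
        first_ops.append((op, n))
        if consumes_ref:
            ref_used += n
        if consumes_read:
            read_used += n
    total_read = a.read_consumed()
    first_cigar = first_ops + [("S", total_read - sum(n for op, n in first_ops if op in "SMI"))]
    second_clip = second_read_start or 0
    second_cigar = [("S", second_clip)] + second_ops
    first_cigar = [(op, n) for op, n in first_cigar if n > 0]
    second_cigar = [(op, n) for op, n in second_cigar if n > 0]
    from dataclasses import replace

    return [
        replace(a, cigar=first_cigar),
        replace(a, start=1, cigar=second_cigar),
    ]


def write_sam(
    alignments: list[Alignment],
    mt: MitoReference,
    decoys: list[tuple[str, str]] | None,
    path: str | Path,
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": mt.name, "LN": mt.length}]
        + [{"SN": n, "LN": len(s)} for n, s in decoys or []],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for a in alignments:
            pieces = _split_at_origin(a, mt.length) if a.ref_name == mt.name else [a]
            for i, piece in enumerate(pieces):
                seg = pysam.AlignedSegment(fh.header)
                seg.query_name = a.read_id
                seg.query_sequence = piece.sequence
                seg.query_qualities = pysam.qualitystring_to_array(piece.quality)
                seg.reference_id = fh.header.get_tid(piece.ref_name)
                seg.reference_start = piece.start - 1
                seg.cigartuples = [(_OP2CODE[op], n) for op, n in piece.cigar]
                seg.mapping_quality = 60
                flag = 16 if piece.strand == "-" else 0
                if i > 0:
                    flag |= 2048  # supplementary: the wrapped tail
                seg.flag = flag
                seg.set_tag("AS", piece.score)
                seg.set_tag("XO", piece.origin)
                fh.write(seg)


def read_sam(path: str | Path, mt_name: str = "chrM") -> list[Alignment]:
    out = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            cigar = [(_CODE2OP[c], n) for c, n in seg.cigartuples]
            qual = "".join(chr(q + 33) for q in seg.query_qualities)
            out.append(
                Alignment(
                    read_id=seg.query_name,
                    ref_name=seg.reference_name,
                    ref_class="mt" if seg.reference_name == mt_name else "nuclear",
                    start=seg.reference_start + 1,
                    strand="-" if seg.is_reverse else "+",
                    score=int(seg.get_tag("AS")) if seg.has_tag("AS") else 0,
                    cigar=cigar,
                    sequence=seg.query_sequence,
                    quality=qual,
                    origin=seg.get_tag("XO") if seg.has_tag("XO") else "mt",
                )
            )
    return out


def write_filter_report(report: list[FilterDecision], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tmt_score\tnuclear_score\tdecision\n")
        for d in report:
            mt = d.mt_score if d.mt_score is not None else "NA"
            nuc = d.nuclear_score if d.nuclear_score is not None else "NA"
            fh.write(f"{d.read_id}\t{mt}\t{nuc}\t{'keep' if d.kept else 'discard'}\n")
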