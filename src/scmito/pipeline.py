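"""End-to-end convenience drivers: reads -> alignments -> calls -> summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

from . import align as al
from . import call as vc
from . import haplo, qc
from .phylotree import ToyPhylotree
from .reference import MitoReference
from .simulate import ReadSet


@dataclass
class CellResult:
    cell_id: str
    alignments: list[al.Alignment]
    pileup: vc.Pileup
    calls: list[vc.VariantCall]
    consensus: vc.ConsensusAssembly
    predictions: list[haplo.HaplogroupPrediction] | None = None

    @property
    def callset_dict(self):
        return {c.key(): (c.af, c.total) for c in self.calls}


def reconstruct_cell(
    reads: ReadSet,
    index: al.AlignmentIndex,
    ref: MitoReference,
    cell_id: str = "cell",
    trim_cfg: al.TrimConfig | None = None,
    tree: ToyPhylotree | None = None,
    min_base_quality: int = 30,
    min_support: int = 5,
    hf_threshold: float = 0.8,
    min_depth: int = 5,
) -> CellResult:
    """Trim, align, NUMT-filter, deduplicate, pileup, call, assemble, classify."""
    if trim_cfg is not None:
        reads = al.trim_reads(reads, trim_cfg)
    per_read = al.align_readset(reads, index)
    kept, _report = al.filter_numts(per_read)
    kept = al.remove_duplicates(kept)
    pileup = vc.build_pileup(kept, ref, min_base_quality=min_base_quality)
    calls = vc.call_variants(pileup, ref, min_support=min_support)
    consensus = vc.build_consensus(
        pileup, calls, ref, hf_threshold=hf_threshold, min_depth=min_depth
    )
    preds = None
    if tree is not None:
        preds = haplo.classify(
            calls,
            consensus.callable_intervals(),
            tree,
            genome_length=ref.length,
            min_depth=min_depth,
            hf=hf_threshold,
        )
    return CellResult(cell_id, kept, pileup, calls, consensus, preds)
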