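"""Haplogroup prediction with a reliability score.

A reconstructed genome's observed variant set (SNP calls at sufficient depth
and heteroplasmy fraction) is compared against the cumulative defining
variants of every haplogroup in a Phylotree-like table. For each haplogroup,
``Nph_exp`` counts its defining SNPs whose positions fall inside the genome's
callable intervals — uncovered sites are not held against the prediction —
and ``Nph`` counts how many of those are actually observed. The reliability
score is ``P_Hg = Nph / Nph_exp``. Predictions are ranked by P_Hg, ties going
to the larger Nph_exp (the more specific haplogroup) and then to the
lexicographically smaller name. A genome whose callable breadth is below 10%
is reported unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .call import VariantCall
from .phylotree import ToyPhylotree, Variant

UNRESOLVED_BREADTH_PCT = 10.0


@dataclass(frozen=True)
class HaplogroupPrediction:
    haplogroup: str
    nph: int
    nph_exp: int
    p_hg: float
    resolved: bool


def cumulative_variants(tree: ToyPhylotree, haplogroup: str) -> set[Variant]:
    """Defining variants of a haplogroup: union along the root-to-node path."""
    return tree.cumulative_variants(haplogroup)


def _in_intervals(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def classify(
    calls: list[VariantCall],
    callable_intervals: list[tuple[int, int]],
    tree: ToyPhylotree,
    genome_length: int,
    min_depth: int = 5,
    hf: float = 0.8,
) -> list[HaplogroupPrediction]:
    """Ranked haplogroup predictions for one reconstructed genome."""
    if not tree.nodes:
        raise ValueError("empty haplogroup tree")
    observed = {
        (c.pos, c.ref, c.alt)
        for c in calls
        if c.vtype == "snp" and c.total >= min_depth and c.af >= hf
    }
    breadth = 100.0 * sum(e - s + 1 for s, e in callable_intervals) / genome_length
    resolved = breadth >= UNRESOLVED_BREADTH_PCT

    preds = []
    for name in tree.names:
        defining = {
            v for v in tree.cumulative_variants(name)
            if len(v[1]) == 1 and len(v[2]) == 1  # SNPs only
        }
        evaluable = {v for v in defining if _in_intervals(v[0], callable_intervals)}
        nph_exp = len(evaluable)
        nph = len(evaluable & observed)
        p_hg = nph / nph_exp if nph_exp else 0.0
        preds.append(HaplogroupPrediction(name, nph, nph_exp, p_hg, resolved))
    preds.sort(key=lambda p: (-p.p_hg, -p.nph_exp, p.haplogroup))
    return preds


def write_predictions_tsv(preds: list[HaplogroupPrediction], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("haplogroup\tNph\tNph_exp\tP_Hg\tresolved\n")
        for p in preds:
            fh.write(
                f"{p.haplogroup}\t{p.nph}\t{p.nph_exp}\t{p.p_hg:.4f}\t"
                f"{int(p.resolved)}\n"
            )
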