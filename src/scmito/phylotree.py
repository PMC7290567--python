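"""Toy haplogroup tree in the style of Phylotree.

A haplogroup is a node in a rooted tree; each node carries the variants that
arose on the branch leading to it. The variant set *defining* a haplogroup is
the cumulative union along the root-to-node path. Back-mutations (reversions)
are notated as a later entry at the same position whose alternate allele is
the original reference base; applying the path left to right makes the
reversion override the ancestral state.

File format: TSV with columns (haplogroup, parent, variants), where variants
is a comma-separated list of ``<pos><REF>><ALT>`` tokens (e.g. ``750A>G``) and
the root has parent ``-``. This can ingest similarly flattened exports of the
real Phylotree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

Variant = tuple[int, str, str]  # (1-based pos, ref allele, alt allele)

_TOKEN = re.compile(r"^(\d+)([ACGT]+)>([ACGT]+)$")


def parse_variant(token: str) -> Variant:
    m = _TOKEN.match(token.strip())
    if not m:
        raise ValueError(f"malformed variant token: {token!r}")
    return int(m.group(1)), m.group(2), m.group(3)


def format_variant(v: Variant) -> str:
    return f"{v[0]}{v[1]}>{v[2]}"


@dataclass
class ToyPhylotree:
    """Rooted haplogroup tree; ``nodes`` maps name -> (parent or None, variants)."""

    nodes: dict[str, tuple[str | None, list[Variant]]]

    def __post_init__(self) -> None:
        roots = [n for n, (p, _) in self.nodes.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        for name, (parent, _) in self.nodes.items():
            if parent is not None and parent not in self.nodes:
                raise ValueError(f"node {name!r} has unknown parent {parent!r}")

    @property
    def root(self) -> str:
        return next(n for n, (p, _) in self.nodes.items() if p is None)

    @property
    def names(self) -> list[str]:
        return list(self.nodes)

    def leaves(self) -> list[str]:
        parents = {p for _, (p, _) in self.nodes.items() if p is not None}
        return [n for n in self.nodes if n not in parents]

    def path(self, name: str) -> list[str]:
        """Root-to-node sequence of haplogroup names."""
        if name not in self.nodes:
            raise KeyError(f"unknown haplogroup {name!r}")
        out = []
        cur: str | None = name
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur][0]
        return out[::-1]

    def cumulative_variants(self, name: str) -> set[Variant]:
        """Union of defining variants along the root-to-node path.

        A later entry at an already-variant position rewrites the alternate
        allele; if it restores the original reference allele the position
        drops out of the set entirely (a back-mutation).
        """
        state: dict[int, tuple[str, str]] = {}  # pos -> (original ref, current alt)
        for node in self.path(name):
            for pos, ref, alt in self.nodes[node][1]:
                if pos in state:
                    orig = state[pos][0]
                    if alt == orig:
                        del state[pos]
                    else:
                        state[pos] = (orig, alt)
                else:
                    state[pos] = (ref, alt)
        return {(pos, ref, alt) for pos, (ref, alt) in state.items()}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("haplogroup\tparent\tvariants\n")
            for name, (parent, variants) in self.nodes.items():
                toks = ",".join(format_variant(v) for v in variants)
                fh.write(f"{name}\t{parent or '-'}\t{toks or '-'}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ToyPhylotree":
        nodes: dict[str, tuple[str | None, list[Variant]]] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.lower().startswith("haplogroup"):
                raise ValueError("tree TSV must start with a 'haplogroup' header line")
            for line in fh:
                if not line.strip():
                    continue
                name, parent, toks = line.rstrip("\n").split("\t")
                variants = (
                    [parse_variant(t) for t in toks.split(",")] if toks != "-" else []
                )
                nodes[name] = (None if parent == "-" else parent, variants)
        return cls(nodes)
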