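"""Packaged example data: a synthetic circular reference and a toy tree.

``synthetic_mt.fa`` is a 16,569 bp random sequence (NOT the human rCRS; it is
generated by :func:`scmito.simulate.build_reference` with seed 20205) and
``toy_phylotree.tsv`` is a haplogroup table consistent with it. They exist so
the command-line tools and examples have ready-made inputs; tests regenerate
equivalent objects programmatically.
"""

from __future__ import annotations

from importlib import resources

from .phylotree import ToyPhylotree
from .reference import MitoReference

PACKAGED_REFERENCE_SEED = 20205
PACKAGED_TREE_SEED = 20206


def load_reference() -> MitoReference:
    from .simulate import read_fasta

    path = resources.files("scmito").joinpath("data", "synthetic_mt.fa")
    with resources.as_file(path) as p:
        name, seq = read_fasta(p)[0]
    return MitoReference(name=name, sequence=seq)


def load_tree() -> ToyPhylotree:
    path = resources.files("scmito").joinpath("data", "toy_phylotree.tsv")
    with resources.as_file(path) as p:
        return ToyPhylotree.from_tsv(p)
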