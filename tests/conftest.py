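import numpy as np
import pytest

from scmito import datasets
from scmito import simulate as sim
from scmito.align import Alignment, AlignmentIndex


@pytest.fixture(scope="session")
def ref2k():
    return sim.build_reference(2000, seed=101, name="chrM")


@pytest.fixture(scope="session")
def idx2k(ref2k):
    return AlignmentIndex(ref2k, [], k=15)


@pytest.fixture(scope="session")
def ref_full():
    return datasets.load_reference()


@pytest.fixture(scope="session")
def tree_full():
    return datasets.load_tree()


@pytest.fixture
def aln_factory():
    """Build minimal mtDNA alignments for pileup/QC tests."""

    def make(
        start,
        seq,
        qual=None,
        cigar=None,
        read_id="r0",
        strand="+",
        ref_class="mt",
        score=None,
    ):
        if qual is None:
            qual = chr(33 + 35) * len(seq)  # Q35 everywhere
        if cigar is None:
            cigar = [("M", len(seq))]
        return Alignment(
            read_id=read_id,
            ref_name="chrM",
            ref_class=ref_class,
            start=start,
            strand=strand,
            score=score if score is not None else len(seq),
            cigar=cigar,
            sequence=seq,
            quality=qual,
        )

    return make


def other_base(b: str) -> str:
    return "ACGT"[("ACGT".index(b) + 1) % 4]


@pytest.fixture(scope="session")
def other():
    return other_base
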