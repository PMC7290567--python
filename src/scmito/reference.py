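"""Circular mitochondrial reference genome container.

All genomic coordinates in this package are 1-based against a single circular
reference (as in the human rCRS convention). Positions are reduced modulo the
genome length, so an interval may wrap through the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class MitoReference:
    """A circular mtDNA reference sequence with 1-based coordinates."""

    name: str
    sequence: str
    is_circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("reference sequence is empty")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(f"reference contains non-ACGT characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def normalize(self, pos: int) -> int:
        """Reduce a 1-based position modulo the genome length into [1, L]."""
        return (pos - 1) % self.length + 1

    def base(self, pos: int) -> str:
        return self.sequence[(pos - 1) % self.length]

    def fetch(self, start: int, length: int) -> str:
        """Circular substring of ``length`` bases starting at 1-based ``start``."""
        if length < 0:
            raise ValueError("negative length")
        s = (start - 1) % self.length
        doubled = self.sequence + self.sequence
        if length <= 2 * self.length - s:
            return doubled[s : s + length]
        # pathological (> whole genome twice); build explicitly
        reps = (s + length) // self.length + 1
        return (self.sequence * reps)[s : s + length]
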