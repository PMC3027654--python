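"""Marker identifiers and the IUPAC nucleotide alphabet.

The barcode uses two plastid regions — the coding *rbcL* gene (~1300 bp)
and the faster-evolving noncoding *trnL-F* region (~900 bp) — plus the
nuclear *PgiC* fragment-length marker used to split plastid-identical
species complexes.
"""

from __future__ import annotations

import enum

__all__ = [
    "Marker",
    "IUPAC_CODES",
    "AMBIGUITY_SETS",
    "STATE_MASKS",
    "GAP",
    "MISSING",
    "reverse_complement",
]


class Marker(str, enum.Enum):
    """A sequenced locus."""

    RBCL = "rbcL"
    TRNLF = "trnL-F"
    PGIC = "PgiC"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


GAP = "-"
MISSING = "?"

#: IUPAC code -> set of elementary bases it may stand for.
AMBIGUITY_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_CODES = frozenset(AMBIGUITY_SETS)

_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}

#: IUPAC code (plus gap/missing) -> 4-bit state-set mask used by the
#: parsimony engine. Gaps are treated as missing data for tree scoring.
STATE_MASKS: dict[str, int] = {
    code: sum(_BIT[b] for b in bases) for code, bases in AMBIGUITY_SETS.items()
}
STATE_MASKS[GAP] = 15
STATE_MASKS[MISSING] = 15

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-?",
    "TGCAYRSWMKVHDBN-?",
)


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string, preserving ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]
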