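"""Standard genetic code tables and small sequence utilities.

Everything downstream (codon-usage scores, adaptiveness, the synthetic
generator) works on in-frame codon lists over the DNA alphabet; RNA input is
transliterated (U -> T) at parse time.
"""
from __future__ import annotations

import itertools

BASES = "TCAG"

# Standard code, third base fastest, in TCAG order.
_AA_STRING = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

CODON_TABLE: dict[str, str] = {
    b1 + b2 + b3: aa
    for (b1, b2, b3), aa in zip(itertools.product(BASES, repeat=3), _AA_STRING)
}

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")

ALL_CODONS: tuple[str, ...] = tuple(sorted(CODON_TABLE))
ALL_CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(ALL_CODONS)}

SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ALL_CODONS if c not in STOP_CODONS
)
SENSE_CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(_AA_STRING) - {"*"}))

#: amino acid -> tuple of its sense codons
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TABLE[c] == aa)
    for aa in AMINO_ACIDS
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def codons_of(seq: str) -> list[str]:
    """Split an in-frame nucleotide string into codons (length must be 3k)."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


def translate(codons) -> str:
    """Translate an iterable of codons into a one-letter protein string.

    Stop codons translate to ``*``.
    """
    return "".join(CODON_TABLE[c] for c in codons)
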