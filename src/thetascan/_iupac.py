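"""IUPAC nucleotide code tables shared across the package (DNA alphabet)."""

from __future__ import annotations

IUPAC: dict[str, frozenset[str]] = {
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

#: Characters allowed in subject sequences.
VALID_SEQ_CHARS = frozenset(IUPAC)
#: Unambiguous subject characters; everything else counts toward the n-ratio.
UNAMBIGUOUS = frozenset("ACGT")

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: Watson-Crick base pairs, 5' strand character x 3' strand character.
WC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})
#: G-T (G-U in RNA) wobble pairs.
WOBBLE_PAIRS = frozenset({("G", "T"), ("T", "G")})


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(COMPLEMENT)[::-1]


def normalize(seq: str) -> str:
    """Uppercase a sequence and map RNA U to DNA T."""
    return seq.upper().replace("U", "T")
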