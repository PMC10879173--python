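"""Genetic-code assignment from coding-density comparison.

ORFs are called with a deterministic maximal-ORF scanner (six frames, starts
ATG/GTG/TTG, stop set per genetic code); the coding density of a contig is
the fraction covered by the union of ORF intervals.  A contig is recoded if
an alternative code's density exceeds the standard-code (11) density by a
size-dependent threshold: 10% below 100 kbp, 5% at or above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from ._iupac import normalize, revcomp

__all__ = [
    "STOP_SETS",
    "START_CODONS",
    "CodingDensityResult",
    "find_orfs",
    "coding_density",
    "assign_code",
    "recoding_summary",
]

#: stop codons per supported genetic code
STOP_SETS: dict[int, frozenset[str]] = {
    11: frozenset({"TAA", "TAG", "TGA"}),
    15: frozenset({"TAA", "TGA"}),       # TAG reassigned (Gln)
    4: frozenset({"TAA", "TAG"}),        # TGA reassigned (Trp)
}

START_CODONS = frozenset({"ATG", "GTG", "TTG"})

#: minimum ORF length in nt (start through stop, inclusive)
MIN_ORF_LEN = 90

#: contigs shorter than this use the 10% threshold, others 5%
SIZE_CUTOFF = 100_000
THRESHOLD_SMALL = 0.10
THRESHOLD_LARGE = 0.05


@dataclass(frozen=True)
class CodingDensityResult:
    contig: str
    length: int
    density: Mapping[int, float]
    assigned_code: int
    margin: float


def _scan_frame(seq: str, offset: int, stops: frozenset[str], min_len: int):
    """Maximal ORFs in one forward frame; yields (start, end) in nt coords.

    An ORF opens at the first start codon after a stop (or the sequence
    edge) and closes at the next in-frame stop (inclusive) or at the last
    complete codon of the frame.
    """
    orf_start = -1
    pos = offset
    n = len(seq)
    while pos + 3 <= n:
        codon = seq[pos:pos + 3]
        if orf_start < 0:
            if codon in START_CODONS:
                orf_start = pos
        elif codon in stops:
            end = pos + 3
            if end - orf_start >= min_len:
                yield orf_start, end
            orf_start = -1
        pos += 3
    if orf_start >= 0 and pos - orf_start >= min_len:
        yield orf_start, pos


def find_orfs(
    seq: str, code: int, min_len: int = MIN_ORF_LEN
) -> list[tuple[int, int, str]]:
    """All maximal ORFs >= ``min_len`` nt across six frames.

    Returns (start, end, strand) tuples in forward 0-based half-open
    coordinates.
    """
    if code not in STOP_SETS:
        raise ValueError(f"unsupported genetic code {code}; expected 11, 15 or 4")
    seq = normalize(seq)
    stops = STOP_SETS[code]
    n = len(seq)
    orfs: list[tuple[int, int, str]] = []
    for off in range(3):
        orfs.extend((a, b, "+") for a, b in _scan_frame(seq, off, stops, min_len))
    rc = revcomp(seq)
    for off in range(3):
        orfs.extend(
            (n - b, n - a, "-") for a, b in _scan_frame(rc, off, stops, min_len)
        )
    orfs.sort()
    return orfs


def coding_density(
    orfs: Iterable[tuple[int, int, str]] | Iterable[tuple[int, int]],
    genome_length: int,
) -> float:
    """Union length of ORF intervals (strands projected) / genome length."""
    if genome_length <= 0:
        return 0.0
    ivals = sorted((o[0], o[1]) for o in orfs)
    covered = 0
    cur_start, cur_end = None, None
    for a, b in ivals:
        if cur_end is None or a > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = a, b
        else:
            cur_end = max(cur_end, b)
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered / genome_length


def assign_code(
    seq: str,
    contig: str = "seq",
    min_len: int = MIN_ORF_LEN,
    threshold_small: float = THRESHOLD_SMALL,
    threshold_large: float = THRESHOLD_LARGE,
    size_cutoff: int = SIZE_CUTOFF,
) -> CodingDensityResult:
    """Compute densities under codes 11/15/4 and assign the contig's code.

    The alternative code with the largest density excess over code 11 wins
    if the excess reaches the size-dependent threshold; an exact tie between
    codes 15 and 4 is unresolvable and falls back to code 11.
    """
    seq = normalize(seq)
    n = len(seq)
    density = {
        code: coding_density(find_orfs(seq, code, min_len), n)
        for code in (11, 15, 4)
    }
    threshold = threshold_small if n < size_cutoff else threshold_large
    excess = {code: density[code] - density[11] for code in (15, 4)}
    best = max(excess, key=lambda c: excess[c])
    if excess[best] >= threshold and excess[15] != excess[4]:
        assigned = best
    else:
        assigned = 11
    return CodingDensityResult(
        contig=contig,
        length=n,
        density=density,
        assigned_code=assigned,
        margin=density[assigned] - density[11],
    )


def recoding_summary(
    results: Sequence[CodingDensityResult],
    theta_contigs: Iterable[str] = (),
    trna_assoc_contigs: Iterable[str] = (),
    sup_assoc_contigs: Iterable[str] = (),
) -> dict:
    """Fractions of codes 11/15/4 in four strata of contigs.

    Strata: (i) all contigs, (ii) theta-ribozyme-containing, (iii) contigs
    with tRNA-associated ribozymes, (iv) contigs with suppressor-tRNA-
    associated ribozymes.  Empty strata are reported with ``n = 0`` and
    ``fractions = None``.
    """
    theta = set(theta_contigs)
    trna = set(trna_assoc_contigs)
    sup = set(sup_assoc_contigs)
    strata = {
        "all": [r for r in results],
        "theta": [r for r in results if r.contig in theta],
        "trna_associated": [r for r in results if r.contig in trna],
        "sup_associated": [r for r in results if r.contig in sup],
    }
    out = {}
    for name, rows in strata.items():
        n = len(rows)
        if n == 0:
            out[name] = {"n": 0, "fractions": None}
            continue
        fractions = {
            code: sum(1 for r in rows if r.assigned_code == code) / n
            for code in (11, 15, 4)
        }
        out[name] = {"n": n, "fractions": fractions}
    return out
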