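"""tRNA association, genomic-context classification and pair bookkeeping.

A ribozyme hit is tRNA-associated when a tRNA 3' end lies within a +/-5 nt
window of the hit's cleavage site on the same contig and strand.  Distances
are signed along the coding strand: positive when the ribozyme starts
downstream of the tRNA 3' end.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._iupac import UNAMBIGUOUS, normalize
from .motif_engine import Hit, RibozymeRecord

__all__ = [
    "TRNAAnnotation",
    "AssociationRecord",
    "TRNARecord",
    "associate",
    "classify_context",
    "is_suppressor",
    "has_cca_tail",
    "dereplicate_trnas",
    "name_pairs",
    "pair_name",
    "fold_enrichment",
    "association_summary",
]

#: anticodon (DNA) -> stop codon read (RNA), i.e. suppressor table
_SUPPRESSOR = {"CTA": "UAG", "TCA": "UGA", "TTA": "UAA"}

#: default association window (nt) around the cleavage site
ASSOCIATION_WINDOW = 5
#: hits farther than this from any ORF edge are "distal"
DISTAL_CUTOFF = 200


@dataclass(frozen=True)
class TRNAAnnotation:
    """A tRNA gene annotation (detection is upstream of this package)."""

    contig: str
    strand: str
    begin: int  # 0-based
    end: int    # half-open
    anticodon: str
    isotype: str
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.begin < self.end:
            raise ValueError(f"tRNA {self.contig}:{self.begin}-{self.end}: begin >= end")
        if len(self.anticodon) != 3:
            raise ValueError(f"anticodon must be a 3-mer, got {self.anticodon!r}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def three_prime_end(self) -> int:
        """Strand-aware forward coordinate of the last tRNA nucleotide."""
        return self.end - 1 if self.strand == "+" else self.begin


@dataclass(frozen=True)
class AssociationRecord:
    ribozyme: Hit
    trna: TRNAAnnotation
    distance: int
    adjacency: str  # "direct" (|d|<=1) or "near" (2<=|d|<=5)
    pair_name: str | None = None


def _signed_distance(hit: Hit, trna: TRNAAnnotation) -> int:
    """tRNA 3' end to cleavage site along the coding strand."""
    if trna.strand == "+":
        return hit.cleavage_site - trna.three_prime_end
    return trna.three_prime_end - hit.cleavage_site


def associate(
    hits: Iterable[Hit],
    trnas: Sequence[TRNAAnnotation],
    window: int = ASSOCIATION_WINDOW,
    allow_antisense: bool = False,
) -> list[AssociationRecord]:
    """Pair each hit with its nearest in-window tRNA (at most one per hit).

    Ties on |distance| are broken in favour of the upstream tRNA (positive
    distance), then by the tRNA 3' end coordinate for determinism.
    """
    by_contig: dict[str, list[TRNAAnnotation]] = defaultdict(list)
    for t in trnas:
        by_contig[t.contig].append(t)

    records: list[AssociationRecord] = []
    for hit in hits:
        best: tuple | None = None
        for t in by_contig.get(hit.contig, ()):
            if not allow_antisense and t.strand != hit.strand:
                continue
            d = _signed_distance(hit, t)
            if abs(d) > window:
                continue
            key = (abs(d), 0 if d > 0 else 1, t.three_prime_end)
            if best is None or key < best[0]:
                best = (key, t, d)
        if best is not None:
            _, t, d = best
            records.append(
                AssociationRecord(
                    ribozyme=hit,
                    trna=t,
                    distance=d,
                    adjacency="direct" if abs(d) <= 1 else "near",
                )
            )
    return records


def classify_context(
    hit: Hit,
    orf_intervals: Sequence[tuple[int, int, str]],
    distal_cutoff: int = DISTAL_CUTOFF,
) -> str:
    """Classify a non-tRNA-associated hit relative to ORFs on its contig.

    ``orf_intervals`` are (start, end, strand) tuples in forward coordinates.
    Returns one of ``intragenic``, ``noncoding_sense``, ``noncoding_antisense``
    or ``distal``.  A hit overlapping any ORF by >=1 nt is intragenic; with no
    ORF within ``distal_cutoff`` nt the hit is distal; otherwise the strand of
    the nearest ORF decides sense vs antisense (tie -> downstream ORF).
    """
    if not orf_intervals:
        return "distal"
    nearest: tuple | None = None
    for start, end, strand in orf_intervals:
        if start < hit.end and hit.start < end:
            return "intragenic"
        if end <= hit.start:
            gap = hit.start - end
            downstream = hit.strand == "-"
        else:
            gap = start - hit.end
            downstream = hit.strand == "+"
        key = (gap, 0 if downstream else 1, start)
        if nearest is None or key < nearest[0]:
            nearest = (key, strand, gap)
    _, orf_strand, gap = nearest
    if gap > distal_cutoff:
        return "distal"
    return "noncoding_sense" if orf_strand == hit.strand else "noncoding_antisense"


def is_suppressor(anticodon: str) -> str | None:
    """Stop codon read by ``anticodon`` (DNA 3-mer), or None.

    CTA -> UAG (amber), TCA -> UGA (opal), TTA -> UAA (ochre).
    """
    ac = normalize(anticodon)
    if len(ac) != 3 or any(ch not in UNAMBIGUOUS for ch in ac):
        raise ValueError(f"malformed anticodon {anticodon!r}")
    return _SUPPRESSOR.get(ac)


def has_cca_tail(sequence: str) -> bool:
    """True iff the genomically encoded tRNA ends in CCA."""
    if not sequence:
        raise ValueError("empty tRNA sequence")
    return normalize(sequence).endswith("CCA")


@dataclass(frozen=True)
class TRNARecord:
    """A dereplicated tRNA keyed by sequence (or annotation identity)."""

    key: str
    isotype: str
    occurrences: int
    rank: int
    annotations: tuple[TRNAAnnotation, ...] = field(default=(), compare=False)


def dereplicate_trnas(trnas: Iterable[TRNAAnnotation]) -> list[TRNARecord]:
    """Rank tRNAs by descending occurrence of identical sequence.

    tRNAs without a sequence are keyed by (isotype, anticodon).  Ties are
    broken lexicographically by key, as for ribozyme records.
    """
    groups: dict[tuple[str, str], list[TRNAAnnotation]] = defaultdict(list)
    for t in trnas:
        key = t.sequence if t.sequence else f"{t.isotype}:{t.anticodon}"
        groups[(key, t.isotype)].append(t)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [
        TRNARecord(
            key=key,
            isotype=isotype,
            occurrences=len(anns),
            rank=rank,
            annotations=tuple(anns),
        )
        for rank, ((key, isotype), anns) in enumerate(ordered, start=1)
    ]


def pair_name(isotype: str, trna_rank: int, ribozyme_rank: int) -> str:
    return f"tRNA{isotype}{trna_rank:04d}_Θ{ribozyme_rank:04d}"


def name_pairs(
    pairs: Iterable[tuple[TRNARecord, RibozymeRecord]],
) -> list[str]:
    """Name tRNA/ribozyme pairs from their occurrence ranks."""
    names = []
    for trna, rz in pairs:
        if trna.rank is None or rz.rank is None:  # defensive; ranks are ints
            raise ValueError("unranked input to name_pairs")
        if trna.rank < 1 or rz.rank < 1:
            raise ValueError("ranks must be 1-based")
        names.append(pair_name(trna.isotype, trna.rank, rz.rank))
    return names


def fold_enrichment(p_subset: float, p_background: float) -> float:
    """Ratio of a subset fraction over a background fraction."""
    if not 0 <= p_subset <= 1:
        raise ValueError("p_subset outside [0, 1]")
    if not 0 < p_background <= 1:
        raise ValueError("p_background must be in (0, 1]")
    return p_subset / p_background


def association_summary(
    associations: Sequence[AssociationRecord],
    n_hits: int | None = None,
) -> dict:
    """Counts by isotype, suppressor fraction and adjacency fractions."""
    n = len(associations)
    by_isotype = Counter(a.trna.isotype for a in associations)
    n_direct = sum(1 for a in associations if a.adjacency == "direct")
    n_sup = 0
    for a in associations:
        try:
            if is_suppressor(a.trna.anticodon):
                n_sup += 1
        except ValueError:
            pass
    out = {
        "n_associations": n,
        "counts_by_isotype": dict(sorted(by_isotype.items())),
        "suppressor_fraction": (n_sup / n) if n else None,
        "direct_fraction": (n_direct / n) if n else None,
        "near_fraction": ((n - n_direct) / n) if n else None,
    }
    if n_hits is not None:
        out["n_hits"] = n_hits
        out["associated_fraction"] = (n / n_hits) if n_hits else None
    return out
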