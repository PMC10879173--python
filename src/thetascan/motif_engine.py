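"""Structural motif engine: descriptor parsing, double-strand scanning,
false-positive variants, hit classification, dereplication and consensus.

A descriptor is an ordered list of structural elements (single strands and
the two strands of each helix, which may interleave so that pseudoknots can
be expressed).  Scanning finds every placement of the descriptor on a DNA
sequence such that per-element IUPAC constraints hold, helix strands are
reverse-complementary position by position (with optional G-T wobble), and
the fraction of ambiguous subject nucleotides does not exceed the
descriptor's n-ratio.

Descriptor file dialect (UTF-8, ``#`` starts a comment)::

    order: p1 j12 p2 p3 l3 p3' p1' j42 p2'
    p1   6:6  GNNNNN  wobble=1
    j12  1:3  -
    ...
    catalytic: j42 0
    cleavage:  p1
    nratio: 0.1

An id ending in ``'`` denotes the 3' strand of the helix named by the
unprimed id; helix definition lines are written once, for the unprimed id,
and their length range and (5'-strand) constraint apply to both strands.
Constraints are IUPAC strings of length ``max_len``; a match of length
``L < max_len`` is checked against the first ``L`` constraint characters.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

from ._iupac import (
    IUPAC,
    UNAMBIGUOUS,
    VALID_SEQ_CHARS,
    WC_PAIRS,
    WOBBLE_PAIRS,
    normalize,
    revcomp,
)

__all__ = [
    "Element",
    "ElementKind",
    "Descriptor",
    "DescriptorError",
    "Hit",
    "Locus",
    "RibozymeRecord",
    "VARIANTS",
    "parse_descriptor",
    "load_descriptor",
    "derive_fp_variants",
    "scan",
    "classify_hits",
    "fp_rate",
    "dereplicate",
    "element_consensus",
]

VARIANTS = ("active", "CdA", "CdG", "CdU")

#: catalytic-position nucleotide of each variant (DNA alphabet)
_VARIANT_BASE = {"active": "C", "CdA": "A", "CdG": "G", "CdU": "T"}
_BASE_VARIANT = {v: k for k, v in _VARIANT_BASE.items()}


class DescriptorError(ValueError):
    """Raised for malformed descriptor files or invalid descriptor states."""


class ElementKind(str, Enum):
    SINGLE_STRAND = "single_strand"
    HELIX_5P = "helix_5p"
    HELIX_3P = "helix_3p"


@dataclass(frozen=True)
class Element:
    id: str
    kind: ElementKind
    min_len: int
    max_len: int
    constraint: str = ""
    pairing_partner: str | None = None
    allow_wobble: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.min_len <= self.max_len):
            raise DescriptorError(
                f"element {self.id}: invalid length range "
                f"{self.min_len}:{self.max_len}"
            )
        if self.constraint and len(self.constraint) != self.max_len:
            raise DescriptorError(
                f"element {self.id}: constraint length {len(self.constraint)} "
                f"!= max_len {self.max_len}"
            )
        for ch in self.constraint:
            if ch not in IUPAC:
                raise DescriptorError(
                    f"element {self.id}: non-IUPAC character {ch!r} in constraint"
                )
        if self.kind is ElementKind.SINGLE_STRAND and self.pairing_partner:
            raise DescriptorError(f"element {self.id}: single strand with partner")
        if self.kind is not ElementKind.SINGLE_STRAND and not self.pairing_partner:
            raise DescriptorError(f"element {self.id}: helix strand without partner")


@dataclass(frozen=True)
class Descriptor:
    name: str
    elements: tuple[Element, ...]
    catalytic_element: str
    catalytic_offset: int
    cleavage_element: str
    max_ambiguous_fraction: float = 0.1
    variant: str = "active"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        ids = [e.id for e in self.elements]
        if len(set(ids)) != len(ids):
            raise DescriptorError(f"duplicate element ids in {self.name}")
        index = {e.id: e for e in self.elements}
        for el in self.elements:
            if el.kind is ElementKind.SINGLE_STRAND:
                continue
            partner = index.get(el.pairing_partner or "")
            if partner is None:
                raise DescriptorError(
                    f"unpaired helix strand {el.id} in {self.name}"
                )
            if partner.pairing_partner != el.id:
                raise DescriptorError(
                    f"asymmetric helix pairing {el.id}/{el.pairing_partner}"
                )
            if (partner.min_len, partner.max_len) != (el.min_len, el.max_len):
                raise DescriptorError(
                    f"helix strands {el.id}/{partner.id} have unequal length ranges"
                )
        if self.catalytic_element not in index:
            raise DescriptorError(
                f"catalytic element {self.catalytic_element!r} not in order"
            )
        cat = index[self.catalytic_element]
        if not (0 <= self.catalytic_offset < cat.max_len):
            raise DescriptorError(
                f"catalytic offset {self.catalytic_offset} out of range for "
                f"{cat.id}"
            )
        if self.catalytic_offset >= len(cat.constraint):
            raise DescriptorError(
                f"catalytic position of {cat.id} has no identity constraint"
            )
        base = cat.constraint[self.catalytic_offset]
        if base not in _BASE_VARIANT:
            raise DescriptorError(
                f"catalytic position constraint must be a single nucleotide, "
                f"got {base!r}"
            )
        if _BASE_VARIANT[base] != self.variant:
            raise DescriptorError(
                f"catalytic base {base!r} inconsistent with variant {self.variant!r}"
            )
        if self.cleavage_element not in index:
            raise DescriptorError(
                f"cleavage element {self.cleavage_element!r} not in order"
            )
        if not (0.0 <= self.max_ambiguous_fraction <= 1.0):
            raise DescriptorError("nratio must be within [0, 1]")

    # -- convenience ------------------------------------------------------
    def element(self, element_id: str) -> Element:
        for el in self.elements:
            if el.id == element_id:
                return el
        raise KeyError(element_id)

    @property
    def catalytic_base(self) -> str:
        return self.element(self.catalytic_element).constraint[self.catalytic_offset]

    @property
    def min_total_len(self) -> int:
        return sum(e.min_len for e in self.elements)

    @property
    def max_total_len(self) -> int:
        return sum(e.max_len for e in self.elements)

    def with_catalytic_base(self, base: str) -> "Descriptor":
        """Return a copy whose catalytic position is constrained to ``base``."""
        if base not in _BASE_VARIANT:
            raise DescriptorError(f"invalid catalytic base {base!r}")
        variant = _BASE_VARIANT[base]
        new_elements = []
        for el in self.elements:
            if el.id == self.catalytic_element:
                cons = list(el.constraint)
                cons[self.catalytic_offset] = base
                el = replace(el, constraint="".join(cons))
            new_elements.append(el)
        return replace(
            self,
            name=f"{self.name}.{variant}" if variant != "active" else self.name,
            elements=tuple(new_elements),
            variant=variant,
        )


# ---------------------------------------------------------------------------
# descriptor parsing
# ---------------------------------------------------------------------------

def parse_descriptor(text: str, name: str = "descriptor") -> Descriptor:
    """Parse descriptor-file content into a validated :class:`Descriptor`."""
    order: list[str] | None = None
    defs: dict[str, tuple[int, int, str, bool, int]] = {}
    catalytic: tuple[str, int] | None = None
    cleavage: str | None = None
    nratio = 0.1

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("order:"):
            if order is not None:
                raise DescriptorError(f"{name}:{lineno}: duplicate order line")
            order = line[len("order:"):].split()
            if not order:
                raise DescriptorError(f"{name}:{lineno}: empty order line")
            continue
        if line.startswith("catalytic:"):
            parts = line[len("catalytic:"):].split()
            if len(parts) != 2 or not parts[1].isdigit():
                raise DescriptorError(
                    f"{name}:{lineno}: expected 'catalytic: <id> <offset>'"
                )
            catalytic = (parts[0], int(parts[1]))
            continue
        if line.startswith("cleavage:"):
            parts = line[len("cleavage:"):].split()
            if len(parts) != 1:
                raise DescriptorError(f"{name}:{lineno}: expected 'cleavage: <id>'")
            cleavage = parts[0]
            continue
        if line.startswith("nratio:"):
            try:
                nratio = float(line[len("nratio:"):])
            except ValueError as exc:
                raise DescriptorError(f"{name}:{lineno}: bad nratio") from exc
            continue
        parts = line.split()
        if len(parts) < 2 or ":" not in parts[1]:
            raise DescriptorError(
                f"{name}:{lineno}: expected '<id> <min>:<max> [constraint] "
                f"[wobble=0|1]', got {raw!r}"
            )
        el_id = parts[0]
        if el_id.endswith("'"):
            raise DescriptorError(
                f"{name}:{lineno}: helix 3' strand {el_id} must not be defined; "
                f"define the unprimed id once"
            )
        if el_id in defs:
            raise DescriptorError(f"{name}:{lineno}: duplicate definition of {el_id}")
        lo_s, _, hi_s = parts[1].partition(":")
        try:
            lo, hi = int(lo_s), int(hi_s)
        except ValueError as exc:
            raise DescriptorError(f"{name}:{lineno}: bad length range") from exc
        constraint = ""
        wobble = True
        declared_helix = False
        for extra in parts[2:]:
            if extra == "-":
                continue
            if extra.startswith("wobble="):
                wobble = extra != "wobble=0"
                declared_helix = True  # wobble flags only make sense on helices
            else:
                constraint = normalize(extra)
        defs[el_id] = (lo, hi, constraint, wobble, declared_helix)

    if order is None:
        raise DescriptorError(f"{name}: missing order line")
    if catalytic is None:
        raise DescriptorError(f"{name}: missing catalytic directive")
    if cleavage is None:
        raise DescriptorError(f"{name}: missing cleavage directive")

    counts = Counter(order)
    for el_id, n in counts.items():
        if n > 1:
            raise DescriptorError(f"{name}: element {el_id} repeated in order")

    elements: list[Element] = []
    for el_id in order:
        primed = el_id.endswith("'")
        base_id = el_id[:-1] if primed else el_id
        if base_id not in defs:
            raise DescriptorError(f"{name}: unknown element id {el_id} in order line")
        lo, hi, constraint, wobble, declared_helix = defs[base_id]
        if declared_helix and not primed and base_id + "'" not in counts:
            raise DescriptorError(f"{name}: unpaired helix strand {base_id}")
        if primed:
            if base_id not in counts:
                raise DescriptorError(f"{name}: unpaired helix strand {el_id}")
            elements.append(
                Element(el_id, ElementKind.HELIX_3P, lo, hi, "", base_id, wobble)
            )
        elif base_id + "'" in counts:
            elements.append(
                Element(
                    el_id, ElementKind.HELIX_5P, lo, hi, constraint,
                    base_id + "'", wobble,
                )
            )
        else:
            elements.append(
                Element(el_id, ElementKind.SINGLE_STRAND, lo, hi, constraint)
            )
    for el_id in defs:
        if el_id not in counts:
            if el_id + "'" in counts:
                raise DescriptorError(f"{name}: unpaired helix strand {el_id}'")
            raise DescriptorError(f"{name}: defined element {el_id} not in order")

    # variant is inferred from the catalytic-position constraint
    cat_el = next((e for e in elements if e.id == catalytic[0]), None)
    if cat_el is None:
        raise DescriptorError(f"{name}: catalytic element {catalytic[0]!r} not in order")
    if catalytic[1] >= len(cat_el.constraint):
        raise DescriptorError(
            f"{name}: catalytic position of {catalytic[0]} has no identity constraint"
        )
    base = cat_el.constraint[catalytic[1]]
    variant = _BASE_VARIANT.get(base)
    if variant is None:
        raise DescriptorError(
            f"{name}: catalytic position constraint must be A, C, G or T, got {base!r}"
        )
    return Descriptor(
        name=name,
        elements=tuple(elements),
        catalytic_element=catalytic[0],
        catalytic_offset=catalytic[1],
        cleavage_element=cleavage,
        max_ambiguous_fraction=nratio,
        variant=variant,
    )


def load_descriptor(path, name: str | None = None) -> Descriptor:
    """Read a descriptor file from ``path``."""
    import os

    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    return parse_descriptor(text, name or os.path.basename(str(path)))


def derive_fp_variants(d: Descriptor) -> tuple[Descriptor, Descriptor, Descriptor]:
    """Derive the three inactive (false-positive) descriptors CdA, CdG, CdU.

    The returned descriptors are identical to ``d`` except at the catalytic
    position, whose constraint is set to A, G and T respectively.
    """
    if d.variant != "active":
        raise DescriptorError(
            f"false-positive variants can only be derived from the active "
            f"descriptor, not {d.variant!r}"
        )
    return tuple(d.with_catalytic_base(b) for b in ("A", "G", "T"))  # type: ignore


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hit:
    """One motif placement, in forward-strand 0-based half-open coordinates."""

    contig: str
    start: int
    end: int
    strand: str
    variant: str
    sequence: str
    element_spans: tuple[tuple[str, int, int], ...]
    cleavage_site: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Hit") -> bool:
        return (
            self.contig == other.contig
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


class _Matcher:
    """Backtracking matcher for one descriptor over one (hit-strand) string."""

    def __init__(self, d: Descriptor):
        self.d = d
        self.elements = d.elements
        self.n_el = len(d.elements)
        self.index = {e.id: i for i, e in enumerate(d.elements)}
        # per-element, per-position allowed character sets (None = unconstrained)
        self.allowed: list[list[frozenset[str] | None]] = []
        for el in d.elements:
            sets: list[frozenset[str] | None] = []
            for k in range(el.max_len):
                if k < len(el.constraint) and el.constraint[k] != "N":
                    sets.append(IUPAC[el.constraint[k]])
                else:
                    sets.append(None)
            self.allowed.append(sets)
        self.pairs_ok: list[frozenset[tuple[str, str]]] = []
        for el in d.elements:
            ok = WC_PAIRS | WOBBLE_PAIRS if el.allow_wobble else WC_PAIRS
            self.pairs_ok.append(ok)
        # minimum total length of elements i..end (helix 3' uses its own range,
        # equal to the partner's by construction)
        self.suffix_min = [0] * (self.n_el + 1)
        for i in range(self.n_el - 1, -1, -1):
            self.suffix_min[i] = self.suffix_min[i + 1] + d.elements[i].min_len

    def matches_from(self, s: str, start: int) -> dict[int, list[tuple[int, int]]]:
        """All match end positions from ``start``; first span set per end.

        Returns a mapping end -> list of per-element (start, end) spans in
        the coordinates of ``s`` (one representative length assignment,
        found with element lengths iterated in ascending order).
        """
        out: dict[int, list[tuple[int, int]]] = {}
        spans: list[tuple[int, int]] = [(0, 0)] * self.n_el
        n = len(s)
        elements = self.elements
        allowed = self.allowed
        suffix_min = self.suffix_min

        def check_fixed(i: int, pos: int, length: int) -> bool:
            sets = allowed[i]
            for k in range(length):
                req = sets[k]
                if req is None:
                    continue
                ch = s[pos + k]
                if ch not in req and ch not in UNAMBIGUOUS:
                    continue  # ambiguous subject char: compatible
                if ch not in req:
                    return False
            return True

        def check_pairing(i: int, pos: int, length: int) -> bool:
            el = elements[i]
            p_start, p_end = spans[self.index[el.pairing_partner]]
            ok = self.pairs_ok[i]
            for k in range(length):
                a = s[p_start + k]
                b = s[pos + length - 1 - k]
                if a not in UNAMBIGUOUS or b not in UNAMBIGUOUS:
                    continue
                if (a, b) not in ok:
                    return False
            return True

        def rec(i: int, pos: int) -> None:
            if i == self.n_el:
                if pos not in out:
                    out[pos] = spans.copy()
                return
            el = elements[i]
            if el.kind is ElementKind.HELIX_3P:
                p_start, p_end = spans[self.index[el.pairing_partner]]
                length = p_end - p_start
                if pos + length + suffix_min[i + 1] > n:
                    return
                if not check_pairing(i, pos, length):
                    return
                spans[i] = (pos, pos + length)
                rec(i + 1, pos + length)
                return
            for length in range(el.min_len, el.max_len + 1):
                if pos + length + suffix_min[i + 1] > n:
                    break
                if not check_fixed(i, pos, length):
                    # a longer match includes the failing position again
                    break
                spans[i] = (pos, pos + length)
                rec(i + 1, pos + length)

        rec(0, start)
        return out

    def first_anchor(self) -> frozenset[str] | None:
        """Allowed characters at the very first matched position, if fixed."""
        for el, sets in zip(self.elements, self.allowed):
            if el.min_len > 0:
                req = sets[0]
                if req is None:
                    return None
                ambiguous = VALID_SEQ_CHARS - UNAMBIGUOUS
                return frozenset(req) | ambiguous
            if el.max_len > 0:
                return None  # element may be empty: no fixed anchor
        return None


def _count_ambiguous(s: str) -> int:
    return sum(1 for ch in s if ch not in UNAMBIGUOUS)


def scan(
    d: Descriptor,
    seq: str,
    both_strands: bool = True,
    contig: str = "seq",
) -> list[Hit]:
    """Scan ``seq`` for all placements of descriptor ``d``.

    Every distinct ``(start, end, strand)`` satisfying the descriptor is
    reported once, with element spans from one representative length
    assignment.  Reverse-strand hits are reported in forward coordinates
    with strand ``-``.  An empty sequence yields an empty list.
    """
    seq = normalize(seq)
    for ch in set(seq):
        if ch not in VALID_SEQ_CHARS:
            raise ValueError(f"invalid sequence character {ch!r}")
    matcher = _Matcher(d)
    n = len(seq)
    hits: list[Hit] = []
    strands = ("+", "-") if both_strands else ("+",)
    min_total = matcher.suffix_min[0]
    for strand in strands:
        s = seq if strand == "+" else revcomp(seq)
        anchor = matcher.first_anchor()
        last_start = n - min_total
        for start in range(0, last_start + 1):
            if anchor is not None and s[start] not in anchor:
                continue
            for end, spans in matcher.matches_from(s, start).items():
                sub = s[start:end]
                if end > start and _count_ambiguous(sub) / len(sub) > (
                    d.max_ambiguous_fraction
                ):
                    continue
                if strand == "+":
                    f_start, f_end = start, end
                    el_spans = tuple(
                        (el.id, a, b) for el, (a, b) in zip(d.elements, spans)
                    )
                else:
                    f_start, f_end = n - end, n - start
                    el_spans = tuple(
                        (el.id, n - b, n - a) for el, (a, b) in zip(d.elements, spans)
                    )
                ci = matcher.index[d.cleavage_element]
                ca, cb = spans[ci]
                cleavage_site = ca if strand == "+" else n - ca - 1
                hits.append(
                    Hit(
                        contig=contig,
                        start=f_start,
                        end=f_end,
                        strand=strand,
                        variant=d.variant,
                        sequence=sub,
                        element_spans=el_spans,
                        cleavage_site=cleavage_site,
                    )
                )
    return hits


# ---------------------------------------------------------------------------
# classification, rates, dereplication, consensus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Locus:
    """A genomic interval carrying one classification label."""

    contig: str
    start: int
    end: int
    strand: str
    label: str  # "true_positive" or "false_positive(<variant>)"
    hits: tuple[Hit, ...]


def classify_hits(
    active_hits: Iterable[Hit], fp_hits: Iterable[Hit]
) -> list[Locus]:
    """Merge overlapping hits into loci and label each locus.

    A locus matched by the active motif is a true positive regardless of any
    false-positive motif matching the same locus; remaining loci are labeled
    by their false-positive variant.
    """
    by_key: dict[tuple[str, str], list[Hit]] = defaultdict(list)
    for h in list(active_hits) + list(fp_hits):
        by_key[(h.contig, h.strand)].append(h)

    loci: list[Locus] = []
    for (ctg, strand), hits in sorted(by_key.items()):
        hits.sort(key=lambda h: (h.start, h.end))
        cluster: list[Hit] = []
        cluster_end = -1
        for h in hits + [None]:  # type: ignore[list-item]
            if h is not None and (not cluster or h.start < cluster_end):
                cluster.append(h)
                cluster_end = max(cluster_end, h.end)
                continue
            if cluster:
                if any(x.variant == "active" for x in cluster):
                    label = "true_positive"
                else:
                    variant = min(
                        (x.variant for x in cluster), key=VARIANTS.index
                    )
                    label = f"false_positive({variant})"
                loci.append(
                    Locus(
                        ctg,
                        min(x.start for x in cluster),
                        cluster_end,
                        strand,
                        label,
                        tuple(cluster),
                    )
                )
            if h is not None:
                cluster = [h]
                cluster_end = h.end
    return loci


def fp_rate(loci: Iterable[Locus]) -> float:
    """Fraction of unique false-positive sequences among all unique sequences.

    Uniqueness is by the exact matched nucleotide string; a sequence seen at
    both true- and false-positive loci counts as true positive.
    """
    tp: set[str] = set()
    fp: set[str] = set()
    for locus in loci:
        target = tp if locus.label == "true_positive" else fp
        for h in locus.hits:
            target.add(h.sequence)
    fp -= tp
    total = len(tp) + len(fp)
    if total == 0:
        raise ValueError("fp_rate undefined for empty hit set")
    return len(fp) / total


@dataclass(frozen=True)
class RibozymeRecord:
    sequence: str
    occurrences: int
    rank: int
    name: str
    hit_list: tuple[Hit, ...] = field(default=(), compare=False)


def dereplicate(hits: Iterable[Hit], name_format: str = "Θ%04d") -> list[RibozymeRecord]:
    """Collapse hits to unique sequences ranked by descending occurrence.

    Ties are broken lexicographically by sequence, so the ranking is
    deterministic across runs.
    """
    groups: dict[str, list[Hit]] = defaultdict(list)
    for h in hits:
        groups[h.sequence].append(h)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [
        RibozymeRecord(
            sequence=seq,
            occurrences=len(hs),
            rank=rank,
            name=name_format % rank,
            hit_list=tuple(hs),
        )
        for rank, (seq, hs) in enumerate(ordered, start=1)
    ]


#: conservation tiers used for consensus annotation (fraction of sequences
#: sharing the modal character at an aligned position)
CONSERVATION_TIERS = (0.97, 0.90, 0.75)


def element_consensus(
    records: Sequence[RibozymeRecord] | Sequence[str],
    d: Descriptor,
) -> list[dict]:
    """Element-anchored per-position nucleotide frequency profile.

    Every record is re-matched to ``d`` (full length, forward strand);
    variable-length elements are aligned left-anchored with ``-`` padding.
    Returns one dict per aligned position with keys ``element``, ``offset``,
    ``frequencies``, ``modal``, ``modal_fraction`` and ``tier`` (one of
    ``">=0.97"``, ``">=0.90"``, ``">=0.75"`` or ``"none"``).
    """
    seqs = [r.sequence if isinstance(r, RibozymeRecord) else r for r in records]
    if not seqs:
        raise ValueError("element_consensus requires at least one record")
    per_record_spans: list[dict[str, str]] = []
    for seq in seqs:
        full = [
            h for h in scan(d, seq, both_strands=False)
            if h.start == 0 and h.end == len(seq)
        ]
        if not full:
            raise ValueError(f"record does not match descriptor: {seq}")
        spans = {eid: seq[a:b] for eid, a, b in full[0].element_spans}
        per_record_spans.append(spans)

    profile: list[dict] = []
    for el in d.elements:
        width = max(len(spans[el.id]) for spans in per_record_spans)
        for k in range(width):
            counts: Counter[str] = Counter()
            for spans in per_record_spans:
                piece = spans[el.id]
                counts[piece[k] if k < len(piece) else "-"] += 1
            total = sum(counts.values())
            modal, modal_n = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
            frac = modal_n / total
            tier = "none"
            for t in CONSERVATION_TIERS:
                if frac >= t:
                    tier = f">={t:.2f}"
                    break
            profile.append(
                {
                    "element": el.id,
                    "offset": k,
                    "frequencies": {b: c / total for b, c in sorted(counts.items())},
                    "modal": modal,
                    "modal_fraction": frac,
                    "tier": tier,
                }
            )
    return profile
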