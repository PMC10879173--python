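"""Independent brute-force oracle for descriptor scanning.

Enumerates every start position and every combination of element lengths
with :func:`itertools.product` and checks each candidate placement directly
against the descriptor semantics.  Deliberately naive and structured
differently from the package scanner so the two can disagree.
"""

from itertools import product

from thetascan._iupac import IUPAC, normalize
from thetascan.motif_engine import Descriptor, ElementKind

_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "T"), ("T", "G")}
_PLAIN = set("ACGT")


def _segments(d: Descriptor, lengths: dict[str, int], start: int):
    """Element (start, end) spans for one length assignment."""
    spans = {}
    pos = start
    for el in d.elements:
        if el.kind is ElementKind.HELIX_3P:
            n = lengths[el.pairing_partner]
        else:
            n = lengths[el.id]
        spans[el.id] = (pos, pos + n)
        pos += n
    return spans, pos


def _placement_ok(d: Descriptor, s: str, spans) -> bool:
    for el in d.elements:
        a, b = spans[el.id]
        piece = s[a:b]
        if el.kind is not ElementKind.HELIX_3P:
            for k, ch in enumerate(piece):
                if k >= len(el.constraint):
                    continue
                allowed = IUPAC[el.constraint[k]]
                if ch in _PLAIN and ch not in allowed:
                    return False
        else:
            pa, pb = spans[el.pairing_partner]
            partner = s[pa:pb]
            pairs = _WC | _WOBBLE if el.allow_wobble else _WC
            for k in range(len(piece)):
                x, y = partner[k], piece[len(piece) - 1 - k]
                if x in _PLAIN and y in _PLAIN and (x, y) not in pairs:
                    return False
    return True


def brute_force_scan(d: Descriptor, seq: str, both_strands: bool = True):
    """Set of (start, end, strand) placements, forward coordinates."""
    seq = normalize(seq)
    var_ids = [
        el.id for el in d.elements if el.kind is not ElementKind.HELIX_3P
    ]
    ranges = [
        range(d.element(i).min_len, d.element(i).max_len + 1) for i in var_ids
    ]
    found = set()
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        s = seq if strand == "+" else _revcomp(seq)
        n = len(s)
        for combo in product(*ranges):
            lengths = dict(zip(var_ids, combo))
            for start in range(n + 1):
                spans, end = _segments(d, lengths, start)
                if end > n:
                    continue
                if not _placement_ok(d, s, spans):
                    continue
                if end > start:
                    n_amb = sum(1 for ch in s[start:end] if ch not in _PLAIN)
                    if n_amb / (end - start) > d.max_ambiguous_fraction:
                        continue
                if strand == "+":
                    found.add((start, end, "+"))
                else:
                    found.add((n - end, n - start, "-"))
    return found


def _revcomp(s: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp.get(c, c) for c in reversed(s))
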