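"""Phage-like synthetic contigs, reads and annotation tables with a
ground-truth manifest, so that every pipeline stage can be tested without
external databases.

Generated contigs contain ribozyme motif instances (active and
catalytically substituted), tRNA cassettes with defined 3' ends and
spacings, ORFs written in genetic code 11 or 15 (with a controlled
in-frame TAG rate), and random intergenic background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from ._iupac import IUPAC, revcomp
from .motif_engine import (
    Descriptor,
    Element,
    ElementKind,
    derive_fp_variants,
)
from .recoding import STOP_SETS, START_CODONS
from .trna_annotate import TRNAAnnotation

__all__ = [
    "GenomeSpec",
    "ManifestFeature",
    "Manifest",
    "sample_motif_instance",
    "generate_trna_cassette",
    "build_genome",
    "sample_reads",
    "DEFAULT_ANTICODONS",
]

#: non-suppressor anticodons used for sense tRNAs (DNA alphabet)
DEFAULT_ANTICODONS: dict[str, str] = {
    "Val": "TAC",
    "Leu": "TAG",
    "Met": "CAT",
    "Gly": "GCC",
    "Gln": "TTG",
}
SUPPRESSOR_ANTICODON = "CTA"  # reads amber (UAG)

_WOBBLE_SWAP = {"C": "T", "A": "G"}  # 3'-strand WC partner -> wobble partner


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n)) if n > 0 else ""


def sample_motif_instance(d: Descriptor, seed=None, wobble_prob: float = 0.1) -> str:
    """Sample a nucleotide string satisfying descriptor ``d``.

    Element lengths are drawn uniformly within their ranges and nucleotides
    uniformly within their IUPAC constraints; helix 3' strands are generated
    reverse-complementary to their 5' strands, with G-T wobble substitutions
    at probability ``wobble_prob`` where the descriptor allows wobble.
    """
    rng = _rng(seed)
    lengths: dict[str, int] = {}
    pieces: dict[str, str] = {}
    for el in d.elements:
        if el.kind is ElementKind.HELIX_3P:
            continue
        lengths[el.id] = int(rng.integers(el.min_len, el.max_len + 1))
    out: list[str] = []
    for el in d.elements:
        if el.kind is ElementKind.HELIX_3P:
            partner = pieces[el.pairing_partner]
            chars = list(revcomp(partner))
            if el.allow_wobble:
                for i, ch in enumerate(chars):
                    if ch in _WOBBLE_SWAP and rng.random() < wobble_prob:
                        chars[i] = _WOBBLE_SWAP[ch]
            piece = "".join(chars)
        else:
            n = lengths[el.id]
            chars = []
            for k in range(n):
                if k < len(el.constraint):
                    options = sorted(IUPAC[el.constraint[k]])
                else:
                    options = list("ACGT")
                chars.append(str(rng.choice(options)))
            piece = "".join(chars)
            pieces[el.id] = piece
        out.append(piece)
    return "".join(out)


@dataclass(frozen=True)
class ManifestFeature:
    type: str  # "ribozyme", "trna", "orf"
    contig: str
    start: int
    end: int
    strand: str
    attrs: Mapping[str, object] = field(default_factory=dict)


@dataclass
class Manifest:
    """Ground truth for one or more generated contigs."""

    features: list[ManifestFeature] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def of_type(self, ftype: str, contig: str | None = None) -> list[ManifestFeature]:
        return [
            f for f in self.features
            if f.type == ftype and (contig is None or f.contig == contig)
        ]

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": self.params,
                "features": [asdict(f) for f in self.features],
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "Manifest":
        obj = json.loads(text)
        return cls(
            features=[ManifestFeature(**f) for f in obj["features"]],
            params=obj["params"],
        )

    def merge(self, other: "Manifest") -> None:
        self.features.extend(other.features)


def generate_trna_cassette(
    descriptor: Descriptor,
    isotype: str = "Val",
    anticodon: str | None = None,
    spacing: int = 0,
    cca: bool = False,
    seed=None,
) -> tuple[str, TRNAAnnotation, dict]:
    """A tRNA placeholder followed (after ``spacing`` nt) by a ribozyme.

    ``spacing`` is the number of nucleotides between the tRNA 3' end and the
    ribozyme's G1; negative values make the ribozyme overwrite the tRNA's
    annotated 3' end (emulating imprecise end prediction).  Returns the
    cassette string, the tRNA annotation in cassette-local coordinates and a
    dict describing the embedded ribozyme (start, sequence, variant).
    """
    if not -5 <= spacing <= 10:
        raise ValueError("spacing must be within [-5, 10]")
    rng = _rng(seed)
    anticodon = anticodon or DEFAULT_ANTICODONS.get(isotype, "TAC")
    trna_len = int(rng.integers(70, 91))
    trna = list(_random_dna(rng, trna_len))
    trna[34:37] = list(anticodon)
    if cca:
        trna[-3:] = list("CCA")
    elif "".join(trna[-3:]) == "CCA":
        trna[-1] = "T"
    trna_seq = "".join(trna)

    rz_seq = sample_motif_instance(descriptor, rng)
    rz_start = trna_len + spacing  # coordinate of G1 in the cassette
    cassette = trna_seq[:rz_start] + rz_seq if spacing < 0 else (
        trna_seq + _random_dna(rng, spacing) + rz_seq
    )
    annotation = TRNAAnnotation(
        contig="cassette",
        strand="+",
        begin=0,
        end=trna_len,
        anticodon=anticodon,
        isotype=isotype,
        sequence=trna_seq,
    )
    rz_info = {
        "start": rz_start,
        "end": rz_start + len(rz_seq),
        "sequence": rz_seq,
        "variant": descriptor.variant,
        "spacing": spacing,
    }
    return cassette, annotation, rz_info


@dataclass
class GenomeSpec:
    """Design parameters for one synthetic contig."""

    length: int = 20_000
    contig_id: str = "contig"
    n_ribozymes: Mapping[str, int] = field(
        default_factory=lambda: {"active": 2, "CdA": 0, "CdG": 0, "CdU": 0}
    )
    n_trna_cassettes: int = 2
    spacings: Sequence[int] = (0,)
    isotypes: Sequence[str] = ("Val", "Leu", "Met", "Gly")
    suppressor_fraction: float = 0.0
    cca_fraction: float = 0.0
    genetic_code: int = 11
    orf_density_target: float = 0.8
    alt_gene_fraction: float = 1.0
    tag_rate: float = 0.15
    orf_len_codons: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genetic_code not in (11, 15):
            raise ValueError("genetic_code must be 11 or 15")
        for frac in (self.suppressor_fraction, self.cca_fraction,
                     self.orf_density_target, self.tag_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be within [0, 1]")


def _random_gene(rng: np.random.Generator, n_codons: int,
                 tag_rate: float = 0.0) -> str:
    """A forward-strand gene: start codon, sense codons, stop codon.

    With ``tag_rate`` zero the gene is "universal": its body avoids all
    three stop codons and it ends in TAA, so it reads identically under
    codes 11, 15 and 4.  With a positive ``tag_rate`` in-frame TAG codons
    (read as Gln under code 15) are inserted, at least one per gene, and
    the gene ends in TAA or TGA; under codes 11 and 4 such genes fragment.
    """
    stops = STOP_SETS[11]  # body must be sense under every supported code
    body: list[str] = []
    bases = list("ACGT")
    while len(body) < n_codons:
        if tag_rate and rng.random() < tag_rate:
            body.append("TAG")
            continue
        codon = "".join(rng.choice(bases, size=3))
        if codon in stops:
            continue
        body.append(codon)
    if tag_rate and "TAG" not in body:
        body[int(rng.integers(0, len(body)))] = "TAG"
    stop = str(rng.choice(["TAA", "TGA"])) if tag_rate else "TAA"
    return "ATG" + "".join(body) + stop


def build_genome(spec: GenomeSpec, descriptor: Descriptor) -> tuple[str, Manifest]:
    """Assemble a contig from shuffled feature blocks and random background.

    ``descriptor`` must be the active motif; substituted variants are
    derived from it for the requested false-positive instances.
    """
    if descriptor.variant != "active":
        raise ValueError("build_genome expects the active descriptor")
    rng = _rng(spec.seed)
    variants = {"active": descriptor}
    for fp in derive_fp_variants(descriptor):
        variants[fp.variant] = fp

    blocks: list[tuple[str, list[tuple[str, int, int, str, dict]]]] = []

    # tRNA-ribozyme cassettes (always built from the active motif)
    spacings = list(spec.spacings) or [0]
    for i in range(spec.n_trna_cassettes):
        if spec.suppressor_fraction and rng.random() < spec.suppressor_fraction:
            isotype, anticodon = "Sup", SUPPRESSOR_ANTICODON
        else:
            isotype = str(rng.choice(list(spec.isotypes)))
            anticodon = DEFAULT_ANTICODONS.get(isotype, "TAC")
        spacing = int(spacings[i % len(spacings)])
        cca = bool(spec.cca_fraction and rng.random() < spec.cca_fraction)
        cassette, ann, rz = generate_trna_cassette(
            descriptor, isotype, anticodon, spacing, cca, rng
        )
        feats = [
            ("trna", ann.begin, ann.end, "+",
             {"isotype": isotype, "anticodon": anticodon, "cca": cca,
              "sequence": ann.sequence}),
            ("ribozyme", rz["start"], rz["end"], "+",
             {"variant": rz["variant"], "sequence": rz["sequence"],
              "spacing": spacing, "cassette": True}),
        ]
        blocks.append((cassette, feats))

    # isolated ribozymes per variant
    for variant in ("active", "CdA", "CdG", "CdU"):
        for _ in range(int(spec.n_ribozymes.get(variant, 0))):
            rz_seq = sample_motif_instance(variants[variant], rng)
            blocks.append(
                (rz_seq,
                 [("ribozyme", 0, len(rz_seq), "+",
                   {"variant": variant, "sequence": rz_seq, "cassette": False})])
            )

    # ORF blocks toward the designed coding density; for code-15 genomes a
    # fraction of genes carry in-frame TAG codons (the designed excess)
    target_nt = int(spec.orf_density_target * spec.length)
    gene_nt = 3 * spec.orf_len_codons + 6
    n_genes = -(-target_nt // gene_nt) if target_nt else 0  # ceil
    n_alt = (
        int(round(spec.alt_gene_fraction * n_genes))
        if spec.genetic_code == 15 else 0
    )
    orf_nt = 0
    alt_nt = 0
    for gi in range(n_genes):
        alt = gi < n_alt
        gene = _random_gene(rng, spec.orf_len_codons, spec.tag_rate if alt else 0.0)
        blocks.append(
            (gene, [("orf", 0, len(gene), "+",
                     {"code": spec.genetic_code, "alt": alt})])
        )
        orf_nt += len(gene)
        if alt:
            alt_nt += len(gene)

    feature_nt = sum(len(b[0]) for b in blocks)
    if feature_nt > spec.length:
        raise ValueError(
            f"infeasible packing: features need {feature_nt} nt but "
            f"length={spec.length} (reduce n_ribozymes/n_trna_cassettes/"
            f"orf_density_target)"
        )

    # shuffle blocks and distribute the remaining length as spacers
    order = rng.permutation(len(blocks))
    n_gaps = len(blocks) + 1
    slack = spec.length - feature_nt
    cuts = np.sort(rng.integers(0, slack + 1, size=n_gaps - 1))
    gaps = np.diff(np.concatenate(([0], cuts, [slack])))

    seq_parts: list[str] = []
    manifest = Manifest(params={"spec": asdict(spec)})
    pos = 0
    for gi, bi in enumerate(order):
        gap = int(gaps[gi])
        seq_parts.append(_random_dna(rng, gap))
        pos += gap
        block_seq, feats = blocks[bi]
        for ftype, fs, fe, strand, attrs in feats:
            manifest.features.append(
                ManifestFeature(
                    type=ftype,
                    contig=spec.contig_id,
                    start=pos + fs,
                    end=pos + fe,
                    strand=strand,
                    attrs=dict(attrs),
                )
            )
        seq_parts.append(block_seq)
        pos += len(block_seq)
    seq_parts.append(_random_dna(rng, int(gaps[-1])))
    seq = "".join(seq_parts)
    assert len(seq) == spec.length
    manifest.params["designed_density"] = orf_nt / spec.length
    manifest.params["designed_excess"] = alt_nt / spec.length
    manifest.params["genetic_code"] = spec.genetic_code
    manifest.features.sort(key=lambda f: (f.contig, f.start, f.end, f.type))
    return seq, manifest


def sample_reads(
    genome: str,
    read_length: int = 150,
    n_reads: int = 100,
    seed=None,
) -> list[tuple[str, str]]:
    """Uniformly sampled reads from both strands; deterministic per seed.

    Returns (read_id, sequence) tuples; ids encode start and strand so the
    mapping back to the genome is exact.
    """
    if read_length > len(genome):
        raise ValueError("read_length exceeds genome length")
    rng = _rng(seed)
    reads = []
    for i in range(n_reads):
        start = int(rng.integers(0, len(genome) - read_length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        sub = genome[start:start + read_length]
        if strand == "-":
            sub = revcomp(sub)
        reads.append((f"read{i:06d}|{start}|{strand}", sub))
    return reads
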