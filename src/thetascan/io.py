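"""File-format plumbing: FASTA, GFF3, TSV tables and run headers."""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .motif_engine import Hit
from .trna_annotate import AssociationRecord, TRNAAnnotation

__all__ = [
    "read_fasta",
    "write_fasta",
    "hits_to_tsv",
    "hits_from_tsv",
    "hits_to_gff3",
    "read_trna_table",
    "write_trna_table",
    "associations_to_tsv",
    "read_kinetics_table",
    "run_header",
    "file_sha256",
]

HIT_COLUMNS = (
    "contig", "start", "end", "strand", "variant", "sequence", "cleavage_site",
)
TRNA_COLUMNS = (
    "contig", "begin", "end", "strand", "isotype", "anticodon", "sequence",
)


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly gzipped) multi-FASTA into an ordered id->sequence map."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path, records: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def write_reads(path, reads, fastq: bool = False, quality: str = "I") -> None:
    """Write (id, sequence) reads as FASTA, or FASTQ with a constant quality."""
    with open(path, "w", encoding="utf-8") as fh:
        for rid, seq in reads:
            if fastq:
                fh.write(f"@{rid}\n{seq}\n+\n{quality * len(seq)}\n")
            else:
                fh.write(f">{rid}\n{seq}\n")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_header(**meta) -> list[str]:
    """Comment lines recording tool version and input hashes."""
    fields = {"tool": f"thetascan {__version__}", **meta}
    return [f"# {k}={v}" for k, v in fields.items()]


def _write_table(path, columns: Sequence[str], rows: Iterable[Sequence],
                 header_lines: Sequence[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def hits_to_tsv(path, hits: Iterable[Hit], header_lines: Sequence[str] = ()) -> None:
    _write_table(
        path, HIT_COLUMNS,
        (
            (h.contig, h.start, h.end, h.strand, h.variant, h.sequence,
             h.cleavage_site)
            for h in hits
        ),
        header_lines,
    )


def hits_from_tsv(path) -> list[Hit]:
    hits = []
    with open(path, encoding="utf-8") as fh:
        cols = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if cols is None:
                cols = line.split("\t")
                missing = set(HIT_COLUMNS) - set(cols)
                if missing:
                    raise ValueError(f"hit table missing columns: {sorted(missing)}")
                continue
            rec = dict(zip(cols, line.split("\t")))
            hits.append(
                Hit(
                    contig=rec["contig"],
                    start=int(rec["start"]),
                    end=int(rec["end"]),
                    strand=rec["strand"],
                    variant=rec["variant"],
                    sequence=rec["sequence"],
                    element_spans=(),
                    cleavage_site=int(rec["cleavage_site"]),
                )
            )
    return hits


def hits_to_gff3(path, hits: Iterable[Hit], names: dict[str, str] | None = None,
                 header_lines: Sequence[str] = ()) -> None:
    """Write hits as GFF3 (1-based inclusive coordinates, type 'ribozyme')."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for line in header_lines:
            fh.write(line + "\n")
        for h in hits:
            name = (names or {}).get(h.sequence, ".")
            attrs = (
                f"variant={h.variant};name={name};cleavage_site={h.cleavage_site}"
            )
            fh.write(
                "\t".join(
                    (
                        h.contig, "thetascan", "ribozyme",
                        str(h.start + 1), str(h.end), ".", h.strand, ".", attrs,
                    )
                )
                + "\n"
            )


def write_trna_table(path, trnas: Iterable[TRNAAnnotation],
                     header_lines: Sequence[str] = ()) -> None:
    _write_table(
        path, TRNA_COLUMNS,
        (
            (t.contig, t.begin, t.end, t.strand, t.isotype, t.anticodon,
             t.sequence or "")
            for t in trnas
        ),
        header_lines,
    )


def read_trna_table(path) -> list[TRNAAnnotation]:
    """Read the documented tRNA TSV dialect (column order fixed, header row)."""
    trnas = []
    with open(path, encoding="utf-8") as fh:
        cols = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if cols is None:
                cols = line.split("\t")
                missing = set(TRNA_COLUMNS[:-1]) - set(cols)
                if missing:
                    raise ValueError(f"tRNA table missing columns: {sorted(missing)}")
                continue
            rec = dict(zip(cols, line.split("\t")))
            trnas.append(
                TRNAAnnotation(
                    contig=rec["contig"],
                    begin=int(rec["begin"]),
                    end=int(rec["end"]),
                    strand=rec["strand"],
                    isotype=rec["isotype"],
                    anticodon=rec["anticodon"],
                    sequence=rec.get("sequence") or None,
                )
            )
    return trnas


def associations_to_tsv(path, associations: Iterable[AssociationRecord],
                        header_lines: Sequence[str] = ()) -> None:
    cols = (
        "contig", "rz_start", "rz_end", "strand", "cleavage_site",
        "trna_begin", "trna_end", "isotype", "anticodon", "distance",
        "adjacency", "pair_name",
    )
    _write_table(
        path, cols,
        (
            (
                a.ribozyme.contig, a.ribozyme.start, a.ribozyme.end,
                a.ribozyme.strand, a.ribozyme.cleavage_site,
                a.trna.begin, a.trna.end, a.trna.isotype, a.trna.anticodon,
                a.distance, a.adjacency, a.pair_name or ".",
            )
            for a in associations
        ),
        header_lines,
    )


def read_kinetics_table(path) -> list[dict]:
    """Read a kinetics TSV with columns time_min, replicate, and either f or
    I_tRNA/I_substrate, plus optional condition_type/condition_value."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        cols = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if cols is None:
                cols = line.split("\t")
                if "time_min" not in cols or not (
                    "f" in cols or {"I_tRNA", "I_substrate"} <= set(cols)
                ):
                    raise ValueError(
                        "kinetics table needs time_min and either f or "
                        "I_tRNA/I_substrate columns"
                    )
                continue
            rows.append(dict(zip(cols, line.split("\t"))))
    return rows


def write_json(path, obj) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
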