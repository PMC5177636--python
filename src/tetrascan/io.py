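"""Sequence and interval I/O.

Reads multi-record FASTA and GenBank flat files into plain
:class:`SequenceRecord` objects, reads feature intervals from GFF3 or a
simple 4/5-column TSV, and provides the elementary sequence operations
(reverse complement, G+C content) every downstream stage relies on.

All user-facing coordinates are 1-based inclusive, the GFF3 convention.
Sequences are normalised on ingest: uppercased, U mapped to T; any
character outside the IUPAC nucleotide alphabet is a hard error naming
the record and offending position.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

log = logging.getLogger(__name__)

#: IUPAC nucleotide codes accepted after normalisation.
IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

FEATURE_KINDS = ("CDS", "rRNA", "other")


def normalize_sequence(raw: str, record_id: str = "<sequence>") -> str:
    """Uppercase, map U->T and validate against the IUPAC alphabet.

    Raises ``ValueError`` naming the record and the 1-based position of
    the first invalid residue.
    """
    seq = raw.upper().replace("U", "T")
    for pos, ch in enumerate(seq, start=1):
        if ch not in IUPAC_NUCLEOTIDES:
            raise ValueError(
                f"record {record_id!r}: invalid residue {ch!r} at position {pos}"
            )
    if not seq:
        raise ValueError(f"record {record_id!r}: empty sequence")
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence.

    ``seq`` is normalised on construction (uppercase, U->T); invalid
    residues raise immediately.
    """

    id: str
    seq: str
    description: str = ""
    source: str = "synthetic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize_sequence(self.seq, self.id))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class FeatureInterval:
    """A 1-based inclusive annotation interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    kind: str = "other"
    label: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"interval {self.label or self.kind} on {self.seq_id}: "
                f"require 1 <= start <= end, got [{self.start}, {self.end}]"
            )
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement (IUPAC-aware; N complements to N)."""
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - IUPAC_NUCLEOTIDES
    if bad:
        raise ValueError(f"invalid residue(s) {sorted(bad)} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """G+C percentage over unambiguous bases.

    N and other ambiguity codes are excluded from both numerator and
    denominator; a sequence with no unambiguous base raises.
    """
    seq = seq.upper().replace("U", "T")
    gc = sum(seq.count(b) for b in "GC")
    at = sum(seq.count(b) for b in "AT")
    if gc + at == 0:
        raise ValueError("G+C content undefined: no unambiguous bases")
    return 100.0 * gc / (gc + at)


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a multi-record FASTA file, preserving record order."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(
                id=rec.id,
                seq=str(rec.seq),
                description=rec.description,
                source=str(path),
            )
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description) for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_genbank(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read GenBank flat file(s); sequence extraction only."""
    records = [
        SequenceRecord(
            id=rec.id, seq=str(rec.seq), description=rec.description, source=str(path)
        )
        for rec in SeqIO.parse(str(path), "genbank")
    ]
    if not records:
        raise ValueError(f"{path}: no GenBank records found")
    return records


def _kind_from_type(feature_type: str) -> str:
    t = feature_type.strip()
    if t.upper() == "CDS":
        return "CDS"
    if t.lower() in {"rrna", "rrna_gene"} or t == "rRNA":
        return "rRNA"
    return "other"


def _gff3_label(attributes: str, fallback: str) -> str:
    for part in attributes.strip().split(";"):
        if "=" in part:
            key, value = part.split("=", 1)
            if key.strip() in {"ID", "Name"}:
                return value.strip()
    return fallback


def read_intervals(
    path: str | os.PathLike,
    format: str = "gff3",
    lengths: dict[str, int] | None = None,
) -> list[FeatureInterval]:
    """Read feature intervals from GFF3 or 4/5-column TSV.

    TSV columns: seq_id, start, end, kind[, label]. When ``lengths`` maps
    sequence ids to lengths, coordinates are validated against them.
    Malformed lines raise ``ValueError`` naming the line number; an empty
    file yields an empty collection with a logged warning.
    """
    if format not in {"gff3", "tsv"}:
        raise ValueError(f"unknown interval format {format!r}")
    intervals: list[FeatureInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if format == "gff3":
                    if len(cols) < 8:
                        raise ValueError(f"expected >= 8 tab-separated columns")
                    seq_id, _, ftype, start_s, end_s = cols[0], cols[1], cols[2], cols[3], cols[4]
                    kind = _kind_from_type(ftype)
                    label = _gff3_label(cols[8] if len(cols) > 8 else "", ftype)
                else:
                    if len(cols) < 4:
                        raise ValueError("expected >= 4 tab-separated columns")
                    seq_id, start_s, end_s, kind = cols[0], cols[1], cols[2], cols[3]
                    kind = _kind_from_type(kind)
                    label = cols[4] if len(cols) > 4 else ""
                start, end = int(start_s), int(end_s)
                if end < start:
                    raise ValueError(f"end {end} < start {start}")
                if lengths is not None and seq_id in lengths and end > lengths[seq_id]:
                    raise ValueError(
                        f"end {end} beyond sequence {seq_id!r} length {lengths[seq_id]}"
                    )
                intervals.append(
                    FeatureInterval(seq_id=seq_id, start=start, end=end, kind=kind, label=label)
                )
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from None
    if not intervals:
        log.warning("%s: no intervals found", path)
    return intervals


def write_intervals_gff3(
    intervals: Sequence[FeatureInterval], path: str | os.PathLike, source: str = "tetrascan"
) -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for iv in intervals:
            ftype = {"CDS": "CDS", "rRNA": "rRNA"}.get(iv.kind, "region")
            attrs = f"ID={iv.label}" if iv.label else "."
            handle.write(
                f"{iv.seq_id}\t{source}\t{ftype}\t{iv.start}\t{iv.end}\t.\t+\t.\t{attrs}\n"
            )
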