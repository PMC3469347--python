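"""Readers/writers for the plain-text formats the toolkit consumes.

Four formats: FASTA sequence sets, 12-column tabular pairwise alignments
(the de facto BLAST ``outfmt 6`` layout), two-column count tables and
two-column gene-to-category annotation tables.

Coordinates are 1-based inclusive only at the file boundary; everything
downstream works with 0-based half-open intervals on the subject sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: 12-column tabular alignment layout.
OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence, nucleotide (``nt``) or amino-acid (``aa``)."""

    id: str
    seq: str
    moltype: str = "nt"

    def __post_init__(self) -> None:
        if self.moltype not in ("nt", "aa"):
            raise ValueError(f"moltype must be 'nt' or 'aa', got {self.moltype!r}")
        if not self.seq:
            raise ValueError(f"empty sequence for id {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignmentRecord:
    """One pairwise alignment row (one HSP).

    ``qstart``/``qend`` and ``sstart``/``send`` are kept as read from the
    file (1-based inclusive; subject coordinates may be reversed for
    minus-strand nucleotide hits).  ``s_lo``/``s_hi`` expose the subject
    interval normalised to 0-based half-open forward orientation, which is
    the only coordinate form the coverage and assignment code uses.
    ``subject_units`` records whether subject positions count nucleotides
    or amino acids (translated / protein searches).
    """

    qseqid: str
    sseqid: str
    pident: float
    aln_len: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    subject_units: str = "nt"

    def __post_init__(self) -> None:
        if self.subject_units not in ("nt", "aa"):
            raise ValueError(f"subject_units must be 'nt' or 'aa'")
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError(f"pident out of [0,100]: {self.pident}")
        if self.aln_len <= 0:
            raise ValueError(f"aln_len must be positive: {self.aln_len}")
        if self.evalue < 0:
            raise ValueError(f"negative evalue: {self.evalue}")

    @property
    def s_lo(self) -> int:
        """0-based half-open lower bound of the subject interval."""
        return min(self.sstart, self.send) - 1

    @property
    def s_hi(self) -> int:
        """0-based half-open upper bound of the subject interval."""
        return max(self.sstart, self.send)

    @property
    def subject_interval(self) -> tuple[int, int]:
        return (self.s_lo, self.s_hi)


@dataclass
class CountsTable:
    """Per-id unique-read counts plus the library size N used in RPKM."""

    counts: dict[str, int]
    total_mapped: int

    def __post_init__(self) -> None:
        for key, value in self.counts.items():
            if value < 0:
                raise ValueError(f"negative count for {key!r}: {value}")
        if self.counts and self.total_mapped < max(self.counts.values()):
            raise ValueError("total_mapped smaller than a single count")
        if self.total_mapped <= 0:
            raise ValueError("total_mapped must be positive")


AnnotationTable = dict[str, set[str]]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, moltype: str = "nt") -> list[SequenceRecord]:
    """Read a FASTA file; the header token before the first whitespace is the id."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for id {rec.id!r} in {path}")
        records.append(SequenceRecord(id=rec.id, seq=seq, moltype=moltype))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# 12-column tabular alignments

def read_alignments(path: str | Path, subject_units: str = "nt") -> list[AlignmentRecord]:
    """Parse a 12-column tab-separated alignment table.

    Raises ``ValueError`` naming the offending line for malformed rows.
    """
    rows: list[AlignmentRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated fields, got {len(fields)}"
                )
            try:
                rows.append(
                    AlignmentRecord(
                        qseqid=fields[0],
                        sseqid=fields[1],
                        pident=float(fields[2]),
                        aln_len=int(fields[3]),
                        mismatch=int(fields[4]),
                        gapopen=int(fields[5]),
                        qstart=int(fields[6]),
                        qend=int(fields[7]),
                        sstart=int(fields[8]),
                        send=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                        subject_units=subject_units,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return rows


def write_alignments(rows: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for r in rows:
            handle.write(
                "\t".join(
                    [
                        r.qseqid,
                        r.sseqid,
                        f"{r.pident:.2f}",
                        str(r.aln_len),
                        str(r.mismatch),
                        str(r.gapopen),
                        str(r.qstart),
                        str(r.qend),
                        str(r.sstart),
                        str(r.send),
                        f"{r.evalue:.3g}",
                        f"{r.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Count tables

def read_counts(path: str | Path) -> CountsTable:
    """Read a 2-column (id, count) TSV.

    An optional ``#total_mapped=N`` header takes precedence over the column
    sum as the library size.
    """
    counts: dict[str, int] = {}
    total_mapped: int | None = None
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("total_mapped="):
                    total_mapped = int(body.split("=", 1)[1])
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields")
            key, raw = fields
            value = int(raw)
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative count for {key!r}")
            if key in counts:
                raise ValueError(f"{path}:{lineno}: duplicate id {key!r}")
            counts[key] = value
    if total_mapped is None:
        total_mapped = sum(counts.values())
    return CountsTable(counts=counts, total_mapped=total_mapped)


def write_counts(table: CountsTable, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(f"#total_mapped={table.total_mapped}\n")
        for key, value in table.counts.items():
            handle.write(f"{key}\t{value}\n")


# ---------------------------------------------------------------------------
# Annotation tables

def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a gene<TAB>category table, one pair per row."""
    ann: AnnotationTable = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields")
            gene, category = fields
            if not category:
                raise ValueError(f"{path}:{lineno}: empty category id")
            ann.setdefault(gene, set()).add(category)
    return ann


def write_annotations(ann: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as handle:
        for gene in sorted(ann):
            for category in sorted(ann[gene]):
                handle.write(f"{gene}\t{category}\n")
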