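"""Domain records and readers/writers for FASTA, FASTQ, SAM/BAM and report CSVs.

Conventions used throughout the package:

* coordinates are 1-based inclusive on the forward strand of the source contig;
* a FASTA record id is the first whitespace-delimited header token, the full
  header line is retained as ``description``;
* residues are uppercased on read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import pysam

__all__ = [
    "SequenceRecord",
    "AlignmentRecord",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "read_alignments",
]

FASTA_WRAP = 60  # column width used when writing sequences

NUCLEOTIDES = set("ACGTN")
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
STANDARD_AA_SET = set(STANDARD_AA)


@dataclass
class SequenceRecord:
    """A named nucleotide or protein sequence with optional provenance.

    ``start``/``end`` are 1-based inclusive coordinates on the forward strand
    of ``source_contig``; for a called gene they span start codon through stop
    codon, so ``end - start + 1`` equals the gene's nucleotide length.
    """

    id: str
    seq: str
    alphabet: str = "protein"  # "nucleotide" | "protein"
    sample: str = ""
    description: str = ""
    source_contig: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    strand: Optional[str] = None  # "+" | "-"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord requires a non-empty id")
        if not self.seq:
            raise ValueError(f"SequenceRecord {self.id!r} has an empty sequence")
        if self.start is not None and self.end is not None:
            if not (1 <= self.start <= self.end):
                raise ValueError(
                    f"record {self.id!r}: invalid coordinates {self.start}..{self.end}"
                )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"record {self.id!r}: invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignmentRecord:
    """A single read alignment against a reference gene/protein id."""

    read_id: str
    ref_id: Optional[str]
    pos: Optional[int]  # 1-based leftmost mapped position; None when unmapped
    mapq: int
    mapped: bool
    primary: bool
    supplementary: bool
    mate_number: int  # 1 or 2 for paired reads, 0 for unpaired

    def __post_init__(self) -> None:
        if self.mapped and (self.pos is None or self.pos < 1):
            raise ValueError(f"mapped record {self.read_id!r} requires pos >= 1")
        if not self.mapped and self.pos is not None:
            raise ValueError(f"unmapped record {self.read_id!r} must not carry a pos")


def read_fasta(path: str | os.PathLike, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Order is preserved; sequence lines are concatenated with whitespace
    stripped and uppercased; duplicate ids raise a ``ValueError``.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: Optional[str] = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        rid = header.split()[0] if header.split() else ""
        if not rid:
            raise ValueError(f"{path}: FASTA header with no id")
        if rid in seen:
            raise ValueError(f"{path}: duplicate sequence id {rid!r}")
        seen.add(rid)
        records.append(
            SequenceRecord(
                id=rid, seq="".join(chunks).upper(), alphabet=alphabet, description=header
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                header = line[1:]
                chunks = []
            elif line.strip():
                if header is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append("".join(line.split()))
        flush()
    if not records:
        raise ValueError(f"{path}: no records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    """Write records as FASTA, wrapped at 60 columns, preserving input order."""
    records = list(records)
    if not records:
        raise ValueError("write_fasta: empty record collection")
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), FASTA_WRAP):
                fh.write(rec.seq[i : i + FASTA_WRAP] + "\n")


def read_fastq(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTQ file (fixtures only; qualities are discarded)."""
    records: list[SequenceRecord] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or len(lines) % 4 != 0:
        raise ValueError(f"{path}: truncated FASTQ")
    for i in range(0, len(lines), 4):
        if not lines[i].startswith("@"):
            raise ValueError(f"{path}: malformed FASTQ record at line {i + 1}")
        rid = lines[i][1:].split()[0]
        records.append(SequenceRecord(id=rid, seq=lines[i + 1].upper(), alphabet="nucleotide"))
    if not records:
        raise ValueError(f"{path}: no records")
    return records


def write_fastq(reads: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write (id, sequence) pairs as FASTQ with uniform qualities (fixtures only)."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_alignments(
    path: str | os.PathLike,
) -> tuple[list[AlignmentRecord], dict[str, int]]:
    """Read a SAM/BAM file into alignment records plus header reference lengths.

    The reference-length map is needed downstream for RPKM.  pysam already
    rejects alignments whose reference is absent from the header.
    """
    path = os.fspath(path)
    mode = "rb" if path.endswith(".bam") else "r"
    recs: list[AlignmentRecord] = []
    with pysam.AlignmentFile(path, mode, check_sq=False) as af:
        ref_lengths = {name: length for name, length in zip(af.references, af.lengths)}
        for aln in af:
            mapped = not aln.is_unmapped
            if mapped and aln.reference_name not in ref_lengths:
                raise ValueError(
                    f"{path}: alignment references {aln.reference_name!r} absent from header"
                )
            mate = 0
            if aln.is_paired:
                mate = 1 if aln.is_read1 else 2
            recs.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    ref_id=aln.reference_name if mapped else None,
                    pos=aln.reference_start + 1 if mapped else None,
                    mapq=aln.mapping_quality,
                    mapped=mapped,
                    primary=not aln.is_secondary,
                    supplementary=aln.is_supplementary,
                    mate_number=mate,
                )
            )
    return recs, ref_lengths
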