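"""Read counting per candidate gene and CPM/RPKM/TPM normalization.

Counting follows the plain samtools idiom: every mapped, primary,
non-supplementary record adds one to its reference gene, so each mate of a
proper pair contributes one read.  Totals cover the genes quantified (the
homology hits), not the whole metagenome — CPM/TPM are therefore relative to
the screened candidate set, which is the quantity the screening report needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .seqio import AlignmentRecord

__all__ = ["AbundanceRecord", "count_reads", "normalize"]


@dataclass
class AbundanceRecord:
    gene_id: str
    length_bp: int
    raw_count: int
    cpm: float
    rpkm: float
    tpm: float

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"gene {self.gene_id!r}: length_bp must be >= 1")
        if self.raw_count < 0 or self.cpm < 0 or self.tpm < 0:
            raise ValueError(f"gene {self.gene_id!r}: negative abundance value")


def count_reads(
    alignments: Iterable[AlignmentRecord], genes: Mapping[str, int]
) -> dict[str, int]:
    """Reads per gene: mapped + primary + non-supplementary records count.

    ``genes`` maps gene id to nucleotide length; genes with no alignments get
    a zero count.  An alignment against an unknown gene raises.
    """
    counts = {g: 0 for g in genes}
    for aln in alignments:
        if not aln.mapped or not aln.primary or aln.supplementary:
            continue
        if aln.ref_id not in counts:
            raise ValueError(f"alignment references unknown gene {aln.ref_id!r}")
        counts[aln.ref_id] += 1
    return counts


def normalize(counts: Mapping[str, int], lengths: Mapping[str, int]) -> list[AbundanceRecord]:
    """CPM, RPKM and TPM per gene from raw counts and lengths in bp.

    cpm = c/N * 1e6;  rpkm = c / (l/1e3 * N/1e6);  tpm = (c/l) / sum(c/l) * 1e6.
    With zero total counts all normalized fields are 0.
    """
    for g in counts:
        if g not in lengths:
            raise ValueError(f"no length for gene {g!r}")
        if lengths[g] < 1:
            raise ValueError(f"gene {g!r}: non-positive length")
    ids = list(counts)
    N = sum(counts[g] for g in ids)
    rates = {g: counts[g] / lengths[g] for g in ids}
    rate_total = sum(rates.values())
    records = []
    for g in ids:
        c, l = counts[g], lengths[g]
        if N == 0:
            cpm = rpkm = tpm = 0.0
        else:
            cpm = c / N * 1e6
            rpkm = c / ((l / 1e3) * (N / 1e6))
            tpm = (rates[g] / rate_total * 1e6) if rate_total > 0 else 0.0
        records.append(
            AbundanceRecord(gene_id=g, length_bp=l, raw_count=c, cpm=cpm, rpkm=rpkm, tpm=tpm)
        )
    return records
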