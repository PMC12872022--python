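"""Stand-in bacterial gene caller: six-frame maximal ORF finding.

This is deliberately simple — one gene per stop codon, longest in-frame
start-to-stop ORF, alternative starts GTG/TTG translated as M — and is the
caller every test and fixture in this package uses.  An external caller's
protein FASTA can always be supplied directly in ``proteins`` mode instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .seqio import NUCLEOTIDES, SequenceRecord

__all__ = ["OrfParams", "find_orfs", "call_genes", "translate", "reverse_complement"]

START_CODONS = {"ATG", "GTG", "TTG"}
STOP_CODONS = {"TAA", "TAG", "TGA"}

# Standard genetic code (DNA codons).
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class OrfParams:
    """Parameters of the internal ORF caller."""

    min_aa_len: int = 30
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.min_aa_len < 1:
            raise ValueError("min_aa_len must be >= 1")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a coding sequence; the first codon is always rendered as M.

    The trailing stop codon, if present, is dropped.  Codons containing N
    are rejected — the caller never emits them.
    """
    if len(cds) % 3 != 0:
        raise ValueError("coding sequence length not divisible by 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon not in CODON_TABLE:
            raise ValueError(f"untranslatable codon {codon!r}")
        aas.append(CODON_TABLE[codon])
    if aas and aas[-1] == "*":
        aas.pop()
    if "*" in aas:
        raise ValueError("internal stop codon in coding sequence")
    if aas:
        aas[0] = "M"
    return "".join(aas)


def _orfs_in_frame(seq: str, offset: int) -> list[tuple[int, int]]:
    """0-based [start, stop-codon-end) intervals of maximal ORFs in one frame.

    One ORF per stop codon: the FIRST start codon after the previous stop.
    Codons containing N terminate any pending ORF (treated as non-coding).
    """
    out = []
    start = None
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            start = None
            continue
        if codon in STOP_CODONS:
            if start is not None:
                out.append((start, i + 3))
            start = None
        elif start is None and codon in START_CODONS:
            start = i
    return out


def find_orfs(contig: SequenceRecord, params: OrfParams | None = None) -> list[SequenceRecord]:
    """All maximal start-to-stop ORFs with >= ``min_aa_len`` residues on 6 frames.

    Outputs carry forward-strand 1-based inclusive coordinates that span the
    start codon through the stop codon, and ids ``<contig>_<n>`` numbered in
    order of forward-strand start position.
    """
    params = params or OrfParams()
    if contig.alphabet != "nucleotide" or not set(contig.seq) <= NUCLEOTIDES:
        raise ValueError(f"contig {contig.id!r}: not a nucleotide sequence over ACGTN")
    seq = contig.seq
    n = len(seq)
    found: list[tuple[int, int, str, str]] = []  # (fwd_start0, fwd_end0_excl, strand, protein)
    strands = [("+", seq)]
    if params.both_strands:
        strands.append(("-", reverse_complement(seq)))
    for strand, s in strands:
        for offset in range(3):
            for a, b in _orfs_in_frame(s, offset):
                protein = translate(s[a:b])
                if len(protein) < params.min_aa_len:
                    continue
                if strand == "+":
                    found.append((a, b, "+", protein))
                else:
                    # map reverse-strand interval back to forward coordinates
                    found.append((n - b, n - a, "-", protein))
    # number along the forward strand; ties (same start) broken by end then strand
    found.sort(key=lambda t: (t[0], t[1], t[2]))
    out = []
    for i, (a, b, strand, protein) in enumerate(found, start=1):
        out.append(
            SequenceRecord(
                id=f"{contig.id}_{i}",
                seq=protein,
                alphabet="protein",
                sample=contig.sample,
                source_contig=contig.id,
                start=a + 1,
                end=b,
                strand=strand,
            )
        )
    return out


def call_genes(
    records: Iterable[SequenceRecord],
    mode: str,
    params: OrfParams | None = None,
) -> list[SequenceRecord]:
    """Dispatch on input mode: pass proteins through, or call ORFs per record."""
    records = list(records)
    if mode == "proteins":
        for rec in records:
            if rec.alphabet == "nucleotide":
                raise ValueError(f"record {rec.id!r}: nucleotide input in proteins mode")
        return records
    if mode not in ("contigs", "genome"):
        raise ValueError(f"unknown input mode {mode!r}")
    proteins: list[SequenceRecord] = []
    for rec in records:
        if rec.alphabet == "protein" or not set(rec.seq) <= NUCLEOTIDES:
            raise ValueError(f"record {rec.id!r}: protein input in {mode} mode")
        proteins.extend(find_orfs(rec, params))
    return proteins
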