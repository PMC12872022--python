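"""Deterministic generators for every synthetic input the pipeline needs.

These emulate the study conditions end to end: per-polymer seed families with
controlled identity to a consensus, decoy proteomes of distant or shuffled
homologs, metagenomic contigs with planted genes at known coordinates, and
error-free paired reads tiled to exact per-gene depths (so abundance
assertions can be exact rather than statistical).

Everything is seeded; the same spec and seed reproduce identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .genecall import CODON_TABLE, STOP_CODONS, reverse_complement
from .seqio import STANDARD_AA, SequenceRecord

__all__ = [
    "FamilySpec",
    "PlantedGene",
    "PlantedTruth",
    "generate_family",
    "shuffled_decoys",
    "mutated_decoys",
    "generate_metagenome",
    "generate_reads",
]

_AA = np.array(list(STANDARD_AA))
# residue -> synonymous codons (stops excluded); first residue always uses ATG
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in CODON_TABLE.items():
    if aa != "*":
        _CODONS_FOR.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR:
    _CODONS_FOR[aa].sort()


@dataclass
class FamilySpec:
    polymer: str
    # typical depolymerase catalytic domains are a couple hundred residues
    consensus_length: int = 180
    n_members: int = 12
    identity_band: tuple[float, float] = (0.7, 0.9)
    indel_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.identity_band
        if not (0 < lo <= hi <= 1):
            raise ValueError("identity_band must satisfy 0 < lo <= hi <= 1")
        if self.consensus_length < 30:
            raise ValueError("consensus_length must be >= 30")


@dataclass
class PlantedGene:
    gene_id: str
    polymer: str  # polymer label or "negative"
    contig: str
    start: int  # 1-based inclusive, forward strand, spans start..stop codon
    end: int
    strand: str
    protein: str
    cds: str  # coding sequence incl. stop codon, gene orientation
    depth: int = 0


@dataclass
class PlantedTruth:
    genes: dict[str, PlantedGene] = field(default_factory=dict)

    def positives(self) -> list[PlantedGene]:
        return [g for g in self.genes.values() if g.polymer != "negative"]

    def negatives(self) -> list[PlantedGene]:
        return [g for g in self.genes.values() if g.polymer == "negative"]


def _skewed_composition(rng: np.random.Generator) -> np.ndarray:
    # Dirichlet(0.5) gives a family-specific skewed residue usage
    return rng.dirichlet(np.full(20, 0.5))


def _mutate(
    consensus: str,
    target_identity: float,
    indel_rate: float,
    rng: np.random.Generator,
    comp: np.ndarray,
) -> tuple[str, list[str], dict[int, str]]:
    """One derived member: returns (sequence, per-position column, insertions).

    ``column[i]`` is the member's residue at consensus position i or '-' for a
    deletion; ``insertions[i]`` holds residues inserted after position i.
    """
    L = len(consensus)
    n_sub = int(round((1.0 - target_identity) * L))
    sub_pos = rng.choice(L, size=n_sub, replace=False) if n_sub else np.array([], dtype=int)
    column = list(consensus)
    for p in sub_pos:
        choices = [a for a in STANDARD_AA if a != consensus[p]]
        column[p] = choices[rng.integers(len(choices))]
    insertions: dict[int, str] = {}
    n_indel = rng.binomial(L, indel_rate)
    for _ in range(n_indel):
        p = int(rng.integers(1, L - 1))  # keep termini intact
        if rng.random() < 0.5:
            if column[p] != "-":
                column[p] = "-"
        else:
            ins = "".join(rng.choice(_AA, size=1, p=comp))
            insertions[p] = insertions.get(p, "") + ins
    seq = "".join(
        (column[i] if column[i] != "-" else "") + insertions.get(i, "") for i in range(L)
    )
    return seq, column, insertions


def generate_family(
    spec: FamilySpec, max_retries: int = 50
) -> tuple[SequenceRecord, list[SequenceRecord], list[str]]:
    """A seed family: (consensus, members, msa rows aligned to each other).

    Member identities to the consensus are verified with the package's own
    pairwise identity and resampled until they land inside the band.
    """
    from .search import pairwise_identity  # deferred: avoids an import cycle

    rng = np.random.default_rng(spec.seed)
    comp = _skewed_composition(rng)
    consensus_seq = "M" + "".join(rng.choice(_AA, size=spec.consensus_length - 1, p=comp))
    consensus = SequenceRecord(
        id=f"{spec.polymer}_consensus", seq=consensus_seq, alphabet="protein"
    )
    lo, hi = spec.identity_band
    members: list[SequenceRecord] = []
    columns: list[list[str]] = []
    inserts: list[dict[int, str]] = []
    for m in range(spec.n_members):
        for attempt in range(max_retries):
            target = rng.uniform(lo, hi)
            seq, col, ins = _mutate(consensus_seq, target, spec.indel_rate, rng, comp)
            if not seq or seq[0] != "M":
                continue
            realized = pairwise_identity(seq, consensus_seq)
            if lo <= realized <= hi:
                members.append(
                    SequenceRecord(id=f"{spec.polymer}_m{m + 1}", seq=seq, alphabet="protein")
                )
                columns.append(col)
                inserts.append(ins)
                break
        else:
            raise ValueError(
                f"could not realize identity band {spec.identity_band} "
                f"for member {m + 1} after {max_retries} attempts"
            )
    # MSA by construction: one column per consensus position, plus insert
    # columns sized to the widest insertion any member has at that position
    L = len(consensus_seq)
    ins_width = {i: max((len(ins.get(i, "")) for ins in inserts), default=0) for i in range(L)}
    msa = []
    for col, ins in zip(columns, inserts):
        row = []
        for i in range(L):
            row.append(col[i])
            gap_fill = ins.get(i, "")
            row.append(gap_fill + "-" * (ins_width[i] - len(gap_fill)))
        msa.append("".join(row))
    return consensus, members, msa


def shuffled_decoys(
    members: Sequence[SequenceRecord], n: int, seed: int, prefix: str = "decoy"
) -> list[SequenceRecord]:
    """Non-homologous decoys: residue-shuffled copies of family members."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        src = members[int(rng.integers(len(members)))]
        letters = list(src.seq)
        rng.shuffle(letters)
        if "M" in letters:  # keep a start-like residue up front for back-translation
            letters.remove("M")
            letters.insert(0, "M")
        out.append(SequenceRecord(id=f"{prefix}_{i + 1}", seq="".join(letters), alphabet="protein"))
    return out


def mutated_decoys(
    consensus: SequenceRecord,
    n: int,
    identity_band: tuple[float, float],
    seed: int,
    prefix: str = "distant",
) -> list[SequenceRecord]:
    """Distant homologs of a consensus at a controlled identity band."""
    from .search import pairwise_identity

    rng = np.random.default_rng(seed)
    comp = _skewed_composition(rng)
    lo, hi = identity_band
    out = []
    for i in range(n):
        for _ in range(100):
            target = rng.uniform(lo, hi)
            seq, _, _ = _mutate(consensus.seq, target, 0.0, rng, comp)
            if lo <= pairwise_identity(seq, consensus.seq) <= hi:
                out.append(SequenceRecord(id=f"{prefix}_{i + 1}", seq=seq, alphabet="protein"))
                break
        else:
            raise ValueError(f"could not realize identity band {identity_band}")
    return out


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous codons; initial M becomes ATG; a stop codon is appended."""
    codons = ["ATG"]
    for aa in protein[1:]:
        opts = _CODONS_FOR[aa]
        codons.append(opts[int(rng.integers(len(opts)))])
    stops = sorted(STOP_CODONS)
    codons.append(stops[int(rng.integers(len(stops)))])
    return "".join(codons)


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def generate_metagenome(
    families: Sequence[tuple[str, Sequence[SequenceRecord]]],
    n_background_genes: int = 10,
    contig_length_range: tuple[int, int] = (2000, 5000),
    seed: int = 0,
    sample: str = "synthetic",
) -> tuple[list[SequenceRecord], PlantedTruth]:
    """Contigs with planted family genes plus shuffled background genes.

    Each protein is back-translated, wrapped with an in-frame guard stop
    immediately upstream so the internal ORF caller recovers exactly the
    planted interval, and embedded at a recorded coordinate and strand in
    random background DNA.
    """
    if not families:
        raise ValueError("generate_metagenome requires at least one family")
    rng = np.random.default_rng(seed)
    all_members = [m for _, members in families for m in members]
    genes: list[tuple[str, str, str]] = []  # (gene_id, polymer, cds incl. stop)
    for polymer, members in families:
        for m in members:
            genes.append((m.id, polymer, back_translate(m.seq, rng)))
    bg = shuffled_decoys(all_members, n_background_genes, seed=seed + 1, prefix="background")
    for d in bg:
        genes.append((d.id, "negative", back_translate(d.seq, rng)))
    order = rng.permutation(len(genes))
    genes = [genes[i] for i in order]

    lo, hi = contig_length_range
    truth = PlantedTruth()
    contigs: list[SequenceRecord] = []
    i = 0
    c_num = 0
    while i < len(genes):
        c_num += 1
        target = int(rng.integers(lo, hi + 1))
        parts: list[str] = []
        pos = 0
        contig_id = f"contig_{c_num}"
        placed = 0
        while i < len(genes):
            gene_id, polymer, cds = genes[i]
            spacer = int(rng.integers(20, 101))
            cassette_len = spacer + 3 + len(cds)  # spacer + guard stop + cds
            if placed > 0 and pos + cassette_len > target:
                break
            if cassette_len > hi:
                raise ValueError(f"contig range {contig_length_range} too short for {gene_id!r}")
            strand = "+" if rng.random() < 0.5 else "-"
            cassette = _random_dna(spacer, rng) + "TAA" + cds
            g_start = pos + spacer + 3 + 1  # 1-based start of the CDS
            g_end = pos + cassette_len
            if strand == "-":
                cassette = reverse_complement(cassette)
                # forward-strand coordinates of the reverse-oriented CDS
                g_start_f = pos + 1
                g_end_f = pos + len(cds)
                g_start, g_end = g_start_f, g_end_f
            parts.append(cassette)
            pos += cassette_len
            truth.genes[gene_id] = PlantedGene(
                gene_id=gene_id, polymer=polymer, contig=contig_id,
                start=g_start, end=g_end, strand=strand,
                protein=_protein_of(cds), cds=cds,
            )
            placed += 1
            i += 1
        if pos < target:
            parts.append(_random_dna(target - pos, rng))
            pos = target
        contigs.append(
            SequenceRecord(
                id=contig_id, seq="".join(parts), alphabet="nucleotide", sample=sample
            )
        )
    return contigs, truth


def _protein_of(cds: str) -> str:
    from .genecall import translate

    return translate(cds)


def generate_reads(
    truth: PlantedTruth,
    depths: Mapping[str, int],
    read_length: int = 75,
    insert_size: int = 200,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], str, dict[str, int]]:
    """Error-free paired reads tiled over each gene's CDS at exact depth.

    ``depths[gene_id]`` is the number of read PAIRS; each mate counts as one
    read downstream, so the expected raw count is ``2 * depth``.  Returns
    (R1 reads, R2 reads, SAM text of the true alignments, expected counts);
    reads are (id, sequence) pairs and the SAM references the gene CDS ids.
    A gene shorter than the insert (or read) raises.
    """
    r1: list[tuple[str, str]] = []
    r2: list[tuple[str, str]] = []
    sam_lines = ["@HD\tVN:1.6\tSO:unsorted"]
    expected: dict[str, int] = {}
    gene_ids = [g for g in truth.genes if depths.get(g, 0) > 0]
    for g in gene_ids:
        sam_lines.append(f"@SQ\tSN:{g}\tLN:{len(truth.genes[g].cds)}")
    body: list[str] = []
    for g in gene_ids:
        gene = truth.genes[g]
        d = int(depths[g])
        L = len(gene.cds)
        if read_length > L or insert_size > L:
            raise ValueError(f"gene {g!r} (len {L}) shorter than read/insert size")
        expected[g] = 2 * d
        span = L - insert_size
        for j in range(d):
            p = 1 + (j * span) // max(d - 1, 1) if d > 1 else 1
            frag = gene.cds[p - 1 : p - 1 + insert_size]
            seq1 = frag[:read_length]
            seq2 = reverse_complement(frag[-read_length:])
            rid = f"{g}_pair{j + 1}"
            r1.append((rid, seq1))
            r2.append((rid, seq2))
            p2 = p + insert_size - read_length
            qual = "I" * read_length
            body.append(
                f"{rid}\t99\t{g}\t{p}\t60\t{read_length}M\t=\t{p2}\t{insert_size}\t{seq1}\t{qual}"
            )
            body.append(
                f"{rid}\t147\t{g}\t{p2}\t60\t{read_length}M\t=\t{p}\t{-insert_size}\t"
                f"{reverse_complement(seq2)}\t{qual}"
            )
    sam_text = "\n".join(sam_lines + body) + "\n"
    for g, d in depths.items():
        if d == 0:
            expected[g] = 0
    return r1, r2, sam_text, expected
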