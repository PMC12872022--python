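"""Seed-set clustering, pairwise-alignment fallback search, and hit filters.

Clustering follows the CD-HIT greedy-incremental convention: sequences are
scanned longest-first and join the first existing representative they match
at or above the identity threshold, where identity is the number of identical
aligned residues divided by the length of the shorter sequence.

The pairwise search is a Smith–Waterman fallback for polymers whose seed sets
are too heterogeneous to align into an MSA; raw scores are converted to bits
and E-values with standard gapped-BLOSUM62 Karlin–Altschul constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .hmm import TOOL_HMM, TOOL_PAIRWISE, HomologyHit
from .seqio import SequenceRecord

__all__ = [
    "Cluster",
    "PairwiseParams",
    "pairwise_identity",
    "greedy_cluster",
    "pairwise_search",
    "filter_hits",
]


@dataclass
class PairwiseParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")


@dataclass
class Cluster:
    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    identity_threshold: float = 0.95


def _aligner(params: PairwiseParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.mode = mode
    # first gap residue costs open+extend, each further residue costs extend
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def pairwise_identity(a: str, b: str, params: PairwiseParams | None = None) -> float:
    """Fraction of identical residues under a global alignment.

    Denominator is the length of the shorter sequence (CD-HIT convention),
    so a perfect substring match scores 1.0.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires two non-empty sequences")
    params = params or PairwiseParams()
    aligner = _aligner(params, "global")
    aln = next(iter(aligner.align(a, b)))
    sa, sb = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    return matches / min(len(a), len(b))


def greedy_cluster(
    seqs: Iterable[SequenceRecord],
    threshold: float = 0.95,
    params: PairwiseParams | None = None,
) -> list[Cluster]:
    """CD-HIT-style greedy incremental clustering.

    Sequences sorted by length descending (ties: id ascending) are assigned to
    the first representative they match at ``identity >= threshold``; a
    sequence matching no representative founds a new cluster.  The founder is
    therefore always the longest member.
    """
    if not (0 < threshold <= 1):
        raise ValueError("identity threshold must be in (0, 1]")
    seqs = list(seqs)
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("greedy_cluster requires unique sequence ids")
    order = sorted(seqs, key=lambda s: (-len(s.seq), s.id))
    clusters: list[Cluster] = []
    reps: list[SequenceRecord] = []
    for rec in order:
        for cluster, rep in zip(clusters, reps):
            if pairwise_identity(rec.seq, rep.seq, params) >= threshold:
                cluster.member_ids.append(rec.id)
                break
        else:
            clusters.append(
                Cluster(representative_id=rec.id, member_ids=[rec.id], identity_threshold=threshold)
            )
            reps.append(rec)
    return clusters


def smith_waterman_score(query: str, target: str, params: PairwiseParams | None = None) -> float:
    """Raw Smith–Waterman local alignment score."""
    params = params or PairwiseParams()
    aligner = _aligner(params, "local")
    return float(aligner.score(query, target))


def pairwise_search(
    query: SequenceRecord | str,
    targets: Sequence[SequenceRecord],
    polymer: str,
    params: PairwiseParams | None = None,
    db_size: int | None = None,
) -> list[HomologyHit]:
    """Local-alignment search of one query protein against a seed set.

    Each target yields one hit with bit score ``S = (lambda*S_raw - ln K)/ln 2``
    and ``E = m*n*2**(-S)`` where m is the query length and n the total target
    length.  The bias term is structurally 0 for this tool.  Hits are returned
    best-first (ties broken by target id).
    """
    params = params or PairwiseParams()
    if not targets:
        raise ValueError("pairwise_search requires a non-empty target set")
    if isinstance(query, SequenceRecord):
        qid, qseq = query.id, query.seq
    else:
        qid, qseq = "query", query
    if not qseq:
        raise ValueError("empty query sequence")
    m = len(qseq)
    n_total = sum(len(t.seq) for t in targets)
    hits = []
    for t in targets:
        raw = smith_waterman_score(qseq, t.seq, params)
        bits = (params.karlin_lambda * raw - math.log(params.karlin_k)) / math.log(2)
        e = m * n_total * 2.0 ** (-bits)
        hits.append(
            HomologyHit(
                protein_id=qid,
                polymer=polymer,
                tool=TOOL_PAIRWISE,
                bitscore=bits,
                evalue=e,
                bias=0.0,
                envelope=None,
            )
        )
    order = sorted(range(len(hits)), key=lambda i: (-hits[i].bitscore, targets[i].id))
    return [hits[i] for i in order]


def filter_hits(
    hits: Iterable[HomologyHit],
    evalue_max: float = 1e-5,
    bitscore_min: float = 20.0,
    bias_fraction: float = 0.10,
) -> list[HomologyHit]:
    """The screening filter: ``E < evalue_max``, ``S > bitscore_min``, and for
    profile-HMM hits only, ``bias < bias_fraction * S``.  All inequalities are
    strict; input order is preserved."""
    kept = []
    for h in hits:
        if not (h.evalue < evalue_max and h.bitscore > bitscore_min):
            continue
        if h.tool == TOOL_HMM and not (h.bias < bias_fraction * h.bitscore):
            continue
        kept.append(h)
    return kept
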