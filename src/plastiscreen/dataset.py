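"""Training-data construction: negative mining, one-hot labels, cluster-aware splits.

Negatives are distant homologs mined from decoy proteomes with the same
profile-HMM screen and filters used at prediction time, mirroring how the
positive families' profiles pull in look-alike sequences that lack the
activity.  Train/test splitting operates on whole identity clusters so that
no near-duplicate pair straddles the split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .hmm import TOOL_HMM, HomologyHit, ProfileHMM, bias_score, evalue, forward_bitscore, viterbi_align
from .search import filter_hits, greedy_cluster
from .seqio import SequenceRecord

__all__ = ["LabeledProtein", "SplitResult", "mine_negatives", "cluster_split", "one_hot_labels"]


@dataclass
class LabeledProtein:
    record: SequenceRecord
    labels: np.ndarray  # one-hot over the configured polymer list; all-zero = negative
    provenance: str = "positive_db"  # "positive_db" | "negative_mined"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")


@dataclass
class SplitResult:
    train_ids: list[str]
    test_ids: list[str]
    seed: int
    test_cluster_fraction: float = 0.2
    cluster_of: dict[str, str] = field(default_factory=dict)  # id -> representative id


def mine_negatives(
    profiles: Sequence[ProfileHMM],
    proteomes: Sequence[SequenceRecord],
    evalue_max: float = 1e-5,
    bitscore_min: float = 20.0,
    bias_fraction: float = 0.10,
    n_polymers: int | None = None,
) -> list[LabeledProtein]:
    """Screen decoy proteomes and keep every filter-passing protein as a negative.

    Each kept protein gets all-zero labels (length = number of profiles unless
    ``n_polymers`` overrides it) and provenance ``negative_mined``.
    """
    if not proteomes:
        raise ValueError("mine_negatives requires a non-empty proteome set")
    for p in profiles:
        if p.calibration is None:
            raise ValueError(f"profile {p.polymer!r} is not calibrated")
    k = n_polymers if n_polymers is not None else len(profiles)
    db_size = len(proteomes)
    negatives = []
    for rec in proteomes:
        hits = []
        for profile in profiles:
            s = forward_bitscore(profile, rec.seq)
            e = evalue(s, profile.calibration, db_size)
            if e >= evalue_max or s <= bitscore_min:
                continue  # cheap pre-check; Viterbi/bias only for near-passing hits
            _, env, _ = viterbi_align(profile, rec.seq)
            b = bias_score(profile, rec.seq, env)
            hits.append(
                HomologyHit(
                    protein_id=rec.id, polymer=profile.polymer, tool=TOOL_HMM,
                    bitscore=s, evalue=e, bias=b, envelope=env,
                )
            )
        if filter_hits(hits, evalue_max, bitscore_min, bias_fraction):
            negatives.append(
                LabeledProtein(record=rec, labels=np.zeros(k, dtype=int), provenance="negative_mined")
            )
    return negatives


def cluster_split(
    data: Sequence[LabeledProtein],
    identity: float = 0.95,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> SplitResult:
    """Cluster at ``identity`` and assign whole clusters to train or test.

    Clusters are shuffled with ``seed``; the first ``ceil(test_fraction * n)``
    clusters become the test side.  Because the split is by cluster count, the
    realized sequence fractions need not be exactly 80/20.
    """
    records = [d.record for d in data]
    clusters = greedy_cluster(records, threshold=identity)
    n = len(clusters)
    if n < 5:
        raise ValueError(f"cluster_split needs >= 5 clusters, got {n}")
    n_test = math.ceil(test_fraction * n)
    if n_test == 0 or n_test == n:
        raise ValueError("test_fraction yields an empty train or test side")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    test_ids: list[str] = []
    train_ids: list[str] = []
    cluster_of: dict[str, str] = {}
    for rank, ci in enumerate(order):
        cluster = clusters[ci]
        side = test_ids if rank < n_test else train_ids
        side.extend(cluster.member_ids)
        for mid in cluster.member_ids:
            cluster_of[mid] = cluster.representative_id
    # restore input ordering within each side for determinism of downstream use
    pos = {d.record.id: i for i, d in enumerate(data)}
    train_ids.sort(key=pos.__getitem__)
    test_ids.sort(key=pos.__getitem__)
    return SplitResult(
        train_ids=train_ids,
        test_ids=test_ids,
        seed=seed,
        test_cluster_fraction=test_fraction,
        cluster_of=cluster_of,
    )


def one_hot_labels(
    records: Iterable[tuple[str, Sequence[str]]] | Iterable,
    polymers: Sequence[str],
) -> np.ndarray:
    """Build the n-by-k multi-label matrix from per-record polymer annotations.

    ``records`` yields ``(id, [polymer, ...])`` pairs; an empty list marks a
    negative.  Unknown polymer labels raise a ``ValueError``.
    """
    index = {p: i for i, p in enumerate(polymers)}
    rows = []
    for rec_id, labels in records:
        row = np.zeros(len(polymers), dtype=int)
        for lab in labels:
            if lab not in index:
                raise ValueError(f"record {rec_id!r}: unknown polymer label {lab!r}")
            row[index[lab]] = 1
        rows.append(row)
    return np.array(rows, dtype=int) if rows else np.zeros((0, len(polymers)), dtype=int)
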