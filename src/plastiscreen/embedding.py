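"""Protein preprocessing and fixed-length embeddings by mean pooling.

Candidate proteins are trimmed of terminal ambiguous residues (X), validated
against the 20 standard amino acids, embedded per residue, and mean-pooled
into one fixed-length vector per protein.

The default embedder is context-free and deterministic (25 dimensions: a
20-way one-hot plus five scaled physicochemical scalars), so the whole
pipeline runs without any model download.  An adapter contract lets a
transformer protein language model be plugged in behind the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .seqio import STANDARD_AA, STANDARD_AA_SET

__all__ = [
    "EmbedderContract",
    "EmbeddingVector",
    "preprocess_sequence",
    "embed_protein",
    "default_embedder",
    "protbert_adapter",
]


@dataclass
class EmbedderContract:
    """A per-residue embedder: ``per_residue(seq)`` returns a (len, dim) matrix."""

    name: str
    dim: int
    per_residue: Callable[[str], np.ndarray]


@dataclass
class EmbeddingVector:
    protein_id: str
    values: np.ndarray
    embedder_name: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite embedding for {self.protein_id!r}")


def preprocess_sequence(seq: str) -> str:
    """Trim terminal runs of X/x, uppercase, and validate residues.

    Any internal nonstandard residue (B, Z, J, U, O, ``*``, internal X, ...)
    raises a ``ValueError`` naming its 1-based position in the trimmed
    sequence; a sequence empty after trimming also raises.
    """
    if not seq:
        raise ValueError("empty sequence")
    cleaned = seq.upper().strip("X")
    if not cleaned:
        raise ValueError("sequence empty after trimming ambiguous residues")
    for pos, c in enumerate(cleaned, start=1):
        if c not in STANDARD_AA_SET:
            raise ValueError(f"nonstandard residue {c!r} at position {pos}")
    return cleaned


def embed_protein(
    seq: str, embedder: EmbedderContract, protein_id: str = ""
) -> EmbeddingVector:
    """Mean-pool the per-residue matrix into one fixed-length vector."""
    try:
        matrix = np.asarray(embedder.per_residue(seq), dtype=float)
    except Exception as exc:  # attach provenance to embedder failures
        raise RuntimeError(f"embedder {embedder.name!r} failed on {protein_id!r}: {exc}") from exc
    if matrix.shape != (len(seq), embedder.dim):
        raise ValueError(
            f"embedder {embedder.name!r} returned shape {matrix.shape}, "
            f"expected ({len(seq)}, {embedder.dim})"
        )
    return EmbeddingVector(
        protein_id=protein_id, values=matrix.mean(axis=0), embedder_name=embedder.name
    )


# Kyte–Doolittle hydropathy
_HYDROPATHY = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4, "H": -3.2,
    "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5,
    "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}
# net side-chain charge at pH 7 (His treated as neutral)
_CHARGE = {**{a: 0.0 for a in STANDARD_AA}, "D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}
_AROMATIC = {"F", "W", "Y", "H"}
_POLAR = {"S", "T", "N", "Q", "Y", "C", "D", "E", "K", "R", "H"}
# monoisotopic residue masses (Da)
_MONO_MASS = {
    "A": 71.03711, "C": 103.00919, "D": 115.02694, "E": 129.04259, "F": 147.06841,
    "G": 57.02146, "H": 137.05891, "I": 113.08406, "K": 128.09496, "L": 113.08406,
    "M": 131.04049, "N": 114.04293, "P": 97.05276, "Q": 128.05858, "R": 156.10111,
    "S": 87.03203, "T": 101.04768, "V": 99.06841, "W": 186.07931, "Y": 163.06333,
}


def _build_residue_table() -> np.ndarray:
    table = np.zeros((20, 25))
    for i, a in enumerate(STANDARD_AA):
        table[i, i] = 1.0  # one-hot block, alphabetical ACDEFGHIKLMNPQRSTVWY
        table[i, 20] = _HYDROPATHY[a] / 5.0
        table[i, 21] = _CHARGE[a]
        table[i, 22] = 1.0 if a in _AROMATIC else 0.0
        table[i, 23] = 1.0 if a in _POLAR else 0.0
        table[i, 24] = _MONO_MASS[a] / 200.0
    return table


_RESIDUE_TABLE = _build_residue_table()
_AA_IDX = {a: i for i, a in enumerate(STANDARD_AA)}


def default_embedder() -> EmbedderContract:
    """The context-free 25-dimensional embedder (one-hot + physicochemistry).

    Mean pooling of a context-free embedder is permutation invariant: two
    sequences with the same residue composition embed identically.  That is a
    deliberate trade of expressiveness for determinism and zero dependencies.
    """

    def per_residue(seq: str) -> np.ndarray:
        idx = [_AA_IDX[c] for c in seq]
        return _RESIDUE_TABLE[idx]

    return EmbedderContract(name="onehot-physchem-v1", dim=25, per_residue=per_residue)


def protbert_adapter(model_source: str, device: str = "cpu") -> EmbedderContract:
    """Wrap an external per-residue protein language model.

    Applies the space-separated residue formatting such models expect and
    strips special-token rows (CLS/SEP) so that only residue positions enter
    the mean pool.  Requires ``transformers`` and ``torch`` plus a local model;
    when unavailable the pipeline runs with :func:`default_embedder` instead.
    """
    try:
        import torch  # noqa: F401
        from transformers import AutoModel, AutoTokenizer
    except ImportError as exc:
        raise RuntimeError(
            "transformers/torch not available; use default_embedder() instead"
        ) from exc
    try:
        tokenizer = AutoTokenizer.from_pretrained(model_source, do_lower_case=False)
        model = AutoModel.from_pretrained(model_source)
    except Exception as exc:
        raise RuntimeError(
            f"could not load protein language model from {model_source!r}; "
            "use default_embedder() instead"
        ) from exc
    model.eval()
    model.to(device)
    dim = int(model.config.hidden_size)

    def per_residue(seq: str) -> np.ndarray:
        import torch

        spaced = " ".join(seq)
        tokens = tokenizer(spaced, return_tensors="pt").to(device)
        with torch.no_grad():
            hidden = model(**tokens).last_hidden_state[0].cpu().numpy()
        # drop CLS (first) and SEP (last) rows: pool across residues only
        hidden = hidden[1 : 1 + len(seq)]
        return hidden

    return EmbedderContract(name=f"plm:{model_source}", dim=dim, per_residue=per_residue)
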