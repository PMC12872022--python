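"""End-to-end screen: gene calling, homology filters, embedding, classification,
abundance, and the three report files (summary.csv, hits.fasta, abundance.csv).

The flow per run: call genes from the input (or pass proteins through), score
every protein against each requested polymer's profile HMM (or its pairwise
seed set where no profile exists), apply the E-value/bitscore/bias filters,
embed the survivors, attach classifier probabilities for polymers with model
support, quantify abundance when alignments are supplied, and write reports
with a deterministic row order so identical runs are byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .abundance import count_reads, normalize
from .classifier import ClassifierModel, predict_scores
from .dataset import one_hot_labels  # noqa: F401  (re-exported convenience)
from .embedding import default_embedder, embed_protein, preprocess_sequence
from .genecall import OrfParams, call_genes
from .hmm import (
    TOOL_HMM,
    HomologyHit,
    ProfileHMM,
    bias_score,
    evalue,
    forward_bitscore,
    load_profile,
    viterbi_align,
)
from .search import PairwiseParams, filter_hits, pairwise_search
from .seqio import SequenceRecord, read_alignments, read_fasta, write_fasta

__all__ = ["RunConfig", "Resources", "RunResult", "run_pipeline", "write_summary",
           "load_resources"]

SUMMARY_COLUMNS = [
    "protein_id", "sample", "polymer", "tool", "evalue", "bitscore", "bias",
    "ml_mode", "ml_score", "passes_high_confidence",
]


@dataclass
class RunConfig:
    polymers: list[str]
    contigs: Optional[str] = None
    genome: Optional[str] = None
    proteins: Optional[str] = None
    reads: Optional[str] = None  # SAM/BAM of read alignments against hit genes
    sensitive: bool = False
    high_confidence_threshold: float = 0.7
    benchmark_threshold: float = 0.5
    cores: int = 1
    gpu: bool = False
    seed: int = 0
    output_dir: str = "plastiscreen_out"
    min_aa_len: int = 30

    def __post_init__(self) -> None:
        inputs = [p for p in (self.contigs, self.genome, self.proteins) if p is not None]
        if len(inputs) != 1:
            raise ValueError("exactly one of contigs/genome/proteins must be set")
        for t in (self.high_confidence_threshold, self.benchmark_threshold):
            if not 0 < t < 1:
                raise ValueError("thresholds must be in (0, 1)")

    @property
    def input_mode(self) -> str:
        if self.contigs is not None:
            return "contigs"
        if self.genome is not None:
            return "genome"
        return "proteins"

    @property
    def input_path(self) -> str:
        return self.contigs or self.genome or self.proteins  # type: ignore[return-value]


@dataclass
class Resources:
    """Profiles, pairwise seed sets and optional classifier models per run."""

    profiles: dict[str, ProfileHMM] = field(default_factory=dict)
    pairwise_seeds: dict[str, list[SequenceRecord]] = field(default_factory=dict)
    models: dict[str, ClassifierModel] = field(default_factory=dict)  # mode -> model
    pairwise_params: PairwiseParams = field(default_factory=PairwiseParams)

    def available_polymers(self) -> list[str]:
        return sorted(set(self.profiles) | set(self.pairwise_seeds))


@dataclass
class RunResult:
    summary_path: str
    hits_path: Optional[str]
    abundance_path: Optional[str]
    rows: list[dict]
    stage_counts: dict[str, int]


def load_resources(directory: str) -> Resources:
    """Load a resource directory: profiles/*.txt, seeds/*.fasta, models/*.json."""
    from .classifier import load_model

    res = Resources()
    pdir = os.path.join(directory, "profiles")
    if os.path.isdir(pdir):
        for name in sorted(os.listdir(pdir)):
            if name.endswith(".txt"):
                prof = load_profile(os.path.join(pdir, name))
                res.profiles[prof.polymer] = prof
    sdir = os.path.join(directory, "seeds")
    if os.path.isdir(sdir):
        for name in sorted(os.listdir(sdir)):
            if name.endswith((".fasta", ".fa")):
                polymer = name.rsplit(".", 1)[0]
                res.pairwise_seeds[polymer] = read_fasta(os.path.join(sdir, name))
    mdir = os.path.join(directory, "models")
    if os.path.isdir(mdir):
        for mode in ("default", "sensitive"):
            path = os.path.join(mdir, f"{mode}.json")
            if os.path.exists(path):
                res.models[mode] = load_model(path)
    return res


def _screen_protein_hmm(
    rec: SequenceRecord, profile: ProfileHMM, db_size: int,
    evalue_max: float, bitscore_min: float,
) -> Optional[HomologyHit]:
    try:
        seq = preprocess_sequence(rec.seq)
    except ValueError:
        return None  # unscorable residues; skipped with a stage count
    s = forward_bitscore(profile, seq)
    e = evalue(s, profile.calibration, db_size)
    if e >= evalue_max or s <= bitscore_min:
        return None  # cannot pass the filter; skip the costlier Viterbi/bias pass
    _, env, _ = viterbi_align(profile, seq)
    b = bias_score(profile, seq, env)
    return HomologyHit(
        protein_id=rec.id, polymer=profile.polymer, tool=TOOL_HMM,
        bitscore=s, evalue=e, bias=b, envelope=env,
    )


def run_pipeline(
    config: RunConfig,
    resources: Resources,
    records: Optional[Sequence[SequenceRecord]] = None,
    evalue_max: float = 1e-5,
    bitscore_min: float = 20.0,
    bias_fraction: float = 0.10,
) -> RunResult:
    """Run the full screen and write reports under ``config.output_dir``.

    ``records`` may supply the input directly; otherwise it is read from the
    configured FASTA path.
    """
    missing = [p for p in config.polymers if p not in resources.available_polymers()]
    if missing:
        raise ValueError(
            f"no profile or seed set for polymer(s) {missing}; "
            f"available: {resources.available_polymers()}"
        )
    if records is None:
        alphabet = "protein" if config.input_mode == "proteins" else "nucleotide"
        records = read_fasta(config.input_path, alphabet=alphabet)
    counts: dict[str, int] = {}
    proteins = call_genes(records, config.input_mode, OrfParams(min_aa_len=config.min_aa_len))
    counts["genes_called"] = len(proteins)
    db_size = max(len(proteins), 1)

    raw_hits: list[HomologyHit] = []
    for polymer in config.polymers:
        if polymer in resources.profiles:
            profile = resources.profiles[polymer]
            if profile.calibration is None:
                raise ValueError(f"profile for {polymer!r} is not calibrated")
            for rec in proteins:
                hit = _screen_protein_hmm(rec, profile, db_size, evalue_max, bitscore_min)
                if hit is not None:
                    raw_hits.append(hit)
        else:
            targets = resources.pairwise_seeds[polymer]
            for rec in proteins:
                try:
                    seq = preprocess_sequence(rec.seq)
                except ValueError:
                    continue
                hits = pairwise_search(
                    SequenceRecord(id=rec.id, seq=seq), targets, polymer,
                    resources.pairwise_params, db_size,
                )
                raw_hits.append(hits[0])  # best hit per (protein, polymer)
    counts["hits_pre_filter"] = len(raw_hits)
    hits = filter_hits(raw_hits, evalue_max, bitscore_min, bias_fraction)
    counts["hits_post_filter"] = len(hits)

    # embed survivors once; classify where a model supports the polymer
    by_protein = {rec.id: rec for rec in proteins}
    survivor_ids = sorted({h.protein_id for h in hits})
    embedder = default_embedder()
    mode = "sensitive" if config.sensitive else "default"
    model = resources.models.get(mode)
    embeddings: dict[str, np.ndarray] = {}
    for pid in survivor_ids:
        seq = preprocess_sequence(by_protein[pid].seq)
        embeddings[pid] = embed_protein(seq, embedder, pid).values
    counts["embedded"] = len(embeddings)

    scores: dict[str, dict[str, float]] = {pid: {} for pid in survivor_ids}
    if model is not None and survivor_ids:
        X = np.vstack([embeddings[pid] for pid in survivor_ids])
        S = predict_scores(model, X)
        for i, pid in enumerate(survivor_ids):
            for j, polymer in enumerate(model.polymers):
                scores[pid][polymer] = float(S[i, j])
    counts["classified"] = sum(1 for v in scores.values() if v)

    rows = []
    for h in hits:
        rec = by_protein[h.protein_id]
        ml_score = scores.get(h.protein_id, {}).get(h.polymer)
        rows.append(
            {
                "protein_id": h.protein_id,
                "sample": rec.sample,
                "polymer": h.polymer,
                "tool": h.tool,
                "evalue": h.evalue,
                "bitscore": h.bitscore,
                "bias": h.bias,
                "ml_mode": mode if ml_score is not None else "",
                "ml_score": ml_score,
                "passes_high_confidence": (
                    ml_score is not None and ml_score > config.high_confidence_threshold
                ),
            }
        )

    os.makedirs(config.output_dir, exist_ok=True)
    summary_path = os.path.join(config.output_dir, "summary.csv")
    write_summary(rows, summary_path)
    hits_path = None
    if survivor_ids:
        hits_path = os.path.join(config.output_dir, "hits.fasta")
        write_fasta([by_protein[pid] for pid in survivor_ids], hits_path)

    abundance_path = None
    if config.reads is not None:
        alignments, ref_lengths = read_alignments(config.reads)
        genes = {g: ref_lengths[g] for g in ref_lengths if g in set(survivor_ids)}
        if genes:
            kept = [a for a in alignments if not a.mapped or a.ref_id in genes]
            gene_counts = count_reads(kept, genes)
            abundance_records = normalize(gene_counts, genes)
            abundance_path = os.path.join(config.output_dir, "abundance.csv")
            with open(abundance_path, "w") as fh:
                fh.write("gene_id,length_bp,raw_count,cpm,rpkm,tpm\n")
                for r in sorted(abundance_records, key=lambda r: r.gene_id):
                    fh.write(
                        f"{r.gene_id},{r.length_bp},{r.raw_count},"
                        f"{r.cpm:.6f},{r.rpkm:.6f},{r.tpm:.6f}\n"
                    )
            counts["abundance_genes"] = len(abundance_records)

    log_path = os.path.join(config.output_dir, "run.log")
    with open(log_path, "w") as fh:
        for k, v in counts.items():
            fh.write(f"{k}\t{v}\n")
    return RunResult(
        summary_path=summary_path,
        hits_path=hits_path,
        abundance_path=abundance_path,
        rows=rows,
        stage_counts=counts,
    )


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_summary(rows: Sequence[dict], path: str) -> None:
    """Deterministic summary.csv: fixed column order, scores at 6 significant
    digits, rows sorted by (sample, polymer, descending bitscore, id)."""
    ordered = sorted(
        rows, key=lambda r: (r["sample"], r["polymer"], -r["bitscore"], r["protein_id"])
    )
    with open(path, "w") as fh:
        fh.write(",".join(SUMMARY_COLUMNS) + "\n")
        for r in ordered:
            fh.write(",".join(_fmt(r[c]) for c in SUMMARY_COLUMNS) + "\n")
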