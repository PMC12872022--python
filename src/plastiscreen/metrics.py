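"""Evaluation metrics, bootstrap confidence intervals, and the benchmark harness.

Precision, recall, F1 and the Matthews correlation coefficient are computed
from 2x2 confusion counts with the usual zero-denominator conventions
(0 by definition).  Confidence intervals come from a percentile bootstrap of
example-level resamples.  The benchmark harness maps KEGG-orthology
annotations or classifier scores onto confusion counts per polymer, using
K21104 as the correct PET-hydrolase assignment and K05973/K03932 as the
correct PHB-depolymerase assignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "precision_recall_f1",
    "f1_from_pr",
    "mcc",
    "bootstrap_ci",
    "paired_ttest",
    "pearson_r",
    "benchmark_confusion",
    "hits_per_million",
    "PLASTIZYME_KOS",
]

# KEGG orthologs accepted as correct plastizyme annotations per polymer
PLASTIZYME_KOS = {
    "PET": frozenset({"K21104"}),
    "PHB": frozenset({"K05973", "K03932"}),
}


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class EvaluationReport:
    polymer: str
    model_name: str
    precision: float
    recall: float
    f1: float
    mcc: Optional[float] = None
    ci95: Optional[dict] = None  # metric name -> (lo, hi)
    n_bootstrap: int = 0
    seed: int = 0


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); zero denominators give 0."""
    p = c.TP / (c.TP + c.FP) if (c.TP + c.FP) else 0.0
    r = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) else 0.0
    return p, r, f1


def f1_from_pr(p: float, r: float) -> float:
    """Harmonic mean of precision and recall (0 when both vanish)."""
    return 2 * p * r / (p + r) if (p + r) else 0.0


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    denom_sq = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom_sq == 0:
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / float(np.sqrt(denom_sq))


def bootstrap_ci(
    y_true: Sequence,
    y_pred: Sequence,
    metric: Callable[[np.ndarray, np.ndarray], float],
    n: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, float, float]:
    """Percentile bootstrap of ``metric`` over example-level resamples.

    Returns ``(mean, lo, hi)``.  Inputs are canonically sorted by
    ``(y_true, y_pred)`` before resampling, so the result does not depend on
    input ordering.  Resamples where the metric is undefined (``nan``) are
    skipped; if every resample is undefined an error is raised.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred) or len(y_true) < 2:
        raise ValueError("bootstrap_ci requires two equal-length vectors of size >= 2")
    order = np.lexsort((y_pred, y_true))
    y_true, y_pred = y_true[order], y_pred[order]
    rng = np.random.default_rng(seed)
    size = len(y_true)
    vals = []
    for _ in range(n):
        idx = rng.integers(0, size, size=size)
        v = metric(y_true[idx], y_pred[idx])
        if not np.isnan(v):
            vals.append(v)
    if not vals:
        raise ValueError("metric undefined in every bootstrap resample")
    vals = np.asarray(vals)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
    return float(vals.mean()), float(lo), float(hi)


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Paired two-sided t-test; errors on zero difference variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired_ttest requires two equal-length vectors of size >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero variance of paired differences")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("pearson_r requires two equal-length vectors of size >= 2")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def benchmark_confusion(
    predictions: Mapping[str, object],
    truth: Mapping[str, Iterable[str]],
    scheme: str = "ko",
    polymers: Sequence[str] = ("PET", "PHB"),
    score_threshold: float = 0.5,
) -> dict[str, ConfusionCounts]:
    """Confusion counts per polymer from annotations or scores.

    ``truth`` maps each polymer name to its positive protein-id set plus
    ``"negative"`` to the negative-control ids; the sets must be disjoint.

    * ``scheme='ko'``: ``predictions[pid]`` is a set of KO ids; a truth-set
      protein carrying that polymer's correct KO is a TP, otherwise an FN; a
      negative-set protein carrying any plastizyme KO is an FP, otherwise a TN.
    * ``scheme='score'``: ``predictions[pid]`` maps polymer -> score; positive
      iff score strictly exceeds ``score_threshold``.
    """
    sets = {k: set(v) for k, v in truth.items()}
    all_ids: set[str] = set()
    for name, ids in sets.items():
        overlap = all_ids & ids
        if overlap:
            raise ValueError(f"protein(s) {sorted(overlap)} present in two truth sets")
        all_ids |= ids
    negatives = sets.get("negative", set())
    out: dict[str, ConfusionCounts] = {}
    any_ko = frozenset().union(*PLASTIZYME_KOS.values())
    for polymer in polymers:
        pos = sets.get(polymer, set())
        tp = fp = fn = tn = 0
        for pid in sorted(pos):
            if _is_positive(predictions.get(pid), polymer, scheme, score_threshold):
                tp += 1
            else:
                fn += 1
        for pid in sorted(negatives):
            pred = predictions.get(pid)
            if scheme == "ko":
                hit = bool(set(pred or ()) & any_ko)
            else:
                hit = _is_positive(pred, polymer, scheme, score_threshold)
            if hit:
                fp += 1
            else:
                tn += 1
        out[polymer] = ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)
    return out


def _is_positive(pred, polymer: str, scheme: str, threshold: float) -> bool:
    if pred is None:
        return False
    if scheme == "ko":
        return bool(set(pred) & PLASTIZYME_KOS.get(polymer, frozenset()))
    if scheme == "score":
        score = pred.get(polymer) if isinstance(pred, Mapping) else pred
        return score is not None and score > threshold
    raise ValueError(f"unknown benchmark scheme {scheme!r}")


def hits_per_million(n_hits: int, n_proteins: int) -> float:
    """Hit count normalized per million predicted proteins in the sample."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    return n_hits / n_proteins * 1e6
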