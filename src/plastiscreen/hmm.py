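"""Profile hidden Markov models for polymer-specific enzyme families.

A per-family model is built from a seed multiple sequence alignment and used
to score candidate proteins with forward/Viterbi bit scores, Gumbel-calibrated
E-values and a composition-bias correction.

Architecture
------------
Plan7-like single-hit local alignment: L match states (columns with gap
fraction < 0.5), insert and delete states per node, no flanking or multi-hit
states.  Local entry is uniform over match states (1/L each); local exit from
match state k has probability 1/(L-k+1), which makes every exit point equally
likely along a pure match path and forces exit at the last node.  Unaligned
flanking residues are emitted by the null model and cancel in the log-odds
score, so the dynamic programming runs entirely in log-odds space.

The bit score is ``log2 P(seq | profile) / P(seq | null)`` summed over all
paths (forward) or maximised (Viterbi).  E-values come from a Gumbel fit to
forward scores of random null-model sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .seqio import STANDARD_AA, SequenceRecord

__all__ = [
    "ProfileHMM",
    "CalibrationParams",
    "HomologyHit",
    "TOOL_HMM",
    "TOOL_PAIRWISE",
    "build_profile",
    "forward_bitscore",
    "viterbi_align",
    "calibrate_evalues",
    "fit_gumbel",
    "evalue",
    "bias_score",
    "save_profile",
    "load_profile",
]

TOOL_HMM = "hmm"
TOOL_PAIRWISE = "pairwise"

AA_INDEX = {a: i for i, a in enumerate(STANDARD_AA)}
N_AA = 20
LN2 = np.log(2.0)
_TINY = 1e-300  # probability floor so log space never sees -inf from model zeros
DEFAULT_SEED = 42


@dataclass
class CalibrationParams:
    """Gumbel location/scale (in bits) fitted to null forward scores."""

    mu: float
    lam: float
    n_calibration: int
    seed: int

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("calibration lambda must be > 0")
        if self.n_calibration < 100:
            raise ValueError("calibration requires n >= 100 null sequences")


@dataclass
class ProfileHMM:
    polymer: str
    match_emissions: np.ndarray  # (L, 20)
    insert_emissions: np.ndarray  # (L, 20); row L-1 unused (no insert after last node)
    t_mm: np.ndarray  # (L,) node-k distributions over next-node targets
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    null_background: np.ndarray  # (20,)
    calibration: Optional[CalibrationParams] = None

    @property
    def L(self) -> int:
        return self.match_emissions.shape[0]

    def __post_init__(self) -> None:
        L = self.match_emissions.shape[0]
        if L < 1:
            raise ValueError("profile needs at least one match state")
        for name in ("match_emissions", "insert_emissions"):
            arr = getattr(self, name)
            if arr.shape != (L, N_AA):
                raise ValueError(f"{name} must be (L, 20)")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")
        if not np.allclose(self.null_background.sum(), 1.0, atol=1e-9):
            raise ValueError("null_background must sum to 1")
        m_rows = self.t_mm + self.t_mi + self.t_md
        if not np.allclose(m_rows[:-1], 1.0, atol=1e-9):
            raise ValueError("match transition rows must sum to 1")
        if L > 1:
            if not np.allclose((self.t_im + self.t_ii)[:-1], 1.0, atol=1e-9):
                raise ValueError("insert transition rows must sum to 1")
            if not np.allclose((self.t_dm + self.t_dd)[:-1], 1.0, atol=1e-9):
                raise ValueError("delete transition rows must sum to 1")

    # -- local entry/exit (uniform scheme, see module docstring) --
    @property
    def entry(self) -> np.ndarray:
        return np.full(self.L, 1.0 / self.L)

    @property
    def exit(self) -> np.ndarray:
        k = np.arange(self.L)
        return 1.0 / (self.L - k)


def _as_aligned_rows(msa: Iterable) -> list[str]:
    rows = []
    for item in msa:
        rows.append(item.seq if isinstance(item, SequenceRecord) else str(item))
    return [r.upper() for r in rows]


def build_profile(msa: Iterable, polymer: str, pseudocount_weight: float = 1.0) -> ProfileHMM:
    """Estimate a profile from an aligned seed family (gap symbol ``-``).

    Columns with gap fraction < 0.5 become match states.  Emission and
    transition counts are smoothed with ``pseudocount_weight`` times the
    background (uniform for transitions) and normalised.  The null model is
    the residue frequency of the seed set, falling back to uniform when the
    seed set holds fewer than 100 residues.
    """
    rows = _as_aligned_rows(msa)
    if len(rows) < 2:
        raise ValueError("build_profile needs at least 2 aligned sequences")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged alignment")
    if pseudocount_weight <= 0:
        raise ValueError("pseudocount_weight must be positive")

    cols = np.array([list(r) for r in rows])
    gap_frac = (cols == "-").mean(axis=0)
    is_match = gap_frac < 0.5
    L = int(is_match.sum())
    if L == 0:
        raise ValueError("alignment yields zero match columns")

    # null background from seed residues
    residues = [c for r in rows for c in r if c != "-"]
    for c in residues:
        if c not in AA_INDEX:
            raise ValueError(f"nonstandard residue {c!r} in alignment")
    if len(residues) < 100:
        bg = np.full(N_AA, 1.0 / N_AA)
    else:
        counts = np.zeros(N_AA)
        for c in residues:
            counts[AA_INDEX[c]] += 1
        bg = counts / counts.sum()

    match_counts = np.zeros((L, N_AA))
    insert_counts = np.zeros((L, N_AA))
    # transition counts per source node
    c_mm = np.zeros(L); c_mi = np.zeros(L); c_md = np.zeros(L)
    c_im = np.zeros(L); c_ii = np.zeros(L)
    c_dm = np.zeros(L); c_dd = np.zeros(L)

    match_col_idx = np.flatnonzero(is_match)
    for r in rows:
        # per-sequence state path over columns; flanking inserts (before first
        # or after last match column) are treated as unmodelled
        path: list[tuple[str, int]] = []  # (state, node k in 1..L)
        k = 0
        for j, c in enumerate(r):
            if is_match[j]:
                k += 1
                path.append(("M" if c != "-" else "D", k))
            elif c != "-":
                if 1 <= k < L:
                    path.append(("I", k))
                    insert_counts[k - 1, AA_INDEX[c]] += 1
        for (s1, k1), (s2, k2) in zip(path, path[1:]):
            if s1 == "M":
                if s2 == "M":
                    c_mm[k1 - 1] += 1
                elif s2 == "I":
                    c_mi[k1 - 1] += 1
                else:
                    c_md[k1 - 1] += 1
            elif s1 == "I":
                (c_im if s2 == "M" else c_ii)[k1 - 1] += 1
            else:  # D
                if s2 == "M":
                    c_dm[k1 - 1] += 1
                elif s2 == "D":
                    c_dd[k1 - 1] += 1
                # D -> I is not part of the architecture; skipped
    # match emissions from residues observed in match columns
    for r in rows:
        for node, j in enumerate(match_col_idx, start=1):
            c = r[j]
            if c != "-":
                match_counts[node - 1, AA_INDEX[c]] += 1

    w = pseudocount_weight
    match_em = match_counts + w * bg
    match_em /= match_em.sum(axis=1, keepdims=True)
    ins_em = insert_counts + w * bg
    ins_em /= ins_em.sum(axis=1, keepdims=True)

    def norm3(a, b, c):
        s = a + b + c
        return a / s, b / s, c / s

    def norm2(a, b):
        s = a + b
        return a / s, b / s

    t_mm, t_mi, t_md = norm3(c_mm + w / 3, c_mi + w / 3, c_md + w / 3)
    t_im, t_ii = norm2(c_im + w / 2, c_ii + w / 2)
    t_dm, t_dd = norm2(c_dm + w / 2, c_dd + w / 2)
    # last node transitions are structurally unused; fix to a valid row
    t_mm[-1], t_mi[-1], t_md[-1] = 1.0, 0.0, 0.0
    t_im[-1], t_ii[-1] = 1.0, 0.0
    t_dm[-1], t_dd[-1] = 1.0, 0.0

    return ProfileHMM(
        polymer=polymer,
        match_emissions=match_em,
        insert_emissions=ins_em,
        t_mm=t_mm, t_mi=t_mi, t_md=t_md,
        t_im=t_im, t_ii=t_ii,
        t_dm=t_dm, t_dd=t_dd,
        null_background=bg,
    )


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([AA_INDEX[c] for c in seq], dtype=np.intp)
    except KeyError:
        for pos, c in enumerate(seq, start=1):
            if c not in AA_INDEX:
                raise ValueError(f"nonstandard residue {c!r} at position {pos}") from None
        raise


def _log(p: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(p, _TINY))


def _score_tables(profile: ProfileHMM, null: Optional[np.ndarray], local: bool = True):
    bg = profile.null_background if null is None else np.asarray(null, dtype=float)
    lo_m = _log(profile.match_emissions) - _log(bg)[None, :]
    lo_i = _log(profile.insert_emissions) - _log(bg)[None, :]
    ex = profile.exit
    # in global mode exit happens only after node L with probability 1, so the
    # match transitions are not scaled down by a local-exit term
    stay = 1.0 - ex if local else np.ones_like(ex)
    return {
        "lo_m": lo_m,
        "lo_i": lo_i,
        "l_entry": _log(profile.entry),
        "l_exit": _log(ex),
        "l_mm": _log(stay * profile.t_mm),
        "l_mi": _log(stay * profile.t_mi),
        "l_md": _log(stay * profile.t_md),
        "l_im": _log(profile.t_im),
        "l_ii": _log(profile.t_ii),
        "l_dm": _log(profile.t_dm),
        "l_dd": _log(profile.t_dd),
    }


def _delete_row(vm_row: np.ndarray, l_md: np.ndarray, l_dd: np.ndarray) -> np.ndarray:
    """VD over nodes for one residue row, via a prefix log-sum-exp scan.

    VD[k] = LSE over j<k of VM[j] + l_md[j] + sum_{j<m<k} l_dd[m].
    """
    L = vm_row.shape[0]
    vd = np.full(L, -np.inf)
    if L < 2:
        return vd
    s = np.concatenate([[0.0], np.cumsum(l_dd[1:-1])])  # s[j] = sum l_dd[1..j] (0-based)
    u = vm_row[:-1] + l_md[:-1] - s
    acc = np.logaddexp.accumulate(u)
    vd[1:] = acc + s
    return vd


def forward_bitscore(
    profile: ProfileHMM,
    seq: str,
    mode: str = "local",
    null: Optional[np.ndarray] = None,
) -> float:
    """All-paths log-odds bit score of ``seq`` under the profile.

    ``mode='local'`` (default) allows the alignment to cover any subsequence;
    ``mode='global'`` forces entry at node 1 on the first residue and exit at
    node L on the last (deletions still allowed in between).
    """
    if mode not in ("local", "global"):
        raise ValueError(f"unknown mode {mode!r}")
    local = mode == "local"
    x = _encode(seq)
    n = x.shape[0]
    L = profile.L
    t = _score_tables(profile, null, local=local)
    NEG = -np.inf
    vm_prev = np.full(L, NEG)
    vi_prev = np.full(L, NEG)
    vd_prev = np.full(L, NEG)
    total = NEG
    for i in range(n):
        em = t["lo_m"][:, x[i]]
        # match
        vm = np.full(L, NEG)
        if local:
            vm = t["l_entry"].copy()
        elif i == 0:
            vm[0] = 0.0
        cont = np.full(L, NEG)
        cont[1:] = np.logaddexp(
            np.logaddexp(vm_prev[:-1] + t["l_mm"][:-1], vi_prev[:-1] + t["l_im"][:-1]),
            vd_prev[:-1] + t["l_dm"][:-1],
        )
        vm = np.logaddexp(vm, cont) + em
        # delete (depends on current-row match values)
        vd = _delete_row(vm, t["l_md"], t["l_dd"])
        # insert
        vi = np.logaddexp(vm_prev + t["l_mi"], vi_prev + t["l_ii"]) + t["lo_i"][:, x[i]]
        vi[-1] = NEG  # no insert state after the last node
        if local:
            total = np.logaddexp(total, np.logaddexp.reduce(vm + t["l_exit"]))
        vm_prev, vi_prev, vd_prev = vm, vi, vd
    if not local:
        total = np.logaddexp(vm_prev[-1], vd_prev[-1]) if L > 1 else vm_prev[-1]
    if not np.isfinite(total):
        total = -np.inf
    return float(total / LN2)


def viterbi_align(
    profile: ProfileHMM,
    seq: str,
    null: Optional[np.ndarray] = None,
) -> tuple[float, tuple[int, int], list[tuple[str, int]]]:
    """Best local alignment: (bit score, envelope, state path).

    The envelope is the 1-based inclusive span of residues emitted by
    match/insert states on the optimal path.
    """
    x = _encode(seq)
    n = x.shape[0]
    L = profile.L
    t = _score_tables(profile, null)
    NEG = -np.inf
    # vm/vi/vd[i][k]; back pointers: (state, i, k) or ("B",-1,-1)
    vm = np.full((n, L), NEG)
    vi = np.full((n, L), NEG)
    vd = np.full((n, L), NEG)
    ptr: dict[tuple[str, int, int], tuple[str, int, int]] = {}
    for i in range(n):
        for k in range(L):
            em = t["lo_m"][k, x[i]]
            best, src = t["l_entry"][k], ("B", -1, -1)
            if i > 0 and k > 0:
                cands = [
                    (vm[i - 1, k - 1] + t["l_mm"][k - 1], ("M", i - 1, k - 1)),
                    (vi[i - 1, k - 1] + t["l_im"][k - 1], ("I", i - 1, k - 1)),
                    (vd[i - 1, k - 1] + t["l_dm"][k - 1], ("D", i - 1, k - 1)),
                ]
                for v, s in cands:
                    if v > best:
                        best, src = v, s
            vm[i, k] = best + em
            ptr[("M", i, k)] = src
            if k > 0:
                a = vm[i, k - 1] + t["l_md"][k - 1]
                b = vd[i, k - 1] + t["l_dd"][k - 1]
                vd[i, k] = max(a, b)
                ptr[("D", i, k)] = ("M", i, k - 1) if a >= b else ("D", i, k - 1)
            if i > 0 and k < L - 1:
                a = vm[i - 1, k] + t["l_mi"][k]
                b = vi[i - 1, k] + t["l_ii"][k]
                vi[i, k] = max(a, b) + t["lo_i"][k, x[i]]
                ptr[("I", i, k)] = ("M", i - 1, k) if a >= b else ("I", i - 1, k)
    end_scores = vm + t["l_exit"][None, :]
    flat = int(np.argmax(end_scores))
    i_end, k_end = divmod(flat, L)
    score = float(end_scores[i_end, k_end] / LN2)
    # traceback
    path: list[tuple[str, int]] = []
    emitted: list[int] = []
    node = ("M", i_end, k_end)
    while node != ("B", -1, -1):
        state, i, k = node
        path.append((state, k + 1))
        if state in ("M", "I"):
            emitted.append(i)
        node = ptr[node]
    path.reverse()
    envelope = (min(emitted) + 1, max(emitted) + 1)
    return score, envelope, path


def _random_null_seqs(
    bg: np.ndarray, lengths: Sequence[int], rng: np.random.Generator
) -> list[str]:
    aas = np.array(list(STANDARD_AA))
    return ["".join(rng.choice(aas, size=n, p=bg)) for n in lengths]


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Gumbel fit: returns (mu, lam) with lam = 1/scale."""
    scores = np.asarray(scores, dtype=float)
    if scores.std() == 0:
        raise ValueError("degenerate score distribution: all scores equal")
    loc, scale = stats.gumbel_r.fit(scores)
    return float(loc), float(1.0 / scale)


def calibrate_evalues(
    profile: ProfileHMM,
    n_random: int = 200,
    len_distribution: int | Sequence[int] = 150,
    seed: int = DEFAULT_SEED,
) -> CalibrationParams:
    """Fit Gumbel E-value parameters from forward scores of null sequences.

    ``len_distribution`` is either a fixed length or a pool of lengths
    sampled uniformly.  Deterministic given ``seed``.
    """
    if n_random < 100:
        raise ValueError("calibration requires n_random >= 100")
    rng = np.random.default_rng(seed)
    if isinstance(len_distribution, int):
        lengths = [len_distribution] * n_random
    else:
        pool = np.asarray(list(len_distribution), dtype=int)
        lengths = list(rng.choice(pool, size=n_random))
    seqs = _random_null_seqs(profile.null_background, lengths, rng)
    scores = np.array([forward_bitscore(profile, s) for s in seqs])
    mu, lam = fit_gumbel(scores)
    return CalibrationParams(mu=mu, lam=lam, n_calibration=n_random, seed=seed)


def evalue(S: float, cal: Optional[CalibrationParams], db_size: int) -> float:
    """Expected false hits at bit score >= S in a database of ``db_size``.

    P(score >= S) under the fitted Gumbel is 1 - exp(-exp(-lam (S - mu)));
    E = db_size * P.  Monotone non-increasing in S.
    """
    if cal is None:
        raise ValueError("profile is not calibrated; run calibrate_evalues first")
    if db_size < 1:
        raise ValueError("db_size must be >= 1")
    x = cal.lam * (S - cal.mu)
    p = -np.expm1(-np.exp(-x))
    return float(db_size * p)


def bias_score(profile: ProfileHMM, seq: str, envelope: tuple[int, int]) -> float:
    """Composition-bias correction in bits (null2-style).

    Two forward passes: one with the profile's null background, one with the
    null set to the add-one-smoothed residue composition of the envelope.
    ``B = max(0, S_bg - S_comp)``: score explainable by skewed composition.
    """
    a, b = envelope
    if not (1 <= a <= b <= len(seq)):
        raise ValueError(f"envelope {envelope} out of bounds for sequence of length {len(seq)}")
    env = seq[a - 1 : b]
    counts = np.zeros(N_AA)
    for c in env:
        counts[AA_INDEX[c]] += 1
    comp = (counts + 1.0) / (counts.sum() + N_AA)
    s_bg = forward_bitscore(profile, seq)
    s_comp = forward_bitscore(profile, seq, null=comp)
    return max(0.0, s_bg - s_comp)


@dataclass
class HomologyHit:
    """A screened protein with its homology evidence for one polymer."""

    protein_id: str
    polymer: str
    tool: str  # TOOL_HMM | TOOL_PAIRWISE
    bitscore: float
    evalue: float
    bias: float = 0.0
    envelope: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")
        if self.bias < 0:
            raise ValueError("bias must be >= 0")


# ---------------------------------------------------------------------------
# plain-text profile serialization
# ---------------------------------------------------------------------------

def save_profile(profile: ProfileHMM, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("PLASTISCREEN-PROFILE 1\n")
        fh.write(f"POLYMER {profile.polymer}\n")
        fh.write(f"L {profile.L}\n")
        fh.write("BACKGROUND " + " ".join(f"{v:.10e}" for v in profile.null_background) + "\n")
        for name in ("match_emissions", "insert_emissions"):
            fh.write(name.upper() + "\n")
            for row in getattr(profile, name):
                fh.write(" ".join(f"{v:.10e}" for v in row) + "\n")
        fh.write("TRANSITIONS\n")
        for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd"):
            fh.write(name + " " + " ".join(f"{v:.10e}" for v in getattr(profile, name)) + "\n")
        if profile.calibration is not None:
            c = profile.calibration
            fh.write(f"CALIBRATION {c.mu:.10e} {c.lam:.10e} {c.n_calibration} {c.seed}\n")


def load_profile(path: str) -> ProfileHMM:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or not lines[0].startswith("PLASTISCREEN-PROFILE"):
        raise ValueError(f"{path}: not a profile file")
    polymer = lines[1].split(" ", 1)[1]
    L = int(lines[2].split()[1])
    bg = np.array([float(v) for v in lines[3].split()[1:]])
    idx = 4
    mats = {}
    for name in ("MATCH_EMISSIONS", "INSERT_EMISSIONS"):
        assert lines[idx] == name, f"{path}: expected {name}"
        idx += 1
        mats[name] = np.array(
            [[float(v) for v in lines[idx + r].split()] for r in range(L)]
        )
        idx += L
    assert lines[idx] == "TRANSITIONS"
    idx += 1
    trans = {}
    for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd"):
        parts = lines[idx].split()
        assert parts[0] == name
        trans[name] = np.array([float(v) for v in parts[1:]])
        idx += 1
    cal = None
    if idx < len(lines) and lines[idx].startswith("CALIBRATION"):
        _, mu, lam, n, seed = lines[idx].split()
        cal = CalibrationParams(float(mu), float(lam), int(n), int(seed))
    return ProfileHMM(
        polymer=polymer,
        match_emissions=mats["MATCH_EMISSIONS"],
        insert_emissions=mats["INSERT_EMISSIONS"],
        null_background=bg,
        calibration=cal,
        **trans,
    )
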