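import numpy as np
import pytest
from Bio.Align import substitution_matrices

import plastiscreen as ps
from plastiscreen.hmm import TOOL_HMM, TOOL_PAIRWISE, HomologyHit
from plastiscreen.search import smith_waterman_score
from plastiscreen.seqio import STANDARD_AA


def prot(id, seq):
    return ps.SequenceRecord(id=id, seq=seq)


class TestPairwiseIdentity:
    def test_identical(self):
        assert ps.pairwise_identity("MKV", "MKV") == 1.0

    def test_one_mismatch(self):
        assert ps.pairwise_identity("MKV", "MKA") == pytest.approx(2 / 3)

    def test_substring_uses_shorter_denominator(self):
        assert ps.pairwise_identity("MKV", "MKVLIPGA") == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ps.pairwise_identity("", "MKV")


def nw_score_oracle(a, b, gap_open=11.0, gap_extend=1.0):
    """Independent affine-gap global alignment score (Gotoh DP)."""
    mat = substitution_matrices.load("BLOSUM62")
    NEG = -1e9
    open_cost = gap_open + gap_extend
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a aligned to gap)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -open_cost - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -open_cost - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = mat[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - open_cost, X[i - 1, j] - gap_extend,
                          Y[i - 1, j] - open_cost)
            Y[i, j] = max(M[i, j - 1] - open_cost, Y[i, j - 1] - gap_extend,
                          X[i, j - 1] - open_cost)
    return max(M[n, m], X[n, m], Y[n, m])


def sw_score_oracle(a, b, gap_open=11.0, gap_extend=1.0):
    """Independent affine-gap local alignment score."""
    mat = substitution_matrices.load("BLOSUM62")
    NEG = -1e9
    open_cost = gap_open + gap_extend
    n, m = len(a), len(b)
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = mat[a[i - 1], b[j - 1]]
            M[i, j] = max(0.0, max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s)
            X[i, j] = max(M[i - 1, j] - open_cost, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - open_cost, Y[i, j - 1] - gap_extend)
            best = max(best, M[i, j])
    return best


def test_global_alignment_score_matches_dp_oracle():
    rng = np.random.default_rng(5)
    aas = list(STANDARD_AA)
    from plastiscreen.search import PairwiseParams, _aligner

    aligner = _aligner(PairwiseParams(), "global")
    for _ in range(8):
        a = "".join(rng.choice(aas, size=rng.integers(5, 30)))
        b = "".join(rng.choice(aas, size=rng.integers(5, 30)))
        assert aligner.score(a, b) == pytest.approx(nw_score_oracle(a, b))


def test_smith_waterman_textbook_pair_matches_oracle():
    a, b = "HEAGAWGHEE", "PAWHEAE"
    assert smith_waterman_score(a, b) == pytest.approx(sw_score_oracle(a, b))


def test_smith_waterman_random_pairs_match_oracle():
    rng = np.random.default_rng(6)
    aas = list(STANDARD_AA)
    for _ in range(5):
        a = "".join(rng.choice(aas, size=20))
        b = "".join(rng.choice(aas, size=25))
        assert smith_waterman_score(a, b) == pytest.approx(sw_score_oracle(a, b))


class TestGreedyCluster:
    def test_identical_sequences_one_cluster(self):
        seqs = [prot(f"s{i}", "MKVLIPGATREWQNDF" * 3) for i in range(3)]
        clusters = ps.greedy_cluster(seqs)
        assert len(clusters) == 1 and len(clusters[0].member_ids) == 3

    def test_distant_pair_two_singletons(self):
        clusters = ps.greedy_cluster([prot("a", "MKVLIPGATREWQNDF"), prot("b", "MWWWHHHCCCYYYNNN")])
        assert len(clusters) == 2

    def test_representative_is_longest_member(self):
        seqs = [prot("short", "MKVLIPGATREWQNDF"), prot("long", "MKVLIPGATREWQNDFAA")]
        (c,) = ps.greedy_cluster(seqs, threshold=0.9)
        assert c.representative_id == "long"

    def test_planted_duplicates_cocluster(self, pet_family):
        _, _, members, _ = pet_family
        rng = np.random.default_rng(17)
        seqs = list(members)
        dup_of = {}
        for m in members[:5]:
            letters = list(m.seq)
            for p in rng.choice(len(letters), size=max(1, len(letters) // 50), replace=False):
                letters[p] = "A"
            did = m.id + "_dup"
            seqs.append(prot(did, "".join(letters)))
            dup_of[did] = m.id
        clusters = ps.greedy_cluster(seqs, threshold=0.95)
        membership = {mid: c.representative_id for c in clusters for mid in c.member_ids}
        for did, src in dup_of.items():
            assert membership[did] == membership[src]

    def test_clustering_is_a_partition(self, pet_family):
        _, _, members, _ = pet_family
        clusters = ps.greedy_cluster(members, threshold=0.95)
        all_ids = [m for c in clusters for m in c.member_ids]
        assert sorted(all_ids) == sorted(m.id for m in members)

    def test_bad_threshold_errors(self):
        with pytest.raises(ValueError):
            ps.greedy_cluster([prot("a", "MKV")], threshold=1.5)


class TestPairwiseSearch:
    def test_self_hit_ranks_first(self):
        targets = [prot("t1", "MWWWHHHCCCYYYNNNQQ"), prot("t2", "MKVLIPGATREWQNDFAA")]
        hits = ps.pairwise_search(prot("t2", "MKVLIPGATREWQNDFAA"), targets, "PLA")
        assert hits[0].bitscore == max(h.bitscore for h in hits)
        assert hits[0].tool == TOOL_PAIRWISE and hits[0].bias == 0.0

    def test_doubling_target_length_doubles_evalue(self):
        t1 = [prot("t1", "MWWWHHHCCCYYYNNN")]
        t2 = t1 + [prot("t2", "MWWWHHHCCCYYYNNN")]
        (h1,) = ps.pairwise_search("MKVLIPGATREWQNDF", t1, "PLA")
        h2 = ps.pairwise_search("MKVLIPGATREWQNDF", t2, "PLA")[0]
        assert h2.evalue == pytest.approx(2 * h1.evalue, rel=1e-9)

    def test_empty_inputs_error(self):
        with pytest.raises(ValueError):
            ps.pairwise_search("MKV", [], "PLA")


class TestFilterHits:
    def hit(self, e, s, b, tool=TOOL_HMM):
        return HomologyHit(protein_id="p", polymer="PET", tool=tool, bitscore=s, evalue=e, bias=b)

    def test_bias_rule_keeps_and_removes(self):
        kept = ps.filter_hits([self.hit(1e-6, 30, 2)])
        assert len(kept) == 1
        assert ps.filter_hits([self.hit(1e-6, 30, 4)]) == []

    def test_bias_rule_scoped_to_hmm_tool(self):
        assert len(ps.filter_hits([self.hit(1e-6, 30, 4, tool=TOOL_PAIRWISE)])) == 1

    def test_exhaustive_boundary_grid(self):
        """All three rules on a grid that includes every equality case."""
        for e in (1e-6, 1e-5, 1e-4):
            for s in (19.0, 20.0, 21.0, 30.0):
                for frac in (0.09, 0.10, 0.11):
                    b = frac * s
                    for tool in (TOOL_HMM, TOOL_PAIRWISE):
                        kept = ps.filter_hits([self.hit(e, s, b, tool)])
                        expected = e < 1e-5 and s > 20.0
                        if tool == TOOL_HMM:
                            expected = expected and b < 0.10 * s
                        assert bool(kept) == expected, (e, s, frac, tool)

    def test_idempotent_and_order_preserving(self):
        hits = [self.hit(1e-7, 40, 1), self.hit(1e-8, 25, 0.5), self.hit(1e-6, 30, 2)]
        once = ps.filter_hits(hits)
        assert ps.filter_hits(once) == once
        assert [h.bitscore for h in once] == [40, 25, 30]
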