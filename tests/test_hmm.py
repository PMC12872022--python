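import numpy as np
import pytest
from scipy import stats

import plastiscreen as ps
from plastiscreen.seqio import STANDARD_AA

from conftest import enumerate_paths, random_profile

IX = {a: i for i, a in enumerate(STANDARD_AA)}


def zero_entropy_profile(consensus="MKV"):
    L = len(consensus)
    em = np.zeros((L, 20))
    for k, a in enumerate(consensus):
        em[k, IX[a]] = 1.0
    return ps.ProfileHMM(
        polymer="zero",
        match_emissions=em,
        insert_emissions=np.full((L, 20), 1 / 20),
        t_mm=np.ones(L), t_mi=np.zeros(L), t_md=np.zeros(L),
        t_im=np.ones(L), t_ii=np.zeros(L),
        t_dm=np.ones(L), t_dd=np.zeros(L),
        null_background=np.full(20, 1 / 20),
    )


class TestBuildProfile:
    def test_degenerate_identical_sequences(self):
        prof = ps.build_profile(["MKV", "MKV", "MKV"], "X", pseudocount_weight=1e-9)
        assert prof.L == 3
        for k, a in enumerate("MKV"):
            assert prof.match_emissions[k, IX[a]] == pytest.approx(1.0, abs=1e-6)

    def test_majority_gap_column_is_not_match(self):
        prof = ps.build_profile(["MKV", "M-V", "M-V"], "X")
        assert prof.L == 2  # middle column is gap in 2/3 sequences

    def test_emissions_match_counting_oracle(self):
        rng = np.random.default_rng(3)
        aas = list(STANDARD_AA)
        msa = ["".join(rng.choice(aas, size=15)) for _ in range(20)]
        w = 0.7
        prof = ps.build_profile(msa, "X", pseudocount_weight=w)
        residues = "".join(msa)
        counts_bg = np.zeros(20)
        for c in residues:
            counts_bg[IX[c]] += 1
        bg = counts_bg / counts_bg.sum()
        for k in range(15):
            col = np.zeros(20)
            for row in msa:
                col[IX[row[k]]] += 1
            expected = (col + w * bg) / (col + w * bg).sum()
            np.testing.assert_allclose(prof.match_emissions[k], expected, rtol=1e-12)

    def test_ragged_alignment_errors(self):
        with pytest.raises(ValueError, match="ragged"):
            ps.build_profile(["MKV", "MK"], "X")

    def test_all_gap_columns_error(self):
        with pytest.raises(ValueError):
            ps.build_profile(["---", "---"], "X")

    def test_small_seed_set_uniform_background(self):
        prof = ps.build_profile(["MKV", "MKV"], "X")
        np.testing.assert_allclose(prof.null_background, 1 / 20)


class TestScoring:
    def test_global_consensus_closed_form(self):
        prof = zero_entropy_profile("MKV")
        score = ps.forward_bitscore(prof, "MKV", mode="global")
        assert score == pytest.approx(3 * np.log2(20), rel=1e-12)

    def test_forward_at_least_viterbi(self, pet_profile):
        rng = np.random.default_rng(0)
        aas = list(STANDARD_AA)
        for _ in range(10):
            seq = "".join(rng.choice(aas, size=rng.integers(30, 120)))
            fwd = ps.forward_bitscore(pet_profile, seq)
            vit, _, _ = ps.viterbi_align(pet_profile, seq)
            assert fwd >= vit - 1e-9

    def test_forward_matches_enumeration_on_tiny_instances(self):
        for seed in range(6):
            L = 2 + seed % 3
            prof = random_profile(L, seed)
            rng = np.random.default_rng(100 + seed)
            seq = "".join(rng.choice(list(STANDARD_AA), size=L + 1))
            weights = enumerate_paths(prof, seq)
            expected = np.log2(sum(weights))
            assert ps.forward_bitscore(prof, seq) == pytest.approx(expected, rel=1e-9)

    def test_viterbi_matches_enumeration_max(self):
        for seed in range(6):
            prof = random_profile(3, seed)
            rng = np.random.default_rng(200 + seed)
            seq = "".join(rng.choice(list(STANDARD_AA), size=4))
            weights = enumerate_paths(prof, seq)
            vit, _, _ = ps.viterbi_align(prof, seq)
            assert vit == pytest.approx(np.log2(max(weights)), rel=1e-9)

    def test_global_matches_enumeration(self):
        for seed in range(4):
            prof = random_profile(3, seed)
            rng = np.random.default_rng(300 + seed)
            seq = "".join(rng.choice(list(STANDARD_AA), size=4))
            weights = enumerate_paths(prof, seq, mode="global")
            expected = np.log2(sum(weights))
            got = ps.forward_bitscore(prof, seq, mode="global")
            assert got == pytest.approx(expected, rel=1e-9)

    def test_viterbi_consensus_envelope_covers_sequence(self):
        prof = zero_entropy_profile("MKVW")
        score, env, path = ps.viterbi_align(prof, "MKVW")
        assert env == (1, 4)
        assert path == [("M", 1), ("M", 2), ("M", 3), ("M", 4)]

    def test_nonstandard_residue_rejected(self, pet_profile):
        with pytest.raises(ValueError, match="position"):
            ps.forward_bitscore(pet_profile, "MKXV")


class TestCalibration:
    def test_gumbel_fit_recovers_known_parameters(self):
        rng = np.random.default_rng(13)
        draws = stats.gumbel_r.rvs(loc=5.0, scale=1 / 0.7, size=5000, random_state=rng)
        mu, lam = ps.fit_gumbel(draws)
        assert mu == pytest.approx(5.0, rel=0.05)
        assert lam == pytest.approx(0.7, rel=0.05)

    def test_location_equivariance(self):
        rng = np.random.default_rng(2)
        scores = rng.gumbel(3.0, 1.5, size=2000)
        mu1, lam1 = ps.fit_gumbel(scores)
        mu2, lam2 = ps.fit_gumbel(scores + 4.0)
        assert mu2 == pytest.approx(mu1 + 4.0, rel=1e-6)
        assert lam2 == pytest.approx(lam1, rel=1e-6)

    def test_calibration_deterministic(self, pet_profile):
        c1 = ps.calibrate_evalues(pet_profile, 100, 80, seed=5)
        c2 = ps.calibrate_evalues(pet_profile, 100, 80, seed=5)
        assert (c1.mu, c1.lam) == (c2.mu, c2.lam)

    def test_degenerate_scores_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            ps.fit_gumbel(np.full(200, 3.0))


class TestEvalue:
    CAL = ps.CalibrationParams(mu=5.0, lam=0.7, n_calibration=1000, seed=0)

    def test_closed_form_at_mu(self):
        assert ps.evalue(5.0, self.CAL, 1) == pytest.approx(1 - np.exp(-1), rel=1e-12)

    def test_vanishes_for_large_scores(self):
        assert ps.evalue(1e4, self.CAL, 10**9) == 0.0

    def test_formula_on_grid_and_monotonicity(self):
        grid = np.linspace(-5, 60, 200)
        evals = [ps.evalue(s, self.CAL, 50) for s in grid]
        direct = [50 * -np.expm1(-np.exp(-0.7 * (s - 5.0))) for s in grid]
        np.testing.assert_allclose(evals, direct, rtol=1e-9)
        assert all(a >= b for a, b in zip(evals, evals[1:]))

    def test_db_size_scaling(self):
        e1 = ps.evalue(10.0, self.CAL, 100)
        e2 = ps.evalue(10.0, self.CAL, 700)
        assert e2 == pytest.approx(7 * e1, rel=1e-12)

    def test_uncalibrated_profile_errors(self):
        with pytest.raises(ValueError, match="calibrate"):
            ps.evalue(10.0, None, 100)


class TestBias:
    def test_background_composition_envelope_near_zero(self, pet_profile):
        # sequence drawn from the profile's own null background
        rng = np.random.default_rng(8)
        seq = "".join(
            rng.choice(list(STANDARD_AA), size=200, p=pet_profile.null_background)
        )
        b = ps.bias_score(pet_profile, seq, (1, len(seq)))
        assert b <= 0.6  # add-one smoothing keeps the two nulls slightly apart

    def test_low_complexity_envelope_positive_bias(self, pet_profile):
        # poly-K skews the envelope composition far from the background
        seq = "K" * 120
        b = ps.bias_score(pet_profile, seq, (1, 120))
        assert b > 0

    def test_two_pass_recomputation_equals_reported(self, pet_profile, pet_family):
        _, _, members, _ = pet_family
        seq = members[0].seq
        _, env, _ = ps.viterbi_align(pet_profile, seq)
        b = ps.bias_score(pet_profile, seq, env)
        counts = np.zeros(20)
        for c in seq[env[0] - 1 : env[1]]:
            counts[IX[c]] += 1
        comp = (counts + 1) / (counts.sum() + 20)
        expected = max(
            0.0,
            ps.forward_bitscore(pet_profile, seq)
            - ps.forward_bitscore(pet_profile, seq, null=comp),
        )
        assert b == pytest.approx(expected, rel=1e-12)

    def test_empty_envelope_errors(self, pet_profile):
        with pytest.raises(ValueError):
            ps.bias_score(pet_profile, "MKV", (2, 1))


def test_planted_family_separation(pet_profile, pet_family):
    """True members score >= 20 bits; shuffled copies score lower."""
    _, _, members, _ = pet_family
    rng = np.random.default_rng(97)
    wins = 0
    for m in members:
        s_true = ps.forward_bitscore(pet_profile, m.seq)
        assert s_true >= 20.0
        letters = list(m.seq)
        rng.shuffle(letters)
        if ps.forward_bitscore(pet_profile, "".join(letters)) < s_true:
            wins += 1
    assert wins >= 0.95 * len(members)


def test_profile_serialization_round_trip(tmp_path, pet_profile):
    p = tmp_path / "pet.profile.txt"
    ps.save_profile(pet_profile, p)
    back = ps.load_profile(p)
    assert back.polymer == "PET" and back.L == pet_profile.L
    np.testing.assert_allclose(back.match_emissions, pet_profile.match_emissions, rtol=1e-9)
    assert back.calibration.mu == pytest.approx(pet_profile.calibration.mu)
    seq = "MKVLIPGATREW" * 5
    assert ps.forward_bitscore(back, seq) == pytest.approx(
        ps.forward_bitscore(pet_profile, seq), rel=1e-9
    )
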