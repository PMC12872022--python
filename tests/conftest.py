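"""Shared fixtures: synthetic families, calibrated profiles, planted metagenomes.

Everything is generated at test time from fixed seeds; nothing is read from
disk except files the tests themselves write into tmp dirs.
"""

from __future__ import annotations

import numpy as np
import pytest

import plastiscreen as ps


@pytest.fixture(scope="session")
def pet_family():
    spec = ps.FamilySpec(polymer="PET", n_members=10, identity_band=(0.7, 0.9), seed=41)
    consensus, members, msa = ps.generate_family(spec)
    return spec, consensus, members, msa


@pytest.fixture(scope="session")
def pet_profile(pet_family):
    _, _, _, msa = pet_family
    profile = ps.build_profile(msa, "PET")
    profile.calibration = ps.calibrate_evalues(profile, n_random=200, len_distribution=150, seed=7)
    return profile


@pytest.fixture(scope="session")
def phb_family():
    spec = ps.FamilySpec(polymer="PHB", n_members=10, identity_band=(0.7, 0.9), seed=43)
    consensus, members, msa = ps.generate_family(spec)
    return spec, consensus, members, msa


@pytest.fixture(scope="session")
def phb_profile(phb_family):
    _, _, _, msa = phb_family
    profile = ps.build_profile(msa, "PHB")
    profile.calibration = ps.calibrate_evalues(profile, n_random=200, len_distribution=150, seed=7)
    return profile


def random_profile(L: int, seed: int) -> ps.ProfileHMM:
    """A small random but valid profile for oracle-equivalence tests."""
    rng = np.random.default_rng(seed)

    def dirichlet_rows(shape):
        return rng.dirichlet(np.ones(shape[1]), size=shape[0])

    match_em = dirichlet_rows((L, 20))
    ins_em = dirichlet_rows((L, 20))
    m3 = rng.dirichlet(np.ones(3), size=L)
    i2 = rng.dirichlet(np.ones(2), size=L)
    d2 = rng.dirichlet(np.ones(2), size=L)
    m3[-1] = [1.0, 0.0, 0.0]
    i2[-1] = [1.0, 0.0]
    d2[-1] = [1.0, 0.0]
    return ps.ProfileHMM(
        polymer="test",
        match_emissions=match_em,
        insert_emissions=ins_em,
        t_mm=m3[:, 0], t_mi=m3[:, 1], t_md=m3[:, 2],
        t_im=i2[:, 0], t_ii=i2[:, 1],
        t_dm=d2[:, 0], t_dd=d2[:, 1],
        null_background=rng.dirichlet(np.ones(20)),
    )


def enumerate_paths(profile: ps.ProfileHMM, seq: str, mode: str = "local"):
    """Brute-force enumeration of every state path's probability odds weight.

    Independent of the dynamic programming: walks the state graph explicitly
    and returns the list of path weights (odds vs the null model).
    """
    from plastiscreen.seqio import STANDARD_AA

    ix = {a: i for i, a in enumerate(STANDARD_AA)}
    x = [ix[c] for c in seq]
    L, n = profile.L, len(x)
    bg = profile.null_background
    em = profile.match_emissions / bg
    ins = profile.insert_emissions / bg
    entry, ex = profile.entry, profile.exit
    stay = 1.0 - ex
    local = mode == "local"
    weights: list[float] = []

    def extend(state, k, i, w):
        if w == 0.0:
            return
        if state == "M":
            if local:
                weights.append(w * ex[k])
            elif k == L - 1 and i == n - 1:
                weights.append(w)
            s = stay[k] if local else 1.0
            if k + 1 < L and i + 1 < n:
                extend("M", k + 1, i + 1, w * s * profile.t_mm[k] * em[k + 1][x[i + 1]])
            if k < L - 1 and i + 1 < n:
                extend("I", k, i + 1, w * s * profile.t_mi[k] * ins[k][x[i + 1]])
            if k + 1 < L:
                extend("D", k + 1, i, w * s * profile.t_md[k])
        elif state == "I":
            if k + 1 < L and i + 1 < n:
                extend("M", k + 1, i + 1, w * profile.t_im[k] * em[k + 1][x[i + 1]])
            if i + 1 < n:
                extend("I", k, i + 1, w * profile.t_ii[k] * ins[k][x[i + 1]])
        else:  # D
            if not local and k == L - 1 and i == n - 1:
                weights.append(w)
            if k + 1 < L and i + 1 < n:
                extend("M", k + 1, i + 1, w * profile.t_dm[k] * em[k + 1][x[i + 1]])
            if k + 1 < L:
                extend("D", k + 1, i, w * profile.t_dd[k])

    if local:
        for i in range(n):
            for k in range(L):
                extend("M", k, i, entry[k] * em[k][x[i]])
    else:
        extend("M", 0, 0, em[0][x[0]])
    return weights
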