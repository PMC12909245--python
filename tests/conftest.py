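import itertools
import math

import numpy as np
import pytest

from nlrkit.profile_hmm import ProfileHMM


AB4 = "ACGT"


def make_random_profile(L: int, alphabet: str, rng: np.random.Generator) -> ProfileHMM:
    """A random valid profile over an arbitrary alphabet (test helper)."""
    K = len(alphabet)
    em = rng.dirichlet(np.ones(K), size=L)
    bg = np.full(K, 1.0 / K)
    tm = rng.dirichlet(np.ones(3), size=L - 1)
    ti = rng.dirichlet(np.ones(2), size=L - 1)
    td = rng.dirichlet(np.ones(2), size=L - 1)
    prof = ProfileHMM(
        name=f"rand_L{L}",
        alphabet=alphabet,
        match_emissions=em,
        insert_emissions=bg.copy(),
        background=bg,
        t_mm=tm[:, 0],
        t_mi=tm[:, 1],
        t_md=tm[:, 2],
        t_im=ti[:, 0],
        t_ii=ti[:, 1],
        t_dm=td[:, 0],
        t_dd=td[:, 1],
        entry=np.full(L, 1.0 / L),
        exit_=1.0 / (L - np.arange(L, dtype=float)),
    )
    prof.validate()
    return prof


def brute_force_local_scores(prof: ProfileHMM, seq: str) -> tuple[float, float]:
    """Independent oracle: enumerate every local path explicitly.

    Returns (max path score, log2-sum over all paths) in bits.  Coded
    directly from the state diagram, independently of the DP recurrences.
    """
    L, n = prof.L, len(seq)
    idx = {c: i for i, c in enumerate(prof.alphabet)}
    x = [idx[c] for c in seq]
    lg = math.log2
    keep = 1.0 - prof.exit_
    scores: list[float] = []

    def em_m(k, i):
        return lg(prof.match_emissions[k, x[i]] / prof.background[x[i]])

    def em_i(i):
        return lg(prof.insert_emissions[x[i]] / prof.background[x[i]])

    def rec(state, k, i, score):
        if state == "M":
            scores.append(score + lg(prof.exit_[k]))
            if k < L - 1:
                cont = score + lg(keep[k])
                if i < n:
                    rec("M", k + 1, i + 1, cont + lg(prof.t_mm[k]) + em_m(k + 1, i))
                    rec("I", k, i + 1, cont + lg(prof.t_mi[k]) + em_i(i))
                rec("D", k + 1, i, cont + lg(prof.t_md[k]))
        elif state == "I":
            if i < n:
                rec("I", k, i + 1, score + lg(prof.t_ii[k]) + em_i(i))
                rec("M", k + 1, i + 1, score + lg(prof.t_im[k]) + em_m(k + 1, i))
        else:  # D
            if k < L - 1:
                if i < n:
                    rec("M", k + 1, i + 1, score + lg(prof.t_dm[k]) + em_m(k + 1, i))
                rec("D", k + 1, i, score + lg(prof.t_dd[k]))

    for start in range(n):
        for k in range(L):
            rec("M", k, start + 1, lg(prof.entry[k]) + em_m(k, start))
    if not scores:
        return -math.inf, -math.inf
    m = max(scores)
    return m, m + lg(sum(2.0 ** (s - m) for s in scores))


def all_sequences(alphabet: str, max_len: int):
    for n in range(1, max_len + 1):
        for tup in itertools.product(alphabet, repeat=n):
            yield "".join(tup)


@pytest.fixture(scope="session")
def small_library():
    """Compact calibrated domain library shared across tests."""
    from nlrkit.profile_hmm import calibrate_null
    from nlrkit.synthetic_data import default_domain_library

    lib = default_domain_library(
        seed=0, domains=["NACHT", "CARD", "DEATH", "LRR", "WD40"]
    )
    for name, prof in lib.profiles.items():
        calibrate_null(prof, (150, 450), n_shuffles=300, seed=100, alpha=1e-3)
    return lib
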