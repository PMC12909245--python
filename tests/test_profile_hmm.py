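import math

import numpy as np
import pytest

from nlrkit.io_formats import AMINO_ACIDS, ProteinRecord
from nlrkit.profile_hmm import (
    GumbelNull,
    MultipleAlignment,
    ProfileHMM,
    build_profile,
    calibrate_null,
    extract_domain_region,
    forward_local,
    random_background_sequence,
    scan_proteome,
    select_conserved_block,
    viterbi_local,
)
from nlrkit.synthetic_data import make_domain_msa

from conftest import AB4, all_sequences, brute_force_local_scores, make_random_profile


def random_msa(rng, n_rows=6, n_cols=20, gap_prob=0.2):
    rows = []
    for _ in range(n_rows):
        rows.append(
            "".join(
                "-" if rng.random() < gap_prob else rng.choice(list(AMINO_ACIDS))
                for _ in range(n_cols)
            )
        )
    return MultipleAlignment(tuple(f"r{i}" for i in range(n_rows)), tuple(rows))


class TestBuildProfile:
    def test_identical_ungapped_rows_give_peaked_match_states(self):
        msa = MultipleAlignment(("a", "b", "c", "d"), ("MKVLC",) * 4)
        prof = build_profile(msa)
        assert prof.L == 5
        assert prof.consensus() == "MKVLC"
        for k, res in enumerate("MKVLC"):
            assert prof.alphabet[np.argmax(prof.match_emissions[k])] == res

    def test_gappy_column_excluded_by_threshold(self):
        msa = MultipleAlignment(
            ("a", "b", "c", "d"), ("MK-VL", "MK-VL", "MK-VL", "MKAVL")
        )
        prof = build_profile(msa, gap_fraction_threshold=0.5)
        assert prof.L == 4  # the 3/4-gapped column is not a match state

    def test_too_few_match_states_raises(self):
        msa = MultipleAlignment(("a", "b"), ("M---", "M---"))
        with pytest.raises(ValueError, match="match state"):
            build_profile(msa)

    def test_distributions_normalized_on_random_alignments(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            msa = random_msa(rng, n_rows=int(rng.integers(2, 8)))
            try:
                prof = build_profile(msa)
            except ValueError:
                continue  # too gappy to yield 2 match states
            prof.validate(atol=1e-9)  # checks every distribution sums to 1

    def test_json_round_trip(self, tmp_path):
        msa = make_domain_msa("D", 20, seed=3)
        prof = build_profile(msa, name="D")
        calibrate_null(prof, 100, n_shuffles=100, seed=1)
        prof.to_json(tmp_path / "d.json")
        back = ProfileHMM.from_json(tmp_path / "d.json")
        np.testing.assert_allclose(back.match_emissions, prof.match_emissions)
        assert back.null.threshold_bits == pytest.approx(prof.null.threshold_bits)


class TestSelectConservedBlock:
    def test_ungapped_alignment_returned_unchanged(self):
        msa = MultipleAlignment(("a", "b"), ("MKVLITAGPTRE", "MKVLITAGPTRE"))
        out = select_conserved_block(msa, min_occupancy=0.5, min_run=5)
        assert out.rows == msa.rows

    def test_gappy_flank_removed(self):
        msa = MultipleAlignment(("a", "b"), ("--MKVLITAG", "--MKVLITAG"))
        out = select_conserved_block(msa, min_occupancy=0.5, min_run=5)
        assert out.rows == ("MKVLITAG", "MKVLITAG")

    def test_no_qualifying_run_raises(self):
        msa = MultipleAlignment(("a", "b"), ("M-M-M-", "-M-M-M"))
        with pytest.raises(ValueError, match="lower"):
            select_conserved_block(msa, min_occupancy=0.9, min_run=3)

    def test_matches_exhaustive_window_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            msa = random_msa(rng, n_rows=4, n_cols=int(rng.integers(5, 40)), gap_prob=0.4)
            occ = [msa.occupancy(j) >= 0.5 for j in range(msa.length)]
            # oracle: best contiguous window where all columns qualify
            best = (0, 0)
            for i in range(msa.length):
                for j in range(i + 1, msa.length + 1):
                    if all(occ[i:j]) and (j - i) > (best[1] - best[0]):
                        best = (i, j)
            if best[1] - best[0] < 3:
                with pytest.raises(ValueError):
                    select_conserved_block(msa, 0.5, 3)
            else:
                out = select_conserved_block(msa, 0.5, 3)
                assert out.rows == msa.slice_columns(*best).rows


class TestViterbi:
    def test_consensus_aligns_full_length_all_match(self):
        msa = make_domain_msa("D", 30, seed=2)
        prof = build_profile(msa)
        cons = prof.consensus()
        hit = viterbi_local(prof, cons)
        assert (hit.ali_start, hit.ali_end) == (1, len(cons))
        assert all(s == "M" for s, _ in hit.path)

    def test_matches_brute_force_path_enumeration(self):
        rng = np.random.default_rng(17)
        for L in (2, 3, 4):
            prof = make_random_profile(L, AB4, rng)
            for seq in all_sequences(AB4, 4):
                expect, _ = brute_force_local_scores(prof, seq)
                got = viterbi_local(prof, seq).bitscore
                assert got == pytest.approx(expect, rel=1e-9, abs=1e-9)

    def test_background_flanks_leave_optimum_unchanged(self):
        rng = np.random.default_rng(23)
        msa = make_domain_msa("D", 25, seed=9)
        prof = build_profile(msa)
        core = prof.consensus()
        base = viterbi_local(prof, core)
        for _ in range(10):
            left = random_background_sequence(int(rng.integers(5, 40)), rng)
            right = random_background_sequence(int(rng.integers(5, 40)), rng)
            padded = viterbi_local(prof, left + core + right)
            assert padded.bitscore == pytest.approx(base.bitscore, abs=1e-9)
            assert padded.ali_start == len(left) + 1
            assert padded.ali_end == len(left) + len(core)

    def test_x_residues_score_at_background(self):
        msa = make_domain_msa("D", 20, seed=4)
        prof = build_profile(msa)
        cons = prof.consensus()
        with_x = "X" * 5 + cons + "X" * 5
        assert viterbi_local(prof, with_x).bitscore == pytest.approx(
            viterbi_local(prof, cons).bitscore, abs=1e-9
        )


def degenerate_single_path_profile(word: str, alphabet: str = AB4) -> ProfileHMM:
    """0/1 profile admitting exactly one non-zero-probability path."""
    L, K = len(word), len(alphabet)
    em = np.zeros((L, K))
    for k, c in enumerate(word):
        em[k, alphabet.index(c)] = 1.0
    bg = np.full(K, 1.0 / K)
    one = np.ones(L - 1)
    zero = np.zeros(L - 1)
    entry = np.zeros(L)
    entry[0] = 1.0
    exit_ = np.zeros(L)
    exit_[-1] = 1.0
    return ProfileHMM(
        "degen", alphabet, em, bg.copy(), bg,
        t_mm=one, t_mi=zero, t_md=zero,
        t_im=one, t_ii=zero, t_dm=one, t_dd=zero,
        entry=entry, exit_=exit_,
    )


class TestForward:
    def test_single_path_profile_forward_equals_viterbi(self):
        prof = degenerate_single_path_profile("ACGT")
        v = viterbi_local(prof, "ACGT").bitscore
        f = forward_local(prof, "ACGT")
        assert f == pytest.approx(v, abs=1e-9)

    def test_matches_brute_force_log_sum(self):
        rng = np.random.default_rng(29)
        prof = make_random_profile(3, AB4, rng)
        for seq in all_sequences(AB4, 4):
            _, expect = brute_force_local_scores(prof, seq)
            assert forward_local(prof, seq) == pytest.approx(expect, rel=1e-9, abs=1e-9)

    def test_forward_dominates_viterbi_on_random_inputs(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            L = int(rng.integers(2, 6))
            prof = make_random_profile(L, AB4, rng)
            seq = "".join(rng.choice(list(AB4), size=int(rng.integers(1, 15))))
            assert forward_local(prof, seq) >= viterbi_local(prof, seq).bitscore - 1e-12


class TestCalibration:
    def test_alpha_one_threshold_below_all_null_scores(self):
        msa = make_domain_msa("D", 15, seed=6)
        prof = build_profile(msa)
        calibrate_null(prof, 50, n_shuffles=100, seed=2, alpha=1e-3)
        assert prof.null.threshold_for(1.0) == -math.inf

    def test_threshold_monotone_in_alpha(self):
        msa = make_domain_msa("D", 15, seed=6)
        prof = build_profile(msa)
        calibrate_null(prof, 50, n_shuffles=150, seed=2)
        alphas = [0.5, 0.1, 1e-2, 1e-3, 1e-4]
        thrs = [prof.null.threshold_for(a) for a in alphas]
        assert thrs == sorted(thrs)

    def test_planted_consensus_scores_above_threshold(self):
        # profile from a 10-row, 30-column synthetic seed alignment
        msa = make_domain_msa("D", 30, n_rows=10, seed=42)
        prof = build_profile(msa)
        thr = calibrate_null(prof, (100, 300), n_shuffles=500, seed=42, alpha=1e-3)
        rng = np.random.default_rng(42)
        above = 0
        trials = 100
        for _ in range(trials):
            flankl = random_background_sequence(int(rng.integers(20, 120)), rng)
            flankr = random_background_sequence(int(rng.integers(20, 120)), rng)
            seq = flankl + prof.consensus() + flankr
            if viterbi_local(prof, seq).bitscore > thr:
                above += 1
        assert above >= 0.99 * trials

    def test_degenerate_variance_falls_back_with_warning(self):
        # emissions equal to background: every decoy scores identically
        K = len(AMINO_ACIDS)
        bg = np.full(K, 1.0 / K)
        L = 4
        prof = ProfileHMM(
            "flat", AMINO_ACIDS, np.tile(bg, (L, 1)), bg.copy(), bg,
            t_mm=np.full(L - 1, 0.98), t_mi=np.full(L - 1, 0.01), t_md=np.full(L - 1, 0.01),
            t_im=np.full(L - 1, 0.9), t_ii=np.full(L - 1, 0.1),
            t_dm=np.full(L - 1, 0.9), t_dd=np.full(L - 1, 0.1),
            entry=np.full(L, 1.0 / L), exit_=1.0 / (L - np.arange(L, dtype=float)),
        )
        with pytest.warns(UserWarning, match="degenerate"):
            thr = calibrate_null(prof, 30, n_shuffles=100, seed=1)
        assert thr > prof.null.location

    def test_significance_decreases_with_score(self):
        null = GumbelNull(location=10.0, scale=2.0, alpha=1e-3, threshold_bits=0.0)
        sigs = [null.significance(s) for s in (5.0, 10.0, 20.0, 40.0)]
        assert sigs == sorted(sigs, reverse=True)
        assert 0.0 <= sigs[-1] < sigs[0] <= 1.0


class TestScan:
    def test_two_planted_copies_give_two_disjoint_hits(self, small_library):
        prof = small_library.profile("NACHT")
        cons = prof.consensus()
        rng = np.random.default_rng(8)
        linker = random_background_sequence(40, rng)
        seq = linker + cons + linker + cons + linker
        protein = ProteinRecord(id="p1", sequence=seq)
        hits = scan_proteome([prof], [protein])
        assert len(hits) == 2
        (h1, h2) = sorted(hits, key=lambda h: h.ali_start)
        assert h1.ali_end < h2.ali_start
        # spans line up with the planted copies
        assert abs(h1.ali_start - (len(linker) + 1)) <= 2
        assert abs(h2.ali_start - (2 * len(linker) + len(cons) + 1)) <= 2

    def test_empty_proteome_empty_table(self, small_library):
        assert scan_proteome([small_library.profile("NACHT")], []) == []

    def test_permutation_equivariance(self, small_library):
        rng = np.random.default_rng(9)
        prof = small_library.profile("LRR")
        prots = [
            ProteinRecord(id=f"p{i}", sequence=random_background_sequence(120, rng))
            for i in range(6)
        ]
        prots[2] = ProteinRecord(id="p2", sequence=prots[2].sequence + prof.consensus())
        fwd = scan_proteome([prof], prots)
        rev = scan_proteome([prof], prots[::-1])
        key = lambda h: (h.protein_id, h.model, h.ali_start, h.ali_end, h.bitscore)
        assert sorted(fwd, key=key) == sorted(rev, key=key)

    def test_uncalibrated_profile_rejected(self):
        msa = make_domain_msa("D", 15, seed=1)
        prof = build_profile(msa)
        with pytest.raises(ValueError, match="calibrat"):
            scan_proteome([prof], [ProteinRecord(id="p", sequence="MKVLIT")])


class TestExtractRegion:
    def test_flank_zero_exact_span_and_clipping(self):
        from nlrkit.io_formats import DomainHit

        protein = ProteinRecord(id="p", sequence="ACDEFGHIKLMNPQRSTVWY")
        hit = DomainHit("p", "D", 5, 9, 10.0)
        assert extract_domain_region(protein, hit, flank=0) == "FGHIK"
        assert extract_domain_region(protein, hit, flank=100) == protein.sequence

    def test_length_matches_span_plus_actual_flanks(self):
        from nlrkit.io_formats import DomainHit

        rng = np.random.default_rng(13)
        protein = ProteinRecord(id="p", sequence=random_background_sequence(80, rng))
        for _ in range(50):
            s = int(rng.integers(1, 70))
            e = s + int(rng.integers(0, 80 - s))
            flank = int(rng.integers(0, 30))
            hit = DomainHit("p", "D", s, e, 1.0)
            region = extract_domain_region(protein, hit, flank)
            left = s - max(1, s - flank)
            right = min(80, e + flank) - e
            assert len(region) == (e - s + 1) + left + right
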