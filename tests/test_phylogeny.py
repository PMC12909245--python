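import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from nlrkit.phylogeny import (
    align_domains,
    bipartitions,
    bootstrap_support,
    canonical_order,
    distance_matrix,
    grouping_statistic,
    neighbor_joining,
    tree_from_newick,
    tree_to_newick,
    write_phylip,
)
from nlrkit.profile_hmm import MultipleAlignment
from nlrkit.synthetic_data import (
    evolve_alignment,
    random_additive_tree,
    species_duplication_scenario,
    tree_distances,
)
from nlrkit.io_formats import AMINO_ACIDS


def sp_score(msa: MultipleAlignment) -> float:
    """Sum-of-pairs BLOSUM62 score of an alignment (test metric)."""
    from Bio.Align import substitution_matrices

    B = substitution_matrices.load("BLOSUM62")
    total = 0.0
    for r1, r2 in itertools.combinations(msa.rows, 2):
        for a, b in zip(r1, r2):
            if a != "-" and b != "-":
                total += B[a][b]
            elif a != b:  # residue vs gap
                total -= 4.0
    return total


class TestAlignDomains:
    def test_identical_pair_gapless(self):
        out = align_domains({"a": "MKVLITAGPT", "b": "MKVLITAGPT"})
        assert out.rows == ("MKVLITAGPT", "MKVLITAGPT")

    def test_identical_rows_stay_identical(self):
        out = align_domains({"a": "MKVLITAGPTREPLD", "b": "MKVLITAGPTREPLD",
                             "c": "MKVITAGPTRPLD"})
        assert out.rows[0] == out.rows[1]

    def test_guide_tree_beats_naive_left_to_right_merge(self):
        # triples where merge order matters: a and c are close relatives,
        # b is divergent, and the input order a, b, c makes the naive
        # left-to-right merge pair the distant sequences first
        from nlrkit.phylogeny import _merge_profiles

        rng = np.random.default_rng(97)
        guided_total = naive_total = 0.0
        for _ in range(10):
            base = "".join(rng.choice(list(AMINO_ACIDS), size=50))
            close = "".join(c for c in base if rng.random() > 0.05)
            far = "".join(
                rng.choice(list(AMINO_ACIDS)) if rng.random() < 0.5 else c
                for c in base
                if rng.random() > 0.2
            )
            triple = {"a": base, "b": far, "c": close}
            guided = align_domains(triple)
            ra, rb = _merge_profiles([triple["a"]], [triple["b"]])
            rab, rc = _merge_profiles(ra + rb, [triple["c"]])
            naive = MultipleAlignment(("a", "b", "c"), tuple(rab + rc))
            assert sp_score(guided) >= sp_score(naive)
            guided_total += sp_score(guided)
            naive_total += sp_score(naive)
        assert guided_total >= naive_total

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_domains({"a": "MKV"})


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        msa = MultipleAlignment(("a", "b"), ("MKVLITAGPT", "MKVLITAGPT"))
        assert distance_matrix(msa, "p")["a", "b"] == 0.0

    def test_p_distance_direct_count(self):
        msa = MultipleAlignment(("a", "b"), ("MKVLITAGPT", "MKVIITAGPT"))
        assert distance_matrix(msa, "p")["a", "b"] == pytest.approx(0.1)

    def test_poisson_closed_form(self):
        msa = MultipleAlignment(("a", "b"), ("MKVLITAGPT", "MKVIITAGPT"))
        d = distance_matrix(msa, "poisson")["a", "b"]
        assert d == pytest.approx(-np.log(0.9), abs=1e-12)

    def test_gap_only_overlap_rejected(self):
        msa = MultipleAlignment(("a", "b"), ("MK--", "--VL"))
        with pytest.raises(ValueError, match="ungapped"):
            distance_matrix(msa)

    def test_unknown_model_rejected(self):
        msa = MultipleAlignment(("a", "b"), ("MK", "MK"))
        with pytest.raises(ValueError):
            distance_matrix(msa, "jc")


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]), ["a", "b", "c"])
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_four_taxon_additive_recovery_vs_least_squares(self):
        # additive matrix from a known quartet ((a,b),(c,d))
        dm = DistanceMatrix(
            np.array(
                [[0, 5, 9, 10], [5, 0, 10, 11], [9, 10, 0, 7], [10, 11, 7, 0.0]]
            ),
            ["a", "b", "c", "d"],
        )
        tree = neighbor_joining(dm)
        assert bipartitions(tree) == {frozenset({"c", "d"})}
        # oracle: least-squares fit over all 3 unrooted quartet topologies
        best_topo, best_rss = None, np.inf
        for topo in ({"a", "b"}, {"a", "c"}, {"a", "d"}):
            # solve for 5 branch lengths minimizing squared error
            pairs = list(itertools.combinations("abcd", 2))
            A = []
            for x, y in pairs:
                row = [0.0] * 5  # ea, eb, ec, ed, internal
                for leaf, col in zip("abcd", range(4)):
                    if leaf in (x, y):
                        row[col] = 1.0
                same_side = ({x, y} == topo) or ({x, y} == set("abcd") - topo)
                if not same_side:
                    row[4] = 1.0
                A.append(row)
            b = np.array([dm[x, y] for x, y in pairs])
            sol, rss, *_ = np.linalg.lstsq(np.array(A), b, rcond=None)
            resid = float(((np.array(A) @ sol - b) ** 2).sum())
            if resid < best_rss:
                best_rss, best_topo = resid, topo
        sibling_pair = frozenset(set("abcd") - best_topo) if "a" in best_topo else frozenset(best_topo)
        assert bipartitions(tree) == {sibling_pair}

    def test_exact_recovery_from_random_additive_matrices(self):
        for seed in range(20):
            n = 4 + seed % 9  # 4..12 leaves
            true = random_additive_tree(n, seed=seed)
            ids, D = tree_distances(true)
            got = neighbor_joining(DistanceMatrix(D, ids))
            assert bipartitions(got) == bipartitions(true)
            dm_got = got.tip_tip_distances()
            for a, b in itertools.combinations(ids, 2):
                assert dm_got[a, b] == pytest.approx(
                    DistanceMatrix(D, ids)[a, b], abs=1e-9
                )

    def test_agrees_with_independent_nj_implementation(self):
        for seed in (3, 7, 13):
            true = random_additive_tree(9, seed=seed)
            ids, D = tree_distances(true)
            dm = DistanceMatrix(D, ids)
            assert bipartitions(neighbor_joining(dm)) == bipartitions(skbio_nj(dm))

    def test_equidistant_matrix_deterministic(self):
        dm = DistanceMatrix(np.ones((5, 5)) - np.eye(5), list("abcde"))
        t1 = tree_to_newick(canonical_order(neighbor_joining(dm)))
        t2 = tree_to_newick(canonical_order(neighbor_joining(dm)))
        assert t1 == t2

    def test_too_few_taxa_rejected(self):
        dm = DistanceMatrix(np.array([[0, 1], [1, 0.0]]), ["a", "b"])
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    def test_no_negative_branch_lengths(self):
        rng = np.random.default_rng(101)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            M = rng.uniform(0.1, 2.0, size=(n, n))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0.0)
            tree = neighbor_joining(DistanceMatrix(M, [f"t{i}" for i in range(n)]))
            for node in tree.traverse():
                if node.parent is not None:
                    assert node.length >= 0.0


class TestNewick:
    def test_round_trip_byte_stable_after_canonical_order(self):
        tree = random_additive_tree(8, seed=5)
        canonical_order(tree)
        s1 = tree_to_newick(tree)
        back = tree_from_newick(s1)
        canonical_order(back)
        assert tree_to_newick(back) == s1

    def test_phylip_export(self, tmp_path):
        msa = MultipleAlignment(("a", "b"), ("MKVL", "MKVI"))
        p = tmp_path / "x.phy"
        write_phylip(msa, p)
        header, *rows = p.read_text().strip().split("\n")
        assert header.split() == ["2", "4"]
        assert len(rows) == 2


class TestBootstrap:
    def test_constant_alignment_gives_full_support(self):
        # every replicate equals the point estimate, so all supports are 100
        msa = MultipleAlignment(
            ("a", "b", "c", "d", "e"),
            ("MKVL" * 5, "MKVL" * 5, "MKVL" * 5, "MKVL" * 5, "MKVL" * 5),
        )
        tree = bootstrap_support(msa, n_replicates=5, seed=1)
        for node in tree.non_tips():
            if node.parent is not None and node.name:
                assert float(node.name) == 100.0

    def test_supports_within_bounds(self):
        true = random_additive_tree(8, seed=21)
        msa, _ = evolve_alignment(true, n_columns=120, subst_prob=0.08, seed=21)
        tree = bootstrap_support(msa, n_replicates=30, seed=2)
        vals = [float(n.name) for n in tree.non_tips() if n.parent is not None and n.name]
        assert vals and all(0.0 <= v <= 100.0 for v in vals)

    def test_zero_replicates_rejected(self):
        msa = MultipleAlignment(("a", "b", "c"), ("MK", "MK", "MK"))
        with pytest.raises(ValueError):
            bootstrap_support(msa, n_replicates=0)


class TestGroupingStatistic:
    def test_species_sorted_caterpillar_is_one(self):
        nwk = "((((a1:1,a2:1):1,a3:1):5,((b1:1,b2:1):1,b3:1):5):1);"
        tree = tree_from_newick(nwk)
        attrs = {n: n[0] for n in ("a1", "a2", "a3", "b1", "b2", "b3")}
        assert grouping_statistic(tree, attrs) == 1.0

    def test_alternating_equal_branches_conservative_zero(self):
        # star tree: every leaf equidistant; ties include other species
        nwk = "(a1:1,b1:1,a2:1,b2:1);"
        tree = tree_from_newick(nwk)
        attrs = {"a1": "a", "a2": "a", "b1": "b", "b2": "b"}
        assert grouping_statistic(tree, attrs) == 0.0

    def test_missing_attribute_rejected(self):
        tree = tree_from_newick("(a:1,b:1,c:1);")
        with pytest.raises(ValueError, match="missing"):
            grouping_statistic(tree, {"a": "x", "b": "y"})

    def test_matches_brute_force_all_pairs(self):
        for seed in (1, 2, 3):
            true = random_additive_tree(4 + 4 * seed, seed=seed)  # up to 16 leaves
            rng = np.random.default_rng(seed)
            tips = [t.name for t in true.tips()]
            attrs = {t: f"grp{rng.integers(3)}" for t in tips}
            got = grouping_statistic(true, attrs)
            # oracle: explicit parent-walk path lengths
            def path_len(x, y):
                anc_x = {}
                node = x
                d = 0.0
                while node is not None:
                    anc_x[id(node)] = d
                    d += node.length or 0.0
                    node = node.parent
                node, d = y, 0.0
                while id(node) not in anc_x:
                    d += node.length or 0.0
                    node = node.parent
                return d + anc_x[id(node)]

            tip_nodes = {t.name: t for t in true.tips()}
            matched = 0
            for t in tips:
                dists = sorted(
                    (path_len(tip_nodes[t], tip_nodes[o]), o) for o in tips if o != t
                )
                dmin = dists[0][0]
                nearest = [o for d, o in dists if d <= dmin + 1e-12]
                if all(attrs[o] == attrs[t] for o in nearest):
                    matched += 1
            assert got == pytest.approx(matched / len(tips))

    def test_species_beats_category_under_species_duplication(self):
        msa, sp, cat = species_duplication_scenario(seed=9)
        tree = neighbor_joining(distance_matrix(msa, "poisson"))
        assert grouping_statistic(tree, sp) > grouping_statistic(tree, cat)
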