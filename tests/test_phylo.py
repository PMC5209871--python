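import numpy as np
import pytest

from oracles import enumerate_site_likelihood_and_posteriors

from lipevol.io_core import ALPHABET, MultipleAlignment, ProteinRecord, parse_newick
from lipevol.model import build_wag_model
from lipevol.phylo import (
    DistanceMatrix,
    bootstrap_support,
    distance_matrix,
    log_likelihood,
    ml_pairwise_distance,
    neighbor_joining,
    optimize_branch_lengths,
    root_with_outgroup,
    tree_bipartitions,
    unroot,
)
from lipevol.simdata import SimulationConfig, simulate_family, simulate_tree


def random_msa(rng, ids, length):
    letters = np.array(list(ALPHABET))
    return MultipleAlignment(
        [
            ProteinRecord(i, "".join(letters[rng.integers(20, size=length)]))
            for i in ids
        ]
    )


class TestPairwiseDistance:
    def test_identical_sequences_give_zero(self, wag):
        assert ml_pairwise_distance("ARNDCQEG", "ARNDCQEG", wag) < 1e-6

    def test_gap_columns_skipped(self, wag):
        t1 = ml_pairwise_distance("ARND", "ARNC", wag)
        t2 = ml_pairwise_distance("ARND-X", "ARNC-G", wag)
        assert t1 == pytest.approx(t2, abs=1e-9)

    def test_no_comparable_columns_rejected(self, wag):
        with pytest.raises(ValueError):
            ml_pairwise_distance("--A", "XX-", wag)

    def test_beats_dense_grid(self, wag):
        """The returned distance maximizes the likelihood against a
        1000-point grid oracle."""
        rng = np.random.default_rng(3)
        letters = np.array(list(ALPHABET))
        log_pi = np.log(wag.pi)

        def loglik(a, b, t):
            P = wag.transition_matrix(t)
            return sum(
                log_pi[ALPHABET.index(x)]
                + np.log(P[ALPHABET.index(x), ALPHABET.index(y)])
                for x, y in zip(a, b)
            )

        for _ in range(3):
            a = "".join(letters[rng.integers(20, size=60)])
            b = list(a)
            for k in rng.integers(0, 60, size=12):
                b[k] = letters[rng.integers(20)]
            b = "".join(b)
            t_hat = ml_pairwise_distance(a, b, wag)
            best_grid = max(
                loglik(a, b, t) for t in np.linspace(1e-6, 20, 1000)
            )
            assert loglik(a, b, t_hat) >= best_grid - 1e-9

    def test_recovers_simulated_divergence(self):
        """Median estimate within 10% of truth at 1000 sites."""
        for t_true in (0.1, 0.5, 1.0):
            fam_model = build_wag_model("wag_default")
            rng = np.random.default_rng(int(t_true * 100))
            estimates = []
            for _ in range(20):
                P = fam_model.transition_matrix(t_true)
                x = rng.choice(20, size=1000, p=fam_model.pi)
                cum = np.cumsum(P[x], axis=1)
                y = (cum < rng.random((1000, 1))).sum(axis=1)
                a = "".join(ALPHABET[i] for i in x)
                b = "".join(ALPHABET[i] for i in y)
                estimates.append(ml_pairwise_distance(a, b, fam_model))
            assert np.median(estimates) == pytest.approx(t_true, rel=0.10)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float),
        )
        tree = neighbor_joining(dm)
        lengths = {
            leaf.name: leaf.length for leaf in tree.leaves()
        }
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_exact_recovery_of_stated_additive_tree(self):
        # path distances of ((A:1,B:2):1,(C:3,D:4));
        taxa = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(taxa, D))
        bips = tree_bipartitions(tree)
        assert bips == {frozenset({"A", "B"})} or bips == {
            frozenset({"C", "D"})
        }
        dists = tree.leaf_distances()
        for i, a in enumerate(taxa):
            for j in range(i + 1, 4):
                key = tuple(sorted((a, taxa[j])))
                assert dists[key] == pytest.approx(D[i, j], abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_additive_matrices_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        tree = simulate_tree(n, seed=seed + 1000, mean_branch_length=0.5)
        true_d = tree.leaf_distances()
        taxa = sorted(tree.leaf_names())
        D = np.zeros((len(taxa), len(taxa)))
        for i, a in enumerate(taxa):
            for j in range(i + 1, len(taxa)):
                D[i, j] = D[j, i] = true_d[(a, taxa[j])]
        out = neighbor_joining(DistanceMatrix(taxa, D))
        assert tree_bipartitions(out) == tree_bipartitions(unroot(tree))
        got = out.leaf_distances()
        for key, val in true_d.items():
            assert got[key] == pytest.approx(val, abs=1e-9)

    def test_identical_taxa_form_zero_length_cherry(self):
        dm = DistanceMatrix(
            ["a", "b", "c", "d"],
            np.array(
                [[0, 0, 2, 2], [0, 0, 2, 2], [2, 2, 0, 1], [2, 2, 1, 0]],
                dtype=float,
            ),
        )
        tree = neighbor_joining(dm)
        assert frozenset({"a", "b"}) in tree_bipartitions(tree) or frozenset(
            {"c", "d"}
        ) in tree_bipartitions(tree)
        la = tree.find_leaf("a").length
        lb = tree.find_leaf("b").length
        assert la == 0.0 and lb == 0.0

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(
                DistanceMatrix(["a", "b"], np.array([[0.0, 1], [1, 0]]))
            )


class TestLogLikelihood:
    def test_single_site_zero_branches(self, wag):
        msa = MultipleAlignment(
            [ProteinRecord("a", "A"), ProteinRecord("b", "A")]
        )
        tree = parse_newick("(a:0,b:0);")
        assert log_likelihood(tree, msa, wag) == pytest.approx(
            np.log(wag.pi[0]), abs=1e-12
        )

    @pytest.mark.parametrize("n_leaves,n_sites,seed", [
        (3, 2, 0), (4, 3, 1), (4, 2, 2), (5, 3, 3), (5, 5, 4),
    ])
    def test_matches_exhaustive_enumeration(self, wag, n_leaves, n_sites, seed):
        rng = np.random.default_rng(seed)
        tree = simulate_tree(n_leaves, seed=seed, mean_branch_length=0.4)
        msa = random_msa(rng, tree.leaf_names(), n_sites)
        site_liks, _ = enumerate_site_likelihood_and_posteriors(
            tree, msa, wag
        )
        assert log_likelihood(tree, msa, wag) == pytest.approx(
            float(np.log(site_liks).sum()), abs=1e-9
        )

    def test_invariant_under_rerooting(self, wag):
        rng = np.random.default_rng(9)
        tree = simulate_tree(6, seed=9, mean_branch_length=0.3)
        msa = random_msa(rng, tree.leaf_names(), 30)
        base = log_likelihood(tree, msa, wag)
        for leaf in tree.leaf_names():
            rerooted = root_with_outgroup(tree, leaf)
            assert log_likelihood(rerooted, msa, wag) == pytest.approx(
                base, abs=1e-8
            )

    def test_missing_leaf_sequence_rejected(self, wag, small_msa):
        tree = parse_newick("((a:1,b:1):1,(c:1,zz:1):1);")
        with pytest.raises(ValueError):
            log_likelihood(tree, small_msa, wag)


class TestOptimizeBranchLengths:
    def test_reaches_at_least_truth_likelihood(self, wag):
        fam = simulate_family(
            SimulationConfig(n_leaves=5, root_length=150, seed=4,
                             lid_interval=(80, 110), oxyanion_position=30,
                             catalytic_position=60)
        )
        truth_ll = log_likelihood(fam.true_tree, fam.true_alignment, wag)
        perturbed = fam.true_tree.copy()
        rng = np.random.default_rng(0)
        for node in perturbed.postorder():
            if node.parent is not None:
                node.length = float(rng.uniform(0.01, 0.5))
        fitted, final_ll = optimize_branch_lengths(
            perturbed, fam.true_alignment, wag
        )
        assert final_ll >= truth_ll - 1e-6

    def test_zero_variation_drives_lengths_to_zero(self, wag):
        msa = MultipleAlignment(
            [ProteinRecord(i, "ARNDARND") for i in ("a", "b", "c", "d")]
        )
        tree = parse_newick("((a:0.3,b:0.2):0.1,(c:0.4,d:0.1):0.2);")
        fitted, _ = optimize_branch_lengths(tree, msa, wag)
        for node in fitted.postorder():
            if node.parent is not None:
                assert node.length < 1e-5

    def test_single_branch_matches_grid_search(self, wag):
        msa = MultipleAlignment(
            [ProteinRecord("a", "ARNDCQEGHILK"), ProteinRecord("b", "ARNDCQEGWYVK")]
        )
        tree = parse_newick("(a:0.5,b:0.0);")
        fitted, final_ll = optimize_branch_lengths(tree, msa, wag)
        grid_best = max(
            log_likelihood(parse_newick(f"(a:{t},b:0.0);"), msa, wag)
            for t in np.linspace(1e-6, 2.0, 10_000)
        )
        assert final_ll >= grid_best - 1e-4


class TestRooting:
    def test_three_leaf_outgroup_bipartition(self):
        tree = parse_newick("(a:1,b:2,c:3);")
        rooted = root_with_outgroup(tree, "c")
        sides = [
            sorted(l.name for l in child.postorder() if l.is_leaf)
            for child in rooted.root.children
        ]
        assert sorted(sides) == [["a", "b"], ["c"]]

    def test_path_lengths_preserved(self, random_tree_factory):
        tree = random_tree_factory(7, seed=12)
        before = tree.leaf_distances()
        rooted = root_with_outgroup(tree, "t03")
        after = rooted.leaf_distances()
        for key, val in before.items():
            assert after[key] == pytest.approx(val, abs=1e-12)

    def test_reroot_then_unroot_restores_topology(self, random_tree_factory):
        tree = random_tree_factory(6, seed=21)
        un = unroot(tree)
        rooted = root_with_outgroup(un, "t05")
        back = unroot(rooted)
        assert tree_bipartitions(back) == tree_bipartitions(un)

    def test_unknown_outgroup_rejected(self, random_tree_factory):
        with pytest.raises(KeyError):
            root_with_outgroup(random_tree_factory(5, seed=1), "nope")


@pytest.fixture(scope="module")
def clean_msa():
    # conflict-free, low-divergence signal: ten columns support each
    # non-trivial split, the rest are constant
    seqs = {
        "a": "R" * 10 + "A" * 10 + "G" * 40,
        "b": "R" * 10 + "A" * 10 + "G" * 38 + "C" * 2,
        "c": "A" * 20 + "G" * 40,
        "d": "A" * 10 + "N" * 10 + "G" * 40,
        "e": "A" * 10 + "N" * 10 + "G" * 38 + "D" * 2,
    }
    return MultipleAlignment([ProteinRecord(i, s) for i, s in seqs.items()])


class TestBootstrap:
    def test_conflict_free_signal_gives_full_support(self, wag, clean_msa):
        support = bootstrap_support(clean_msa, wag, n_reps=20, seed=0)
        assert support and all(v == 1.0 for v in support.values())

    def test_reproducible_given_seed(self, wag, clean_msa):
        s1 = bootstrap_support(clean_msa, wag, n_reps=10, seed=42)
        s2 = bootstrap_support(clean_msa, wag, n_reps=10, seed=42)
        assert s1 == s2

    def test_supports_in_unit_interval_and_order_invariant(self, wag, clean_msa):
        shuffled = MultipleAlignment(list(reversed(clean_msa.records)))
        s1 = bootstrap_support(clean_msa, wag, n_reps=10, seed=7)
        s2 = bootstrap_support(shuffled, wag, n_reps=10, seed=7)
        assert all(0.0 <= v <= 1.0 for v in s1.values())
        assert s1 == s2
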