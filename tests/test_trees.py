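import numpy as np
import pytest
from skbio import TreeNode

from favtree import trees as tr
from favtree.calibration import preset
from favtree.distances import DistanceMatrix
from favtree.io import read_newick
from favtree.synthetic import FixtureSpec, gen_additive_matrix, gen_best_hit_tables, random_tree


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        m = DistanceMatrix(["A", "B", "C"], np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0.0]]))
        t = tr.neighbor_joining(m)
        lengths = {tip.name: tip.length for tip in t.tips()}
        assert lengths == {"A": 1.0, "B": 3.0, "C": 5.0}

    def test_four_taxon_additive_recovery(self):
        # generated from ((A:1,B:2):1,(C:3,D:4))
        v = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0.0]]
        )
        t = tr.neighbor_joining(DistanceMatrix(list("ABCD"), v))
        truth = read_newick("((A:1,B:2):1,(C:3,D:4));")
        assert tr.rf_distance(t, truth) == 0
        internal = [n.length for n in t.non_tips(include_self=False)]
        assert internal == pytest.approx([1.0])

    def test_two_taxa_single_edge(self):
        t = tr.neighbor_joining(DistanceMatrix(["A", "B"], np.array([[0, 7.0], [7.0, 0]])))
        assert sum(tip.length for tip in t.tips()) == pytest.approx(7.0)

    def test_nan_rejected(self):
        m = DistanceMatrix(["A", "B", "C"], np.full((3, 3), np.nan))
        with pytest.raises(ValueError):
            tr.neighbor_joining(m)

    @pytest.mark.parametrize("seed", range(5))
    def test_additive_recovery_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        truth = random_tree(n, seed=rng)
        m = gen_additive_matrix(truth)
        est = tr.neighbor_joining(m)
        assert tr.rf_distance(est, truth) == 0
        assert tr.cophenetic_correlation(est, m) == pytest.approx(1.0, abs=1e-9)


class TestJukesCantor:
    def test_zero_divergence(self):
        m = tr.jukes_cantor_distance([("a", "ACGT" * 10), ("b", "ACGT" * 10)])
        assert m[("a", "b")] == 0.0

    def test_closed_form_at_p_tenth(self):
        a = "A" * 100
        b = "C" * 10 + "A" * 90
        m = tr.jukes_cantor_distance([("a", a), ("b", b)])
        assert m[("a", "b")] == pytest.approx(0.107326, abs=1e-6)

    def test_saturation_rejected_with_pair_name(self):
        a = "A" * 100
        b = "C" * 75 + "A" * 25
        with pytest.raises(ValueError, match=r"saturation.*\(a, b\)"):
            tr.jukes_cantor_distance([("a", a), ("b", b)])

    def test_large_but_finite_below_saturation(self):
        a = "A" * 100
        b = "C" * 74 + "A" * 26
        m = tr.jukes_cantor_distance([("a", a), ("b", b)])
        assert np.isfinite(m[("a", "b")]) and m[("a", "b")] > 2.5


class TestConsensus:
    def test_identical_trees_full_support(self):
        t = read_newick("((A,B),(C,D),E);")
        cons = tr.majority_consensus([t.copy() for _ in range(100)])
        assert tr.rf_distance(cons, t) == 0
        supports = [n.support for n in cons.non_tips(include_self=False)]
        assert supports and all(s == 100 for s in supports)

    def test_sixty_forty_majority(self):
        t1 = read_newick("((A,B),(C,D),E);")
        t2 = read_newick("((A,C),(B,D),E);")
        cons = tr.majority_consensus([t1] * 60 + [t2] * 40)
        clades = {frozenset(tip.name for tip in n.tips()): n.support
                  for n in cons.non_tips(include_self=False)}
        assert clades.get(frozenset("AB")) == 60 or clades.get(frozenset("CDE")) == 60

    def test_exact_tie_excluded(self):
        t1 = read_newick("((A,B),(C,D),E);")
        t2 = read_newick("((A,C),(B,D),E);")
        cons = tr.majority_consensus([t1, t2])
        assert list(cons.non_tips(include_self=False)) == []  # star tree

    def test_leaf_mismatch_rejected(self):
        t1 = read_newick("((A,B),C);")
        t2 = read_newick("((A,B),D);")
        with pytest.raises(ValueError, match="leaf sets"):
            tr.majority_consensus([t1, t2])

    def test_extended_majority_adds_compatible_minority(self):
        t1 = read_newick("(((A,B),C),(D,E),F);")
        t2 = read_newick("(((A,B),D),(C,E),F);")
        strict = tr.majority_consensus([t1, t2])
        extended = tr.majority_consensus([t1, t2], extended=True)
        assert len(list(extended.non_tips(include_self=False))) > len(
            list(strict.non_tips(include_self=False))
        )


class TestRobinsonFoulds:
    def test_identical_zero(self):
        t = read_newick("((A,B),(C,D),E);")
        assert tr.rf_distance(t, t.copy()) == 0

    def test_conflicting_quartets(self):
        t1 = read_newick("((A,B),(C,D));")
        t2 = read_newick("((A,C),(B,D));")
        assert tr.rf_distance(t1, t2) == 2

    def test_rooting_invariance(self):
        t1 = read_newick("(((A,B),C),D);")
        t2 = read_newick("((A,B),(C,D));")
        assert tr.rf_distance(t1, t2) == 0

    def test_symmetry_random_pairs(self):
        for seed in range(5):
            t1 = random_tree(7, seed=seed)
            t2 = random_tree(7, seed=seed + 100)
            assert tr.rf_distance(t1, t2) == tr.rf_distance(t2, t1)

    def test_leaf_mismatch_rejected(self):
        with pytest.raises(ValueError, match="leaf sets"):
            tr.rf_distance(read_newick("((A,B),C);"), read_newick("((A,B),Z);"))


def _noiseless_fixture(n_taxa=6, genes=150, seed=5):
    tree = random_tree(n_taxa, seed=seed)
    spec = FixtureSpec(taxa=[t.name for t in tree.tips()], seed=seed,
                       gene_count=genes, tree=tree)
    return tree, gen_best_hit_tables(spec)


class TestBootstrap:
    def test_replicate_count_and_support_range(self):
        tree, tables = _noiseless_fixture()
        spec = tr.BootstrapSpec(b=20, k=50, seed=9)
        trees, cons = tr.bootstrap_trees(tables, preset(), spec)
        assert len(trees) == 20
        for node in cons.non_tips(include_self=False):
            assert 0 < node.support <= 20

    def test_fixed_seed_reproducible(self):
        tree, tables = _noiseless_fixture()
        spec = tr.BootstrapSpec(b=5, k=40, seed=3)
        trees1, _ = tr.bootstrap_trees(tables, preset(), spec)
        trees2, _ = tr.bootstrap_trees(tables, preset(), spec)
        for a, b in zip(trees1, trees2):
            assert str(a) == str(b)

    def test_noiseless_tables_give_unanimous_support(self):
        tree, tables = _noiseless_fixture()
        spec = tr.BootstrapSpec(b=10, k=30, seed=1)
        trees, cons = tr.bootstrap_trees(tables, preset(), spec)
        assert tr.rf_distance(cons, tree) == 0
        for node in cons.non_tips(include_self=False):
            assert node.support == 10

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            tr.BootstrapSpec(b=0)
        with pytest.raises(ValueError):
            tr.BootstrapSpec(k=0)
        with pytest.raises(ValueError):
            tr.BootstrapSpec(index_tag="F_MAX")


class TestGeneReduction:
    def test_full_fraction_reproduces_point_tree(self):
        tree, tables = _noiseless_fixture()
        target = sorted({t for t, s in tables if t == s})[0]
        res = tr.gene_reduction_experiment(tables, target, 1.0, replicates=3,
                                           index_tags=("F_AV",), seed=4, model=preset())
        full = tr.tree_from_tables(tables, preset())
        for t in res["F_AV"].trees:
            assert tr.rf_distance(t, full) == 0

    def test_agreement_counts_out_of_replicates(self):
        tree, tables = _noiseless_fixture()
        target = sorted({t for t, s in tables if t == s})[0]
        res = tr.gene_reduction_experiment(tables, target, 0.10, replicates=4,
                                           index_tags=("F_AV", "F_H"), seed=4, model=preset())
        for tag in ("F_AV", "F_H"):
            for node in res[tag].consensus.non_tips(include_self=False):
                assert 1 <= node.support <= 4

    def test_too_small_subset_rejected(self):
        tree, tables = _noiseless_fixture(genes=50)
        target = sorted({t for t, s in tables if t == s})[0]
        with pytest.raises(ValueError, match="at least 10"):
            tr.gene_reduction_experiment(tables, target, 0.1, model=preset())

    def test_unknown_taxon_rejected(self):
        tree, tables = _noiseless_fixture()
        with pytest.raises(ValueError, match="self-table"):
            tr.gene_reduction_experiment(tables, "nope", 0.5, model=preset())


class TestOutgroupRooting:
    def test_rooting_preserves_unrooted_topology(self):
        tree = random_tree(6, seed=2)
        name = next(iter(tree.tips())).name
        rooted = tr.root_with_outgroup(tree, name)
        assert tr.rf_distance(rooted, tree) == 0
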