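import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aprkit.ancestor import log_likelihood
from aprkit.evomodel import AAModel, load_matrix
from aprkit.seqio import Alignment, Sequence
from aprkit.simulate import random_tree, simulate_alignment
from aprkit.tree import PhyloTree, TreeError
from aprkit.treeinfer import (
    DistanceMatrix, bootstrap_support, distance_matrix, ml_pairwise_distance,
    neighbor_joining, nni_search, optimize_branch_lengths,
)


class TestMLPairwiseDistance:
    def test_identical_sequences_near_zero(self, lg_model):
        s = Sequence("a", "MKVWQERTYIPASDFGHKLC" * 5)
        assert ml_pairwise_distance(s, Sequence("b", s.residues), lg_model) <= 1e-4

    def test_exact_symmetry(self, lg_gamma_model):
        tree = PhyloTree.from_newick("(A:0.4,B:0.4);")
        sim = simulate_alignment(tree, lg_gamma_model, 300, seed=5)
        a, b = sim.alignment.sequences
        assert (ml_pairwise_distance(a, b, lg_gamma_model)
                == ml_pairwise_distance(b, a, lg_gamma_model))

    def test_simulation_consistency(self, uniform_model):
        tree = PhyloTree.from_newick("(A:0.25,B:0.25);")
        sim = simulate_alignment(tree, uniform_model, 5000, seed=7)
        a, b = sim.alignment.sequences
        d = ml_pairwise_distance(a, b, uniform_model)
        assert d == pytest.approx(0.5, abs=0.05)

    def test_no_comparable_sites_rejected(self, lg_model):
        with pytest.raises(ValueError, match="comparable"):
            ml_pairwise_distance(
                Sequence("a", "MK--"), Sequence("b", "--VW"), lg_model
            )


class TestNeighborJoining:
    def test_worked_four_taxon_example(self):
        # additive distances from tip edges (A:1,B:2,C:3,D:4), internal 1
        D = DistanceMatrix(
            list("ABCD"),
            np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], float),
        )
        t = neighbor_joining(D)
        assert t.bipartitions() == {frozenset("AB")}
        lengths = {n.name: n.length for n in t.tips()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        internal = [n for n in t.preorder()
                    if n is not t.root and not n.is_tip][0]
        assert internal.length == pytest.approx(1.0)

    def test_three_taxa_exact_lengths(self):
        D = DistanceMatrix(list("ABC"),
                           np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float))
        t = neighbor_joining(D)
        lengths = {n.name: n.length for n in t.tips()}
        assert lengths["A"] == pytest.approx((2 + 3 - 5) / 2)
        assert lengths["B"] == pytest.approx((2 + 5 - 3) / 2)
        assert lengths["C"] == pytest.approx((3 + 5 - 2) / 2)

    def test_label_order_invariance(self):
        rng = np.random.default_rng(0)
        base = random_tree(7, seed=31)
        D = _additive_matrix(base)
        t1 = neighbor_joining(D)
        perm = rng.permutation(len(D.labels))
        D2 = DistanceMatrix([D.labels[i] for i in perm],
                            D.matrix[np.ix_(perm, perm)])
        t2 = neighbor_joining(D2)
        assert t1.bipartitions() == t2.bipartitions()

    def test_asymmetric_matrix_rejected(self):
        M = np.zeros((3, 3)); M[0, 1] = 1.0
        with pytest.raises(ValueError):
            DistanceMatrix(list("ABC"), M)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(min_value=4, max_value=10), st.integers(0, 10_000))
    def test_additive_recovery_property(self, ntips, seed):
        tree = random_tree(ntips, branch_range=(0.1, 1.0), seed=seed)
        D = _additive_matrix(tree)
        recovered = neighbor_joining(D)
        assert recovered.bipartitions() == tree.bipartitions()


def _additive_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Exact path-length distances on the tree (the additive oracle)."""
    tips = tree.tips()
    labels = [t.name for t in tips]
    ancestors = {}
    for t in tips:
        path = {}
        node, dist = t, 0.0
        while node is not None:
            path[id(node)] = dist
            dist += node.length or 0.0
            node = node.parent
        ancestors[t.name] = path
    n = len(tips)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pa, pb = ancestors[labels[i]], ancestors[labels[j]]
            best = min(pa[k] + pb[k] for k in pa if k in pb)
            M[i, j] = M[j, i] = best
    return DistanceMatrix(labels, M)


class TestBranchLengthOptimization:
    def _sim(self, seed=3, ncol=500):
        true = PhyloTree.from_newick("((A:0.2,B:0.3):0.3,(C:0.15,D:0.25):0.1);")
        model = AAModel("LG", *load_matrix("LG"), alpha=1.0)
        return true, model, simulate_alignment(true, model, ncol, seed=seed).alignment

    def test_monotone_and_fixed_point(self):
        true, model, aln = self._sim()
        before = log_likelihood(true, aln, model).lnL
        opt, res = optimize_branch_lengths(true, aln, model)
        assert res.lnL >= before
        opt2, res2 = optimize_branch_lengths(opt, aln, model, max_sweeps=1)
        assert res2.lnL - res.lnL < 1e-6  # already at the optimum

    def test_simulated_length_recovery(self):
        true = PhyloTree.from_newick("((A:0.2,B:0.3):0.3,(C:0.15,D:0.25):0.1);")
        model = AAModel("LG", *load_matrix("LG"))
        aln = simulate_alignment(true, model, 2000, seed=17).alignment
        opt, _ = optimize_branch_lengths(true, aln, model)
        true_len = {frozenset(t.name for t in true._subtree_tips(n)): n.length
                    for n in true.preorder() if n.parent}
        for n in opt.preorder():
            if not n.parent:
                continue
            key = frozenset(t.name for t in opt._subtree_tips(n))
            assert n.length == pytest.approx(true_len[key], rel=0.20)

    def test_missing_lengths_need_initializer(self, lg_model):
        tree = PhyloTree.from_newick("((A,B),(C,D));")
        _, model, aln = self._sim()
        with pytest.raises(ValueError, match="initializer"):
            optimize_branch_lengths(tree, aln, model)
        opt, res = optimize_branch_lengths(tree, aln, model, init=0.1)
        assert np.isfinite(res.lnL)

    def test_consistent_with_ancestor_loglik(self):
        true, model, aln = self._sim()
        opt, res = optimize_branch_lengths(true, aln, model)
        assert res.lnL == pytest.approx(
            log_likelihood(opt, aln, model).lnL, abs=1e-10
        )


class TestNNI:
    def test_recovers_true_topology_from_wrong_start(self):
        true = PhyloTree.from_newick("((A:0.2,B:0.2):0.3,(C:0.2,D:0.2):0.1);")
        model = AAModel("LG", *load_matrix("LG"))
        aln = simulate_alignment(true, model, 1000, seed=23).alignment
        wrong = PhyloTree.from_newick("((A:0.2,C:0.2):0.3,(B:0.2,D:0.2):0.1);")
        found, res = nni_search(wrong, aln, model)
        assert found.bipartitions() == true.bipartitions()

    def test_no_move_at_optimum_and_monotone(self):
        true = PhyloTree.from_newick("((A:0.2,B:0.2):0.3,(C:0.2,D:0.2):0.1);")
        model = AAModel("LG", *load_matrix("LG"))
        aln = simulate_alignment(true, model, 500, seed=29).alignment
        start_lnL = log_likelihood(true, aln, model).lnL
        found, res = nni_search(true, aln, model)
        assert found.bipartitions() == true.bipartitions()
        assert res.lnL >= start_lnL

    def test_nonbinary_rejected(self):
        star = PhyloTree.from_newick("(A:1,B:1,C:1,D:1);")
        model = AAModel("LG", *load_matrix("LG"))
        aln = Alignment([Sequence(n, "MKV") for n in "ABCD"])
        with pytest.raises(TreeError, match="binary"):
            nni_search(star, aln, model)


class TestBootstrap:
    def _fixture(self):
        true = PhyloTree.from_newick("((A:0.2,B:0.2):0.4,(C:0.2,D:0.2):0.1);")
        model = AAModel("LG", *load_matrix("LG"))
        aln = simulate_alignment(true, model, 500, seed=41).alignment
        return true, model, aln

    def test_bit_reproducible(self):
        true, model, aln = self._fixture()
        b1 = bootstrap_support(aln, model, true, n_replicates=3, seed=11)
        b2 = bootstrap_support(aln, model, true, n_replicates=3, seed=11)
        assert b1.support == b2.support

    def test_support_range_and_coverage(self):
        true, model, aln = self._fixture()
        b = bootstrap_support(aln, model, true, n_replicates=5, seed=1)
        assert set(b.support) == true.bipartitions()
        assert all(0.0 <= v <= 1.0 for v in b.support.values())
        annotated = b.annotate(true)
        internal = [n for n in annotated.preorder()
                    if n.parent and not n.is_tip]
        assert all(n.support is not None for n in internal)

    def test_invalid_replicates(self):
        true, model, aln = self._fixture()
        with pytest.raises(ValueError):
            bootstrap_support(aln, model, true, n_replicates=0)


class TestRootInvariance:
    def test_lnl_invariant_under_rerooting(self, lg_gamma_model):
        tree = random_tree(8, seed=3)
        sim = simulate_alignment(tree, lg_gamma_model, 100, seed=3)
        base = log_likelihood(tree, sim.alignment, lg_gamma_model).lnL
        for node in tree.internals():
            if node is tree.root:
                continue
            re = tree.rerooted_at(node)
            assert abs(
                log_likelihood(re, sim.alignment, lg_gamma_model).lnL - base
            ) < 1e-8
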