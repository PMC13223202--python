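import subprocess

import numpy as np
import pytest

from aprkit._pruning import PruningEngine
from aprkit.ancestor import (
    AncestralPosterior, extract_map_sequence, label_nodes, log_likelihood,
    marginal_posteriors, mrca_id, reconstruct_gap_states,
)
from aprkit.evomodel import AAModel
from aprkit.seqio import AA_ORDER, Alignment, Sequence, write_fasta, write_newick
from aprkit.tree import PhyloTree
from conftest import random_alignment, random_models
from oracles import brute_loglik, brute_posteriors


class TestLogLikelihood:
    def test_two_taxa_one_site_vs_enumeration(self, lg_model):
        tree = PhyloTree.from_newick("(A:0.3,B:0.6);")
        aln = Alignment([Sequence("A", "M"), Sequence("B", "M")])
        res = log_likelihood(tree, aln, lg_model)
        # direct 20-term summation over the root state
        m = AA_ORDER.index("M")
        P1 = lg_model.transition_matrix(0.3)
        P2 = lg_model.transition_matrix(0.6)
        direct = np.log(np.sum(lg_model.pi * P1[:, m] * P2[:, m]))
        assert res.lnL == pytest.approx(direct, abs=1e-12)

    def test_quartet_vs_enumeration(self, quartet_tree, quartet_alignment):
        for model in random_models(2, seed=5):
            res = log_likelihood(quartet_tree, quartet_alignment, model)
            brute = brute_loglik(quartet_tree, quartet_alignment, model)
            assert res.lnL == pytest.approx(brute, rel=1e-10)

    def test_all_gap_column_contributes_zero(self, lg_model):
        tree = PhyloTree.from_newick("(A:0.3,B:0.6);")
        a1 = Alignment([Sequence("A", "MK"), Sequence("B", "ML")])
        a2 = Alignment([Sequence("A", "MK-"), Sequence("B", "ML-")])
        l1 = log_likelihood(tree, a1, lg_model).lnL
        l2 = log_likelihood(tree, a2, lg_model).lnL
        assert l1 == pytest.approx(l2, abs=1e-12)

    def test_label_mismatch_rejected(self, lg_model):
        tree = PhyloTree.from_newick("(A:0.3,X:0.6);")
        aln = Alignment([Sequence("A", "M"), Sequence("B", "M")])
        with pytest.raises(ValueError, match="mismatch"):
            log_likelihood(tree, aln, lg_model)

    def test_missing_branch_length_rejected(self, lg_model):
        tree = PhyloTree.from_newick("(A:0.3,B);")
        aln = Alignment([Sequence("A", "M"), Sequence("B", "M")])
        with pytest.raises(ValueError, match="branch length"):
            log_likelihood(tree, aln, lg_model)

    def test_matches_phangorn(self, tmp_path):
        """Independent cross-check against the R phangorn pml kernel."""
        from aprkit.evomodel import load_matrix
        from aprkit.simulate import random_tree, simulate_alignment

        tree = random_tree(5, branch_range=(0.1, 0.4), seed=2)
        model = AAModel("LG", *load_matrix("LG"), alpha=0.9)
        sim = simulate_alignment(tree, model, 60, seed=2)
        fa, nwk = tmp_path / "x.fasta", tmp_path / "x.nwk"
        write_fasta(sim.alignment.sequences, fa)
        write_newick(tree, nwk)
        mine = log_likelihood(tree, sim.alignment, model).lnL
        script = (
            'suppressMessages(library(phangorn));'
            f'aln <- read.phyDat("{fa}", format="fasta", type="AA");'
            f'tr <- read.tree("{nwk}");'
            'fit <- pml(tr, aln, model="LG", k=4, shape=0.9);'
            'cat(sprintf("%.10f", logLik(fit)))'
        )
        out = subprocess.run(["Rscript", "-e", script],
                             capture_output=True, text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        assert mine == pytest.approx(float(out.stdout.strip()), abs=1e-6)


class TestMarginalPosteriors:
    def test_quartet_vs_enumeration(self, quartet_tree, quartet_alignment):
        model = random_models(1, seed=9)[0]
        lab = label_nodes(quartet_tree)
        posts = marginal_posteriors(quartet_tree, quartet_alignment, model, labeling=lab)
        brute = brute_posteriors(quartet_tree, quartet_alignment, model)
        for post in posts:
            node = lab.node(post.node_id)
            assert np.abs(post.probs - brute[id(node)]).max() < 1e-10
            assert np.abs(post.probs.sum(axis=1) - 1.0).max() < 1e-9

    def test_zero_length_branch_copies_tip(self, lg_model):
        tree = PhyloTree.from_newick("((A:0.0,B:1.5):0.5,(C:1.5,D:1.5):0.5);")
        aln = Alignment([Sequence(n, r) for n, r in
                         [("A", "W"), ("B", "X"), ("C", "X"), ("D", "X")]])
        lab = label_nodes(tree)
        posts = {p.node_id: p for p in
                 marginal_posteriors(tree, aln, lg_model, labeling=lab)}
        # the internal node joined to tip A by a zero branch
        ab_node = next(
            nid for nid in lab.internal_ids
            if {t.name for t in tree._subtree_tips(lab.node(nid))} == {"A", "B"}
        )
        w = AA_ORDER.index("W")
        assert posts[ab_node].probs[0, w] >= 0.999

    def test_consensus_pull_on_star(self, lg_model):
        tree = PhyloTree.from_newick("(A:0.4,B:0.4,C:0.4);")
        aln = Alignment([Sequence(n, "A") for n in "AB"] + [Sequence("C", "A")])
        post = marginal_posteriors(tree, aln, lg_model)[0]
        a = AA_ORDER.index("A")
        assert post.map_residues == "A"
        assert post.probs[0, a] > lg_model.pi[a]

    def test_root_invariance(self, lg_gamma_model):
        aln = random_alignment(list("ABCDEFGH"), 30, seed=3)
        from aprkit.simulate import random_tree

        tree = random_tree(8, seed=13)
        for node in tree.tips():
            node.name = "ABCDEFGH"[int(node.name[1:]) - 1]
        lnL = log_likelihood(tree, aln, lg_gamma_model).lnL
        lab = label_nodes(tree)
        posts = {p.node_id: p for p in
                 marginal_posteriors(tree, aln, lg_gamma_model, labeling=lab)}

        def vertex_key(t, node):
            """Rooting-invariant vertex id: the partition of tips induced
            by deleting the vertex."""
            all_tips = frozenset(t.tip_labels())
            parts = [
                frozenset(x.name for x in t._subtree_tips(c))
                for c in node.children
            ]
            rest = all_tips - frozenset().union(*parts)
            if rest:
                parts.append(rest)
            return frozenset(parts)

        keys1 = {vertex_key(tree, lab.node(nid)): nid for nid in lab.internal_ids}
        target = [n for n in tree.internals() if n is not tree.root][0]
        re = tree.rerooted_at(target)
        assert abs(log_likelihood(re, aln, lg_gamma_model).lnL - lnL) < 1e-9
        lab2 = label_nodes(re)
        posts2 = {p.node_id: p for p in
                  marginal_posteriors(re, aln, lg_gamma_model, labeling=lab2)}
        matched = 0
        for nid2 in lab2.internal_ids:
            key = vertex_key(re, lab2.node(nid2))
            if key in keys1:
                assert np.abs(
                    posts[keys1[key]].probs - posts2[nid2].probs
                ).max() < 1e-9
                matched += 1
        assert matched == len(lab2.internal_ids)  # every vertex agrees


class TestGapReconstruction:
    def _aln(self, rows):
        return Alignment([Sequence(n, r) for n, r in rows])

    def test_all_tip_gap_column_absent(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        aln = self._aln([("A", "-K"), ("B", "-K"), ("C", "-K"), ("D", "-K")])
        states = reconstruct_gap_states(tree, aln)
        for arr in states.values():
            assert not arr[0] and arr[1]

    def test_root_tie_resolves_to_presence(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        aln = self._aln([("A", "-"), ("B", "-"), ("C", "K"), ("D", "K")])
        states = reconstruct_gap_states(tree, aln)
        lab = label_nodes(tree)
        root_id = lab.id_of(tree.root)
        assert states[root_id][0]


class TestMapSequence:
    def _post(self, probs):
        probs = np.asarray(probs, float)
        from aprkit.ancestor import _map_indices

        idx = _map_indices(probs)
        return AncestralPosterior(
            node_id=9, probs=probs,
            map_residues="".join(AA_ORDER[i] for i in idx),
            max_probs=probs[np.arange(len(idx)), idx],
        )

    def test_uniform_posterior_meanpp(self):
        post = self._post(np.full((4, 20), 0.05))
        seq, mean_pp = extract_map_sequence(post, {9: np.ones(4, bool)})
        assert mean_pp == pytest.approx(0.05)
        assert seq.residues == "AAAA"  # alphabetical tie-break

    def test_simple_map_and_gap_mask(self):
        probs = np.zeros((2, 20))
        probs[0, AA_ORDER.index("L")] = 0.6
        probs[0, AA_ORDER.index("M")] = 0.4
        probs[1, AA_ORDER.index("W")] = 1.0
        post = self._post(probs)
        seq, mean_pp = extract_map_sequence(
            post, {9: np.array([True, False])}
        )
        assert seq.residues == "L-"
        assert mean_pp == pytest.approx(0.6)

    def test_unknown_node_rejected(self):
        post = self._post(np.full((1, 20), 0.05))
        with pytest.raises(KeyError):
            extract_map_sequence(post, {9: np.ones(1, bool)}, node_id=12)


class TestNodeLabeling:
    def test_ladder_tree_scheme(self):
        t = PhyloTree.from_newick("(T1:1,(T2:1,(T3:1,(T4:1,T5:1):1):1):1);")
        lab = label_nodes(t)
        tips = {n.name: lab.id_of(n) for n in t.tips()}
        assert tips == {"T1": 1, "T2": 2, "T3": 3, "T4": 4, "T5": 5}
        assert lab.id_of(t.root) == 6
        assert lab.internal_ids == [6, 7, 8, 9]

    def test_stable_across_reparses(self):
        text = "((A:1,B:1):1,(C:1,(D:1,E:1):1):1);"
        l1 = label_nodes(PhyloTree.from_newick(text))
        l2 = label_nodes(PhyloTree.from_newick(text))
        t1 = l1.table()
        t2 = l2.table()
        assert t1.equals(t2)

    def test_mrca_addressing(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,(C:1,(D:1,E:1):1):1);")
        lab = label_nodes(t)
        assert mrca_id(t, ["D", "E"], lab) == 9
        assert mrca_id(t, ["A", "B"], lab) == 7
        assert mrca_id(t, ["A", "C"], lab) == 6
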