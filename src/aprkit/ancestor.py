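"""Marginal (empirical-Bayes) ancestral sequence reconstruction.

Given a fixed tree, alignment and substitution model, the posterior
distribution over the 20 amino acids is computed for every internal
node and alignment column by the inside-outside decomposition of the
pruning algorithm, integrating over rate categories with their
per-site posterior weights.  Ancestral gap placement is a separate
small-parsimony (Fitch) pass on the binary presence/absence character,
since the likelihood model treats gaps as missing data.

Internal nodes are addressed by deterministic integer ids: tips are
numbered 1..n in their order of appearance in the Newick string, and
internal nodes n+1..2n-1 in preorder from the stored root — the same
convention PAML uses to name ancestors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._pruning import PruningEngine
from .evomodel import LikelihoodResult
from .seqio import AA_ORDER, Alignment, Sequence
from .tree import Node, PhyloTree

__all__ = [
    "AncestralPosterior",
    "NodeLabeling",
    "log_likelihood",
    "marginal_posteriors",
    "reconstruct_gap_states",
    "extract_map_sequence",
    "label_nodes",
    "mrca_id",
]


@dataclass
class AncestralPosterior:
    """Per-column 20-state posterior for one internal node."""

    node_id: int
    probs: np.ndarray          # (ncol, 20), rows of non-gap columns sum to 1
    map_residues: str          # MAP residue per column (ties alphabetical)
    max_probs: np.ndarray      # (ncol,) posterior of the MAP residue

    @property
    def ncol(self) -> int:
        return self.probs.shape[0]

    def mean_pp(self, present: np.ndarray | None = None) -> float:
        """Mean MAP posterior over the given present-column mask
        (all columns if None)."""
        mask = np.ones(self.ncol, bool) if present is None else present
        if not mask.any():
            raise ValueError("no present columns")
        return float(self.max_probs[mask].mean())


class NodeLabeling:
    """Bijection between tree nodes and PAML-style integer ids."""

    def __init__(self, tree: PhyloTree):
        tips = tree.tips()
        n = len(tips)
        self.n_tips = n
        self._id_of: dict[int, int] = {}
        self._node_of: dict[int, Node] = {}
        for i, tip in enumerate(tips, start=1):
            self._id_of[id(tip)] = i
            self._node_of[i] = tip
        next_id = n + 1
        for node in tree.preorder():
            if not node.is_tip:
                self._id_of[id(node)] = next_id
                self._node_of[next_id] = node
                next_id += 1
        self.tree = tree

    def id_of(self, node: Node) -> int:
        return self._id_of[id(node)]

    def node(self, node_id: int) -> Node:
        try:
            return self._node_of[node_id]
        except KeyError:
            raise KeyError(f"no node with id {node_id}") from None

    @property
    def internal_ids(self) -> list[int]:
        return sorted(i for i in self._node_of if i > self.n_tips)

    def table(self) -> pd.DataFrame:
        rows = []
        for nid in self.internal_ids:
            node = self._node_of[nid]
            rows.append({
                "node": nid,
                "children": ",".join(
                    str(self._id_of[id(c)]) for c in node.children
                ),
                "tips": ",".join(
                    sorted(t.name for t in self.tree._subtree_tips(node))
                ),
            })
        return pd.DataFrame(rows)


def label_nodes(tree: PhyloTree) -> NodeLabeling:
    return NodeLabeling(tree)


def mrca_id(tree: PhyloTree, tip_labels: list[str], labeling: NodeLabeling | None = None) -> int:
    """Id of the most recent common ancestor of the given tips."""
    labeling = labeling or NodeLabeling(tree)
    want = set(tip_labels)
    missing = want - set(tree.tip_labels())
    if missing:
        raise KeyError(f"unknown tips {sorted(missing)}")
    best = None
    for node in tree.postorder():
        if node.is_tip:
            continue
        tipset = {t.name for t in tree._subtree_tips(node)}
        if want <= tipset and (best is None or len(tipset) < len(best[1])):
            best = (node, tipset)
    if best is None:  # only the root covers them
        best = (tree.root, set(tree.tip_labels()))
    return labeling.id_of(best[0])


def log_likelihood(tree: PhyloTree, alignment: Alignment, model) -> LikelihoodResult:
    """Phylogenetic log-likelihood by Felsenstein pruning."""
    engine = PruningEngine(tree, alignment, model)
    n_branches = sum(1 for n in tree.preorder() if n is not tree.root)
    npar = (
        n_branches
        + (1 if model.alpha is not None else 0)
        + (1 if model.p_inv > 0 else 0)
        + (19 if model.freq_mode == "observed" else 0)
    )
    return LikelihoodResult(
        lnL=engine.loglik(), nparams=max(npar, 1), per_site_lnL=engine.site_logliks()
    )


def marginal_posteriors(
    tree: PhyloTree, alignment: Alignment, model,
    labeling: NodeLabeling | None = None,
) -> list[AncestralPosterior]:
    """Empirical-Bayes marginal posteriors for every internal node."""
    engine = PruningEngine(tree, alignment, model)
    labeling = labeling or NodeLabeling(tree)
    out = []
    for nid in labeling.internal_ids:
        node = labeling.node(nid)
        probs = engine.node_posteriors(node)
        map_idx = _map_indices(probs)
        out.append(AncestralPosterior(
            node_id=nid,
            probs=probs,
            map_residues="".join(AA_ORDER[i] for i in map_idx),
            max_probs=probs[np.arange(len(map_idx)), map_idx],
        ))
    return out


def _map_indices(probs: np.ndarray) -> np.ndarray:
    """Argmax per row with ties broken alphabetically by one-letter code."""
    alpha_rank = np.argsort(list(AA_ORDER))          # positions sorted A..Y
    ranked = probs[:, alpha_rank]
    best = ranked.argmax(axis=1)                     # first max = alphabetical
    return alpha_rank[best]


def reconstruct_gap_states(tree: PhyloTree, alignment: Alignment,
                           labeling: NodeLabeling | None = None) -> dict[int, np.ndarray]:
    """Fitch small-parsimony presence/absence reconstruction.

    Returns, per internal node id, a boolean (ncol,) array: True where
    the ancestor is reconstructed as having a residue.  Root ties
    resolve to presence.
    """
    labeling = labeling or NodeLabeling(tree)
    ncol = alignment.ncol
    PRESENT, ABSENT, BOTH = 1, 2, 3  # bitmask sets

    sets: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            seq = alignment[node.name].residues
            arr = np.fromiter(
                (ABSENT if c == "-" else PRESENT for c in seq), np.int8, ncol
            )
        else:
            child_sets = [sets[id(c)] for c in node.children]
            inter = child_sets[0]
            union = child_sets[0]
            for cs in child_sets[1:]:
                inter = inter & cs
                union = union | cs
            arr = np.where(inter != 0, inter, union)
        sets[id(node)] = arr

    states: dict[int, np.ndarray] = {}
    for node in tree.preorder():
        s = sets[id(node)]
        if node is tree.root:
            chosen = np.where(s == ABSENT, ABSENT, PRESENT)  # tie -> present
        else:
            parent_state = states[id(node.parent)]
            keep = (s & parent_state) != 0
            single = np.where(s == BOTH, PRESENT, s)  # BOTH w/o parent match: present
            chosen = np.where(keep, parent_state, single)
        states[id(node)] = chosen

    return {
        nid: states[id(labeling.node(nid))] == PRESENT
        for nid in labeling.internal_ids
    }


def extract_map_sequence(
    posterior: AncestralPosterior,
    gap_states: dict[int, np.ndarray],
    node_id: int | None = None,
) -> tuple[Sequence, float]:
    """MAP ancestral sequence ('-' at reconstructed-absent columns) and
    its mean posterior probability over present columns."""
    nid = posterior.node_id if node_id is None else node_id
    if nid != posterior.node_id:
        raise KeyError(f"posterior is for node {posterior.node_id}, not {nid}")
    if nid not in gap_states:
        raise KeyError(f"no gap reconstruction for node {nid}")
    present = gap_states[nid]
    chars = [
        (c if p else "-")
        for c, p in zip(posterior.map_residues, present)
    ]
    seq = Sequence(f"node{nid}", "".join(chars))
    return seq, posterior.mean_pp(present)
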