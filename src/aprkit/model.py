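"""High-level modelling interface.

:class:`PhyloML` bundles an alignment (and optionally a fixed tree and
substitution model) into a model object whose :meth:`~PhyloML.fit`
runs the inference — model selection if no substitution model was
fixed, neighbor-joining start tree, branch-length optimisation, NNI
refinement, optional bootstrap — and returns a
:class:`PhyloMLResults` carrying the fitted tree, the log-likelihood,
the parameter estimates and their diagnostics, with
:meth:`~PhyloMLResults.summary`, ancestral reconstruction and
simulation hanging off it.

    >>> model = PhyloML(alignment)                      # doctest: +SKIP
    >>> res = model.fit(seed=1, bootstrap=100)          # doctest: +SKIP
    >>> print(res.summary())                            # doctest: +SKIP
    >>> anc = res.ancestral()                           # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ancestor as _ancestor
from . import treeinfer as _treeinfer
from .evomodel import AAModel, LikelihoodResult, load_matrix, select_model
from .seqio import Alignment, Sequence
from .tree import PhyloTree

__all__ = ["PhyloML", "PhyloMLResults", "AncestralReconstruction"]


class PhyloML:
    """Maximum-likelihood phylogenetics model for a protein alignment.

    Parameters
    ----------
    alignment:
        The fixed multiple sequence alignment (columns that are gaps in
        every sequence are dropped).
    tree:
        Optional fixed topology.  If omitted, a neighbor-joining start
        tree is built from ML pairwise distances and refined by NNI.
    substitution_model:
        Optional :class:`~aprkit.evomodel.AAModel`.  If omitted, AIC
        model selection over *candidates* picks one.
    candidates, plus_gamma, plus_inv, plus_f, k:
        Model-selection search space (ignored when *substitution_model*
        is given).
    """

    def __init__(
        self,
        alignment: Alignment,
        tree: PhyloTree | None = None,
        substitution_model: AAModel | None = None,
        candidates: list[str] | None = None,
        plus_gamma: bool = True,
        plus_inv: bool = True,
        plus_f: bool = False,
        k: int = 4,
    ):
        self.alignment = alignment.drop_all_gap_columns()
        self.tree = tree
        self.substitution_model = substitution_model
        self.candidates = candidates
        self.plus_gamma = plus_gamma
        self.plus_inv = plus_inv
        self.plus_f = plus_f
        self.k = k

    @classmethod
    def from_files(cls, alignment_path: str, tree_path: str | None = None, **kw):
        from . import seqio

        if str(alignment_path).endswith((".phy", ".phylip")):
            aln = seqio.read_phylip_interleaved(alignment_path)
        else:
            aln = Alignment(seqio.read_fasta(alignment_path))
        tree = seqio.read_newick(tree_path) if tree_path else None
        return cls(aln, tree=tree, **kw)

    # -----------------------------------------------------------------

    def _start_tree(self, model: AAModel) -> PhyloTree:
        D = _treeinfer.distance_matrix(self.alignment, model)
        return _treeinfer.neighbor_joining(D)

    def fit(
        self,
        nni: bool = True,
        bootstrap: int = 0,
        seed: int = 0,
    ) -> "PhyloMLResults":
        """Run the full inference and return the results object."""
        selection_table = None
        model = self.substitution_model
        if model is None:
            base = AAModel("LG", *load_matrix("LG"))
            start = self.tree or self._start_tree(base)
            model, selection_table = select_model(
                self.alignment, start,
                candidates=self.candidates,
                plus_gamma=self.plus_gamma, plus_inv=self.plus_inv,
                plus_f=self.plus_f, k=self.k,
            )
            tree = start
        else:
            tree = self.tree or self._start_tree(model)

        if not tree.has_branch_lengths():
            tree, _ = _treeinfer.optimize_branch_lengths(
                tree, self.alignment, model, init=0.1
            )
        if nni and tree.n_tips > 3:
            tree, res = _treeinfer.nni_search(tree, self.alignment, model)
        else:
            tree, res = _treeinfer.optimize_branch_lengths(
                tree, self.alignment, model, init=0.1
            )

        boot = None
        if bootstrap > 0:
            boot = _treeinfer.bootstrap_support(
                self.alignment, model, tree, n_replicates=bootstrap, seed=seed
            )
            tree = boot.annotate(tree)

        return PhyloMLResults(
            model=self, substitution_model=model, tree=tree,
            likelihood=res, selection_table=selection_table,
            bootstrap=boot, seed=seed,
        )


@dataclass
class PhyloMLResults:
    """Fitted phylogeny: point estimates, uncertainty and diagnostics."""

    model: PhyloML
    substitution_model: AAModel
    tree: PhyloTree
    likelihood: LikelihoodResult
    selection_table: pd.DataFrame | None = None
    bootstrap: "_treeinfer.BootstrapResult | None" = None
    seed: int = 0
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def llf(self) -> float:
        return self.likelihood.lnL

    @property
    def nparams(self) -> int:
        return self.likelihood.nparams

    @property
    def aic(self) -> float:
        return 2.0 * self.nparams - 2.0 * self.llf

    @property
    def params(self) -> pd.Series:
        """Branch lengths keyed by the subtree tip set below each edge."""
        rows = {}
        for node in self.tree.preorder():
            if node is self.tree.root:
                continue
            key = node.name or "|".join(
                sorted(t.name for t in self.tree._subtree_tips(node))
            )
            rows[key] = node.length
        return pd.Series(rows, name="branch_length")

    def summary(self) -> str:
        m = self.substitution_model
        lines = [
            "Maximum-likelihood phylogeny",
            "=" * 60,
            f"Taxa:                 {self.tree.n_tips}",
            f"Alignment columns:    {self.model.alignment.ncol}",
            f"Substitution model:   {m.label}",
            f"Gamma shape (alpha):  {m.alpha if m.alpha is not None else '-'}",
            f"Invariant fraction:   {m.p_inv:.4g}",
            f"Rate categories:      {m.k if m.alpha is not None else 1}",
            f"Log-likelihood:       {self.llf:.4f}",
            f"Free parameters:      {self.nparams}",
            f"AIC:                  {self.aic:.4f}",
            f"Tree length:          {self.tree.total_branch_length():.4f}",
        ]
        if self.bootstrap is not None:
            vals = list(self.bootstrap.support.values())
            lines.append(
                f"Bootstrap:            {self.bootstrap.n_replicates} replicates, "
                f"mean support {np.mean(vals):.2f}" if vals else
                f"Bootstrap:            {self.bootstrap.n_replicates} replicates"
            )
        if self.selection_table is not None:
            lines += ["", "Model selection (AIC, best first):",
                      self.selection_table.head(5).to_string(index=False)]
        return "\n".join(lines)

    # -- downstream analyses ------------------------------------------

    def ancestral(self) -> "AncestralReconstruction":
        if "anc" not in self._cache:
            self._cache["anc"] = AncestralReconstruction(
                self.tree, self.model.alignment, self.substitution_model
            )
        return self._cache["anc"]

    def simulate(self, ncol: int, seed: int = 0):
        from .simulate import simulate_alignment

        return simulate_alignment(self.tree, self.substitution_model, ncol, seed)


class AncestralReconstruction:
    """Marginal ancestral reconstruction bound to a fitted phylogeny."""

    def __init__(self, tree: PhyloTree, alignment: Alignment, model: AAModel):
        self.tree = tree
        self.alignment = alignment
        self.substitution_model = model
        self.labeling = _ancestor.label_nodes(tree)
        self.posteriors = _ancestor.marginal_posteriors(
            tree, alignment, model, labeling=self.labeling
        )
        self.gap_states = _ancestor.reconstruct_gap_states(
            tree, alignment, labeling=self.labeling
        )

    def map_sequence(self, node_id: int) -> tuple[Sequence, float]:
        for post in self.posteriors:
            if post.node_id == node_id:
                return _ancestor.extract_map_sequence(post, self.gap_states)
        raise KeyError(f"no internal node {node_id}")

    def map_sequences(self) -> dict[int, tuple[Sequence, float]]:
        return {p.node_id: _ancestor.extract_map_sequence(p, self.gap_states)
                for p in self.posteriors}

    def mrca(self, tip_labels: list[str]) -> int:
        return _ancestor.mrca_id(self.tree, tip_labels, self.labeling)

    def node_table(self) -> pd.DataFrame:
        return self.labeling.table()

    def posterior_table(self) -> pd.DataFrame:
        from .seqio import AA_ORDER

        rows = []
        for post in self.posteriors:
            present = self.gap_states[post.node_id]
            for col in range(post.ncol):
                row = {"node": post.node_id, "column": col + 1,
                       "map": post.map_residues[col] if present[col] else "-",
                       "max_pp": post.max_probs[col]}
                row.update({f"p_{a}": post.probs[col, i]
                            for i, a in enumerate(AA_ORDER)})
                rows.append(row)
        return pd.DataFrame(rows)
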