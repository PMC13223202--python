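"""Felsenstein pruning kernel.

One engine instance binds a tree, an alignment and a substitution
model, and serves every likelihood-based computation in the toolkit:
the log-likelihood itself, per-branch vectors for single-branch length
optimisation, and the inside/outside vectors needed for marginal
ancestral posteriors.

Implementation notes:

* Alignment columns are compressed to unique site patterns with
  multiplicities; all per-site arrays are (ncat, npat, 20).
* Underflow is handled by per-node, per-(category, pattern) scaling:
  conditional-likelihood vectors are renormalised to max 1 and the log
  scale factors are accumulated and re-applied inside a log-sum-exp
  over rate categories, so category mixing stays exact.
* Gap and 'X' tip states contribute an all-ones vector (missing data);
  a zero-rate (invariant) category simply uses P = I, which makes the
  category's likelihood vanish on variable patterns as it must.
* The model is reversible, so the tree may be rooted anywhere; the
  outside ("down") recursion places the stationary distribution at the
  stored root.
"""

from __future__ import annotations

import numpy as np

from .tree import Node, PhyloTree

_TIP_PARTIALS = np.vstack([np.eye(20), np.ones((1, 20))])  # code 20 = missing


class PruningEngine:
    def __init__(self, tree: PhyloTree, alignment, model):
        tips = set(tree.tip_labels())
        ids = set(alignment.ids)
        if tips != ids:
            raise ValueError(
                f"tree/alignment label mismatch: only_tree={sorted(tips - ids)}, "
                f"only_alignment={sorted(ids - tips)}"
            )
        for node in tree.preorder():
            if node is not tree.root and node.length is None:
                raise ValueError("tree has missing branch lengths")

        self.tree = tree
        self.model = model
        self.nodes: list[Node] = list(tree.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.root_idx = self.index[id(tree.root)]

        codes = alignment.to_codes(order=None)
        order = {sid: r for r, sid in enumerate(alignment.ids)}
        self.patterns, self.inverse, self.counts = _compress(codes)
        self.tip_rows = {
            id(n): order[n.name] for n in self.nodes if n.is_tip
        }

        cats = model.rate_categories()
        self.rates = cats.rates
        self.weights = cats.weights
        self.ncat = cats.k
        self.npat = self.patterns.shape[1]
        self.ncol = codes.shape[1]
        self._spectral = model.spectral
        self._dirty = True

    # -- transition matrices ------------------------------------------

    def _pmats(self, t: float) -> np.ndarray:
        """(ncat, 20, 20) transition matrices for branch length t."""
        out = np.empty((self.ncat, 20, 20))
        for c, r in enumerate(self.rates):
            if r == 0.0 or t == 0.0:
                out[c] = np.eye(20)
            else:
                out[c] = self._spectral.transition_matrix(t * r)
        return out

    # -- inside/outside passes ----------------------------------------

    def refresh(self) -> None:
        n_nodes, ncat, npat = len(self.nodes), self.ncat, self.npat
        up = [None] * n_nodes
        upscale = [None] * n_nodes
        msg = [None] * n_nodes       # message from node to its parent
        pmat = [None] * n_nodes

        for i, node in enumerate(self.nodes):
            if node.is_tip:
                row = self.tip_rows[id(node)]
                tipvec = _TIP_PARTIALS[self.patterns[row]]          # (npat, 20)
                up[i] = np.broadcast_to(tipvec, (ncat, npat, 20))
                upscale[i] = np.zeros((ncat, npat))
            else:
                prod = None
                scale = np.zeros((ncat, npat))
                for child in node.children:
                    j = self.index[id(child)]
                    if pmat[j] is None:
                        pmat[j] = self._pmats(child.length)
                    m = np.einsum("cab,cpb->cpa", pmat[j], up[j])
                    msg[j] = m
                    prod = m if prod is None else prod * m
                    scale += upscale[j]
                mx = prod.max(axis=2)
                safe = np.where(mx > 0, mx, 1.0)
                up[i] = prod / safe[:, :, None]
                upscale[i] = scale + np.log(safe)
            if node is not self.tree.root and pmat[i] is None:
                pmat[i] = self._pmats(node.length)

        pi = self.model.pi
        down = [None] * n_nodes
        downscale = [None] * n_nodes
        r = self.root_idx
        down[r] = np.broadcast_to(pi, (ncat, npat, 20))
        downscale[r] = np.zeros((ncat, npat))

        for node in self.tree.preorder():
            i = self.index[id(node)]
            if node.is_tip:
                continue
            kids = [self.index[id(c)] for c in node.children]
            for j in kids:
                rest = down[i].copy()
                scale = downscale[i].copy()
                for j2 in kids:
                    if j2 == j:
                        continue
                    rest *= msg[j2]
                    scale += upscale[j2]
                dv = np.einsum("cpb,cba->cpa", rest, pmat[j])
                mx = dv.max(axis=2)
                safe = np.where(mx > 0, mx, 1.0)
                down[j] = dv / safe[:, :, None]
                downscale[j] = scale + np.log(safe)

        self._up, self._upscale = up, upscale
        self._msg, self._pmat = msg, pmat
        self._down, self._downscale = down, downscale
        self._dirty = False

    def invalidate(self) -> None:
        self._dirty = True

    def _ensure(self) -> None:
        if self._dirty:
            self.refresh()

    # -- likelihood ----------------------------------------------------

    def pattern_logliks(self) -> np.ndarray:
        self._ensure()
        r = self.root_idx
        s = np.einsum("cpa,a->cp", self._up[r], self.model.pi)
        with np.errstate(divide="ignore"):
            terms = np.log(self.weights)[:, None] + np.log(s) + self._upscale[r]
        return _logsumexp0(terms)

    def site_logliks(self) -> np.ndarray:
        return self.pattern_logliks()[self.inverse]

    def loglik(self) -> float:
        return float(self.counts @ self.pattern_logliks())

    # -- marginal posteriors -------------------------------------------

    def node_posteriors(self, node: Node) -> np.ndarray:
        """(ncol, 20) marginal posterior state probabilities at *node*,
        mixing rate categories by their per-site posterior weight."""
        self._ensure()
        i = self.index[id(node)]
        joint = self._up[i] * self._down[i]                      # (ncat, npat, 20)
        ls = self._upscale[i] + self._downscale[i]
        shift = ls.max(axis=0)                                    # (npat,)
        num = np.einsum(
            "c,cpa->pa", self.weights, joint * np.exp(ls - shift)[:, :, None]
        )
        tot = num.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        post = num / tot
        return post[self.inverse]

    # -- single-branch optimisation ------------------------------------

    def edge_context(self, node: Node):
        """Pre-computed vectors for optimising the branch above *node*.

        Returns a function lnL(t) that evaluates the tree likelihood
        with that single branch set to t, everything else fixed.
        """
        if node is self.tree.root:
            raise ValueError("the root has no branch")
        self._ensure()
        i = self.index[id(node)]
        parent = node.parent
        p = self.index[id(parent)]
        kids = [self.index[id(c)] for c in parent.children]
        A = self._down[p].copy()
        Ascale = self._downscale[p].copy()
        for j in kids:
            if j == i:
                continue
            A *= self._msg[j]
            Ascale += self._upscale[j]
        B = self._up[i]
        ls = Ascale + self._upscale[i]
        counts, weights, rates = self.counts, self.weights, self.rates
        spectral = self._spectral

        def lnL(t: float) -> float:
            s = np.empty((self.ncat, self.npat))
            for c, r in enumerate(rates):
                if r == 0.0 or t == 0.0:
                    P = None
                    s[c] = np.einsum("pa,pa->p", A[c], B[c])
                else:
                    P = spectral.transition_matrix(t * r)
                    s[c] = np.einsum("pb,ba,pa->p", A[c], P, B[c])
            with np.errstate(divide="ignore"):
                terms = np.log(weights)[:, None] + np.log(s) + ls
            return float(counts @ _logsumexp0(terms))

        return lnL


def _compress(codes: np.ndarray):
    patterns, inverse, counts = np.unique(
        codes, axis=1, return_inverse=True, return_counts=True
    )
    return patterns, np.asarray(inverse).ravel(), counts.astype(float)


def _logsumexp0(terms: np.ndarray) -> np.ndarray:
    """Log-sum-exp over axis 0, tolerating -inf entries."""
    mx = terms.max(axis=0)
    mx_safe = np.where(np.isfinite(mx), mx, 0.0)
    with np.errstate(invalid="ignore"):
        out = mx_safe + np.log(np.exp(terms - mx_safe).sum(axis=0))
    return out
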