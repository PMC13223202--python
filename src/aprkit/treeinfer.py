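"""Maximum-likelihood tree inference on a fixed alignment.

The search strategy is deliberately simple and fully deterministic:
ML pairwise distances feed a neighbor-joining start tree, branch
lengths are optimised one at a time by bounded Brent search, and the
topology is refined by nearest-neighbor-interchange (NNI) hill
climbing, accepting the single best improving move per iteration.
Nonparametric bootstrap support resamples alignment columns and
repeats the (seeded, bit-reproducible) pipeline per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from ._pruning import PruningEngine
from .evomodel import AAModel, LikelihoodResult
from .seqio import AA_INDEX, Alignment, Sequence
from .tree import Node, PhyloTree, TreeError

__all__ = [
    "DistanceMatrix",
    "BootstrapResult",
    "ml_pairwise_distance",
    "distance_matrix",
    "neighbor_joining",
    "optimize_branch_lengths",
    "nni_search",
    "bootstrap_support",
    "fit_fixed_topology",
]

MAX_DISTANCE = 10.0
MIN_BRANCH = 1e-8


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix/labels size mismatch")
        if not np.array_equal(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.all(np.isfinite(m)):
            raise ValueError("non-finite distances")
        self.matrix = m


@dataclass
class BootstrapResult:
    n_replicates: int
    support: dict[frozenset, float]   # canonical bipartition -> fraction
    seed: int

    def annotate(self, tree: PhyloTree) -> PhyloTree:
        """Copy of *tree* with per-internal-edge support fractions."""
        out = tree.copy()
        all_tips = frozenset(out.tip_labels())
        for node in out.preorder():
            if node.is_tip or node is out.root:
                continue
            side = frozenset(t.name for t in out._subtree_tips(node))
            if len(side) < 2 or len(all_tips - side) < 2:
                continue
            key = PhyloTree._canonical_side(side, all_tips - side)
            node.support = self.support.get(key, 0.0)
        return out


# ---------------------------------------------------------------------------
# ML pairwise distances

def _mixture_joint(model: AAModel, t: float) -> np.ndarray:
    """Symmetrised joint probability sum_c w_c pi_a P_ab(t r_c)."""
    cats = model.rate_categories()
    pi = model.pi
    M = np.zeros((20, 20))
    for r, w in zip(cats.rates, cats.weights):
        if r == 0.0 or t == 0.0:
            M += w * np.diag(pi)
        else:
            J = pi[:, None] * model.spectral.transition_matrix(t * r)
            M += w * 0.5 * (J + J.T)
    return M


def ml_pairwise_distance(seqA: Sequence, seqB: Sequence, model: AAModel) -> float:
    """Maximum-likelihood distance between two aligned sequences.

    Sites where either residue is a gap or 'X' are skipped; the count
    matrix is symmetrised, which together with reversibility makes the
    distance exactly symmetric in its arguments.
    """
    if len(seqA) != len(seqB):
        raise ValueError("sequences must be aligned (equal length)")
    counts = np.zeros((20, 20))
    for a, b in zip(seqA.residues, seqB.residues):
        ia, ib = AA_INDEX.get(a, 20), AA_INDEX.get(b, 20)
        if ia < 20 and ib < 20:
            counts[ia, ib] += 1
    if counts.sum() == 0:
        raise ValueError(
            f"no comparable (co-non-gap) sites between {seqA.id!r} and {seqB.id!r}"
        )
    C = 0.5 * (counts + counts.T)
    mask = C > 0

    def neg_lnL(t: float) -> float:
        M = _mixture_joint(model, t)
        with np.errstate(divide="ignore"):
            lg = np.log(M[mask])
        return -float(np.sum(C[mask] * lg))

    res = minimize_scalar(
        neg_lnL, bounds=(1e-6, MAX_DISTANCE), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def distance_matrix(alignment: Alignment, model: AAModel) -> DistanceMatrix:
    n = len(alignment)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = ml_pairwise_distance(
                alignment.sequences[i], alignment.sequences[j], model
            )
            D[i, j] = D[j, i] = d
    return DistanceMatrix(alignment.ids, D)


# ---------------------------------------------------------------------------
# Neighbor joining

def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Negative branch-length estimates are clamped to 0; ties in the
    Q-criterion break to the lowest (row, col) index pair; the tree is
    returned rooted at the final 3-way join.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [Node(name=lab) for lab in D.labels]
    active = list(range(n))
    d = D.matrix.astype(float).copy()

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (row, col) among ties, in active-index order
        flat = np.argmin(Q)
        qmin = Q.flat[flat]
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=0))
        i_loc, j_loc = min((min(a, b), max(a, b)) for a, b in ties)
        i, j = active[i_loc], active[j_loc]

        dij = d[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        lj = dij - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)

        parent = Node()
        parent.add(nodes[i])
        parent.add(nodes[j])
        new_idx = len(nodes)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new_idx, k] = d[k, new_idx] = 0.5 * (d[i, k] + d[j, k] - dij)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    a, b, c = active
    root = Node()
    nodes[a].length = max(0.5 * (d[a, b] + d[a, c] - d[b, c]), 0.0)
    nodes[b].length = max(0.5 * (d[a, b] + d[b, c] - d[a, c]), 0.0)
    nodes[c].length = max(0.5 * (d[a, c] + d[b, c] - d[a, b]), 0.0)
    for k in (a, b, c):
        root.add(nodes[k])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Branch-length optimisation

def optimize_branch_lengths(
    tree: PhyloTree,
    alignment: Alignment,
    model: AAModel,
    max_sweeps: int = 50,
    tol: float = 1e-6,
    init: float | None = None,
) -> tuple[PhyloTree, LikelihoodResult]:
    """Round-robin single-branch Brent optimisation to a local optimum.

    The log-likelihood is non-decreasing across sweeps; iteration stops
    when a full sweep improves it by less than *tol*.
    """
    work = tree.copy()
    for node in work.preorder():
        if node is work.root or node.length is not None:
            continue
        if init is None:
            raise ValueError("tree has missing branch lengths and no initializer")
        node.length = init
    engine = PruningEngine(work, alignment, model)
    prev = engine.loglik()
    order = [n for n in work.postorder() if n is not work.root]
    for _ in range(max_sweeps):
        for node in order:
            f = engine.edge_context(node)
            cur_val = f(node.length)
            res = minimize_scalar(
                lambda t: -f(t), bounds=(MIN_BRANCH, MAX_DISTANCE),
                method="bounded", options={"xatol": 1e-8},
            )
            if -res.fun > cur_val:
                node.length = float(res.x)
                engine.invalidate()
        cur = engine.loglik()
        if cur - prev < tol:
            break
        prev = cur
    return work, _result(engine, work, model)


def _result(engine: PruningEngine, tree: PhyloTree, model: AAModel) -> LikelihoodResult:
    n_branches = sum(1 for n in tree.preorder() if n is not tree.root)
    npar = (
        n_branches
        + (1 if model.alpha is not None else 0)
        + (1 if model.p_inv > 0 else 0)
        + (19 if model.freq_mode == "observed" else 0)
    )
    return LikelihoodResult(lnL=engine.loglik(), nparams=max(npar, 1))


# ---------------------------------------------------------------------------
# NNI topology search

def _check_binary_unrooted(tree: PhyloTree) -> PhyloTree:
    work = tree.copy()
    if len(work.root.children) == 2:
        work = work.unrooted()
    for node in work.internals():
        expected = 3 if node is work.root else 2
        if node is work.root and work.n_tips == 3:
            expected = 3
        if len(node.children) != expected:
            raise TreeError("NNI requires a binary unrooted tree")
    return work


def _find_edge_child(tree: PhyloTree, side: frozenset) -> Node:
    for node in tree.preorder():
        if node is tree.root or node.is_tip:
            continue
        if frozenset(t.name for t in tree._subtree_tips(node)) == side:
            return node
    raise TreeError(f"no internal edge with side {sorted(side)}")


def _nni_neighbors(tree: PhyloTree, side: frozenset) -> list[PhyloTree]:
    """The two NNI rearrangements across the internal edge whose child
    side (tip set) is *side*."""
    out = []
    for which in (0, 1):
        t = tree.copy()
        v = _find_edge_child(t, side)
        if v.parent is not t.root:
            t = t.rerooted_at(v.parent)
            v = _find_edge_child(t, side)
        u = v.parent  # the root
        others = sorted((c for c in u.children if c is not v), key=t.min_tip)
        w = others[0]
        c = sorted(v.children, key=t.min_tip)[which]
        u.children[u.children.index(w)] = c
        v.children[v.children.index(c)] = w
        c.parent, w.parent = u, v
        out.append(t)
    return out


def _internal_edge_sides(tree: PhyloTree) -> list[frozenset]:
    all_tips = frozenset(tree.tip_labels())
    sides = []
    for node in tree.preorder():
        if node is tree.root or node.is_tip:
            continue
        side = frozenset(t.name for t in tree._subtree_tips(node))
        if len(side) >= 2 and len(all_tips - side) >= 2:
            sides.append(side)
    sides.sort(key=lambda s: (len(s), tuple(sorted(s))))
    return sides


def nni_search(
    tree: PhyloTree,
    alignment: Alignment,
    model: AAModel,
    tol: float = 1e-6,
    max_rounds: int = 50,
) -> tuple[PhyloTree, LikelihoodResult]:
    """NNI hill climbing with full branch-length re-optimisation of
    every candidate rearrangement; deterministic scan order (edges in
    canonical bipartition order), single best improving move accepted
    per round."""
    work = _check_binary_unrooted(tree)
    work, res = optimize_branch_lengths(work, alignment, model, init=0.1)
    for _ in range(max_rounds):
        best_tree, best_res = None, None
        for side in _internal_edge_sides(work):
            for cand in _nni_neighbors(work, side):
                cand_opt, cand_res = optimize_branch_lengths(
                    cand, alignment, model
                )
                if best_res is None or cand_res.lnL > best_res.lnL:
                    best_tree, best_res = cand_opt, cand_res
        if best_res is not None and best_res.lnL > res.lnL + tol:
            work, res = best_tree, best_res
        else:
            break
    return work, res


# ---------------------------------------------------------------------------
# Bootstrap

def bootstrap_support(
    alignment: Alignment,
    model: AAModel,
    tree: PhyloTree,
    n_replicates: int = 500,
    seed: int = 0,
    nni: bool = False,
    opt_sweeps: int = 2,
) -> BootstrapResult:
    """Nonparametric column bootstrap.

    Each replicate resamples ncol columns with replacement from a
    deterministic per-replicate substream of *seed*, reruns ML
    distances + NJ + branch-length optimisation (+ NNI if requested)
    with the point estimates of the model held fixed, and counts
    bipartitions.  Supports are reported for the input tree's internal
    edges.  Replicate branch optimisation is capped at *opt_sweeps*
    sweeps: without NNI the counted bipartitions come from NJ alone,
    so replicate branch lengths need not be polished.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    targets = tree.bipartitions()
    hits = {side: 0 for side in targets}
    ncol = alignment.ncol
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        cols = rng.integers(0, ncol, size=ncol)
        seqs = [
            Sequence(s.id, "".join(s.residues[c] for c in cols))
            for s in alignment.sequences
        ]
        rep_aln = Alignment(seqs)
        D = distance_matrix(rep_aln, model)
        rep_tree = neighbor_joining(D)
        if nni:
            rep_tree, _ = nni_search(rep_tree, rep_aln, model)
        else:
            rep_tree, _ = optimize_branch_lengths(
                rep_tree, rep_aln, model, init=0.1, max_sweeps=opt_sweeps
            )
        found = rep_tree.bipartitions()
        for side in targets:
            if side in found:
                hits[side] += 1
    support = {side: hits[side] / n_replicates for side in targets}
    return BootstrapResult(n_replicates, support, seed)


# ---------------------------------------------------------------------------
# Fixed-topology model fitting (used by AIC model selection)

def fit_fixed_topology(
    tree: PhyloTree,
    alignment: Alignment,
    model: AAModel,
    optimize_alpha: bool = False,
    optimize_pinv: bool = False,
    rounds: int = 4,
    tol: float = 1e-5,
) -> tuple[AAModel, PhyloTree, LikelihoodResult]:
    """Optimise branch lengths and, optionally, gamma shape alpha
    (bounds [0.02, 100]) and invariant fraction p_inv (bounds
    [0, 0.99]) on a fixed topology by coordinate ascent."""
    work = tree.copy()
    cur_model = model
    if not optimize_alpha and not optimize_pinv:
        rounds = 1  # nothing to alternate with
    result = None
    prev = -np.inf
    for _ in range(rounds):
        work, result = optimize_branch_lengths(work, alignment, cur_model, init=0.1)
        if optimize_alpha:
            def neg_a(a):
                m = cur_model.with_params(alpha=float(a))
                return -PruningEngine(work, alignment, m).loglik()
            ra = minimize_scalar(
                neg_a, bounds=(0.02, 100.0), method="bounded",
                options={"xatol": 1e-6},
            )
            if -ra.fun > result.lnL:
                cur_model = cur_model.with_params(alpha=float(ra.x))
        if optimize_pinv:
            def neg_p(p):
                m = cur_model.with_params(p_inv=float(p))
                return -PruningEngine(work, alignment, m).loglik()
            rp = minimize_scalar(
                neg_p, bounds=(0.0, 0.99), method="bounded",
                options={"xatol": 1e-6},
            )
            cand = cur_model.with_params(p_inv=float(rp.x))
            if -rp.fun > PruningEngine(work, alignment, cur_model).loglik():
                cur_model = cand
        lnL = PruningEngine(work, alignment, cur_model).loglik()
        if lnL - prev < tol:
            break
        prev = lnL
    final = PruningEngine(work, alignment, cur_model)
    n_branches = sum(1 for n in work.preorder() if n is not work.root)
    npar = (
        n_branches
        + (1 if cur_model.alpha is not None else 0)
        + (1 if cur_model.p_inv > 0 else 0)
        + (19 if cur_model.freq_mode == "observed" else 0)
    )
    return cur_model, work, LikelihoodResult(lnL=final.loglik(), nparams=max(npar, 1))
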