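"""Independent brute-force oracles used by the test suite.

These deliberately avoid the pruning recursion and its scaling
machinery: the likelihood is computed by enumerating every joint
assignment of states to internal nodes, with plain gather/product
arithmetic.  Feasible only for tiny trees, which is the point.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from aprkit.seqio import AA_INDEX


def _edge_pmats(tree, model, rate):
    return {
        id(n): model.transition_matrix(n.length, rate)
        for n in tree.preorder() if n.parent is not None
    }


def _assignments(n_internal):
    A = np.array(
        list(itertools.product(range(20), repeat=n_internal)), dtype=np.int64
    )
    return A.reshape(-1, n_internal)


def joint_site_weights(tree, aln, model, col):
    """(n_assignments, n_internal) assignment array and the per-assignment
    joint probability P(data, internal states) at alignment column *col*
    (0-based), summed over rate categories."""
    internals = [n for n in tree.preorder() if not n.is_tip]
    idx = {id(n): i for i, n in enumerate(internals)}
    A = _assignments(len(internals))
    cats = model.rate_categories()
    obs = {s.id: AA_INDEX.get(s.residues[col], 20) for s in aln.sequences}
    pi = model.pi
    total = np.zeros(len(A))
    for rate, w in zip(cats.rates, cats.weights):
        P = _edge_pmats(tree, model, rate)
        p = pi[A[:, idx[id(tree.root)]]].copy()
        for n in tree.preorder():
            if n.parent is None:
                continue
            pa = A[:, idx[id(n.parent)]]
            if n.is_tip:
                o = obs[n.name]
                if o < 20:
                    p *= P[id(n)][pa, o]
            else:
                p *= P[id(n)][pa, A[:, idx[id(n)]]]
        total += w * p
    return A, total, internals


def brute_loglik(tree, aln, model):
    out = 0.0
    for col in range(aln.ncol):
        _, joint, _ = joint_site_weights(tree, aln, model, col)
        out += np.log(joint.sum())
    return out


def brute_posteriors(tree, aln, model):
    """dict id(node) -> (ncol, 20) posterior for every internal node."""
    internals = [n for n in tree.preorder() if not n.is_tip]
    out = {id(n): np.zeros((aln.ncol, 20)) for n in internals}
    for col in range(aln.ncol):
        A, joint, internals = joint_site_weights(tree, aln, model, col)
        z = joint.sum()
        for i, n in enumerate(internals):
            acc = np.zeros(20)
            np.add.at(acc, A[:, i], joint)
            out[id(n)][col] = acc / z
    return out


def brute_best_via_path(G: nx.Graph, s: str, t: str, via: str):
    """Minimum-hop simple path s->t through *via*, ties by maximum
    cumulative strength then lexicographic; full enumeration."""
    best = None
    for path in nx.all_simple_paths(G, s, t):
        if via not in path:
            continue
        strength = sum(G[a][b]["strength"] for a, b in zip(path, path[1:]))
        key = (len(path), -strength, path)
        if best is None or key < best:
            best = key
    return None if best is None else best[2]


def brute_best_path(G: nx.Graph, s: str, t: str):
    best = None
    for path in nx.all_simple_paths(G, s, t):
        strength = sum(G[a][b]["strength"] for a, b in zip(path, path[1:]))
        key = (len(path), -strength, path)
        if best is None or key < best:
            best = key
    return None if best is None else best[2]


def gamma_category_means_numeric(alpha: float, k: int) -> np.ndarray:
    """Mean rate per equal-probability gamma slab by direct numerical
    integration of x * pdf(x) (mean-1 parameterisation)."""
    from scipy import integrate, stats

    dist = stats.gamma(a=alpha, scale=1.0 / alpha)
    edges = [dist.ppf(i / k) for i in range(k + 1)]
    edges[0], edges[-1] = 0.0, np.inf
    rates = []
    for a, b in zip(edges[:-1], edges[1:]):
        val, _ = integrate.quad(lambda x: x * dist.pdf(x), a, b, limit=200)
        rates.append(val * k)
    return np.asarray(rates)
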