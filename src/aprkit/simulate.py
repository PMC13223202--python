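"""Synthetic-data generation.

Two generators back the whole test surface of the toolkit:

* sequence evolution along a tree under a reversible amino-acid model
  with discrete-gamma (+ invariant) site rates, recording the true
  state at every internal node so ancestral-reconstruction accuracy
  can be measured against ground truth;
* toy protein structures with planted heavy-atom contacts at exact
  distances (and optional ligand groups), emitted as fixed-column PDB
  text, so contact and network code can be validated against known
  geometry.

Randomness comes from a single seeded numpy Generator with a
documented draw order: per-site rate categories first, then the root
states, then child states branch by branch in preorder (within a
branch, draws are grouped by rate category and parent state).  Replay
with the same seed is bit-identical.  Indels are not simulated: the
analyses treat gaps as missing data, so a gap process would add no
tested behaviour (gaps can be planted by masking downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ancestor import NodeLabeling
from .evomodel import AAModel
from .seqio import AA_ORDER, Alignment, Sequence, Structure, read_pdb
from .tree import Node, PhyloTree

__all__ = [
    "SimulationResult",
    "simulate_alignment",
    "random_tree",
    "StructureSpec",
    "synthetic_structure",
    "SimulationError",
]


class SimulationError(ValueError):
    pass


@dataclass
class SimulationResult:
    alignment: Alignment                 # tip sequences
    ancestors: dict[int, Sequence]       # node id -> true ancestral sequence
    tree: PhyloTree
    model: AAModel
    site_categories: np.ndarray          # per-site rate-category index
    seed: int
    labeling: NodeLabeling = field(repr=False, default=None)


def simulate_alignment(tree: PhyloTree, model: AAModel, ncol: int,
                       seed: int = 0) -> SimulationResult:
    """Evolve *ncol* sites along *tree* under *model*, recording every
    internal-node state."""
    if ncol < 1:
        raise ValueError("ncol must be >= 1")
    for node in tree.preorder():
        if node is not tree.root and node.length is None:
            raise ValueError("tree has missing branch lengths")

    rng = np.random.default_rng(seed)
    cats = model.rate_categories()
    site_cat = rng.choice(cats.k, size=ncol, p=cats.weights)
    pi = model.pi
    states: dict[int, np.ndarray] = {}
    states[id(tree.root)] = rng.choice(20, size=ncol, p=pi)

    pcache: dict[tuple[float, int], np.ndarray] = {}

    def pmat(t: float, c: int) -> np.ndarray:
        key = (t, c)
        if key not in pcache:
            P = model.transition_matrix(t, cats.rates[c])
            # exact row-stochastic for sampling
            pcache[key] = P / P.sum(axis=1, keepdims=True)
        return pcache[key]

    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_states = states[id(node.parent)]
        child = np.empty(ncol, dtype=np.int64)
        for c in range(cats.k):
            in_cat = site_cat == c
            if not in_cat.any():
                continue
            P = pmat(node.length, c)
            for a in range(20):
                sel = in_cat & (parent_states == a)
                n = int(sel.sum())
                if n:
                    child[sel] = rng.choice(20, size=n, p=P[a])
        states[id(node)] = child

    labeling = NodeLabeling(tree)
    tips = [
        Sequence(n.name, _decode(states[id(n)]))
        for n in tree.tips()
    ]
    ancestors = {
        nid: Sequence(f"node{nid}", _decode(states[id(labeling.node(nid))]))
        for nid in labeling.internal_ids
    }
    return SimulationResult(
        alignment=Alignment(tips),
        ancestors=ancestors,
        tree=tree,
        model=model,
        site_categories=site_cat,
        seed=seed,
        labeling=labeling,
    )


def _decode(codes: np.ndarray) -> str:
    return "".join(AA_ORDER[c] for c in codes)


def random_tree(ntips: int, branch_range: tuple[float, float] = (0.05, 0.5),
                seed: int = 0) -> PhyloTree:
    """Uniform random binary (unrooted) topology by sequential random
    edge attachment; branch lengths uniform in *branch_range*; tips
    labelled T1..Tn."""
    if ntips < 3:
        raise ValueError("ntips must be >= 3")
    lo, hi = branch_range
    if not (0 <= lo <= hi) or hi <= 0:
        raise ValueError(f"degenerate branch range {branch_range}")
    rng = np.random.default_rng(seed)

    root = Node()
    for i in range(3):
        root.add(Node(name=f"T{i + 1}"))
    edges = list(root.children)  # any non-root node defines an edge
    for i in range(3, ntips):
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        mid = Node()
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add(target)
        tip = mid.add(Node(name=f"T{i + 1}"))
        edges.extend([mid, tip])
    tree = PhyloTree(root)
    for node in tree.preorder():
        if node is not tree.root:
            node.length = float(rng.uniform(lo, hi))
    return tree


# ---------------------------------------------------------------------------
# Toy structures with planted contacts

@dataclass
class StructureSpec:
    """Geometry request for a synthetic structure.

    ``residues``: list of (resname, n_atoms) — each residue gets a CA
    at its centre plus side-chain atoms.  ``contacts``: (i, j, dist)
    with 1-based residue indices: the minimum heavy-atom distance
    between the two residues will equal *dist* (within 0.01 A).
    ``ligand_distances``: (i, dist) pairs planting the minimum
    distance between the ligand group and residue i.
    """

    residues: list[tuple[str, int]]
    contacts: list[tuple[int, int, float]] = field(default_factory=list)
    ligand_name: str | None = None
    ligand_distances: list[tuple[int, float]] = field(default_factory=list)
    chain: str = "A"
    separation: float = 50.0


_SIDE_NAMES = ["CB", "CG", "CD", "CE", "CZ"]


def _side_name(k: int) -> str:
    return _SIDE_NAMES[k] if k < len(_SIDE_NAMES) else f"C{k + 1}"


def synthetic_structure(spec: StructureSpec, seed: int = 0,
                        path: str | None = None) -> tuple[Structure, str]:
    """Build PDB text realising *spec* and parse it back.

    Returns ``(structure, pdb_text)``; if *path* is given the text is
    also written there.  Raises :class:`SimulationError` when the
    requested distances cannot be realised (verified after placement).
    """
    n = len(spec.residues)
    if n < 1:
        raise SimulationError("need at least one residue")
    for i, j, d in spec.contacts:
        if not (1 <= i <= n and 1 <= j <= n) or i == j:
            raise SimulationError(f"bad contact pair ({i}, {j})")
        if d <= 0:
            raise SimulationError("contact distance must be > 0")

    # residue centres on a circle whose chord between neighbours is the
    # requested separation
    R = spec.separation / (2 * np.sin(np.pi / max(n, 3)))
    centres = np.array([
        [R * np.cos(2 * np.pi * i / max(n, 3)), R * np.sin(2 * np.pi * i / max(n, 3)), 0.0]
        for i in range(n)
    ])

    side_positions: list[list[np.ndarray]] = [[] for _ in range(n)]
    used: list[int] = [0] * n

    def take_slot(i: int) -> int:
        _, n_atoms = spec.residues[i]
        if used[i] >= n_atoms - 1:
            raise SimulationError(
                f"residue {i + 1} has too few atoms for its planted contacts"
            )
        used[i] += 1
        return used[i] - 1

    planted: list[list[np.ndarray]] = [[] for _ in range(n)]
    for i1, j1, d in spec.contacts:
        i, j = i1 - 1, j1 - 1
        ci, cj = centres[i], centres[j]
        u = (cj - ci) / np.linalg.norm(cj - ci)
        m = 0.5 * (ci + cj)
        take_slot(i)
        take_slot(j)
        planted[i].append(m - 0.5 * d * u)
        planted[j].append(m + 0.5 * d * u)

    # remaining side-chain atoms hug the centre along z
    for i in range(n):
        _, n_atoms = spec.residues[i]
        n_free = n_atoms - 1 - len(planted[i])
        side_positions[i] = planted[i] + [
            centres[i] + np.array([0.0, 0.0, 0.4 * (k + 1)])
            for k in range(n_free)
        ]

    lig_atoms: list[np.ndarray] = []
    for i1, d in spec.ligand_distances:
        if spec.ligand_name is None:
            raise SimulationError("ligand distances given but no ligand_name")
        i = i1 - 1
        ci = centres[i]
        inward = -ci / np.linalg.norm(ci)
        lig_atoms.append(ci + inward * d)
    if spec.ligand_name is not None and not lig_atoms:
        lig_atoms.append(np.zeros(3))

    lines = []
    serial = 1
    for i, (resname, _) in enumerate(spec.residues):
        atoms = [("CA", centres[i])] + [
            (_side_name(k), pos) for k, pos in enumerate(side_positions[i])
        ]
        for name, pos in atoms:
            lines.append(_pdb_line("ATOM", serial, name, resname, spec.chain,
                                   i + 1, pos))
            serial += 1
    for k, pos in enumerate(lig_atoms):
        lines.append(_pdb_line("HETATM", serial, _side_name(k), spec.ligand_name,
                               "L", 900 + k, pos, element="C"))
        serial += 1
    lines.append("END")
    text = "\n".join(lines) + "\n"

    import io
    import tempfile, os
    if path is not None:
        with open(path, "w", newline="\n") as fh:
            fh.write(text)
        structure = read_pdb(path, name="synthetic")
    else:
        with tempfile.NamedTemporaryFile(
            "w", suffix=".pdb", delete=False, newline="\n"
        ) as fh:
            fh.write(text)
            tmp = fh.name
        try:
            structure = read_pdb(tmp, name="synthetic")
        finally:
            os.unlink(tmp)

    _verify(structure, spec)
    return structure, text


def _pdb_line(record: str, serial: int, name: str, resname: str, chain: str,
              resseq: int, pos: np.ndarray, element: str = "C") -> str:
    return (
        f"{record:<6}{serial:>5} {name:<4}{resname:>4} {chain}{resseq:>4}    "
        f"{pos[0]:>8.3f}{pos[1]:>8.3f}{pos[2]:>8.3f}{1.0:>6.2f}{0.0:>6.2f}"
        f"          {element:>2}"
    )


def _verify(structure: Structure, spec: StructureSpec, tol: float = 0.01) -> None:
    from scipy.spatial.distance import cdist

    prot = structure.protein_residues()
    for i1, j1, d in spec.contacts:
        a, b = prot[i1 - 1], prot[j1 - 1]
        got = float(cdist(a.coords(), b.coords()).min())
        if abs(got - d) > tol:
            raise SimulationError(
                f"infeasible spec: contact {i1}-{j1} requested {d:.3f} A, "
                f"achieved {got:.3f} A"
            )
    if spec.ligand_name:
        lig = np.vstack([
            r.coords() for r in structure.ligand_groups()[spec.ligand_name]
        ])
        for i1, d in spec.ligand_distances:
            got = float(cdist(prot[i1 - 1].coords(), lig).min())
            if abs(got - d) > tol:
                raise SimulationError(
                    f"infeasible spec: ligand-residue {i1} requested {d:.3f} A, "
                    f"achieved {got:.3f} A"
                )
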