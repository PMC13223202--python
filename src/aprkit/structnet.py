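"""Structure-based contact and network analyses.

Three layers, all on heavy atoms only:

* ligand contacts — protein residues with any heavy atom within a
  cutoff (default 4 Å) of any ligand heavy atom; backbone atoms count,
  since backbone-mediated substrate contacts are real (e.g. glycines).
* residue contact pairs — all pairs between two residue selections
  with minimum heavy-atom distance within a cutoff (default 6 Å).
* protein structure network (PSN) — residues as nodes (side-chain
  heavy atoms; Calpha stands in for glycine), edges weighted by the
  interaction strength I_ij = 100 * n_ij / sqrt(N_i * N_j) where n_ij
  counts inter-residue atom pairs within the atom cutoff (default 3 Å)
  and N_i is the node's atom count (an override table may be supplied
  where tabulated normalisation factors are preferred).  Sequence
  neighbours (|i - j| <= 1 within a chain) are excluded.  Shortest
  communication pathways are minimum-hop paths, ties broken by maximum
  cumulative strength, optionally constrained to pass through given
  residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .seqio import Residue, Structure

__all__ = [
    "ContactSet",
    "PathSet",
    "ligand_contacts",
    "residue_contact_pairs",
    "build_psn",
    "communication_paths",
    "reached_targets",
]

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass
class ContactSet:
    ligand: str
    cutoff: float
    contacts: list[tuple[str, str, str, float]]  # (chain, resnum, resname, min dist)

    @property
    def residue_numbers(self) -> list[int]:
        return [int("".join(ch for ch in num if ch.isdigit() or ch == "-"))
                for _, num, _, _ in self.contacts]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.contacts, columns=["chain", "residue", "resname", "min_distance"]
        )


@dataclass
class PathSet:
    paths: list[list[str]]                 # residue keys "chain:number"
    strengths: list[float] = field(default_factory=list)
    via: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.paths)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "path": [" -> ".join(p) for p in self.paths],
            "hops": [len(p) - 1 for p in self.paths],
            "strength": self.strengths,
        })


def _min_distance(res_a: Residue, res_b: Residue,
                  names_a=None, names_b=None) -> float:
    ca = res_a.coords(names_a)
    cb = res_b.coords(names_b)
    if ca.size == 0 or cb.size == 0:
        return np.inf
    return float(cdist(ca, cb).min())


def ligand_contacts(structure: Structure, ligand_name: str,
                    cutoff: float = 4.0) -> ContactSet:
    """Protein residues with any heavy atom within *cutoff* of any
    heavy atom of the named ligand group."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    groups = structure.ligand_groups()
    if ligand_name not in groups:
        raise KeyError(
            f"ligand {ligand_name!r} not in structure "
            f"(available: {sorted(groups)})"
        )
    lig_coords = np.vstack([r.coords() for r in groups[ligand_name]])
    contacts = []
    for res in structure.protein_residues():
        dmin = float(cdist(res.coords(), lig_coords).min())
        if dmin <= cutoff:
            contacts.append((res.chain, res.number, res.name, dmin))
    contacts.sort(key=lambda c: (c[0], _numkey(c[1])))
    return ContactSet(ligand_name, cutoff, contacts)


def _numkey(resnum: str):
    digits = "".join(ch for ch in resnum if ch.isdigit() or ch == "-")
    suffix = "".join(ch for ch in resnum if ch.isalpha())
    return (int(digits), suffix)


def _resolve(structure: Structure, selector, chain: str | None) -> list[Residue]:
    """Residue selector: an int/str residue number, a Residue, or an
    iterable of those."""
    if isinstance(selector, Residue):
        return [selector]
    if isinstance(selector, (int, str)):
        selector = [selector]
    out = []
    residues = structure.protein_residues(chain)
    by_number = {r.number: r for r in residues}
    for item in selector:
        if isinstance(item, Residue):
            out.append(item)
            continue
        key = str(item)
        if key not in by_number:
            raise KeyError(f"residue {key!r} not found"
                           + (f" in chain {chain}" if chain else ""))
        out.append(by_number[key])
    return out


def residue_contact_pairs(
    structure: Structure,
    setA,
    setB,
    cutoff: float = 6.0,
    chain: str | None = None,
) -> pd.DataFrame:
    """All (a in A, b in B) residue pairs with minimum heavy-atom
    distance <= cutoff, with that distance per pair."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    A = _resolve(structure, setA, chain)
    B = _resolve(structure, setB, chain)
    rows = []
    for a in A:
        for b in B:
            if a is b:
                continue
            d = _min_distance(a, b)
            if d <= cutoff:
                rows.append({
                    "res_a": f"{a.chain}:{a.number}", "name_a": a.name,
                    "res_b": f"{b.chain}:{b.number}", "name_b": b.name,
                    "min_distance": d,
                })
    return pd.DataFrame(rows, columns=["res_a", "name_a", "res_b", "name_b", "min_distance"])


def _node_atoms(res: Residue) -> list:
    """PSN node atom set: side-chain heavy atoms; Calpha for glycine."""
    side = [a for a in res.atoms if a.name not in BACKBONE_ATOMS]
    if not side:
        side = [a for a in res.atoms if a.name == "CA"]
    return side


def build_psn(
    structure: Structure,
    atom_cutoff: float = 3.0,
    i_min: float = 0.0,
    chain: str | None = None,
    normalization: dict[str, float] | None = None,
) -> nx.Graph:
    """Protein structure network as a networkx Graph.

    Node keys are "chain:number"; node attributes: resname, n_atoms.
    Edge attributes: n_pairs (atom pairs within *atom_cutoff*) and
    strength I_ij = 100 * n_pairs / sqrt(N_i * N_j); edges are kept
    when I_ij > i_min.  *normalization* optionally overrides N per
    residue name (webPSN-style tabulated factors).
    """
    if atom_cutoff <= 0:
        raise ValueError("atom_cutoff must be > 0")
    if i_min < 0:
        raise ValueError("i_min must be >= 0")
    if chain is None:
        chains = structure.chains
        protein_chains = [
            c for c in chains if structure.protein_residues(c)
        ]
        chain = protein_chains[0] if protein_chains else None
    residues = structure.protein_residues(chain)
    if not residues:
        raise ValueError("no protein residues in structure")

    G = nx.Graph()
    atom_sets, norms = [], []
    for res in residues:
        atoms = _node_atoms(res)
        key = f"{res.chain}:{res.number}"
        N = (normalization or {}).get(res.name, float(len(atoms)))
        G.add_node(key, resname=res.name, n_atoms=len(atoms), seqnum=res.seqnum)
        atom_sets.append(np.array([[a.x, a.y, a.z] for a in atoms]).reshape(-1, 3))
        norms.append(N)

    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            ri, rj = residues[i], residues[j]
            if abs(ri.seqnum - rj.seqnum) <= 1 and ri.chain == rj.chain:
                continue  # sequence neighbours excluded
            if atom_sets[i].size == 0 or atom_sets[j].size == 0:
                continue
            n_pairs = int((cdist(atom_sets[i], atom_sets[j]) <= atom_cutoff).sum())
            if n_pairs == 0:
                continue
            if norms[i] <= 0 or norms[j] <= 0:
                continue
            strength = 100.0 * n_pairs / np.sqrt(norms[i] * norms[j])
            if strength > i_min:
                G.add_edge(
                    f"{ri.chain}:{ri.number}", f"{rj.chain}:{rj.number}",
                    n_pairs=n_pairs, strength=strength,
                )
    return G


def _path_strength(G: nx.Graph, path: list[str]) -> float:
    return sum(G[a][b]["strength"] for a, b in zip(path, path[1:]))


def _best_constrained_path(G: nx.Graph, s: str, t: str, via: str):
    """Minimum-hop simple path s -> t passing through *via*; ties by
    maximum cumulative strength, then lexicographic.  Iterative
    deepening from the unconstrained lower bound."""
    try:
        lower = nx.shortest_path_length(G, s, via) + nx.shortest_path_length(G, via, t)
    except nx.NetworkXNoPath:
        return None
    n_nodes = G.number_of_nodes()
    for limit in range(lower, n_nodes):
        best = None
        for path in nx.all_simple_paths(G, s, t, cutoff=limit):
            if via not in path:
                continue
            key = (len(path), -_path_strength(G, path), path)
            if best is None or key < best:
                best = key
        if best is not None:
            return best[2]
    return None


def _best_path(G: nx.Graph, s: str, t: str):
    if not nx.has_path(G, s, t):
        return None
    best = None
    for path in nx.all_shortest_paths(G, s, t):
        key = (len(path), -_path_strength(G, path), path)
        if best is None or key < best:
            best = key
    return best[2]


def communication_paths(
    network: nx.Graph,
    sources,
    targets,
    via=None,
) -> PathSet:
    """Shortest communication pathways from *sources* to *targets*.

    Shortest = minimum hop count; ties break to maximum cumulative
    strength, then lexicographically.  With *via* residues given, one
    best path is reported per (source, target, via-node) combination,
    each required to pass through that via node and remain simple.
    Disconnected pairs and via nodes absent from the network are
    skipped (empty result rather than an error).  Output order is
    deterministic (sorted by path node lists).
    """
    sources = [sources] if isinstance(sources, str) else sorted(sources)
    targets = [targets] if isinstance(targets, str) else sorted(targets)
    if not sources or not targets:
        raise ValueError("sources and targets must be non-empty")
    vias = None
    if via is not None:
        vias = [via] if isinstance(via, str) else sorted(via)
        vias = [v for v in vias if v in network]

    seen: set[tuple] = set()
    paths: list[list[str]] = []
    for s in sources:
        if s not in network:
            continue
        for t in targets:
            if t not in network or s == t:
                continue
            if vias is None:
                p = _best_path(network, s, t)
                cands = [p] if p else []
            else:
                cands = []
                for v in vias:
                    p = (_best_path(network, s, t) if v in (s, t)
                         else _best_constrained_path(network, s, t, v))
                    if p:
                        cands.append(p)
            for p in cands:
                key = tuple(p)
                if key not in seen:
                    seen.add(key)
                    paths.append(p)
    paths.sort()
    return PathSet(
        paths=paths,
        strengths=[_path_strength(network, p) for p in paths],
        via=vias or [],
    )


def reached_targets(pathset: PathSet, targets) -> list[str]:
    """Sorted, de-duplicated subset of *targets* appearing in any path."""
    targets = {targets} if isinstance(targets, str) else set(targets)
    hit = set()
    for p in pathset.paths:
        hit.update(t for t in targets if t in p)
    return sorted(hit)
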