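"""Sequence, alignment and structure I/O.

Readers and writers for the plain-text formats used throughout the
toolkit: FASTA, interleaved PHYLIP, Newick, PAML-style amino-acid
exchangeability files (``.dat``) and fixed-column PDB.  Also hosts the
residue-numbering bookkeeping (:class:`ResidueNumberMap`) that lets
downstream analyses translate between alignment columns and the
ungapped residue numbering of any member sequence.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO as _BioSeqIO

__all__ = [
    "AA_ORDER",
    "AA_INDEX",
    "Sequence",
    "Alignment",
    "ResidueNumberMap",
    "Atom",
    "Residue",
    "Structure",
    "SeqIOError",
    "read_fasta",
    "write_fasta",
    "read_phylip_interleaved",
    "write_phylip_interleaved",
    "read_newick",
    "write_newick",
    "read_exchangeability_dat",
    "read_pdb",
]

#: Canonical one-letter amino-acid order (PAML / .dat file convention).
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

#: Characters treated as missing data in likelihood computations.
MISSING_CHARS = frozenset("-X")

_VALID_CHARS = frozenset(AA_ORDER) | MISSING_CHARS


class SeqIOError(ValueError):
    """Malformed input file or violated format contract."""


@dataclass(frozen=True)
class Sequence:
    """A named protein sequence, possibly gapped.

    ``residues`` is an uppercase string over the 20 one-letter codes
    plus ``-`` (gap) and ``X`` (unknown residue, treated as missing
    data downstream).
    """

    id: str
    residues: str

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise SeqIOError(f"sequence id must be a non-empty token, got {self.id!r}")
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) < 1:
            raise SeqIOError(f"sequence {self.id!r} is empty")
        for pos, c in enumerate(self.residues, start=1):
            if c not in _VALID_CHARS:
                raise SeqIOError(
                    f"illegal residue character {c!r} at position {pos} of sequence {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace("-", "")


class Alignment:
    """An ordered collection of equal-length gapped sequences."""

    def __init__(self, sequences: list[Sequence]):
        if len(sequences) < 2:
            raise SeqIOError("an alignment needs at least 2 sequences")
        ncol = len(sequences[0])
        for s in sequences:
            if len(s) != ncol:
                raise SeqIOError(
                    f"sequence {s.id!r} has length {len(s)}, expected {ncol}"
                )
        ids = [s.id for s in sequences]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SeqIOError(f"duplicate sequence ids: {dup}")
        self.sequences = list(sequences)
        self.ncol = ncol
        self._by_id = {s.id: s for s in sequences}

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, seq_id: str) -> Sequence:
        try:
            return self._by_id[seq_id]
        except KeyError:
            raise KeyError(f"no sequence with id {seq_id!r} in alignment") from None

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment) and self.sequences == other.sequences
        )

    def column(self, col: int) -> str:
        """Residues of 1-based column *col*, in sequence order."""
        if not 1 <= col <= self.ncol:
            raise IndexError(f"column {col} outside 1..{self.ncol}")
        return "".join(s.residues[col - 1] for s in self.sequences)

    def drop_all_gap_columns(self) -> "Alignment":
        """Return a copy without columns that are gaps in every sequence."""
        keep = [
            c for c in range(self.ncol)
            if any(s.residues[c] != "-" for s in self.sequences)
        ]
        if len(keep) == self.ncol:
            return self
        return Alignment(
            [Sequence(s.id, "".join(s.residues[c] for c in keep)) for s in self.sequences]
        )

    def to_codes(self, order: list[str] | None = None) -> np.ndarray:
        """Integer matrix (ntaxa, ncol): 0..19 per AA_ORDER, 20 for gap/X.

        *order* selects/reorders rows by sequence id.
        """
        ids = order if order is not None else self.ids
        out = np.empty((len(ids), self.ncol), dtype=np.int8)
        for r, sid in enumerate(ids):
            seq = self[sid].residues
            out[r] = [AA_INDEX.get(c, 20) for c in seq]
        return out

    def number_map(self, seq_id: str) -> "ResidueNumberMap":
        return ResidueNumberMap(self[seq_id])


class ResidueNumberMap:
    """Bidirectional map between 1-based alignment columns and 1-based
    ungapped residue numbers of one aligned sequence."""

    def __init__(self, sequence: Sequence):
        self.seq_id = sequence.id
        self._col_of_res: dict[int, int] = {}
        self._res_of_col: dict[int, int] = {}
        res = 0
        for col, c in enumerate(sequence.residues, start=1):
            if c != "-":
                res += 1
                self._col_of_res[res] = col
                self._res_of_col[col] = res
        self.nres = res

    def column(self, residue_number: int) -> int:
        """Alignment column holding ungapped residue *residue_number*."""
        try:
            return self._col_of_res[residue_number]
        except KeyError:
            raise KeyError(
                f"{self.seq_id}: no residue number {residue_number} (1..{self.nres})"
            ) from None

    def residue(self, column: int) -> int | None:
        """Ungapped residue number at alignment *column*; None at a gap."""
        return self._res_of_col.get(column)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> list[Sequence]:
    records = list(_BioSeqIO.parse(str(path), "fasta"))
    if not records:
        raise SeqIOError(f"no FASTA records in {path}")
    seqs = [Sequence(r.id, str(r.seq)) for r in records]
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise SeqIOError(f"duplicate ids in {path}: {dup}")
    return seqs


def write_fasta(seqs: list[Sequence], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w", newline="\n") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# PHYLIP interleaved ("relaxed-strict" dialect: names left-justified in a
# 10-character field, sequence text in blocks of 60 columns, blank line
# between blocks)

_PHYLIP_NAME_WIDTH = 10
_PHYLIP_BLOCK = 60


def write_phylip_interleaved(aln: Alignment, path: str | os.PathLike) -> None:
    names = []
    for s in aln.sequences:
        name = s.id[:_PHYLIP_NAME_WIDTH]
        names.append(name)
    if len(set(names)) != len(names):
        raise SeqIOError("sequence ids collide after 10-character truncation")
    with open(path, "w", newline="\n") as fh:
        fh.write(f" {len(aln)} {aln.ncol}\n")
        for start in range(0, aln.ncol, _PHYLIP_BLOCK):
            if start:
                fh.write("\n")
            for name, s in zip(names, aln.sequences):
                chunk = s.residues[start:start + _PHYLIP_BLOCK]
                prefix = name.ljust(_PHYLIP_NAME_WIDTH) if start == 0 else " " * _PHYLIP_NAME_WIDTH
                fh.write(prefix + chunk + "\n")


def read_phylip_interleaved(path: str | os.PathLike) -> Alignment:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise SeqIOError(f"empty PHYLIP file {path}")
    header = lines[0].split()
    if len(header) != 2 or not all(tok.isdigit() for tok in header):
        raise SeqIOError(f"bad PHYLIP header line {lines[0]!r}")
    ntaxa, ncol = int(header[0]), int(header[1])
    body = [ln for ln in lines[1:] if ln.strip()]
    if len(body) % ntaxa != 0:
        raise SeqIOError(
            f"PHYLIP body has {len(body)} sequence lines, not a multiple of {ntaxa} taxa"
        )
    nblocks = len(body) // ntaxa
    names: list[str] = []
    parts: list[list[str]] = [[] for _ in range(ntaxa)]
    for b in range(nblocks):
        for i in range(ntaxa):
            line = body[b * ntaxa + i]
            if b == 0:
                name = line[:_PHYLIP_NAME_WIDTH].strip()
                if not name:
                    raise SeqIOError(f"missing taxon name on line {line!r}")
                names.append(name)
            chunk = line[_PHYLIP_NAME_WIDTH:].replace(" ", "")
            parts[i].append(chunk)
    seqs = []
    for name, chunks in zip(names, parts):
        residues = "".join(chunks)
        if len(residues) != ncol:
            raise SeqIOError(
                f"taxon {name!r}: {len(residues)} columns, header promised {ncol}"
            )
        seqs.append(Sequence(name, residues))
    if len(seqs) != ntaxa:
        raise SeqIOError(f"found {len(seqs)} taxa, header promised {ntaxa}")
    return Alignment(seqs)


# ---------------------------------------------------------------------------
# Newick (delegates to the tree module; re-exported here so all formats
# share one entry point)

def read_newick(text_or_path: str):
    from .tree import PhyloTree

    text = text_or_path
    if os.path.exists(text_or_path) and not text_or_path.strip().startswith("("):
        with open(text_or_path) as fh:
            text = fh.read()
    return PhyloTree.from_newick(text)


def write_newick(tree, path: str | os.PathLike | None = None) -> str:
    text = tree.to_newick()
    if path is not None:
        with open(path, "w", newline="\n") as fh:
            fh.write(text + "\n")
    return text


# ---------------------------------------------------------------------------
# PAML-style exchangeability .dat files

def read_exchangeability_dat(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Read a PAML-layout amino-acid model file.

    Layout: 190 lower-triangle exchangeabilities (rows 2..20 of a
    20x20 symmetric matrix, row by row) followed by 20 equilibrium
    frequencies, whitespace/newline separated.  Returns ``(S, pi)``
    with S symmetric, zero diagonal, and pi renormalised to sum to 1
    (accepted only if the file's values sum to 1 +/- 1e-4).
    """
    with open(path) as fh:
        tokens = fh.read().split()
    try:
        values = [float(t) for t in tokens]
    except ValueError as e:
        raise SeqIOError(f"non-numeric token in {path}: {e}") from None
    if len(values) < 210:
        raise SeqIOError(
            f"{path}: expected 190 exchangeabilities + 20 frequencies, got {len(values)} numbers"
        )
    tri, freqs = values[:190], values[190:210]
    if any(v < 0 for v in tri):
        raise SeqIOError(f"{path}: negative exchangeability")
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = tri[k]
            k += 1
    pi = np.asarray(freqs, dtype=float)
    if np.any(pi < 0):
        raise SeqIOError(f"{path}: negative frequency")
    total = pi.sum()
    if abs(total - 1.0) > 1e-4:
        raise SeqIOError(f"{path}: frequencies sum to {total:.6f}, outside 1 +/- 1e-4")
    pi = pi / total
    return S, pi


# ---------------------------------------------------------------------------
# PDB

@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Residue:
    chain: str
    number: str          # author residue number with insertion code appended
    name: str
    atoms: list[Atom] = field(default_factory=list)
    is_ligand: bool = False

    @property
    def seqnum(self) -> int:
        """Numeric part of the residue number (insertion code stripped)."""
        digits = "".join(c for c in self.number if c.isdigit() or c == "-")
        return int(digits)

    def coords(self, atom_names: set[str] | None = None) -> np.ndarray:
        atoms = self.atoms if atom_names is None else [
            a for a in self.atoms if a.name in atom_names
        ]
        return np.array([[a.x, a.y, a.z] for a in atoms]).reshape(-1, 3)


@dataclass
class Structure:
    """Heavy-atom protein structure with ligand groups.

    Waters and hydrogens are removed during parsing; alternate
    locations other than blank/'A' are dropped.  Residue identity is
    the author residue number with any insertion code appended, which
    preserves the original numbering without renumbering.
    """

    name: str
    residues: list[Residue]

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain, None)
        return list(seen)

    def protein_residues(self, chain: str | None = None) -> list[Residue]:
        return [
            r for r in self.residues
            if not r.is_ligand and (chain is None or r.chain == chain)
        ]

    def ligand_groups(self) -> dict[str, list[Residue]]:
        groups: dict[str, list[Residue]] = {}
        for r in self.residues:
            if r.is_ligand:
                groups.setdefault(r.name, []).append(r)
        return groups

    def find(self, chain: str, number: int | str) -> Residue:
        key = str(number)
        for r in self.residues:
            if r.chain == chain and r.number == key:
                return r
        raise KeyError(f"residue {chain}/{number} not in structure {self.name}")


_WATER_NAMES = {"HOH", "WAT", "DOD"}


def read_pdb(path: str | os.PathLike, name: str | None = None) -> Structure:
    """Parse a fixed-column PDB file into a heavy-atom :class:`Structure`."""
    import gemmi

    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise SeqIOError(f"{path}: no models")
    model = st[0]
    residues: list[Residue] = []
    n_atoms = 0
    for chain in model:
        for res in chain:
            if res.name in _WATER_NAMES or res.is_water():
                continue
            is_ligand = res.het_flag == "H"
            number = f"{res.seqid.num}{res.seqid.icode.strip()}"
            atoms = []
            for atom in res:
                if atom.is_hydrogen():
                    continue
                if atom.altloc not in ("", "\0", "A"):
                    continue
                atoms.append(
                    Atom(atom.name, atom.element.name, atom.pos.x, atom.pos.y, atom.pos.z)
                )
            if atoms:
                residues.append(Residue(chain.name, number, res.name, atoms, is_ligand))
                n_atoms += len(atoms)
    if n_atoms == 0:
        raise SeqIOError(f"{path}: no ATOM records survive filtering")
    return Structure(name or os.path.basename(str(path)), residues)
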