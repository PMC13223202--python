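"""Family-level sequence statistics.

Pairwise percent identity (denominator: columns where both sequences
have a residue), per-column conservation and sequence-logo information
content, clade-restricted conservation of a reference position, and
divergent-position reports with residue-number translation between
sequences (e.g. mapping an ancestral position onto the numbering of a
human orthologue).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import AA_ORDER, Alignment, Sequence

__all__ = [
    "percent_identity",
    "identity_matrix",
    "conservation_profile",
    "clade_conservation",
    "divergent_positions",
]

MAX_IC_BITS = float(np.log2(20))


def percent_identity(seqA: Sequence, seqB: Sequence) -> float:
    """100 x identical co-non-gap pairs / co-non-gap columns.

    'X' never counts as identical (unknown residues match nothing).
    """
    if len(seqA) != len(seqB):
        raise ValueError("sequences must be aligned (equal length)")
    both = ident = 0
    for a, b in zip(seqA.residues, seqB.residues):
        if a == "-" or b == "-":
            continue
        both += 1
        if a == b and a != "X":
            ident += 1
    if both == 0:
        raise ValueError(
            f"no co-non-gap columns between {seqA.id!r} and {seqB.id!r}"
        )
    return 100.0 * ident / both


def identity_matrix(alignment: Alignment) -> pd.DataFrame:
    """Symmetric percent-identity matrix (diagonal exactly 100)."""
    ids = alignment.ids
    n = len(ids)
    M = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = percent_identity(
                alignment.sequences[i], alignment.sequences[j]
            )
    return pd.DataFrame(M, index=ids, columns=ids)


def conservation_profile(alignment: Alignment) -> pd.DataFrame:
    """Per-column residue frequencies (gaps excluded), consensus and
    information content.

    IC = log2(20) - H where H is the Shannon entropy (bits) of the
    non-gap residue frequencies; no small-sample correction.  All-gap
    columns get IC 0 and consensus '-'.  Columns are 1-based.
    """
    rows = []
    for col in range(1, alignment.ncol + 1):
        residues = [c for c in alignment.column(col) if c != "-"]
        counted = [c for c in residues if c != "X"]
        freqs = np.zeros(20)
        if counted:
            for c in counted:
                freqs[AA_ORDER.index(c)] += 1
            freqs /= freqs.sum()
            nz = freqs[freqs > 0]
            ic = MAX_IC_BITS + float(np.sum(nz * np.log2(nz)))
            best = int(np.argmax(freqs))
            consensus = AA_ORDER[best]
            fraction = float(freqs[best])
        else:
            ic, consensus, fraction = 0.0, "-", 0.0
        row = {"column": col, "consensus": consensus,
               "consensus_fraction": fraction, "ic_bits": max(ic, 0.0)}
        row.update({f"f_{a}": freqs[i] for i, a in enumerate(AA_ORDER)})
        rows.append(row)
    return pd.DataFrame(rows)


def clade_conservation(
    alignment: Alignment,
    clade_ids: list[str],
    reference_id: str,
    reference_position: int,
    count_gaps_as_mismatch: bool = False,
) -> float:
    """Percent of clade sequences matching the reference residue at the
    reference sequence's ungapped position *reference_position*.

    By default only clade sequences with a residue at that column enter
    the denominator; with *count_gaps_as_mismatch* gapped sequences
    count as mismatches.
    """
    for cid in clade_ids:
        if cid not in alignment:
            raise KeyError(f"clade id {cid!r} not in alignment")
    refmap = alignment.number_map(reference_id)
    col = refmap.column(reference_position)
    ref_res = alignment[reference_id].residues[col - 1]
    if ref_res == "-":
        raise ValueError(
            f"reference position {reference_position} is gapped in {reference_id!r}"
        )
    match = total = 0
    for cid in clade_ids:
        res = alignment[cid].residues[col - 1]
        if res == "-":
            if count_gaps_as_mismatch:
                total += 1
            continue
        total += 1
        if res == ref_res:
            match += 1
    if total == 0:
        raise ValueError("no clade sequence has a residue at that column")
    return 100.0 * match / total


def divergent_positions(
    alignment: Alignment,
    idA: str,
    idB: str,
    numbering_reference: str | None = None,
) -> pd.DataFrame:
    """All co-non-gap columns where sequences A and B differ.

    Reports, per divergent column, the 1-based alignment column, the
    two residues, and each sequence's own ungapped residue number.  An
    optional third sequence adds a translated numbering column (NaN
    where that sequence is gapped), enabling statements like
    "ancestral position 253 corresponds to human 244".
    """
    a, b = alignment[idA], alignment[idB]
    map_a = alignment.number_map(idA)
    map_b = alignment.number_map(idB)
    if numbering_reference in (idA, idB):
        numbering_reference = None  # its numbering is already a column
    map_r = alignment.number_map(numbering_reference) if numbering_reference else None
    rows = []
    for col in range(1, alignment.ncol + 1):
        ra, rb = a.residues[col - 1], b.residues[col - 1]
        if ra == "-" or rb == "-" or ra == rb:
            continue
        row = {
            "column": col,
            f"res_{idA}": ra,
            f"res_{idB}": rb,
            f"pos_{idA}": map_a.residue(col),
            f"pos_{idB}": map_b.residue(col),
        }
        if map_r is not None:
            row[f"pos_{numbering_reference}"] = map_r.residue(col)
        rows.append(row)
    cols = ["column", f"res_{idA}", f"res_{idB}", f"pos_{idA}", f"pos_{idB}"]
    if numbering_reference:
        cols.append(f"pos_{numbering_reference}")
    return pd.DataFrame(rows, columns=cols)
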