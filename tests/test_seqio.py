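import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aprkit import seqio
from aprkit.seqio import (
    AA_ORDER, Alignment, ResidueNumberMap, Sequence, SeqIOError,
    read_exchangeability_dat, read_fasta, read_newick, read_pdb,
    read_phylip_interleaved, write_fasta, write_newick,
    write_phylip_interleaved,
)
from aprkit.tree import PhyloTree, TreeError

ids_st = st.text(alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghij0123456789_",
                 min_size=1, max_size=8)
residues_st = st.text(alphabet=AA_ORDER + "-X", min_size=1, max_size=40)


class TestFasta:
    def test_minimal_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nMKV\n")
        assert read_fasta(p) == [Sequence("a", "MKV")]

    def test_case_normalization(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nmkv\n")
        assert read_fasta(p)[0].residues == "MKV"

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(SeqIOError):
            read_fasta(p)

    def test_duplicate_ids_error(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nMK\n>a\nVV\n")
        with pytest.raises(SeqIOError, match="duplicate"):
            read_fasta(p)

    def test_illegal_residue_reports_position(self):
        with pytest.raises(SeqIOError, match="position 2"):
            Sequence("a", "MOV")

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(
        st.tuples(ids_st, residues_st), min_size=1, max_size=6,
        unique_by=lambda t: t[0],
    ))
    def test_round_trip(self, tmp_path_factory, records):
        seqs = [Sequence(i, r) for i, r in records]
        p = tmp_path_factory.mktemp("fa") / "x.fasta"
        write_fasta(seqs, p)
        assert read_fasta(p) == seqs


class TestPhylip:
    def test_minimal_file(self, tmp_path):
        p = tmp_path / "a.phy"
        p.write_text(" 2 4\nA         MK-V\nB         MKAV\n")
        aln = read_phylip_interleaved(p)
        assert aln.ncol == 4 and aln.ids == ["A", "B"]

    def test_header_mismatch_errors(self, tmp_path):
        p = tmp_path / "a.phy"
        p.write_text(" 3 4\nA         MK-V\nB         MKAV\n")
        with pytest.raises(SeqIOError):
            read_phylip_interleaved(p)

    def test_truncation_collision_errors(self, tmp_path):
        seqs = [Sequence("longname" + s, "MKV") for s in ("AAA", "AAB")]
        with pytest.raises(SeqIOError, match="collide"):
            write_phylip_interleaved(Alignment(seqs), tmp_path / "x.phy")

    def test_blocking_dialect(self, tmp_path):
        aln = Alignment([Sequence("A", "M" * 130), Sequence("B", "K" * 130)])
        p = tmp_path / "x.phy"
        write_phylip_interleaved(aln, p)
        lines = p.read_text().splitlines()
        assert lines[0].split() == ["2", "130"]
        assert lines[1].startswith("A".ljust(10)) and len(lines[1]) == 70
        assert lines[3] == ""  # blank line between blocks
        assert read_phylip_interleaved(p) == aln

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.lists(ids_st, min_size=2, max_size=6, unique=True),
        st.integers(min_value=1, max_value=150),
        st.randoms(use_true_random=False),
    )
    def test_round_trip(self, tmp_path_factory, names, ncol, rnd):
        seqs = [
            Sequence(n, "".join(rnd.choice(AA_ORDER + "-X") for _ in range(ncol)))
            for n in names
        ]
        p = tmp_path_factory.mktemp("phy") / "x.phy"
        write_phylip_interleaved(Alignment(seqs), p)
        assert read_phylip_interleaved(p) == Alignment(seqs)


class TestNewick:
    def test_small_tree(self):
        t = read_newick("((A:1,B:2):1,C:3);")
        assert t.n_tips == 3 and len(t.internals()) == 2

    def test_missing_lengths_flagged(self):
        t = read_newick("(A,B);")
        assert not t.has_branch_lengths()

    def test_unbalanced_parens(self):
        with pytest.raises(TreeError):
            read_newick("((A:1,B:2):1,C:3;")

    def test_duplicate_tips(self):
        with pytest.raises(TreeError, match="duplicate"):
            read_newick("((A:1,A:2):1,C:3);")

    def test_negative_length(self):
        with pytest.raises(TreeError, match="negative"):
            read_newick("((A:1,B:-2):1,C:3);")

    def test_support_values_parsed(self):
        t = read_newick("((A:1,B:2)95:1,C:3);")
        internal = [n for n in t.internals() if n is not t.root][0]
        assert internal.support == 95.0

    def test_round_trip_42_tips(self):
        from aprkit.simulate import random_tree

        t = random_tree(42, seed=9)
        text = write_newick(t)
        t2 = read_newick(text)
        assert t2.bipartitions() == t.bipartitions()
        lengths1 = sorted(n.length for n in t.preorder() if n.parent)
        lengths2 = sorted(n.length for n in t2.preorder() if n.parent)
        assert all(
            math.isclose(a, b, rel_tol=1e-9) for a, b in zip(lengths1, lengths2)
        )

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(min_value=3, max_value=20), st.integers(0, 10_000))
    def test_round_trip_random(self, ntips, seed):
        from aprkit.simulate import random_tree

        t = random_tree(ntips, seed=seed)
        text1 = write_newick(t)
        assert write_newick(read_newick(text1)) == text1


class TestExchangeabilityDat:
    def test_wrong_count_errors(self, tmp_path):
        p = tmp_path / "toy.dat"
        p.write_text("0.5 0.5\n")
        with pytest.raises(SeqIOError, match="190"):
            read_exchangeability_dat(p)

    def test_uniform_file(self, tmp_path):
        p = tmp_path / "uni.dat"
        p.write_text(" ".join(["1.0"] * 190) + "\n" + " ".join(["0.05"] * 20) + "\n")
        S, pi = read_exchangeability_dat(p)
        assert np.all(S[~np.eye(20, dtype=bool)] == 1.0)
        assert np.allclose(pi, 0.05)

    def test_lg_matrix(self):
        from aprkit.evomodel import load_matrix

        S, pi = load_matrix("LG")
        assert np.allclose(S, S.T) and np.all(np.diag(S) == 0)
        assert abs(pi.sum() - 1.0) < 1e-12
        # spot-check against the published LG values
        assert S[1, 0] == pytest.approx(0.425093, abs=1e-6)   # R-A
        assert pi[0] == pytest.approx(0.079066, abs=1e-4)     # freq(A)

    def test_bad_frequency_sum(self, tmp_path):
        p = tmp_path / "bad.dat"
        p.write_text(" ".join(["1.0"] * 190) + "\n" + " ".join(["0.06"] * 20) + "\n")
        with pytest.raises(SeqIOError, match="sum"):
            read_exchangeability_dat(p)


PDB_SNIPPET = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  HA  ALA A   1      12.000   7.000  -5.000  1.00  0.00           H
ATOM      4  CA AGLY A   2      12.685   7.166  -5.263  1.00  0.00           C
ATOM      5  CA BGLY A   2      99.000  99.000  99.000  1.00  0.00           C
ATOM      6  CA  SER A   3      14.000   8.000  -5.000  1.00  0.00           C
HETATM    7  O   HOH A 101      20.000  20.000  20.000  1.00  0.00           O
HETATM    8  C1  DMF A 201       0.000   0.000   0.000  1.00  0.00           C
END
"""


class TestPdb:
    def test_synthetic_three_residues(self, tmp_path):
        p = tmp_path / "x.pdb"
        p.write_text(PDB_SNIPPET)
        st_ = read_pdb(p)
        prot = st_.protein_residues()
        assert len(prot) == 3
        # waters and hydrogens dropped, altloc B dropped
        assert sum(len(r.atoms) for r in prot) == 4
        assert list(st_.ligand_groups()) == ["DMF"]

    def test_no_atoms_errors(self, tmp_path):
        p = tmp_path / "x.pdb"
        p.write_text("REMARK nothing\nEND\n")
        with pytest.raises(SeqIOError):
            read_pdb(p)


class TestResidueNumberMap:
    def test_round_trip_property(self):
        seq = Sequence("s", "MK--VW-A")
        m = ResidueNumberMap(seq)
        for col in range(1, len(seq) + 1):
            r = m.residue(col)
            if seq.residues[col - 1] == "-":
                assert r is None
            else:
                assert m.column(r) == col

    def test_known_numbers(self):
        m = ResidueNumberMap(Sequence("s", "-MK-V"))
        assert m.residue(2) == 1 and m.column(3) == 5
        assert m.nres == 3


class TestAlignment:
    def test_ragged_rejected(self):
        with pytest.raises(SeqIOError):
            Alignment([Sequence("a", "MK"), Sequence("b", "MKV")])

    def test_all_gap_column_removal(self):
        aln = Alignment([Sequence("a", "M-K"), Sequence("b", "V-W")])
        clean = aln.drop_all_gap_columns()
        assert clean.ncol == 2
        assert clean["a"].residues == "MK"
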