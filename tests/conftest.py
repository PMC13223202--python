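import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from aprkit.evomodel import AAModel, load_matrix
from aprkit.seqio import AA_ORDER, Alignment, Sequence
from aprkit.tree import PhyloTree


@pytest.fixture(scope="session")
def uniform_model():
    S = np.ones((20, 20))
    np.fill_diagonal(S, 0.0)
    return AAModel("uniform", S, np.full(20, 0.05))


@pytest.fixture(scope="session")
def lg_model():
    return AAModel("LG", *load_matrix("LG"))


@pytest.fixture(scope="session")
def lg_gamma_model():
    return AAModel("LG", *load_matrix("LG"), alpha=1.0)


@pytest.fixture
def quartet_tree():
    return PhyloTree.from_newick("((A:0.3,B:0.5):0.2,(C:0.1,D:0.7):0.4);")


@pytest.fixture
def quartet_alignment():
    rng = np.random.default_rng(7)
    seqs = []
    for name in "ABCD":
        res = "".join(rng.choice(list(AA_ORDER + "-"), size=6))
        seqs.append(Sequence(name, res))
    return Alignment(seqs)


def random_models(n, seed, k_choices=(1, 2, 3), with_inv=True):
    """Random reversible AA models for oracle comparisons."""
    rng = np.random.default_rng(seed)
    models = []
    for i in range(n):
        S = rng.uniform(0.05, 2.0, (20, 20))
        S = 0.5 * (S + S.T)
        np.fill_diagonal(S, 0.0)
        pi = rng.dirichlet(np.full(20, 5.0))
        alpha = float(rng.uniform(0.3, 2.0)) if rng.random() < 0.7 else None
        p_inv = float(rng.uniform(0.0, 0.3)) if (with_inv and rng.random() < 0.5) else 0.0
        k = int(rng.choice(k_choices))
        models.append(AAModel(f"rand{i}", S, pi, alpha=alpha, p_inv=p_inv, k=k))
    return models


def random_alignment(names, ncol, seed, gap_frac=0.1):
    rng = np.random.default_rng(seed)
    chars = list(AA_ORDER)
    seqs = []
    for name in names:
        res = [
            "-" if rng.random() < gap_frac else str(rng.choice(chars))
            for _ in range(ncol)
        ]
        seqs.append(Sequence(name, "".join(res)))
    aln = Alignment(seqs)
    # ensure no all-gap column
    return aln.drop_all_gap_columns()
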