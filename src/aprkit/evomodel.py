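"""Amino-acid substitution models.

A reversible 20-state model is assembled from a symmetric
exchangeability matrix ``S`` and equilibrium frequencies ``pi`` as

    q_ij = S_ij * pi_j   (i != j),     q_ii = -sum_j q_ij,

rescaled so the expected substitution rate at equilibrium,
``-sum_i pi_i q_ii``, is exactly 1: branch lengths are then expected
substitutions per site.  Among-site rate variation is modelled by the
discrete-gamma approximation (k equal-probability categories, each
represented by its conditional mean rate) optionally mixed with a
zero-rate invariant-sites class; the composite category mean is kept
at exactly 1 so the branch-length scale is unchanged.

Transition probabilities P(t) = expm(Q t) are computed through the
symmetrised eigendecomposition: with D = diag(sqrt(pi)),
B = D Q D^-1 is symmetric, so Q = D^-1 (V L V') D with an orthogonal V
and real eigenvalues L, and P(t) = D^-1 V exp(L t) V' D.

Model choice follows the usual AIC ranking: each candidate
exchangeability matrix is fitted (branch lengths plus alpha and/or
p_inv) on a fixed topology and scored with AIC = 2k - 2 lnL.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammainc, gammaincinv

from .seqio import AA_ORDER, read_exchangeability_dat

__all__ = [
    "AAModel",
    "RateCategories",
    "LikelihoodResult",
    "build_rate_matrix",
    "transition_matrix",
    "Spectral",
    "discrete_gamma_rates",
    "apply_invariant",
    "aic",
    "load_matrix",
    "available_matrices",
    "observed_frequencies",
    "select_model",
]

BUILTIN_MATRICES = ("LG", "WAG", "JTT", "Dayhoff")


@dataclass(frozen=True)
class RateCategories:
    """Discrete rate mixture: non-negative rates with probabilities
    summing to 1 and mean rate exactly 1."""

    rates: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rates, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if r.shape != w.shape or r.ndim != 1:
            raise ValueError("rates and weights must be equal-length 1-D arrays")
        if np.any(r < 0) or np.any(w < 0):
            raise ValueError("negative rate or weight")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "rates", r)
        object.__setattr__(self, "weights", w)

    @property
    def k(self) -> int:
        return len(self.rates)

    @property
    def mean(self) -> float:
        return float(self.rates @ self.weights)


@dataclass
class LikelihoodResult:
    lnL: float
    nparams: int
    per_site_lnL: np.ndarray | None = None

    def __post_init__(self):
        if not np.isfinite(self.lnL):
            raise ValueError(f"non-finite log-likelihood {self.lnL}")
        if self.nparams < 1:
            raise ValueError("nparams must be >= 1")


def build_rate_matrix(S: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Reversible rate matrix from exchangeabilities and frequencies,
    scaled to one expected substitution per unit branch length."""
    S = np.asarray(S, dtype=float)
    pi = np.asarray(pi, dtype=float)
    n = len(pi)
    if S.shape != (n, n) or not np.allclose(S, S.T):
        raise ValueError("S must be symmetric")
    if np.any(pi <= 0):
        raise ValueError("equilibrium frequencies must be strictly positive")
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(pi @ np.diag(Q))
    if mu <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return Q / mu


class Spectral:
    """Cached symmetrised eigendecomposition of a reversible Q."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        pi = np.asarray(pi, dtype=float)
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]
        B = 0.5 * (B + B.T)  # enforce exact symmetry before eigh
        lam, V = np.linalg.eigh(B)
        if not np.all(np.isfinite(lam)):
            raise ValueError("non-finite eigenvalues")
        self.pi = pi
        self._d = d
        self._lam = lam
        self._V = V

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError(f"negative time {t}")
        E = (self._V * np.exp(self._lam * t)) @ self._V.T
        E = 0.5 * (E + E.T)  # keep sqrt(pi_i pi_j)-symmetry exact
        P = (E / self._d[:, None]) * self._d[None, :]
        np.clip(P, 0.0, 1.0, out=P)
        return P


def transition_matrix(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t) for a reversible Q, via :class:`Spectral`."""
    return Spectral(Q, pi).transition_matrix(t)


def discrete_gamma_rates(alpha: float, k: int) -> RateCategories:
    """Yang-style discrete gamma: k equal-probability categories, each
    carrying the mean of the unit-mean gamma(alpha) within its
    inter-quantile slab."""
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be > 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return RateCategories(np.array([1.0]), np.array([1.0]))
    # boundaries of Gamma(shape=alpha, rate=alpha) slabs
    qs = np.arange(1, k) / k
    bounds = gammaincinv(alpha, qs) / alpha
    edges = np.concatenate([[0.0], bounds, [np.inf]])
    # E[X; a<X<b] for unit-mean gamma = F_{alpha+1}(alpha*b) - F_{alpha+1}(alpha*a)
    upper = np.where(np.isinf(edges[1:]), 1.0, gammainc(alpha + 1, alpha * edges[1:]))
    lower = gammainc(alpha + 1, alpha * edges[:-1])
    rates = k * (upper - lower)
    weights = np.full(k, 1.0 / k)
    rates = rates / (rates @ weights)  # exact unit mean
    return RateCategories(rates, weights)


def apply_invariant(p_inv: float, cats: RateCategories) -> RateCategories:
    """Mix a zero-rate invariant class of weight p_inv into *cats*,
    rescaling the variable-rate categories so the mean stays 1."""
    if not 0.0 <= p_inv < 1.0:
        raise ValueError("p_inv must be in [0, 1)")
    if p_inv == 0.0:
        return cats
    rates = np.concatenate([[0.0], cats.rates / (1.0 - p_inv)])
    weights = np.concatenate([[p_inv], cats.weights * (1.0 - p_inv)])
    rates = rates.copy()
    mean = rates @ weights
    rates[1:] /= mean  # exact unit mean after floating-point composition
    return RateCategories(rates, weights)


def aic(lnL: float, nparams: int) -> float:
    if not np.isfinite(lnL):
        raise ValueError("non-finite lnL")
    if nparams < 1:
        raise ValueError("nparams must be >= 1")
    return 2.0 * nparams - 2.0 * lnL


@dataclass(frozen=True)
class AAModel:
    """A fully specified amino-acid substitution model."""

    name: str
    S: np.ndarray
    pi: np.ndarray
    alpha: float | None = None
    p_inv: float = 0.0
    k: int = 4
    freq_mode: str = "model"  # "model" | "observed"
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if np.any(np.asarray(self.pi) <= 0):
            raise ValueError("pi must be strictly positive")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError("p_inv must be in [0, 1)")

    @property
    def label(self) -> str:
        s = self.name
        if self.alpha is not None:
            s += "+G"
        if self.p_inv > 0:
            s += "+I"
        if self.freq_mode == "observed":
            s += "+F"
        return s

    @property
    def Q(self) -> np.ndarray:
        if "Q" not in self._cache:
            self._cache["Q"] = build_rate_matrix(self.S, self.pi)
        return self._cache["Q"]

    @property
    def spectral(self) -> Spectral:
        if "spec" not in self._cache:
            self._cache["spec"] = Spectral(self.Q, self.pi)
        return self._cache["spec"]

    def rate_categories(self) -> RateCategories:
        if self.alpha is None:
            cats = RateCategories(np.array([1.0]), np.array([1.0]))
        else:
            cats = discrete_gamma_rates(self.alpha, self.k)
        return apply_invariant(self.p_inv, cats)

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        if rate == 0.0 or t == 0.0:
            return np.eye(len(self.pi))
        return self.spectral.transition_matrix(t * rate)

    def with_params(self, **kw) -> "AAModel":
        return replace(self, _cache={}, **kw)


def load_matrix(name_or_path: str) -> tuple[np.ndarray, np.ndarray]:
    """Load a built-in matrix by name (LG, WAG, JTT, Dayhoff) or any
    PAML-style .dat file by path."""
    key = name_or_path.lower()
    if key in {m.lower() for m in BUILTIN_MATRICES}:
        ref = importlib.resources.files("aprkit.data") / f"{key}.dat"
        with importlib.resources.as_file(ref) as path:
            return read_exchangeability_dat(path)
    return read_exchangeability_dat(name_or_path)


def available_matrices() -> tuple[str, ...]:
    return BUILTIN_MATRICES


def observed_frequencies(alignment) -> np.ndarray:
    """Equilibrium frequencies counted from the alignment's non-gap,
    non-X residues (no pseudocount)."""
    counts = np.zeros(20)
    for seq in alignment.sequences:
        for c in seq.residues:
            i = AA_ORDER.find(c)
            if i >= 0:
                counts[i] += 1
    if np.any(counts == 0):
        missing = [AA_ORDER[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(
            f"observed frequencies contain zeros for {missing}; +F unusable here"
        )
    return counts / counts.sum()


def select_model(
    alignment,
    tree,
    candidates: list[str] | None = None,
    plus_gamma: bool = True,
    plus_inv: bool = True,
    plus_f: bool = False,
    k: int = 4,
) -> tuple[AAModel, pd.DataFrame]:
    """AIC model selection over candidate matrices and +G/+I/+F options.

    Branch lengths and, where applicable, alpha and p_inv are optimised
    on the fixed input topology for every candidate x option
    combination.  Free-parameter count: (2n - 3) branch lengths, plus
    1 for +G, 1 for +I, 19 for +F.  Returns the minimum-AIC model and
    the full ranking table (sorted by AIC ascending).
    """
    from .treeinfer import fit_fixed_topology

    if candidates is None:
        candidates = list(BUILTIN_MATRICES)
    if not candidates:
        raise ValueError("empty candidate list")
    missing = set(tree.tip_labels()) ^ set(alignment.ids)
    if missing:
        raise ValueError(f"tree/alignment label mismatch: {sorted(missing)}")

    n = tree.n_tips
    base_params = 2 * n - 3
    freq_modes = ["model"] + (["observed"] if plus_f else [])
    gamma_opts = [False, True] if plus_gamma else [False]
    inv_opts = [False, True] if plus_inv else [False]

    rows = []
    fitted: dict[str, AAModel] = {}
    for cand in candidates:
        S, pi_model = load_matrix(cand)
        for fmode in freq_modes:
            pi = observed_frequencies(alignment) if fmode == "observed" else pi_model
            for g in gamma_opts:
                for i_opt in inv_opts:
                    model = AAModel(
                        name=cand, S=S, pi=pi,
                        alpha=1.0 if g else None,
                        p_inv=0.05 if i_opt else 0.0,
                        k=k, freq_mode=fmode,
                    )
                    fit_model, _, res = fit_fixed_topology(
                        tree, alignment, model,
                        optimize_alpha=g, optimize_pinv=i_opt,
                    )
                    npar = base_params + int(g) + int(i_opt) + (19 if fmode == "observed" else 0)
                    rows.append({
                        "matrix": cand,
                        "options": fit_model.label[len(cand):] or "-",
                        "lnL": res.lnL,
                        "nparams": npar,
                        "AIC": aic(res.lnL, npar),
                    })
                    fitted[fit_model.label] = fit_model

    table = pd.DataFrame(rows).sort_values("AIC", kind="stable").reset_index(drop=True)
    table["dAIC"] = table["AIC"] - table["AIC"].iloc[0]
    best_row = table.iloc[0]
    best_label = best_row["matrix"] + (best_row["options"] if best_row["options"] != "-" else "")
    return fitted[best_label], table
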