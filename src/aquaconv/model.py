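"""Empirical amino-acid substitution models with discrete-gamma rate variation.

The model is the standard time-reversible 20-state CTMC: a symmetric
exchangeability matrix ``S`` (here JTT) combined with equilibrium frequencies
``pi``, giving the rate matrix

    Q_ij = S_ij * pi_j    (i != j),   Q_ii = -sum_{j != i} Q_ij,

normalised so that the expected substitution rate at equilibrium,
``-sum_i pi_i Q_ii``, equals one — branch lengths are then expected
substitutions per site.  Among-site rate variation uses Yang's discrete
approximation to a Gamma(alpha, alpha) distribution: K equiprobable
categories, each represented by its conditional mean rate.

Frequencies may be the model's own ("model" mode) or estimated from the
analysed gene alignment ("empirical", the "+F" convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

__all__ = [
    "SubstitutionModel",
    "jtt_exchangeabilities",
    "jtt_frequencies",
    "build_rate_matrix",
    "gamma_category_rates",
]

_N_STATES = 20


def _load_jtt() -> tuple[np.ndarray, np.ndarray]:
    text = resources.files("aquaconv.data").joinpath("jtt.dat").read_text()
    rows = [ln.split() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    S = np.zeros((_N_STATES, _N_STATES))
    for i, row in enumerate(rows[:-1], start=1):
        vals = [float(x) for x in row]
        S[i, : len(vals)] = vals
        S[: len(vals), i] = vals
    freqs = np.array([float(x) for x in rows[-1]])
    return S, freqs / freqs.sum()


_JTT_S, _JTT_PI = _load_jtt()


def jtt_exchangeabilities() -> np.ndarray:
    """The JTT symmetric exchangeability matrix (zero diagonal)."""
    return _JTT_S.copy()


def jtt_frequencies() -> np.ndarray:
    """JTT model equilibrium frequencies."""
    return _JTT_PI.copy()


def build_rate_matrix(S: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Assemble and normalise the reversible rate matrix Q from S and pi.

    Q satisfies detailed balance (pi_i Q_ij = pi_j Q_ji) by construction and
    is scaled to one expected substitution per site per unit time.
    """
    S = np.asarray(S, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0):
        raise ValueError("equilibrium frequencies must be strictly positive")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("equilibrium frequencies must sum to 1")
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    if mu <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return Q / mu


def gamma_category_rates(alpha: float, K: int = 4) -> np.ndarray:
    """Mean rates of the K equiprobable categories of Gamma(alpha, alpha).

    The gamma is cut at its K-quantiles and each category represented by its
    conditional mean, computed in closed form from the regularised incomplete
    gamma function; the category means average to 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be > 0")
    if K < 1:
        raise ValueError("need at least one rate category")
    if K == 1:
        return np.ones(1)
    cuts = gamma_dist.ppf(np.arange(1, K) / K, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], cuts, [np.inf]])
    # E[X | a < X < b] for X~Gamma(alpha, rate alpha) via the alpha+1 CDF
    upper = gammainc(alpha + 1, alpha * edges[1:])
    lower = gammainc(alpha + 1, alpha * edges[:-1])
    return K * (upper - lower)


@dataclass
class SubstitutionModel:
    """JTT(+F) with K-category discrete-gamma rates.

    Parameters
    ----------
    pi : equilibrium frequencies; defaults to the JTT model frequencies.
    alpha : gamma shape for among-site rate variation.
    n_categories : number of equiprobable rate categories K.
    """

    pi: np.ndarray = field(default_factory=jtt_frequencies)
    alpha: float = 1.0
    n_categories: int = 4
    S: np.ndarray = field(default_factory=jtt_exchangeabilities)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.Q = build_rate_matrix(self.S, self.pi)
        self.rates = gamma_category_rates(self.alpha, self.n_categories)
        # reversible Q is similar to a symmetric matrix; eigendecompose once
        d = np.sqrt(self.pi)
        B = (self.Q * d[:, None]) / d[None, :]
        B = (B + B.T) / 2.0
        w, U = np.linalg.eigh(B)
        self._eigval = w
        self._left = U.T * d[None, :]        # U^T D^{1/2}
        self._right = U / d[:, None]         # D^{-1/2} U

    @classmethod
    def jtt(cls, alpha: float = 1.0, n_categories: int = 4) -> "SubstitutionModel":
        return cls(alpha=alpha, n_categories=n_categories)

    @classmethod
    def jtt_f(cls, aln, alpha: float = 1.0, n_categories: int = 4) -> "SubstitutionModel":
        """JTT exchangeabilities with frequencies taken from the gene ("+F")."""
        from .alignment import empirical_frequencies

        return cls(pi=empirical_frequencies(aln), alpha=alpha, n_categories=n_categories)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); row-stochastic for all t >= 0."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        if t == 0.0:
            return np.eye(_N_STATES)
        P = (self._right * np.exp(self._eigval * t)[None, :]) @ self._left
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=1, keepdims=True)

    def transition_matrices(self, t: float) -> np.ndarray:
        """(K, 20, 20) stack of P(r_k * t), one per rate category."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        if t == 0.0:
            return np.broadcast_to(np.eye(_N_STATES), (self.n_categories, _N_STATES, _N_STATES)).copy()
        expwt = np.exp(np.outer(self.rates * t, self._eigval))  # (K, 20)
        P = (self._right[None, :, :] * expwt[:, None, :]) @ self._left
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=2, keepdims=True)
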