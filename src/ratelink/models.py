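"""Substitution models: GTR+G+I for nucleotides and Mk+G for characters.

Rate matrices are scaled so the mean instantaneous rate at stationarity is
1, making branch lengths expected numbers of changes per site/character.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

__all__ = [
    "NucModelParams",
    "MorphModelParams",
    "discrete_gamma_rates",
    "DEFAULT_GTR",
]

NUC_STATES = "ACGT"


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean rates of ``n_categories`` equal-probability bins of Gamma(shape, mean 1).

    Uses the category-mean discretization: the mean of the distribution
    within each quantile bin, which averages exactly to 1.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    if n_categories < 1:
        raise ValueError("need at least one category")
    if n_categories == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.arange(1, n_categories) / n_categories, a=shape, scale=1.0 / shape)
    upper = gammainc(shape + 1, np.concatenate([edges * shape, [np.inf]]))
    lower = gammainc(shape + 1, np.concatenate([[0.0], edges * shape]))
    return n_categories * (upper - lower)


@dataclass(frozen=True)
class NucModelParams:
    """GTR+G+I parameterization.

    ``exchangeabilities`` are the six symmetric rates in the order
    AC, AG, AT, CG, CT, GT.
    """

    exchangeabilities: tuple = (1.0, 2.0, 1.0, 1.0, 4.0, 1.0)
    base_freqs: tuple = (0.30, 0.20, 0.25, 0.25)
    gamma_shape: float = 0.5
    p_inv: float = 0.2
    n_categories: int = 4

    def __post_init__(self):
        ex = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.base_freqs, dtype=float)
        if ex.shape != (6,) or np.any(ex <= 0):
            raise ValueError("need 6 positive exchangeabilities")
        if pi.shape != (4,) or abs(pi.sum() - 1.0) > 1e-12 or np.any(pi <= 0):
            raise ValueError("base frequencies must be 4 positive values summing to 1")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if not 0 <= self.p_inv < 1:
            raise ValueError("p_inv must be in [0, 1)")

    @property
    def k_states(self) -> int:
        return 4

    @property
    def freqs(self) -> np.ndarray:
        return np.asarray(self.base_freqs, dtype=float)

    def rate_matrix(self) -> np.ndarray:
        """Scaled GTR generator Q with mean rate 1 at stationarity."""
        s = np.zeros((4, 4))
        idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for r, (i, j) in zip(self.exchangeabilities, idx):
            s[i, j] = s[j, i] = r
        pi = self.freqs
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.dot(pi, np.diag(q))
        return q / mu

    def eigensystem(self):
        """(eigenvalues, U, U^-1) such that P(t) = U diag(exp(w t)) U^-1.

        Uses the symmetrized form D^1/2 Q D^-1/2 for numerical stability.
        """
        pi = self.freqs
        d = np.sqrt(pi)
        q = self.rate_matrix()
        b = (q * d[:, None]) / d[None, :]
        w, v = np.linalg.eigh((b + b.T) / 2.0)
        u = v / d[:, None]
        uinv = v.T * d[None, :]
        return w, u, uinv

    def transition_probs(self, lengths: np.ndarray) -> np.ndarray:
        """P(t) for an array of branch lengths; output shape ``lengths.shape + (4, 4)``."""
        w, u, uinv = self.eigensystem()
        t = np.asarray(lengths, dtype=float)
        e = np.exp(np.multiply.outer(t, w))
        p = np.einsum("ik,...k,kj->...ij", u, e, uinv)
        return np.clip(p, 0.0, None)

    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.gamma_shape, self.n_categories)


DEFAULT_GTR = NucModelParams()


@dataclass(frozen=True)
class MorphModelParams:
    """Symmetric k-state Mk model with gamma among-character rate variation."""

    k_states: int = 2
    char_rate_shape: float = 1.39
    n_categories: int = 4

    def __post_init__(self):
        if self.k_states < 2:
            raise ValueError("k_states must be at least 2")
        if self.char_rate_shape <= 0:
            raise ValueError("char_rate_shape must be positive")

    @property
    def freqs(self) -> np.ndarray:
        return np.full(self.k_states, 1.0 / self.k_states)

    def rate_matrix(self) -> np.ndarray:
        k = self.k_states
        q = np.full((k, k), 1.0 / (k - 1))
        np.fill_diagonal(q, -1.0)
        return q

    def transition_probs(self, lengths: np.ndarray) -> np.ndarray:
        """Closed-form Mk transition probabilities (mean rate 1)."""
        k = self.k_states
        t = np.asarray(lengths, dtype=float)
        e = np.exp(-k * t / (k - 1))
        same = 1.0 / k + (k - 1) / k * e
        diff = 1.0 / k - e / k
        p = np.broadcast_to(diff[..., None, None], t.shape + (k, k)).copy()
        ii = np.arange(k)
        p[..., ii, ii] = same[..., None]
        return p

    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.char_rate_shape, self.n_categories)

    @property
    def p_inv(self) -> float:
        return 0.0
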