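"""GTR substitution model, base frequencies and discrete-gamma rates.

The instantaneous rate matrix is built as ``Q_ij = r_ij * pi_j`` (i != j)
with the GT exchangeability fixed to 1 as the reference, the diagonal set
for zero row sums, and the whole matrix normalized so one unit of branch
length equals one expected substitution per site at stationarity.
Time reversibility lets us diagonalize the similarity-transformed symmetric
matrix, which is both stable and cheap to exponentiate for many branch
length x rate-category combinations at once.

Rate heterogeneity across sites uses the discretized gamma model: ``ncat``
equal-probability categories whose rates are the mean of the unit-mean
gamma density over each quantile interval, renormalized so the weighted
mean rate is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

RATE_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")


class ModelError(ValueError):
    pass


@dataclass
class GTRParams:
    """Six exchangeabilities in order AC, AG, AT, CG, CT, GT; GT == 1 is the
    fixed reference, so five are free.  All equal gives Jukes-Cantor."""

    rates: np.ndarray = field(default_factory=lambda: np.ones(6))

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (6,):
            raise ModelError("GTR needs 6 exchangeabilities (AC AG AT CG CT GT)")
        if np.any(self.rates <= 0):
            raise ModelError("GTR exchangeabilities must be positive")

    @classmethod
    def jc(cls) -> "GTRParams":
        return cls(np.ones(6))

    def normalized(self) -> "GTRParams":
        return GTRParams(self.rates / self.rates[5])

    def copy(self) -> "GTRParams":
        return GTRParams(self.rates.copy())


@dataclass
class BaseFrequencies:
    """Stationary nucleotide frequencies (A, C, G, T); three free."""

    pi: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (4,):
            raise ModelError("need 4 base frequencies")
        if np.any(self.pi <= 0):
            raise ModelError("base frequencies must be strictly positive")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ModelError("base frequencies must sum to 1")
        self.pi = self.pi / self.pi.sum()

    @classmethod
    def uniform(cls) -> "BaseFrequencies":
        return cls(np.full(4, 0.25))

    @classmethod
    def empirical(cls, paln, pseudocount: float = 1.0) -> "BaseFrequencies":
        """Counted frequencies over unambiguous characters, for initialization."""
        bits = np.array([1, 2, 4, 8], dtype=np.uint8)
        counts = np.zeros(4)
        flat = paln.patterns
        w = paln.weights
        for s, b in enumerate(bits):
            hit = (flat == b)
            counts[s] = float((hit * w[None, :]).sum())
        counts += pseudocount
        return cls(counts / counts.sum())

    def copy(self) -> "BaseFrequencies":
        return BaseFrequencies(self.pi.copy())


from functools import lru_cache


@lru_cache(maxsize=16384)
def _gamma_category_rates(alpha: float, ncat: int) -> tuple:
    # unit-mean gamma: shape alpha, rate alpha
    probs = np.arange(1, ncat) / ncat
    cuts = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], cuts, [np.inf]])
    # mean over [a,b] of x f(x) dx equals P(shape alpha+1 in [a,b]) for the
    # unit-mean parameterization; each category has probability 1/ncat
    upper = gammainc(alpha + 1.0, alpha * edges[1:])
    lower = gammainc(alpha + 1.0, alpha * edges[:-1])
    rates = ncat * (upper - lower)
    return tuple(rates / rates.mean())


def discretize_gamma(alpha: float, ncat: int = 4) -> "GammaRHAS":
    """Equal-probability discrete gamma categories with mean-of-interval rates."""
    if alpha <= 0:
        raise ModelError("gamma shape alpha must be > 0")
    if ncat < 1:
        raise ModelError("ncat must be >= 1")
    if ncat == 1:
        return GammaRHAS(alpha=alpha, ncat=1, category_rates=np.array([1.0]))
    rates = np.array(_gamma_category_rates(float(alpha), int(ncat)))
    return GammaRHAS(alpha=alpha, ncat=ncat, category_rates=rates)


@dataclass
class GammaRHAS:
    """Discrete-gamma rate heterogeneity; category probabilities are 1/ncat
    and category rates have weighted mean 1."""

    alpha: float
    ncat: int
    category_rates: np.ndarray

    def __post_init__(self):
        self.category_rates = np.asarray(self.category_rates, dtype=float)
        if self.alpha <= 0:
            raise ModelError("gamma shape alpha must be > 0")
        if len(self.category_rates) != self.ncat:
            raise ModelError("category rate count mismatch")
        if abs(self.category_rates.mean() - 1.0) > 1e-9:
            raise ModelError("category rates must average to 1")

    @classmethod
    def none(cls) -> "GammaRHAS":
        """Single-category (rate-homogeneous) model."""
        return cls(alpha=np.inf, ncat=1, category_rates=np.array([1.0]))

    @property
    def category_probs(self) -> np.ndarray:
        return np.full(self.ncat, 1.0 / self.ncat)

    def copy(self) -> "GammaRHAS":
        return GammaRHAS(self.alpha, self.ncat, self.category_rates.copy())


_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass
class RateMatrix:
    """Normalized GTR rate matrix with a cached spectral decomposition."""

    Q: np.ndarray
    pi: np.ndarray
    eigvals: np.ndarray
    # P(t) = right @ diag(exp(eigvals * t)) @ left
    right: np.ndarray
    left: np.ndarray

    def transition(self, t: float, rate: float = 1.0) -> np.ndarray:
        return transition_probabilities(self, t, rate)

    def transition_batch(self, distances: np.ndarray) -> np.ndarray:
        """P(d) for an array of evolutionary distances; output shape
        ``distances.shape + (4, 4)``."""
        d = np.asarray(distances, dtype=float)
        ex = np.exp(np.multiply.outer(d, self.eigvals))  # (..., 4)
        P = np.einsum("ij,...j,jk->...ik", self.right, ex, self.left)
        return np.clip(P, 0.0, None)


def normalized_q(gtr: GTRParams, freqs: BaseFrequencies) -> np.ndarray:
    """The normalized 4x4 rate matrix alone (no spectral cache)."""
    pi = freqs.pi
    Q = np.zeros((4, 4))
    for r, (i, j) in zip(gtr.rates, _PAIRS):
        Q[i, j] = r * pi[j]
        Q[j, i] = r * pi[i]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(Q)))  # expected rate at stationarity
    if mu <= 0 or not np.isfinite(mu):
        raise ModelError("degenerate rate matrix (zero mean rate)")
    return Q / mu


def build_rate_matrix(gtr: GTRParams, freqs: BaseFrequencies) -> RateMatrix:
    pi = freqs.pi
    Q = normalized_q(gtr, freqs)
    # symmetrize: S = D Q D^-1 with D = diag(sqrt(pi)) is symmetric by
    # detailed balance, so eigh applies
    sq = np.sqrt(pi)
    S = (sq[:, None] * Q) / sq[None, :]
    S = 0.5 * (S + S.T)
    w, U = np.linalg.eigh(S)
    right = U / sq[:, None]
    left = U.T * sq[None, :]
    return RateMatrix(Q=Q, pi=pi.copy(), eigvals=w, right=right, left=left)


def transition_probabilities(Q: RateMatrix, t: float, rate: float = 1.0) -> np.ndarray:
    """P = exp(Q * t * rate); rows sum to 1, entries clipped at 0."""
    if t < 0:
        raise ModelError("branch length must be >= 0")
    if rate <= 0:
        raise ModelError("category rate must be > 0")
    return Q.transition_batch(np.asarray(t * rate))
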