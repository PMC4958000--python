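"""General time-reversible substitution model with invariant sites and
discrete-gamma rate variation (GTR+I+G).

Conventions: bases are ordered A, C, G, T; exchangeabilities are ordered
AC, AG, AT, CG, CT, GT with the GT rate conventionally fixed to 1 during
estimation.  The rate matrix Q is scaled so the mean substitution rate at
stationarity is 1, and the discrete-gamma category rates (Yang's
equal-probability bins, category rate = bin mean) have mean 1; invariant
sites are a separate mixture component of weight ``p_inv``.  A branch length
t is therefore the expected number of substitutions per *variable* site.

Transition kernels are computed by eigendecomposition of the symmetrized
rate matrix, which is numerically stable for reversible Q; rows of P(t) are
clipped at 0 and renormalized to guard against round-off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from phylorigins.errors import ValidationError

BASES = "ACGT"
PAIR_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")
# (row, col) index of each exchangeability in the 4x4 rate matrix
_PAIR_IDX = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass(frozen=True)
class GTRModel:
    """GTR+I+G parameters.

    exchangeabilities: six positive relative rates (AC, AG, AT, CG, CT, GT);
    stationary_freqs: A, C, G, T frequencies (normalized on construction);
    p_inv: proportion of invariant sites; gamma_shape: alpha of the gamma
    rate distribution; n_rate_categories: discrete categories (default 4).
    """

    exchangeabilities: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    stationary_freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    p_inv: float = 0.0
    gamma_shape: float = np.inf
    n_rate_categories: int = 4

    def __post_init__(self) -> None:
        ex = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.stationary_freqs, dtype=float)
        if ex.shape != (6,) or (ex <= 0).any():
            raise ValidationError("need 6 strictly positive exchangeabilities")
        if pi.shape != (4,) or (pi < 0).any() or pi.sum() <= 0:
            raise ValidationError("need 4 non-negative frequencies with positive sum")
        if not (0.0 <= self.p_inv <= 1.0):
            raise ValidationError("p_inv must lie in [0, 1]")
        if not self.gamma_shape > 0:
            raise ValidationError("gamma_shape must be positive")
        if self.n_rate_categories < 1:
            raise ValidationError("need at least one rate category")
        object.__setattr__(self, "exchangeabilities", tuple(ex))
        object.__setattr__(self, "stationary_freqs", tuple(pi / pi.sum()))

    # -- classmethods ------------------------------------------------------

    @classmethod
    def jc(cls, p_inv: float = 0.0, gamma_shape: float = np.inf) -> "GTRModel":
        """Jukes–Cantor: equal rates and frequencies."""
        return cls(p_inv=p_inv, gamma_shape=gamma_shape)

    # -- rate matrix -------------------------------------------------------

    @property
    def freqs(self) -> np.ndarray:
        return np.asarray(self.stationary_freqs)

    def rate_matrix(self) -> np.ndarray:
        """Q normalized to mean rate 1 at stationarity."""
        pi = self.freqs
        Q = np.zeros((4, 4))
        for rate, (i, j) in zip(self.exchangeabilities, _PAIR_IDX):
            Q[i, j] = rate * pi[j]
            Q[j, i] = rate * pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        if mu <= 0:
            raise ValidationError("degenerate rate matrix (zero mean rate)")
        return Q / mu

    def _eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigendecomposition via the symmetrized form of the reversible Q
        (cached: the model is immutable and kernels are requested per branch
        and per rate category)."""
        cached = self.__dict__.get("_eigen_cache")
        if cached is not None:
            return cached
        pi = self.freqs
        if (pi == 0).any():
            raise ValidationError(
                "zero stationary frequency: transition kernels undefined"
            )
        Q = self.rate_matrix()
        sqrt_pi = np.sqrt(pi)
        S = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        eigval, eigvec = np.linalg.eigh((S + S.T) / 2.0)
        left = eigvec.T * sqrt_pi[None, :]
        right = eigvec / sqrt_pi[:, None]
        object.__setattr__(self, "_eigen_cache", (eigval, right, left))
        return eigval, right, left

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q · rate · t); a valid stochastic matrix."""
        if t < 0:
            raise ValidationError("branch length must be non-negative")
        eigval, right, left = self._eigen()
        P = (right * np.exp(eigval * rate * t)) @ left
        P = np.clip(P, 0.0, None)
        P /= P.sum(axis=1, keepdims=True)
        return P

    # -- rate heterogeneity ------------------------------------------------

    def gamma_category_rates(self) -> np.ndarray:
        """Mean-1 discrete-gamma rates (equal-probability bins, bin means)."""
        k = self.n_rate_categories
        a = self.gamma_shape
        if k == 1 or not np.isfinite(a):
            return np.ones(k)
        edges = gamma_dist.ppf(np.linspace(0.0, 1.0, k + 1), a, scale=1.0 / a)
        # E[X · 1(l < X < u)] for X ~ Gamma(a, 1/a) equals
        # gammainc(a+1, u·a) - gammainc(a+1, l·a); each bin has mass 1/k
        upper = np.where(np.isinf(edges[1:]), 1.0, gammainc(a + 1.0, edges[1:] * a))
        lower = gammainc(a + 1.0, edges[:-1] * a)
        rates = k * (upper - lower)
        return rates / rates.mean()

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "exchangeabilities": list(self.exchangeabilities),
            "stationary_freqs": list(self.stationary_freqs),
            "p_inv": self.p_inv,
            "gamma_shape": None if np.isinf(self.gamma_shape) else self.gamma_shape,
            "n_rate_categories": self.n_rate_categories,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GTRModel":
        shape = data.get("gamma_shape")
        return cls(
            exchangeabilities=tuple(data["exchangeabilities"]),
            stationary_freqs=tuple(data["stationary_freqs"]),
            p_inv=data.get("p_inv", 0.0),
            gamma_shape=np.inf if shape is None else shape,
            n_rate_categories=data.get("n_rate_categories", 4),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GTRModel":
        return cls.from_dict(json.loads(Path(path).read_text()))
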