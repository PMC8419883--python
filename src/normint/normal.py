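"""Normal-distribution data model and whitening geometry.

A k-dimensional normal N(mu, Sigma) is standardized through its symmetric
square root S = Sigma^(1/2): z = S^-1 (x - mu) is standard normal, and S acts
as the multidimensional standard deviation (its eigen-axes are the axes of
the 1-sd error ellipsoid).  All integration and classification routines in
this package work in that whitened space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "NormalDist",
    "sym_sqrt",
    "standardize_quadratic",
    "mahalanobis",
]

#: relative tolerance for declaring a matrix symmetric
SYM_RTOL = 1e-8
#: eigenvalues above -EIG_RTOL * max(eig) are clipped to zero in sym_sqrt
EIG_RTOL = 1e-10


def _as_sym(M: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Validate symmetry within tolerance and return the symmetrized matrix."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square, got shape {M.shape}")
    scale = max(np.max(np.abs(M)), 1e-300)
    if np.max(np.abs(M - M.T)) > SYM_RTOL * scale:
        raise ValueError(f"{name} is not symmetric within tolerance")
    return (M + M.T) / 2.0


@dataclass(frozen=True)
class NormalDist:
    """A k-dimensional normal distribution N(mu, Sigma).

    Parameters
    ----------
    mu : (k,) array_like
        Mean vector, in feature units.
    Sigma : (k, k) array_like
        Covariance matrix (symmetric positive semidefinite). Operations that
        whiten (integration, classification) additionally require strict
        positive definiteness.
    """

    mu: np.ndarray
    Sigma: np.ndarray
    _S: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        Sigma = np.atleast_2d(_as_sym(self.Sigma, "Sigma"))
        if mu.shape[0] != Sigma.shape[0]:
            raise ValueError(
                f"mu has length {mu.shape[0]} but Sigma is {Sigma.shape}"
            )
        evals = linalg.eigvalsh(Sigma)
        if evals[0] < -EIG_RTOL * max(evals[-1], 1e-300):
            raise ValueError("Sigma is not positive semidefinite")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "Sigma", Sigma)
        object.__setattr__(self, "_S", None)

    @property
    def dim(self) -> int:
        return self.mu.shape[0]

    @property
    def S(self) -> np.ndarray:
        """Symmetric square root of the covariance (cached)."""
        if self._S is None:
            object.__setattr__(self, "_S", sym_sqrt(self.Sigma))
        return self._S

    def whiten(self, x: np.ndarray) -> np.ndarray:
        """Map points x (.., k) to the standardized space z = S^-1 (x - mu)."""
        S = self.S
        x = np.asarray(x, dtype=float)
        return np.linalg.solve(S, (x - self.mu).T).T

    def unwhiten(self, z: np.ndarray) -> np.ndarray:
        """Map standardized points back: x = S z + mu."""
        z = np.asarray(z, dtype=float)
        return z @ self.S + self.mu

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.multivariate_normal(self.mu, self.Sigma, size=n)

    # -- JSON round trip -----------------------------------------------
    def to_dict(self) -> dict:
        return {"mu": self.mu.tolist(), "Sigma": self.Sigma.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalDist":
        return cls(np.asarray(d["mu"], float), np.asarray(d["Sigma"], float))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "NormalDist":
        return cls.from_dict(json.loads(s))


def sym_sqrt(Sigma: np.ndarray) -> np.ndarray:
    """Symmetric positive-semidefinite square root S with S @ S = Sigma.

    Computed by eigen-decomposition; eigenvalues within ``EIG_RTOL`` of zero
    (relative to the largest) are floored at zero, more negative ones raise.
    """
    Sigma = _as_sym(Sigma, "Sigma")
    evals, vecs = linalg.eigh(Sigma)
    floor = -EIG_RTOL * max(evals[-1], 1e-300)
    if evals[0] < floor:
        raise ValueError("matrix is not positive semidefinite")
    evals = np.clip(evals, 0.0, None)
    return (vecs * np.sqrt(evals)) @ vecs.T


def standardize_quadratic(q, normal: NormalDist):
    """Re-express a quadratic q(x) in the whitened space of ``normal``.

    Returns coefficients (Q2t, q1t, q0t) such that with z = S^-1 (x - mu),
    qt(z) = q(x) identically:

        Q2t = S Q2 S,  q1t = 2 S Q2 mu + S q1,  q0t = q(mu).
    """
    from .domains import QuadraticCoeffs  # local import avoids a cycle

    S = normal.S
    mu = normal.mu
    evals = linalg.eigvalsh(normal.Sigma)
    if evals[0] <= EIG_RTOL * max(evals[-1], 1e-300):
        raise ValueError("standardization requires a strictly positive-definite Sigma")
    Q2, q1, q0 = q.Q2, q.q1, q.q0
    if Q2.shape[0] != normal.dim:
        raise ValueError("quadratic and normal dimensions do not match")
    Q2t = S @ Q2 @ S
    q1t = 2.0 * S @ Q2 @ mu + S @ q1
    q0t = float(mu @ Q2 @ mu + q1 @ mu + q0)
    return QuadraticCoeffs(Q2t, q1t, q0t)


def mahalanobis(mu_a, mu_b, Sigma) -> float:
    """Mahalanobis distance sqrt((mu_a-mu_b)' Sigma^-1 (mu_a-mu_b))."""
    mu_a = np.atleast_1d(np.asarray(mu_a, float))
    mu_b = np.atleast_1d(np.asarray(mu_b, float))
    Sigma = np.atleast_2d(_as_sym(Sigma, "Sigma"))
    d = mu_a - mu_b
    try:
        c = linalg.cho_factor(Sigma)
    except linalg.LinAlgError as e:
        raise ValueError("Sigma must be strictly positive definite") from e
    return float(np.sqrt(d @ linalg.cho_solve(c, d)))
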