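"""Discriminability indices, detection-task performance, and ROC curves.

The Bayes discriminability index d'_b is minus twice the standard-normal
quantile of the Bayes error between two classes — the separation of two
unit-variance normals with the same overlap.  The classical approximations
d'_a (rms sd) and d'_e (average sd) are provided for comparison, along with
yes/no, two-interval and m-interval task performance and single-criterion /
likelihood-ratio ROC curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import integrate as sint
from scipy import stats
from scipy.special import ndtri

from .classify import (
    ValueStructure,
    _prob_positive,
    bayes_boundary_two,
    classify_normals,
)
from .domains import QuadraticCoeffs
from .gx2 import gx2_cdf, gx2_params, gx2_pdf, gx2_sf
from .normal import NormalDist, mahalanobis, sym_sqrt

__all__ = [
    "TaskResult",
    "dprime_approx",
    "dprime_bayes",
    "yes_no_errors",
    "two_interval",
    "m_interval_accuracy",
    "roc_curve",
    "RocCurve",
]


@dataclass
class TaskResult:
    """Performance of an optimal binary task: Bayes error/accuracy, the
    discriminability indices, the quadratic boundary used, and the
    generalized chi-square parameters of the decision variable per class."""

    p_e: float
    p_c: float
    d_b: float
    d_a: float
    d_e: float
    boundary: Optional[QuadraticCoeffs]
    aux: dict = field(default_factory=dict)


def dprime_approx(a: NormalDist, b: NormalDist) -> tuple[float, float]:
    """Approximate indices (d_a, d_e).

    d_a is the Mahalanobis distance of the means under the pooled (rms)
    covariance (Sigma_a + Sigma_b)/2; d_e uses the average of the symmetric
    sd matrices, S_avg = (S_a + S_b)/2.
    """
    d_a = mahalanobis(a.mu, b.mu, (a.Sigma + b.Sigma) / 2.0)
    S_avg = (sym_sqrt(a.Sigma) + sym_sqrt(b.Sigma)) / 2.0
    d_e = float(np.linalg.norm(np.linalg.solve(S_avg, a.mu - b.mu)))
    return d_a, d_e


def bayes_error_two(a: NormalDist, b: NormalDist,
                    method: str = "gx2") -> float:
    """Bayes error with equal priors and unit values."""
    vs = ValueStructure.equal(2)
    bound = bayes_boundary_two(a, b, vs)
    p_Ba = 1.0 - _prob_positive(a, bound, method)
    p_Ab = _prob_positive(b, bound, method)
    return 0.5 * (p_Ba + p_Ab)


def dprime_bayes(a: NormalDist, b: NormalDist,
                 method: str = "gx2") -> tuple[float, float, bool]:
    """Bayes discriminability d_b = -2 Phi^-1(Bayes error).

    Returns (d_b, p_e, fallback).  When the Bayes error underflows double
    precision, 1d problems fall back to d_e (flagged); in higher dimensions
    d_b is +inf with the flag set.
    """
    p_e = bayes_error_two(a, b, method)
    if p_e > 0.0:
        return float(-2.0 * ndtri(p_e)), p_e, False
    if a.dim == 1:
        return dprime_approx(a, b)[1], 0.0, True
    return math.inf, 0.0, True


def yes_no_errors(mu_a: float, sigma_a: float, mu_b: float, sigma_b: float
                  ) -> tuple[float, float, float]:
    """Closed-form Bayes error rates of the equal-priors 1d yes/no task.

    The log-likelihood ratio l(x) of a vs b is a scaled and shifted
    noncentral chi-square with 1 degree of freedom under each class, so the
    error rates (p(B|a), p(A|b)) are noncentral chi-square probabilities;
    p_e is their average.  Equal sds reduce to the flat-boundary formula
    Phi(-|mu_a - mu_b| / (2 sigma)).
    """
    if sigma_a <= 0 or sigma_b <= 0:
        raise ValueError("sds must be positive")
    if abs(sigma_a - sigma_b) <= 1e-12 * max(sigma_a, sigma_b):
        p = float(stats.norm.cdf(-abs(mu_a - mu_b) / (2.0 * sigma_a)))
        return p, p, p
    if sigma_a < sigma_b:  # swap so the first class is the wider one
        p_Ab, p_Ba, p_e = yes_no_errors(mu_b, sigma_b, mu_a, sigma_a)
        return p_Ba, p_Ab, p_e

    va, vb = sigma_a**2, sigma_b**2
    acoef = 1.0 / vb - 1.0 / va  # > 0

    def l(x):
        return ((x - mu_b) / sigma_b) ** 2 - ((x - mu_a) / sigma_a) ** 2 \
            + 2.0 * math.log(sigma_b / sigma_a)

    h = (mu_b * va - mu_a * vb) / (va - vb)  # vertex of l
    l_min = l(h)
    if l_min >= 0.0:  # l positive everywhere: always answer A
        return 0.0, 1.0, 0.5
    c_a = -l_min / (acoef * va)
    c_b = -l_min / (acoef * vb)
    nc_a = ((mu_a - h) / sigma_a) ** 2
    nc_b = ((mu_b - h) / sigma_b) ** 2
    p_Ba = float(stats.ncx2.cdf(c_a, df=1, nc=nc_a))
    p_Ab = float(stats.ncx2.sf(c_b, df=1, nc=nc_b))
    return p_Ba, p_Ab, 0.5 * (p_Ba + p_Ab)


def _pair_to_two_interval(a: NormalDist, b: NormalDist
                          ) -> tuple[NormalDist, NormalDist]:
    """Joint classes ab and ba: concatenated means, block-diagonal covariances
    in opposite order."""
    k = a.dim
    mu_ab = np.concatenate([a.mu, b.mu])
    mu_ba = np.concatenate([b.mu, a.mu])
    Z = np.zeros((k, k))
    S_ab = np.block([[a.Sigma, Z], [Z, b.Sigma]])
    S_ba = np.block([[b.Sigma, Z], [Z, a.Sigma]])
    return NormalDist(mu_ab, S_ab), NormalDist(mu_ba, S_ba)


def two_interval(a: NormalDist, b: NormalDist, method: str = "auto"
                 ) -> TaskResult:
    """Optimal two-interval (2AFC) task between a and b.

    The task is a single classification between the joint classes ab and ba;
    the optimal boundary compares the log-likelihood ratios of the two
    stimuli, and the error is a generalized chi-square (or 2k-d ray-trace)
    probability.
    """
    ab, ba = _pair_to_two_interval(a, b)
    res = classify_normals([ab, ba], method=method)
    return TaskResult(
        p_e=res.aux.get("p_e_bayes", res.error_matrix.p_e),
        p_c=1.0 - res.aux.get("p_e_bayes", res.error_matrix.p_e),
        d_b=res.d_b, d_a=res.d_a, d_e=res.d_e,
        boundary=res.boundary, aux=res.aux,
    )


def _loglik_quad_1d(mu_a, sigma_a, mu_b, sigma_b) -> QuadraticCoeffs:
    """Quadratic coefficients of the 1d log-likelihood ratio l(x) of a vs b."""
    va, vb = sigma_a**2, sigma_b**2
    Q2 = np.array([[1.0 / vb - 1.0 / va]])
    q1 = np.array([2.0 * mu_a / va - 2.0 * mu_b / vb])
    q0 = mu_b**2 / vb - mu_a**2 / va + 2.0 * math.log(sigma_b / sigma_a)
    return QuadraticCoeffs(Q2, q1, q0)


def m_interval_accuracy(m: int, mu_a: float, sigma_a: float,
                        mu_b: float, sigma_b: float) -> float:
    """Maximum accuracy of the m-interval task: the signal is located by the
    largest log-likelihood ratio, so p(c) = int F_b^(m-1)(l) f_a(l) dl over
    the distributions of l under each class."""
    if m < 2:
        raise ValueError("need at least two intervals")
    quad = _loglik_quad_1d(mu_a, sigma_a, mu_b, sigma_b)
    pa = gx2_params(NormalDist([mu_a], [[sigma_a**2]]), quad)
    pb = gx2_params(NormalDist([mu_b], [[sigma_b**2]]), quad)
    if pa.is_degenerate or pb.is_degenerate:  # identical classes: guessing
        return 1.0 / m
    from .gx2 import gx2_inv

    # quantile-based limits: chi-square tails reach far beyond mean + k sd
    lo = min(gx2_inv(1e-11, pa), gx2_inv(1e-11, pb))
    hi = max(gx2_inv(1.0 - 1e-11, pa), gx2_inv(1.0 - 1e-11, pb))
    val, _ = sint.quad(
        lambda x: gx2_cdf(x, pb) ** (m - 1) * gx2_pdf(x, pa),
        lo, hi, epsabs=1e-10, limit=400,
    )
    return float(min(max(val, 0.0), 1.0))


@dataclass
class RocCurve:
    """(false alarm, hit) pairs along a swept criterion, the area under the
    curve, and the Bayes-index estimate from the farthest-from-diagonal
    point."""

    criteria: np.ndarray
    p_fa: np.ndarray
    p_hit: np.ndarray
    auc: float
    best_accuracy: float
    d_b_est: float


def _empirical_sf(samples: np.ndarray, c: np.ndarray) -> np.ndarray:
    s = np.sort(np.asarray(samples, float))
    return 1.0 - np.searchsorted(s, c, side="right") / len(s)


def roc_curve(a, b, mode: str = "likelihood_ratio",
              n_grid: int = 201) -> RocCurve:
    """ROC curve between classes a (signal) and b.

    'criterion' sweeps a scalar criterion over 1d values (normals or sample
    arrays); 'likelihood_ratio' sweeps the offset of the Bayes boundary
    between two normals in any dimension — the criterion moves along the
    contours of the log-likelihood ratio.  The area under the curve is
    trapezoidal; the point maximizing p(hit) - p(false alarm) is the farthest
    from the diagonal, and twice the z-score of its accuracy estimates d_b.
    """
    if n_grid < 3:
        raise ValueError("grid too small")
    if mode == "criterion":
        if isinstance(a, NormalDist):
            if a.dim != 1 or b.dim != 1:
                raise ValueError("criterion mode needs 1d classes")
            mus = [a.mu[0], b.mu[0]]
            sds = [math.sqrt(a.Sigma[0, 0]), math.sqrt(b.Sigma[0, 0])]
            lo = min(m - 10 * s for m, s in zip(mus, sds))
            hi = max(m + 10 * s for m, s in zip(mus, sds))
            c = np.linspace(lo, hi, n_grid)
            hit = stats.norm.sf(c, a.mu[0], sds[0])
            fa = stats.norm.sf(c, b.mu[0], sds[1])
        else:
            a = np.asarray(a, float).ravel()
            b = np.asarray(b, float).ravel()
            allv = np.concatenate([a, b])
            c = np.linspace(allv.min() - 1e-9, allv.max() + 1e-9, n_grid)
            hit = _empirical_sf(a, c)
            fa = _empirical_sf(b, c)
    elif mode == "likelihood_ratio":
        bound = bayes_boundary_two(a, b, ValueStructure.equal(2))
        pa = gx2_params(a, bound)
        pb = gx2_params(b, bound)
        zs = np.linspace(-10.0, 10.0, n_grid)
        # criteria uniform in each class's standardized units, merged
        c = np.unique(np.concatenate([
            pa.mean() + math.sqrt(pa.var()) * zs,
            pb.mean() + math.sqrt(pb.var()) * zs,
        ]))
        hit = np.asarray(gx2_sf(c, pa))
        fa = np.asarray(gx2_sf(c, pb))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    order = np.argsort(fa)
    fa_s = np.concatenate([[0.0], fa[order], [1.0]])
    hit_s = np.concatenate([[0.0], hit[order], [1.0]])
    auc = float(np.trapezoid(hit_s, fa_s))
    best = float(np.max((hit + 1.0 - fa) / 2.0))
    d_b_est = float(2.0 * ndtri(best)) if best < 1.0 else math.inf
    return RocCurve(c, fa, hit, auc, best, d_b_est)
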