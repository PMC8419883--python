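"""Distributions of scalar (and vector) functions of a normal vector.

A scalar field f on R^k maps a normal vector x to a decision variable f(x);
its cdf at c is the normal probability of the domain c - f(x) > 0, evaluated
by ray tracing.  The pdf follows by finite differences, the inverse cdf by
root finding, and joint laws of two fields by integrating over intersected
domains.  Monotone transforms of 1d normals (e.g. the lognormal) are covered
as the special case k = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import optimize

from .domains import DEFAULT_TRACE_RADIUS, Domain, combine_domains
from .integrate import norm_prob
from .normal import NormalDist

__all__ = [
    "FuncOfNormal",
    "func_cdf",
    "func_pdf",
    "func_inv",
    "func_moments",
    "joint_cdf",
    "joint_pdf",
]

#: relative finite-difference step for pdf evaluation
FD_STEP = 1e-5


@dataclass(frozen=True)
class FuncOfNormal:
    """A scalar field f (vectorized over (..., k) points) of a normal vector,
    traced within ``m`` sd of the mean."""

    f: Callable[[np.ndarray], np.ndarray]
    normal: NormalDist
    m: float = DEFAULT_TRACE_RADIUS

    def domain_below(self, c: float) -> Domain:
        return Domain.implicit(lambda x, _c=c: _c - self.f(x), m=self.m)


def func_cdf(fn: FuncOfNormal, c: float, tol: float = 1e-8) -> float:
    """P(f(x) < c): the normal probability in the implicit domain c - f(x) > 0."""
    return norm_prob(fn.normal, fn.domain_below(c), tol=tol,
                     collect_boundary=False).p


def func_pdf(fn: FuncOfNormal, c: float, tol: float = 1e-8) -> float:
    """Density of f(x) at c by a central difference of the cdf."""
    h = max(FD_STEP, FD_STEP * abs(c))
    lo = func_cdf(fn, c - h, tol)
    hi = func_cdf(fn, c + h, tol)
    return max((hi - lo) / (2.0 * h), 0.0)


def func_inv(fn: FuncOfNormal, p: float, tol: float = 1e-8,
             xtol: float = 1e-8) -> float:
    """Quantile of f(x): root of func_cdf(c) = p, bracketed from f(mu)."""
    if not 0.0 < p < 1.0:
        raise ValueError("probability must be strictly inside (0, 1)")
    c0 = float(np.asarray(fn.f(fn.normal.mu[None, :])).ravel()[0])
    step = max(1.0, abs(c0))
    lo = hi = c0
    flo = fhi = func_cdf(fn, c0, tol)
    for _ in range(200):
        if flo <= p:
            break
        lo -= step
        step *= 2.0
        flo = func_cdf(fn, lo, tol)
    else:
        raise RuntimeError("could not bracket the quantile from below")
    step = max(1.0, abs(c0))
    for _ in range(200):
        if fhi >= p:
            break
        hi += step
        step *= 2.0
        fhi = func_cdf(fn, hi, tol)
    else:
        raise RuntimeError("could not bracket the quantile from above")
    if lo == hi:
        return lo
    return float(optimize.brentq(lambda c: func_cdf(fn, c, tol) - p, lo, hi,
                                 xtol=xtol))


def func_moments(fn: FuncOfNormal, n_grid: int = 256, p_tail: float = 1e-5,
                 tol: float = 1e-8) -> tuple[float, float]:
    """Mean and sd of f(x), from its cdf on a regular grid between the p_tail
    and 1 - p_tail quantiles (the truncated tail mass is renormalized)."""
    lo = func_inv(fn, p_tail, tol)
    hi = func_inv(fn, 1.0 - p_tail, tol)
    c = np.linspace(lo, hi, n_grid)
    F = np.array([func_cdf(fn, ci, tol) for ci in c])
    dF = np.diff(F)
    mids = 0.5 * (c[:-1] + c[1:])
    mass = dF.sum()
    mean = float((mids * dF).sum() / mass)
    var = float(((mids - mean) ** 2 * dF).sum() / mass)
    return mean, float(np.sqrt(var))


def joint_cdf(f1, f2, normal: NormalDist, c1: float, c2: float,
              m: float = DEFAULT_TRACE_RADIUS, tol: float = 1e-8) -> float:
    """Joint cdf P(f1(x) < c1, f2(x) < c2): the normal probability in the
    intersection of the two sublevel domains."""
    d1 = Domain.implicit(lambda x: c1 - np.asarray(f1(x)), m=m)
    d2 = Domain.implicit(lambda x: c2 - np.asarray(f2(x)), m=m)
    dom = combine_domains("intersect", [d1, d2])
    return norm_prob(normal, dom, tol=tol, collect_boundary=False).p


def joint_pdf(f1, f2, normal: NormalDist, c1: float, c2: float,
              m: float = DEFAULT_TRACE_RADIUS, tol: float = 1e-9) -> float:
    """Joint density of (f1(x), f2(x)) by a 2x2 cross stencil on the joint cdf.

    The mixed second difference divides by h1*h2, so the stencil is much
    wider than the scalar-pdf step: quadrature noise in the four cdf values
    would otherwise swamp the derivative.
    """
    h1 = 0.02 * max(1.0, abs(c1))
    h2 = 0.02 * max(1.0, abs(c2))
    pp = joint_cdf(f1, f2, normal, c1 + h1, c2 + h2, m, tol)
    pm = joint_cdf(f1, f2, normal, c1 + h1, c2 - h2, m, tol)
    mp = joint_cdf(f1, f2, normal, c1 - h1, c2 + h2, m, tol)
    mm = joint_cdf(f1, f2, normal, c1 - h1, c2 - h2, m, tol)
    return max((pp - pm - mp + mm) / (4.0 * h1 * h2), 0.0)
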