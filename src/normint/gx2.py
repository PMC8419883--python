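"""Generalized chi-square distribution of quadratic forms of normal vectors.

Any quadratic q(x) of a normal vector x follows a generalized chi-square
law: a weighted sum of independent noncentral chi-square variables plus an
independent normal,

    q(x) ~ sum_j w_j chi2'(k_j, lam_j) + N(m, s^2).

The parameters follow from the eigen-decomposition of the whitened quadratic;
the cdf/pdf come from numerical inversion of the characteristic function
(an Imhof-type oscillatory integral), with the pure-normal and single-weight
cases delegated to their exact scipy distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import integrate as sint
from scipy import linalg, optimize, stats

from .domains import QuadraticCoeffs
from .normal import NormalDist, standardize_quadratic

__all__ = [
    "GX2Params",
    "gx2_params",
    "gx2_cdf",
    "gx2_pdf",
    "gx2_inv",
    "gx2_rand",
]

#: eigenvalues within this relative distance are merged into one weight
WEIGHT_MERGE_RTOL = 1e-8
#: default absolute tolerance of the characteristic-function inversion
CDF_TOL = 1e-10


@dataclass(frozen=True)
class GX2Params:
    """Parameters (w, k, lam, m, s) of a generalized chi-square variable."""

    w: np.ndarray
    k: np.ndarray
    lam: np.ndarray
    m: float
    s: float

    def __post_init__(self):
        w = np.atleast_1d(np.asarray(self.w, dtype=float))
        k = np.atleast_1d(np.asarray(self.k, dtype=int))
        lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        if not (w.shape == k.shape == lam.shape):
            raise ValueError("w, k, lam must have equal lengths")
        if np.any(w == 0.0) or len(np.unique(w)) != len(w):
            raise ValueError("weights must be unique and nonzero")
        if np.any(k < 1) or np.any(lam < 0) or self.s < 0:
            raise ValueError("require k >= 1, lam >= 0, s >= 0")
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "m", float(self.m))
        object.__setattr__(self, "s", float(self.s))

    def mean(self) -> float:
        return float(self.w @ (self.k + self.lam) + self.m)

    def var(self) -> float:
        return float(2.0 * self.w**2 @ (self.k + 2.0 * self.lam) + self.s**2)

    @property
    def is_degenerate(self) -> bool:
        return len(self.w) == 0 and self.s == 0.0

    def to_dict(self) -> dict:
        return {"w": self.w.tolist(), "k": self.k.tolist(),
                "lam": self.lam.tolist(), "m": self.m, "s": self.s}

    @classmethod
    def from_dict(cls, d: dict) -> "GX2Params":
        return cls(np.asarray(d["w"], float), np.asarray(d["k"], int),
                   np.asarray(d["lam"], float), d["m"], d["s"])

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "GX2Params":
        return cls.from_dict(json.loads(s))


def gx2_params(normal: NormalDist, q: QuadraticCoeffs) -> GX2Params:
    """Generalized chi-square parameters of q(x) for x ~ normal.

    The quadratic is whitened, its matrix eigen-decomposed, and noncentral
    chi-squares with (numerically) equal eigenvalues merged into one weighted
    term; coordinates with zero eigenvalue contribute the normal component.
    """
    qt = standardize_quadratic(q, normal)
    D, R = linalg.eigh(qt.Q2)
    b = R.T @ qt.q1
    scale = max(np.max(np.abs(D)), 1e-300)
    nz = np.abs(D) > WEIGHT_MERGE_RTOL * scale

    w_list, k_list, lam_list = [], [], []
    used = np.zeros(len(D), dtype=bool)
    order = np.argsort(D)
    for i in order:
        if used[i] or not nz[i]:
            continue
        grp = nz & ~used & (np.abs(D - D[i]) <= WEIGHT_MERGE_RTOL * scale)
        used |= grp
        wj = float(D[grp].mean())
        w_list.append(wj)
        k_list.append(int(grp.sum()))
        lam_list.append(float(np.sum(b[grp] ** 2) / (4.0 * wj**2)))

    s = float(np.sqrt(np.sum(b[~nz] ** 2)))
    w = np.asarray(w_list)
    lam = np.asarray(lam_list)
    m = float(qt.q0 - (w @ lam if len(w) else 0.0))
    return GX2Params(w, np.asarray(k_list, int), lam, m, s)


def _imhof_parts(t, p: GX2Params):
    """Modulus rho(t) and bounded phase phi(t) of the characteristic
    function; the full phase of cf(t) e^(-itx) is phi(t) + (m - x) t."""
    t = np.asarray(t, dtype=float)
    wt = np.multiply.outer(t, p.w)  # (..., J)
    den = 1.0 + 4.0 * wt**2
    phi = (
        0.5 * (np.arctan(2.0 * wt) @ p.k.astype(float))
        + (wt / den) @ p.lam
    )
    log_rho = (
        -0.5 * p.s**2 * t**2
        - (2.0 * wt**2 / den) @ p.lam
        - 0.25 * np.log(den) @ p.k.astype(float)
    )
    return np.exp(log_rho), phi


def _imhof_quad(p: GX2Params, x: float, kind: str, tol: float) -> float:
    """Gil-Pelaez / Imhof inversion of the characteristic function.

    cdf:  F(x) = 1/2 - (1/pi) int_0^inf rho(t) sin(phi(t) + c t) / t dt
    pdf:  f(x) =       (1/pi) int_0^inf rho(t) cos(phi(t) + c t)     dt

    with c = m - x.  The envelope decays only algebraically when s = 0, so
    the oscillating tail is integrated with Fourier-weighted quadrature
    (QAWF) against sin(|c| t) and cos(|c| t); the head and the
    non-oscillatory cases use plain adaptive quadrature.
    """
    c = p.m - x

    def integrand(t):
        rho, phi = _imhof_parts(t, p)
        th = phi + c * t
        if kind == "cdf":
            return rho * np.sin(th) / t
        return rho * np.cos(th)

    eps = tol * np.pi
    oscillatory = p.s == 0.0 and abs(c) > 1e-6
    if not oscillatory:
        out = sint.quad(integrand, 0.0, np.inf, epsabs=eps, limit=1000,
                        full_output=True)
        val, abserr = out[0], out[1]
    else:
        a = 1.0 / max(np.max(np.abs(p.w)), abs(c), 1.0)
        head = sint.quad(integrand, 0.0, a, epsabs=eps / 2, limit=500,
                         full_output=True)

        def g_sin(t):  # coefficient of sin(|c| t)
            rho, phi = _imhof_parts(t, p)
            base = rho * np.cos(phi) if kind == "cdf" else -rho * np.sin(phi)
            return np.sign(c) * base / (t if kind == "cdf" else 1.0)

        def g_cos(t):  # coefficient of cos(|c| t)
            rho, phi = _imhof_parts(t, p)
            base = rho * np.sin(phi) if kind == "cdf" else rho * np.cos(phi)
            return base / (t if kind == "cdf" else 1.0)

        tail_s = sint.quad(g_sin, a, np.inf, weight="sin", wvar=abs(c),
                           epsabs=eps / 4, limit=500, full_output=True)
        tail_c = sint.quad(g_cos, a, np.inf, weight="cos", wvar=abs(c),
                           epsabs=eps / 4, limit=500, full_output=True)
        val = head[0] + tail_s[0] + tail_c[0]
        abserr = head[1] + tail_s[1] + tail_c[1]
        out = (val, abserr)
    if abserr > max(1e3 * tol, 1e-6):
        raise RuntimeError(
            "characteristic-function inversion failed "
            f"(estimated error {abserr:.2e})"
        )
    if kind == "cdf":
        return float(np.clip(0.5 - val / np.pi, 0.0, 1.0))
    return float(max(val / np.pi, 0.0))


def gx2_cdf(x, params: GX2Params, tol: float = CDF_TOL):
    """P(gx2 <= x); exact for the pure-normal and single-weight cases, else by
    Imhof-type inversion of the characteristic function."""
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    p = params
    if len(p.w) == 0:
        if p.s == 0.0:
            out = (xs >= p.m).astype(float)  # point mass at m
        else:
            out = stats.norm.cdf(xs, loc=p.m, scale=p.s)
    elif len(p.w) == 1 and p.s == 0.0:
        y = (xs - p.m) / p.w[0]
        nc = stats.ncx2(df=p.k[0], nc=p.lam[0])
        out = nc.cdf(y) if p.w[0] > 0 else nc.sf(y)
    else:
        out = np.array([_imhof_quad(p, xi, "cdf", tol) for xi in xs])
    return out if np.ndim(x) else float(out[0])


def gx2_sf(x, params: GX2Params, tol: float = CDF_TOL):
    """Upper tail P(gx2 > x), kept accurate in the far tail for the exact cases."""
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    p = params
    if len(p.w) == 0:
        if p.s == 0.0:
            out = (xs < p.m).astype(float)
        else:
            out = stats.norm.sf(xs, loc=p.m, scale=p.s)
    elif len(p.w) == 1 and p.s == 0.0:
        y = (xs - p.m) / p.w[0]
        nc = stats.ncx2(df=p.k[0], nc=p.lam[0])
        out = nc.sf(y) if p.w[0] > 0 else nc.cdf(y)
    else:
        out = np.array([1.0 - _imhof_quad(p, xi, "cdf", tol) for xi in xs])
    return out if np.ndim(x) else float(out[0])


def gx2_pdf(x, params: GX2Params, tol: float = CDF_TOL):
    """Density of the generalized chi-square (continuous cases only)."""
    p = params
    if p.is_degenerate:
        raise ValueError("degenerate point mass has no density")
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    if len(p.w) == 0:
        out = stats.norm.pdf(xs, loc=p.m, scale=p.s)
    elif len(p.w) == 1 and p.s == 0.0:
        y = (xs - p.m) / p.w[0]
        out = stats.ncx2.pdf(y, df=p.k[0], nc=p.lam[0]) / abs(p.w[0])
    else:
        out = np.array([_pdf_one(p, xi, tol) for xi in xs])
    return out if np.ndim(x) else float(out[0])


def _pdf_one(p: GX2Params, x: float, tol: float) -> float:
    try:
        return _imhof_quad(p, x, "pdf", tol)
    except RuntimeError:
        # far tails: the oscillatory inversion loses its error control while
        # the density underflows; fall back to differencing the cdf
        h = 1e-6 * max(np.sqrt(p.var()), 1.0)
        lo = _imhof_quad(p, x - h, "cdf", tol)
        hi = _imhof_quad(p, x + h, "cdf", tol)
        return max((hi - lo) / (2.0 * h), 0.0)


def gx2_inv(prob: float, params: GX2Params, tol: float = CDF_TOL) -> float:
    """Inverse cdf by bracketed root finding, starting from mean +/- 10 sd."""
    if not 0.0 < prob < 1.0:
        raise ValueError("probability must be strictly inside (0, 1)")
    p = params
    if len(p.w) == 0:
        if p.s == 0.0:
            return p.m
        return float(stats.norm.ppf(prob, loc=p.m, scale=p.s))
    if len(p.w) == 1 and p.s == 0.0:
        nc = stats.ncx2(df=p.k[0], nc=p.lam[0])
        y = nc.ppf(prob) if p.w[0] > 0 else nc.isf(prob)
        return float(p.w[0] * y + p.m)
    mu, sd = p.mean(), np.sqrt(p.var())
    lo, hi = mu - 10.0 * sd, mu + 10.0 * sd
    span = hi - lo
    while gx2_cdf(lo, p, tol) > prob:
        lo -= span
        span *= 2.0
    while gx2_cdf(hi, p, tol) < prob:
        hi += span
        span *= 2.0
    return float(optimize.brentq(lambda x: gx2_cdf(x, p, tol) - prob, lo, hi,
                                 xtol=1e-12 * max(1.0, sd)))


def gx2_rand(n: int, params: GX2Params, seed=None) -> np.ndarray:
    """n seeded draws: sum of weighted noncentral chi-squares plus the normal."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p = params
    out = np.full(n, p.m, dtype=float)
    for wj, kj, lj in zip(p.w, p.k, p.lam):
        out += wj * stats.ncx2.rvs(df=kj, nc=lj, size=n, random_state=rng)
    if p.s > 0:
        out += p.s * rng.standard_normal(n)
    return out
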