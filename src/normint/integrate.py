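"""Ray-trace integration of a multivariate normal over an arbitrary domain.

The normal is whitened to a standard spherical one, and the integral is taken
in polar form: along each direction n the 1d probability content of the
domain's trace is computed from the chi distribution (the radial law of a
standard normal), and these per-ray contents alpha(n) are added over a grid
of angles covering half the angular space (each ray is bidirectional).  Up to
4 dimensions the angular integral is done by adaptive quadrature; beyond that
by Monte-Carlo sampling of ray directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate as sint
from scipy import special

from .domains import Domain, RayTrace
from .normal import NormalDist

__all__ = [
    "ray_cdf",
    "ray_pdf",
    "slice_probability",
    "norm_prob",
    "IntegrationResult",
    "AngularGrid",
    "total_angle",
    "fibonacci_sphere",
]

DEFAULT_TOL = 1e-8
DEFAULT_N_RAYS = 100_000


def total_angle(k: int) -> float:
    """Total solid angle Omega_k = 2 pi^(k/2) / Gamma(k/2) (2 in 1d, 2pi in 2d,
    4pi in 3d, 2pi^2 in 4d)."""
    return 2.0 * math.pi ** (k / 2.0) / math.gamma(k / 2.0)


def ray_cdf(z, k: int):
    """Distribution of the standard k-d normal along a bidirectional ray:
    Phi_ray(z) = [1 + sign(z) F_chi_k(|z|)] / 2, where F_chi_k is the chi cdf
    (the radial law of a standard normal), expressed through the regularized
    incomplete gamma function."""
    if k < 1:
        raise ValueError("dimension k must be >= 1")
    z = np.asarray(z, dtype=float)
    out = 0.5 * (1.0 + np.sign(z) * special.gammainc(k / 2.0, z * z / 2.0))
    return out if out.ndim else float(out)


def ray_pdf(z, k: int):
    """Density of the ray distribution: the chi density reflected to negative z,
    phi_ray(z) = f_chi_k(|z|) / 2.  Equals the standard normal density at k=1."""
    if k < 1:
        raise ValueError("dimension k must be >= 1")
    z = np.abs(np.asarray(z, dtype=float))
    if k == 1:  # the z^(k-1) factor is identically 1: standard normal density
        out = np.exp(-z * z / 2.0) / math.sqrt(2.0 * math.pi)
    else:
        with np.errstate(divide="ignore"):
            logz = np.where(z > 0, np.log(np.where(z > 0, z, 1.0)), -np.inf)
        logpdf = ((k - 1) * logz - z * z / 2.0
                  - (k / 2.0 - 1.0) * math.log(2.0) - math.lgamma(k / 2.0))
        out = 0.5 * np.exp(logpdf)
    return out if out.ndim else float(out)


def _ray_sf(z, k: int):
    """Complementary ray cdf Phi_bar_ray, via the upper incomplete gamma so
    that far-tail values do not round to zero."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    if pos.any():
        out[pos] = 0.5 * special.gammaincc(k / 2.0, z[pos] ** 2 / 2.0)
    if not pos.all():
        neg = ~pos
        out[neg] = 0.5 * (1.0 + special.gammainc(k / 2.0, z[neg] ** 2 / 2.0))
    return out


def slice_probability(trace: RayTrace, k: int) -> float:
    """Probability content alpha in [0, 2] of an angular slice, per unit
    slice angle, given the domain's trace along the slice's bidirectional ray:

        alpha = psi + 1 + 2 psi * sum_i (-1)^i Phi_bar_ray(z_i),

    the first crossing entering with sign opposite to psi.
    """
    psi = trace.psi
    alpha = psi + 1.0
    if trace.roots and psi != 0:
        z = np.asarray(trace.roots)
        signs = (-1.0) ** np.arange(1, len(z) + 1)
        alpha += 2.0 * psi * float(signs @ _ray_sf(z, k))
    return float(np.clip(alpha, 0.0, 2.0))


@dataclass
class IntegrationResult:
    """Probability of a normal in a domain, with diagnostics.

    boundary_points are domain-boundary crossings found along the integration
    rays, mapped back to the original (unwhitened) space.
    """

    p: float
    p_complement: float
    boundary_points: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"p": self.p, "p_complement": self.p_complement}
        d.update({k: v for k, v in self.diagnostics.items()
                  if isinstance(v, (int, float, str))})
        return d


@dataclass(frozen=True)
class AngularGrid:
    """Directions and quadrature weights covering half the angular space.

    For deterministic kinds the weights sum to Omega_k / 2 (each
    bidirectional ray accounts for both directions)."""

    directions: np.ndarray
    weights: np.ndarray
    kind: str

    def __post_init__(self):
        norms = np.linalg.norm(self.directions, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("directions must be unit vectors")
        if self.kind != "monte_carlo":
            k = self.directions.shape[-1]
            if not math.isclose(float(np.sum(self.weights)),
                                total_angle(k) / 2.0, rel_tol=1e-8):
                raise ValueError("weights must sum to half the total angle")

    @classmethod
    def uniform_2d(cls, n: int) -> "AngularGrid":
        dirs = uniform_half_circle(n)
        return cls(dirs, np.full(n, math.pi / n), "uniform")

    @classmethod
    def fibonacci_3d(cls, n: int) -> "AngularGrid":
        dirs = fibonacci_sphere(n)
        return cls(dirs, np.full(n, 2.0 * math.pi / n), "fibonacci")


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors on the half 2-sphere (z >= 0), with equal
    solid-angle weights; useful for visualizing 3d boundaries."""
    i = np.arange(n) + 0.5
    z = i / n  # upper hemisphere
    phi = math.pi * (1.0 + 5**0.5) * i
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def uniform_half_circle(n: int) -> np.ndarray:
    th = (np.arange(n) + 0.5) * math.pi / n
    return np.column_stack([np.cos(th), np.sin(th)])


def _alpha_batch(domain: Domain, mu, S, dirs: np.ndarray, k: int,
                 bpoints: list | None) -> np.ndarray:
    """alpha for a batch of unit directions (n, k); quadratic domains are
    fully vectorized, other formats trace ray by ray."""
    v = dirs @ S  # whitened ray z n maps to the line mu + z (S n)
    if domain.kind == "quadratic":
        q = domain.quad
        a = np.einsum("ni,ij,nj->n", v, q.Q2, v)
        b = v @ (2.0 * (q.Q2 @ mu) + q.q1)
        c = float(q(mu[None, :])[0])
        scale = np.maximum(np.maximum(np.abs(a), np.abs(b)),
                           max(abs(c), 1e-300))
        alpha = np.empty(len(dirs))
        is_quad = np.abs(a) > 1e-14 * scale
        is_lin = ~is_quad & (np.abs(b) > 1e-14 * scale)
        is_const = ~is_quad & ~is_lin

        alpha[is_const] = np.sign(c) + 1.0
        if np.any(is_lin):
            bl = b[is_lin]
            psi = -np.sign(bl)
            r = -c / bl
            alpha[is_lin] = psi + 1.0 - 2.0 * psi * _ray_sf(r, k)
            if bpoints is not None:
                bpoints.append(mu + r[:, None] * v[is_lin])
        if np.any(is_quad):
            aq, bq = a[is_quad], b[is_quad]
            psi = np.sign(aq)
            disc = bq * bq - 4.0 * aq * c
            al = psi + 1.0
            has = disc > 0.0
            if np.any(has):
                sgnb = np.where(bq[has] >= 0.0, 1.0, -1.0)
                qq = -0.5 * (bq[has] + sgnb * np.sqrt(disc[has]))
                r1 = qq / aq[has]
                r2 = c / qq
                zlo = np.minimum(r1, r2)
                zhi = np.maximum(r1, r2)
                ph = psi[has]
                al[has] += 2.0 * ph * (_ray_sf(zhi, k) - _ray_sf(zlo, k))
                if bpoints is not None:
                    vh = v[is_quad][has]
                    bpoints.append(mu + zlo[:, None] * vh)
                    bpoints.append(mu + zhi[:, None] * vh)
            alpha[is_quad] = al
        return np.clip(alpha, 0.0, 2.0)

    if domain.kind == "implicit":
        from .domains import _trace_implicit_lines

        # chunk so the scan grid (rays x cells x k) stays within memory
        step = max(1, 2_000_000 // (domain.cells + 1))
        alpha = np.empty(len(dirs))
        for s in range(0, len(dirs), step):
            vs = v[s:s + step]
            psi, roots = _trace_implicit_lines(domain.f, mu, vs, domain.m,
                                               domain.cells)
            al = psi + 1.0
            for i, r in enumerate(roots):
                if len(r) and psi[i] != 0:
                    signs = (-1.0) ** np.arange(1, len(r) + 1)
                    al[i] += 2.0 * psi[i] * float(signs @ _ray_sf(r, k))
                if bpoints is not None and len(r):
                    bpoints.append(mu + r[:, None] * vs[i])
            alpha[s:s + step] = al
        return np.clip(alpha, 0.0, 2.0)

    alpha = np.empty(len(dirs))
    for i, vi in enumerate(v):
        tr = domain.trace(mu, vi)
        if bpoints is not None and tr.roots:
            bpoints.append(mu + np.asarray(tr.roots)[:, None] * vi)
        alpha[i] = slice_probability(tr, k)
    return alpha


_GL10 = np.polynomial.legendre.leggauss(10)
_GL21 = np.polynomial.legendre.leggauss(21)


def _panel_quad(g, a: float, b: float, atol: float,
                max_panels: int = 4000, breakpoints=None,
                noise_floor: float = 0.0) -> float:
    """Panel-adaptive Gauss quadrature of a *vectorized* integrand g on
    [a, b]: each panel is estimated with 10- and 21-point Gauss rules (their
    difference is the error estimate) and the worst panels are bisected.
    All panels of a round are evaluated in a single call to g, which keeps
    the per-point cost at numpy speed.  Kinked but piecewise-smooth
    integrands (per-ray probability over angle) converge quickly because
    each kink is confined to one shrinking panel.  ``breakpoints`` seeds the
    initial panel edges (locations where the integrand is known to be
    non-smooth, e.g. tangent and asymptotic directions of a quadric), so no
    narrow feature can be missed by the sampling.
    """
    def eval_panels(lo, hi):
        mid = (lo + hi) / 2.0
        half = (hi - lo) / 2.0
        xs = np.concatenate([
            (mid[:, None] + half[:, None] * _GL10[0]).ravel(),
            (mid[:, None] + half[:, None] * _GL21[0]).ravel(),
        ])
        vals = np.asarray(g(xs))
        n = len(lo)
        v10 = vals[:10 * n].reshape(n, 10)
        v21 = vals[10 * n:].reshape(n, 21)
        i21 = (v21 @ _GL21[1]) * half
        err = np.abs(i21 - (v10 @ _GL10[1]) * half)
        return i21, err

    edges = [a, b]
    if breakpoints is not None:
        edges += [p for p in breakpoints if a < p < b]
    edges = np.unique(np.asarray(edges, dtype=float))
    lo, hi = edges[:-1], edges[1:]
    vals, errs = eval_panels(lo, hi)
    for _ in range(200):
        if errs.sum() <= atol or len(lo) >= max_panels:
            break
        split = errs > max(atol / (2.0 * len(lo)), noise_floor)
        if not np.any(split):
            break
        slo, shi = lo[split], hi[split]
        smid = (slo + shi) / 2.0
        clo = np.concatenate([slo, smid])
        chi_ = np.concatenate([smid, shi])
        cvals, cerrs = eval_panels(clo, chi_)
        lo = np.concatenate([lo[~split], clo])
        hi = np.concatenate([hi[~split], chi_])
        vals = np.concatenate([vals[~split], cvals])
        errs = np.concatenate([errs[~split], cerrs])
    return float(vals.sum())


_CHUNK = 2_000_000  # cap on points per vectorized integrand call


def _baq(g, a: float, b: float, atol: float, n_owners: int,
         breakpoints=None, init_panels: int = 4,
         max_rounds: int = 40, noise_floor: float = 0.0,
         max_panels_per_owner: int = 120) -> np.ndarray:
    """Batched adaptive quadrature: n_owners independent integrals of a
    shared vectorized integrand g(t, owner) over [a, b], refined together.

    Each owner's integral is split into panels estimated by nested 10/21
    Gauss rules; every refinement round evaluates the new panels of all
    owners in one call to g, so the work stays vectorized no matter how
    many integrals are in flight.  ``breakpoints`` (list per owner) seeds
    panel edges at known non-smooth points; otherwise ``init_panels``
    uniform panels are used.  Returns the (n_owners,) integral values.
    """
    if breakpoints is None:
        edges = np.linspace(a, b, init_panels + 1)
        lo0 = np.tile(edges[:-1], n_owners)
        hi0 = np.tile(edges[1:], n_owners)
        own0 = np.repeat(np.arange(n_owners), init_panels)
    else:
        # flat representation: (values, owner index), vectorized assembly
        bvals, bown = breakpoints
        inside = (bvals > a) & (bvals < b)
        bvals, bown = bvals[inside], bown[inside]
        order = np.lexsort((bvals, bown))
        bvals, bown = bvals[order], bown[order]
        starts = np.searchsorted(bown, np.arange(n_owners))
        # per owner: lo = [a, v_1..v_n], hi = [v_1..v_n, b]
        lo0 = np.insert(bvals, starts, a)
        own0 = np.insert(bown, starts, np.arange(n_owners))
        hi0 = np.append(lo0[1:], b)
        counts = np.bincount(bown, minlength=n_owners) + 1
        hi0[np.cumsum(counts) - 1] = b

    def eval_panels(lo, hi, own):
        mid = (lo + hi) / 2.0
        half = (hi - lo) / 2.0
        n = len(lo)
        ts = np.concatenate([
            (mid[:, None] + half[:, None] * _GL10[0]).ravel(),
            (mid[:, None] + half[:, None] * _GL21[0]).ravel(),
        ])
        owners = np.concatenate([np.repeat(own, 10), np.repeat(own, 21)])
        if len(ts) > _CHUNK:
            vals = np.concatenate([
                np.asarray(g(ts[i:i + _CHUNK], owners[i:i + _CHUNK]))
                for i in range(0, len(ts), _CHUNK)])
        else:
            vals = np.asarray(g(ts, owners))
        v10 = vals[:10 * n].reshape(n, 10)
        v21 = vals[10 * n:].reshape(n, 21)
        i21 = (v21 @ _GL21[1]) * half
        err = np.abs(i21 - (v10 @ _GL10[1]) * half)
        return i21, err

    lo, hi, own = lo0, hi0, own0
    vals, errs = eval_panels(lo, hi, own)
    for _ in range(max_rounds):
        owner_err = np.bincount(own, weights=errs, minlength=n_owners)
        owner_cnt = np.bincount(own, minlength=n_owners)
        active = (owner_err > atol) & (owner_cnt < max_panels_per_owner)
        if not np.any(active):
            break
        # panels whose apparent error is at the integrand's own noise level
        # cannot be improved by splitting
        thresh = np.maximum(atol / (2.0 * owner_cnt[own]), noise_floor)
        split = active[own] & (errs > thresh)
        if not np.any(split):
            break
        slo, shi, sown = lo[split], hi[split], own[split]
        smid = (slo + shi) / 2.0
        clo = np.concatenate([slo, smid])
        chi_ = np.concatenate([smid, shi])
        cown = np.concatenate([sown, sown])
        cvals, cerrs = eval_panels(clo, chi_, cown)
        keep = ~split
        lo = np.concatenate([lo[keep], clo])
        hi = np.concatenate([hi[keep], chi_])
        own = np.concatenate([own[keep], cown])
        vals = np.concatenate([vals[keep], cvals])
        errs = np.concatenate([errs[keep], cerrs])
    return np.bincount(own, weights=vals, minlength=n_owners)


def _trig_quartic(f0, f1, f2, f3, f4):
    """tan(t/2)-substitution quartic coefficients of F(t) = f0 + f1 cos t
    + f2 sin t + f3 cos^2 t + f4 cos t sin t."""
    return (
        f0 - f1 + f3,
        2.0 * f2 - 2.0 * f4,
        2.0 * f0 - 2.0 * f3,
        2.0 * f2 + 2.0 * f4,
        f0 + f1 + f3,
    )


def _trig_roots_many(coeff_rows) -> list[float]:
    """Zeros in (0, pi) of several degree-2 trig polynomials at once, via
    batched companion-matrix eigenvalues of their tan(t/2) quartics."""
    comps = []
    extra: list[float] = []
    for row in coeff_rows:
        c = np.asarray(_trig_quartic(*row), dtype=float)
        scale = np.max(np.abs(c))
        if scale == 0.0 or not np.all(np.isfinite(c)):
            continue
        c = c / scale
        nz = np.flatnonzero(np.abs(c) > 1e-14)
        if len(nz) == 0:
            continue
        c = c[nz[0]:]
        n = len(c) - 1
        if n == 0:
            continue
        if n < 4:  # degenerate leading terms: solve the low order directly
            for r in np.roots(c):
                if abs(r.imag) < 1e-9 * (1.0 + abs(r.real)) and r.real > 0.0:
                    extra.append(2.0 * math.atan(r.real))
            continue
        comp = np.zeros((4, 4))
        comp[1:, :3] = np.eye(3)
        comp[0, :] = -c[1:] / c[0]
        comps.append(comp)
    out = extra
    if comps:
        ev = np.linalg.eigvals(np.stack(comps)).ravel()
        real = np.abs(ev.imag) < 1e-9 * (1.0 + np.abs(ev.real))
        for r in ev.real[real & (ev.real > 0.0)]:
            out.append(2.0 * math.atan(r))
    return out


def _circle_breakpoints(q, o, w0v, cv, sv) -> list[float]:
    """Angles t in (0, pi) where the trace of the quadratic q along the line
    x(z) = o + z v(t), with v(t) = w0v + cos(t) cv + sin(t) sv, changes
    character: zeros of the leading coefficient a(t) (asymptotic directions)
    and of the discriminant (tangent directions)."""
    Q = q.Q2
    g = 2.0 * (Q @ np.asarray(o, float)) + q.q1
    c0 = float(q(np.asarray(o, float)[None, :])[0])
    qf = lambda x, y: float(x @ Q @ y)
    # a(t) in the basis {1, cos t, sin t, cos^2 t, cos t sin t}
    g0 = qf(w0v, w0v) + qf(sv, sv)
    g1 = 2.0 * qf(w0v, cv)
    g2 = 2.0 * qf(w0v, sv)
    g3 = qf(cv, cv) - qf(sv, sv)
    g4 = 2.0 * qf(cv, sv)
    b0, b1, b2 = float(g @ w0v), float(g @ cv), float(g @ sv)
    # disc(t) = b(t)^2 - 4 c0 a(t), same basis
    f = (
        b0 * b0 + b2 * b2 - 4.0 * c0 * g0,
        2.0 * b0 * b1 - 4.0 * c0 * g1,
        2.0 * b0 * b2 - 4.0 * c0 * g2,
        b1 * b1 - b2 * b2 - 4.0 * c0 * g3,
        2.0 * b1 * b2 - 4.0 * c0 * g4,
    )
    return sorted(_trig_roots_many([f, (g0, g1, g2, g3, g4)]))


def _sweep_breakpoints(domain: Domain, mu, S, w0, cdir, sdir):
    """Breakpoints for a great-circle direction sweep, or a uniform seeding
    for domains whose feature locations are not known analytically."""
    if domain.kind == "quadratic":
        return _circle_breakpoints(domain.quad, mu, S @ w0, S @ cdir, S @ sdir)
    return list(np.linspace(0.0, math.pi, 33)[1:-1])


def _circle_breakpoints_batch(q, o, W0, C, Sv):
    """Per-sweep breakpoints for a batch of great-circle sweeps at once.

    W0, C, Sv are (M, k) arrays of (already covariance-mapped) constant,
    cosine and sine line-direction vectors; the two degree-2 trig
    polynomials (leading coefficient and discriminant) of every sweep are
    solved together through batched companion-matrix eigenvalues.
    """
    Q = q.Q2
    g = 2.0 * (Q @ np.asarray(o, float)) + q.q1
    c0 = float(q(np.asarray(o, float)[None, :])[0])
    QW, QC, QS = W0 @ Q, C @ Q, Sv @ Q
    g0 = np.einsum("ij,ij->i", QW, W0) + np.einsum("ij,ij->i", QS, Sv)
    g1 = 2.0 * np.einsum("ij,ij->i", QW, C)
    g2 = 2.0 * np.einsum("ij,ij->i", QW, Sv)
    g3 = np.einsum("ij,ij->i", QC, C) - np.einsum("ij,ij->i", QS, Sv)
    g4 = 2.0 * np.einsum("ij,ij->i", QC, Sv)
    b0, b1, b2 = W0 @ g, C @ g, Sv @ g
    fs = np.stack([  # disc(t) then a(t), both (M, 5)
        np.stack([b0 * b0 + b2 * b2 - 4 * c0 * g0,
                  2 * b0 * b1 - 4 * c0 * g1,
                  2 * b0 * b2 - 4 * c0 * g2,
                  b1 * b1 - b2 * b2 - 4 * c0 * g3,
                  2 * b1 * b2 - 4 * c0 * g4], axis=1),
        np.stack([g0, g1, g2, g3, g4], axis=1),
    ])  # (2, M, 5)
    M = W0.shape[0]
    # tan-half quartic coefficients, (2, M, 5) highest degree first
    f0, f1, f2, f3, f4 = (fs[..., i] for i in range(5))
    quart = np.stack([f0 - f1 + f3, 2 * f2 - 2 * f4, 2 * f0 - 2 * f3,
                      2 * f2 + 2 * f4, f0 + f1 + f3], axis=-1)
    quart = quart.reshape(2 * M, 5)
    scale = np.max(np.abs(quart), axis=1)
    ok = (scale > 0) & np.all(np.isfinite(quart), axis=1)
    quart[ok] /= scale[ok, None]
    lead = ok & (np.abs(quart[:, 0]) > 1e-14)
    vals_parts, own_parts = [], []
    if np.any(lead):
        rows = np.flatnonzero(lead)
        comp = np.zeros((len(rows), 4, 4))
        comp[:, 1:, :3] = np.eye(3)
        comp[:, 0, :] = -quart[rows, 1:] / quart[rows, 0, None]
        ev = np.linalg.eigvals(comp)
        good = (np.abs(ev.imag) < 1e-9 * (1.0 + np.abs(ev.real))) \
            & (ev.real > 0)
        rr, cc = np.nonzero(good)
        vals_parts.append(2.0 * np.arctan(ev.real[rr, cc]))
        own_parts.append(rows[rr] % M)
    # degenerate leading coefficients: rare, solve per row
    for r in np.flatnonzero(ok & ~lead):
        c = quart[r]
        nz = np.flatnonzero(np.abs(c) > 1e-14)
        if len(nz) == 0 or len(c) - 1 - nz[0] == 0:
            continue
        for u in np.roots(c[nz[0]:]):
            if abs(u.imag) < 1e-9 * (1.0 + abs(u.real)) and u.real > 0:
                vals_parts.append(np.array([2.0 * math.atan(u.real)]))
                own_parts.append(np.array([r % M]))
    if vals_parts:
        return (np.concatenate(vals_parts),
                np.concatenate(own_parts).astype(np.intp))
    return np.empty(0), np.empty(0, dtype=np.intp)


def norm_prob(
    normal: NormalDist,
    domain: Domain,
    method: str = "auto",
    tol: float = DEFAULT_TOL,
    n_rays: int = DEFAULT_N_RAYS,
    seed=None,
    collect_boundary: bool = True,
    boundary_grid: AngularGrid | None = None,
) -> IntegrationResult:
    """Probability of ``normal`` in ``domain`` by the ray-trace method.

    method 'grid' uses adaptive angular cubature (k <= 4); 'mc' uses
    Monte-Carlo ray directions with a standard-error estimate; 'auto' picks
    'grid' for k <= 3 and 'mc' above.
    """
    k = normal.dim
    if method == "auto":
        method = "grid" if k <= 3 else "mc"
    if method not in ("grid", "mc"):
        raise ValueError(f"unknown method {method!r}")
    if method == "grid" and k > 4:
        raise ValueError("grid quadrature is supported only up to 4 dimensions")

    S, mu = normal.S, normal.mu
    bpoints: list[np.ndarray] | None = [] if collect_boundary else None

    diagnostics: dict = {"method": method}
    if method == "grid":
        om = total_angle(k)
        if k == 1:
            # the angular integral degenerates to the two directions
            al = _alpha_batch(domain, mu, S,
                              np.array([[1.0], [-1.0]]), k, bpoints)
            p = float(al.mean() / 2.0)
            diagnostics["n_rays"] = 2
        elif k == 2:
            def alpha_theta(th):
                dirs = np.column_stack([np.cos(th), np.sin(th)])
                return _alpha_batch(domain, mu, S, dirs, k, bpoints)

            bps = _sweep_breakpoints(domain, mu, S,
                                     np.zeros(2), np.eye(2)[0], np.eye(2)[1])
            val = _panel_quad(alpha_theta, 0.0, math.pi, tol * om,
                              breakpoints=bps)
            p = val / om
        elif k == 3:
            # inner polar sweep batched over all requested azimuths; outer
            # azimuth panel-adaptive
            quadratic = domain.kind == "quadratic"
            if quadratic:
                SQ = S  # line vectors are S @ n
                Se3 = SQ @ np.array([0.0, 0.0, 1.0])
                Se1 = SQ @ np.array([1.0, 0.0, 0.0])
                Se2 = SQ @ np.array([0.0, 1.0, 0.0])

            def inner_batch(phis):
                M = len(phis)
                cph, sph = np.cos(phis), np.sin(phis)
                if quadratic:
                    C = np.tile(Se3, (M, 1))
                    Sv = cph[:, None] * Se1 + sph[:, None] * Se2
                    bps = _circle_breakpoints_batch(
                        domain.quad, mu, np.zeros((M, 3)), C, Sv)
                else:
                    bps = None

                def g(th, ownr):
                    st = np.sin(th)
                    dirs = np.column_stack([
                        st * cph[ownr], st * sph[ownr], np.cos(th)])
                    return _alpha_batch(domain, mu, S, dirs, k, bpoints) * st

                return _baq(g, 0.0, math.pi, tol * om / (8.0 * math.pi),
                            M, breakpoints=bps, init_panels=16)

            val = _panel_quad(inner_batch, 0.0, math.pi, tol * om,
                              breakpoints=list(
                                  np.linspace(0.0, math.pi, 9)[1:-1]))
            p = val / om
        else:  # k == 4: three batched levels over the half 3-sphere
            quadratic = domain.kind == "quadratic"
            e = np.eye(4)
            Se = S @ e  # columns S e_i

            def level3(chs, ths):
                """phi-integral of alpha for (chi, theta) pairs."""
                M = len(chs)
                sc, cc = np.sin(chs), np.cos(chs)
                st, ct = np.sin(ths), np.cos(ths)
                A = sc * st
                if quadratic:
                    W0 = (np.outer(sc * ct, Se[:, 2])
                          + np.outer(cc, Se[:, 3]))
                    C = np.outer(A, Se[:, 0])
                    Sv = np.outer(A, Se[:, 1])
                    bps = _circle_breakpoints_batch(domain.quad, mu,
                                                    W0, C, Sv)
                else:
                    bps = None

                def g(ph, ownr):
                    dirs = np.column_stack([
                        A[ownr] * np.cos(ph), A[ownr] * np.sin(ph),
                        (sc * ct)[ownr], cc[ownr]])
                    return _alpha_batch(domain, mu, S, dirs, k, bpoints)

                return _baq(g, 0.0, math.pi, tol * om / 100.0,
                            M, breakpoints=bps, init_panels=8)

            def level2(chs):
                M = len(chs)

                def g(th, ownr):
                    return level3(chs[ownr], th) * np.sin(th)

                vals = _baq(g, 0.0, math.pi, tol * om / 30.0,
                            M, init_panels=8,
                            noise_floor=3.0 * tol * om / 100.0)
                return vals * np.sin(chs) ** 2

            val = _panel_quad(level2, 0.0, math.pi, tol * om / 2.0,
                              breakpoints=list(
                                  np.linspace(0.0, math.pi, 9)[1:-1]),
                              noise_floor=3.0 * tol * om / 30.0)
            p = val / om
        diagnostics["tol"] = tol
    else:
        rng = np.random.default_rng(seed)
        dirs = rng.standard_normal((int(n_rays), k))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        alphas = _alpha_batch(domain, mu, S, dirs, k, bpoints)
        p = float(alphas.mean() / 2.0)
        se = float(alphas.std(ddof=1) / 2.0 / math.sqrt(len(alphas)))
        diagnostics.update(n_rays=int(n_rays), se=se, seed=seed)
        if se > tol:
            diagnostics["warning"] = (
                f"standard error {se:.2e} exceeds requested tolerance {tol:.2e}"
            )

    if boundary_grid is not None:
        bpoints = []
        _alpha_batch(domain, mu, S, boundary_grid.directions, k, bpoints)

    p = float(min(max(p, 0.0), 1.0))
    if bpoints:
        boundary = np.concatenate([np.atleast_2d(b) for b in bpoints])
    else:
        boundary = np.empty((0, k))
    return IntegrationResult(p, 1.0 - p, boundary, diagnostics)
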