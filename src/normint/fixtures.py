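"""Seeded fixture generation: random normals, non-normal samples, and the
builtin demonstration domains (torus, polyhedron, trig field, circle union,
power function)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .domains import Domain, QuadraticCoeffs, combine_domains
from .normal import NormalDist

__all__ = [
    "generate_fixture",
    "random_normal",
    "random_normals",
    "random_quadratic",
    "t_samples",
    "skewed_samples",
    "torus_field",
    "polyhedron_field",
    "trig_field",
    "power_field",
    "two_circles_domain",
    "builtin_domain",
]


def random_spd(k: int, rng: np.random.Generator,
               eig_range=(0.3, 3.0)) -> np.ndarray:
    """Random SPD matrix: a random rotation of a positive diagonal."""
    A = rng.standard_normal((k, k))
    Q, _ = np.linalg.qr(A)
    eigs = rng.uniform(*eig_range, size=k)
    return (Q * eigs) @ Q.T


def random_normal(k: int, rng: np.random.Generator,
                  mean_scale: float = 1.0) -> NormalDist:
    return NormalDist(rng.normal(0.0, mean_scale, size=k), random_spd(k, rng))


def random_normals(k: int, n_classes: int, seed=None,
                   mean_scale: float = 1.0) -> list[NormalDist]:
    rng = np.random.default_rng(seed)
    return [random_normal(k, rng, mean_scale) for _ in range(n_classes)]


def random_quadratic(k: int, rng: np.random.Generator,
                     scale: float = 1.0) -> QuadraticCoeffs:
    A = rng.standard_normal((k, k)) * scale
    return QuadraticCoeffs((A + A.T) / 2.0, rng.standard_normal(k) * scale,
                           rng.standard_normal() * scale)


def t_samples(n: int, k: int, df: float = 3.0, seed=None,
              mu=None, scale=None) -> np.ndarray:
    """Multivariate-t draws (heavy-tailed, non-normal)."""
    rng = np.random.default_rng(seed)
    mu = np.zeros(k) if mu is None else np.asarray(mu, float)
    scale = np.eye(k) if scale is None else np.asarray(scale, float)
    g = rng.chisquare(df, size=n) / df
    z = rng.multivariate_normal(np.zeros(k), scale, size=n)
    return mu + z / np.sqrt(g)[:, None]


def skewed_samples(n: int, k: int, seed=None, shift: float = 0.0,
                   rate: float = 1.0) -> np.ndarray:
    """Deliberately non-normal (exponentially skewed) class for adequacy
    demos: independent exponential margins, shifted."""
    rng = np.random.default_rng(seed)
    return shift + rng.exponential(1.0 / rate, size=(n, k))


def labeled_frame(arrays, labels) -> pd.DataFrame:
    """Stack per-class sample arrays into a labeled table (features x1..xk)."""
    frames = []
    for X, lab in zip(arrays, labels):
        X = np.atleast_2d(X)
        df = pd.DataFrame(X, columns=[f"x{i+1}" for i in range(X.shape[1])])
        df["label"] = lab
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---- builtin demonstration fields -----------------------------------------

def torus_field(a: float = 1.0, b: float = 2.0):
    """3d torus a - (b - sqrt(x1^2+x2^2))^2 - x3^2 > 0: tube of squared radius
    a around a ring of radius b in the x1-x2 plane."""

    def f(x):
        x = np.atleast_2d(np.asarray(x, float))
        r = np.sqrt(x[:, 0] ** 2 + x[:, 1] ** 2)
        return a - (b - r) ** 2 - x[:, 2] ** 2

    return f


def polyhedron_field(radius: float = 1.0):
    """4d cross-polytope sum_i |x_i| < radius."""

    def f(x):
        x = np.atleast_2d(np.asarray(x, float))
        return radius - np.abs(x).sum(axis=1)

    return f


def trig_field():
    """h(x) = x1 sin x2 - x2 cos x1."""

    def f(x):
        x = np.atleast_2d(np.asarray(x, float))
        return x[:, 0] * np.sin(x[:, 1]) - x[:, 1] * np.cos(x[:, 0])

    return f


def power_field():
    """f(x, y) = x^y (defined for x > 0)."""

    def f(x):
        x = np.atleast_2d(np.asarray(x, float))
        return x[:, 0] ** x[:, 1]

    return f


def two_circles_domain(centers=((-0.75, 0.0), (0.75, 0.0)),
                       radius: float = 1.0) -> Domain:
    """Union of two discs."""
    doms = []
    for cx, cy in centers:
        Q2 = -np.eye(2)
        q1 = 2.0 * np.array([cx, cy])
        q0 = radius**2 - cx**2 - cy**2
        doms.append(Domain.quadratic(QuadraticCoeffs(Q2, q1, q0)))
    return combine_domains("union", doms)


def builtin_domain(name: str, params: dict | None = None) -> Domain:
    params = dict(params or {})
    if name == "torus":
        m = params.pop("m", 10.0)
        return Domain.implicit(torus_field(**params), m=m)
    if name == "polyhedron":
        m = params.pop("m", 10.0)
        return Domain.implicit(polyhedron_field(**params), m=m)
    if name == "trig":
        m = params.pop("m", 10.0)
        return Domain.implicit(trig_field(), m=m)
    if name == "two_circles":
        return two_circles_domain(**params)
    raise ValueError(f"unknown builtin domain {name!r}")


def generate_fixture(kind: str, params: dict | None = None, seed=None):
    """Seeded fixtures for tests and demos; identical seed, identical output.

    kinds: 'random_normals' (means and random SPD covariances),
    't_samples' (heavy-tailed class draws), 'skewed_samples' (exponential,
    non-normal), 'builtin_domain' (named demonstration domain).
    """
    params = dict(params or {})
    if kind == "random_normals":
        return random_normals(params.get("k", 2),
                              params.get("n_classes", 2), seed,
                              params.get("mean_scale", 1.0))
    if kind == "t_samples":
        return t_samples(params.get("n", 1000), params.get("k", 2),
                         params.get("df", 3.0), seed,
                         params.get("mu"), params.get("scale"))
    if kind == "skewed_samples":
        return skewed_samples(params.get("n", 1000), params.get("k", 2),
                              seed, params.get("shift", 0.0),
                              params.get("rate", 1.0))
    if kind == "builtin_domain":
        return builtin_domain(params.pop("name"), params)
    raise ValueError(f"unknown fixture kind {kind!r}")
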