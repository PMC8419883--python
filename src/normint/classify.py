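"""Bayes-optimal and custom classification among normal distributions.

Between two normals the Bayes classifier is a quadratic boundary beta(x) in
the log expected-value-gain ratio; its error rates are generalized chi-square
tail probabilities (or ray-trace integrals for custom, non-quadratic
boundaries).  Among more normals, each decision region is an intersection of
pairwise quadratic regions and is integrated by ray tracing.  Labeled samples
can be fitted by maximum likelihood and the boundary further optimized for
the sample by direct search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .domains import Domain, QuadraticCoeffs, combine_domains
from .gx2 import GX2Params, gx2_params, gx2_sf
from .integrate import norm_prob
from .normal import NormalDist

__all__ = [
    "ValueStructure",
    "ErrorMatrix",
    "ClassifyResult",
    "bayes_boundary_two",
    "classification_regions",
    "classify_normals",
    "classify_samples",
    "fit_normals",
    "optimize_boundary",
    "decision_variable",
    "project_axis",
]


@dataclass(frozen=True)
class ValueStructure:
    """Priors p_i and outcome values v_ij (value of classifying i as j).

    The Bayes rule depends on the values only through the relative gains
    v_i = v_ii - sum_{j != i} v_ij.
    """

    priors: np.ndarray
    V: np.ndarray

    def __post_init__(self):
        priors = np.atleast_1d(np.asarray(self.priors, dtype=float))
        V = np.atleast_2d(np.asarray(self.V, dtype=float))
        if np.any(priors < 0) or abs(priors.sum() - 1.0) > 1e-8:
            raise ValueError("priors must be nonnegative and sum to 1")
        if V.shape != (len(priors), len(priors)) or not np.all(np.isfinite(V)):
            raise ValueError("V must be a finite square matrix matching priors")
        object.__setattr__(self, "priors", priors / priors.sum())
        object.__setattr__(self, "V", V)

    @classmethod
    def equal(cls, n_classes: int) -> "ValueStructure":
        """Equal priors, unit value matrix (accuracy-maximizing)."""
        return cls(np.full(n_classes, 1.0 / n_classes), np.eye(n_classes))

    @property
    def gains(self) -> np.ndarray:
        """Relative value gains v_i = v_ii - sum_{j!=i} v_ij."""
        off = self.V.sum(axis=1) - np.diag(self.V)
        return np.diag(self.V) - off

    @property
    def n_classes(self) -> int:
        return len(self.priors)


@dataclass(frozen=True)
class ErrorMatrix:
    """Outcome probabilities p_mat[i, j] = p(classified j | true i)."""

    p_mat: np.ndarray
    priors: np.ndarray

    def __post_init__(self):
        p = np.atleast_2d(np.asarray(self.p_mat, dtype=float))
        pr = np.atleast_1d(np.asarray(self.priors, dtype=float))
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("rows of the error matrix must sum to 1")
        object.__setattr__(self, "p_mat", p)
        object.__setattr__(self, "priors", pr)

    @property
    def p_e(self) -> float:
        """Prior-weighted overall error."""
        return float(self.priors @ (1.0 - np.diag(self.p_mat)))

    @property
    def p_c(self) -> float:
        return 1.0 - self.p_e

    def to_dict(self) -> dict:
        return {"p_mat": self.p_mat.tolist(), "priors": self.priors.tolist(),
                "p_e": self.p_e}


@dataclass
class ClassifyResult:
    error_matrix: ErrorMatrix
    boundary: Optional[QuadraticCoeffs]
    d_b: Optional[float] = None
    d_a: Optional[float] = None
    d_e: Optional[float] = None
    aux: dict = field(default_factory=dict)


def bayes_boundary_two(a: NormalDist, b: NormalDist,
                       vs: Optional[ValueStructure] = None) -> QuadraticCoeffs:
    """Bayes classifier between two normals: choose the first class where

        beta(x) = x' Q2 x + q1' x + q0 > 0,

    with Q2 = (Sigma_b^-1 - Sigma_a^-1)/2, q1 = Sigma_a^-1 mu_a -
    Sigma_b^-1 mu_b, and q0 collecting the Mahalanobis, log-determinant and
    log prior-gain terms.
    """
    if vs is None:
        vs = ValueStructure.equal(2)
    ga, gb = vs.gains
    pa, pb = vs.priors
    if pa * ga <= 0 or pb * gb <= 0:
        raise ValueError("prior-weighted relative gains must be positive")
    ca = linalg.cho_factor(a.Sigma)
    cb = linalg.cho_factor(b.Sigma)
    ia = linalg.cho_solve(ca, np.eye(a.dim))
    ib = linalg.cho_solve(cb, np.eye(b.dim))
    Q2 = (ib - ia) / 2.0
    q1 = ia @ a.mu - ib @ b.mu
    logdet_a = 2.0 * np.sum(np.log(np.diag(ca[0])))
    logdet_b = 2.0 * np.sum(np.log(np.diag(cb[0])))
    q0 = (
        0.5 * (b.mu @ ib @ b.mu - a.mu @ ia @ a.mu)
        + 0.5 * (logdet_b - logdet_a)
        + np.log((pa * ga) / (pb * gb))
    )
    return QuadraticCoeffs(Q2, q1, float(q0))


def classification_regions(classes: Sequence[NormalDist],
                           vs: Optional[ValueStructure] = None) -> list[Domain]:
    """Decision region of each class: the intersection over the others of its
    pairwise Bayes quadratic regions (min-of-quadratics)."""
    n = len(classes)
    if vs is None:
        vs = ValueStructure.equal(n)
    g = vs.gains
    regions = []
    for i in range(n):
        doms = []
        for j in range(n):
            if j == i:
                continue
            pair = ValueStructure(
                np.array([vs.priors[i], vs.priors[j]])
                / (vs.priors[i] + vs.priors[j]),
                np.diag([g[i], g[j]]),
            )
            doms.append(Domain.quadratic(
                bayes_boundary_two(classes[i], classes[j], pair)))
        regions.append(doms[0] if len(doms) == 1
                       else combine_domains("intersect", doms))
    return regions


def _prob_positive(normal: NormalDist, boundary: QuadraticCoeffs,
                   method: str, **kw) -> float:
    """P(beta(x) > 0) for x ~ normal, by the generalized chi-square tail or
    the ray method."""
    if method == "gx2":
        p = gx2_params(normal, boundary)
        if p.is_degenerate:
            return float(p.m > 0.0)
        return float(gx2_sf(0.0, p))
    return norm_prob(normal, Domain.quadratic(boundary),
                     collect_boundary=False, **kw).p


def classify_normals(
    classes: Sequence[NormalDist],
    vs: Optional[ValueStructure] = None,
    boundary: Optional[QuadraticCoeffs | Domain] = None,
    method: str = "auto",
    **integ_kw,
) -> ClassifyResult:
    """Error matrix of Bayes-optimal (or custom-boundary) classification.

    Two classes use the quadratic boundary beta (or the supplied custom one);
    probabilities come from the generalized chi-square method when the
    boundary is quadratic (method 'gx2' or 'auto') and from ray tracing
    otherwise.  More than two classes intersect pairwise quadratic regions
    and always integrate by rays.  For two classes under unit values, the
    discriminability indices d_b, d_a, d_e are attached.
    """
    n = len(classes)
    if n < 2:
        raise ValueError("need at least two classes")
    if vs is None:
        vs = ValueStructure.equal(n)
    if n == 2:
        custom_domain = None
        if boundary is None:
            bound = bayes_boundary_two(classes[0], classes[1], vs)
        elif isinstance(boundary, QuadraticCoeffs):
            bound = boundary
        elif isinstance(boundary, Domain) and boundary.kind == "quadratic":
            bound = boundary.quad
        else:
            custom_domain = boundary
            bound = None
        if custom_domain is not None:
            if method == "gx2":
                raise ValueError("gx2 method requires a quadratic boundary")
            p_a = norm_prob(classes[0], custom_domain,
                            collect_boundary=False, **integ_kw).p
            p_b = norm_prob(classes[1], custom_domain,
                            collect_boundary=False, **integ_kw).p
        else:
            meth = "gx2" if method in ("auto", "gx2") else "ray"
            p_a = _prob_positive(classes[0], bound, meth, **integ_kw)
            p_b = _prob_positive(classes[1], bound, meth, **integ_kw)
        p_mat = np.array([[p_a, 1.0 - p_a], [p_b, 1.0 - p_b]])
        em = ErrorMatrix(p_mat, vs.priors)
        res = ClassifyResult(em, bound)
        if np.array_equal(vs.V, np.eye(2)):
            from . import dprime  # runtime import; dprime builds on classify

            res.d_a, res.d_e = dprime.dprime_approx(classes[0], classes[1])
            d_b, p_e_opt, fallback = dprime.dprime_bayes(classes[0], classes[1])
            res.d_b = d_b
            res.aux["p_e_bayes"] = p_e_opt
            res.aux["d_b_fallback"] = fallback
            if bound is not None:
                res.aux["decision_var"] = [gx2_params(c, bound) for c in classes]
        return res

    if boundary is not None:
        raise ValueError("custom boundaries are supported for two classes only")
    regions = classification_regions(classes, vs)
    p_mat = np.empty((n, n))
    for i, cls_i in enumerate(classes):
        for j, reg in enumerate(regions):
            p_mat[i, j] = norm_prob(cls_i, reg, collect_boundary=False,
                                    **integ_kw).p
        p_mat[i] /= p_mat[i].sum()  # absorb quadrature residue
    return ClassifyResult(ErrorMatrix(p_mat, vs.priors), None)


def classify_samples(X: np.ndarray, labels: np.ndarray,
                     regions_or_boundary, class_order: Sequence) -> np.ndarray:
    """Empirical outcome-fraction matrix of labeled samples under a boundary
    (beta > 0 chooses the first class; exact zeros go to the second) or a
    list of decision-region domains."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    n = len(class_order)
    counts = np.zeros((n, n))
    if isinstance(regions_or_boundary, QuadraticCoeffs):
        assigned = np.where(regions_or_boundary(X) > 0, 0, 1)
    else:
        inside = np.column_stack([r.contains(X) for r in regions_or_boundary])
        assigned = np.argmax(inside, axis=1)
        none = ~inside.any(axis=1)
        if np.any(none):  # boundary ties: fall back to the last class
            assigned[none] = n - 1
    for i, lab in enumerate(class_order):
        sel = labels == lab
        for j in range(n):
            counts[i, j] = np.sum(assigned[sel] == j)
        counts[i] /= max(sel.sum(), 1)
    return counts


def fit_normals(samples: pd.DataFrame, label_col: str = "label"):
    """Maximum-likelihood normals per class from a labeled sample table.

    Means are sample means, covariances are normalized by the class count n
    (ML, not n-1), priors are relative frequencies.  Returns (classes,
    labels, ValueStructure with unit values).
    """
    if label_col not in samples.columns:
        raise ValueError(f"label column {label_col!r} not found")
    feats = [c for c in samples.columns if c != label_col]
    labels = sorted(samples[label_col].unique())
    if len(labels) < 2:
        raise ValueError("need at least two classes")
    classes, counts = [], []
    for lab in labels:
        X = samples.loc[samples[label_col] == lab, feats].to_numpy(dtype=float)
        if len(X) < 2:
            raise ValueError(f"class {lab!r} needs at least two observations")
        mu = X.mean(axis=0)
        Sigma = np.cov(X, rowvar=False, ddof=0)
        Sigma = np.atleast_2d(Sigma)
        if np.linalg.matrix_rank(Sigma) < Sigma.shape[0]:
            raise ValueError(f"class {lab!r} has a singular sample covariance")
        classes.append(NormalDist(mu, Sigma))
        counts.append(len(X))
    priors = np.asarray(counts, float) / sum(counts)
    return classes, labels, ValueStructure(priors, np.eye(len(labels)))


def _pack(q: QuadraticCoeffs) -> np.ndarray:
    k = q.dim
    iu = np.triu_indices(k)
    return np.concatenate([q.Q2[iu], q.q1, [q.q0]])


def _unpack(v: np.ndarray, k: int) -> QuadraticCoeffs:
    iu = np.triu_indices(k)
    nq = len(iu[0])
    Q2 = np.zeros((k, k))
    Q2[iu] = v[:nq]
    Q2 = (Q2 + Q2.T) - np.diag(np.diag(Q2))
    return QuadraticCoeffs(Q2, v[nq:nq + k], v[-1])


def sample_value(X: np.ndarray, labels: np.ndarray, bound: QuadraticCoeffs,
                 vs: ValueStructure, class_order: Sequence) -> float:
    """Prior- and value-weighted expected outcome of classifying the samples."""
    p_mat = classify_samples(X, labels, bound, class_order)
    return float(vs.priors @ np.sum(p_mat * vs.V, axis=1))


def optimize_boundary(
    samples: pd.DataFrame,
    init: Optional[QuadraticCoeffs] = None,
    vs: Optional[ValueStructure] = None,
    label_col: str = "label",
    maxfev: int = 10_000,
) -> QuadraticCoeffs:
    """Sample-optimized quadratic boundary gamma between two labeled classes.

    Starting from ``init`` (the Bayes boundary of the fitted normals by
    default; a lower-dimensional boundary is zero-padded into the full
    feature space), the (k+1)(k+2)/2 free coefficients are rescaled to unit
    norm and optimized by Nelder-Mead direct search to maximize the samples'
    expected outcome value.  The returned boundary never scores below init.
    """
    classes, class_order, vs_fit = fit_normals(samples, label_col)
    if len(class_order) != 2:
        raise ValueError("boundary optimization works on two classes")
    if vs is None:
        vs = vs_fit
    feats = [c for c in samples.columns if c != label_col]
    k = len(feats)
    X = samples[feats].to_numpy(dtype=float)
    labels = samples[label_col].to_numpy()
    if init is None:
        init = bayes_boundary_two(classes[0], classes[1], vs)
    elif init.dim < k:  # warm start from an augmented feature space
        Q2 = np.zeros((k, k))
        Q2[:init.dim, :init.dim] = init.Q2
        q1 = np.zeros(k)
        q1[:init.dim] = init.q1
        init = QuadraticCoeffs(Q2, q1, init.q0)

    v0 = _pack(init)
    nrm = np.linalg.norm(v0)
    if nrm > 0:
        v0 = v0 / nrm

    def neg_value(v):
        n = np.linalg.norm(v)
        if n == 0 or not np.all(np.isfinite(v)):
            return 1e9
        return -sample_value(X, labels, _unpack(v / n, k), vs, class_order)

    res = optimize.minimize(
        neg_value, v0, method="Nelder-Mead",
        options={"maxfev": maxfev, "xatol": 1e-6, "fatol": 1e-10,
                 "adaptive": True},
    )
    cand = _unpack(res.x / np.linalg.norm(res.x), k)
    val_init = sample_value(X, labels, init, vs, class_order)
    val_cand = sample_value(X, labels, cand, vs, class_order)
    # the sample value is piecewise constant; never return a worse boundary
    return cand if val_cand >= val_init else init


def decision_variable(data, boundary: QuadraticCoeffs):
    """Project onto the scalar Bayes decision variable beta(x).

    Samples (n, k arrays) map to their beta values (classifying the scalars
    against 0 preserves every classification outcome); a NormalDist maps to
    the generalized chi-square parameters of its beta distribution.
    """
    if isinstance(data, NormalDist):
        if data.dim != boundary.dim:
            raise ValueError("boundary and normal dimensions differ")
        return gx2_params(data, boundary)
    X = np.atleast_2d(np.asarray(data, dtype=float))
    if X.shape[-1] != boundary.dim:
        raise ValueError("boundary and data dimensions differ")
    return boundary(X)


def project_axis(normal: NormalDist, w: np.ndarray) -> NormalDist:
    """1d normal of the projection w'x for a unit vector w."""
    w = np.asarray(w, dtype=float)
    w = w / np.linalg.norm(w)
    return NormalDist(np.array([w @ normal.mu]),
                      np.array([[w @ normal.Sigma @ w]]))
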