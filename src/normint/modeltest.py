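"""Testing whether fitted normals adequately predict classification counts.

Rather than testing normality directly, the comparison is made on what a
classification experiment can resolve: for a family of boundaries swept
through the space, the outcome counts (hits, false alarms, each error-matrix
cell and the overall error) predicted by the fitted normals are compared with
those of the true source, each as a binomial mean +/- sd band at the
experiment's number of trials.  A normal model is adequate when the bands
overlap along the whole sweep; judging "close enough" is left to the
investigator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import (
    ErrorMatrix,
    ValueStructure,
    bayes_boundary_two,
    classification_regions,
    classify_samples,
    _prob_positive,
)
from .domains import Domain, QuadraticCoeffs
from .integrate import norm_prob
from .normal import NormalDist

__all__ = ["BoundaryFamily", "OutcomeBands", "make_family", "outcome_bands"]


@dataclass(frozen=True)
class BoundaryFamily:
    """A one-parameter family of classification boundaries.

    kinds: 'lr_offset' shifts the constant offset q0 of the two-class Bayes
    boundary (contours of the log-likelihood ratio; reference at offset 0);
    'cov_scale' rebuilds boundaries from covariances scaled by each factor
    (reference at 1); 'prior_sweep' rebuilds multi-class regions under each
    assumed prior vector (reference at the true priors).
    """

    kind: str
    grid: np.ndarray
    classes: tuple
    vs: ValueStructure

    def member(self, param):
        """The classifier at one grid value: a QuadBoundary for two classes,
        or a list of decision-region Domains for more."""
        cls = list(self.classes)
        if self.kind == "lr_offset":
            base = bayes_boundary_two(cls[0], cls[1], self.vs)
            return QuadraticCoeffs(base.Q2, base.q1, base.q0 + float(param))
        if self.kind == "cov_scale":
            scaled = [NormalDist(c.mu, c.Sigma * float(param)) for c in cls]
            if len(cls) == 2:
                return bayes_boundary_two(scaled[0], scaled[1], self.vs)
            return classification_regions(scaled, self.vs)
        if self.kind == "prior_sweep":
            priors = np.asarray(param, dtype=float)
            vs = ValueStructure(priors / priors.sum(), self.vs.V)
            if len(cls) == 2:
                return bayes_boundary_two(cls[0], cls[1], vs)
            return classification_regions(cls, vs)
        raise ValueError(f"unknown family kind {self.kind!r}")


def make_family(classes: Sequence[NormalDist], vs: Optional[ValueStructure],
                kind: str, grid) -> BoundaryFamily:
    if kind not in ("lr_offset", "cov_scale", "prior_sweep"):
        raise ValueError(f"unknown family kind {kind!r}")
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty parameter grid")
    if kind == "lr_offset" and len(classes) != 2:
        raise ValueError("lr_offset families need exactly two classes")
    if vs is None:
        vs = ValueStructure.equal(len(classes))
    return BoundaryFamily(kind, grid, tuple(classes), vs)


@dataclass
class OutcomeBands:
    """Binomial mean +/- sd bands of each outcome fraction along the sweep,
    under the normal model and under the true source (paired for overlay)."""

    grid: np.ndarray
    outcomes: list  # outcome names: 'p(J|i)' cells and 'p_e'
    model_mean: np.ndarray  # (n_grid, n_outcomes)
    model_sd: np.ndarray
    true_mean: np.ndarray
    true_sd: np.ndarray
    n_trials: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, mm, ms, tm, ts in zip(self.grid, self.model_mean,
                                     self.model_sd, self.true_mean,
                                     self.true_sd):
            for o, a, b, c, d in zip(self.outcomes, mm, ms, tm, ts):
                rows.append({"param": g, "outcome": o, "model_mean": a,
                             "model_sd": b, "true_mean": c, "true_sd": d})
        return pd.DataFrame(rows)

    def max_band_separation(self, outcome: str) -> float:
        """Largest |model - true| along the sweep, in units of the band sd."""
        j = self.outcomes.index(outcome)
        sd = np.maximum(np.sqrt(self.model_sd[:, j] ** 2
                                + self.true_sd[:, j] ** 2), 1e-12)
        return float(np.max(np.abs(self.model_mean[:, j]
                                   - self.true_mean[:, j]) / sd))


def _model_matrix(classes, member, vs, **kw) -> np.ndarray:
    n = len(classes)
    p = np.empty((n, n))
    if isinstance(member, QuadraticCoeffs):
        for i, c in enumerate(classes):
            pi = _prob_positive(c, member, "gx2")
            p[i] = [pi, 1.0 - pi]
    else:
        for i, c in enumerate(classes):
            for j, reg in enumerate(member):
                p[i, j] = norm_prob(c, reg, collect_boundary=False, **kw).p
            p[i] /= p[i].sum()
    return p


def outcome_bands(
    true_samples: pd.DataFrame,
    model: Sequence[NormalDist],
    family: BoundaryFamily,
    n_trials: int = 100,
    n_boot: int = 1000,
    seed=None,
    label_col: str = "label",
    **integ_kw,
) -> OutcomeBands:
    """Outcome-count bands along a boundary family.

    For every boundary, each error-matrix cell is computed analytically under
    the fitted normal ``model`` and by (bootstrap-resampled) classification of
    the true source's labeled samples; each is reported as the binomial
    mean +/- sd of the outcome fraction at ``n_trials`` per class, and the
    overall error as the prior-weighted combination with propagated sd.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    feats = [c for c in true_samples.columns if c != label_col]
    labels_all = sorted(true_samples[label_col].unique())
    n = len(labels_all)
    if n != len(model):
        raise ValueError("sample classes and model classes do not match")
    X = true_samples[feats].to_numpy(dtype=float)
    y = true_samples[label_col].to_numpy()
    priors = family.vs.priors

    names = [f"p({labels_all[j]}|{labels_all[i]})"
             for i in range(n) for j in range(n)] + ["p_e"]
    n_out = len(names)
    G = len(family.grid) if family.kind != "prior_sweep" else len(family.grid)
    mm = np.empty((G, n_out))
    ms = np.empty((G, n_out))
    tm = np.empty((G, n_out))
    ts = np.empty((G, n_out))

    # bootstrap index draws, shared across boundaries for a smooth sweep
    class_idx = [np.flatnonzero(y == lab) for lab in labels_all]
    n_rep = max(1, min(n_boot, 50))  # fraction means stabilize quickly
    boots = [rng.integers(0, len(ix), size=(n_rep, len(ix)))
             for ix in class_idx]

    for g, param in enumerate(family.grid):
        if family.kind == "prior_sweep" and n > 2:
            pvec = np.full(n, (1.0 - param) / (n - 1))
            pvec[1] = param  # sweep the second class's assumed prior
            member = family.member(pvec)
        elif family.kind == "prior_sweep":
            member = family.member([1.0 - param, param])
        else:
            member = family.member(param)

        p_model = _model_matrix(model, member, family.vs, **integ_kw)
        regions = member
        p_true = np.empty((n, n))
        for i, (ix, bt) in enumerate(zip(class_idx, boots)):
            # mean over bootstrap resamples of the classified fractions
            frac = np.zeros(n)
            for rep in bt:
                cm = classify_samples(X[ix][rep], y[ix][rep], regions,
                                      labels_all)
                frac += cm[i]
            p_true[i] = frac / len(bt)

        for p_mat, mean_out, sd_out in ((p_model, mm, ms), (p_true, tm, ts)):
            cells = p_mat.ravel()
            sds = np.sqrt(cells * (1.0 - cells) / n_trials)
            err = priors @ (1.0 - np.diag(p_mat))
            err_sd = np.sqrt(np.sum(
                (priors**2)
                * np.diag(p_mat) * (1.0 - np.diag(p_mat)) / n_trials))
            mean_out[g] = np.concatenate([cells, [err]])
            sd_out[g] = np.concatenate([sds, [err_sd]])

    return OutcomeBands(family.grid, names, mm, ms, tm, ts, n_trials)
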