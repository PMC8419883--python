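import numpy as np
import pandas as pd
import pytest
from scipy import stats

from normint import (
    Domain,
    NormalDist,
    QuadraticCoeffs,
    ValueStructure,
    bayes_boundary_two,
    classify_normals,
    classify_samples,
    decision_variable,
    fit_normals,
    gx2_rand,
    mahalanobis,
    optimize_boundary,
    project_axis,
)
from normint.classify import sample_value
from normint.fixtures import labeled_frame, random_normal, random_spd, t_samples


def two_1d(mu_a=0.0, sa=1.0, mu_b=1.0, sb=1.0):
    return NormalDist([mu_a], [[sa**2]]), NormalDist([mu_b], [[sb**2]])


class TestBayesBoundary:
    def test_equal_covariances_give_flat_boundary(self, rng):
        Sigma = random_spd(2, rng)
        a = NormalDist([0.0, 0.0], Sigma)
        b = NormalDist([1.0, -0.5], Sigma)
        bound = bayes_boundary_two(a, b)
        assert np.max(np.abs(bound.Q2)) < 1e-10

    def test_prior_gain_shifts_only_offset(self):
        a, b = two_1d(0.0, 1.0, 1.0, 2.0)
        vs1 = ValueStructure([0.5, 0.5], np.eye(2))
        vs2 = ValueStructure([2.0 / 3.0, 1.0 / 3.0], np.eye(2))
        b1 = bayes_boundary_two(a, b, vs1)
        b2 = bayes_boundary_two(a, b, vs2)
        assert np.allclose(b1.Q2, b2.Q2)
        assert np.allclose(b1.q1, b2.q1)
        assert b2.q0 - b1.q0 == pytest.approx(np.log(2.0))

    def test_nonpositive_gain_rejected(self):
        a, b = two_1d()
        vs = ValueStructure([0.5, 0.5], np.array([[0.0, 1.0], [0.0, 1.0]]))
        with pytest.raises(ValueError):
            bayes_boundary_two(a, b, vs)


class TestClassifyNormals:
    def test_classic_equal_variance_error(self):
        a, b = two_1d(0.0, 1.0, 1.0, 1.0)
        res = classify_normals([a, b])
        expected = stats.norm.cdf(-0.5)
        assert res.error_matrix.p_mat[0, 1] == pytest.approx(expected, abs=1e-12)
        assert res.error_matrix.p_mat[1, 0] == pytest.approx(expected, abs=1e-12)
        assert res.d_b == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_gx2_and_ray_agree(self, rng, k):
        a, b = random_normal(k, rng), random_normal(k, rng)
        r_gx2 = classify_normals([a, b], method="gx2")
        r_ray = classify_normals([a, b], method="ray")
        assert np.max(np.abs(r_gx2.error_matrix.p_mat
                             - r_ray.error_matrix.p_mat)) < 1e-6

    def test_rows_sum_to_one(self, rng):
        classes = [random_normal(2, rng) for _ in range(3)]
        res = classify_normals(classes, tol=1e-6)
        assert np.allclose(res.error_matrix.p_mat.sum(axis=1), 1.0)

    def test_label_swap_transposes_error_matrix(self, rng):
        a, b = random_normal(2, rng), random_normal(2, rng)
        p_ab = classify_normals([a, b]).error_matrix.p_mat
        p_ba = classify_normals([b, a]).error_matrix.p_mat
        # relabeling permutes both rows and columns
        assert np.allclose(p_ab, p_ba[::-1][:, ::-1], atol=1e-9)

    def test_multiclass_with_two_reduces_to_pairwise(self, rng):
        a, b = random_normal(2, rng), random_normal(2, rng)
        direct = classify_normals([a, b], method="ray").error_matrix.p_mat
        via_regions = classify_normals([a, b], method="gx2").error_matrix.p_mat
        assert np.allclose(direct, via_regions, atol=1e-6)

    def test_three_class_2d_matches_simulation(self, rng):
        classes = [
            NormalDist([0.0, 0.0], [[1.0, 0.3], [0.3, 0.8]]),
            NormalDist([2.5, 0.5], [[0.7, -0.2], [-0.2, 1.2]]),
            NormalDist([1.0, 2.5], [[1.1, 0.0], [0.0, 0.5]]),
        ]
        res = classify_normals(classes, tol=1e-6)
        n = 10**5
        from normint.classify import classification_regions

        regions = classification_regions(classes)
        for i, c in enumerate(classes):
            x = c.sample(n, rng)
            inside = np.column_stack([r.contains(x) for r in regions])
            frac = inside.mean(axis=0)
            se = np.sqrt(frac * (1 - frac) / n) + 1e-6
            assert np.all(np.abs(frac - res.error_matrix.p_mat[i]) < 3.5 * se)

    def test_bayes_boundary_is_locally_optimal(self, rng):
        a, b = random_normal(2, rng), random_normal(2, rng)
        res = classify_normals([a, b])
        base = res.error_matrix.p_e
        bound = res.boundary
        for _ in range(5):
            pert = QuadraticCoeffs(
                bound.Q2 + 0.05 * random_spd(2, rng) - 0.05 * np.eye(2),
                bound.q1 + 0.05 * rng.normal(size=2),
                bound.q0 + 0.05 * rng.normal())
            alt = classify_normals([a, b], boundary=pert)
            assert alt.error_matrix.p_e >= base - 1e-9

    def test_custom_nonquadratic_boundary_needs_ray(self, rng):
        a, b = random_normal(2, rng), random_normal(2, rng)
        dom = Domain.implicit(
            lambda x: 1.0 - np.abs(np.atleast_2d(x)).sum(axis=1))
        with pytest.raises(ValueError):
            classify_normals([a, b], boundary=dom, method="gx2")


class TestFitNormals:
    def test_two_point_class_hand_computation(self):
        df = labeled_frame(
            [np.array([[-1.0], [1.0]]), np.array([[3.0], [5.0], [4.0]])],
            ["a", "b"])
        classes, labels, vs = fit_normals(df)
        assert labels == ["a", "b"]
        assert classes[0].mu[0] == pytest.approx(0.0)
        # ML covariance divides by n, not n-1
        assert classes[0].Sigma[0, 0] == pytest.approx(1.0)
        assert np.allclose(vs.priors, [0.4, 0.6])

    def test_priors_are_relative_frequencies(self, rng):
        df = labeled_frame(
            [rng.normal(size=(75, 2)), rng.normal(size=(25, 2)) + 3.0],
            ["a", "b"])
        _, _, vs = fit_normals(df)
        assert np.allclose(vs.priors, [0.75, 0.25])

    def test_large_sample_consistency(self, rng):
        true = NormalDist([1.0, -2.0], [[2.0, 0.5], [0.5, 1.0]])
        X = true.sample(20000, rng)
        df = labeled_frame([X, rng.normal(size=(50, 2)) + 9.0], ["a", "b"])
        classes, _, _ = fit_normals(df)
        se = np.sqrt(np.diag(true.Sigma) / len(X))
        assert np.all(np.abs(classes[0].mu - true.mu) < 4 * se)
        assert np.max(np.abs(classes[0].Sigma - true.Sigma)) < 0.1

    def test_missing_label_column(self):
        with pytest.raises(ValueError):
            fit_normals(pd.DataFrame({"x1": [1.0, 2.0]}))


class TestOptimizeBoundary:
    def test_separable_clouds_reach_perfect_accuracy(self, rng):
        Xa = rng.normal(size=(40, 2)) * 0.2
        Xb = rng.normal(size=(40, 2)) * 0.2 + np.array([3.0, 0.0])
        df = labeled_frame([Xa, Xb], ["a", "b"])
        # deliberately offset initial boundary misclassifies some points
        bad = QuadraticCoeffs(np.zeros((2, 2)), [-1.0, 0.0], 2.4)
        gamma = optimize_boundary(df, init=bad)
        X = df[["x1", "x2"]].to_numpy()
        labels = df["label"].to_numpy()
        counts = classify_samples(X, labels, gamma, ["a", "b"])
        assert counts[0, 0] == 1.0 and counts[1, 1] == 1.0

    def test_gamma_never_scores_below_bayes_init(self, rng):
        Xa = t_samples(150, 2, df=3.0, seed=3, mu=[0.0, 0.0])
        Xb = t_samples(150, 2, df=3.0, seed=4, mu=[2.0, 1.0])
        df = labeled_frame([Xa, Xb], ["a", "b"])
        classes, order, vs = fit_normals(df)
        beta = bayes_boundary_two(classes[0], classes[1], vs)
        gamma = optimize_boundary(df)
        X = df[["x1", "x2"]].to_numpy()
        labels = df["label"].to_numpy()
        assert sample_value(X, labels, gamma, vs, order) >= \
            sample_value(X, labels, beta, vs, order)


class TestDecisionVariable:
    def test_sample_counts_preserved_exactly(self, rng):
        a, b = random_normal(2, rng), random_normal(2, rng)
        bound = bayes_boundary_two(a, b)
        X = np.vstack([a.sample(500, rng), b.sample(500, rng)])
        labels = np.array(["a"] * 500 + ["b"] * 500)
        full = classify_samples(X, labels, bound, ["a", "b"])
        scalars = decision_variable(X, bound)
        one_d = np.where(scalars > 0, "A", "B")
        assert (one_d[:500] == "A").mean() == full[0, 0]
        assert (one_d[500:] == "B").mean() == full[1, 1]

    def test_normal_maps_to_gx2_of_boundary(self, rng):
        a, b = random_normal(2, rng), random_normal(2, rng)
        bound = bayes_boundary_two(a, b)
        params = decision_variable(a, bound)
        draws = gx2_rand(10**5, params, seed=9)
        direct = bound(a.sample(10**5, rng))
        assert abs(draws.mean() - direct.mean()) < \
            4 * direct.std() / np.sqrt(len(direct)) + 4 * draws.std() / np.sqrt(len(draws))

    def test_axis_projection_is_marginal(self, rng):
        nd = random_normal(3, rng)
        proj = project_axis(nd, [1.0, 0.0, 0.0])
        assert proj.mu[0] == pytest.approx(nd.mu[0])
        assert proj.Sigma[0, 0] == pytest.approx(nd.Sigma[0, 0])


class TestEqualCovarianceIdentity:
    def test_d_b_equals_mahalanobis(self, rng):
        Sigma = random_spd(2, rng)
        a = NormalDist([0.0, 0.0], Sigma)
        b = NormalDist([1.5, -0.7], Sigma)
        res = classify_normals([a, b])
        assert res.d_b == pytest.approx(
            mahalanobis(a.mu, b.mu, Sigma), abs=1e-9)
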