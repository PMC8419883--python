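import math

import numpy as np
import pytest
from scipy import stats

from normint import (
    NormalDist,
    classify_normals,
    dprime_approx,
    dprime_bayes,
    m_interval_accuracy,
    mahalanobis,
    roc_curve,
    two_interval,
    yes_no_errors,
)
from normint.fixtures import random_normal, random_spd


def nd1(mu, sigma):
    return NormalDist([mu], [[sigma**2]])


class TestApproxIndices:
    def test_equal_sds_reduce_to_classic_dprime(self):
        d_a, d_e = dprime_approx(nd1(0.0, 0.5), nd1(1.0, 0.5))
        assert d_a == pytest.approx(2.0)
        assert d_e == pytest.approx(2.0)

    def test_equal_covariances_equal_mahalanobis(self, rng):
        Sigma = random_spd(2, rng)
        a = NormalDist([0.0, 0.0], Sigma)
        b = NormalDist([1.0, 1.0], Sigma)
        d_a, d_e = dprime_approx(a, b)
        d_m = mahalanobis(a.mu, b.mu, Sigma)
        assert d_a == pytest.approx(d_m)
        assert d_e == pytest.approx(d_m)

    def test_extreme_sd_ratio_limit(self):
        # sd ratio 1e4: the rms index underestimates by the 1/sqrt(2) factor
        d_a, d_e = dprime_approx(nd1(0.0, 1e4), nd1(1.0, 1.0))
        assert d_a / d_e == pytest.approx(1.0 / math.sqrt(2.0), abs=1e-3)

    def test_ordering_d_a_below_d_e(self, rng):
        for _ in range(1000):
            k = int(rng.integers(1, 3))
            a, b = random_normal(k, rng), random_normal(k, rng)
            d_a, d_e = dprime_approx(a, b)
            assert d_a <= d_e + 1e-12


class TestBayesIndex:
    def test_equal_covariance_identity(self, rng):
        Sigma = random_spd(3, rng)
        a = NormalDist([0.0, 0.0, 0.0], Sigma)
        b = NormalDist([0.8, -0.3, 1.1], Sigma)
        d_b, p_e, fb = dprime_bayes(a, b)
        assert not fb
        assert d_b == pytest.approx(mahalanobis(a.mu, b.mu, Sigma), abs=1e-9)

    def test_variance_only_discriminability(self):
        d_b, p_e, _ = dprime_bayes(nd1(0.0, 1.0), nd1(0.0, 2.0))
        assert d_b > 0.0
        assert p_e < 0.5

    def test_symmetry(self, rng):
        for _ in range(5):
            a, b = random_normal(2, rng), random_normal(2, rng)
            assert dprime_bayes(a, b)[0] == pytest.approx(
                dprime_bayes(b, a)[0], rel=1e-9)

    def test_1d_underflow_falls_back_to_d_e(self):
        a, b = nd1(0.0, 1.0), nd1(200.0, 1.0)
        d_b, p_e, fb = dprime_bayes(a, b)
        assert fb and p_e == 0.0
        assert d_b == pytest.approx(dprime_approx(a, b)[1])

    def test_convergence_of_d_e_to_d_b(self):
        # fixed sd ratio, growing separation: d_e approaches d_b
        ratios = []
        for sep in (2.0, 10.0, 60.0):
            a, b = nd1(0.0, 2.0), nd1(sep, 1.0)
            d_b = dprime_bayes(a, b)[0]
            d_e = dprime_approx(a, b)[1]
            ratios.append(d_e / d_b)
        assert abs(ratios[-1] - 1.0) < 0.01
        assert abs(ratios[-1] - 1.0) < abs(ratios[1] - 1.0) < abs(ratios[0] - 1.0)


class TestYesNo:
    def test_equal_variance_limit(self):
        p_Ba, p_Ab, p_e = yes_no_errors(0.0, 1.0, 1.0, 1.0)
        assert p_e == pytest.approx(stats.norm.cdf(-0.5))

    def test_matches_boundary_classification(self, rng):
        for _ in range(5):
            mu_a, mu_b = rng.normal(size=2) * 2.0
            s_a, s_b = rng.uniform(0.5, 2.0, size=2)
            p_Ba, p_Ab, p_e = yes_no_errors(mu_a, s_a, mu_b, s_b)
            res = classify_normals([nd1(mu_a, s_a), nd1(mu_b, s_b)])
            assert p_Ba == pytest.approx(res.error_matrix.p_mat[0, 1], abs=1e-9)
            assert p_Ab == pytest.approx(res.error_matrix.p_mat[1, 0], abs=1e-9)

    def test_variance_only_case(self):
        _, _, p_e = yes_no_errors(0.0, 2.0, 0.0, 1.0)
        assert p_e < 0.5

    def test_invalid_sd(self):
        with pytest.raises(ValueError):
            yes_no_errors(0.0, -1.0, 1.0, 1.0)


class TestTwoInterval:
    def test_equal_sd_closed_form(self):
        a, b = nd1(0.0, 1.0), nd1(1.5, 1.0)
        res = two_interval(a, b)
        assert res.p_c == pytest.approx(stats.norm.cdf(1.5 / math.sqrt(2.0)),
                                        abs=1e-9)

    def test_identical_classes_are_guessing(self):
        res = two_interval(nd1(0.3, 1.2), nd1(0.3, 1.2))
        assert res.p_c == pytest.approx(0.5, abs=1e-9)

    def test_gx2_and_ray_routes_agree(self, rng):
        for _ in range(3):
            mus = rng.normal(size=2)
            sds = rng.uniform(0.6, 1.8, size=2)
            a, b = nd1(mus[0], sds[0]), nd1(mus[1], sds[1])
            r1 = two_interval(a, b, method="gx2")
            r2 = two_interval(a, b, method="ray")
            assert r1.p_e == pytest.approx(r2.p_e, abs=1e-8)

    def test_sqrt2_scaling_of_approx_indices(self, rng):
        from normint.dprime import _pair_to_two_interval

        for _ in range(10):
            mus = rng.normal(size=2) * 2
            sds = rng.uniform(0.5, 2.0, size=2)
            a, b = nd1(mus[0], sds[0]), nd1(mus[1], sds[1])
            ab, ba = _pair_to_two_interval(a, b)
            d_a1, d_e1 = dprime_approx(a, b)
            d_a2, d_e2 = dprime_approx(ab, ba)
            assert d_a2 == pytest.approx(math.sqrt(2.0) * d_a1, rel=1e-9)
            assert d_e2 == pytest.approx(math.sqrt(2.0) * d_e1, rel=1e-9)


class TestMInterval:
    def test_two_intervals_match_two_interval_task(self):
        a, b = nd1(0.0, 1.0), nd1(1.2, 0.7)
        p2 = m_interval_accuracy(2, 0.0, 1.0, 1.2, 0.7)
        assert p2 == pytest.approx(two_interval(a, b).p_c, abs=1e-8)

    @pytest.mark.parametrize("m", [2, 3, 5])
    def test_identical_classes_guess_at_1_over_m(self, m):
        assert m_interval_accuracy(m, 0.4, 1.1, 0.4, 1.1) == pytest.approx(1.0 / m)

    def test_decreasing_in_m(self):
        accs = [m_interval_accuracy(m, 0.0, 1.0, 1.0, 1.0) for m in (2, 3, 4)]
        assert accs[0] > accs[1] > accs[2]

    def test_equal_sd_matches_simulation(self, rng):
        mu_a, mu_b, sigma = 1.0, 0.0, 1.0
        m = 3
        p = m_interval_accuracy(m, mu_a, sigma, mu_b, sigma)
        n = 10**6
        x = rng.normal(mu_b, sigma, size=(n, m))
        x[:, 0] = rng.normal(mu_a, sigma, size=n)
        # equal sds: the max-likelihood-ratio rule is the max-value rule
        hits = (np.argmax(x, axis=1) == 0).mean()
        assert abs(p - hits) < 3 * math.sqrt(p * (1 - p) / n)


class TestRoc:
    def test_curve_endpoints(self):
        a, b = nd1(0.0, 1.0), nd1(1.0, 2.0)
        curve = roc_curve(a, b, mode="criterion")
        assert curve.p_fa.min() == pytest.approx(0.0, abs=1e-9)
        assert curve.p_fa.max() == pytest.approx(1.0, abs=1e-9)
        assert curve.p_hit.min() == pytest.approx(0.0, abs=1e-9)
        assert curve.p_hit.max() == pytest.approx(1.0, abs=1e-9)

    def test_lr_auc_equals_two_interval_accuracy(self, rng):
        for _ in range(3):
            mus = rng.normal(size=2)
            sds = rng.uniform(0.6, 1.6, size=2)
            a, b = nd1(mus[0], sds[0]), nd1(mus[1], sds[1])
            curve = roc_curve(a, b, mode="likelihood_ratio")
            assert curve.auc == pytest.approx(two_interval(a, b).p_c,
                                              abs=1e-3)

    def test_farthest_point_recovers_d_b(self, rng):
        for _ in range(3):
            a = nd1(rng.normal(), rng.uniform(0.7, 1.5))
            b = nd1(rng.normal() + 1.0, rng.uniform(0.7, 1.5))
            curve = roc_curve(a, b, mode="likelihood_ratio")
            d_b = dprime_bayes(a, b)[0]
            assert curve.d_b_est == pytest.approx(d_b, abs=0.05)

    def test_empirical_criterion_mode(self, rng):
        xa = rng.normal(1.0, 1.0, 2000)
        xb = rng.normal(0.0, 1.0, 2000)
        curve = roc_curve(xa, xb, mode="criterion")
        # AUC approximates the classic equal-variance value
        expected = stats.norm.cdf(1.0 / math.sqrt(2.0))
        assert curve.auc == pytest.approx(expected, abs=0.03)
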