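import math

import numpy as np
import pytest
from scipy import integrate as sint
from scipy import stats

from normint import (
    Domain,
    NormalDist,
    QuadraticCoeffs,
    RayTrace,
    combine_domains,
    norm_prob,
    ray_cdf,
    ray_pdf,
    slice_probability,
    total_angle,
)
from normint.fixtures import random_normal, random_quadratic


class TestRayDistribution:
    def test_1d_density_is_standard_normal(self):
        for z in (-2.0, 0.0, 2.0):
            assert ray_pdf(z, 1) == pytest.approx(stats.norm.pdf(z))

    @pytest.mark.parametrize("k", [1, 2, 3, 7])
    def test_cdf_symmetry_and_limits(self, k):
        assert ray_cdf(0.0, k) == pytest.approx(0.5)
        assert ray_cdf(-40.0, k) == pytest.approx(0.0, abs=1e-12)
        assert ray_cdf(40.0, k) == pytest.approx(1.0)
        zs = np.linspace(-5, 5, 41)
        assert np.all(np.diff(ray_cdf(zs, k)) >= 0)

    def test_3d_cdf_chi_oracle(self):
        # via the incomplete gamma form of the chi cdf
        expected = (1 + stats.chi.cdf(1.0, 3)) / 2
        assert ray_cdf(1.0, 3) == pytest.approx(expected)

    @pytest.mark.parametrize("k", [1, 2, 4])
    def test_pdf_integrates_to_one(self, k):
        val, _ = sint.quad(lambda z: ray_pdf(z, k), -12, 12, limit=200)
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_invalid_dimension(self):
        with pytest.raises(ValueError):
            ray_cdf(0.0, 0)


class TestSliceProbability:
    def test_fully_inside(self):
        assert slice_probability(RayTrace(1, ()), 2) == pytest.approx(2.0)

    def test_single_entry(self):
        z1 = 0.8
        expected = 2 * (1 - ray_cdf(z1, 3))
        assert slice_probability(RayTrace(-1, (z1,)), 3) == pytest.approx(expected)

    def test_two_crossings_inside_start(self):
        z1, z2 = -0.5, 1.2
        expected = 2 - 2 * (1 - ray_cdf(z1, 2)) + 2 * (1 - ray_cdf(z2, 2))
        assert slice_probability(RayTrace(1, (z1, z2)), 2) == pytest.approx(expected)

    def test_grazing_is_half(self):
        assert slice_probability(RayTrace(0, ()), 3) == pytest.approx(1.0)


class TestTotalAngle:
    def test_known_values(self):
        assert total_angle(1) == pytest.approx(2.0)
        assert total_angle(2) == pytest.approx(2 * math.pi)
        assert total_angle(3) == pytest.approx(4 * math.pi)
        assert total_angle(4) == pytest.approx(2 * math.pi**2)


class TestNormProb:
    def test_whole_space(self):
        nd = NormalDist(np.zeros(2), np.eye(2))
        dom = Domain.implicit(lambda x: np.ones(len(np.atleast_2d(x))))
        assert norm_prob(nd, dom).p == pytest.approx(1.0)

    def test_halfplane_closed_form(self):
        nd = NormalDist(np.zeros(2), np.eye(2))
        q = QuadraticCoeffs(np.zeros((2, 2)), [1.0, 0.0], -1.0)
        r = norm_prob(nd, Domain.quadratic(q))
        assert r.p == pytest.approx(stats.norm.cdf(-1.0), abs=1e-9)
        assert r.p + r.p_complement == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_complement_sums_to_one(self, rng, k):
        nd = random_normal(k, rng)
        dom = Domain.quadratic(random_quadratic(k, rng))
        inv = combine_domains("invert", [dom])
        p1 = norm_prob(nd, dom, collect_boundary=False).p
        p2 = norm_prob(nd, inv, collect_boundary=False).p
        assert p1 + p2 == pytest.approx(1.0, abs=2e-8)

    def test_rotation_invariance_2d(self, rng):
        nd = random_normal(2, rng)
        q = random_quadratic(2, rng)
        th = rng.uniform(0, 2 * math.pi)
        R = np.array([[math.cos(th), -math.sin(th)],
                      [math.sin(th), math.cos(th)]])
        ndr = NormalDist(R @ nd.mu, R @ nd.Sigma @ R.T)
        qr = QuadraticCoeffs(R @ q.Q2 @ R.T, R @ q.q1, q.q0)
        p1 = norm_prob(nd, Domain.quadratic(q), collect_boundary=False).p
        p2 = norm_prob(ndr, Domain.quadratic(qr), collect_boundary=False).p
        assert p1 == pytest.approx(p2, abs=1e-7)

    def test_boundary_points_lie_on_boundary(self, rng):
        nd = random_normal(2, rng)
        q = random_quadratic(2, rng)
        r = norm_prob(nd, Domain.quadratic(q))
        assert len(r.boundary_points) > 0
        # root precision is relative to the point's scale
        resid = np.abs(q(r.boundary_points))
        scale = 1.0 + np.sum(r.boundary_points**2, axis=1)
        assert np.max(resid / scale) < 1e-9

    def test_truncation_radius_bound(self):
        # enlarging the trace radius changes p by less than 2*Phi_bar(m)
        nd = NormalDist(np.zeros(2), np.eye(2))
        f = lambda x: 4.0 - np.einsum("...i,...i->...", x, x)
        p3 = norm_prob(nd, Domain.implicit(f, m=3.0), collect_boundary=False).p
        p8 = norm_prob(nd, Domain.implicit(f, m=8.0), collect_boundary=False).p
        assert abs(p3 - p8) < 2 * stats.norm.sf(3.0)

    def test_mc_seeded_and_consistent(self, rng):
        nd = NormalDist(np.zeros(4), np.eye(4))
        q = random_quadratic(4, rng)
        dom = Domain.quadratic(q)
        r1 = norm_prob(nd, dom, method="mc", n_rays=20000, seed=1,
                       collect_boundary=False)
        r2 = norm_prob(nd, dom, method="mc", n_rays=20000, seed=1,
                       collect_boundary=False)
        r3 = norm_prob(nd, dom, method="mc", n_rays=20000, seed=2,
                       collect_boundary=False)
        assert r1.p == r2.p
        se = math.hypot(r1.diagnostics["se"], r3.diagnostics["se"])
        assert abs(r1.p - r3.p) < 4 * se

    def test_boundary_grid_fibonacci_sphere(self):
        from normint import AngularGrid

        grid = AngularGrid.fibonacci_3d(200)
        assert np.isclose(grid.weights.sum(), 2 * math.pi)
        nd = NormalDist(np.zeros(3), np.eye(3))
        q = QuadraticCoeffs(-np.eye(3), np.zeros(3), 1.0)  # unit sphere
        r = norm_prob(nd, Domain.quadratic(q), boundary_grid=grid)
        radii = np.linalg.norm(r.boundary_points, axis=1)
        assert len(radii) == 400  # two crossings per bidirectional ray
        assert np.allclose(radii, 1.0, atol=1e-12)

    def test_grid_rejected_beyond_4d(self):
        nd = NormalDist(np.zeros(5), np.eye(5))
        dom = Domain.quadratic(
            QuadraticCoeffs(np.eye(5), np.zeros(5), -1.0))
        with pytest.raises(ValueError):
            norm_prob(nd, dom, method="grid")
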