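# normint

Integrate multivariate normal distributions over arbitrary domains, compute
distributions of arbitrary functions of normal vectors, and evaluate
Bayes-optimal classification performance — error matrices, the Bayes
discriminability index d′_b, ROC curves, and yes/no / two-interval /
m-interval task accuracy.

Models of decision-making under uncertainty (ideal observers in vision
science and psychophysics, Gaussian discriminant analysis, probabilistic
planning) constantly need the probability of a normal vector
**x** ~ N(μ, Σ) landing in some region Ω. Outside a few special cases there
is no closed form, Cartesian grids waste effort on correlated, elongated
normals, and Monte Carlo cannot resolve the tiny error rates of
well-separated classes. `normint` provides two complementary engines:

- **Generalized chi-square.** For a quadratic region
  q(**x**) = **x**′Q₂**x** + q₁′**x** + q₀ > 0, whiten with the symmetric
  square root S = Σ^½ and eigen-decompose: q(**x**) is distributed as
  Σⱼ wⱼ χ′²(kⱼ, λⱼ) + N(m, s²), a generalized chi-square whose cdf follows
  from characteristic-function inversion. Exact for every quadratic —
  ellipsoids, hyperboloids, paraboloids, degenerate conics — in any
  dimension.
- **Ray tracing.** For any region, whiten, switch to polar coordinates, and
  integrate outward along bidirectional rays. Along a ray the standard
  normal follows the chi distribution, so the content of the ray's trace
  (initial sign ψ plus sorted crossing points z_i) is a short sum of chi
  tail probabilities; adaptive angular quadrature (k ≤ 4) or Monte-Carlo
  ray sampling (k > 4) adds the rays up. Regions can be quadratics,
  implicit fields f(**x**) > 0, explicit ray-trace callables, or set
  combinations (invert/intersect/union) of any of these.

On top of the integrators: pdf/cdf/inverse-cdf of any scalar f(**x**)
(the cdf at c is the normal probability of c − f(**x**) > 0), joint laws of
vector functions, the Bayes classifier between normals with priors and
outcome values (a quadratic boundary β(**x**)), multi-class
min-of-quadratics regions, maximum-likelihood fitting of labeled samples
with sample-optimized boundaries, the discriminability indices
d′_a ≤ d′_e ≤ d′_b = −2Φ⁻¹(Bayes error), and boundary-sweep tests of
whether fitted normals predict classification counts within binomial
uncertainty.

## Worked example

The distribution of a nonlinear function of a correlated normal pair, with
no special structure to exploit:

```python
import numpy as np
from normint import FuncOfNormal, NormalDist, func_inv, func_moments

rho, sx, sy = 0.8, 0.1, 0.2
nd = NormalDist([1.0, 2.0], [[sx**2, rho*sx*sy], [rho*sx*sy, sy**2]])
f = FuncOfNormal(lambda x: x[:, 0] ** x[:, 1], nd, m=8.0)

mean, sd = func_moments(f, n_grid=221, tol=1e-7)
median = func_inv(f, 0.5, tol=1e-7)
print(f"mean={mean:.3f} median={median:.3f} sd={sd:.3f}")
```

prints

```
mean=1.027 median=1.000 sd=0.211
```

so x^y has mean 1.03, median 1.00 and sd 0.21: every quantile and moment of
an arbitrary pushforward of a normal is available through the same three
calls. A classification example:

```python
from normint import NormalDist, classify_normals

a = NormalDist([0.0], [[1.0]])
b = NormalDist([1.0], [[1.0]])
res = classify_normals([a, b])
print(f"p(e)={res.error_matrix.p_e:.4f} d_b={res.d_b:.3f}")
```

prints `p(e)=0.3085 d_b=1.000` — the classic equal-variance unit-d′ pair.

## Command line

```sh
normint integrate --config problem.json --out result.json
normint classify  --config samples.json
normint roc       --config pair.json --out curve.json
normint normtest  --config samples.json --out bands.json
normint gx2       --config quadratic.json
```

Configs are JSON (or YAML) holding normal parameters, domain coefficients
or builtin domain names, and labeled-sample CSV paths; every output records
the seed, method and tolerances used.

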