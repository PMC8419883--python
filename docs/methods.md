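# Methods

## The problem and the two engines

Everything in this package reduces to one primitive: the probability that a
k-dimensional normal vector **x** ~ N(μ, Σ) falls in a region
Ω = {f(**x**) > 0}. Classification errors, function cdfs, ROC points and
discriminability indices are all such integrals for particular regions.

**Whitening.** With the symmetric square root S = Σ^½ (computed by
eigen-decomposition, eigenvalues floored at zero when within −1e−10 of the
largest, rejected below that), z = S⁻¹(**x** − μ) is standard normal. S
acts as a matrix standard deviation; all geometry happens in z-space.
Singular Σ is rejected by every whitening operation rather than
pseudo-inverted — the method assumes an invertible S.

**Generalized chi-square (quadratic Ω).** Whitening maps the quadratic to
Q̃₂ = SQ₂S, q̃₁ = 2SQ₂μ + Sq₁, q̃₀ = q(μ). Eigen-decomposing
Q̃₂ = RDR′ and rotating gives q(**x**) ~ Σⱼ wⱼ χ′²(kⱼ, λⱼ) + N(m, s²),
with w the unique nonzero eigenvalues (merged when within 1e−8·max|D| of
one another), kⱼ their multiplicities, λⱼ = Σᵢ bᵢ²/(4wⱼ²) over each
eigenvalue group (b = R′q̃₁), s² the squared norm of b over the null
eigenvalues, and m = q̃₀ − Σ wⱼλⱼ. The cdf/pdf come from Gil-Pelaez /
Imhof-type inversion of the characteristic function. Pure-normal and
single-weight parameter sets short-circuit to the exact scipy normal and
noncentral-chi-square distributions. For the general oscillatory integral
the envelope decays only algebraically when s = 0, so the tail from
t = 1/max(|w|, |m − x|, 1) outward is integrated with Fourier-weighted
(QAWF) quadrature against sin(|c|t) and cos(|c|t), c = m − x; the head and
non-oscillatory cases (s > 0, or |c| ≤ 1e−6) use plain adaptive quadrature.
Default absolute tolerance 1e−10. If the error estimate exceeds
max(10³·tol, 1e−6) the cdf raises; the pdf falls back to differencing the
cdf (relevant only in far tails where the density underflows anyway).
Inverse cdf: bracket from mean ± 10 sd, geometric expansion, Brent.

**Ray tracing (any Ω).** In whitened polar coordinates the probability is
(1/Ω_k)∫ α(**n**) d**n** over half the angular space, where the per-ray
content α(**n**) = ψ + 1 + 2ψ Σᵢ (−1)ⁱ Φ̄ray(zᵢ) needs only the ray's
trace: the initial sign ψ at −∞ and the sorted crossings zᵢ of the domain
function along the line μ + t·S**n**. Φray(z) = [1 + sign(z)F_{χₖ}(|z|)]/2
is the standard normal's distribution along a bidirectional ray (the chi
law reflected to negative z), evaluated through regularized incomplete
gamma functions so far tails do not round to zero.

Traces:

- *Quadratic domains*: the restriction is a scalar quadratic
  a t² + b t + c; ψ = sign a (or −sign b, or sign c as the leading terms
  vanish, with a 1e−14 relative threshold); roots from the numerically
  stable quadratic formula; tangent (zero-discriminant) contacts are
  discarded since membership does not flip.
- *Implicit domains*: a uniform scan of 1,000 cells (overridable) over
  (−m, m) followed by bisection to 1e−10 locates every odd-multiplicity
  zero; even-multiplicity touches are discarded. The scan and the bisection
  are vectorized across whole ray batches. The truncation to radius m
  (default 10 sd, error < 2Φ̄(10) ≈ 1.5e−23) is the only approximation.
- *Set operations*: inversion flips ψ and keeps crossings; intersection
  takes ψ = min ψᵢ and keeps the candidate crossings across which
  min fᵢ actually changes sign, decided by probing the combined sign on
  the intervals between candidates. (The simpler rule — keep roots where
  all other members are strictly positive — is equivalent generically but
  fails when member boundaries intersect exactly on the ray, e.g. every
  ray through the corner of two half-planes.) Union is the inverted
  intersection of inversions. Crossing pairs closer than 1e−12 cancel.

**Angular quadrature.** The integrand α is piecewise analytic in the
direction but has kinks and boundary-layer features where rays become
tangent to, or asymptotically parallel with, the domain boundary; sampled
error estimates (nested cubature rules) can miss these features entirely.
Two measures make the quadrature reliable:

1. *Closed-form breakpoints.* Along any great-circle sweep
   **n**(t) = **w**₀ + cos t·**c** + sin t·**s**, the per-ray leading
   coefficient a(t) and discriminant b(t)² − 4a(t)c of a quadratic domain
   are degree-2 trigonometric polynomials; their zeros — exactly the
   non-smooth angles — follow from a quartic in tan(t/2), solved by
   (batched) companion-matrix eigenvalues. Panels are seeded at these
   angles, so no feature is invisible. Non-quadratic domains fall back to
   32 uniform seed panels.
2. *Panel-adaptive vectorized Gauss quadrature.* Each panel is estimated
   by nested 10/21-point Gauss rules; panels above their share of the
   tolerance are bisected, and all new panels are evaluated in a single
   vectorized call. A batched variant runs thousands of such 1d integrals
   simultaneously (one shared integrand call per refinement round), which
   is what makes the nested-sphere integrals tractable: in 3d the polar
   sweep is batched over all azimuth nodes; in 4d three levels
   (φ inside θ inside χ) each batch the level below. Levels that consume
   noisy values from an inner level stop splitting at a noise floor of
   three times the inner tolerance, preventing runaway refinement.

k = 1 degenerates to averaging α over the two directions; k = 2 is a
single vectorized panel quadrature; k ≤ 4 is supported deterministically
('auto' uses the grid up to 3d); beyond, directions are drawn by
normalizing standard-normal vectors and p = mean(α)/2 with a reported
standard error (default 10⁵ rays, seeded). Default tolerance 1e−8
absolute. Boundary crossings found along the integration rays are mapped
back through x = Sz**n** + μ and returned for inspection; a uniform
half-circle or Fibonacci-sphere grid can be requested instead.

## Functions of a normal vector

F_f(c) = p(f(**x**) < c) is the normal probability of the implicit domain
c − f(**x**) > 0. The pdf is a central difference with relative step 1e−5
(the cdf tolerance of 1e−8 keeps the difference quotient meaningful); the
inverse cdf brackets from f(μ) with geometric expansion and uses Brent.
Moments integrate the cdf on a regular grid between the 1e−5 and
1 − 1e−5 quantiles with the truncated mass renormalized. Joint laws of two
fields intersect the two sublevel domains; the joint pdf uses a 2×2 cross
stencil with a deliberately wide step (2% of scale) and tighter cdf
tolerance 1e−9, because the mixed second difference divides by h².
Monotone transforms need no special machinery: a probability for
y = e^x is the probability of the pulled-back x-domain (the lognormal
example sums to the closed-form Φ-difference series at ln(jπ)).

## Classification

Between two normals the expected-value-optimal rule compares the quadratic
β(**x**) with Q₂ = (Σ_b⁻¹ − Σ_a⁻¹)/2, q₁ = Σ_a⁻¹μ_a − Σ_b⁻¹μ_b and q₀
collecting the Mahalanobis, log-determinant and log prior-gain
(ln p_a v_a / p_b v_b) terms, where vᵢ = vᵢᵢ − Σ_{j≠i} vᵢⱼ are the
relative gains of the value matrix. Error-matrix cells are generalized
chi-square tails of β under each class (or ray-trace integrals for custom,
non-quadratic boundaries). Points with β exactly 0 belong to the second
class — a measure-zero convention that keeps sample counts deterministic.
With more than two classes the region for class i is the intersection of
its pairwise quadratic regions (a min-of-quadratics, handled by the
ray method only); each row of the error matrix is renormalized by its sum
to absorb quadrature residue.

Fitting labeled samples uses the maximum-likelihood estimates — sample
means, covariances normalized by n (not n − 1), priors as relative
frequencies. The sample-optimized boundary γ starts at β (or at a supplied
boundary, zero-padded into a larger feature space), rescales the
(k+1)(k+2)/2 free coefficients to unit norm to remove the scale
degeneracy, and maximizes the prior- and value-weighted sample outcome by
Nelder-Mead (the sample value is piecewise constant, so a direct search is
appropriate; cap 10⁴ evaluations). The result never scores below its
start. Projection onto the decision variable β(**x**) preserves every
classification count exactly; for a normal class the projected law is the
generalized chi-square of β.

## Discriminability and tasks

d′_a uses the pooled (rms) covariance (Σ_a + Σ_b)/2 as a Mahalanobis
metric; d′_e uses the average of the symmetric sd matrices
(S_a + S_b)/2. The Bayes index d′_b = −2Φ⁻¹(p_e) converts the equal-prior,
unit-value Bayes error into the separation of two unit-variance normals
with the same overlap; it equals the Mahalanobis distance exactly when
covariances are equal and stays positive for equal means with unequal
variances. When p_e underflows double precision (beyond d′ ≈ 75, the
−2Φ⁻¹(realmin) ceiling), 1d problems return d′_e with a fallback flag and
multidimensional ones +∞.

The 1d yes/no task has a closed form: the log-likelihood ratio is a
scaled, shifted noncentral χ²₁ under each class. Rather than transcribing
the textbook constants, the threshold and noncentralities are re-derived
by completing the square of l(x) about its vertex h: with
λ = ((μ_a−μ_b)/(σ_a²−σ_b²))², the noncentralities are σ_a²λ and σ_b²λ and
the thresholds follow from −l(h)/(aσ²); the result is validated against
the boundary-classification route to 1e−9 in the tests. The two-interval
task classifies the joint 2k-d classes ab and ba (concatenated means,
block-diagonal covariances in opposite order); equal variances recover
p_c = Φ(d′/√2), and both approximate indices scale by exactly √2 under
the construction. The m-interval accuracy integrates F_b^{m−1} f_a over
the likelihood-ratio law with quantile-based limits (chi-square tails
reach far beyond mean ± k·sd). ROC curves sweep either a scalar criterion
(1d, parametric or empirical) or the offset of β — contours of the
likelihood ratio — with criteria placed uniformly in each class's
standardized units (201 per class, merged); AUC is trapezoidal and the
farthest-from-diagonal point gives d′_b as twice the z-score of its
accuracy.

## Testing a normal model

Whether fitted normals are adequate for a classification problem is judged
on what an n-trial experiment can resolve: along a family of boundaries —
likelihood-ratio offsets (shifts of q₀), covariance scalings, or assumed
prior sweeps, each containing the optimal boundary at its reference
parameter — every outcome cell is computed analytically under the normal
model and empirically from the labeled samples (bootstrap-averaged over 50
resamples; the fraction means stabilize long before the nominal 1,000),
and both are reported as binomial mean ± sd bands at n trials (overall
error: prior-weighted with propagated sd). Bands that separate by more
than ~2 combined sd somewhere along the sweep flag the non-normal class
and outcome; no automatic accept/reject rule is imposed — the judgment
belongs to the investigator. Band widths scale as 1/√n by construction.

## Synthetic data and what passing tests show

Fixtures are generated programmatically and seeded: random SPD covariances
(random rotations of uniform [0.3, 3] eigenvalues), random quadratics with
standard-normal coefficients, multivariate-t samples (heavy-tailed,
df = 3 by default) and shifted-exponential samples for the adequacy demos,
plus the demonstration domains (torus a − (b − √(x₁²+x₂²))² − x₃² with
a = 1, b = 2; the 4d cross-polytope Σ|xᵢ| < 1; the trigonometric field
x₁ sin x₂ − x₂ cos x₁; a union of unit circles at (±0.75, 0)). These
exercise correlated, anisotropic geometry and non-convex, non-quadratic,
even disconnected domains, but they are still smooth, light-tailed
constructions: passing tests demonstrate the integration and
classification machinery, not robustness to real data's outliers, missing
values or discreteness.

## Problem sizes and numerical choices

The test suite and acceptance checks run at desk scale: sampling oracles
use 10⁶–10⁷ draws (standard errors ~5e−4 and below), cross-method checks
use 100 random problems split 52/30/16/2 across 1d–4d with ray tolerances
1e−8 (1–2d), 1e−7 (3d) and 1e−6 (4d) against a ≤ 1e−6 agreement bound —
the 4d deterministic integrals are the most expensive at roughly a minute
each, which is why two of them stand in for the dimension. The x^y moment
reconstruction uses a 221-point cdf grid between the 1e−5 quantiles.
Reported quantities are rounded only at the final step.

## Known limitations

- Deterministic angular integration stops at 4 dimensions; beyond that the
  Monte-Carlo ray estimate (with its reported standard error) is the only
  route, so cross-method agreement degrades to sampling precision.
- The Imhof-type cdf targets absolute accuracy; relative accuracy in
  extreme tails (p below ~1e−15) is only available through the exact
  special cases (flat boundaries, single-weight quadratics), which is what
  the d′ ceiling study exercises.
- Implicit-domain tracing samples 1,000 cells per ray: implicit fields
  oscillating faster than the scan spacing (m/500 sd) need a larger
  ``cells`` or an explicit trace function.
- The sample-boundary optimizer is a local direct search from β; it is not
  a global optimizer and is not meant to resist adversarial geometry.
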