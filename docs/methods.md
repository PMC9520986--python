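# Methods

## The model

`fractalknots` studies how the random-knotting probability of a closed
polymer depends on its fractal dimension d_f (R ~ N^(1/d_f): d_f = 2 is
the ideal chain, d_f = 3 the fractal globule, chromatin sits in between).
Conformations come from the ring-adapted **beta model**: the Fourier
modes of the closed bead chain are independent zero-mean Gaussians with
eigenvalues

    lambda_q = 4 k |sin(pi q / N)|**chi,   q = 1 … N-1,   chi = 1 + 2/d_f,

in reduced units k_B T = b = 1, with the dumbbell spring constant
k = d (spatial dimension d ∈ {2, 3}). Each Cartesian component of mode q
has variance 1/lambda_q; the q = 0 mode (center of mass) is pinned at the
origin, and the paired modes q and N − q share the degenerate eigenvalue.
chi = 2 recovers the Rouse ring exactly; for general chi the mean-squared
internal distances scale as s^(2/d_f) on scales 1 ≪ s ≪ N.

Sampling draws the N − 1 real mode coefficients (cosine/sine pairs plus,
for even N, the Nyquist mode) and applies the inverse FFT; the forward
transform inverts it to machine precision, which the tests exercise as a
round-trip identity. All exact structural expectations used as oracles
follow from the spectrum:

    <|X_q|^2>            = d / lambda_q
    <|R_{j+s} - R_j|^2>  = (4 d / N) Σ_q sin^2(pi q s / N) / lambda_q
    <Rg^2>               = (d / N) Σ_q 1 / lambda_q

For the ideal ring the internal-distance formula reduces to s(N−s)/N;
that closed form motivates fitting structural exponents against the
closure-corrected abscissa s(N−s)/N rather than s (for d_f = 2 the fit
is then exact at any N; for other d_f it removes the leading closure
bias). The exponent-recovery suite runs at N = 1600 with window
10 ≤ s ≤ 100, where the residual finite-size error is within the test
tolerances for all four probed fractal dimensions; convergence to
2/d_f is notably slow for swollen spectra (d_f < 3/2), which the tests
acknowledge by checking the estimator against the exact-curve regression
rather than the naive asymptote.

## Knot detection

A 3D ring is typed by the knot determinant |Δ(−1)| (Alexander polynomial
at t = −1): 1 for the unknot, 3 for the trefoil, 5 for the figure-eight,
odd for every knot; `is_trivial` ⇔ determinant 1. The pipeline is

1. **KMT simplification** — a bead is elided when the triangle it spans
   with its neighbours is not pierced by any other chain segment,
   iterated to a fixed point (numba kernel with an AABB prefilter;
   coplanar geometry is resolved by an in-plane triangle test so planar
   polygons reduce to triangles). Degenerate (collinear) triangles are
   removable. Segments sharing a vertex with the triangle are tested
   with that endpoint shrunk inward by 1e-7 of the segment length, so
   touching at the shared corner does not block elision.
2. **Generic projection** — orthogonal projection along a random
   direction; among 3 candidate directions the one with fewest crossings
   is diagrammed first (a pure speed choice; the determinant is
   projection-independent and the tests verify it). A projection is
   rejected (and retried, up to 20 times) when a crossing falls within
   eps = 1e-9 × diameter of a vertex, two crossing points coincide,
   depths are ambiguous, or projected segments overlap.
3. **Determinant** — from the Wirtinger/Fox-calculus crossing matrix at
   t = −1 (over-arc +2, incoming/outgoing under-arcs −1; rows sum to
   zero), delete one row and column and take |det| in exact integer
   arithmetic. The determinant is computed modulo 30-bit primes with a
   numba elimination kernel and reconstructed by incremental CRT; primes
   are added until the symmetric residue is stable for two consecutive
   primes (each agreeing extra prime multiplies confidence by ~2^30),
   capped at the Hadamard bound where the result is certified. A
   pure-Python Bareiss (fraction-free) elimination is kept as the
   independent cross-check in the tests. Diagrams with ≤ 2 crossings are
   unknots by inspection and skip the matrix.

Composite knots report the product determinant and count as nontrivial.
Knots with unit determinant (first: 10_124) would be miscalled trivial;
they are vanishingly rare in these ensembles and the trivial/nontrivial
split is all the statistics below require.

In 2D, "knotting" is the existence of an intersection between two
non-adjacent segments (adjacent segments always meet at their shared
bead and are excluded; grazing contacts within 1e-12 × diameter count as
intersections but have measure zero under the Gaussian model). The
production vectorized sweep is checked against a plain all-pairs
orientation-predicate loop.

## Statistics

The unknot probability follows P0(N) = C exp(−N/N0). Per (d_f, N) the
unknot fraction gets a Wilson 95% interval; ln p0 is regressed on N with
delta-method weights trials·p0/(1−p0), excluding saturated points
(p0 ≥ 0.99 or ≤ 0.01, or zero unknots), giving N0 = −1/slope and
mu = ln N0 with propagated error. The exponential law is asymptotic: at
desk-scale statistics a real quadratic curvature of ln P0 is resolvable
for N ≲ 1.5 N0 at large d_f (the crossover into the asymptotic regime),
so the residual-linearity checks run on windows N ≳ 1.5 N0 there, where
the reduced chi-square returns to ≈ 1.

mu(d_f) is fit by weighted nonlinear least squares with two competing
forms — the theory's double exponential mu = c1 exp(c2 d_f) + c3 and the
scaling-style logarithm mu = c1 ln(d_f + c2) + c3 — from 16 deterministic
starts spanning sign combinations (ties by smallest |c2|). Models are
compared by a small-sample-corrected information criterion on the
weighted residual sum of squares plus a Wald–Wolfowitz runs test on
residual signs; this stands in for an appendix-level statistical
analysis that is not reproduced here.

## Theory

Topological excluded volume swells the unknotted ring on scales above
N0. The generalized Flory balance of a two-body interaction
v N²/R^d against the entropy R²/N^(2/d_f) of an ideal fractal chain
gives nu = 2(1 + 1/d_f)/(d + 2) and the swollen spectral exponent
gamma = 1 + 2 nu; gamma = chi exactly at d_f = 3/2 (in 3D), and the
Flory estimate is only trusted for d_f > 1.7 (outputs below carry an
`extrapolated` flag). The two-regime mode-amplitude model uses the bare
spectrum for q′ > N/(2 N0) and the gamma-spectrum, with a continuity
prefactor sin(pi/(2 N0))^(gamma−chi), below it.

Differentiating ln P0 = ln C − N/N0 with respect to chi and evaluating
the Gaussian averages turns the two-regime model into a linear ODE

    d mu / d d_f = f1(d_f) mu + f2(d_f),
    f1(x) = −2 (2x − 3) / (x² (x + 6)),
    f2(x) = −f1(x) [ln(pi/2) − 6 (x + 1)/(x + 6)]        (3D),

whose frozen-coefficient solution is the double exponential above with
c2 = f1 and c3 = −f2/f1. Over the campaign grid restricted to the
trusted range d_f > 1.7 the coefficient functions are roughly constant;
their representative values (arithmetic means over those nine grid
points) are c2 ≈ −0.063 and c3 ≈ −2.23. The restriction matters: f1
changes sign at d_f = 3/2, so a "roughly constant" summary over the full
grid would be meaningless.

Two scale conventions coexist deliberately. The **sample estimator** of
d ln P0/d chi uses the exact Gaussian identity

    d ln P0 / d chi = <dH/dchi> − <dH/dchi>_0,
    dH/dchi = (1/2) Σ_q lambda_q ln sin(pi q/N) |X_q|²,

with the unconstrained average analytic by equipartition; it carries the
full factor d from the vector modes and is exact at every N. The
**coefficient functions** f1/f2 are normalized per component (no factor
d): in that convention their representative values line up with the
double-exponential fit constants of the Monte-Carlo mu(d_f) curve at the
per-component scale, and the analytic derivative then *under*-estimates
|d mu/d d_f| — consistently with the measured finite-size behaviour of
the estimator (below). The package treats this normalization as part of
the theory's definition; the tests pin both conventions independently.

### Finite-size behaviour of the derivative estimator

Converting d ln P0/d chi to d mu/d d_f via the chain rule
(dchi/dd_f = −2/d_f²) and the exponential law neglects the
chi-dependence of the prefactor C, an O(N0/N) bias. Measured at
d_f = 5/2 (N0 ≈ 140): the estimator gives −0.72 ± 0.12 at N = 200
versus a numerical-differentiation value of −1.22 ± 0.04, closing to
−1.10 ± 0.19 at N = 400. The acceptance test therefore asserts the
null (zero when the constraint is disabled), correct sign, magnitude
within a factor 2 at N = 200, monotone approach from N = 100 to 400,
and agreement within combined uncertainties at N = 400 — not agreement
at N = 200, which the bias rules out at desk-scale precision.

## Campaign design and problem sizes

Campaigns derive every random stream from one seed via
`SeedSequence(seed, spawn_key=(i_df, i_N))`, making outputs
byte-reproducible. The desk-scale default is 2000 samples per (d_f, N)
point (paper-scale presets of 2×10⁴–10⁵ are a parameter away); N grids
sit at fixed multiples (0.6–3.0) of a planning estimate of N0, capped at
N ≤ 400 where the planning N0 is large (small d_f), and a fixed small-N
ladder in 2D where rings self-intersect within a handful of segments.
The acceptance suite runs: a seven-point d_f campaign at 1500
samples/point; asymptotic-window curves at d_f ∈ {3, 5} with 3000
samples/point; the d_f = 5 knotting-length measurement on
N ∈ {40, …, 240} with 3000 samples/point; 10⁵ Gaussian pentagons and
10⁶ hexagons for the stick-number floor (a projection with ≤ 2 crossings
certifies the unknot, so only candidate polygons enter the full
pipeline). At these sizes the scaled-down campaign reproduces the
double-exponential fit constants to within ~5–10% of their full-scale
values, with AICc separating the two functional forms by ≳ 50.

## What the synthetic data does and does not show

All inputs are generated by the beta model itself; there is no external
data. The model realizes prescribed large-scale fractal dimension with
strictly Gaussian, independent modes — it has no excluded volume, no
local liquid structure, no persistence-length physics, and d_f > d
configurations are geometrically admissible only because of that
idealization. Passing tests therefore validate the topological
machinery and the statistical theory *for this model class*; they do not
by themselves transfer the quantitative constants to chromatin or melt
rings, where local conformations differ.

## Numerical choices and limitations

- Projection degeneracy tolerance 1e-9 × diameter; planar-intersection
  tolerance 1e-12 × diameter; both configurable.
- Exponential-fit window excludes p0 outside (0.01, 0.99); bounds are
  arguments.
- The mu ODE integrates with solve_ivp (RK45, rtol 1e-8).
- Multi-start nonlinear fits are deterministic; non-convergence raises.
- KMT fixed points of dense (d_f ≳ 4, large N) rings can retain a few
  hundred crossings; the CRT determinant stays exact but those points
  dominate campaign cost (~10–15 ms per ring at N = 240, d_f = 5).
- The trivial/nontrivial call inherits the determinant's blind spot for
  unit-determinant knots; an optional second evaluation point of the
  Alexander polynomial is not implemented because P0 statistics do not
  need it at these chain lengths.
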