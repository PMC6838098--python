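# Methods

## Model

The package solves, for the population density u(x, t) of a single invading
species on a 2-D geographic domain in degree coordinates,

    ∂u/∂t − div(ν ∇u) + b·∇u + u(u − γ) = f,

with homogeneous Neumann (zero-flux) boundary conditions. The reaction term
u(γ − u) is logistic: u grows towards the local carrying capacity γ where
γ > 0 and decays where γ < 0. The model assumes dispersal is random at the
individual level but smooth at the population level (the classical premise
of reaction-diffusion invasion models); it does not represent rare
long-distance jumps, demographic stochasticity, or inter-species
competition.

Units: lengths in degrees (lon = x, lat = y; no projection to metres — all
reference parameters are stated in degree units), time in years, density in
arbitrary individuals-per-area units consistent with the capacity scale.
Configuration values in months are divided by 12 at parse time.

### Coefficients

* Diffusivity ν ≥ 0, default 5×10⁻⁴ deg²/yr (constant in the reference
  scenario).
* Carrying capacity from elevation z (metres): γ(z) = α(10 − z/100), i.e.
  10 at sea level, 0 at 1000 m, negative above. γ is deliberately **not**
  clamped at zero: with γ < 0 the reaction strictly removes population, so
  high terrain is hostile rather than merely neutral; this is what makes a
  ridge an absolute barrier. α is a dimensionless capacity scale (the
  second uncertain input in the UQ layer), default 1.
* Transport b supports river polylines rasterized to nodal velocities but
  ships zero in the reference scenario.
* Masks multiply γ and ν on named node sets (less-hospitable regions);
  lake masks force γ = 0 exactly. Overlapping multiplicative masks compose
  in list order; disjoint masks commute.
* All coefficient accessors take t; the reference scenario is
  time-independent, and seasonal variants are meant to be composed at
  configuration level (periodic callables), not modelled here.

## Terrain

SRTM HGT tiles are read as big-endian int16, 1201² (3 arc-sec) or 3601²
(1 arc-sec); rows are reordered so indices increase with (lat, lon), and
the −32768 void sentinel becomes a mask. Elevation at arbitrary points is
bilinear in the four surrounding cells; if any of the four is void, the
query falls back to the nearest non-void cell's value (voids are rare and
the PDE needs z defined everywhere). Since downloads cannot be assumed, a
synthetic generator produces a deterministic analytic surface — a Gaussian
ridge of amplitude A along a parallel, optionally broken by a Gaussian
valley gap and perturbed by seeded noise — exercising the identical
elevation pathway; it emulates the one feature of real terrain the model
cares about (a capacity-blocking ridge with a pass) and none of the
small-scale roughness, drainage structure, or voids of real tiles, so
passing tests demonstrate correct mechanics, not calibrated realism.

## Meshing

Domains are lat/lon rectangles: the region of interest plus a buffer
margin (default 0.5°) that pushes the zero-flux boundary away from the
area whose dynamics matter. The build order is: structured right-triangle
background grid; size-field refinement (the region of interest and any
feature geometries impose smaller local target edge lengths — a triangle is
refined while its longest edge exceeds the minimum target over its vertices
and centroid); elevation attachment; gradient-driven refinement of
triangles whose P1 elevation gradient exceeds a threshold (default
2000 m/deg; elevation is re-interpolated from the grid after each pass so
midpoints carry true grid values).

All refinement is conforming marked-edge longest-edge bisection: the
longest edge of every selected triangle is marked, marking is closed so a
triangle with any marked edge also has its longest edge marked, and marked
edges are bisected consistently on both sides. On structured
right-triangle grids, bisection alternates between two similarity classes,
so the initial minimum angle (45° for square cells) is preserved under
arbitrary refinement, no hanging nodes can occur, and the result is
deterministic — the reasons this mechanism was chosen over red-green
subdivision or re-meshing. General polygonal boundaries are out of scope
(they would need a constrained Delaunay mesher); interior structure is
expressed through the size field instead.

## Discretization

P1 Lagrange elements. Element integration rules are the cheapest exact
ones for each integrand: the consistent mass block (|T|/12)[[2,1,1],
[1,2,1],[1,1,2]] (a lumped option exists but is off by default); ν and b
sampled at element centroids, exact because P1 gradients are constant per
element (for ν this is exact even for linearly varying coefficients; for b
it is exact only for constant velocity — a one-point rule, consistent of
order h otherwise); the cubic reaction integrand (γ and u both P1)
integrated by the 4-point degree-3 triangle rule. Assembly is vectorized
over triangles in a fixed order, so matrices are bit-reproducible.

Invariants maintained and tested: M symmetric with positive diagonal and
ΣM = |Ω|; A symmetric positive semi-definite with A·1 = 0; B·1 = 0
(pure-Neumann kernels).

## Time stepping

Semi-implicit IMEX with uniform Δt (default 0.1 months = 1/120 yr):

    (M + Δt A + Δt B) uⁿ⁺¹ = M uⁿ + Δt F(uⁿ).

Without transport the matrix is SPD and each step is solved by conjugate
gradients with a symmetric Jacobi preconditioner (the matrix is
mass-dominated for realistic Δt, so CG reaches the 10⁻¹⁰ relative-residual
contract in a few iterations; an incomplete-LU preconditioner is *not*
used on the SPD path because ILU is nonsymmetric and can make CG diverge).
With transport, BiCGStab preconditioned by incomplete LU is used under the
same residual contract. The matrix and preconditioner are built once and
reused across steps whenever the coefficients are time-independent.

Two deliberate choices:

* **Accuracy is first order in Δt.** The explicit reaction is forward
  Euler; on spatially uniform fields the full scheme reduces *exactly* to
  the scalar recurrence uⁿ⁺¹ = uⁿ + Δt uⁿ(γ − uⁿ), whose peak relative
  error against the closed-form logistic over γt ≤ 5 is ≈ 8.7% at
  Δt = 1/120 yr and γ = 10/yr, halving with Δt. The tests assert exactly
  this behaviour (exact scalar reduction, first-order convergence) rather
  than a tighter bound the scheme cannot meet.
* **Nonnegativity floor.** The consistent-mass discretization has no
  discrete maximum principle; sharp fronts undershoot slightly, and under
  the logistic reaction a negative value is dynamically unstable (it grows
  like e^{γt} and eventually blows up). `run_simulation` therefore floors
  the density at 0 after every step. The floor only removes unphysical
  negative values, is inert on nonnegative states (all uniform-field
  reductions are unaffected), and can be disabled.

Outputs: density snapshots at a configurable stride (default every 10
steps, bounding memory), probe series every step by P1 interpolation in
the containing triangle, and the nodal arrival-time field — the first
upward crossing of the threshold (default 1), located by linear
interpolation between the bracketing steps, +inf where never reached.
Front speed along a transect is estimated as the inverse slope of the
least-squares fit of arrival time against distance; on a homogeneous strip
at ν = 5×10⁻⁴, γ = 10 with edge length 0.0025° it recovers 2√(νγ) within
3%. The initial colony is a sharp indicator circle of configurable
amplitude (default 10, the sea-level capacity — the value is not dictated
by anything physical beyond "established population", so it is exposed in
the configuration).

## Uncertainty quantification

Inputs are data-given sample sets (or histograms, whose moments use bin
midpoints weighted by counts — both paths are tested against each other).
For each input, raw moments μ₀..μ₂ₘ define the Hankel matrix [μᵢ₊ⱼ]; its
Cholesky factor yields the three-term recurrence of the moment-orthonormal
polynomials, and the eigen-decomposition of the associated Jacobi matrix
yields the m-point Gaussian rule (exact for monomials to degree 2m−1
against the sample moments; the Hankel matrix is scaled before
factorization so tiny-magnitude inputs such as ν ~ 10⁻⁴ stay well
conditioned, and a non-positive-definite Hankel matrix raises a degeneracy
error suggesting a lower order).

The d-dimensional design is the standard Smolyak combination

    A(l, d) = Σ_{l+1 ≤ |i| ≤ l+d} (−1)^{l+d−|i|} C(d−1, l+d−|i|) ⊗ₖ U^{iₖ},

with the i-point rule as U^i, duplicates merged with summed weights
(weights may be negative; they sum to 1 and are used only for projection,
never to build PDFs). At level 1 with two inputs the merged grid is the
5-point cross (in 1-D the combination collapses to the plain 2-point
rule). The surrogate basis is the tensor-product orthonormal family
truncated at total degree ≤ level (3 functions at level 1, d = 2), and
projection is discrete pseudo-spectral with the squared basis function in
the denominator (the discrete norm):

    aₖ = Σᵢ w(ηᵢ) ψₖ(ηᵢ) θᵢ / Σᵢ ψₖ(ηᵢ)² θᵢ.

Surrogate statistics come from Monte-Carlo bootstrap resampling of the
stored input samples (independent across dimensions, seeded, default 10⁵
draws). Mean and σ of whole snapshot fields are computed from the MC
moments of the basis vector (algebraically identical to realizing every
field sample, at a fraction of the memory); per-probe PDFs, and
arrival-time distributions (per-realization threshold crossing with
linear-in-time interpolation of the surrogate series), are computed from
batched realizations. Under the reference inputs ν ~ N(5×10⁻⁴, 1.2×10⁻⁴)
and α ~ U(0, 2), note that the ν samples have a negative tail at ≈ 4σ;
with realistic sample sizes this is immaterial and the quadrature nodes
μ±σ are safely positive.

A structural property worth knowing: in the wake of the front the density
sits at its logistic equilibrium u = αγ₀(z), so the wake standard
deviation is exactly γ₀·std(α) ≈ 5.8 at sea level under α ~ U(0, 2) — σ
peaks near the front (where arrival-time spread mixes "arrived" and "not
yet") and then relaxes to that plateau, not to zero. Only when the
capacity scale is certain does the wake σ vanish.

## The bundled demo

`demo_scenario()` is sized to run the full pipeline (deterministic run
plus the 5-run UQ and 10⁵-sample surrogate MC) in about a minute on one
CPU: 1°×1° region of interest with a 0.2° buffer, 60 arc-sec synthetic
terrain, ~5000 mesh nodes after gradient refinement, Δt = 0.1 months over
10 years. The geography (1200 m ridge, 1000 m hostile line, one valley
gap) is chosen so the qualitative invasion logic — westward deflection,
gap crossing, never-invaded crest — is a property the tests can assert.

## Known limitations

* Rectangular computational domains only; no curved geographic boundaries.
* First-order accuracy in time; no adaptive Δt; explicit reaction imposes
  the usual mild step restriction (Δt·γ small).
* One-point coefficient sampling makes strongly varying ν/b within single
  elements inaccurate — refine the mesh there instead (the gradient-driven
  pass exists for exactly this).
* No transport stabilization (SUPG): strongly advection-dominated runs
  will oscillate; the intended regime is diffusion/reaction-dominated.
* Independent uncertain inputs, levels ≤ 3, no adaptive sparse grids, no
  Bayesian calibration of coefficients from field data.
* Long-distance dispersal, multi-species competition and seasonality
  models are out of scope (time-dependent coefficients are only a hook).
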