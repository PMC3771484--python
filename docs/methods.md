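# Methods

## The model

`liverzones` implements a minimal mechanistic model of liver zonation: two
hepatocyte subtypes, distinguished by the enzymes they carry, line a
representative capillary (sinusoid) of length L with blood flowing
unidirectionally from the inlet at x = 0. Writing ρ₁(x,t) and ρ₂(x,t) for
the linear densities of the two cell types, each type grows logistically
against a shared ceiling of cell sites σ (contact inhibition) and dies at a
rate βᵢ(c) = μᵢ + νᵢ(c₀ − c) that rises linearly as the local oxygen
concentration c falls below the inlet value c₀. Oxygen is convected with
the blood (flow rate f) and consumed at rates k₁ρ₁ + k₂ρ₂; because the
consumption response is quasisteady, c(x,t) is determined at every instant
by the cumulative consumption upstream of x:

    c(x,t) = c₀ − (1/f) ∫₀ˣ (k₁ρ₁ + k₂ρ₂) dξ.

Substituting the death law and the oxygen balance yields two coupled
nonlinear integro-partial differential equations:

    ∂ρᵢ/∂t = ρᵢ [ Kᵢ(σ − ρ₁ − ρ₂) − μᵢ − (νᵢ/f) ∫₀ˣ (k₁ρ₁ + k₂ρ₂) dξ ].

Rescaling t by the net growth capacity c₁ = K₁σ − μ₁, x by fK₁/(ν₁k₁) and
densities by c₁/K₁ collapses the eleven rate constants to four dimensionless
groups θ = k₂/k₁, γ = K₂/K₁, λ = K₁c₂/(K₂c₁), η = ν₂K₁/(ν₁K₂) and a scaled
length Λ:

    ∂v₁/∂t = v₁ [ 1 − v₁ − v₂ − J ],      ∂v₂/∂t = γ v₂ [ λ − v₁ − v₂ − ηJ ],
    J(x,t) = ∫₀ˣ (v₁ + θv₂) dξ.

Viability requires Kᵢσ > μᵢ for both types (enforced at parameter
construction, with an explicit escape hatch for exploratory use), and ν₁ > 0
names the first type as the oxygen-sensitive one.

## Zone formation and the stationary state

A Volterra-style competitive-exclusion argument on the log-ratio
ln(ρ₁^K₂/ρ₂^K₁) predicts that when

    η < λ < 1   and   x* := ln((1−η)/(λ−η)) < Λ,

the capillary splits at x*: the first type excludes the second upstream and
vice versa downstream, with the stationary state

    v₁ = e^(−x), v₂ = 0            on [0, x*),
    v₁ = 0, v₂ = A₂ e^(−ηθ(x−x*))  on (x*, Λ],    A₂ = (λ−η)/(1−η).

Each species jumps at x*, but e^(−x*) = A₂, so the total density is
continuous — a coincidence the package asserts in tests and exploits in the
node convention below. Each zone profile solves a linear Volterra integral
equation of the second kind; its decomposition series has term n
proportional to xⁿ/n! (or (x−x*)ⁿ/n!) with alternating signs, and sums to
the exponential. The `stationary` module provides the series both via the
package's trapezoid quadrature (the operational path) and via the analytic
term formulas (an independent check path).

In the dimensional frame the same boundary reads
x* = (fK₁/(ν₁k₁)) ln(Bc₁/(K₁(ν₁c₂ − ν₂c₁))) with A = μ₂K₁ − μ₁K₂,
B = ν₁K₂ − ν₂K₁, and the downstream plateau D = (ν₁c₂ − ν₂c₁)/B. Frame
consistency (the dimensional boundary equals the length scale times the
dimensionless one; D equals the density scale times A₂) holds algebraically
and is verified to ~1e−14 relative error over 100 random parameter draws.
A historical printing of the net growth capacities uses a fixed index on μ;
the package reads cᵢ = Kᵢσ − μᵢ throughout, the only reading under which
the two frames are mutually consistent.

## Power series in time

With t-independent initial data, inverting ∂/∂t in the decomposition
scheme and expanding the quadratic and integral nonlinearities as Cauchy
products makes term n of the series exactly a monomial coefficient·tⁿ, so
the solution is a power series v₁ = Σ αₙ(x)tⁿ, v₂ = Σ βₙ(x)tⁿ with

    αₙ₊₁ = [αₙ − Σₖ αₖαₙ₋ₖ − Σₖ αₖβₙ₋ₖ − Σₖ αₖJₙ₋ₖ] / (n+1),
    βₙ₊₁ = γ[λβₙ − Σₖ αₖβₙ₋ₖ − Σₖ βₖβₙ₋ₖ − η Σₖ βₖJₙ₋ₖ] / (n+1),

where Jₘ = ∫₀ˣ(αₘ + θβₘ) dξ. The η weight on the second species' integral
Cauchy product follows from expanding γv₂(λ − v₁ − v₂ − ηJ) directly; some
circulating printings of the low-order terms drop or rescale this weight, or
replace a sum between the I₂ and I₃ groups of α₂ with a product.
`low_order_term_report` quantifies each variant against the recurrence: the
re-derived grouping matches to ~1e−17 while the variants differ at ~1e−3 on
a test scenario, so the re-derivation is authoritative.

Three independent cross-checks guard this machinery:

- **Closed forms.** For equal initial profiles v₀, the first- and
  second-order coefficients have closed forms in v₀ and the nested integrals
  I₁ = ∫v₀, I₂ = ∫v₀², I₃ = ∫I₁v₀ (derived symbolically from the recurrence,
  a different algebraic path from the term-by-term code).
- **Taylor oracle.** Since each decomposition term is a tⁿ monomial, the
  series coefficients must equal the Taylor coefficients of the true
  solution. `taylor_oracle` computes those by repeated differentiation of
  the right-hand side, organised as truncated polynomial arithmetic in t
  per grid node. Agreement holds at ~1e−16 relative through order 6.
  Comparisons are relative to the coefficient scale because sup|coefₙ|
  grows like (Λ(1+θ))ⁿ/n! and can exceed 1e4 on long domains.
- **Reference trajectory.** The order-N truncation evaluated at time t must
  deviate from the method-of-lines solution like C·t^(N+1); halving t
  shrinks the error by 2^(N+1), verified at N = 4 (measured ratios 29–33
  against the nominal 32).

**Trust time.** The series has a finite (unknown) convergence radius in t.
`estimate_trust_time` applies a ratio-test heuristic — 0.5/r with r the
largest ratio sup|coefₙ₊₁|/sup|coefₙ| over the last three orders — and
evaluation beyond it only warns. This is a package heuristic, not a model
statement; stationary inputs (all higher coefficients zero) report +∞. In
the truncation-scaling check the comparison time is 0.4·trust_time, well
inside the convergence range while keeping the measured errors far above
the integrator tolerance floor.

## Reference solver

The method-of-lines integrator discretizes x on the shared closed uniform
grid and treats J as a dense lower-triangular coupling (each node's rate
depends on all upstream nodes), recomputed by cumulative trapezoid at every
right-hand-side evaluation. Time stepping is adaptive DOP853 at rtol 1e−9,
atol 1e−12 by default; the method and tolerances are arguments (any
`solve_ivp` method, e.g. LSODA, serves as a stiff fallback, though the
system is non-stiff at the densities of interest). States are not floored
at zero — the map stays faithful to the equations, small tolerance-level
undershoot is tolerated and reported — unless the exploratory `clip` flag
is set, which floors at output times and is recorded in the trajectory
metadata.

Long-time zone formation is asserted at θ = γ = 1, λ = 0.5, η = 0.2, Λ = 3
from equal constant profiles 0.1: x* = ln(0.8/0.3) ≈ 0.9808, and by t = 200
all four zone metrics (extinction sup-norms and profile errors, margin 0.2
around x*) fall below 0.01 — in practice to ~3e−5 — and still decrease
between t = 100 and t = 200, guarding against premature readout. t = 200
stands in for the asymptotic limit; the model states no convergence rate,
so the package reports metrics at user-chosen horizons rather than claiming
one.

## Numerical choices

- **One quadrature operator.** All integrals use the composite trapezoid on
  closed uniform grids with value 0 at the inlet node: second-order
  accurate, exact for linear integrands, deterministic. Analytic I₁/I₂/I₃
  and analytic series terms exist only as check paths.
- **Grids.** Closed intervals with both endpoints as nodes (the inlet node
  is required by the integral term); default 401 nodes. Uniformity is
  validated to 1e−9 relative spacing tolerance.
- **Node at the jump.** A node falling exactly at x* takes the left-limit
  value for species 1 and the right-limit value for species 2; the model
  does not define the point value, so this convention is the package's and
  is recorded in output metadata. The two one-sided values coincide
  numerically (e^(−x*) = A₂).
- **Residual order at the jump.** The stationarity-residual checks use
  θ = 1, where the total consumption integrand v₁ + θv₂ is continuous
  (kink only) across the species jump and the trapezoid keeps its O(h²)
  order on any grid. For θ ≠ 1 the integrand itself jumps inside the cell
  straddling x*, contributing an O(h)·(1−θ)A₂ error with a
  placement-dependent sign to all downstream nodes; residuals then degrade
  to first order near the boundary. This is a property of the quadrature,
  not of the stationary solution.
- **Strict comparisons.** Zone-condition inequalities are exact (no
  epsilon); borderline equalities report false with a boundary-case note,
  since the underlying argument needs strict ordering.
- **Purity.** `rhs_dimensionless` never clips negative excursions;
  positivity handling is the caller's decision.

## Synthetic scenarios

The model fixes only the admissible region, not concrete numbers, so the
generator's ranges are package choices made once: θ, γ log-uniform on
[1/4, 4] (order-of-magnitude asymmetry either way), η uniform on [0, 0.8],
λ uniform on (η, 1) for zone-forming draws — else on (0, 2) so no-zone
regimes appear — and Λ = x* + U(0.5, 2.5) so the length condition holds by
construction. Initial-profile families (equal constants, Gaussians, ramps,
distinct constants, perturbed stationary states) are nonnegative and
bounded by 1, at moderate sub-capacity levels (constants U(0.05, 0.3),
Gaussian peaks U(0.1, 0.5), perturbation amplitude 0.01). Dimensional sets
invert the nondimensionalization with seeded positive scales; zone-forming
dimensionless draws automatically satisfy viability and the strict ordering
inequalities. One integer seed drives every draw; identical seeds give
bit-identical scenarios.

What the generator does **not** emulate: real sinusoids have discrete cells,
stochastic division, axial diffusion, pulsatile and heterogeneous flow, and
more than two cell types. Passing tests therefore demonstrate the internal
consistency of the model and its solution methods — not agreement with
measured liver data, of which the model uses none.

## Problem sizes

Default test and validation scales: 401-node grids (801 for refinement
checks), series order 8 (6 for oracle comparisons), 25 stationary series
terms, horizons up to t = 200 for zone formation, 100 draws for frame
consistency and 1000 for generator constraint checks. The full suite and
the acceptance script each run in seconds at these sizes.

## Known limitations

- The 25-term stationary series reaches ~1e−12 truncation error only where
  the exponent magnitude stays ≲ 3; validation restricts series/closed-form
  comparisons to that sub-domain on longer capillaries.
- Series evaluation beyond the trust time diverges rapidly (no Padé or
  other acceleration is attempted); the reference solver is the tool for
  long horizons.
- Negative oxygen concentrations (consumption exceeding supply) are
  returned as computed with a model-validity warning; the model itself is
  silent on this regime.
- The zone-formation asymptotics are demonstrated numerically at
  configurable parameters; no PDE-theoretic convergence proof is attempted.
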