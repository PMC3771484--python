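# liverzones

A tested implementation of a two-cell-type model of **liver zonation**: the
spatial partitioning of metabolic function along the blood-flow axis of a
hepatic capillary. Two hepatocyte subtypes compete for cell sites and for
convected oxygen; because each cell's death rate depends on the oxygen
consumed by *all cells upstream of it*, the governing equations are
nonlinear integro-partial differential equations:

    ∂ρᵢ/∂t = ρᵢ [ Kᵢ(σ − ρ₁ − ρ₂) − μᵢ − (νᵢ/f) ∫₀ˣ (k₁ρ₁ + k₂ρ₂) dξ ],  i = 1, 2

or, after nondimensionalization to the groups θ = k₂/k₁, γ = K₂/K₁,
λ = K₁c₂/(K₂c₁), η = ν₂K₁/(ν₁K₂) on the scaled interval [0, Λ]:

    ∂v₁/∂t = v₁ [ 1 − v₁ − v₂ − J ],   ∂v₂/∂t = γ v₂ [ λ − v₁ − v₂ − ηJ ],
    J(x,t) = ∫₀ˣ (v₁ + θv₂) dξ.

When η < λ < 1 and x\* = ln((1−η)/(λ−η)) < Λ, competitive exclusion splits
the capillary into two zones with a jump at x\*: upstream v₁ → e^(−x) with
v₂ → 0, downstream v₂ → ((λ−η)/(1−η))·e^(−ηθ(x−x\*)) with v₁ → 0.

The package provides:

- **`model_core`** — parameter containers, the nondimensionalization map,
  viability/zone-condition checks, the death-rate and oxygen-balance laws,
  and the dimensionless right-hand side;
- **`stationary`** — the zone boundary x\* in both frames, the piecewise
  stationary profile, and the Adomian decomposition series for the two
  stationary zone equations (term n ∝ xⁿ/n!, summing to the exponentials);
- **`adm_timeseries`** — power-series-in-time solutions via the Adomian
  recurrence (coefficients αₙ(x), βₙ(x) of tⁿ), closed-form low-order
  terms, an independent Taylor-coefficient oracle, and a ratio-test trust
  time;
- **`reference_solver`** — a method-of-lines integrator (adaptive DOP853,
  rtol 1e−9 / atol 1e−12) serving as ground truth, plus zone-formation
  metrics;
- **`scenarios`** — seeded synthetic parameter sets and initial profiles
  satisfying the model's constraints;
- **`cli_io` / `cli`** — YAML/JSON/CSV interfaces and the `liverzones`
  command line (`stationary`, `adm`, `simulate`, `scenario`, `validate`).

It is aimed at mathematical biologists and numerical analysts who want a
reproducible, cross-checked reference for integro-PDE competition models
with convected resources — every analytic claim in the package is verified
against an independent numerical route.

## Worked example

```python
import numpy as np
from liverzones import (
    DimensionlessParams, GridFunction, adm_expand, integrate,
    stationary_profile, x_star_dimensionless, zone_metrics,
)

q = DimensionlessParams(theta=1.0, gamma=1.0, lam=0.5, eta=0.2, Lambda=3.0)
print("x* =", x_star_dimensionless(q))
zones = stationary_profile(q, 401)
print("downstream plateau =", zones.amplitude2)

# start both cell types at the same constant density 0.1
v0 = GridFunction.constant(0.1, 0.0, q.Lambda, 401)

# short-time: the order-8 power series vs the reference integrator
series = adm_expand(v0, v0, q, N=8)
traj = integrate(v0, v0, q, [0.05, 200.0])
s = series.evaluate(0.05)
print("series vs reference at t=0.05:",
      np.max(np.abs(s.species1.values - traj.states[0].species1.values)))

# long-time: the zones have formed
m = zone_metrics(traj.states[1], q, delta=0.2)
print("zone metrics at t=200:", m.max())
```

Output:

```
x* = 0.9808292530117263
downstream plateau = 0.37499999999999994
series vs reference at t=0.05: 2.7755575615628914e-17
zone metrics at t=200: 3.317620014819944e-05
```

The boundary sits at x\* = ln(0.8/0.3) ≈ 0.981; the second species'
stationary plateau is (λ−η)/(1−η) = 0.375. The power series and the
integrator agree to machine precision at short time, and by t = 200 the
state is within 3.3e−5 of the piecewise stationary zone pattern everywhere
outside a 0.2 margin around the jump.

The same computations are available from the shell, e.g.

```bash
liverzones scenario --seed 3 --out demo/
liverzones simulate --params demo/params.yaml --init demo/initial.csv \
    --t-end 200 --out demo/trajectory.csv
liverzones validate --seed 0 --out demo/report.json
```

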