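# invasim

Finite-element simulation of invasive-species dispersal over real terrain,
with moment-based polynomial-chaos uncertainty quantification.

## The problem

When an alien species establishes a colony, environmental managers need
short-term forecasts of where it will spread and when it will reach
sensitive locations — and, because the species' parameters are usually
known only as rough distributions, they need error bars on those forecasts.
`invasim` is aimed at that workflow: spatial ecologists and conservation
modellers who want a landscape-aware spread model with quantified
parametric uncertainty, running in minutes on a laptop.

## The model

The population density u(x, t) obeys a generalized Fisher (reaction-
diffusion-advection) equation on a 2-D geographic domain Ω, in degree
coordinates:

    ∂u/∂t − div(ν ∇u) + b·∇u + u(u − γ) = f        in Ω × [0, T],

with zero-flux (homogeneous Neumann) boundaries on an enlarged buffer
domain so boundary artifacts stay away from the region of interest.

* ν(x, t) — diffusivity (deg²/yr), reduced across barriers;
* b(x, t) — transport velocity (deg/yr), e.g. rivers; zero by default;
* γ(x, t) — carrying capacity; the reference law ties it to elevation,
  γ(z) = α(10 − z/100), so capacity is 10 at sea level, vanishes at
  1000 m, and is *negative* (hostile) above — mountain ridges become true
  barriers;
* f — external source (zero by default).

In homogeneous terrain the equation develops invasion fronts travelling at
the classical minimal speed c = 2√(νγ).

Space is discretized with P1 (piecewise-linear) finite elements on
triangular meshes built by a data-driven procedure: structured background
grid, refinement over the region of interest, per-node elevation
interpolated from SRTM HGT tiles (or a synthetic terrain generator), and
gradient-driven refinement where the terrain is steep. Time stepping is
semi-implicit (IMEX): diffusion and transport implicit, reaction explicit,

    (M + Δt A + Δt B) uⁿ⁺¹ = M uⁿ + Δt F(uⁿ),      Δt = 0.1 months.

Parametric uncertainty (here: ν and the capacity scale α) propagates by
data-driven arbitrary Polynomial Chaos: Gaussian quadratures are built from
the raw statistical moments of each input sample set, combined into a
Smolyak sparse grid (5 model runs for two inputs at level 1), the model
output is projected onto moment-orthonormal polynomials, and the cheap
surrogate is Monte-Carlo sampled for density PDFs, mean/σ fields and
arrival-time distributions.

## Worked example

The bundled demo (`examples/ridge_invasion.toml`, also available as
`invasim.demo_scenario()`) places a colony north-east of a 1200 m ridge
whose only passable crossing is a valley gap:

```python
import numpy as np
from invasim import demo_scenario, simulate
from invasim.scenario import build_mesh, run_scenario_uq
from invasim.solver import interpolate_field

sc = demo_scenario()
mesh = build_mesh(sc)
print(mesh.n_nodes, mesh.n_triangles)        # 5047 9968
res = simulate(sc, mesh=mesh)
arr = res.arrival_time
hostile = mesh.node_elevation > 1000
print(np.isfinite(arr[hostile]).sum())       # 0  (the crest is never invaded)
for name, p in sc.probes.items():
    t = interpolate_field(mesh, arr, np.array([p]))[0]
    print(f"{name}: arrival {t:.2f} yr")
# north: arrival 0.43 yr
# gap: arrival 3.69 yr
# south: arrival 4.80 yr
```

The species reaches the north probe within half a year, but the south probe
— geometrically closer to the colony than the gap — only after 4.8 years,
because the route has to detour west through the valley at 3.7 years.

Uncertainty propagation with ν ~ N(5×10⁻⁴, 1.2×10⁻⁴) and α ~ U(0, 2):

```python
uq, diag = run_scenario_uq(sc, mesh=mesh)
print(diag["n_runs"])                        # 5   (level-1 sparse grid)
s = uq.probe_std["gap"]
print(f"{s.max():.2f} at {uq.probe_times[s.argmax()]:.2f} yr -> {s[-1]:.2f}")
# 8.56 at 3.97 yr -> 5.68
```

The density standard deviation at the gap peaks (8.56) while the front
passes and then relaxes to the equilibrium-uncertainty plateau (5.68) set
by the uncertain capacity scale α.

The same pipeline runs from the shell:

```sh
invasim mesh     --config examples/ridge_invasion.toml --out out/
invasim simulate --config examples/ridge_invasion.toml --out out/
invasim uq       --config examples/ridge_invasion.toml --out out/
```

writing Triangle-format meshes, legacy-VTK density/arrival/σ fields, and
CSV probe series and PDFs.

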