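# Methods

## Physical model

The package simulates a dilute aqueous suspension of gravitactic
microorganisms (*Paramecium caudatum*-like upward swimmers) and denser
nanoparticles inside a closed two-dimensional rectangular cavity of
aspect ratio `A = L/H`, driven by small heated wall segments.  Three
buoyancy mechanisms compete: the microorganism density excess
(bioconvection), thermal expansion (natural convection) and the
nanoparticle load.  All quantities are dimensionless: lengths scaled by
the cavity height `H`, time by the microorganism diffusion time
`H²/Dm`, velocity by `Dm/H`.

With the stream function ψ (`u = ∂ψ/∂x2`, `v = −∂ψ/∂x1`) and the
vorticity ω the governing system is

```
∇²ψ = −ω
∂ω/∂t + u·∇ω = Sc ∇²ω − Sc·Ra ∂n/∂x1 + Le·Sc·RaT ∂θ/∂x1 − Le·Sc·Ran ∂ϕ/∂x1
∂n/∂t = −∇·[(u + Pe ĵ) n] + ∇²n
∂θ/∂t + u·∇θ = Le ∇²θ + rρ δBm ∇ϕ·∇θ + rρ δTm |∇θ|²
∂ϕ/∂t + u·∇ϕ = δBm ∇²ϕ + δTm ∇²θ
```

`n` is the microorganism concentration (swimming upward at speed Pe),
θ the temperature (0 on cold walls, 1 on source segments), ϕ the
nanoparticle volume fraction (deviation form).  The last two terms of
the temperature equation are the Brownian and thermophoretic
heat-coupling of the two-component nanofluid; the ϕ equation carries
the matching thermophoretic drift through `δTm ∇²θ`.

Sign conventions: gravity acts along −x2; positive ω is
counter-clockwise; a heated segment on the bottom-left drives a
clockwise (ψ < 0) cell with upflow above the source.

### Parameters

| group | meaning | default |
|---|---|---|
| Ra | bioconvection Rayleigh number | 1900 |
| RaT | thermal Rayleigh number | 1708 |
| Ran | nanoparticle Rayleigh number | varied, 0–0.14 |
| Sc, Le, Pe | Schmidt, Lewis, swimming Peclet | 1 |
| Pen | nanoparticle (settling) Peclet | 0.1 |
| δBm | Brownian/microorganism diffusivity ratio | 0.1 (0.1–1.9 studied) |
| δTm | thermophoretic parameter | 0.1 (0.01–0.1 studied) |
| rρ | particle/fluid heat-capacity ratio | 2.5 |
| A | aspect ratio | 5 |
| N̄ | microorganism concentration scale | 1 |

The defaults are the operating point of the study the solver supports:
bioconvection dominant (Ra = 1900), natural convection at its classical
onset value (RaT = 1708), unit transport ratios, weak settling.  N̄ is a
free scale (its printed definition is not usable as written) and only
multiplies the rest profile.  `dimensionless_groups` converts a full
dimensional description (SI units) into these groups; the solver itself
never sees units.

Two source geometries are predefined: case 1, a segment on the left
tenth of the bottom wall; case 2, a segment on the middle fifth
(x2 ∈ [0.4, 0.6]) of the left wall.  The extents are configurable —
the study geometry fixes only the placement, and steady amplitudes are
sensitive to the extent.

### Rest (basic) states

At rest the microorganism profile balances upward swimming against
diffusion, `nb(x2) = N̄ Pe e^{Pe x2}/(e^{Pe}−1)` (vertical mean N̄;
the Pe → 0 limit is uniform).  The nanoparticle rest profile is taken
as `ϕb = −δBm θb + (1−δBm) x2 + δBm` with θb = 0.  Note ϕb is *not* a
zero-flux stationary state of the ϕ equation (its vertical Brownian
flux is the nonzero constant `δBm(1−δBm)`); it is retained as the
conventional initial condition, and the early transient redistributes
it at conserved total content.

## Boundary conditions

* ψ = 0 on all walls (impermeable); no-slip enters through the Thom
  wall-vorticity closure `ω_wall = −2 ψ_adj/h²`.
* θ: Dirichlet, 0 on walls and `theta_value` (default 1) on source
  segments, endpoints rounded to the nearest node and included.
  Bottom/top walls own the corner nodes, so a source reaching a corner
  keeps it hot.
* n: zero normal gradient on the side walls (second-order one-sided);
  zero total vertical flux `Pe·n − ∂n/∂x2 = 0` on top/bottom.
* ϕ: zero total flux `δBm ∂ϕ/∂n + δTm ∂θ/∂n = 0` on **all four** walls
  (Brownian diffusion balancing thermophoresis).

Two printed-variant toggles exist and are off by default.
`micro_bc_includes_pen` adds `n·Pen` to the microorganism wall flux;
with it the exponential rest profile is no longer stationary, so the
consistent default drops it.  `nano_bc_includes_pen` adds a settling
term `−Pen·ϕ` to the vertical ϕ flux.  This variant is dynamically
pathological: the transport equation contains no matching settling
advection, so the wall flux never closes, and because the ϕ mean mode
is quasi-neutral (homogeneous decay rate ~Pen²/δBm ≈ 6·10⁻³ per time
unit at δBm = 1.6) the total content drifts essentially forever — long
runs show ϕ falling without bound at a θ-controlled constant rate, and
no convergence criterion can be met.  The same applies to a plain
Neumann side-wall condition for ϕ: a cold wall adjacent to warm fluid
carries a tangential thermophoretic leak.  The conserving closure used
here is exact: since the steady temperature field satisfies
`∮ ∂θ/∂n dΓ = 0`, zero total wall flux conserves `∫ϕ dA` identically,
and the discretisation below preserves that to rounding.

### Flux-conservative wall discretisation

The n and ϕ wall conditions are discretised at the *half cell* next to
the wall: the total face flux — carried flow, swimming/settling,
diffusion, and (for ϕ) thermophoresis — is zeroed using the mean of the
wall and adjacent values against their first difference.  These are
linear closures `f_wall = α f_adj + γ` and they are folded directly
into the implicit ADI line systems, so they hold at the new time level.
Because the interior stencil is a telescoping sum of exactly these face
fluxes, the scheme's conserved functional — the interior node sum — is
conserved to rounding for any flow (measured: constant to ~10⁻⁷
relative over 5000 convective steps; a one-time ~3·10⁻⁵ adjustment
remains from the explicit θ-coupling during the initial transient).
The quadrature total including wall rows varies by O(h) as the slaved
wall boundary layers re-equilibrate; that is a quadrature-weight
effect, not transport through the walls.  At rest the closures
reproduce the plain Neumann/flux conditions and make the discrete
exponential rest profile `n_j ∝ r^j`, `r = (2+Pe·h)/(2−Pe·h)`, an
exact fixed point.  One-sided wall-node forms were tried first and leak
mass at a constant rate (~10⁻⁵ relative per 1000 steps for n; unbounded
drift for ϕ through the discontinuous source-edge θ gradients), which
no steady-state tolerance survives.

## Numerics

* Uniform node-centred grid, arrays indexed `(i, j) = (x1, x2)`.
* Space: second-order centred differences; advection in conservative
  flux form (the centred velocity field is discretely divergence-free
  in the interior, mixed centred differences commuting).
* Time: Peaceman–Rachford ADI.  Each half-step of dt/2 is implicit in
  one direction (advection + diffusion along the line, tridiagonal
  Thomas solves) with the transverse terms and all coupling sources
  explicit; wall handlers re-applied after each half-step.  Coupling
  terms (buoyancy gradients, `rρδBm ∇ϕ·∇θ`, `rρδTm|∇θ|²`,
  `δTm∇²θ`) are evaluated at the start-of-step level, keeping every
  line system linear and tridiagonal.
* Sub-step order: ω → ψ (Poisson) → wall ω (Thom) → n → θ → ϕ, so all
  buoyancy sources use one common time level.
* Poisson: direct DST-I (fast sine transform) solve of the 5-point
  Dirichlet Laplacian — exact to rounding; the residual contract
  (≤ tol, relative to the forcing magnitude) is checked per call.
* Line systems keep a diagonal-dominance guard; a violation raises an
  unstable-step error instead of letting the solve degrade silently.
* Divergence handling: a non-finite field aborts the run, the step is
  halved and the run restarts (up to four halvings).

### Time step

Default `dt = 1e-4`.  The binding stability limit is not the ADI core
(stable at ≥100× the explicit diffusive limit) but the explicit
Thom wall-vorticity coupling, which requires roughly
`dt ≲ dx2²/Sc`; at the study resolution (81 vertical nodes,
dx2 = 1/80, dx2² ≈ 1.6·10⁻⁴) `dt = 2e-4` produces grid-scale wall
oscillations that blow up while `1e-4` is robust across the studied
parameter range.

### Convergence criterion

A run is converged when, for every field,
`max_nodes |f^{m+1} − f^m| / max(1, max|f^{m+1}|) ≤ ε` with
ε = 1e-6 by default.  The per-field scaling keeps the criterion
meaningful across magnitudes: wall vorticity is `2/dx2²` (≈1.3·10⁴)
times the stream function, so an unscaled threshold would bind the
stream function at ~10⁻¹⁰ — rounding level — while leaving the
concentrations essentially unconstrained.

## Diagnostics

* `global_extrema`: ψ reported as the signed value of largest
  magnitude (rotation sense visible); n, θ, ϕ as plain maxima.
* Roll counting: connected-region labelling of |ψ| > 5% of max|ψ|,
  separately per sign domain (4-connectivity); invariant under
  rescaling and sign flip; 0 below an absolute floor of 1e-10.
* Onset estimation: on a ψmax-vs-Ran sweep, the first interval whose
  slope is positive and exceeds 5× the median of the preceding slopes;
  the estimate is the interval midpoint.  Scale-invariant; requires ≥3
  converged points.
* Ran sweeps warm-start each run from the previous converged state
  (the physical protocol of slowly increasing particle load); on the
  coarse mesh this changes converged answers only within the
  convergence tolerance.
* Mesh study: converged ψmax/ϕmax per mesh per probe Ran; the selected
  mesh is the coarsest within 0.5% of the finest at every probe.  Runs
  chain across the mesh ladder (each mesh warm-starts from the previous
  mesh's state, interpolated), so the comparison isolates pure
  discretisation differences and the fine meshes converge quickly.

## Problem sizes and accuracy trade-offs

Production diagnostics use the 101×81 mesh for reference extrema and a
reduced 41×31 mesh (with dt = 1e-3, inside its wall-vorticity limit)
for Ran sweeps, where onset location — not amplitude — is the target;
the unit-test suite
runs on coarser meshes (≈31×41 and below) where every property it
checks (second-order convergence, conservation, symmetry, stationarity)
is already sharply resolved.  Warm starting across sweep points and
across Ran probes is used throughout to keep wall-clock times at
minutes per study.

## Known limitations

* Steady amplitudes depend on the heated-segment extent, which the
  study geometry leaves open; extents are configurable and the defaults
  are stated above.
* The discontinuous wall temperature at source edges limits local
  accuracy of θ-derived quantities to first order in the edge cells;
  the conservative ϕ closure is constructed so this does not leak
  particles.
* The printed-variant wall fluxes (`*_includes_pen`) admit no steady
  state (see above); they are provided for comparison runs, not for
  converged studies.
* The nanoparticle buoyancy term `Le·Sc·Ran ∂ϕ/∂x1` is, at the studied
  magnitudes (Ran ≤ 0.14, ϕ = O(1)), four to five orders of magnitude
  smaller than the microorganism term (Ra = 1900), so steady
  diagnostics respond to Ran only at the 0.1% level; sweeps over this
  range probe the estimator machinery more than any physical
  transition.  Note that evaluating Ran's own definition with
  water/metal-oxide properties at millimetre scales gives values of
  order 1e4, far above the studied range.
* ϕmax concentrates near the discontinuous source edge, which makes it
  the most mesh-sensitive diagnostic (several percent between the mesh
  ladder's levels, against 0.1% for smooth-field quantities).
* No turbulence, no 3D effects, no adaptive meshing; steady states
  only — transient trajectories are time-accurate only to the ADI
  splitting error O(dt²).
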