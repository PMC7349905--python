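# Methods

## Model

One protein species on a 1D domain of length `L` (μm), cycling between a
membrane-bound state `m(x,t)` and a cytosolic state `c(x,t)` (both line
densities, 1/μm):

```
∂t c + ∂x(v_f(x) c) = D_c ∂x² c − f(m, c)
∂t m                = D_m ∂x² m + f(m, c)
```

Boundaries are periodic (circular flows, large microfluidic chambers) or
no-flux (the symmetry axis of a rotationally symmetric cortical flow).
The reactions exchange protein between the two states with
`f(m,c) = a(m) c − d(m) m`; the kinetics are pluggable through the
`(a, d)` decomposition, and the shipped default is

```
a(m) = k_on + k_fb m,     d(m) = k_off / (K_D + m).
```

Defaults (units μm, s, 1/μm throughout): `k_on = 1`, `k_fb = 1 μm/s`,
`k_off = 2`, `K_D = 1`, `n̄ = 5`, `D_m = 0.01 μm²/s`, `D_c = 10 μm²/s`,
`L = 10 μm`. Membrane diffusion is slow compared to cytosolic diffusion,
as in cells. The mean total density `n̄` is the conserved control
parameter.

Assumptions: the flow only advects the cytosolic state (membrane-bound
protein is anchored); the flow field is prescribed, not generated by the
proteins; one species, two states; 1D geometry.

## Homogeneous states and the nullcline

`homogeneous_state(n̄)` solves `f(m*, n̄ − m*) = 0` by bisection of
`g(m) = a(m)(n̄ − m) − d(m) m` on `[0, n̄]`. If several roots exist the
smallest-`m` root — the branch continuously connected to the origin — is
returned and a warning lists all roots (for the default kinetics a single
root was observed throughout the explored range `n̄ ≤ 20`). Root residual
tolerance is 1e−12; the linearization `f_m, f_c` is closed-form, so the
nullcline slope `s_nc = −f_m/f_c` carries no numerical-differentiation
error. `local_equilibria` applies the same solver pointwise to a density
profile, which by the smallest-root convention cannot jump branches
between neighbouring points.

## Linear stability under uniform flow

Fourier modes `exp(σt + iqx)` of the linearized dynamics give a 2×2
eigenvalue problem; `dispersion` computes both eigenvalues with LAPACK and
labels "the" branch `σ(q)` as the one with the larger real part at each
`q` (ties broken by the larger imaginary part and logged; branch
continuity across `q` is not enforced). The tests cross-check every
eigenvalue against the independent trace/determinant quadratic formula.

Anchors and limits implemented:

* `q = 0`: eigenvalues exactly `{0, f_m − f_c}`; the zero mode reflects
  mass conservation. Only homogeneously stable states (`σ₁ = f_m − f_c <
  0`, equivalently `s_nc > −1`) are analyzed further.
* Long-wavelength expansion to `O(q²)`:
  `σ(q) ≈ −(1+s_nc)⁻¹ [ i s_nc v_f q + (D_m + s_nc D_c) q² +
  s_nc v_f² q² / (f_c (1+s_nc)²) ]`. Requiring a positive `q²`
  coefficient of `Re σ` gives the instability criterion
  `s_nc < −D_m / (D_c + v_f²/(f_c (1+s_nc)²))`. The threshold is
  implemented in this cleared-denominator form, which is finite for
  `D_c = 0` with `v_f ≠ 0` (flow can replace diffusion entirely) and
  tends to `0⁻` as `|v_f| → ∞` (criterion degenerates to `s_nc < 0`).
  It is undefined for `D_c = 0, v_f = 0` and raises.
* Slow flow: `σ(q) ≈ σ⁰(q) + i v_f q² A(q)`. `A(q)` is defined
  *operationally* as the numerical limit
  `[Im σ(q; +ε) − Im σ(q; −ε)] / (2 ε q²)` with `ε = 1e−3 μm/s`
  (step-halving to `ε = 1e−4` agrees to 1%), never from a printed
  phase-velocity shortcut, because the literature notation is ambiguous
  about one power of `q`. `A(q) > 0` on the unstable band is the
  first-order statement of upstream propagation.
* Fast flow: `σ(q) ≈ f_m − D_m q² + i f_c f_m/(v_f q)`; the growth rate
  loses its `D_c` and `v_f` dependence and the drift speed decays as
  `1/v_f`. At the defaults, `v_f = 1e4` reproduces the full dispersion at
  `q*` to better than 1e−4 relative.
* An eigenvector-phase diagnostic (`eigenvector_phase`) reports the
  complex phase between the cytosolic and membrane components of the
  dominant eigenvector; its large-`v_f` saturation value is measured, not
  assumed.

`unstable_band` brackets `Re σ(q_max) = 0` with a composite
logarithmic-plus-linear grid (512 points up to four times an analytic
envelope bound `√(f_m/D_m)`) followed by Brent root-finding (tolerance
1e−10) and bounded maximization for `q*`.

## Conservative finite-volume dynamics

Space is discretized into `N` uniform cells (centers `x_i = (i+½)Δx`,
default `N = 256`; the convergence test also runs 512). Diffusion uses
central face gradients; advection uses the conservative face flux
`v_f(x_face)·c_face` with first-order upwinding by the sign of the face
velocity. At the default operating point the cell Péclet number
`v_f Δx / D_c ≈ 0.08` (at `v_f = 20`, `N = 256`), so upwinding's numerical
diffusion is a ≲2% perturbation of `D_c`; a central-flux option exists for
convergence studies. Because every interior face flux enters the discrete
divergence twice with opposite signs — and no-flux walls carry zero
diffusive *and* advective flux — the discrete total mass is conserved
identically; the measured ledger drift is at the 1e−13 level, dominated by
solver roundoff, against a 1e−6 acceptance bound.

Time integration: `scipy.integrate.solve_ivp` BDF with `rtol = 1e−8`,
`atol = 1e−10` and an analytic sparse Jacobian (constant transport
operators plus pointwise reaction blocks). Flow onset `t0` and optional
shutoff `t_off` split the integration interval so no discontinuity falls
inside a solver step. Concentrations that undershoot zero by more than
−1e−12 would be clamped with a logged warning (never observed in the
shipped scenarios); the right-hand side itself evaluates the smooth
kinetics formulas and tolerates the tiny negative excursions an implicit
solver may probe.

Initial conditions (`make_initial`) are mass-neutral by construction:

* *homogeneous-noise*: seeded zero-mean Gaussian noise of RMS amplitude
  `1e−3 n̄` (default) added to `m` and subtracted from `c`, so the local
  total density is exactly uniform. This emulates small uncorrelated
  fluctuations around the uniform state; it does not model demographic
  noise during the nonlinear stage (the dynamics after initialization are
  deterministic), so passing tests speak to the deterministic PDE, not to
  stochastic effects in real cells.
* *single-peak*: a Gaussian bump (width `L/10`, amplitude `0.6 c*`) moved
  from cytosol to membrane at mid-domain, then relaxed without flow until
  the membrane profile changes by less than 1e−8 (relative sup-norm) per
  10 s. The pre-flow stationary state is thus a reconstruction — the
  relaxation endpoint is insensitive to the bump's exact shape because the
  stationary single-peak state at fixed mass is unique up to translation.

## Pattern diagnostics

* **Peak tracking**: sub-grid position by parabolic interpolation through
  the maximum and its neighbours, unwrapped across the periodic boundary;
  `v_p` is the least-squares slope over the analysis window with its
  residual standard error. Steady propagation requires the instantaneous
  speed spread below 2% (absolute floor 1e−5 μm/s for stationary
  patterns); multi-peak or unsteady windows withhold `v_p` (NaN) with a
  logged warning.
* **Phase-plane loop**: nullcline crossings of `c(x) − c_nc(m(x))` by
  sign change and linear interpolation; on each flank of the peak
  (upstream/downstream assigned by the sign of `v_f`) the crossing closest
  to the peak is `c_L`/`c_R`. The loop area is the shoelace sum over the
  x-ordered closed polygon. For stationary no-flow patterns the points are
  collinear on the flux-balance line of slope `−D_m/D_c` to ~1e−15 of the
  data range.
* **Linear prediction of the peak speed**: the relevant mode for a fully
  formed peak is the shortest unstable one, `q_max`, evaluated at the
  pattern's inflection composition — the *middle* intersection of the
  flux-balance line with the nullcline. That composition can lie on a
  nullcline branch not connected to the origin, so the local state is
  built directly from the intersection point rather than from a root
  search in `n`. Prediction: `−Im σ(q_max)/q_max`; it matches the
  simulated speed in sign and within a factor of two in the slow-flow
  regime, and shares the linear-in-`v_f` (slow) and `1/v_f` (fast)
  scalings.
* **Mesa/peak classification**: homogeneous if the amplitude is below
  `1e−3 n̄`; otherwise the high plateau is the longest contiguous run of
  cells within 5% of the amplitude below the maximum, and the interface
  width is the 10–90% rise distance averaged over the two flanks. A mesa
  requires the plateau to span at least `plateau_factor = 1.5` interface
  widths. Rationale for 1.5: a pure curvature cap (two interfaces
  concatenated — the definition of a peak) yields a plateau/rise ratio of
  about 0.6 independent of scale, while profiles pinned at the third
  flux-balance–nullcline intersection measure ≳2.3; the default sits
  between the two clusters. All three thresholds are keyword-exposed, and
  the measured widths are always reported so the transition point is an
  output, not an assumption.
* **Regional lateral instability**: `unstable_density_range` scans the
  homogeneous branch over `(0, n_cap]` (400 points, edges refined by
  bisection) for densities satisfying the slope criterion; a snapshot's
  cells are marked where the local total density falls inside the no-flow
  range, and the instability counts as triggered once a contiguous marked
  region is wider than the shortest unstable wavelength `2π/q_max` at the
  region's mean composition.

## Scenario reconstructions

The canonical protocols fix every printed parameter and reconstruct the
rest; reconstructed values are logged at run time.

* *Upstream propagation* (periodic, `L = 10`, defaults): stationary peak,
  uniform `v_f = 20` switched on at `t0 = 240 s`. Measured
  `v_p = −3.6e−3 μm/s`; across the sweep `v_f ∈ {0.5 … 200}` the speed is
  maximal at `v_f = 20` and correlates with `c_L − c_R` at `|r| = 0.995`.
* *Mesa-to-peak* (`n̄ = 7`, `D_m = 0.1`, `L = 20`): the per-panel cytosol
  diffusion is not printed; at `D_c = 10` the stationary profile is a
  rounded dome whose maximum sits 3% below the third intersection —
  borderline. The mesa operating point uses `D_c = 5`, where the maximum
  pins at the intersection (to 0.3%) with a 6.9 μm plateau. "Slow/fast
  flow" are 1 and 50 μm/s, "fast diffusion" is 100× the base; the ladders
  `v_f ∈ {0, 1, 5, 15, 50}` and `D_c ∈ {5, 10, 100, 500}` each cross the
  mesa/peak boundary exactly once.
* *Flow-induced polarization* (no-flux, `L = 20`, parabolic profile
  `v_max (1 − 4(x/L − ½)²)` with `v_max = 5`, flow off at `t = 400 s`):
  the mean density is set at run time to `0.95 n_minus` (persistence
  case) or `0.3 n_minus` (decay case), where `n_minus ≈ 1.504` is the
  lower edge of the no-flow laterally unstable density range. The flow
  piles mass up at the downstream wall, the regional instability triggers
  there before the membrane amplitude reaches 10% of its flow-on value,
  and after flow removal the pattern persists (amplitude change −0.13%
  per 500 s, measured from 100 s after shutoff to skip the shape
  readjustment) or decays to homogeneity, respectively.

## Known limitations

* One species, prescribed flow: no antagonistic second species, no
  mechanochemical feedback of the pattern on the flow, no
  concentration-dependent flow fields.
* 1D fixed domain; no deformable or higher-dimensional geometry.
* The linear analysis applies to uniform flow only; for non-uniform
  profiles the package offers the regional (local-density) criterion, not
  a global linearization.
* First-order upwind advection trades a small effective increase of `D_c`
  (set by the cell Péclet number) for positivity and robustness; at flow
  speeds far above the defaults with coarse grids, use more cells or the
  central scheme and check convergence.
* The mesa/peak label is a threshold on continuous geometry; near the
  transition the reported widths matter more than the label.
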