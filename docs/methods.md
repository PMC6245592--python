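# Methods

## Photosynthetic-factory kinetics

The reaction model is the three-state photosynthetic factory: resting (R),
activated (A) and photoinhibited (B) fractions with irradiance-driven
transitions R→A (rate αI), A→B (βI), A→R (γ, the production step) and B→R
(δ, recovery).  In matrix form dy/dt = [𝒜 + u·ℬ]y with u = I/q1 the
normalized irradiance.  The package carries two parameter surfaces:

* raw rates `PSFRates` — the Wu–Merchuk set for *Porphyridium* sp.
  (α = 1.935·10⁻³, β = 5.785·10⁻⁷ µE⁻¹ m², γ = 0.1460, δ = 4.796·10⁻⁴ s⁻¹,
  κ = 3.647·10⁻³, Me = 0.059 h⁻¹), and
* the reduced parameters `PSFReparam` q1…q5, where q1 = √(γδ/αβ) ≈ 250.1
  µE m⁻² s⁻¹ is the optimal irradiance, q2 = √(αβγ/δ(α+β)²) ≈ 0.3016 the
  shape parameter of the steady light curve, q4 = αq1 ≈ 0.484 s⁻¹ the fast
  rate scale and q5 = β/α ≈ 2.99·10⁻⁴ the (small) inhibition ratio.

The case-study preset `CASE_STUDY_REPARAM` uses the *rounded* q2 = 0.3,
q4 = 0.5, q1 = 250 (≤ 3.5% from the recomputed values): under these the
tabulated quantities come out exactly — yA_ss(1) = 0.625,
yB_ss(1) = 0.1875, and the Damköhler identity Da = 260/Re.  Both presets
are first-class; everything internal runs on normalized u, converting to
physical irradiance only at the light-field boundary.

**Steady states and the O(q5) caveat.**  The closed forms
yA_ss = (u/q2)/(u² + u/q2 + 1), yB_ss = u²/(·) are the q5 → 0 (singular
perturbation) limit of the generator's invariant distribution: the
inhibition inflow u·q4·q5·yA perturbs the R–A balance at first order in
q5.  For the real q5 ≈ 3·10⁻⁴ the gap peaks at |Δ| ≈ 1.9·10⁻⁴ (at u = 1)
and shrinks linearly with q5 (property-tested).  Consequently long-time
integrations of the full ODE agree with the closed forms at their printed
precision (3–4 significant figures), while agreeing with the numerically
computed nullspace of the generator to integrator tolerance.  Tests and
documentation treat the closed forms as the model's reduced-limit steady
states, not as the exact nullspace.

**Integration.**  The full model is stiff (eigenvalues −0.63 and
−0.59·10⁻³ s⁻¹ at u = 1; ratio ≈ 1.07·10³).  `simulate_full` uses the BDF
integrator with the analytic Jacobian M(u(t)), defaults rtol 10⁻⁸ /
atol 10⁻¹⁰.  For constant light the matrix exponential expm(M·t) serves as
an exactness oracle in the tests.  The fast-reduced model is a scalar
linear relaxation of yA with rate q4(u_local + q2) toward
(u_av+q2)/(u_local+q2)·(u_local/u_av)·yA_ss(u_av), with yB frozen at
yB_ss(u_av); it is solved in closed form (no integrator error).

**Maintenance-term reading.**  Me is printed as a rate (h⁻¹) but appears
inside a dimensionless bracket in the growth law.  The default
`growth_rate` reading treats it as a rate subtracted after the κγ growth
conversion, µ = 3600·κγ·ȳA − Me [h⁻¹], which yields µ = 1.139 h⁻¹ at the
productivity ceiling ȳA = 0.625; the alternative dimensionless reading
µ = 3600·κγ(ȳA − Me) is available via `me_mode="fraction"`.  The printed
κγ ≈ 5.3·10⁻⁴ s⁻¹ is treated as exact; statements that it is "of order
10⁻⁴" are taken as order-of-magnitude prose.

## Light field

Beer–Lambert attenuation from the bottom wall, u(z) = u0·e^(−Λz), with
optical thickness Ot = ΛL.  The case study fixes Ot = 8 ln 2 ≈ 5.5 (the
far wall receives u0/256) and chooses u0 = Ot/(1 − e^(−Ot)) ≈ 5.567 so the
depth average is u_av = 1, the optimum for a perfectly mixed culture.
Attenuation is held constant during a transport run (biomass treated as
quasi-static); recompute Λ(cx) between macro-steps if biomass growth is
applied.  The textbook thin-culture profile ratio u(z)/u_av ≈ Ot·e^(−Ot
z/L) is provided but flagged: it drops a factor (1 − e^(−Ot))⁻¹, a 0.4%
understatement at Ot ≈ 5.5, where the culture is in fact optically thick.

## Cavity flow

Steady lid-driven cavity in streamfunction–vorticity form: explicit
pseudo-time stepping of the vorticity transport equation, a direct
prefactorized sparse solve (UMFPACK-style LU via `scipy.sparse.splu`) of
the ψ-Poisson equation every step, and Thom's first-order wall-vorticity
closure.  Convection differencing is central (second order) while the
cell Péclet number Re/n ≤ 16 and first-order upwind beyond, where the
explicit central iteration diverges; the switch is automatic and
overridable.  Convergence is declared when the relative vorticity change
per step falls below `tol` (default 10⁻⁷); divergence raises with the
iteration count and scheme.

Validation: at Re = 100 on a 64² grid the centerline velocity minimum is
−0.2115 (lid units) at z/L = 0.453, against the published benchmark
tabulation −0.2109 at 0.4531 (fine-grid reference −0.2140); coarser grids
converge monotonically toward it.  Re = 1000 on 64² reproduces the primary
vortex qualitatively; it is deliberately not used for quantitative
centerline claims.  ν defaults to 10⁻⁶ m² s⁻¹ (water), the value under
which Da·Re = 260 for L = 0.02 m.  The solver is laminar only: above
Re ≈ 5000 it warns, and the well-mixed turbulent regime (the Re = 10⁵
case) is represented by the transport module's ideal-mixing mode, not by a
turbulence model.  Transient cavity oscillations are neglected (steady
solve).

The analytic vortex fixture ψ = A·sin(πx/L)sin(πz/L) provides an exactly
solenoidal closed-streamline flow for tests; its node streamfunction is
zeroed on the walls so face fluxes vanish there identically.

## Transport–reaction coupling

One time step is a first-order Lie split: advection → dispersion →
reaction.

* **Advection** is conservative first-order upwind on cell faces.  Face
  velocities are finite differences of the node streamfunction, which
  makes the discrete field *exactly* divergence-free (telescoping) and the
  wall-normal fluxes exactly zero; uniform fields and the per-cell sum
  yR + yA + yB = 1 are then preserved to machine precision.  The step is
  sub-cycled so each explicit sub-step respects the CFL bound (target
  0.9); with sub-cycling disabled a CFL violation is a hard error before
  stepping.
* **Dispersion** uses implicit-Euler ADI sweeps with zero-flux walls
  (unconditionally stable; banded solves factored once).  De defaults to
  ν/Sc with Schmidt number 1 (10⁻⁶ m² s⁻¹), configurable.
* **Reaction** applies, per cell, the exact constant-light propagator
  expm(M(u(z))·dt) (precomputed once per grid row, since irradiance varies
  only with height) or the reduced closed form.  The stiff part is
  therefore unconditionally stable and free of time-integration error.

Default dt = 0.025 s; the mixing study in the acceptance tests uses
dt = 0.05 s and a 2000-s horizon on a 64² grid (a deliberate desk-scale
setting: the slow photoinhibition transient, time constant ≈ 1630 s, is
then only partially decayed, and the tests bound it analytically rather
than running the 20 000-s horizon).  Fractions are clipped to [0, 1] only
with a logged warning and a counted event; clip events are asserted zero
in the test fixtures.

**Ideal-mixing mode.**  The infinite-dispersion limit is implemented
exactly: fields are homogenized and react under the depth-averaged
generator, which — because M(u) is affine in u — is just M(u_av).  The
mode is therefore equivalent to a single-parcel ODE at the average
irradiance and approaches the ceiling yA_ss(u_av) = 0.625 (up to the
O(q5) gap).  The alternative "homogenize, then react at local u" ordering
was measured to carry O(dt) splitting bias (≈ 4·10⁻³ at dt = 0.05 s) and
is not used.  Initial conditions default to all-rested (yR, yA, yB) =
(1, 0, 0); the reduced mode starts with yB at its frozen quasi-steady
value 0.1875.

## Lagrangian cross-check

Cells are massless tracers (no inertia, no shear response; they do not
modify the flow).  `trace` integrates dx/dt = v(x) with classical RK4 on a
hand-rolled bilinear interpolant of the cell-centered velocities, with
specular reflection at the impermeable walls; a stagnation start returns a
stationary trajectory with a warning.  The irradiance history u(t) =
u(z(t)) drives the full kinetics through the stiff integrator.  Matched
limits are property-tested: constant histories reduce to constant-light
integration; square-wave cycles much faster than the 1.5-s reaction time
average to yA_ss(mean u) (the flashing-light enhancement in Lagrangian
form), cycles much slower than photoinhibition average the steady-state
curve quasi-statically; and on a closed streamline with De = 0 the
Eulerian cell time-average of yA agrees with the trajectory-integrated
kinetics within the upwind discretization error (tolerance 0.05 at the
32²-grid, dt = 0.01 s setting).

## Performance metrics

J/cx is the spatio-temporal mean of yA — trapezoid time average of the
spatial mean over an averaging window defaulting to the post-transient
second half of the record — bounded by max_u yA_ss = 1/(1+2q2) = 0.625.
The Damköhler number Da = (1/t_r)(L²/ν)/Re with t_r = 1/[q4(u_av+q2)] =
1.538 s compares transport and reaction times; Re = 0 maps to Da = ∞.
The mixing sweep runs the transport pipeline per mixing level, records
failures without aborting, reports the nominal Da = 260/Re for the
ideal-mixing stand-in (flagged in the `ideal_mixing` column), and sorts by
decreasing Da so the enhancement appears as a monotone J column.  The
closed-form sweep endpoints are 0.3986 for no mixing (depth integral of
yA_ss(u(z)) by partial fractions: with q2 = 0.3 the integrand factors over
(u+3)(u+1/3), giving (1.25/Ot)·ln[(u+1/3)/(u+3)] between the wall
irradiances) and 0.625 for ideal mixing.

## What the synthetic inputs do and do not represent

The analytic vortex and the cavity flow are idealized stand-ins for one
Taylor-vortex cell: closed streamlines, steady, laminar, 2-D.  Passing
tests demonstrate the coupling mechanism (trajectory × light gradient →
light/dark cycles → enhancement), not quantitative productivity of any
real reactor: real systems add 3-D unsteady flow, turbulent dispersion
with an unknown Schmidt number, light scattering, photoacclimation, and
shear-stress damage (the maintenance term is held constant here).  Gas and
nutrient species are not transported; biomass is constant within a run.

## Numerical defaults

| quantity | default | note |
|---|---|---|
| grid | 64×64 cells, L = 0.02 m | ~10⁴ cells |
| dt (transport) | 0.025 s | 0.05 s in the desk-scale mixing study |
| dt_out | 10 s | spatial means recorded |
| ODE tolerances | rtol 10⁻⁸, atol 10⁻¹⁰ | BDF, analytic Jacobian |
| cavity tol | 10⁻⁷ relative vorticity change | 10⁻⁶ in large sweeps |
| De | 10⁻⁶ m² s⁻¹ (Sc = 1) | 0 for stagnant runs |
| CFL target | 0.9 | advection sub-cycling |

Determinism: the whole pipeline is seed-free and bit-reproducible (fixed
iteration orders, direct solvers); re-running a case with the same
configuration reproduces its outputs exactly.
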