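# psfcav

Coupled simulation of photosynthetic reaction kinetics, hydrodynamics and
light attenuation in a 2-D microalgae culture system.

## The problem

Microalgae in a photobioreactor do not experience the steady average light
of the vessel: mixing carries each cell between the bright illuminated wall
and the dark interior, so its photosynthetic apparatus is driven by
hydrodynamically induced light/dark cycles.  Experiments show that fast
cycles grow cultures *better* than the equivalent constant average light —
the **flashing-light enhancement**.  `psfcav` reproduces this effect from
first principles for a canonical geometry: a square cavity of side
L = 2 cm, illuminated through the bottom, stirred by a moving top wall
(one idealized Taylor-vortex cell of a Couette–Taylor photobioreactor).

## The model

**Kinetics.** Each photosynthetic unit is in one of three states — rested
R, activated A, inhibited B — with fractions y = (yR, yA, yB) evolving as

    dy/dt = [𝒜 + u(t) ℬ] y,

where u = I/I_opt is the irradiance normalized by the optimal level
q1 ≈ 250 µE m⁻² s⁻¹.  The generator (Wu–Merchuk parameters for
*Porphyridium* sp.) has zero column sums and a fast/slow spectrum:
light/dark reactions relax in ~1.5 s while photoinhibition builds over
~30 min (eigenvalues −0.63 and −0.59·10⁻³ s⁻¹ at u = 1, a stiffness ratio
of ~10³).  The steady activated fraction

    yA_ss(u) = (u/q2) / (u² + u/q2 + 1)

peaks at u = 1 with yA_ss = 0.625 (q2 = 0.3).  A singular-perturbation
("fast-reduced") scalar model for yA with yB frozen is also provided.

**Flow.** Steady incompressible lid-driven-cavity velocity fields from a
streamfunction–vorticity solver (validated against the published Re = 100
centerline benchmark), plus an exactly solenoidal analytic vortex fixture.

**Light.** Beer–Lambert attenuation u(z) = u0·e^(−Λz) from the bottom
wall; the case study uses optical thickness Ot = ΛL = 8 ln 2 ≈ 5.5 with
the incident level chosen so the depth average is u_av = 1.

**Coupling.** The three fractions are transported by the frozen velocity
field with an advection–diffusion–reaction solver (conservative upwind
advection, implicit ADI dispersion, exact per-cell reaction propagators).
A Lagrangian module (particle tracking → irradiance history → kinetics
along the trajectory) provides an independent cross-check.  Productivity
is measured by the normalized performance index J/cx — the spatio-temporal
mean of yA, bounded by 0.625 — and mixing intensity by the Damköhler
number, which for this geometry in water obeys Da = 260/Re.

## Worked example

```python
import numpy as np
import psfcav as p

ss = p.steady_state(1.0, q2=0.3)
print(f"steady state at u=1: yR={ss.yR:.4f} yA={ss.yA:.4f} yB={ss.yB:.4f}")
print(f"Da at Re=1000: {p.damkohler(1000.0):.3f}")
print(f"growth at yA=0.625: {p.growth_rate(0.625):.3f} 1/h")

grid = p.Grid2D(32, 32, 0.02)
light = p.LightField.from_average(1.0, 8*np.log(2), 0.02)
cfg = p.TransportConfig(dt=0.05, T=600.0, mode="reduced", dt_out=10.0)
df = p.mixing_sweep(["none", 1000.0, ("ideal", 100000.0)], light=light,
                    grid=grid, config=cfg)
print(df[["label", "Re", "Da", "J_norm", "mu_per_h"]].to_string(index=False))
```

prints

```
steady state at u=1: yR=0.1875 yA=0.6250 yB=0.1875
Da at Re=1000: 0.260
growth at yA=0.625: 1.139 1/h
  label       Re     Da   J_norm  mu_per_h
   none      0.0    inf 0.425408  0.756450
Re=1000   1000.0 0.2600 0.461475  0.825585
  ideal 100000.0 0.0026 0.625000  1.139039
```

Read: at the optimal average irradiance a perfectly stirred culture keeps
5/8 of its photosynthetic units activated and grows at 1.14 h⁻¹; without
mixing, the bright-dark stratification wastes capacity (J/cx ≈ 0.43 here);
stirring at Re = 1000 recovers part of the gap, and the enhancement grows
monotonically as the Damköhler number falls — the flashing-light effect.

A command-line interface exposes the same pipeline:
`psfcav kinetics|flow|simulate|trace|sweep|case` (see `psfcav --help`).
Configuration files are flat `key = value` text; an empty file reproduces
the default case study.

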