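# gravinet

A reduced-order (0D) simulator of pulsatile blood flow through a continuous
heart-to-eye arterial network, built to compare an upright Earth-gravity
case against a simulated-microgravity case (stroke volume +20%, external
iliac outlet resistance +93%, g = 0).

The package implements:

* **Blended blood rheology** (`gravinet.rheology`) — Fåhraeus-Lindqvist
  diameter-dependent viscosity below 0.6 mm vessel diameter (Pries-type
  in-vitro relative viscosity, haematocrit 0.45, plasma 1.2 mPa·s),
  Carreau-Yasuda shear thinning above 1.2 mm
  (η∞ = 0.0035 Pa·s, η0 = 0.16 Pa·s, λ = 8.2 s, a = 0.64, n = 0.2128),
  and a linear blend in between.
* **Structured fractal-tree outlets** (`gravinet.fractal_outlets`) —
  deterministic asymmetric bifurcating trees grown below each retinal
  arteriole outlet down to a 4 μm capillary diameter, collapsed to an
  equivalent Hagen-Poiseuille resistance.
* **Boundary conditions** (`gravinet.boundary_conditions`) — regional
  cardiac-output split table (subclavian computed as the residual, 6.09%),
  Murray's-law (r³-weighted) outlet resistances at the systolic operating
  point, and conversion of any designed resistance into an
  effective-viscosity "extruded outlet" of length twice the outlet diameter.
* **Quasi-static network solver** (`gravinet.network_solver`) — per-instant
  linear nodal solves in piezometric pressure (gravity enters as
  hydrostatic elevation heads; outlets see zero pressure at their own
  elevation), with under-relaxed Picard iteration on the shear-dependent
  viscosities, cyclic convergence checking, and the microgravity case
  transform.
* **Synthetic geometry** (`gravinet.synthetic_geometry`) — a stand-in
  heart-to-eye tree with the published regional outlet counts (72 outlets),
  a 163 μm central retinal artery, upright elevations, and a parametric
  single-peaked inflow waveform with exact stroke-volume normalization.
* **Metrics** (`gravinet.metrics_report`) — peak/average flow extraction,
  percent-change and bilateral paired-mean operators, Poiseuille wall shear
  stress, TAWSS, OSI, and a gravity-vs-microgravity comparison table.

Being a memoryless resistive network (no compliance or inertia), the solver
reproduces flow redistribution and shear trends, but oscillatory metrics
are degenerate: OSI is identically zero for non-reversing inflow.

## Command line

```sh
# generate the synthetic network, outlet table and inflow waveform
gravinet synth --seed 0 --out geom/

# solve one case (writes per-outlet cycle-averaged flows)
gravinet run-case --network geom/ --case gravity --out flows_g.csv
gravinet run-case --network geom/ --case microgravity --out flows_ug.csv

# run both cases and emit comparison tables + run manifest
gravinet compare-cases --network geom/ --out comparison/
```

All files are plain CSV/JSON; see `gravinet.io` for column layouts.

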