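# Methods

`stentflow` simulates the first seconds-to-minutes of platelet accumulation
around coronary stent struts implanted in a vessel wall, with and without
peri-strut tissue defects (the morphological correlate of late stent
malapposition under drug-eluting stents). It couples an incompressible
Navier–Stokes solver on a masked Cartesian grid to Lagrangian "virtual
platelets" carrying a stochastic receptor-bond model. This note records the
model, its closure choices, the numerical methods, and what the desk-scale
results do and do not demonstrate.

## Geometry and scenario

Coordinates: `y` streamwise, `z` wall-normal (wall surface at `z = 0`,
fluid above), `x` transverse. The computational domain is a near-wall
channel patch of a 3 mm vessel: resolving the full cylinder is unnecessary
for the dynamics within a few strut diameters of the wall, so the default
domain is a rectangular patch with a free-slip symmetry lid. The 2-D `y–z`
mode (one transverse cell, a configurable represented slab thickness for
all volumetric bookkeeping) is the working default; the solver also runs in
3-D with periodic transverse boundaries.

Struts are rigid cylinders of diameter d = 0.09144 mm with axes along `x`,
centered at `z = 0` so exactly half is embedded. A tissue defect is a
groove carved out of the wall around a strut: fluid occupies
`-depth <= z < 0` within a horizontal distance `d/2 + width` of the strut
axis, with `width = d` (the stated defect size) and `depth = d/2` by
default (the depth is not fixed by any source; `d/2` exposes the whole
buried half, the geometric reading of malapposition). Strut spacing
(0.5 mm center-to-center) is likewise a free choice, as is the
representation of the stent as a transverse strut array rather than a
curved ring.

Surface patches carry reactivity factors: injured wall 1.0, defect cavity
1.0, strut metal 0.1, healthy endothelium 0.0. The injured (reactive) wall
is the stented segment only — from one strut diameter upstream of the first
strut to five diameters downstream of the last, coinciding with the default
counting region. Making the entire wall reactive is qualitatively wrong:
the upstream segment then scavenges the near-wall platelet layer before it
reaches the struts (entrance depletion), moving the adhesion pattern
upstream of the stent.

## Blood flow

Incompressible Navier–Stokes, Newtonian blood (ρ = 1000 kg/m³,
μ = 1.004 mPa·s, i.e. ν = 1.004 mm²/s; the source's printed
"0.001004 m²/s" is dimensionally inconsistent and is read as dynamic
viscosity). Channel Reynolds number ≈ 30–70, strut Reynolds number ≈ 2:
viscous laminar, no turbulence model.

Solver: Chorin projection on a staggered (MAC) grid — explicit first-order
upwind advection, explicit centered diffusion, exact pressure projection via
a prefactorized sparse direct solve (SuperLU). Substeps obey a harmonic
combination of the advective CFL and 90% of the FTCS diffusive bound.
Solids are a staircase binary mask; every velocity face adjacent to a solid
cell is held at zero (first-order immersed boundary), with the strut
resolved by ≥ 6 cells per diameter (grid spacing d/6 enforced near struts).
Boundary conditions: prescribed inflow at `y = 0` (developed half-channel
Poiseuille profile of unit mean by default; plug optional), convective
outflow with `p = 0` projection ghost, no-slip bottom, free-slip lid,
periodic transverse. After projection the discrete divergence is at direct-
solver precision (measured ≲ 1e-12/s) and inlet/outlet flux balance is
exact to rounding.

The inflow waveform is a sawtooth ramping linearly from 0 to 22.5 mm/s
(section mean). The ramp period defaults to the 30 s perfusion, i.e. the
flow accelerates linearly over the whole run. The source statement
("pulsatile flow with a linear change from 0 to 22.5 mm/sec") fixes no
period; the 30 s reading is chosen by model identification: it is the only
reading under which "almost no platelets adhered at 1 second" and a
few-hundred-per-mm² density at 30 s can hold simultaneously (see *Tether
kinetics* below). The period is a config knob; a 1 s cardiac-cycle sawtooth
is one line of configuration away.

Because the ramp is slow compared with the viscous equilibration time of
the patch (≈ 0.4 s), the engine treats the flow as quasi-steady: it solves
steady fields at a ladder of inflow levels (warm-started continuation, 12
levels by default) and linearly interpolates between them at each coupling
step. A fully unsteady time-stepped flow table remains available
(`flow_model: unsteady`) and is the path exercised by the solver tests.

Known resolution limit: at strut Reynolds number ≈ 2 a smooth half-buried
cylinder separates only marginally; the staircase d/6 and d/12 grids show
no reversed streamwise flow behind a bare strut (a weak corner eddy appears
at d/18). The recirculation that matters for adhesion — inside the defect
cavity — is robust already at d/6.

## Virtual platelets

Platelets are point parcels with a nominal 1 µm radius used for drag, gap
computation, and excluded volume (centers never closer than one radius to
any surface; seeding and injection respect this). They are seeded uniformly
over the fluid at 300 × 10⁶/ml (3 × 10⁵/mm³; a Poisson draw of the exact
expected count) and replenished at the inlet by Poisson injection
proportional to the instantaneous inflow flux, flux-weighted across the
inlet profile. One computational parcel may represent `parcel_weight`
physical platelets; reported densities are rescaled accordingly.

Free platelets move with the interpolated fluid velocity (midpoint
second-order integration) plus Brownian displacements with the
Stokes–Einstein diffusivity at 310 K (D ≈ 2.3 × 10⁻⁷ mm²/s). Brownian
motion is the only cross-streamline transport in the model — red-cell-
enhanced dispersion, the dominant margination mechanism in whole blood, is
out of scope — and it is load-bearing: without it the sub-micrometre
capture layer at the wall depletes permanently in steady parallel flow and
wall adhesion dies out. Passing results therefore demonstrate the
defect/no-defect *contrast* under diffusive near-wall transport, not
absolute whole-blood adhesion rates.

### Tether kinetics

A FREE platelet whose surface-to-surface gap to the nearest reactive patch
is at most δ_cap = 0.5 µm forms a tether with per-step probability
`1 − exp(−k_on · s · r · g(t) · Δt)` where `r` is the patch reactivity,
`s` the calibration scale, and `g(t) = U(t)/U_peak` the shear gate: the
on-rate scales with the instantaneous driving flow, emulating shear-
mediated GPIbα–VWF capture. The gate is global rather than local-shear so
that the stagnant defect cavities — whose exposed collagen binds at all
shears — are not spuriously silenced. The gate is what makes the 1 s
density two orders of magnitude below the 30 s density under the 30 s ramp:
early in the run both transport to the wall and the on-rate are small.

The receptors are lumped: the initial tether stands for GPIbα–VWF capture;
activation (triggered immediately on adhesion by default, delay
configurable) multiplies the bond spring constant by α and divides the
unstressed off-rate by α, switching the same bond record to firm
GPIIb/IIIa-like parameters. α defaults to 1000, making firm adhesion
effectively irreversible over 30 s (survival ≈ 86% against the unstressed
off-rate alone): the reported monotone accumulation curves are only
reproducible in this regime — at α ≈ 10 the adhered population churns
(lifetime ~2 s) and decays. None of the kinetic constants is printed in
any source; all are configurable, and the absolute level is set by a single
calibration (below).

### Bond mechanics and rupture

The bond is a Kelvin–Voigt element, `F = k·x + c·ẋ` (tensile positive,
extension beyond a 1 µm rest length), with k = 1 µN/m and c = 1 nN·s/m by
default. Tethered/adhered platelets obey a quasi-static balance of Stokes
drag `6πμa(u_f − u_p)` against the bond force: the radial extension follows
the linear overdamped relaxation `x → x∞ + (x − x∞)e^(−Δt/τ)` with
`x∞ = max(γ u_r, 0)/k` and `τ = (γ + c)/k` (integrated exactly over the
step), while the platelet swings tangentially with the local flow at fixed
bond length. Compression is cut off at zero (the wall provides the normal
constraint). Rupture is Bell-type: `k_off(F) = k_off0 · exp(F/F_c)` with
k_off0 = 5 s⁻¹ and F_c = 20 pN, sampled per step as
`1 − exp(−k_off Δt)`. A monolayer packing cap (one platelet per 4 µm² of
wall footprint, bookkept in 2 µm bins) bounds local accumulation.

## Coupling, counting, calibration

The engine advances flow lookup → free advection + diffusion → contact
resolution → tether attempts → bonded force balance → activation → rupture
→ inlet replenishment → outflow removal, every Δt = 0.01 s, logging every
tether/activate/rupture event with position and patch. A platelet
conservation identity (in-domain + exited − injected = seeded) holds
exactly at every step, and runs are bit-reproducible given the seed.

Adhered density is the count of ADHERED parcels (a switch includes
TETHERED) whose wall-projected position falls in the counting region — by
default 1 d upstream of the first strut to 5 d downstream of the last, the
full width — times parcel weight over the region area, sampled every 0.1 s.
Per-strut upstream/downstream bands of width d, Fig-3-style wall-normal
velocity maps (sampled 1 µm above the staircase wall, never below the
nominal wall plane `z = 0`), VTK snapshots and CSV time series are exported
by the observables module and the CLI.

Because the original adhesion constants are unavailable, absolute densities
are matched by a one-scalar calibration: a monotone bracketing/bisection
search over a global multiplier on k_on until the **no-defect** 30 s
density matches 490/mm² (tolerance 12%). The with-defect arm inherits the
scale unchanged and is a genuine prediction; at desk scale it lands a
factor ≈ 4–5 above the no-defect arm (reported ratio ≈ 7), driven by the
extra reactive cavity surface, cavity recirculation residence, and the
stronger toward-wall flow downstream of struts when defects are present.

## Problem sizes and runtime

The desk-scale study (the package's reference configuration, used by the
test suite and the acceptance script) is 2-D: a 2.0 × 0.6 mm patch, 0.1 mm
represented thickness, two struts at y = 0.7/1.2 mm, grid d/6
(131 × 43 cells), ~36 000 parcels, full 30 s perfusion. One flow table
takes ~50 s and one perfusion ~30 s on a single CPU; the complete
calibration-plus-ten-paired-seeds study runs in ~15 minutes. The full-scale
geometry of the source (3 mm vessel, Xeon-Phi-class resolution) is
expressible in the same configuration but is not the tested path.

## Limitations

- No red-cell–platelet interaction: near-wall excess and shear-induced
  dispersion are absent, so calibrated on-rates absorb transport physics.
- One-way coupling: adhered platelets do not obstruct the flow; no
  aggregation beyond a packing cap, no coagulation cascade or fibrin.
- First-order staircase walls; strut-scale boundary layers are ~6–10 cells.
- The 2-D slab ignores transverse wake structure; 3-D runs are supported
  but untested against the headline numbers.
- Quasi-steady flow interpolation assumes the waveform varies slowly
  against the viscous time; for sub-second pulsation use the unsteady mode.
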