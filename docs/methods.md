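# Methods

This note documents the models, numerical choices and limitations of
`poroseg` — the porous-medium flow approach to volumetric image
segmentation — at the level of detail a user needs to interpret results and
a maintainer needs to modify defaults.

## Model overview and assumptions

The method treats a greyscale volume as a porous material.  Three physical
assumptions underpin it:

1. **Linear partial-volume mixing.**  A voxel's intensity is the
   volume-weighted blend of pure-fluid and pure-solid intensities, so the
   fluid fraction is `ε = (I_v − I_s)/(I_f − I_s)`.  This holds well for CT
   (attenuation is nearly linear in material density) and degrades under
   beam hardening or strong reconstruction-kernel effects, which are not
   modelled.
2. **Shrunken-voxel resistance.**  A boundary voxel is idealised as a solid
   slab of height `(1−ε)d` opposing a fluid slab of height `εd`.  Deriving
   the Ergun-type friction law with hydraulic radius `εd` and subtracting
   the open-voxel reference gives, after replacing physical with superficial
   velocity (`v = v_s/ε`), the viscous resistance
   `P_v = A (1−ε)² μ/(ε³ d²)` with `A = 3` and inertial constant `B = 0`.
   The constants are not free parameters: the package re-derives them by
   simulation (see *Calibration*).
3. **Creeping flow.**  With inlet Reynolds numbers below one, the flow fills
   the domain by porosity alone, without inertial artefacts such as
   separation or recirculation-driven asymmetry.  The solver therefore drops
   the convective term entirely (linear Stokes–Brinkman); this is a design
   choice, not merely a numerical convenience — it makes the solution exactly
   linear in the inlet speed and deterministic.

The working fluid is arbitrary: per-voxel Blake numbers
`Bl = (ρud/μ)·ε/(1−ε)` are ~10⁻⁷ near boundaries at the default inlet speed,
so viscous resistance dominates for any sensible fluid.  Presets `blood`
(ρ = 1030 kg m⁻³, μ = 0.004 Pa s), `air` (ρ = 1.18415 kg m⁻³,
μ = 1.85508×10⁻⁵ Pa s) and `unit` (water-like) are provided.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| coarse range `(I_min, I_max)` | user input | intensity | inclusive at both ends; conservative bounds suffice — the final surface is insensitive to the exact choice |
| `(I_f, I_s)` | coarse bounds | intensity | by default mapped from the coarse range with a bright-/dark-fluid switch; set explicitly when the true reference intensities are known (phantoms do this) |
| `eps_min` | 0.1 | – | closed bound: ε ≤ 0.1 voxels become solid; the resistance law is singular as ε → 0 |
| target spacing | 0.1 mm (aneurysm), 0.25 mm (airway) | mm | isotropic resample before the porous model; skipped when the input is already isotropic and no target is set |
| inlet speed | 10⁻⁴ | m/s | keeps inlet Re < 1 in all presets |
| solver tolerance | 10⁻⁸ | – | relative momentum/continuity residual; the inner CG runs two decades tighter |
| sweep | 33 log-spaced values in [10⁻¹⁴, 10⁻⁶] | m/s | the reference iso₀ (inlet/10 for compact objects, inlet for complex ones) is appended if absent |
| plateau slope threshold | 5 % of max slope | – | documented, overridable heuristic replacing the visual judgement of the original procedure |
| indicator | dR | – | `dr` (area-based) is preferable for scroll-like geometries; both are always reported |

## Calibration

`calibration` reproduces the single-voxel channel experiment.  The fluid
strip of height `εd` is meshed with 64 square cells across (no-slip bottom,
shear-free top, fully developed half-parabolic inflow, zero-pressure
outflow); the streamwise pressure gradient is the least-squares slope of
column-averaged pressure.  The plane-Poiseuille closed form
`Δp/L = 3 μ v/(εd)²` serves as the independent oracle: the discrete solver
converges to it at second order (0.08 % at 32 cells, 0.02 % at 64).

The default campaign is `d ∈ {0.25, 1.0} mm × ε ∈ {0.3, 0.5, 0.7, 0.9} ×`
four velocities log-spaced in `[5×10⁻⁴, 4] m/s` — a deliberate reduction of
the full 4 × 10 × 15 grid, justified because the friction relation is exact
rather than statistical.  The fit `f_b = A/Re_b + B` is unweighted linear
least squares in `1/Re_b`.  Because the solver is inertia-free, `B`
vanishes identically; the original experiment reached the same conclusion
with a laminar Navier–Stokes solver at velocities up to 4 m/s.

The packed-bed voxel alternative (spherical particles inside the voxel,
Blake–Kozeny constant 150) is implemented for comparison only: its
non-dimensionalisation of the *same* pressure drops yields per-porosity
constants with a coefficient of variation above 0.5, i.e. no single
resistance law — the quantitative form of the collapse/non-collapse
dichotomy.

## Flow solver numerics

* MAC staggered grid: face-normal velocities, cell-centred pressures,
  7-point Laplacian; face resistance is the mean of the adjacent cells'
  `P_v`.  The saddle-point system is symmetric by construction.
* No-slip tangential walls use ghost reflection (`u_ghost = −u`), symmetry
  and outflow use zero-gradient ghosts; the outlet pressure ghost sits at
  the ghost-cell centre (distance h), an O(h/2) placement shift that keeps
  the system symmetric and is below scheme accuracy.
* Small systems (≤ ~45 k unknowns) are solved by sparse LU on the full
  saddle matrix; larger ones by conjugate gradients on the pressure Schur
  complement with per-axis LU factors of the velocity block and a
  variable-coefficient pressure-Poisson preconditioner
  (`Cᵀ diag(A)⁻¹ C`).  Both paths are deterministic; residuals are checked
  after the solve and a failure raises rather than returning a degraded
  field.
* Degenerate topology: fluid components that do not connect an inlet face to
  an outlet face cannot carry the prescribed influx consistently and are
  reassigned to solid (counted and logged); this also removes isolated
  cells.  If nothing connects, the solver warns and returns the zero
  solution (zero net flux).
* Discrete mass conservation is exact to solver tolerance; inlet/outlet
  fluxes balance to ~10⁻¹² relative in practice.

## Iso-surface extraction and selection

Marching cubes runs on the speed field padded with one zero voxel so
surfaces close at the grid boundary.  The pipeline extracts on
`log10(speed)` by default: level sets are unchanged, but edge interpolation
becomes meaningful where the speed decays exponentially across the
Brinkman boundary layer (decay length `sqrt(μ/P_v)`, far below one voxel),
which is precisely where the segmentation surface lives.  Linear-space
interpolation remains available (`log_interp=False`).

The spherical-model indicator keeps the `2π(r₀+dr)²` area convention of the
original formulation (a sphere's area is `4πr²`); the constant rescales
`r₀` and `dr` jointly and does not move plateau or inflexion locations.
Plateau detection: slopes of the indicator against `log₁₀ iso`; segments
below 5 % of the maximum slope form plateaus (minimum two consecutive
segments); with a terminal upturn at low iso the plateau's low-iso edge
(the inflexion) is chosen, otherwise its high-iso edge (the plateau start).
Ties between plateaus resolve to the lowest-iso plateau.  A flat or
plateau-free curve raises an error instructing a manual choice.

Cloud-to-mesh (C2M) statistics use an exact point-to-triangle distance
(k-d tree candidate search with a guaranteed refinement pass) and are
normalised by the *original* in-plane pixel size, not the upsampled
spacing.

## Synthetic phantoms: what they emulate, and what they do not

The generator renders unions of analytic solids (spheres, capsules, torus
segments, Y-bifurcations) through the same linear partial-volume model the
segmentation inverts, with per-voxel fluid fractions from stratified
sub-sampling of the signed distance function (error ≤ 1/n per boundary
voxel at n³ sub-samples; n = 3 by default).  Realism knobs: slice-thickness
Gaussian blur along z (applied before noise, acquisition order), additive
Gaussian noise, and speckle blobs emulating stray bright/dark clutter.
Default noise (sd 10 at a 200-intensity contrast) puts the phantom CNR at
20, inside the 5.9–62.8 range spanned by typical clinical CT volumes.

What phantoms do **not** emulate: CT physics (beam hardening,
reconstruction kernels, streaks), anatomical texture, motion, and
intensity inhomogeneity.  Passing phantom tests therefore demonstrates the
pipeline's geometric and numerical correctness under the stated noise
model — not clinical performance, which requires real data.

Ground truth is delivered both as the analytic SDF and as a marching-cubes
mesh at 2× grid refinement, so C2M evaluations use an effectively exact
reference; a coaxial capsule-plus-sphere configuration has a closed-form
union volume (two-sphere lens correction) used to validate the reference
mesh itself to < 1 %.

## Problem sizes and defaults used in the shipped checks

The test suite and acceptance script run at desk scale by design: the
calibration campaign uses the reduced grid above (32 two-dimensional solves
at 64 cells across, ~5 s total); the end-to-end phantom is 64³ voxels at
0.5 mm with ~16 k fluid cells (solve ~8 s, full pipeline ~13 s).  These
sizes were chosen because the quantities being checked (exact friction-law
algebra, second-order solver convergence, sub-voxel C2M on a two-primitive
phantom) are already fully resolved there; the pipeline itself handles
larger grids through the iterative solver path.

## Known limitations

* Isotropic, scalar resistance only; no tensor-valued anisotropy.
* No transient flow, turbulence, non-Newtonian rheology, or slip-interface
  (Beavers–Joseph) wall conditions.
* No mesh post-processing for CFD (smoothing, inlet/outlet extrusion); the
  output is the raw marching-cubes surface.
* Plateau detection is a heuristic with a documented threshold; curves from
  very low-contrast or pathological data may require the manual override.
* DICOM support covers plain single-frame CT series with uniform slice
  spacing; irregular series are rejected rather than resampled.
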