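# poroseg

Physics-based segmentation of volumetric medical images by porous-medium
flow.  Instead of thresholding intensity directly, `poroseg` translates each
voxel's greyscale value into a porosity, converts porosity into a viscous
flow resistance, solves steady creeping flow through the resulting porous
domain, and extracts the target object (a vessel lumen, an aneurysm sac, an
airway) as a velocity-magnitude iso-surface.  Because the velocity varies
smoothly through partial-volume boundary voxels, the surface is resolved at
sub-voxel precision and is robust to image noise.

Intended users: researchers in vascular/airway image analysis and
computational haemodynamics who need smooth, watertight lumen surfaces from
CT/CTA volumes, and anyone who wants a fully scripted, deterministic
segmentation pipeline with ground-truthed synthetic phantoms for testing.

## Method

1. **Partial volume → porosity.**  A voxel straddling the fluid–tissue
   boundary blends the pure-fluid and pure-solid intensities, so the fluid
   fraction (porosity) is recovered linearly and clipped to [0, 1]:

   ```
   ε = (I_v − I_s) / (I_f − I_s)
   ```

   Voxels with ε ≤ 0.1 are treated as entirely solid and removed from the
   flow domain.

2. **Porosity → resistance (shrunken-voxel model).**  Each boundary voxel is
   modelled as opposing solid and fluid slabs.  Calibrating the resulting
   Ergun-type friction law against resolved 2-D channel flow gives a purely
   viscous resistance with constant A = 3 (the inertial constant B vanishes
   in the creeping regime):

   ```
   P_v = 3 (1 − ε)² μ / (ε³ d²)        [kg m⁻³ s⁻¹]
   ```

   with `d` the isotropic voxel edge and `μ` the working-fluid viscosity.
   The calibration campaign — friction factor `f_b = (Δp/L) ε d/(ρ v²)`
   versus bed Reynolds number `Re_b = ε ρ v d/μ` — collapses onto the single
   hyperbola `f_b = 3/Re_b` for all porosities, whereas the alternative
   packed-bed voxel scaling does not collapse; both diagnostics ship with
   the package.

3. **Creeping flow.**  Steady Stokes–Brinkman equations
   `0 = −∇p + μ∇²v_s − P_v v_s`, `∇·v_s = 0` are discretised on a MAC
   staggered voxel grid (inlet velocity 10⁻⁴ m/s, outlet pressure zero,
   no-slip walls) and solved by a sparse direct factorisation or a
   Schur-complement CG.

4. **Velocity iso-surface selection.**  Sweeping iso-values over
   10⁻¹⁴…10⁻⁶ m/s, the segmented volume V and area A are matched to a model
   sphere, `(4/3)π(R₀+dR)³ = V` and `2π(r₀+dr)² = A`.  The plateau of dR/dr
   against log iso marks thresholds the surface is insensitive to; the
   plateau's terminal inflexion (or its start when no noise upturn exists)
   is the selected segmentation value.  Marching cubes with log-space edge
   interpolation extracts the final watertight surface.

Accuracy is evaluated with cloud-to-mesh (C2M) distances against ground
truth, normalised by the original in-plane pixel size.

## Worked example

Segment a noisy synthetic aneurysm phantom (64³ voxels at 0.5 mm, a 3.2 mm
radius parent vessel with a 6 mm radius sac, contrast-to-noise ratio 20):

```python
from poroseg import aneurysm_phantom, PipelineConfig, run_pipeline

img, gt = aneurysm_phantom(tube_radius_mm=3.2, sac_radius_mm=6.0,
                           neck_offset_mm=7.0, shape=(64, 64, 64),
                           spacing_mm=0.5, noise_sd=10.0, seed=7)
cfg = PipelineConfig(coarse_range=(50, 250), i_fluid=200.0, i_solid=0.0,
                     target_spacing_mm=None, fluid="blood",
                     output_dir="demo_out")
report = run_pipeline(cfg, image=img, reference_mesh=gt.mesh)
print(report.to_text())
```

prints (timings vary):

```
solve                    7.58 s  {'fluid': 16186, ... 'method': 'schur'}
select                   0.00 s  {'method': 'plateau-start', 'iso': 1.778e-08}
extract                  0.04 s  {'vertices': 6181, 'watertight': True}
evaluate                 0.10 s  {'mean': 0.208, 'max': 1.388, 'sd': 0.190, ...}
chosen iso:   1.7782794100389228e-08 (plateau-start)
mass balance: {'inlet_flux': 3.575e-09, 'outlet_flux': 3.575e-09, ...}
```

Reading the output: 16 186 of 262 144 voxels survive coarse thresholding
and form the flow domain; the indicator curve plateaus and the iso-value
1.78×10⁻⁸ m/s is selected automatically; the extracted surface is
watertight, and its mean C2M distance to the analytic ground truth is 0.21
voxels (sd 0.19) — sub-voxel agreement.  Inlet and outlet fluxes balance to
machine precision.  `demo_out/` contains the sweep CSV, the selection
report and the STL surface.

The calibration that fixes the resistance constant can be re-run from the
command line:

```bash
poroseg calibrate --analytic
# A = 3.000000  B = -6.978e-16  rms = 5.610e-15
# collapse CV shrunken = 2.669e-16  packed = 0.543
```

Other CLI subcommands: `poroseg segment` (full pipeline on an image file),
`poroseg phantom` (generate test fixtures), `poroseg evaluate` (C2M between
two meshes), `poroseg sweep-report` (indicator-curve table/plot).

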