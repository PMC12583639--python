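# symphysim

Desk-scale biomechanics of the pubic symphysis during single-leg stance.

Knowing how the pubic symphysis — the fibrocartilaginous midline joint of the
pelvis — is loaded while standing and walking matters for deciding pelvic-
fracture loading regimes and for designing fixation hardware, and it bears on
why a fluid-filled cleft (the interpubic cavity) forms inside the disc of
young walkers. The load cannot be measured in vivo, so it is studied with
finite-element models: bone with CT-density-mapped elastoplastic properties,
a hyperelastic interpubic disc, the hip-joint reaction force of the stance
phase, and the pelvic muscle forces obtained from Hill-type musculoskeletal
models via static optimization.

`symphysim` packages that analysis chain as a tested Python library:

* **`symphysim.materials`** — density calibration ρ = 1.54·ρ_CT + 0.0784 and
  the bone power laws E(ρ), σ_y(ρ) with post-yield softening
  (σ_min, E_p, ε_ab); Mooney–Rivlin disc energy
  W = C10(I1−3) + C01(I2−3) + C11(I1−3)(I2−3) with C10 = 0.1, C01 = 0.45,
  C11 = 0.6 MPa and its closed-form incompressible uniaxial stress.
* **`symphysim.muscles`** — Hill-type force
  F = a·F0·f_L·f_v·cos α and static optimization
  min Σa_i² s.t. Σ a_i F_i r_ij = Q_j, 0.01 ≤ a_i ≤ 1 (exact active-set QP),
  plus the packaged 27-muscle stance force table.
* **`symphysim.solver`** — incremental small-deformation FE on linear
  tetrahedra with tie constraints, distributed couplings, fixed and spring
  supports (total SIJ stiffness k = 4285 N/mm), and secant-modulus iteration
  through the bone softening curve.
* **`symphysim.synthetic`** — a parametric toy pelvis (two bone bodies with
  iliac-wing plates + slit-like disc, cortical-shell/cancellous-core density,
  27 named attachment sites) so everything runs without subject CT data.
* **`symphysim.postprocess`** — von Mises (reduced) stress σ_red,
  logarithmic principal strains, per-part summary tables and load-case
  comparisons with explicit bases.
* **`symphysim.meshio`** — Gmsh MSH 2.2, legacy VTK and Abaqus-INP-subset
  readers/writers; density and material tables as CSV.

See `docs/methods.md` for the model details and their assumptions.

## Worked example

```sh
python examples/bone_material_laws.py
```

prints the per-density material cards the FE pipeline assigns:

```
rho      tissue       E [MPa]   sigma_y [MPa]  sigma_min  eps_ab
0.500  cancellous      610.9         0.736      0.66    0.059
0.945  compact        1733.8        52.366      6.90    0.174
1.600  compact        8823.7       130.221     47.93    0.343

Yield-branch gap at rho = 0.945: -0.0007 MPa (continuous to < 0.1 MPa)

Stress-strain breakpoints at rho = 0.945 (strain, stress MPa):
  ( 0.00000,   0.000)
  ( 0.03020,  52.366)
  ( 0.17381,  52.366)
  ( 0.38483,   6.903)
```

— the two yield branches meet at the 0.945 g/cm³ tissue threshold, and the
uniaxial curve rises elastically to 52.4 MPa, holds a plastic plateau to
17% strain, then softens to the 6.9 MPa residual stress.

```sh
python examples/muscle_static_optimization.py
```

solves a three-abductor moment balance:

```
              name  activation    force_N
 abductor anterior    0.336349 269.078864
   abductor middle    0.550389 660.466301
abductor posterior    0.206396 123.837432
objective sum(a^2) = 0.45866, moment residual = 1.46e-11 N*mm
```

— activations scale with strength and moment arm, the 60 N·m target is met to
solver precision, and the packaged stance table (1632.4 N over 27 muscles,
zeros preserved) is printed below it.

The remaining examples run the disc law (`disc_mooney_rivlin.py`) and the
full toy-pelvis pipeline (`toy_pelvis_pipeline.py`: generate → density →
materials → two FE solves → per-part report and comparison). The same
pipeline is scriptable from the shell:

```sh
symphysim run -c config.yaml -o outdir --seed 42
```

with subcommands `generate`, `materials`, `muscles`, `solve`, `report`, and
`run --resume`; exit codes 0/2/3/4 for success / config error /
non-convergence / I/O error.

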