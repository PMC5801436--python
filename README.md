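# megfem

Finite-element forward solvers for magnetoencephalography (MEG) and
electroencephalography (EEG) on regular hexahedral meshes, with both a
continuous Galerkin (CG) and a symmetric interior-penalty discontinuous
Galerkin (DG) discretization, and with a **conservative flux** treatment of
the magnetic-field integration that preserves the charge-conservation
structure of the underlying physics.

## The problem

MEG source analysis requires the *forward problem*: given a neural current
dipole **M** δ(**r** − **r**₀) inside a head volume conductor with
conductivity σ(**r**), predict the magnetic field at sensors outside the
head.  The field splits into the analytic primary part and a secondary part
driven by the volume return currents,

    B(r) = Bp(r) − μ0/4π ∫ σ ∇u(r') × (r − r') / |r − r'|³ d³r' ,

so the quality of the MEG prediction is tied to the quality of the electric
potential u, the solution of the EEG forward problem
∇·(σ∇u) = ∇·jᵖ with insulating (homogeneous Neumann) boundary.

This package implements:

* **Subtraction source model** — u = u∞ + u_corr, where the singular dipole
  potential u∞ in an unbounded homogeneous conductor is known analytically
  and the smooth correction u_corr is solved numerically.
* **CG-FEM** (trilinear nodal elements) and **DG-FEM** (element-wise
  trilinear, symmetric interior penalty with conductivity-weighted averages)
  on regular hexahedral meshes built from voxel segmentations.
* **Two MEG integrators for the DG scheme**: the plain (non-conservative)
  element-wise flux σ∇u_h, and the conservative numerical flux
  {σ∇u_h} − η(σ̂/h)⟦u_h⟧, which satisfies an exact element-wise discrete
  conservation identity and is extended into the volume in the lowest-order
  Raviart–Thomas space before Biot–Savart integration.
* **Transfer matrices** B_MEG = S K⁻¹ so that many-dipole studies cost one
  matrix–vector product per source.
* **Closed-form validation oracle** (Sarvas sphere solution) plus a complete
  multi-layer-sphere study harness with the standard error metrics

      RDM% = 50 ‖ f_num/‖f_num‖ − f_ana/‖f_ana‖ ‖₂   (topography)
      MAG% = 100 (‖f_num‖/‖f_ana‖ − 1)               (magnitude)

For whom: researchers in bioelectromagnetic forward/inverse modeling who
want a transparent, pure-Python reference implementation of conservative
DG-FEM MEG modeling, including the skull-leakage scenarios that motivate DG
discretizations in EEG.

## Worked example

Solve one tangential dipole at eccentricity 0.5025 (19.6 mm below the
brain/CSF interface) in the standard four-layer sphere (radii 78/80/86/92 mm,
conductivities 0.33/1.79/0.01/0.43 S/m) discretized at 4 mm, and score the
secondary field at 64 magnetometers on a 110 mm sphere against the
closed-form solution:

    $ megfem solve --resolution-mm 4 --method dg --flux conservative --ecc 0.5025
    dg-conservative: secondary-field RDM% = 1.26, MAG% = -5.27

    $ megfem solve --resolution-mm 4 --method dg --flux nodal --ecc 0.5025
    dg-nodal: secondary-field RDM% = 1.51, MAG% = -10.89

    $ megfem solve --resolution-mm 4 --method cg --ecc 0.5025
    cg: secondary-field RDM% = 0.29, MAG% = +0.01

Topography errors of around a percent at this depth are typical for a 4 mm
mesh (the continuous discretization is the most accurate here); errors
grow rapidly as sources approach the brain/CSF conductivity jump (the
subtraction approach samples ∇u∞ near its singularity), which is why the
validation studies scan logarithmically spaced eccentricities up to 0.9873.
The same machinery runs the full study suite, e.g.

    megfem study flux --n-dipoles 20 --ecc 0.9796 --out scratch/flux

which compares the conservative and non-conservative DG flux integrators on
identical potentials and writes summary/sample CSV tables.

The library API mirrors the pipeline: `voxelize_sphere` / `build_hex_mesh` /
`build_skeleton` → `assemble_cg_stiffness` / `assemble_dg_stiffness` +
`assemble_*_rhs` → `solve_neumann` / `solve_dg` → `assemble_S_nodal` /
`conservative_flux` + `rt0_project` + `assemble_rt0_moments` →
`full_b_field`, with `compute_transfer` for leadfield reuse.

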