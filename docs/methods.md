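# Methods

## Model

The quasistatic bioelectromagnetic forward problem is solved in two stages.

**EEG stage.**  The electric potential of a point current dipole
jᵖ = **M** δ(**r** − **r**₀) in a piecewise-homogeneous volume conductor Ω
solves ∇·(σ∇u) = ∇·jᵖ with σ∇u·**n** = 0 on ∂Ω.  The dipole singularity is
removed by the *subtraction* split u = u∞ + u_corr: with σ∞ the (isotropic)
conductivity of the element containing the dipole,

    u∞(r) = M·(r − r0) / (4π σ∞ |r − r0|³)

is the exact potential of the dipole in an unbounded homogeneous conductor,
and the smooth correction solves

    −∇·(σ∇u_corr) = ∇·(σ_corr ∇u∞),   σ∇u_corr·n = −σ∇u∞·n on ∂Ω,

with σ_corr = σ − σ∞ vanishing in the homogeneous neighborhood of the
source.  Two discretizations are provided on regular hexahedral meshes of
edge h:

* CG: trilinear nodal elements; K_ij = ∫σ∇φ_i·∇φ_j.
* DG: element-wise trilinear (8 corner coefficients per element), symmetric
  interior penalty.  On each internal face, with conductivity-weighted
  averages {v} = (σ_f v_e + σ_e v_f)/(σ_e+σ_f) and jumps
  ⟦v⟧ = v_e n_e + v_f n_f, the bilinear form carries the consistency terms
  −∫{σ∇u}·⟦v⟧ − ∫{σ∇v}·⟦u⟧ and the penalty η∫(σ̂/h)⟦u⟧·⟦v⟧, where
  σ̂ = 2σ_eσ_f/(σ_e+σ_f) is the harmonic mean.  With these weights
  {σ∇u}·n = (σ̂/2)(∂ₙu_e + ∂ₙu_f), so every face matrix is a fixed
  reference matrix per axis scaled by the single scalar σ̂h.

Both systems are pure-Neumann: symmetric, with the constants as kernel,
fixed by a zero-mean gauge.  The magnetic field depends only on ∇u, so the
gauge is immaterial (tested).

**MEG stage.**  The field at a point magnetometer **c** is
B = Bᵖ + B∞ˢ + B_corrˢ, the primary part analytic and the secondary parts
Biot–Savart volume integrals of σ∇u_h∞ and of the correction flux.  The
singularity potential enters through its *interpolant* in the discretization
space (vertex values), mirroring the correction solve's discretization so
that the large individual errors of B∞ˢ and B_corrˢ near the source cancel
in their sum.  Three flux representations are available:

* CG / DG nodal: σ∇u_h element-wise ("non-conservative" in the DG case —
  the broken gradient ignores the inter-element jump currents).
* DG conservative: the interior-penalty numerical flux
  ĵ = {σ∇u_corr} − η(σ̂/h)⟦u_corr⟧ on the internal skeleton.  It satisfies
  an exact element-wise balance: total outward numerical flux = correction
  source content, up to the algebraic solver residual (this identity is an
  algebraic consequence of testing the discrete system with an element's
  characteristic function, and is asserted to machine precision for
  arbitrary coefficient vectors in the tests).  The skeleton flux is
  extended into the volume by lowest-order Raviart–Thomas interpolation:
  one degree of freedom per mesh face, the normal flux at the face
  centroid, with "tent" basis functions supported on the two adjacent
  elements.  Boundary faces carry the prescribed Neumann datum
  −σ∞∇u∞·n (the convention consistent with the discrete balance; a zero
  alternative would only perturb the far, weak boundary contribution).

All integration operators (S matrices, RT0 moments) depend on geometry and
conductivity only, which enables the transfer-matrix shortcut
B_MEG = S K⁻¹, computed row-wise from K x = Sᵀ column by symmetry of K.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| η (penalty) | 1.13 | Interior-penalty strength. Coercivity requires η above a threshold measured at ≈1.0 for the four-layer conductivity contrast (dense eigensolve on a small sphere); the default sits just above it. This near-threshold regime is also where the conservative/non-conservative flux distinction is physically informative: at large η the broken solution is forced toward the continuous one, the jumps (and with them the conservative flux's jump correction and the nodal flux's conservation defect) shrink, and the two integrators converge to each other. The conservative integrator's accuracy is essentially η-independent; the nodal one degrades steeply toward the threshold. |
| σ̂ (face conductivity) | harmonic mean | Companion of the conductivity-weighted average; penalizes with the smaller conductivity, the regime that matters at the skull. |
| solver tol | 1e-8 | Relative residual of the preconditioned CG iteration; studies use 1e-7 (4 mm) / 1e-5 (2 mm) since field errors are orders of magnitude above. |
| stiffness/rhs quadrature | 2×2×2 Gauss (2×2 faces) | Exact for the trilinear stiffness; for the rhs, ∇u∞ is smooth wherever σ_corr ≠ 0, and *raising* the face order moves quadrature points toward face corners near the source where ∇u∞ spikes — low order is deliberately robust here. Configurable. |
| Biot–Savart quadrature | 3×3×3 Gauss | Sensors are ≥ 18 mm from the scalp (110 vs 92 mm), the kernel is smooth; validated against 10⁶-point Monte-Carlo to 3 significant digits. |
| μ0 | 4π×10⁻⁷ T·m/A | fixed. |
| dipole strength | 1 A·m | RDM%/MAG% are scale-invariant. |

## Synthetic data

The generators produce exactly the study conditions of the sphere
validation: nested four-layer spheres (brain/CSF/skull/skin, outer radii
78/80/86/92 mm, conductivities 0.33/1.79/0.01/0.43 S/m) voxelized at 4, 2
or 1 mm on a grid symmetric about the center with voxel centers at
half-integer multiples of h and closed-ball labeling.  This convention
reproduces the reference mesh sizes (4 mm: 51,104 elements / 56,235
vertices; 1 mm: 3,262,312 / 3,342,701) and the thinned-skull (82 mm) 2 mm
model's 10,080 leaky vertices exactly.  Dipoles are area-uniform on shells
at the eight logarithmic eccentricities 0.1 … 0.9873 of the brain radius
(78 mm) with one uniformly random unit tangent each; dipoles whose
containing element is not brain-labeled are excluded from statistics.
Sensors are a deterministic spherical Fibonacci lattice at 110 mm — the
mean-over-sensors statistics are insensitive to the particular quasi-uniform
arrangement.  The seeded generator is bit-reproducible.

What this does *not* emulate: realistic head geometry (MRI-derived
six-compartment models), anisotropic conductivity, coil-surface flux
integration (sensors are point magnetometers), sensor noise, and real skull
holes (the "leaky" model is a deliberately under-resolved thin skull, not a
trepanation).  Passing the sphere studies therefore validates the numerics
and the conservation structure, not anatomical fidelity.

## Numerical choices

* Vertex dedup and element lookup are integer-lattice exact; element
  ownership of a point is half-open [x, x+h), so face/edge dipoles have a
  unique owner.  A dipole within 10⁻⁹h of a vertex is perturbed by 10⁻⁹h
  (with a warning): the nodal interpolant of u∞ would otherwise be
  evaluated at its pole.
* Solvers: conjugate gradients. The nodal (CG) systems are preconditioned
  with a geometric multigrid V-cycle built on the vertex lattice
  (all-even-coordinate coarsening, renormalized trilinear prolongation,
  Galerkin coarse operators, damped-Jacobi smoothing, pinned direct solve
  at ≲3000 unknowns).  The DG systems use an auxiliary-space
  preconditioner: one V-cycle on the continuous nodal restriction (whose
  Galerkin operator coincides with the CG stiffness exactly) plus a
  block-Jacobi sweep.  Typical iteration counts at 4 mm: 19 (CG), ≈40 (DG).
* The per-element conservation balance evaluates the numerical flux at
  face centroids times area (exact: the flux trace is bilinear on each
  face) and the source/boundary face integrals with the same Gauss rule as
  the assembly, so the identity holds to the solver residual, not merely to
  quadrature error.  The global compatibility defect of the right-hand
  side (a quadrature-level boundary error, ~10⁻⁸ relative for interior
  sources) is distributed uniformly by the mean-removal gauge and sets a
  negligible floor (~10⁻¹¹‖b‖ per element at 4 mm).
* Degenerate inputs raise typed errors: radial sources (vanishing analytic
  field) in the metrics, sensors inside the conductor, field evaluation at
  the dipole, non-coercive penalty, incompatible matrix/basis pairings.

## Study scales

The shipped study defaults are desk-sized and state the conditions used by
the test suite and the acceptance script: 4 mm meshes with ≥50 dipoles per
eccentricity shell and 64 sensors for the flux-comparison study; 2 mm
meshes with 3 dipoles per shell and 12 sensors for the refinement and
leaky-model comparisons (the leaky and regular models are always paired on
identical dipole sets, so their difference is free of sampling noise).
Full-scale runs (1000 dipoles per shell, 256 sensors, 1 mm meshes) use the
same code paths by passing larger numbers; the 1 mm DG system has ≈26M
unknowns and is a cluster-scale computation.

## Known limitations

* The conservative integrator's magnitude bias at 4 mm is dominated by the
  interpolation of u∞ near the source (shared with all integrators) and by
  the lowest-order RT0 extension; raising the broken polynomial degree and
  the Raviart–Thomas order would reduce both, at higher cost.
* The EEG side is the substrate here: electrode modeling and EEG error
  statistics against the analytic series are not implemented.
* Anisotropic σ is not supported (the subtraction split is implemented for
  scalar σ∞, sufficient for all shipped models).
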