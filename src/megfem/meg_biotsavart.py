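"""Biot-Savart integration of the secondary magnetic field.

The secondary field at a point magnetometer ``c`` is

    B_s(c) = -mu0/(4 pi) int_Omega sigma grad(u)(r') x (c - r') / |c - r'|^3 ,

split by the subtraction approach into a part driven by the interpolated
singularity potential and a part driven by the computed correction
potential.  Three flux representations are supported:

* nodal (continuous basis):        sigma grad(u_h), integrated element-wise;
* nodal (broken basis):            the same formula on the broken space —
  the *non-conservative* variant;
* conservative (broken basis):     the interior-penalty numerical flux
  ``{sigma grad u} - eta (sigma_hat / h) [[u]]`` which satisfies an exact
  element-wise discrete conservation identity; it lives on the mesh
  skeleton and is extended into the volume in the lowest-order
  Raviart-Thomas space (face-normal degrees of freedom at the face
  centroids) before the volume integration.

All integration matrices depend only on geometry and conductivity, never on
the source, which is what makes the transfer-matrix shortcut possible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import _reference as ref
from .analytic import (
    MU0,
    Dipole,
    SensorArray,
    grad_singularity_potential,
    primary_b_field,
    singularity_potential,
)
from .eeg_cg import PotentialField, effective_dipole, source_sigma
from .eeg_dg import DEFAULT_ETA, face_average_weights, face_sigma_hat
from .spheremesh import HexMesh, Skeleton

__all__ = [
    "FaceFluxField",
    "RT0Field",
    "BFieldSet",
    "assemble_S_nodal",
    "apply_S_nodal",
    "integrate_current_fields",
    "nodal_current_builder",
    "rt0_current_builder",
    "flux_matrix",
    "conservative_flux",
    "boundary_flux_values",
    "rt0_project",
    "evaluate_rt0",
    "assemble_rt0_moments",
    "assemble_S_corr_DG",
    "rt0_b_field",
    "uinf_coefficients",
    "element_balance",
    "element_balance_nodal",
    "full_b_field",
]

_CROSS = {  # unit axis e_d x k, as index/sign recipes
    0: ((None, 0.0), (2, -1.0), (1, 1.0)),
    1: ((2, 1.0), (None, 0.0), (0, -1.0)),
    2: ((1, -1.0), (0, 1.0), (None, 0.0)),
}


def _axis_cross(d: int, kern: np.ndarray) -> np.ndarray:
    """e_d x kern for kern (..., 3)."""
    out = np.zeros_like(kern)
    for c, (idx, s) in enumerate(_CROSS[d]):
        if idx is not None:
            out[..., c] = s * kern[..., idx]
    return out


def _check_sensors(mesh: HexMesh, sensors: SensorArray) -> None:
    if np.any(mesh.locate_element(sensors.positions) >= 0):
        raise ValueError("sensors must lie outside the mesh (singular kernel)")


def _chunks(n: int, size: int):
    for lo in range(0, n, size):
        yield lo, min(lo + size, n)


# ---------------------------------------------------------------------------
# nodal flux integration
# ---------------------------------------------------------------------------

def assemble_S_nodal(
    mesh: HexMesh,
    sensors: SensorArray,
    basis_kind: str = "cg-trilinear",
    quad_order: int = 3,
    chunk: int = 20000,
) -> np.ndarray:
    """Secondary-field integration matrix for the element-wise nodal flux.

    Entry ``(3 n + c, i)`` is the ``c`` component at sensor ``n`` of
    ``-mu0/(4 pi) int sigma grad(phi_i) x (c_n - r') / |c_n - r'|^3``.
    The same matrix integrates the interpolated singularity potential and
    the correction potential.  Rows are sensor-major (3 Cartesian rows per
    point magnetometer).
    """
    _check_sensors(mesh, sensors)
    qpts, w = ref.volume_rule(quad_order)
    g = ref.shape_gradients(qpts)
    wg = w[:, None, None] * g  # (Q, 8, 3)
    E = mesh.n_elements
    ndof = mesh.n_vertices if basis_kind == "cg-trilinear" else 8 * E
    S = np.zeros((3 * len(sensors), ndof))
    origins = mesh.element_origins()
    coeff_all = -MU0 / (4.0 * np.pi) * mesh.element_sigma * mesh.h**2
    for lo, hi in _chunks(E, chunk):
        pts = origins[lo:hi, None, :] + qpts[None, :, :] * mesh.h  # (C, Q, 3)
        coeff = coeff_all[lo:hi]
        for n, c in enumerate(sensors.positions):
            d = c[None, None, :] - pts
            nrm = np.linalg.norm(d, axis=2)
            kern = d / nrm[:, :, None] ** 3
            A = np.tensordot(wg, kern, axes=([0], [1]))  # (8, 3, C, 3)
            cross = np.stack(
                [
                    A[:, 1, :, 2] - A[:, 2, :, 1],
                    A[:, 2, :, 0] - A[:, 0, :, 2],
                    A[:, 0, :, 1] - A[:, 1, :, 0],
                ]
            )  # (3, 8, C)
            vals = cross * coeff[None, None, :]
            if basis_kind == "cg-trilinear":
                cols = mesh.elements[lo:hi]  # (C, 8)
                for comp in range(3):
                    np.add.at(S[3 * n + comp], cols.ravel(), vals[comp].T.ravel())
            else:
                flat = slice(8 * lo, 8 * hi)
                for comp in range(3):
                    S[3 * n + comp, flat] = vals[comp].T.ravel()
    return S


def integrate_current_fields(
    mesh: HexMesh,
    sensors: SensorArray,
    builders: list,
    quad_order: int = 3,
    chunk: int = 20000,
) -> list[np.ndarray]:
    """Biot-Savart integrals of several volume current densities in a single
    kernel pass (the kernel evaluation per sensor dominates the cost, so
    integrating the singularity, correction and reconstructed fluxes of one
    forward solve together is ~3x cheaper than separate passes).

    ``builders`` are callables ``f(lo, hi) -> (C, Q, 3)`` returning the
    weighted current density (including all prefactors and the volume
    scale) at the quadrature points of the element chunk.  Returns one
    ``(n_sensors, 3)`` array per builder.
    """
    _check_sensors(mesh, sensors)
    qpts, w = ref.volume_rule(quad_order)
    E = mesh.n_elements
    origins = mesh.element_origins()
    outs = [np.zeros((len(sensors), 3)) for _ in builders]
    for lo, hi in _chunks(E, chunk):
        pts = origins[lo:hi, None, :] + qpts[None, :, :] * mesh.h
        Js = [b(lo, hi) for b in builders]
        for n, c in enumerate(sensors.positions):
            d = c[None, None, :] - pts
            nrm = np.linalg.norm(d, axis=2)
            kern = d / nrm[:, :, None] ** 3
            for out, J in zip(outs, Js):
                out[n] += np.einsum("q,eqa->a", w, np.cross(J, kern))
    return outs


def nodal_current_builder(
    mesh: HexMesh, potential: PotentialField, quad_order: int = 3
):
    """Chunk builder for the element-wise nodal flux ``sigma grad(u_h)``
    (with the Biot-Savart prefactor), for ``integrate_current_fields``."""
    qpts, _ = ref.volume_rule(quad_order)
    g = ref.shape_gradients(qpts)
    ue = potential.element_coefficients()
    coeff = -MU0 / (4.0 * np.pi) * mesh.element_sigma * mesh.h**2

    def build(lo: int, hi: int) -> np.ndarray:
        J = np.einsum("ei,qia->eqa", ue[lo:hi], g)
        J *= coeff[lo:hi, None, None]
        return J

    return build


def apply_S_nodal(
    mesh: HexMesh,
    sensors: SensorArray,
    potential: PotentialField,
    quad_order: int = 3,
    chunk: int = 20000,
) -> np.ndarray:
    """Matrix-free ``S_nodal @ coefficients`` (identical quadrature), for
    meshes too large to hold the dense integration matrix.  Returns
    ``(n_sensors, 3)``."""
    return integrate_current_fields(
        mesh,
        sensors,
        [nodal_current_builder(mesh, potential, quad_order)],
        quad_order,
        chunk,
    )[0]


# ---------------------------------------------------------------------------
# conservative flux and its Raviart-Thomas extension
# ---------------------------------------------------------------------------

@dataclass
class FaceFluxField:
    """Scalar normal flux per skeleton face [A/m^2], tied to the canonical
    face normals (+axis on internal faces, outward on boundary faces)."""

    internal: np.ndarray  # (Fi,)
    boundary: np.ndarray  # (Fb,)
    mesh: HexMesh
    skeleton: Skeleton


@dataclass
class RT0Field:
    """Lowest-order Raviart-Thomas coefficients: one normal-flux degree of
    freedom per mesh face (value of the normal component at the centroid)."""

    alpha_internal: np.ndarray
    alpha_boundary: np.ndarray
    mesh: HexMesh
    skeleton: Skeleton


def flux_matrix(
    mesh: HexMesh, skeleton: Skeleton | None = None, eta: float = DEFAULT_ETA
) -> sp.csr_matrix:
    """Sparse map from broken coefficients to the conservative flux
    ``{sigma grad u} . n - eta (sigma_hat / h) [[u]] . n`` at the internal
    face centroids, shape ``(Fi, 8 E)``."""
    if skeleton is None:
        skeleton = mesh.skeleton
    sigma_hat = face_sigma_hat(mesh, skeleton)
    Fi = skeleton.n_internal
    h = mesh.h
    rows = np.repeat(np.arange(Fi), 16)
    cols = np.empty((Fi, 16), dtype=np.int64)
    data = np.empty((Fi, 16))
    for axis in range(3):
        m = skeleton.face_axis == axis
        if not m.any():
            continue
        Te, De = ref.face_centroid_trace(axis, 1)
        Tf, Df = ref.face_centroid_trace(axis, 0)
        a_e = 0.5 * De - eta * Te
        a_f = 0.5 * Df + eta * Tf
        s = sigma_hat[m] / h
        e, f = skeleton.face_elems[m, 0], skeleton.face_elems[m, 1]
        cols[m, :8] = 8 * e[:, None] + np.arange(8)
        cols[m, 8:] = 8 * f[:, None] + np.arange(8)
        data[m, :8] = s[:, None] * a_e
        data[m, 8:] = s[:, None] * a_f
    return sp.csr_matrix(
        (data.ravel(), (rows, cols.ravel())),
        shape=(Fi, 8 * mesh.n_elements),
    )


def boundary_flux_values(
    mesh: HexMesh,
    skeleton: Skeleton,
    dipole: Dipole,
    sigma_inf: float | None = None,
) -> np.ndarray:
    """Neumann datum ``- sigma_inf grad(u_inf) . n`` at the boundary face
    centroids (the prescribed correction flux through the domain boundary)."""
    dipole = effective_dipole(mesh, dipole)
    if sigma_inf is None:
        sigma_inf = source_sigma(mesh, dipole)
    gu = grad_singularity_potential(dipole, sigma_inf, skeleton.bnd_centroids)
    return -sigma_inf * np.einsum("fa,fa->f", gu, skeleton.bnd_normals)


def conservative_flux(
    potential: PotentialField,
    skeleton: Skeleton | None = None,
    eta: float = DEFAULT_ETA,
    dipole: Dipole | None = None,
    sigma_inf: float | None = None,
    _flux_matrix: sp.csr_matrix | None = None,
) -> FaceFluxField:
    """Evaluate the conservative numerical flux of a broken potential at the
    face centroids; boundary faces carry the Neumann datum when a dipole is
    given (zero otherwise)."""
    if potential.basis_kind != "dg-trilinear":
        raise ValueError("conservative flux requires a broken (dg-trilinear) potential")
    mesh = potential.mesh
    if skeleton is None:
        skeleton = mesh.skeleton
    F = _flux_matrix if _flux_matrix is not None else flux_matrix(mesh, skeleton, eta)
    internal = F @ potential.coefficients
    if dipole is not None:
        boundary = boundary_flux_values(mesh, skeleton, dipole, sigma_inf)
    else:
        boundary = np.zeros(skeleton.n_boundary)
    return FaceFluxField(internal=internal, boundary=boundary, mesh=mesh, skeleton=skeleton)


def rt0_project(flux: FaceFluxField) -> RT0Field:
    """Raviart-Thomas interpolation: the RT0 degree of freedom of each face
    IS the normal flux at its centroid."""
    return RT0Field(
        alpha_internal=np.asarray(flux.internal, dtype=float).copy(),
        alpha_boundary=np.asarray(flux.boundary, dtype=float).copy(),
        mesh=flux.mesh,
        skeleton=flux.skeleton,
    )


def _face_dirs(mesh: HexMesh, skeleton: Skeleton) -> np.ndarray:
    """Sign of the canonical normal of ``element_faces[K, slot]`` along its
    axis: +1 except for lower-side boundary faces, ``(E, 6)`` float."""
    Fi = skeleton.n_internal
    dirs = np.ones_like(skeleton.element_faces, dtype=float)
    is_bnd = skeleton.element_faces >= Fi
    for axis in range(3):
        slot = 2 * axis  # lower faces
        m = is_bnd[:, slot]
        dirs[m, slot] = -1.0
    return dirs


def _element_alphas(field: RT0Field) -> np.ndarray:
    """Directed RT0 coefficients per element face slot, ``(E, 6)``:
    coefficient times the axis-sign of its canonical normal."""
    sk = field.skeleton
    alpha = np.concatenate([field.alpha_internal, field.alpha_boundary])
    return alpha[sk.element_faces] * _face_dirs(field.mesh, sk)


def evaluate_rt0(field: RT0Field, points: np.ndarray) -> np.ndarray:
    """Point evaluation of the RT0 extension; component ``d`` interpolates
    linearly between the directed fluxes of the two faces normal to ``d``."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    mesh = field.mesh
    els = mesh.locate_element(pts)
    if np.any(els < 0):
        raise ValueError("evaluation point outside the mesh")
    t = (pts - mesh.element_origins()[els]) / mesh.h
    a = _element_alphas(field)[els]  # (n, 6)
    out = np.empty_like(pts)
    for d in range(3):
        out[:, d] = a[:, 2 * d] * (1.0 - t[:, d]) + a[:, 2 * d + 1] * t[:, d]
    return out[0] if np.asarray(points).ndim == 1 else out


def assemble_rt0_moments(
    mesh: HexMesh,
    skeleton: Skeleton | None = None,
    sensors: SensorArray | None = None,
    quad_order: int = 3,
    chunk: int = 20000,
) -> np.ndarray:
    """Biot-Savart moment of every RT0 basis function at every sensor,
    shape ``(3 n_sensors, Fi + Fb)``: column ``k`` is
    ``-mu0/(4 pi) int psi_k(r') x (c_n - r') / |c_n - r'|^3`` over the one-
    or two-element support of face ``k``.  The conservative-flux secondary
    field is ``moments @ alpha``."""
    if skeleton is None:
        skeleton = mesh.skeleton
    if sensors is None:
        raise TypeError("sensors are required")
    _check_sensors(mesh, sensors)
    qpts, w = ref.volume_rule(quad_order)
    tents = ref.tent_weights(quad_order)  # (Q, 6)
    wt = w[:, None] * tents
    E = mesh.n_elements
    M = np.zeros((3 * len(sensors), skeleton.n_internal + skeleton.n_boundary))
    origins = mesh.element_origins()
    dirs = _face_dirs(mesh, skeleton)
    coeff = -MU0 / (4.0 * np.pi) * mesh.h**3
    for lo, hi in _chunks(E, chunk):
        pts = origins[lo:hi, None, :] + qpts[None, :, :] * mesh.h
        fcols = skeleton.element_faces[lo:hi]  # (C, 6)
        fdirs = dirs[lo:hi]
        for n, c in enumerate(sensors.positions):
            d = c[None, None, :] - pts
            nrm = np.linalg.norm(d, axis=2)
            kern = d / nrm[:, :, None] ** 3
            A = np.tensordot(wt, kern, axes=([0], [1]))  # (6, C, 3) tent-weighted kernel
            for slot in range(6):
                axis = slot // 2
                m = coeff * fdirs[:, slot][:, None] * _axis_cross(axis, A[slot])
                for comp in range(3):
                    np.add.at(M[3 * n + comp], fcols[:, slot], m[:, comp])
    return M


def assemble_S_corr_DG(
    mesh: HexMesh,
    skeleton: Skeleton | None = None,
    sensors: SensorArray | None = None,
    eta: float = DEFAULT_ETA,
    quad_order: int = 3,
    moments: np.ndarray | None = None,
) -> np.ndarray:
    """Conservative-flux integration matrix over broken coefficients:
    RT0 moments composed with the potential-to-flux map of the internal
    skeleton (the boundary faces carry the source-dependent Neumann datum
    and are added separately by ``full_b_field``)."""
    if skeleton is None:
        skeleton = mesh.skeleton
    if moments is None:
        moments = assemble_rt0_moments(mesh, skeleton, sensors, quad_order)
    F = flux_matrix(mesh, skeleton, eta)
    return moments[:, : skeleton.n_internal] @ F


def rt0_current_builder(field: RT0Field, quad_order: int = 3):
    """Chunk builder for the Raviart-Thomas extended conservative flux
    (with the Biot-Savart prefactor), for ``integrate_current_fields``."""
    mesh = field.mesh
    _, w = ref.volume_rule(quad_order)
    tents = ref.tent_weights(quad_order)
    a = _element_alphas(field)  # (E, 6)
    coeff = -MU0 / (4.0 * np.pi) * mesh.h**3

    def build(lo: int, hi: int) -> np.ndarray:
        V = np.empty((hi - lo, len(w), 3))
        for d in range(3):
            V[:, :, d] = (
                a[lo:hi, 2 * d, None] * tents[None, :, 2 * d]
                + a[lo:hi, 2 * d + 1, None] * tents[None, :, 2 * d + 1]
            )
        V *= coeff
        return V

    return build


def rt0_b_field(
    field: RT0Field,
    sensors: SensorArray,
    quad_order: int = 3,
    chunk: int = 20000,
) -> np.ndarray:
    """Matrix-free Biot-Savart integration of an RT0 flux field,
    ``(n_sensors, 3)``; identical quadrature to ``assemble_rt0_moments``."""
    return integrate_current_fields(
        field.mesh,
        sensors,
        [rt0_current_builder(field, quad_order)],
        quad_order,
        chunk,
    )[0]


# ---------------------------------------------------------------------------
# discrete conservation diagnostics
# ---------------------------------------------------------------------------

def _source_face_integrals(
    mesh: HexMesh,
    skeleton: Skeleton,
    dipole: Dipole,
    sigma_inf: float,
    quad_order: int,
    weighted: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Face integrals of the singularity-driven source flux.

    Returns ``(internal, boundary)``: per internal face
    ``int {sigma_corr grad u_inf} . n ds`` (conductivity-weighted average if
    ``weighted``, else per-side one-sided values summed later) and per
    boundary face ``int sigma_inf grad u_inf . n_out ds``.
    """
    pts2d, w = ref.face_rule(quad_order)
    h = mesh.h
    origins = mesh.element_origins()
    sigma_corr = mesh.element_sigma - sigma_inf
    we, wf = face_average_weights(mesh, skeleton)
    e_ids, f_ids = skeleton.face_elems[:, 0], skeleton.face_elems[:, 1]
    internal = np.zeros(skeleton.n_internal)
    for axis in range(3):
        m = np.nonzero(skeleton.face_axis == axis)[0]
        if len(m) == 0:
            continue
        p3 = ref.face_points_3d(axis, 0, pts2d)
        pts = origins[f_ids[m], None, :] + p3[None, :, :] * h
        gu = grad_singularity_potential(dipole, sigma_inf, pts.reshape(-1, 3)).reshape(
            len(m), -1, 3
        )
        gint = h * h * np.einsum("q,fq->f", w, gu[:, :, axis])
        if weighted:
            cf = we[m] * sigma_corr[e_ids[m]] + wf[m] * sigma_corr[f_ids[m]]
        else:
            cf = np.ones(len(m))
        internal[m] = cf * gint

    boundary = np.zeros(skeleton.n_boundary)
    for axis in range(3):
        for side in (0, 1):
            m = np.nonzero((skeleton.bnd_axis == axis) & (skeleton.bnd_side == side))[0]
            if len(m) == 0:
                continue
            p3 = ref.face_points_3d(axis, side, pts2d)
            pts = origins[skeleton.bnd_elem[m], None, :] + p3[None, :, :] * h
            gu = grad_singularity_potential(
                dipole, sigma_inf, pts.reshape(-1, 3)
            ).reshape(len(m), -1, 3)
            sgn = 1.0 if side == 1 else -1.0
            boundary[m] = sigma_inf * h * h * sgn * np.einsum("q,fq->f", w, gu[:, :, axis])
    return internal, boundary


def element_balance(
    flux: FaceFluxField,
    dipole: Dipole,
    sigma_inf: float | None = None,
    quad_order: int = 2,
) -> np.ndarray:
    """Per-element discrete conservation residual of the conservative flux:

        sum_{faces of K} (outward numerical flux) - (correction source in K)

    For the solved interior-penalty potential this equals minus the sum of
    the solver residual over the element's degrees of freedom, hence it
    vanishes to solver tolerance for every element.  ``quad_order`` must
    match the right-hand-side assembly for the identity to be exact.
    """
    mesh, sk = flux.mesh, flux.skeleton
    dipole = effective_dipole(mesh, dipole)
    if sigma_inf is None:
        sigma_inf = source_sigma(mesh, dipole)
    src_int, src_bnd = _source_face_integrals(
        mesh, sk, dipole, sigma_inf, quad_order, weighted=True
    )
    h2 = mesh.h**2
    bal = np.zeros(mesh.n_elements)
    e_ids, f_ids = sk.face_elems[:, 0], sk.face_elems[:, 1]
    # outward numerical flux: centroid value x area is exact (bilinear trace);
    # the boundary outflux is the prescribed Neumann datum, integrated with
    # the same face rule as the assembly so the identity holds to solver
    # tolerance (not just to quadrature error)
    np.add.at(bal, e_ids, flux.internal * h2 + src_int)
    np.add.at(bal, f_ids, -(flux.internal * h2 + src_int))
    np.add.at(bal, sk.bnd_elem, -src_bnd)
    return bal


def element_balance_nodal(
    potential: PotentialField,
    dipole: Dipole,
    sigma_inf: float | None = None,
    quad_order: int = 2,
) -> np.ndarray:
    """Per-element conservation residual of the plain (non-conservative)
    nodal flux ``sigma_K grad u_K``, each element using its own one-sided
    trace: nonzero wherever the broken solution jumps, most visibly across
    the high-contrast skull interfaces."""
    mesh = potential.mesh
    sk = mesh.skeleton
    dipole = effective_dipole(mesh, dipole)
    if sigma_inf is None:
        sigma_inf = source_sigma(mesh, dipole)
    ue = potential.element_coefficients()
    sigma_corr = mesh.element_sigma - sigma_inf
    h = mesh.h
    bal = np.zeros(mesh.n_elements)
    # one-sided flux through all 6 faces of each element (centroid x area exact)
    for axis in range(3):
        for side in (0, 1):
            _, D = ref.face_centroid_trace(axis, side)
            sgn = 1.0 if side == 1 else -1.0
            bal += sgn * mesh.element_sigma * (ue @ D) * h  # (1/h grad) * h^2 area
    # one-sided source content: + int_dK sigma_corr grad(u_inf) . n_out
    pts2d, w = ref.face_rule(quad_order)
    origins = mesh.element_origins()
    for axis in range(3):
        for side in (0, 1):
            p3 = ref.face_points_3d(axis, side, pts2d)
            pts = origins[:, None, :] + p3[None, :, :] * h
            gu = grad_singularity_potential(
                dipole, sigma_inf, pts.reshape(-1, 3)
            ).reshape(mesh.n_elements, -1, 3)
            sgn = 1.0 if side == 1 else -1.0
            bal += sigma_corr * h * h * sgn * np.einsum("q,fq->f", w, gu[:, :, axis])
    return bal


# ---------------------------------------------------------------------------
# assembled fields
# ---------------------------------------------------------------------------

@dataclass
class BFieldSet:
    """Per-dipole magnetic field at the sensors, decomposed into the
    analytic primary part and the two numerically integrated secondary
    parts; the total is the exact sum of its parts."""

    Bp: np.ndarray  # (N, 3)
    Bs_inf: np.ndarray
    Bs_corr: np.ndarray

    @property
    def Bs(self) -> np.ndarray:
        return self.Bs_inf + self.Bs_corr

    @property
    def B(self) -> np.ndarray:
        return self.Bp + self.Bs_inf + self.Bs_corr


def uinf_coefficients(
    mesh: HexMesh,
    dipole: Dipole,
    sigma_inf: float | None = None,
    basis_kind: str = "cg-trilinear",
) -> np.ndarray:
    """Interpolant coefficients of the singularity potential (vertex values;
    gathered element-wise for the broken basis)."""
    dipole = effective_dipole(mesh, dipole)
    if sigma_inf is None:
        sigma_inf = source_sigma(mesh, dipole)
    uv = singularity_potential(dipole, sigma_inf, mesh.vertices)
    if basis_kind == "cg-trilinear":
        return uv
    return uv[mesh.elements].ravel()


def full_b_field(
    dipole: Dipole,
    sensors: SensorArray,
    eeg_solution: PotentialField,
    S_infty: np.ndarray,
    S_corr: np.ndarray,
    sigma_inf: float | None = None,
    boundary_moments: np.ndarray | None = None,
    skeleton: Skeleton | None = None,
) -> BFieldSet:
    """Assemble the full field ``B = Bp + Bs_inf + Bs_corr``.

    ``S_infty`` integrates the interpolated singularity potential and must
    match the solution's basis; ``S_corr`` integrates the correction
    potential (nodal matrix, or the RT0-composed conservative matrix).  For
    the conservative pairing, pass ``boundary_moments`` (the boundary-face
    columns of the RT0 moment matrix) so the prescribed Neumann flux through
    the domain boundary enters the volume extension.
    """
    mesh = eeg_solution.mesh
    n = len(eeg_solution.coefficients)
    if S_infty.shape[1] != n or S_corr.shape[1] != n:
        raise ValueError(
            "integration matrix / discretization pairing mismatch: "
            f"{S_infty.shape[1]} and {S_corr.shape[1]} columns vs {n} dofs"
        )
    dipole = effective_dipole(mesh, dipole)
    if sigma_inf is None:
        sigma_inf = source_sigma(mesh, dipole)
    uinf = uinf_coefficients(mesh, dipole, sigma_inf, eeg_solution.basis_kind)
    Bp = primary_b_field(dipole, sensors.positions)
    Bs_inf = (S_infty @ uinf).reshape(-1, 3)
    Bs_corr = (S_corr @ eeg_solution.coefficients).reshape(-1, 3)
    if boundary_moments is not None:
        sk = skeleton if skeleton is not None else mesh.skeleton
        alpha_bnd = boundary_flux_values(mesh, sk, dipole, sigma_inf)
        Bs_corr = Bs_corr + (boundary_moments @ alpha_bnd).reshape(-1, 3)
    return BFieldSet(Bp=Bp, Bs_inf=Bs_inf, Bs_corr=Bs_corr)
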