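"""Continuous-Galerkin discretization of the subtraction correction problem.

The dipole's singular potential ``u_inf`` (known analytically in an unbounded
homogeneous conductor of conductivity ``sigma_inf``) is subtracted from the
unknown; the smooth correction potential solves a Poisson problem with pure
Neumann data,

    - div(sigma grad u_corr) = div(sigma_corr grad u_inf)      in Omega
      sigma grad u_corr . n  = - sigma grad u_inf . n          on dOmega

with ``sigma_corr = sigma - sigma_inf`` vanishing in the homogeneous
neighborhood of the source.  Trilinear nodal elements on the regular
hexahedral mesh; the stiffness matrix is singular with the constants in its
kernel, fixed by a zero-mean gauge (the magnetic field depends only on
gradients, so the gauge is immaterial).

``sigma_inf`` defaults to the conductivity of the element containing the
dipole; with all study sources in the brain compartment this guarantees the
homogeneous neighborhood the subtraction approach requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _reference as ref
from .analytic import Dipole, grad_singularity_potential
from .errors import SolverError
from .spheremesh import HexMesh

__all__ = [
    "CGSystem",
    "PotentialField",
    "assemble_cg_stiffness",
    "assemble_cg_rhs",
    "solve_neumann",
    "effective_dipole",
    "source_sigma",
]


@dataclass
class PotentialField:
    """Coefficient vector over a basis descriptor.

    ``basis_kind`` is ``"cg-trilinear"`` (one coefficient per mesh vertex) or
    ``"dg-trilinear"`` (8 element-local corner coefficients, element-major).
    """

    basis_kind: str
    coefficients: np.ndarray
    mesh: HexMesh

    def __post_init__(self):
        n = len(self.coefficients)
        expect = {
            "cg-trilinear": self.mesh.n_vertices,
            "dg-trilinear": 8 * self.mesh.n_elements,
        }[self.basis_kind]
        if n != expect:
            raise ValueError(f"{self.basis_kind}: expected {expect} coefficients, got {n}")

    def element_coefficients(self) -> np.ndarray:
        """Corner values per element, ``(E, 8)``, for either basis."""
        if self.basis_kind == "cg-trilinear":
            return self.coefficients[self.mesh.elements]
        return self.coefficients.reshape(self.mesh.n_elements, 8)


@dataclass
class CGSystem:
    """Assembled nodal stiffness operator (symmetric, constants in kernel)."""

    K: sp.csr_matrix
    mesh: HexMesh
    metadata: dict = field(default_factory=dict)

    @property
    def n_dofs(self) -> int:
        return self.K.shape[0]

    @cached_property
    def _multigrid(self):
        """Geometric V-cycle preconditioner on the vertex lattice."""
        from ._mg import LatticeMultigrid

        lattice = np.rint((self.mesh.vertices - self.mesh.origin) / self.mesh.h).astype(
            np.int64
        )
        return LatticeMultigrid(self.K, lattice)

    def solve(self, rhs: np.ndarray, tol: float = 1e-8, maxiter: int = 1000) -> np.ndarray:
        """Zero-mean solution of ``K u = rhs`` (rhs mean-removed first) by
        conjugate gradients with the multigrid preconditioner."""
        b = rhs - rhs.mean()
        nb = np.linalg.norm(b)
        if nb == 0.0:
            return np.zeros_like(b)
        M = self._multigrid.as_linear_operator()
        x, info = spla.cg(self.K, b, M=M, rtol=tol, atol=0.0, maxiter=maxiter)
        if info != 0:
            res = np.linalg.norm(self.K @ x - b) / nb
            raise SolverError(
                f"Neumann solve did not converge in {maxiter} iterations", residual=res
            )
        return x - x.mean()


def shared_cg_system(mesh: HexMesh, quad_order: int = 2) -> "CGSystem":
    """Per-mesh cached nodal system (assembly and multigrid setup are paid
    once even when several discretizations use the same mesh)."""
    cache = mesh.metadata.setdefault("_shared", {})
    key = ("cg_system", quad_order)
    if key not in cache:
        cache[key] = assemble_cg_stiffness(mesh, quad_order)
    return cache[key]


def source_sigma(mesh: HexMesh, dipole: Dipole) -> float:
    """Conductivity of the element containing the dipole (the homogeneous
    neighborhood conductivity ``sigma_inf`` of the subtraction split)."""
    e = mesh.locate_element(dipole.position[None, :])[0]
    if e < 0:
        raise ValueError("dipole lies outside the mesh")
    return float(mesh.element_sigma[e])


def effective_dipole(mesh: HexMesh, dipole: Dipole) -> Dipole:
    """Perturb a dipole sitting (numerically) on a mesh vertex by 1e-9 h;
    the nodal interpolant of ``u_inf`` would otherwise be singular."""
    e = mesh.locate_element(dipole.position[None, :])[0]
    if e < 0:
        raise ValueError("dipole lies outside the mesh")
    corners = mesh.vertices[mesh.elements[e]]
    dmin = np.linalg.norm(corners - dipole.position, axis=1).min()
    if dmin < 1e-9 * mesh.h:
        warnings.warn(
            "dipole coincides with a mesh vertex; perturbing by 1e-9 h",
            stacklevel=2,
        )
        shift = 1e-9 * mesh.h / np.sqrt(3.0)
        return Dipole(dipole.position + shift, dipole.moment)
    return dipole


def assemble_cg_stiffness(mesh: HexMesh, quad_order: int = 2) -> CGSystem:
    """K_ij = int sigma grad(phi_i) . grad(phi_j); on a regular mesh every
    element matrix is ``sigma_e * h *`` the reference stiffness."""
    Kref = ref.reference_stiffness(quad_order)
    E = mesh.n_elements
    data = (mesh.element_sigma * mesh.h)[:, None, None] * Kref[None, :, :]
    rows = np.broadcast_to(mesh.elements[:, :, None], (E, 8, 8))
    cols = np.broadcast_to(mesh.elements[:, None, :], (E, 8, 8))
    K = sp.coo_matrix(
        (data.ravel(), (rows.ravel(), cols.ravel())),
        shape=(mesh.n_vertices, mesh.n_vertices),
    ).tocsr()
    return CGSystem(K=K, mesh=mesh, metadata={"quad_order": quad_order})


def _volume_rhs_terms(
    mesh: HexMesh, dipole: Dipole, sigma_inf: float, quad_order: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-element nodal contributions of
    ``- int sigma_corr grad(u_inf) . grad(v)`` over elements where
    ``sigma_corr != 0``.  Returns (element ids, (n, 8) values)."""
    sigma_corr = mesh.element_sigma - sigma_inf
    els = np.nonzero(sigma_corr != 0.0)[0]
    if len(els) == 0:
        return els, np.zeros((0, 8))
    qpts, w = ref.volume_rule(quad_order)
    g = ref.shape_gradients(qpts)  # (Q, 8, 3) reference
    pts = mesh.element_origins()[els, None, :] + qpts[None, :, :] * mesh.h
    gu = grad_singularity_potential(dipole, sigma_inf, pts.reshape(-1, 3)).reshape(
        len(els), -1, 3
    )
    # h^3 volume scale times 1/h for the physical test gradient
    vals = -mesh.h**2 * sigma_corr[els, None] * np.einsum(
        "q,qia,eqa->ei", w, g, gu
    )
    return els, vals


def _boundary_rhs_terms(
    mesh: HexMesh, dipole: Dipole, sigma_inf: float, quad_order: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-boundary-face nodal contributions of
    ``- int_dOmega sigma_inf grad(u_inf) . n v``.
    Returns (element ids, (n, 8) values)."""
    sk = mesh.skeleton
    pts2d, w = ref.face_rule(quad_order)
    vals = np.zeros((sk.n_boundary, 8))
    origins = mesh.element_origins()
    for axis in range(3):
        for side in (0, 1):
            m = (sk.bnd_axis == axis) & (sk.bnd_side == side)
            if not m.any():
                continue
            T = ref.face_trace(axis, side, quad_order)  # (Q, 8)
            p3 = ref.face_points_3d(axis, side, pts2d)  # (Q, 3) reference
            pts = origins[sk.bnd_elem[m], None, :] + p3[None, :, :] * mesh.h
            gu = grad_singularity_potential(
                dipole, sigma_inf, pts.reshape(-1, 3)
            ).reshape(m.sum(), -1, 3)
            gn = gu[:, :, axis] * (1.0 if side == 1 else -1.0)
            vals[m] = -sigma_inf * mesh.h**2 * np.einsum("q,fq,qi->fi", w, gn, T)
    return sk.bnd_elem, vals


def assemble_cg_rhs(
    mesh: HexMesh,
    dipole: Dipole,
    sigma_inf: float | None = None,
    quad_order: int = 2,
    boundary_quad_order: int | None = None,
) -> np.ndarray:
    """Right-hand side of the correction problem: volume term over the
    inhomogeneous elements plus the Neumann boundary term, both with the
    analytic ``grad u_inf`` at the quadrature points."""
    dipole = effective_dipole(mesh, dipole)
    if sigma_inf is None:
        sigma_inf = source_sigma(mesh, dipole)
    rhs = np.zeros(mesh.n_vertices)
    els, vals = _volume_rhs_terms(mesh, dipole, sigma_inf, quad_order)
    np.add.at(rhs, mesh.elements[els].ravel(), vals.ravel())
    bels, bvals = _boundary_rhs_terms(
        mesh, dipole, sigma_inf, boundary_quad_order or quad_order
    )
    np.add.at(rhs, mesh.elements[bels].ravel(), bvals.ravel())
    return rhs


def solve_neumann(
    system: CGSystem, rhs: np.ndarray, tol: float = 1e-8
) -> PotentialField:
    """Zero-mean correction potential; the full potential is
    ``u = u_corr + u_inf``."""
    x = system.solve(rhs, tol=tol)
    return PotentialField("cg-trilinear", x, system.mesh)
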