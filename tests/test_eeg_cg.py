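import numpy as np
import pytest

from megfem.analytic import Dipole, grad_singularity_potential
from megfem.eeg_cg import (
    PotentialField,
    assemble_cg_rhs,
    assemble_cg_stiffness,
    effective_dipole,
    solve_neumann,
    source_sigma,
)

from conftest import make_box_mesh


def oracle_trilinear_stiffness(h, sigma, n_gauss=5):
    """Independent high-order quadrature of the trilinear element stiffness
    (own shape functions and Gauss rule, no package code)."""
    x, w = np.polynomial.legendre.leggauss(n_gauss)
    x = 0.5 * (x + 1.0)
    w = 0.5 * w
    corners = [(a, b, c) for c in (0, 1) for b in (0, 1) for a in (0, 1)]

    def grad(i, p):
        a, b, c = corners[i]
        lx = p[0] if a else 1 - p[0]
        ly = p[1] if b else 1 - p[1]
        lz = p[2] if c else 1 - p[2]
        dx = 1.0 if a else -1.0
        dy = 1.0 if b else -1.0
        dz = 1.0 if c else -1.0
        return np.array([dx * ly * lz, lx * dy * lz, lx * ly * dz]) / h

    K = np.zeros((8, 8))
    for ix, wx in zip(x, w):
        for iy, wy in zip(x, w):
            for iz, wz in zip(x, w):
                p = (ix, iy, iz)
                G = np.array([grad(i, p) for i in range(8)])
                K += wx * wy * wz * sigma * (G @ G.T) * h**3
    return K


_CORNERS = [(a, b, c) for c in (0, 1) for b in (0, 1) for a in (0, 1)]


def _oracle_shapes(p):
    """Trilinear shape values and gradients at points ``p`` (n, 3) on the
    unit cube, derived independently of the package: ``(n, 8)`` and
    ``(n, 8, 3)`` in reference units."""
    n = len(p)
    vals = np.empty((n, 8))
    grads = np.empty((n, 8, 3))
    for i, (a, b, c) in enumerate(_CORNERS):
        l = np.stack(
            [p[:, 0] if a else 1 - p[:, 0],
             p[:, 1] if b else 1 - p[:, 1],
             p[:, 2] if c else 1 - p[:, 2]]
        )
        s = np.array([1.0 if a else -1.0, 1.0 if b else -1.0, 1.0 if c else -1.0])
        vals[:, i] = l[0] * l[1] * l[2]
        grads[:, i, 0] = s[0] * l[1] * l[2]
        grads[:, i, 1] = l[0] * s[1] * l[2]
        grads[:, i, 2] = l[0] * l[1] * s[2]
    return vals, grads


def _oracle_rules(n=7):
    x, w = np.polynomial.legendre.leggauss(n)
    x = 0.5 * (x + 1.0)
    w = 0.5 * w
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    vol_p = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    vol_w = (w[:, None, None] * w[None, :, None] * w[None, None, :]).ravel()
    U, V = np.meshgrid(x, x, indexing="ij")
    face_p = np.column_stack([U.ravel(), V.ravel()])
    face_w = (w[:, None] * w[None, :]).ravel()
    return vol_p, vol_w, face_p, face_w


def oracle_subtraction_rhs(mesh, dip, si):
    """Independent quadrature of the correction-problem right-hand side
    (volume over inhomogeneous elements + Neumann boundary term)."""
    vol_p, vol_w, face_p, face_w = _oracle_rules()
    h = mesh.h
    origins = mesh.element_origins()
    sc = mesh.element_sigma - si
    _, G = _oracle_shapes(vol_p)  # (Q, 8, 3) reference
    expect = np.zeros(mesh.n_vertices)
    for e in np.nonzero(sc != 0)[0]:
        pts = origins[e] + vol_p * h
        gu = grad_singularity_potential(dip, si, pts)  # (Q, 3)
        contrib = -sc[e] * h**2 * np.einsum("q,qia,qa->i", vol_w, G, gu)
        np.add.at(expect, mesh.elements[e], contrib)
    sk = mesh.skeleton
    for k in range(sk.n_boundary):
        e = sk.bnd_elem[k]
        axis, side = sk.bnd_axis[k], sk.bnd_side[k]
        p3 = np.empty((len(face_p), 3))
        p3[:, axis] = float(side)
        tang = [d for d in range(3) if d != axis]
        p3[:, tang[0]], p3[:, tang[1]] = face_p[:, 0], face_p[:, 1]
        T, _ = _oracle_shapes(p3)
        pts = origins[e] + p3 * h
        gn = grad_singularity_potential(dip, si, pts)[:, axis]
        gn = gn if side == 1 else -gn
        contrib = -si * h**2 * np.einsum("q,q,qi->i", face_w, gn, T)
        np.add.at(expect, mesh.elements[e], contrib)
    return expect


class TestStiffness:
    def test_single_element_matches_quadrature_oracle(self, unit_element):
        K = assemble_cg_stiffness(unit_element).K.toarray()
        Kref = oracle_trilinear_stiffness(h=0.01, sigma=0.8)
        # map package vertex order (lattice-sorted) to local corner order
        perm = unit_element.elements[0]
        np.testing.assert_allclose(
            K[np.ix_(perm, perm)], Kref, rtol=1e-12, atol=1e-15 * np.abs(Kref).max()
        )

    def test_row_sums_vanish(self, tiny_two_layer):
        K = assemble_cg_stiffness(tiny_two_layer).K
        scale = np.abs(K.data).max()
        assert np.abs(K.sum(axis=1)).max() <= 1e-12 * scale

    def test_linear_in_conductivity(self, cube2_mesh):
        K1 = assemble_cg_stiffness(cube2_mesh).K
        doubled = make_box_mesh((2, 2, 2), sigma=1.4)
        K2 = assemble_cg_stiffness(doubled).K
        np.testing.assert_allclose(K2.toarray(), 2.0 * K1.toarray(), rtol=1e-13)

    def test_energy_positive_for_nonconstant_fields(self, cube2_mesh):
        K = assemble_cg_stiffness(cube2_mesh).K
        rng = np.random.default_rng(0)
        for _ in range(5):
            u = rng.standard_normal(K.shape[0])
            u -= u.mean()
            assert u @ (K @ u) > 0


class TestRhs:
    def test_homogeneous_mesh_leaves_boundary_term_only(self, cube2_mesh):
        # sigma == sigma_inf everywhere: the volume term vanishes identically,
        # so doubling the volume quadrature order changes nothing
        dip = Dipole(np.array([0.011, 0.009, 0.008]), np.array([0.0, 1.0, 0.0]))
        r2 = assemble_cg_rhs(cube2_mesh, dip, sigma_inf=0.7, quad_order=2)
        r4 = assemble_cg_rhs(cube2_mesh, dip, sigma_inf=0.7, quad_order=4,
                             boundary_quad_order=2)
        np.testing.assert_allclose(r2, r4, rtol=1e-12, atol=1e-18)

    def test_compatibility_total_flux_vanishes(self, tiny_two_layer):
        dip = Dipole(np.array([0.0015, 0.0011, 0.0008]), np.array([0.0, 1.0, 0.0]))
        rhs = assemble_cg_rhs(tiny_two_layer, dip, boundary_quad_order=5)
        assert abs(rhs.sum()) <= 1e-8 * np.linalg.norm(rhs)

    def test_matches_refined_quadrature_oracle(self, tiny_four_layer):
        # independent brute-force evaluation of the volume + boundary terms:
        # own 7-point tensor Gauss rule and own shape-function formulas
        mesh = tiny_four_layer
        dip = Dipole(np.array([0.0012, -0.0009, 0.0014]), np.array([1.0, 0.0, 0.0]))
        si = source_sigma(mesh, dip)
        rhs = assemble_cg_rhs(mesh, dip, si, quad_order=6, boundary_quad_order=6)
        expect = oracle_subtraction_rhs(mesh, dip, si)
        np.testing.assert_allclose(rhs, expect, rtol=1e-6, atol=1e-6 * np.abs(expect).max())

    def test_dipole_outside_mesh_rejected(self, cube2_mesh):
        dip = Dipole(np.array([1.0, 1.0, 1.0]), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(ValueError):
            assemble_cg_rhs(cube2_mesh, dip)

    def test_vertex_coincident_dipole_perturbed_with_warning(self, cube2_mesh):
        dip = Dipole(np.array([0.01, 0.01, 0.01]), np.array([1.0, 0.0, 0.0]))
        with pytest.warns(UserWarning):
            moved = effective_dipole(cube2_mesh, dip)
        assert np.linalg.norm(moved.position - dip.position) > 0


class TestSolve:
    def test_zero_rhs_gives_zero_field(self, tiny_two_layer):
        system = assemble_cg_stiffness(tiny_two_layer)
        u = solve_neumann(system, np.zeros(system.n_dofs))
        assert np.abs(u.coefficients).max() == 0.0

    def test_matches_dense_solve_oracle(self, tiny_two_layer):
        system = assemble_cg_stiffness(tiny_two_layer)
        rng = np.random.default_rng(1)
        b = rng.standard_normal(system.n_dofs)
        b -= b.mean()
        u = system.solve(b, tol=1e-10)
        x = np.linalg.lstsq(system.K.toarray(), b, rcond=None)[0]
        x -= x.mean()
        np.testing.assert_allclose(u, x, atol=1e-8 * np.abs(x).max())

    def test_gauge_constant_shift_invariance(self, tiny_two_layer):
        # adding a constant to the rhs (incompatible part) is projected out
        system = assemble_cg_stiffness(tiny_two_layer)
        rng = np.random.default_rng(2)
        b = rng.standard_normal(system.n_dofs)
        b -= b.mean()
        u1 = system.solve(b.copy(), tol=1e-10)
        u2 = system.solve(b + 3.7, tol=1e-10)
        np.testing.assert_allclose(u1, u2, atol=1e-9 * np.abs(u1).max())

    def test_solution_residual_within_tolerance(self, tiny_two_layer):
        mesh = tiny_two_layer
        dip = Dipole(np.array([0.0021, 0.0011, 0.0005]), np.array([0.0, 1.0, 0.0]))
        system = assemble_cg_stiffness(mesh)
        rhs = assemble_cg_rhs(mesh, dip)
        u = solve_neumann(system, rhs, tol=1e-8)
        b = rhs - rhs.mean()
        res = np.linalg.norm(system.K @ u.coefficients - b) / np.linalg.norm(b)
        assert res <= 1e-8
        assert abs(u.coefficients.mean()) < 1e-14 * np.abs(u.coefficients).max()


class TestPotentialField:
    def test_coefficient_length_validated(self, cube2_mesh):
        with pytest.raises(ValueError):
            PotentialField("cg-trilinear", np.zeros(5), cube2_mesh)
        with pytest.raises(ValueError):
            PotentialField("dg-trilinear", np.zeros(5), cube2_mesh)
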