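import numpy as np
import pytest

from megfem import meg_biotsavart as meg
from megfem.analytic import MU0, Dipole, SensorArray
from megfem.eeg_cg import PotentialField, source_sigma
from megfem.eeg_dg import assemble_dg_rhs, assemble_dg_stiffness, solve_dg

from conftest import make_box_mesh

SENSOR = SensorArray(np.array([[0.05, 0.02, -0.03]]))


def linear_potential(mesh, gradient):
    vals = mesh.vertices @ np.asarray(gradient)
    return PotentialField("dg-trilinear", vals[mesh.elements].ravel(), mesh)


class TestNodalIntegration:
    def test_constant_potential_produces_no_field(self, unit_element):
        S = meg.assemble_S_nodal(unit_element, SENSOR, "cg-trilinear")
        assert np.abs(S @ np.ones(8)).max() <= 1e-14 * np.abs(S).max()

    def test_columns_match_monte_carlo_oracle(self, unit_element):
        # 1e6 uniform points; agreement to 3 significant digits
        S = meg.assemble_S_nodal(unit_element, SENSOR, "cg-trilinear", quad_order=3)
        rng = np.random.default_rng(7)
        pts = rng.random((1_000_000, 3)) * 0.01
        corners = [(a, b, c) for c in (0, 1) for b in (0, 1) for a in (0, 1)]
        d = SENSOR.positions[0][None] - pts
        kern = d / np.linalg.norm(d, axis=1, keepdims=True) ** 3
        t = pts / 0.01
        for vid in range(8):
            i = int(np.nonzero(unit_element.elements[0] == vid)[0][0])
            a, b, c = corners[i]
            l = [t[:, 0] if a else 1 - t[:, 0], t[:, 1] if b else 1 - t[:, 1],
                 t[:, 2] if c else 1 - t[:, 2]]
            s = [1.0 if a else -1.0, 1.0 if b else -1.0, 1.0 if c else -1.0]
            g = np.column_stack(
                [s[0] * l[1] * l[2], l[0] * s[1] * l[2], l[0] * l[1] * s[2]]
            ) / 0.01
            mc = -MU0 / (4 * np.pi) * 0.8 * 0.01**3 * np.cross(g, kern).mean(axis=0)
            np.testing.assert_allclose(S[:, vid], mc, rtol=5e-3, atol=1e-4 * np.abs(mc).max())

    def test_matrix_and_matrix_free_routes_agree(self, grid3_mesh):
        rng = np.random.default_rng(1)
        u = rng.standard_normal(grid3_mesh.n_vertices)
        pot = PotentialField("cg-trilinear", u, grid3_mesh)
        S = meg.assemble_S_nodal(grid3_mesh, SENSOR, "cg-trilinear")
        direct = meg.apply_S_nodal(grid3_mesh, SENSOR, pot)
        np.testing.assert_allclose(
            (S @ u).reshape(-1, 3), direct, rtol=1e-12, atol=1e-30
        )

    def test_sensor_inside_mesh_rejected(self, grid3_mesh):
        inside = SensorArray(np.array([[0.015, 0.015, 0.015]]))
        with pytest.raises(ValueError):
            meg.assemble_S_nodal(grid3_mesh, inside)


class TestConservativeFlux:
    def test_continuous_linear_potential_uniform_sigma(self, grid3_mesh):
        g = np.array([2.0, -1.0, 0.5])
        flux = meg.conservative_flux(linear_potential(grid3_mesh, g), eta=3.0)
        sk = grid3_mesh.skeleton
        expect = sk.face_normals @ g  # sigma = 1
        np.testing.assert_allclose(flux.internal, expect, rtol=1e-12)
        assert np.abs(flux.boundary).max() == 0.0  # no source given

    def test_zero_potential_zero_flux(self, grid3_mesh):
        pot = PotentialField(
            "dg-trilinear", np.zeros(8 * grid3_mesh.n_elements), grid3_mesh
        )
        flux = meg.conservative_flux(pot)
        assert np.abs(flux.internal).max() == 0.0

    def test_balance_identity_for_arbitrary_coefficients(self, tiny_four_layer):
        # the per-element flux balance equals minus the element-summed
        # algebraic residual for ANY coefficient vector, to machine precision
        mesh = tiny_four_layer
        dip = Dipole(np.array([0.0012, 0.0008, 0.0015]), np.array([0.0, 0.0, 1.0]))
        si = source_sigma(mesh, dip)
        dgs = assemble_dg_stiffness(mesh)
        rhs = assemble_dg_rhs(mesh, mesh.skeleton, dip, si)
        rng = np.random.default_rng(4)
        u = rng.standard_normal(dgs.n_dofs)
        pot = PotentialField("dg-trilinear", u, mesh)
        flux = meg.conservative_flux(pot, mesh.skeleton, dgs.eta, dip, si)
        bal = meg.element_balance(flux, dip, si)
        rowsums = (dgs.K @ u - rhs).reshape(-1, 8).sum(axis=1)
        scale = np.abs(dgs.K @ u).max()
        np.testing.assert_allclose(bal, -rowsums, atol=1e-11 * scale)


class TestRT0:
    def test_dof_interpolation_at_face_centroids(self, grid3_mesh):
        sk = grid3_mesh.skeleton
        rng = np.random.default_rng(2)
        field = meg.RT0Field(
            rng.standard_normal(sk.n_internal),
            rng.standard_normal(sk.n_boundary),
            grid3_mesh,
            sk,
        )
        # shift centroids inward so half-open element lookup picks a support
        # element; the normal component is continuous across the face
        eps = 1e-9
        for k in range(0, sk.n_internal, 7):
            axis = sk.face_axis[k]
            p = sk.face_centroids[k].copy()
            p[axis] -= eps
            v = meg.evaluate_rt0(field, p)
            assert v[axis] == pytest.approx(field.alpha_internal[k], rel=1e-6)

    def test_reproduces_constant_fields(self, grid3_mesh):
        sk = grid3_mesh.skeleton
        v0 = np.array([0.3, -1.2, 0.7])
        field = meg.RT0Field(
            sk.face_normals @ v0, sk.bnd_normals @ v0, grid3_mesh, sk
        )
        rng = np.random.default_rng(3)
        pts = rng.random((100, 3)) * 0.0299 + 5e-5
        np.testing.assert_allclose(meg.evaluate_rt0(field, pts),
                                   np.tile(v0, (100, 1)), atol=1e-12)

    def test_elementwise_divergence_is_constant(self, grid3_mesh):
        sk = grid3_mesh.skeleton
        rng = np.random.default_rng(5)
        field = meg.RT0Field(
            rng.standard_normal(sk.n_internal),
            rng.standard_normal(sk.n_boundary),
            grid3_mesh,
            sk,
        )
        h = grid3_mesh.h
        centers = grid3_mesh.element_centers()
        for e in range(0, grid3_mesh.n_elements, 5):
            # divergence by central differences at two interior points
            divs = []
            for shift in (np.zeros(3), np.array([0.2, -0.15, 0.1]) * h):
                p = centers[e] + shift
                div = 0.0
                for d, ed in enumerate(np.eye(3)):
                    vp = meg.evaluate_rt0(field, p + 0.1 * h * ed)[d]
                    vm = meg.evaluate_rt0(field, p - 0.1 * h * ed)[d]
                    div += (vp - vm) / (0.2 * h)
                divs.append(div)
            # equals total outflux / volume
            slots = sk.element_faces[e]
            alpha = np.concatenate([field.alpha_internal, field.alpha_boundary])
            out = sum(
                alpha[slots[s]] * sk.element_face_sign[e, s] * h * h for s in range(6)
            )
            assert divs[0] == pytest.approx(divs[1], rel=1e-9, abs=1e-9)
            assert divs[0] == pytest.approx(out / h**3, rel=1e-9, abs=1e-9)

    def test_moment_columns_match_monte_carlo(self, grid3_mesh):
        sk = grid3_mesh.skeleton
        M = meg.assemble_rt0_moments(grid3_mesh, sk, SENSOR, quad_order=3)
        rng = np.random.default_rng(11)
        k = 5
        alpha = np.zeros(sk.n_internal)
        alpha[k] = 1.0
        field = meg.RT0Field(alpha, np.zeros(sk.n_boundary), grid3_mesh, sk)
        mc = np.zeros(3)
        for el in sk.face_elems[k]:
            orig = grid3_mesh.element_origins()[el]
            pts = rng.random((500_000, 3)) * grid3_mesh.h + orig
            psi = meg.evaluate_rt0(field, pts)
            d = SENSOR.positions[0][None] - pts
            kern = d / np.linalg.norm(d, axis=1, keepdims=True) ** 3
            mc += -MU0 / (4 * np.pi) * grid3_mesh.h**3 * np.cross(psi, kern).mean(axis=0)
        np.testing.assert_allclose(M[:, k], mc, rtol=5e-3, atol=1e-3 * np.abs(mc).max())

    def test_moment_matrix_and_matrix_free_agree(self, grid3_mesh):
        sk = grid3_mesh.skeleton
        rng = np.random.default_rng(6)
        field = meg.RT0Field(
            rng.standard_normal(sk.n_internal),
            rng.standard_normal(sk.n_boundary),
            grid3_mesh,
            sk,
        )
        M = meg.assemble_rt0_moments(grid3_mesh, sk, SENSOR)
        alpha = np.concatenate([field.alpha_internal, field.alpha_boundary])
        np.testing.assert_allclose(
            (M @ alpha).reshape(-1, 3),
            meg.rt0_b_field(field, SENSOR),
            rtol=1e-12,
            atol=1e-30,
        )


class TestConservativeIntegrator:
    def test_zero_jump_uniform_sigma_matches_nodal_integrator(self, grid3_mesh):
        # for a globally continuous potential on uniform conductivity the
        # conservative flux reduces to the nodal one; the two integrators
        # then differ only by quadrature-representation error
        g = np.array([1.0, 0.4, -0.8])
        pot = linear_potential(grid3_mesh, g)
        S = meg.assemble_S_nodal(grid3_mesh, SENSOR, "dg-trilinear")
        Sc = meg.assemble_S_corr_DG(grid3_mesh, grid3_mesh.skeleton, SENSOR, eta=2.0)
        b_nodal = S @ pot.coefficients
        b_cons = Sc @ pot.coefficients
        # the RT0 extension ignores the prescribed boundary flux here, so
        # compare including the boundary moments with the exact datum
        Mb = meg.assemble_rt0_moments(grid3_mesh, grid3_mesh.skeleton, SENSOR)[
            :, grid3_mesh.skeleton.n_internal:
        ]
        alpha_b = grid3_mesh.skeleton.bnd_normals @ g  # sigma = 1
        b_cons = b_cons + Mb @ alpha_b
        # both quadratures see the exact same constant current density
        np.testing.assert_allclose(b_cons, b_nodal, rtol=1e-9)

    def test_linearity(self, grid3_mesh):
        Sc = meg.assemble_S_corr_DG(grid3_mesh, grid3_mesh.skeleton, SENSOR, eta=2.0)
        rng = np.random.default_rng(8)
        u, v = rng.standard_normal((2, Sc.shape[1]))
        np.testing.assert_allclose(
            Sc @ (2.0 * u - 3.0 * v), 2.0 * (Sc @ u) - 3.0 * (Sc @ v), rtol=1e-12
        )


class TestFullField:
    def test_total_is_exact_sum_of_parts(self):
        rng = np.random.default_rng(9)
        parts = rng.standard_normal((3, 4, 3))
        bset = meg.BFieldSet(Bp=parts[0], Bs_inf=parts[1], Bs_corr=parts[2])
        np.testing.assert_array_equal(bset.B, parts.sum(axis=0))
        np.testing.assert_array_equal(bset.Bs, parts[1] + parts[2])

    def test_pairing_mismatch_rejected(self, tiny_four_layer):
        mesh = tiny_four_layer
        dip = Dipole(np.array([0.0012, 0.0008, 0.0015]), np.array([0.0, 0.0, 1.0]))
        u = PotentialField("dg-trilinear", np.zeros(8 * mesh.n_elements), mesh)
        S_wrong = np.zeros((3, mesh.n_vertices))  # continuous-basis column count
        with pytest.raises(ValueError):
            meg.full_b_field(dip, SENSOR, u, S_wrong, S_wrong)

    def test_full_field_assembly_and_decomposition(self, tiny_four_layer):
        mesh = tiny_four_layer
        dip = Dipole(np.array([0.0012, 0.0008, 0.0015]), np.array([0.0, 0.0, 1.0]))
        si = source_sigma(mesh, dip)
        dgs = assemble_dg_stiffness(mesh)
        rhs = assemble_dg_rhs(mesh, mesh.skeleton, dip, si)
        u = solve_dg(dgs, rhs, tol=1e-8)
        S = meg.assemble_S_nodal(mesh, SENSOR, "dg-trilinear")
        Sc = meg.assemble_S_corr_DG(mesh, mesh.skeleton, SENSOR, eta=dgs.eta)
        Mb = meg.assemble_rt0_moments(mesh, mesh.skeleton, SENSOR)[
            :, mesh.skeleton.n_internal:
        ]
        bset = meg.full_b_field(
            dip, SENSOR, u, S, Sc, sigma_inf=si,
            boundary_moments=Mb, skeleton=mesh.skeleton,
        )
        np.testing.assert_array_equal(bset.B, bset.Bp + bset.Bs_inf + bset.Bs_corr)
        assert np.all(np.isfinite(bset.B))
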