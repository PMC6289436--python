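"""Plane elasticity core: constitutive law, stiffness, constraints,
objectivity, and an independent triangle-element cross-check."""

import numpy as np
import pytest

from patellasim.fem import (
    BoundaryConditions,
    ElasticMaterial,
    ElementMatrices,
    FiberSpec,
    TABLE_MATERIALS,
    constitutive_matrix,
    default_knee_bcs,
    element_stiffness,
    solve_elasticity,
    stress_strain_measures,
)
from patellasim.fixtures import fiber_bar_error, patch_test_error
from patellasim.geometry import KneeGeometryConfig, build_knee_mesh, rectangle_mesh

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


class TestConstitutive:
    def test_plane_stress_entries_for_tendon_matrix(self):
        # direct evaluation of E/(1-nu^2) * [[1,nu,0],[nu,1,0],[0,0,(1-nu)/2]]
        D = constitutive_matrix(ElasticMaterial(6.1, 0.4))
        assert D[0, 0] == pytest.approx(7.261904761904762, rel=1e-12)
        assert D[0, 1] == pytest.approx(2.904761904761905, rel=1e-12)
        assert D[2, 2] == pytest.approx(2.178571428571429, rel=1e-12)

    def test_material_invariants_enforced(self):
        with pytest.raises(ValueError):
            ElasticMaterial(-1.0, 0.3)
        with pytest.raises(ValueError):
            ElasticMaterial(1.0, 0.5)


class TestElementStiffness:
    @pytest.mark.parametrize("name", sorted(TABLE_MATERIALS))
    def test_symmetric_psd_with_three_rigid_modes(self, name):
        K = element_stiffness(TABLE_MATERIALS[name], None, UNIT_SQUARE)
        assert np.allclose(K, K.T, atol=1e-12)
        w = np.linalg.eigvalsh(K)
        assert w.min() > -1e-10
        assert (np.abs(w) < 1e-9).sum() == 3  # 2 translations + 1 rotation

    def test_fiber_contribution_matches_hand_assembled_bar(self):
        assert fiber_bar_error() < 1e-12

    def test_continuum_fiber_adds_axial_stiffness_only(self):
        mat = TABLE_MATERIALS["tendon_matrix"]
        base = element_stiffness(mat, None, UNIT_SQUARE)
        fib = element_stiffness(
            mat, FiberSpec(model="continuum"), UNIT_SQUARE,
            fiber_direction=np.array([1.0, 0.0]),
        )
        dK = fib - base
        # pure y-translation and y-stretch see no fiber stiffness
        uy = np.array([0, 1, 0, 1, 0, 1, 0, 1], dtype=float)
        assert np.abs(dK @ uy).max() < 1e-10
        ux_stretch = np.array([0, 0, 1, 0, 1, 0, 0, 0], dtype=float)
        assert ux_stretch @ dK @ ux_stretch > 100.0


class TestSolve:
    @pytest.mark.parametrize("name", sorted(TABLE_MATERIALS))
    def test_patch_constant_strain_reproduced(self, name):
        assert patch_test_error(TABLE_MATERIALS[name]) < 1e-10

    def test_zero_prescribed_displacement_gives_zero_solution(self, coarse_mesh):
        sol = solve_elasticity(
            coarse_mesh, fiber=FiberSpec(),
            bcs=default_knee_bcs(coarse_mesh, pull_mm=0.0),
        )
        assert np.abs(sol.u).max() < 1e-12
        assert np.abs(sol.stress).max() < 1e-10

    def test_default_knee_solve_residual_and_compression_location(self, coarse_mesh):
        sol = solve_elasticity(coarse_mesh, fiber=FiberSpec(),
                               bcs=default_knee_bcs(coarse_mesh))
        assert sol.residual < 1e-9
        contact = set(coarse_mesh.boundary_tags["FEMUR_CONTACT_LINE"].tolist())
        peak = int(np.argmin(sol.sigma_hyd_matrix[: coarse_mesh.n_tendon_elements]))
        assert contact.intersection(coarse_mesh.elements[peak].tolist())

    def test_sliding_nodes_stay_on_the_condyle(self, coarse_mesh):
        sol = solve_elasticity(coarse_mesh, fiber=FiberSpec(),
                               bcs=default_knee_bcs(coarse_mesh))
        contact = coarse_mesh.boundary_tags["FEMUR_CONTACT_LINE"]
        normals = coarse_mesh.nodes[contact]
        normals = normals / np.linalg.norm(normals, axis=1)[:, None]
        normal_disp = np.einsum("ij,ij->i", sol.u[contact], normals)
        # interior contact nodes (ends are Dirichlet-free here) cannot move radially
        assert np.abs(normal_disp).max() < 1e-10

    def test_frame_objectivity_under_37_degree_rotation(self, coarse_config):
        base = build_knee_mesh(coarse_config)
        sol0 = solve_elasticity(base, fiber=FiberSpec(), bcs=default_knee_bcs(base))
        phi = np.deg2rad(37.0)
        R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        rot = build_knee_mesh(coarse_config)
        rot.nodes = base.nodes @ R.T
        rot.element_fiber_dir = base.element_fiber_dir @ R.T
        sol1 = solve_elasticity(rot, fiber=FiberSpec(), bcs=default_knee_bcs(rot))
        for f0, f1 in (
            (sol0.sigma_hyd_matrix, sol1.sigma_hyd_matrix),
            (sol0.eps1, sol1.eps1),
        ):
            scale = np.abs(f0).max()
            assert np.abs(f0 - f1).max() / scale < 1e-8
        # displacements rotate with the frame
        assert np.abs(sol1.u - sol0.u @ R.T).max() < 1e-8

    def test_cantilever_converges_toward_beam_theory(self):
        # fiberless cantilever tip deflection under end load approaches the
        # Timoshenko closed form monotonically from below under refinement
        L, H, P, E, nu = 8.0, 1.0, 0.1, 100.0, 0.3
        I = H**3 / 12.0
        kappa = 10.0 * (1 + nu) / (12 + 11 * nu)
        G = E / (2 * (1 + nu))
        exact = P * L**3 / (3 * E * I) + P * L / (kappa * G * H)
        tips = []
        for nx, ny in ((16, 2), (32, 4), (64, 8)):
            mesh = rectangle_mesh(nx, ny, L, H)
            left = mesh.boundary_tags["LEFT"]
            loads = np.zeros((mesh.n_nodes, 2))
            right = mesh.boundary_tags["RIGHT"]
            loads[right, 1] = -P / len(right)
            bcs = BoundaryConditions(left, np.zeros((len(left), 2)), loads=loads)
            sol = solve_elasticity(
                mesh, materials={"tendon_matrix": ElasticMaterial(E, nu)},
                fiber=None, bcs=bcs,
            )
            tips.append(-sol.u[right, 1].mean())
        assert tips[0] < tips[1] < tips[2] < exact * 1.02
        assert tips[2] > 0.9 * exact


class TestMeasures:
    def _solution_with_stress(self, sxx, syy, sxy):
        from patellasim.fem import ElasticSolution

        stress = np.array([[sxx, syy, sxy]])
        strain = np.array([[sxx, syy, 2 * sxy]])  # shape only; eps1 from strain
        return ElasticSolution(
            u=np.zeros((1, 2)), strain=strain, stress=stress,
            stress_matrix=stress, sigma_hyd=np.array([(sxx + syy) / 2]),
            sigma_hyd_matrix=np.array([(sxx + syy) / 2]),
            eps1=np.array([0.0]), compliance=0.0, residual=0.0,
        )

    def test_isotropic_compression(self):
        sol = self._solution_with_stress(-2.0, -2.0, 0.0)
        sig, _ = stress_strain_measures(sol, phase="total")
        assert sig[0] == pytest.approx(-2.0)

    def test_pure_shear_is_traceless_with_positive_principal_strain(self):
        from patellasim.fem import _principal_max

        sol = self._solution_with_stress(0.0, 0.0, 1.0)
        sig, _ = stress_strain_measures(sol, phase="total")
        assert sig[0] == pytest.approx(0.0)
        assert _principal_max(np.array([[0.0, 0.0, 1.0]]))[0] > 0

    def test_uniaxial_compression_halves(self):
        sol = self._solution_with_stress(-1.0, 0.0, 0.0)
        sig, _ = stress_strain_measures(sol, phase="total")
        assert sig[0] == pytest.approx(-0.5)


# ---------------------------------------------------------------------------
# independent cross-check: constant-strain triangles


def _cst_solve(mesh, bcs, material):
    """Minimal independent plane-stress solver: each quad split into two
    linear triangles, Dirichlet plus rotated sliding constraints."""
    E_mod, nu = material.young_modulus, material.poisson_ratio
    D = E_mod / (1 - nu * nu) * np.array(
        [[1, nu, 0], [nu, 1, 0], [0, 0, (1 - nu) / 2]]
    )
    n = 2 * mesh.n_nodes
    K = np.zeros((n, n))
    tris = []
    for conn in mesh.elements:
        tris.append((conn[0], conn[1], conn[2]))
        tris.append((conn[0], conn[2], conn[3]))
    for tri in tris:
        p = mesh.nodes[list(tri)]
        area = 0.5 * np.linalg.det(
            np.array([[1, *p[0]], [1, *p[1]], [1, *p[2]]])
        )
        beta = [p[(i + 1) % 3][1] - p[(i + 2) % 3][1] for i in range(3)]
        gamma = [p[(i + 2) % 3][0] - p[(i + 1) % 3][0] for i in range(3)]
        B = np.zeros((3, 6))
        for i in range(3):
            B[0, 2 * i] = beta[i]
            B[1, 2 * i + 1] = gamma[i]
            B[2, 2 * i] = gamma[i]
            B[2, 2 * i + 1] = beta[i]
        B /= 2 * area
        ke = B.T @ D @ B * area
        dofs = np.array([[2 * t, 2 * t + 1] for t in tri]).ravel()
        K[np.ix_(dofs, dofs)] += ke
    T = np.eye(n)
    for node, tang in zip(bcs.sliding_nodes, bcs.sliding_tangents):
        i = 2 * int(node)
        T[i : i + 2, i : i + 2] = np.column_stack([tang, [-tang[1], tang[0]]])
    Kr = T.T @ K @ T
    u_fix = np.zeros(n)
    fixed = np.zeros(n, bool)
    for node, val in zip(bcs.dirichlet_nodes, bcs.dirichlet_values):
        u_fix[2 * node : 2 * node + 2] = val
        fixed[2 * node : 2 * node + 2] = True
    for node in bcs.sliding_nodes:
        fixed[2 * node + 1] = True
    free = ~fixed
    rhs = -Kr[np.ix_(free, fixed)] @ u_fix[fixed]
    u_rot = u_fix.copy()
    u_rot[free] = np.linalg.solve(Kr[np.ix_(free, free)], rhs)
    u = (T @ u_rot).reshape(-1, 2)
    sig_hyd = np.zeros(mesh.n_elements)
    for e, conn in enumerate(mesh.elements):
        vals = []
        for tri in ((conn[0], conn[1], conn[2]), (conn[0], conn[2], conn[3])):
            p = mesh.nodes[list(tri)]
            area = 0.5 * np.linalg.det(
                np.array([[1, *p[0]], [1, *p[1]], [1, *p[2]]])
            )
            beta = [p[(i + 1) % 3][1] - p[(i + 2) % 3][1] for i in range(3)]
            gamma = [p[(i + 2) % 3][0] - p[(i + 1) % 3][0] for i in range(3)]
            B = np.zeros((3, 6))
            for i in range(3):
                B[0, 2 * i] = beta[i]
                B[1, 2 * i + 1] = gamma[i]
                B[2, 2 * i] = gamma[i]
                B[2, 2 * i + 1] = beta[i]
            B /= 2 * area
            s = D @ (B @ u[list(tri)].reshape(-1))
            vals.append((s[0] + s[1]) / 2)
        sig_hyd[e] = np.mean(vals)
    return u, sig_hyd


def test_mini_knee_fixture_passes():
    from patellasim.fixtures import run_fixture

    result = run_fixture("mini_knee")
    assert result.passed
    assert result.details["peak_sigma_hyd_matrix"] < 0


def test_wrap_compression_agrees_with_triangle_oracle():
    """The fiberless coarse knee: quad solver vs an independently written
    constant-strain-triangle solver must agree on the compressive wrap
    pattern (correlation) and on the peak's location on the contact line."""
    cfg = KneeGeometryConfig(n_through_thickness=4, n_along_length=20)
    mesh = build_knee_mesh(cfg)
    bcs = default_knee_bcs(mesh)
    mat = TABLE_MATERIALS["tendon_matrix"]
    sol = solve_elasticity(mesh, materials={"tendon_matrix": mat}, fiber=None,
                           bcs=bcs)
    _, sig_cst = _cst_solve(mesh, bcs, mat)
    r = np.corrcoef(sol.sigma_hyd[: mesh.n_tendon_elements],
                    sig_cst[: mesh.n_tendon_elements])[0, 1]
    assert r > 0.95
    contact = set(mesh.boundary_tags["FEMUR_CONTACT_LINE"].tolist())
    for field in (sol.sigma_hyd, sig_cst):
        peak = int(np.argmin(field[: mesh.n_tendon_elements]))
        assert contact.intersection(mesh.elements[peak].tolist())
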