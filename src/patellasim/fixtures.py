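"""Validation fixtures: small deterministic problems with independent
oracles, runnable without any external data.

Five fixtures cover the solver stack: a 1D diffusion bar against a
truncated Fourier series, a constant-strain patch test, a single fiber
bar element against the hand-assembled axial link, the classic cantilever
compliance-minimization benchmark, and a coarse knee solve checking the
location of the compressive wrap stresses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .geometry import KneeGeometryConfig, Region, build_knee_mesh, rectangle_mesh
from .fem import (
    BoundaryConditions,
    ElasticMaterial,
    ElementMatrices,
    FiberSpec,
    TABLE_MATERIALS,
    bar_stiffness,
    constitutive_matrix,
    default_knee_bcs,
    element_stiffness,
    solve_elasticity,
)
from .topopt import SimpParams, optimize
from .transport import TransportSolver

__all__ = ["ValidationFixture", "FixtureResult", "make_validation_fixtures",
           "run_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = (
    "diffusion_bar_1d",
    "patch_test",
    "bar_fiber_element",
    "cantilever_simp",
    "mini_knee",
)


@dataclass
class FixtureResult:
    name: str
    passed: bool
    error_norm: float
    details: dict = field(default_factory=dict)


@dataclass
class ValidationFixture:
    name: str
    description: str
    runner: Callable[[], FixtureResult]

    def run(self) -> FixtureResult:
        return self.runner()


# ---------------------------------------------------------------------------
# 1. diffusion bar vs Fourier series


def diffusion_bar_error(n_elements: int = 100, diffusivity: float = 1.0,
                        t_end: float = 0.02, n_terms: int = 50) -> float:
    """Relative L2 error of the FE diffusion step against the closed-form
    cosine series for a unit bar with a step initial condition and no-flux
    ends.  dt scales with h, so the first-order implicit-Euler time error
    dominates and the total error halves under mesh doubling."""
    length = 1.0
    mesh = rectangle_mesh(n_elements, 1, width=length, height=length / n_elements)
    solver = TransportSolver(mesh)
    x = mesh.nodes[:, 0]
    s = np.where(x < 0.5, 1.0, np.where(x > 0.5, 0.0, 0.5))
    h = length / n_elements
    dt = 0.1 * h / diffusivity
    n_steps = int(np.ceil(t_end / dt))
    dt = t_end / n_steps
    for _ in range(n_steps):
        s = solver.implicit_step(s, dt, diffusivity, cache_key="bar")
    solver.clear_cache()

    exact = np.full_like(x, 0.5)
    for n in range(1, n_terms + 1):
        a_n = 2.0 * np.sin(n * np.pi / 2.0) / (n * np.pi)
        exact += (
            a_n
            * np.cos(n * np.pi * x / length)
            * np.exp(-diffusivity * (n * np.pi / length) ** 2 * t_end)
        )
    w = solver.mass
    err = np.sqrt(w @ (s - exact) ** 2) / np.sqrt(w @ exact**2)
    return float(err)


def _run_diffusion_bar() -> FixtureResult:
    err = diffusion_bar_error(100)
    return FixtureResult(
        "diffusion_bar_1d", err < 0.02, err, {"n_elements": 100, "tolerance": 0.02}
    )


# ---------------------------------------------------------------------------
# 2. constant-strain patch test


def patch_test_error(material: ElasticMaterial, plane: str = "stress") -> float:
    """Max relative deviation of the interior stress from D_m eps under a
    linear boundary displacement (bilinear quads reproduce constant strain
    exactly, so the deviation should be at rounding level)."""
    mesh = rectangle_mesh(3, 3, 1.0, 1.0)
    grad = np.array([[2e-3, 5e-4], [-8e-4, 1.5e-3]])  # du_i/dx_j
    boundary = np.unique(
        np.concatenate([mesh.boundary_tags[k] for k in ("LEFT", "RIGHT", "TOP",
                                                        "BOTTOM")])
    )
    values = mesh.nodes[boundary] @ grad.T
    bcs = BoundaryConditions(dirichlet_nodes=boundary, dirichlet_values=values)
    sol = solve_elasticity(
        mesh, materials={"tendon_matrix": material}, fiber=None, bcs=bcs, plane=plane
    )
    eps = np.array([grad[0, 0], grad[1, 1], grad[0, 1] + grad[1, 0]])
    sigma_exact = constitutive_matrix(material, plane) @ eps
    err = np.abs(sol.stress - sigma_exact[None, :]).max() / np.abs(sigma_exact).max()
    return float(err)


def _run_patch_test() -> FixtureResult:
    errs = {name: patch_test_error(mat) for name, mat in TABLE_MATERIALS.items()}
    worst = max(errs.values())
    return FixtureResult("patch_test", worst < 1e-10, worst, {"per_material": errs})


# ---------------------------------------------------------------------------
# 3. fiber bar element vs hand-assembled link


def fiber_bar_error() -> float:
    """Difference between the assembled fiber contribution on a unit square
    (horizontal fibers, bar model) and the two hand-assembled axial links
    of tributary area 1/2 on the bottom and top edges."""
    mesh = rectangle_mesh(1, 1, 1.0, 1.0)
    fiber = FiberSpec(fiber_modulus=800.0, model="bar")
    with_f = ElementMatrices(mesh, None, fiber).assemble().toarray()
    without = ElementMatrices(mesh, None, None).assemble().toarray()
    contribution = with_f - without

    expected = np.zeros((8, 8))
    conn = mesh.elements[0]
    for n0, n1 in ((conn[0], conn[1]), (conn[3], conn[2])):
        k = bar_stiffness(mesh.nodes[n0], mesh.nodes[n1], 800.0 * 0.5)
        dofs = [2 * n0, 2 * n0 + 1, 2 * n1, 2 * n1 + 1]
        for a in range(4):
            for b in range(4):
                expected[dofs[a], dofs[b]] += k[a, b]
    return float(np.abs(contribution - expected).max() / np.abs(expected).max())


def _run_fiber_bar() -> FixtureResult:
    err = fiber_bar_error()
    return FixtureResult("bar_fiber_element", err < 1e-12, err, {})


# ---------------------------------------------------------------------------
# 4. SIMP cantilever benchmark


def cantilever_simp(params: SimpParams | None = None):
    """32x20 cantilever (fixed left edge, downward unit point load at the
    right edge midheight, E=1, nu=0.3): the standard compliance-
    minimization sanity surface."""
    nx, ny = 32, 20
    mesh = rectangle_mesh(nx, ny, float(nx), float(ny))
    params = params or SimpParams(
        volume_fraction=0.4, penalization=3.0, move_limit=0.2, damping=0.5,
        filter_radius=1.5, max_iterations=200, change_tolerance=0.01,
    )
    left = mesh.boundary_tags["LEFT"]
    loads = np.zeros((mesh.n_nodes, 2))
    mid_right = mesh.boundary_tags["RIGHT"][ny // 2]
    loads[mid_right, 1] = -1.0
    bcs = BoundaryConditions(
        dirichlet_nodes=left,
        dirichlet_values=np.zeros((len(left), 2)),
        loads=loads,
    )
    materials = {"tendon_matrix": ElasticMaterial(1.0, 0.3)}
    return optimize(mesh, bcs, params, materials=materials, fiber=None)


def _run_cantilever() -> FixtureResult:
    density = cantilever_simp()
    c = density.compliances
    ratio = float(c[-1] / c[0])
    vol_ok = all(abs(v - 0.4) < 1e-3 for _, v, _ in density.history)
    passed = density.converged and ratio < 0.5 and vol_ok
    return FixtureResult(
        "cantilever_simp",
        passed,
        ratio,
        {
            "iterations": len(density.history),
            "converged": density.converged,
            "volume_constraint_ok": vol_ok,
            "initial_compliance": float(c[0]),
            "final_compliance": float(c[-1]),
        },
    )


# ---------------------------------------------------------------------------
# 5. coarse knee cross-check


def mini_knee_config() -> KneeGeometryConfig:
    return KneeGeometryConfig(
        flexion_angle_deg=90.0, n_through_thickness=4, n_along_length=20
    )


def _run_mini_knee() -> FixtureResult:
    mesh = build_knee_mesh(mini_knee_config())
    sol = solve_elasticity(mesh, fiber=FiberSpec(), bcs=default_knee_bcs(mesh))
    contact = set(mesh.boundary_tags["FEMUR_CONTACT_LINE"].tolist())
    peak = int(np.argmin(sol.sigma_hyd_matrix[: mesh.n_tendon_elements]))
    peak_on_contact = bool(contact.intersection(mesh.elements[peak].tolist()))
    passed = sol.residual < 1e-9 and peak_on_contact
    return FixtureResult(
        "mini_knee",
        passed,
        sol.residual,
        {
            "peak_compressive_element": peak,
            "peak_sigma_hyd_matrix": float(sol.sigma_hyd_matrix.min()),
            "peak_adjacent_to_contact_line": peak_on_contact,
        },
    )


def make_validation_fixtures() -> list[ValidationFixture]:
    """The five deterministic validation problems with their oracles."""
    return [
        ValidationFixture(
            "diffusion_bar_1d",
            "100-element bar, step initial condition vs 50-term cosine series",
            _run_diffusion_bar,
        ),
        ValidationFixture(
            "patch_test",
            "3x3 constant-strain patch for every tissue material",
            _run_patch_test,
        ),
        ValidationFixture(
            "bar_fiber_element",
            "unit-square fiber overlay vs hand-assembled axial links",
            _run_fiber_bar,
        ),
        ValidationFixture(
            "cantilever_simp",
            "32x20 cantilever compliance minimization benchmark",
            _run_cantilever,
        ),
        ValidationFixture(
            "mini_knee",
            "4x20 knee solve: compressive peak on the contact line",
            _run_mini_knee,
        ),
    ]


def run_fixture(name: str) -> FixtureResult:
    for fx in make_validation_fixtures():
        if fx.name == name:
            return fx.run()
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
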