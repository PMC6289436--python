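"""Linear-elastic plane finite elements for the composite tendon.

Bilinear quadrilaterals with 2x2 Gauss integration model the isotropic
matrix; collagen fibers are overlaid as 2-node axial bar elements running
along the element edges parallel to the local tendon centerline (an
equivalent rank-one continuum stiffness is available behind a switch).
Contact with the rigid femoral condyle is bilateral sliding: contact-line
nodes have their degrees of freedom rotated into a tangent/normal frame and
the normal component fixed.

Sign conventions: tension positive, hydrostatic stress negative in
compression.  Plane stress is the default; ``plane="strain"`` switches the
constitutive matrix and includes the out-of-plane stress in the 3-trace
hydrostatic measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import QuadMesh, Region, _GP, _shape_derivatives

__all__ = [
    "ElasticMaterial",
    "FiberSpec",
    "BoundaryConditions",
    "ElasticSolution",
    "constitutive_matrix",
    "element_stiffness",
    "solve_elasticity",
    "stress_strain_measures",
    "default_knee_bcs",
    "TABLE_MATERIALS",
]


@dataclass(frozen=True)
class ElasticMaterial:
    """Isotropic linear-elastic material (E in MPa)."""

    young_modulus: float
    poisson_ratio: float

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError("young_modulus must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5)")


#: Literature tissue properties used throughout: cartilage, tendon matrix,
#: tendon fiber (MPa).
TABLE_MATERIALS = {
    "cartilage": ElasticMaterial(6.1, 0.497),
    "tendon_matrix": ElasticMaterial(6.1, 0.4),
    "tendon_fiber": ElasticMaterial(800.0, 0.4),
}


@dataclass(frozen=True)
class FiberSpec:
    """Tendon fiber reinforcement along the local centerline direction.

    ``model="bar"`` overlays 2-node axial links on element edges parallel to
    the fibers, with tributary cross-section area summing to the tendon
    thickness per unit depth; ``model="continuum"`` instead adds the
    rank-one stiffness E_f (a x a)(a x a)^T to the element constitutive
    matrix.  Both reduce to the same axial stiffness pattern for a fiber on
    the horizontal axis.
    """

    fiber_modulus: float = 800.0
    volume_fraction_scaling: float = 1.0
    model: str = "bar"

    def __post_init__(self) -> None:
        if self.fiber_modulus <= 0 or self.volume_fraction_scaling <= 0:
            raise ValueError("fiber modulus and volume fraction must be positive")
        if self.model not in ("bar", "continuum"):
            raise ValueError("fiber model must be 'bar' or 'continuum'")


@dataclass
class BoundaryConditions:
    """Dirichlet + sliding constraints for the knee problem.

    ``dirichlet_nodes``/``dirichlet_values`` carry both the fixed tibia end
    (zeros) and the prescribed quadriceps pull.  ``sliding_nodes`` may move
    only along ``sliding_tangents`` (unit vectors); their normal component
    is fixed to zero.  ``loads`` is an optional (N, 2) nodal force array for
    force-controlled problems.
    """

    dirichlet_nodes: np.ndarray
    dirichlet_values: np.ndarray  # (n, 2)
    sliding_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    sliding_tangents: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    loads: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.sliding_nodes) != len(self.sliding_tangents):
            raise ValueError("one tangent per sliding node required")
        if np.intersect1d(self.dirichlet_nodes, self.sliding_nodes).size:
            raise ValueError("dirichlet and sliding node sets must be disjoint")
        if len(self.sliding_tangents):
            norms = np.linalg.norm(self.sliding_tangents, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-12):
                raise ValueError("sliding tangents must be unit vectors")


@dataclass
class ElasticSolution:
    """Displacement and derived element fields of one elastic solve."""

    u: np.ndarray  # (N, 2) mm
    strain: np.ndarray  # (E, 3) Voigt [exx, eyy, gxy], Gauss-averaged
    stress: np.ndarray  # (E, 3) total (matrix + fiber), MPa
    stress_matrix: np.ndarray  # (E, 3) matrix phase only, MPa
    sigma_hyd: np.ndarray  # (E,) in-plane mean of the total stress
    sigma_hyd_matrix: np.ndarray  # (E,) in-plane mean of the matrix stress
    eps1: np.ndarray  # (E,) maximum principal strain
    compliance: float  # u^T F (force-controlled runs)
    residual: float  # relative |K u - F| on free DOFs


def constitutive_matrix(material: ElasticMaterial, plane: str = "stress") -> np.ndarray:
    """3x3 isotropic constitutive matrix in Voigt notation."""
    E, nu = material.young_modulus, material.poisson_ratio
    if plane == "stress":
        c = E / (1.0 - nu * nu)
        return c * np.array(
            [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1.0 - nu) / 2.0]]
        )
    if plane == "strain":
        c = E / ((1.0 + nu) * (1.0 - 2.0 * nu))
        return c * np.array(
            [
                [1.0 - nu, nu, 0.0],
                [nu, 1.0 - nu, 0.0],
                [0.0, 0.0, (1.0 - 2.0 * nu) / 2.0],
            ]
        )
    raise ValueError("plane must be 'stress' or 'strain'")


def _fiber_voigt(direction: np.ndarray) -> np.ndarray:
    """Voigt vector a = [a1^2, a2^2, a1 a2] such that a . eps is the axial
    strain along ``direction``."""
    a1, a2 = direction
    return np.array([a1 * a1, a2 * a2, a1 * a2])


def _bmatrix(coords: np.ndarray, xi: float, eta: float):
    dN = _shape_derivatives(xi, eta)
    J = dN @ coords
    detJ = np.linalg.det(J)
    if detJ <= 0:
        from .geometry import GeometryError

        raise GeometryError("non-positive Jacobian in element integration")
    dNdx = np.linalg.solve(J, dN)  # (2, 4)
    B = np.zeros((3, 8))
    B[0, 0::2] = dNdx[0]
    B[1, 1::2] = dNdx[1]
    B[2, 0::2] = dNdx[1]
    B[2, 1::2] = dNdx[0]
    return B, detJ


def element_stiffness(
    material: ElasticMaterial,
    fiber: FiberSpec | None,
    coords: np.ndarray,
    fiber_direction: np.ndarray | None = None,
    plane: str = "stress",
) -> np.ndarray:
    """8x8 stiffness of one bilinear quad (2x2 Gauss).

    A ``fiber`` is included here only in its continuum (rank-one) form; the
    bar overlay is assembled globally on element edges.
    """
    D = constitutive_matrix(material, plane)
    if fiber is not None and fiber.model == "continuum":
        if fiber_direction is None:
            raise ValueError("continuum fiber needs a direction")
        a = _fiber_voigt(np.asarray(fiber_direction) / np.linalg.norm(fiber_direction))
        D = D + fiber.fiber_modulus * fiber.volume_fraction_scaling * np.outer(a, a)
    K = np.zeros((8, 8))
    for xi in _GP:
        for eta in _GP:
            B, detJ = _bmatrix(coords, xi, eta)
            K += B.T @ D @ B * detJ
    return K


def bar_stiffness(p0: np.ndarray, p1: np.ndarray, ea: float) -> np.ndarray:
    """4x4 stiffness of a 2-node axial link with axial stiffness ``ea`` = E*A."""
    d = p1 - p0
    L = np.linalg.norm(d)
    d = d / L
    tt = np.outer(d, d)
    k = ea / L
    K = np.zeros((4, 4))
    K[:2, :2] = tt
    K[2:, 2:] = tt
    K[:2, 2:] = -tt
    K[2:, :2] = -tt
    return k * K


# ---------------------------------------------------------------------------
# assembly


def _region_material(materials: dict, region_code: int) -> ElasticMaterial:
    region = Region(region_code)
    if region == Region.FEMUR_CARTILAGE or region in (
        Region.CARTILAGE_PATELLA,
        Region.CARTILAGE_TIBIA,
    ):
        return materials.get("cartilage", TABLE_MATERIALS["cartilage"])
    return materials.get("tendon_matrix", TABLE_MATERIALS["tendon_matrix"])


class ElementMatrices:
    """Precomputed unscaled element matrices for fast repeated assembly
    (used every SIMP iteration)."""

    def __init__(
        self,
        mesh: QuadMesh,
        materials: dict | None = None,
        fiber: FiberSpec | None = None,
        plane: str = "stress",
    ):
        materials = materials or TABLE_MATERIALS
        self.mesh = mesh
        self.plane = plane
        self.fiber = fiber
        E = mesh.n_elements
        self.Ke = np.zeros((E, 8, 8))
        self.dofmap = np.zeros((E, 8), dtype=np.int64)
        for e in range(E):
            conn = mesh.elements[e]
            coords = mesh.nodes[conn]
            mat = _region_material(materials, mesh.element_region[e])
            fdir = (
                mesh.element_fiber_dir[e] if mesh.element_fiber_dir is not None else None
            )
            use_fiber = (
                fiber
                if (fiber is not None and e < mesh.n_tendon_elements)
                else None
            )
            self.Ke[e] = element_stiffness(
                mat, use_fiber if (use_fiber and fiber.model == "continuum") else None,
                coords, fdir, plane,
            )
            dofs = np.empty(8, dtype=np.int64)
            dofs[0::2] = 2 * conn
            dofs[1::2] = 2 * conn + 1
            self.dofmap[e] = dofs

        # fiber bars on the two centerline-parallel edges of each tendon
        # element; each edge carries half the element's through-thickness
        # extent as tributary cross-section, so the fiber area over a full
        # tendon cross-section sums to the tendon thickness
        self.bars: list[tuple[int, np.ndarray, np.ndarray]] = []
        if fiber is not None and fiber.model == "bar":
            areas = np.abs(mesh.element_areas())
            for e in range(mesh.n_tendon_elements):
                conn = mesh.elements[e]
                edges = ((conn[0], conn[1]), (conn[3], conn[2]))
                lengths = [
                    np.linalg.norm(mesh.nodes[n1] - mesh.nodes[n0]) for n0, n1 in edges
                ]
                a_half = (
                    areas[e] / (lengths[0] + lengths[1]) * fiber.volume_fraction_scaling
                )
                for n0, n1 in edges:
                    kbar = bar_stiffness(
                        mesh.nodes[n0], mesh.nodes[n1], fiber.fiber_modulus * a_half
                    )
                    dofs = np.array(
                        [2 * n0, 2 * n0 + 1, 2 * n1, 2 * n1 + 1], dtype=np.int64
                    )
                    self.bars.append((e, dofs, kbar))

    def assemble(
        self,
        element_scale: np.ndarray | None = None,
        bar_scale: np.ndarray | None = None,
    ) -> sp.csr_matrix:
        """Global stiffness; ``element_scale[e]`` multiplies element e's
        matrix, as in SIMP density penalization.  ``bar_scale`` scales the
        fiber bars separately (defaults to ``element_scale``)."""
        n = 2 * self.mesh.n_nodes
        scale = (
            np.ones(self.mesh.n_elements) if element_scale is None else element_scale
        )
        bscale = scale if bar_scale is None else bar_scale
        data = (self.Ke * scale[:, None, None]).ravel()
        rows = np.repeat(self.dofmap, 8, axis=1).ravel()
        cols = np.tile(self.dofmap, (1, 8)).ravel()
        if self.bars:
            bd, br, bc = [], [], []
            for e, dofs, kbar in self.bars:
                bd.append((kbar * bscale[e]).ravel())
                br.append(np.repeat(dofs, 4))
                bc.append(np.tile(dofs, 4))
            data = np.concatenate([data, *bd])
            rows = np.concatenate([rows, *br])
            cols = np.concatenate([cols, *bc])
        K = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
        return K


def _sliding_rotation(mesh: QuadMesh, bcs: BoundaryConditions) -> sp.csr_matrix:
    """Block-diagonal rotation taking (tangent, normal) DOFs of sliding
    nodes to global x/y; identity elsewhere."""
    n = 2 * mesh.n_nodes
    T = sp.lil_matrix((n, n))
    T.setdiag(1.0)
    for node, tang in zip(bcs.sliding_nodes, bcs.sliding_tangents):
        tx, ty = tang
        nx, ny = -ty, tx
        i = 2 * int(node)
        T[i, i], T[i, i + 1] = tx, nx
        T[i + 1, i], T[i + 1, i + 1] = ty, ny
    return T.tocsr()


def solve_elasticity(
    mesh: QuadMesh,
    materials: dict | None = None,
    fiber: FiberSpec | None = None,
    bcs: BoundaryConditions | None = None,
    plane: str = "stress",
    element_scale: np.ndarray | None = None,
    bar_scale: np.ndarray | None = None,
    matrices: ElementMatrices | None = None,
) -> ElasticSolution:
    """Solve K u = F under Dirichlet + sliding constraints and derive the
    element strain/stress fields and Carter stimuli."""
    materials = materials or TABLE_MATERIALS
    if bcs is None:
        bcs = default_knee_bcs(mesh)
    if matrices is None:
        matrices = ElementMatrices(mesh, materials, fiber, plane)
    K = matrices.assemble(element_scale, bar_scale)
    n = K.shape[0]

    F = np.zeros(n)
    if bcs.loads is not None:
        F = bcs.loads.reshape(-1).astype(float).copy()

    T = _sliding_rotation(mesh, bcs)
    Kr = (T.T @ K @ T).tocsr()
    Fr = T.T @ F

    u_fix = np.zeros(n)
    fixed = np.zeros(n, dtype=bool)
    for node, val in zip(bcs.dirichlet_nodes, bcs.dirichlet_values):
        u_fix[2 * int(node)] = val[0]
        u_fix[2 * int(node) + 1] = val[1]
        fixed[2 * int(node)] = fixed[2 * int(node) + 1] = True
    for node in bcs.sliding_nodes:
        fixed[2 * int(node) + 1] = True  # rotated normal component

    free = ~fixed
    rhs = Fr[free] - Kr[free][:, fixed] @ u_fix[fixed]
    Kff = Kr[free][:, free]
    u_rot = u_fix.copy()
    u_rot[free] = spla.spsolve(Kff.tocsc(), rhs)

    res = Kff @ u_rot[free] - rhs
    denom = max(np.linalg.norm(rhs), np.linalg.norm(Kff @ u_rot[free]), 1e-30)
    residual = float(np.linalg.norm(res) / denom)

    u = (T @ u_rot).reshape(-1, 2)
    compliance = float(u.reshape(-1) @ F)
    return _derive_fields(mesh, materials, fiber, u, plane, element_scale, compliance,
                          residual)


def _derive_fields(mesh, materials, fiber, u, plane, element_scale, compliance,
                   residual) -> ElasticSolution:
    E = mesh.n_elements
    strain = np.zeros((E, 3))
    stress_m = np.zeros((E, 3))
    stress = np.zeros((E, 3))
    scale = np.ones(E) if element_scale is None else element_scale
    for e in range(E):
        conn = mesh.elements[e]
        coords = mesh.nodes[conn]
        ue = u[conn].reshape(-1)
        eps = np.zeros(3)
        for xi in _GP:
            for eta in _GP:
                B, _ = _bmatrix(coords, xi, eta)
                eps += B @ ue
        eps /= 4.0
        strain[e] = eps
        Dm = constitutive_matrix(_region_material(materials, mesh.element_region[e]),
                                 plane)
        sm = scale[e] * (Dm @ eps)
        stress_m[e] = sm
        stress[e] = sm
        if fiber is not None and e < mesh.n_tendon_elements:
            a = _fiber_voigt(mesh.element_fiber_dir[e])
            ef = fiber.fiber_modulus * fiber.volume_fraction_scaling
            stress[e] = sm + scale[e] * ef * (a @ eps) * a

    sigma_hyd = _hydrostatic(stress, strain, materials, mesh, plane)
    sigma_hyd_m = _hydrostatic(stress_m, strain, materials, mesh, plane)
    eps1 = _principal_max(strain)
    return ElasticSolution(
        u=u,
        strain=strain,
        stress=stress,
        stress_matrix=stress_m,
        sigma_hyd=sigma_hyd,
        sigma_hyd_matrix=sigma_hyd_m,
        eps1=eps1,
        compliance=compliance,
        residual=residual,
    )


def _hydrostatic(stress, strain, materials, mesh, plane) -> np.ndarray:
    """In-plane mean stress; under plane strain the out-of-plane stress
    sigma_zz = nu (sxx + syy) joins the 3-trace."""
    s = 0.5 * (stress[:, 0] + stress[:, 1])
    if plane == "strain":
        nus = np.array(
            [
                _region_material(materials, r).poisson_ratio
                for r in mesh.element_region
            ]
        )
        szz = nus * (stress[:, 0] + stress[:, 1])
        s = (stress[:, 0] + stress[:, 1] + szz) / 3.0
    return s


def _principal_max(strain: np.ndarray) -> np.ndarray:
    exx, eyy, gxy = strain[:, 0], strain[:, 1], strain[:, 2]
    c = 0.5 * (exx + eyy)
    r = np.sqrt((0.5 * (exx - eyy)) ** 2 + (0.5 * gxy) ** 2)
    return c + r


def stress_strain_measures(
    solution: ElasticSolution, phase: str = "matrix"
) -> tuple[np.ndarray, np.ndarray]:
    """Return (hydrostatic stress, max principal strain) element fields.

    ``phase="matrix"`` (default) evaluates the hydrostatic stress in the
    matrix phase only — the pressure environment of the cells between the
    fibers — while ``phase="total"`` includes the fiber axial stress.
    """
    if phase == "matrix":
        return solution.sigma_hyd_matrix, solution.eps1
    if phase == "total":
        return solution.sigma_hyd, solution.eps1
    raise ValueError("phase must be 'matrix' or 'total'")


def default_knee_bcs(
    mesh: QuadMesh, pull_mm: float = 1.0, as_force: bool = False
) -> BoundaryConditions:
    """Quadriceps contraction boundary conditions on the knee mesh.

    The muscle end is displaced ``pull_mm`` along the quadriceps axis (away
    from the joint), the tibia end is fully fixed, and the contact-line
    nodes slide tangentially on the rigid condyle.  With ``as_force`` the
    muscle end is left free; caller supplies loads separately.
    """
    cfg = mesh.config
    nt = cfg.n_through_thickness
    muscle = mesh.boundary_tags["MUSCLE_END"]
    tibia = mesh.boundary_tags["TIBIA_END"]
    contact = mesh.boundary_tags["FEMUR_CONTACT_LINE"]
    # quadriceps axis from the first two inner-line nodes (frame-consistent)
    d = mesh.nodes[muscle[0]] - mesh.nodes[int(muscle[0]) + (nt + 1)]
    d = d / np.linalg.norm(d)

    # sliding tangents from node position relative to the condyle centre;
    # the centre is the mean of contact positions minus radius*normal --
    # recovered robustly by circle fit through the contact nodes
    centre = _fit_circle_centre(mesh.nodes[contact])
    radial = mesh.nodes[contact] - centre
    radial /= np.linalg.norm(radial, axis=1)[:, None]
    tangents = np.column_stack([radial[:, 1], -radial[:, 0]])

    # muscle-end corner node lies on the contact line only if the arc starts
    # at station 0; by construction sets are disjoint for default geometry
    if as_force:
        dirichlet = tibia
        values = np.zeros((len(tibia), 2))
    else:
        dirichlet = np.concatenate([muscle, tibia])
        values = np.vstack(
            [np.tile(d * pull_mm, (len(muscle), 1)), np.zeros((len(tibia), 2))]
        )
    keep = ~np.isin(contact, dirichlet)
    return BoundaryConditions(
        dirichlet_nodes=dirichlet,
        dirichlet_values=values,
        sliding_nodes=contact[keep],
        sliding_tangents=tangents[keep],
    )


def _fit_circle_centre(points: np.ndarray) -> np.ndarray:
    """Least-squares circle centre through >= 3 points (Kasa fit)."""
    x, y = points[:, 0], points[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones(len(x))])
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:2]


def reaction_forces(
    mesh: QuadMesh,
    solution_u: np.ndarray,
    matrices: ElementMatrices,
    node_set: np.ndarray,
) -> np.ndarray:
    """Nodal reactions K u restricted to ``node_set`` (shape (len, 2))."""
    K = matrices.assemble()
    r = (K @ solution_u.reshape(-1)).reshape(-1, 2)
    return r[node_set]
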