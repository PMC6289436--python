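"""Parametric 2D knee-joint geometry and structured quadrilateral meshing.

The domain is a developing quadriceps/patellar tendon of uniform thickness
wrapped around a circular femoral condyle: a straight quadriceps segment,
a circular arc subtending the knee flexion angle, and a straight patellar
segment.  For the biochemical model an annular femoral-cartilage sector of
fixed radial depth sits inside the contact arc and shares the interface
nodes with the tendon.

Coordinates are millimetres with the origin at the condyle centre.  The
quadriceps segment is tangent to the condyle at the top (polar angle 90°)
and runs horizontally; the wrap arc proceeds clockwise through the flexion
angle; the patellar segment leaves tangentially at the far end.  Flexion is
measured between the directions of the two straight segments, which equals
the arc's subtended angle.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Region",
    "KneeGeometryConfig",
    "QuadMesh",
    "ElementCorrespondence",
    "build_knee_mesh",
    "element_correspondence",
]


class Region(enum.IntEnum):
    """Tissue/region label of a mesh element."""

    FEMUR_CARTILAGE = 0
    SCX_DOMAIN = 1
    MESENCHYME = 2
    TENDON = 3
    CARTILAGE_PATELLA = 4
    CARTILAGE_TIBIA = 5
    INTERZONE = 6


#: Region codes that count as cartilage for diffusion/differentiation rules.
CARTILAGE_REGIONS = (
    Region.FEMUR_CARTILAGE,
    Region.CARTILAGE_PATELLA,
    Region.CARTILAGE_TIBIA,
)


class GeometryError(ValueError):
    """Raised when a mesh cannot be generated or has inverted elements."""


@dataclass(frozen=True)
class KneeGeometryConfig:
    """Parameters of the wrapped-tendon knee geometry.

    Lengths in mm.  ``flexion_angle_deg`` is both the angle between the two
    straight tendon segments and the angle subtended by the contact arc, so
    the tendon/condyle coincident area grows with flexion.
    """

    flexion_angle_deg: float = 90.0
    condyle_radius: float = 4.0
    tendon_thickness: float = 1.75
    quadriceps_segment_length: float = 6.0
    patellar_segment_length: float = 6.0
    n_through_thickness: int = 8
    n_along_length: int = 120
    include_femur_region: bool = False
    femur_depth: float = 2.0
    n_femur_radial: int = 4
    # Initial Scx-cell domain as a fraction interval of the tendon
    # centerline, measured from the muscle (quadriceps) end.  The default
    # ends one element short of the wrap arc so tendon progenitors must
    # migrate onto the condyle before any differentiation can start there.
    scx_start_frac: float = 0.0
    scx_end_frac: float = 0.28

    def __post_init__(self) -> None:
        if not 0.0 < self.flexion_angle_deg < 180.0:
            raise ValueError(
                f"flexion_angle_deg must be in (0, 180), got {self.flexion_angle_deg}"
            )
        if self.condyle_radius <= 0 or self.tendon_thickness <= 0:
            raise ValueError("condyle_radius and tendon_thickness must be positive")
        if self.quadriceps_segment_length <= 0 or self.patellar_segment_length <= 0:
            raise ValueError("segment lengths must be positive")
        if self.n_through_thickness < 2 or self.n_along_length < 2:
            raise ValueError("element counts must be >= 2")
        if self.include_femur_region and (
            self.femur_depth <= 0
            or self.femur_depth >= self.condyle_radius
            or self.n_femur_radial < 1
        ):
            raise ValueError("invalid femoral-cartilage region parameters")
        if not 0.0 <= self.scx_start_frac < self.scx_end_frac <= 1.0:
            raise ValueError("scx fractions must satisfy 0 <= start < end <= 1")

    @property
    def wrap_angle_rad(self) -> float:
        return np.deg2rad(self.flexion_angle_deg)

    @property
    def centerline_radius(self) -> float:
        return self.condyle_radius + 0.5 * self.tendon_thickness

    @property
    def centerline_length(self) -> float:
        return (
            self.quadriceps_segment_length
            + self.centerline_radius * self.wrap_angle_rad
            + self.patellar_segment_length
        )

    def along_subdivisions(self) -> tuple[int, int, int]:
        """Split ``n_along_length`` over (quadriceps, arc, patellar) segments
        proportionally to centerline length; every segment gets >= 1 element."""
        L = self.centerline_length
        nq = max(1, int(round(self.n_along_length * self.quadriceps_segment_length / L)))
        npat = max(1, int(round(self.n_along_length * self.patellar_segment_length / L)))
        narc = self.n_along_length - nq - npat
        if narc < 1:
            raise GeometryError(
                "n_along_length too small to give the wrap arc an element"
            )
        return nq, narc, npat


@dataclass
class QuadMesh:
    """Structured bilinear-quad mesh with region and boundary tags.

    Tendon elements come first (station-major, then through-thickness layer),
    followed by femoral-cartilage elements when present.  ``tendon_ij[e]``
    holds the structured (along, through) index of tendon element ``e``.
    """

    config: KneeGeometryConfig
    nodes: np.ndarray  # (N, 2)
    elements: np.ndarray  # (E, 4) CCW connectivity
    element_region: np.ndarray  # (E,) Region codes
    boundary_tags: dict[str, np.ndarray] = field(default_factory=dict)
    tendon_ij: np.ndarray | None = None  # (E_t, 2)
    element_s: np.ndarray | None = None  # centerline coordinate of element centre
    element_segment: np.ndarray | None = None  # 0 quad, 1 arc, 2 patellar, -1 femur
    element_fiber_dir: np.ndarray | None = None  # (E, 2) local centerline tangent
    n_tendon_elements: int = 0

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def tendon_elements(self) -> np.ndarray:
        return np.arange(self.n_tendon_elements)

    def femur_elements(self) -> np.ndarray:
        return np.arange(self.n_tendon_elements, self.n_elements)

    def element_coords(self, e: int) -> np.ndarray:
        return self.nodes[self.elements[e]]

    def element_areas(self) -> np.ndarray:
        """Areas by the shoelace formula (positive for CCW quads)."""
        p = self.nodes[self.elements]  # (E, 4, 2)
        x, y = p[..., 0], p[..., 1]
        xr, yr = np.roll(x, -1, axis=1), np.roll(y, -1, axis=1)
        return 0.5 * np.sum(x * yr - xr * y, axis=1)

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def element_adjacency(self) -> list[list[int]]:
        """Edge (4-)adjacency over all elements, via shared element edges."""
        edge_map: dict[tuple[int, int], int] = {}
        adj: list[list[int]] = [[] for _ in range(self.n_elements)]
        for e, conn in enumerate(self.elements):
            for k in range(4):
                a, b = int(conn[k]), int(conn[(k + 1) % 4])
                key = (a, b) if a < b else (b, a)
                if key in edge_map:
                    other = edge_map[key]
                    adj[e].append(other)
                    adj[other].append(e)
                else:
                    edge_map[key] = e
        return adj


@dataclass(frozen=True)
class ElementCorrespondence:
    """Bijective element map between two meshes of equal structured layout."""

    mapping: np.ndarray  # mapping[e in mesh A] -> e in mesh B

    def __post_init__(self) -> None:
        m = np.sort(self.mapping)
        if not np.array_equal(m, np.arange(len(m))):
            raise ValueError("element correspondence is not a bijection")


# Gauss points of the 2x2 rule on [-1, 1]^2
_GP = np.array([-1.0, 1.0]) / np.sqrt(3.0)


def _shape_derivatives(xi: float, eta: float) -> np.ndarray:
    """d(N_1..4)/d(xi, eta) for the bilinear quad, shape (2, 4)."""
    return 0.25 * np.array(
        [
            [-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)],
            [-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)],
        ]
    )


def check_jacobians(mesh: QuadMesh) -> None:
    """Raise :class:`GeometryError` naming the first element whose Jacobian
    is non-positive at any 2x2 Gauss point."""
    for e in range(mesh.n_elements):
        coords = mesh.element_coords(e)
        for xi in _GP:
            for eta in _GP:
                J = _shape_derivatives(xi, eta) @ coords
                if np.linalg.det(J) <= 0.0:
                    raise GeometryError(
                        f"element {e} has non-positive Jacobian at Gauss point "
                        f"({xi:.4f}, {eta:.4f})"
                    )


def _centerline_stations(config: KneeGeometryConfig):
    """Inner-surface points, outward normals, tangents, and centerline arc
    coordinate at each along-station, plus the segment id of each element
    column."""
    nq, narc, npat = config.along_subdivisions()
    r = config.condyle_radius
    Lq = config.quadriceps_segment_length
    Lp = config.patellar_segment_length
    theta = config.wrap_angle_rad
    Rc = config.centerline_radius

    a0 = np.pi / 2.0
    pts, normals, tangents, s_arc = [], [], [], []
    # quadriceps straight segment, muscle end first
    q0 = np.array([r * np.cos(a0), r * np.sin(a0)])
    T0 = np.array([np.sin(a0), -np.cos(a0)])
    N0 = np.array([np.cos(a0), np.sin(a0)])
    for i in range(nq):
        frac = i / nq
        pts.append(q0 - (1.0 - frac) * Lq * T0)
        normals.append(N0)
        tangents.append(T0)
        s_arc.append(frac * Lq)
    # wrap arc (clockwise: polar angle decreases)
    for k in range(narc + 1):
        a = a0 - theta * k / narc
        pts.append(np.array([r * np.cos(a), r * np.sin(a)]))
        normals.append(np.array([np.cos(a), np.sin(a)]))
        tangents.append(np.array([np.sin(a), -np.cos(a)]))
        s_arc.append(Lq + Rc * theta * k / narc)
    # patellar straight segment
    a1 = a0 - theta
    q1 = np.array([r * np.cos(a1), r * np.sin(a1)])
    T1 = np.array([np.sin(a1), -np.cos(a1)])
    N1 = np.array([np.cos(a1), np.sin(a1)])
    for i in range(1, npat + 1):
        frac = i / npat
        pts.append(q1 + frac * Lp * T1)
        normals.append(N1)
        tangents.append(T1)
        s_arc.append(Lq + Rc * theta + frac * Lp)
    segment_of_column = np.concatenate(
        [np.zeros(nq, int), np.ones(narc, int), np.full(npat, 2, int)]
    )
    return (
        np.array(pts),
        np.array(normals),
        np.array(tangents),
        np.array(s_arc),
        segment_of_column,
        (nq, narc, npat),
    )


def build_knee_mesh(config: KneeGeometryConfig) -> QuadMesh:
    """Build the structured wrapped-tendon mesh for one flexion angle.

    Returns a :class:`QuadMesh` with tendon elements tagged SCX_DOMAIN or
    MESENCHYME (by the configured Scx centerline interval) and, when
    ``config.include_femur_region`` is set, FEMUR_CARTILAGE elements in an
    annular sector of depth ``femur_depth`` inside the contact arc.
    """
    pts, normals, tangents, s_arc, seg_col, (nq, narc, npat) = _centerline_stations(
        config
    )
    n_stations = len(pts)  # n_along + 1
    nt = config.n_through_thickness
    t = config.tendon_thickness

    # tendon nodes: station-major, layer j = 0 (inner) .. nt (outer)
    layers = np.linspace(0.0, t, nt + 1)
    nodes = (
        pts[:, None, :] + layers[None, :, None] * normals[:, None, :]
    ).reshape(-1, 2)

    def nid(i: int, j: int) -> int:
        return i * (nt + 1) + j

    elements, regions, ij, elem_s, elem_seg, fiber = [], [], [], [], [], []
    L = config.centerline_length
    s_lo = config.scx_start_frac * L
    s_hi = config.scx_end_frac * L
    for i in range(n_stations - 1):
        for j in range(nt):
            elements.append([nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)])
            s_mid = 0.5 * (s_arc[i] + s_arc[i + 1])
            regions.append(
                Region.SCX_DOMAIN if s_lo <= s_mid <= s_hi else Region.MESENCHYME
            )
            ij.append((i, j))
            elem_s.append(s_mid)
            elem_seg.append(seg_col[i])
            tv = tangents[i] + tangents[i + 1]
            fiber.append(tv / np.linalg.norm(tv))
    n_tendon = len(elements)

    boundary = {
        "MUSCLE_END": np.array([nid(0, j) for j in range(nt + 1)]),
        "TIBIA_END": np.array([nid(n_stations - 1, j) for j in range(nt + 1)]),
        "FEMUR_CONTACT_LINE": np.array([nid(i, 0) for i in range(nq, nq + narc + 1)]),
    }
    boundary["GDF5_SOURCE_LINE"] = boundary["FEMUR_CONTACT_LINE"].copy()
    free = [nid(i, nt) for i in range(n_stations)]
    free += [nid(i, 0) for i in range(0, nq)]
    free += [nid(i, 0) for i in range(nq + narc + 1, n_stations)]
    boundary["FREE_SURFACE"] = np.array(sorted(set(free)))

    nodes_list = [nodes]
    if config.include_femur_region:
        # annular sector below the contact arc; its outer ring reuses the
        # tendon's inner arc nodes
        nf = config.n_femur_radial
        radii = np.linspace(
            config.condyle_radius - config.femur_depth, config.condyle_radius, nf + 1
        )
        a0 = np.pi / 2.0
        theta = config.wrap_angle_rad
        arc_angles = a0 - theta * np.arange(narc + 1) / narc
        femur_new = []  # nodes for rings 0..nf-1
        base = nodes.shape[0]

        def fnid(k: int, jr: int) -> int:
            # ring jr in 0..nf ; outermost ring maps to shared tendon nodes
            if jr == nf:
                return nid(nq + k, 0)
            return base + jr * (narc + 1) + k

        for jr in range(nf):
            for a in arc_angles:
                femur_new.append([radii[jr] * np.cos(a), radii[jr] * np.sin(a)])
        nodes_list.append(np.array(femur_new))
        for k in range(narc):
            for jr in range(nf):
                elements.append(
                    [fnid(k, jr), fnid(k + 1, jr), fnid(k + 1, jr + 1), fnid(k, jr + 1)]
                )
                regions.append(Region.FEMUR_CARTILAGE)
                elem_s.append(np.nan)
                elem_seg.append(-1)
                am = 0.5 * (arc_angles[k] + arc_angles[k + 1])
                fiber.append(np.array([np.sin(am), -np.cos(am)]))

    mesh = QuadMesh(
        config=config,
        nodes=np.vstack(nodes_list),
        elements=np.array(elements, dtype=np.int64),
        element_region=np.array([int(r) for r in regions], dtype=np.int64),
        boundary_tags=boundary,
        tendon_ij=np.array(ij, dtype=np.int64),
        element_s=np.array(elem_s),
        element_segment=np.array(elem_seg, dtype=np.int64),
        element_fiber_dir=np.array(fiber),
        n_tendon_elements=n_tendon,
    )
    check_jacobians(mesh)
    return mesh


def element_correspondence(mesh_a: QuadMesh, mesh_b: QuadMesh) -> ElementCorrespondence:
    """Map elements of ``mesh_a`` onto ``mesh_b`` by structured index.

    Meshes built with identical subdivision counts enumerate their elements
    in the same structured order, so the correspondence is the identity
    permutation; differing subdivisions raise ``ValueError``.
    """
    ca, cb = mesh_a.config, mesh_b.config
    if (
        ca.n_through_thickness != cb.n_through_thickness
        or ca.n_along_length != cb.n_along_length
        or mesh_a.n_elements != mesh_b.n_elements
    ):
        raise ValueError(
            "meshes are incompatible: subdivision counts differ "
            f"({ca.n_through_thickness}x{ca.n_along_length} vs "
            f"{cb.n_through_thickness}x{cb.n_along_length})"
        )
    return ElementCorrespondence(mapping=np.arange(mesh_a.n_elements))


def with_angle(config: KneeGeometryConfig, angle_deg: float) -> KneeGeometryConfig:
    """Copy of ``config`` at a different flexion angle (same subdivisions)."""
    return replace(config, flexion_angle_deg=angle_deg)


def rectangle_mesh(
    nx: int,
    ny: int,
    width: float = 1.0,
    height: float = 1.0,
    region: Region = Region.MESENCHYME,
) -> QuadMesh:
    """Structured nx-by-ny quad mesh of [0, width] x [0, height].

    Used by the validation fixtures (patch test, diffusion bar, SIMP
    cantilever).  Boundary tags LEFT/RIGHT/BOTTOM/TOP hold the edge node
    sets; fibers, when attached, run along +x.
    """
    xs = np.linspace(0.0, width, nx + 1)
    ys = np.linspace(0.0, height, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i: int, j: int) -> int:
        return i * (ny + 1) + j

    elements, ij = [], []
    for i in range(nx):
        for j in range(ny):
            elements.append([nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)])
            ij.append((i, j))
    n_el = len(elements)
    boundary = {
        "LEFT": np.array([nid(0, j) for j in range(ny + 1)]),
        "RIGHT": np.array([nid(nx, j) for j in range(ny + 1)]),
        "BOTTOM": np.array([nid(i, 0) for i in range(nx + 1)]),
        "TOP": np.array([nid(i, ny) for i in range(nx + 1)]),
    }
    centroids_x = np.array(
        [(xs[i] + xs[i + 1]) / 2 for i, _ in ij]
    )
    mesh = QuadMesh(
        config=None,  # type: ignore[arg-type]
        nodes=nodes,
        elements=np.array(elements, dtype=np.int64),
        element_region=np.full(n_el, int(region), dtype=np.int64),
        boundary_tags=boundary,
        tendon_ij=np.array(ij, dtype=np.int64),
        element_s=centroids_x,
        element_segment=np.zeros(n_el, dtype=np.int64),
        element_fiber_dir=np.tile(np.array([1.0, 0.0]), (n_el, 1)),
        n_tendon_elements=n_el,
    )
    check_jacobians(mesh)
    return mesh
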