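"""Biochemical model of patella onset (chemotaxis + diffusion + cell rules).

The quadriceps/patellar tendon anlage starts as mesenchyme with a domain of
Scx-positive tendon progenitor cells.  TGF-beta released by the muscle end,
the femoral epiphysis and the tibial end attracts the Scx cells
chemotactically; once the muscle front senses Scx cells it expresses FGF,
which turns Scx-rich mesenchyme into tendon; BMP diffusing from the
epiphyses turns Scx-rich mesenchyme into cartilage (the future patella and
the tibial eminence); and GDF-5, a joint-interzone marker left on the
femur/tendon interface, converts cartilage into interzone so the patella
detaches from the femur while staying embedded in the tendon.

Cell density b follows a Keller-Segel equation
``db/dt = div(mu grad b - chi b grad s_TGF) + g(b)`` and each molecule s_i
follows ``ds/dt = D_i laplacian(s)`` with fixed-value sources and no-flux
exterior boundaries; diffusion is slowed by a configurable factor inside
cartilage.  Tissue state changes by threshold rules evaluated per element
on element-averaged nodal values, and all transitions are irreversible.

Molecular parameters have no measured literature values; the shipped
defaults are calibrated (see ``defaults/calibrated_defaults.yaml`` and
docs/methods.md) to reproduce the qualitative event sequence at 90 degrees
flexion and the absence of a patella at 30-45 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    KneeGeometryConfig,
    QuadMesh,
    Region,
    build_knee_mesh,
)
from .transport import TransportSolver

__all__ = [
    "SPECIES",
    "MoleculeField",
    "CellDensityField",
    "DifferentiationThresholds",
    "BiochemParams",
    "FieldState",
    "TissueHistory",
    "step_diffusion",
    "step_chemotaxis",
    "update_sources",
    "apply_differentiation",
    "run_theory1",
    "patella_component",
]

SPECIES = ("TGFB", "BMP", "FGF", "GDF5")

#: regions in which molecular diffusion is slowed ("low diffusion" in
#: cartilaginous tissue) — includes interzone, which is former cartilage
_LOW_DIFFUSION_REGIONS = frozenset(
    {
        int(Region.FEMUR_CARTILAGE),
        int(Region.CARTILAGE_PATELLA),
        int(Region.CARTILAGE_TIBIA),
        int(Region.INTERZONE),
    }
)


@dataclass
class MoleculeField:
    """Nodal concentration of one signalling molecule (ng/ml)."""

    species: str
    values: np.ndarray
    diffusion_coefficient: float
    low_diffusion_factor: float = 0.1

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion coefficient must be >= 0")


@dataclass
class CellDensityField:
    """Scx-cell density (cells per volume) and its transport coefficients.

    ``mu`` and ``chi`` are constants by default; concentration-dependent
    forms can be emulated by rescaling per step through the hooks in
    :func:`step_chemotaxis`.  Growth g = r b (1 - b/b_max) is disabled
    (r = 0) unless configured.
    """

    b: np.ndarray
    mu: float
    chi: float
    growth_rate: float = 0.0
    b_max: float = np.inf


@dataclass(frozen=True)
class DifferentiationThresholds:
    """Threshold concentrations of the cellular-automaton tissue rules."""

    b_c_th: float
    s_bmp_th: float
    s_fgf_th: float
    s_gdf5_th: float

    def __post_init__(self) -> None:
        for name in ("b_c_th", "s_bmp_th", "s_fgf_th", "s_gdf5_th"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class BiochemParams:
    """Full parameter set of the biochemical simulation."""

    diffusion: dict[str, float]
    sources: dict[str, float]
    thresholds: DifferentiationThresholds
    mu: float
    chi: float
    b0: float
    #: per-species diffusivity multiplier inside cartilaginous tissue; the
    #: molecule/tissue table slows TGF-beta, BMP and FGF in cartilage but
    #: not the interzone marker GDF-5
    low_diffusion_factor: dict[str, float] | float = 0.1
    growth_rate: float = 0.0
    b_max: float = np.inf
    b_sense: float | None = None  # default: b_c_th / 2
    sense_layers: int = 2
    dt: float = 0.1
    n_steps: int = 1500
    snapshot_every: int = 50

    def __post_init__(self) -> None:
        missing = [s for s in SPECIES if s not in self.diffusion or s not in self.sources]
        if missing:
            raise ValueError(f"missing molecular parameters for {missing}")
        if not isinstance(self.low_diffusion_factor, dict):
            self.low_diffusion_factor = {
                sp_name: float(self.low_diffusion_factor) for sp_name in SPECIES
            }
        if self.b_sense is None:
            self.b_sense = self.thresholds.b_c_th / 2.0

    def factor(self, species: str) -> float:
        return self.low_diffusion_factor.get(species, 1.0)

    @classmethod
    def default(cls) -> "BiochemParams":
        from .config import calibrated_defaults

        d = calibrated_defaults()["biochem"]
        return cls(
            diffusion=dict(d["diffusion"]),
            sources=dict(d["sources"]),
            thresholds=DifferentiationThresholds(**d["thresholds"]),
            mu=d["mu"],
            chi=d["chi"],
            b0=d["b0"],
            growth_rate=d.get("growth_rate", 0.0),
            b_max=d.get("b_max", np.inf),
            low_diffusion_factor=d["low_diffusion_factor"],
            b_sense=d.get("b_sense"),
            sense_layers=d.get("sense_layers", 2),
            dt=d["dt"],
            n_steps=d["n_steps"],
            snapshot_every=d.get("snapshot_every", 50),
        )


@dataclass
class FieldState:
    """All nodal fields plus per-element tissue state at one instant."""

    molecules: dict[str, MoleculeField]
    cells: CellDensityField
    tissue: np.ndarray  # (E,) Region codes, evolves from mesh.element_region
    fgf_active: bool = False
    time: float = 0.0
    version: int = 0  # bumped when the low-diffusion element set changes


@dataclass
class TissueHistory:
    """Recorded outcome of one biochemical run."""

    times: list[float] = field(default_factory=list)
    tissue_snapshots: list[np.ndarray] = field(default_factory=list)
    event_log: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    final_state: FieldState | None = None
    patella_element_count: int = 0
    patella_elements: np.ndarray = field(default_factory=lambda: np.array([], int))

    def events_in_order(self) -> list[tuple[str, float]]:
        return sorted(self.event_log.items(), key=lambda kv: kv[1])


# ---------------------------------------------------------------------------
# sources and transport steps


def source_node_sets(mesh: QuadMesh) -> dict[str, np.ndarray]:
    """Fixed-value (Dirichlet) node sets per species.

    TGF-beta: muscle end, femoral epiphysis interface and tibia end;
    BMP: femoral interface and tibia end; GDF-5: femoral interface;
    FGF: muscle end (active only after sensing).
    """
    muscle = mesh.boundary_tags["MUSCLE_END"]
    tibia = mesh.boundary_tags["TIBIA_END"]
    femur = mesh.boundary_tags["GDF5_SOURCE_LINE"]
    return {
        "TGFB": np.unique(np.concatenate([muscle, femur, tibia])),
        "BMP": np.unique(np.concatenate([femur, tibia])),
        "GDF5": femur.copy(),
        "FGF": muscle.copy(),
    }


def _element_diffusivity(
    field_: MoleculeField, tissue: np.ndarray
) -> np.ndarray:
    d = np.full(tissue.shape, field_.diffusion_coefficient)
    low = np.isin(tissue, list(_LOW_DIFFUSION_REGIONS))
    d[low] *= field_.low_diffusion_factor
    return d


def step_diffusion(
    field_: MoleculeField,
    mesh: QuadMesh,
    dt: float,
    solver: TransportSolver | None = None,
    tissue: np.ndarray | None = None,
    dirichlet_nodes: np.ndarray | None = None,
    dirichlet_value: float = 0.0,
    cache_key=None,
) -> MoleculeField:
    """One implicit-Euler step of ``ds/dt = D_i laplacian(s)`` with no-flux
    exterior boundaries and optional fixed-value source nodes."""
    solver = solver or TransportSolver(mesh)
    tissue = mesh.element_region if tissue is None else tissue
    if field_.diffusion_coefficient == 0.0:
        return field_
    d = _element_diffusivity(field_, tissue)
    new = solver.implicit_step(
        field_.values, dt, d, dirichlet_nodes, dirichlet_value, cache_key=cache_key
    )
    return replace(field_, values=new)


def step_chemotaxis(
    cells: CellDensityField,
    attractant: MoleculeField,
    mesh: QuadMesh,
    dt: float,
    solver: TransportSolver | None = None,
    mobile_elements: np.ndarray | None = None,
    cache_key=None,
) -> CellDensityField:
    """One semi-implicit Keller-Segel step for the Scx-cell density.

    Diffusion (mu) is implicit; the chemotactic flux toward the attractant
    gradient and the optional logistic growth are explicit.  ``mobile_elements``
    restricts cell transport (cells do not migrate through the femoral
    cartilage).  With chi = 0 and r = 0 the update is identical to
    :func:`step_diffusion` with coefficient mu.
    """
    if attractant.species != "TGFB":
        raise ValueError("the chemoattractant is TGF-beta")
    solver = solver or TransportSolver(mesh)
    E = mesh.n_elements
    mask = np.zeros(E, dtype=bool)
    if mobile_elements is None:
        mask[:] = True
    else:
        mask[mobile_elements] = True
    mu_e = np.where(mask, cells.mu, 0.0)
    chi_e = np.where(mask, cells.chi, 0.0)

    explicit = None
    if cells.chi != 0.0:
        C = solver.chemo_matrix(attractant.values, chi_e)
        solver.check_cfl(dt, solver.max_step(C))
        explicit = C @ cells.b
    if cells.growth_rate != 0.0:
        g = cells.growth_rate * cells.b * (1.0 - cells.b / cells.b_max)
        g_mass = solver.mass * g
        explicit = g_mass if explicit is None else explicit + g_mass

    b_new = solver.implicit_step(
        cells.b, dt, mu_e, explicit_rhs=explicit, cache_key=cache_key
    )
    return replace(cells, b=b_new)


def update_sources(
    state: FieldState,
    mesh: QuadMesh,
    params: BiochemParams,
    solver: TransportSolver | None = None,
) -> FieldState:
    """Re-impose source concentrations and handle FGF activation.

    The muscle front senses the element-averaged Scx density over the
    ``sense_layers`` element columns nearest the muscle end; once it
    exceeds ``b_sense`` the FGF source switches on permanently.
    """
    solver = solver or TransportSolver(mesh)
    sets = source_node_sets(mesh)
    for sp_name in ("TGFB", "BMP", "GDF5"):
        state.molecules[sp_name].values[sets[sp_name]] = params.sources[sp_name]
    if not state.fgf_active:
        b_el = solver.element_average(state.cells.b)
        near = mesh.tendon_ij[:, 0] < params.sense_layers
        if near.any() and b_el[mesh.tendon_elements()][near].mean() >= params.b_sense:
            state.fgf_active = True
    if state.fgf_active:
        state.molecules["FGF"].values[sets["FGF"]] = params.sources["FGF"]
    return state


# ---------------------------------------------------------------------------
# differentiation rules


def _tibia_side(mesh: QuadMesh) -> np.ndarray:
    """True for tendon elements whose new cartilage is labelled tibial
    (nearer the tibial epiphysis than the femoral arc along the centerline)."""
    cfg = mesh.config
    s = mesh.element_s[: mesh.n_tendon_elements]
    s_arc_end = (
        cfg.quadriceps_segment_length + cfg.centerline_radius * cfg.wrap_angle_rad
    )
    L = cfg.centerline_length
    d_tibia = L - s
    d_femur = np.where(s > s_arc_end, s - s_arc_end,
                       np.where(s < cfg.quadriceps_segment_length,
                                cfg.quadriceps_segment_length - s, 0.0))
    return d_tibia < d_femur


def apply_differentiation(
    state: FieldState,
    thresholds: DifferentiationThresholds,
    mesh: QuadMesh,
    solver: TransportSolver | None = None,
) -> FieldState:
    """One pass of the threshold tissue rules (irreversible transitions).

    Order per element: cartilage + GDF-5 -> interzone first, then the BMP
    (cartilage) rule, then the FGF (tendon) rule — an element meeting both
    molecule thresholds in the same step becomes cartilage.
    """
    solver = solver or TransportSolver(mesh)
    b = solver.element_average(state.cells.b)
    bmp = solver.element_average(state.molecules["BMP"].values)
    fgf = solver.element_average(state.molecules["FGF"].values)
    gdf5 = solver.element_average(state.molecules["GDF5"].values)
    tissue = state.tissue
    cart = np.isin(
        tissue,
        [int(Region.CARTILAGE_PATELLA), int(Region.CARTILAGE_TIBIA),
         int(Region.FEMUR_CARTILAGE)],
    )
    to_interzone = cart & (gdf5 >= thresholds.s_gdf5_th)

    progenitor = np.isin(tissue, [int(Region.SCX_DOMAIN), int(Region.MESENCHYME)])
    gate = progenitor & (b >= thresholds.b_c_th)
    to_cartilage = gate & (bmp >= thresholds.s_bmp_th)
    to_tendon = gate & (fgf >= thresholds.s_fgf_th) & ~to_cartilage

    changed = to_interzone.any() or to_cartilage.any() or to_tendon.any()
    if not changed:
        return state
    new = tissue.copy()
    new[to_interzone] = int(Region.INTERZONE)
    tibial = np.zeros(mesh.n_elements, dtype=bool)
    tibial[: mesh.n_tendon_elements] = _tibia_side(mesh)
    new[to_cartilage & tibial] = int(Region.CARTILAGE_TIBIA)
    new[to_cartilage & ~tibial] = int(Region.CARTILAGE_PATELLA)
    new[to_tendon] = int(Region.TENDON)
    state.tissue = new
    if to_interzone.any() or to_cartilage.any():
        state.version += 1  # low-diffusion element set changed
    return state


# ---------------------------------------------------------------------------
# patella identification and the main loop


def patella_component(
    tissue: np.ndarray, mesh: QuadMesh, adjacency: list[list[int]] | None = None
) -> tuple[np.ndarray, bool]:
    """Largest connected patellar-cartilage component free of the femur.

    Returns (element ids, detached) where the component qualifies only if
    none of its elements is edge-adjacent to femoral cartilage (separation
    across interzone elements is allowed, since interzone breaks the
    cartilage adjacency), and ``detached`` additionally requires adjacency
    to at least one interzone element.
    """
    adjacency = adjacency or mesh.element_adjacency()
    is_pat = tissue == int(Region.CARTILAGE_PATELLA)
    seen = np.zeros(mesh.n_elements, dtype=bool)
    best: list[int] = []
    best_detached = False
    for start in np.flatnonzero(is_pat):
        if seen[start]:
            continue
        comp, stack = [], [int(start)]
        seen[start] = True
        touches_femur = touches_interzone = False
        while stack:
            e = stack.pop()
            comp.append(e)
            for nb in adjacency[e]:
                if is_pat[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
                elif tissue[nb] == int(Region.FEMUR_CARTILAGE):
                    touches_femur = True
                elif tissue[nb] == int(Region.INTERZONE):
                    touches_interzone = True
        if not touches_femur and len(comp) > len(best):
            best = comp
            best_detached = touches_interzone
    return np.array(sorted(best), dtype=int), best_detached


def make_initial_state(mesh: QuadMesh, params: BiochemParams) -> FieldState:
    n = mesh.n_nodes
    molecules = {
        sp_name: MoleculeField(
            sp_name,
            np.zeros(n),
            params.diffusion[sp_name],
            params.factor(sp_name),
        )
        for sp_name in SPECIES
    }
    b = np.zeros(n)
    scx_nodes = np.unique(
        mesh.elements[mesh.element_region == int(Region.SCX_DOMAIN)]
    )
    b[scx_nodes] = params.b0
    cells = CellDensityField(
        b, params.mu, params.chi, params.growth_rate, params.b_max
    )
    return FieldState(
        molecules=molecules,
        cells=cells,
        tissue=mesh.element_region.copy(),
    )


def run_theory1(
    config: KneeGeometryConfig,
    params: BiochemParams | None = None,
    mesh: QuadMesh | None = None,
    keep_fields: bool = False,
) -> TissueHistory:
    """Run the biochemical loop (diffuse -> chemotax -> sources ->
    differentiate) to the configured horizon and report events and the
    final patella-like component."""
    params = params or BiochemParams.default()
    if mesh is None:
        if not config.include_femur_region:
            config = replace(config, include_femur_region=True)
        mesh = build_knee_mesh(config)
    solver = TransportSolver(mesh)
    state = make_initial_state(mesh, params)
    sets = source_node_sets(mesh)
    adjacency = mesh.element_adjacency()
    history = TissueHistory()
    update_sources(state, mesh, params, solver)

    mobile = np.flatnonzero(mesh.element_region != int(Region.FEMUR_CARTILAGE))

    def record_events(t: float) -> None:
        log = history.event_log
        tissue = state.tissue
        if "tendon_start" not in log and (tissue == int(Region.TENDON)).any():
            log["tendon_start"] = t
        if "patella_cartilage_start" not in log and (
            tissue == int(Region.CARTILAGE_PATELLA)
        ).any():
            log["patella_cartilage_start"] = t
        if "femur_patella_merge" not in log:
            pat = np.flatnonzero(tissue == int(Region.CARTILAGE_PATELLA))
            for e in pat:
                if any(
                    tissue[nb] == int(Region.FEMUR_CARTILAGE) for nb in adjacency[e]
                ):
                    log["femur_patella_merge"] = t
                    break
        if "interzone_start" not in log and (
            tissue == int(Region.INTERZONE)
        ).any():
            log["interzone_start"] = t
        if "detachment" not in log:
            comp, detached = patella_component(tissue, mesh, adjacency)
            if len(comp) and detached:
                log["detachment"] = t

    for step in range(1, params.n_steps + 1):
        t = step * params.dt
        ver = state.version
        for sp_name in SPECIES:
            if sp_name == "FGF" and not state.fgf_active:
                continue
            dn = sets[sp_name] if (sp_name != "FGF" or state.fgf_active) else None
            state.molecules[sp_name] = step_diffusion(
                state.molecules[sp_name],
                mesh,
                params.dt,
                solver,
                tissue=state.tissue,
                dirichlet_nodes=dn,
                dirichlet_value=params.sources[sp_name],
                cache_key=(sp_name, ver),
            )
        state.cells = step_chemotaxis(
            state.cells,
            state.molecules["TGFB"],
            mesh,
            params.dt,
            solver,
            mobile_elements=mobile,
            cache_key=("CELLS", 0),
        )
        update_sources(state, mesh, params, solver)
        apply_differentiation(state, params.thresholds, mesh, solver)
        state.time = t
        record_events(t)
        if step % params.snapshot_every == 0 or step == params.n_steps:
            history.times.append(t)
            history.tissue_snapshots.append(state.tissue.copy())

    comp, detached = patella_component(state.tissue, mesh, adjacency)
    history.patella_elements = comp
    history.patella_element_count = int(len(comp))
    if detached and len(comp) and "detachment" not in history.event_log:
        history.event_log["detachment"] = state.time

    # warn when the tendon never spanned muscle -> tibia (the tibial
    # insertion eminence counts: the tendon attaches via that cartilage)
    tendon_cols = set(
        mesh.tendon_ij[
            np.flatnonzero(
                np.isin(
                    state.tissue[: mesh.n_tendon_elements],
                    [int(Region.TENDON), int(Region.CARTILAGE_TIBIA)],
                )
            ),
            0,
        ].tolist()
    )
    n_cols = mesh.config.n_along_length
    spanned = all(
        c in tendon_cols for c in (0, n_cols - 1)
    ) and len(tendon_cols) > 0.9 * n_cols
    if not spanned:
        history.warnings.append(
            "horizon reached before the tendon spanned muscle to tibia"
        )
    history.final_state = state if keep_fields else FieldState(
        molecules={}, cells=state.cells, tissue=state.tissue,
        fgf_active=state.fgf_active, time=state.time,
    )
    return history
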