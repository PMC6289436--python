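"""Tissue differentiation rules, sources, sensing, and the run loop."""

import numpy as np
import pytest

from patellasim.biochem import (
    BiochemParams,
    CellDensityField,
    DifferentiationThresholds,
    FieldState,
    MoleculeField,
    SPECIES,
    apply_differentiation,
    make_initial_state,
    patella_component,
    run_theory1,
    source_node_sets,
    update_sources,
)
from patellasim.geometry import KneeGeometryConfig, Region, build_knee_mesh
from patellasim.transport import TransportSolver

THRESHOLDS = DifferentiationThresholds(
    b_c_th=0.5, s_bmp_th=5.0, s_fgf_th=2.0, s_gdf5_th=5.0
)


@pytest.fixture(scope="module")
def small_knee():
    cfg = KneeGeometryConfig(
        n_through_thickness=2, n_along_length=12, include_femur_region=True,
        n_femur_radial=2,
    )
    mesh = build_knee_mesh(cfg)
    return mesh, TransportSolver(mesh)


def _blank_state(mesh, params=None):
    params = params or BiochemParams(
        diffusion={s: 0.1 for s in SPECIES},
        sources={s: 10.0 for s in SPECIES},
        thresholds=THRESHOLDS,
        mu=0.01, chi=0.0, b0=1.0,
    )
    return make_initial_state(mesh, params), params


def _set_element(mesh, values, element, value):
    values[mesh.elements[element]] = value


class TestDifferentiationRules:
    def test_bmp_with_cells_makes_cartilage_even_when_fgf_high(self, small_knee):
        mesh, solver = small_knee
        state, _ = _blank_state(mesh)
        e = int(np.flatnonzero(mesh.element_segment == 1)[0])  # arc element
        _set_element(mesh, state.cells.b, e, 1.0)
        _set_element(mesh, state.molecules["BMP"].values, e, 6.0)
        _set_element(mesh, state.molecules["FGF"].values, e, 6.0)
        apply_differentiation(state, THRESHOLDS, mesh, solver)
        assert state.tissue[e] == int(Region.CARTILAGE_PATELLA)

    def test_cell_density_gate_blocks_differentiation(self, small_knee):
        mesh, solver = small_knee
        state, _ = _blank_state(mesh)
        e = int(np.flatnonzero(mesh.element_segment == 1)[1])
        state.cells.b[:] = 0.0
        _set_element(mesh, state.molecules["BMP"].values, e, 9.0)
        _set_element(mesh, state.molecules["FGF"].values, e, 9.0)
        before = state.tissue[e]
        apply_differentiation(state, THRESHOLDS, mesh, solver)
        assert state.tissue[e] == before

    def test_fgf_with_cells_makes_tendon(self, small_knee):
        mesh, solver = small_knee
        state, _ = _blank_state(mesh)
        e = 0
        _set_element(mesh, state.cells.b, e, 1.0)
        _set_element(mesh, state.molecules["FGF"].values, e, 3.0)
        apply_differentiation(state, THRESHOLDS, mesh, solver)
        assert state.tissue[e] == int(Region.TENDON)

    def test_gdf5_converts_cartilage_to_interzone(self, small_knee):
        mesh, solver = small_knee
        state, _ = _blank_state(mesh)
        e = int(np.flatnonzero(mesh.element_segment == 1)[2])
        state.tissue[e] = int(Region.CARTILAGE_PATELLA)
        _set_element(mesh, state.molecules["GDF5"].values, e, 6.0)
        apply_differentiation(state, THRESHOLDS, mesh, solver)
        assert state.tissue[e] == int(Region.INTERZONE)

    def test_gdf5_does_not_touch_mesenchyme_or_tendon(self, small_knee):
        mesh, solver = small_knee
        state, _ = _blank_state(mesh)
        e_mes = int(np.flatnonzero(state.tissue == int(Region.MESENCHYME))[0])
        state.molecules["GDF5"].values[:] = 9.0
        apply_differentiation(state, THRESHOLDS, mesh, solver)
        assert state.tissue[e_mes] == int(Region.MESENCHYME)

    def test_tibial_label_near_tibia_end(self, small_knee):
        mesh, solver = small_knee
        state, _ = _blank_state(mesh)
        last = mesh.n_tendon_elements - 1  # tibia-end element
        _set_element(mesh, state.cells.b, last, 1.0)
        _set_element(mesh, state.molecules["BMP"].values, last, 6.0)
        apply_differentiation(state, THRESHOLDS, mesh, solver)
        assert state.tissue[last] == int(Region.CARTILAGE_TIBIA)


class TestSources:
    def test_fgf_inactive_without_cells(self, small_knee):
        mesh, solver = small_knee
        state, params = _blank_state(mesh)
        state.cells.b[:] = 0.0
        update_sources(state, mesh, params, solver)
        assert not state.fgf_active
        assert np.all(state.molecules["FGF"].values == 0.0)

    def test_fgf_activates_permanently_when_muscle_senses_cells(self, small_knee):
        mesh, solver = small_knee
        state, params = _blank_state(mesh)
        state.cells.b[:] = 1.0
        update_sources(state, mesh, params, solver)
        assert state.fgf_active
        muscle = mesh.boundary_tags["MUSCLE_END"]
        assert np.all(state.molecules["FGF"].values[muscle] == 10.0)
        state.cells.b[:] = 0.0  # cells leave; source stays on
        update_sources(state, mesh, params, solver)
        assert state.fgf_active

    def test_dirichlet_sources_retain_values(self, small_knee):
        mesh, solver = small_knee
        state, params = _blank_state(mesh)
        update_sources(state, mesh, params, solver)
        sets = source_node_sets(mesh)
        for name in ("TGFB", "BMP", "GDF5"):
            assert np.all(state.molecules[name].values[sets[name]] == 10.0)


@pytest.fixture(scope="module")
def short_history():
    params = BiochemParams.default()
    params.n_steps = 400
    params.snapshot_every = 40
    cfg = KneeGeometryConfig(include_femur_region=True)
    return run_theory1(cfg, params)


class TestRunLoop:
    def test_transitions_are_irreversible(self, short_history):
        # per-state element counts never decrease for terminal tissues
        for state_id in (Region.TENDON, Region.CARTILAGE_PATELLA,
                         Region.CARTILAGE_TIBIA, Region.INTERZONE):
            counts = [int((snap == int(state_id)).sum())
                      for snap in short_history.tissue_snapshots]
            assert counts == sorted(counts)

    def test_event_sequence_starts_with_tendon(self, short_history):
        log = short_history.event_log
        assert "tendon_start" in log and "patella_cartilage_start" in log
        assert log["tendon_start"] < log["patella_cartilage_start"]

    def test_no_cells_means_no_differentiation(self):
        cfg = KneeGeometryConfig(
            include_femur_region=True, n_through_thickness=4, n_along_length=40,
            n_femur_radial=2,
        )
        params = BiochemParams.default()
        params.b0 = 0.0
        params.growth_rate = 0.0
        params.n_steps = 50
        history = run_theory1(cfg, params)
        tissue = history.final_state.tissue
        assert not np.isin(
            tissue,
            [int(Region.TENDON), int(Region.CARTILAGE_PATELLA),
             int(Region.CARTILAGE_TIBIA)],
        ).any()


class TestPatellaComponent:
    def test_component_touching_femur_is_disqualified(self, small_knee):
        mesh, _ = small_knee
        tissue = mesh.element_region.copy()
        arc = np.flatnonzero(mesh.element_segment == 1)
        inner = [e for e in arc if mesh.tendon_ij[e][1] == 0]
        tissue[inner[0]] = int(Region.CARTILAGE_PATELLA)  # touches femur
        comp, detached = patella_component(tissue, mesh)
        assert len(comp) == 0

    def test_interzone_band_detaches_component(self, small_knee):
        mesh, _ = small_knee
        tissue = mesh.element_region.copy()
        arc = np.flatnonzero(mesh.element_segment == 1)
        inner = [e for e in arc if mesh.tendon_ij[e][1] == 0]
        outer = [e for e in arc if mesh.tendon_ij[e][1] == 1]
        for e in inner:
            tissue[e] = int(Region.INTERZONE)
        for e in outer[:3]:
            tissue[e] = int(Region.CARTILAGE_PATELLA)
        comp, detached = patella_component(tissue, mesh)
        assert len(comp) == 3
        assert detached
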