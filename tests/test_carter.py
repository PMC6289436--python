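"""Carter mechanoregulation: averaging operator, thresholding, scenarios."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from patellasim.carter import (
    AngleWeighting,
    CarterParams,
    SCENARIOS,
    carter_differentiate,
    run_theory2,
    weighted_average_field,
)
from patellasim.geometry import KneeGeometryConfig, build_knee_mesh


@pytest.fixture(scope="module")
def coarse_cfg():
    return KneeGeometryConfig(n_through_thickness=4, n_along_length=40)


@pytest.fixture(scope="module")
def coarse_mesh_local(coarse_cfg):
    return build_knee_mesh(coarse_cfg)


class TestWeighting:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            AngleWeighting(angles=(30.0, 90.0), weights=(0.5, 0.6))

    def test_single_angle_identity(self):
        f = np.arange(10.0)
        w = AngleWeighting(angles=(90.0,), weights=(1.0,))
        assert np.array_equal(weighted_average_field([f], w), f)

    def test_convex_combination(self):
        f = np.linspace(-3, 5, 17)
        w = AngleWeighting(angles=(30.0, 90.0), weights=(0.25, 0.75))
        out = weighted_average_field([f, 3 * f], w)
        assert np.allclose(out, 2.5 * f, atol=1e-12)

    def test_identical_fields_unchanged(self):
        f = np.random.default_rng(3).normal(size=40)
        w = AngleWeighting(angles=(30.0, 90.0), weights=(0.5, 0.5))
        assert np.allclose(weighted_average_field([f, f.copy()], w), f)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=5))
    def test_average_bounded_by_envelope(self, raw_weights):
        w = np.array(raw_weights) / sum(raw_weights)
        rng = np.random.default_rng(7)
        fields = [rng.normal(size=30) for _ in w]
        weighting = AngleWeighting(
            angles=tuple(range(len(w))), weights=tuple(w / w.sum())
        )
        out = weighted_average_field(fields, weighting)
        stack = np.stack(fields)
        assert np.all(out <= stack.max(axis=0) + 1e-12)
        assert np.all(out >= stack.min(axis=0) - 1e-12)


class TestDifferentiate:
    def test_unreachable_threshold_gives_empty_mask(self, coarse_mesh_local):
        sig = -np.ones(coarse_mesh_local.n_elements)
        eps = np.zeros(coarse_mesh_local.n_elements)
        mask = carter_differentiate(sig, eps, CarterParams(), coarse_mesh_local,
                                    threshold=-100.0)
        assert mask.element_count == 0
        assert np.isnan(mask.centroid).all()

    def test_zero_threshold_counts_compressed_elements(self, coarse_mesh_local):
        rng = np.random.default_rng(11)
        sig = rng.normal(size=coarse_mesh_local.n_elements)
        eps = np.zeros(coarse_mesh_local.n_elements)
        params = CarterParams(epsilon_tensile_max=np.inf)
        mask = carter_differentiate(sig, eps, params, coarse_mesh_local,
                                    threshold=-1e-300)
        tendon = sig[: coarse_mesh_local.n_tendon_elements]
        assert mask.element_count == int((tendon <= 0).sum())

    def test_mask_grows_as_threshold_relaxes(self, coarse_mesh_local):
        rng = np.random.default_rng(5)
        sig = rng.normal(scale=2.0, size=coarse_mesh_local.n_elements)
        eps = np.abs(rng.normal(scale=0.02, size=coarse_mesh_local.n_elements))
        params = CarterParams()
        sizes = [
            carter_differentiate(sig, eps, params, coarse_mesh_local, threshold=t)
            .element_count
            for t in (-3.0, -2.0, -1.0, -0.5)
        ]
        assert sizes == sorted(sizes)

    def test_mask_grows_with_strain_allowance(self, coarse_mesh_local):
        rng = np.random.default_rng(6)
        sig = rng.normal(scale=2.0, size=coarse_mesh_local.n_elements)
        eps = np.abs(rng.normal(scale=0.05, size=coarse_mesh_local.n_elements))
        sizes = [
            carter_differentiate(
                sig, eps, CarterParams(epsilon_tensile_max=em),
                coarse_mesh_local, threshold=-1.0,
            ).element_count
            for em in (0.01, 0.05, 0.1, np.inf)
        ]
        assert sizes == sorted(sizes)


@pytest.fixture(scope="module")
def scenario_results(coarse_cfg):
    return {name: run_theory2(coarse_cfg, name) for name in SCENARIOS}


class TestRunTheory2:
    def test_published_scenario_area_ordering(self, scenario_results):
        # the smallest patella occurs when weighting the smallest angles
        areas = {k: r.mask.area_mm2 for k, r in scenario_results.items()}
        assert (
            areas["weighting_low_flexion"]
            <= areas["weighting_high_flexion"]
            <= areas["heavily_weighting_high_flexion"]
        )
        assert areas["weighting_low_flexion"] < areas[
            "heavily_weighting_high_flexion"
        ]

    def test_mask_confined_to_contact_arc(self, scenario_results):
        for r in scenario_results.values():
            mesh = r.reference_mesh
            on = np.flatnonzero(r.mask.mask[: mesh.n_tendon_elements])
            assert len(on) > 0
            arc_frac = (mesh.element_segment[on] == 1).mean()
            assert arc_frac > 0.9

    def test_all_weight_on_reference_equals_single_solve(self, coarse_cfg):
        w = AngleWeighting(angles=(90.0,), weights=(1.0,))
        res = run_theory2(coarse_cfg, w)
        from patellasim.fem import FiberSpec, default_knee_bcs, solve_elasticity
        from patellasim.fem import stress_strain_measures

        mesh = res.reference_mesh
        sol = solve_elasticity(mesh, fiber=FiberSpec(), bcs=default_knee_bcs(mesh))
        sig, eps1 = stress_strain_measures(sol, phase="matrix")
        direct = carter_differentiate(sig, eps1, CarterParams(), mesh,
                                      threshold=res.mask.threshold_used)
        assert np.array_equal(res.mask.mask, direct.mask)

    def test_averaged_field_projection_shapes(self, scenario_results):
        r = next(iter(scenario_results.values()))
        assert r.averaged_sigma_hyd.shape == (r.reference_mesh.n_elements,)
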