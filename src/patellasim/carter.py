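"""Carter mechanoregulation of the wrapped tendon (mechanical theory).

Fibrous tissue under high compressive hydrostatic stress and low principal
tensile strain differentiates into cartilage.  The tendon is solved
elastically at a set of knee flexion angles, the per-element hydrostatic
stress is projected onto the 90-degree reference mesh through the
structured element correspondence, averaged with scenario weights that
represent the share of time the embryonic knee spends at each angle, and
thresholded into the predicted patella mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    ElementCorrespondence,
    KneeGeometryConfig,
    QuadMesh,
    build_knee_mesh,
    element_correspondence,
    with_angle,
)
from .fem import (
    ElasticSolution,
    FiberSpec,
    default_knee_bcs,
    solve_elasticity,
    stress_strain_measures,
)

__all__ = [
    "CarterParams",
    "AngleWeighting",
    "PatellaMask",
    "SCENARIOS",
    "SWEEP_ANGLES",
    "weighted_average_field",
    "carter_differentiate",
    "run_theory2",
]

#: flexion angles of the published sweep (degrees)
SWEEP_ANGLES = (30.0, 45.0, 60.0, 90.0, 110.0)

#: named weighting scenarios over SWEEP_ANGLES
SCENARIOS = {
    "weighting_high_flexion": (0.05, 0.10, 0.15, 0.25, 0.45),
    "weighting_low_flexion": (0.60, 0.25, 0.09, 0.05, 0.01),
    "heavily_weighting_high_flexion": (0.01, 0.05, 0.09, 0.25, 0.60),
}


@dataclass(frozen=True)
class CarterParams:
    """Differentiation thresholds of the mechanoregulation rule.

    ``sigma_hyd_cart`` is the compressive hydrostatic-stress threshold
    (negative, MPa); when ``None`` it is set per run to
    ``-threshold_fraction * |peak compressive stress at 90 degrees|``, a
    scale-free default recorded in the run summary.  ``epsilon_tensile_max``
    caps the maximum principal tensile strain allowed for differentiation.
    ``stress_phase`` selects the matrix-phase or total (fiber-inclusive)
    hydrostatic stress as the stimulus.
    """

    sigma_hyd_cart: float | None = None
    threshold_fraction: float = 0.3
    epsilon_tensile_max: float = 0.08
    stress_phase: str = "matrix"

    def __post_init__(self) -> None:
        if self.sigma_hyd_cart is not None and self.sigma_hyd_cart >= 0:
            raise ValueError("sigma_hyd_cart must be negative (compression)")
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must lie in (0, 1)")
        if self.epsilon_tensile_max <= 0:
            raise ValueError("epsilon_tensile_max must be positive")


@dataclass(frozen=True)
class AngleWeighting:
    """Convex weights over a list of flexion angles."""

    angles: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.angles) != len(self.weights):
            raise ValueError("one weight per angle required")
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")

    @classmethod
    def scenario(cls, name: str) -> "AngleWeighting":
        return cls(angles=SWEEP_ANGLES, weights=SCENARIOS[name])


@dataclass
class PatellaMask:
    """Boolean per-element cartilage-differentiation mask with summary."""

    mask: np.ndarray  # (E,) bool over the reference mesh, tendon only
    element_count: int
    area_mm2: float
    centroid: np.ndarray  # (2,), nan when the mask is empty
    threshold_used: float
    epsilon_max_used: float


def weighted_average_field(
    fields: list[np.ndarray],
    weighting: AngleWeighting,
    correspondences: list[ElementCorrespondence] | None = None,
) -> np.ndarray:
    """Per-element convex combination of per-angle element fields mapped
    onto the reference mesh by the given correspondences."""
    if len(fields) != len(weighting.angles):
        raise ValueError("one field per angle required")
    out = np.zeros_like(fields[0], dtype=float)
    for k, (f, w) in enumerate(zip(fields, weighting.weights)):
        if correspondences is not None:
            mapped = np.empty_like(f)
            mapped[correspondences[k].mapping] = f
            f = mapped
        out += w * f
    return out


def carter_differentiate(
    sigma_hyd: np.ndarray,
    epsilon_1: np.ndarray,
    params: CarterParams,
    mesh: QuadMesh,
    threshold: float | None = None,
) -> PatellaMask:
    """Apply the phase rule: cartilage where the hydrostatic stress is at
    least as compressive as the threshold and the principal tensile strain
    stays below ``epsilon_tensile_max``."""
    thr = threshold if threshold is not None else params.sigma_hyd_cart
    if thr is None:
        raise ValueError("no hydrostatic threshold resolved; pass one explicitly")
    tendon = np.zeros(mesh.n_elements, dtype=bool)
    tendon[: mesh.n_tendon_elements] = True
    mask = tendon & (sigma_hyd <= thr) & (epsilon_1 <= params.epsilon_tensile_max)
    areas = mesh.element_areas()
    count = int(mask.sum())
    area = float(areas[mask].sum())
    centroid = (
        mesh.element_centroids()[mask].mean(axis=0) if count else np.full(2, np.nan)
    )
    return PatellaMask(
        mask=mask,
        element_count=count,
        area_mm2=area,
        centroid=centroid,
        threshold_used=float(thr),
        epsilon_max_used=params.epsilon_tensile_max,
    )


@dataclass
class Theory2Result:
    mask: PatellaMask
    averaged_sigma_hyd: np.ndarray
    solutions: dict[float, ElasticSolution]
    reference_mesh: QuadMesh
    scenario: AngleWeighting


def run_theory2(
    config: KneeGeometryConfig,
    scenario: AngleWeighting | str = "weighting_high_flexion",
    params: CarterParams = CarterParams(),
    fiber: FiberSpec | None = None,
    pull_mm: float = 1.0,
    reference_angle: float = 90.0,
) -> Theory2Result:
    """Solve every scenario angle, project onto the reference mesh, average
    with the scenario weights, and differentiate.

    The hydrostatic threshold, when not given absolutely, is 30% of the
    peak compressive stimulus of the reference-angle solve.
    """
    if isinstance(scenario, str):
        scenario = AngleWeighting.scenario(scenario)
    fiber = fiber or FiberSpec()
    ref_mesh = build_knee_mesh(with_angle(config, reference_angle))

    sig_fields, eps_fields, correspondences = [], [], []
    solutions: dict[float, ElasticSolution] = {}
    for angle in scenario.angles:
        mesh = (
            ref_mesh
            if angle == reference_angle
            else build_knee_mesh(with_angle(config, angle))
        )
        sol = solve_elasticity(
            mesh, fiber=fiber, bcs=default_knee_bcs(mesh, pull_mm=pull_mm)
        )
        solutions[angle] = sol
        sig, eps1 = stress_strain_measures(sol, phase=params.stress_phase)
        sig_fields.append(sig)
        eps_fields.append(eps1)
        correspondences.append(element_correspondence(mesh, ref_mesh))

    sigma_avg = weighted_average_field(sig_fields, scenario, correspondences)
    eps_avg = weighted_average_field(eps_fields, scenario, correspondences)

    thr = params.sigma_hyd_cart
    if thr is None:
        if reference_angle in solutions:
            ref_sol = solutions[reference_angle]
        else:
            ref_sol = solve_elasticity(
                ref_mesh, fiber=fiber, bcs=default_knee_bcs(ref_mesh, pull_mm=pull_mm)
            )
        ref_sig, _ = stress_strain_measures(ref_sol, phase=params.stress_phase)
        peak = float(ref_sig[: ref_mesh.n_tendon_elements].min())
        if peak >= 0:
            raise ValueError("no compressive stress at the reference angle")
        thr = params.threshold_fraction * peak

    mask = carter_differentiate(sigma_avg, eps_avg, params, ref_mesh, threshold=thr)
    return Theory2Result(
        mask=mask,
        averaged_sigma_hyd=sigma_avg,
        solutions=solutions,
        reference_mesh=ref_mesh,
        scenario=scenario,
    )
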