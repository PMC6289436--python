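"""Run configuration: YAML loading, schema validation, defaults.

Two packaged defaults files feed every run: ``literature_defaults.yaml`` holds
published constants (geometry, tissue properties, scenario weights) and
``calibrated_defaults.yaml`` holds the stand-in values this package
calibrated itself (molecular parameters, thresholds, optimizer settings).
A user YAML file overrides any subset; unknown keys and out-of-range
values are reported together in one validation error.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .geometry import KneeGeometryConfig
from .biochem import BiochemParams, DifferentiationThresholds
from .carter import CarterParams
from .topopt import SimpParams

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "literature_defaults",
    "calibrated_defaults",
]


class ConfigError(ValueError):
    """Carries every validation violation found in a config file."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(violations))


def _load_packaged(name: str) -> dict:
    text = resources.files("patellasim.defaults").joinpath(name).read_text()
    return yaml.safe_load(text)


def literature_defaults() -> dict:
    return _load_packaged("literature_defaults.yaml")


def calibrated_defaults() -> dict:
    return _load_packaged("calibrated_defaults.yaml")


_KNOWN_TOP_KEYS = {
    "theory",
    "flexion_angle_deg",
    "geometry",
    "biochem",
    "carter",
    "simp",
    "scenario",
    "output_directory",
    "snapshot_interval",
    "log_level",
}


@dataclass
class RunConfig:
    """Fully resolved configuration for one simulation run."""

    theory: int
    geometry: KneeGeometryConfig
    biochem: BiochemParams | None = None
    carter: CarterParams | None = None
    simp: SimpParams | None = None
    scenario: str = "weighting_high_flexion"
    output_directory: str = "out"
    snapshot_interval: int = 100
    log_level: str = "INFO"
    raw: dict = field(default_factory=dict)

    def resolved_dict(self) -> dict:
        """Plain-YAML echo of the configuration, for provenance files."""
        out = copy.deepcopy(self.raw)
        out["theory"] = self.theory
        out.setdefault("geometry", {})
        g = self.geometry
        out["geometry"] = {
            "flexion_angle_deg": g.flexion_angle_deg,
            "condyle_radius": g.condyle_radius,
            "tendon_thickness": g.tendon_thickness,
            "quadriceps_segment_length": g.quadriceps_segment_length,
            "patellar_segment_length": g.patellar_segment_length,
            "n_through_thickness": g.n_through_thickness,
            "n_along_length": g.n_along_length,
            "include_femur_region": g.include_femur_region,
        }
        return out


def _build_geometry(raw: dict, violations: list[str], theory: int) -> KneeGeometryConfig | None:
    lit = literature_defaults()["geometry"]
    calib = calibrated_defaults()["geometry"]
    kwargs = {
        "condyle_radius": lit["condyle_radius"],
        "tendon_thickness": lit["tendon_thickness"],
        "quadriceps_segment_length": calib["quadriceps_segment_length"],
        "patellar_segment_length": calib["patellar_segment_length"],
        "n_through_thickness": calib["n_through_thickness"],
        "n_along_length": calib["n_along_length"],
        "femur_depth": calib["femur_depth"],
        "n_femur_radial": calib["n_femur_radial"],
        "scx_start_frac": calib["scx_start_frac"],
        "scx_end_frac": calib["scx_end_frac"],
        "include_femur_region": theory == 1,
    }
    geo_raw = dict(raw.get("geometry") or {})
    if "flexion_angle_deg" in raw:
        kwargs["flexion_angle_deg"] = raw["flexion_angle_deg"]
    allowed = set(KneeGeometryConfig.__dataclass_fields__)
    for key, val in geo_raw.items():
        if key not in allowed:
            violations.append(f"geometry.{key}: unknown key")
        else:
            kwargs[key] = val
    try:
        return KneeGeometryConfig(**kwargs)
    except (ValueError, TypeError) as err:
        violations.append(f"geometry: {err}")
        return None


def _build_biochem(raw: dict, violations: list[str]) -> BiochemParams | None:
    d = copy.deepcopy(calibrated_defaults()["biochem"])
    user = raw.get("biochem") or {}
    for key, val in user.items():
        if key not in d:
            violations.append(f"biochem.{key}: unknown key")
        elif isinstance(d[key], dict):
            d[key].update(val)
        else:
            d[key] = val
    try:
        return BiochemParams(
            diffusion=dict(d["diffusion"]),
            sources=dict(d["sources"]),
            thresholds=DifferentiationThresholds(**d["thresholds"]),
            mu=d["mu"],
            chi=d["chi"],
            b0=d["b0"],
            growth_rate=d.get("growth_rate", 0.0),
            b_max=d.get("b_max", float("inf")),
            low_diffusion_factor=d["low_diffusion_factor"],
            b_sense=d.get("b_sense"),
            sense_layers=d.get("sense_layers", 2),
            dt=d["dt"],
            n_steps=d["n_steps"],
            snapshot_every=d.get("snapshot_every", 100),
        )
    except (ValueError, TypeError, KeyError) as err:
        violations.append(f"biochem: {err}")
        return None


def _build_carter(raw: dict, violations: list[str]) -> CarterParams | None:
    d = dict(calibrated_defaults()["carter"])
    user = raw.get("carter") or {}
    allowed = set(CarterParams.__dataclass_fields__)
    for key, val in user.items():
        if key not in allowed:
            violations.append(f"carter.{key}: unknown key")
        else:
            d[key] = val
    try:
        return CarterParams(**d)
    except (ValueError, TypeError) as err:
        violations.append(f"carter: {err}")
        return None


def _build_simp(raw: dict, violations: list[str]) -> SimpParams | None:
    d = dict(calibrated_defaults()["simp"])
    d["penalization"] = literature_defaults()["simp"]["penalization"]
    user = raw.get("simp") or {}
    allowed = set(SimpParams.__dataclass_fields__)
    for key, val in user.items():
        if key not in allowed:
            violations.append(f"simp.{key}: unknown key")
        else:
            d[key] = val
    try:
        return SimpParams(**d)
    except (ValueError, TypeError) as err:
        violations.append(f"simp: {err}")
        return None


def build_config(raw: dict) -> RunConfig:
    """Validate a raw mapping and resolve it against the defaults."""
    violations: list[str] = []
    raw = raw or {}
    for key in raw:
        if key not in _KNOWN_TOP_KEYS:
            violations.append(f"{key}: unknown key")
    theory = raw.get("theory")
    if theory is None:
        violations.append("theory: missing (must be 1, 2 or 3)")
        theory = 0
    elif theory not in (1, 2, 3):
        violations.append(f"theory: must be 1, 2 or 3, got {theory!r}")
    scenario = raw.get("scenario", "weighting_high_flexion")
    if scenario not in literature_defaults()["scenarios"]:
        violations.append(
            f"scenario: unknown {scenario!r}; choose from "
            f"{sorted(literature_defaults()['scenarios'])}"
        )
    geometry = _build_geometry(raw, violations, theory)
    # validate any block the file mentions, even if the theory is wrong too
    biochem = (
        _build_biochem(raw, violations)
        if theory in (0, 1) or "biochem" in raw else None
    )
    carter = (
        _build_carter(raw, violations)
        if theory in (0, 2) or "carter" in raw else None
    )
    simp = (
        _build_simp(raw, violations)
        if theory in (0, 3) or "simp" in raw else None
    )
    if violations:
        raise ConfigError(violations)
    return RunConfig(
        theory=int(theory),
        geometry=geometry,
        biochem=biochem,
        carter=carter,
        simp=simp,
        scenario=scenario,
        output_directory=raw.get("output_directory", "out"),
        snapshot_interval=int(raw.get("snapshot_interval", 100)),
        log_level=str(raw.get("log_level", "INFO")),
        raw=dict(raw),
    )


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["file must contain a YAML mapping"])
    return build_config(raw)
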