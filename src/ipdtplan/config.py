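"""Structured run configuration with unit-suffixed keys.

YAML keys carry explicit unit suffixes (``*_cm``, ``*_mW_per_cm``,
``*_mW_cm2``, ``*_J_cm2``, ``*_s``) to prevent unit drift between the
config surface and the cm-based internals. Unknown keys are rejected;
defaults are the published planning values (soft-tissue/blood optical
properties, the 8.6 mW/cm^2 / 9.5 J/cm^2 critical-structure limits and
the 8.6 mW/cm^2 / 45 J/cm^2 effective rate-based dose thresholds).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .geometry import CDFPlacement
from .optics import DEFAULT_PROPERTIES, OpticalProperties
from .optimize import SafetyLimits


@dataclass
class SceneConfig:
    fixture: str = "phantom"  # 'phantom' | 'airway' | 'mesh'
    mesh_path: str | None = None
    params: dict = field(default_factory=dict)


@dataclass
class SolverConfig:
    mode: str = "steady"
    target_h_cm: float | None = None


@dataclass
class RunConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    properties: dict[str, OpticalProperties] = field(
        default_factory=lambda: dict(DEFAULT_PROPERTIES)
    )
    fibers: list[CDFPlacement] = field(default_factory=list)
    limits: SafetyLimits = field(default_factory=SafetyLimits)
    solver: SolverConfig = field(default_factory=SolverConfig)
    output_dir: str = "ipdtplan_out"

    def config_hash(self) -> str:
        """Stable hash of the normalized configuration (for artifacts)."""
        blob = json.dumps(_normalize(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _normalize(cfg: RunConfig) -> dict:
    return {
        "scene": asdict(cfg.scene),
        "properties": {
            k: {
                "mu_a_per_cm": v.mu_a,
                "mu_s_prime_per_cm": v.mu_s_prime,
                "refractive_index": v.refractive_index,
            }
            for k, v in sorted(cfg.properties.items())
        },
        "fibers": [
            {
                "entry_point_cm": list(map(float, f.p0)),
                "axis": list(map(float, f.axis)),
                "diffuser_length_cm": f.diffuser_length,
                "diffuser_diameter_cm": f.diffuser_diameter,
                "intensity_mW_per_cm": f.intensity,
                "treatment_time_s": f.treatment_time,
            }
            for f in cfg.fibers
        ],
        "limits": asdict(cfg.limits),
        "solver": asdict(cfg.solver),
        "output_dir": cfg.output_dir,
    }


_LIMIT_KEYS = {
    "cs_irradiance_max_mW_cm2": "cs_irradiance_max",
    "cs_fluence_max_J_cm2": "cs_fluence_max",
    "effective_irradiance_mW_cm2": "effective_irradiance",
    "effective_fluence_J_cm2": "effective_fluence",
    "intensity_max_mW_per_cm": "intensity_max",
    "intensity_min_mW_per_cm": "intensity_min",
    "power_increment_mW": "power_increment",
}

_PROP_KEYS = {"mu_a_per_cm", "mu_s_prime_per_cm", "refractive_index"}
_FIBER_KEYS = {
    "entry_point_cm",
    "axis",
    "diffuser_length_cm",
    "diffuser_diameter_cm",
    "intensity_mW_per_cm",
    "treatment_time_s",
}
_TOP_KEYS = {"scene", "properties", "fibers", "limits", "solver", "output_dir"}
_SCENE_KEYS = {"fixture", "mesh_path", "params"}
_SOLVER_KEYS = {"mode", "target_h_cm"}


def validate_config(raw: dict | str | Path) -> RunConfig:
    """Normalize a raw (or YAML-file) configuration; raise with an itemized
    error list on unknown keys, bad units or negative physical quantities."""
    if isinstance(raw, (str, Path)):
        raw = yaml.safe_load(Path(raw).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a mapping")
    errors: list[str] = []
    for k in raw:
        if k not in _TOP_KEYS:
            errors.append(f"unknown key {k!r}")

    cfg = RunConfig()
    sc = raw.get("scene", {})
    if isinstance(sc, dict):
        for k in sc:
            if k not in _SCENE_KEYS:
                errors.append(f"scene: unknown key {k!r}")
        cfg.scene = SceneConfig(
            fixture=sc.get("fixture", "phantom"),
            mesh_path=sc.get("mesh_path"),
            params=sc.get("params", {}) or {},
        )
        if cfg.scene.fixture not in ("phantom", "airway", "mesh"):
            errors.append(f"scene.fixture {cfg.scene.fixture!r} not recognized")
        if cfg.scene.fixture == "mesh" and not cfg.scene.mesh_path:
            errors.append("scene.fixture 'mesh' requires scene.mesh_path")
    else:
        errors.append("scene must be a mapping")

    props = dict(DEFAULT_PROPERTIES)
    for region, spec in (raw.get("properties") or {}).items():
        unknown = set(spec) - _PROP_KEYS
        if unknown:
            errors.append(f"properties.{region}: unknown keys {sorted(unknown)}")
            continue
        base = props.get(region)
        mu_a = spec.get("mu_a_per_cm", base.mu_a if base else None)
        mu_sp = spec.get("mu_s_prime_per_cm", base.mu_s_prime if base else None)
        n = spec.get(
            "refractive_index", base.refractive_index if base else 1.37
        )
        if mu_a is None or mu_sp is None:
            errors.append(f"properties.{region}: incomplete specification")
            continue
        try:
            props[region] = OpticalProperties.from_reduced(mu_a, mu_sp, n)
        except ValueError as e:
            errors.append(f"properties.{region}: {e}")
    cfg.properties = props

    fibers = []
    for i, f in enumerate(raw.get("fibers") or []):
        unknown = set(f) - _FIBER_KEYS
        if unknown:
            errors.append(f"fibers[{i}]: unknown keys {sorted(unknown)}")
            continue
        try:
            fibers.append(
                CDFPlacement(
                    entry_point=tuple(f["entry_point_cm"]),
                    axis=tuple(f["axis"]),
                    diffuser_length=f["diffuser_length_cm"],
                    diffuser_diameter=f.get("diffuser_diameter_cm", 0.098),
                    intensity=f.get("intensity_mW_per_cm", 0.0),
                    treatment_time=f.get("treatment_time_s", 0.0),
                )
            )
        except (KeyError, ValueError, TypeError) as e:
            errors.append(f"fibers[{i}]: {e}")
    cfg.fibers = fibers

    lim = raw.get("limits") or {}
    kw = {}
    for k, v in lim.items():
        if k not in _LIMIT_KEYS:
            errors.append(f"limits: unknown key {k!r} (unit-suffixed keys required)")
        else:
            kw[_LIMIT_KEYS[k]] = v
    try:
        cfg.limits = SafetyLimits(**kw)
    except (ValueError, TypeError) as e:
        errors.append(f"limits: {e}")

    sol = raw.get("solver") or {}
    for k in sol:
        if k not in _SOLVER_KEYS:
            errors.append(f"solver: unknown key {k!r}")
    cfg.solver = SolverConfig(
        mode=sol.get("mode", "steady"), target_h_cm=sol.get("target_h_cm")
    )
    if cfg.solver.mode not in ("steady", "transient"):
        errors.append(f"solver.mode {cfg.solver.mode!r} not recognized")
    th = cfg.solver.target_h_cm
    if th is not None and th <= 0:
        errors.append("solver.target_h_cm must be positive")

    cfg.output_dir = raw.get("output_dir", "ipdtplan_out")
    if errors:
        raise ValueError(
            "invalid configuration:\n  - " + "\n  - ".join(errors)
        )
    return cfg
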