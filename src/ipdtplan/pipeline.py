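"""End-to-end planning pipeline and artifact writing.

``run_pipeline`` ties the tested stages together: build (or load) the
scene, solve one steady field per fiber, optimize powers and times when a
tumor region is present (or produce the phantom validation report when the
scene is the calibration phantom), and write the artifact set — mesh,
per-fiber fields (VTU), DVH table (CSV), plan (JSON), and a stage log that
echoes every design-decision value (diffuser diameter, surface-irradiance
conversion, tie rule). Runs are deterministic; every artifact embeds the
configuration hash.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dose as dose_mod
from .agreement import phantom_validation_report
from .config import RunConfig
from .dose import solve_per_cdf_maps
from .fem import probe_field
from .geometry import Scene
from .io import write_probe_csv, write_scene, write_vtu
from .optimize import optimize_plan
from .scenes import make_airway_scene, make_phantom_scene


@dataclass
class PipelineResult:
    scene: Scene
    maps: object
    plan: object | None
    validation: tuple | None
    artifacts: dict[str, Path] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def _build_scene(cfg: RunConfig) -> Scene:
    kind = cfg.scene.fixture
    params = dict(cfg.scene.params)
    if kind == "phantom":
        if cfg.solver.target_h_cm is not None:
            params.setdefault("target_h", cfg.solver.target_h_cm)
        return make_phantom_scene(**params)
    if kind == "airway":
        if cfg.solver.target_h_cm is not None:
            params.setdefault("target_h", cfg.solver.target_h_cm)
        return make_airway_scene(cdfs=cfg.fibers, **params)
    from .io import read_scene

    return read_scene(cfg.scene.mesh_path)


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the configured run and write artifacts to the output directory."""
    out = Path(out_dir if out_dir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    log: list[str] = []
    events: list[dict] = []

    current = {"stage": "setup"}

    def stage(name: str, msg: str = "") -> None:
        current["stage"] = name
        log.append(f"[{time.strftime('%H:%M:%S')}] {name} {msg}".rstrip())
        events.append({"stage": name, "message": msg, "config_hash": chash})

    try:
        stage("scene", f"fixture={cfg.scene.fixture}")
        scene = _build_scene(cfg)
        if cfg.fibers and cfg.scene.fixture == "mesh":
            scene.cdfs = list(cfg.fibers)
        if not scene.cdfs:
            raise ValueError("no fiber placements; add fibers to the configuration")
        stage(
            "scene",
            f"{scene.n_nodes} nodes, {scene.n_tets} tets; "
            f"diffuser_diameter={scene.cdfs[0].diffuser_diameter} cm; "
            "p_laser = power / (lateral + cap area); domination ties excluded",
        )
        artifacts: dict[str, Path] = {}
        mesh_path = out / "scene.msh"
        write_scene(scene, mesh_path)
        artifacts["mesh"] = mesh_path

        stage("solve", "one steady solve per fiber")
        maps = solve_per_cdf_maps(scene, cfg.properties)
        for k in range(maps.n_fibers):
            p = out / f"field_{k}.vtu"
            write_vtu(
                scene, p, {"irradiance_mW_cm2": maps.unit_fields[k], }
            )
            artifacts[f"field_{k}"] = p

        plan = None
        validation = None
        if "tumor" in scene.region_names.values():
            stage("optimize", "domination sub-maps power/time optimization")
            plan = optimize_plan(maps, cfg.limits)
            final = maps.with_intensities(plan.intensities_mw_per_cm).with_times(
                plan.times_s
            )
            flu = dose_mod.total_fluence(final)
            thresholds = np.linspace(1.0, 100.0, 34)
            curve = dose_mod.dvh_curve(flu, "tumor", thresholds)
            import pandas as pd

            dvh_path = out / "dvh.csv"
            pd.DataFrame(
                {
                    "fluence_J_cm2": curve.thresholds,
                    "tumor_volume_fraction": curve.volume_fraction,
                }
            ).to_csv(dvh_path, index=False)
            artifacts["dvh"] = dvh_path
            plan_path = out / "plan.json"
            blob = plan.to_dict()
            blob["config_hash"] = chash
            blob["units"] = {
                "power": "mW",
                "intensity": "mW/cm",
                "time": "s",
                "irradiance": "mW/cm^2",
                "fluence": "J/cm^2",
            }
            plan_path.write_text(json.dumps(blob, indent=1, sort_keys=True))
            artifacts["plan"] = plan_path
            stage("optimize", f"powers {plan.powers_mw.tolist()} mW")
        elif scene.detectors is not None:
            stage("validate", "phantom detector comparison")
            from .fem import ScalarField

            fld = ScalarField(scene, maps.unit_fields[0], "irradiance")
            sim = probe_field(fld, scene.detectors)
            table, ccc_res = phantom_validation_report(sim)
            probe_path = out / "phantom_probes.csv"
            write_probe_csv(table["distance_mm"], sim, probe_path)
            artifacts["probes"] = probe_path
            report_path = out / "validation.json"
            report_path.write_text(
                json.dumps(
                    {
                        "config_hash": chash,
                        "ccc": ccc_res.ccc,
                        "ci": [ccc_res.ci_low, ccc_res.ci_high],
                        "ci_method": ccc_res.method,
                        "table": table.to_dict(orient="records"),
                    },
                    indent=1,
                )
            )
            artifacts["validation"] = report_path
            validation = (table, ccc_res)
            stage("validate", f"CCC={ccc_res.ccc:.4f}")

        (out / "run.log").write_text("\n".join(log) + "\n")
        (out / "events.jsonl").write_text(
            "\n".join(json.dumps(e) for e in events) + "\n"
        )
        artifacts["log"] = out / "run.log"
        return PipelineResult(
            scene=scene,
            maps=maps,
            plan=plan,
            validation=validation,
            artifacts=artifacts,
            log=log,
        )
    except Exception as e:
        where = current["stage"]
        log.append(f"[{time.strftime('%H:%M:%S')}] error in stage {where!r}: {e}")
        (out / "run.log").write_text("\n".join(log) + "\n")
        raise RuntimeError(
            f"pipeline stage {where!r} failed: {e} "
            "(check the configuration for this stage; see run.log)"
        ) from e
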