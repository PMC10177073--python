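"""Shared fixtures: small deterministic scenes and synthetic fiber maps."""

from __future__ import annotations

import numpy as np
import pytest

import ipdtplan as ip
from ipdtplan.geometry import Scene, Tube, boundary_faces_with_parents
from ipdtplan.meshing import cartesian_mesh

PHANTOM_PROPS = {"phantom": ip.PHANTOM}


@pytest.fixture(scope="session")
def coarse_phantom():
    """Very coarse phantom block (a few thousand nodes, sub-second solve)."""
    return ip.make_phantom_scene(target_h=1.47)


@pytest.fixture(scope="session")
def coarse_phantom_solution(coarse_phantom):
    system = ip.assemble_system(coarse_phantom, PHANTOM_PROPS)
    field = ip.solve_steady(system, ip.sources_from_cdfs(coarse_phantom))
    return system, field


@pytest.fixture(scope="session")
def small_phantom():
    return ip.make_phantom_scene(target_h=0.98)


@pytest.fixture(scope="session")
def small_phantom_solution(small_phantom):
    system = ip.assemble_system(small_phantom, PHANTOM_PROPS)
    field = ip.solve_steady(system, ip.sources_from_cdfs(small_phantom))
    return system, field


def _tiny_airway_cdfs():
    return [
        ip.CDFPlacement((0.35, 0.0, -0.8), (0.0, 0.0, 1.0), 1.5,
                        intensity=100.0, treatment_time=500.0),
        ip.CDFPlacement((-0.45, 0.15, -0.6), (0.0, 0.0, 1.0), 1.2,
                        intensity=100.0, treatment_time=500.0),
    ]


@pytest.fixture(scope="session")
def tiny_airway():
    """Two-fiber airway scene: ellipsoidal tumor, one vessel, bronchus."""
    return ip.make_airway_scene(
        tumor_semiaxes=(1.1, 0.9, 0.9),
        vessel_specs=[((-2.0, 1.55, -2.0), (2.0, 1.55, 2.0), 0.4)],
        bronchus_spec=((-2.0, -1.7, 0.0), (2.0, -1.7, 0.0), 0.5),
        margin=0.8,
        target_h=0.45,
        cdfs=_tiny_airway_cdfs(),
    )


@pytest.fixture(scope="session")
def tiny_airway_maps(tiny_airway):
    return ip.solve_per_cdf_maps(tiny_airway, ip.DEFAULT_PROPERTIES)


def make_box_scene(
    n=(4, 2, 2),
    extent=(2.0, 1.0, 1.0),
    region_fn=None,
    cdfs=(),
    vessels=(),
    bronchus=None,
) -> Scene:
    """Hand-built box scene for unit tests; regions assigned per tet centroid.

    ``region_fn(centroids) -> tag array`` defaults to all normal tissue
    (tag 3); tags are 1=tumor, 2=critical_structure, 3=normal_tissue.
    """
    xs = np.linspace(0.0, extent[0], n[0] + 1)
    ys = np.linspace(0.0, extent[1], n[1] + 1)
    zs = np.linspace(0.0, extent[2], n[2] + 1)
    grid = cartesian_mesh(xs, ys, zs)
    nodes, tets = grid["nodes"], grid["tets"]
    cent = nodes[tets].mean(axis=1)
    region = (
        np.full(len(tets), 3, dtype=np.int64)
        if region_fn is None
        else np.asarray(region_fn(cent), dtype=np.int64)
    )
    faces, _ = boundary_faces_with_parents(tets)
    names = {}
    for tag, name in ((1, "tumor"), (2, "critical_structure"), (3, "normal_tissue")):
        if tag in set(np.unique(region)):
            names[tag] = name
    scene = Scene(
        nodes=nodes,
        tets=tets,
        tet_region=region,
        region_names=names,
        facets=faces,
        facet_tag=np.ones(len(faces), dtype=np.int64),
        surface_names={1: "outer"},
        cdfs=list(cdfs),
        vessels=list(vessels),
        bronchus=bronchus,
    )
    scene.validate()
    return scene


def tumor_cs_box():
    """Box split into tumor (x < 1) and critical structure (x >= 1)."""
    return make_box_scene(
        n=(4, 2, 2),
        region_fn=lambda c: np.where(c[:, 0] < 1.0, 1, 2),
    )


def synthetic_maps(scene, fields, intensities=None, times=None) -> ip.PerCDFMaps:
    """PerCDFMaps around hand-written nodal fields (one row per fiber)."""
    fields = np.atleast_2d(np.asarray(fields, dtype=float))
    k = fields.shape[0]
    cdfs = [
        ip.CDFPlacement((0.2 + 0.3 * i, 0.5, 0.1), (0, 0, 1.0), 0.8, intensity=100.0)
        for i in range(k)
    ]
    ref = np.full(k, 100.0)
    return ip.PerCDFMaps(
        scene=scene,
        cdfs=cdfs,
        unit_fields=fields,
        reference_intensities=ref,
        intensities=ref.copy() if intensities is None else np.asarray(intensities, float),
        times=np.full(k, 500.0) if times is None else np.asarray(times, float),
    )


@pytest.fixture()
def toy_scene():
    return tumor_cs_box()
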