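"""Scene fixtures: phantom and synthetic airway-tumor geometries.

The phantom scene reproduces the solid-phantom dosimetry bench: a
homogeneous optical phantom block with a single cylindrical diffuser fiber
(CDF) and isotropic detectors at fixed radial distances in the diffuser
mid-plane. The airway scene is a synthetic stand-in for segmented patient
anatomy: an ellipsoidal tumor next to a bronchus cavity, with optional
major-vessel tubes as critical structures, embedded in a normal-tissue
block. No imaging data is required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import (
    DEFAULT_DIFFUSER_DIAMETER,
    CDFPlacement,
    Scene,
    Tube,
    boundary_faces_with_parents,
    points_segment_distance,
    segment_segment_distance,
)
from .meshing import (
    cartesian_mesh,
    compact_mesh,
    refined_axis,
    revolved_block_mesh,
    symmetric_band_grid,
)

# Default far-field element size for the phantom mesh, cm. Near the diffuser
# the radial spacing is diffuser_diameter / 2 and grows geometrically to
# 10x that at the outer boundary; target_h rescales the whole grading.
PHANTOM_DEFAULT_H = 0.49


def make_phantom_scene(
    mu_a: float = 0.224,
    mu_s_prime: float = 4.99,
    diffuser_length: float = 2.0,
    diffuser_diameter: float = DEFAULT_DIFFUSER_DIAMETER,
    detector_distances_mm: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0),
    block_edge: float = 10.0,
    target_h: float | None = None,
    intensity: float = 100.0,
) -> Scene:
    """Build the homogeneous phantom block with one centered CDF.

    The diffuser axis is +z through the block center; the emitting band
    spans ``|z| <= diffuser_length / 2`` on the wall of a full-height
    channel of the fiber diameter. Detectors are analytic points at the
    requested radial distances (mm) in the mid-plane z = 0.

    ``mu_a`` / ``mu_s_prime`` (1/cm) are recorded in ``scene.meta`` for the
    solver configuration; ``target_h`` (cm) scales the mesh grading
    (default 0.49 far-field, diffuser-radius spacing at the source).
    """
    if diffuser_diameter >= block_edge:
        raise ValueError("diffuser_diameter must be smaller than block_edge")
    half = block_edge / 2.0
    d_max = max(detector_distances_mm, default=0.0) / 10.0
    if d_max + 2.0 > half:
        raise ValueError(
            f"block_edge {block_edge} cm cannot contain a detector at "
            f"{d_max * 10:.0f} mm with a 2 cm margin"
        )
    if diffuser_length / 2.0 + 2.0 > half:
        raise ValueError("block_edge too small for the diffuser plus 2 cm margin")

    h = PHANTOM_DEFAULT_H if target_h is None else float(target_h)
    if h <= 0:
        raise ValueError("target_h must be positive")
    f = h / PHANTOM_DEFAULT_H
    a = diffuser_diameter / 2.0
    h_near = a / 5.0 * f  # sub-radius wall spacing resolves the K0-like gradient
    hz_fine = min(0.13 * f, diffuser_length / 4.0)
    # multiple of 8 so azimuthal nodes land exactly on the cube diagonals
    n_theta = int(np.clip(8 * round(30.0 / f / 8.0), 8, 96))

    band = diffuser_length / 2.0
    z_grid = symmetric_band_grid(
        half, band + min(0.3, half - band), hz_fine, 0.32 * f
    )
    # keep exact nodes at the band edges so facets never straddle them
    z_grid = np.unique(np.round(np.concatenate([z_grid, [-band, band]]), 12))

    shell = min(d_max + 0.3, half) if d_max > 0 else min(2.8, half)
    radial = _radial_fractions(a, half, h_near, 0.16 * f, 0.32 * f, shell)
    grid = revolved_block_mesh(a, half, z_grid, n_theta, h_near, h, radial_s=radial)
    nodes, tets = grid["nodes"], grid["tets"]
    node_i = grid["node_i"]

    faces, _ = boundary_faces_with_parents(tets)
    on_channel = np.all(node_i[faces] == 0, axis=1)
    zc = nodes[faces, 2]
    tol = 1e-9
    in_band = np.all((zc >= -band - tol) & (zc <= band + tol), axis=1)
    facet_tag = np.where(on_channel & in_band, 2, np.where(on_channel, 3, 1))

    cdf = CDFPlacement(
        entry_point=(0.0, 0.0, -band),
        axis=(0.0, 0.0, 1.0),
        diffuser_length=diffuser_length,
        diffuser_diameter=diffuser_diameter,
        intensity=intensity,
    )
    detectors = (
        np.array([[d / 10.0, 0.0, 0.0] for d in detector_distances_mm])
        if len(detector_distances_mm)
        else None
    )
    scene = Scene(
        nodes=nodes,
        tets=tets,
        tet_region=np.ones(len(tets), dtype=np.int64),
        region_names={1: "phantom"},
        facets=faces,
        facet_tag=facet_tag,
        surface_names={1: "outer", 2: "diffuser_0", 3: "shaft_0"},
        cdfs=[cdf],
        detectors=detectors,
        meta={
            "mu_a": mu_a,
            "mu_s_prime": mu_s_prime,
            "target_h": h,
            "diffuser_diameter": diffuser_diameter,
            "kind": "phantom",
        },
    )
    scene.validate()
    return scene


def _radial_fractions(
    a: float,
    R: float,
    h_near: float,
    h_shell: float,
    h_far: float,
    shell: float,
    ratio: float = 1.3,
) -> np.ndarray:
    """Radial station fractions s in [0, 1] for the revolved phantom grid.

    Spacing starts at ``h_near`` on the fiber wall, grows geometrically but
    is capped at ``h_shell`` through the detector shell (rho < shell) and at
    ``h_far`` beyond — the far cap stays below a diffusion attenuation
    length so the exponential decay remains resolved.
    """
    r, hcur = a, h_near
    pts = [a]
    while r < R - 1e-12:
        cap = h_shell if r < shell else h_far
        hcur = min(hcur * ratio, cap)
        r = min(r + hcur, R)
        pts.append(r)
    pts = np.asarray(pts)
    pts = a + (pts - a) * ((R - a) / (pts[-1] - a))
    return (pts - a) / (R - a)


def _inside_ellipsoid(points: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
    return np.sum((points / semiaxes) ** 2, axis=1) <= 1.0


def make_airway_scene(
    tumor_semiaxes: tuple[float, float, float] = (2.0, 1.5, 1.5),
    vessel_specs: list[tuple[tuple, tuple, float]] = (),
    bronchus_spec: tuple[tuple, tuple, float] | None = None,
    margin: float = 1.5,
    target_h: float = 0.16,
    cdfs: list[CDFPlacement] = (),
) -> Scene:
    """Synthetic airway-tumor scene on a graded Cartesian tet grid.

    The tumor is an axis-aligned ellipsoid centered at the origin; vessels
    and the bronchus are finite cylinders given as ``(p0, p1, radius)``.
    The bronchus and the diffuser segments are carved out as cavities;
    regions (tumor / critical_structure / normal_tissue) are assigned by
    element centroid. Fiber cavities are staircase approximations at the
    local grid resolution — adequate for planning logic, whose safety
    checks operate centimeters from the source.
    """
    semi = np.asarray(tumor_semiaxes, dtype=float)
    if np.any(semi <= 0):
        raise ValueError("tumor semiaxes must be positive")
    if margin <= 0:
        raise ValueError("margin must be positive")
    vessels = [Tube(tuple(p0), tuple(p1), float(r)) for p0, p1, r in vessel_specs]
    bronchus = Tube(*bronchus_spec) if bronchus_spec is not None else None
    for t in vessels + ([bronchus] if bronchus else []):
        if t.radius <= 0 or np.linalg.norm(t.b - t.a) < 1e-9:
            raise ValueError("degenerate tube specification")
    # tumor fully inside a vessel is a degenerate nesting
    for v in vessels:
        probes = np.concatenate([np.diag(semi), -np.diag(semi), [[0, 0, 0]]])
        if np.all(points_segment_distance(probes, v.a, v.b) <= v.radius):
            raise ValueError("tumor is contained in a vessel (degenerate nesting)")

    # bounding box
    lo = -semi - margin
    hi = semi + margin
    for t in vessels + ([bronchus] if bronchus else []):
        for p in (t.a, t.b):
            lo = np.minimum(lo, p - t.radius - margin)
            hi = np.maximum(hi, p + t.radius + margin)
    cdfs = list(cdfs)
    h_fine = max(target_h / 3.0, 0.04)
    axes = []
    for ax in range(3):
        windows = [
            (
                min(c.p0[ax], c.p1[ax]) - 3 * h_fine,
                max(c.p0[ax], c.p1[ax]) + 3 * h_fine,
                h_fine,
            )
            for c in cdfs
        ]
        axes.append(refined_axis(lo[ax], hi[ax], target_h, windows))
    grid = cartesian_mesh(*axes)
    nodes, tets = grid["nodes"], grid["tets"]
    cent = nodes[tets].mean(axis=1)

    in_tumor = _inside_ellipsoid(cent, semi)
    in_vessel = np.zeros(len(tets), dtype=bool)
    for v in vessels:
        in_vessel |= points_segment_distance(cent, v.a, v.b) <= v.radius
    if np.any(in_tumor & in_vessel):
        raise ValueError("tumor and vessel regions overlap; regions must partition the domain")

    remove_reason = np.zeros(len(tets), dtype=np.int64)  # 0 keep, -1 bronchus, k+1 fiber k
    if bronchus is not None:
        remove_reason[
            points_segment_distance(cent, bronchus.a, bronchus.b) <= bronchus.radius
        ] = -1
    for k, cdf in enumerate(cdfs):
        carve = max(cdf.radius, 0.75 * h_fine)
        mask = points_segment_distance(cent, cdf.p0, cdf.p1) <= carve
        if not np.any(mask):
            raise ValueError(f"fiber {k} cavity is not resolved by the mesh")
        remove_reason[mask] = k + 1

    keep = remove_reason == 0
    region = np.where(in_tumor, 1, np.where(in_vessel, 2, 3))[keep]
    kept_tets = tets[keep]
    nodes, kept_tets = compact_mesh(nodes, kept_tets)

    faces, parents = boundary_faces_with_parents(kept_tets)
    fcent = nodes[faces].mean(axis=1)
    facet_tag = np.ones(len(faces), dtype=np.int64)
    surface_names = {1: "outer"}
    box_lo, box_hi = nodes.min(axis=0), nodes.max(axis=0)
    on_box = np.zeros(len(faces), dtype=bool)
    for ax in range(3):
        on_box |= np.all(np.abs(nodes[faces, ax] - box_lo[ax]) < 1e-9, axis=1)
        on_box |= np.all(np.abs(nodes[faces, ax] - box_hi[ax]) < 1e-9, axis=1)
    interior = ~on_box
    for k, cdf in enumerate(cdfs):
        carve = max(cdf.radius, 0.75 * h_fine)
        near = points_segment_distance(fcent, cdf.p0, cdf.p1) <= carve + 1.5 * h_fine
        tag = 10 + k
        facet_tag[interior & near] = tag
        surface_names[tag] = f"diffuser_{k}"
    # remaining interior cavity facets (bronchus wall) stay 'outer' (Robin)

    region_names = {}
    present = set(np.unique(region))
    for tag, name in ((1, "tumor"), (2, "critical_structure"), (3, "normal_tissue")):
        if tag in present:
            region_names[tag] = name
    scene = Scene(
        nodes=nodes,
        tets=kept_tets,
        tet_region=region,
        region_names=region_names,
        facets=faces,
        facet_tag=facet_tag,
        surface_names=surface_names,
        cdfs=cdfs,
        vessels=vessels,
        bronchus=bronchus,
        meta={"target_h": target_h, "kind": "airway", "tumor_semiaxes": tuple(semi)},
    )
    scene.validate()
    return scene


@dataclass(frozen=True)
class ConstraintCheck:
    name: str
    passed: bool
    measured: float
    limit: str


def check_placement_constraints(
    cdf: CDFPlacement,
    scene: Scene,
    bronchus_axis: Tube | None = None,
) -> list[ConstraintCheck]:
    """Clinical fiber-placement checks: insertion angle, depth, clearance.

    * insertion angle between the fiber axis and the bronchus axis within
      [30 deg, 40 deg];
    * insertion depth — distance from the bronchus wall crossing of the
      fiber line to the distal diffuser tip — at most 4 cm;
    * minimum clearance from the diffuser segment to any critical-structure
      surface at least 6 mm.

    Reporting only: every check returns its measured value.
    """
    bronchus = bronchus_axis or scene.bronchus
    if bronchus is None:
        raise ValueError("scene has no bronchus specification")
    axis = np.asarray(cdf.axis, dtype=float)
    bdir = bronchus.direction
    cosang = abs(float(axis @ bdir))
    angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
    checks = [
        ConstraintCheck("insertion_angle_deg", 30.0 <= angle <= 40.0, angle, "[30, 40]")
    ]

    depth = _insertion_depth(cdf, bronchus)
    checks.append(ConstraintCheck("insertion_depth_cm", depth <= 4.0, depth, "<= 4"))

    if scene.vessels:
        clear = min(
            segment_segment_distance(cdf.p0, cdf.p1, v.a, v.b) - v.radius
            for v in scene.vessels
        )
    else:
        clear = math.inf
    checks.append(
        ConstraintCheck("vessel_clearance_cm", clear >= 0.6, clear, ">= 0.6")
    )
    return checks


def _insertion_depth(cdf: CDFPlacement, bronchus: Tube) -> float:
    """Distance from the fiber line's bronchus-wall crossing to the distal tip.

    Solves |(p(t) - proj_bronchus(p(t)))| = bronchus radius along the fiber
    line p(t) = tip - t * axis (t measured back from the tip); falls back to
    the diffuser-tip-to-entry distance when the line misses the bronchus.
    """
    tip = cdf.p1
    axis = np.asarray(cdf.axis, dtype=float)
    b0, bd = bronchus.a, bronchus.direction
    # perpendicular distance to the (infinite) bronchus axis as function of t
    w = tip - b0
    w_perp = w - (w @ bd) * bd
    a_perp = axis - (axis @ bd) * bd
    # |w_perp - t a_perp|^2 = r^2
    A = a_perp @ a_perp
    B = -2.0 * (w_perp @ a_perp)
    C = w_perp @ w_perp - bronchus.radius**2
    if A < 1e-14:
        return float(np.linalg.norm(tip - cdf.p0))
    disc = B * B - 4 * A * C
    if disc < 0:
        return float(np.linalg.norm(tip - cdf.p0))
    roots = [(-B - math.sqrt(disc)) / (2 * A), (-B + math.sqrt(disc)) / (2 * A)]
    ts = [t for t in roots if t > 0]
    if not ts:
        return float(np.linalg.norm(tip - cdf.p0))
    return float(min(ts))
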