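"""Scene containers: tagged tetrahedral meshes, fiber placements, regions.

Coordinates are dimensional (cm), right-handed. A :class:`Scene` owns the
tetrahedral mesh, per-element region tags, tagged boundary facets, the
cylindrical diffuser fiber (CDF) placements, optional analytic detector
points, and — for synthetic airway scenes — the analytic vessel/bronchus
descriptors used by the clinical placement-constraint checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

REGION_NAMES = ("tumor", "critical_structure", "normal_tissue", "phantom")

#: Default clinical cylindrical diffuser outer diameter, cm.
DEFAULT_DIFFUSER_DIAMETER = 0.098


@dataclass(frozen=True)
class CDFPlacement:
    """Geometry and light settings of one cylindrical diffuser fiber.

    The diffuser segment runs from ``entry_point`` (proximal end of the
    emitting segment) to ``entry_point + diffuser_length * axis``.

    intensity is the prescribed light intensity in mW per cm of diffuser;
    total power (mW) is ``intensity * diffuser_length``.
    """

    entry_point: tuple[float, float, float]
    axis: tuple[float, float, float]
    diffuser_length: float
    diffuser_diameter: float = DEFAULT_DIFFUSER_DIAMETER
    intensity: float = 0.0  # mW/cm
    treatment_time: float = 0.0  # s

    def __post_init__(self) -> None:
        ax = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(ax) - 1.0) > 1e-9:
            raise ValueError(f"axis must be a unit vector, |axis|={np.linalg.norm(ax)}")
        if self.diffuser_length <= 0:
            raise ValueError("diffuser_length must be positive")
        if self.diffuser_diameter <= 0:
            raise ValueError("diffuser_diameter must be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be nonnegative")
        if self.treatment_time < 0:
            raise ValueError("treatment_time must be nonnegative")

    # -- derived geometry ------------------------------------------------
    @property
    def p0(self) -> np.ndarray:
        return np.asarray(self.entry_point, dtype=float)

    @property
    def p1(self) -> np.ndarray:
        return self.p0 + self.diffuser_length * np.asarray(self.axis, dtype=float)

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.p0 + self.p1)

    @property
    def radius(self) -> float:
        return 0.5 * self.diffuser_diameter

    @property
    def power(self) -> float:
        """Total emitted power, mW."""
        return self.intensity * self.diffuser_length

    @property
    def lateral_area(self) -> float:
        """Lateral cylinder area pi*d*L, cm^2."""
        return np.pi * self.diffuser_diameter * self.diffuser_length

    @property
    def surface_area(self) -> float:
        """Total diffuser surface area: lateral plus the two end caps, cm^2."""
        return self.lateral_area + 2.0 * np.pi * self.radius**2

    @property
    def p_laser(self) -> float:
        """Dirichlet surface irradiance, mW/cm^2.

        Total emitted power divided by the total diffuser surface area, so
        the prescribed output power is conserved over the source surface.
        """
        return self.power / self.surface_area

    def with_intensity(self, intensity: float) -> "CDFPlacement":
        return replace(self, intensity=float(intensity))

    def with_time(self, treatment_time: float) -> "CDFPlacement":
        return replace(self, treatment_time=float(treatment_time))


@dataclass(frozen=True)
class RegionLabel:
    """A named tissue region bound to a mesh volume tag."""

    name: str
    mesh_tag: int

    def __post_init__(self) -> None:
        if self.name not in REGION_NAMES:
            raise ValueError(
                f"unknown region name {self.name!r}; expected one of {REGION_NAMES}"
            )


@dataclass(frozen=True)
class Tube:
    """Analytic finite cylinder (axis segment + radius) for vessels/bronchus."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float

    @property
    def a(self) -> np.ndarray:
        return np.asarray(self.p0, dtype=float)

    @property
    def b(self) -> np.ndarray:
        return np.asarray(self.p1, dtype=float)

    @property
    def direction(self) -> np.ndarray:
        d = self.b - self.a
        return d / np.linalg.norm(d)


def segment_segment_distance(
    p0: np.ndarray, p1: np.ndarray, q0: np.ndarray, q1: np.ndarray
) -> float:
    """Minimum distance between two 3D line segments."""
    u = p1 - p0
    v = q1 - q0
    w0 = p0 - q0
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w0, v @ w0
    denom = a * c - b * b
    if denom > 1e-14:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:  # parallel
        s = 0.0
    t = (b * s + e) / c if c > 1e-14 else 0.0
    t = np.clip(t, 0.0, 1.0)
    # refine s for the clamped t
    if a > 1e-14:
        s = np.clip((b * t - d) / a, 0.0, 1.0)
    return float(np.linalg.norm((p0 + s * u) - (q0 + t * v)))


def points_segment_distance(
    points: np.ndarray, a: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """Distance from each point to the segment [a, b] (vectorized)."""
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-30:
        return np.linalg.norm(points - a, axis=-1)
    t = np.clip(((points - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[..., None] * ab
    return np.linalg.norm(points - proj, axis=-1)


@dataclass
class Scene:
    """Tagged tetrahedral mesh with fiber placements and region metadata.

    Attributes
    ----------
    nodes : (N, 3) float array, cm.
    tets : (M, 4) int array of node indices, positively oriented.
    tet_region : (M,) int array of volume tags.
    region_names : mapping volume tag -> region name.
    facets : (F, 3) int array of boundary triangle node indices.
    facet_tag : (F,) int array of surface tags.
    surface_names : mapping surface tag -> surface name
        ('outer', 'diffuser_<k>', or 'shaft_<k>').
    cdfs : fiber placements; 'diffuser_<k>' tags refer to ``cdfs[k]``.
    detectors : optional (K, 3) analytic probe points, cm.
    vessels / bronchus : analytic tubes behind the critical-structure and
        airway geometry (synthetic scenes only).
    """

    nodes: np.ndarray
    tets: np.ndarray
    tet_region: np.ndarray
    region_names: dict[int, str]
    facets: np.ndarray
    facet_tag: np.ndarray
    surface_names: dict[int, str]
    cdfs: list[CDFPlacement] = field(default_factory=list)
    detectors: np.ndarray | None = None
    vessels: list[Tube] = field(default_factory=list)
    bronchus: Tube | None = None
    meta: dict = field(default_factory=dict)

    # -- basic sizes -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_tets(self) -> int:
        return self.tets.shape[0]

    @property
    def regions(self) -> list[RegionLabel]:
        return [RegionLabel(name, tag) for tag, name in sorted(self.region_names.items())]

    # -- volumes ---------------------------------------------------------
    def tet_volumes(self) -> np.ndarray:
        x = self.nodes[self.tets]
        e = x[:, 1:, :] - x[:, :1, :]
        return np.linalg.det(e) / 6.0

    def region_tags(self, region: "str | RegionLabel | int") -> list[int]:
        if isinstance(region, RegionLabel):
            return [region.mesh_tag]
        if isinstance(region, (int, np.integer)):
            if int(region) not in self.region_names:
                raise KeyError(f"unknown region tag {region}")
            return [int(region)]
        tags = [t for t, n in self.region_names.items() if n == region]
        if not tags:
            raise KeyError(f"unknown region {region!r}")
        return tags

    def region_tet_mask(self, region) -> np.ndarray:
        tags = self.region_tags(region)
        return np.isin(self.tet_region, tags)

    def region_volume(self, region) -> float:
        return float(self.tet_volumes()[self.region_tet_mask(region)].sum())

    def region_node_indices(self, region) -> np.ndarray:
        """Indices of nodes belonging to any tetrahedron of the region."""
        return np.unique(self.tets[self.region_tet_mask(region)])

    # -- surfaces --------------------------------------------------------
    def surface_tag_for(self, name: str) -> int:
        for tag, n in self.surface_names.items():
            if n == name:
                return tag
        raise KeyError(f"unknown surface {name!r}")

    def facet_mask(self, name: str) -> np.ndarray:
        return self.facet_tag == self.surface_tag_for(name)

    def diffuser_surface_names(self) -> list[str]:
        return [n for n in self.surface_names.values() if n.startswith("diffuser_")]

    def facet_areas(self, mask: np.ndarray | None = None) -> np.ndarray:
        tri = self.facets if mask is None else self.facets[mask]
        x = self.nodes[tri]
        return 0.5 * np.linalg.norm(
            np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]), axis=1
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Enforce the mesh invariants; raise ValueError on violation."""
        if self.n_tets == 0 or self.n_nodes == 0:
            raise ValueError("empty mesh")
        vols = self.tet_volumes()
        if not np.all(vols > 0):
            raise ValueError(
                f"{int(np.sum(vols <= 0))} tetrahedra with non-positive volume"
            )
        unknown = set(np.unique(self.tet_region)) - set(self.region_names)
        if unknown:
            raise ValueError(f"tetrahedra with unknown region tags {sorted(unknown)}")
        if self.facets.shape[0] != self.facet_tag.shape[0]:
            raise ValueError("facet/tag length mismatch")
        unknown_s = set(np.unique(self.facet_tag)) - set(self.surface_names)
        if unknown_s:
            raise ValueError(f"boundary facets with unknown tags {sorted(unknown_s)}")
        # boundary facet set must match the topological boundary exactly
        boundary = _boundary_faces(self.tets)
        tagged = {tuple(sorted(f)) for f in self.facets}
        missing = boundary - tagged
        extra = tagged - boundary
        if missing:
            raise ValueError(
                f"{len(missing)} boundary facets carry no surface tag"
            )
        if extra:
            raise ValueError(f"{len(extra)} tagged facets are not on the boundary")

    def node_region_mask(self, region) -> np.ndarray:
        mask = np.zeros(self.n_nodes, dtype=bool)
        mask[self.region_node_indices(region)] = True
        return mask


def _boundary_faces(tets: np.ndarray) -> set[tuple[int, int, int]]:
    faces = np.concatenate(
        [tets[:, [0, 1, 2]], tets[:, [0, 1, 3]], tets[:, [0, 2, 3]], tets[:, [1, 2, 3]]]
    )
    faces = np.sort(faces, axis=1)
    order = np.lexsort(faces.T)
    faces = faces[order]
    dup = np.all(faces[1:] == faces[:-1], axis=1)
    keep = np.ones(len(faces), dtype=bool)
    keep[1:][dup] = False
    keep[:-1][dup] = False
    return {tuple(f) for f in faces[keep]}


def boundary_faces_with_parents(tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Boundary triangles of a tet mesh and the owning tet index of each."""
    faces = np.concatenate(
        [tets[:, [0, 1, 2]], tets[:, [0, 1, 3]], tets[:, [0, 2, 3]], tets[:, [1, 2, 3]]]
    )
    parents = np.tile(np.arange(len(tets)), 4)
    key = np.sort(faces, axis=1)
    order = np.lexsort(key.T)
    key, faces, parents = key[order], faces[order], parents[order]
    dup = np.all(key[1:] == key[:-1], axis=1)
    keep = np.ones(len(faces), dtype=bool)
    keep[1:][dup] = False
    keep[:-1][dup] = False
    return faces[keep], parents[keep]
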