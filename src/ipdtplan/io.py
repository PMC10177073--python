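"""Scene and field I/O.

Scenes are exchanged as Gmsh MSH 4.1 ASCII (region and surface tags as
physical groups) with a JSON sidecar (``<stem>.scene.json``) carrying the
fiber placements, detector points, analytic tubes and units. Fields export
to VTU (ASCII XML) point data for visualization, probe tables to CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import REGION_NAMES, CDFPlacement, Scene, Tube

_UNITS = {
    "length": "cm",
    "irradiance": "mW/cm^2",
    "fluence": "J/cm^2",
    "power": "mW",
    "intensity": "mW/cm",
    "time": "s",
}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".scene.json")


def write_scene(scene: Scene, path) -> None:
    """Write a validated scene as MSH 4.1 plus the JSON sidecar."""
    scene.validate()
    path = Path(path)
    n = scene.n_nodes
    surface_tags = sorted(scene.surface_names)
    region_tags = sorted(scene.region_names)
    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]

    lines.append("$PhysicalNames")
    lines.append(str(len(surface_tags) + len(region_tags)))
    for t in surface_tags:
        lines.append(f'2 {t} "{scene.surface_names[t]}"')
    for t in region_tags:
        lines.append(f'3 {t} "{scene.region_names[t]}"')
    lines.append("$EndPhysicalNames")

    lines.append("$Entities")
    lines.append(f"0 0 {len(surface_tags)} {len(region_tags)}")
    for t in surface_tags:
        lines.append(f"{t} 0 0 0 0 0 0 1 {t} 0")
    for t in region_tags:
        lines.append(f"{t} 0 0 0 0 0 0 1 {t} 0")
    lines.append("$EndEntities")

    lines.append("$Nodes")
    lines.append(f"1 {n} 1 {n}")
    lines.append(f"3 {region_tags[0]} 0 {n}")
    lines.extend(str(i + 1) for i in range(n))
    lines.extend(
        f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in scene.nodes
    )
    lines.append("$EndNodes")

    lines.append("$Elements")
    blocks = []
    for t in surface_tags:
        idx = np.where(scene.facet_tag == t)[0]
        blocks.append((2, t, 2, scene.facets[idx]))
    for t in region_tags:
        idx = np.where(scene.tet_region == t)[0]
        blocks.append((3, t, 4, scene.tets[idx]))
    blocks = [b for b in blocks if len(b[3])]
    total = sum(len(b[3]) for b in blocks)
    lines.append(f"{len(blocks)} {total} 1 {total}")
    eid = 1
    for dim, tag, etype, conn in blocks:
        lines.append(f"{dim} {tag} {etype} {len(conn)}")
        for row in conn:
            lines.append(f"{eid} " + " ".join(str(v + 1) for v in row))
            eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")

    side = {
        "units": _UNITS,
        "cdfs": [
            {
                "entry_point": list(map(float, c.p0)),
                "axis": list(map(float, c.axis)),
                "diffuser_length": c.diffuser_length,
                "diffuser_diameter": c.diffuser_diameter,
                "intensity": c.intensity,
                "treatment_time": c.treatment_time,
            }
            for c in scene.cdfs
        ],
        "detectors": None
        if scene.detectors is None
        else np.asarray(scene.detectors).tolist(),
        "vessels": [
            {"p0": list(v.a), "p1": list(v.b), "radius": v.radius}
            for v in scene.vessels
        ],
        "bronchus": None
        if scene.bronchus is None
        else {
            "p0": list(scene.bronchus.a),
            "p1": list(scene.bronchus.b),
            "radius": scene.bronchus.radius,
        },
        "meta": scene.meta,
    }
    _sidecar(path).write_text(json.dumps(side, indent=1))


def _read_blocks(text: str) -> dict[str, list[str]]:
    blocks = {}
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        if lines[i].startswith("$") and not lines[i].startswith("$End"):
            name = lines[i][1:]
            j = i + 1
            while j < len(lines) and not lines[j].startswith("$End"):
                j += 1
            blocks[name] = lines[i + 1 : j]
            i = j + 1
        else:
            i += 1
    return blocks


def read_scene(path) -> Scene:
    """Read an MSH 4.1 scene written by :func:`write_scene`.

    Unknown region or surface names are rejected with the offending tag;
    the reconstructed scene is re-validated (untagged boundary facets and
    empty meshes raise).
    """
    path = Path(path)
    blocks = _read_blocks(path.read_text())
    if "Nodes" not in blocks or "Elements" not in blocks:
        raise ValueError(f"{path} is not an MSH file with nodes and elements")

    surface_names: dict[int, str] = {}
    region_names: dict[int, str] = {}
    for line in blocks.get("PhysicalNames", [])[1:]:
        parts = line.split(maxsplit=2)
        if len(parts) < 3:
            continue
        dim, tag = int(parts[0]), int(parts[1])
        name = parts[2].strip().strip('"')
        if dim == 2:
            if name != "outer" and not name.startswith(("diffuser_", "shaft_")):
                raise ValueError(f"unknown surface tag name {name!r} (tag {tag})")
            surface_names[tag] = name
        elif dim == 3:
            if name not in REGION_NAMES:
                raise ValueError(f"unknown region tag name {name!r} (tag {tag})")
            region_names[tag] = name

    # entity -> physical tag (per dim)
    ent_phys = {2: {}, 3: {}}
    ent_lines = blocks.get("Entities", [])
    if ent_lines:
        counts = list(map(int, ent_lines[0].split()))
        rows = ent_lines[1:]
        row = counts[0] + counts[1]  # skip points and curves
        for dim, cnt in ((2, counts[2]), (3, counts[3])):
            for _ in range(cnt):
                parts = rows[row].split()
                tag = int(parts[0])
                nphys = int(parts[7])
                ent_phys[dim][tag] = int(parts[8]) if nphys else tag
                row += 1

    node_lines = blocks["Nodes"]
    header = node_lines[0].split()
    n_nodes = int(header[1])
    coords = np.empty((n_nodes, 3))
    tag_to_idx = {}
    row = 1
    filled = 0
    while filled < n_nodes:
        _, _, _, n_blk = map(int, node_lines[row].split()[:4])
        tags = [int(node_lines[row + 1 + i]) for i in range(n_blk)]
        for i in range(n_blk):
            xyz = list(map(float, node_lines[row + 1 + n_blk + i].split()))
            tag_to_idx[tags[i]] = filled + i
            coords[filled + i] = xyz
        filled += n_blk
        row += 1 + 2 * n_blk

    elem_lines = blocks["Elements"]
    n_blocks = int(elem_lines[0].split()[0])
    row = 1
    tets, tet_region, facets, facet_tag = [], [], [], []
    for _ in range(n_blocks):
        dim, etag, etype, n_blk = map(int, elem_lines[row].split())
        phys = ent_phys[dim].get(etag, etag) if dim in ent_phys else etag
        for i in range(n_blk):
            parts = elem_lines[row + 1 + i].split()
            conn = [tag_to_idx[int(v)] for v in parts[1:]]
            if etype == 4:
                tets.append(conn)
                tet_region.append(phys)
            elif etype == 2:
                facets.append(conn)
                facet_tag.append(phys)
        row += 1 + n_blk
    if not tets:
        raise ValueError("empty mesh: no tetrahedra")

    cdfs, detectors, vessels, bronchus, meta = [], None, [], None, {}
    sc = _sidecar(path)
    if sc.exists():
        side = json.loads(sc.read_text())
        cdfs = [
            CDFPlacement(
                entry_point=tuple(c["entry_point"]),
                axis=tuple(c["axis"]),
                diffuser_length=c["diffuser_length"],
                diffuser_diameter=c["diffuser_diameter"],
                intensity=c["intensity"],
                treatment_time=c["treatment_time"],
            )
            for c in side.get("cdfs", [])
        ]
        if side.get("detectors") is not None:
            detectors = np.asarray(side["detectors"], dtype=float)
        vessels = [
            Tube(tuple(v["p0"]), tuple(v["p1"]), v["radius"])
            for v in side.get("vessels", [])
        ]
        if side.get("bronchus"):
            b = side["bronchus"]
            bronchus = Tube(tuple(b["p0"]), tuple(b["p1"]), b["radius"])
        meta = side.get("meta", {})

    scene = Scene(
        nodes=coords,
        tets=np.asarray(tets, dtype=np.int64),
        tet_region=np.asarray(tet_region, dtype=np.int64),
        region_names=region_names,
        facets=np.asarray(facets, dtype=np.int64),
        facet_tag=np.asarray(facet_tag, dtype=np.int64),
        surface_names=surface_names,
        cdfs=cdfs,
        detectors=detectors,
        vessels=vessels,
        bronchus=bronchus,
        meta=meta,
    )
    scene.validate()
    return scene


def write_vtu(scene: Scene, path, point_data: dict[str, np.ndarray] | None = None) -> None:
    """Export the mesh with optional nodal fields as ASCII VTU."""
    path = Path(path)
    pd_arrays = point_data or {}
    n, m = scene.n_nodes, scene.n_tets
    out = []
    out.append('<?xml version="1.0"?>')
    out.append(
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">'
    )
    out.append("<UnstructuredGrid>")
    out.append(f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">')
    out.append("<Points>")
    out.append('<DataArray type="Float64" NumberOfComponents="3" format="ascii">')
    out.extend(" ".join(f"{v:.17g}" for v in row) for row in scene.nodes)
    out.append("</DataArray>")
    out.append("</Points>")
    out.append("<Cells>")
    out.append('<DataArray type="Int64" Name="connectivity" format="ascii">')
    out.extend(" ".join(map(str, row)) for row in scene.tets)
    out.append("</DataArray>")
    out.append('<DataArray type="Int64" Name="offsets" format="ascii">')
    out.append(" ".join(str(4 * (i + 1)) for i in range(m)))
    out.append("</DataArray>")
    out.append('<DataArray type="UInt8" Name="types" format="ascii">')
    out.append(" ".join("10" for _ in range(m)))
    out.append("</DataArray>")
    out.append("</Cells>")
    out.append("<CellData>")
    out.append('<DataArray type="Int64" Name="region" format="ascii">')
    out.append(" ".join(map(str, scene.tet_region)))
    out.append("</DataArray>")
    out.append("</CellData>")
    out.append("<PointData>")
    for name, arr in pd_arrays.items():
        out.append(f'<DataArray type="Float64" Name="{name}" format="ascii">')
        out.append(" ".join(f"{v:.17g}" for v in np.asarray(arr, dtype=float)))
        out.append("</DataArray>")
    out.append("</PointData>")
    out.append("</Piece>")
    out.append("</UnstructuredGrid>")
    out.append("</VTKFile>")
    path.write_text("\n".join(out) + "\n")


def write_probe_csv(distances_mm, irradiances, path) -> None:
    """Detector readout table as CSV (distance_mm, irradiance_mW_cm2)."""
    pd.DataFrame(
        {"distance_mm": distances_mm, "irradiance_mW_cm2": irradiances}
    ).to_csv(path, index=False)
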