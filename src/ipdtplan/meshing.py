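"""Structured tetrahedral mesh generation.

Two deterministic generators cover the planning geometries:

* a revolved annular grid for the calibration-phantom block — a cube with a
  full-height cylindrical channel (the fiber track) whose wall carries the
  diffuser Dirichlet band; node rings are mapped radially so the outer
  boundary is exactly the cube surface, and
* a graded Cartesian grid for synthetic airway scenes, with cavities carved
  for the bronchus and the diffuser fibers and regions tagged by element
  centroid.

Hexahedral cells are split into six tetrahedra with the Freudenthal (Kuhn)
pattern, which is conforming on structured grids. Both generators are pure
functions of their parameters: identical inputs give identical meshes.
"""

from __future__ import annotations

import numpy as np

# Freudenthal subdivision: corner bit order (x, y, z) ->
# [v000, v100, v010, v110, v001, v101, v011, v111]
_FREUDENTHAL = np.array(
    [
        [0, 1, 3, 7],
        [0, 1, 5, 7],
        [0, 2, 3, 7],
        [0, 2, 6, 7],
        [0, 4, 5, 7],
        [0, 4, 6, 7],
    ],
    dtype=np.int64,
)


def split_hexes(hexes: np.ndarray) -> np.ndarray:
    """Split (H, 8) hex corner indices into (6H, 4) tetrahedra."""
    return hexes[:, _FREUDENTHAL].reshape(-1, 4)


def orient_tets(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Swap two vertices of negatively oriented tets so all volumes are > 0."""
    x = nodes[tets]
    vol = np.linalg.det(x[:, 1:, :] - x[:, :1, :]) / 6.0
    flip = vol < 0
    tets = tets.copy()
    tets[flip, 0], tets[flip, 1] = tets[flip, 1], tets[flip, 0].copy()
    return tets


def graded_steps(length: float, h0: float, h_max: float, ratio: float = 1.3) -> np.ndarray:
    """1D node offsets over [0, length]: spacing h0 growing geometrically to h_max.

    The final grid is rescaled slightly so the last node lands on ``length``.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    steps = []
    h, total = min(h0, length), 0.0
    while total < length - 1e-12:
        steps.append(min(h, length - total))
        total += steps[-1]
        h = min(h * ratio, h_max)
    pts = np.concatenate([[0.0], np.cumsum(steps)])
    return pts * (length / pts[-1])


def symmetric_band_grid(
    half_height: float, band: float, h_fine: float, h_max: float, ratio: float = 1.3
) -> np.ndarray:
    """Symmetric z grid on [-H, H]: uniform h_fine inside [-band, band]
    (with nodes exactly at 0 and +-band), geometric coarsening outside."""
    n_band = max(1, int(np.ceil(band / h_fine)))
    fine = np.linspace(0.0, band, n_band + 1)
    outer = band + graded_steps(half_height - band, h_fine, h_max, ratio)[1:]
    half = np.concatenate([fine, outer])
    return np.unique(np.concatenate([-half[::-1], half]))


def refined_axis(
    lo: float,
    hi: float,
    h_coarse: float,
    fine_windows: list[tuple[float, float, float]] = (),
    growth: float = 0.35,
) -> np.ndarray:
    """Graded 1D grid on [lo, hi]; spacing h_fine inside each (a, b, h_fine)
    window, growing linearly with distance up to h_coarse outside."""

    def local_h(x: float) -> float:
        h = h_coarse
        for a, b, hf in fine_windows:
            d = max(a - x, x - b, 0.0)
            h = min(h, hf + growth * d)
        return h

    pts = [lo]
    while pts[-1] < hi - 1e-12:
        pts.append(min(pts[-1] + local_h(pts[-1]), hi))
    pts = np.asarray(pts)
    if len(pts) > 2 and (pts[-1] - pts[-2]) < 0.4 * local_h(pts[-2]):
        pts = np.delete(pts, -2)  # avoid a sliver next to the end
    return pts


# ---------------------------------------------------------------------------
# revolved annular block (phantom)
# ---------------------------------------------------------------------------


def revolved_block_mesh(
    channel_radius: float,
    half_edge: float,
    z_grid: np.ndarray,
    n_theta: int,
    h_near: float,
    h_far: float,
    ratio: float = 1.3,
    radial_s: np.ndarray | None = None,
) -> dict:
    """Cube block [-half_edge, half_edge]^3-ish with a full-height axial channel.

    The grid is a tensor product in (radial index i, angular index j, axial
    index k); for each azimuth theta_j the radial stations are stretched so
    the outermost ring lies exactly on the square cross-section boundary.
    Returns nodes, tets and per-node (i, k) indices for facet classification.
    """
    a = channel_radius
    if a >= half_edge:
        raise ValueError("channel radius must be smaller than the block half-edge")
    theta = np.arange(n_theta) * (2.0 * np.pi / n_theta)
    # radial fraction grid graded for the reference radius half_edge
    ref_len = half_edge - a
    if radial_s is None:
        s = graded_steps(ref_len, h_near, h_far, ratio) / ref_len
    else:
        s = np.asarray(radial_s, dtype=float)
    n_r = len(s)
    # theta-dependent outer radius maps the outer ring onto the square
    r_outer = half_edge / np.maximum(np.abs(np.cos(theta)), np.abs(np.sin(theta)))
    radii = a + np.outer(s, (r_outer - a))  # (n_r, n_theta)

    n_z = len(z_grid)
    # node index (i, j, k) -> ((i * n_theta) + j) * n_z + k
    rr = radii[:, :, None]
    tt = theta[None, :, None]
    zz = z_grid[None, None, :]
    x = rr * np.cos(tt) * np.ones_like(zz)
    y = rr * np.sin(tt) * np.ones_like(zz)
    z = np.broadcast_to(zz, x.shape)
    nodes = np.stack([x, y, z], axis=-1).reshape(-1, 3)

    def nid(i, j, k):
        return (i * n_theta + (j % n_theta)) * n_z + k

    i_idx, j_idx, k_idx = np.meshgrid(
        np.arange(n_r - 1), np.arange(n_theta), np.arange(n_z - 1), indexing="ij"
    )
    i_idx, j_idx, k_idx = i_idx.ravel(), j_idx.ravel(), k_idx.ravel()
    hexes = np.stack(
        [
            nid(i_idx, j_idx, k_idx),
            nid(i_idx + 1, j_idx, k_idx),
            nid(i_idx, j_idx + 1, k_idx),
            nid(i_idx + 1, j_idx + 1, k_idx),
            nid(i_idx, j_idx, k_idx + 1),
            nid(i_idx + 1, j_idx, k_idx + 1),
            nid(i_idx, j_idx + 1, k_idx + 1),
            nid(i_idx + 1, j_idx + 1, k_idx + 1),
        ],
        axis=1,
    )
    tets = orient_tets(nodes, split_hexes(hexes))
    node_i = np.repeat(np.arange(n_r), n_theta * n_z)
    node_k = np.tile(np.arange(n_z), n_r * n_theta)
    return {
        "nodes": nodes,
        "tets": tets,
        "node_i": node_i,
        "node_k": node_k,
        "n_r": n_r,
        "n_theta": n_theta,
        "z_grid": z_grid,
    }


# ---------------------------------------------------------------------------
# Cartesian block (airway scenes)
# ---------------------------------------------------------------------------


def cartesian_mesh(xs: np.ndarray, ys: np.ndarray, zs: np.ndarray) -> dict:
    """Tensor-product tet mesh of a box; returns nodes and tets."""
    nx, ny, nz = len(xs), len(ys), len(zs)
    if min(nx, ny, nz) < 2:
        raise ValueError("need at least two grid planes per axis")
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    i, j, k = np.meshgrid(
        np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1), indexing="ij"
    )
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    hexes = np.stack(
        [
            nid(i, j, k),
            nid(i + 1, j, k),
            nid(i, j + 1, k),
            nid(i + 1, j + 1, k),
            nid(i, j, k + 1),
            nid(i + 1, j, k + 1),
            nid(i, j + 1, k + 1),
            nid(i + 1, j + 1, k + 1),
        ],
        axis=1,
    )
    tets = orient_tets(nodes, split_hexes(hexes))
    return {"nodes": nodes, "tets": tets}


def compact_mesh(nodes: np.ndarray, tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop nodes not referenced by any tetrahedron and renumber."""
    used = np.unique(tets)
    remap = -np.ones(len(nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return nodes[used], remap[tets]
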