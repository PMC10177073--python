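"""P1 finite-element solver for the optical diffusion equation.

The fluence rate (the field the planning literature calls "irradiance")
phi(r, t) in mW/cm^2 obeys

    (1/c_n) d(phi)/dt - div(alpha_n grad phi) / c_n ... equivalently
    d(phi)/dt + div(-alpha_n grad phi) + c_n mu_a phi = 0

with a Dirichlet surface source phi = P_laser on each active diffuser
surface, a background-light initial condition phi(r, 0) = P_bg, and the
Robin condition c_n phi + alpha_n grad(phi).n = 0 on the outer boundary.
The weak form is assembled with linear tetrahedral elements; steady state
(the planning default — light equilibrates in nanoseconds) drops the time
derivative, and a backward (implicit) Euler stepper mirrors the transient
problem for verification.

Inactive diffuser surfaces are held at phi = 0 (a perfectly absorbing dark
fiber). This convention makes single-fiber solutions superpose exactly to
the all-fibers-on solution, which the dose accumulation and the power
optimizer rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree
from scipy.special import k0 as bessel_k0

from .geometry import Scene, boundary_faces_with_parents
from .optics import OpticalProperties

#: Above this many free nodes the steady solve switches from a sparse
#: direct factorization to Jacobi-preconditioned conjugate gradients.
DIRECT_SOLVER_NODE_LIMIT = 200_000
SOLVER_RTOL = 1e-10


@dataclass(frozen=True)
class SourceSpec:
    """One active diffuser surface with its Dirichlet irradiance (mW/cm^2)."""

    surface_tag: str
    p_laser: float

    def __post_init__(self) -> None:
        if self.p_laser < 0:
            raise ValueError("p_laser must be nonnegative")


@dataclass(frozen=True)
class TransientSettings:
    """Implicit-Euler stepping controls; p_bg is the background light."""

    dt: float
    t_end: float
    p_bg: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_end < self.dt:
            raise ValueError("t_end must be at least dt")
        if self.p_bg < 0:
            raise ValueError("p_bg must be nonnegative")


@dataclass
class ScalarField:
    """Nodal scalar field over a scene (irradiance mW/cm^2 or fluence J/cm^2)."""

    scene: Scene
    values: np.ndarray
    quantity: str = "irradiance"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.scene.n_nodes,):
            raise ValueError("value count must equal node count")
        if self.quantity not in ("irradiance", "fluence", "effective_fluence"):
            raise ValueError(f"unknown quantity {self.quantity!r}")

    def scaled(self, c: float) -> "ScalarField":
        return ScalarField(self.scene, c * self.values, self.quantity, dict(self.meta))

    def validate(self) -> None:
        vmax = float(self.values.max(initial=0.0))
        if self.quantity == "irradiance" and self.values.min(initial=0.0) < -1e-9 * max(
            vmax, 1.0
        ):
            raise ValueError("irradiance field has negative values beyond tolerance")


@dataclass
class AssembledSystem:
    """Weak-form operators on a scene (all SI-in-cm, weighted as assembled).

    ``mass`` is the plain mass matrix (time-derivative term), ``stiffness``
    the diffusion operator weighted by alpha_n, ``absorption`` the mass
    weighted by c_n mu_a, and ``robin`` the outer-boundary mass weighted by
    c_n. The steady operator is their sum (stiffness + absorption + robin).
    """

    scene: Scene
    properties: dict[str, OpticalProperties]
    mass: sp.csr_matrix
    stiffness: sp.csr_matrix
    absorption: sp.csr_matrix
    robin: sp.csr_matrix
    dirichlet_nodes: dict[str, np.ndarray]
    _steady_factor: object = field(default=None, repr=False)

    @property
    def steady_operator(self) -> sp.csr_matrix:
        return (self.stiffness + self.absorption + self.robin).tocsr()

    @property
    def all_dirichlet(self) -> np.ndarray:
        if not self.dirichlet_nodes:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(list(self.dirichlet_nodes.values())))

    def region_property(self, name: str) -> OpticalProperties:
        return self.properties[name]


def _local_p1(scene: Scene) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-tet volumes, barycentric gradients (M, 4, 3) and node coords."""
    x = scene.nodes[scene.tets]
    e = x[:, 1:, :] - x[:, :1, :]
    det = np.linalg.det(e)
    vol = det / 6.0
    inv = np.linalg.inv(e)
    grads = np.empty((len(scene.tets), 4, 3))
    grads[:, 1:, :] = np.transpose(inv, (0, 2, 1))  # columns of E^{-1}
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    return vol, grads, x


def _scatter(tets: np.ndarray, local: np.ndarray, n: int) -> sp.csr_matrix:
    """Assemble (M, 4, 4) local matrices into a global sparse matrix."""
    rows = np.repeat(tets, 4, axis=1).reshape(-1)
    cols = np.tile(tets, (1, 4)).reshape(-1)
    return sp.coo_matrix((local.reshape(-1), (rows, cols)), shape=(n, n)).tocsr()


def assemble_system(
    scene: Scene, properties: dict[str, OpticalProperties]
) -> AssembledSystem:
    """Assemble mass, diffusion, absorption and Robin operators.

    ``properties`` maps region names (or RegionLabel) to optical
    properties; every region present in the scene must be covered.
    """
    props = {}
    for key, val in properties.items():
        props[getattr(key, "name", key)] = val
    for tag, name in scene.region_names.items():
        if name not in props:
            raise KeyError(f"missing optical properties for region {name!r}")

    vol, grads, _ = _local_p1(scene)
    n = scene.n_nodes
    tets = scene.tets

    alpha = np.empty(scene.n_tets)
    cmua = np.empty(scene.n_tets)
    for tag, name in scene.region_names.items():
        mask = scene.tet_region == tag
        alpha[mask] = props[name].alpha_n
        cmua[mask] = props[name].c_n * props[name].mu_a

    gg = np.einsum("mid,mjd->mij", grads, grads)
    k_local = (alpha * vol)[:, None, None] * gg
    stiffness = _scatter(tets, k_local, n)

    m_pattern = (np.ones((4, 4)) + np.eye(4)) / 20.0
    m_local = vol[:, None, None] * m_pattern
    mass = _scatter(tets, m_local, n)
    absorption = _scatter(tets, (cmua * vol)[:, None, None] * m_pattern, n)

    # Robin term over outer-boundary facets only (not diffuser surfaces)
    faces, parents = boundary_faces_with_parents(scene.tets)
    face_key = {tuple(sorted(f)): p for f, p in zip(faces, parents)}
    try:
        outer_tag = scene.surface_tag_for("outer")
        outer = scene.facets[scene.facet_tag == outer_tag]
    except KeyError:
        outer = scene.facets[:0]
    if len(outer):
        tri = scene.nodes[outer]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        cn = np.array(
            [
                props[scene.region_names[scene.tet_region[face_key[tuple(sorted(f))]]]].c_n
                for f in outer
            ]
        )
        s_pattern = (np.ones((3, 3)) + np.eye(3)) / 12.0
        s_local = (cn * areas)[:, None, None] * s_pattern
        rows = np.repeat(outer, 3, axis=1).reshape(-1)
        cols = np.tile(outer, (1, 3)).reshape(-1)
        robin = sp.coo_matrix((s_local.reshape(-1), (rows, cols)), shape=(n, n)).tocsr()
    else:
        robin = sp.csr_matrix((n, n))

    dirichlet = {}
    for name in scene.diffuser_surface_names():
        tag = scene.surface_tag_for(name)
        dirichlet[name] = np.unique(scene.facets[scene.facet_tag == tag])
    return AssembledSystem(
        scene=scene,
        properties=props,
        mass=mass,
        stiffness=stiffness,
        absorption=absorption,
        robin=robin,
        dirichlet_nodes=dirichlet,
    )


def _dirichlet_values(system: AssembledSystem, sources: list[SourceSpec]) -> np.ndarray:
    """Full-length vector of boundary values; inactive diffusers pinned at 0."""
    known = set(system.scene.diffuser_surface_names())
    g = np.zeros(system.scene.n_nodes)
    for s in sources:
        if s.surface_tag not in known:
            raise KeyError(f"unknown diffuser surface {s.surface_tag!r}")
        g[system.dirichlet_nodes[s.surface_tag]] = s.p_laser
    return g


def solve_steady(system: AssembledSystem, sources: list[SourceSpec]) -> ScalarField:
    """Steady-state irradiance field for the given active diffuser sources."""
    scene = system.scene
    fixed = system.all_dirichlet
    if (
        len(fixed) == 0
        and system.absorption.count_nonzero() == 0
        and system.robin.count_nonzero() == 0
    ):
        raise ValueError(
            "singular system: no Dirichlet surface, no absorption, no Robin boundary"
        )
    g = _dirichlet_values(system, sources)
    a = system.steady_operator
    free = np.setdiff1d(np.arange(scene.n_nodes), fixed, assume_unique=False)
    if not np.any(g > 0):
        return ScalarField(scene, np.zeros(scene.n_nodes), "irradiance", {"residual": 0.0})
    b = -a[free][:, fixed] @ g[fixed]
    x = _solve_spd(system, a, free, b)
    phi = g.copy()
    phi[free] = x
    res = float(np.linalg.norm(a[free] @ phi) / max(np.linalg.norm(b), 1e-300))
    fld = ScalarField(scene, phi, "irradiance", {"residual": res})
    return fld


def _solve_spd(system, a, free, b):
    if len(free) <= DIRECT_SOLVER_NODE_LIMIT:
        if system._steady_factor is None:
            system._steady_factor = spla.splu(a[free][:, free].tocsc())
        return system._steady_factor.solve(b)
    aff = a[free][:, free].tocsr()
    pre = sp.diags(1.0 / aff.diagonal())
    x, info = spla.cg(aff, b, rtol=SOLVER_RTOL, maxiter=20_000, M=pre)
    if info != 0:
        raise RuntimeError(f"conjugate-gradient solver did not converge (info={info})")
    return x


@dataclass
class TransientResult:
    times: np.ndarray
    frames: np.ndarray  # (n_frames, n_nodes)
    scene: Scene

    def field(self, i: int) -> ScalarField:
        return ScalarField(self.scene, self.frames[i], "irradiance")

    @property
    def final(self) -> ScalarField:
        return self.field(-1)


def solve_transient(
    system: AssembledSystem, sources: list[SourceSpec], settings: TransientSettings
) -> TransientResult:
    """Implicit (backward) Euler integration of the transient problem.

    The first frame is the background irradiance P_bg everywhere except the
    Dirichlet nodes; stepping is unconditionally stable and the trajectory
    approaches the steady solution for t_end >> 1 / (c_n mu_a).
    """
    scene = system.scene
    g = _dirichlet_values(system, sources)
    fixed = system.all_dirichlet
    free = np.setdiff1d(np.arange(scene.n_nodes), fixed)
    a = system.steady_operator
    m = system.mass
    dt = settings.dt
    n_steps = max(1, int(round(settings.t_end / dt)))

    phi = np.full(scene.n_nodes, settings.p_bg)
    phi[fixed] = g[fixed]
    frames = [phi.copy()]
    lhs = (m + dt * a)[free][:, free].tocsc()
    factor = spla.splu(lhs)
    m_ff = m[free][:, free]
    m_fc = m[free][:, fixed]
    a_fc = a[free][:, fixed]
    rhs_c = -dt * (a_fc @ g[fixed])
    for _ in range(n_steps):
        rhs = m_ff @ phi[free] + rhs_c
        phi = phi.copy()
        phi[free] = factor.solve(rhs)
        frames.append(phi)
    times = np.arange(n_steps + 1) * dt
    return TransientResult(times=times, frames=np.array(frames), scene=scene)


def analytic_infinite_cylinder(
    props: OpticalProperties, a: float, p_laser: float, rho
) -> np.ndarray | float:
    """Irradiance around an infinitely long diffuser in a homogeneous medium.

    phi(rho) = P_laser K0(mu_eff rho) / K0(mu_eff a) — the cylindrical
    diffusion solution with Dirichlet value P_laser on the fiber surface
    rho = a. Independent closed-form oracle for the FEM in the quasi-2D
    (long-diffuser, mid-plane) limit.
    """
    if a <= 0:
        raise ValueError("fiber radius must be positive")
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr < a):
        raise ValueError("rho must be >= fiber radius a")
    out = p_laser * bessel_k0(props.mu_eff * rho_arr) / bessel_k0(props.mu_eff * a)
    return float(out) if np.isscalar(rho) else out


def probe_field(field: ScalarField, points) -> np.ndarray:
    """Barycentric P1 interpolation of the field at arbitrary interior points."""
    scene = field.scene
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cents = scene.nodes[scene.tets].mean(axis=1)
    tree = _centroid_tree(scene)
    k = min(64, scene.n_tets)
    _, cand = tree.query(pts, k=k)
    cand = np.atleast_2d(cand)
    out = np.empty(len(pts))
    x = scene.nodes[scene.tets]
    for p_i, (p, cands) in enumerate(zip(pts, cand)):
        lam = _barycentric(x[cands], p)
        ok = np.all(lam > -1e-9, axis=1)
        if not np.any(ok):  # fall back to brute force before declaring outside
            lam_all = _barycentric(x, p)
            ok_all = np.all(lam_all > -1e-9, axis=1)
            if not np.any(ok_all):
                raise ValueError(f"point {p.tolist()} is outside the meshed domain")
            t = int(np.argmax(ok_all))
            out[p_i] = lam_all[t] @ field.values[scene.tets[t]]
        else:
            t = cands[int(np.argmax(ok))]
            lam_t = lam[int(np.argmax(ok))]
            out[p_i] = lam_t @ field.values[scene.tets[t]]
    return out


_TREE_CACHE: dict[int, cKDTree] = {}


def _centroid_tree(scene: Scene) -> cKDTree:
    key = id(scene)
    tree = _TREE_CACHE.get(key)
    if tree is None or tree.n != scene.n_tets:
        tree = cKDTree(scene.nodes[scene.tets].mean(axis=1))
        _TREE_CACHE.clear()
        _TREE_CACHE[key] = tree
    return tree


def _barycentric(tet_coords: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of point p in each tet of (T, 4, 3)."""
    single = tet_coords.ndim == 2
    tc = tet_coords[None] if single else tet_coords
    e = np.transpose(tc[:, 1:, :] - tc[:, :1, :], (0, 2, 1))
    rhs = p - tc[:, 0, :]
    lam123 = np.linalg.solve(e, rhs[:, :, None])[:, :, 0]
    lam0 = 1.0 - lam123.sum(axis=1, keepdims=True)
    lam = np.concatenate([lam0, lam123], axis=1)
    return lam[0] if single else lam


def sources_from_cdfs(scene: Scene, active: list[int] | None = None) -> list[SourceSpec]:
    """SourceSpecs for the scene's fibers (all, or the given indices)."""
    idx = range(len(scene.cdfs)) if active is None else active
    return [SourceSpec(f"diffuser_{k}", scene.cdfs[k].p_laser) for k in idx]


def flux_balance(
    system: AssembledSystem, field: ScalarField, sources: list[SourceSpec]
) -> dict[str, float]:
    """Discrete energy budget of a steady solution.

    Returns the c-weighted absorbed power, Robin boundary outflow, Dirichlet
    source inflow (reaction sum) and their relative imbalance; the discrete
    identity inflow = absorbed + outflow holds up to solver tolerance.
    """
    phi = field.values
    absorbed = float(np.sum(system.absorption @ phi))
    outflow = float(np.sum(system.robin @ phi))
    a = system.steady_operator
    fixed = system.all_dirichlet
    inflow = float(np.sum((a @ phi)[fixed]))
    scale = max(abs(inflow), abs(absorbed) + abs(outflow), 1e-300)
    return {
        "absorbed": absorbed,
        "robin_outflow": outflow,
        "source_inflow": inflow,
        "relative_imbalance": abs(inflow - absorbed - outflow) / scale,
    }


def mesh_convergence_study(
    scene_factory,
    levels: int,
    properties: dict[str, OpticalProperties],
    coarsest_h: float,
    refine_ratio: float = 1.5,
    probe_points=None,
    converged_tol: float = 0.02,
):
    """Probe steady irradiances across h-refinement levels.

    ``scene_factory(target_h)`` must return a scene with fibers (and, when
    ``probe_points`` is None, detector points). Reports the probed values
    per level and the successive maximum relative change; convergence is
    flagged when that change drops below ``converged_tol`` (2% default).
    """
    import pandas as pd

    if levels < 2:
        raise ValueError("levels must be >= 2")
    rows = []
    prev = None
    for lev in range(levels):
        h = coarsest_h / refine_ratio**lev
        scene = scene_factory(h)
        pts = probe_points if probe_points is not None else scene.detectors
        if pts is None:
            raise ValueError("no probe points: scene has no detectors")
        system = assemble_system(scene, properties)
        fld = solve_steady(system, sources_from_cdfs(scene))
        vals = probe_field(fld, pts)
        change = (
            np.nan
            if prev is None
            else float(np.max(np.abs(vals - prev) / np.maximum(np.abs(prev), 1e-300)))
        )
        rows.append(
            {
                "target_h": h,
                "n_tets": scene.n_tets,
                "n_nodes": scene.n_nodes,
                "probed": vals,
                "successive_rel_change": change,
                "converged": bool(change < converged_tol) if prev is not None else False,
            }
        )
        prev = vals
    return pd.DataFrame(rows)
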