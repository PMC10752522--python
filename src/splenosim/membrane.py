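"""Coarse-grained RBC membrane mechanics.

Three-dimensional meshes carry the standard cellular-level model: wormlike
chain (WLC) + power-law (POW) springs on edges, dihedral-angle bending
energy, local and global area penalties, and a global volume penalty. Forces
are the exact analytic gradient of the total energy; the reference (stress
free) state is the as-generated mesh.

The macroscopic shear modulus E_s maps to mesh-level spring parameters
through the analytic hexagonal-network relation: with x0 = l0/l_max the
equilibrium spring extension ratio and POW exponent m,

    E_s = [ √3 kBT / (4 l_max x0) (x0/(2(1-x0)^3) - 1/(4(1-x0)^2) + 1/4)
            + 3√3 kp / (4 l0^3) ] ,   m = 2,

which is solved for the persistence length p (kp follows from force balance
at l0). The bending constant is k_b = 2 E_b / √3.

A two-dimensional contour variant (closed polygon: harmonic edge springs,
turning-angle bending, global enclosed-area and perimeter penalties) serves
the reduced desk-scale mode; its mapping constants from (E_s, E_b) are
documented package choices.

Oxygenation dependence: sickle cells stiffen 5× under normoxia and 50×
under hypoxia relative to the normal moduli E_s0 = 4.792 μN/m and
E_b0 = 2.9e-19 J.

Units: μm, s, pN, energy pN·μm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .adhesion import KBT_310
from .geometry import TriMesh, mesh_area_volume

__all__ = [
    "E_S0",
    "E_B0",
    "MembraneParams",
    "MembraneState",
    "MEMBRANE_PRESETS",
    "condition_params",
    "membrane_forces",
    "membrane_energy",
    "stretch_test",
    "Contour2D",
    "contour_forces",
    "contour_energy",
    "make_flat_hex_patch",
    "patch_shear_modulus",
    "SpringOverextensionError",
]

#: normal-RBC shear modulus [pN/μm == μN/m] and bending modulus [pN·μm]
E_S0 = 4.792
E_B0 = 2.9e-19 / 1e-18  # 2.9e-19 J -> 0.29 pN·μm


class SpringOverextensionError(RuntimeError):
    """An edge reached the WLC maximum extension (model undefined beyond)."""


@dataclass(frozen=True)
class MembraneParams:
    """Mesh-level elastic parameter set.

    ``E_s``/``E_b`` are the macroscopic shear/bending moduli; ``x0`` the
    equilibrium-to-maximum spring extension ratio; ``m`` the POW exponent.
    Stiffnesses of the penalty terms keep local/global area and volume within
    a fraction of a percent during dynamics.
    """

    E_s: float = E_S0
    E_b: float = E_B0
    x0: float = 1.0 / 2.2
    m: int = 2
    k_area_local: float = 200.0  # pN/μm
    k_area_global: float = 1000.0  # pN/μm
    k_volume: float = 1000.0  # pN/μm²
    kBT: float = KBT_310
    # 2D contour mapping constants (dimensionless / per-μm factors)
    edge_spring_scale_2d: float = 0.25
    bend_scale_2d: float = 0.5
    k_area_2d: float = 50.0
    k_perimeter_2d: float = 50.0

    def __post_init__(self) -> None:
        for name in ("E_s", "E_b", "k_area_local", "k_area_global", "k_volume"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 < self.x0 < 1:
            raise ValueError("x0 must be in (0, 1)")

    @property
    def moduli_multiple(self) -> tuple[float, float]:
        return self.E_s / E_S0, self.E_b / E_B0


MEMBRANE_PRESETS: dict[str, MembraneParams] = {
    "normal": MembraneParams(E_s=E_S0, E_b=E_B0),
    "sickle_normoxia": MembraneParams(E_s=5 * E_S0, E_b=5 * E_B0),
    "sickle_hypoxia": MembraneParams(E_s=50 * E_S0, E_b=50 * E_B0),
}


def condition_params(
    condition: str, base: MembraneParams | None = None, cell_type: str = "sickle"
) -> MembraneParams:
    """Oxygenation-dependent moduli: sickle cells are 5× (normoxia) or 50×
    (hypoxia) stiffer than normal; normal cells are unaffected."""
    base = MEMBRANE_PRESETS["normal"] if base is None else base
    if cell_type == "normal":
        return base
    if cell_type != "sickle":
        raise ValueError(f"unknown cell type {cell_type!r}")
    if condition == "normoxia":
        mult = 5.0
    elif condition == "hypoxia":
        mult = 50.0
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return replace(base, E_s=mult * base.E_s, E_b=mult * base.E_b)


# ---------------------------------------------------------------------------
# Spring parameter mapping
# ---------------------------------------------------------------------------


def _wlc_pow_constants(params: MembraneParams, l0_mean: float) -> tuple[float, float]:
    """Persistence length p and mean POW coefficient kp for the target E_s.

    Per-edge POW coefficients scale as l0_e² so every edge is individually at
    equilibrium at its own rest length (exactly stress-free reference)."""
    x0, kBT = params.x0, params.kBT
    l_max = l0_mean / x0
    a1 = np.sqrt(3.0) * kBT / (4.0 * l_max * x0) * (
        x0 / (2.0 * (1 - x0) ** 3) - 1.0 / (4.0 * (1 - x0) ** 2) + 0.25
    )
    b = 1.0 / (4.0 * (1 - x0) ** 2) - 0.25 + x0
    a2 = 3.0 * np.sqrt(3.0) * kBT * b / (4.0 * l0_mean)
    p = (a1 + a2) / params.E_s
    kp = l0_mean**2 * (kBT / p) * b
    return p, kp


def _pow_b(params: MembraneParams) -> float:
    x0 = params.x0
    return 1.0 / (4.0 * (1 - x0) ** 2) - 0.25 + x0


# ---------------------------------------------------------------------------
# Membrane state (3D)
# ---------------------------------------------------------------------------


@dataclass
class MembraneState:
    """Positions/velocities plus frozen reference (stress-free) quantities."""

    positions: np.ndarray
    velocities: np.ndarray
    triangles: np.ndarray
    edges: np.ndarray  # (E, 2)
    wings: np.ndarray  # (E, 2) opposite vertices (k, h) per edge
    ref_edge_length: np.ndarray
    ref_dihedral: np.ndarray
    ref_tri_area: np.ndarray
    ref_area: float
    ref_volume: float
    persistence: float
    k_pow: float

    @classmethod
    def from_mesh(cls, mesh: TriMesh, params: MembraneParams) -> "MembraneState":
        mesh.validate()
        edges = mesh.edges
        wings = _edge_wings(mesh.triangles, edges)
        x = mesh.vertices.copy()
        lengths = np.linalg.norm(x[edges[:, 1]] - x[edges[:, 0]], axis=1)
        dihedrals = _dihedral_angles(x, edges, wings)
        _, tri_areas = mesh.triangle_normals_areas()
        area, volume = mesh_area_volume(mesh)
        p, kp = _wlc_pow_constants(params, float(lengths.mean()))
        return cls(
            positions=x,
            velocities=np.zeros_like(x),
            triangles=mesh.triangles.copy(),
            edges=edges,
            wings=wings,
            ref_edge_length=lengths,
            ref_dihedral=dihedrals,
            ref_tri_area=tri_areas,
            ref_area=area,
            ref_volume=volume,
            persistence=p,
            k_pow=kp,
        )


def _edge_wings(triangles: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """For each undirected edge (i, j), the two opposite (wing) vertices,
    ordered so wing 0 belongs to the triangle containing directed (i, j)."""
    lookup: dict[tuple[int, int], int] = {}
    for t in triangles:
        for a, b, c in ((t[0], t[1], t[2]), (t[1], t[2], t[0]), (t[2], t[0], t[1])):
            lookup[(int(a), int(b))] = int(c)
    wings = np.empty_like(edges)
    for e, (i, j) in enumerate(edges):
        wings[e, 0] = lookup[(int(i), int(j))]
        wings[e, 1] = lookup[(int(j), int(i))]
    return wings


def _dihedral_angles(x: np.ndarray, edges: np.ndarray, wings: np.ndarray) -> np.ndarray:
    """Signed dihedral angle about each edge (proper dihedral k-i-j-h)."""
    xi, xj = x[edges[:, 0]], x[edges[:, 1]]
    xk, xh = x[wings[:, 0]], x[wings[:, 1]]
    b1 = xi - xk
    b2 = xj - xi
    b3 = xh - xj
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    sin_t = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / np.where(b2n < 1e-300, 1.0, b2n)
    cos_t = np.einsum("ij,ij->i", n1, n2)
    return np.arctan2(sin_t, cos_t)


def _dihedral_gradients(x, edges, wings):
    """θ and its gradients w.r.t. (k, i, j, h) for every edge."""
    xi, xj = x[edges[:, 0]], x[edges[:, 1]]
    xk, xh = x[wings[:, 0]], x[wings[:, 1]]
    b1 = xi - xk
    b2 = xj - xi
    b3 = xh - xj
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    sin_t = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / b2n
    cos_t = np.einsum("ij,ij->i", n1, n2)
    theta = np.arctan2(sin_t, cos_t)
    g_k = (-b2n / n1sq)[:, None] * n1
    g_h = (b2n / n2sq)[:, None] * n2
    c12 = (np.einsum("ij,ij->i", b1, b2) / b2n**2)[:, None]
    c32 = (np.einsum("ij,ij->i", b3, b2) / b2n**2)[:, None]
    g_i = -(1.0 + c12) * g_k + c32 * g_h
    g_j = c12 * g_k - (1.0 + c32) * g_h
    return theta, g_k, g_i, g_j, g_h


def _triangle_area_gradients(x, triangles):
    v0, v1, v2 = x[triangles[:, 0]], x[triangles[:, 1]], x[triangles[:, 2]]
    n = np.cross(v1 - v0, v2 - v0)
    a = 0.5 * np.linalg.norm(n, axis=1)
    nhat = n / (2.0 * a)[:, None]
    g0 = 0.5 * np.cross(nhat, v2 - v1)
    g1 = 0.5 * np.cross(nhat, v0 - v2)
    g2 = 0.5 * np.cross(nhat, v1 - v0)
    return a, g0, g1, g2


def membrane_energy(state: MembraneState, params: MembraneParams, positions=None) -> float:
    """Total membrane elastic energy at ``positions`` (default: state's)."""
    x = state.positions if positions is None else positions
    kBT, p, kp = params.kBT, state.persistence, state.k_pow
    l = np.linalg.norm(x[state.edges[:, 1]] - x[state.edges[:, 0]], axis=1)
    l_max = state.ref_edge_length / params.x0
    xr = l / l_max
    if np.any(xr >= 1.0):
        raise SpringOverextensionError("edge beyond WLC maximum extension")
    e_wlc = kBT * l_max / (4.0 * p) * (3.0 * xr**2 - 2.0 * xr**3) / (1.0 - xr)
    kp_e = state.ref_edge_length**2 * (kBT / p) * _pow_b(params)
    e_pow = kp_e / l
    theta = _dihedral_angles(x, state.edges, state.wings)
    k_b = 2.0 * params.E_b / np.sqrt(3.0)
    e_bend = k_b * (1.0 - np.cos(theta - state.ref_dihedral))
    a, *_ = _triangle_area_gradients(x, state.triangles)
    e_la = params.k_area_local * (a - state.ref_tri_area) ** 2 / (2.0 * state.ref_tri_area)
    area = a.sum()
    e_ga = params.k_area_global * (area - state.ref_area) ** 2 / (2.0 * state.ref_area)
    vol = np.einsum(
        "ij,ij->i", x[state.triangles[:, 0]], np.cross(x[state.triangles[:, 1]], x[state.triangles[:, 2]])
    ).sum() / 6.0
    e_vol = params.k_volume * (vol - state.ref_volume) ** 2 / (2.0 * state.ref_volume)
    return float(e_wlc.sum() + e_pow.sum() + e_bend.sum() + e_la.sum() + e_ga + e_vol)


def membrane_forces(state: MembraneState, params: MembraneParams, positions=None) -> np.ndarray:
    """Per-vertex elastic force, the exact −∇ of :func:`membrane_energy`.

    Internal forces only: they sum to zero and carry no net torque. Raises
    :class:`SpringOverextensionError` if an edge reaches max extension.
    """
    x = state.positions if positions is None else positions
    f = np.zeros_like(x)
    kBT, p, kp = params.kBT, state.persistence, state.k_pow
    ei, ej = state.edges[:, 0], state.edges[:, 1]
    d = x[ej] - x[ei]
    l = np.linalg.norm(d, axis=1)
    l_max = state.ref_edge_length / params.x0
    xr = l / l_max
    if np.any(xr >= 1.0):
        raise SpringOverextensionError("edge beyond WLC maximum extension")
    # dE/dl: WLC tension (positive) minus POW repulsion
    t_wlc = (kBT / p) * (1.0 / (4.0 * (1.0 - xr) ** 2) - 0.25 + xr)
    kp_e = state.ref_edge_length**2 * (kBT / p) * _pow_b(params)
    t_pow = -kp_e / l**2
    tension = t_wlc + t_pow
    fvec = (tension / l)[:, None] * d  # force on i toward j when tension > 0
    np.add.at(f, ei, fvec)
    np.add.at(f, ej, -fvec)

    theta, g_k, g_i, g_j, g_h = _dihedral_gradients(x, state.edges, state.wings)
    k_b = 2.0 * params.E_b / np.sqrt(3.0)
    dE = (k_b * np.sin(theta - state.ref_dihedral))[:, None]
    np.add.at(f, state.wings[:, 0], -dE * g_k)
    np.add.at(f, ei, -dE * g_i)
    np.add.at(f, ej, -dE * g_j)
    np.add.at(f, state.wings[:, 1], -dE * g_h)

    a, g0, g1, g2 = _triangle_area_gradients(x, state.triangles)
    coef_local = (params.k_area_local * (a - state.ref_tri_area) / state.ref_tri_area)[:, None]
    area = a.sum()
    coef_global = params.k_area_global * (area - state.ref_area) / state.ref_area
    for gi, col in ((g0, 0), (g1, 1), (g2, 2)):
        np.add.at(f, state.triangles[:, col], -(coef_local + coef_global) * gi)

    t0, t1, t2 = state.triangles.T
    vol = np.einsum("ij,ij->i", x[t0], np.cross(x[t1], x[t2])).sum() / 6.0
    coef_v = params.k_volume * (vol - state.ref_volume) / state.ref_volume
    np.add.at(f, t0, -coef_v * np.cross(x[t1], x[t2]) / 6.0)
    np.add.at(f, t1, -coef_v * np.cross(x[t2], x[t0]) / 6.0)
    np.add.at(f, t2, -coef_v * np.cross(x[t0], x[t1]) / 6.0)
    return f


# ---------------------------------------------------------------------------
# Quasi-static stretch test (calibration harness)
# ---------------------------------------------------------------------------


def stretch_test(
    mesh: TriMesh,
    params: MembraneParams,
    force_range: np.ndarray,
    load_fraction: float = 0.1,
) -> dict[str, np.ndarray]:
    """Axial stretching of a cell between opposing end loads.

    Forces ±F/2 are spread over the ``load_fraction`` of vertices at each x
    extreme; each load level is relaxed quasi-statically (L-BFGS on the total
    energy with the analytic gradient). Returns axial and transverse
    diameters per force [pN]. Deterministic.
    """
    from scipy.optimize import minimize

    state = MembraneState.from_mesh(mesh, params)
    x0 = state.positions.copy()
    n = len(x0)
    n_load = max(int(round(load_fraction * n)), 3)
    order = np.argsort(x0[:, 0])
    neg, pos = order[:n_load], order[-n_load:]
    axial, transverse = [], []
    forces = np.asarray(force_range, dtype=np.float64)
    current = x0.copy()
    for F in forces:
        load = np.zeros_like(x0)
        load[pos, 0] = 0.5 * F / n_load
        load[neg, 0] = -0.5 * F / n_load

        def fun(flat):
            pts = flat.reshape(-1, 3)
            try:
                e = membrane_energy(state, params, pts) - np.sum(load * pts)
                g = -(membrane_forces(state, params, pts) + load)
            except SpringOverextensionError:
                return 1e12, np.zeros_like(flat)
            return e, g.ravel()

        res = minimize(fun, current.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-9})
        current = res.x.reshape(-1, 3)
        axial.append(np.ptp(current[:, 0]))
        transverse.append(np.ptp(current[:, 1]))
    return {
        "force": forces,
        "axial_diameter": np.asarray(axial),
        "transverse_diameter": np.asarray(transverse),
    }


# ---------------------------------------------------------------------------
# Flat-patch shear modulus validation
# ---------------------------------------------------------------------------


def make_flat_hex_patch(n: int = 10, l0: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Flat triangulated hexagonal-lattice patch (positions, triangles)."""
    pts = []
    index = {}
    for row in range(n):
        for col in range(n):
            x = (col + 0.5 * (row % 2)) * l0
            y = row * l0 * np.sqrt(3.0) / 2.0
            index[(row, col)] = len(pts)
            pts.append((x, y, 0.0))
    tris = []
    for row in range(n - 1):
        for col in range(n - 1):
            a = index[(row, col)]
            b = index[(row, col + 1)]
            c = index[(row + 1, col)]
            d = index[(row + 1, col + 1)]
            if row % 2 == 0:
                tris.append((a, b, c))
                tris.append((b, d, c))
            else:
                tris.append((a, b, d))
                tris.append((a, d, c))
    return np.asarray(pts, dtype=np.float64), np.asarray(tris, dtype=np.int64)


def patch_shear_modulus(params: MembraneParams, n: int = 12, l0: float = 0.5,
                        gamma: float = 5e-3) -> float:
    """Effective shear modulus of the spring network from the energy density
    under affine simple shear of a flat patch.

    Simple shear preserves triangle areas exactly, so only the springs
    contribute; μ_eff = d²u/dγ² by central differences. Independent of the
    force path (energies only)."""
    pts, tris = make_flat_hex_patch(n, l0)
    edges = np.unique(np.sort(np.concatenate(
        [tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]]), axis=1), axis=0)
    lengths0 = np.linalg.norm(pts[edges[:, 1]] - pts[edges[:, 0]], axis=1)
    p, kp = _wlc_pow_constants(params, float(lengths0.mean()))
    l_max = lengths0 / params.x0
    e1 = pts[tris[:, 1], :2] - pts[tris[:, 0], :2]
    e2 = pts[tris[:, 2], :2] - pts[tris[:, 0], :2]
    area = 0.5 * np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]).sum()

    def spring_energy(g):
        q = pts.copy()
        q[:, 0] += g * q[:, 1]
        l = np.linalg.norm(q[edges[:, 1]] - q[edges[:, 0]], axis=1)
        xr = l / l_max
        e = params.kBT * l_max / (4.0 * p) * (3 * xr**2 - 2 * xr**3) / (1 - xr) + kp / l
        return e.sum()

    u = (spring_energy(gamma) - 2 * spring_energy(0.0) + spring_energy(-gamma)) / gamma**2
    return float(u / area)


# ---------------------------------------------------------------------------
# 2D contour membrane (reduced desk-scale mode)
# ---------------------------------------------------------------------------


@dataclass
class Contour2D:
    """Closed-polygon membrane state for the 2D reduced mode."""

    positions: np.ndarray  # (N, 2)
    velocities: np.ndarray
    ref_edge_length: np.ndarray
    ref_angle: np.ndarray
    ref_area: float
    ref_perimeter: float
    k_edge: float
    k_angle: float
    k_area: float
    k_perimeter: float

    @classmethod
    def from_polygon(cls, positions: np.ndarray, params: MembraneParams) -> "Contour2D":
        x = np.asarray(positions, dtype=np.float64)
        n = len(x)
        d = np.roll(x, -1, axis=0) - x
        lengths = np.linalg.norm(d, axis=1)
        angles = _turning_angles(x)
        area = _polygon_area(x)
        if area < 0:
            raise ValueError("polygon must be counter-clockwise")
        l0 = float(lengths.mean())
        return cls(
            positions=x.copy(),
            velocities=np.zeros_like(x),
            ref_edge_length=lengths,
            ref_angle=angles,
            ref_area=area,
            ref_perimeter=float(lengths.sum()),
            k_edge=params.edge_spring_scale_2d * params.E_s,
            k_angle=params.bend_scale_2d * params.E_b / l0,
            k_area=params.k_area_2d,
            k_perimeter=params.k_perimeter_2d,
        )


def _polygon_area(x: np.ndarray) -> float:
    return float(0.5 * np.sum(x[:, 0] * np.roll(x[:, 1], -1) - np.roll(x[:, 0], -1) * x[:, 1]))


def _turning_angles(x: np.ndarray) -> np.ndarray:
    e_prev = x - np.roll(x, 1, axis=0)
    e_next = np.roll(x, -1, axis=0) - x
    cross = e_prev[:, 0] * e_next[:, 1] - e_prev[:, 1] * e_next[:, 0]
    dot = np.einsum("ij,ij->i", e_prev, e_next)
    return np.arctan2(cross, dot)


def contour_energy(c: Contour2D, positions=None) -> float:
    x = c.positions if positions is None else positions
    d = np.roll(x, -1, axis=0) - x
    l = np.linalg.norm(d, axis=1)
    e_spring = 0.5 * c.k_edge * ((l - c.ref_edge_length) ** 2).sum()
    phi = _turning_angles(x)
    e_bend = c.k_angle * (1.0 - np.cos(phi - c.ref_angle)).sum()
    area = _polygon_area(x)
    e_area = 0.5 * c.k_area * (area - c.ref_area) ** 2 / c.ref_area
    peri = l.sum()
    e_peri = 0.5 * c.k_perimeter * (peri - c.ref_perimeter) ** 2 / c.ref_perimeter
    return float(e_spring + e_bend + e_area + e_peri)


def contour_forces(c: Contour2D, positions=None) -> np.ndarray:
    """Exact −∇ of :func:`contour_energy` (numpy reference used by tests;
    the engine kernel mirrors it)."""
    x = c.positions if positions is None else positions
    n = len(x)
    f = np.zeros_like(x)
    d = np.roll(x, -1, axis=0) - x
    l = np.linalg.norm(d, axis=1)
    dhat = d / l[:, None]
    # springs + perimeter (both act along edges)
    peri = l.sum()
    tension = c.k_edge * (l - c.ref_edge_length) + c.k_perimeter * (peri - c.ref_perimeter) / c.ref_perimeter
    fvec = tension[:, None] * dhat
    f += fvec
    f -= np.roll(fvec, 1, axis=0)
    # bending: E = ½ k Σ (φ_i - φ0_i)²; φ_i depends on x_{i-1}, x_i, x_{i+1}
    e_prev = x - np.roll(x, 1, axis=0)
    e_next = np.roll(x, -1, axis=0) - x
    lp = np.linalg.norm(e_prev, axis=1) ** 2
    ln = np.linalg.norm(e_next, axis=1) ** 2
    phi = _turning_angles(x)
    coef = c.k_angle * np.sin(phi - c.ref_angle)
    perp_prev = np.column_stack([-e_prev[:, 1], e_prev[:, 0]]) / lp[:, None]
    perp_next = np.column_stack([-e_next[:, 1], e_next[:, 0]]) / ln[:, None]
    # φ_i = angle(e_next) - angle(e_prev):
    # dφ_i/dx_{i-1} = +perp_prev ; dφ_i/dx_{i+1} = +perp_next ;
    # dφ_i/dx_i = -perp_prev - perp_next
    grad_prev = perp_prev
    grad_next = perp_next
    grad_self = -perp_prev - perp_next
    f -= coef[:, None] * grad_self
    np.add.at(f, (np.arange(n) - 1) % n, -coef[:, None] * grad_prev)
    np.add.at(f, (np.arange(n) + 1) % n, -coef[:, None] * grad_next)
    # area: dA/dx_i = ½ (y_{i+1} - y_{i-1}, x_{i-1} - x_{i+1})
    area = _polygon_area(x)
    ca = c.k_area * (area - c.ref_area) / c.ref_area
    grad_a = 0.5 * np.column_stack([
        np.roll(x[:, 1], -1) - np.roll(x[:, 1], 1),
        np.roll(x[:, 0], 1) - np.roll(x[:, 0], -1),
    ])
    f -= ca * grad_a
    return f
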