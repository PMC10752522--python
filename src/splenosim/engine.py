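"""Orchestration: units, configuration, seeding, time integration.

The engine advances suspensions of elastic cells past rigid wall-adhered
macrophages in a shear channel. The workhorse is the reduced 2D mode: cell
cross-sections (closed polygons) move in the (x, z) plane under membrane
elasticity, ambient Couette flow with Stokes drag and settling, thermal
noise, stochastic adhesion bonds to macrophage arcs, Morse intercellular
forces, and soft excluded-volume repulsion from walls and macrophages. A
velocity-Verlet integrator runs inside a numba kernel in fixed-size chunks;
all randomness is drawn from named, chunk-keyed Philox streams, which makes
runs bitwise reproducible and restartable at chunk boundaries.

Times reported to the user are multiplied by ``time_scaling`` (an accelerated
time-scale relabelling); the dynamics are invariant to it.

Internal units: μm, s, pN. :class:`UnitSystem` maps between these physical
units and the native simulation-unit convention of the adhesion parameter
table (length 1 μm, time 1.845e-3 s, stress 4.82e-2 μN/m).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml
from numba import njit

from . import geometry
from .adhesion import (
    KBT_310,
    ADHESION_PRESETS,
    AdhesionParams,
    AggregationParams,
    BondRegistry,
)
from .fluid import AmbientShearCoupling, ChannelDomain, DpdParams, TimestepError, couette_profile
from .geometry import MacrophageSpec
from .membrane import MEMBRANE_PRESETS, Contour2D, MembraneParams

__all__ = [
    "UnitSystem",
    "map_units",
    "SimulationConfig",
    "CellGroup",
    "SimulationState",
    "Trajectory",
    "Simulation",
    "initialize",
    "PackingError",
    "rbc_outline_2d",
]


class PackingError(ValueError):
    """Requested hematocrit cannot be realised without overlaps."""


# ---------------------------------------------------------------------------
# Units
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UnitSystem:
    """Simulation-unit ↔ physical-unit conversion.

    Anchors follow the adhesion parameter table's dual columns: the length
    unit is 1 μm; the time unit comes from the on-rate column
    (100 sim ↔ 5.42e4 s⁻¹); the stress unit from the reactive-strength
    column (10.58 sim ↔ 0.51 μN/m). All other factors are derived from
    these three.
    """

    length_um: float = 1.0
    time_s: float = 100.0 / 5.42e4
    stress_uN_per_m: float = 0.51 / 10.58

    def factor(self, quantity: str) -> float:
        """Physical units per simulation unit for ``quantity``."""
        L, T, S = self.length_um, self.time_s, self.stress_uN_per_m
        table = {
            "length": L,  # μm
            "time": T,  # s
            "rate": 1.0 / T,  # 1/s
            "velocity": L / T,  # μm/s
            "stress": S,  # μN/m (also spring stiffness)
            "force": S * L,  # pN  (μN/m · μm = 1e-12 N)
            "energy": S * L * L,  # pN·μm
        }
        if quantity not in table:
            raise KeyError(f"unknown quantity {quantity!r}")
        return table[quantity]

    def to_physical(self, value, quantity: str):
        return np.asarray(value, dtype=np.float64) * self.factor(quantity)

    def to_simulation(self, value, quantity: str):
        return np.asarray(value, dtype=np.float64) / self.factor(quantity)


def map_units(value, quantity: str, direction: str, units: UnitSystem | None = None):
    """Convert ``value`` between simulation and physical units.

    ``direction`` is ``"to_physical"`` or ``"to_simulation"``; round trips
    are identities to better than 1e-12 relative.
    """
    units = UnitSystem() if units is None else units
    if direction == "to_physical":
        return units.to_physical(value, quantity)
    if direction == "to_simulation":
        return units.to_simulation(value, quantity)
    raise ValueError("direction must be 'to_physical' or 'to_simulation'")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellGroup:
    """A population of identical cells: morphology and count."""

    shape: str = "biconcave"
    count: int = 1


@dataclass
class SimulationConfig:
    """Everything needed for a reproducible run.

    The velocity schedule is piecewise-constant: a list of (start time [s],
    top-wall speed [μm/s]) pairs; a single pair means constant velocity.
    ``hematocrit`` (area fraction in 2D mode) is realised by scaling the
    channel length at fixed cell count, mirroring the experimental protocol.
    """

    domain: ChannelDomain = field(default_factory=lambda: ChannelDomain(L_x=200.0, h=20.0))
    fluid: DpdParams = field(default_factory=DpdParams)
    membrane_condition: str = "sickle_hypoxia"
    adhesion_preset: str = "hypoxia"
    adhesion_overrides: dict = field(default_factory=dict)
    aggregation: AggregationParams = field(default_factory=lambda: AggregationParams(enabled=False))
    cells: list[CellGroup] = field(default_factory=lambda: [CellGroup("sickle", 8)])
    hematocrit: float | None = 0.02
    macrophages: list[MacrophageSpec] = field(
        default_factory=lambda: [MacrophageSpec(radius=11.0, cap_height=11.0, base_center=(30.0, 0.0))]
    )
    velocity_schedule: list[tuple[float, float]] = field(default_factory=lambda: [(0.0, 150.0)])
    n_steps: int = 100_000
    dt: float = 2.0e-5
    output_every: int = 1000
    master_seed: int = 0
    time_scaling: float = 1.0
    mode: str = "2d"
    coupling: AmbientShearCoupling = field(default_factory=AmbientShearCoupling)
    n_vertices_2d: int = 32
    vertex_relax_time: float = 1.0e-3  # s, inertia m_v = ζ_v · τ
    adhesive_site_spacing: int = 2
    wall_repulsion_k: float = 25.0  # pN/μm
    wall_repulsion_range: float = 0.15  # μm
    store_positions: bool = True
    chunk_steps: int = 500

    def validate(self) -> None:
        if self.hematocrit is not None and not (0.0 < self.hematocrit <= 0.7):
            raise ValueError("hematocrit must lie in (0, 0.7]")
        if any(u < 0 for _, u in self.velocity_schedule) or not self.velocity_schedule:
            raise ValueError("velocity schedule must be nonempty and nonnegative")
        if self.membrane_condition not in MEMBRANE_PRESETS:
            raise ValueError(f"unknown membrane preset {self.membrane_condition!r}")
        if self.adhesion_preset not in ADHESION_PRESETS:
            raise ValueError(f"unknown adhesion preset {self.adhesion_preset!r}")
        for m in self.macrophages:
            m.validate()
        if self.mode not in ("2d", "3d"):
            raise ValueError("mode must be '2d' or '3d'")
        if self.dt <= 0 or self.n_steps < 0:
            raise ValueError("dt must be positive, n_steps nonnegative")

    @property
    def adhesion(self) -> AdhesionParams:
        base = ADHESION_PRESETS[self.adhesion_preset]
        return dataclasses.replace(base, **self.adhesion_overrides) if self.adhesion_overrides else base

    @property
    def membrane(self) -> MembraneParams:
        return MEMBRANE_PRESETS[self.membrane_condition]

    def u_top_at(self, t: float) -> float:
        u = self.velocity_schedule[0][1]
        for t0, val in self.velocity_schedule:
            if t >= t0 - 1e-15:
                u = val
        return u

    def to_yaml(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return yaml.safe_dump(enc(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        raw = yaml.safe_load(text)
        raw["domain"] = ChannelDomain(**raw["domain"])
        raw["fluid"] = DpdParams(**raw["fluid"])
        raw["aggregation"] = AggregationParams(**raw["aggregation"])
        raw["cells"] = [CellGroup(**c) for c in raw["cells"]]
        raw["macrophages"] = [
            MacrophageSpec(
                radius=m["radius"],
                cap_height=m["cap_height"],
                base_center=tuple(m["base_center"]),
                radius_range=tuple(m["radius_range"]),
            )
            for m in raw["macrophages"]
        ]
        raw["velocity_schedule"] = [tuple(p) for p in raw["velocity_schedule"]]
        raw["coupling"] = AmbientShearCoupling(**raw["coupling"])
        return cls(**raw)

    def config_hash(self) -> str:
        import hashlib

        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# 2D cell outlines
# ---------------------------------------------------------------------------


def rbc_outline_2d(shape: str, n_vertices: int = 32, seed: int = 0,
                   target_area: float | None = None) -> np.ndarray:
    """Closed (x, z) cross-section polygon for one cell morphology,
    counter-clockwise, resampled to uniform arclength.

    All shapes are normalised to the same enclosed area (the discocyte
    cross-section, ≈10.6 μm², unless ``target_area`` overrides), the 2D
    counterpart of equal cell volume.
    """
    dense = 1024
    if shape == "biconcave":
        rho = np.linspace(-1.0, 1.0, dense // 2)
        top = np.column_stack([0.5 * geometry._EF_D0 * rho, geometry.biconcave_profile(np.abs(rho))])
        bottom = top[::-1].copy()
        bottom[:, 1] *= -1.0
        outline = np.vstack([top, bottom[1:-1]])
    elif shape == "elongated":
        t = np.linspace(0, 2 * np.pi, dense, endpoint=False)
        outline = np.column_stack([6.8 * np.cos(t), 1.35 * np.sin(t)])
    elif shape == "granular":
        rng = np.random.default_rng(seed)
        phase = rng.uniform(0, 2 * np.pi)
        t = np.linspace(0, 2 * np.pi, dense, endpoint=False)
        r = 1.9 * (1.0 + 0.16 * np.cos(5 * t + phase))
        outline = np.column_stack([r * np.cos(t), r * np.sin(t)])
    elif shape == "sickle":
        t = np.linspace(0, 2 * np.pi, dense, endpoint=False)
        body = np.column_stack([7.0 * np.cos(t), 1.3 * np.sin(t)])
        curv = 0.09
        rad = 1.0 / curv
        th = body[:, 0] * curv
        x, z = body[:, 0].copy(), body[:, 1].copy()
        body[:, 0] = (rad + z) * np.sin(th)
        body[:, 1] = (rad + z) * np.cos(th) - rad
        outline = body
    else:
        raise ValueError(f"unknown shape {shape!r}")
    # ensure counter-clockwise
    area = 0.5 * np.sum(
        outline[:, 0] * np.roll(outline[:, 1], -1) - np.roll(outline[:, 0], -1) * outline[:, 1]
    )
    if area < 0:
        outline = outline[::-1].copy()
        area = -area
    if target_area is None:
        if shape == "biconcave":
            target_area = area
        else:
            target_area = rbc_outline_2d("biconcave", n_vertices=n_vertices)[0] * 0.0 + _BICONCAVE_AREA_2D
    outline *= np.sqrt(target_area / area)
    # uniform arclength resample
    seg = np.linalg.norm(np.roll(outline, -1, axis=0) - outline, axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    snew = np.linspace(0.0, total, n_vertices, endpoint=False)
    closed = np.vstack([outline, outline[:1]])
    out = np.column_stack(
        [np.interp(snew, s, closed[:, 0]), np.interp(snew, s, closed[:, 1])]
    )
    return out


def _compute_biconcave_area_2d() -> float:
    rho = np.linspace(-1.0, 1.0, 2001)
    x = 0.5 * geometry._EF_D0 * rho
    z = geometry.biconcave_profile(np.abs(rho))
    return float(2.0 * np.trapezoid(z, x))


_BICONCAVE_AREA_2D = _compute_biconcave_area_2d()


# ---------------------------------------------------------------------------
# Simulation state and trajectory
# ---------------------------------------------------------------------------


@dataclass
class SimulationState:
    """All mutable dynamical state; advanced only by the engine."""

    positions: np.ndarray  # (N, 2)
    velocities: np.ndarray
    bonded: np.ndarray  # (N,) uint8
    anchor: np.ndarray  # (N, 2)
    t_form: np.ndarray  # (N,)
    step: int
    time: float

    def copy(self) -> "SimulationState":
        return SimulationState(
            self.positions.copy(),
            self.velocities.copy(),
            self.bonded.copy(),
            self.anchor.copy(),
            self.t_form.copy(),
            self.step,
            self.time,
        )


@dataclass
class Trajectory:
    """Snapshots at the output cadence (times in reported, scaled units)."""

    times: list = field(default_factory=list)
    centroids: list = field(default_factory=list)  # (C, 2) per snapshot
    cell_speeds: list = field(default_factory=list)  # (C,) per snapshot
    bond_counts: list = field(default_factory=list)  # (C,) per snapshot
    u_top: list = field(default_factory=list)
    positions: list = field(default_factory=list)  # optional full frames

    def as_arrays(self) -> dict[str, np.ndarray]:
        return {
            "times": np.asarray(self.times),
            "centroids": np.asarray(self.centroids),
            "cell_speeds": np.asarray(self.cell_speeds),
            "bond_counts": np.asarray(self.bond_counts),
            "u_top": np.asarray(self.u_top),
        }


# ---------------------------------------------------------------------------
# Chunked 2D dynamics kernel
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _assay_chunk_kernel(
    pos, vel, forces,
    bonded, anchor_x, anchor_z, t_form,
    cell_of, cell_start, cell_end, ip_idx, im_idx,
    rest_edge, rest_cos, rest_sin, rest_area, rest_perim,
    k_edge, k_angle, k_area, k_perim,
    mac_cx, mac_cz, mac_r,
    adhesive, K_s, l0, d_on, d_off, sig_on, sig_off, k_on0, k_off0, kBT,
    morse_depth, morse_beta, morse_r0, morse_cutoff, morse_attract,
    zeta_v, m_v, buoy_v, bl_thick, lift_vol, lift_fac, deflect, U_top, h, Lx,
    wall_k, wall_range,
    dt, n_steps, step0, time0,
    normals, uniforms,
    rec_every, rec_cent, rec_vel, rec_nb, rec_count,
    cell_min_gap,
):
    """Advance ``n_steps`` of the reduced 2D dynamics; returns (#records, status).

    status 0 = ok, 1 = NaN/instability detected (abort).
    """
    n = pos.shape[0]
    n_cells = cell_start.shape[0]
    n_mac = mac_cx.shape[0]
    sqrt_noise = np.sqrt(2.0 * zeta_v * kBT / dt)
    n_rec = 0
    cent = np.empty((n_cells, 2))
    ex = np.empty(n)
    ez = np.empty(n)
    el = np.empty(n)
    ca_arr = np.empty(max(n_cells, 1))
    cp_arr = np.empty(max(n_cells, 1))
    mc2 = morse_cutoff * morse_cutoff
    # stochastic dissociation can fire only if the uniform draw is below
    # this bound (P_off <= 1 - exp(-k_off0 dt) <= k_off0 dt)
    poff_bound = k_off0 * dt
    for s in range(n_steps):
        step = step0 + s
        # --- forces (fresh each step: the state (x, v) is Markov) ---
        for i in range(n):
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0

        # membrane elasticity: one edge pass, per-cell sums, one force pass
        for i in range(n):
            j = ip_idx[i]
            dx = pos[j, 0] - pos[i, 0]
            dz = pos[j, 1] - pos[i, 1]
            # a cell spans << Lx/2; no minimum image needed within a cell
            ln = np.sqrt(dx * dx + dz * dz)
            if ln < 1e-12:
                ln = 1e-12
            ex[i] = dx
            ez[i] = dz
            el[i] = ln
        for c in range(n_cells):
            peri = 0.0
            area = 0.0
            for i in range(cell_start[c], cell_end[c]):
                peri += el[i]
                j = ip_idx[i]
                area += pos[i, 0] * pos[j, 1] - pos[j, 0] * pos[i, 1]
            area *= 0.5
            ca_arr[c] = k_area[c] * (area - rest_area[c]) / rest_area[c]
            cp_arr[c] = k_perim[c] * (peri - rest_perim[c]) / rest_perim[c]
        for i in range(n):
            c = cell_of[i]
            j = ip_idx[i]
            im = im_idx[i]
            # edge spring + perimeter tension on edge (i -> j)
            tension = k_edge[c] * (el[i] - rest_edge[i]) + cp_arr[c]
            inv_l = 1.0 / el[i]
            fx = tension * ex[i] * inv_l
            fz = tension * ez[i] * inv_l
            forces[i, 0] += fx
            forces[i, 1] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fz
            # enclosed-area gradient: ½(z_{i+1}-z_{i-1}, x_{i-1}-x_{i+1})
            caf = ca_arr[c]
            forces[i, 0] -= caf * 0.5 * (pos[j, 1] - pos[im, 1])
            forces[i, 1] -= caf * 0.5 * (pos[im, 0] - pos[j, 0])
            # bending at vertex i between edges (im -> i) and (i -> j):
            # E = k(1 - cos(φ-φ0)), coef = dE/dφ = k sin(φ-φ0)
            e1x = ex[im]
            e1z = ez[im]
            e2x = ex[i]
            e2z = ez[i]
            l1 = el[im]
            l2 = el[i]
            inv12 = 1.0 / (l1 * l2)
            sinp = (e1x * e2z - e1z * e2x) * inv12
            cosp = (e1x * e2x + e1z * e2z) * inv12
            coef = k_angle[c] * (sinp * rest_cos[i] - cosp * rest_sin[i])
            il1 = 1.0 / (l1 * l1)
            il2 = 1.0 / (l2 * l2)
            p1x = -e1z * il1
            p1z = e1x * il1
            p2x = -e2z * il2
            p2z = e2x * il2
            # dφ/dx_{i-1} = +p1 ; dφ/dx_i = -p1-p2 ; dφ/dx_{i+1} = +p2
            forces[im, 0] -= coef * p1x
            forces[im, 1] -= coef * p1z
            forces[i, 0] += coef * (p1x + p2x)
            forces[i, 1] += coef * (p1z + p2z)
            forces[j, 0] -= coef * p2x
            forces[j, 1] -= coef * p2z

        # ambient drag + settling + noise; the Couette profile is deflected
        # around the nearest macrophage (potential-flow diversion) and damped
        # in a thin no-slip layer on the cap
        S_sh = U_top / h
        for i in range(n):
            zi = pos[i, 1]
            ux = S_sh * zi
            uz = 0.0
            if deflect == 1 and n_mac > 0:
                br2 = 1e30
                bxt = 0.0
                bzt = 0.0
                bR = 1.0
                for mth in range(n_mac):
                    dxm = pos[i, 0] - mac_cx[mth]
                    dxm -= Lx * np.floor(dxm / Lx + 0.5)
                    dzm = zi - mac_cz[mth]
                    r2m = dxm * dxm + dzm * dzm
                    if r2m < br2:
                        br2 = r2m
                        bxt = dxm
                        bzt = dzm
                        bR = mac_r[mth]
                R2 = bR * bR
                if br2 <= R2:
                    ux = 0.0
                    uz = 0.0
                elif br2 < 16.0 * R2:
                    inv = 1.0 / br2
                    cos2 = (bxt * bxt - bzt * bzt) * inv
                    sin2 = 2.0 * bxt * bzt * inv
                    fac = R2 * inv
                    uloc = S_sh * zi
                    ux = uloc * (1.0 - fac * cos2)
                    uz = -uloc * fac * sin2
                    if bl_thick > 0.0:
                        dsurf = np.sqrt(br2) - bR
                        if dsurf < bl_thick:
                            g = dsurf / bl_thick
                            ux *= g
                            uz *= g
            # deformability-induced wall lift (soft cells drift up)
            z_eff = zi if zi > 2.0 else 2.0
            uz += S_sh * lift_vol * lift_fac[cell_of[i]] / (z_eff * z_eff)
            forces[i, 0] += -zeta_v * (vel[i, 0] - ux) + sqrt_noise * normals[s, i, 0]
            forces[i, 1] += -zeta_v * (vel[i, 1] - uz) - buoy_v + sqrt_noise * normals[s, i, 1]

        # bottom/top wall soft repulsion
        for i in range(n):
            if pos[i, 1] < wall_range:
                forces[i, 1] += wall_k * (wall_range - pos[i, 1])
            elif pos[i, 1] > h - wall_range:
                forces[i, 1] -= wall_k * (pos[i, 1] - (h - wall_range))

        # macrophages: repulsion + stochastic bonds. Vertices farther than
        # ``margin`` above every cap are skipped (no repulsion or binding is
        # possible there; cell_min_gap stays exact below the margin).
        margin = 3.0
        for i in range(n):
            # nearest macrophage surface point
            best_gap = 1e30
            bx = 0.0
            bz = 0.0
            nx_ = 0.0
            nz_ = 0.0
            for mth in range(n_mac):
                dxm = pos[i, 0] - mac_cx[mth]
                dxm -= Lx * np.floor(dxm / Lx + 0.5)
                dzm = pos[i, 1] - mac_cz[mth]
                reach = mac_r[mth] + margin
                if dxm * dxm + dzm * dzm > reach * reach:
                    continue
                dist = np.sqrt(dxm * dxm + dzm * dzm)
                if dist < 1e-12:
                    continue
                px = mac_cx[mth] + dxm / dist * mac_r[mth]
                pz = mac_cz[mth] + dzm / dist * mac_r[mth]
                if pz < 0.0:
                    halfw = np.sqrt(max(mac_r[mth] ** 2 - mac_cz[mth] ** 2, 0.0))
                    if dxm >= 0:
                        px = mac_cx[mth] + halfw
                    else:
                        px = mac_cx[mth] - halfw
                    pz = 0.0
                    ddx = pos[i, 0] - px
                    ddx -= Lx * np.floor(ddx / Lx + 0.5)
                    gap = np.sqrt(ddx * ddx + pos[i, 1] * pos[i, 1])
                    gnx = ddx / max(gap, 1e-12)
                    gnz = pos[i, 1] / max(gap, 1e-12)
                else:
                    gap = dist - mac_r[mth]
                    gnx = dxm / dist
                    gnz = dzm / dist
                if gap < best_gap:
                    best_gap = gap
                    bx = px
                    bz = pz
                    nx_ = gnx
                    nz_ = gnz
            if n_mac > 0:
                c_i = cell_of[i]
                if best_gap < cell_min_gap[c_i]:
                    cell_min_gap[c_i] = best_gap
                if best_gap < wall_range:
                    fmag = wall_k * (wall_range - best_gap)
                    forces[i, 0] += fmag * nx_
                    forces[i, 1] += fmag * nz_
                # stochastic bond update
                if bonded[i] == 1:
                    dxa = pos[i, 0] - anchor_x[i]
                    dxa -= Lx * np.floor(dxa / Lx + 0.5)
                    dza = pos[i, 1] - anchor_z[i]
                    lb = np.sqrt(dxa * dxa + dza * dza)
                    broke = False
                    if lb >= d_off:
                        broke = True
                    elif uniforms[s, i, 1] < poff_bound:
                        koff = k_off0 * np.exp(-sig_off * (lb - l0) ** 2 / (2.0 * kBT))
                        poff = 1.0 - np.exp(-koff * dt)
                        if poff > uniforms[s, i, 1]:
                            broke = True
                    if broke:
                        bonded[i] = 0
                    else:
                        fb = -K_s * (lb - l0)
                        if lb > 1e-12:
                            forces[i, 0] += fb * dxa / lb
                            forces[i, 1] += fb * dza / lb
                elif adhesive[i] == 1:
                    gl = abs(best_gap)
                    if gl < d_on:
                        kon = k_on0 * np.exp(-sig_on * (gl - l0) ** 2 / (2.0 * kBT))
                        pon = 1.0 - np.exp(-kon * dt)
                        if pon > uniforms[s, i, 0]:
                            bonded[i] = 1
                            anchor_x[i] = bx
                            anchor_z[i] = bz
                            t_form[i] = time0 + (s + 1) * dt

        # intercellular Morse (with centroid prune)
        for c in range(n_cells):
            cxs = 0.0
            czs = 0.0
            for i in range(cell_start[c], cell_end[c]):
                cxs += pos[i, 0]
                czs += pos[i, 1]
            cent[c, 0] = cxs / (cell_end[c] - cell_start[c])
            cent[c, 1] = czs / (cell_end[c] - cell_start[c])
        for ca_ in range(n_cells):
            for cb_ in range(ca_ + 1, n_cells):
                dxc = cent[ca_, 0] - cent[cb_, 0]
                dxc -= Lx * np.floor(dxc / Lx + 0.5)
                dzc = cent[ca_, 1] - cent[cb_, 1]
                if dxc * dxc + dzc * dzc > (15.5 + morse_cutoff) ** 2:
                    continue
                for i in range(cell_start[ca_], cell_end[ca_]):
                    for j in range(cell_start[cb_], cell_end[cb_]):
                        dzp = pos[i, 1] - pos[j, 1]
                        if dzp > morse_cutoff or dzp < -morse_cutoff:
                            continue
                        dxp = pos[i, 0] - pos[j, 0]
                        dxp -= Lx * np.floor(dxp / Lx + 0.5)
                        if dxp > morse_cutoff or dxp < -morse_cutoff:
                            continue
                        r2 = dxp * dxp + dzp * dzp
                        if r2 < mc2 and r2 > 1e-24:
                            r = np.sqrt(r2)
                            e = np.exp(-morse_beta * (r - morse_r0))
                            fm = 2.0 * morse_beta * morse_depth * (e * e - e)
                            if morse_attract == 0 and fm < 0.0:
                                fm = 0.0
                            fx = fm * dxp / r
                            fy = fm * dzp / r
                            forces[i, 0] += fx
                            forces[i, 1] += fy
                            forces[j, 0] -= fx
                            forces[j, 1] -= fy

        # kick + drift; x stays unwrapped (intra-cell geometry needs no
        # minimum image), z reflects at the walls
        ok = True
        for i in range(n):
            vel[i, 0] += dt / m_v * forces[i, 0]
            vel[i, 1] += dt / m_v * forces[i, 1]
            pos[i, 0] += dt * vel[i, 0]
            pos[i, 1] += dt * vel[i, 1]
            if pos[i, 1] < 0.0:
                pos[i, 1] = -pos[i, 1]
                vel[i, 1] = -vel[i, 1]
            elif pos[i, 1] > h:
                pos[i, 1] = 2.0 * h - pos[i, 1]
                vel[i, 1] = -vel[i, 1]
            if not (np.isfinite(pos[i, 0]) and np.isfinite(pos[i, 1])):
                ok = False
        if not ok:
            return n_rec, 1

        # recording
        if (step + 1) % rec_every == 0:
            for c in range(n_cells):
                a0, a1 = cell_start[c], cell_end[c]
                sx = 0.0
                sz = 0.0
                svx = 0.0
                svz = 0.0
                nb = 0
                for i in range(a0, a1):
                    sx += pos[i, 0]
                    sz += pos[i, 1]
                    svx += vel[i, 0]
                    svz += vel[i, 1]
                    if bonded[i] == 1:
                        nb += 1
                nc = a1 - a0
                rec_cent[rec_count + n_rec, c, 0] = sx / nc
                rec_cent[rec_count + n_rec, c, 1] = sz / nc
                rec_vel[rec_count + n_rec, c, 0] = svx / nc
                rec_vel[rec_count + n_rec, c, 1] = svz / nc
                rec_nb[rec_count + n_rec, c] = nb
            n_rec += 1
    return n_rec, 0


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def _cell_bounding_radius(outline: np.ndarray) -> float:
    c = outline.mean(axis=0)
    return float(np.linalg.norm(outline - c, axis=1).max())


def initialize(config: SimulationConfig) -> tuple[SimulationState, dict]:
    """Build the initial state: cells placed without overlap, away from the
    macrophages; returns (state, static arrays bundle for the kernel).

    If ``config.hematocrit`` is set, the channel length is rescaled at fixed
    cell count to realise it (the experimental Hct protocol); the resulting
    domain is stored in the returned bundle. Raises :class:`PackingError`
    with the achievable Hct if the cells cannot be placed.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence((config.master_seed, 101)))
    shapes = []
    for grp in config.cells:
        shapes.extend([grp.shape] * grp.count)
    n_cells = len(shapes)
    outlines = [
        rbc_outline_2d(s, config.n_vertices_2d, seed=int(rng.integers(2**31)))
        for s in shapes
    ]
    cell_area = float(sum(abs(_polyarea(o)) for o in outlines))
    domain = config.domain
    if config.hematocrit is not None and n_cells > 0:
        L = cell_area / (config.hematocrit * domain.h)
        min_L = 2.0 * max(m.radius for m in config.macrophages) + 10.0 if config.macrophages else 10.0
        if L < min_L:
            achievable = cell_area / (min_L * domain.h)
            raise PackingError(
                f"hematocrit {config.hematocrit} infeasible; achievable <= {achievable:.4f}"
            )
        domain = dataclasses.replace(domain, L_x=float(L))

    # place cells: random x/z, avoiding macrophage discs and each other
    placed = []
    radii = [_cell_bounding_radius(o) for o in outlines]
    max_try = 4000
    for idx, outline in enumerate(outlines):
        r = radii[idx]
        ok = False
        for _ in range(max_try):
            x = rng.uniform(0.0, domain.L_x)
            z = rng.uniform(r + 0.5, domain.h - r - 0.5)
            good = True
            for m in config.macrophages:
                dx = x - m.base_center[0]
                dx -= domain.L_x * np.round(dx / domain.L_x)
                if np.hypot(dx, z - (m.cap_height - m.radius)) < m.radius + r + 1.0:
                    good = False
                    break
            if good:
                for (px, pz), pr in placed:
                    dx = x - px
                    dx -= domain.L_x * np.round(dx / domain.L_x)
                    if np.hypot(dx, z - pz) < r + pr + 0.5:
                        good = False
                        break
            if good:
                placed.append(((x, z), r))
                ok = True
                break
        if not ok:
            achievable = config.hematocrit * len(placed) / max(n_cells, 1) if config.hematocrit else None
            raise PackingError(
                f"could not place cell {idx}; achievable hematocrit ≈ {achievable}"
            )
    # rotate cells randomly and translate to their slots
    positions = []
    for outline, ((x, z), _r) in zip(outlines, placed):
        ang = rng.uniform(0, 2 * np.pi)
        ca_, sa_ = np.cos(ang), np.sin(ang)
        rot = outline @ np.array([[ca_, sa_], [-sa_, ca_]])
        rot += np.array([x, z]) - rot.mean(axis=0)
        positions.append(rot)
    n_total = sum(len(p) for p in positions)
    pos = np.vstack(positions) if positions else np.zeros((0, 2))
    vel = np.zeros_like(pos)
    # start moving with the local flow to avoid an impulsive transient
    u0 = config.u_top_at(0.0)
    if n_total:
        vel[:, 0] = u0 * pos[:, 1] / domain.h

    cell_start = np.zeros(n_cells, dtype=np.int64)
    cell_end = np.zeros(n_cells, dtype=np.int64)
    off = 0
    for c, p in enumerate(positions):
        cell_start[c] = off
        off += len(p)
        cell_end[c] = off
    cell_of = np.zeros(n_total, dtype=np.int64)
    for c in range(n_cells):
        cell_of[cell_start[c]:cell_end[c]] = c

    membrane = config.membrane
    rest_edge = np.zeros(n_total)
    rest_angle = np.zeros(n_total)
    ip_idx = np.zeros(n_total, dtype=np.int64)
    im_idx = np.zeros(n_total, dtype=np.int64)
    for c in range(n_cells):
        idx = np.arange(cell_start[c], cell_end[c])
        ip_idx[idx] = np.roll(idx, -1)
        im_idx[idx] = np.roll(idx, 1)
    rest_area = np.zeros(max(n_cells, 1))
    rest_perim = np.zeros(max(n_cells, 1))
    k_edge = np.zeros(max(n_cells, 1))
    k_angle = np.zeros(max(n_cells, 1))
    k_area = np.zeros(max(n_cells, 1))
    k_perim = np.zeros(max(n_cells, 1))
    for c, outline in enumerate(outlines):
        ct = Contour2D.from_polygon(outline, membrane)
        sl = slice(cell_start[c], cell_end[c])
        rest_edge[sl] = ct.ref_edge_length
        rest_angle[sl] = ct.ref_angle
        rest_area[c] = ct.ref_area
        rest_perim[c] = ct.ref_perimeter
        k_edge[c] = ct.k_edge
        k_angle[c] = ct.k_angle
        k_area[c] = ct.k_area
        k_perim[c] = ct.k_perimeter

    adhesive = np.zeros(n_total, dtype=np.uint8)
    for c in range(n_cells):
        idx = np.arange(cell_start[c], cell_end[c])
        adhesive[idx[:: max(config.adhesive_site_spacing, 1)]] = 1

    mac_cx = np.array([m.base_center[0] for m in config.macrophages], dtype=np.float64)
    mac_cz = np.array([m.cap_height - m.radius for m in config.macrophages], dtype=np.float64)
    mac_r = np.array([m.radius for m in config.macrophages], dtype=np.float64)

    state = SimulationState(
        positions=pos,
        velocities=vel,
        bonded=np.zeros(n_total, dtype=np.uint8),
        anchor=np.zeros((n_total, 2)),
        t_form=np.full(n_total, np.nan),
        step=0,
        time=0.0,
    )
    bundle = {
        "domain": domain,
        "cell_start": cell_start,
        "cell_end": cell_end,
        "cell_of": cell_of,
        "rest_edge": rest_edge,
        "rest_angle": rest_angle,
        "rest_cos": np.cos(rest_angle),
        "rest_sin": np.sin(rest_angle),
        "ip_idx": ip_idx,
        "im_idx": im_idx,
        "rest_area": rest_area,
        "rest_perim": rest_perim,
        "k_edge": k_edge,
        "k_angle": k_angle,
        "k_area": k_area,
        "k_perim": k_perim,
        "adhesive": adhesive,
        "mac_cx": mac_cx,
        "mac_cz": mac_cz,
        "mac_r": mac_r,
        "shapes": shapes,
        "hematocrit_realised": cell_area / (domain.L_x * domain.h) if n_cells else 0.0,
    }
    return state, bundle


def _polyarea(x: np.ndarray) -> float:
    return float(0.5 * np.sum(x[:, 0] * np.roll(x[:, 1], -1) - np.roll(x[:, 0], -1) * x[:, 1]))


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------


class Simulation:
    """A reproducible reduced-mode run.

    Randomness comes from three named streams (initialization, thermal
    noise, bond lambdas), each keyed by (master_seed, stream id, chunk
    index), so identical configs and seeds give bitwise-identical
    trajectories and runs can resume from a saved state at any chunk
    boundary.
    """

    NOISE_STREAM = 1
    BOND_STREAM = 2

    def __init__(self, config: SimulationConfig):
        config.validate()
        if config.mode != "2d":
            raise NotImplementedError(
                "the engine orchestrates the reduced 2D mode; 3D building "
                "blocks live in the geometry/membrane/fluid/adhesion modules"
            )
        self.config = config
        self.state, self.bundle = initialize(config)
        self.trajectory = Trajectory()
        self.cell_min_gap = np.full(len(self.bundle["cell_start"]), np.inf)
        self._record_initial()

    # -- randomness -------------------------------------------------------
    def _chunk_rng(self, stream: int, chunk: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence((self.config.master_seed, stream, chunk))
        )

    # -- persistence ------------------------------------------------------
    def save(self, path: str) -> None:
        import h5py

        st = self.state
        with h5py.File(path, "w") as f:
            f.attrs["step"] = st.step
            f.attrs["time"] = st.time
            f.attrs["config_yaml"] = self.config.to_yaml()
            f.create_dataset("positions", data=st.positions)
            f.create_dataset("velocities", data=st.velocities)
            f.create_dataset("bonded", data=st.bonded)
            f.create_dataset("anchor", data=st.anchor)
            f.create_dataset("t_form", data=st.t_form)
            f.create_dataset("cell_min_gap", data=self.cell_min_gap)

    @classmethod
    def load(cls, path: str) -> "Simulation":
        import h5py

        with h5py.File(path, "r") as f:
            config = SimulationConfig.from_yaml(f.attrs["config_yaml"])
            sim = cls.__new__(cls)
            sim.config = config
            sim.state, sim.bundle = initialize(config)
            sim.state.positions = f["positions"][...]
            sim.state.velocities = f["velocities"][...]
            sim.state.bonded = f["bonded"][...]
            sim.state.anchor = f["anchor"][...]
            sim.state.t_form = f["t_form"][...]
            sim.state.step = int(f.attrs["step"])
            sim.state.time = float(f.attrs["time"])
            sim.trajectory = Trajectory()
            sim.cell_min_gap = f["cell_min_gap"][...]
        return sim

    # -- dynamics ---------------------------------------------------------
    def _record_initial(self) -> None:
        st, b = self.state, self.bundle
        n_cells = len(b["cell_start"])
        if n_cells == 0:
            return
        cents = np.empty((n_cells, 2))
        vels = np.empty((n_cells, 2))
        nb = np.zeros(n_cells, dtype=np.int64)
        for c in range(n_cells):
            sl = slice(b["cell_start"][c], b["cell_end"][c])
            cents[c] = st.positions[sl].mean(axis=0)
            vels[c] = st.velocities[sl].mean(axis=0)
            nb[c] = int(st.bonded[sl].sum())
        self.trajectory.times.append(st.time * self.config.time_scaling)
        self.trajectory.centroids.append(cents)
        self.trajectory.cell_speeds.append(np.linalg.norm(vels, axis=1))
        self.trajectory.bond_counts.append(nb)
        self.trajectory.u_top.append(self.config.u_top_at(st.time))
        if self.config.store_positions:
            self.trajectory.positions.append(st.positions.copy())

    def run(self, n_steps: int | None = None) -> Trajectory:
        """Advance ``n_steps`` (default: config.n_steps − current step)."""
        cfg = self.config
        st = self.state
        b = self.bundle
        total = cfg.n_steps - st.step if n_steps is None else n_steps
        if total <= 0 or len(b["cell_start"]) == 0:
            return self.trajectory
        n = st.positions.shape[0]
        p = cfg.adhesion
        memb = cfg.membrane
        coup = dataclasses.replace(cfg.coupling, n_vertices=cfg.n_vertices_2d)
        zeta_v = coup.zeta_vertex
        m_v = zeta_v * cfg.vertex_relax_time
        buoy_v = coup.buoyant_weight / coup.n_vertices
        agg = cfg.aggregation
        cs = cfg.chunk_steps
        from .membrane import E_S0

        lift_fac = np.where(
            b["k_edge"] > 0, memb.edge_spring_scale_2d * E_S0 / np.maximum(b["k_edge"], 1e-12), 1.0
        )
        forces = np.zeros_like(st.positions)
        anchor_x = np.ascontiguousarray(st.anchor[:, 0])
        anchor_z = np.ascontiguousarray(st.anchor[:, 1])
        done = 0
        while done < total:
            chunk = st.step // cs
            offset = st.step - chunk * cs
            steps_now = min(cs - offset, total - done)
            noise = self._chunk_rng(self.NOISE_STREAM, chunk).standard_normal((cs, n, 2))[
                offset : offset + steps_now
            ]
            unis = self._chunk_rng(self.BOND_STREAM, chunk).random((cs, n, 2))[
                offset : offset + steps_now
            ]
            u_top = cfg.u_top_at(st.time)
            rec_every = cfg.output_every
            max_rec = steps_now // rec_every + 2
            n_cells = len(b["cell_start"])
            rec_cent = np.zeros((max_rec, n_cells, 2))
            rec_vel = np.zeros((max_rec, n_cells, 2))
            rec_nb = np.zeros((max_rec, n_cells), dtype=np.int64)
            n_rec, status = _assay_chunk_kernel(
                st.positions, st.velocities, forces,
                st.bonded, anchor_x, anchor_z, st.t_form,
                b["cell_of"], b["cell_start"], b["cell_end"],
                b["ip_idx"], b["im_idx"],
                b["rest_edge"], b["rest_cos"], b["rest_sin"],
                b["rest_area"], b["rest_perim"],
                b["k_edge"], b["k_angle"], b["k_area"], b["k_perim"],
                b["mac_cx"], b["mac_cz"], b["mac_r"],
                b["adhesive"], p.K_s, p.l0, p.d_on, p.d_off,
                p.sigma_on, p.sigma_off, p.k_on0, p.k_off0, p.kBT,
                agg.depth, agg.beta, agg.r0, agg.cutoff,
                1 if agg.enabled else 0,
                zeta_v, m_v, buoy_v, coup.boundary_layer, coup.lift_volume,
                lift_fac, 1 if coup.deflect_flow else 0, u_top, b["domain"].h, b["domain"].L_x,
                cfg.wall_repulsion_k, cfg.wall_repulsion_range,
                cfg.dt, steps_now, st.step, st.time,
                noise, unis,
                rec_every, rec_cent, rec_vel, rec_nb, 0,
                self.cell_min_gap,
            )
            if status != 0:
                raise TimestepError(
                    f"instability (NaN) at step {st.step}; reduce dt or stiffness"
                )
            st.step += steps_now
            st.time = st.step * cfg.dt
            done += steps_now
            for r in range(n_rec):
                self.trajectory.times.append(
                    (st.time - (n_rec - 1 - r) * rec_every * cfg.dt) * cfg.time_scaling
                )
                self.trajectory.centroids.append(rec_cent[r].copy())
                self.trajectory.cell_speeds.append(np.linalg.norm(rec_vel[r], axis=1))
                self.trajectory.bond_counts.append(rec_nb[r].copy())
                self.trajectory.u_top.append(u_top)
            if cfg.store_positions:
                self.trajectory.positions.append(st.positions.copy())
        st.anchor[:, 0] = anchor_x
        st.anchor[:, 1] = anchor_z
        return self.trajectory

    # -- derived ----------------------------------------------------------
    def registry(self) -> BondRegistry:
        """Current bonds as an adhesion-module registry view."""
        b = self.bundle
        reg = BondRegistry(len(self.state.positions), dim=2, cell_of_vertex=b["cell_of"])
        reg.bonded = self.state.bonded.astype(bool)
        reg.anchor = self.state.anchor.copy()
        reg.t_form = self.state.t_form.copy()
        return reg
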