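"""Particle-based solvent (dissipative particle dynamics) and flow coupling.

The solvent is a set of soft particles interacting through the classic DPD
force triplet inside a cutoff r_c,

    F_C = a (1 - r/r_c) r̂
    F_D = -γ w(r)² (r̂·v_ij) r̂          w(r) = (1 - r/r_c)^s
    F_R = σ w(r) ξ_ij r̂ / √Δt          σ² = 2 γ k_B T  (fluctuation–dissipation)

with per-pair symmetric Gaussian noise ξ_ij = ξ_ji, so pair forces are
exactly antisymmetric and the thermostat conserves momentum. The shear
channel is bounded by bounce-back walls at z = 0 and z = h dressed with
frozen wall-particle layers that move with the wall (no-slip); x and y are
periodic. The top wall moves at U_top, driving Couette flow — the linear
shear approximation of the near-wall flow in the microfluidic chamber.

Two coupling routes to membranes are provided:

* explicit: membrane vertices participate in DPD dissipative/random (and
  soft repulsive) pairs with the solvent — used by the fidelity mode;
* ambient: the analytic Couette profile plus a Stokes-like per-vertex drag
  with matched thermal noise — the fast reduced mode used by the desk-scale
  assays, where the solvent degrees of freedom are integrated out.

The DPD parameter values are reconstructions (number density, a, γ are not
published for this system); defaults follow conventional DPD water practice
and are exposed in the configuration.

Units: μm, s, pN; energy pN·μm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .adhesion import KBT_310

__all__ = [
    "DpdParams",
    "ChannelDomain",
    "FluidState",
    "AmbientShearCoupling",
    "TimestepError",
    "make_solvent",
    "dpd_pair_forces",
    "apply_boundaries",
    "couple_membrane",
    "dpd_step",
    "couette_profile",
    "run_couette",
    "kinetic_temperature",
]


class TimestepError(RuntimeError):
    """A particle moved farther than the boundary scheme can handle."""


@dataclass(frozen=True)
class DpdParams:
    """DPD interaction parameters.

    ``sigma_dpd`` must satisfy the fluctuation–dissipation relation
    σ² = 2 γ k_B T; the constructor rejects inconsistent values. Use
    ``DpdParams.from_gamma`` to derive σ automatically.
    """

    a: float = 0.08  # pN, conservative repulsion at r = 0
    gamma: float = 4.0e-3  # pN·s/μm (Schmidt number adequate for laminar microflow)
    sigma_dpd: float = float(np.sqrt(8.0e-3 * KBT_310))
    rc: float = 1.0  # μm
    kBT: float = KBT_310
    weight_exponent: float = 0.25
    dt: float = 2.5e-5  # s
    mass: float = 1.0e-6  # pN·s²/μm per particle
    density: float = 4.0  # particles per rc^d

    def __post_init__(self) -> None:
        if self.rc <= 0 or self.dt <= 0 or self.mass <= 0:
            raise ValueError("rc, dt, mass must be positive")
        target = np.sqrt(2.0 * self.gamma * self.kBT)
        if not np.isclose(self.sigma_dpd, target, rtol=1e-10, atol=0.0):
            raise ValueError(
                f"sigma_dpd={self.sigma_dpd} violates fluctuation-dissipation; "
                f"expected sqrt(2 gamma kBT) = {target}"
            )

    @classmethod
    def from_gamma(cls, gamma: float, kBT: float = KBT_310, **kw) -> "DpdParams":
        return cls(gamma=gamma, sigma_dpd=float(np.sqrt(2.0 * gamma * kBT)), kBT=kBT, **kw)


@dataclass(frozen=True)
class ChannelDomain:
    """Shear channel: periodic in x (and y), walls at z = 0 and z = h."""

    L_x: float = 25.0
    L_y: float = 4.0
    h: float = 20.0
    U_top: float = 0.0

    def __post_init__(self) -> None:
        if self.h <= 0 or self.L_x <= 0 or self.L_y <= 0:
            raise ValueError("domain dimensions must be positive")
        if self.U_top < 0:
            raise ValueError("U_top must be nonnegative")


@dataclass
class FluidState:
    """Solvent particles plus frozen wall-dressing particles.

    The ``n_free`` leading entries are mobile; the rest are frozen wall
    particles whose velocities are the wall velocities.
    """

    positions: np.ndarray
    velocities: np.ndarray
    n_free: int

    @property
    def free_positions(self) -> np.ndarray:
        return self.positions[: self.n_free]

    @property
    def free_velocities(self) -> np.ndarray:
        return self.velocities[: self.n_free]


def couette_profile(z, domain: ChannelDomain):
    """Analytic steady Couette profile u(z) = U_top z / h."""
    return domain.U_top * np.asarray(z, dtype=np.float64) / domain.h


def kinetic_temperature(state: FluidState, params: DpdParams, plane2d: bool = True) -> float:
    """Kinetic temperature from velocity fluctuations about the per-bin mean
    streamwise flow, in energy units (compare against kBT)."""
    v = state.free_velocities.copy()
    z = state.free_positions[:, 2]
    nbins = 40
    edges = np.linspace(z.min() - 1e-9, z.max() + 1e-9, nbins + 1)
    which = np.digitize(z, edges) - 1
    for b in range(nbins):
        sel = which == b
        if sel.sum() > 1:
            v[sel, 0] -= v[sel, 0].mean()
    dof = 2 if plane2d else 3
    comps = [0, 2] if plane2d else [0, 1, 2]
    return float(params.mass * np.sum(v[:, comps] ** 2) / (dof * len(v)))


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def make_solvent(
    domain: ChannelDomain,
    params: DpdParams,
    seed: int,
    plane2d: bool = True,
    init: str = "profile",
) -> FluidState:
    """Uniform random solvent filling the channel, plus frozen wall layers.

    ``init='profile'`` starts velocities at the analytic Couette profile plus
    thermal noise (the steady state); ``'rest'`` starts from rest.
    """
    rng = np.random.default_rng(seed)
    if plane2d:
        n = int(round(params.density * domain.L_x * domain.h / params.rc**2))
    else:
        n = int(round(params.density * domain.L_x * domain.L_y * domain.h / params.rc**3))
    pos = np.empty((n, 3))
    pos[:, 0] = rng.uniform(0, domain.L_x, n)
    pos[:, 1] = 0.0 if plane2d else rng.uniform(0, domain.L_y, n)
    pos[:, 2] = rng.uniform(0, domain.h, n)
    vth = np.sqrt(params.kBT / params.mass)
    vel = vth * rng.normal(size=(n, 3))
    vel -= vel.mean(axis=0)  # zero net thermal momentum
    if plane2d:
        vel[:, 1] = 0.0
    if init == "profile":
        vel[:, 0] += couette_profile(pos[:, 2], domain)
    # frozen wall layers of thickness rc
    wall_pos, wall_vel = [], []
    spacing = (1.0 / params.density) ** (1.0 / (2 if plane2d else 3)) * params.rc
    nz = max(int(np.ceil(params.rc / spacing)), 1)
    nx = max(int(round(domain.L_x / spacing)), 1)
    ny = 1 if plane2d else max(int(round(domain.L_y / spacing)), 1)
    for iz in range(nz):
        for ix in range(nx):
            for iy in range(ny):
                x = (ix + 0.5) * domain.L_x / nx
                y = 0.0 if plane2d else (iy + 0.5) * domain.L_y / ny
                zo = (iz + 0.5) * spacing
                wall_pos.append((x, y, -zo))
                wall_vel.append((0.0, 0.0, 0.0))
                wall_pos.append((x, y, domain.h + zo))
                wall_vel.append((domain.U_top, 0.0, 0.0))
    positions = np.vstack([pos, np.asarray(wall_pos)])
    velocities = np.vstack([vel, np.asarray(wall_vel)])
    return FluidState(positions=positions, velocities=velocities, n_free=n)


# ---------------------------------------------------------------------------
# Pair forces (numba kernel, 3D cell list; 2D runs as a monolayer at y = 0)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _dpd_forces_kernel(
    pos, vel, n_free, Lx, Ly, h, rc, a, gamma, sigma, s_exp, inv_sqrt_dt, seed, plane2d,
    cross_only,
):
    n = pos.shape[0]
    f = np.zeros((n, 3))
    np.random.seed(seed)
    zlo = -2.0 * rc
    zhi = h + 2.0 * rc
    ncx = max(int(Lx / rc), 1)
    ncy = 1 if plane2d else max(int(Ly / rc), 1)
    ncz = max(int((zhi - zlo) / rc), 1)
    cx = Lx / ncx
    cy = Ly / max(ncy, 1)
    cz = (zhi - zlo) / ncz
    head = -1 * np.ones(ncx * ncy * ncz, dtype=np.int64)
    nxt = -1 * np.ones(n, dtype=np.int64)
    cell_of = np.empty(n, dtype=np.int64)
    for i in range(n):
        ix = int(pos[i, 0] / cx) % ncx
        iy = 0 if plane2d else int(pos[i, 1] / cy) % ncy
        iz = int((pos[i, 2] - zlo) / cz)
        if iz < 0:
            iz = 0
        if iz >= ncz:
            iz = ncz - 1
        c = (ix * ncy + iy) * ncz + iz
        cell_of[i] = c
        nxt[i] = head[c]
        head[c] = i
    rc2 = rc * rc
    for i in range(n):
        ix = cell_of[i] // (ncy * ncz) % ncx
        iy = cell_of[i] // ncz % ncy
        iz = cell_of[i] % ncz
        for dx in range(-1, 2):
            jx = (ix + dx) % ncx
            for dy in range(-1, 2):
                if plane2d and dy != 0:
                    continue
                jy = (iy + dy) % ncy
                for dz in range(-1, 2):
                    jz = iz + dz
                    if jz < 0 or jz >= ncz:
                        continue
                    j = head[(jx * ncy + jy) * ncz + jz]
                    while j >= 0:
                        if j > i:
                            rx = pos[i, 0] - pos[j, 0]
                            rx -= Lx * np.round(rx / Lx)
                            ry = 0.0 if plane2d else pos[i, 1] - pos[j, 1]
                            if not plane2d:
                                ry -= Ly * np.round(ry / Ly)
                            rz = pos[i, 2] - pos[j, 2]
                            r2 = rx * rx + ry * ry + rz * rz
                            if cross_only == 1:
                                same_group = (i < n_free) == (j < n_free)
                            else:
                                same_group = i >= n_free and j >= n_free
                            if r2 < rc2 and r2 > 1e-24 and not same_group:
                                r = np.sqrt(r2)
                                ex, ey, ez = rx / r, ry / r, rz / r
                                w = (1.0 - r / rc) ** s_exp
                                vx = vel[i, 0] - vel[j, 0]
                                vy = vel[i, 1] - vel[j, 1]
                                vz = vel[i, 2] - vel[j, 2]
                                rv = ex * vx + ey * vy + ez * vz
                                xi = np.random.normal()
                                fmag = (
                                    a * (1.0 - r / rc)
                                    - gamma * w * w * rv
                                    + sigma * w * xi * inv_sqrt_dt
                                )
                                f[i, 0] += fmag * ex
                                f[i, 1] += fmag * ey
                                f[i, 2] += fmag * ez
                                f[j, 0] -= fmag * ex
                                f[j, 1] -= fmag * ey
                                f[j, 2] -= fmag * ez
                        j = nxt[j]
    if plane2d:
        for i in range(n):
            f[i, 1] = 0.0
    return f


def dpd_pair_forces(
    state: FluidState,
    params: DpdParams,
    domain: ChannelDomain,
    seed_stream: int,
    plane2d: bool = True,
    cross_only: bool = False,
) -> np.ndarray:
    """Per-particle DPD forces (conservative + dissipative + random).

    Pairwise antisymmetric by construction (Newton's third law exact);
    per-pair symmetric noise keyed by ``seed_stream``. Coincident particles
    contribute zero force (soft potential, never NaN). Frozen wall–wall
    pairs are skipped.
    """
    return _dpd_forces_kernel(
        state.positions,
        state.velocities,
        state.n_free,
        domain.L_x,
        domain.L_y,
        domain.h,
        params.rc,
        params.a,
        params.gamma,
        params.sigma_dpd,
        params.weight_exponent,
        1.0 / np.sqrt(params.dt),
        int(seed_stream) % (2**31 - 1),
        plane2d,
        1 if cross_only else 0,
    )


def apply_boundaries(state: FluidState, domain: ChannelDomain) -> FluidState:
    """Periodic wrap in x (and y) and bounce-back at the walls.

    A particle crossing z = 0 or z = h is reflected about the wall with its
    velocity reversed in the wall frame (imparting the wall's tangential
    velocity on average). Raises :class:`TimestepError` if a particle
    penetrated deeper than h/2 in one step.
    """
    pos = state.positions[: state.n_free]
    vel = state.velocities[: state.n_free]
    if np.any(pos[:, 2] < -0.5 * domain.h) or np.any(pos[:, 2] > 1.5 * domain.h):
        raise TimestepError("particle displacement exceeded h/2 in one step")
    below = pos[:, 2] < 0.0
    pos[below, 2] *= -1.0
    vel[below] *= -1.0
    above = pos[:, 2] > domain.h
    pos[above, 2] = 2.0 * domain.h - pos[above, 2]
    vel[above] *= -1.0
    vel[above, 0] += 2.0 * domain.U_top
    pos[:, 0] %= domain.L_x
    pos[:, 1] %= domain.L_y
    return state


def dpd_step(
    state: FluidState,
    params: DpdParams,
    domain: ChannelDomain,
    forces: np.ndarray,
    seed_stream: int,
    plane2d: bool = True,
) -> np.ndarray:
    """One velocity-Verlet step (returns the forces for the next step)."""
    dt, m = params.dt, params.mass
    nf = state.n_free
    state.velocities[:nf] += 0.5 * dt / m * forces[:nf]
    state.positions[:nf] += dt * state.velocities[:nf]
    apply_boundaries(state, domain)
    new_forces = dpd_pair_forces(state, params, domain, seed_stream, plane2d)
    state.velocities[:nf] += 0.5 * dt / m * new_forces[:nf]
    return new_forces


def run_couette(
    domain: ChannelDomain,
    params: DpdParams,
    n_steps: int,
    seed: int,
    plane2d: bool = True,
    sample_every: int = 20,
    warmup: int = 1000,
    init: str = "profile",
) -> dict:
    """Drive the channel and accumulate the time-averaged velocity profile
    and kinetic temperature. Returns profile bin centres, mean u_x(z), the
    temperature estimate, and the final state."""
    state = make_solvent(domain, params, seed, plane2d=plane2d, init=init)
    forces = dpd_pair_forces(state, params, domain, seed + 1, plane2d)
    nbins = 20
    edges = np.linspace(0.0, domain.h, nbins + 1)
    centers = 0.5 * (edges[1:] + edges[:-1])
    acc = np.zeros(nbins)
    cnt = np.zeros(nbins)
    temps = []
    for step in range(n_steps):
        forces = dpd_step(state, params, domain, forces, seed + 2 + step, plane2d)
        if step >= warmup and step % sample_every == 0:
            z = state.free_positions[:, 2]
            which = np.clip(np.digitize(z, edges) - 1, 0, nbins - 1)
            np.add.at(acc, which, state.free_velocities[:, 0])
            np.add.at(cnt, which, 1.0)
            temps.append(kinetic_temperature(state, params, plane2d))
    profile = acc / np.maximum(cnt, 1.0)
    return {
        "z": centers,
        "u_x": profile,
        "temperature": float(np.mean(temps)) if temps else np.nan,
        "state": state,
    }


# ---------------------------------------------------------------------------
# Fluid–membrane coupling
# ---------------------------------------------------------------------------


def couple_membrane(
    fluid_state: FluidState,
    params: DpdParams,
    domain: ChannelDomain,
    membrane_positions: np.ndarray,
    membrane_velocities: np.ndarray,
    seed_stream: int,
    plane2d: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Explicit DPD coupling: solvent ↔ membrane-vertex pair forces.

    The merged system is evaluated in cross-pairs-only mode (solvent ↔
    vertex interactions exclusively), giving an exact equal-and-opposite
    (solvent, membrane) force pair.
    """
    if np.any(membrane_positions[:, 2] < 0) or np.any(membrane_positions[:, 2] > domain.h):
        raise ValueError("membrane outside the channel domain")
    n_s = fluid_state.positions.shape[0]
    pos = np.vstack([fluid_state.positions, membrane_positions])
    vel = np.vstack([fluid_state.velocities, membrane_velocities])
    merged = FluidState(pos, vel, n_free=n_s)
    f_all = dpd_pair_forces(merged, params, domain, seed_stream, plane2d, cross_only=True)
    return f_all[:n_s], f_all[n_s:]


# ---------------------------------------------------------------------------
# Ambient-flow (reduced) coupling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmbientShearCoupling:
    """Analytic shear background plus per-vertex Stokes drag.

    The solvent is integrated out: each membrane vertex feels
    F = -ζ_v (v - u(x)) + f_g ẑ + √(2 ζ_v k_B T / Δt) ξ, with ζ_v the
    per-vertex drag (cell drag / vertex count) and noise satisfying
    fluctuation–dissipation. The background u(x) is the Couette profile
    deflected around each macrophage cap (potential-flow diversion around a
    cylinder) and damped to zero inside a thin boundary layer on the cap so
    the obstacle is no-slip. Cells settle at ``settling_velocity`` (the
    observed RBC sedimentation scale); the corresponding buoyant weight is
    ζ_cell · v_s. The drag coefficient is a calibration constant of the
    reduced model, fixed by the detachment-velocity calibration.
    """

    zeta_cell: float = 7.2e-3  # pN·s/μm, whole-cell drag (detachment-calibrated)
    n_vertices: int = 32
    settling_velocity: float = 4.0  # μm/s
    boundary_layer: float = 0.0  # μm, optional no-slip ramp thickness on the cap
    #: deformability-induced wall-lift volume scale [μm³]: soft cells drift
    #: away from the wall with u_lift = γ̇ · lift_volume · (E_s0/E_s) / z²
    lift_volume: float = 1200.0
    #: optionally divert the background flow around the caps (potential-flow
    #: deflection); the default reduced model uses the plain Couette profile
    deflect_flow: bool = False
    kBT: float = KBT_310

    @property
    def zeta_vertex(self) -> float:
        return self.zeta_cell / self.n_vertices

    @property
    def buoyant_weight(self) -> float:
        """Per-cell weight excess [pN] consistent with the settling speed."""
        return self.zeta_cell * self.settling_velocity

    def velocity_field(
        self,
        positions: np.ndarray,
        domain: ChannelDomain,
        macrophages: list | None = None,
    ) -> np.ndarray:
        """Background flow (u_x, u_z) at 2D points (x, z)."""
        pos = np.asarray(positions, dtype=np.float64)
        S = domain.U_top / domain.h
        u = np.column_stack([S * pos[:, 1], np.zeros(len(pos))])
        if not macrophages:
            return u
        # deflection by the nearest macrophage only (caps are well separated)
        best_r2 = np.full(len(pos), np.inf)
        best = np.zeros((len(pos), 3))  # x̃, z̃, R
        for m in macrophages:
            xc = m.base_center[0]
            zc = m.cap_height - m.radius
            dx = pos[:, 0] - xc
            dx -= domain.L_x * np.round(dx / domain.L_x)
            dz = pos[:, 1] - zc
            r2 = dx * dx + dz * dz
            sel = r2 < best_r2
            best_r2[sel] = r2[sel]
            best[sel] = np.column_stack([dx, dz, np.full(len(pos), m.radius)])[sel]
        xt, zt, R = best.T
        R2 = R * R
        near = best_r2 < 16.0 * R2
        inside = best_r2 <= R2
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / best_r2
            cos2 = (xt * xt - zt * zt) * inv
            sin2 = 2.0 * xt * zt * inv
            fac = R2 * inv
            uloc = S * pos[:, 1]
            ux = uloc * (1.0 - fac * cos2)
            uz = -uloc * fac * sin2
            g = np.clip((np.sqrt(best_r2) - R) / self.boundary_layer, 0.0, 1.0)
        sel = near & ~inside
        u[sel, 0] = (ux * g)[sel]
        u[sel, 1] = (uz * g)[sel]
        u[inside] = 0.0
        return u

    def lift_velocity(self, z, domain: ChannelDomain, stiffness_ratio: float = 1.0):
        """Deformability-induced drift away from the bottom wall [μm/s].

        ``stiffness_ratio`` is E_s0/E_s of the cell: soft (normal) cells lift
        strongly, 50× stiffened hypoxic cells barely at all."""
        z_eff = np.maximum(np.asarray(z, dtype=np.float64), 2.0)
        shear = domain.U_top / domain.h
        return shear * self.lift_volume * stiffness_ratio / z_eff**2

    def forces(
        self,
        positions: np.ndarray,
        velocities: np.ndarray,
        domain: ChannelDomain,
        dt: float,
        noise: np.ndarray,
        macrophages: list | None = None,
        stiffness_ratio: float = 1.0,
    ) -> np.ndarray:
        """Drag + settling + lift + thermal forces for 2D (x, z) arrays."""
        u = self.velocity_field(positions, domain, macrophages)
        u[:, 1] += self.lift_velocity(positions[:, 1], domain, stiffness_ratio)
        f = -self.zeta_vertex * (velocities - u)
        f[:, 1] -= self.buoyant_weight / self.n_vertices
        f += np.sqrt(2.0 * self.zeta_vertex * self.kBT / dt) * noise
        return f
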