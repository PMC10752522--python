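"""Stochastic receptor–ligand adhesion between RBCs and macrophages, and
Morse-potential RBC–RBC aggregation.

The adhesion model is the Hammer–Apte / Bell–Dembo stochastic bond scheme:
within a formation cutoff ``d_on`` an unbonded membrane vertex forms a spring
bond to the nearest point of the macrophage surface with probability

    P_on  = 1 - exp(-k_on Δt),    k_on  = k_on0  exp(-σ_on (l-l0)² / 2 k_B T)

and a live bond dissociates with probability

    P_off = 1 - exp(-k_off Δt),   k_off = k_off0 exp(-σ_off (l-l0)² / 2 k_B T)

while bonds stretched to the dissociation cutoff ``d_off`` rupture
deterministically (a stretched bond cannot persist beyond its reactive
distance). Live bonds are Hookean springs of stiffness ``K_s`` and rest
length ``l0``; the adhesion energy is U = ½ Σ K_s (l - l0)² and forces are
its exact gradient.

Units: μm, s, pN (energy pN·μm). ``KBT_310`` is k_B·T at body temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "KBT_310",
    "AdhesionParams",
    "AggregationParams",
    "Bond",
    "BondRegistry",
    "ADHESION_PRESETS",
    "MacrophageArc2D",
    "MacrophageCap3D",
    "formation_rate",
    "dissociation_rate",
    "formation_probability",
    "dissociation_probability",
    "stochastic_update",
    "bond_forces",
    "adhesion_energy",
    "morse_energy",
    "morse_aggregation_forces",
]

#: k_B T at 310 K in pN·μm.
KBT_310 = 1.380649e-23 * 310.0 / 1e-18  # = 4.280e-3


@dataclass(frozen=True)
class AdhesionParams:
    """One oxygenation condition's bond-kinetics parameter set.

    K_s [μN/m == pN/μm] spring stiffness; l0 [μm] rest length; d_on/d_off
    [μm] formation/dissociation cutoffs; σ_on/σ_off [pN/μm] reactive
    strengths; k_on0/k_off0 [1/s] unstressed rates; kBT [pN·μm].
    """

    K_s: float
    l0: float = 0.3
    d_on: float = 0.75
    d_off: float = 0.75
    sigma_on: float = 0.51
    sigma_off: float = 0.17
    k_on0: float = 5.42e4
    k_off0: float = 2.71
    kBT: float = KBT_310

    def __post_init__(self) -> None:
        for name in ("K_s", "l0", "d_on", "d_off", "sigma_on", "sigma_off", "k_on0", "k_off0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.kBT <= 0:
            raise ValueError("kBT must be positive")
        if not self.l0 < self.d_on:
            raise ValueError("require l0 < d_on")

    def reported_range_violations(self) -> list[str]:
        """Check the literature ranges the parameter table cites.

        The rest length the model actually uses (0.3 μm) sits above the
        0.0–0.2 μm literature range quoted alongside it; that known exception
        is admitted here.
        """
        ranges = {
            "K_s": (1.0, 1e4),
            "l0": (0.0, 0.3),
            "d_on": (0.0, 1.0),
            "d_off": (0.0, 1.0),
            "sigma_on": (0.05, 0.75),
            "sigma_off": (0.05, 0.75),
            "k_on0": (1e3, 1.2e6),
            "k_off0": (0.5, 300.0),
        }
        out = []
        for name, (lo, hi) in ranges.items():
            v = getattr(self, name)
            if not (lo - 1e-12 <= v <= hi + 1e-12):
                out.append(f"{name}={v} outside [{lo}, {hi}]")
        return out


#: Calibrated presets. The sickle rows are the published normoxia/hypoxia
#: parameter sets; the ``normal`` row shares the normoxia kinetics with the
#: spring stiffness obtained by the detachment-velocity fitting procedure
#: (normal cells release at ≈500 μm/s).
ADHESION_PRESETS: dict[str, AdhesionParams] = {
    "normal": AdhesionParams(K_s=2.7, k_on0=5.42e4, k_off0=2.71),
    "normoxia": AdhesionParams(K_s=2.9, k_on0=5.42e4, k_off0=2.71),
    "hypoxia": AdhesionParams(K_s=6.7, k_on0=8.14e4, k_off0=0.54),
}


@dataclass(frozen=True)
class AggregationParams:
    """Morse-potential intercellular aggregation.

    ``D_e`` is the well depth per vertex pair in units of k_B·T; ``beta``
    the inverse interaction width [1/μm]; ``r0`` the equilibrium membrane
    separation [μm]; ``cutoff`` the interaction range [μm].
    """

    D_e: float = 15.0
    beta: float = 3.84
    r0: float = 0.4
    cutoff: float = 1.6
    enabled: bool = True
    kBT: float = KBT_310

    def __post_init__(self) -> None:
        if self.D_e < 0:
            raise ValueError("D_e must be nonnegative")
        if self.cutoff <= self.r0:
            raise ValueError("cutoff must exceed r0")

    @property
    def depth(self) -> float:
        """Well depth in pN·μm."""
        return self.D_e * self.kBT


# ---------------------------------------------------------------------------
# Rates and probabilities (Bell/Dembo forms)
# ---------------------------------------------------------------------------


def formation_rate(l, p: AdhesionParams):
    """k_on(l): maximal at l = l0, even in (l - l0)."""
    l = np.asarray(l, dtype=np.float64)
    return p.k_on0 * np.exp(-p.sigma_on * (l - p.l0) ** 2 / (2.0 * p.kBT))


def dissociation_rate(l, p: AdhesionParams):
    """k_off(l) with the rupture-strength weight σ_off."""
    l = np.asarray(l, dtype=np.float64)
    return p.k_off0 * np.exp(-p.sigma_off * (l - p.l0) ** 2 / (2.0 * p.kBT))


def formation_probability(k_on, dt: float):
    """P_on = 1 - exp(-k_on Δt) ∈ [0, 1)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return -np.expm1(-np.asarray(k_on, dtype=np.float64) * dt)


def dissociation_probability(k_off, dt: float):
    """P_off = 1 - exp(-k_off Δt) ∈ [0, 1)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return -np.expm1(-np.asarray(k_off, dtype=np.float64) * dt)


# ---------------------------------------------------------------------------
# Macrophage surfaces (rigid)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MacrophageArc2D:
    """Circular-arc macrophage cross-section in the (x, z) plane, wall at
    z = 0: circle of ``radius`` centred at (x_c, cap_height - radius),
    clipped to z >= 0."""

    x_center: float
    radius: float
    cap_height: float

    @property
    def center(self) -> np.ndarray:
        return np.array([self.x_center, self.cap_height - self.radius])

    def nearest_point(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest surface point and signed gap (positive outside) for
        points ``x`` of shape (N, 2)."""
        d = x - self.center
        dist = np.linalg.norm(d, axis=-1)
        safe = np.where(dist < 1e-12, 1.0, dist)
        on_sphere = self.center + d / safe[..., None] * self.radius
        below = on_sphere[..., 1] < 0.0
        if np.any(below):
            # clamp to the rim where the arc meets the wall
            half_w = np.sqrt(max(self.radius**2 - self.center[1] ** 2, 0.0))
            rim_x = self.x_center + np.sign(d[..., 0]) * half_w
            on_sphere[below, 0] = np.broadcast_to(rim_x, dist.shape)[below]
            on_sphere[below, 1] = 0.0
        gap = np.linalg.norm(x - on_sphere, axis=-1)
        inside = dist < self.radius
        gap = np.where(inside & ~below, -(self.radius - dist), gap)
        return on_sphere, gap


@dataclass(frozen=True)
class MacrophageCap3D:
    """Spherical-cap macrophage surface in 3D, wall plane z = 0."""

    base_center: tuple[float, float]
    radius: float
    cap_height: float

    @property
    def center(self) -> np.ndarray:
        return np.array([self.base_center[0], self.base_center[1], self.cap_height - self.radius])

    def nearest_point(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = x - self.center
        dist = np.linalg.norm(d, axis=-1)
        safe = np.where(dist < 1e-12, 1.0, dist)
        on_sphere = self.center + d / safe[..., None] * self.radius
        below = on_sphere[..., 2] < 0.0
        if np.any(below):
            lat = d[..., :2]
            lat_n = np.linalg.norm(lat, axis=-1)
            lat_safe = np.where(lat_n < 1e-12, 1.0, lat_n)
            half_w = np.sqrt(max(self.radius**2 - self.center[2] ** 2, 0.0))
            rim = np.empty_like(on_sphere)
            rim[..., :2] = np.asarray(self.base_center) + lat / lat_safe[..., None] * half_w
            rim[..., 2] = 0.0
            on_sphere = np.where(below[..., None], rim, on_sphere)
        gap = np.linalg.norm(x - on_sphere, axis=-1)
        inside = dist < self.radius
        gap = np.where(inside & ~below, -(self.radius - dist), gap)
        return on_sphere, gap


# ---------------------------------------------------------------------------
# Bond registry and the per-step stochastic update
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Bond:
    """One live bond: RBC vertex index, fixed anchor on the macrophage."""

    rbc_vertex: int
    anchor: np.ndarray
    length: float
    formation_time: float


class BondRegistry:
    """Live bonds keyed by RBC vertex (at most one bond per vertex).

    Stored as dense arrays aligned with the vertex array for vectorized
    updates; mutated only through :func:`stochastic_update`.
    """

    def __init__(self, n_vertices: int, dim: int = 2, cell_of_vertex: np.ndarray | None = None):
        self.n_vertices = int(n_vertices)
        self.dim = int(dim)
        self.bonded = np.zeros(self.n_vertices, dtype=bool)
        self.anchor = np.zeros((self.n_vertices, self.dim))
        self.t_form = np.full(self.n_vertices, np.nan)
        self.cell_of_vertex = (
            np.zeros(self.n_vertices, dtype=np.int64) if cell_of_vertex is None else np.asarray(cell_of_vertex)
        )

    def bonds(self, positions: np.ndarray) -> list[Bond]:
        out = []
        for i in np.flatnonzero(self.bonded):
            out.append(
                Bond(
                    rbc_vertex=int(i),
                    anchor=self.anchor[i].copy(),
                    length=float(np.linalg.norm(positions[i] - self.anchor[i])),
                    formation_time=float(self.t_form[i]),
                )
            )
        return out

    def n_bonds_per_cell(self, n_cells: int | None = None) -> np.ndarray:
        n = int(self.cell_of_vertex.max()) + 1 if n_cells is None else n_cells
        return np.bincount(self.cell_of_vertex[self.bonded], minlength=n)

    @property
    def n_bonds(self) -> int:
        return int(self.bonded.sum())

    def copy(self) -> "BondRegistry":
        new = BondRegistry(self.n_vertices, self.dim, self.cell_of_vertex.copy())
        new.bonded = self.bonded.copy()
        new.anchor = self.anchor.copy()
        new.t_form = self.t_form.copy()
        return new


def stochastic_update(
    registry: BondRegistry,
    rbc_vertices: np.ndarray,
    macrophage_surface,
    p: AdhesionParams,
    rng_stream: np.random.Generator,
    dt: float,
    time: float = 0.0,
    adhesive_mask: np.ndarray | None = None,
) -> BondRegistry:
    """One Monte-Carlo bond formation/dissociation sweep (in place).

    Formation: an unbonded adhesive vertex whose gap to the surface satisfies
    l < d_on binds iff P_on(l) > λ1; the anchor is the nearest surface point
    at formation time and stays fixed (the macrophage is rigid).
    Dissociation: a live bond of length l is removed iff λ2 < P_off(l) while
    l < d_off, or deterministically once l >= d_off.

    λ1 and λ2 draws are consumed from the dedicated ``rng_stream`` in a fixed
    order (all formation candidates, then all live bonds), so runs are
    reproducible for a given stream.
    """
    if not isinstance(rng_stream, np.random.Generator):
        raise TypeError("rng_stream must be a seeded numpy Generator")
    x = np.asarray(rbc_vertices, dtype=np.float64)
    nearest, gap = macrophage_surface.nearest_point(x)

    candidates = (~registry.bonded) & (np.abs(gap) < p.d_on)
    if adhesive_mask is not None:
        candidates &= adhesive_mask
    idx_c = np.flatnonzero(candidates)
    if len(idx_c):
        lam1 = rng_stream.uniform(size=len(idx_c))
        p_on = formation_probability(formation_rate(np.abs(gap[idx_c]), p), dt)
        form = p_on > lam1
        sel = idx_c[form]
        registry.bonded[sel] = True
        registry.anchor[sel] = nearest[sel]
        registry.t_form[sel] = time

    idx_b = np.flatnonzero(registry.bonded & (registry.t_form < time))
    if len(idx_b):
        l = np.linalg.norm(x[idx_b] - registry.anchor[idx_b], axis=1)
        lam2 = rng_stream.uniform(size=len(idx_b))
        p_off = dissociation_probability(dissociation_rate(l, p), dt)
        off = (p_off > lam2) | (l >= p.d_off)
        sel = idx_b[off]
        registry.bonded[sel] = False
        registry.t_form[sel] = np.nan
    return registry


def adhesion_energy(registry: BondRegistry, positions: np.ndarray, p: AdhesionParams) -> float:
    """U_adh = ½ Σ K_s (l - l0)² over live bonds."""
    idx = np.flatnonzero(registry.bonded)
    if not len(idx):
        return 0.0
    l = np.linalg.norm(positions[idx] - registry.anchor[idx], axis=1)
    return float(0.5 * p.K_s * np.sum((l - p.l0) ** 2))


def bond_forces(
    registry: BondRegistry, positions: np.ndarray, p: AdhesionParams
) -> tuple[np.ndarray, np.ndarray]:
    """Forces on RBC vertices from live bonds, F = -∂U_adh/∂X.

    Returns (per-vertex forces, net reaction force on the macrophage); the
    reaction is equal and opposite by construction.
    """
    f = np.zeros_like(positions, dtype=np.float64)
    idx = np.flatnonzero(registry.bonded)
    if len(idx):
        d = positions[idx] - registry.anchor[idx]
        l = np.linalg.norm(d, axis=1)
        safe = np.where(l < 1e-12, 1.0, l)
        f[idx] = -p.K_s * (l - p.l0)[:, None] * d / safe[:, None]
    return f, -f.sum(axis=0)


# ---------------------------------------------------------------------------
# Morse aggregation
# ---------------------------------------------------------------------------


def morse_energy(r, p: AggregationParams):
    """U(r) = D_e [e^{-2β(r-r0)} - 2 e^{-β(r-r0)}], zero beyond the cutoff."""
    r = np.asarray(r, dtype=np.float64)
    e = np.exp(-p.beta * (r - p.r0))
    u = p.depth * (e * e - 2.0 * e)
    return np.where(r < p.cutoff, u, 0.0)


def _morse_force_mag(r, p: AggregationParams, repulsive_only: bool):
    """Scalar force magnitude along r̂ (positive = repulsive)."""
    e = np.exp(-p.beta * (r - p.r0))
    f = 2.0 * p.beta * p.depth * (e * e - e)  # -dU/dr
    if repulsive_only:
        f = np.clip(f, 0.0, None)
    return np.where(r < p.cutoff, f, 0.0)


def morse_aggregation_forces(
    cell_positions: list[np.ndarray], p: AggregationParams
) -> list[np.ndarray]:
    """Pairwise vertex forces between distinct cells from the Morse potential.

    With ``p.enabled`` false the attractive tail is removed and only the
    repulsive core remains (intercellular excluded volume). Forces are equal
    and opposite, zero at r = r0 (enabled) and beyond the cutoff.
    """
    forces = [np.zeros_like(x, dtype=np.float64) for x in cell_positions]
    for a in range(len(cell_positions)):
        for b in range(a + 1, len(cell_positions)):
            xa, xb = cell_positions[a], cell_positions[b]
            d = xa[:, None, :] - xb[None, :, :]
            r = np.linalg.norm(d, axis=-1)
            mask = r < p.cutoff
            if not mask.any():
                continue
            fmag = _morse_force_mag(r, p, repulsive_only=not p.enabled)
            safe = np.where(r < 1e-12, 1.0, r)
            fvec = (fmag / safe)[..., None] * d
            forces[a] += fvec.sum(axis=1)
            forces[b] -= fvec.sum(axis=0)
    return forces
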