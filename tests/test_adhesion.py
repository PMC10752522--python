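"""Stochastic bond kinetics: closed forms, presets, Markov stationarity,
bond mechanics, Morse aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splenosim.adhesion import (
    ADHESION_PRESETS,
    AdhesionParams,
    AggregationParams,
    BondRegistry,
    KBT_310,
    MacrophageArc2D,
    adhesion_energy,
    bond_forces,
    dissociation_probability,
    dissociation_rate,
    formation_probability,
    formation_rate,
    morse_aggregation_forces,
    morse_energy,
    stochastic_update,
)


class TestRates:
    def test_rate_at_rest_length(self):
        p = ADHESION_PRESETS["normoxia"]
        assert formation_rate(p.l0, p) == pytest.approx(p.k_on0)
        assert dissociation_rate(p.l0, p) == pytest.approx(p.k_off0)

    def test_hypoxia_off_rate_value(self):
        p = ADHESION_PRESETS["hypoxia"]
        assert dissociation_rate(p.l0, p) == pytest.approx(0.54)
        assert formation_rate(p.l0, p) == pytest.approx(8.14e4)

    def test_flat_rate_when_strength_zero(self):
        p = AdhesionParams(K_s=1.0, sigma_on=0.0, sigma_off=0.0)
        ls = np.linspace(0, 2, 7)
        assert np.allclose(formation_rate(ls, p), p.k_on0)
        assert np.allclose(dissociation_rate(ls, p), p.k_off0)

    def test_rate_at_thermal_displacements(self):
        """Direct arithmetic at reference displacements: e^-1/2 at
        sqrt(kBT/σ_on), e^-1 at sqrt(2 kBT/σ_on); even in (l - l0)."""
        p = ADHESION_PRESETS["normoxia"]
        half = np.sqrt(p.kBT / p.sigma_on)
        full = np.sqrt(2.0 * p.kBT / p.sigma_on)
        assert formation_rate(p.l0 + half, p) == pytest.approx(p.k_on0 * np.exp(-0.5), rel=1e-12)
        assert formation_rate(p.l0 + full, p) == pytest.approx(p.k_on0 * np.exp(-1.0), rel=1e-12)
        assert formation_rate(p.l0 - full, p) == pytest.approx(p.k_on0 * np.exp(-1.0), rel=1e-12)

    def test_probability_closed_form(self):
        k = 100.0
        dt = np.log(2.0) / k
        assert formation_probability(k, dt) == pytest.approx(0.5)
        assert dissociation_probability(k, dt) == pytest.approx(0.5)

    @given(k=st.floats(0, 1e6), dt=st.floats(1e-9, 1.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_probability_bounds(self, k, dt):
        p = formation_probability(k, dt)
        assert 0.0 <= p <= 1.0
        if k * dt < 30.0:  # below float64 saturation of 1 - exp(-k dt)
            assert p < 1.0

    def test_probability_vanishes_with_dt(self):
        assert formation_probability(1e4, 1e-12) < 1e-7

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            formation_probability(1.0, 0.0)


class TestPresets:
    def test_table_values_exact(self):
        nor = ADHESION_PRESETS["normoxia"]
        hyp = ADHESION_PRESETS["hypoxia"]
        assert (nor.k_on0, nor.k_off0, nor.K_s) == (5.42e4, 2.71, 2.9)
        assert (hyp.k_on0, hyp.k_off0, hyp.K_s) == (8.14e4, 0.54, 6.7)
        for p in (nor, hyp):
            assert p.l0 == 0.3 and p.d_on == 0.75 and p.d_off == 0.75
            assert p.sigma_on == 0.51 and p.sigma_off == 0.17

    def test_presets_within_reported_ranges(self):
        for name, p in ADHESION_PRESETS.items():
            assert p.reported_range_violations() == []

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            AdhesionParams(K_s=-1.0)
        with pytest.raises(ValueError):
            AdhesionParams(K_s=1.0, l0=0.8, d_on=0.75)


class TestStochasticUpdate:
    def _surface(self):
        return MacrophageArc2D(x_center=0.0, radius=11.0, cap_height=11.0)

    def _vertices_at_gap(self, n, gap):
        # n points straight above the apex at the given surface gap
        x = np.linspace(-0.5, 0.5, n)
        return np.column_stack([x, np.full(n, 11.0 + gap)])

    def test_no_formation_when_rate_zero(self):
        p = AdhesionParams(K_s=1.0, k_on0=0.0)
        reg = BondRegistry(10, dim=2)
        x = self._vertices_at_gap(10, 0.3)
        rng = np.random.default_rng(0)
        for _ in range(50):
            stochastic_update(reg, x, self._surface(), p, rng, dt=1e-3)
        assert reg.n_bonds == 0

    def test_no_dissociation_when_rate_zero(self):
        p = AdhesionParams(K_s=1.0, k_off0=0.0, sigma_off=0.0)
        reg = BondRegistry(10, dim=2)
        x = self._vertices_at_gap(10, 0.3)
        rng = np.random.default_rng(0)
        for k in range(50):
            stochastic_update(reg, x, self._surface(), p, rng, dt=1e-3, time=k * 1e-3)
        assert reg.n_bonds == 10

    def test_deterministic_rupture_beyond_cutoff(self):
        p = AdhesionParams(K_s=1.0, k_off0=0.0, sigma_off=0.0)
        reg = BondRegistry(5, dim=2)
        x = self._vertices_at_gap(5, 0.3)
        rng = np.random.default_rng(0)
        stochastic_update(reg, x, self._surface(), p, rng, dt=1e-3, time=0.0)
        assert reg.n_bonds == 5
        far = self._vertices_at_gap(5, 2.0)  # stretch all bonds past d_off
        stochastic_update(reg, far, self._surface(), p, rng, dt=1e-3, time=1e-3)
        assert reg.n_bonds == 0

    def test_unseeded_stream_rejected(self):
        p = AdhesionParams(K_s=1.0)
        reg = BondRegistry(3, dim=2)
        with pytest.raises(TypeError):
            stochastic_update(reg, self._vertices_at_gap(3, 0.3), self._surface(), p,
                              np.random, dt=1e-3)

    def test_fixed_gap_stationary_bound_fraction(self):
        """Held at l = l0, the bound fraction converges to the two-state
        Markov stationary value k_on/(k_on + k_off)."""
        p = AdhesionParams(K_s=1.0, k_on0=300.0, k_off0=150.0,
                           sigma_on=0.0, sigma_off=0.0)
        dt = 1e-3
        n = 400
        reg = BondRegistry(n, dim=2)
        x = self._vertices_at_gap(n, p.l0)
        rng = np.random.default_rng(42)
        n_steps = 3000
        burn = 500
        acc = 0.0
        cnt = 0
        for k in range(n_steps):
            stochastic_update(reg, x, self._surface(), p, rng, dt=dt, time=k * dt)
            if k >= burn:
                acc += reg.n_bonds / n
                cnt += 1
        measured = acc / cnt
        # exact stationary value of the discrete chain with P_on/P_off
        pon = 1 - np.exp(-p.k_on0 * dt)
        poff = 1 - np.exp(-p.k_off0 * dt)
        expected = pon / (pon + poff)
        assert measured == pytest.approx(expected, rel=0.02)


class TestBondForces:
    def test_zero_at_rest_length(self):
        p = ADHESION_PRESETS["hypoxia"]
        reg = BondRegistry(1, dim=2)
        reg.bonded[0] = True
        reg.anchor[0] = (0.0, 0.0)
        x = np.array([[0.0, p.l0]])
        f, reaction = bond_forces(reg, x, p)
        assert np.allclose(f, 0.0)
        assert np.allclose(reaction, 0.0)

    def test_single_bond_magnitude(self):
        """Hypoxia stiffness 6.7 μN/m stretched 0.1 μm pulls with 0.67 pN."""
        p = ADHESION_PRESETS["hypoxia"]
        reg = BondRegistry(1, dim=2)
        reg.bonded[0] = True
        reg.anchor[0] = (0.0, 0.0)
        x = np.array([[0.0, p.l0 + 0.1]])
        f, reaction = bond_forces(reg, x, p)
        assert np.linalg.norm(f[0]) == pytest.approx(0.67, rel=1e-12)
        assert f[0, 1] < 0  # attractive (pulled back toward the anchor)
        assert np.allclose(reaction, -f.sum(axis=0))

    def test_force_is_negative_energy_gradient(self, rng):
        p = ADHESION_PRESETS["normoxia"]
        n = 12
        reg = BondRegistry(n, dim=2)
        reg.bonded[:] = True
        reg.anchor = rng.normal(size=(n, 2))
        x = reg.anchor + rng.normal(scale=0.3, size=(n, 2))
        f, _ = bond_forces(reg, x, p)
        h = 1e-7
        for i in range(n):
            for d in range(2):
                xp = x.copy(); xp[i, d] += h
                xm = x.copy(); xm[i, d] -= h
                fd = -(adhesion_energy(reg, xp, p) - adhesion_energy(reg, xm, p)) / (2 * h)
                assert f[i, d] == pytest.approx(fd, rel=1e-6, abs=1e-9)


class TestMorse:
    def test_zero_force_at_minimum(self):
        p = AggregationParams()
        a = np.array([[0.0, 0.0]])
        b = np.array([[p.r0, 0.0]])
        fa, fb = morse_aggregation_forces([a, b], p)
        assert np.allclose(fa, 0.0, atol=1e-12)

    def test_equal_opposite_and_cutoff(self, rng):
        p = AggregationParams()
        a = rng.normal(size=(6, 2))
        b = rng.normal(size=(5, 2)) + 1.0
        fa, fb = morse_aggregation_forces([a, b], p)
        assert np.allclose(fa.sum(axis=0), -fb.sum(axis=0))
        far = b + 100.0
        fa2, fb2 = morse_aggregation_forces([a, far], p)
        assert np.allclose(fa2, 0.0) and np.allclose(fb2, 0.0)

    def test_disabled_keeps_repulsive_core_only(self):
        p = AggregationParams(enabled=False)
        a = np.array([[0.0, 0.0]])
        close = np.array([[0.2, 0.0]])   # r < r0: repulsion
        apart = np.array([[0.8, 0.0]])   # r > r0: would attract if enabled
        fa, _ = morse_aggregation_forces([a, close], p)
        assert fa[0, 0] < 0  # pushed away
        fa2, _ = morse_aggregation_forces([a, apart], p)
        assert np.allclose(fa2, 0.0)

    def test_energy_minimum_location(self):
        p = AggregationParams()
        r = np.linspace(0.2, p.cutoff - 1e-3, 2000)
        u = morse_energy(r, p)
        assert r[np.argmin(u)] == pytest.approx(p.r0, abs=2e-3)

    def test_doublet_remains_aggregated(self):
        """Two flat contours released at contact separation stay bound for
        10^4 steps when the well depth exceeds the thermal scale."""
        from splenosim.engine import SimulationConfig, Simulation, CellGroup
        from splenosim.fluid import ChannelDomain

        cfg = SimulationConfig(
            domain=ChannelDomain(L_x=60.0, h=20.0),
            membrane_condition="sickle_hypoxia",
            adhesion_preset="hypoxia",
            aggregation=AggregationParams(enabled=True, D_e=5.0),
            cells=[CellGroup("biconcave", 2)],
            hematocrit=None,
            macrophages=[],
            velocity_schedule=[(0.0, 0.0)],
            n_steps=10_000,
            dt=2e-5,
            output_every=1000,
            master_seed=0,
            store_positions=False,
        )
        sim = Simulation(cfg)
        st_ = sim.state
        b = sim.bundle
        # stack the two cells with membranes one Morse r0 apart
        for c in (0, 1):
            sl = slice(b["cell_start"][c], b["cell_end"][c])
            st_.positions[sl] -= st_.positions[sl].mean(axis=0)
            st_.positions[sl] += np.array([30.0, 10.0 + (2.0 + cfg.aggregation.r0) * c])
            st_.velocities[sl] = 0.0
        sim.run()
        a = sim.trajectory.as_arrays()
        gapz = a["centroids"][-1, 1, 1] - a["centroids"][-1, 0, 1]
        assert abs(gapz) < 4.0  # still a doublet, not drifted apart
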