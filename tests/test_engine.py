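"""Engine: unit mapping, configuration round trip, determinism, restart
equivalence, conservation during dynamics."""

import dataclasses

import numpy as np
import pytest

from splenosim.engine import (
    CellGroup,
    PackingError,
    Simulation,
    SimulationConfig,
    UnitSystem,
    initialize,
    map_units,
    rbc_outline_2d,
)
from splenosim.fluid import ChannelDomain
from splenosim.geometry import MacrophageSpec


class TestUnitSystem:
    def test_reactive_strength_dual_column(self):
        u = UnitSystem()
        assert u.to_physical(10.58, "stress") == pytest.approx(0.51)
        assert u.to_simulation(0.51, "stress") == pytest.approx(10.58)

    def test_on_rate_dual_column(self):
        u = UnitSystem()
        assert u.to_physical(100.0, "rate") == pytest.approx(5.42e4)
        assert u.to_physical(150.0, "rate") == pytest.approx(8.13e4, rel=1e-3)

    def test_off_rate_and_stiffness_columns(self):
        u = UnitSystem()
        assert u.to_physical(0.001, "rate") == pytest.approx(0.542, rel=1e-3)
        assert u.to_physical(50.0, "stress") == pytest.approx(2.41, rel=1e-3)
        assert u.to_physical(150.0, "stress") == pytest.approx(7.23, rel=1e-3)

    @pytest.mark.parametrize(
        "quantity", ["length", "time", "rate", "velocity", "stress", "force", "energy"]
    )
    def test_round_trip_identity(self, quantity):
        u = UnitSystem()
        x = 1.2345678901234
        back = u.to_simulation(u.to_physical(x, quantity), quantity)
        assert back == pytest.approx(x, rel=1e-12)

    def test_unknown_quantity(self):
        with pytest.raises(KeyError):
            map_units(1.0, "pressure", "to_physical")


class TestOutlines:
    @pytest.mark.parametrize("shape", ["biconcave", "elongated", "granular", "sickle"])
    def test_equal_area_counter_clockwise(self, shape):
        out = rbc_outline_2d(shape, 32, seed=1)
        area = 0.5 * np.sum(
            out[:, 0] * np.roll(out[:, 1], -1) - np.roll(out[:, 0], -1) * out[:, 1]
        )
        ref = rbc_outline_2d("biconcave", 32)
        ref_area = 0.5 * np.sum(
            ref[:, 0] * np.roll(ref[:, 1], -1) - np.roll(ref[:, 0], -1) * ref[:, 1]
        )
        assert area > 0
        assert area == pytest.approx(ref_area, rel=0.02)

    def test_sickle_is_bent(self):
        out = rbc_outline_2d("sickle", 48)
        ext = np.ptp(out, axis=0)
        assert ext[0] > 1.5 * ext[1]  # elongated overall
        # crescent: the bend shifts the area centroid off the chord midline
        # (a symmetric ellipse gives exactly zero here)
        assert abs(out[:, 1].mean() - 0.5 * (out[:, 1].min() + out[:, 1].max())) > 0.1


def _small_config(**kw):
    base = dict(
        membrane_condition="sickle_hypoxia",
        adhesion_preset="hypoxia",
        cells=[CellGroup("sickle", 3)],
        hematocrit=0.02,
        macrophages=[MacrophageSpec(radius=9.0, cap_height=9.0, base_center=(30.0, 0.0))],
        n_steps=4000,
        output_every=500,
        master_seed=42,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestInitialize:
    def test_hematocrit_realised(self):
        cfg = _small_config()
        _, bundle = initialize(cfg)
        assert bundle["hematocrit_realised"] == pytest.approx(0.02, rel=0.05)

    def test_zero_cells_valid(self):
        cfg = _small_config(cells=[], hematocrit=None)
        state, bundle = initialize(cfg)
        assert state.positions.shape[0] == 0

    def test_infeasible_hematocrit_raises(self):
        cfg = _small_config(hematocrit=0.69)
        with pytest.raises(PackingError):
            initialize(cfg)

    def test_cells_do_not_overlap_macrophages(self):
        cfg = _small_config()
        state, bundle = initialize(cfg)
        for mx, mz, mr in zip(bundle["mac_cx"], bundle["mac_cz"], bundle["mac_r"]):
            d = np.hypot(state.positions[:, 0] - mx, state.positions[:, 1] - mz)
            assert np.all(d > mr)


class TestDeterminismAndRestart:
    def test_bitwise_determinism(self):
        a = Simulation(_small_config())
        a.run()
        b = Simulation(_small_config())
        b.run()
        assert np.array_equal(a.state.positions, b.state.positions)
        assert np.array_equal(a.state.velocities, b.state.velocities)
        assert np.array_equal(a.state.bonded, b.state.bonded)

    def test_restart_equivalence(self, tmp_path):
        """run(N) is bitwise identical to run(N/2) -> save -> load -> run(N/2)."""
        full = Simulation(_small_config())
        full.run(4000)
        half = Simulation(_small_config())
        half.run(2000)
        p = str(tmp_path / "state.h5")
        half.save(p)
        resumed = Simulation.load(p)
        resumed.run(2000)
        assert np.array_equal(full.state.positions, resumed.state.positions)
        assert np.array_equal(full.state.velocities, resumed.state.velocities)
        assert np.array_equal(full.state.bonded, resumed.state.bonded)

    def test_time_scaling_only_relabels(self):
        a = Simulation(_small_config())
        a.run()
        b = Simulation(_small_config(time_scaling=60.0))
        b.run()
        assert np.array_equal(a.state.positions, b.state.positions)
        ta = np.asarray(a.trajectory.times)
        tb = np.asarray(b.trajectory.times)
        assert np.allclose(tb, 60.0 * ta)

    def test_seed_changes_trajectory(self):
        a = Simulation(_small_config())
        a.run()
        b = Simulation(_small_config(master_seed=43))
        b.run()
        assert not np.array_equal(a.state.positions, b.state.positions)


class TestDynamics:
    def test_membrane_area_drift_small(self):
        """Global enclosed-area drift below 1% over 1e5 steps (the 2D
        counterpart of volume conservation)."""
        cfg = _small_config(n_steps=100_000, output_every=10_000)
        sim = Simulation(cfg)
        b = sim.bundle
        sim.run()
        for c in range(len(b["cell_start"])):
            sl = slice(b["cell_start"][c], b["cell_end"][c])
            x = sim.state.positions[sl]
            area = 0.5 * np.sum(
                x[:, 0] * np.roll(x[:, 1], -1) - np.roll(x[:, 0], -1) * x[:, 1]
            )
            assert area == pytest.approx(b["rest_area"][c], rel=0.01)

    def test_no_binding_control(self):
        """With formation switched off, cells advect past macrophages and
        never bind."""
        cfg = _small_config(
            adhesion_overrides={"k_on0": 0.0}, n_steps=20_000, velocity_schedule=[(0.0, 150.0)]
        )
        sim = Simulation(cfg)
        sim.run()
        arr = sim.trajectory.as_arrays()
        assert arr["bond_counts"].sum() == 0
        # suspension keeps moving with the flow
        assert arr["cell_speeds"][-1].mean() > 10.0

    def test_config_yaml_round_trip(self):
        cfg = _small_config()
        text = cfg.to_yaml()
        back = SimulationConfig.from_yaml(text)
        assert back.to_yaml() == text
        assert back.config_hash() == cfg.config_hash()

    def test_walls_impermeable(self):
        cfg = _small_config(n_steps=20_000)
        sim = Simulation(cfg)
        sim.run()
        z = sim.state.positions[:, 1]
        assert np.all(z >= 0.0) and np.all(z <= cfg.domain.h)

    def test_kernel_matches_reference_contour_forces(self, rng):
        """One kernel step with coupling/noise/adhesion switched off
        reproduces the numpy membrane reference forces."""
        from splenosim.engine import _assay_chunk_kernel
        from splenosim.membrane import MEMBRANE_PRESETS, Contour2D, contour_forces

        params = MEMBRANE_PRESETS["sickle_normoxia"]
        outline = rbc_outline_2d("granular", 24, seed=2)
        x = outline + 0.08 * rng.normal(size=outline.shape)
        ct = Contour2D.from_polygon(outline, params)
        f_ref = contour_forces(ct, x)

        n = len(x)
        pos = x + np.array([40.0, 10.0])
        forces = np.zeros_like(pos)
        idx = np.arange(n)
        empty = np.zeros(0)
        nrec, status = _assay_chunk_kernel(
            pos.copy(), np.zeros_like(pos), forces,
            np.zeros(n, np.uint8), np.zeros(n), np.zeros(n), np.full(n, np.nan),
            np.zeros(n, np.int64), np.array([0], np.int64), np.array([n], np.int64),
            np.roll(idx, -1), np.roll(idx, 1),
            ct.ref_edge_length.copy(), np.cos(ct.ref_angle), np.sin(ct.ref_angle),
            np.array([ct.ref_area]), np.array([ct.ref_perimeter]),
            np.array([ct.k_edge]), np.array([ct.k_angle]),
            np.array([ct.k_area]), np.array([ct.k_perimeter]),
            empty, empty, empty,
            np.zeros(n, np.uint8), 1.0, 0.3, 0.75, 0.75, 0.51, 0.17, 0.0, 0.0,
            4.28e-3, 0.0, 3.84, 0.4, 1.6, 0,
            0.0, 1.0, 0.0, 0.0, 0.0, np.ones(1), 0, 0.0, 20.0, 1000.0,
            0.0, 0.15, 1e-12, 1, 0, 0.0,
            np.zeros((1, n, 2)), np.full((1, n, 2), 2.0),
            10**9, np.zeros((2, 1, 2)), np.zeros((2, 1, 2)),
            np.zeros((2, 1), np.int64), 0, np.full(1, np.inf),
        )
        assert status == 0
        assert np.abs(forces - f_ref).max() < 1e-9 * max(np.abs(f_ref).max(), 1.0)
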