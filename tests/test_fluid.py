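"""DPD solvent: fluctuation-dissipation, momentum conservation, boundaries,
Couette linearity, temperature control, ambient coupling."""

import numpy as np
import pytest

from splenosim.fluid import (
    AmbientShearCoupling,
    ChannelDomain,
    DpdParams,
    FluidState,
    TimestepError,
    apply_boundaries,
    couette_profile,
    dpd_pair_forces,
    kinetic_temperature,
    make_solvent,
    run_couette,
)


class TestDpdParams:
    def test_fluctuation_dissipation_enforced(self):
        with pytest.raises(ValueError):
            DpdParams(gamma=1e-3, sigma_dpd=0.5)

    def test_from_gamma_consistent(self):
        p = DpdParams.from_gamma(2e-3)
        assert p.sigma_dpd == pytest.approx(np.sqrt(2 * 2e-3 * p.kBT))


class TestPairForces:
    def _two_particle_state(self, separation):
        pos = np.array([[5.0, 0.0, 10.0], [5.0 + separation, 0.0, 10.0]])
        vel = np.zeros((2, 3))
        return FluidState(pos, vel, n_free=2)

    def test_zero_beyond_cutoff(self):
        p = DpdParams()
        dom = ChannelDomain()
        st = self._two_particle_state(1.5 * p.rc)
        f = dpd_pair_forces(st, p, dom, seed_stream=1)
        assert np.allclose(f, 0.0)

    def test_newtons_third_law_exact(self, rng):
        p = DpdParams()
        dom = ChannelDomain()
        n = 120
        pos = np.column_stack([
            rng.uniform(0, dom.L_x, n), np.zeros(n), rng.uniform(0, dom.h, n)
        ])
        vel = rng.normal(scale=50.0, size=(n, 3))
        vel[:, 1] = 0.0
        st = FluidState(pos, vel, n_free=n)
        f = dpd_pair_forces(st, p, dom, seed_stream=7)
        assert np.abs(f.sum(axis=0)).max() < 1e-10 * max(np.abs(f).max(), 1.0)

    def test_coincident_particles_finite(self):
        p = DpdParams()
        dom = ChannelDomain()
        st = self._two_particle_state(0.0)
        f = dpd_pair_forces(st, p, dom, seed_stream=1)
        assert np.all(np.isfinite(f))

    def test_deterministic_given_seed(self, rng):
        p = DpdParams()
        dom = ChannelDomain()
        n = 50
        pos = np.column_stack([
            rng.uniform(0, dom.L_x, n), np.zeros(n), rng.uniform(0, dom.h, n)
        ])
        st = FluidState(pos.copy(), np.zeros((n, 3)), n)
        st2 = FluidState(pos.copy(), np.zeros((n, 3)), n)
        f1 = dpd_pair_forces(st, p, dom, seed_stream=11)
        f2 = dpd_pair_forces(st2, p, dom, seed_stream=11)
        assert np.array_equal(f1, f2)


class TestBoundaries:
    def test_bounce_back_bottom(self):
        dom = ChannelDomain(U_top=100.0)
        pos = np.array([[5.0, 0.0, -0.3]])
        vel = np.array([[10.0, 0.0, -20.0]])
        st = FluidState(pos, vel, 1)
        apply_boundaries(st, dom)
        assert st.positions[0, 2] == pytest.approx(0.3)
        assert st.velocities[0, 2] == pytest.approx(20.0)

    def test_bounce_back_top_imparts_wall_velocity(self):
        dom = ChannelDomain(U_top=100.0)
        pos = np.array([[5.0, 0.0, dom.h + 0.2]])
        vel = np.array([[10.0, 0.0, 30.0]])
        st = FluidState(pos, vel, 1)
        apply_boundaries(st, dom)
        assert st.positions[0, 2] == pytest.approx(dom.h - 0.2)
        assert st.velocities[0, 2] == pytest.approx(-30.0)
        assert st.velocities[0, 0] == pytest.approx(2 * dom.U_top - 10.0)

    def test_excessive_displacement_raises(self):
        dom = ChannelDomain()
        st = FluidState(np.array([[1.0, 0.0, -0.6 * dom.h]]), np.zeros((1, 3)), 1)
        with pytest.raises(TimestepError):
            apply_boundaries(st, dom)

    def test_periodic_wrap_x(self):
        dom = ChannelDomain()
        st = FluidState(np.array([[dom.L_x + 1.0, 0.0, 5.0]]), np.zeros((1, 3)), 1)
        apply_boundaries(st, dom)
        assert st.positions[0, 0] == pytest.approx(1.0)


class TestCouetteAndTemperature:
    """Short driven channel runs: the linear profile is self-sustaining and
    the thermostat holds kBT."""

    @pytest.fixture(scope="class")
    def couette(self):
        dom = ChannelDomain(L_x=20.0, h=20.0, U_top=500.0)
        par = DpdParams()
        return run_couette(dom, par, n_steps=4000, seed=3, warmup=1000), dom, par

    def test_profile_linear_within_tolerance(self, couette):
        res, dom, par = couette
        z, u = res["z"], res["u_x"]
        inner = (z > 2.0) & (z < dom.h - 2.0)
        dev = np.abs(u - couette_profile(z, dom))[inner].max()
        assert dev < 0.05 * dom.U_top

    def test_temperature_within_three_percent(self, couette):
        res, dom, par = couette
        assert res["temperature"] == pytest.approx(par.kBT, rel=0.03)

    def test_zero_drive_zero_mean_flow(self):
        dom = ChannelDomain(L_x=15.0, h=15.0, U_top=0.0)
        par = DpdParams()
        res = run_couette(dom, par, n_steps=2500, seed=5, warmup=500)
        vth = np.sqrt(par.kBT / par.mass)
        # channel-wide mean flow vanishes (momentum is conserved exactly);
        # individual bins keep slowly decaying hydrodynamic modes
        assert abs(res["u_x"].mean()) < 0.05 * vth
        assert np.abs(res["u_x"]).max() < 0.5 * vth


class TestAmbientCoupling:
    def test_settling_and_buoyancy_consistent(self):
        c = AmbientShearCoupling()
        assert c.buoyant_weight == pytest.approx(c.zeta_cell * c.settling_velocity)

    def test_drag_relaxes_to_profile(self):
        c = AmbientShearCoupling()
        dom = ChannelDomain(U_top=200.0)
        pos = np.array([[10.0, 10.0]])
        vel = np.array([[0.0, 0.0]])
        f = c.forces(pos, vel, dom, dt=1e-5, noise=np.zeros((1, 2)),
                     stiffness_ratio=0.0)
        # stationary vertex in moving fluid is dragged forward; with lift
        # switched off only the buoyant weight acts vertically
        assert f[0, 0] == pytest.approx(c.zeta_vertex * couette_profile(10.0, dom))
        assert f[0, 1] == pytest.approx(-c.buoyant_weight / c.n_vertices)
        f_lift = c.forces(pos, vel, dom, dt=1e-5, noise=np.zeros((1, 2)),
                          stiffness_ratio=1.0)
        assert f_lift[0, 1] > f[0, 1]

    def test_lift_decreases_with_stiffness_and_height(self):
        c = AmbientShearCoupling()
        dom = ChannelDomain(U_top=150.0)
        soft = c.lift_velocity(5.0, dom, stiffness_ratio=1.0)
        stiff = c.lift_velocity(5.0, dom, stiffness_ratio=0.02)
        high = c.lift_velocity(15.0, dom, stiffness_ratio=1.0)
        assert soft > stiff and soft > high > 0

    def test_velocity_field_reduces_to_couette_far_from_caps(self):
        from splenosim.geometry import MacrophageSpec

        c = AmbientShearCoupling(deflect_flow=True)
        dom = ChannelDomain(L_x=200.0, U_top=100.0)
        macs = [MacrophageSpec(radius=10.0, cap_height=10.0, base_center=(50.0, 0.0))]
        pts = np.array([[150.0, 10.0], [50.0, 15.0]])
        u = c.velocity_field(pts, dom, macs)
        assert u[0, 0] == pytest.approx(couette_profile(10.0, dom), rel=1e-2)
        # directly above the cap the flow accelerates
        assert u[1, 0] > couette_profile(15.0, dom)
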