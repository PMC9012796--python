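import numpy as np
import pytest

from pipacsim import (
    DropletSizeSpec,
    DropletState,
    GasProperties,
    SimulationConfig,
    drag_force,
    gravitational_force,
    particle_reynolds,
    relaxation_time,
    simulate,
    step,
    stokes_number,
    weber_number,
)
from pipacsim.core_model import GRAVITY
from pipacsim.droplet_transport import (
    detect_deposition,
    particle_reynolds_as_printed,
)
from pipacsim.gas_flow import UnsupportedPhysicsError
from pipacsim.nebulizer import InjectionSchedule

MU = GasProperties().dynamic_viscosity  # 1.4709e-5 Pa s


class TestForces:
    def test_relaxation_time_baseline(self):
        assert relaxation_time(1070, 30e-6, MU) == pytest.approx(3.64e-3, rel=2e-3)

    def test_relaxation_time_scales_with_diameter_squared(self):
        assert relaxation_time(1070, 60e-6, MU) == pytest.approx(
            4 * relaxation_time(1070, 30e-6, MU)
        )

    def test_relaxation_time_vanishes_for_viscous_gas(self):
        assert relaxation_time(1070, 30e-6, 1e6) < 1e-12

    def test_drag_zero_at_equilibrium(self):
        assert np.all(drag_force(MU, 30e-6, np.zeros(3)) == 0.0)

    def test_drag_magnitude(self):
        F = drag_force(MU, 30e-6, np.array([1.0, 0, 0]))
        assert np.linalg.norm(F) == pytest.approx(4.16e-9, rel=2e-3)

    def test_drag_equals_mass_over_tau_identity(self):
        # F_D / m_p == u_rel / tau_p (algebraic identity of the Stokes law)
        d, rho = 30e-6, 1070.0
        u_rel = np.array([0.3, -0.1, 0.7])
        mass = rho * np.pi / 6 * d**3
        tau = relaxation_time(rho, d, MU)
        assert np.allclose(drag_force(MU, d, u_rel) / mass, u_rel / tau)

    def test_gravity_magnitude_and_scaling(self):
        F = gravitational_force(1070, 30e-6)
        assert np.linalg.norm(F) == pytest.approx(1.48e-10, rel=5e-3)
        assert F[2] < 0
        F2 = gravitational_force(1070, 60e-6)
        assert np.linalg.norm(F2) == pytest.approx(8 * np.linalg.norm(F))
        assert np.all(gravitational_force(1070, 0.0) == 0.0)


class TestDimensionlessNumbers:
    def test_particle_reynolds(self, gas):
        assert particle_reynolds(gas, 0.0, 30e-6) == 0.0
        assert particle_reynolds(gas, 1.0, 30e-6) == pytest.approx(4.03, rel=2e-3)
        assert particle_reynolds(gas, 2.0, 30e-6) == pytest.approx(
            2 * particle_reynolds(gas, 1.0, 30e-6)
        )

    def test_printed_form_retained(self):
        assert particle_reynolds_as_printed(1070, 1.0, MU) == pytest.approx(
            1070 / MU
        )

    def test_stokes_number(self):
        tau = relaxation_time(1070, 30e-6, MU)
        assert stokes_number(tau, 15.92, 200e-6) == pytest.approx(579, rel=3e-3)
        assert stokes_number(tau, 0.0, 200e-6) == 0.0
        # Stk scales with d_p^2 through the relaxation time
        tau2 = relaxation_time(1070, 60e-6, MU)
        assert stokes_number(tau2, 15.92, 200e-6) == pytest.approx(
            4 * stokes_number(tau, 15.92, 200e-6)
        )

    def test_weber_number(self):
        assert weber_number(1000, 15.92, 30e-6, 0.072) == pytest.approx(
            105.6, rel=2e-3
        )
        assert weber_number(1000, 0.0, 30e-6, 0.072) == 0.0
        assert weber_number(1000, 2 * 15.92, 30e-6, 0.072) == pytest.approx(
            4 * weber_number(1000, 15.92, 30e-6, 0.072)
        )
        with pytest.raises(ValueError):
            weber_number(1000, 1.0, 30e-6, 0.0)


def closed_form(state, u, E, gas, t):
    """Independent closed-form solution for constant forcing."""
    tau = state.density * state.diameter**2 / (18 * gas.dynamic_viscosity)
    g = np.array([0.0, 0.0, -GRAVITY])
    u_inf = u + tau * (g + state.charge * E / state.mass)
    dv = state.velocity - u_inf
    v = u_inf + dv * np.exp(-t / tau)
    x = state.position + u_inf * t + dv * tau * (1 - np.exp(-t / tau))
    return x, v


class TestExponentialIntegrator:
    def setup_method(self):
        self.gas = GasProperties()
        self.state = DropletState(
            position=np.array([0.0, 0.0, 0.10]),
            velocity=np.array([1.0, -2.0, -15.92]),
            diameter=30e-6,
            density=1070.0,
            charge=-5e-14,
        )
        self.u = np.array([0.1, 0.0, -0.2])
        self.E = np.array([1e4, -2e4, 5e4])

    def test_matches_closed_form_over_many_steps(self):
        n_steps = 10_000
        dt = 1e-4
        s = self.state
        for _ in range(n_steps):
            s = step(s, self.u, self.E, dt, self.gas)
        x_ref, v_ref = closed_form(self.state, self.u, self.E, self.gas,
                                   n_steps * dt)
        assert np.allclose(s.position, x_ref, rtol=1e-9, atol=1e-15)
        assert np.allclose(s.velocity, v_ref, rtol=1e-9, atol=1e-15)

    def test_matches_scipy_ivp(self):
        # independent numerical route: integrate the stiff ODE directly
        from scipy.integrate import solve_ivp

        tau = relaxation_time(1070, 30e-6, self.gas.dynamic_viscosity)
        g = np.array([0.0, 0.0, -GRAVITY])

        def rhs(_, y):
            v = y[3:]
            acc = (self.u - v) / tau + g + self.state.charge * self.E / self.state.mass
            return np.concatenate([v, acc])

        t_end = 20 * tau
        sol = solve_ivp(
            rhs, (0, t_end),
            np.concatenate([self.state.position, self.state.velocity]),
            method="Radau", rtol=1e-12, atol=1e-16,
        )
        s = step(self.state, self.u, self.E, t_end, self.gas)
        assert np.allclose(s.position, sol.y[:3, -1], rtol=1e-7, atol=1e-12)
        assert np.allclose(s.velocity, sol.y[3:, -1], rtol=1e-7, atol=1e-12)

    def test_semigroup_two_half_steps_equal_one(self):
        dt = 3e-3
        one = step(self.state, self.u, self.E, dt, self.gas)
        half = step(self.state, self.u, self.E, dt / 2, self.gas)
        two = step(half, self.u, self.E, dt / 2, self.gas)
        assert np.allclose(one.position, two.position, rtol=1e-13, atol=1e-18)
        assert np.allclose(one.velocity, two.velocity, rtol=1e-13, atol=1e-18)

    def test_fixed_point_at_equilibrium_velocity(self):
        tau = relaxation_time(1070, 30e-6, self.gas.dynamic_viscosity)
        u_inf = self.u + tau * (
            np.array([0, 0, -GRAVITY])
            + self.state.charge * self.E / self.state.mass
        )
        s = DropletState(
            position=np.zeros(3), velocity=u_inf, diameter=30e-6, density=1070.0,
            charge=self.state.charge,
        )
        s2 = step(s, self.u, self.E, 0.05, self.gas)
        assert np.allclose(s2.velocity, u_inf, rtol=1e-12)

    def test_terminal_velocity_after_settling(self):
        # from rest in quiescent gas the residual decays as exp(-t/tau);
        # 15 relaxation times bring it below 1e-6 of the terminal speed
        tau = relaxation_time(1070, 30e-6, self.gas.dynamic_viscosity)
        s = DropletState(
            position=np.array([0.0, 0.0, 1e3]),  # far from walls
            velocity=np.zeros(3), diameter=30e-6, density=1070.0,
        )
        s = step(s, np.zeros(3), np.zeros(3), 15 * tau, self.gas)
        v_t = tau * GRAVITY
        assert v_t == pytest.approx(0.0357, rel=2e-3)
        assert abs(-s.velocity[2] - v_t) / v_t < 1e-6

    def test_deposited_state_rejected(self):
        s = DropletState(
            position=np.zeros(3), velocity=np.zeros(3), diameter=30e-6,
            density=1070.0, status="deposited",
        )
        with pytest.raises(ValueError):
            step(s, np.zeros(3), np.zeros(3), 0.1, self.gas)
        with pytest.raises(ValueError):
            step(self.state, self.u, self.E, -1.0, self.gas)


class TestDepositionRule:
    def test_center_within_diameter_of_wall_deposits(self, geometry):
        s = DropletState(
            position=np.array([0.0, 0.0, 10e-6]), velocity=np.zeros(3),
            diameter=30e-6, density=1070.0,
        )
        out = detect_deposition(s, geometry)
        assert out.status == "deposited"
        assert out.deposit_surface == "bottom"

    def test_far_from_walls_stays_airborne(self, geometry):
        s = DropletState(
            position=np.array([0.0, 0.0, 0.076]), velocity=np.zeros(3),
            diameter=30e-6, density=1070.0,
        )
        assert detect_deposition(s, geometry).status == "airborne"

    def test_vanishing_diameter_requires_contact(self, geometry):
        s = DropletState(
            position=np.array([0.0, 0.0, 10e-6]), velocity=np.zeros(3),
            diameter=0.5e-6, density=1070.0,
        )
        assert detect_deposition(s, geometry).status == "airborne"


class TestSimulate:
    def test_empty_injection(self, geometry):
        with pytest.warns(UserWarning):
            rec = simulate(SimulationConfig(n_parcels=0), geometry=geometry)
        assert len(rec) == 0

    def test_single_large_droplet_reaches_bottom(self, geometry):
        # stopping distance tau*u0 ~ 0.16 m exceeds the cavity height
        sched = InjectionSchedule(
            emission_times=np.array([0.0]),
            diameters=np.array([50e-6]),
            velocities=np.array([[0.0, 0.0, -15.92]]),
        )
        cfg = SimulationConfig(
            droplet_spec=DropletSizeSpec.monodisperse(50.0), n_parcels=1
        )
        rec = simulate(cfg, geometry=geometry, schedule=sched)
        assert rec.n_deposited == 1
        assert rec.surfaces[0] == "bottom"
        # frozen one diameter above the floor by the adhesion rule
        assert rec.final_positions[0, 2] == pytest.approx(50e-6, abs=1e-6)

    def test_conservation_and_bookkeeping(self, geometry):
        cfg = SimulationConfig(n_parcels=800, seed=11)
        rec = simulate(cfg, geometry=geometry)
        assert rec.n_deposited + rec.n_airborne == len(rec) == 800
        assert np.all(rec.flight_times >= 0)
        assert np.all(geometry.contains(rec.final_positions, tol=1e-9))

    def test_airborne_remainder_for_fine_aerosol(self, geometry):
        # 1 um droplets settle at ~40 um/s: they cannot reach the floor
        # within a short run and must be reported airborne, not forced down
        cfg = SimulationConfig(
            droplet_spec=DropletSizeSpec.monodisperse(1.0),
            n_parcels=300, seed=4, total_time=60.0,
        )
        rec = simulate(cfg, geometry=geometry)
        assert rec.n_airborne == 300
        assert np.allclose(
            rec.flight_times, 60.0 - rec.emission_times, atol=1e-6
        )

    def test_determinism_same_seed(self, geometry):
        cfg = SimulationConfig(n_parcels=500, seed=21)
        a = simulate(cfg, geometry=geometry)
        b = simulate(cfg, geometry=geometry)
        assert np.array_equal(a.final_positions, b.final_positions)
        assert np.array_equal(a.flight_times, b.flight_times)

    def test_lateral_symmetry_of_deposits(self, geometry):
        cfg = SimulationConfig(n_parcels=5000, seed=13)
        rec = simulate(cfg, geometry=geometry)
        mean_lateral = rec.deposit_positions()[:, :2].mean(axis=0)
        assert np.all(np.abs(mean_lateral) < 1.5e-3)

    def test_dense_cloud_refused(self, geometry):
        sched = InjectionSchedule(
            emission_times=np.zeros(5000),
            diameters=np.full(5000, 800e-6),
            velocities=np.zeros((5000, 3)),
        )
        with pytest.raises(UnsupportedPhysicsError):
            simulate(SimulationConfig(), geometry=geometry, schedule=sched)
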