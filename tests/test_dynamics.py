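import numpy as np
import pytest
from scipy.integrate import solve_ivp

import mnpheat as mh
from mnpheat.constants import K_B
from mnpheat.dynamics import ou_coefficients, step, thermal_torque


class TestThermalTorque:
    def test_zero_temperature(self, rng):
        assert np.all(thermal_torque(2.2e-27, 0.0, 1e-11, rng) == 0.0)

    def test_variance_matches_fdt(self, rng):
        """Sample variance of 1e6 draws within 1% of 2 zeta k_B T / dt."""
        zeta, T, dt = 2.2e-27, 320.0, 1e-11
        draws = thermal_torque(zeta, T, dt, rng, size=1_000_000)
        expect = 2 * zeta * K_B * T / dt
        assert draws.mean(axis=0) == pytest.approx([0, 0, 0],
                                                   abs=3e-3 * np.sqrt(expect))
        assert draws.var(axis=0) == pytest.approx([expect] * 3, rel=0.01)

    def test_linear_in_friction(self, rng):
        a = thermal_torque(1e-27, 320.0, 1e-11,
                           np.random.Generator(np.random.Philox(1)),
                           size=200_000).var()
        b = thermal_torque(2e-27, 320.0, 1e-11,
                           np.random.Generator(np.random.Philox(1)),
                           size=200_000).var()
        assert b / a == pytest.approx(2.0, rel=1e-12)


class TestOUCoefficients:
    def test_frictionless_limit_is_velocity_verlet(self):
        c1, drift, sw, c1th, c2th = ou_coefficients(0.0, 1e-11, 5.0)
        assert (c1, drift) == (1.0, 1e-11)
        assert sw == c1th == c2th == 0.0

    def test_series_matches_closed_form_at_crossover(self):
        """The small-x series and the closed form agree where they hand over."""
        sigma2 = 3.7
        dt = 1.0
        for gamma in (0.049, 0.051):
            c1, drift, sw, c1th, c2th = ou_coefficients(gamma, dt, sigma2)
            x = gamma * dt
            f = 2 * x - 3 + 4 * np.exp(-x) - np.exp(-2 * x)
            var_th = sigma2 * f / gamma ** 2
            assert c1th ** 2 + c2th ** 2 == pytest.approx(var_th, rel=1e-6)

    def test_stationary_velocity_variance(self):
        """Iterating w -> c1 w + sw xi preserves the variance sigma2."""
        sigma2 = 2.5
        c1, _, sw, _, _ = ou_coefficients(0.84, 1.0, sigma2)
        assert c1 ** 2 * sigma2 + sw ** 2 == pytest.approx(sigma2, rel=1e-12)


class TestDeterministicDynamics:
    def test_energy_conservation_single_dipole(self):
        """zeta = 0, T = 0: precession in a uniform field conserves
        -mu.B + (1/2) I w^2 to 1e-6 relative over 1e5 steps."""
        p = mh.SimulationParams(temperature=0.0, external_field=(0, 0, 1e-3))
        lat = mh.build_square_lattice(1, 1.0)
        e0 = np.array([[np.sin(1.0), 0.0, np.cos(1.0)]])
        state = mh.DipoleLatticeState(e0, np.zeros((1, 3)), p.moment, lat)
        nb = [np.empty(0, dtype=np.int64)]
        # frictionless: override zeta by taking gamma -> 0 through viscosity
        p = p.replace(viscosity=1e-30)
        def energy():
            return (-p.moment * state.orientations[0] @ [0, 0, 1e-3]
                    + 0.5 * p.inertia * state.angular_velocities[0] @
                    state.angular_velocities[0])
        zero = (np.zeros((1, 3)), np.zeros((1, 3)))
        e_start = energy()
        tq = None
        for _ in range(100_000):
            tq = step(state, p, nb, noise=zero, torque=tq)
        assert energy() == pytest.approx(e_start, rel=1e-6)

    def test_trajectory_matches_reference_ode(self):
        """The splitting integrator tracks a high-accuracy ODE solve of the
        same deterministic equations."""
        p = mh.SimulationParams(temperature=0.0, external_field=(0, 1e-3, 1e-3),
                                viscosity=1e-30)
        lat = mh.build_square_lattice(1, 1.0)
        state = mh.DipoleLatticeState(np.array([[1.0, 0.0, 0.0]]),
                                      np.array([[0.0, 0.0, 2e5]]),
                                      p.moment, lat)
        nb = [np.empty(0, dtype=np.int64)]
        y0 = np.concatenate([state.orientations[0],
                             state.angular_velocities[0]])
        b = np.array(p.external_field)

        def rhs(_, y):
            e, w = y[:3], y[3:]
            torque = p.moment * np.cross(e, b)
            return np.concatenate([np.cross(w, e), torque / p.inertia])

        n_steps = 10_000
        t_end = n_steps * p.time_step
        sol = solve_ivp(rhs, (0, t_end), y0, rtol=1e-11, atol=1e-14,
                        dense_output=True)
        zero = (np.zeros((1, 3)), np.zeros((1, 3)))
        tq = None
        for _ in range(n_steps):
            tq = step(state, p, nb, noise=zero, torque=tq)
        ref = sol.sol(t_end)
        assert state.orientations[0] == pytest.approx(ref[:3], abs=1e-5)

    def test_exponential_velocity_damping(self):
        """T = 0 with friction: |w| decays as exp(-zeta t / I), with
        I/zeta ~ 12 ps for the 5 nm reference particle."""
        p = mh.SimulationParams(temperature=0.0)
        lat = mh.build_square_lattice(1, 1.0)
        state = mh.DipoleLatticeState(np.array([[1.0, 0.0, 0.0]]),
                                      np.array([[0.0, 0.0, 1e6]]),
                                      p.moment, lat)
        nb = [np.empty(0, dtype=np.int64)]
        zero = (np.zeros((1, 3)), np.zeros((1, 3)))
        tq = None
        for _ in range(50):
            tq = step(state, p, nb, noise=zero, torque=tq)
        expect = 1e6 * np.exp(-50 * p.time_step / p.momentum_relaxation_time)
        assert state.angular_velocities[0, 2] == pytest.approx(expect,
                                                               rel=1e-9)


class TestSimulate:
    def test_determinism(self, free_lattice):
        p = mh.SimulationParams(seed=99)
        kw = dict(interactions=False, n_steps=30_000, burn_in_steps=1_000)
        tr1 = mh.simulate(p, free_lattice, **kw)
        tr2 = mh.simulate(mh.SimulationParams(seed=99), free_lattice, **kw)
        assert np.array_equal(tr1.M, tr2.M)
        tr3 = mh.simulate(mh.SimulationParams(seed=100), free_lattice, **kw)
        assert not np.array_equal(tr1.M, tr3.M)

    def test_kernel_matches_reference_step(self, free_lattice):
        """The compiled chunk kernel and the pure-numpy step produce the
        same trajectory from the same noise."""
        p = mh.SimulationParams(seed=5)
        lat = mh.build_square_lattice(2, 10e-9, particle_radius=5e-9)
        rng = np.random.Generator(np.random.Philox(7))
        state = mh.DipoleLatticeState.random(lat, p.moment, rng)
        e0 = state.orientations.copy()
        w0 = state.angular_velocities.copy()
        n_steps = 50
        xi1 = rng.standard_normal((n_steps, 4, 3))
        xi2 = rng.standard_normal((n_steps, 4, 3))
        nb = mh.neighbor_table(lat, p.cutoff)
        tq = None
        for s in range(n_steps):
            tq = step(state, p, nb, noise=(xi1[s], xi2[s]), torque=tq)
        e_ref = state.orientations.copy()

        from mnpheat import _kernels
        from mnpheat.constants import MU0_OVER_4PI
        indptr, indices, rhat, inv_r3 = mh.neighbor_csr(lat, p.cutoff)
        e = e0.copy()
        w = w0.copy()
        tq = np.empty((4, 3))
        bint = np.empty((4, 3))
        b = np.zeros(3)
        _kernels.compute_torques(e, indptr, indices, rhat, inv_r3, b,
                                 MU0_OVER_4PI * p.moment, p.moment, tq, bint)
        c1, drift, sw, c1th, c2th = ou_coefficients(
            p.friction / p.inertia, p.time_step, K_B * p.temperature / p.inertia)
        _kernels.run_chunk(e, w, tq, bint, indptr, indices, rhat, inv_r3,
                           b, np.zeros(3), 0.0, p.time_step, p.moment,
                           MU0_OVER_4PI * p.moment, 1.0 / p.inertia,
                           c1, drift, sw, c1th, c2th, xi1, xi2, 0, 10 ** 9,
                           np.empty((1, 3)), 0, False,
                           np.zeros((4, 3)), np.zeros((4, 3)), np.zeros(3))
        assert e == pytest.approx(e_ref, rel=1e-10, abs=1e-12)

    def test_orientations_stay_unit(self, free_lattice):
        p = mh.SimulationParams(seed=2)
        tr = mh.simulate(p, free_lattice, interactions=False,
                         n_steps=20_000, burn_in_steps=0)
        e = tr.diagnostics["final_state"].orientations
        assert np.linalg.norm(e, axis=1) == pytest.approx(np.ones(16),
                                                          abs=1e-12)

    def test_magnetization_bounded(self, free_lattice):
        p = mh.SimulationParams(seed=2)
        tr = mh.simulate(p, free_lattice, interactions=False,
                         n_steps=50_000, burn_in_steps=1_000)
        n_mu = free_lattice.n_particles * p.moment
        assert np.all(np.linalg.norm(tr.M, axis=1) <= n_mu * (1 + 1e-12))
        # uniform sampling grid
        dt = np.diff(tr.sample_times)
        assert dt == pytest.approx(dt[0])

    def test_equipartition_short_run(self, free_lattice):
        """<I w_k^2> = k_B T per axis (the exact OU thermostat)."""
        p = mh.SimulationParams(seed=8)
        tr = mh.simulate(p, free_lattice, interactions=False,
                         n_steps=200_000, burn_in_steps=20_000)
        assert tr.diagnostics["equipartition"] == pytest.approx(
            np.ones(3), rel=0.05)

    def test_zero_temperature_relaxes_to_zero_torque(self):
        """Damped T = 0 dynamics of an interacting lattice ends with no
        residual torque on any particle."""
        p = mh.SimulationParams(temperature=0.0, seed=3)
        lat = mh.build_square_lattice(4, 10e-9, particle_radius=5e-9)
        rng = np.random.Generator(np.random.Philox(17))
        state = mh.DipoleLatticeState.random(lat, p.moment, rng)
        tr = mh.simulate(p, lat, initial=state, n_steps=200_000,
                         burn_in_steps=0)
        final = tr.diagnostics["final_state"]
        nb = mh.neighbor_table(lat, p.cutoff)
        tq = mh.torques(final, nb)
        b = mh.local_fields(final, nb)
        scale = p.moment * np.linalg.norm(b, axis=1).max()
        assert np.abs(tq).max() < 1e-3 * scale
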