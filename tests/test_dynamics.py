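"""Integrator contracts: limits, thermostat, determinism, diffusion."""

import numpy as np
import pytest

from peptagg import (
    ForceField,
    IntegratorParams,
    SystemSpec,
    SystemState,
    Topology,
    kinetic_temperature,
    maxwell_boltzmann_velocities,
    measure_diffusion,
    random_initial_config,
    sd_leapfrog_step,
    simulate,
)
from peptagg.model import KB

# an LJ scale so small the beads are effectively free but all force-field
# invariants still hold
GAS_FF = ForceField(epsilon=1e-10, sigma=0.02, lj_cutoff=0.05, k_theta=0.0)


def _free_beads(n, box, seed, temperature=303.0):
    topo = Topology(n, 1)
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, box, size=(n, 3))
    vel = maxwell_boltzmann_velocities(n, topo.mass, temperature, rng)
    return SystemState(pos, vel, box), topo


class TestIntegratorParams:
    def test_defaults_match_study_settings(self):
        ip = IntegratorParams()
        assert (ip.dt, ip.temperature, ip.tau_f) == (0.025, 303.0, 0.17)

    def test_zero_friction_time_rejected(self):
        with pytest.raises(ValueError):
            IntegratorParams(tau_f=0.0)

    def test_infinite_tau_is_frictionless(self):
        a, c = IntegratorParams(tau_f=np.inf).ou_coefficients(72.0)
        assert (a, c) == (1.0, 0.0)


class TestLeapfrogStep:
    def test_null_dynamics(self):
        state, topo = _free_beads(4, 10.0, 0, temperature=0.0)
        state.velocities[:] = 0.0
        ip = IntegratorParams(temperature=0.0)
        rng = np.random.default_rng(0)
        out = sd_leapfrog_step(state, topo, GAS_FF, ip, rng)
        np.testing.assert_allclose(out.positions, state.positions)

    def test_frictionless_harmonic_dimer_second_order(self, ff):
        """Leap-frog error vs the closed-form oscillator shrinks as dt^2."""
        topo = Topology(1, 2)
        mu = topo.mass / 2  # reduced mass of the dimer
        omega = np.sqrt(ff.k_b / mu)
        amp = 0.01
        box = 10.0
        errs = []
        for dt in (0.025, 0.0125):
            n_steps = int(round(25.0 / dt))  # fixed physical time, ~24 periods
            ip = IntegratorParams(dt=dt, tau_f=np.inf, temperature=0.0)
            pos = np.array([[5.0 - (ff.r0 + amp) / 2, 5, 5], [5.0 + (ff.r0 + amp) / 2, 5, 5]])
            # exclude LJ so only the bond acts
            ff_bond = ff.replace(epsilon=1e-12, k_theta=0.0)
            # half-step velocity initialisation for the closed-form comparison:
            # x(t) = r0 + amp cos(w t)  =>  v(-dt/2) = -amp w sin(-w dt/2) per dof
            v_rel = amp * omega * np.sin(omega * dt / 2)
            vel = np.array([[-v_rel / 2, 0, 0], [v_rel / 2, 0, 0]])
            res = simulate(
                SystemState(pos, vel, box), topo, ff_bond, ip, n_steps,
                traj_stride=max(1, n_steps // 500), log_stride=n_steps,
                store_unwrapped=True,
            )
            sep = np.linalg.norm(
                res.unwrapped[:, 1, :] - res.unwrapped[:, 0, :], axis=1
            )
            t = res.times
            expected = ff.r0 + amp * np.cos(omega * t)
            errs.append(np.abs(sep - expected).max())
        assert errs[0] / errs[1] > 3.0  # ~4 for a second-order scheme
        # leap-frog phase drift bound: amp * (w dt)^2/24 * w T, plus margin
        bound = 2.0 * amp * (omega * 0.025) ** 2 / 24 * omega * 25.0
        assert errs[0] < bound

    def test_frictionless_energy_conservation(self, ff):
        state, topo = random_initial_config(
            SystemSpec(n_chains=5, chain_length=8, c0=2.8, seed=3), ff
        )
        ip = IntegratorParams(tau_f=np.inf, temperature=0.0)
        res = simulate(state, topo, ff, ip, 10_000, traj_stride=10_000, log_stride=20)
        log = res.log.iloc[:-1]  # final row pairs PE with a single half-step KE
        total = (log["potential"] + log["kinetic"]).to_numpy()
        scale = log["kinetic"].mean()
        drift = abs(np.polyfit(log["time"], total, 1)[0]) * (
            log["time"].iloc[-1] - log["time"].iloc[0]
        )
        assert drift / scale < 1e-3

    def test_determinism(self, small_system, ff):
        state, topo = small_system
        ip = IntegratorParams(seed=11)
        r1 = simulate(state.copy(), topo, ff, ip, 200, traj_stride=50, log_stride=50)
        r2 = simulate(state.copy(), topo, ff, ip, 200, traj_stride=50, log_stride=50)
        np.testing.assert_array_equal(r1.positions, r2.positions)


class TestThermostat:
    def test_free_particle_stationary_temperature(self):
        """OU velocity update is exact: long-run mean T = set T."""
        state, topo = _free_beads(64, 20.0, 5)
        ip = IntegratorParams(seed=6)
        res = simulate(state, topo, GAS_FF, ip, 20_000, traj_stride=20_000, log_stride=10)
        temps = res.log["temperature"].to_numpy()
        assert np.mean(temps[len(temps) // 10 :]) == pytest.approx(303.0, rel=0.02)

    @pytest.mark.parametrize("epsilon,k_theta", [(1.3, 10.0), (2.0, 1000.0)])
    def test_interacting_system_temperature(self, epsilon, k_theta):
        """Kinetic T within 2% of 303 K across the study parameter grid."""
        ff = ForceField(epsilon=epsilon, k_theta=k_theta)
        state, topo = random_initial_config(
            SystemSpec(n_chains=5, chain_length=8, c0=30.0, seed=8), ff
        )
        ip = IntegratorParams(seed=9)
        res = simulate(state, topo, ff, ip, 100_000, traj_stride=100_000, log_stride=25)
        temps = res.log["temperature"].to_numpy()
        mean_t = np.mean(temps[len(temps) // 10 :])
        assert mean_t == pytest.approx(303.0, rel=0.02)


class TestKineticTemperature:
    def test_zero_velocities(self):
        state, topo = _free_beads(10, 10.0, 0, temperature=0.0)
        state.velocities[:] = 0.0
        assert kinetic_temperature(state, topo) == 0.0

    def test_single_bead_closed_form(self):
        topo = Topology(1, 1)
        v = np.sqrt(3 * KB * 303.0 / topo.mass)
        state = SystemState(
            np.zeros((1, 3)), np.array([[v, 0.0, 0.0]]), 10.0
        )
        assert kinetic_temperature(state, topo) == pytest.approx(303.0)

    def test_maxwell_boltzmann_sample(self):
        # sampling SD of T over N beads is T sqrt(2/(3N)) ~ 2.5 K; allow 3 sigma
        state, topo = _free_beads(10_000, 50.0, 12)
        assert kinetic_temperature(state, topo) == pytest.approx(303.0, abs=7.5)


class TestDiffusion:
    def test_stationary_particle(self):
        traj = np.zeros((100, 3))
        res = measure_diffusion(np.arange(100.0), traj)
        assert res.D == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_brownian_coefficient(self):
        d_true = 5e-3  # nm^2/ps
        dt = 1.0
        rng = np.random.default_rng(21)
        steps = rng.normal(0, np.sqrt(2 * d_true * dt), size=(4000, 200, 3))
        traj = np.cumsum(steps, axis=0)
        res = measure_diffusion(np.arange(4000.0) * dt, traj)
        assert res.D == pytest.approx(d_true, rel=0.05)

    def test_einstein_relation_for_free_beads(self):
        """Langevin free particle: D = kB T tau_f / m."""
        state, topo = _free_beads(256, 30.0, 31)
        ip = IntegratorParams(seed=32)
        res = simulate(
            state, topo, GAS_FF, ip, 120_000,
            traj_stride=40, log_stride=120_000, store_unwrapped=True,
        )
        d_expected = KB * 303.0 * ip.tau_f / topo.mass
        # fit lags well beyond tau_f but short against the run length, so
        # many independent displacement intervals enter the average
        out = measure_diffusion(res.times, res.unwrapped, fit_start=30.0, fit_end=300.0)
        assert out.D == pytest.approx(d_expected, rel=0.05)

    def test_ballistic_to_diffusive_crossover(self):
        """MSD ~ (3 kB T/m) t^2 for t << tau_f, ~ 6 D t for t >> tau_f."""
        state, topo = _free_beads(256, 30.0, 41)
        ip = IntegratorParams(seed=42)
        res = simulate(
            state, topo, GAS_FF, ip, 4_000,
            traj_stride=1, log_stride=4_000, store_unwrapped=True,
        )
        pos = res.unwrapped
        t = res.times

        def msd_at(k):
            d = pos[k:] - pos[:-k]
            return float(np.mean(np.sum(d * d, axis=-1)))

        # short lag: one step = dt << tau_f
        k_short = 2
        tau_short = t[k_short]
        ballistic = 3 * KB * 303.0 / topo.mass * tau_short**2
        assert msd_at(k_short) == pytest.approx(ballistic, rel=0.15)
        # long lag: >> tau_f
        k_long = 2000
        d_einstein = KB * 303.0 * ip.tau_f / topo.mass
        assert msd_at(k_long) == pytest.approx(6 * d_einstein * t[k_long], rel=0.15)

    def test_too_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            measure_diffusion(np.arange(3.0), np.zeros((3, 3)))
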