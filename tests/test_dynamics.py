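"""Constraint pipeline, hybrid integrator statistics, minimizer and
schedule contracts."""

import numpy as np
import pytest

from flextop.core import (
    BOLTZMANN_KJ_MOL_K,
    AttributeState,
    ScheduleStage,
    SimulationSystem,
    FTParticle,
)
from flextop.dynamics import (
    HybridIntegrator,
    apply_charge_constraints,
    brownian_attribute_step,
    cap_charge_variance,
    clamp_attribute_bounds,
    enforce_charge_sum,
    minimize,
    run_schedule,
)
from flextop.forces import SystemArrays
from conftest import make_system


class TestClamp:
    def test_charge_clamped_to_half(self):
        assert clamp_attribute_bounds(AttributeState(0.7, 0.25, 0.5)).q == 0.5

    def test_interior_values_unchanged(self):
        attrs = clamp_attribute_bounds(AttributeState(0.1, 0.25, 0.5))
        assert (attrs.q, attrs.sigma, attrs.epsilon) == (0.1, 0.25, 0.5)

    def test_epsilon_floor(self):
        assert clamp_attribute_bounds(AttributeState(0.0, 0.25, 0.01)).epsilon == 0.03


class TestChargeSum:
    def test_uniform_shift_hand_value(self):
        shifted = enforce_charge_sum(np.array([0.1, 0.2, -0.1]), 0.0)
        np.testing.assert_allclose(shifted, [0.1 - 0.2 / 3, 0.2 - 0.2 / 3, -0.1 - 0.2 / 3])
        assert shifted.sum() == pytest.approx(0.0, abs=1e-15)

    def test_zero_sum_input_unchanged(self):
        q = np.array([0.3, -0.3, 0.0])
        np.testing.assert_array_equal(enforce_charge_sum(q, 0.0), q)

    def test_single_charge_forced_to_target(self):
        np.testing.assert_allclose(enforce_charge_sum(np.array([0.4]), 0.0), [0.0])


class TestVarianceCap:
    def test_scaling_hand_value(self):
        q = np.array([0.4, -0.4, 0.4, -0.4])
        capped = cap_charge_variance(q, 0.08)
        # S_q = 0.16 -> scale deviations by sqrt(0.08/0.16)
        np.testing.assert_allclose(np.abs(capped), np.sqrt(0.08), rtol=1e-12)
        assert np.var(capped) == pytest.approx(0.08, rel=1e-12)

    def test_below_cap_is_identity(self):
        q = np.array([0.1, -0.1, 0.05, -0.05])
        np.testing.assert_array_equal(cap_charge_variance(q, 0.08), q)

    def test_rms_bound_after_full_pipeline(self, rng):
        # zero-mean charges can never exceed rms sqrt(S_max) = 0.2828
        for _ in range(200):
            q = rng.uniform(-2, 2, size=rng.integers(2, 20))
            out, _, _, state = apply_charge_constraints(
                q, np.full_like(q, 0.25), np.full_like(q, 0.5), 0.0, 0.08
            )
            assert np.sqrt(np.mean(out**2)) <= 0.283
            assert abs(out.sum()) <= 1e-12  # sweeps converge to the exact sum
            assert state.s_q <= 0.08 + 1e-12
            assert out.min() >= -0.5 and out.max() <= 0.5


def _single_particle_system(**kwargs):
    return make_system([((0.0, 0.0, 0.0), 0.25, 0.22, 0.25)], **kwargs)


class TestBrownianAttributeStep:
    def test_fixed_point_at_zero_temperature(self):
        system = _single_particle_system()
        # target sum 0.25 so the sum constraint does not move the single charge
        system.force_params.charge_constraint.target_sum = 0.25
        q, sigma, epsilon = brownian_attribute_step(system, temperature=0.0)
        assert q[0] == pytest.approx(0.25, abs=1e-12)
        assert epsilon[0] == pytest.approx(0.25, abs=1e-12)

    def test_attributes_stay_in_bounds(self, rng):
        system = make_system(
            [(rng.uniform(-0.2, 0.2, 3), 0.0, 0.2, 0.5) for _ in range(5)]
        )
        for _ in range(200):
            q, sigma, epsilon = brownian_attribute_step(system, 300.0, rng=rng)
        assert np.all((q >= -0.5) & (q <= 0.5))
        assert np.all((sigma >= 0.2) & (sigma <= 0.36))
        assert np.all((epsilon >= 0.03) & (epsilon <= 1.5))

    def test_ornstein_uhlenbeck_stationary_variance(self):
        """Charge under the quadratic attribute restraint reaches ~kT/curvature."""
        n = 50  # independent particles, far apart, no mutual forces
        particles = [((3.0 * i, 0.0, 0.0), 0.25, 0.22, 0.25) for i in range(n)]
        system = make_system(particles)
        fp = system.force_params
        fp.supercharge = 0.0
        fp.ft_ft_lj = False
        fp.charge_constraint.s_max = 1e6  # disable cap for the statistics
        fp.charge_constraint.target_sum = 0.25 * n
        fp.centroid.k = 0.0
        fp.continuity.k = 0.0
        arrays = SystemArrays.from_system(system)
        # freeze sigma and epsilon so the sigmoid switch cannot drift open
        # and release the charge restraint mid-run
        arrays.mob_sigma[:] = 0.0
        arrays.mob_epsilon[:] = 0.0
        temperature = 300.0
        # curvature of B f(sigma) (q - 1/4)^2 at sigma=0.22 is ~2B
        f = 1.0 / (1.0 + np.exp(200 * (0.22 - 0.3)))
        curvature = 2 * 275.3 * f
        expected = BOLTZMANN_KJ_MOL_K * temperature / curvature
        rng = np.random.default_rng(99)
        integ = HybridIntegrator(arrays, 0.002, 1.0, rng)
        samples = []
        for step in range(30000):
            integ.step(temperature)
            if step > 5000 and step % 20 == 0:
                samples.append(arrays.q.copy())
        var = np.var(np.concatenate(samples) - 0.25)
        assert var == pytest.approx(expected, rel=0.05)


class TestLangevinPositions:
    def test_equipartition_in_harmonic_well(self):
        """Position variance in the centroid restraint well ~ kT/k_spring."""
        # independent particles held only by a pure harmonic: the centroid
        # restraint with d0 = 0 is harmonic everywhere; all pair terms off
        n = 20
        offsets = np.random.default_rng(0).uniform(-0.05, 0.05, (n, 3))
        particles = [(offsets[i], 0.0, 0.22, 0.25) for i in range(n)]
        system = make_system(particles)
        fp = system.force_params
        fp.centroid.d0 = 0.0
        fp.centroid.k = 500.0
        fp.attr_force.A = 0.0
        fp.attr_force.B = 0.0
        fp.ft_ft_elec = "off"
        fp.ft_ft_lj = False
        fp.continuity.k = 0.0
        arrays = SystemArrays.from_system(system)
        # freeze attributes by zeroing their mobilities' effect
        arrays.mob_q[:] = 0.0
        arrays.mob_sigma[:] = 0.0
        arrays.mob_epsilon[:] = 0.0
        temperature = 300.0
        # friction 5/ps decorrelates the well coordinate quickly
        integ = HybridIntegrator(arrays, 0.002, 5.0, np.random.default_rng(7))
        samples = []
        for step in range(40000):
            integ.step(temperature)
            if step > 5000 and step % 10 == 0:
                samples.append(arrays.ft_pos.copy())
        var = np.var(np.asarray(samples).reshape(-1, 3), axis=0).mean()
        # radial harmonic 0.5 k r^2 -> per-axis variance kT/k
        expected = BOLTZMANN_KJ_MOL_K * temperature / 500.0
        assert var == pytest.approx(expected, rel=0.05)

    def test_restrained_mobile_environment_atom_stays_near_reference(self):
        from flextop.core import EnvironmentAtom, ScheduleStage

        system = make_system([((0.0, 0.0, 0.0), 0.1, 0.25, 0.5)])
        system.environment = [
            EnvironmentAtom(
                position=np.array([0.6, 0.0, 0.0]), q=0.0, sigma=0.3, epsilon=0.5,
                mobile=True, group="backbone",
            )
        ]
        ref = system.environment[0].position.copy()
        restraints = {"backbone": 400.0 * 4.184}
        traj = run_schedule(
            system,
            [ScheduleStage(300.0, 3000, restraints=restraints)],
            save_every=1000,
            rng=np.random.default_rng(8),
        )
        drift = np.linalg.norm(system.environment[0].position - ref)
        # thermal width of the 1673 kJ/mol/nm^2 well is ~0.04 nm per axis
        assert 0.0 < drift < 0.2

    def test_frozen_environment_atoms_never_move(self, rng):
        system = make_system(
            [((0.0, 0.0, 0.0), 0.1, 0.25, 0.5)],
            environment=[((0.5, 0.0, 0.0), -0.3, 0.3, 0.5), ((-0.5, 0.1, 0.0), 0.3, 0.3, 0.5)],
        )
        arrays = SystemArrays.from_system(system)
        before = arrays.env_pos.copy()
        integ = HybridIntegrator(arrays, 0.002, 1.0, rng)
        for _ in range(2000):
            integ.step(300.0)
        np.testing.assert_array_equal(arrays.env_pos, before)


class TestMinimize:
    def test_local_minimum_is_fixed_point(self):
        system = _single_particle_system()
        system.force_params.charge_constraint.target_sum = 0.25
        before = system.particles[0].attrs.q
        minimize(system, what="attributes", tolerance=1.0)
        assert system.particles[0].attrs.q == pytest.approx(before, abs=1e-6)

    def test_charge_converges_to_restraint_minimum_below_sigma_030(self):
        system = make_system([((0.0, 0.0, 0.0), -0.4, 0.22, 0.25)])
        minimize(system, what="attributes", tolerance=0.1)
        assert system.particles[0].attrs.q == pytest.approx(0.25, abs=0.01)

    def test_energy_never_increases(self, random_small_system, rng):
        from flextop.forces import total_energy

        for _ in range(5):
            system = random_small_system(rng)
            e0 = total_energy(system).total
            minimize(system, what="positions", max_steps=50)
            assert total_energy(system).total <= e0 + 1e-9


class TestRunSchedule:
    def toy(self):
        system = make_system(
            [
                ((0.0, 0.0, 0.0), 0.01, 0.2, 0.5),
                ((0.2, 0.0, 0.0), -0.01, 0.2, 0.5),
                ((0.0, 0.2, 0.0), 0.0, 0.2, 0.7),
            ]
        )
        return system

    def test_frame_count_is_floor_division(self):
        traj = run_schedule(
            self.toy(),
            [ScheduleStage(temperature=100.0, steps=1000)],
            save_every=300,
            rng=np.random.default_rng(0),
        )
        assert len(traj) == 3
        assert [f.step for f in traj.frames] == [300, 600, 900]

    def test_zero_step_schedule_gives_empty_trajectory(self):
        traj = run_schedule(
            self.toy(),
            [ScheduleStage(temperature=100.0, steps=0)],
            save_every=10,
            rng=np.random.default_rng(0),
        )
        assert len(traj) == 0

    def test_same_seed_gives_bitwise_identical_trajectories(self):
        runs = []
        for _ in range(2):
            traj = run_schedule(
                self.toy(),
                [ScheduleStage(50.0, 200), ScheduleStage(150.0, 500)],
                save_every=100,
                rng=np.random.default_rng(42),
            )
            runs.append(traj)
        for fa, fb in zip(runs[0].frames, runs[1].frames):
            np.testing.assert_array_equal(fa.positions, fb.positions)
            np.testing.assert_array_equal(fa.q, fb.q)
            np.testing.assert_array_equal(fa.sigma, fb.sigma)
            np.testing.assert_array_equal(fa.epsilon, fb.epsilon)

    def test_constraints_hold_after_every_step(self):
        traj = run_schedule(
            self.toy(),
            [ScheduleStage(300.0, 3000)],
            save_every=500,
            rng=np.random.default_rng(3),
        )
        d = traj.diagnostics
        assert d["max_charge_sum_deviation"] < 1e-12
        assert d["max_s_q"] <= 0.08 + 1e-12
        assert d["bound_violation_steps"] == 0
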