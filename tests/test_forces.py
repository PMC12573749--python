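"""Energy terms: hand-computed values, analytic-gradient consistency,
and symmetry invariances."""

import dataclasses

import numpy as np
import pytest

from flextop.core import COULOMB_CONSTANT, ContinuityParams
from flextop.errors import SingularGeometryError
from flextop.forces import (
    SystemArrays,
    attr_restraint,
    centroid_restraint,
    compute_energy,
    continuity,
    ft_env_nonbonded,
    ft_ft_electrostatics,
    ft_ft_lj,
    total_energy,
)
from conftest import make_system


class TestFtEnvNonbonded:
    def test_unit_charge_pair_recovers_coulomb_constant(self):
        system = make_system(
            [((0.0, 0.0, 0.0), 1.0, 0.3, 0.0)],
            environment=[((1.0, 0.0, 0.0), -1.0, 0.3, 0.0)],
        )
        report = ft_env_nonbonded(system)
        assert report.terms["ft_env"] == pytest.approx(-COULOMB_CONSTANT, abs=1e-12)

    def test_lj_zero_crossing_at_mixed_sigma(self):
        # sigma_ij = (0.2 + 0.4) / 2 = 0.3; at r = sigma_ij LJ vanishes
        system = make_system(
            [((0.0, 0.0, 0.0), 0.0, 0.2, 0.25)],
            environment=[((0.3, 0.0, 0.0), 0.0, 0.4, 1.0)],
        )
        assert ft_env_nonbonded(system).terms["ft_env"] == pytest.approx(0.0, abs=1e-12)

    def test_geometric_epsilon_mixing_at_well_minimum(self):
        # eps_ij = sqrt(0.25 * 1.0) = 0.5; minimum depth -eps_ij at r = 2^(1/6) sigma_ij
        sigma_ij = 0.3
        system = make_system(
            [((0.0, 0.0, 0.0), 0.0, 0.2, 0.25)],
            environment=[((sigma_ij * 2 ** (1 / 6), 0.0, 0.0), 0.0, 0.4, 1.0)],
        )
        assert ft_env_nonbonded(system).terms["ft_env"] == pytest.approx(-0.5, rel=1e-12)

    def test_coincident_positions_raise(self):
        system = make_system(
            [((0.0, 0.0, 0.0), 0.1, 0.3, 0.5)],
            environment=[((0.0, 0.0, 0.0), 0.1, 0.3, 0.5)],
        )
        with pytest.raises(SingularGeometryError):
            ft_env_nonbonded(system)


class TestFtFtElectrostatics:
    def pair(self, q1, q2, r):
        return make_system([((0, 0, 0), q1, 0.3, 0.0), ((r, 0, 0), q2, 0.3, 0.0)])

    def test_supercharged_pair_value(self):
        report = ft_ft_electrostatics(self.pair(0.5, -0.5, 0.5), g=1.5)
        expected = 1.5 * COULOMB_CONSTANT * (-0.25) / 0.5
        assert report.terms["ft_ft_elec"] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(-104.2016, abs=1e-3)

    def test_zero_factor_gives_zero(self):
        assert ft_ft_electrostatics(self.pair(0.4, 0.3, 0.4), g=0.0).terms[
            "ft_ft_elec"
        ] == pytest.approx(0.0)

    def test_exact_linearity_in_g(self, rng):
        particles = [
            (rng.uniform(-0.5, 0.5, 3), rng.uniform(-0.5, 0.5), 0.3, 0.0) for _ in range(5)
        ]
        system = make_system(particles)
        e1 = ft_ft_electrostatics(system, g=1.0).terms["ft_ft_elec"]
        e2 = ft_ft_electrostatics(system, g=2.0).terms["ft_ft_elec"]
        assert e2 == pytest.approx(2.0 * e1, rel=1e-14)

    def test_repulsive_only_keeps_like_charge_terms(self):
        system = self.pair(0.4, -0.4, 0.5)
        system.force_params = dataclasses.replace(system.force_params, ft_ft_elec="repulsive")
        assert ft_ft_electrostatics(system).terms["ft_ft_elec"] == 0.0
        system2 = self.pair(0.4, 0.4, 0.5)
        system2.force_params = dataclasses.replace(system2.force_params, ft_ft_elec="repulsive")
        assert ft_ft_electrostatics(system2).terms["ft_ft_elec"] > 0.0


class TestFtFtLJ:
    def test_zero_epsilon_gives_zero(self):
        system = make_system([((0, 0, 0), 0.0, 0.3, 0.0), ((0.25, 0, 0), 0.0, 0.3, 0.0)])
        assert ft_ft_lj(system).terms["ft_ft_lj"] == pytest.approx(0.0)

    def test_zero_crossing(self):
        system = make_system([((0, 0, 0), 0.0, 0.3, 1.0), ((0.3, 0, 0), 0.0, 0.3, 1.0)])
        assert ft_ft_lj(system).terms["ft_ft_lj"] == pytest.approx(0.0, abs=1e-12)

    def test_well_minimum_depth(self):
        r = 0.3 * 2 ** (1 / 6)
        system = make_system([((0, 0, 0), 0.0, 0.3, 1.0), ((r, 0, 0), 0.0, 0.3, 1.0)])
        assert ft_ft_lj(system).terms["ft_ft_lj"] == pytest.approx(-1.0, rel=1e-12)


class TestContinuity:
    def test_single_component_has_zero_energy(self):
        system = make_system(
            [
                ((0.0, 0, 0), 0, 0.3, 0.5),
                ((0.2, 0, 0), 0, 0.3, 0.5),
                ((0.4, 0, 0), 0, 0.3, 0.5),
            ]
        )
        assert continuity(system).terms["continuity"] == 0.0

    def test_two_singletons_harmonic_value(self):
        system = make_system([((0, 0, 0), 0, 0.3, 0.5), ((0.35, 0, 0), 0, 0.3, 0.5)])
        # k (r - d)^2 = 10000 * 0.10^2
        assert continuity(system).terms["continuity"] == pytest.approx(100.0, rel=1e-9)

    def test_edge_at_exact_cutoff_is_connected(self):
        system = make_system([((0, 0, 0), 0, 0.3, 0.5), ((0.25, 0, 0), 0, 0.3, 0.5)])
        assert continuity(system).terms["continuity"] == 0.0

    @pytest.mark.parametrize("pairing", ["closest", "all"])
    def test_energy_zero_iff_single_component(self, rng, pairing):
        for _ in range(50):
            n = rng.integers(2, 8)
            system = make_system(
                [(rng.uniform(-0.5, 0.5, 3), 0.0, 0.3, 0.5) for _ in range(n)]
            )
            system.force_params.continuity = ContinuityParams(pairing=pairing)
            arrays = SystemArrays.from_system(system)
            energy = compute_energy(arrays, terms=("continuity",)).total
            # oracle: union-find over the pairwise distance matrix
            pos = arrays.ft_pos
            d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            adj = d <= 0.25
            seen = {0}
            frontier = [0]
            while frontier:
                i = frontier.pop()
                for j in np.where(adj[i])[0]:
                    if j not in seen:
                        seen.add(int(j))
                        frontier.append(int(j))
            single = len(seen) == n
            assert (energy == 0.0) == single


class TestAttrRestraint:
    def test_zero_at_quarter_quarter(self):
        system = make_system([((0, 0, 0), 0.25, 0.22, 0.25)])
        assert attr_restraint(system).terms["attr_restraint"] == pytest.approx(0.0, abs=1e-12)

    def test_sigmoid_midpoint(self):
        # at sigma = 0.3 the switch is exactly 1/2
        system = make_system([((0, 0, 0), 0.25, 0.3, 1.25)])
        expected = 0.5 * 941.5 * (1.25 - 0.25) ** 2
        assert attr_restraint(system).terms["attr_restraint"] == pytest.approx(expected, rel=1e-12)

    def test_low_sigma_hand_value(self):
        system = make_system([((0, 0, 0), 0.0, 0.20, 0.03)])
        expected = 941.5 * (0.03 - 0.25) ** 2 + 275.3 * (0.0 - 0.25) ** 2
        report = attr_restraint(system)
        assert report.terms["attr_restraint"] == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(62.77485, abs=1e-4)


class TestCentroidRestraint:
    @pytest.mark.parametrize(
        "distance, expected",
        [(0.5, 0.0), (1.0, 0.5 * 1000.0 * 0.1**2), (0.9, 0.0)],
    )
    def test_flat_bottom_values(self, distance, expected):
        system = make_system([((distance, 0, 0), 0.0, 0.3, 0.5)])
        assert centroid_restraint(system).terms["centroid_restraint"] == pytest.approx(
            expected, rel=1e-12
        )


class TestTotalEnergy:
    def test_isolated_particle_at_restraint_minimum_has_zero_total(self):
        system = make_system([((0.1, 0, 0), 0.25, 0.22, 0.25)])
        assert total_energy(system).total == pytest.approx(0.0, abs=1e-12)

    def test_total_is_sum_of_individual_terms(self, random_small_system, rng):
        system = random_small_system(rng)
        report = total_energy(system)
        parts = (
            ft_env_nonbonded(system).terms["ft_env"]
            + ft_ft_electrostatics(system).terms["ft_ft_elec"]
            + ft_ft_lj(system).terms["ft_ft_lj"]
            + continuity(system).terms["continuity"]
            + attr_restraint(system).terms["attr_restraint"]
            + centroid_restraint(system).terms["centroid_restraint"]
        )
        assert report.total == pytest.approx(parts, rel=1e-10)

    def test_rigid_motion_invariance(self, random_small_system, rng):
        from scipy.spatial.transform import Rotation

        system = random_small_system(rng)
        e0 = total_energy(system).total
        rot = Rotation.random(random_state=5).as_matrix()
        shift = np.array([1.3, -0.7, 2.1])
        for p in system.particles:
            p.position = rot @ p.position + shift
        for a in system.environment:
            a.position = rot @ a.position + shift
        system.centroid = rot @ system.centroid + shift
        assert total_energy(system).total == pytest.approx(e0, rel=1e-9)


def _continuity_is_smooth(system, margin=1e-3):
    """True when the configuration is away from the kinks of the
    continuity term (pairs near the cutoff or ambiguous bridge pairs),
    where a finite difference straddles a non-smooth point."""
    arrays = SystemArrays.from_system(system)
    pos = arrays.ft_pos
    r = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    np.fill_diagonal(r, np.inf)
    cutoff = arrays.params.continuity.cutoff
    if np.any(np.abs(r - cutoff) < margin):
        return False
    from flextop.forces import _connected_components

    labels = _connected_components(r, cutoff)
    sizes = np.bincount(labels)
    largest = int(np.argmax(sizes))
    for c in range(labels.max() + 1):
        if c == largest:
            continue
        inside = np.where(labels == c)[0]
        outside = np.where(labels != c)[0]
        candidates = np.sort(r[np.ix_(inside, outside)].ravel())
        if len(candidates) > 1 and candidates[1] - candidates[0] < margin:
            return False
    return True


def _finite_difference_check(system, h=1e-6, rtol=1e-4):
    arrays = SystemArrays.from_system(system)
    report = compute_energy(arrays)
    # cancellation noise of a central difference scales with the energy
    # magnitude: eps_machine * |E| / (2h)
    energy_scale = max(abs(v) for v in report.terms.values()) + 1.0
    noise_floor = 1e-6 + 5.0 * np.finfo(float).eps * energy_scale / (2 * h)

    def energy_after(setter, delta):
        setter(delta)
        value = compute_energy(arrays).total
        setter(-delta)
        return value

    checks = []
    for i in range(arrays.n_ft):
        for k in range(3):
            def set_pos(d, i=i, k=k):
                arrays.ft_pos[i, k] += d

            fd = (energy_after(set_pos, h) - energy_after(set_pos, -h)) / (2 * h)
            checks.append((fd, report.ft_position_grad[i, k]))
        for attr_array, grad in (
            (arrays.q, report.charge_grad),
            (arrays.sigma, report.sigma_grad),
            (arrays.epsilon, report.epsilon_grad),
        ):
            def set_attr(d, arr=attr_array, i=i):
                arr[i] += d

            fd = (energy_after(set_attr, h) - energy_after(set_attr, -h)) / (2 * h)
            checks.append((fd, grad[i]))
    for fd, analytic in checks:
        assert analytic == pytest.approx(fd, rel=rtol, abs=noise_floor + rtol * abs(fd))


def test_gradients_match_finite_differences_on_randomized_systems(random_small_system):
    rng = np.random.default_rng(2024)
    checked = 0
    while checked < 100:
        n_ft = int(rng.integers(2, 11))
        n_env = int(rng.integers(0, 6))
        system = random_small_system(rng, n_ft=n_ft, n_env=n_env)
        if not _continuity_is_smooth(system):
            continue  # redraw: FD is invalid across a continuity kink
        _finite_difference_check(system)
        checked += 1
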