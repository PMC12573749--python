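import numpy as np
import pytest

from flextop.core import (
    AttributeState,
    EnvironmentAtom,
    FTParticle,
    SimulationSystem,
)


def make_system(particles, environment=(), centroid=(0.0, 0.0, 0.0), **kwargs):
    """Bare-bones SimulationSystem from (position, q, sigma, epsilon) tuples."""
    parts = [
        FTParticle(position=np.asarray(p[0], dtype=float), attrs=AttributeState(*p[1:]))
        for p in particles
    ]
    env = [
        EnvironmentAtom(position=np.asarray(e[0], dtype=float), q=e[1], sigma=e[2], epsilon=e[3])
        for e in environment
    ]
    return SimulationSystem(environment=env, particles=parts, centroid=np.asarray(centroid), **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_small_system():
    """Factory for randomized small systems with attributes inside bounds."""

    def sample_separated(rng, n, spread, existing=None, min_dist=0.12):
        # rejection-sample positions with a minimum separation so that
        # no pair sits deep inside the LJ core (astronomical energies
        # there drown finite differences in floating-point noise)
        points = [] if existing is None else list(existing)
        start = len(points)
        while len(points) - start < n:
            trial = rng.uniform(-spread, spread, 3)
            if all(np.linalg.norm(trial - p) >= min_dist for p in points):
                points.append(trial)
        return points[start:]

    def build(rng, n_ft=6, n_env=4, spread=0.6):
        ft_pos = sample_separated(rng, n_ft, spread)
        env_pos = sample_separated(rng, n_env, 1.0, existing=ft_pos)
        particles = [
            (ft_pos[i], rng.uniform(-0.5, 0.5), rng.uniform(0.2, 0.36), rng.uniform(0.03, 1.5))
            for i in range(n_ft)
        ]
        environment = [
            (env_pos[j], rng.uniform(-1.0, 1.0), 0.3, rng.uniform(0.1, 1.0))
            for j in range(n_env)
        ]
        return make_system(particles, environment)

    return build
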