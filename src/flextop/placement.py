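"""Initialization of FT particle positions and attributes in the pocket.

Trial positions are drawn from an isotropic Gaussian centred on the
binding-site centroid (per-axis standard deviation 0.9 nm) and accepted
when they (1) keep at least 0.20 nm from every environment atom,
(2) keep at least 0.15 nm from every already-placed particle, and
(3) lie within 0.25 nm of the nearest already-placed particle, so that
the initial configuration forms one contiguous cluster.  Criterion (3)
is vacuous for the first particle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import INIT_BOUNDS, SimulationSystem
from .errors import PlacementError

PLACEMENT_FAILURE_GUIDANCE = (
    "placement failed: delete more water molecules or consider a smaller "
    "number of particles"
)


@dataclass
class PlacementSpec:
    """Sampling distribution and acceptance criteria for initialization."""

    centroid: np.ndarray  # nm
    gaussian_width: float = 0.9  # per-axis std dev [nm]
    min_env_distance: float = 0.20  # criterion 1 [nm]
    min_ft_distance: float = 0.15  # criterion 2 [nm]
    max_nearest_ft_distance: float = 0.25  # criterion 3 [nm]
    max_trials: int = 10_000
    max_restarts: int = 10

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        if not (0 < self.min_ft_distance < self.max_nearest_ft_distance):
            raise ValueError(
                "require 0 < min FT distance < max nearest-FT distance, got "
                f"{self.min_ft_distance} / {self.max_nearest_ft_distance}"
            )


def remove_nearest_solvent(
    system: SimulationSystem, centroid: np.ndarray, count: int
) -> SimulationSystem:
    """Delete the ``count`` solvent-tagged atoms nearest the centroid.

    Ties are broken by stable input order.  Mutates and returns the
    system.
    """
    if count == 0:
        return system
    centroid = np.asarray(centroid, dtype=float)
    solvent_idx = [i for i, a in enumerate(system.environment) if a.solvent]
    if len(solvent_idx) < count:
        raise ValueError(
            f"cannot remove {count} solvent atoms: only {len(solvent_idx)} present"
        )
    dists = [
        (float(np.linalg.norm(system.environment[i].position - centroid)), i)
        for i in solvent_idx
    ]
    # sort by distance; python sort is stable so ties keep input order
    dists.sort(key=lambda t: t[0])
    drop = {i for _, i in dists[:count]}
    system.environment = [a for i, a in enumerate(system.environment) if i not in drop]
    return system


def check_positions(
    positions: np.ndarray, env_positions: np.ndarray, spec: PlacementSpec
) -> bool:
    """Brute-force re-check of criteria (1)-(3) on a full configuration."""
    positions = np.asarray(positions, dtype=float)
    for i, pos in enumerate(positions):
        if env_positions.size:
            if np.linalg.norm(env_positions - pos, axis=1).min() < spec.min_env_distance:
                return False
        others = np.delete(positions, i, axis=0)
        if others.size:
            d = np.linalg.norm(others - pos, axis=1)
            if d.min() < spec.min_ft_distance:
                return False
    # criterion 3 is checked against the placement order implicitly;
    # post-hoc, require every particle except one seed to be within the
    # nearest-neighbour cutoff (connectivity of the cutoff graph)
    if len(positions) > 1:
        for i, pos in enumerate(positions):
            others = np.delete(positions, i, axis=0)
            if np.linalg.norm(others - pos, axis=1).min() > spec.max_nearest_ft_distance:
                return False
    return True


def sample_positions(
    spec: PlacementSpec,
    env_positions: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Place ``n`` particle positions satisfying the acceptance criteria.

    Rejection sampling with restart logic: if ``max_trials`` draws do
    not complete the placement, everything is discarded and the
    procedure starts over, up to ``max_restarts`` times.
    """
    if n < 1:
        raise ValueError("need at least one particle")
    env_positions = np.asarray(env_positions, dtype=float).reshape(-1, 3)
    for _restart in range(spec.max_restarts):
        placed: list[np.ndarray] = []
        trials = 0
        while len(placed) < n and trials < spec.max_trials:
            trials += 1
            pos = spec.centroid + spec.gaussian_width * rng.standard_normal(3)
            if env_positions.size:
                if np.linalg.norm(env_positions - pos, axis=1).min() < spec.min_env_distance:
                    continue
            if placed:
                d = np.linalg.norm(np.asarray(placed) - pos, axis=1)
                if d.min() < spec.min_ft_distance:
                    continue
                if d.min() > spec.max_nearest_ft_distance:
                    continue
            placed.append(pos)
        if len(placed) == n:
            return np.asarray(placed)
    raise PlacementError(PLACEMENT_FAILURE_GUIDANCE)


def sample_attributes(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw initial attributes: q near-neutral, sigma at its minimum.

    q ~ U[-0.01, 0.01]; epsilon ~ U[0.03, 1.50]; sigma = 0.20 exactly.
    Returns (q, sigma, epsilon) arrays of length ``n``.
    """
    if n < 1:
        raise ValueError("need at least one particle")
    q = rng.uniform(*INIT_BOUNDS["q"], size=n)
    epsilon = rng.uniform(*INIT_BOUNDS["epsilon"], size=n)
    sigma = np.full(n, INIT_BOUNDS["sigma"][0])
    return q, sigma, epsilon
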