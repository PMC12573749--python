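"""Synthetic desk-scale test systems.

``make_toy_pocket`` builds a rigid spherical cage of frozen LJ atoms
standing in for a protein binding pocket, optionally decorated with
fixed charged sites (e.g. one -1.0 e carboxylate-like site) and
solvent-like mobile particles.  ``make_reference_pseudoligands`` builds
small hand-coded charged-particle sets spanning distinct descriptor
regimes, for exercising the grid metrics without any external data.
"""

from __future__ import annotations

import numpy as np

from .core import (
    AttributeMobilities,
    AttributeState,
    EnvironmentAtom,
    FTParticle,
    ForceParams,
    SimulationSystem,
)
from .gridfield import ChargedParticleSet
from .placement import PlacementSpec, sample_attributes, sample_positions


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """n near-uniform points on a sphere of the given radius."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    y = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - y * y)
    theta = phi * i
    pts = np.stack([r * np.cos(theta), y, r * np.sin(theta)], axis=1)
    return radius * pts


#: Packing volume per particle used to size the pocket cavity
#: [nm^3]; matches the heavy-atom density of drug-like ligands
#: (roughly one heavy atom per 25-35 A^3).
PACKING_VOLUME_PER_PARTICLE = 0.03


def pocket_radius_for(n_particles: int, wall_contact: float = 0.27) -> float:
    """Cavity wall radius giving ligand-like packing for n particles.

    The free cavity (radius R) holds the particles at the heavy-atom
    density of real ligands; the wall-atom shell sits one LJ contact
    distance further out.
    """
    free_r = (3.0 * n_particles * PACKING_VOLUME_PER_PARTICLE / (4.0 * np.pi)) ** (1.0 / 3.0)
    return free_r + wall_contact


def default_anionic_site(n_particles: int) -> tuple[np.ndarray, float]:
    """A carboxylate-like fixed -1.0 e site just inside the pocket wall."""
    return np.array([0.0, 0.0, -(pocket_radius_for(n_particles) - 0.1)]), -1.0


def make_toy_pocket(
    radius: float | None = None,
    n_cage_atoms: int | None = None,
    charged_sites: list[tuple[np.ndarray, float]] | None = None,
    rng: np.random.Generator | None = None,
    n_particles: int = 10,
    n_solvent: int = 0,
    force_params: ForceParams | None = None,
    seed: int = 0,
    place_particles: bool = True,
    n_shells: int = 2,
    shell_spacing: float = 0.2,
) -> SimulationSystem:
    """A rigid spherical pocket cavity with optional charged sites.

    The pocket is a cavity inside a filled medium: ``n_shells``
    concentric shells of frozen LJ atoms (sigma 0.3 nm, epsilon
    0.5 kJ/mol, q 0) starting at ``radius``, so that the outside of the
    pocket is occupied — as the protein interior is around a real
    binding site — and trial placements or escaping particles cannot
    wander off.  The default radius packs ``n_particles`` at the
    heavy-atom density of drug-like ligands (:func:`pocket_radius_for`).
    The binding-site centroid is the cavity centre.  ``charged_sites``
    is a list of (position [nm], charge [e]) pairs added as frozen
    environment atoms.  When ``place_particles`` is true,
    ``n_particles`` FT particles are initialized inside with the
    standard placement procedure and initial-attribute distributions.
    """
    if radius is None:
        radius = pocket_radius_for(n_particles)
    if not radius > 0.5:
        raise ValueError("cage radius must exceed 0.5 nm")
    rng = rng if rng is not None else np.random.default_rng(seed)
    shells = []
    for k in range(n_shells):
        r_k = radius + k * shell_spacing
        if n_cage_atoms is not None and k == 0:
            n_k = n_cage_atoms
        else:
            # area density ~ one atom per 0.042 nm^2 (spacing ~0.2 nm)
            n_k = max(12, int(round(4.0 * np.pi * r_k**2 / 0.042)))
        shells.append(_fibonacci_sphere(n_k, r_k))
    cage = np.concatenate(shells, axis=0)
    # construction sanity: no two cage atoms may coincide
    diff = cage[:, None, :] - cage[None, :, :]
    d = np.sqrt(np.einsum("...k,...k->...", diff, diff))
    np.fill_diagonal(d, np.inf)
    if d.min() < 1e-6:
        raise ValueError("overlapping cage atoms; reduce n_cage_atoms or grow radius")

    environment = [
        EnvironmentAtom(position=p, q=0.0, sigma=0.3, epsilon=0.5, group="frozen", name="CAGE")
        for p in cage
    ]
    for pos, q in charged_sites or []:
        environment.append(
            EnvironmentAtom(
                position=np.asarray(pos, dtype=float),
                q=float(q),
                sigma=0.3,
                epsilon=0.5,
                group="frozen",
                name="SITE",
            )
        )
    for k in range(n_solvent):
        # solvent-like neutral particles scattered inside the cage
        pos = rng.uniform(-0.5, 0.5, size=3) * radius
        environment.append(
            EnvironmentAtom(
                position=pos,
                q=0.0,
                sigma=0.25,
                epsilon=0.3,
                group="other",
                solvent=True,
                name=f"W{k}",
            )
        )

    centroid = np.zeros(3)
    particles: list[FTParticle] = []
    if place_particles:
        env_positions = np.array([a.position for a in environment])
        spec = PlacementSpec(centroid=centroid)
        # In a real system the pocket is a cavity in a filled medium, so
        # trial positions beyond the wall are rejected by the distance
        # criterion against surrounding atoms.  The toy wall is a thin
        # shell with vacuum outside; stand in for the medium by
        # re-sampling until the whole cluster sits inside the cavity.
        for _attempt in range(500):
            positions = sample_positions(spec, env_positions, n_particles, rng)
            if np.linalg.norm(positions - centroid, axis=1).max() <= radius - 0.15:
                break
        else:
            raise ValueError("could not seat the particle cluster inside the cavity")
        q, sigma, epsilon = sample_attributes(n_particles, rng)
        particles = [
            FTParticle(
                position=positions[i],
                attrs=AttributeState(q=q[i], sigma=sigma[i], epsilon=epsilon[i]),
                mobilities=AttributeMobilities(),
            )
            for i in range(n_particles)
        ]

    return SimulationSystem(
        environment=environment,
        particles=particles,
        centroid=centroid,
        force_params=force_params if force_params is not None else ForceParams(),
        seed=seed,
    )


def make_reference_pseudoligands() -> dict[str, ChargedParticleSet]:
    """Hand-coded reference particle sets with distinct descriptor regimes.

    Units are Angstrom (grid convention).  The sets are:

    ``small_polar``
        A compact 5-site cluster with one strongly polar centre;
        non-zero PSA, high globularity.
    ``large_apolar``
        A roomy 8-site cluster with all |q| <= 0.1; PSA is exactly 0.
    ``elongated_zwitterion``
        A linear chain carrying +0.5 / -0.5 termini; low globularity
        and a large dipole.
    """
    small_polar = ChargedParticleSet(
        positions=np.array(
            [
                [0.0, 0.0, 0.0],
                [1.5, 0.0, 0.0],
                [0.0, 1.5, 0.0],
                [0.0, 0.0, 1.5],
                [1.0, 1.0, 1.0],
            ]
        ),
        charges=np.array([0.45, -0.15, -0.15, -0.15, 0.0]),
        diameters=np.full(5, 3.0),
    )
    large_apolar = ChargedParticleSet(
        positions=np.array(
            [
                [0.0, 0.0, 0.0],
                [2.5, 0.0, 0.0],
                [0.0, 2.5, 0.0],
                [0.0, 0.0, 2.5],
                [2.5, 2.5, 0.0],
                [2.5, 0.0, 2.5],
                [0.0, 2.5, 2.5],
                [2.5, 2.5, 2.5],
            ]
        ),
        charges=np.array([0.1, -0.1, 0.05, -0.05, 0.1, -0.1, 0.05, -0.05]),
        diameters=np.full(8, 3.4),
    )
    n_chain = 7
    # carboxylate/ammonium-like terminal charges, strong enough that the
    # clipped EP map has nonempty positive and negative lobes
    elongated_zwitterion = ChargedParticleSet(
        positions=np.array([[2.0 * i, 0.0, 0.0] for i in range(n_chain)]),
        charges=np.array([0.8] + [0.0] * (n_chain - 2) + [-0.8]),
        diameters=np.full(n_chain, 3.0),
    )
    return {
        "small_polar": small_polar,
        "large_apolar": large_apolar,
        "elongated_zwitterion": elongated_zwitterion,
    }
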