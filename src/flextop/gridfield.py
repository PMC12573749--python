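"""Gridded density / electrostatic-potential maps and derived metrics.

All grid quantities are Angstrom-based: positions and diameters in
Angstrom, volumes in A^3, surface areas in A^2.  Electrostatic
potentials are expressed in units of the Coulomb constant k (i.e. the
raw sum q_i / r_ix with r in Angstrom), so an isovalue of "0.3 k"
corresponds to a grid value of 0.3.

The default lattice spacing is delta = 1.0 A.  A grid point counts as
occupied by a particle when its distance to the particle centre is less
than half the particle diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, UndefinedOverlapError

#: Clip threshold for the ternary electrostatic-potential map, in units
#: of the Coulomb constant.
EP_CLIP_THRESHOLD = 0.3


@dataclass(frozen=True)
class GridSpec:
    """Regular cubic lattice: origin, spacing delta [A], shape."""

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"grid shape must be positive, got {self.shape}")

    def points(self) -> np.ndarray:
        """All grid-point coordinates, shape (nx, ny, nz, 3)."""
        axes = [
            self.origin[d] + self.spacing * np.arange(self.shape[d]) for d in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)


@dataclass
class ScalarField:
    """A scalar value per grid point."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}"
            )


@dataclass
class ChargedParticleSet:
    """Point particles with charges and hard diameters, Angstrom units."""

    positions: np.ndarray  # (n, 3) A
    charges: np.ndarray  # (n,) e
    diameters: np.ndarray  # (n,) A

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float)
        self.diameters = np.asarray(self.diameters, dtype=float)
        if np.any(self.diameters <= 0):
            raise ValueError("particle diameters must be positive")

    def __len__(self) -> int:
        return len(self.charges)

    @classmethod
    def from_frame(cls, frame) -> "ChargedParticleSet":
        """Convert a TrajectoryFrame (nm units) to Angstrom particles.

        The LJ sigma parameter is used as the particle diameter, as in
        the grid occupancy rule r < sigma/2.
        """
        return cls(
            positions=frame.positions * 10.0,
            charges=frame.q,
            diameters=frame.sigma * 10.0,
        )


def shared_grid(
    particle_sets: list[ChargedParticleSet],
    spacing: float = 1.0,
    padding: float = 2.0,
) -> GridSpec:
    """Common grid covering every set: padded union bounding box.

    The origin is snapped down onto the delta lattice anchored at
    (0, 0, 0) so that two calls over overlapping regions sample
    identical points.
    """
    if not particle_sets:
        raise ValueError("need at least one particle set")
    lo = np.min([ps.positions.min(axis=0) - ps.diameters.max() / 2 for ps in particle_sets], axis=0)
    hi = np.max([ps.positions.max(axis=0) + ps.diameters.max() / 2 for ps in particle_sets], axis=0)
    lo = np.floor((lo - padding) / spacing) * spacing
    hi = hi + padding
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / spacing)) + 1 for d in range(3))
    return GridSpec(origin=tuple(float(x) for x in lo), spacing=spacing, shape=shape)


def _occupancy(particles: ChargedParticleSet, spec: GridSpec) -> np.ndarray:
    """Boolean occupancy: point within diameter/2 of any particle."""
    pts = spec.points()
    occ = np.zeros(spec.shape, dtype=bool)
    for pos, diam in zip(particles.positions, particles.diameters):
        d2 = np.sum((pts - pos) ** 2, axis=-1)
        occ |= d2 < (diam / 2.0) ** 2
    return occ


def density_grid(particles: ChargedParticleSet, spec: GridSpec) -> ScalarField:
    """Binary occupancy field (1 inside any particle, else 0)."""
    return ScalarField(spec=spec, values=_occupancy(particles, spec).astype(float))


def ep_grid(particles: ChargedParticleSet, spec: GridSpec) -> ScalarField:
    """Electrostatic potential in units of k: sum_i q_i / r_ix.

    Points inside any particle (r < diameter/2) are set to exactly zero
    after summation, both to avoid singular values and because such
    points are inaccessible to binding-site residues.
    """
    pts = spec.points()
    v = np.zeros(spec.shape)
    inside = np.zeros(spec.shape, dtype=bool)
    for pos, q, diam in zip(particles.positions, particles.charges, particles.diameters):
        d2 = np.sum((pts - pos) ** 2, axis=-1)
        mask = d2 < (diam / 2.0) ** 2
        inside |= mask
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = q / np.sqrt(d2)
        contrib[mask] = 0.0
        v += contrib
    v[inside] = 0.0
    return ScalarField(spec=spec, values=v)


def clip_ep(field: ScalarField, threshold: float = EP_CLIP_THRESHOLD) -> ScalarField:
    """Ternary map: +1 where V > threshold, -1 where V < -threshold, else 0."""
    v = np.zeros_like(field.values)
    v[field.values > threshold] = 1.0
    v[field.values < -threshold] = -1.0
    return ScalarField(spec=field.spec, values=v)


def _require_same_grid(x: ScalarField, y: ScalarField) -> None:
    if x.spec != y.spec:
        raise ValueError("fields are comparable only on identical grids")


def shape_overlap(x: ScalarField, y: ScalarField) -> float:
    """O_S(x, y) = 1 - sum|x_i - y_i| / (sum x_i + sum y_i), in [0, 1]."""
    _require_same_grid(x, y)
    denom = float(x.values.sum() + y.values.sum())
    if denom <= 0:
        raise UndefinedOverlapError("shape overlap of two empty fields is undefined")
    return 1.0 - float(np.abs(x.values - y.values).sum()) / denom


def electrostatic_overlap(x: ScalarField, y: ScalarField) -> float:
    """O_E(x, y) = 2 sum x_i y_i / (sum|x_i| + sum|y_i|), in [-1, 1].

    1 for identical nonzero ternary maps, negative for anticorrelated
    maps.
    """
    _require_same_grid(x, y)
    denom = float(np.abs(x.values).sum() + np.abs(y.values).sum())
    if denom <= 0:
        raise UndefinedOverlapError("electrostatic overlap of two all-zero maps is undefined")
    return 2.0 * float((x.values * y.values).sum()) / denom


def descriptors(
    particles: ChargedParticleSet,
    spec: GridSpec | None = None,
    spacing: float = 1.0,
    polar_charge_threshold: float = 0.3,
    include_globularity: bool = True,
) -> dict[str, float]:
    """Grid-based molecular descriptors: volume, PSA, globularity.

    volume
        Number of occupied grid cells times delta^3 [A^3].
    psa
        Number of unoccupied cells 6-face-adjacent to a polar cell
        (a cell occupied by an atom with |q| > 0.3) times delta^2 [A^2].
    globularity
        Ratio of the grid volume to the volume of the minimum
        encompassing sphere, whose diameter is the largest
        particle-particle distance; requires >= 2 particles.
    """
    if spec is None:
        spec = shared_grid([particles], spacing=spacing) if len(particles) else None
    if len(particles) == 0:
        return {"volume": 0.0, "psa": 0.0, "globularity": float("nan")}
    delta = spec.spacing
    occ = _occupancy(particles, spec)
    volume = float(occ.sum()) * delta**3

    polar_mask = np.abs(particles.charges) > polar_charge_threshold
    if polar_mask.any():
        polar_particles = ChargedParticleSet(
            positions=particles.positions[polar_mask],
            charges=particles.charges[polar_mask],
            diameters=particles.diameters[polar_mask],
        )
        polar = _occupancy(polar_particles, spec)
    else:
        polar = np.zeros(spec.shape, dtype=bool)
    # unoccupied cells with a face-adjacent polar neighbour
    adjacent = np.zeros(spec.shape, dtype=bool)
    for axis in range(3):
        for shift in (1, -1):
            adjacent |= np.roll(polar, shift, axis=axis) & ~_roll_edge_mask(
                spec.shape, axis, shift
            )
    psa = float((adjacent & ~occ).sum()) * delta**2

    if not include_globularity:
        return {"volume": volume, "psa": psa}
    if len(particles) < 2:
        raise DegenerateGeometryError("globularity requires at least two particles")
    diff = particles.positions[:, None, :] - particles.positions[None, :, :]
    dmax = float(np.sqrt(np.einsum("...k,...k->...", diff, diff)).max())
    if dmax <= 0:
        raise DegenerateGeometryError("globularity undefined for coincident particles")
    sphere_volume = (4.0 / 3.0) * np.pi * (dmax / 2.0) ** 3
    return {"volume": volume, "psa": psa, "globularity": volume / sphere_volume}


def _roll_edge_mask(shape: tuple[int, int, int], axis: int, shift: int) -> np.ndarray:
    """Mask of cells whose np.roll neighbour wrapped around the grid edge."""
    mask = np.zeros(shape, dtype=bool)
    idx = [slice(None)] * 3
    idx[axis] = 0 if shift == 1 else -1
    mask[tuple(idx)] = True
    return mask


def dipole_magnitude(particles: ChargedParticleSet) -> float:
    """|sum q_i (r_i - r_centroid)| in e*A.

    The reference point is the geometric centroid of the particle set;
    for zero net charge the dipole is independent of the reference.
    """
    if len(particles) == 0:
        return 0.0
    ref = particles.positions.mean(axis=0)
    dipole = ((particles.positions - ref) * particles.charges[:, None]).sum(axis=0)
    return float(np.linalg.norm(dipole))


def mean_squared_ep(field: ScalarField) -> float:
    """Mean over grid points of V_EP^2 (units of k^2)."""
    return float(np.mean(field.values**2))
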