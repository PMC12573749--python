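"""Domain types, physical constants, units and configuration.

Internal unit system: lengths in nm, energies in kJ/mol, charges in
elementary charge units (e), time in ps, masses in amu (g/mol).  With
these units 1 amu nm^2/ps^2 == 1 kJ/mol, so no conversion factors appear
in the integrator.  Grid-based analysis reports Angstrom-based
quantities; the conversion factor is exactly 10.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Coulomb constant k_e in (kJ/mol) nm e^-2.
COULOMB_CONSTANT = 138.935456

#: Boltzmann constant in kJ/mol/K.
BOLTZMANN_KJ_MOL_K = 0.00831446261815324

#: Thermochemical calorie, used to convert the restraint constants
#: quoted in kcal/mol/nm^2 for the restrained heating stage.
KCAL_TO_KJ = 4.184

#: nm -> Angstrom.
NM_TO_ANGSTROM = 10.0

# Attribute bounds enforced by the integrator ("during simulation").
SIM_BOUNDS = {
    "q": (-0.5, 0.5),
    "sigma": (0.20, 0.36),
    "epsilon": (0.03, 1.50),
}

# Attribute bounds used at initialization: charges start near neutral,
# sigma starts at its minimum to reduce initial overlaps.
INIT_BOUNDS = {
    "q": (-0.01, 0.01),
    "sigma": (0.20, 0.20),
    "epsilon": (0.03, 1.50),
}


@dataclass
class AttributeState:
    """The dynamic nonbonded attributes of one flexible-topology particle.

    Parameters
    ----------
    q : float
        Partial charge [e].
    sigma : float
        Lennard-Jones radius parameter [nm].
    epsilon : float
        Lennard-Jones well depth [kJ/mol].
    """

    q: float
    sigma: float
    epsilon: float

    def as_array(self) -> np.ndarray:
        return np.array([self.q, self.sigma, self.epsilon], dtype=float)


@dataclass
class AttributeMobilities:
    """Brownian mobilities mu_a for each attribute.

    Units are attribute-unit^2 / (kJ/mol) / ps.  Attributes are meant to
    relax roughly an order of magnitude more slowly than positions
    (relaxation time ~1/(mu k) against the attribute-restraint
    curvature); see the methods note for how the defaults were chosen.
    """

    q: float = 2e-4
    sigma: float = 5e-5
    epsilon: float = 5e-5


@dataclass
class FTParticle:
    """A particle whose nonbonded attributes are degrees of freedom."""

    position: np.ndarray
    attrs: AttributeState
    mobilities: AttributeMobilities = field(default_factory=AttributeMobilities)
    mass: float = 12.0  # amu

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class EnvironmentAtom:
    """A fixed-attribute atom of the binding-pocket environment."""

    position: np.ndarray
    q: float
    sigma: float
    epsilon: float
    mobile: bool = False
    group: str = "frozen"  # restraint group: backbone | other | frozen
    solvent: bool = False
    name: str = ""
    mass: float = 12.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class ContinuityParams:
    """Harmonic attraction between disconnected particle components.

    ``pairing`` selects which inter-component pairs receive the
    harmonic k (r - d)^2 term: "closest" (default) applies it only to
    the single closest pair linking each non-largest component to its
    nearest other component — the energy is then continuous at the
    connect/disconnect boundary; "all" applies it to every pair of
    particles from different components, which pulls fragments together
    harder but makes the energy jump discontinuously when a component
    splits off.
    """

    cutoff: float = 0.25  # nm
    k: float = 10000.0  # kJ/mol/nm^2
    pairing: str = "closest"  # "closest" | "all"


@dataclass
class AttrForceParams:
    """Restraint coupling charge and well depth to sigma.

    V = A f(sigma) (epsilon - offset)^2 + B f(sigma) (q - offset)^2 with
    f a sigmoid switching off as sigma crosses ``center``.  A and B were
    fit against the attribute distribution of a large set of
    CGenFF-parametrized molecules and are adopted as given.
    """

    A: float = 941.5
    B: float = 275.3
    C: float = 200.0  # switch steepness [1/nm]
    center: float = 0.3  # nm
    offset: float = 0.25


@dataclass
class CentroidRestraintParams:
    """Flat-bottom restraint keeping particles near the site centroid."""

    d0: float = 0.9  # nm
    k: float = 1000.0  # kJ/mol/nm^2


@dataclass
class ChargeConstraintParams:
    """Sum and variance constraints on the particle charges."""

    target_sum: float = 0.0  # e
    s_max: float = 0.08  # e^2


@dataclass
class ForceParams:
    """All force-field parameter blocks and term toggles."""

    continuity: ContinuityParams = field(default_factory=ContinuityParams)
    attr_force: AttrForceParams = field(default_factory=AttrForceParams)
    centroid: CentroidRestraintParams = field(default_factory=CentroidRestraintParams)
    charge_constraint: ChargeConstraintParams = field(default_factory=ChargeConstraintParams)
    coulomb_constant: float = COULOMB_CONSTANT
    supercharge: float = 1.5  # g factor on FT-FT electrostatics
    # FT-FT electrostatics mode: "physical" (g * full Coulomb sum),
    # "repulsive" (keep only q_i q_j > 0 pairs) or "off".
    ft_ft_elec: str = "physical"
    # Steric FT-FT Lennard-Jones term; prevents collapse of oppositely
    # charged pairs under supercharged attraction.
    ft_ft_lj: bool = True
    # Pair-distance cutoff [nm] for nonbonded terms; None = no cutoff
    # (exact summation, the default for small non-periodic systems).
    nonbonded_cutoff: float | None = None


@dataclass
class ScheduleStage:
    """One stage of the heating/production schedule."""

    temperature: float  # K
    steps: int
    # restraint group -> force constant [kJ/mol/nm^2] applied to mobile
    # environment atoms of that group; None = unrestrained stage.
    restraints: dict[str, float] | None = None


@dataclass
class SimulationSystem:
    """Environment atoms + flexible-topology particles + run parameters."""

    environment: list[EnvironmentAtom]
    particles: list[FTParticle]
    centroid: np.ndarray
    force_params: ForceParams = field(default_factory=ForceParams)
    box: np.ndarray | None = None  # periodic box lengths [nm] or None
    timestep: float = 0.002  # ps (2 fs)
    friction: float = 1.0  # Langevin friction [1/ps]
    temperature: float = 300.0  # K, production default
    seed: int = 0

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: conv(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, list):
                return [conv(o) for o in obj]
            return obj

        return conv(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationSystem":
        env = [EnvironmentAtom(**a) for a in data["environment"]]
        particles = [
            FTParticle(
                position=p["position"],
                attrs=AttributeState(**p["attrs"]),
                mobilities=AttributeMobilities(**p["mobilities"]),
                mass=p.get("mass", 12.0),
            )
            for p in data["particles"]
        ]
        fp = data["force_params"]
        force_params = ForceParams(
            continuity=ContinuityParams(**fp["continuity"]),
            attr_force=AttrForceParams(**fp["attr_force"]),
            centroid=CentroidRestraintParams(**fp["centroid"]),
            charge_constraint=ChargeConstraintParams(**fp["charge_constraint"]),
            coulomb_constant=fp["coulomb_constant"],
            supercharge=fp["supercharge"],
            ft_ft_elec=fp["ft_ft_elec"],
            ft_ft_lj=fp["ft_ft_lj"],
            nonbonded_cutoff=fp.get("nonbonded_cutoff"),
        )
        return cls(
            environment=env,
            particles=particles,
            centroid=np.asarray(data["centroid"], dtype=float),
            force_params=force_params,
            box=None if data.get("box") is None else np.asarray(data["box"], dtype=float),
            timestep=data["timestep"],
            friction=data["friction"],
            temperature=data["temperature"],
            seed=data["seed"],
        )


@dataclass
class TrajectoryFrame:
    """Positions and attributes of all FT particles at one saved step."""

    step: int
    positions: np.ndarray  # (N, 3) nm
    q: np.ndarray  # (N,) e
    sigma: np.ndarray  # (N,) nm
    epsilon: np.ndarray  # (N,) kJ/mol

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)


def validate_system(system: SimulationSystem) -> list[str]:
    """Check every type invariant; return a list of violation messages.

    An empty list means the system is valid.  The system is never
    mutated.
    """
    violations: list[str] = []
    if system.n_particles < 1:
        violations.append("system must contain at least one FT particle")
    if not (system.timestep > 0):
        violations.append(f"timestep must be positive, got {system.timestep}")
    if not np.all(np.isfinite(system.centroid)):
        violations.append("binding-site centroid must be finite")

    for i, p in enumerate(system.particles):
        a = p.attrs
        for attr_name, value in (("q", a.q), ("sigma", a.sigma), ("epsilon", a.epsilon)):
            lo, hi = SIM_BOUNDS[attr_name]
            if not (lo <= value <= hi):
                violations.append(
                    f"particle {i}: {attr_name} = {value} outside bound [{lo}, {hi}]"
                )
        for attr_name, mu in (("q", p.mobilities.q), ("sigma", p.mobilities.sigma),
                              ("epsilon", p.mobilities.epsilon)):
            if not (mu > 0):
                violations.append(f"particle {i}: mobility for {attr_name} must be > 0")
        if not np.all(np.isfinite(p.position)):
            violations.append(f"particle {i}: non-finite position")

    fp = system.force_params
    nonneg = {
        "continuity.cutoff": fp.continuity.cutoff,
        "continuity.k": fp.continuity.k,
        "attr_force.A": fp.attr_force.A,
        "attr_force.B": fp.attr_force.B,
        "centroid.d0": fp.centroid.d0,
        "centroid.k": fp.centroid.k,
        "supercharge": fp.supercharge,
    }
    for key, value in nonneg.items():
        if value < 0:
            violations.append(f"force parameter {key} must be >= 0, got {value}")
    if not (fp.charge_constraint.s_max > 0):
        violations.append(f"charge constraint S_max must be > 0, got {fp.charge_constraint.s_max}")
    if fp.ft_ft_elec not in ("physical", "repulsive", "off"):
        violations.append(f"unknown FT-FT electrostatics mode {fp.ft_ft_elec!r}")
    return violations


def rng_streams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    """Independent named RNG streams derived from one seed.

    One configuration seed drives placement, initial attributes and the
    thermostats through separate streams so that changing the number of
    draws in one stage does not perturb the others.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def default_heating_temperatures(production_temperature: float = 300.0) -> list[float]:
    """The heating ladder, truncated at the production temperature."""
    ladder = [10.0, 20.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0]
    return [t for t in ladder if t <= production_temperature]


def build_schedule(
    production_temperature: float = 300.0,
    heating_steps: int = 100_000,
    production_steps: int = 1_000_000,
    restrained_first_stage: bool = True,
    backbone_k: float = 400.0 * KCAL_TO_KJ,
    other_k: float = 40.0 * KCAL_TO_KJ,
) -> list[ScheduleStage]:
    """Standard schedule: restrained low-T stage, heating ladder, production.

    The first stage (lowest temperature) carries harmonic restraints on
    mobile environment atoms; restraints are removed for the remainder.
    The final stage is the production stage at ``production_temperature``.
    """
    temps = default_heating_temperatures(production_temperature)
    stages: list[ScheduleStage] = []
    if restrained_first_stage:
        stages.append(
            ScheduleStage(
                temperature=temps[0],
                steps=heating_steps,
                restraints={"backbone": backbone_k, "other": other_k},
            )
        )
    for t in temps:
        stages.append(ScheduleStage(temperature=t, steps=heating_steps))
    stages.append(ScheduleStage(temperature=production_temperature, steps=production_steps))
    return stages
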