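"""Energy terms and analytic gradients for flexible-topology systems.

Every term returns an :class:`EnergyReport` carrying the term energies
and the gradients of the total with respect to particle positions and
to the dynamic attributes (q, sigma, epsilon).  Gradients are analytic;
the test suite checks them against central finite differences.

Terms
-----
``ft_env``
    Lennard-Jones + Coulomb between FT particles and environment atoms,
    with Lorentz-Berthelot mixing (arithmetic sigma, geometric epsilon).
``ft_ft_elec``
    Supercharged Coulomb between FT pairs: g * sum k_e q_i q_j / r_ij.
``ft_ft_lj``
    Steric LJ between FT pairs (same mixing rules); optional.
``continuity``
    Harmonic attraction k (r - d)^2 between the closest pairs bridging
    disconnected components of the cutoff graph.
``attr_restraint``
    Per-particle restraint A f(sigma)(eps-1/4)^2 + B f(sigma)(q-1/4)^2
    with sigmoidal switch f(sigma).
``centroid_restraint``
    Flat-bottom harmonic keeping each particle within d0 of the site
    centroid.
``env_restraint``
    Harmonic position restraints on mobile environment atoms (used in
    the restrained heating stage only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ForceParams, SimulationSystem
from .errors import SingularGeometryError

ALL_TERMS = (
    "ft_env",
    "ft_ft_elec",
    "ft_ft_lj",
    "continuity",
    "attr_restraint",
    "centroid_restraint",
)


@dataclass
class SystemArrays:
    """Flat array view of a :class:`SimulationSystem` for fast evaluation."""

    ft_pos: np.ndarray  # (N, 3) nm
    q: np.ndarray  # (N,) e
    sigma: np.ndarray  # (N,) nm
    epsilon: np.ndarray  # (N,) kJ/mol
    env_pos: np.ndarray  # (M, 3) nm
    env_q: np.ndarray
    env_sigma: np.ndarray
    env_epsilon: np.ndarray
    env_mobile: np.ndarray  # (M,) bool
    env_group: list[str]
    env_ref_pos: np.ndarray  # (M, 3) reference positions for restraints
    ft_mass: np.ndarray  # (N,) amu
    env_mass: np.ndarray
    mob_q: np.ndarray  # (N,) Brownian mobilities
    mob_sigma: np.ndarray
    mob_epsilon: np.ndarray
    centroid: np.ndarray  # (3,)
    params: ForceParams
    box: np.ndarray | None = None

    @classmethod
    def from_system(cls, system: SimulationSystem) -> "SystemArrays":
        env = system.environment
        parts = system.particles
        return cls(
            ft_pos=np.array([p.position for p in parts], dtype=float).reshape(len(parts), 3),
            q=np.array([p.attrs.q for p in parts], dtype=float),
            sigma=np.array([p.attrs.sigma for p in parts], dtype=float),
            epsilon=np.array([p.attrs.epsilon for p in parts], dtype=float),
            env_pos=np.array([a.position for a in env], dtype=float).reshape(len(env), 3),
            env_q=np.array([a.q for a in env], dtype=float),
            env_sigma=np.array([a.sigma for a in env], dtype=float),
            env_epsilon=np.array([a.epsilon for a in env], dtype=float),
            env_mobile=np.array([a.mobile for a in env], dtype=bool),
            env_group=[a.group for a in env],
            env_ref_pos=np.array([a.position for a in env], dtype=float).reshape(len(env), 3),
            ft_mass=np.array([p.mass for p in parts], dtype=float),
            env_mass=np.array([a.mass for a in env], dtype=float),
            mob_q=np.array([p.mobilities.q for p in parts], dtype=float),
            mob_sigma=np.array([p.mobilities.sigma for p in parts], dtype=float),
            mob_epsilon=np.array([p.mobilities.epsilon for p in parts], dtype=float),
            centroid=np.asarray(system.centroid, dtype=float),
            params=system.force_params,
            box=None if system.box is None else np.asarray(system.box, dtype=float),
        )

    def write_back(self, system: SimulationSystem) -> None:
        """Copy positions and attributes back into the object model."""
        for i, p in enumerate(system.particles):
            p.position = self.ft_pos[i].copy()
            p.attrs.q = float(self.q[i])
            p.attrs.sigma = float(self.sigma[i])
            p.attrs.epsilon = float(self.epsilon[i])
        for j, a in enumerate(system.environment):
            a.position = self.env_pos[j].copy()

    @property
    def n_ft(self) -> int:
        return self.ft_pos.shape[0]

    @property
    def n_env(self) -> int:
        return self.env_pos.shape[0]


@dataclass
class EnergyReport:
    """Per-term energies and full gradient vectors."""

    terms: dict[str, float] = field(default_factory=dict)
    ft_position_grad: np.ndarray = None  # (N, 3) kJ/mol/nm
    env_position_grad: np.ndarray = None  # (M, 3)
    charge_grad: np.ndarray = None  # (N,) kJ/mol/e
    sigma_grad: np.ndarray = None  # (N,) kJ/mol/nm
    epsilon_grad: np.ndarray = None  # (N,) dimensionless

    @classmethod
    def zeros(cls, n_ft: int, n_env: int) -> "EnergyReport":
        return cls(
            terms={},
            ft_position_grad=np.zeros((n_ft, 3)),
            env_position_grad=np.zeros((n_env, 3)),
            charge_grad=np.zeros(n_ft),
            sigma_grad=np.zeros(n_ft),
            epsilon_grad=np.zeros(n_ft),
        )

    @property
    def total(self) -> float:
        return float(sum(self.terms.values()))


def _displacements(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Pairwise displacement vectors a[:, None] - b[None, :], minimum image."""
    d = a[:, None, :] - b[None, :, :]
    if box is not None:
        d -= box * np.round(d / box)
    return d


def _check_distances(r: np.ndarray, context: str) -> None:
    if r.size and float(r.min()) <= 0.0:
        raise SingularGeometryError(f"coincident particles in {context} (r = 0)")


def _pair_nonbonded(
    report: EnergyReport,
    arrays: SystemArrays,
    *,
    lj: bool,
    coulomb_scale: float,
    repulsive_only: bool,
    ft_ft: bool,
) -> float:
    """Shared kernel for the FT-env and FT-FT nonbonded terms.

    Returns the term energy and accumulates all gradients in ``report``.
    For FT-FT, both members of each pair receive attribute gradients.
    """
    p = arrays.params
    ke = p.coulomb_constant
    if ft_ft:
        n = arrays.n_ft
        if n < 2:
            return 0.0
        ii, jj = np.triu_indices(n, k=1)
        diff = arrays.ft_pos[ii] - arrays.ft_pos[jj]
        if arrays.box is not None:
            diff -= arrays.box * np.round(diff / arrays.box)
        qj, sj, ej = arrays.q[jj], arrays.sigma[jj], arrays.epsilon[jj]
        qi, si, ei = arrays.q[ii], arrays.sigma[ii], arrays.epsilon[ii]
    else:
        if arrays.n_env == 0:
            return 0.0
        diff = _displacements(arrays.ft_pos, arrays.env_pos, arrays.box)
        qi = arrays.q[:, None]
        si = arrays.sigma[:, None]
        ei = arrays.epsilon[:, None]
        qj, sj, ej = arrays.env_q[None, :], arrays.env_sigma[None, :], arrays.env_epsilon[None, :]

    r2 = np.einsum("...k,...k->...", diff, diff)
    r = np.sqrt(r2)
    _check_distances(r, "FT-FT pair" if ft_ft else "FT-environment pair")
    inv_r = 1.0 / r

    cut = p.nonbonded_cutoff
    within = None if cut is None else (r <= cut)

    energy = 0.0
    dVdr = np.zeros_like(r)

    if lj:
        sij = 0.5 * (si + sj)
        eij = np.sqrt(ei * ej)
        sr2 = (sij * inv_r) ** 2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        vlj = 4.0 * eij * (sr12 - sr6)
        dlj_dr = 4.0 * eij * (6.0 * sr6 - 12.0 * sr12) * inv_r
        # d(vlj)/d(sigma_ij), times d(sigma_ij)/d(sigma_i) = 1/2
        with np.errstate(divide="ignore", invalid="ignore"):
            dlj_dsig_i = np.where(sij > 0, 0.5 * 4.0 * eij * (12.0 * sr12 - 6.0 * sr6) / sij, 0.0)
            # d(vlj)/d(eps_i) = vlj / (2 eps_i); exactly 0 when eij == 0
            dlj_deps_i = np.where(ei > 0, vlj / (2.0 * np.maximum(ei, 1e-300)), 0.0)
            dlj_deps_j = np.where(ej > 0, vlj / (2.0 * np.maximum(ej, 1e-300)), 0.0)
        if within is not None:
            vlj = np.where(within, vlj, 0.0)
            dlj_dr = np.where(within, dlj_dr, 0.0)
            dlj_dsig_i = np.where(within, dlj_dsig_i, 0.0)
            dlj_deps_i = np.where(within, dlj_deps_i, 0.0)
            dlj_deps_j = np.where(within, dlj_deps_j, 0.0)
        energy += float(vlj.sum())
        dVdr += dlj_dr
        if ft_ft:
            np.add.at(report.sigma_grad, ii, dlj_dsig_i)
            np.add.at(report.sigma_grad, jj, dlj_dsig_i)  # symmetric in the pair
            np.add.at(report.epsilon_grad, ii, dlj_deps_i)
            np.add.at(report.epsilon_grad, jj, dlj_deps_j)
        else:
            report.sigma_grad += dlj_dsig_i.sum(axis=1)
            report.epsilon_grad += dlj_deps_i.sum(axis=1)

    if coulomb_scale != 0.0:
        qq = qi * qj
        if repulsive_only:
            keep = qq > 0
        else:
            keep = None
        vc = coulomb_scale * ke * qq * inv_r
        dq_i = coulomb_scale * ke * qj * inv_r
        dq_j = coulomb_scale * ke * qi * inv_r
        if keep is not None:
            vc = np.where(keep, vc, 0.0)
            dq_i = np.where(keep, dq_i, 0.0)
            dq_j = np.where(keep, dq_j, 0.0)
        if within is not None:
            vc = np.where(within, vc, 0.0)
            dq_i = np.where(within, dq_i, 0.0)
            dq_j = np.where(within, dq_j, 0.0)
        energy += float(vc.sum())
        dVdr += -vc * inv_r
        if ft_ft:
            np.add.at(report.charge_grad, ii, dq_i)
            np.add.at(report.charge_grad, jj, dq_j)
        else:
            report.charge_grad += dq_i.sum(axis=1)

    # position gradients: dV/dx_i = dV/dr * (x_i - x_j)/r
    gvec = (dVdr * inv_r)[..., None] * diff
    if ft_ft:
        np.add.at(report.ft_position_grad, ii, gvec)
        np.add.at(report.ft_position_grad, jj, -gvec)
    else:
        report.ft_position_grad += gvec.sum(axis=1)
        report.env_position_grad += -gvec.sum(axis=0)
    return energy


def _connected_components(r: np.ndarray, cutoff: float) -> np.ndarray:
    """Component label per particle for the cutoff graph (edges r <= cutoff)."""
    n = r.shape[0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    adj = r <= cutoff
    for i in range(n - 1):
        row = adj[i]
        for j in range(i + 1, n):
            if row[j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    labels = np.array([find(i) for i in range(n)])
    # relabel 0..k-1
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def _continuity(report: EnergyReport, arrays: SystemArrays) -> float:
    """Harmonic attraction bridging disconnected cutoff-graph components.

    With ``pairing="all"`` every pair of particles from two different
    components contributes k (r - d)^2; with ``pairing="closest"`` each
    component other than the largest contributes a single term for the
    closest pair joining it to its nearest other component (duplicate
    pairs counted once).  Energy is zero iff the graph has a single
    component.
    """
    cp = arrays.params.continuity
    n = arrays.n_ft
    if n < 2:
        return 0.0
    diff = _displacements(arrays.ft_pos, arrays.ft_pos, arrays.box)
    r = np.sqrt(np.einsum("...k,...k->...", diff, diff))
    np.fill_diagonal(r, np.inf)
    labels = _connected_components(r, cp.cutoff)
    n_comp = labels.max() + 1
    if n_comp == 1:
        return 0.0
    if cp.pairing == "all":
        ii, jj = np.where(
            (labels[:, None] != labels[None, :]) & (np.arange(n)[:, None] < np.arange(n))
        )
        rij = r[ii, jj]
        delta = rij - cp.cutoff
        energy = float(cp.k * (delta * delta).sum())
        g = (2.0 * cp.k * delta / rij)[:, None] * diff[ii, jj]
        np.add.at(report.ft_position_grad, ii, g)
        np.add.at(report.ft_position_grad, jj, -g)
        return energy
    sizes = np.bincount(labels)
    largest = int(np.argmax(sizes))
    pairs: set[tuple[int, int]] = set()
    for c in range(n_comp):
        if c == largest:
            continue
        inside = np.where(labels == c)[0]
        outside = np.where(labels != c)[0]
        sub = r[np.ix_(inside, outside)]
        k_flat = int(np.argmin(sub))
        i = int(inside[k_flat // len(outside)])
        j = int(outside[k_flat % len(outside)])
        pairs.add((min(i, j), max(i, j)))
    energy = 0.0
    for i, j in pairs:
        rij = r[i, j]
        delta = rij - cp.cutoff
        energy += cp.k * delta * delta
        g = 2.0 * cp.k * delta / rij
        d = diff[i, j]
        report.ft_position_grad[i] += g * d
        report.ft_position_grad[j] -= g * d
    return energy


def _attr_restraint(report: EnergyReport, arrays: SystemArrays) -> float:
    ap = arrays.params.attr_force
    x = np.clip(ap.C * (arrays.sigma - ap.center), -500.0, 500.0)
    f = 1.0 / (1.0 + np.exp(x))
    fprime = -ap.C * f * (1.0 - f)
    de = arrays.epsilon - ap.offset
    dq = arrays.q - ap.offset
    pref = ap.A * de * de + ap.B * dq * dq
    energy = float((pref * f).sum())
    report.sigma_grad += pref * fprime
    report.epsilon_grad += 2.0 * ap.A * f * de
    report.charge_grad += 2.0 * ap.B * f * dq
    return energy


def _centroid_restraint(report: EnergyReport, arrays: SystemArrays) -> float:
    cp = arrays.params.centroid
    diff = arrays.ft_pos - arrays.centroid
    d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    # H(0) = 0: the restraint activates strictly outside d0
    out = d > cp.d0
    if not out.any():
        return 0.0
    delta = np.where(out, d - cp.d0, 0.0)
    energy = float(0.5 * cp.k * (delta * delta).sum())
    with np.errstate(invalid="ignore"):
        g = np.where(out, cp.k * delta / np.maximum(d, 1e-300), 0.0)
    report.ft_position_grad += g[:, None] * diff
    return energy


def _env_restraint(
    report: EnergyReport, arrays: SystemArrays, restraints: dict[str, float]
) -> float:
    energy = 0.0
    for j in range(arrays.n_env):
        if not arrays.env_mobile[j]:
            continue
        k = restraints.get(arrays.env_group[j])
        if not k:
            continue
        d = arrays.env_pos[j] - arrays.env_ref_pos[j]
        energy += 0.5 * k * float(d @ d)
        report.env_position_grad[j] += k * d
    return energy


def compute_energy(
    arrays: SystemArrays,
    terms: tuple[str, ...] | None = None,
    restraints: dict[str, float] | None = None,
) -> EnergyReport:
    """Evaluate the selected energy terms and their gradients.

    Parameters
    ----------
    arrays
        Flat array view of the system.
    terms
        Subset of :data:`ALL_TERMS`; None evaluates every enabled term.
    restraints
        Stage restraint map (group -> force constant) for mobile
        environment atoms; adds an ``env_restraint`` term when given.
    """
    p = arrays.params
    if terms is None:
        terms = ALL_TERMS
    report = EnergyReport.zeros(arrays.n_ft, arrays.n_env)
    if "ft_env" in terms:
        report.terms["ft_env"] = _pair_nonbonded(
            report, arrays, lj=True, coulomb_scale=1.0, repulsive_only=False, ft_ft=False
        )
    if "ft_ft_elec" in terms and p.ft_ft_elec != "off":
        report.terms["ft_ft_elec"] = _pair_nonbonded(
            report,
            arrays,
            lj=False,
            coulomb_scale=p.supercharge,
            repulsive_only=(p.ft_ft_elec == "repulsive"),
            ft_ft=True,
        )
    if "ft_ft_lj" in terms and p.ft_ft_lj:
        report.terms["ft_ft_lj"] = _pair_nonbonded(
            report, arrays, lj=True, coulomb_scale=0.0, repulsive_only=False, ft_ft=True
        )
    if "continuity" in terms:
        report.terms["continuity"] = _continuity(report, arrays)
    if "attr_restraint" in terms:
        report.terms["attr_restraint"] = _attr_restraint(report, arrays)
    if "centroid_restraint" in terms:
        report.terms["centroid_restraint"] = _centroid_restraint(report, arrays)
    if restraints is not None:
        report.terms["env_restraint"] = _env_restraint(report, arrays, restraints)
    return report


# ---------------------------------------------------------------------------
# Public per-term operations on SimulationSystem objects


def ft_env_nonbonded(system: SimulationSystem) -> EnergyReport:
    """LJ + Coulomb between FT particles and environment atoms (mixed rules)."""
    return compute_energy(SystemArrays.from_system(system), terms=("ft_env",))


def ft_ft_electrostatics(system: SimulationSystem, g: float | None = None) -> EnergyReport:
    """Supercharged FT-FT Coulomb energy: g * sum k_e q_i q_j / r_ij."""
    arrays = SystemArrays.from_system(system)
    if g is not None:
        import dataclasses as _dc

        arrays.params = _dc.replace(arrays.params, supercharge=g)
    report = EnergyReport.zeros(arrays.n_ft, arrays.n_env)
    if arrays.params.ft_ft_elec == "off":
        report.terms["ft_ft_elec"] = 0.0
        return report
    report.terms["ft_ft_elec"] = _pair_nonbonded(
        report,
        arrays,
        lj=False,
        coulomb_scale=arrays.params.supercharge,
        repulsive_only=(arrays.params.ft_ft_elec == "repulsive"),
        ft_ft=True,
    )
    return report


def ft_ft_lj(system: SimulationSystem) -> EnergyReport:
    """Steric FT-FT Lennard-Jones term (same mixing rules as FT-env)."""
    arrays = SystemArrays.from_system(system)
    report = EnergyReport.zeros(arrays.n_ft, arrays.n_env)
    report.terms["ft_ft_lj"] = _pair_nonbonded(
        report, arrays, lj=True, coulomb_scale=0.0, repulsive_only=False, ft_ft=True
    )
    return report


def continuity(system: SimulationSystem) -> EnergyReport:
    """Harmonic attraction between disconnected cutoff-graph components."""
    return compute_energy(SystemArrays.from_system(system), terms=("continuity",))


def attr_restraint(system: SimulationSystem) -> EnergyReport:
    """Sigmoid-switched quadratic restraint on (q, epsilon) below sigma=0.3."""
    return compute_energy(SystemArrays.from_system(system), terms=("attr_restraint",))


def centroid_restraint(system: SimulationSystem) -> EnergyReport:
    """Flat-bottom harmonic on each particle's distance to the centroid."""
    return compute_energy(SystemArrays.from_system(system), terms=("centroid_restraint",))


def total_energy(
    system: SimulationSystem, restraints: dict[str, float] | None = None
) -> EnergyReport:
    """All enabled terms with complete gradient vectors."""
    return compute_energy(SystemArrays.from_system(system), restraints=restraints)
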