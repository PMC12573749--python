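"""Hybrid integrator: Langevin positions, Brownian attributes.

Positions evolve with Langevin dynamics (BAOAB splitting); the dynamic
attributes (q, sigma, epsilon) evolve with overdamped Brownian dynamics,
which avoids ascribing velocities to the attributes and makes the
attribute bounds easy to enforce.  After every attribute step a
constraint pipeline runs: clamp to bounds, shift charges to the target
sum, cap the charge variance at S_max, final clamp.

The charge-variance cap divides the charge deviations from the mean by
sqrt(S_q / S_max) whenever S_q = (1/n) sum_i (q_i - qbar)^2 exceeds
S_max; combined with the zero-sum constraint this bounds the rms charge
at sqrt(S_max).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    BOLTZMANN_KJ_MOL_K,
    SIM_BOUNDS,
    AttributeState,
    ScheduleStage,
    SimulationSystem,
    TrajectoryFrame,
)
from .errors import IntegrationError
from .forces import SystemArrays, _connected_components, _displacements, compute_energy

__all__ = [
    "ChargeConstraintState",
    "HybridIntegrator",
    "Trajectory",
    "brownian_attribute_step",
    "cap_charge_variance",
    "clamp_attribute_bounds",
    "clamp_attributes",
    "enforce_charge_sum",
    "langevin_position_step",
    "minimize",
    "run_schedule",
]


@dataclass
class ChargeConstraintState:
    """Snapshot of the charge-constraint diagnostics after enforcement."""

    target_sum: float
    s_max: float
    s_q: float
    mean_q: float


# ---------------------------------------------------------------------------
# Constraint pipeline


def clamp_attributes(
    q: np.ndarray, sigma: np.ndarray, epsilon: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project each attribute array onto its closed simulation interval."""
    return (
        np.clip(q, *SIM_BOUNDS["q"]),
        np.clip(sigma, *SIM_BOUNDS["sigma"]),
        np.clip(epsilon, *SIM_BOUNDS["epsilon"]),
    )


def clamp_attribute_bounds(attrs: AttributeState) -> AttributeState:
    """Single-particle convenience form of :func:`clamp_attributes`."""
    lo, hi = SIM_BOUNDS["q"]
    q = min(max(attrs.q, lo), hi)
    lo, hi = SIM_BOUNDS["sigma"]
    sigma = min(max(attrs.sigma, lo), hi)
    lo, hi = SIM_BOUNDS["epsilon"]
    epsilon = min(max(attrs.epsilon, lo), hi)
    return AttributeState(q=q, sigma=sigma, epsilon=epsilon)


def enforce_charge_sum(charges: np.ndarray, target: float = 0.0) -> np.ndarray:
    """Uniformly shift the charges so that their sum equals ``target``."""
    charges = np.asarray(charges, dtype=float)
    n = charges.size
    return charges - (charges.sum() - target) / n


def cap_charge_variance(charges: np.ndarray, s_max: float) -> np.ndarray:
    """Scale charge deviations from the mean so that S_q <= S_max.

    S_q = (1/n) sum (q_i - qbar)^2.  When S_q > S_max the deviations are
    multiplied by sqrt(S_max / S_q), giving exactly S_q = S_max; the mean
    (and hence the charge sum) is preserved.
    """
    charges = np.asarray(charges, dtype=float)
    mean = charges.mean()
    dev = charges - mean
    s_q = float(np.mean(dev * dev))
    if s_q <= s_max:
        return charges.copy()
    return mean + dev * np.sqrt(s_max / s_q)


def apply_charge_constraints(
    q: np.ndarray,
    sigma: np.ndarray,
    epsilon: np.ndarray,
    target: float,
    s_max: float,
    tol: float = 1e-13,
    max_sweeps: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, ChargeConstraintState]:
    """Constraint pipeline: sweeps of clamp -> sum shift -> variance cap.

    The three charge constraints (box bounds, fixed sum, capped
    variance) are convex sets with a nonempty intersection, so
    alternating the projections converges to a point satisfying all
    three simultaneously; sweeps repeat until every constraint holds to
    ``tol``.  Almost always a single sweep suffices — further sweeps
    only trigger when the clamp truncates an outlier charge, which
    would otherwise leave a small residual in the sum.
    """
    lo, hi = SIM_BOUNDS["q"]
    sigma = np.clip(sigma, *SIM_BOUNDS["sigma"])
    epsilon = np.clip(epsilon, *SIM_BOUNDS["epsilon"])
    q = np.asarray(q, dtype=float)
    for _ in range(max_sweeps):
        q = np.clip(q, lo, hi)
        q = enforce_charge_sum(q, target)
        q = cap_charge_variance(q, s_max)
        if (
            q.min() >= lo - tol
            and q.max() <= hi + tol
            and abs(q.sum() - target) <= tol
            and np.var(q) <= s_max + tol
        ):
            break
    q = np.clip(q, lo, hi)
    state = ChargeConstraintState(
        target_sum=target,
        s_max=s_max,
        s_q=float(np.var(q)),
        mean_q=float(np.mean(q)),
    )
    return q, sigma, epsilon, state


# ---------------------------------------------------------------------------
# Integrator


class HybridIntegrator:
    """BAOAB Langevin positions + Brownian attributes with constraints.

    One force evaluation per step: the closing velocity half-kick uses
    the freshly computed force at the new positions, which is cached and
    reused for the opening half-kick of the next step.  The attribute
    gradients from the same evaluation drive the Brownian attribute
    update.
    """

    def __init__(
        self,
        arrays: SystemArrays,
        timestep: float,
        friction: float,
        rng: np.random.Generator,
    ):
        self.arrays = arrays
        self.dt = float(timestep)
        self.friction = float(friction)
        self.rng = rng
        self.ft_vel = np.zeros_like(arrays.ft_pos)
        self.env_vel = np.zeros_like(arrays.env_pos)
        self._c1 = np.exp(-self.friction * self.dt)
        self._c2 = np.sqrt(1.0 - self._c1 * self._c1)
        self._report = None
        self._restraints_key = None
        self.last_constraint_state: ChargeConstraintState | None = None

    def _force_eval(self, restraints):
        report = compute_energy(self.arrays, restraints=restraints)
        ft_f = -report.ft_position_grad
        env_f = -report.env_position_grad
        if not np.isfinite(ft_f).all():
            bad = int(np.argwhere(~np.isfinite(ft_f))[0][0])
            raise IntegrationError(f"non-finite force on FT particle {bad}")
        if not np.isfinite(env_f).all():
            bad = int(np.argwhere(~np.isfinite(env_f))[0][0])
            raise IntegrationError(f"non-finite force on environment atom {bad}")
        return report, ft_f, env_f

    def step(self, temperature: float, restraints: dict[str, float] | None = None) -> None:
        a = self.arrays
        dt = self.dt
        kbt = BOLTZMANN_KJ_MOL_K * temperature
        key = None if restraints is None else tuple(sorted(restraints.items()))
        if self._report is None or key != self._restraints_key:
            self._report, self._ft_f, self._env_f = self._force_eval(restraints)
            self._restraints_key = key

        mobile = a.env_mobile
        # B (half kick)
        self.ft_vel += 0.5 * dt * self._ft_f / a.ft_mass[:, None]
        if mobile.any():
            self.env_vel[mobile] += 0.5 * dt * self._env_f[mobile] / a.env_mass[mobile, None]
        # A (half drift)
        a.ft_pos += 0.5 * dt * self.ft_vel
        if mobile.any():
            a.env_pos[mobile] += 0.5 * dt * self.env_vel[mobile]
        # O (thermostat)
        scale = np.sqrt(kbt / a.ft_mass)[:, None]
        self.ft_vel = self._c1 * self.ft_vel + self._c2 * scale * self.rng.standard_normal(
            self.ft_vel.shape
        )
        if mobile.any():
            escale = np.sqrt(kbt / a.env_mass[mobile])[:, None]
            self.env_vel[mobile] = (
                self._c1 * self.env_vel[mobile]
                + self._c2 * escale * self.rng.standard_normal((int(mobile.sum()), 3))
            )
        # A (half drift)
        a.ft_pos += 0.5 * dt * self.ft_vel
        if mobile.any():
            a.env_pos[mobile] += 0.5 * dt * self.env_vel[mobile]
        # force at new positions, B (half kick)
        self._report, self._ft_f, self._env_f = self._force_eval(restraints)
        self.ft_vel += 0.5 * dt * self._ft_f / a.ft_mass[:, None]
        if mobile.any():
            self.env_vel[mobile] += 0.5 * dt * self._env_f[mobile] / a.env_mass[mobile, None]

        # Brownian attribute update from the same report
        r = self._report
        for grad in (r.charge_grad, r.sigma_grad, r.epsilon_grad):
            if not np.isfinite(grad).all():
                bad = int(np.argwhere(~np.isfinite(grad))[0][0])
                raise IntegrationError(f"non-finite attribute gradient on particle {bad}")
        noise = self.rng.standard_normal((3, a.n_ft))
        a.q -= a.mob_q * dt * r.charge_grad
        a.q += np.sqrt(2.0 * kbt * a.mob_q * dt) * noise[0]
        a.sigma -= a.mob_sigma * dt * r.sigma_grad
        a.sigma += np.sqrt(2.0 * kbt * a.mob_sigma * dt) * noise[1]
        a.epsilon -= a.mob_epsilon * dt * r.epsilon_grad
        a.epsilon += np.sqrt(2.0 * kbt * a.mob_epsilon * dt) * noise[2]

        cc = a.params.charge_constraint
        a.q, a.sigma, a.epsilon, self.last_constraint_state = apply_charge_constraints(
            a.q, a.sigma, a.epsilon, cc.target_sum, cc.s_max
        )


# ---------------------------------------------------------------------------
# Single-step operations (spec surface; thin wrappers over the integrator)


def langevin_position_step(
    system: SimulationSystem,
    temperature: float,
    timestep: float | None = None,
    friction: float | None = None,
    rng: np.random.Generator | None = None,
    velocities: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One stochastic Langevin step of the FT positions.

    Returns the updated positions and velocities; frozen environment
    atoms are untouched.  For long runs prefer :class:`HybridIntegrator`
    or :func:`run_schedule`, which carry velocity state internally.
    """
    rng = rng if rng is not None else np.random.default_rng(system.seed)
    arrays = SystemArrays.from_system(system)
    integ = HybridIntegrator(
        arrays,
        timestep if timestep is not None else system.timestep,
        friction if friction is not None else system.friction,
        rng,
    )
    if velocities is not None:
        integ.ft_vel = np.array(velocities, dtype=float)
    # Run a full hybrid step but restore the attributes: this op moves
    # positions only.
    q0, s0, e0 = arrays.q.copy(), arrays.sigma.copy(), arrays.epsilon.copy()
    integ.step(temperature)
    arrays.q, arrays.sigma, arrays.epsilon = q0, s0, e0
    arrays.write_back(system)
    return arrays.ft_pos.copy(), integ.ft_vel.copy()


def brownian_attribute_step(
    system: SimulationSystem,
    temperature: float,
    timestep: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One overdamped Brownian step of all attributes + constraint pipeline.

    a <- a - mu_a dt dV/da + sqrt(2 kB T mu_a dt) xi, then
    clamp -> charge-sum shift -> variance cap -> final clamp.
    Returns the updated (q, sigma, epsilon) arrays.
    """
    rng = rng if rng is not None else np.random.default_rng(system.seed)
    dt = timestep if timestep is not None else system.timestep
    arrays = SystemArrays.from_system(system)
    kbt = BOLTZMANN_KJ_MOL_K * temperature
    report = compute_energy(arrays)
    for grad in (report.charge_grad, report.sigma_grad, report.epsilon_grad):
        if not np.isfinite(grad).all():
            bad = int(np.argwhere(~np.isfinite(grad))[0][0])
            raise IntegrationError(f"non-finite attribute gradient on particle {bad}")
    noise = rng.standard_normal((3, arrays.n_ft))
    arrays.q += -arrays.mob_q * dt * report.charge_grad + np.sqrt(
        2.0 * kbt * arrays.mob_q * dt
    ) * noise[0]
    arrays.sigma += -arrays.mob_sigma * dt * report.sigma_grad + np.sqrt(
        2.0 * kbt * arrays.mob_sigma * dt
    ) * noise[1]
    arrays.epsilon += -arrays.mob_epsilon * dt * report.epsilon_grad + np.sqrt(
        2.0 * kbt * arrays.mob_epsilon * dt
    ) * noise[2]
    cc = arrays.params.charge_constraint
    arrays.q, arrays.sigma, arrays.epsilon, _ = apply_charge_constraints(
        arrays.q, arrays.sigma, arrays.epsilon, cc.target_sum, cc.s_max
    )
    arrays.write_back(system)
    return arrays.q.copy(), arrays.sigma.copy(), arrays.epsilon.copy()


# ---------------------------------------------------------------------------
# Minimization


def minimize(
    system: SimulationSystem,
    what: str = "attributes",
    max_steps: int = 1000,
    tolerance: float = 100.0,
) -> SimulationSystem:
    """Projected gradient descent on one coordinate block.

    Parameters
    ----------
    what
        "attributes" minimizes over (q, sigma, epsilon) with bound
        projection; "positions" minimizes over FT (and mobile
        environment) positions.
    tolerance
        Stop when the rms gradient over the block drops below this value
        [kJ/mol per unit coordinate].

    Energy is non-increasing across accepted steps (backtracking line
    search; a candidate is accepted only if its energy does not exceed
    the current one).
    """
    if what not in ("attributes", "positions"):
        raise ValueError(f"unknown block {what!r}")
    arrays = SystemArrays.from_system(system)
    report = compute_energy(arrays)
    energy = report.total
    if not np.isfinite(energy):
        raise IntegrationError("non-finite energy at start of minimization")

    alpha = 1e-4
    for _ in range(max_steps):
        if what == "attributes":
            grad = np.concatenate([report.charge_grad, report.sigma_grad, report.epsilon_grad])
        else:
            grad = np.concatenate(
                [
                    report.ft_position_grad.ravel(),
                    report.env_position_grad[arrays.env_mobile].ravel(),
                ]
            )
        rms = float(np.sqrt(np.mean(grad * grad))) if grad.size else 0.0
        if rms < tolerance:
            break
        accepted = False
        # cap the largest single-coordinate move at 0.02 (nm or attribute
        # units) so steep-overlap gradients cannot tunnel particles
        # through repulsive walls
        gmax = float(np.abs(grad).max())
        trial = min(alpha, 0.02 / gmax) if gmax > 0 else alpha
        for _bt in range(40):
            cand = _apply_step(arrays, what, grad, trial)
            cand_report = compute_energy(cand)
            if np.isfinite(cand_report.total) and cand_report.total <= energy:
                arrays = cand
                report = cand_report
                energy = cand_report.total
                accepted = True
                alpha = trial * 1.5
                break
            trial *= 0.5
        if not accepted:
            break
    arrays.write_back(system)
    return system


def _apply_step(arrays: SystemArrays, what: str, grad: np.ndarray, alpha: float) -> SystemArrays:
    import copy

    cand = copy.copy(arrays)
    cand.ft_pos = arrays.ft_pos.copy()
    cand.env_pos = arrays.env_pos.copy()
    cand.q = arrays.q.copy()
    cand.sigma = arrays.sigma.copy()
    cand.epsilon = arrays.epsilon.copy()
    n = arrays.n_ft
    if what == "attributes":
        gq, gs, ge = grad[:n], grad[n : 2 * n], grad[2 * n :]
        cand.q -= alpha * gq
        cand.sigma -= alpha * gs
        cand.epsilon -= alpha * ge
        cand.q, cand.sigma, cand.epsilon = clamp_attributes(cand.q, cand.sigma, cand.epsilon)
    else:
        gft = grad[: 3 * n].reshape(n, 3)
        cand.ft_pos -= alpha * gft
        mob = arrays.env_mobile
        if mob.any():
            genv = grad[3 * n :].reshape(-1, 3)
            cand.env_pos[mob] -= alpha * genv
    return cand


# ---------------------------------------------------------------------------
# Schedule runner


@dataclass
class Trajectory:
    """Saved production frames plus per-run constraint diagnostics."""

    frames: list[TrajectoryFrame] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)


def run_schedule(
    system: SimulationSystem,
    stages: list[ScheduleStage],
    save_every: int = 2000,
    rng: np.random.Generator | None = None,
    write_back: bool = True,
) -> Trajectory:
    """Execute the stages in order; save frames during the final stage.

    The last stage is the production stage: every ``save_every``-th step
    of it is saved as a :class:`TrajectoryFrame`.  Per-step constraint
    diagnostics (worst charge-sum deviation, largest S_q, attribute
    bound violations, per-frame rms charge and cutoff-graph component
    count) are accumulated in ``Trajectory.diagnostics``.  Deterministic
    for a given rng/seed.
    """
    if not stages:
        raise ValueError("schedule must contain at least one stage")
    rng = rng if rng is not None else np.random.default_rng(system.seed)
    arrays = SystemArrays.from_system(system)
    integ = HybridIntegrator(arrays, system.timestep, system.friction, rng)
    cc = arrays.params.charge_constraint

    traj = Trajectory()
    max_sum_dev = 0.0
    max_s_q = 0.0
    bound_violations = 0
    max_step_rms_q = 0.0
    frame_rms_q: list[float] = []
    frame_components: list[int] = []

    for stage_idx, stage in enumerate(stages):
        production = stage_idx == len(stages) - 1
        for local_step in range(stage.steps):
            try:
                integ.step(stage.temperature, stage.restraints)
            except IntegrationError as err:
                raise IntegrationError(
                    f"stage {stage_idx} (T={stage.temperature} K), "
                    f"step {local_step}: {err}"
                ) from err
            q = arrays.q
            max_sum_dev = max(max_sum_dev, abs(float(q.sum()) - cc.target_sum))
            dev = q - q.mean()
            s_q = float(np.mean(dev * dev))
            max_s_q = max(max_s_q, s_q)
            rms_q = float(np.sqrt(np.mean(q * q)))
            max_step_rms_q = max(max_step_rms_q, rms_q)
            if (
                q.min() < SIM_BOUNDS["q"][0]
                or q.max() > SIM_BOUNDS["q"][1]
                or arrays.sigma.min() < SIM_BOUNDS["sigma"][0]
                or arrays.sigma.max() > SIM_BOUNDS["sigma"][1]
                or arrays.epsilon.min() < SIM_BOUNDS["epsilon"][0]
                or arrays.epsilon.max() > SIM_BOUNDS["epsilon"][1]
            ):
                bound_violations += 1
            if production and (local_step + 1) % save_every == 0:
                traj.frames.append(
                    TrajectoryFrame(
                        step=local_step + 1,
                        positions=arrays.ft_pos.copy(),
                        q=arrays.q.copy(),
                        sigma=arrays.sigma.copy(),
                        epsilon=arrays.epsilon.copy(),
                    )
                )
                frame_rms_q.append(rms_q)
                frame_components.append(_count_components(arrays))

    traj.diagnostics = {
        "max_charge_sum_deviation": max_sum_dev,
        "max_s_q": max_s_q,
        "bound_violation_steps": bound_violations,
        "max_step_rms_charge": max_step_rms_q,
        "frame_rms_charge": frame_rms_q,
        "frame_components": frame_components,
    }
    if write_back:
        arrays.write_back(system)
    return traj


def _count_components(arrays: SystemArrays) -> int:
    if arrays.n_ft < 2:
        return 1
    diff = _displacements(arrays.ft_pos, arrays.ft_pos, arrays.box)
    r = np.sqrt(np.einsum("...k,...k->...", diff, diff))
    np.fill_diagonal(r, np.inf)
    labels = _connected_components(r, arrays.params.continuity.cutoff)
    return int(labels.max() + 1)
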