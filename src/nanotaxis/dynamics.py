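"""Leapfrog stochastic (Langevin) dynamics with frozen beads and COM forces.

The integrator is the kick / friction-noise / drift splitting of leapfrog
Langevin dynamics: after the force kick, velocities are damped by
``exp(-gamma dt)`` and refreshed with the matching thermal noise, then
positions drift.  With the noise switched off and gamma -> 0 this reduces to
plain leapfrog (useful for energy-conservation checks); with noise on, the
stationary velocity distribution of a free particle is exactly Maxwellian at
the thermostat temperature.

Frozen beads (surface receptor anchors) are never integrated: their
velocities are pinned at zero and their positions are bit-identical across
the whole trajectory.  A constant external force on a group is distributed
over the group's mobile beads in proportion to their masses, which realizes
a constant force on the group's center of mass.  A one-sided power-law
restraint on the COM height keeps the particle near the surface; a
reflecting floor just above the surface plane guards the 9-3 wall from
penetration at the odd extreme velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forcefield import EnergyBreakdown, ForceField, RestraintParams
from .system import System
from .units import KB

__all__ = [
    "IntegratorParams",
    "ExternalForce",
    "Trajectory",
    "InstabilityError",
    "langevin_step",
    "run_md",
    "minimize",
    "kinetic_temperature",
    "thermalize",
]


def minimize(system: System, forcefield: ForceField, n_steps: int = 200,
             max_disp: float = 0.02) -> System:
    """Damped displacement-capped descent to relax bad contacts, in place.

    The production protocol minimizes before thermalizing, so builder
    artifacts (an unlucky counterion placement, a strained bond) cannot blow
    up the first Langevin steps.
    """
    ev = forcefield.evaluator(system)
    mobile = ~system.frozen
    for _ in range(n_steps):
        _, forces = ev.compute(system.positions)
        fmax = np.abs(forces[mobile]).max() if mobile.any() else 0.0
        if fmax < 10.0:
            break
        system.positions[mobile] += forces[mobile] * (max_disp / fmax)
    return system


class InstabilityError(RuntimeError):
    """A bead moved more than half a cutoff in one step."""


@dataclass(frozen=True)
class IntegratorParams:
    """Langevin integrator settings: 20 fs step, 300 K, per-bead friction."""

    dt: float = 0.02          # ps
    temperature: float = 300.0  # K
    gamma: float = 1.0        # ps^-1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.gamma <= 0 or self.temperature <= 0:
            raise ValueError("dt, gamma and temperature must be positive")


@dataclass(frozen=True)
class ExternalForce:
    """Constant force (kJ/mol/nm) on a group's center of mass.

    Distributed mass-weighted over the group's mobile beads so the group COM
    feels exactly ``vector``.
    """

    group: str = "np"
    vector: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class Trajectory:
    """Frames (times, positions, optional velocities, energy breakdowns)."""

    times: list[float] = field(default_factory=list)
    positions: list[np.ndarray] = field(default_factory=list)
    velocities: list[np.ndarray] = field(default_factory=list)
    energies: list[EnergyBreakdown] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    system: System | None = None  # final state (types/groups/topology)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def times_array(self) -> np.ndarray:
        return np.asarray(self.times)

    def positions_array(self) -> np.ndarray:
        return np.stack(self.positions)

    def com_trace(self, group: str) -> np.ndarray:
        """(n_frames, 3) mass-weighted COM of a named group over time."""
        idx = self.system.group(group)
        m = self.system.masses[idx]
        pos = self.positions_array()[:, idx]
        return (pos * m[None, :, None]).sum(axis=1) / m.sum()


def kinetic_temperature(system: System) -> float:
    """Instantaneous kinetic temperature of the mobile beads, K."""
    mobile = ~system.frozen
    n_dof = 3 * int(mobile.sum())
    if n_dof == 0:
        return 0.0
    ke = 0.5 * float((system.masses[mobile] * (system.velocities[mobile] ** 2).sum(axis=1)).sum())
    return 2.0 * ke / (n_dof * KB)


def thermalize(system: System, temperature: float, rng: np.random.Generator) -> None:
    """Draw Maxwell-Boltzmann velocities for the mobile beads, in place."""
    sigma = np.sqrt(KB * temperature / system.masses)
    system.velocities[:] = rng.normal(size=(system.n_beads, 3)) * sigma[:, None]
    system.velocities[system.frozen] = 0.0


def langevin_step(
    system: System,
    forces: np.ndarray,
    params: IntegratorParams,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> System:
    """One in-place leapfrog Langevin update; frozen beads stay put."""
    mobile = ~system.frozen
    m = system.masses
    v = system.velocities
    v[mobile] += forces[mobile] / m[mobile, None] * params.dt
    if noise:
        if rng is None:
            raise ValueError("noise=True requires an RNG")
        c1 = np.exp(-params.gamma * params.dt)
        c2 = np.sqrt((1.0 - c1 * c1) * KB * params.temperature / m[mobile])
        v[mobile] = c1 * v[mobile] + c2[:, None] * rng.normal(size=(int(mobile.sum()), 3))
    system.positions[mobile] += v[mobile] * params.dt
    system.time += params.dt
    return system


def _group_weights(system: System, group: str) -> tuple[np.ndarray, np.ndarray]:
    idx = system.group(group)
    idx = idx[~system.frozen[idx]]
    m = system.masses[idx]
    return idx, m / m.sum()


def run_md(
    system: System,
    n_steps: int,
    params: IntegratorParams,
    forcefield: ForceField,
    external: ExternalForce | None = None,
    restraint: RestraintParams | None = None,
    traj_stride: int = 100,
    bias_hook=None,
    stop=None,
    noise: bool = True,
    reporters: list | None = None,
    report_stride: int = 1000,
    copy: bool = True,
    rng: np.random.Generator | None = None,
    evaluator=None,
    record_initial: bool = True,
) -> Trajectory:
    """Integrate ``n_steps`` of Langevin dynamics and collect a trajectory.

    ``bias_hook(step, system, forces) -> float`` may add bias forces in place
    and return the bias energy (used by metadynamics); ``stop(step, system)``
    terminates the run early when true.  Identical (system, seed, config)
    give bit-identical trajectories on one platform.  A displacement larger
    than half the nonbonded cutoff in one step raises
    :class:`InstabilityError` with the last good frame kept in the returned
    trajectory.
    """
    sys_ = system.copy() if copy else system
    if rng is None:
        rng = np.random.default_rng(params.seed)
    ev = evaluator if evaluator is not None else forcefield.evaluator(sys_)
    mobile = ~sys_.frozen
    m = sys_.masses
    # frozen beads get zero inverse mass and zero noise amplitude, so the
    # whole-array update below leaves them (and their zero velocity) intact
    inv_m = np.where(mobile & (m > 0), 1.0 / m, 0.0)
    c1 = np.exp(-params.gamma * params.dt)
    c2 = np.sqrt((1.0 - c1 * c1) * KB * params.temperature) * np.sqrt(inv_m)
    inv_m_dt = (inv_m * params.dt)[:, None]
    c2_col = c2[:, None]
    max_disp = 0.5 * forcefield.pair_table.r_cut
    floor = None
    if forcefield.wall is not None:
        floor = forcefield.wall.z_ref + 0.05
        wall_mask = ev.wall_mask

    ext_idx = ext_w = None
    if external is not None:
        ext_idx, ext_w = _group_weights(sys_, external.group)
        ext_vec = np.asarray(external.vector, dtype=float)
    res_idx = res_w = None
    if restraint is not None:
        res_idx, res_w = _group_weights(sys_, restraint.group)

    traj = Trajectory(system=sys_, metadata={"seed": params.seed, "dt": params.dt})

    def add_extras(pos: np.ndarray, forces: np.ndarray, bd: EnergyBreakdown) -> None:
        if ext_idx is not None:
            forces[ext_idx] += ext_w[:, None] * ext_vec[None, :]
            bd.external = -float(np.dot(ext_vec, (pos[ext_idx] * ext_w[:, None]).sum(axis=0)))
        if res_idx is not None:
            z_com = float((pos[res_idx, 2] * res_w).sum())
            dz = z_com - restraint.z0
            if dz > 0:
                bd.restraint = restraint.kappa * dz**restraint.exp
                fz = -restraint.kappa * restraint.exp * dz ** (restraint.exp - 1)
                forces[res_idx, 2] += res_w * fz

    def record(step: int, bd: EnergyBreakdown) -> None:
        traj.times.append(sys_.time)
        traj.positions.append(sys_.positions.copy())
        traj.energies.append(bd)

    bd, forces = ev.compute(sys_.positions)
    add_extras(sys_.positions, forces, bd)
    if bias_hook is not None:
        bias_hook(0, sys_, forces)
    if record_initial:
        record(0, bd)

    v = sys_.velocities
    pos = sys_.positions
    n = sys_.n_beads
    for step in range(1, n_steps + 1):
        v += forces * inv_m_dt
        if noise:
            v *= c1
            v += c2_col * rng.normal(size=(n, 3))
        step_disp = np.abs(v).max() * params.dt if n else 0.0
        if step_disp > max_disp:
            raise InstabilityError(
                f"step {step}: displacement {step_disp:.3f} nm exceeds half the "
                f"cutoff; last good frame at t = {sys_.time:.3f} ps"
            )
        pos += v * params.dt
        if floor is not None:
            low = wall_mask & (pos[:, 2] < floor)
            if low.any():
                pos[low, 2] = 2 * floor - pos[low, 2]
                v[low, 2] *= -1.0
        sys_.time += params.dt

        bd, forces = ev.compute(pos)
        add_extras(pos, forces, bd)
        if bias_hook is not None:
            bias_hook(step, sys_, forces)
        if step % traj_stride == 0 or step == n_steps:
            record(step, bd)
        if reporters and step % report_stride == 0:
            for rep in reporters:
                rep(step, sys_, bd)
        if stop is not None and stop(step, sys_):
            if step % traj_stride != 0 and step != n_steps:
                record(step, bd)
            break
    return traj
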