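"""Core particle-system container: bead types, topology, box.

A :class:`System` is the package's in-memory representation of one simulated
configuration: coordinates and velocities in nm / nm ps^-1, a per-bead type
index into a registry of :class:`BeadType`, harmonic bonds and angles, named
bead groups, and a box that is periodic in x and y only (the surface breaks
translational symmetry along z).

Positions are stored *unwrapped*: the integrator never folds coordinates back
into the box, so center-of-mass collective variables are continuous across
periodic images by construction.  The minimum-image convention is applied in
x and y wherever distances are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# Roles recognised by builders and observables.
ROLES = (
    "monomer",
    "guest",
    "oligomer-core",
    "oligomer-tail",
    "oligomer-head-charged",
    "receptor-base",
    "receptor-linker",
    "receptor-head",
    "counterion",
)


@dataclass(frozen=True)
class BeadType:
    """One coarse-grained bead species.

    Parameters
    ----------
    name : str
        Unique label used in pair tables and coordinate files.
    mass : float
        amu.  CG beads default to 72 amu (four-heavy-atom convention).
    charge : float
        Elementary charges.
    radius : float
        nm; used by the SASA observable.
    role : str
        One of :data:`ROLES`.
    frozen : bool
        Frozen beads are excluded from integration forever.
    """

    name: str
    mass: float = 72.0
    charge: float = 0.0
    radius: float = 0.26
    role: str = "monomer"
    frozen: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown bead role {self.role!r}")
        if not self.frozen and self.mass <= 0:
            raise ValueError("mobile beads need mass > 0")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


@dataclass(frozen=True)
class Box:
    """Orthorhombic box, periodic in x and y only."""

    lx: float
    ly: float
    lz: float
    periodic: tuple[bool, bool, bool] = (True, True, False)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz])


def minimum_image(dr: np.ndarray, box: Box | None) -> np.ndarray:
    """Apply the minimum-image convention along the periodic axes (x, y)."""
    if box is None:
        return dr
    dr = np.array(dr, dtype=float, copy=True)
    for ax, (length, per) in enumerate(zip((box.lx, box.ly, box.lz), box.periodic)):
        if per:
            dr[..., ax] -= length * np.round(dr[..., ax] / length)
    return dr


@dataclass
class System:
    """Beads + topology + box for one configuration.

    ``bonds`` rows are ``(i, j, r0, k)`` with U = k/2 (r - r0)^2;
    ``angles`` rows are ``(i, j, k, theta0_rad, k_theta)`` with
    U = k_theta/2 (theta - theta0)^2.
    """

    positions: np.ndarray                      # (N, 3) nm
    types: list[BeadType]                      # registry
    type_index: np.ndarray                     # (N,) int
    velocities: np.ndarray | None = None       # (N, 3) nm/ps
    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 4)))
    angles: np.ndarray = field(default_factory=lambda: np.zeros((0, 5)))
    groups: dict[str, np.ndarray] = field(default_factory=dict)
    box: Box | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.type_index = np.asarray(self.type_index, dtype=np.intp)
        if self.velocities is None:
            self.velocities = np.zeros_like(self.positions)
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(-1, 3)
        self.velocities[self.frozen] = 0.0

    # -- per-bead views ----------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def masses(self) -> np.ndarray:
        return np.array([self.types[t].mass for t in self.type_index], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([self.types[t].charge for t in self.type_index], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([self.types[t].radius for t in self.type_index], dtype=float)

    @property
    def frozen(self) -> np.ndarray:
        return np.array([self.types[t].frozen for t in self.type_index], dtype=bool)

    @property
    def roles(self) -> np.ndarray:
        return np.array([self.types[t].role for t in self.type_index])

    @property
    def names(self) -> np.ndarray:
        return np.array([self.types[t].name for t in self.type_index])

    def net_charge(self) -> float:
        return float(self.charges.sum())

    def group(self, name: str) -> np.ndarray:
        if name not in self.groups:
            raise KeyError(f"no bead group named {name!r}")
        return self.groups[name]

    def com(self, group: str | np.ndarray | None = None) -> np.ndarray:
        """Mass-weighted center of mass of a group (default: all beads)."""
        idx = (
            np.arange(self.n_beads)
            if group is None
            else (self.group(group) if isinstance(group, str) else np.asarray(group))
        )
        if len(idx) == 0:
            raise ValueError("empty group has no center of mass")
        m = self.masses[idx]
        return (self.positions[idx] * m[:, None]).sum(axis=0) / m.sum()

    def copy(self) -> "System":
        return replace(
            self,
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            type_index=self.type_index.copy(),
            bonds=self.bonds.copy(),
            angles=self.angles.copy(),
            groups={k: v.copy() for k, v in self.groups.items()},
        )

    # -- topology helpers --------------------------------------------------
    def exclusions(self) -> set[tuple[int, int]]:
        """Nonbonded exclusions: bonded 1-2 and 1-3 pairs (ordered i < j)."""
        adj: dict[int, set[int]] = {}
        for row in self.bonds:
            i, j = int(row[0]), int(row[1])
            adj.setdefault(i, set()).add(j)
            adj.setdefault(j, set()).add(i)
        excl: set[tuple[int, int]] = set()
        for i, nbrs in adj.items():
            for j in nbrs:
                excl.add((min(i, j), max(i, j)))
                for k in adj.get(j, ()):  # 1-3 via j
                    if k != i:
                        excl.add((min(i, k), max(i, k)))
        return excl


def merge(a: System, b: System, box: Box | None = None) -> System:
    """Concatenate two systems; types are deduplicated by name.

    Group names common to both are concatenated; bonds/angles are re-indexed.
    """
    types = list(a.types)
    name_to_idx = {t.name: i for i, t in enumerate(types)}
    remap = np.zeros(len(b.types), dtype=np.intp)
    for k, t in enumerate(b.types):
        if t.name in name_to_idx:
            if types[name_to_idx[t.name]] != t:
                raise ValueError(f"conflicting bead type definition for {t.name!r}")
            remap[k] = name_to_idx[t.name]
        else:
            name_to_idx[t.name] = len(types)
            remap[k] = len(types)
            types.append(t)
    off = a.n_beads
    bonds_b = b.bonds.copy()
    angles_b = b.angles.copy()
    if len(bonds_b):
        bonds_b[:, :2] += off
    if len(angles_b):
        angles_b[:, :3] += off
    groups: dict[str, np.ndarray] = {k: v.copy() for k, v in a.groups.items()}
    for k, v in b.groups.items():
        shifted = v + off
        groups[k] = np.concatenate([groups[k], shifted]) if k in groups else shifted
    return System(
        positions=np.vstack([a.positions, b.positions]),
        types=types,
        type_index=np.concatenate([a.type_index, remap[b.type_index]]),
        velocities=np.vstack([a.velocities, b.velocities]),
        bonds=np.vstack([a.bonds, bonds_b]) if len(a.bonds) or len(bonds_b) else a.bonds,
        angles=np.vstack([a.angles, angles_b]) if len(a.angles) or len(angles_b) else a.angles,
        groups=groups,
        box=box if box is not None else (a.box or b.box),
        time=0.0,
    )
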