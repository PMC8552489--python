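"""Seeded, deterministic construction of nanoparticles, surfaces and systems.

Two nanoparticle resolutions are supported:

* **mCG** — one bead per monomer.  The paper-scale assembly has 1925 monomer
  beads with a handful of encapsulated guest beads.  The builder places beads
  on a jittered cubic lattice filling a ball (self-assembly MD would give the
  same downstream physics at far higher cost) with guests on the innermost
  sites.
* **fCG-like** — a generic parameterizable amphiphilic oligomer: a branched
  core carrying hydrophobic tails (inward) and 1-3 carboxylate-like charged
  heads (outward, -1 e each).  Oligomers are arranged radially into a micelle
  and relaxed by a short damped quench to remove overlaps.

Surfaces are rectangular region layouts with target receptor densities
(receptors nm^-2).  Receptors are either single frozen beads (mCG) or
three-bead tethered chains whose base is frozen and whose head carries +1 e
(fCG).  The realized receptor count in every region is exactly
``round(area * rho)`` (half away from zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .system import BeadType, Box, System, merge

__all__ = [
    "OligomerTemplate",
    "Region",
    "SurfaceSpec",
    "build_nanoparticle_mcg",
    "build_nanoparticle_fcg",
    "build_surface",
    "two_region_spec",
    "gradient_stripes_spec",
    "assemble_system",
    "round_half_away",
]

BOND_R0 = 0.47    # nm, default CG bond length
BOND_K = 4000.0   # kJ mol^-1 nm^-2


def round_half_away(x: float) -> int:
    """Round half away from zero (so 0.5 -> 1), used for receptor counts."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


# ---------------------------------------------------------------------------
# Oligomer template (fCG-like mode)
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class OligomerTemplate:
    """Generic amphiphilic oligomer: branched core, tails, charged heads.

    The default is the trivalent variant: one core bead, three hydrophobic
    two-bead tails, three -1 e hydrophilic heads (net charge -3 e).
    ``n_charged_heads`` in {1, 2, 3} selects the mono-/di-/trivalent variant.
    """

    n_core: int = 1
    n_hydrophobic_tails: int = 3
    tail_length: int = 2
    n_charged_heads: int = 3
    bond_r0: float = BOND_R0
    bond_k: float = BOND_K
    angle_theta0: float = math.pi      # rad; keeps arms extended
    angle_k: float = 25.0              # kJ mol^-1 rad^-2

    def __post_init__(self) -> None:
        if self.n_charged_heads not in (1, 2, 3):
            raise ValueError("n_charged_heads must be 1, 2 or 3")
        if self.n_core < 1 or self.n_hydrophobic_tails < 0 or self.tail_length < 1:
            raise ValueError("invalid template topology")

    @property
    def n_beads(self) -> int:
        return self.n_core + self.n_hydrophobic_tails * self.tail_length + self.n_charged_heads

    @property
    def net_charge(self) -> float:
        return -float(self.n_charged_heads)

    def local_layout(self) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
        """Beads in a local frame with +z the outward (head) direction.

        Returns (positions, role names per bead, bonds, angles); bead 0 is
        the core.  The connectivity is a star of arms rooted at the core, a
        connected acyclic graph by construction.
        """
        pos: list[np.ndarray] = [np.zeros(3)]
        roles = ["oligomer-core"]
        bonds: list[tuple] = []
        angles: list[tuple] = []
        # extra core beads stacked sideways
        for c in range(1, self.n_core):
            pos.append(np.array([0.3 * c, 0.0, 0.0]))
            roles.append("oligomer-core")
            bonds.append((c - 1, c, self.bond_r0, self.bond_k))
        nxt = self.n_core
        # tails: splayed around -z
        for t in range(self.n_hydrophobic_tails):
            phi = 2 * math.pi * t / max(self.n_hydrophobic_tails, 1)
            tilt = 0.45
            d = np.array([math.sin(tilt) * math.cos(phi), math.sin(tilt) * math.sin(phi), -math.cos(tilt)])
            prev = 0
            for b in range(self.tail_length):
                pos.append(d * self.bond_r0 * (b + 1))
                roles.append("oligomer-tail")
                bonds.append((prev, nxt, self.bond_r0, self.bond_k))
                if b == 1:
                    angles.append((0, prev, nxt, self.angle_theta0, self.angle_k))
                prev = nxt
                nxt += 1
        # charged heads: splayed around +z
        for h in range(self.n_charged_heads):
            phi = 2 * math.pi * h / self.n_charged_heads + 0.3
            tilt = 0.35
            d = np.array([math.sin(tilt) * math.cos(phi), math.sin(tilt) * math.sin(phi), math.cos(tilt)])
            pos.append(d * self.bond_r0)
            roles.append("oligomer-head-charged")
            bonds.append((0, nxt, self.bond_r0, self.bond_k))
            nxt += 1
        bonds_arr = np.array(bonds, dtype=float) if bonds else np.zeros((0, 4))
        angles_arr = np.array(angles, dtype=float) if angles else np.zeros((0, 5))
        return np.array(pos), roles, bonds_arr, angles_arr


# ---------------------------------------------------------------------------
# Surface specs
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class Region:
    """Axis-aligned rectangle [x0, x1) x [y0, y1) with receptor density rho."""

    x0: float
    x1: float
    y0: float
    y1: float
    rho: float  # receptors nm^-2

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)


@dataclass(frozen=True)
class SurfaceSpec:
    """Rectangular surface tiled by receptor-density regions."""

    lx: float
    ly: float
    regions: tuple[Region, ...]
    receptor_model: str = "monobead_frozen"   # or "tribead_tethered"
    placement: str = "poisson_disc"           # or "lattice"
    head_charge: float = 0.0                  # e, on the topmost receptor bead
    lz: float = 15.0

    def __post_init__(self) -> None:
        if self.receptor_model not in ("monobead_frozen", "tribead_tethered"):
            raise ValueError(f"unknown receptor model {self.receptor_model!r}")
        if self.placement not in ("poisson_disc", "lattice"):
            raise ValueError(f"unknown placement {self.placement!r}")
        area = sum(r.area for r in self.regions)
        if not math.isclose(area, self.lx * self.ly, rel_tol=1e-9):
            raise ValueError("regions must tile the surface exactly")
        for r in self.regions:
            if r.rho < 0:
                raise ValueError("densities must be >= 0")

    def realized_counts(self) -> list[int]:
        return [round_half_away(r.area * r.rho) for r in self.regions]


def two_region_spec(
    lx: float,
    ly: float,
    rho_high: float,
    ratio: float,
    **kwargs,
) -> SurfaceSpec:
    """Two equal-area regions split along x: low density (x < lx/2), then high.

    ``ratio`` is rho_low / rho_high, e.g. 1/64 for the two-region layout with
    a 64-fold density contrast.
    """
    if not 0 < ratio <= 1:
        raise ValueError("ratio must be in (0, 1]")
    regions = (
        Region(0.0, lx / 2, 0.0, ly, rho_high * ratio),
        Region(lx / 2, lx, 0.0, ly, rho_high),
    )
    return SurfaceSpec(lx=lx, ly=ly, regions=regions, **kwargs)


def gradient_stripes_spec(
    stripe_densities: list[float],
    stripe_lx: float,
    ly: float,
    **kwargs,
) -> SurfaceSpec:
    """Consecutive equal-width stripes along x with the given densities.

    The paper-scale rolling layout is ``([0, 0.12, 0.52, 1.12], 30, 30)``:
    a 120 x 30 nm surface whose receptor density grows along x.
    """
    if len(stripe_densities) < 1:
        raise ValueError("need at least one stripe")
    regions = tuple(
        Region(i * stripe_lx, (i + 1) * stripe_lx, 0.0, ly, rho)
        for i, rho in enumerate(stripe_densities)
    )
    return SurfaceSpec(lx=stripe_lx * len(stripe_densities), ly=ly, regions=regions, **kwargs)


# ---------------------------------------------------------------------------
# Nanoparticle builders
# ---------------------------------------------------------------------------
MCG_SIGMA_MM = 0.47  # nm, monomer-monomer LJ sigma in the mCG model


def _lattice_ball(n: int, spacing: float) -> np.ndarray:
    """The n cubic-lattice points closest to the origin, scaled by spacing."""
    m = 1
    while (2 * m + 1) ** 3 < 2 * n + 8:
        m += 1
    ax = np.arange(-m, m + 1)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3).astype(float)
    order = np.argsort((pts**2).sum(axis=1), kind="stable")
    return pts[order[:n]] * spacing


def build_nanoparticle_mcg(
    n_monomers: int,
    n_guests: int = 0,
    packing_radius: float | None = None,
    seed: int = 0,
    sigma: float = MCG_SIGMA_MM,
) -> System:
    """Roughly spherical mCG cluster of monomer beads with interior guests.

    Beads sit on a jittered cubic lattice filling a ball; the ``n_guests``
    innermost sites become guest beads, so guests lie inside the monomer
    shell.  Deterministic under a fixed seed.  If ``packing_radius`` is given
    the lattice spacing is derived from it; a spacing that would bring beads
    closer than 0.9 sigma raises (infeasible density).
    """
    if n_monomers < 1:
        raise ValueError("need at least one monomer")
    if n_guests < 0:
        raise ValueError("n_guests must be >= 0")
    n = n_monomers + n_guests
    if packing_radius is None:
        spacing = 2 ** (1 / 6) * sigma
    else:
        spacing = (4 * math.pi * packing_radius**3 / (3 * n)) ** (1 / 3)
        if spacing < 0.95 * sigma:
            raise ValueError(
                f"packing_radius {packing_radius} nm cannot hold {n} beads "
                f"without overlap (lattice spacing {spacing:.3f} < 0.95 sigma)"
            )
    jitter = min(0.02, (spacing - 0.9 * sigma) / (4 * math.sqrt(3)))
    rng = np.random.default_rng(seed)
    pts = _lattice_ball(n, spacing)
    pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)
    # innermost sites are guests (interior to the monomer shell)
    guest_idx = np.arange(n_guests)
    mono_idx = np.arange(n_guests, n)
    types = [
        BeadType("M", role="monomer", radius=sigma / 2 + 0.1),
        BeadType("G", role="guest", radius=0.43 / 2 + 0.1),
    ]
    type_index = np.zeros(n, dtype=np.intp)
    type_index[guest_idx] = 1
    order = np.concatenate([mono_idx, guest_idx])  # monomers first
    positions = pts[order]
    type_index = type_index[order]
    groups = {
        "monomer": np.arange(n_monomers),
        "guest": np.arange(n_monomers, n),
        "np": np.arange(n),
        "np-charged": np.zeros(0, dtype=np.intp),
    }
    return System(positions=positions, types=types, type_index=type_index, groups=groups)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly uniform unit vectors (golden-spiral construction)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1 - 2 * i / n
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _damped_relax(system: System, n_steps: int, max_disp: float = 0.02) -> None:
    """Short steepest-descent-like quench to remove builder overlaps."""
    from .forcefield import ForceField, fcg_pair_table

    ff = ForceField(fcg_pair_table())
    for _ in range(n_steps):
        _, forces = ff.compute(system)
        fmax = np.abs(forces).max()
        if fmax < 1e-6:
            break
        system.positions += forces * (max_disp / max(fmax, 1e-12))


def build_nanoparticle_fcg(
    template: OligomerTemplate | None = None,
    n_oligomers: int = 44,
    n_guests: int = 10,
    seed: int = 0,
    relax_steps: int = 150,
) -> System:
    """Micelle-like assembly of amphiphilic oligomers with interior guests.

    Oligomer cores sit on a sphere, hydrophobic tails point inward, charged
    heads outward; guest beads fill the interior cavity.  A short damped
    quench (builder-internal) removes residual overlaps.  The default
    trivalent 44-oligomer assembly carries a net bead charge of -132 e.
    """
    template = template or OligomerTemplate()
    if n_oligomers < 1:
        raise ValueError("need at least one oligomer")
    local, roles_local, bonds_local, angles_local = template.local_layout()
    rng = np.random.default_rng(seed)

    tail_reach = template.tail_length * template.bond_r0
    r_guest = 0.0
    if n_guests > 0:
        r_guest = (3 * n_guests * 0.45**3 / (4 * math.pi)) ** (1 / 3) + 0.35
    r_pack = math.sqrt(max(n_oligomers, 2) * 0.75**2 / (4 * math.pi))
    r_core = max(tail_reach + r_guest + 0.15, r_pack, 0.8)

    types = [
        BeadType("C", role="oligomer-core", radius=0.335),
        BeadType("T", role="oligomer-tail", radius=0.335),
        BeadType("H", role="oligomer-head-charged", charge=-1.0, radius=0.335),
        BeadType("G", role="guest", radius=0.315),
    ]
    tname = {"oligomer-core": 0, "oligomer-tail": 1, "oligomer-head-charged": 2}

    positions: list[np.ndarray] = []
    type_index: list[int] = []
    bonds: list[np.ndarray] = []
    angles: list[np.ndarray] = []
    dirs = _fibonacci_sphere(n_oligomers) if n_oligomers > 1 else np.array([[0.0, 0.0, 1.0]])
    nb = template.n_beads
    for o in range(n_oligomers):
        u = dirs[o]
        # rotation taking +z to u
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(z, u)
        s, c = np.linalg.norm(v), float(np.dot(z, u))
        if s < 1e-12:
            rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
        placed = local @ rot.T + u * r_core
        positions.append(placed)
        type_index.extend(tname[r] for r in roles_local)
        b = bonds_local.copy()
        if len(b):
            b[:, :2] += o * nb
        bonds.append(b)
        a = angles_local.copy()
        if len(a):
            a[:, :3] += o * nb
        angles.append(a)
    n_olig_beads = n_oligomers * nb

    # guests in the interior cavity
    if n_guests > 0:
        gpos = _lattice_ball(n_guests, 0.45)
        gpos += rng.uniform(-0.03, 0.03, size=gpos.shape)
        positions.append(gpos)
        type_index.extend([3] * n_guests)

    pos = np.vstack(positions)
    tix = np.array(type_index, dtype=np.intp)
    roles = np.array([types[t].role for t in tix])
    groups = {
        "np": np.arange(n_olig_beads),
        "np-charged": np.flatnonzero(roles == "oligomer-head-charged"),
        "guest": np.arange(n_olig_beads, n_olig_beads + n_guests),
        "monomer": np.arange(n_olig_beads),  # NP body beads (guest-contact partner)
    }
    sys_ = System(
        positions=pos,
        types=types,
        type_index=tix,
        bonds=np.vstack(bonds) if bonds else np.zeros((0, 4)),
        angles=np.vstack(angles) if angles else np.zeros((0, 5)),
        groups=groups,
    )
    if relax_steps > 0:
        _damped_relax(sys_, relax_steps)
    return sys_


# ---------------------------------------------------------------------------
# Surface builder
# ---------------------------------------------------------------------------
def _place_in_region(
    region: Region, count: int, placement: str, rng: np.random.Generator
) -> np.ndarray:
    """xy positions of `count` receptors inside a region."""
    if count == 0:
        return np.zeros((0, 2))
    w, h = region.x1 - region.x0, region.y1 - region.y0
    if placement == "lattice":
        nx = max(1, round_half_away(math.sqrt(count * w / max(h, 1e-12))))
        ny = int(math.ceil(count / nx))
        xs = (np.arange(nx) + 0.5) * (w / nx) + region.x0
        ys = (np.arange(ny) + 0.5) * (h / ny) + region.y0
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
        return pts[:count]
    # poisson_disc: seeded dart throwing with a density-derived minimum gap
    rho = count / region.area
    rmin = 1.0 / math.sqrt(2 * rho) if rho > 0 else 0.0
    placed = np.empty((count, 2))
    n_placed = 0
    attempts = 0
    max_attempts = 2000 * count
    while n_placed < count:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"receptor density {rho:.3f} nm^-2 exceeds the poisson-disc "
                f"packing limit for minimum gap {rmin:.3f} nm"
            )
        cand = rng.uniform((region.x0, region.y0), (region.x1, region.y1))
        attempts += 1
        if n_placed == 0 or (
            np.min(((placed[:n_placed] - cand) ** 2).sum(axis=1)) >= rmin**2
        ):
            placed[n_placed] = cand
            n_placed += 1
    return placed


def build_surface(spec: SurfaceSpec, seed: int = 0) -> System:
    """Receptor-decorated surface fragment with the spec's exact counts.

    Monobead receptors are single frozen beads on the z = 0 plane; tribead
    receptors are vertical base-linker-head chains (base frozen at z = 0,
    head at 0.6 nm carrying ``head_charge``) bonded harmonically with a
    straightening angle term.
    """
    rng = np.random.default_rng(seed)
    xy_all: list[np.ndarray] = []
    for region, count in zip(spec.regions, spec.realized_counts()):
        xy_all.append(_place_in_region(region, count, spec.placement, rng))
    xy = np.vstack(xy_all) if xy_all else np.zeros((0, 2))
    n_rec = len(xy)
    box = Box(spec.lx, spec.ly, spec.lz)

    if spec.receptor_model == "monobead_frozen":
        types = [
            BeadType("RH", charge=spec.head_charge, role="receptor-head", frozen=True,
                     radius=0.335)
        ]
        pos = np.column_stack([xy, np.zeros(n_rec)])
        groups = {
            "receptor": np.arange(n_rec),
            "receptor-head": np.arange(n_rec),
        }
        return System(positions=pos, types=types,
                      type_index=np.zeros(n_rec, dtype=np.intp), groups=groups, box=box)

    types = [
        BeadType("RB", role="receptor-base", frozen=True, radius=0.335),
        BeadType("RL", role="receptor-linker", radius=0.335),
        BeadType("RH", charge=spec.head_charge, role="receptor-head", radius=0.335),
    ]
    pos = np.zeros((3 * n_rec, 3))
    tix = np.zeros(3 * n_rec, dtype=np.intp)
    bonds = np.zeros((2 * n_rec, 4))
    angles = np.zeros((n_rec, 5))
    for k in range(n_rec):
        b = 3 * k
        pos[b] = (*xy[k], 0.0)
        pos[b + 1] = (*xy[k], 0.3)
        pos[b + 2] = (*xy[k], 0.6)
        tix[b:b + 3] = (0, 1, 2)
        bonds[2 * k] = (b, b + 1, 0.3, BOND_K)
        bonds[2 * k + 1] = (b + 1, b + 2, 0.3, BOND_K)
        angles[k] = (b, b + 1, b + 2, math.pi, 50.0)
    groups = {
        "receptor": np.arange(3 * n_rec),
        "receptor-base": np.arange(0, 3 * n_rec, 3),
        "receptor-head": np.arange(2, 3 * n_rec, 3) if n_rec else np.zeros(0, dtype=np.intp),
    }
    return System(positions=pos, types=types, type_index=tix,
                  bonds=bonds, angles=angles, groups=groups, box=box)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------
def assemble_system(
    np_fragment: System,
    surface_fragment: System,
    z_offset: float = 1.0,
    neutralize: bool = False,
    seed: int = 0,
    xy: tuple[float, float] | None = None,
) -> System:
    """Merge an NP fragment onto a surface fragment, optionally neutralizing.

    The NP is translated so its center of mass sits at ``xy`` (box center by
    default) and its lowest bead sits ``z_offset`` above the surface plane.
    With ``neutralize=True``, monovalent counterions of the opposite sign are
    added at random non-overlapping positions until the total charge is 0 e.
    """
    box = surface_fragment.box
    if box is None:
        raise ValueError("surface fragment must carry a box")
    np_frag = np_fragment.copy()
    target_xy = np.array(xy) if xy is not None else np.array([box.lx / 2, box.ly / 2])
    com = np_frag.com()
    np_frag.positions[:, :2] += target_xy - com[:2]
    np_frag.positions[:, 2] += z_offset - np_frag.positions[:, 2].min()

    np_top = np_frag.positions[:, 2].max()
    if np_top + 2.0 > box.lz:
        box = Box(box.lx, box.ly, np_top + 4.0, box.periodic)

    sys_ = merge(surface_fragment, np_frag, box=box)
    if surface_fragment.n_beads and np_frag.n_beads:
        d, _ = cKDTree(surface_fragment.positions).query(np_frag.positions, k=1)
        if d.min() < 0.30:
            raise ValueError(
                f"NP overlaps the surface after placement (min distance "
                f"{d.min():.3f} nm); increase z_offset"
            )

    if neutralize:
        q_net = sys_.net_charge()
        n_ion = round_half_away(abs(q_net))
        if n_ion > 0:
            ion_q = -1.0 if q_net > 0 else 1.0
            rng = np.random.default_rng(seed)
            tree = cKDTree(sys_.positions) if sys_.n_beads else None
            pts = np.empty((n_ion, 3))
            placed = 0
            attempts = 0
            while placed < n_ion:
                if attempts > 20000 * n_ion:
                    raise RuntimeError("could not place counterions without overlap")
                cand = rng.uniform(
                    (0.0, 0.0, 0.8), (box.lx, box.ly, box.lz - 0.5)
                )
                attempts += 1
                ok = tree is None or tree.query(cand, k=1)[0] > 0.5
                if ok and placed and np.min(((pts[:placed] - cand) ** 2).sum(axis=1)) < 0.25:
                    ok = False
                if ok:
                    pts[placed] = cand
                    placed += 1
            ions = System(
                positions=pts,
                types=[BeadType("ION", charge=ion_q, role="counterion", radius=0.25)],
                type_index=np.zeros(n_ion, dtype=np.intp),
                groups={"counterion": np.arange(n_ion)},
            )
            sys_ = merge(sys_, ions, box=box)
    return sys_
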