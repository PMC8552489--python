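"""Energies and forces: LJ 12-6 pairs, screened Coulomb, 9-3 wall, bonded terms.

Nonbonded interactions follow the implicit-solvent CG convention: plain
cutoff at ``r_c`` (default 1.1 nm) with both the LJ and the Coulomb term
cut-and-shifted so the energy is continuous at the cutoff, and a relative
dielectric constant (default 15) standing in for solvent screening.  Cross
pair parameters default to Lorentz-Berthelot mixing unless a pair is
explicitly tabulated -- the mCG model tabulates its monomer-receptor and
guest pairs directly.

The surface is represented by an integrated 9-3 LJ wall normalized so that
its well depth equals the quoted attraction (2.0 kJ mol^-1 by default),
acting on all mobile non-receptor beads.  Periodicity is x/y only
(minimum-image in the plane, open along z).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .system import System
from .units import F_COULOMB

__all__ = [
    "PairTable",
    "WallParams",
    "RestraintParams",
    "EnergyBreakdown",
    "ForceField",
    "Evaluator",
    "lj_pair_energy",
    "coulomb_pair_energy",
    "wall_energy_93",
    "mcg_pair_table",
    "fcg_pair_table",
]

# depth of the bare 9-3 form e*[(2/15)(s/z)^9 - (s/z)^3] is sqrt(10)/3 * e
_93_DEPTH = math.sqrt(10.0) / 3.0


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------
class PairTable:
    """Per-type LJ parameters with Lorentz-Berthelot mixing and overrides.

    ``sigma``/``epsilon`` map type names to self-pair parameters; ``pairs``
    maps unordered name pairs to explicit (sigma, epsilon) overrides (used by
    the mCG model, which defines interactions pairwise rather than per type).
    """

    def __init__(
        self,
        sigma: dict[str, float],
        epsilon: dict[str, float],
        pairs: dict[tuple[str, str], tuple[float, float]] | None = None,
        r_cut: float = 1.1,
        eps_r: float = 15.0,
    ):
        self.sigma = dict(sigma)
        self.epsilon = dict(epsilon)
        self.pairs = {}
        for (a, b), v in (pairs or {}).items():
            self.pairs[tuple(sorted((a, b)))] = (float(v[0]), float(v[1]))
        self.r_cut = float(r_cut)
        self.eps_r = float(eps_r)
        for s in self.sigma.values():
            if s < 0:
                raise ValueError("sigma must be >= 0")
        if self.r_cut <= max(self.sigma.values(), default=0.0):
            raise ValueError("cutoff must exceed the largest sigma")

    def pair_params(self, a: str, b: str) -> tuple[float, float]:
        """(sigma, epsilon) for a type pair; symmetric in (a, b)."""
        key = tuple(sorted((a, b)))
        if key in self.pairs:
            return self.pairs[key]
        sa, sb = self.sigma.get(a, 0.0), self.sigma.get(b, 0.0)
        ea, eb = self.epsilon.get(a, 0.0), self.epsilon.get(b, 0.0)
        return (0.5 * (sa + sb), math.sqrt(ea * eb))

    def matrices(self, type_names: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Dense (sigma, epsilon) matrices over a type registry."""
        n = len(type_names)
        sig = np.zeros((n, n))
        eps = np.zeros((n, n))
        for i, j in itertools.product(range(n), repeat=2):
            sig[i, j], eps[i, j] = self.pair_params(type_names[i], type_names[j])
        return sig, eps


def mcg_pair_table() -> PairTable:
    """Default minimalistic-model pair table.

    Monomer-monomer (the self-assembly strength dE_ass): sigma 0.47 nm,
    epsilon 10 kJ/mol.  Monomer-receptor (the binding strength dE_bind):
    sigma 0.35 nm, epsilon 40 kJ/mol, i.e. a dE_ass/dE_bind ratio of 1/4.
    Guests use sigma 0.43 nm, epsilon 6.5 kJ/mol against themselves and the
    monomers.
    """
    return PairTable(
        sigma={"M": 0.47, "G": 0.43, "RH": 0.43, "ION": 0.35},
        epsilon={"M": 10.0, "G": 6.5, "RH": 1.0, "ION": 1.0},
        pairs={
            ("M", "RH"): (0.35, 40.0),
            ("M", "G"): (0.43, 6.5),
            ("G", "RH"): (0.43, 1.0),
        },
    )


def fcg_pair_table() -> PairTable:
    """Default pair table for the generic amphiphilic-oligomer (fCG-like) mode.

    Hydrophobic tails drive assembly; charged heads bind the +1 e receptor
    heads mainly electrostatically (relative dielectric 15).  Guests are
    weakly bound (sigma 0.43 nm, epsilon 6.5 kJ/mol) so their release upon
    disassembly is prompt.
    """
    return PairTable(
        sigma={"C": 0.47, "T": 0.47, "H": 0.47, "G": 0.43,
               "RB": 0.47, "RL": 0.47, "RH": 0.47, "ION": 0.35},
        epsilon={"C": 3.0, "T": 6.0, "H": 1.0, "G": 6.5,
                 "RB": 1.0, "RL": 1.0, "RH": 1.0, "ION": 1.0},
        pairs={
            ("G", "T"): (0.43, 6.5),
            ("G", "C"): (0.43, 6.5),
            ("H", "RH"): (0.40, 2.0),
        },
    )


@dataclass(frozen=True)
class WallParams:
    """Integrated 9-3 LJ wall at the surface plane.

    ``eps_w`` is the *well depth* in kJ/mol (the physically quoted number);
    the 9-3 prefactor is normalized so the minimum of the potential equals
    -eps_w, at z - z_ref = sigma_w (2/5)^(1/6).
    """

    eps_w: float = 2.0
    sigma_w: float = 0.47
    z_ref: float = 0.0

    def __post_init__(self) -> None:
        if self.eps_w < 0:
            raise ValueError("eps_w must be >= 0")


@dataclass(frozen=True)
class RestraintParams:
    """One-sided harmonic-power restraint on a group's COM height.

    U = kappa (z_com - z0)^exp for z_com > z0, else 0.  The defaults mirror
    the rolling setup: a wall at z0 = 5 nm with kappa = 150, exp = 2 that
    keeps the nanoparticle from jumping far off the surface.
    """

    z0: float = 5.0
    kappa: float = 150.0
    exp: int = 2
    group: str = "np"


@dataclass
class EnergyBreakdown:
    """Potential-energy components, kJ/mol."""

    lj: float = 0.0
    coulomb: float = 0.0
    wall: float = 0.0
    bonded: float = 0.0
    restraint: float = 0.0
    external: float = 0.0

    @property
    def total(self) -> float:
        return self.lj + self.coulomb + self.wall + self.bonded + self.restraint + self.external


# ---------------------------------------------------------------------------
# Elementary pair terms (reference forms; the kernel reimplements them)
# ---------------------------------------------------------------------------
def lj_pair_energy(r: float, sigma: float, epsilon: float,
                   r_cut: float = math.inf) -> float:
    """Cut-and-shifted LJ 12-6 pair energy; zero beyond the cutoff."""
    if r <= 0:
        raise ValueError("bead overlap: r must be > 0")
    if r >= r_cut:
        return 0.0
    u = 4 * epsilon * ((sigma / r) ** 12 - (sigma / r) ** 6)
    if math.isfinite(r_cut):
        u -= 4 * epsilon * ((sigma / r_cut) ** 12 - (sigma / r_cut) ** 6)
    return u


def coulomb_pair_energy(r: float, qi: float, qj: float, eps_r: float = 15.0,
                        r_cut: float = math.inf) -> float:
    """Screened, cut-and-shifted Coulomb pair energy (kJ/mol)."""
    if r <= 0:
        raise ValueError("bead overlap: r must be > 0")
    if r >= r_cut:
        return 0.0
    u = F_COULOMB * qi * qj / (eps_r * r)
    if math.isfinite(r_cut):
        u -= F_COULOMB * qi * qj / (eps_r * r_cut)
    return u


def wall_energy_93(z: float, params: WallParams) -> float:
    """9-3 wall energy at height z; raises below the surface plane."""
    dz = z - params.z_ref
    if dz <= 0:
        raise ValueError("bead penetrated the surface plane")
    s = params.sigma_w / dz
    return params.eps_w / _93_DEPTH * ((2.0 / 15.0) * s**9 - s**3)


def wall_force_93(z: float, params: WallParams) -> float:
    """-dU/dz of the 9-3 wall."""
    dz = z - params.z_ref
    s = params.sigma_w / dz
    # dU/ddz = pref * (-9*(2/15) s^9 + 3 s^3)/dz
    du = params.eps_w / _93_DEPTH * (-(9.0 * 2.0 / 15.0) * s**9 + 3.0 * s**3) / dz
    return -du


# ---------------------------------------------------------------------------
# Numba pair kernel
# ---------------------------------------------------------------------------
@njit(cache=True, fastmath=False)
def _pair_kernel(pos, iidx, jidx, sig, eps, qq, lx, ly, per_x, per_y,
                 rc, eps_r, fcoul, forces):
    e_lj = 0.0
    e_c = 0.0
    rc2 = rc * rc
    for k in range(iidx.shape[0]):
        i = iidx[k]
        j = jidx[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if per_x:
            dx -= lx * round(dx / lx)
        if per_y:
            dy -= ly * round(dy / ly)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2 or r2 <= 0.0:
            continue
        r = math.sqrt(r2)
        fr = 0.0  # dU/dr / r  (negated later)
        e = eps[k]
        if e > 0.0:
            s = sig[k]
            sr6 = (s * s / r2) ** 3
            sr12 = sr6 * sr6
            src6 = (s / rc) ** 6
            e_lj += 4.0 * e * (sr12 - sr6) - 4.0 * e * (src6 * src6 - src6)
            fr += 24.0 * e * (2.0 * sr12 - sr6) / r2
        q = qq[k]
        if q != 0.0:
            pref = fcoul * q / eps_r
            e_c += pref * (1.0 / r - 1.0 / rc)
            fr += pref / (r2 * r)
        fx = fr * dx
        fy = fr * dy
        fz = fr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return e_lj, e_c


@njit(cache=True)
def _bond_kernel(pos, bi, bj, r0, k, lx, ly, per_x, per_y, forces):
    e = 0.0
    for n in range(bi.shape[0]):
        i = bi[n]
        j = bj[n]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if per_x:
            dx -= lx * round(dx / lx)
        if per_y:
            dy -= ly * round(dy / ly)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            r = 1e-12
        d = r - r0[n]
        e += 0.5 * k[n] * d * d
        fmag = -k[n] * d / r
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz
    return e


@njit(cache=True)
def _angle_kernel(pos, ai, aj, ak, th0, kth, lx, ly, per_x, per_y, forces):
    e = 0.0
    for n in range(ai.shape[0]):
        i = ai[n]
        j = aj[n]
        k_ = ak[n]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k_, 0] - pos[j, 0]
        vy = pos[k_, 1] - pos[j, 1]
        vz = pos[k_, 2] - pos[j, 2]
        if per_x:
            ux -= lx * round(ux / lx)
            vx -= lx * round(vx / lx)
        if per_y:
            uy -= ly * round(uy / ly)
            vy -= ly * round(vy / ly)
        nu = math.sqrt(ux * ux + uy * uy + uz * uz)
        nv = math.sqrt(vx * vx + vy * vy + vz * vz)
        uhx, uhy, uhz = ux / nu, uy / nu, uz / nu
        vhx, vhy, vhz = vx / nv, vy / nv, vz / nv
        cos = uhx * vhx + uhy * vhy + uhz * vhz
        if cos > 1.0:
            cos = 1.0
        if cos < -1.0:
            cos = -1.0
        th = math.acos(cos)
        sin = math.sqrt(max(1.0 - cos * cos, 1e-10))
        d = th - th0[n]
        e += 0.5 * kth[n] * d * d
        coef = kth[n] * d / sin
        fix = coef * (vhx - cos * uhx) / nu
        fiy = coef * (vhy - cos * uhy) / nu
        fiz = coef * (vhz - cos * uhz) / nu
        fkx = coef * (uhx - cos * vhx) / nv
        fky = coef * (uhy - cos * vhy) / nv
        fkz = coef * (uhz - cos * vhz) / nv
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k_, 0] += fkx
        forces[k_, 1] += fky
        forces[k_, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz
    return e


# ---------------------------------------------------------------------------
# Evaluator (per-system cached state + neighbor list)
# ---------------------------------------------------------------------------
class Evaluator:
    """Caches per-system arrays and the Verlet-skin neighbor list."""

    def __init__(self, ff: "ForceField", system: System, skin: float = 0.3):
        self.ff = ff
        self.skin = skin
        self.n = system.n_beads
        self.box = system.box
        tnames = [t.name for t in system.types]
        self.sig_mat, self.eps_mat = ff.pair_table.matrices(tnames)
        self.charges = system.charges
        self.frozen = system.frozen
        self.tix = system.type_index
        roles = system.roles
        self.wall_mask = (~self.frozen) & ~np.isin(
            roles, ("receptor-base", "receptor-linker", "receptor-head")
        )
        excl = system.exclusions()
        self._excl_keys = (
            np.array(sorted(i * self.n + j for i, j in excl), dtype=np.int64)
            if excl
            else np.zeros(0, dtype=np.int64)
        )
        self.bonds = system.bonds
        self.angles = system.angles
        b = system.bonds
        self._b = (b[:, 0].astype(np.int64), b[:, 1].astype(np.int64),
                   np.ascontiguousarray(b[:, 2]), np.ascontiguousarray(b[:, 3]))
        a = system.angles
        self._a = (a[:, 0].astype(np.int64), a[:, 1].astype(np.int64),
                   a[:, 2].astype(np.int64), np.ascontiguousarray(a[:, 3]),
                   np.ascontiguousarray(a[:, 4]))
        self._ref_pos: np.ndarray | None = None
        self._pairs: tuple | None = None

    # -- neighbor list -----------------------------------------------------
    def _wrapped(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        box = self.box
        if box is None:
            return pos, None
        w = pos.copy()
        w[:, 0] %= box.lx
        w[:, 1] %= box.ly
        zmin = w[:, 2].min()
        zspan = w[:, 2].max() - zmin
        big = max(10.0 * (zspan + 1.0), 1000.0)
        w[:, 2] = w[:, 2] - zmin + 1.0
        return w, np.array([box.lx, box.ly, big])

    def _build_pairs(self, pos: np.ndarray) -> None:
        rlist = self.ff.pair_table.r_cut + self.skin
        w, boxsize = self._wrapped(pos)
        tree = cKDTree(w, boxsize=boxsize)
        pairs = tree.query_pairs(rlist, output_type="ndarray")
        if len(pairs):
            i, j = pairs[:, 0], pairs[:, 1]
            keep = ~(self.frozen[i] & self.frozen[j])
            i, j = i[keep], j[keep]
            if len(self._excl_keys):
                keys = np.minimum(i, j).astype(np.int64) * self.n + np.maximum(i, j)
                keep = ~np.isin(keys, self._excl_keys, assume_unique=False)
                i, j = i[keep], j[keep]
        else:
            i = j = np.zeros(0, dtype=np.intp)
        ti, tj = self.tix[i], self.tix[j]
        self._pairs = (
            i.astype(np.int64),
            j.astype(np.int64),
            self.sig_mat[ti, tj],
            self.eps_mat[ti, tj],
            self.charges[i] * self.charges[j],
        )
        self._ref_pos = pos.copy()

    def _pairs_current(self, pos: np.ndarray):
        if self._pairs is None or self._ref_pos is None:
            self._build_pairs(pos)
        else:
            disp2 = ((pos - self._ref_pos) ** 2).sum(axis=1).max()
            if disp2 > (0.5 * self.skin) ** 2:
                self._build_pairs(pos)
        return self._pairs

    # -- evaluation --------------------------------------------------------
    def compute(self, pos: np.ndarray) -> tuple[EnergyBreakdown, np.ndarray]:
        """Energy breakdown and per-bead forces at the given positions.

        Forces on frozen beads are reported (for diagnostics) but the
        integrator never applies them.
        """
        ff = self.ff
        forces = np.zeros_like(pos)
        i, j, sig, eps, qq = self._pairs_current(pos)
        box = self.box
        lx = box.lx if box else 1.0
        ly = box.ly if box else 1.0
        per_x = bool(box and box.periodic[0])
        per_y = bool(box and box.periodic[1])
        e_lj, e_c = _pair_kernel(
            pos, i, j, sig, eps, qq, lx, ly, per_x, per_y,
            ff.pair_table.r_cut, ff.pair_table.eps_r, F_COULOMB, forces,
        )
        bd = EnergyBreakdown(lj=e_lj, coulomb=e_c)
        bd.bonded = self._bonded(pos, forces)
        if ff.wall is not None and self.wall_mask.any():
            bd.wall = self._wall(pos, forces)
        return bd, forces

    def _bonded(self, pos: np.ndarray, forces: np.ndarray) -> float:
        box = self.box
        lx = box.lx if box else 1.0
        ly = box.ly if box else 1.0
        per_x = bool(box and box.periodic[0])
        per_y = bool(box and box.periodic[1])
        e = 0.0
        if len(self.bonds):
            bi, bj, r0, k = self._b
            e += _bond_kernel(pos, bi, bj, r0, k, lx, ly, per_x, per_y, forces)
        if len(self.angles):
            ai, aj, ak, th0, kth = self._a
            e += _angle_kernel(pos, ai, aj, ak, th0, kth, lx, ly, per_x, per_y,
                               forces)
        return e

    def _wall(self, pos: np.ndarray, forces: np.ndarray) -> float:
        w = self.ff.wall
        idx = np.flatnonzero(self.wall_mask)
        dz = pos[idx, 2] - w.z_ref
        if (dz <= 0).any():
            raise ValueError("bead penetrated the surface plane")
        s = w.sigma_w / dz
        pref = w.eps_w / _93_DEPTH
        e = float((pref * ((2.0 / 15.0) * s**9 - s**3)).sum())
        forces[idx, 2] += -pref * (-(9.0 * 2.0 / 15.0) * s**9 + 3.0 * s**3) / dz
        return e

    def _mi(self, dr: np.ndarray) -> np.ndarray:
        box = self.box
        if box is None:
            return dr
        if box.periodic[0]:
            dr[:, 0] -= box.lx * np.round(dr[:, 0] / box.lx)
        if box.periodic[1]:
            dr[:, 1] -= box.ly * np.round(dr[:, 1] / box.ly)
        return dr


class ForceField:
    """Pair table + optional wall; evaluates a :class:`System` in one call.

    For repeated evaluation inside a dynamics loop, create an
    :class:`Evaluator` once (it caches type arrays and the neighbor list).
    """

    def __init__(self, pair_table: PairTable, wall: WallParams | None = None):
        self.pair_table = pair_table
        self.wall = wall

    def evaluator(self, system: System, skin: float = 0.3) -> Evaluator:
        return Evaluator(self, system, skin=skin)

    def compute(self, system: System) -> tuple[EnergyBreakdown, np.ndarray]:
        return Evaluator(self, system).compute(system.positions)
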