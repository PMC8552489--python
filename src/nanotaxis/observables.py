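"""Trajectory analysis: engagement, SASA, guest release, MSD, occupancy.

These are the quantities used to characterize nanoparticle behavior on the
surface: how many of its charged beads are engaged by receptors (bounded by
the number of charged beads -- 132 for the trivalent 44-oligomer assembly),
how much its solvent-accessible surface area grows as it deforms or
exfoliates (dSASA%), what fraction of encapsulated guests have been
released, and how it moves (MSD, drift velocity, per-region residence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .builders import SurfaceSpec
from .dynamics import Trajectory
from .system import System

__all__ = [
    "ObservableSeries",
    "ReleaseReport",
    "engagement_count",
    "sasa",
    "delta_sasa_percent",
    "guest_release",
    "msd_and_velocity",
    "region_occupancy",
]


@dataclass
class ObservableSeries:
    """A named time series (times ps, values in the observable's units)."""

    name: str
    times: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must align")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")


def engagement_count(
    system: System,
    charged_group: str = "np-charged",
    receptor_group: str = "receptor-head",
    cutoff: float = 0.6,
) -> int:
    """Number of NP charged beads with at least one receptor head in range.

    A per-bead engagement counter: it saturates at the size of the charged
    group (e.g. 132 for the trivalent 44-oligomer nanoparticle), which makes
    it the multivalency observable of choice.
    """
    ia = system.group(charged_group)
    ib = system.group(receptor_group)
    if len(ia) == 0 or len(ib) == 0:
        return 0
    tree = cKDTree(system.positions[ib])
    d, _ = tree.query(system.positions[ia], k=1,
                      distance_upper_bound=cutoff)
    return int(np.isfinite(d).sum())


def _pair_contact_count(pa: np.ndarray, pb: np.ndarray, cutoff: float) -> np.ndarray:
    """Per-A-bead count of B beads within cutoff (hard counting)."""
    if len(pb) == 0:
        return np.zeros(len(pa), dtype=int)
    tree = cKDTree(pb)
    return np.asarray(tree.query_ball_point(pa, cutoff, return_length=True))


def sasa(
    positions: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 0.19,
    n_sphere_points: int = 960,
) -> float:
    """Shrake-Rupley solvent-accessible surface area in nm^2.

    Numerical SASA over the given beads only (pass the NP group's positions
    and radii).  Backed by biotite's Shrake-Rupley implementation; an
    isolated bead of radius r gives 4 pi (r + probe)^2 to the point-count
    discretization error.
    """
    import biotite.structure as struc

    positions = np.asarray(positions, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if (radii <= 0).any():
        raise ValueError("radii must be positive")
    n = len(positions)
    if n == 0:
        return 0.0
    # biotite works in Angstrom and needs >= 2 atoms: pad with a far dummy
    pad = n == 1
    coords = positions * 10.0
    vdw = radii * 10.0
    if pad:
        far = coords[0] + np.array([1e4, 0.0, 0.0])
        coords = np.vstack([coords, far])
        vdw = np.append(vdw, 1.0)
    arr = struc.AtomArray(len(coords))
    arr.coord = coords.astype(np.float32)
    arr.element = np.array(["C"] * len(coords))
    areas = struc.sasa(
        arr, probe_radius=probe_radius * 10.0, vdw_radii=vdw,
        point_number=n_sphere_points,
    )
    if pad:
        areas = areas[:-1]
    return float(np.nansum(areas)) / 100.0


def delta_sasa_percent(series: np.ndarray, reference: float | None = None) -> np.ndarray:
    """Percent SASA change 100 (SASA(t) - SASA_ref)/SASA_ref.

    The reference defaults to the first frame of the series (the start of
    the production run).
    """
    s = np.asarray(series, dtype=float)
    ref = float(s[0]) if reference is None else float(reference)
    if ref <= 0:
        raise ValueError("reference SASA must be positive")
    return 100.0 * (s - ref) / ref


@dataclass
class ReleaseReport:
    """Per-guest release times and the cumulative release percentage."""

    times: np.ndarray                      # frame times, ps
    release_fraction: np.ndarray           # %, non-decreasing
    guest_release_time: np.ndarray         # ps per guest; nan = not released

    @property
    def final_percent(self) -> float:
        return float(self.release_fraction[-1]) if len(self.release_fraction) else 0.0


def guest_release(
    trajectory: Trajectory,
    guest_group: str = "guest",
    monomer_group: str = "monomer",
    cutoff: float = 0.6,
    persistence: int = 10,
) -> ReleaseReport:
    """Cumulative guest release from the drop in guest-monomer contacts.

    A guest counts as released from the first frame at which its hard
    contact count with the NP body beads is zero for ``persistence``
    consecutive frames (transient detachments are not releases).  The
    cumulative percentage is non-decreasing by construction.
    """
    sys_ = trajectory.system
    ig = sys_.group(guest_group)
    im = sys_.group(monomer_group)
    if len(ig) == 0 or len(im) == 0:
        raise ValueError("empty guest or monomer group")
    times = trajectory.times_array()
    n_frames = len(times)
    zero_run = np.zeros(len(ig), dtype=int)
    release_frame = np.full(len(ig), -1, dtype=int)
    for f in range(n_frames):
        pos = trajectory.positions[f]
        counts = _pair_contact_count(pos[ig], pos[im], cutoff)
        zero_run = np.where(counts == 0, zero_run + 1, 0)
        newly = (zero_run >= persistence) & (release_frame < 0)
        release_frame[newly] = f - persistence + 1
    released_t = np.where(release_frame >= 0, times[np.maximum(release_frame, 0)], np.nan)
    frac = np.array([
        100.0 * ((release_frame >= 0) & (release_frame <= f)).sum() / len(ig)
        for f in range(n_frames)
    ])
    return ReleaseReport(times=times, release_fraction=frac,
                         guest_release_time=released_t)


def msd_and_velocity(
    trajectory: Trajectory,
    group: str = "np",
    axis: int | None = 0,
) -> tuple[ObservableSeries, float]:
    """Time-lag-averaged COM MSD (nm^2) and drift velocity (nm/ps).

    The MSD uses all frame pairs at each lag (positions are stored
    unwrapped, so no image correction is needed); the drift velocity is the
    slope of a least-squares line through the COM coordinate along ``axis``
    (pass None for the magnitude of the full 3D displacement fit).
    """
    times = trajectory.times_array()
    if len(times) < 2:
        raise ValueError("need at least two frames")
    com = trajectory.com_trace(group)
    n = len(times)
    lags = np.arange(1, n)
    msd = np.empty(n - 1)
    for li, lag in enumerate(lags):
        d = com[lag:] - com[:-lag]
        msd[li] = (d**2).sum(axis=1).mean()
    dt = times[1] - times[0]
    series = ObservableSeries("msd", lags * dt, msd, units="nm^2")
    if axis is None:
        disp = np.linalg.norm(com - com[0], axis=1)
        vel = float(np.polyfit(times, disp, 1)[0])
    else:
        vel = float(np.polyfit(times, com[:, axis], 1)[0])
    return series, vel


def region_occupancy(
    trajectory: Trajectory,
    spec: SurfaceSpec,
    group: str = "np",
) -> np.ndarray:
    """Fraction of frames the group COM spends in each surface region.

    The COM (x, y) is wrapped into the box before region assignment;
    fractions sum to 1.
    """
    com = trajectory.com_trace(group)[:, :2]
    com[:, 0] %= spec.lx
    com[:, 1] %= spec.ly
    counts = np.zeros(len(spec.regions))
    for i, r in enumerate(spec.regions):
        inside = (
            (com[:, 0] >= r.x0) & (com[:, 0] < r.x1)
            & (com[:, 1] >= r.y0) & (com[:, 1] < r.y1)
        )
        counts[i] = inside.sum()
    total = counts.sum()
    if total == 0:
        raise ValueError("no frames fell inside the surface")
    return counts / total
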