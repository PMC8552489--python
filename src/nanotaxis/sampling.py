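"""Metadynamics and rare-event kinetics estimation.

Metadynamics deposits repulsive Gaussian kernels along low-dimensional
collective variables (CVs) so the system escapes free-energy minima it would
otherwise be stuck in.  Two CVs are provided: the (x, y) position of a
group's center of mass (used to activate nanoparticle motion on the surface
plane -- no bias acts along z) and a differentiable contacts count between
two groups (used for unbinding).  In the well-tempered variant the kernel
height is damped by the bias already present,
``h_eff = h exp(-V(s)/(k_B T (gamma_b - 1)))``, so the long-time bias tends
to ``-(1 - 1/gamma_b) F(s)``.

Infrequent metadynamics estimates *unbiased* rare-event times from biased
runs: each run's biased time is multiplied by the acceleration factor
``alpha = < exp(beta V(s(t), t)) >`` averaged over the run, and the rescaled
times are pooled into a Poissonian fit ``P(t) = 1 - exp(-t/tau)`` whose
characteristic time ``tau`` is the quantity of interest.  The exponential
self-consistency of the rescaled times (two-sided Kolmogorov-Smirnov test)
is the standard validity check for the protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.spatial import cKDTree
from scipy import stats

from .dynamics import IntegratorParams, Trajectory, run_md
from .forcefield import ForceField, RestraintParams
from .system import System, minimum_image
from .units import KB

__all__ = [
    "CVSpec",
    "MetaDConfig",
    "BiasState",
    "TransitionRecord",
    "PoissonFit",
    "cv_com_xy",
    "cv_contacts",
    "metad_deposit",
    "run_metad",
    "run_multiple_walker",
    "run_infrequent_metad",
    "acceleration_factor",
    "fit_poisson_tau",
]


# ---------------------------------------------------------------------------
# Collective variables
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class CVSpec:
    """A collective variable: ``com_xy`` of one group, or ``contacts``
    between two disjoint groups with switching radius ``r0`` (nm)."""

    kind: str
    groups: tuple[str, ...]
    r0: float = 0.6

    def __post_init__(self) -> None:
        if self.kind not in ("com_xy", "contacts"):
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if self.kind == "contacts":
            if len(self.groups) != 2 or self.r0 <= 0:
                raise ValueError("contacts CV needs two groups and r0 > 0")

    @property
    def dim(self) -> int:
        return 2 if self.kind == "com_xy" else 1


def cv_com_xy(system: System, group: str) -> np.ndarray:
    """(x, y) of a group's mass-weighted COM, continuous across the wrap.

    Coordinates are unwrapped relative to the group's first bead by the
    minimum-image convention before averaging, so a group straddling a
    periodic boundary yields a continuous CV rather than a box-length jump.
    """
    idx = system.group(group)
    if len(idx) == 0:
        raise ValueError("empty group")
    pos = system.positions[idx]
    ref = pos[0]
    d = minimum_image(pos - ref, system.box)
    m = system.masses[idx]
    com = ref + (d * m[:, None]).sum(axis=0) / m.sum()
    return com[:2]


def _contact_pairs(system: System, ia: np.ndarray, ib: np.ndarray, rmax: float):
    """A-B pairs within rmax, with minimum-image displacement vectors."""
    pa, pb = system.positions[ia], system.positions[ib]
    box = system.box
    if box is not None and (box.periodic[0] or box.periodic[1]):
        # all-pairs with minimum image (group sizes stay small)
        dr = pa[:, None, :] - pb[None, :, :]
        dr = minimum_image(dr, box)
        r = np.linalg.norm(dr, axis=-1)
        ii, jj = np.nonzero(r < rmax)
        return ii, jj, dr[ii, jj], r[ii, jj]
    tree = cKDTree(pb)
    out = tree.query_ball_point(pa, rmax)
    ii = np.concatenate([[k] * len(v) for k, v in enumerate(out)]) if len(ia) else np.zeros(0, int)
    jj = np.concatenate([v for v in out]) if len(out) else np.zeros(0, int)
    ii = ii.astype(int)
    jj = np.asarray(jj, dtype=int)
    dr = pa[ii] - pb[jj]
    r = np.linalg.norm(dr, axis=-1)
    return ii, jj, dr, r


def cv_contacts(
    system: System, group_a: str, group_b: str, r0: float = 0.6,
    return_grad: bool = False,
):
    """Differentiable contacts count Sum 1/(1 + (r/r0)^6) over A-B pairs.

    This is the rational 6/12 switching function
    (1 - (r/r0)^6)/(1 - (r/r0)^12) in its reduced form, which equals 1/2 at
    r = r0 and is smooth everywhere.  Pairs beyond 4 r0 contribute < 3e-4
    each and are skipped.  With ``return_grad`` the (sparse) derivative
    ds/dposition is returned for bias forces.
    """
    if r0 <= 0:
        raise ValueError("r0 must be > 0")
    ia, ib = system.group(group_a), system.group(group_b)
    rmax = 4.0 * r0
    ii, jj, dr, r = _contact_pairs(system, ia, ib, rmax)
    x6 = (r / r0) ** 6
    s = float((1.0 / (1.0 + x6)).sum())
    if not return_grad:
        return s
    grad = np.zeros_like(system.positions)
    if len(r):
        # ds/dr = -6 x^5 / (r0 (1+x^6)^2); chain to cartesian via dr/r
        dsdr = -6.0 * x6 / (r * (1.0 + x6) ** 2)
        vec = (dsdr / r)[:, None] * dr
        np.add.at(grad, ia[ii], vec)
        np.add.at(grad, ib[jj], -vec)
    return s, grad


# ---------------------------------------------------------------------------
# Bias state and deposition
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class MetaDConfig:
    """Kernel schedule: height (kJ/mol), per-dimension widths (nm or counts),
    deposit stride (steps), optional well-tempered bias factor."""

    height: float
    widths: tuple[float, ...]
    stride: int
    bias_factor: float | None = None
    log_stride: int = 10

    def __post_init__(self) -> None:
        if self.height <= 0 or self.stride < 1:
            raise ValueError("height and stride must be positive")
        if any(w <= 0 for w in self.widths):
            raise ValueError("widths must be positive")
        if self.bias_factor is not None and self.bias_factor <= 1:
            raise ValueError("bias factor must exceed 1")


@dataclass
class BiasState:
    """Deposited Gaussian kernels defining V(s, t) >= 0.

    ``heights`` are the *effective* (well-tempered damped) heights actually
    deposited; ``times`` the deposit times (ps).
    """

    widths: np.ndarray
    centers: list[np.ndarray] = field(default_factory=list)
    heights: list[float] = field(default_factory=list)
    times: list[float] = field(default_factory=list)

    @property
    def n_kernels(self) -> int:
        return len(self.heights)

    def _mats(self):
        cached = getattr(self, "_cache", None)
        if cached is None or cached[0] != len(self.heights):
            c = np.asarray(self.centers) if self.centers else np.zeros((0, len(self.widths)))
            h = np.asarray(self.heights)
            object.__setattr__(self, "_cache", (len(self.heights), c, h))
            return c, h
        return cached[1], cached[2]

    def value_and_gradient(self, s: np.ndarray) -> tuple[float, np.ndarray]:
        """(V(s), dV/ds) in one pass (hot path of the bias hook)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if not self.heights:
            return 0.0, np.zeros_like(s)
        c, h = self._mats()
        z = (s[None, :] - c) / self.widths[None, :]
        g = h * np.exp(-0.5 * (z**2).sum(axis=1))
        grad = -(g[:, None] * z / self.widths[None, :]).sum(axis=0)
        return float(g.sum()), grad

    def evaluate(self, s: np.ndarray, t: float | None = None) -> float:
        """V(s, t); only kernels deposited at or before t contribute."""
        if not self.centers:
            return 0.0
        c, h = self._mats()
        if t is not None:
            keep = np.asarray(self.times) <= t
            c, h = c[keep], h[keep]
        z = (np.atleast_1d(s)[None, :] - c) / self.widths[None, :]
        return float((h * np.exp(-0.5 * (z**2).sum(axis=1))).sum())

    def gradient(self, s: np.ndarray) -> np.ndarray:
        """dV/ds at s."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if not self.centers:
            return np.zeros_like(s)
        c, h = self._mats()
        z = (s[None, :] - c) / self.widths[None, :]
        g = np.exp(-0.5 * (z**2).sum(axis=1))
        return -((h * g)[:, None] * z / self.widths[None, :]).sum(axis=0)

    def grid_profile(self, grid: np.ndarray) -> np.ndarray:
        """V evaluated on a 1D grid (for free-energy estimates)."""
        if not self.centers:
            return np.zeros_like(grid)
        c, h = self._mats()
        z = (grid[:, None] - c[None, :, 0]) / self.widths[0]
        return (h[None, :] * np.exp(-0.5 * z**2)).sum(axis=1)


def metad_deposit(
    bias: BiasState,
    s: np.ndarray,
    cfg: MetaDConfig,
    temperature: float,
    t: float,
) -> BiasState:
    """Append one kernel at s; well-tempered damping if a bias factor is set."""
    h = cfg.height
    if cfg.bias_factor is not None:
        v = bias.evaluate(s)
        h = cfg.height * np.exp(-v / (KB * temperature * (cfg.bias_factor - 1.0)))
    bias.centers.append(np.atleast_1d(np.asarray(s, dtype=float)).copy())
    bias.heights.append(float(h))
    bias.times.append(float(t))
    return bias


# ---------------------------------------------------------------------------
# Biased dynamics
# ---------------------------------------------------------------------------
def _make_bias_hook(
    cv: CVSpec,
    cfg: MetaDConfig,
    bias: BiasState,
    params: IntegratorParams,
    log: dict,
    deposit: bool = True,
    v_series: list | None = None,
):
    """run_md hook: adds -dV/ds chain-ruled bead forces, deposits, logs."""
    cache: dict = {}

    def hook(step: int, system: System, forces: np.ndarray) -> float:
        if cv.kind == "com_xy":
            if "w" not in cache:
                idx = system.group(cv.groups[0])
                m = system.masses[idx]
                cache["idx"] = idx
                cache["w"] = m / m.sum()
            idx, w = cache["idx"], cache["w"]
            # positions stay unwrapped during dynamics: plain weighted mean
            s = (system.positions[idx, :2] * w[:, None]).sum(axis=0)
            v, g = bias.value_and_gradient(s)
            forces[idx, 0] -= g[0] * w
            forces[idx, 1] -= g[1] * w
        else:
            s_val, grad = cv_contacts(system, cv.groups[0], cv.groups[1], cv.r0,
                                      return_grad=True)
            s = np.array([s_val])
            v, g = bias.value_and_gradient(s)
            forces -= g[0] * grad
        if deposit and step > 0 and step % cfg.stride == 0:
            metad_deposit(bias, s, cfg, params.temperature, system.time)
        if v_series is not None:
            v_series.append(v)
        if step % cfg.log_stride == 0:
            log["time"].append(system.time)
            log["cv"].append(np.atleast_1d(s).copy())
            log["bias"].append(v)
        return v

    return hook


def run_metad(
    system: System,
    cv: CVSpec,
    cfg: MetaDConfig,
    params: IntegratorParams,
    forcefield: ForceField,
    n_steps: int,
    bias: BiasState | None = None,
    restraint: RestraintParams | None = None,
    external=None,
    traj_stride: int = 200,
    stop=None,
) -> tuple[Trajectory, BiasState, dict]:
    """Metadynamics run: Langevin dynamics plus history-dependent CV bias.

    The bias force acts only along the CV (for ``com_xy`` this means only in
    the surface plane -- the particle remains free along z).  Returns the
    trajectory, the final bias state and a COLVAR-style log dict with keys
    ``time``, ``cv``, ``bias``.
    """
    if bias is None:
        bias = BiasState(widths=np.asarray(cfg.widths, dtype=float))
    log: dict = {"time": [], "cv": [], "bias": []}
    hook = _make_bias_hook(cv, cfg, bias, params, log)
    traj = run_md(
        system, n_steps, params, forcefield,
        external=external, restraint=restraint,
        traj_stride=traj_stride, bias_hook=hook, stop=stop,
    )
    log["time"] = np.asarray(log["time"])
    log["cv"] = np.asarray(log["cv"])
    log["bias"] = np.asarray(log["bias"])
    return traj, bias, log


def run_multiple_walker(
    system: System,
    cv: CVSpec,
    cfg: MetaDConfig,
    params: IntegratorParams,
    forcefield: ForceField,
    n_steps: int,
    n_walkers: int,
    seeds: list[int] | None = None,
    traj_stride: int = 200,
) -> tuple[list[Trajectory], BiasState]:
    """Multiple walkers depositing into one shared bias.

    All walkers start from the same configuration (their thermal noise
    streams differ by seed), advance in lockstep one deposit stride at a
    time, and then deposit in walker order -- the kernel merge order is
    deterministic given the seeds.
    """
    if n_walkers < 1:
        raise ValueError("need at least one walker")
    seeds = seeds if seeds is not None else [params.seed + k for k in range(n_walkers)]
    if len(seeds) != n_walkers:
        raise ValueError("one seed per walker required")
    bias = BiasState(widths=np.asarray(cfg.widths, dtype=float))
    walkers = [system.copy() for _ in range(n_walkers)]
    rngs = [np.random.default_rng(s) for s in seeds]
    evs = [forcefield.evaluator(w) for w in walkers]
    logs = [{"time": [], "cv": [], "bias": []} for _ in range(n_walkers)]
    trajs = [Trajectory(system=w, metadata={"seed": s}) for w, s in zip(walkers, seeds)]
    hooks = [
        _make_bias_hook(cv, cfg, bias, params, logs[k], deposit=False)
        for k in range(n_walkers)
    ]
    n_segments, rem = divmod(n_steps, cfg.stride)
    for seg in range(n_segments):
        for k in range(n_walkers):
            seg_traj = run_md(
                walkers[k], cfg.stride, params, forcefield,
                bias_hook=hooks[k], traj_stride=traj_stride,
                copy=False, rng=rngs[k], evaluator=evs[k],
                record_initial=(seg == 0),
            )
            trajs[k].times.extend(seg_traj.times)
            trajs[k].positions.extend(seg_traj.positions)
            trajs[k].energies.extend(seg_traj.energies)
        for k in range(n_walkers):  # synchronized deposits, walker order
            if cv.kind == "com_xy":
                s = cv_com_xy(walkers[k], cv.groups[0])
            else:
                s = np.array([cv_contacts(walkers[k], cv.groups[0], cv.groups[1], cv.r0)])
            metad_deposit(bias, s, cfg, params.temperature, walkers[k].time)
    if rem:
        for k in range(n_walkers):
            seg_traj = run_md(
                walkers[k], rem, params, forcefield,
                bias_hook=hooks[k], traj_stride=traj_stride,
                copy=False, rng=rngs[k], evaluator=evs[k],
                record_initial=(n_segments == 0),
            )
            trajs[k].times.extend(seg_traj.times)
            trajs[k].positions.extend(seg_traj.positions)
            trajs[k].energies.extend(seg_traj.energies)
    return trajs, bias


# ---------------------------------------------------------------------------
# Infrequent metadynamics + kinetics
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class TransitionRecord:
    """One infrequent-MetaD run: biased time, acceleration, unbiased time."""

    t_metad: float          # ps, biased run time at the stop condition
    alpha: float            # acceleration factor <exp(beta V)> >= 1
    cv_final: float
    censored: bool = False  # run exhausted without a transition

    @property
    def time(self) -> float:
        """Unbiased transition time t = alpha * t_MetaD (ps)."""
        return self.alpha * self.t_metad


def log_acceleration_factor(v_series: np.ndarray, temperature: float) -> float:
    """log of the time-average of exp(beta V), via log-sum-exp.

    Stays finite for arbitrarily large deposited bias, where the factor
    itself would overflow a double.
    """
    v = np.asarray(v_series, dtype=float)
    if v.size == 0:
        raise ValueError("empty bias log")
    beta = 1.0 / (KB * temperature)
    return float(logsumexp(beta * v) - np.log(v.size))


def acceleration_factor(v_series: np.ndarray, temperature: float) -> float:
    """Time-average of exp(beta V) over a bias log.

    With V identically zero this is exactly 1; V >= 0 guarantees the factor
    is >= 1, so rescaled times can only stretch.
    """
    return float(np.exp(log_acceleration_factor(v_series, temperature)))


def run_infrequent_metad(
    system: System,
    cv: CVSpec,
    cfg: MetaDConfig,
    params: IntegratorParams,
    forcefield: ForceField,
    max_steps: int,
    stop_threshold: float = 0.5,
    stop_persistence: int = 10,
    monitor_stride: int = 50,
    restraint: RestraintParams | None = None,
) -> TransitionRecord:
    """One infrequent-MetaD escape run terminated by a CV stop rule.

    For the contacts CV the run stops once the switched contacts count stays
    below ``stop_threshold`` for ``stop_persistence`` consecutive monitor
    checks (the "contacts dropped to zero" rule made robust to noise).  The
    bias energy V(s(t), t) is accumulated every step for the acceleration
    factor.  If ``max_steps`` is exhausted the record is flagged censored.
    """
    bias = BiasState(widths=np.asarray(cfg.widths, dtype=float))
    log: dict = {"time": [], "cv": [], "bias": []}
    v_series: list[float] = []
    hook = _make_bias_hook(cv, cfg, bias, params, log, v_series=v_series)

    below = {"count": 0, "cv": np.nan}

    def stop(step: int, sys_: System) -> bool:
        if step % monitor_stride:
            return False
        if cv.kind == "contacts":
            s = cv_contacts(sys_, cv.groups[0], cv.groups[1], cv.r0)
        else:
            s = float(np.linalg.norm(cv_com_xy(sys_, cv.groups[0])))
        below["cv"] = s
        if s < stop_threshold:
            below["count"] += 1
        else:
            below["count"] = 0
        return below["count"] >= stop_persistence

    # already-satisfied stop at t = 0
    if stop(0, system) or (
        cv.kind == "contacts"
        and cv_contacts(system, cv.groups[0], cv.groups[1], cv.r0) < stop_threshold
    ):
        below["count"] = 0
        s0 = (
            cv_contacts(system, cv.groups[0], cv.groups[1], cv.r0)
            if cv.kind == "contacts"
            else float(np.linalg.norm(cv_com_xy(system, cv.groups[0])))
        )
        if s0 < stop_threshold:
            return TransitionRecord(t_metad=0.0, alpha=1.0, cv_final=s0)

    traj = run_md(
        system, max_steps, params, forcefield,
        bias_hook=hook, stop=stop, traj_stride=max(1, max_steps // 50),
        restraint=restraint,
    )
    t_biased = traj.times[-1] - traj.times[0]
    alpha = acceleration_factor(np.asarray(v_series), params.temperature)
    censored = below["count"] < stop_persistence
    return TransitionRecord(
        t_metad=float(t_biased), alpha=alpha,
        cv_final=float(below["cv"]), censored=censored,
    )


# ---------------------------------------------------------------------------
# Poissonian characteristic time
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class PoissonFit:
    """Characteristic time tau of P(n>=1; t) = 1 - exp(-t/tau), with GoF.

    ``tau`` is the exponential maximum-likelihood estimate (the sample mean);
    ``ks_stat``/``p_value`` are the two-sided Kolmogorov-Smirnov statistics
    of the times against Exp(tau).
    """

    tau: float
    n: int
    ks_stat: float
    p_value: float
    method: str = "mle-exponential"

    def cdf(self, t: np.ndarray) -> np.ndarray:
        """Fitted cumulative transition probability P(n>=1; t)."""
        return 1.0 - np.exp(-np.asarray(t) / self.tau)

    def summary(self) -> str:
        lines = [
            "Poissonian transition-time fit",
            "------------------------------",
            f"characteristic time tau : {self.tau:.6g} ps",
            f"sample size             : {self.n}",
            f"KS statistic            : {self.ks_stat:.4f}",
            f"KS p-value              : {self.p_value:.4f}",
            f"method                  : {self.method}",
        ]
        return "\n".join(lines)


def fit_poisson_tau(times: np.ndarray) -> PoissonFit:
    """Fit the Poissonian escape-time law to a sample of transition times.

    The exponential MLE for tau is the sample mean; goodness of fit is the
    two-sided KS test against Exp(tau).  Censored records must be excluded
    by the caller (they carry no transition time).  Scale-equivariant:
    multiplying all times by c multiplies tau by c.
    """
    t = np.asarray(times, dtype=float)
    if t.size < 1:
        raise ValueError("need at least one transition time")
    if (t < 0).any():
        raise ValueError("transition times must be non-negative")
    tau = float(t.mean())
    if t.size >= 2 and tau > 0:
        ks = stats.kstest(t, "expon", args=(0.0, tau))
        ks_stat, p = float(ks.statistic), float(ks.pvalue)
    else:
        ks_stat, p = np.nan, np.nan
    return PoissonFit(tau=tau, n=int(t.size), ks_stat=ks_stat, p_value=p)
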