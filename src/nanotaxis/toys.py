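"""Analytic 1D toy systems used to validate the sampling machinery.

The double well U(x) = B ((x/a)^2 - 1)^2 has minima at x = -a, +a separated
by a barrier of height B, all in closed form -- which makes it the oracle
for two validation pipelines:

* well-tempered metadynamics must recover F(x) = U(x) (up to a constant)
  from -V(x) * gamma_b/(gamma_b - 1);
* infrequent metadynamics + acceleration factor + Poisson fit must recover
  the brute-force mean first-passage time from the left well to the right.

Dynamics here is overdamped Brownian motion, dx = mobility F dt + noise,
with mobility 1/(gamma m) -- the same friction convention as the 3D
integrator.  Both the brute-force ensemble and the biased runs use this
identical propagator, so comparisons are apples to apples.  The biased
propagator keeps the bias on a fixed grid (analytic Gaussian increments for
both V and dV/dx), giving O(1) per-step evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .sampling import MetaDConfig, TransitionRecord, acceleration_factor
from .units import KB

__all__ = [
    "DoubleWell1D",
    "brute_force_fpt",
    "toy_infrequent_metad",
    "toy_wt_metad_profile",
]


@dataclass(frozen=True)
class DoubleWell1D:
    """U(x) = barrier * ((x/a)^2 - 1)^2; minima at +-a, barrier at x = 0."""

    barrier: float = 10.0   # kJ/mol
    a: float = 0.5          # nm
    mass: float = 72.0      # amu
    gamma: float = 1.0      # ps^-1

    def potential(self, x):
        return self.barrier * ((np.asarray(x) / self.a) ** 2 - 1.0) ** 2

    def force(self, x):
        x = np.asarray(x)
        return -4.0 * self.barrier * x * ((x / self.a) ** 2 - 1.0) / self.a**2

    @property
    def mobility(self) -> float:
        return 1.0 / (self.gamma * self.mass)


def brute_force_fpt(
    toy: DoubleWell1D,
    n_walkers: int,
    temperature: float = 300.0,
    dt: float = 0.02,
    x0: float | None = None,
    x_stop: float | None = None,
    seed: int = 0,
    max_steps: int = 5_000_000,
) -> np.ndarray:
    """Unbiased first-passage times (ps) from x0 (-a) to x_stop (+a).

    The whole ensemble is propagated in lockstep; walkers freeze once
    absorbed.  Raises if any walker fails to cross within ``max_steps``
    (increase the budget or lower the barrier).
    """
    x0 = -toy.a if x0 is None else x0
    x_stop = toy.a if x_stop is None else x_stop
    rng = np.random.default_rng(seed)
    mob = toy.mobility
    noise = math.sqrt(2.0 * KB * temperature * mob * dt)
    x = np.full(n_walkers, float(x0))
    t_hit = np.full(n_walkers, -1.0)
    active = np.ones(n_walkers, dtype=bool)
    for step in range(1, max_steps + 1):
        xi = rng.normal(size=n_walkers)  # fixed draw count keeps runs seeded
        x[active] += toy.force(x[active]) * mob * dt + noise * xi[active]
        crossed = active & (x >= x_stop)
        t_hit[crossed] = step * dt
        active &= ~crossed
        if not active.any():
            break
    if active.any():
        raise RuntimeError(f"{int(active.sum())} walkers never crossed within budget")
    return t_hit


@njit(cache=True)
def _metad_1d(
    x0, n_steps, dt, mob, noise, b, a, grid0, dg, vgrid, dvgrid,
    h0, width, stride, wt_denom, x_stop, seed, v_series,
):
    """Overdamped 1D metadynamics with grid-cached bias.

    wt_denom = k_B T (gamma_b - 1) for well-tempered damping, or 0 for
    standard metadynamics.  Returns (steps_done, crossed).
    """
    np.random.seed(seed)
    n_grid = vgrid.shape[0]
    x = x0
    inv_w2 = 1.0 / (width * width)
    for step in range(1, n_steps + 1):
        # linear interpolation of V and dV on the grid (clamped)
        u = (x - grid0) / dg
        if u < 0.0:
            u = 0.0
        if u > n_grid - 1.001:
            u = n_grid - 1.001
        k = int(u)
        frac = u - k
        v = vgrid[k] * (1.0 - frac) + vgrid[k + 1] * frac
        dv = dvgrid[k] * (1.0 - frac) + dvgrid[k + 1] * frac
        f = -4.0 * b * x * ((x / a) ** 2 - 1.0) / (a * a) - dv
        x += f * mob * dt + noise * np.random.normal()
        v_series[step - 1] = v
        if x >= x_stop:
            return step, True
        if step % stride == 0:
            h = h0
            if wt_denom > 0.0:
                h = h0 * math.exp(-v / wt_denom)
            for g in range(n_grid):
                xg = grid0 + g * dg
                z = (xg - x)
                e = h * math.exp(-0.5 * z * z * inv_w2)
                vgrid[g] += e
                dvgrid[g] -= e * z * inv_w2  # d/dxg of h exp(-(xg-x)^2/2w^2)
    return n_steps, False


def _bias_grid(toy: DoubleWell1D, span: float = 2.5, n: int = 801):
    g0 = -span * toy.a
    g1 = span * toy.a
    grid = np.linspace(g0, g1, n)
    return grid, g0, grid[1] - grid[0]


def toy_infrequent_metad(
    toy: DoubleWell1D,
    cfg: MetaDConfig,
    temperature: float = 300.0,
    dt: float = 0.02,
    x0: float | None = None,
    x_stop: float | None = None,
    seed: int = 0,
    max_steps: int = 2_000_000,
) -> TransitionRecord:
    """One infrequent-MetaD escape over the toy barrier -> TransitionRecord.

    Feeds the same acceleration-factor estimator as the 3D pipeline; the
    record's unbiased time is alpha * biased time.
    """
    x0 = -toy.a if x0 is None else x0
    x_stop = toy.a if x_stop is None else x_stop
    grid, g0, dg = _bias_grid(toy)
    vgrid = np.zeros_like(grid)
    dvgrid = np.zeros_like(grid)
    v_series = np.zeros(max_steps)
    wt_denom = (
        KB * temperature * (cfg.bias_factor - 1.0) if cfg.bias_factor else 0.0
    )
    noise = math.sqrt(2.0 * KB * temperature * toy.mobility * dt)
    steps, crossed = _metad_1d(
        float(x0), max_steps, dt, toy.mobility, noise, toy.barrier, toy.a,
        g0, dg, vgrid, dvgrid, cfg.height, cfg.widths[0], cfg.stride,
        wt_denom, float(x_stop), seed, v_series,
    )
    alpha = acceleration_factor(v_series[:steps], temperature)
    return TransitionRecord(
        t_metad=steps * dt, alpha=alpha, cv_final=float(x_stop),
        censored=not crossed,
    )


def toy_wt_metad_profile(
    toy: DoubleWell1D,
    cfg: MetaDConfig,
    n_steps: int,
    temperature: float = 300.0,
    dt: float = 0.02,
    x0: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Long confined well-tempered run; returns (grid, free-energy estimate).

    The estimate is F(x) = -V(x) gamma_b/(gamma_b - 1), the well-tempered
    convergence limit, shifted so its minimum is zero.
    """
    if cfg.bias_factor is None:
        raise ValueError("free-energy recovery needs a well-tempered bias factor")
    x0 = -toy.a if x0 is None else x0
    grid, g0, dg = _bias_grid(toy)
    vgrid = np.zeros_like(grid)
    dvgrid = np.zeros_like(grid)
    v_series = np.zeros(n_steps)
    wt_denom = KB * temperature * (cfg.bias_factor - 1.0)
    noise = math.sqrt(2.0 * KB * temperature * toy.mobility * dt)
    _metad_1d(
        float(x0), n_steps, dt, toy.mobility, noise, toy.barrier, toy.a,
        g0, dg, vgrid, dvgrid, cfg.height, cfg.widths[0], cfg.stride,
        wt_denom, 1e30, seed, v_series,  # no absorbing boundary
    )
    gb = cfg.bias_factor
    f_est = -vgrid * gb / (gb - 1.0)
    f_est -= f_est.min()
    return grid, f_est
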