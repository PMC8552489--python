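"""Validated TOML run configuration.

One TOML file describes a complete experiment: what to build (nanoparticle,
surface, assembly), how to integrate, what bias/external forces to apply and
what to measure.  Unknown keys are rejected at load.  Every artifact the
package writes embeds the configuration hash, so outputs are traceable to
(config, seed).
"""

from __future__ import annotations

import hashlib
import tomllib
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict

from . import builders
from .builders import OligomerTemplate, SurfaceSpec
from .dynamics import ExternalForce, IntegratorParams
from .forcefield import (ForceField, RestraintParams, WallParams,
                         fcg_pair_table, mcg_pair_table)
from .sampling import CVSpec, MetaDConfig

__all__ = ["RunConfig", "load_config", "dump_toml"]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NPSection(_Model):
    n_monomers: int = 200            # mCG mode
    n_oligomers: int = 44            # fCG mode
    n_guests: int = 0
    n_charged_heads: int = 3
    n_tails: int = 3
    tail_length: int = 2


class SurfaceSection(_Model):
    kind: Literal["two_region", "stripes", "uniform"] = "uniform"
    lx: float = 20.0
    ly: float = 20.0
    rho: float = 1.0                          # uniform
    rho_high: float = 1.0                     # two_region
    ratio: float = 0.015625                   # two_region: rho_low/rho_high
    stripe_densities: list[float] = [0.0, 0.12, 0.52, 1.12]
    stripe_lx: float = 30.0
    receptor_model: Literal["monobead_frozen", "tribead_tethered"] = "monobead_frozen"
    placement: Literal["poisson_disc", "lattice"] = "poisson_disc"
    head_charge: float = 0.0
    lz: float = 15.0


class AssemblySection(_Model):
    z_offset: float = 0.8
    neutralize: bool = False
    xy: Optional[list[float]] = None


class IntegratorSection(_Model):
    dt: float = 0.02
    temperature: float = 300.0
    gamma: float = 1.0


class MetadSection(_Model):
    cv: Literal["com_xy", "contacts"] = "com_xy"
    height: float = 20.0
    widths: list[float] = [1.0, 1.0]
    stride: int = 5000
    bias_factor: Optional[float] = None
    r0: float = 0.6
    log_stride: int = 10


class ExternalSection(_Model):
    group: str = "np"
    vector: list[float] = [-100.0, 0.0, 0.0]


class RestraintSection(_Model):
    z0: float = 5.0
    kappa: float = 150.0
    exp: int = 2
    group: str = "np"


class WallSection(_Model):
    eps_w: float = 2.0
    sigma_w: float = 0.47


class ObservablesSection(_Model):
    contact_cutoff: float = 0.6
    persistence: int = 10
    probe_radius: float = 0.19
    sasa_points: int = 960


class ToySection(_Model):
    barrier: float = 10.0
    a: float = 0.5
    mass: float = 72.0
    gamma: float = 1.0


class RunConfig(_Model):
    """Top-level validated run configuration."""

    mode: Literal["mcg", "fcg", "toy1d"] = "mcg"
    seed: int = 0
    np_: NPSection = NPSection()
    surface: SurfaceSection = SurfaceSection()
    assembly: AssemblySection = AssemblySection()
    integrator: IntegratorSection = IntegratorSection()
    metad: Optional[MetadSection] = None
    external: Optional[ExternalSection] = None
    restraint: Optional[RestraintSection] = None
    wall: WallSection = WallSection()
    observables: ObservablesSection = ObservablesSection()
    toy: Optional[ToySection] = None

    # -- factories ---------------------------------------------------------
    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:12]

    def surface_spec(self) -> SurfaceSpec:
        s = self.surface
        common = dict(
            receptor_model=s.receptor_model, placement=s.placement,
            head_charge=s.head_charge, lz=s.lz,
        )
        if s.kind == "two_region":
            return builders.two_region_spec(s.lx, s.ly, s.rho_high, s.ratio, **common)
        if s.kind == "stripes":
            return builders.gradient_stripes_spec(
                s.stripe_densities, s.stripe_lx, s.ly, **common)
        return builders.SurfaceSpec(
            lx=s.lx, ly=s.ly,
            regions=(builders.Region(0.0, s.lx, 0.0, s.ly, s.rho),), **common)

    def build_np(self, seed: int | None = None) -> "builders.System":
        seed = self.seed if seed is None else seed
        if self.mode == "mcg":
            return builders.build_nanoparticle_mcg(
                self.np_.n_monomers, self.np_.n_guests, seed=seed)
        template = OligomerTemplate(
            n_hydrophobic_tails=self.np_.n_tails,
            tail_length=self.np_.tail_length,
            n_charged_heads=self.np_.n_charged_heads,
        )
        return builders.build_nanoparticle_fcg(
            template, self.np_.n_oligomers, self.np_.n_guests, seed=seed)

    def build_system(self, seed: int | None = None) -> "builders.System":
        seed = self.seed if seed is None else seed
        np_frag = self.build_np(seed=seed)
        surf = builders.build_surface(self.surface_spec(), seed=seed + 1)
        xy = tuple(self.assembly.xy) if self.assembly.xy else None
        return builders.assemble_system(
            np_frag, surf, z_offset=self.assembly.z_offset,
            neutralize=self.assembly.neutralize, seed=seed + 2, xy=xy)

    def forcefield(self) -> ForceField:
        table = mcg_pair_table() if self.mode == "mcg" else fcg_pair_table()
        wall = WallParams(eps_w=self.wall.eps_w, sigma_w=self.wall.sigma_w)
        return ForceField(table, wall=wall)

    def integrator_params(self, seed: int | None = None) -> IntegratorParams:
        i = self.integrator
        return IntegratorParams(dt=i.dt, temperature=i.temperature, gamma=i.gamma,
                                seed=self.seed if seed is None else seed)

    def metad_config(self) -> MetaDConfig:
        if self.metad is None:
            raise ValueError("config has no [metad] section")
        m = self.metad
        return MetaDConfig(height=m.height, widths=tuple(m.widths), stride=m.stride,
                           bias_factor=m.bias_factor, log_stride=m.log_stride)

    def cv_spec(self) -> CVSpec:
        m = self.metad
        if m is None:
            raise ValueError("config has no [metad] section")
        if m.cv == "com_xy":
            return CVSpec("com_xy", ("np",))
        return CVSpec("contacts", ("np-charged", "receptor-head"), r0=m.r0)

    def external_force(self) -> ExternalForce | None:
        if self.external is None:
            return None
        return ExternalForce(group=self.external.group,
                             vector=tuple(self.external.vector))

    def restraint_params(self) -> RestraintParams | None:
        if self.restraint is None:
            return None
        r = self.restraint
        return RestraintParams(z0=r.z0, kappa=r.kappa, exp=r.exp, group=r.group)


_SECTION_ALIASES = {"np": "np_"}


def load_config(path) -> RunConfig:
    """Load and validate a TOML run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    raw = {_SECTION_ALIASES.get(k, k): v for k, v in raw.items()}
    return RunConfig.model_validate(raw)


def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_scalar(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def dump_toml(cfg: RunConfig) -> str:
    """Serialize a RunConfig back to TOML (load(dump(x)) == x)."""
    data = cfg.model_dump(exclude_none=True)
    rev = {v: k for k, v in _SECTION_ALIASES.items()}
    out: list[str] = []
    scalars = {k: v for k, v in data.items() if not isinstance(v, dict)}
    tables = {k: v for k, v in data.items() if isinstance(v, dict)}
    for k, v in scalars.items():
        out.append(f"{rev.get(k, k)} = {_toml_scalar(v)}")
    for k, tbl in tables.items():
        out.append(f"\n[{rev.get(k, k)}]")
        for kk, vv in tbl.items():
            if vv is None:
                continue
            out.append(f"{kk} = {_toml_scalar(vv)}")
    return "\n".join(out) + "\n"
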