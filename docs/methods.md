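# Methods

## Models

### Unit system

kJ mol⁻¹, nm, ps, amu, elementary charges, kelvin, package-wide.  In these
units 1 amu nm² ps⁻² = 1 kJ mol⁻¹, so kinetic energies need no conversion
factor; k_B = 0.008314 kJ mol⁻¹ K⁻¹ and the Coulomb prefactor is
138.935 kJ mol⁻¹ nm e⁻².

### Minimalistic (mCG) model

One bead per monomer.  The self-assembly well ΔE_ass is a 12–6 LJ pair with
σ = 0.47 nm, ε = 10 kJ mol⁻¹; the monomer–receptor binding well ΔE_bind has
σ = 0.35 nm, ε = 40 kJ mol⁻¹ (ΔE_ass/ΔE_bind = 1/4, the regime in which
binding can destabilize the assembly).  Guest beads use σ = 0.43 nm,
ε = 6.5 kJ mol⁻¹ against themselves and the monomers.  Receptors are single
frozen beads on the z = 0 plane.  The surface additionally exerts a 9–3
integrated LJ wall on all mobile non-receptor beads,
U(z) = (3/√10) ε_w [(2/15)(σ_w/z)⁹ − (σ_w/z)³], normalized so the well
depth is exactly the quoted ε_w = 2.0 kJ mol⁻¹ (the 9–3 prefactor
convention is otherwise arbitrary; the depth is the physically meaningful
number).  σ_w defaults to 0.47 nm.

Bead masses are not physically constrained at this resolution; all CG beads
default to 72 amu (the common four-heavy-atom convention).

### Oligomer (fCG-like) model

A generic parameterizable amphiphile: one core bead, three two-bead
hydrophobic tails, and 1–3 hydrophilic heads carrying −1 e each, connected
by harmonic bonds (r₀ = 0.47 nm, k = 4000 kJ mol⁻¹ nm⁻²) with a soft
straightening angle on each tail.  The template's net charge equals its
head count, so 44 trivalent oligomers give the −132 e assembly.  Default
nonbonded parameters: tails ε = 6.0 (assembly driver), cores 3.0, heads 1.0
kJ mol⁻¹, all σ = 0.47 nm with Lorentz–Berthelot mixing; guests are
tabulated explicitly at σ = 0.43 nm, ε = 6.5 kJ mol⁻¹ against tails and
cores; the head–receptor pair is tabulated at σ = 0.40 nm so the ±1 e
electrostatic attraction (ε_r = 15) dominates binding.  Receptors are
three-bead tethered chains: frozen base at z = 0, linker, +1 e head, bonds
r₀ = 0.3 nm, plus a straightening angle.  No explicit solvent anywhere;
screening is carried by ε_r = 15 and the Langevin friction.

### Nonbonded evaluation

Plain cutoff at 1.1 nm for both LJ and Coulomb, both cut-and-shifted so the
pair energy is continuous at the cutoff (important for stable 20 fs
Langevin dynamics; no reaction field, no Ewald).  Periodicity is x/y only —
the surface breaks symmetry along z — implemented as minimum image in the
plane.  Neighbor lists come from a periodic k-d tree with a 0.3 nm Verlet
skin, rebuilt when any bead has moved half a skin; frozen–frozen pairs and
bonded 1-2/1-3 pairs are excluded.  A brute-force all-pairs sum reproduces
the listed evaluation exactly in the tests.

## Dynamics

Leapfrog stochastic dynamics in the kick / friction–noise / drift
splitting: v ← v + (f/m)Δt; v ← c₁v + √((1−c₁²)k_BT/m) ξ with
c₁ = e^{−γΔt}; x ← x + vΔt.  For a free particle the stationary velocity
variance is exactly k_BT/m, so the thermostat is unbiased by construction;
with the noise switched off the scheme reduces to plain leapfrog (used in
the energy-conservation test).  Defaults: Δt = 0.02 ps, T = 300 K,
γ = 1 ps⁻¹ per bead.  The friction is not a physically fitted value — all
times in this package are internally consistent but not convertible to the
laboratory times of any particular chemistry.

Frozen beads are excluded from integration entirely.  A constant external
force on a group is distributed mass-weighted over the group's mobile
beads, which realizes exactly that force on the group COM; its drift
velocity F/(γΣm) is verified against the closed form.  The one-sided COM
restraint U = κ(z−z₀)^p (defaults z₀ = 5 nm, κ = 150, p = 2) acts on the
NP COM only.  A reflecting floor 0.05 nm above the surface plane guards the
9–3 wall singularity against the occasional extreme thermal kick.
Production runs are preceded by a damped displacement-capped minimization
(steepest-descent-like, 0.02 nm cap) so builder artifacts cannot destabilize
the first steps.

## Metadynamics

Gaussian kernels are deposited every `stride` steps along the CV;
well-tempered damping multiplies the height by e^{−V/(k_BT(γ_b−1))}.  The
COM-xy CV biases only the particle's position in the surface plane (no
bias force along z); the contacts CV is the rational switch
Σ 1/(1+(r/r₀)⁶) (equal to the 6/12 form (1−x⁶)/(1−x¹²); value ½ at
r = r₀), with r₀ = 0.6 nm by default, differentiable so the bias force
follows from the chain rule.  Kernel widths carry CV units (nm for COM,
dimensionless counts for contacts).  The two-region mCG bias uses standard
(non-tempered) metadynamics with the 20 kJ mol⁻¹ / width 1.0 nm kernel
schedule; a bias factor is used only where kinetics are extracted.

Multiple walkers share one bias: walkers advance in lockstep one deposit
stride at a time and deposit in walker order, so the merged kernel sequence
is deterministic given the seeds.

### Infrequent metadynamics and kinetics

Escape runs deposit sparsely (the deposition period must exceed the bound
state's internal relaxation time) and stop when the monitored CV satisfies
the stop rule; for contacts this is "below 0.5 for 10 consecutive checks",
a noise-robust version of "contacts dropped to zero".  Each run's unbiased
time is t = α·t_MetaD with α = ⟨e^{βV(s(t),t)}⟩ averaged over every step of
the run (log-sum-exp accumulation; α ≥ 1 because V ≥ 0).  The rescaled
times are fitted by the Poisson law P_{n≥1}(t) = 1 − e^{−t/τ}; the MLE for
τ is the sample mean, and a two-sided Kolmogorov–Smirnov test against
Exp(τ) supplies the standard self-consistency diagnostic.  Censored runs
(no transition within the step budget) are excluded from the fit and
reported separately.

### 1D toy validation

The analytic double well U(x) = B((x/a)²−1)² (defaults B = 10 kJ mol⁻¹ ≈
4 k_BT, a = 0.5 nm) is propagated by overdamped Brownian dynamics with the
same friction convention as the 3D engine.  The biased toy keeps V and
dV/dx on a fixed grid (analytic Gaussian increments, linear interpolation),
giving O(1) per-step cost.  Two oracles use it: (i) well-tempered recovery
— −V·γ_b/(γ_b−1) must match U within 0.5 k_BT over the well-to-well window
after a 3×10⁶-step run (h = 1 kJ mol⁻¹, w = 0.1 nm, stride 500, γ_b = 8);
(ii) kinetics — 30 infrequent runs (h = 0.5, w = 0.15 nm, stride 1000,
γ_b = 10) must reproduce the brute-force mean first-passage time (200
walkers) within a factor of 2 with KS p > 0.05.

## Builders

Builders are deterministic under a fixed seed.  The mCG cluster is a
jittered cubic lattice filling a ball (lattice spacing 2^{1/6}σ, jitter
small enough to keep all separations above 0.9 σ), with guests on the
innermost sites; self-assembly MD would give the same downstream physics at
far higher cost.  The micelle builder places oligomer cores on a Fibonacci
sphere, tails inward, heads outward, guests in the cavity, then runs a
short damped quench.  Surface receptor counts are exact:
round-half-away-from-zero of area × ρ per region, so density-ratio checks
(e.g. the 64:1 two-region contrast) are exact up to that integer rounding.
Default placement is seeded dart throwing with minimum gap 1/√(2ρ) (a
packing fraction of π/8, always feasible); lattice placement is kept for
exact-geometry tests.  Counterions (+/−1 e, σ = 0.35 nm) are added at
random non-overlapping positions to zero the total charge.

## Desk-scale study conditions

Two scaled experiments stand in for the full-scale surface studies (full
presets are packaged, but their sampling cost is far beyond a test suite).
Sizes and schedules were fixed once, before being wired into the
validation suite, and are deliberately small:

* **Two-region chemotaxis** — 200-monomer mCG assembly on a 30 × 30 nm
  two-region surface (ρ_high = 0.4 nm⁻², ratio 1/64), started in the sparse
  half; COM-xy metadynamics with the 20 kJ mol⁻¹ / 1.0 nm kernels at a
  stride of 250 steps (denser in time than the full-scale schedule, matching
  the much shorter run), 1.5 × 10⁵ steps — long enough that the transit from
  the sparse start is a minor fraction of the exposure — and 10 seeds.
  Multivalent trapping should leave the assembly in the dense half in nearly
  all seeds and give it the larger share of the run's occupancy.
* **Rolling / release** — 12 trivalent or monovalent oligomers with 6
  guests, pulled by the 100 kJ mol⁻¹ nm⁻¹ COM force across 8 nm stripes of
  ρ = 0 / 0.12 / 0.52 / 1.12 nm⁻², z-restraint at 5 nm (κ = 150, p = 2),
  1.5 × 10⁵ steps, 3 seeds per valence.  For this experiment the
  guest–oligomer well is rescaled from 6.5 to 5.0 kJ mol⁻¹ and the
  head–receptor well deepened to 10 kJ mol⁻¹ (`scaled_fcg_pair_table`):
  with the full-strength guest well, guest escape is a ≥15 k_BT event that
  occurs on the millisecond scales of the original study design and is
  simply invisible in nanosecond runs — the same reasoning that puts the
  kinetics validation on a ≤5 k_BT toy barrier.

What the synthetic systems do **not** emulate: explicit solvent and
hydrodynamics, chemically mapped oligomer force fields, PME electrostatics,
and laboratory time scales (the friction is conventional).  Tests passing
on these systems demonstrate the correctness of the machinery and the
direction of the physical trends, not quantitative rates for any real
chemistry.

## Numerical choices and edge cases

* LJ/Coulomb are cut-and-shifted; energies are continuous, forces have the
  usual small jump at r_c.
* The instability guard triggers when any bead moves more than half the
  cutoff in one step; the last good frame is preserved.
* SASA uses Shrake–Rupley (960 sphere points by default) with radii
  σ/2 + 0.1 nm and probe 0.19 nm; single beads match the analytic sphere to
  <1 %.
* Release uses a hard 0.6 nm contact cutoff and a 10-frame persistence
  window so transient detachments are not counted; the cumulative release
  fraction is non-decreasing by construction.
* Region occupancy wraps the COM into the box before assignment; fractions
  sum to one.
* The Poisson fit requires at least two uncensored times for a KS check; a
  single time yields the point estimate only.
* Degenerate inputs (empty groups, zero-atom files, zero-density surfaces,
  all-censored kinetics) raise explicit errors rather than returning
  placeholder values.

## Known limitations

* No pressure coupling, no constraint algorithms, no reaction-field or
  Ewald electrostatics; the ε_r = 15 screened cutoff is a deliberate
  simplification.
* Standard (non-tempered) metadynamics never converges to a bounded bias:
  in the two-region experiment the kernels eventually overfill the
  dense-region trap and push the assembly back toward the sparse half, so
  the end-of-run position statistic degrades as runs lengthen even while
  the dense-region share of the total exposure keeps improving.  The
  packaged run length favors the occupancy statistic.
* In the rolling/release experiment two release channels compete:
  binding-driven exposure of guests when a multivalent assembly flattens on
  dense receptor regions, and *mechanical* shedding when a weakly bound
  assembly rolls fast under the drag force.  At nanosecond run lengths the
  mechanical channel is strong for monovalent assemblies (they roll
  farthest), so the ranking of release between valences is noisy and can
  invert the slow-time-scale expectation in which disassembly dominates;
  the per-valence *binding* observables (engagement counts, trapping
  position, flattening) discriminate robustly, the release percentages do
  not.
* Absolute time scales are internally consistent only; mapping to
  laboratory kinetics would require calibrating γ against a diffusion
  measurement.
* The generic oligomer is not a chemically mapped molecule; its pair table
  places it in the intended ΔE_ass vs ΔE_bind regime but no more.
* Counterion screening in small boxes is stronger than at realistic
  dilution; neutralization is optional per experiment.
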