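# Methods

## The model

A mitotic chromosome is represented as a flexible bead-spring chain of `N`
spherical monomers of diameter σ (the length unit), each coarse-graining
roughly ten nucleosomes.  Neighbouring monomers are joined by harmonic
springs of natural length `d_B = σ` and coefficient `ε_spr = ε_cut = 1000
kT`.  The springs are *phantom*: they carry no excluded volume of their
own, so one chain segment can pass through another — an implicit stand-in
for topoisomerase II strand passage.  Monomer excluded volume is a purely
repulsive Weeks–Chandler–Andersen (WCA) potential with contact energy
`ε = 1 kT`, cut off at `2^(1/6) σ`, and *energy-capped* at `ε_cut =
1000 kT`: below the cap radius `r_cap ≈ 0.628 σ` (where the uncapped
energy reaches `ε_cut`) the energy is clamped and the pair force is zero.
A `cap_mode="linear"` switch instead continues the potential with the
constant force it has at `r_cap`; the flat clamp is the default.

Condensins are point particles (mass 1, friction 1, no excluded volume)
with two activities:

* **loop holding** — the i-th condensin of a chain is tied to the two
  base-point monomers of its loop, monomers `(i−1)L` and `iL−1`
  (0-based), by zero-natural-length harmonics of coefficient
  `F_loop · ε_cut`.  Loops are consecutive: `M` loops of `L = N/M`
  monomers partition the chain.
* **finite-range attraction** — every condensin pair closer than the
  threshold `Δ` interacts with energy `−F_cond ε_cut (r − Δ)²`, in cis and
  in trans alike, zero at and beyond `Δ`.

The force parameters `F_loop` and `F_cond` are dimensionless, expressed in
units of the cap energy `ε_cut` — the same stiffness scale as the chain
springs.  This scale matters qualitatively: at `kT`-scale coefficients the
condensin terms are inert (no axis, no trans-attraction); at the `ε_cut`
scale the loop bonds press the two base monomers of a loop into contact at
≈ 0.8–0.9 σ (excluded volume stops further approach), so the *dressed*
condensin–condensin contact distance is just under 1 σ.  That floor
reproduces the model's characteristic Δ-dependence: for `Δ < 1` condensins
essentially never come within range; for `1 < Δ < 2.5` they latch into a
condensin axis; for large `Δ` inter-chain (trans) bonds become so deep
that the chains cannot separate.

## Dynamics

Langevin dynamics (`m dv = F dt − γ v dt + √(2γkT) dW`, with `m = γ = kT
= 1`) are integrated with the BAOAB splitting of velocity Verlet: half
kick, half drift, exact Ornstein–Uhlenbeck velocity refresh, half drift,
force recomputation, half kick.  At `γ = 0` the scheme is plain velocity
Verlet, which the test suite uses for microcanonical energy-conservation
checks.  Monomer–monomer WCA forces use a cell list rebuilt every step
(no periodic boundaries); condensin pairs are evaluated all-pairs.  The
cell list reproduces the all-pairs reference forces to 1 × 10⁻¹² relative.

**Timestep.** The nominal model timestep is 0.01.  For chains alone this
is comfortably stable (`ω dt ≈ 0.32` for the springs).  With the
`ε_cut`-scale condensin bonds, however, base-point monomers are pressed to
pair distances ≈ 0.8 σ where the capped-WCA curvature is ≈ 1.4 × 10⁴
kT/σ², putting `ω dt` near the velocity-Verlet stability boundary; in
compacted melts rare fluctuations then detonate (measured kinetic
temperature runs away to ~10³).  The default production timestep is
therefore `dt = 0.005`, at which long melt runs hold `⟨KE⟩/dof ≈
0.5–0.7 kT` (exact equipartition is recovered by `dt = 0.0025`; the
residual ~20 % local heating at 0.005 is accepted as the cost of staying
within practical budgets).  Integrator validation tests (equipartition of
a free chain, dimer energy conservation) run at `dt = 0.01`, where those
systems are stable.

## Initial configurations

1. **Random walk** — each chain starts as an ideal (non-self-avoiding)
   random walk with step `d_B`; the energy cap lets later dynamics resolve
   the initial overlaps.
2. **Shell compaction** — a harmonic spherical wall (force capped at 20
   kT/σ so the drift stays integrable) compacts the chains into a shell of
   diameter `22.85 · n_chains^(1/3)` (22.85 for one chain, 28.79 for two),
   matching chromatin density in the nucleus, followed by thermostatted
   equilibration.  The first half of the compaction schedule runs with the
   energy cap lowered to 10 kT (a soft potential under which overlaps
   melt); before switching to the full potential, residual deep overlaps
   — pairs trapped on the flat part of the cap, where no force acts and
   which would otherwise slide down a 1000 kT cliff once thermal motion
   carries them across the cap radius — are separated explicitly and the
   state is descent-relaxed.
3. **Deterministic loop extrusion** — condensins appear on the mid-loop
   monomer `(i−0.5)L` with both bonds attached there; the bonds step
   outward symmetrically, one monomer per side per advance, with
   `pacing` thermostatted MD steps between advances (100 at the reference
   chain length `N = 5000`, scaled as `N^(2/3)` so the free expansion of
   the released melt stays proportionate at miniature scales).  During
   extrusion the bonds are ordinary stiff bonds (coefficient `ε_spr`,
   zero natural length), which keeps the bond monomers at the condensin
   and makes the finished configuration independent of `F_loop`.
4. **Crossings** — `Cr` times per loop, when the extruded length first
   reaches `k·L/Cr` (capped at `L−3` so the rewire always happens strictly
   inside the loop), the two chain springs flanking the current bond pair
   `(a, b)` are rewired from `(a−1, a), (b, b+1)` to `(a−1, b), (a, b+1)`,
   installing one crossing that mimics a supercoil crossover.  The chain's
   spring graph remains a single path throughout; with `L = 50, Cr = 5`
   crossings fire at extruded lengths 11, 21, 31, 41, 47.
5. **Strain control** — a rewired spring starts stretched by 1–2 σ, which
   at coefficient 1000 is a catapult; after every rewire and advance the
   system is relaxed by displacement-limited steepest descent (step
   clipped at 0.02 σ) until the longest spring is within tolerance of its
   natural length, and velocities are quenched.  A final anneal
   (descent / short MD / quench cycles, then overlap separation) hands a
   strain-free state to production, which re-thermalizes within about one
   friction time.

The deterministic extrusion is an initializer, not a model of extrusion
kinetics: no binding/unbinding, and bonds never change after it completes.

## Observables

* **Gyration tensor / asphericity** — `G_ab = ⟨(r_a − r̄_a)(r_b − r̄_b)⟩`
  per chain; with eigenvalues `λ₁² ≥ λ₂² ≥ λ₃²`, the normalized
  asphericity is `[λ₁² − (λ₂² + λ₃²)/2] / (λ₁² + λ₂² + λ₃²)` (0 = sphere,
  1 = rod) and `R_g = √(λ₁² + λ₂² + λ₃²)`.
* **Overlap** — each loop contributes a sphere (center: loop center of
  mass; radius: farthest loop monomer).  The directional overlap a→b is
  the fraction of chain-a monomers inside the union of chain b's spheres;
  the reported scalar is the mean of the two directions (both directions
  retained).  Symmetrization is a package choice: the source definition is
  one-directional and does not say which.
* **Trans-/cis-attraction** — fraction of condensins with at least one
  condensin of another / the same chain strictly within `Δ`.
* **Segregation metrics** — segregation time = first time the overlap
  crosses 0.2, linearly interpolated between samples (stable under
  resampling); speed = its inverse; runs that never cross are *censored*
  (speed reported as 0, never as a finite value).  Trans-decay time =
  first sample with exactly zero trans pairs sustained for at least one
  further sample (guards against single-sample flicker).
* **Condensin axis profile** — the axis is a polyline whose i-th segment
  joins condensins `5(i−1)` and `5i−1` in chain order; each condensin's
  distance to its own segment is histogrammed (bin width 0.25 σ) and
  normalized to 1 at the origin bin.  The profile is computed for any
  input; it is physically meaningful where an axis exists (roughly
  `1 < Δ < 2.5`).

## Experiments and averaging

`run_experiment` builds one initial configuration per replicate (seeds
spawned deterministically from a master seed via `SeedSequence.spawn`),
runs production dynamics, and aggregates: means over replicates, censored
replicates counted and excluded from mean times.  Default replicates: 5.
Equilibrium values are means over the final quarter of the sampled series.
Sweeps run a grid over (`F_cond`, `Δ`, `F_loop`) and label each point by
the `Δ = 2.5` branch of the shape–segregation correlation.

**Problem sizes.**  The package's test suite and acceptance script run
miniature versions of the study conditions: fixtures `tiny` (N = 60,
M = 3, Cr = 1) for topology checks, `small` (N = 500, M = 10, Cr = 5, loop
length 50 as in the reference setup) for trend reproduction, and `paper`
(N = 5000, M = 100, Cr = 5) for initial-configuration statistics.  For
fixtures the compaction shell is scaled to keep the reference per-chain
density (`D₁ = 22.85 · (N/5000)^(1/3)`).  Scaled-down runs reproduce
directions of effects (Δ-dependence of shape and segregation, ordering of
trans-decay vs segregation), not the full-scale magnitudes: a 500-monomer
chain has far fewer entanglements, segregates faster, and has much larger
shape fluctuations than a 5000-monomer chromosome.

## What the synthetic data does and does not emulate

All inputs are generated internally; there is no external data.  The
generator emulates the study conditions (chain sizes, loop length 50,
crossing counts, densities, force parameters).  It does not emulate
sequence heterogeneity, condensin I/II differences, explicit topoisomerase
kinetics, hydrodynamics, or bending rigidity — all outside the model.
Passing tests therefore show that the implementation reproduces the
*model's* behaviour at the tested sizes, not that the model describes any
particular real chromosome.

## Known limitations

* **Quenched vs thermal extrusion.**  The initializer's descent/quench
  protocol is what makes the extrusion integrable, but it hands over a
  *cold, compact* initial state: the free thermal expansion that a fully
  thermal extrusion would produce (chains swelling well beyond the
  compaction shell, loops hanging open and covering the partner chain)
  never happens.  Full-scale initial configurations are therefore more
  compact (smaller R_g) and show lower loop-sphere overlap than
  thermal-extrusion preparation would give, although they are equally
  entangled topologically.  The initial-report timestamp is recorded so
  either measurement convention (immediately post-extrusion, or after
  extra free equilibration) is reproducible.
* **Entanglement does not survive aggressive scale-down.**  The model's
  short-range-attraction regime (Δ = 0.5) keeps *full-scale* chromosome
  pairs entangled for very long times; 500-monomer chains release their
  entanglements entropically within a few hundred time units regardless
  of condensin activity, so at fixture scale the Δ = 0.5 systems segregate
  too.  Scaled-down runs reproduce the shape trend with Δ and the
  trans-decay-before-segregation ordering, but not censoring contrasts
  that depend on long-lived entanglement.

* The flat energy cap makes the potential non-smooth at `r_cap`; states
  with pairs inside the cap radius are handled (zero force, capped
  energy) but dynamically fragile, which is why the initializer separates
  such pairs explicitly.
* At `dt = 0.005` compacted melts carry ~10–20 % excess kinetic energy in
  stiff local modes; comparisons between parameter sets are made at the
  same timestep.
* Full-scale segregation time-courses (two chains × 5000 monomers ×
  10³–10⁴ time units) take hours of CPU; the packaged experiments default
  to the scaled-down sizes above, with full-scale runs available through
  the same API and CLI.
* The trans-decay criterion ("exactly zero, sustained") is sensitive to
  the sampling cadence for marginal cases; the default cadence samples
  every 10–20 time units.
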