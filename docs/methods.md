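# Methods

This note documents the models implemented in `larvanet`, the choices made
where the design was genuinely open, and what the synthetic fixtures do and
do not establish about real systems.

## Particle transport model

Larvae are point particles in a horizontal flow field. Per 30-minute time
step (daily output), an active particle is

1. **advected** with the classical four-stage Runge–Kutta scheme; velocity
   is sampled at each stage position and stage time and converted from
   m s⁻¹ to angular rates with the local metric (meters per degree
   longitude scaled by cos φ);
2. **diffused** per horizontal axis with the first-order Milstein scheme,
   Δx = √(2K)·ΔW + ½ ∂K/∂x (ΔW² + dt), ΔW ~ N(0, dt). The deterministic
   half of the gradient term is the well-mixed drift correction, so for
   linear K the expected displacement is (∂K/∂x)·dt and for constant K the
   single-step variance is 2K·dt per axis;
3. **moved vertically**: either pinned at a fixed depth (1 m default), or
   sinking at w_sink while swimming toward the preferred depth z_pref at up
   to w_swim; swimming covers only the remaining distance if z_pref is
   reached within the step (sinking continues — the behavioral description
   stops only the swimming). Depths are clamped 0.1 m below the surface
   and 0.1 m above the bathymetry. Vertical advection and diffusion are
   excluded by design: behavior is assumed to dominate them.

Traits are drawn once per particle from clipped normals — draws outside
mean ± n·SD are redistributed uniformly on that band, which preserves the
mean — with w_sink ~ 0.6(3) mm s⁻¹ and w_swim ~ 2.4(20) mm s⁻¹ clipped at
1 SD, and z_pref ~ N(local MLD at spawn, 5 m) clipped at 2 SD. Cohorts are
seeded as a Poisson point process over water with expected density
1.3 particles km⁻² by default (runs in this repository use lower densities;
see *Problem sizes*).

**Beaching.** Land is exactly the zero-interpolated-velocity region: the
field containers guarantee zero velocity on land cells, and the beach test
asks whether the particle's containing cell is land. This is equivalent to
the "interpolated speed is exactly zero" definition on any compliant field
while avoiding false beaching at interior stagnation points (gyre centers)
and in the all-zero diagnostic field. Beached particles, and particles
leaving the lateral domain, are frozen and excluded from all analysis.

**Settlement.** The maximum pelagic larval duration is a constant 45 days.
FD and PD particles settle wherever they are at day 45. SH particles must
spawn over suitable habitat and settle at the first daily output within
the competency window — checks at days 39, 40, …, 45 (seven checks, the
final 7 days) — at which they sit over a suitable cell; otherwise they are
non-viable. A particle that passes over habitat on day d and beaches later
still settles at day d (the settlement logically precedes the beaching).
PD and SH are resolved from one shared simulation so their stochastic
transport is identical.

**Reproducibility.** One seed drives three derived streams (placement,
traits, diffusion). Diffusion noise for step k comes from a
counter-derived Philox stream (`jumped(k)`), particle i reading fixed
slots, so enlarging a cohort never reshuffles the draws of existing
particles, and zero-diffusivity runs are bit-reproducible.

## Hexagonal binning

Positions are binned on a hexagonal grid following the icosahedral
aperture-7 refinement scheme: N(r) = 2 + 120·7^r global cells at
resolution r, of which exactly 12 are pentagons at every resolution (a
consequence of Euler's formula for 3-regular sphere tilings), giving a
mean resolution-5 cell area of ≈ 252.9 km². Regionally the grid is
realized as regular hexagons of exactly that mean area on a Lambert
cylindrical equal-area projection anchored at the domain center, so planar
area equals spherical area and every coordinate maps to exactly one cell.
This reproduces the scheme's resolution ladder and constants without
depending on an external indexing library; the hierarchical parent/child
relation beyond the area ladder is not implemented because the pipeline
never uses it.

## Transport network

Each settled particle contributes one (spawn cell → settlement cell)
transition; intermediate bins are deliberately discarded. Particles
settling in cells where no retained particle spawns are deleted,
*iterated to a fixed point* (deletions can empty a spawn cell, whose
settlers must then be deleted too), so every node keeps out-links and the
transition matrix is row-stochastic to 10⁻¹². Counts are stored as
integers; probabilities are derived on demand.

## Community detection

Node visit rates p are the stationary distribution of the walk that
follows links with probability 1 − τ and teleports with probability
τ = 0.15 to nodes in proportion to their in-link weight (power iteration,
L1 tolerance 10⁻¹²). Teleportation is unrecorded: link flows are
f_ij = p_i·w_ij. Nodes with no in-links get zero visit rate under this
scheme; they are retained and simply contribute no code words (0·log 0 = 0
throughout, logarithms base 2). The two-level map equation is evaluated in
the expanded form

L = plogp(Q) − Σₘ plogp(qₘ↵) − Σₘ plogp(qₘ↳) + Σₘ plogp(pₘ + qₘ↳) − Σᵢ plogp(pᵢ)

with Q the total module-entry flow, qₘ↵/qₘ↳ module entry/exit flows, and
pₘ the module's node-rate sum. Self-loops never contribute to entry or
exit.

**Markov time.** The time parameter t multiplies every module entry and
exit flow inside every term (including the module normalizer pₘ + t·qₘ↳).
At t = 1 this is the standard two-level map equation (verified against an
independent entropic implementation); larger t makes boundary crossings
costlier and yields fewer, larger communities. Default t = 2.

**Optimizer.** Louvain-style seeded greedy search: repeated single-node
moves to the neighboring module (or a fresh module) with the best
codelength decrease — strict improvement > 10⁻¹² bits, candidates scanned
in ascending module id for determinism — followed by recursive module
aggregation; up to 20 outer refinement loops per seed, stopping early
after 5 consecutive non-improving loops; the result is never worse than
the single-module partition. An ensemble over seeds 0..n−1 (default 100;
runs in this repository use smaller ensembles) keeps the minimum-codelength
partition, ties broken toward the lowest seed, and retains all members for
boundary-persistence analysis. An exhaustive Bell-enumeration oracle
(feasible to ~10 nodes) provides the independent optimum in tests.

## Quality metrics

Coherence ρ(c) and fortress F(c) are integer-count ratios from the flow
map (retention and self-recruitment). A community that receives no
settlers has an undefined fortress ratio, reported as missing with a
warning rather than 0, distinguishing "no inflow" from "external inflow
only". Classification precedence: sink if ρ − F ≥ δ, source if F − ρ ≥ δ
(δ = 0.05), else impermeable if min(ρ, F) ≥ h, permeable if
max(ρ, F) < h (h = 0.95), else unclassified; comparisons carry a 10⁻⁹
guard so two-decimal published values compare as printed.

The mixing parameter is operationalized as the mean over member nodes of
the base-2 entropy of the node's within-community renormalized outflow
(self-loops included), divided by log₂ n_c: 1 for perfectly even spreading
over the community, 0 for deterministic routing, and 1 by convention for
singletons (which are included in global averages). The published
description of this metric is verbal; this operationalization satisfies
every stated property.

Global metrics are bin-count-weighted means. The community connectivity
matrix is row-stochastic by construction and its diagonal equals the
coherence ratios bit-exactly. A bin is a boundary bin if at least one grid
neighbor belongs to the network and to a different community; boundary
persistence is the fraction of ensemble partitions in which a bin is a
boundary bin.

## Synthetic fixtures

The two-gyre basin (default 600 km × 600 km, 10 km cells, one-cell land
ring) derives its surface flow from ψ = A sin(πx/L) sin(2πy/L) by centered
differences, so the discrete divergence vanishes and the two gyre centers
are stagnation points. Peak surface speed defaults to 0.1 m s⁻¹ — a
shelf-scale mean circulation for which the gyre recirculation time is
comparable to the 45-day PLD, so habitat patches can retain larvae as
banks do in the emulated systems. Depth attenuates the flow by exp(−z/40 m)
so 1-m and mixed-layer transport differ; months modulate the strength by
1 + 0.2 cos(2π(m − 9)/12) with values anchored mid-month and interpolated
linearly, wrapping mid-December → mid-January. Diffusivity is a uniform
10 m² s⁻¹; MLD is 25 ± 10 m seasonally; bathymetry is a 60–200 m bowl.
Habitat patches grow by stochastic frontier expansion from seeds anchored
on the gyre centers (the retentive features), 7 rings by default (~30% of
the basin).

What the fixtures do **not** emulate: boundary currents, eddies, tides,
interannual variability, coastline geometry, temperature-dependent PLD,
mortality, or observation-based habitat. Passing tests therefore
demonstrate the correctness of the kernels, bookkeeping, network algebra
and optimizer — not oceanographic realism of any particular coastline.

## Problem sizes

Default test and script runs are scaled down from a production
configuration (which would seed 1.3 particles km⁻² and run 100 detection
seeds): the acceptance script seeds ~20,000 particles (0.06 km⁻²) in the
600-km basin, detects with 8 seeds (3 for the Markov-time scan), and the
test suite uses a 300-km basin with ~6,000 particles. These sizes give
hundreds of network nodes and stable community structure while a full run
stays within a few minutes on one core. Physical and behavioral
parameters keep their defaults everywhere.

## Numerical choices

- Entropies: base 2; 0·log 0 := 0; plogp guards against tiny negative
  aggregates from incremental updates.
- Interpolation: bilinear horizontal / linear vertical / linear
  mid-month-anchored cyclic time, shared by gridded and analytic fields;
  indices clamp at the outer cell centers.
- Row-stochasticity is validated at 10⁻⁹ on input and holds at 10⁻¹² on
  construction (integer counts normalized once).
- Degenerate inputs: empty flow maps prune to an empty map with a warning;
  SH without a habitat map raises; MLD exceeding bathymetry raises;
  non-contiguous partition labels raise.
- Vertical clamping clearances are 0.1 m (surface and bottom); the
  behavioral description gives no numbers.
- Open lateral boundaries: exiting particles are excluded like beached
  ones.
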