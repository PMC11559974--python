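# larvanet

Delineating marine subpopulations from simulated larval dispersal.

Many benthic marine species (scallops, mussels, and other broadcast
spawners) are sedentary as adults but disperse as planktonic larvae for
weeks. Where the larvae of one region settle determines which regions form
connected subpopulations — information managers need but cannot observe
directly. `larvanet` implements a network approach to this question:

1. **Simulate** a cohort of larval particles through gridded ocean fields:
   fourth-order Runge–Kutta horizontal advection, first-order Milstein
   horizontal diffusion (with the well-mixed drift correction
   ½ ∂K/∂x (ΔW² + dt)), and vertical behavior — either a fixed near-surface
   depth or simultaneous sinking plus swimming toward a preferred depth
   drawn around the local mixed-layer depth. Per-particle traits come from
   clipped normal distributions and stay constant through dispersal.
   Particles that enter land (the zero-velocity region) beach and are
   discarded.
2. **Reduce** each surviving trajectory to a single transition from its
   spawn bin to its settlement bin on a hexagonal geodesic grid
   (~253 km² cells at the default resolution 5). Normalizing the
   transition counts per spawn bin gives a directed, weighted,
   row-stochastic transport network — a Markov chain on bins.
3. **Detect** flow communities by minimizing the two-level map equation
   L = q H(Q) + Σₘ pₘ H(Pₘ) with a seeded stochastic greedy optimizer run
   over an ensemble of seeds, at a configurable Markov time t (t = 2 by
   default; larger t coarsens the structure). Communities are bins a random
   walker — a larva's lineage — stays inside for a long time:
   subpopulations.
4. **Characterize** each community c with
   - the **coherence ratio** ρ(c): fraction of particles spawned in c that
     settled in c (retention; outward border strength),
   - the **fortress ratio** F(c): fraction of particles settled in c that
     spawned in c (self-recruitment; inward border strength),
   - the **mixing parameter** M(c): how uniformly member bins spread
     particles over the community,
   - a **classification**: sink (ρ − F ≥ 0.05), source (F − ρ ≥ 0.05),
     impermeable (both ≥ 0.95), permeable (both < 0.95),
   plus a community-level row-stochastic connectivity matrix whose diagonal
   is exactly ρ, and the boundary persistence of each bin over the
   detection ensemble.

Three behavioral cases share the machinery: **FD** (fixed 1 m depth),
**PD** (preferred-depth behavior), and **SH** (preferred depth plus
spawn/settlement restricted to suitable habitat, with settlement on the
first day over habitat during the final 7-day competency window of the
45-day pelagic larval duration). PD and SH share one simulation so their
stochastic transport is identical.

Because real hydrodynamic climatologies and habitat rasters are large
external products, the package ships a synthetic-field generator
(`synthfields`): a two-gyre basin with vertical shear, mid-month-anchored
monthly variation, and patchy multi-lineage habitat anchored on the
retentive gyres — enough structure to exercise every stage of the method.

## Worked example

```python
import numpy as np
import larvanet as ln
from larvanet.synthfields import make_mld_and_bathy, gyre_habitat_seeds

fields = make_mld_and_bathy(ln.make_double_gyre())        # 600 km two-gyre basin
grid = ln.HexGrid(5, (float(np.mean(fields.lon)), float(np.mean(fields.lat))))
habitat = ln.make_habitat_patches(
    fields, grid, 3, patch_seeds=gyre_habitat_seeds(fields, grid, 3),
    rng_seed=2, growth_steps=7)

sim = ln.SimConfig(seed_density=0.06, rng_seed=1)         # ~20k particles
cohort = ln.run_simulation(
    ln.seed_cohort(fields, None, sim, ln.BehaviorConfig()), fields)
resolved = ln.resolve_settlement(cohort, "SH", habitat=habitat, grid=grid)

flow_map = ln.prune_to_closed(ln.build_flow_map(resolved, grid))
net = ln.to_network(flow_map)
best, ensemble = ln.ensemble_detect(net, ln.MapEqConfig(markov_time=2.0, n_seeds=8))
quality = ln.community_quality(flow_map, net, best)
print(len(flow_map), net.n_nodes, best.n_communities)
print(tuple(round(x, 2) for x in ln.global_quality(quality)))
```

prints

```
3181 314 68
(0.45, 0.83, 0.77)
```

— of the ~20k seeded particles, 3,181 spawned over suitable habitat,
survived and settled back onto habitat; they occupy 314 hexagonal bins,
which the map equation groups into communities at Markov time 2 (most are
multi-bin subpopulations around the gyre cores plus singleton bins with no
incoming settlers). The global bin-weighted quality metrics — mixing 0.45,
coherence 0.83, fortress 0.77 — say the detected subpopulations retain and
self-recruit most of their larvae, i.e. the partition's boundaries are
real transport barriers.

The same pipeline runs from the shell:

```sh
larvanet run-all --config run.ini --out results/
```

with an INI config holding one section per stage (see
`tests/test_cli.py::TINY_INI` for a complete example).

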