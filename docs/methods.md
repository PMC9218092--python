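# Methods

## Model and assumptions

The simulator follows a host population and one focal symbiont species (or
equivalently the occupants of one niche).  Both sides carry heritable,
continuous investments in cooperation; hosts additionally carry an
investment in a control mechanism that biases benefits toward
more-cooperative symbionts.  The model is deliberately abstract about the
mechanism: control could be immune discrimination against a
microbe-associated molecular pattern, selective feeding, or compartment
sanctions.  Key assumptions:

* **Mass interaction.**  Every host genotype interacts with every symbiont
  genotype each generation, so fitnesses depend on population densities,
  not on pairings.  There is no spatial structure.
* **Trait grids.**  Densities live on 11-point evenly spaced grids
  (endpoints inclusive): hosts on the (a × c) grid, symbionts on the b
  grid.  All integrals in the fitness equations are probability-weighted
  sums over grid points — densities are "proportion of the population at
  this trait value", so no quadrature weights are involved.  Grid
  resolution is configurable (`n_grid`).
* **Replicator selection, no mutation.**  Each selection step multiplies
  a density by max(fitness, 0) and renormalizes.  Fitness weights are
  clamped at zero because replicator weights must be non-negative and host
  fitness can go slightly negative at extreme parameters; a population
  whose weights are all zero raises an extinction error.  Evolution acts
  on standing discretized variation plus immigration only.  Host-side
  variation is never replenished.
* **Relatedness R** is the social-evolution quantity (probability above
  the population average that two symbiont cells share the cooperation
  locus), not phylogenetic relatedness.  It discounts the competition
  denominator of the control weight (a clonal population, R = 1, cannot be
  discriminated within) and splits the symbiont feedback between own and
  population-mean cooperation.

## Generation loop

Each host generation:

1. **Within-host phase**: `generation_ratio − 1` symbiont generations of
   pure growth-rate competition (within-host fitness), each followed by
   trickle immigration at rate `m`.  Ratio 1 therefore reduces exactly to
   the pure between-host model.
2. **Simultaneous selection**: host selection is scored against the
   symbiont distribution the hosts carried during their lifetime (the
   post-within-phase state), while symbiont colonisation (between-host)
   fitness is scored against this generation's hosts; the symbiont update
   is followed by immigration at rate `M`.

The simultaneous update is a deliberate design choice.  Scoring hosts
against the *already reselected* symbiont pool (a fully sequential update)
systematically under-counts the host–symbiont feedback, and at the
headline parameters it loses the close bootstrap race between rising host
investment and declining symbiont cooperation — cooperation then fails to
evolve even in the short-lived-microbiome regime where it should.  Hosts
earn their fitness from the symbionts they actually hosted.

Runs stop after `n_host_generations` (default 200) or when the L1 change
of both densities over one host generation falls below 1e-10.  The engine
is deterministic: identical parameters give bit-identical trajectories.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| `x`, `y` | benefit to host / symbiont of received cooperation | 2.0 | headline regime |
| `R` | symbiont relatedness | 0.5 | ∈ [0, 1] |
| `f` | symbiont-side (suppression) cost of control | 0.02 | enters `e^{−fc}` |
| `g` | host-side direct cost of control | 0.1 | max cost is `g` at `c = c_max` |
| `M` | immigration per host generation | 0.05 | convex mixing with the pool |
| `m` | immigration per symbiont generation | 1e-6 | within-host trickle |
| `generation_ratio` | symbiont generations per host generation | 1 | ≥ 1 |
| `c_max` | upper bound of control | 10.0 | cost term uses `c/c_max`, so the maximal direct cost is `g` regardless of `c_max` |
| `n_grid` | grid points per axis | 11 | |
| `benefit_form` | shape of cooperation→benefit map | linear | see below |

Initial conditions: truncated normals discretized onto the grids —
cooperation (both species) mean 0, SD 0.5 on [0, 1]; control mean 0, SD 1
on [0, c_max].  The means are a convention (only the SDs are prescribed by
the modelling tradition this follows); they give a small but non-zero
amount of cooperation and control variation, without which cooperation
cannot bootstrap.  The environmental pool defaults to the initial symbiont
distribution: largely uncooperative, with the small positive baseline the
truncated normal leaves, and introducing no new parameter.

### Benefit transforms

The mapping from post-control mean cooperation to host benefit is linear
by default.  Three named alternatives are provided, all anchored at (0, 0)
and (1, 1): `diminishing` (saturating hyperbola `u/(u + 0.3(1−u))`),
`accelerating` (its mirror image), and `sigmoidal` (smoothstep
`3u² − 2u³`).  The textbook closed forms sometimes quoted for such curves
can be pathological (a pole inside the unit interval, or values above 1);
`benefit_as_printed` exposes them for inspection, but the anchored curves
above are what the simulator uses.  The transform applies only to the
host-received benefit in W_a; symbiont-side equations are unchanged.

### Within-host fitness weighting

The within-host fitness integral over control levels is weighted by the
marginal density h(c) of control among hosts, so within-host selection
reflects the hosts the symbionts actually occupy.  An unweighted integral
would let empty regions of control space shape within-host competition.

## Escape extension

Symbionts carry an expressed trait B (the thing control monitors) and a
linkage γ, with realized cooperation b = γB.  The control weight q uses B
in both its exponent and its competition denominator; cooperation cost and
feedback use b.  With γ pinned at 1 the extension embeds the base model
exactly (verified to 1e-15 in the tests).

Two conventions required a decision because replicator dynamics cannot
create mass where there is none:

* **Immigrant linkage.**  Immigrants (and the initial population) carry a
  truncated-normal γ distribution (mean 0, SD 0.5) rather than γ = 1:
  environmental microbes express traits for their own reasons, not as part
  of the mutualism.  Without immigrant γ-variation a "free" phase would
  have nothing to select on and the link could never evolve.
* **Reinstating the link.**  Entering (and holding) a "fixed" phase
  projects all mass onto γ = 1, preserving the B-marginal.  The projection
  runs every generation of a fixed phase, which also makes the fixed-phase
  B-dynamics exactly the base model's whatever the pool's γ distribution.

The collapse-and-restore experiment (default schedule: 100 generations
fixed, 15 free, 135 fixed, at generation ratio 100) restores cooperation
only if the link is re-fixed before control has decayed too far: within-
host selection favours cooperators only when `e^{c}`-scale discrimination
outweighs the unit cooperation cost (roughly c > ln 2 at these
parameters).  Scanning free spans of 3–30 generations shows full
restoration up to ~20 and permanent collapse by 30; the default free span
of 15 sits inside the restorable regime.  During a free phase selection
favours (high B, low γ) genotypes and the B–γ covariance turns negative
before the collapse — the population "mimics" cooperation before
abandoning it.

## Individual-based model

The IBM is the exact finite-population counterpart of the deterministic
engine: hosts and microbes are individuals whose traits sit on the same
grids, initialised by sampling the same discretized truncated normals, and
every deterministic reweighting becomes multinomial resampling with the
same fitness weights (with replacement, fixed population sizes).  Within-
host competition uses each host's own microbe distribution in the control
denominator; colonisation uses pooled empirical densities.  Host fitness
is scored against the pooled post-within-phase symbiont distribution,
mirroring the simultaneous update of the deterministic engine.

Pathogens are an influx (default 1e-3 of all microbes per host
generation) of microbes that do not cooperate (b = 0), are suppressed by
host control exactly like non-cooperative symbionts, and additionally harm
their host through the pathogenicity factor
`p_f = e^{vp·c/c_max}·e^{−vp}` (v = virulence, p = within-host pathogen
proportion), which multiplies host fitness.  `p_f` = 1 when p = 0 or
c = c_max: full control nullifies the harm.  The multiplicative insertion
is a design choice: a factor in (0, 1] scales fitness naturally and
vanishes smoothly with the pathogens.  Moderate virulence produces the
strongest selection gradient on control — at extreme v any infected host
is effectively dead regardless of c, which *removes* the gradient.

Default population sizes are the full-scale 10⁴ hosts × 10³ microbes per
host; the tests and the reproduction script run scaled-down
configurations (10³ × 10², ten seeds; tiny instances for exactness
checks), which preserve the qualitative ordering of evolved control with
and without pathogens.

## Outcome classification and sweeps

The deterministic equilibrium is a distribution, not a label.  For regime
diagrams a run counts as **cooperation** when final mean symbiont
cooperation exceeds the environmental-pool mean by at least a margin
(default 0.2) *and* final mean host cooperation exceeds its initial value
by the same margin — mutualism requires both partners to have moved.  The
margin separates the pool baseline (≈ 0.34) from near-full cooperation and
is monotone: enlarging it never converts collapse into cooperation.  Loss
of control (final mean c below 10% of its initial mean while control was
enabled) is a separate flag because it can co-occur with cooperation: with
no immigration, control drives all symbionts cooperative, after which it
has no benefit and decays under its direct cost.

Sweeps take a cartesian product of parameter axes (including a joint
`benefit_xy` axis setting x = y, matching the benefit-to-cost-ratio axis of
the regime diagrams), run the chosen variant per cell independently (order
never matters), classify each cell, and can resume interrupted runs from
per-cell files.  Cell-level failures are recorded without aborting.

## Numerical choices and problem sizes

* Normalization is enforced to 1e-9 at density construction and holds to
  1e-12 across 500-generation runs of every variant (tested).
* Exponential tables for the control weight are cached per parameter set;
  vectorized paths agree with naive scalar loops to 1e-12.
* The reproduction script (`scripts/acceptance.py`) uses: full 200-
  generation regime runs; a 150-generation, 11 × 11 sweep per variant at
  generation ratio 100; a 250-generation escape schedule; a
  400-generation no-immigration run; IBM runs at 10³ hosts × 10² microbes
  with 10 seeds per condition (10 generations for the deterministic
  comparison at ratio 1, 80 generations at ratio 10 for the pathogen
  contrast, with equilibrium control time-averaged over the last 40).
  These sizes are the package's standard desk-scale configuration.
* The pathogen contrast uses v = 100 and influx 1e-2 — strong but rare
  pathogens, the regime the pathogenicity factor was built for.

## What the model does and does not capture

Synthetic dynamics here emulate the logic of host–microbiome coevolution,
not any particular system: there is no spatial structure, no explicit
multi-species community (one niche is followed), no host demography or
epidemiological pathogen transmission, no mutation operator, and no
coevolutionary arms race in the recognition machinery itself (the escape
extension holds the *mechanism* of control fixed and lets only the
trait–cooperation link evolve).  Passing tests show the implementation
reproduces the model's internal logic and regimes; they are not evidence
about any real microbiome.  Host-side variation is finite and never
replenished, so very long runs can effectively fix host traits — a known
limitation that matters for restoration experiments with long escape
phases.
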