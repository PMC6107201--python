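# Methods

## Model overview

`chorusim` simulates one night of mating activity in a treefrog chorus as a
spatially and temporally explicit agent-based model.  The arena is a
1000 × 2500 cm rectangle with hard boundaries.  Males are placed once per
night, hold fixed territories (≥ 50 cm apart, placed sequentially with
rejection of spacing violations), never move, and each carries an integer
call quality — the *pulse number* — drawn from Normal(μ, σ), rounded, and
clamped to ≥ 1.  Pulse counts are integers because frogs discriminate
whole-pulse differences; clamping prevents non-positive quality in the
low-mean/SD-2 condition.  Females enter on the boundary and approach their
chosen male in a straight line at a fixed speed, in synchronous 1-second
cycles (retarget → move → mate), until every female has either mated or
given up.  Mating removes both partners from the pool; nobody is replaced.

Assumptions inherited from the biology of the system: every female hears
every male from anywhere in the arena (cluster sampling — hence no explicit
search cost); males' relative quality ranking is constant over the night;
all females in a run use the same rule; all agents are present from cycle 1.

## Decision rules

* **best_of_n** — candidate = highest pulse number among the *n* closest
  available males (pulse ties → nearer male → lower id).  Re-evaluated
  every cycle, but a standing live target is abandoned only for a
  *strictly* better candidate.  This matters: as the female moves, her
  current target can drop out of the n-closest set, and a plain
  argmax-over-set rule would then switch her to a worse male.  Under the
  trade-up rule every mid-course switch raises target quality, which the
  event log verifies.
* **best_of_n_no_switch** — same selection, re-evaluated only when the
  current target mates with a rival.
* **min_threshold** — closest available male with pulse number ≥ θ,
  retained until he mates.  The comparison is "at least θ": with integer
  qualities, accepting exactly-at-threshold males is what makes a θ equal
  to the population mean leave most females mated.  If no acceptable male
  exists the female takes one random-walk step of one cycle (counted in her
  distance) and is removed unmated — because she hears everything, no
  acceptable male now means none ever.
* **random** — uniform over available males, retained until he mates.

Mating contact is between a female and *her target*: she mates when a move
ends within the contact radius of him.  (Contact with a male she merely
passes does not mate her — a threshold female may not accept a
below-threshold male.)  If several females end a cycle in contact with the
same male, the nearest mates (exact ties broken randomly); the others
re-assess next cycle.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| arena | 1000 × 2500 | cm | realistic wetland size |
| males | 25 | — | fixed chorus size; sex ratio varied via females |
| females | 5–20 | — | operational sex ratio 0.2–0.8 |
| territory spacing | 50 | cm | minimum territory diameter |
| pulse-number mean μ | 6, 12, 18, 24 | pulses/call | empirical population range |
| pulse-number SD σ | 2 | pulses/call | empirical within-night variation |
| speed | 2 | cm/cycle (1 cycle = 1 s) | realistic walking rate; see below |
| contact radius | 5 | cm | one body length |
| cycle cap | 14,400 | cycles | a 4-h night; never binding in practice |

The movement rate and contact distance are calibrated choices, not copied
constants.  All reported distance statistics are geometry-determined and
speed-invariant (halving the speed changes a lone female's travel by less
than one step, which a test asserts); cycle counts therefore are monitored
but never treated as results.  Under the defaults, runs average a few
hundred cycles and none approaches the cap.

Male spatial regimes: *random* is uniform; *gaussian* draws each coordinate
from a truncated normal centered mid-arena with σ = extent/6 (≈ 99.7% of
mass inside before truncation); *inverse_gaussian* shifts the gaussian draw
by half the extent modulo the extent, so density peaks at the boundary, as
on pond shorelines.  The exact σ and edge construction were open choices;
they are fixed once here and their main observable consequence (center
occupancy ordering gaussian > random > inverse-gaussian) is tested.

Females start uniformly along the two *long* edges (the shorelines).  This
was the decisive calibration choice: with starts spread over the whole
perimeter, the straight-line distance from start to a uniformly chosen male
already exceeds the random-strategy travel distance the model is meant to
produce, before any retargeting detours — short-edge starts in an
elongated arena are simply too far from everything.  Shoreline entry
reproduces the travel statistics of all three strategy classes
simultaneously.  Perimeter placement remains available
(`sample_female_positions(..., edges="perimeter")`).

## Sweeps, seeding and reproducibility

A sweep crosses strategies × population means × female counts × spatial
distributions × replicates (default 10 × 4 × 4 × 3 × 100 = 48,000 runs).
Each replicate's seed is `base_seed XOR blake2b(cell labels, replicate)`,
so any cell re-runs bit-for-bit in isolation and chunked execution cannot
change pooled results.  Within a run, a single seeded generator produces
male positions, pulse numbers, female starts, and pre-drawn pools for the
in-run draws (random-strategy choices, the give-up walk direction,
conflict tie-breaks) in a fixed order; a config plus seed is fully
reproducible.  The cycle loop is JIT-compiled (numba); the scalar choice
functions in `strategies.py` are the reference semantics and the tests
assert the compiled path agrees with them.

## Summary statistics

`summarize` reports grouped means with normal-approximation 95% CIs
(1.96 · SE).  The *simulated night* is the replicate unit: by default each
run contributes its per-run mean, so a 20-female night weighs the same as a
5-female night (`weighting="simulation"`).  Row-level pooling
(`weighting="female"`) is available but over-weights high-female-count
cells, which visibly inflates pooled target counts and distances.  Mate
pulse number is averaged over mated females only (table convention); the
distance average optionally restricts to mated females, separating travel
cost from the one-step exits of threshold females who never had an
acceptable option.

The fitness measure is a convex combination of normalized mate quality and
reversed normalized travel: α → 0 weighs quality (e.g., ample energy
reserves), α → 1 weighs distance (e.g., predation pressure).  Its inputs
count unmated females as quality 0 — the lost-opportunity penalty — and the
normalization extremes are taken over the entire outcome database (pulse
extremes over mated males, distance extremes over all females), so strategy
classes share one scale.  `anova_report`/`tukey_hsd` delegate the factorial
ANOVA (sequential type-I, all factors categorical) and post-hoc pairwise
comparisons to statsmodels; they are reporting conveniences, not bespoke
statistics.

## What the generator does and does not emulate

The synthetic chorus reproduces the study conditions: territory spacing,
quality distributions, sex ratios, spatial regimes, shoreline entry, and
single-night synchronous presence.  It does not emulate asynchronous
arrival over the night or across a season, male movement or chorus-tenure
dynamics, satellite/"hot-shot" lek structure, acoustic amplitude and
attenuation, or adaptive (declining) thresholds.  Passing tests therefore
speak to the behavior of the decision rules under these idealized
conditions, not to field-scale prediction.

## Desk-scale replication and numerical choices

`scripts/acceptance.py` and the acceptance tests re-run the design at
reduced replication (20 per cell in the script, 40 in the test suite to
halve the Monte Carlo SE; the full study scale is 100) — 14,400 runs per
pass, seconds to a minute of compute.  Tie-breaks everywhere are
deterministic (distance, then lower id) except the simultaneous-arrival
conflict, which is a seeded random draw; exact floating-point distance ties
essentially never arise from continuous placements.  Degenerate inputs
(empty chorus, infeasible packings, zero-variance limits, one-cycle caps)
raise or resolve explicitly and are unit-tested.

Known limitations: the pooled across-class gradient of travel distance in
the number of females is compressed relative to per-strategy expectations
(the class-pooled best-of-n increase from 5 to 20 females converges to
≈ 79%, while best-of-5 alone shows ≈ 93%); conflict-resolution details not
fixed by the model description could shift this pooled contrast by a few
points.  Absolute pooled distances, target counts, mate qualities and
mating rates are insensitive to these details.
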