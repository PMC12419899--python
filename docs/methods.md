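# Methods

This note documents the model, the conventions and numerical choices the
implementation commits to, what the synthetic-data generator does and
does not emulate, and the known limitations. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data preparation

An *occurrence* is one species from one deposit with a stratigraphic age
interval `[age_younger, age_older]` in Ma. Preparation follows three
rules:

1. **Deduplication.** One occurrence per species per geological stage:
   a species found in deposits of different stages keeps one occurrence
   in each stage; several deposits of the same stage collapse to the
   first in input order. "Similar age" is operationalized as *same
   stage* of the shipped timescale; when no stage label is given, the
   stage containing the occurrence's age midpoint is used. The operation
   is idempotent.
2. **Dating.** Each occurrence is dated by the midpoint of its age
   interval. Using either boundary instead would systematically shift
   species whose deposits span two stages.
3. **Binning.** Species counts are compiled into half-open 1-Myr bins
   `[k, k+1)` Ma indexed from the present (bin 0 = 0–1 Ma); an age
   exactly on a boundary belongs to the bin whose lower edge it equals.
   The count vector has length `ceil(max mean age) + 1` and sums to the
   number of retained occurrences.

The geological timescale ships as a packaged CSV of stage- and
period-level intervals derived from the international
chronostratigraphic chart (Devonian to present). The Holocene is kept as
a single stage-level interval; its formal subdivisions are three orders
of magnitude finer than the 1-Myr analysis grid. Interval lookup places
a boundary age in the *older* interval.

**Multi-rank plan.** Analyses run at family, superfamily, infraorder and
suborder level (plus one pooled order-level dataset). A higher-rank
group whose occurrences all belong to a single lower-rank group is not
analysed twice: it aliases the smaller-rank run and reuses its
posterior, transitively. A family mapped to two superfamilies is a
hierarchy error. Occurrences missing a rank label simply do not
participate at that rank. Extant richness per clade is a required user
input (a richness table); a clade absent from it is treated as extinct.
Whether the order-level analysis should pool all occurrences or
aggregate suborder runs was an open design point; this package pools,
because the order-level record includes occurrences not assignable to
any suborder.

## The model

Time is age in Ma. For a clade with root age `t0` and extinction age
`te` (0 for extant clades), log diversity `y_t = log N_t` follows a
Brownian bridge with per-Myr variance `σ²` between two anchors:
`y(t0) = 0` (a clade starts as one species) and `y(te) = 0` for extinct
clades or `y(0) = log n0` (present-day richness) for extant ones.
Diversity is floored at one species inside the lifespan, enforced as a
hard (`−∞`, unnormalized) prior constraint.

The latent trajectory lives on the 1-Myr grid: a bin belongs to the
lifespan when its midpoint lies in `[te, t0]`; `t0` and `te` themselves
are continuous. The bridge density is the product of Gaussian increment
densities along the chain (old anchor → bin midpoints → young anchor)
divided by the marginal density of the young anchor given the old one; a
lifespan containing no bin midpoint contributes an empty product
(log density 0).

Counts are Poisson observations of the trajectory:

    x_k ~ Poisson(q(m_k) · N_k),    q(t) = q0 · e^(−β t),   β ≥ 0,

with `m_k` the bin midpoint. Any fossil outside `[te, t0]` has zero
probability, which is what anchors `t0` above the oldest fossil. The
preservation rate is *referenced at the present*: `q0` is the expected
number of sampled species per lineage per Myr at age 0. An
origin-referenced variant (`q0 · e^(β(t0−t))`) is the same model family
— `q0` absorbs `e^(β t0)` — but makes every bin's expected count depend
on the root age, which entangles `t0` with the overall preservation
level and was measured to collapse the sampler's root-age effective
sample size by an order of magnitude; the present-referenced form is
used throughout (model, simulator, reference integrator).

**Priors.**

| parameter | prior | default | notes |
|---|---|---|---|
| `t0` (Ma) | Uniform(oldest non-empty bin's older edge, `max_age`) | — | `max_age` is the user's external constraint; run several values |
| `te` (Ma) | Uniform(0, youngest non-empty bin's younger edge) | — | extinct clades only; extant clades pin `te = 0` |
| `σ²` (per Myr) | Exponential | mean 1 | lower support bound 1e-6 (below) |
| `q0` (per lineage per Myr) | Exponential | mean 1 | |
| `β` (per Myr) | Exponential | mean 0.05 | pinned to 0 when `q_var = 0` |

All hyperprior means are overridable in `PriorConfig`; each of
`σ²`/`q0`/`β` can instead be fixed to a point value, which removes it
from sampling. The joint density of (variance, trajectory) is unbounded
along the degenerate direction where the trajectory is exactly linear
and `σ² → 0`; a hard lower bound `σ² ≥ 1e-6` (configurable) keeps the
chain out of that funnel without affecting marginals at meaningful
scales.

## Sampler

Metropolis–Hastings with trajectory augmentation. Moves:

* **Root/extinction sliding windows with segment resampling.** A `t0`
  (or `te`) proposal draws the new value from a symmetric mixture window
  (80% width `w`, 20% width `5w`, `w` adapted), then resamples the
  trajectory segment between the moving anchor and a pivot bin (the
  oldest/youngest bin common to old and new lifespans) from the
  conditional Brownian bridge. Because new trajectory coordinates are
  proposed from their conditional prior, the bridge densities cancel and
  the acceptance ratio reduces to the likelihood ratio times the ratio
  of the pivot value's bridge-marginal densities under the new and old
  anchor; dimension changes carry unit Jacobian.
* **Trajectory block redraws.** A random window (geometric length, mean
  ≈ 8 bins) is redrawn from the bridge conditional on its flanking
  values; accepted on the likelihood ratio alone.
* **Multipliers** on `σ²`, `q0`, `β` (log-scale, Hastings-corrected).

Proposal scales adapt toward a 0.2–0.5 acceptance rate during burn-in
only (default 10%) and freeze afterwards, so every retained sample comes
from a fixed, detailed-balanced kernel. Defaults: 1,000,000 iterations,
sampling every 1,000, two chains. Chains receive sub-seeds spawned
deterministically from the master seed, making results identical whether
chains run serially or concurrently (`n_jobs`). In the batch runner,
per-run seeds are SHA-256 hashes of (master seed, clade, rank, max_age),
so adding a clade never perturbs any other clade's chains.

**Kernel validation.** A *prior-only* mode replaces the likelihood with
a constant **and lifts the diversity floor** — the floor truncates the
bridge prior with `t0`-dependent mass, so only without it is the
root-age marginal exactly uniform; the test suite checks that uniformity
by a goodness-of-fit test on 20,000 samples. With the floor active no
such closed-form marginal exists, which is why the flat-target check is
defined this way.

**Summaries and convergence.** Posterior point estimates are pooled
medians with equal-tailed 95% credible intervals (2.5%/97.5% quantiles,
linear interpolation). ESS uses the autocorrelation-time estimator with
Geyer's initial-positive-sequence truncation, computed per chain and
summed; a run is convergent when every sampled parameter's ESS exceeds
200. Zero-variance series return their length with a degeneracy warning.
Trace logs are tab-separated with a leading `state` column (the dialect
of the standard MCMC trace-inspection tools). Highest-posterior-density
intervals are not reported; the equal-tailed convention is used
throughout.

## Reference integrator

`paleobridge.reference` is an independent brute-force check: it grids
`(t0, te)` and marginalizes the latent trajectory at every node by plain
Monte-Carlo integration over exact bridge draws (built by endpoint
conditioning of an unconditioned walk, with common random numbers across
nodes so integration error cancels in quantiles). A literal grid over
the trajectory itself is impossible because its dimension varies with
`t0`. The integrator is practical only at desk scale and with
`σ²`/`q0`/`β` fixed; its density formulas are deliberately written
self-contained rather than imported from the model module. The test
suite requires the sampler's toy-posterior root-age median to agree with
this quadrature within 1 Myr.

## Synthetic-data generator

The generator produces clades *forward*: log diversity starts at 0 at
`t0` and performs an unconditioned driftless random walk down the bin
grid; the clade dies when diversity first drops below one species
(extinction recorded at the older edge of the crash bin, i.e. the centre
of the half-bin interval consistent with the model's grid convention).
`extant` mode keeps only walks surviving to the present, `extinct` mode
only walks dying earlier — rejection sampling, so the generator shares
no machinery with the bridge-based inference and recovery runs are a
genuine cross-check. Fossil counts are Poisson draws from the same
preservation law the model assumes. Benchmark presets: `extant10`,
`mixed5_5` (5 extant + 5 extinct), `extinct10`, each with a truth table.

Default truth ranges (uniform, all overridable and logged): `t0` ∈
[80, 320] Ma, `σ²` ∈ [0.01, 0.1], `q0` ∈ [0.005, 0.05], `β` ∈ [0, 0.01];
clades are redrawn until they carry at least 3 fossil occurrences, since
the model is undefined for fossil-free clades.

**What passing recovery tests do and do not show.** The generator and
the model agree on the preservation law and the per-Myr random walk, but
differ in two deliberate ways: the generator's survival conditioning is
a first-passage mechanism, whereas the model uses a uniform extinction
prior and an *unnormalized* floor truncation; and the generator's dying
tails hover at `N ≈ 1`, where the floor-truncated bridge's expected
diversity is somewhat higher. Consequently credible intervals are
mildly conservative-to-miscalibrated against this generator —
root-age coverage measured across many simulated clades is near nominal
(~90%), extinction-age coverage somewhat below (~80%), with misses
concentrated in clades whose true ages sit in long unfossilized tails or
exactly on the extinction prior's boundary (which happens whenever the
last living bin is itself fossilized). Passing tests therefore
demonstrate correct inference machinery and approximate calibration, not
exact frequentist coverage; against real data they say nothing about
taxonomic misassignment or preservation spikes (below).

## Orchestration choices

* The prior-sensitivity comparison across `max_age` settings uses a
  paired two-sided Wilcoxon signed-rank test on family-level root-age
  medians (non-parametric, paired by family), with a two-sample
  Kolmogorov–Smirnov statistic as a secondary report; identical inputs
  short-circuit to p = 1, and fewer than 6 complete pairs yields a power
  warning instead of a p-value.
* Origination/extinction tallies per geological period assign each clade
  by its posterior *median* (the per-clade point estimate reported
  everywhere else); ages on a period boundary go to the older period.
* Default `max_age` grid: {325, 350, 386, 407} Ma — spanning the oldest
  putative fossil of the motivating clade and progressively older
  molecular-clock estimates; batch reporting computes all of them.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen so
the full suite completes in minutes on one core: the toy
oracle comparison uses a 4-fossil extinct clade with 400k iterations ×
2 chains against a quadrature with 4,000 bridge draws per grid node;
recovery uses the `mixed5_5` preset at 200k iterations per chain (two
chains); the kernel-uniformity check uses 20,000 retained samples.
Production analyses should use the 1M-iteration defaults.

## Known limitations

* Preservation is smooth in time; concentrated exceptional deposits
  (Lagerstätten) can pull origin/extinction estimates toward their own
  age, and the model contains no term for them.
* Results are conditional on the input taxonomy: paraphyletic or
  misassigned groups distort the count vectors directly.
* The diversity floor is an unnormalized truncation; lifespans far
  beyond the fossil span are penalized slightly more than a normalized
  (first-passage) treatment would, biasing extreme tail extensions
  short.
* Within-bin fossil placement is ignored (bin-midpoint convention);
  ages are only meaningful at the 1-Myr grid resolution.
* The order-level run pools all occurrences; it is not an aggregate of
  the suborder posteriors.
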