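# Methods

## The quantity being estimated

A sampling unit is one plot within one treatment half of one field at one
biweekly session in one year. For each unit the package builds a bipartite
interaction web whose entry `a_ij` is the proportion of individuals of
predator species *i* captured in that unit whose gut content tested
positive for prey target *j*. Webs therefore hold real-valued averaged
proportions, not integer interaction counts.

Network-level specialization is the standardized two-dimensional Shannon
entropy

```
H2       = −Σ_ij p_ij ln p_ij,     p_ij = a_ij / m,   m = Σ_ij a_ij
H2′      = (H2max − H2) / (H2max − H2min)
```

where `H2max` and `H2min` are the largest and smallest entropies attainable
by any non-negative matrix with the observed row and column totals. `H2′`
is 0 when diets are proportional to overall availability and 1 when diets
are fully partitioned; it is invariant to rescaling the matrix, to row and
column permutations, and to the logarithm base.

Because small, sparse webs are biased toward apparent specialization, the
observed `H2′` is referenced to a randomization null (below) and reported
as a Cohen's-d standardized effect size
`ses_d = (H2′_obs − mean(H2′_null)) / sd(H2′_null)` with the null SD in the
denominator (ddof = 1). With a single observed web per unit a pooled
two-sample denominator does not exist; standardizing by the null
distribution's own SD is the z-type convention used here, and positive
values mean more specialized than random.

## Entropy extremes under fixed marginals

* `H2max` uses the continuous closed form: the maximum-entropy coupling of
  fixed marginals is the independence table, so `H2max = H_row + H_col`,
  the sum of the marginal Shannon entropies.
* `H2min` uses a deterministic greedy concentration heuristic. Repeatedly:
  if some remaining row total exactly equals some remaining column total
  (within 1e-12 on the normalized scale), allocate that mass to one cell,
  clearing both at once; otherwise allocate `min(row, col)` to the cell
  pairing the largest remaining row total with the largest remaining column
  total. Ties break on the lowest original index so floating-point runs are
  reproducible. The equal-match rule matters: without it the plain max–max
  greedy demonstrably overshoots the true minimum on small instances
  (e.g. marginals (3,4) × (2,2,3)), because splitting the larger marginal
  across equal partners is better than pairing maxima.

The heuristic always returns the entropy of a realizable table (a vertex of
the transportation polytope), hence an upper bound on the true minimum;
exact minimum-entropy coupling is computationally intractable in general.
On every pair of positive integer marginals with total ≤ 8 on grids up to
3×3 the heuristic attains the exhaustive-enumeration minimum (asserted in
the test suite); beyond that range it can still overshoot (a known case:
marginals (2,2,6) × (3,3,4)). An overshoot shrinks the denominator
`H2max − H2min` and so, if anything, inflates `H2′` slightly toward
specialization — identically for observed and null webs, so the SES is
largely insensitive to it.

Degenerate webs — no interaction mass, a single predator species, or a
single prey target, i.e. `H2max − H2min < 1e-9` — get `valid = false` with
a reason label instead of a value, and are excluded from SES with a log
message. `H2′` is clipped to [0, 1] against floating-point undershoot.
A scaled-integer variant (`integer_scale`: multiply, round, then apply the
same allocation) is available for cross-checks against count-based
implementations of the index.

## The randomization null

"Recombining the diet data points" is read at the individual level, before
species averaging. Three strategies are provided:

* `prey_label_shuffle` (default): within each stratum, each prey target's
  binary detection column is independently permuted across individuals.
  This preserves every prey's total detection count and every individual's
  unit/species assignment — prey availability structure and sampling effort
  are held fixed, and only the predator-species × prey association that
  `H2′` measures is destroyed.
* `cell_shuffle`: all cells of the individual × prey table are permuted
  jointly; only the grand total of detections is conserved.
* `within_unit_shuffle`: the column permutation restricted to each unit.

Cells that would be self-detections never participate in any permutation:
this keeps shuffled data self-detection-free *and* conserves prey column
totals exactly, which re-zeroing after an unrestricted shuffle would not.
The shuffling stratum defaults to year (configurable to treatment or
global): prey availability and assay panels are year-specific, and the SES
time series is reported per year.

For per-unit null draws the implementation does not materialize shuffled
record lists. Permuting a stratum column and reading back the unit's rows
places the column's detections uniformly without replacement over the
eligible rows, so the per-species counts landing in a unit are exactly
multivariate-hypergeometric; the null webs are sampled directly from that
distribution (one draw per species-block per column). A test verifies the
fast path against the literal shuffle-then-rebuild route. Null draws that
yield degenerate webs are dropped and counted, mirroring the treatment of
degenerate observed webs; a unit is flagged when fewer than `min_valid`
(default 30) valid null webs remain. The default `n_randomizations` is a
desk-scale 999; the field-study scale of 99,999 is one config knob away.

Each unit's null stream is seeded from the master seed plus a CRC32 hash of
the unit key, so results are byte-identical under any processing order or
partitioning of the units.

## Synthetic data generator

The generator emulates the field design: years of 3 replicate fields split
into fertilized/unfertilized halves, 4 plots per half, 7 sessions in the
first year and 6 in the second (all configurable). Its purpose is to make
specialization a controllable dial so that parameter recovery can be
tested.

* **Preferences.** Each predator species holds one diet-preference vector
  per session × treatment, drawn from
  Dirichlet(κ(session) · availability). The concentration κ is the dial:
  κ → 0 puts nearly all preference mass on one prey (specialized webs),
  κ → ∞ makes every species track the shared availability weights
  (generalized webs). The default seasonal profile
  κ = (0.1, 0.3, 1, 3, 1, 0.3, 0.1) encodes the U-shaped hypothesis:
  diets concentrated early and late, even at mid-season. Preferences are
  deterministic functions of (seed, species, session, treatment), so all
  units of a treatment share them — the association the null model is
  meant to detect.
* **Captures and detections.** Individuals per species per unit are
  Poisson (default mean 3, a realistic per-plot single-day pitfall catch
  for common taxa); each individual draws a Poisson number of prey data
  points (default mean 2) multinomially from its preference vector,
  collapsed to binary presence. Note the collapse makes the expected
  number of *positive targets* slightly less than the Poisson mean
  (S(1 − e^(−λ/S)) for uniform preferences over S targets). Self-detection
  targets are zeroed at generation time — the generator models
  post-cleaning data — unless `inject_self_detections` is set to exercise
  the cleaner.
* **Treatment effect.** The fertilized availability multiplier (default
  1.5) scales detritivore prey weights (springtails, earthworms) in both
  the preference weights and the community profiles, emulating the
  manure → detritivore enrichment; no quantitative effect size is claimed
  for it, it is a free knob.
* **Community counts.** Pitfall and tiller counts are negative-binomial
  (dispersion 2 by default, emulating pitfall overdispersion) around
  per-taxon seasonal mean profiles that peak mid-season for prey and stay
  flat for predators.
* **Calibration mode.** `shared_preferences` draws ONE preference vector
  for the entire dataset, shared by all species, sessions and treatments.
  This makes diet data points fully exchangeable within any shuffling
  stratum — the no-association regime in which the SES must center on
  zero. Sharing per session only is not sufficient: session-varying
  availability breaks exchangeability under a year-scope shuffle and
  biases the SES.

What the generator does not emulate: DNA detectability decay and PCR
sensitivity/specificity (detections are direct draws from preferences),
species' phenology and migration (capture rates are stationary across the
season), spatial autocorrelation between plots, and any year-specific
mechanism (years are pure replication strata). Passing tests therefore
demonstrate that the pipeline recovers known structure from data satisfying
its own assumptions, not that field data satisfy them.

## Problem sizes and tolerances in the test suite

The suite checks null calibration on a one-year 168-unit design with 999
randomizations (mean SES within ±0.2 of 0 over ≥ 50 valid units) and
U-shape recovery on twenty replicate 28-unit datasets with 199
randomizations each — sizes chosen to give Monte-Carlo standard errors
well inside the asserted bands while keeping a full run on one CPU in
minutes. The entropy-extreme oracle enumerates all integer tables on grids
up to 3×3 with totals ≤ 8 (1772 marginal pairs). Numeric comparisons use
1e-12 for closed forms, 1e-9 for entropy bracketing and degeneracy, and
k·SE bounds for stochastic checks.

## Design choices left open by the problem

* Webs are built at plot level (the full five-part unit key); pooling to
  coarser grains is possible by dropping key fields upstream but is not the
  default.
* Intraguild prey (spiders, ladybeetles, the six beetle taxa) are ordinary
  web columns; `exclude_targets` removes them when a web without
  intraguild links is wanted.
* Natural logarithms throughout (both `H2` machinery and Shannon
  diversity); the diversity base is configurable for cross-checks.
* Mixed-effects and generalized additive models on the SES/diversity time
  series are deliberately out of scope: the tidy per-unit table and
  per-session summaries exported by the reporter are the contract for any
  standard modelling package.
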