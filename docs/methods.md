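# Methods

## Behavioral model and statistics

### Turn calling

A Y-maze is three symmetric arms (default length 12 mm) meeting at a
central hub. Zone assignment partitions the maze: points within
`center_radius` (default 2 mm) of the hub are "center"; any other point
belongs to the arm whose 120°-wide angular sector contains its bearing.
Points on a sector boundary go to the lower arm index — an arbitrary but
deterministic rule. Points beyond the arm length are flagged with a warning
and assigned to the nearest arm rather than dropped, since brief tracking
overshoots should not fragment a visit.

The per-sample zone sequence is run-length encoded and runs shorter than a
debounce window (default 3 samples) are suppressed before visits are
extracted; this absorbs single-frame flicker across the hub or sector
boundaries that centroid tracking noise produces. Both `center_radius` and
the debounce window are configuration, not constants, because how much
flicker real tracking produces depends on the rig.

A turn is a transition between two *different* arms. Re-entering the same
arm is not a turn: the assay's choice is between the two other arms, a
convention adopted from the Y-maze assay lineage this pipeline follows.
"Right" is defined as the transition to the next arm in increasing-bearing
order, which is clockwise on a camera image with y increasing downward. The
sign convention is configurable (`clockwise_is_right`) and immaterial to
the downstream statistics: flipping it maps every bias b to 1−b and leaves
the MAD and every test invariant, a property the suite checks.

Per-fly summaries are the right-turn proportion (turn bias), turns per
minute over the recording, and the turn count. Flies with fewer than 30
turns are excluded (boundary inclusive: 30 turns is kept); their bias
estimates would be dominated by binomial noise.

### Variability inference

The group-level phenotype is the unscaled MAD of per-fly biases:
median(|x_i − median(x)|), with **no** 1.4826 normal-consistency factor.
Its uncertainty is a nonparametric bootstrap SE: the SD (ddof = 1) of the
MAD over 1000 with-replacement resamples of the original size. The
replicate count is a default, not a claim about any particular study; it
puts the Monte Carlo error of the SE well below the SE itself at the
cohort sizes involved.

Two groups are compared by the permutation test on the absolute MAD
difference: pool the two groups, reassign labels preserving group sizes,
recompute |MAD(a) − MAD(b)|, and report the proportion of shuffled
statistics at least as large as the observed one. Defaults: 99,999
shuffles; ties count as exceedances (the "ge" rule), which is conservative
and well defined for degenerate data (all-equal input gives p = 1). A
strict-greater mode and an optional (b+1)/(B+1) small-sample correction
are provided. Each comparison pools and shuffles only the two groups
involved (pairwise pooling); shuffling all six groups jointly is a
defensible alternative but answers a different question, and the pairwise
form matches "difference between group pairs". For total n ≤ 10 the test
can enumerate all C(n, n_a) label assignments exactly (`method="exact"`),
and the Monte Carlo path is tested against that enumeration.

Families of pairwise comparisons reported together are Benjamini–Hochberg
adjusted (step-up, order-preserving, capped at 1); the family is the set of
pairs in one analysis run. Companion rank tests: Kruskal–Wallis on turn
bias across groups, per-group one-sample Wilcoxon signed-rank against 0.5,
and pairwise Mann–Whitney on turn rate with BH adjustment. Groups with
fewer than two flies are skipped with a warning rather than failing the
whole report.

### Survival ANOVA

The experimental unit is the jar (ten flies with one spider, scored after
12 h); the response is the raw per-jar survival percentage. No arcsine or
logit transform is applied by default — with n = 10 jars per cell and
percentages in the 30–65% range the classical ANOVA on raw percentages is
the analysis this assay family reports — though the residual machinery
accepts any transformed column.

`two_way_anova` implements the balanced fully-crossed decomposition
directly (factor-mean sums of squares; all classical ANOVA types coincide
under balance) and rejects unbalanced data rather than silently
re-weighting. It is cross-checked in the tests against an independent OLS
projection oracle (statsmodels `anova_lm`) to 1e-8 relative.

`anova_from_summary` uses the sufficiency of cell (mean, SD, n) under
balance: within-cell SS = Σ(n−1)·sd², between-cell SS from the means
alone. The identity `anova_from_summary ∘ summarize = two_way_anova` holds
to floating tolerance on every balanced dataset and is asserted over 100
random designs. Applied to the published six-cell survival summary
(30 ± 9.4, 32 ± 6.3, 30 ± 15, 62 ± 11.4, 65 ± 8.5, 35 ± 7.1 %, n = 10),
it recovers F(1,54) ≈ 80.9 for rearing condition, F(2,54) ≈ 14.7 for drug
and F(2,54) ≈ 12.5 for the interaction — within 1% of the published 81.37,
14.76 and 12.57; the residual discrepancy is exactly what rounding the
inputs to the printed precision produces.

Tukey HSD flattens the 2×3 layout into one six-level factor and tests all
15 pairs with the studentized range, using the pooled within-cell mean
square and its df (k(n−1) = 54) — standard post-hoc practice after a
significant interaction. p-values come from `scipy.stats.studentized_range`
and are tested against statsmodels' independent implementation.

Note on the design's bookkeeping: the source methods text describes "ten
jars for each survival group (48 jars containing 480 fruit flies)", but six
groups × ten jars is 60, and the per-group Ns printed with the results are
all 10. The reconstruction uses the full balanced 6 × 10 layout (residual
df 54, matching the printed F subscripts); the 48/480 figure appears to be
a typo and is surfaced here rather than resolved.

## The synthetic generator

What it emulates, and the defaults (all overridable in `SimulationConfig`):

- **Individual bias**: each fly draws a lifetime right-turn probability
  from a beta distribution parameterised by mean and concentration
  (α + β). The beta is the minimal exchangeable model for probabilities;
  no generative model is implied by the assay itself. Group means are 0.5
  (no population-level handedness). Concentrations are calibrated through
  the exact quartile identity MAD(beta(α,α)) = Q₀.₇₅ − ½: 18.0 for the
  predator-free groups (MAD 0.08) and 9.65 / 8.15 / 11.6 for the
  spider-reared none / 5-HTP / aMW groups (MAD 0.11 / 0.12 / 0.10), the
  band this assay family reports.
- **Turn timing**: homogeneous Poisson process — count Poisson with mean
  rate × duration, times uniform over the 120-min recording. Group rates
  2.6–3.5 turns/min. Each turn is an independent Bernoulli(bias) choice:
  the generator has **no within-fly temporal structure** (no turn
  autocorrelation, no slow drift in bias, no activity bouts). That is an
  assumption of convenience, not a claim about flies.
- **Trajectories**: piecewise hub → arm-tip → hub excursions at 10 mm/s
  (a typical walking speed for the species), sampled at dt = 0.1 s with
  isotropic Gaussian noise of SD 0.2 mm (sub-pixel centroid jitter for a
  2 MP camera over a ~25 mm arena). Arm entries honor the generating event
  times; when two events are closer than one excursion takes, the later
  entry is pushed back so excursions never overlap — the direction sequence
  is preserved exactly, which is what the round-trip guarantee covers. dt
  must be smaller than the time to cross from hub boundary to arm tip, or
  the simulation raises an undersampling error.
- **Survival**: per-jar binomial(10, p) with group probabilities
  0.30 / 0.32 / 0.30 (predator-free: none / 5-HTP / aMW) and
  0.62 / 0.65 / 0.35 (spider-reared), ten jars per group.
- **Cohort size**: 140 flies per group, within the 116–153 range such
  experiments run.
- **Seeds**: one global seed; each fly gets a `SeedSequence` substream
  keyed by (group, fly index), so enlarging the cohort never reshuffles
  flies already generated, and everything is bit-reproducible.

What passing tests on this generator do **not** show: real tracking noise
is not isotropic Gaussian (occlusions, reflections, identity jumps), real
flies have temporally structured behavior and activity rhythms, and real
bias distributions need not be beta or symmetric. The generator validates
the statistical machinery and the pipeline's plumbing, not the biology;
empirical MADs, permutation p-values and survival contrasts from the
original experiments require the deposited raw data.

## Numerical choices

- Permutation p is a plain exceedance proportion b/B (no +1 by default);
  exceedance comparisons use a 1e-12 absolute tolerance so statistics
  equal up to rounding count as ties.
- The Monte Carlo permutation path vectorises shuffles in chunks of 4096
  rows to bound memory at large B.
- MAD of an even-sized sample uses the midpoint median throughout
  (numpy's convention), including inside the exact enumeration, so the two
  paths are comparable bit-for-bit.
- Degenerate ANOVA inputs (zero residual variance) yield NaN F with a
  `degenerate` flag on the table rather than an exception.
- Sector-boundary ties in zone assignment and label ties in BH are all
  resolved deterministically; reruns with one manifest are bit-identical.

## Problem sizes in the checks

The test suite's calibration checks use 1000 replicate null experiments
(two groups of 150 flies, 999 shuffles each) for the type-I rate and 300
replicates for the power comparison; the acceptance script reports a
400-replicate type-I estimate and a 100-fly round-trip check over 20-min
recordings. These sizes put the binomial error of the estimated rates well
inside the bands being asserted while keeping a full run in the tens of
seconds.

## Known limitations

- Unbalanced designs are rejected, not analysed; v1 scope is the balanced
  experiment the assay produces by construction.
- The survival analysis is end-point only (counts after 12 h); no
  time-to-event modelling.
- Turn calling starts from centroid trajectories; raw video tracking and
  multi-animal identity maintenance are out of scope.
- The loader for externally deposited raw-data schemas is deferred until
  such a schema is in hand; the CSV formats here are the pipeline's own.
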