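# Methods

This note documents the statistical models, the generative model behind the
synthetic data, the numerical choices in the sampler, and the design
decisions taken where more than one defensible option existed.

## Experimental structure assumed

The atomic record is one egg count for one genotype class (mutant or
wildtype) in one vial at one assay age.  Vials house both classes together,
founded with 33 females per class plus males; at each assay age (defaults
5, 19, 33 days of adult life) a matched number of females per class
(default 25, fewer when survival limits, always equal across classes) lays
for 24 h.  The matched-pairs invariant — a mutant record exists iff the
wildtype record exists, with equal `n_females` — is enforced at load time.
Per-vial relative fecundity uses class totals, not per-female rates,
because the design matches female numbers within a vial; `n_females` is
retained for validation and exposure modelling.

Relative fecundity is `ln[(mut+1)/(wt+1)]`; the +1 offset is applied to
both counts unconditionally (not only when a zero occurs), which keeps the
statistic defined and continuous at zero counts and is antisymmetric in its
arguments.

## Deleteriousness model

`eggs ~ type * mutation + (1|vial)`, Poisson error, log link, fit once on
first-age counts and once on counts summed over the assay ages (vials
missing an age are summed over their available ages and listed in the fit
metadata).  Internally the model is parameterized as cell means — a
baseline log count and a mutant-class log-ratio effect per mutation — so
per-line estimands need no reference-level arithmetic; the treatment
-contrast view is a linear combination of the draws.  The selection-style
effect is reported as `s = 1 − exp(log ratio)` per draw, with the
significance test (p_mcmc) on the log scale where zero is the null.

## Aging models

`(mutant eggs | wildtype eggs) ~ age * mutation + (1|vial)`, binomial
error, logit link: the response for one vial-age is the mutant count out of
the vial's total.  If the two class counts are independent Poisson with
means λ_m, λ_w sharing a vial effect, then conditional on their total the
mutant count is binomial with `logit(p) = ln(λ_m/λ_w)` — the vial effect
cancels, so the binomial effects are directly log fecundity ratios.  Age
enters either as a covariate in raw days centered at the first assay age
(slope = per-day change of the log ratio, negative = faster mutant aging)
or as a factor (one effect per mutation × age).  Vial-age rows with zero
total eggs carry no ratio information and are dropped with a logged notice
(vanishingly rare at realistic fecundities).  A vial keeps one random
intercept across its ages.

Derived, per draw and hence with full posterior uncertainty:

* interval differences `effect(later) − effect(earlier)` for each age pair
  (they telescope exactly: diff(5,19) + diff(19,33) = diff(5,33));
* the acceleration contrast: late-interval rate minus early-interval rate,
  normalized per day and rescaled by the early interval length so unequal
  intervals compare fairly (with the default equally spaced ages this is
  literally diff(19,33) − diff(5,19)); negative = the decline steepens;
* among-line variance of the factor-model effects at each age, using the
  n−1 denominator across the chosen mutation subset (the unbiased
  convention; the choice scales the trajectory but cannot change the sign
  of any variance difference), and variance differences between age pairs.
  Variances are computed on the model's logit/log-ratio scale — the scale
  on which the model is linear — not on back-transformed ratios.

## Priors and sampler settings

Weakly informative normal priors: SD 10 on level-type parameters
(per-mutation baselines, per-age effects), SD 2.5 on slope/contrast
parameters, the latter divided by the empirical SD of the predictor column
when the predictor is not binary (autoscaling; the age covariate is the
only such column).  The vial-intercept SD gets an Exponential(1) prior — a
weakly informative choice on a log-scale SD whose plausible values are
well below 1.  Defaults: four chains, 4000 iterations each, first 1000
discarded as warmup, giving 12 000 retained draws; `ModelSpec.fast()` (two
chains of 700/250, not publication grade) exists for simulation studies.
Convergence is evaluated with the classic split potential scale reduction
factor per parameter; fits exceeding 1.05 attach a `ConvergenceWarning`
rather than failing silently.

## The HMC sampler

No gradient-based Bayesian GLMM backend is available in the dependency
set, so the package ships a compact Hamiltonian Monte Carlo sampler
written for exactly these posteriors (smooth, near log-concave, dimension
a few hundred).  Design choices:

* all chains advance in lockstep as rows of a (chains × dim) matrix, so a
  leapfrog step is one vectorized gradient call;
* scalar step size adapted by dual averaging toward a mean acceptance of
  0.8; trajectory length ~1.2 (in mass-normalized units), jittered ±20% in
  the sampling phase to break resonances, capped at 64 leapfrog steps;
* diagonal mass matrix seeded from the **Fisher information** at a
  data-informed starting point (per-parameter curvature of the GLMM
  likelihood plus prior), then refined in two warmup windows with
  Stan-style shrinkage of the variance estimate.  The analytic seeding
  matters: posterior scales here span four orders of magnitude
  (count-level baselines are pinned to ~1e-2 by hundreds of eggs per vial
  while random-effect coordinates are O(1)), far beyond what short
  adaptation windows can bridge alone;
* the Poisson model chooses its random-intercept parameterization from a
  method-of-moments estimate of the vial variance: when among-vial
  variance dominates Poisson count noise the vial log-means are sampled
  directly (centered; the data pin them), otherwise standardized deviates
  are sampled (non-centered; avoids the funnel).  The binomial models are
  always non-centered because the generative design cancels vial effects
  from the ratio, leaving the intercept prior-dominated.

Starting points are method-of-moments estimates (log mean counts, pooled
empirical logits) jittered per chain; the vial SD is sampled on the log
scale with its Jacobian.  With these settings every standard fit in the
test suite reaches split-R-hat < 1.05 on all parameters, typically < 1.01.

## p_mcmc and intervals

`p_mcmc = min(1, 2 × min(frac < 0, frac > 0))` over the pooled post-warmup
draws of a scalar — invariant under sign-preserving monotone transforms and
under sign flips.  All credibility intervals are central 95% posterior
intervals (2.5% and 97.5% quantiles, linear interpolation).

Classification rules, all at two-tailed α = 0.05 and reported without
multiple-testing correction (the full p vector is exposed so users can
correct): *deleterious* = harmful sign with p_mcmc < α in the first-age
Poisson fit **or** the summed fit (union rule; the report records which
fired); *aging* = negative covariate slope with p_mcmc < α; *accelerating*
= aging plus a credibly negative acceleration contrast.

## Kendall's tau

The statistic is tau-b (tie-corrected; identical to tau-a without ties),
delegated to scipy.  Two-tailed p values: for n ≤ 10 the exact permutation
null is enumerated — done on the integer concordant-minus-discordant
statistic in fixed-size blocks, so the comparison is exact integer
arithmetic with bounded memory — because medians of offset log ratios can
tie and the usual exact tables assume no ties; for larger n the normal
approximation with tie-corrected variance (no continuity correction).  The
change-vs-level test (aging rate vs deleteriousness) is conservative by
construction: noise in the earlier-age median enters the level positively
and the change negatively, biasing tau toward negative values; the test
suite reproduces this bias on pure noise.  Survival is aggregated per line
by pooling survivor counts over vials and taking `ln[(mut+1)/(wt+1)]`
(per-vial median available as an option); all-tied inputs return a
flagged, degenerate tau of 0 with p = 1.

## Synthetic experiment generator

For mutation m, vial v with shared intercept u_v ~ N(0, σ_vial²):
wildtype counts are Poisson (optionally negative binomial with a shape
parameter) with mean `exp(μ + γ_a + u_v)`, mutant counts multiply that
mean by `exp(δ_m + β_m(a−a₁) + κ_m(a−a₁)²)`.  Because u_v is shared, the
generator realizes exactly the pairing the binomial conditioning assumes.
Defaults mirror the assay: 20 lines, 20–22 vials each, 25 laying females
per class, ages 5/19/33.  Free parameters that no design table fixes were
set once to realistic values: baseline log eggs μ = ln 600 (~24 eggs per
female per day for young, well-fed females), a wildtype age trajectory of
(0, −0.3, −0.8) on the log scale, σ_vial = 0.2.  Day-33 survival is drawn
per class from a logit (default logit(0.9)); the optional attrition switch
reduces day-33 laying females to the scarcer class's count in both classes,
mirroring the matched-laying protocol, and scales the expected count by the
exposure ratio.

`paper_like_config` produces the study-shaped scenario used in examples
and the acceptance script: 16 of 20 lines deleterious with day-5 effects
spaced from ln 0.95 to ln 0.5, aging slopes β_m = δ_m/30 per day (so more
deleterious lines age faster — the "fanning" structure), κ_m = δ_m/800
(mild late-life acceleration) and mutant survival logits shifted by 2δ_m
(coupling fecundity and survival effects); line order is shuffled by seed.

What the generator does *not* emulate: block effects between experimental
batches, male aging or replacement effects, within-vial female
heterogeneity (frailty), counting error, or attrition before the final
age.  Passing recovery tests therefore demonstrate that the inference
machinery is correct for the model class the analysis assumes — not that
real data satisfy those assumptions.

## Verification strategy and problem sizes

The test suite checks, at sizes chosen to keep the full run to a few
minutes on one CPU: exact agreement of tau-b with an O(n²) brute-force
pair count (1000 random vectors, n ≤ 50, with and without ties) and of
exact p values with full permutation enumeration (n ≤ 8); direct-count
correctness and invariances of p_mcmc; ≥ 90% coverage of generator truth
by 95% intervals for the selection coefficient (8 lines × 20 vials × 20
seeds, δ from 0 to ln 0.5), the per-day aging rate and the acceleration
contrast (6 lines × 20 vials × 12 seeds, β ∈ {0, −0.01, −0.03}, κ ∈
{0, −0.001}); a ~5% null rejection rate and uniform-looking aging p_mcmc
on all-null data (8 lines × 12 vials × 30 seeds); monotone growth and
credible day-5→33 increase of the among-line variance under fanning
effects (16 lines × 20 vials × 10 seeds); the negative-bias reproduction
for the change-vs-level tau (1000 noise resamples); and split-R-hat < 1.05
on every parameter at the full default sampler settings.

## Known limitations

* The sampler is specialized: diagonal mass, scalar step size, fixed
  trajectory-length heuristic.  It is validated for these GLMMs, not a
  general-purpose backend.
* The binomial conditioning argument is exact for (mixed) Poisson counts;
  under strong overdispersion the binomial model's effective sample size
  per vial is optimistic, though the vial intercept absorbs persistent
  per-vial ratio deviations.
* Draws are serialized as `.npz` with JSON metadata (an in-memory arviz
  converter is provided); no netCDF writer is included.
* The loader accepts age-incomplete vials (a vial that died out of one
  class before an assay contributes its earlier ages); downstream fits use
  available pairs, and the summed Poisson fit flags such vials in its
  metadata.
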