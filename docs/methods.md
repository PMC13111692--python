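# Methods

## The behavioural model

Each trial presents two single-outcome lotteries (left/right): `x` tokens
(integer, −3…+3, never 0) with probability `p ∈ {0.25, 0.5, 0.75, 1}`, zero
tokens otherwise.  Subjective value of a lottery is `SEV = w(p)·u(x)` with

* utility `u(x) = x^(1−ρ+)` for `x > 0` and `u(x) = −λ(−x)^(1+ρ−)` for
  `x < 0`, `u(0) = 0`.  Under this parameterization `ρ = 0` is risk-neutral:
  `ρ+ > 0` bends the gain curve concave (risk aversion), `ρ− < 0` bends the
  loss curve convex (risk seeking).  `λ > 1` makes losses loom larger than
  equal gains; at `|x| = 1` the curvature exponents drop out and λ is exactly
  the loss/gain ratio.
* Prelec-I weighting `w(p) = exp(−(−ln p)^α)`, with a separate exponent per
  domain (`α+`, `α−`).  `α > 1` gives an S-shape (small probabilities
  underweighted), `α < 1` an inverted S; fixed points at `p = 1/e` and
  `p = 1` for every α.

Choice is logistic in the SEV difference `Δ = SEV_right − SEV_left`:
`P(right) = 1/(1 + e^(−(μΔ + x0)))`.  `μ ≥ 0` is steepness (higher in
better-trained animals); `x0 > 0` is a right-side bias.  This orientation is
the one consistent with both behavioural statements; the alternative sign
convention (P decreasing in Δ for μ > 0) would contradict them.

Because every lottery has a single non-zero outcome, rank-dependent
(cumulative) weighting is unnecessary; the simple separable form is exact.

## Fitting

All seven parameters are estimated jointly per chunk (a consecutive window
of 1500 trials from one individual) by maximum likelihood.  Within a single
domain, `u` scales linearly in λ for losses, so the loss-side likelihood
depends on λ and a loss-domain steepness only through their product: with a
free per-domain μ, λ would sit on a flat ridge (demonstrated in the test
suite by NLL invariance along `λ → cλ, μ → μ/c` on loss-only trials).
Sharing μ across gain and loss trials is what makes λ identifiable without
mixed-domain pairs; mixed pairs are available in the battery generator but
off by default, matching the within-domain reading of the task.

Numerics: trials are collapsed onto unique (pair, choice) rows with counts,
so an NLL evaluation costs the same for 250 or 75,000 trials; the NLL and
its analytic gradient feed bounded L-BFGS-B; log-probabilities are clamped
at `ln 1e−12` (the gradient is that of the unclamped objective, which
remains informative where the clamp binds).  The likelihood is multimodal in
(α, μ), so each fit is a best-of-N multistart (default N = 10; one start at
the neutral parameters, the rest uniform in the bounds, seeded).  Bounds:
ρ± ∈ [−0.95, 0.95], λ ∈ [0.05, 15], α± ∈ [0.05, 5], μ ∈ [0, 25],
x0 ∈ [−10, 10].  Degenerate chunks are fitted but flagged: side bias ≥ 0.95,
or no trials in one domain (that domain's parameters then sit on a flat
profile).

## The 1500-trial window

`trial_requirement_curve` refits simulated agents on growing trial prefixes.
True parameters are drawn uniformly: the five PT parameters over the fit
bounds, μ over [0.5, 10] and x0 over [−2, 2] — a near-zero μ or an
overwhelming side bias yields choices that carry no information about the
other parameters, which no analysable subject shows.  The error metric is
the absolute error per parameter standardized by that parameter's sampling
range, averaged over the five PT parameters and over agents (the aggregate
is a choice; per-parameter columns are also reported).  The curve falls
steeply to ~1000–1500 trials and flattens after, which is the basis for the
1500-trial analysis window.

## Hierarchy

Classical Elo with logistic base-10/400 expectation, `k = 100`, start 1000
(all configurable): winner gains and loser loses `k·(1 − E_w)`, conserving
total points.  Daily rating = value after the day's last event, carried
forward over event-free days; days before an individual's first event sit at
the start rating.  Exact numeric parity with any particular external Elo
package is not promised — those internals vary; parity with this stated rule
is, and is enforced against a hand-computed oracle.

COP (conflict outcome predictability) over a window is
`|wins − losses| / n_conflicts`; zero conflicts yield a missing value, not 0.
Chunk-level hierarchy covariates are the mean daily Elo over the chunk's
time span and the COP over the same span.

Ordinal ranks are dense (1 = highest, ties share a rank, output ordered by
individual id).

## Filtering

1. Side-bias guard: chunks with side bias ≥ 0.95 are removed first.  With
   fully one-sided choices the likelihood is flat in every PT parameter (x0
   absorbs the behaviour), so the fitted values are arbitrary — the IQR rule
   alone cannot reliably catch them, and letting them into the pooled fences
   would distort those fences.
2. IQR fences per parameter (ρ+, ρ−, α+, α−, λ, raw scale) computed on the
   pooled distribution across all individuals' chunks, linear-interpolation
   quantiles, Q1 − 1.5·IQR / Q3 + 1.5·IQR.  The chunk is the unit of
   removal: one out-of-fence parameter removes the row (the analysis table
   has a single shared observation count across responses).
3. Individuals with fewer than 10 remaining chunks are excluded (strict:
   exactly 10 stays).

All fences, removals and exclusions land in the run manifest so a filter can
be frozen and re-applied.

## The analysis table and mixed models

Per retained chunk: fitted ρ+, ρ−, and natural-log λ, α+, α− (log chosen for
the right-skewed multiplicative parameters; any log base is monotone
equivalent), mean Elo and COP over the chunk span, sex, age category at the
chunk's midpoint (juvenile < 4 y; subadult 4–8 y males / 4–7 y females,
half-open upper bound), and experience = mean cumulative trial index of the
chunk.  Elo and experience are z-scored on the assembled table.

Models: `response ~ age_category + sex + elo_z + elo_z² + experience_z +
(1 | individual)`, REML, random intercept only (each animal occupies a
narrow band of ranks, so subject-wise slopes over the full predictor range
are not estimable), references adult/male, significance at P < 0.01.
`elo_z²` is the square of the z-scored Elo.  Reported per model: estimates
with Wald CIs and P values, σ² (residual), τ00 (intercept variance),
ICC = τ00/(τ00+σ²), and Nakagawa-style marginal/conditional R² (fixed-effect
variance over total).  A second specification replaces elo_z² with COP.  The
engine is statsmodels MixedLM; near-singular variance fits fall back from
gradient-based to derivative-free optimizers and carry warning flags.
Residual diagnostics (normality, heteroscedasticity screens) are emitted as
a report and never gate a fit.

Wilcoxon signed-rank contrasts use the exact null for n ≤ 25 without ties,
the normal approximation otherwise; identical vectors return P = 1 with a
warning.

## Synthetic cohort

The generator emulates the study conditions: 18 individuals (11 males),
ages ~7.2 ± 4.6 y at start, 40 months of activity, ~75,000 trials each
(defaults; studies run reduced sizes, below).  Latent dominance strengths
start N(0,1) and drift as a per-day Gaussian random walk (sd 0.03/day), so
ranks genuinely change over months; conflicts arrive Poisson (12/day),
between uniform random dyads, resolved with win probability
`expit(1.5·Δstrength)` — near-equal opponents are coin flips, which both
produces upsets and makes mid-hierarchy conflict outcomes unpredictable (the
COP U-shape emerges rather than being painted on).

Chunk-level true parameters are `baseline + link·z² + jitter`: baselines per
individual from the cohort-level means (ρ+ 0.182, ρ− −0.508, λ 2.987,
α+ 1.208, α− 0.655; log scale for λ, α) with between-individual sds matching
the mixed models' random-intercept variances; the default rank link is
quadratic in the chunk's z-scored Elo (+0.08 on ρ+, −0.10 on log α+, −0.25
on log λ, zero in the loss domain); chunk jitter sds match the residual
variances.  Values are clipped to the identifiable ranges.  μ ~ N(5, 1)
(min 1) and x0 ~ N(0, 0.3) per individual.  Choices are then simulated
through the behavioural model over the full battery, so the ground truth for
every pipeline stage is known.

What the generator does **not** emulate: token-gauge state, session/device
structure, diurnal and seasonal activity rhythms, kin-structured conflict
networks, unequal trial counts across individuals, or any drift in μ with
training.  Passing tests therefore show that the pipeline recovers the
structure this generative model encodes — not that real data satisfy that
model.

## Validation studies and problem sizes

* U-shape recovery: 20 cohorts of 18 individuals × 30 chunks (45,000 trials
  each, ~60% of the full cohort's chunk count; best-of-5 multistarts),
  full pipeline + LMM per cohort.  Passes when the gain-domain elo_z² term
  is positive and significant (P < 0.01) in ≥ 95% of cohorts and the
  loss-domain term stays at the nominal rate.
* Type-I control: 200 cohorts with a zero rank link, 18 × 12 chunks.  The
  statistical stage runs on the generator's chunk-level ground truth
  (conflicts → Elo → parameters with jitter); the trial-level fitting step,
  validated separately by the recovery studies, is bypassed so 200
  replicates stay fast.  Expected rejection of elo_z² at P < 0.01 is ~1%
  (binomial 99% band ≤ 6/200).
* Recovery curve: 25 agents, grid {250, 500, 1000, 1500, 3000}.

## Known limitations

* Wald P values from the mixed model carry no small-sample df correction;
  with 18 clusters they are mildly anti-conservative for mostly-between
  predictors (the type-I study bounds the practical effect).
* The IQR filter selects on fitted values, which attenuates steep rank
  links slightly (removed chunks are disproportionately extreme-Elo ones).
* Elo values are parity-checked against this package's stated rule, not
  against any external implementation.
* The battery enumerates all condition-consistent pairs uniformly; the live
  task's (unpublished) pair frequencies may differ.
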