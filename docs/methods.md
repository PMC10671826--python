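# Methods

This note records the modelling conventions, estimation choices, defaults and
known limitations of `hhcteams`. Everything quantitative stated here is
computed by the package's tests or by `scripts/acceptance.py`.

## Demand model

Weekly demand is a discrete-time infinite-server queue with batch arrivals:
each case arriving in week *s* contributes *Bᵢ* hours per week for *Sᵢ*
consecutive weeks, with weekly new-case counts *Aₛ*. Counts, lengths of stay
and case volumes are i.i.d. and mutually independent. The stationary mean is
ρ = mₐ mₛ m_g and the variance zρ with peakedness

    z = σ_g²/m_g + m_g + m_g (1 − G_s)(σₐ²/mₐ − 1).

Only the first two moments of each ingredient and the LoS Gini coefficient
enter these formulas; the Monte-Carlo oracle tests exercise this
distribution-free property by swapping arrival families at fixed moments.

Transient moments condition on the current caseload. The remaining-LoS tail
`Sr` of cases already in service must be supplied by the caller; the default
is the equilibrium (stationary-excess) tail `Sr(t) = Σ_{u>t} S(u) / E[S]`,
which is the exact remaining-LoS law of a case inspected at a random time in
steady state. All current cases share one `Sr`; per-case tails conditioned on
elapsed time are not modelled. Demand distributions downstream (skill mix,
scenario engine) use the normal approximation of *N*, appropriate in the
quality-and-efficiency-driven regime where ρ is at least a few dozen hours.
Capacities are fractional throughout (a "server" is one care hour per week).

Pooling assumes independent team demands: loads add, variances add, so pooled
peakedness is the load-weighted mean. Correlated demand across teams (e.g.
epidemic waves) would erode the pooled-variance reduction; the engine does not
model it.

## Estimation conventions

- **Weeks** are ISO weeks; week 0 is the ISO week of the earliest visit in
  the file. Durations are hours.
- **Cases** group visits of one client at one qualification level; a gap of
  more than 30 days between consecutive visits closes the case. LoS is
  `end_week − start_week + 1`, so a case seen in one week has LoS 1 (this
  keeps E[S] ≥ 1 and makes the implied-mean identity well defined).
- **Censoring.** Cases active in the first observed week have unknown start
  and are dropped from LoS estimation by default (their observed duration
  understates the truth); cases active in the last week enter the
  Kaplan–Meier estimator as right-censored. Week 0 is also dropped from the
  arrival-count window, since its starts are confounded with left-censoring.
- **Arrival and case-demand moments** use the n−1 sample variance; case
  demand is measured per (case, active week) observation, so longer cases
  weigh more — consistent with the generator, where the per-case volume is
  independent of the LoS.
- **Kaplan–Meier** estimation is delegated to lifelines; the package stores
  the tail P(S ≥ t) on the integer week grid together with at-risk/event
  counts. **Weibull fitting** is a weighted least-squares regression of
  log(−log S(t)) on log t (weights: at-risk counts), i.e. a curve fit to the
  nonparametric estimate rather than an MLE on the raw durations — the
  intended use is smoothing/extrapolating the KM curve, and an exact Weibull
  tail is recovered to machine precision.
- **Gini and implied means** are computed on the tail truncated at the
  observation horizon. Tail mass beyond ~100 observed weeks is unreliable in
  data of this kind, which is why summary workflows prefer the implied mean
  LoS ρ/(mₐ m_g) over the KM mean.

## Availability, contracts, complexity

- Default presence probability p = 0.79 (12.5% holiday/leave + 8.5% sick
  leave). The dip probability uses the regularized incomplete beta so team
  size may be fractional; at integer thresholds it equals the binomial CDF
  exactly (tested for all M ≤ 30).
- Contract defaults a = 1.5, b_FT = 8, b_PT = 5 correspond to 4 h short
  shifts, 6 h long shifts, 32 h full-time and 20 h part-time weeks. The
  full-time bound is clamped to [0, 1]. Its closed-form inversion returns the
  smallest f₀+f₂ reaching a target full-time share; targets beyond the
  formula's range are met at the all-full-time feasibility threshold
  `min((b_FT−5)/(b_FT−b_PT), 1−1/a)`. Note the bound saturates at exactly 1
  at f₀+f₂ = (b_FT−5)/b_FT, which is generally *smaller* than that
  threshold.
- Interaction counts require integer team sizes except the equal-split
  formula M/2 + M²/(2k), which is meaningful for fractional sub-team sizes.

## Skill-mix solver

The excess recursion is the chained one-step form: e_K = 0 and
e_{k−1} = E(C_k + e_k − N_k)⁺ evaluated with the normal loss function,
treating the incoming excess as a constant. With no minimum contract the
optimum is the backward recursion C_k = max(0, μ_k + η_α σ_k − e_k) — since
costs are non-decreasing in level, every binding constraint is held at its
lower bound.

With a minimum contract ℓ > 0 the solver enumerates all 2^K support patterns
(K ≤ 10 guard; K = 3 in the intended application). Within a pattern, active
levels take max(ℓ, requirement − excess) from the top down; when a skipped
level's requirement is not met by the excess from above, the cheapest active
higher level is lifted by the smallest sufficient amount. The excess chain is
monotone in any upstream capacity, so the lift is a bracketing 1-D root find
(Brent, xtol 1e−10). The cheapest feasible pattern wins; tests compare
against an independent SLSQP-based exhaustive pattern search.

Defaults: η_α = 2 (shortfall probability ≤ 2.3% per level), costs (1, 2, 3)
— ordered but otherwise arbitrary, as only the ordering matters for the
structure of the optimum. Per-level demand defaults to μ_k = ρ_k,
σ_k = √(z_k ρ_k) via the normal approximation.

## Scenario engine

Team size from demand is ⌈ρ/20⌉ workers (20 direct-care hours per worker per
week). The four metrics are utilization 1/(1+γ√(z/ρ)); availability
P(P > l) at l = 0.6; the positive part of capacity-share minus demand-share
summed over levels (skill mix at ℓ = 0); and the complete-graph interaction
count. When per-level demand streams are unavailable, team totals are split
by the organization-wide planned-care proportions (0.67, 0.09, 0.24), with
the team's peakedness applied to every level. The objective weighs the three
fraction-valued terms with λ₁ = λ₃ = λ₄ = 1 by default and the interaction
count with λ₆, which doubles as a scale factor; the merge order is
caller-supplied (the engine performs no geographic optimization).

## Synthetic data generator

The generator emulates the demand structure the estimators target, with
defaults at the cross-team medians: mₐ = 3.6 new cases/week with VMR 1.4,
m_g = 3.3 h/week per case with VMR 4 (gamma-distributed, constant over the
case's weeks), geometric LoS with mean 20 weeks (memoryless; closed-form
Gini q/(1+q) for testing — a discretized Weibull is available for curve-fit
testing), qualification mix (0.67, 0.09, 0.24), day-part profile
(0.686, 0.073, 0.242) (renormalized; the printed percentages sum to 100.1%),
and weekend demand 19.3% below weekdays. Arrival counts come from a family
chosen by the VMR — negative binomial above 1, Poisson at 1, binomial below 1
— because the closed-form moments depend only on the first two moments; for
the binomial case the integer trial count may shift the achieved VMR
slightly, so the sampler exposes its exact moments and oracles use those.

Each active (case, week) materializes one visit record per day part, all on
one weekday drawn with weekend weighting; intra-week visit splitting beyond
day parts is not modelled. One seeded RNG stream drives all draws in a fixed
order (arrivals per week, then per case: level, LoS, volume, coordinates,
then day-of-week per active week), so identical specs yield byte-identical
output.

What the generator does **not** emulate: client-level re-admission
correlation, seasonal or trend components, dependence between LoS and case
volume, spatial clustering, and capacity feedback (demand here is exogenous
planned care). Passing recovery tests therefore show the estimators are
consistent for this structure, not that real visit data satisfies it.

The Monte-Carlo oracles simulate the weekly demand sum directly, using
binomial thinning per arrival-age and the gamma convolution identity for
case-volume sums. Stationary runs truncate the LoS tail where its mass drops
below 1e−9 and refuse horizons with more than 1e−3 tail mass.

## Problem sizes and tolerances

Test simulations use 5,000 replications for stationary oracles, 20,000 for
transient ones, and 300-week synthetic datasets for parameter recovery —
sizes at which three-standard-error bands are a few percent of the targets.
Standard errors for ratio statistics (VMRs, Gini) come from bootstrap
resampling (300 resamples over weeks or cases; 60 for the KM Gini); the
weekly-mean check uses a moving-block bootstrap (block length 40 weeks)
because the series is autocorrelated over roughly the mean LoS. Closed-form
identities are asserted at machine precision (rel. 1e−12); values quoted
from the built-in parameter table carry a 0.5–1% tolerance because the
stored inputs are rounded to two decimals.

## Known limitations

- No finite-server queueing or waiting-list dynamics; capacity feedback and
  admission control are out of scope.
- No routing/scheduling solver: the travel model is the square-root
  approximation only, in km (time conversion is the caller's affair).
- LoS estimation offers no covariate or competing-risk structure; left-open
  cases are dropped rather than treated as left-truncated.
- The skill-mix model excludes supervision/overhead loading of higher
  qualification levels.
- Interaction counts measure potential communication lines, not realized
  coordination load or its quality.
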