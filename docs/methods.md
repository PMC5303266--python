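# Methods

## Estimand and identifying assumptions

The unit is the day. With treatment *W*ᵢ = 1{*X*ᵢ ≥ threshold} defined on the
lag 0–1 exposure mean and potential daily death counts *Y*ᵢ(1), *Y*ᵢ(0), the
target is the sample total AD = Σᵢ *W*ᵢ(*Y*ᵢ(1) − *Y*ᵢ(0)) — a Sample Average
effect of Treatment on the Treated on the count scale (AD = N₁ · SATT).
Identification requires (i) no interference between days and no hidden
treatment versions — the lag 0–1 moving average is used precisely to make the
no-interference assumption more tenable than single-day exposure — and
(ii) unconfoundedness given the background covariates: weather, short- and
long-term seasonality, calendar structure, and influenza epidemics, with
enough overlap that every treated day has a comparable control.

The analysis is split into a **design phase** (design table → propensity
model → matching → balance), which never reads outcome columns — enforced in
the code by giving the matcher scores only — and an **analysis phase** that
sums matched-pair differences. A consequence worth stressing: one match set
serves every outcome, so cause-specific and age-specific totals are exactly
additive, an invariant the tests assert rather than assume.

## Design table

* Exposure summary: lag 0–1 mean of raw PM₁₀; treatment boundary inclusive
  (*X*ᵢ = 40.0 is treated).
* Temperature summary: lag 0–3 mean (current plus previous three days).
* The first three days of a series have undefined lag 0–3 temperature and are
  dropped, not imputed — a negligible loss on multi-year series and one less
  modelling invention.
* Heat indicator: lag 0–3 mean temperature strictly above 28 °C. The choice
  of *which* temperature variable carries the 28 °C rule was genuinely open;
  using the same lag 0–3 summary as the smooth term keeps a single
  temperature variable throughout, and the threshold is a function argument.
* Seasons are meteorological quarters (DJF/MAM/JJA/SON). A separate warm-
  season flag (May 1–Sep 30) is used only as a balance diagnostic.

## Propensity model

Logistic regression of *W* on: season × day-of-week indicators (Monday
reference), season × holiday indicators, influenza / heat / July–August
indicators, a cubic regression spline on the calendar index, and a tensor
product of thin-plate marginal bases in lag 0–3 temperature and humidity.

Numerical choices:

* **Cubic regression spline**: B-spline basis with interior knots at equally
  spaced quantiles; `df` counts columns excluding the intercept (the first
  column of the partition-of-unity basis is dropped). Default 5 df per year,
  so 20 columns on a 4-year series; fractional years round to the nearest
  integer df. No penalization — the rank is fixed a priori, so plain maximum
  likelihood is the correct fit.
* **Thin-plate marginal basis** of rank *k*: eigen-truncation of the radial
  kernel |x−x′|³ on a quantile grid of at most 100 distinct standardized
  values; the leading *k*−2 eigenvectors (ordered by absolute eigenvalue,
  deterministic sign) are whitened by their eigenvalues and joined with the
  null-space columns {1, x}. Spans are nested in *k*; *k* = 2 is exactly the
  null space. Defaults (5, 3) for temperature × humidity give a 15-column
  tensor surface.
* **Degeneracy pruning**: the assembled matrix is reduced to full column rank
  by QR with column pivoting on norm-scaled columns (relative tolerance
  1e-9). The tensor's 1⊗1 column duplicating the intercept is the usual
  casualty.
* **Fit**: IRLS via statsmodels GLM/Binomial (tolerance 1e-10, max 200
  iterations); the score equations Σ(Wᵢ−êᵢ)xᵢⱼ are checked post-fit (max abs
  < 1e-6 in the tests), which also forces mean(ê) = mean(W).
* **Extreme scores**: ê is clipped to [1e-6, 1−1e-6]; matching needs a finite
  ordering, not calibrated tails. A warning is raised only when |logit ê|
  exceeds 36 — i.e. fitted probabilities indistinguishable from 0/1 in double
  precision, the practical signature of separation. Merely large logits are
  normal on deep-winter days and are not flagged.

## Matching

1:1 nearest neighbor on |ê_t − ê_c| with replacement. Ties (exactly equal
distances, including equal control scores) break to the lowest day index —
deterministic and order-independent, verified against an exhaustive
O(N_t·N_c) search. No caliper by default (an optional one reports unmatched
treated days); no temporal exclusion zone around the treated day — worth
remembering when interference is a concern. Matching on the raw probability
scale is the default; a logit-scale option exists and, being a monotone
transform, changes pairings only through unequal tie geometry.

## Balance diagnostics

Standardized differences use the two-sample form
|m_t − m_o| / √((v_t + v_o)/2), with p(1−p) replacing the variance for binary
covariates; % bias is 100(δ_pre − δ_post)/δ_pre. Matched-control statistics
weight each control by its reuse count K (equivalent to explicit replication,
which a test verifies); both the number of distinct controls used and the
effective size ΣK = N₁ are reported, since the two conventions are easy to
conflate. Day-of-year is circular: days map to angles 2π·day/year-length
(366 in leap years, per date), and the two-sample Wheeler–Watson
uniform-scores statistic W = 2Σ_g (C_g² + S_g²)/n_g (mid-ranks for ties) is
reported before and after matching together with its % reduction. Under
random labelling W is asymptotically χ²₂, which the tests check by
permutation; the statistic is used descriptively, not as a test.

## Variance and intervals

Default variance (conditional form): Var(ÂD) = Σᵢ (Wᵢ − (1−Wᵢ)Kᵢ)² σ̂²ᵢ with
σ̂²ᵢ = J/(J+1) · (Yᵢ − Ȳ_J(i))², the J nearest same-treatment-group
neighbors in propensity distance (J = 1 by default; configurable). An
effect-heterogeneity variant — Σ_{W=1}(ÂDᵢ − ÂD/N₁)² plus the
K(K−1)σ̂² reused-control correction — sits behind a flag; which of the two
the matching literature's sample-variance prescription intends is not
uniquely determined, so both are available and the conditional form is the
default. Intervals are normal-approximation at 90% by default. Simulation at
the default study conditions (500 replicates) puts the realized coverage of
the 90% interval in the high 80s — the estimator does not guarantee exact
nominal attainment, and the acceptance band used in testing is 80–97%.

## Sensitivity analysis

The influenza-exclusion analysis keeps the original propensity fit and
matches and simply drops flagged treated days from the summation, recomputing
reuse counts on the retained pairs; re-fitting or re-matching on the subset
is deliberately not done (the subset question is about the same design's
robustness, not a new design).

## Synthetic-data generator

What it emulates: a four-year daily series from a winter-polluted city —
log-normal AR(1) exposure around a winter-peaked seasonal cycle (median
42 μg/m³, seasonal log-amplitude 0.38, AR(1) 0.65, marginal log-SD 0.48),
opposite-phase temperature (13.5 ± 11 °C) and humidity cycles, a fixed
national-holiday calendar with computed Easter Monday, one or two 7–21-day
influenza blocks per winter, and Poisson death counts in 3 causes × 3 age
classes whose log-rates share the seasonal cycle, a cold effect below 15 °C,
a heat effect above 28 °C and the influenza bump. These defaults were
calibrated once, by simulation across seeds, to the intended regime — ≈ 31
natural deaths/day, 45–65% of days treated at the 40 μg/m³ threshold, 5–12%
of days above 100 μg/m³ — and then frozen.

Both potential outcomes are drawn for every day through a shared uniform per
day × stratum (inverse-CDF coupling), so Y(1) ≥ Y(0) whenever the treated
rate is higher, true AD is exact and integer, and increasing the effect size
cannot decrease it. The treated arm adds `effect_size` (default 0.04, chosen
so a four-year run yields a total AD in the ~1000 range at ~31 deaths/day) to
the log-rate of every stratum; an optional `influenza_treated_log_rr` adds
treated-arm excess during epidemics — effect modification that makes the
influenza-exclusion sensitivity analysis consequential in simulation. The
estimand is defined over the analysis days (day 4 onward, matching the design
table's lag trimming); day 1's lag 0–1 exposure uses the only available value
and days 1–3 never enter the estimand.

What it does **not** emulate — and what passing tests therefore do not show:
unconfoundedness holds by construction (mortality depends only on covariates
the propensity model sees), so the simulations validate the estimator's
statistical machinery, not robustness to unmeasured confounding; exposure is
a single noiseless series (no monitor averaging or measurement error);
populations are closed (no holiday out-migration affecting counts beyond the
July–August indicator's role in the propensity model); and mortality
displacement/harvesting dynamics are absent.

## Problem sizes

The test suite and the acceptance script run the full pipeline on 4-year
series (~1460 days, ~70 propensity columns): 500 replicates for interval
coverage, 200 for recovery, 200 at zero effect for null calibration in the
tests; 200/100 in the acceptance script. A single fit-plus-estimate takes a
fraction of a second, the whole suite a few minutes.

## Known limitations

* Nearest-neighbor matching with replacement is biased in finite samples when
  overlap thins; the simulations show a small negative bias (few percent of
  the truth) at the default conditions.
* The day-level σ̂² with J = 1 is itself noisy; variance estimates stabilize
  for larger J at some bias cost.
* Negative day-level ÂDᵢ are expected imputation noise, not evidence against
  an effect; only totals and intervals are interpretable.
* The estimator answers a historical, internal-validity question; it does not
  produce an exposure-response curve and is not designed for projecting
  future impacts.
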