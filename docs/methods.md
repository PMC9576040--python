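# Methods

This note documents the models and procedures implemented in `matesite`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Event segmentation

Detection streams are segmented at two nested time scales. A **visit** is a
maximal run of one shark's detections in which every inter-detection gap is
shorter than `visit_gap_min` (default 60 minutes); a **presence string** is
the analogous run at `string_gap_days` (default 30 days), whose first
detection is an arrival event and last a departure event. Both thresholds
use the convention *gap ≥ threshold splits*, so an exactly 60-minute gap
starts a new visit. A single isolated detection is a zero-duration visit;
an isolated detection at the string scale is a singleton string, which is
kept and flagged rather than dropped — consumers that need both an arrival
and a departure event (the phenology proportions) drop singletons
themselves, so no data are lost at segmentation time.

Two bias flags are attached to strings:

- **Tagging exclusion.** Strings arriving between the tagging date and the
  first April 30 after it are flagged and excluded from phenology, since
  behavior immediately after capture and tagging is disturbed and mating
  season arrivals begin in May. When the animal is tagged January–April the
  cutoff is April 30 of the same year.
- **Edge censoring.** A string whose bounding absence cannot be observed
  (the stream starts or ends within 30 days of it, or no stream bounds are
  known) is left- or right-censored: it contributes no arrival or no
  departure event, respectively. By default a shark's stream starts at its
  tagging date.

Timestamps are interpreted as local standard time throughout (the site does
not observe daylight saving); hour-of-day analyses are meaningless in any
other clock. All on-site receivers are collapsed to one logical station at
load time — the array exists for detection redundancy, not spatial
resolution — and exact duplicate detection rows (overlapping receiver
downloads) are de-duplicated with a logged count.

## Residency and phenology metrics

The mating season is June 1 – July 31 inclusive. Per shark-season residency
metrics use mating-window visits only, clipping visits that cross the
window boundary; the tagging-year season of each shark is omitted to avoid
sampling bias. Visit durations are averaged *within* each shark-season
before any cross-season comparison, so every season carries equal weight
regardless of how many visits it contains, and medians are reported across
shark-seasons (pooling shark-seasons rather than per-shark means; the
alternative is a one-line change on the summary frame). Cumulative time on
site is the sum of clipped visit durations. The arrival→departure span is a
property of the presence string, not of the season: when several strings
overlap one season, each is one span observation, never a sum, and the
season summary carries the longest-overlap string.

Hour-of-day profiles are computed per (sex, season) as 24-bin proportion
vectors — each a point on the simplex — then averaged across seasons with a
sample SD; a sex observed in only one season gets SD 0. Monthly
arrival/departure proportions use non-excluded, non-censored strings with
at least two detections and sum to one within each (sex, event). Daily bins
count a shark-day once regardless of detection count. Weekly temperature
summaries take daily maxima first, then mean and sample SD per ISO week
across years.

## Return histories and cycle classification

A shark is present in a mating season if *any* identification — capture,
PIT scan, visual resight, or acoustic detection — falls inside the window
that year; the per-season method label keeps the most verifiable method
under the configurable ranking capture > PIT_scan > visual > acoustic.
Time-at-large is the integer-year difference between the first and most
recent identification of any kind (not only mating-window ones), and
"monitored over 10 (20) years" means time-at-large strictly greater than
10 (20). A shark is returning if it was identified in any mating season
after its tagging season.

Return intervals are consecutive differences of the sorted present-season
years. Cycle classification keeps the chronological subsequence of 2- and
3-year intervals: intervals of four years or longer are tallied but
excluded (they may contain a mating season that monitoring missed), and
1-year female intervals are treated as identification noise by default —
post-mating females are nearly always absent the following season — but
are tallied separately so the alternative reading remains available. A
switch is an adjacent unequal pair in the retained sequence, so the
sequence (2, 3, 2) contains two switches. The pooled triennial share is
`n₃ / (n₂ + n₃)` over returning females' retained intervals. Cohort report
percentages are rounded half-up to integers, except the triennial share,
which feeds the lifetime-output projection at full precision.

## Potential reproductive lifetime output

Reproduction is projected as a point process on age: events at `a₀`, then
`a₀ + i₁`, `a₀ + i₁ + i₂`, …, counting every event with age ≤ `a₁`, with
no partial events. PRLO is the event count times litter size. Schedules
are a fixed interval, an explicit interval sequence, or a stochastic
mixture drawing each interval independently (3 years with probability
`p`, else 2; expected interval `2 + p`). The mixture estimator is Monte
Carlo with a seeded generator and collapses exactly to the fixed schedules
at `p ∈ {0, 1}`. The reduction statistic `100 (PRLO_ref − PRLO_alt) /
PRLO_ref` is reported to one decimal and is invariant to litter size.

The default parameterization — first event at age 20, last possible at 54,
litter 34 — gives 18 biennial events (612 pups) against 16 events (544
pups) for a mixed schedule of eleven 2-year and four 3-year intervals over
the same span, an 11.1% reduction. The decomposition 612/18 = 544/16 = 34
is inferred from the reference projection rather than fixed by it; all
four quantities are configuration values, never constants of the method.

## Statistical layer

- **Mann–Whitney U**: two-sided, midrank ties; exact enumeration when
  n₁ + n₂ ≤ 12 and the pooled sample is tie-free, otherwise the
  tie-corrected normal approximation (delegated to scipy).
- **Two-sample Anderson–Darling**: the midrank (tie-adjusted) statistic on
  the pooled empirical distribution, computed in-package; p-values by
  label permutation (default 2000 resamples, add-one estimator) or the
  asymptotic interpolation. A degenerate pooled sample gives statistic 0,
  p = 1.
- **Mixed models**: event-proportion analyses encode each event as a
  one-vs-rest binary response per category (month, or return period), with
  shark ID — and year, for phenology models — as random intercepts. Months
  in which no shark ever has an event produce complete or quasi-complete
  separation, under which the binomial likelihood has no finite maximizer;
  the model therefore places independent N(0, `prior_sd`²) priors on the
  fixed-effect coefficients (default `prior_sd` 2.5 on the logit scale, a
  standard weakly informative choice) and reports the posterior mode.
  Random intercepts are integrated by a Laplace approximation (an inner
  Newton solve for the joint mode; exact for the Gaussian family), and
  variance components are optimized on the log scale, bounded away from
  exact zero at σ = e⁻⁷. Standard errors come from the inverse
  finite-difference Hessian of the negative log marginal posterior; when a
  variance component sits on its boundary the fixed-effect block is
  inverted conditionally. With `prior_sd = ∞` and the random SD fixed at
  zero the fit reproduces an ordinary GLM (validated to 1e-5 against an
  independent direct maximization).
- **Factor tests and contrasts**: Wald chi-square `c'V⁻¹c` on the factor's
  coefficient block; all pairwise level differences on the link scale with
  single-step multivariate-normal adjustment over the contrast correlation
  matrix (the Tukey-style adjustment appropriate for non-orthogonal model
  contrasts; Bonferroni available as a fallback) and simultaneous
  intervals at the matching critical value. Tests are two-sided at α =
  0.05. Fits that fail to converge refuse downstream tests rather than
  returning silent results.

## Synthetic-data generator

The generator's defaults are the monitored population's conditions: 89
females and 48 males tagged in staggered years 1993–2014 over a 30-year
study from 1992; per-cycle triennial probability 0.32 and near-annual male
returns (0.85); female arrivals June 24 ± 5 d truncated to June 12 – July
8 and male arrivals May 25 – June 28; bout spans lognormal with medians
11.43 d (F) and 27.14 d (M), departures capped at the second (F) and third
(M) week of July; negative-binomial visit counts with medians 34 (M) and
12.5 (F) and lognormal visit durations targeting season-mean medians of
1 h (M) and 4.4 h (F); gestation-autumn presence for mating-year females
with August days suppressed when the daily maximum exceeds 30 °C;
transmissions every 240 s nominal (uniform jitter 120–360 s) thinned by a
per-transmission detection probability (0.5) and by afternoon (15:00–
17:00) suppression above 29.6 °C; and a 3650-day tag life. Temperature is
an annual sinusoid peaking in early August above 30 °C plus a mid-afternoon
diurnal sinusoid and Gaussian noise, at hourly resolution.

Quantities the monitoring study does not print are generator inventions
chosen once for realism: the lognormal spread parameters, the
negative-binomial dispersion (8), per-season PIT and visual resight
probabilities (0.5 each), the acoustic-tagging fraction (0.55), the autumn
daily presence rates, and the heat-suppression keep-probabilities. Because
individual visit durations are heavy-tailed, the configured duration
medians are interpreted as medians of the *per-season mean* duration (the
reported residency metric), and per-visit draws use median
`m / exp(σ²/2)`.

What the generator deliberately does **not** emulate: mortality and
permanent emigration (every simulated shark keeps returning, so simulated
return percentages approach 100% and are not comparable to a field
cohort's), tag shedding and receiver outages, spatial structure among
receivers, and migration outside the site. Passing recovery tests
therefore show that the pipeline's inferences are correct *given* the
assumed observation process, not that the observation process matches any
particular field system. Cycle *switching* carries no serial dependence:
it is an emergent property of independent per-cycle draws.

Two further calibration notes. First, detection thinning shortens observed
visits (first-to-last detection) and deletes short visits entirely, so
observed medians sit below the generating targets; the between-sex
orderings — males more, shorter visits; females fewer, longer — are what
the generator guarantees. Second, pooled completed-interval shares are
slightly truncation-biased low (≈ 1 point at 30 seasons): a pending
3-year interval is more likely than a 2-year one to be cut off by the end
of monitoring, so the recovered triennial share sits just under the
generating probability even with perfect detection.

## Problem sizes and numerical choices

The test suite and the acceptance script run simulations at 200 females ×
30 seasons for cycle recovery (≈ 2,100 pooled intervals, giving a Monte
Carlo standard error near 1 percentage point on the triennial share), 1000
random streams of up to 200 detections for the segmentation oracle, 200
replicates for the Wald type-I calibration, and 10⁵ draws for mixture
projections — sizes at which every targeted tolerance is comfortably
resolved. Inner Newton solves run to a 1e-10 step norm; the outer
optimizer is L-BFGS-B with log-scale variance bounds [−7, 5]; permutation
p-values use the add-one estimator; all randomness flows from explicit
seeds.

## Known limitations

The GLMM is random-intercept only (no random slopes, one variance per
grouping factor) and reports MAP point estimates with curvature-based
uncertainty, not full posteriors. The single-step adjustment relies on the
asymptotic normality of the contrast estimates. Arrival/departure
censoring is handled by exclusion, not by survival-style modeling. The
pipeline treats the site as one station by design and cannot resolve
within-site space use.
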