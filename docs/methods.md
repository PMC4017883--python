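# Methods

## Sampling model

The sampling unit throughout is one **monitoring day**: one calendar
day of the whole fixed camera array. With `n_cameras` cameras active,
one monitoring day equals `n_cameras` camera days; the conversion
assumes every camera is active on every monitoring day, and an analysis
needing finer effort accounting should supply a pooled daily matrix
that already reflects downtime.

**Independence filter.** Within each (site, species) stream, a
photograph starts a new detection event iff it falls strictly more than
`interval_minutes` (default 30) after the *previous photograph* of that
stream — a rolling-gap rule, so a slow foraging bout photographed every
20 minutes stays one event however long it lasts. A gap of exactly the
interval merges; the boundary is arbitrary but fixed and tested. The
rule is scoped per site because cameras are fixed and the rule targets
re-triggering by one individual; a global per-species scope is
available via `per_site=False` for sensitivity checks. Event dates are
assigned by calendar day in local time; events are not split at
midnight.

**Exclusions.** Guild classification (resident terrestrial / arboreal /
transient) is an *input*: transience is a natural-history judgment, not
something inferable from the records, so an unclassified species is a
hard error rather than a guess.

## Richness estimation

Exact sample-based rarefaction uses the closed-form hypergeometric
expectation, implemented with log-gamma so it is stable for unit counts
well beyond 10⁴. Incidence counts are binarized for all richness math;
raw counts are kept only for summaries. The 95% band on a curve is the
2.5/97.5 percentile of richness over random unit orderings (default
1000, seeded); the analytic expectation itself has no sampling band, so
the permutation band is attached to it, and a pure permutation-mean
mode exists for parity with the common R implementation. The Chao
estimator uses the classic form `S_obs + a1²/(2a2)`; when `a2 = 0` and
`a1 > 0` the bias-corrected `S_obs + a1(a1−1)/(2(a2+1))` is used and
flagged. (The reference R implementation multiplies the add-on term by
`(D−1)/D`; the cross-check test accounts for this definitional
difference.)

**MTE inversion.** The target `p_s · S_max` is compared with `≥` on the
continuous expected-richness scale (no rounding of the target), and the
crossing is found by bisection on the monotone curve. An unreachable
target raises an explicit insufficient-survey error — short pilot
surveys with singleton species routinely have `p_s · S_max > S_obs`,
and clamping would silently understate the required effort.

## Effort allocation

Each grid cell (k sites, w days) averages 1000 replicates; a replicate
draws k sites uniformly without replacement and one *contiguous* window
of w days with uniform start (windows recur across replicates; a
random-days mode exists but is not the default, since rotating real
surveys sample calendar blocks). The denominator of "proportion of
species detected" is the estimated pool `S_max` when the grid is built
through the pipeline (it equals observed richness in the shipped
example), otherwise the observed richness of the data. Cells get
independent child seeds spawned from the grid seed in row-major order
(site axis first), so the grid is reproducible and cells are
independent.

## Per-site curves and rotation

Day-based site curves are exact sample-based rarefaction over that
site's day units; photograph-based curves are individual-based
rarefaction over the site's independent events (the two coincide in
expectation only when every day holds at most one event). Sites differ
in total events, so the cross-site mean and 95% across-site percentile
band are computed only at efforts available at ≥ half the sites, with
the cut effort reported — this avoids end-of-curve artifacts where the
mean would suddenly be dominated by the few longest records. The
rotation point is the smallest effort from which the forward first
difference of the mean curve stays below an explicit `rate_threshold`
(species per unit effort); the threshold has no privileged default
because "the rate of new species declines" is a study-specific
judgment, and a curve that never settles raises an error rather than
returning its endpoint.

## Synthetic surveys

The generator emulates a two-year fixed-array study: 19 sites
stratified 7/7/2/1/2 over five habitat types, 730 days, ~20 species.
Independent events per site-day are Poisson with the species' per-site
rate; rates across the 10 resident species follow a log-normal
(σ = 1.6) profile rescaled so the top three hold 75% of expected
events, with total resident intensity 0.125 events per camera-day —
the dominance and detection intensity of the field survey the package
ships. Seven arboreal species get rates of a few 10⁻⁴ (ground cameras
see them rarely) and three transients get windows of 14–31 days.
Per-site heterogeneity is log-normal (σ = 0.5), mean-normalized.
Bursts: photographs per event are geometric with mean `burst_mean`
(drawn in 1.2–3 for residents, matching the spread of recorded-to-
independent photograph ratios in real data); within-burst gaps are
uniform on [1 s, 29 min]. Event placement partitions the usable day so
that consecutive events of a stream are always > 30 min apart and no
photograph falls after 23:29, so the independence filter recovers the
generated event count *exactly* — the property that makes parameter-
recovery tests sharp. One seed drives everything through per-(species,
site) child seeds spawned in species-major order.

Not modeled (deliberately): diel activity (timestamps uniform within a
day — nothing downstream uses time of day), spatial movement or
home-range structure, habitat covariates on rates, camera downtime.
Passing tests on these simulations therefore show the *estimators* are
correct under the stated sampling model, not that real communities
satisfy that model — in particular real detection histories are
overdispersed (clumped) relative to Poisson, which lowers day-occupancy
for a given event count and raises true MTEs relative to simulated
ones.

## The shipped daily matrix is a stand-in

The per-day detection history behind the shipped example is not
redistributable, so `synthetic_daily_matrix()` reconstructs one from
the published per-species independent-photograph counts: under
homogeneous Poisson detection, species `i` with `IP_i` events over 730
monitoring days occupies `D_i = round(730·(1 − exp(−IP_i/730)))` days,
placed uniformly at random (seeded). Exact rarefaction and the Chao
estimator depend on the matrix only through the `D_i`, so every
reported quantity is invariant to the placement seed. On this
reconstruction the expected-richness curve crosses 9 species at 49
monitoring days and the Chao pool is exactly 10 — but the matrix
remains synthetic: cell values are 0/1 because the number of cameras
detecting a species each day is not reconstructable from the published
counts, and the Poisson assumption understates day-to-day clumping.

## Numerical and design choices

- Percentages (P1, P2) are kept at full precision internally and
  rounded to two decimals only for display.
- Efforts are integers in sampling units; camera-day conversion happens
  only at reporting.
- Problem sizes in the test suite: full-scale checks run one simulated
  19 × 730 survey (shared session fixture) with 1000-replicate grids;
  exhaustive-enumeration oracles run on matrices of ≤ 8 units and
  occupancy arrays of ≤ 4 × 6, where full enumeration is cheap and
  exact.
- The pipeline's YAML config round-trips unchanged, and every output
  file is stamped with the seed and a hash of the configuration that
  produced it.
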