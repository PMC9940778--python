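# Methods

## The measurement problem being emulated

Three instruments claim to measure "population mobility": panel surveys
(self-reported frequency of leaving home, by reason), mobile-network
data (distance-based radius of gyration per device), and GPS-derived
place-visit indices (Community-Mobility-Report style percent changes).
They differ in construct (frequency vs absolute distance vs visits and
length of stay), in coverage, and in error mechanisms.  The package
builds one latent behavioural ground truth and pushes it through all
three observation channels, so that any divergence between the
harmonised series is attributable to the channels, not to the world.

## Latent activity model

Each person carries age group, gender, region, a home location and —
if employed — a workplace, drawn from configurable margins (quota mode
reproduces margins exactly by largest-remainder rounding; probabilistic
mode draws i.i.d.).  Daily trip counts per activity category c follow

    N ~ Poisson(λ),  log λ = log r(c,g) + β(c) S(t) + A cos(2π(doy−182)/365) + ε,

with ε ~ N(0, σ) day-level noise.  Parameters and defaults:

| parameter | default | units / meaning |
| --- | --- | --- |
| base_rate r(c,g) | 0.06–0.8 by category | trips/day at S = 0 |
| stringency_coef β(c) | −0.001 to −0.016 | log-rate per stringency point; discretionary categories (friends, non-food shopping) respond most, essential ones (medicine, pets) least |
| seasonal_amplitude A | 0.15 | log-rate; summer peak (day 182) |
| noise_sd σ | 0.10 | day-level log-rate noise |
| trip_distance_logmean/sd | ln 0.8–ln 6 km, sd 0.6 | lognormal trip distance |
| trip_duration_mean | 0.5–8 h | per category, ±30% jitter |

With β ≈ −0.01, an 80-point stringency swing multiplies rates by
e^{−0.8} ≈ 0.45, which produces mobility dips of the size seen in
pandemic data.  None of these values is estimated from real micro-data;
they are declared, documented free parameters of the simulator, and the
recovery tests show the pipeline returns whatever is injected.

Days are the scheduling unit: out-of-home stays are placed back-to-back
from a waking hour (08:00) with the active day capped at 15 h, and home
stays tile the remainder, so each person-day sums to exactly 24 h and
time weights are well defined.  Work trips of employed persons go to
the fixed workplace; all other destinations are drawn at a lognormal
distance and uniform bearing from home.

The stringency series S(t) is piecewise constant from configured
breakpoints (clamped to [0, 100]); the default profile mimics Austria's
2020–21 policy sequence (hard spring lockdown, summer relaxation,
autumn/winter lockdowns).  A real OxCGRT-style date,value CSV can be
supplied instead.  A configurable region-targeted "partial lockdown"
adds extra stringency points to treated regions in a window — this
injects a known differential effect for the difference-in-differences
analysis.

One global seed is expanded into per-person substreams
(`numpy.random.SeedSequence.spawn`), so outputs are bit-reproducible and
independent of iteration order; the pipeline additionally derives one
substream per stage.

## GSM channel

A device is observed only when it communicates.  Within each stay,
event times follow a Poisson process (default 0.6 events/h, roughly the
cadence of background data traffic); the event is located at the tower
grid node nearest to the stay's location (default spacing 1 km).  The
run configuration adds Gaussian positional scatter (sd 0.35 km) before
snapping, emulating tower oscillation — real stationary devices hop
among neighbouring base stations with load and signal conditions.
Without this scatter a home-bound device registers a single tower all
day and the daily median ROG collapses to exactly zero under hard
lockdowns, which makes baseline-relative changes undefined; with it the
median stays positive, as in real network data.  The scatter parameter
defaults to 0 in the library function itself, which then performs exact
nearest-node assignment.

Dwell weight of an event is the forward inter-event time, truncated at
midnight: a device "stays" at a tower until it is next observed.  The
per-device-day ROG is the time-weighted RMS distance from the
time-weighted centroid (planar Euclidean for synthetic data; haversine
available for lon/lat input).  Single-event device-days are kept with
ROG 0 (configurable minimum-event filter, default keep).  Daily medians
are taken within age×gender cells first; population and marginal series
are share-weighted combinations of the cell medians, with cell shares
the product of the target margins (the raking fixed point when only
marginal targets exist).  The share of devices with ROG strictly above
500 m is available as an alternative aggregate.

## GPS channel

Stays of opted-in persons (default 40%) map onto the six CMR place
categories (food & medicine → grocery_and_pharmacy, non-food shopping
and meeting friends → retail_and_recreation, work → workplaces, sports,
pets and boredom walks → parks, other → transit_stations, home →
residential).  The upstream measure is documented only as "visits and
length of stay", so the daily measure is an explicit blend
α·count + (1−α)·hours with α = 0.5 by default.  Percent change is taken
against a day-of-week-specific baseline (median of the five matching
weekdays in the Jan 3 – Feb 6, 2020 window), exactly the published CMR
construction; the additive composite is the plain sum of the six
percent changes, with residential inversion available behind a flag
(default off, the literal reading).  Any missing component makes the
composite missing rather than silently rescaling the sum.

For cross-channel harmonisation the pipeline needs a *positive level*
series per subgroup, and the raw composite is strongly negative around
the March baseline week, which would flip the sign of baseline-relative
changes.  The pipeline therefore harmonises the GPS channel on an
activity index, the mean over categories of (100 + percent change);
categories with an undefined percent change (zero baseline cell in a
sparse region) drop out of that date's mean.  The composite itself is
still computed and exported.

## Survey channel

22 waves: weekly (1–10), bi-weekly (11–14), monthly (15–22, implemented
as a 28-day cadence so every field week is a Monday-start ISO week);
wave 1 is 2020-03-23..29.  For each panelist and wave the true number of
field-week days with at least one trip per category is read off the
stays, perturbed with Gaussian recall noise (sd 0.7 days), and coded on
the 0–4 never-to-daily scale via the day-count thresholds
{0}→0, {1}→1, {2–3}→2, {4–6}→3, {7}→4.  The exact answer-option
wording between "never" and "daily" is a convention here, centralised
in the response model so alternate maps are one-line changes.  A
social-desirability mechanism lowers an item code by one step with a
configurable probability (optionally scaled by current stringency);
item nonresponse (2%) and wave-over-wave attrition (5%) with
refreshment from the never-sampled pool complete the error model.  The
panel default is 300 of the 500 simulated persons — the real-world
22-wave/~1,500-per-wave scale is a configuration, not a constant.

Processing: drop the 75+ age group (absent from the default margins but
filtered when present), listwise-delete responses with any missing
item, sum the nine codes into the 0–36 index with food+medicine (0–8),
non-food (0–4) and work (0–4) subindices, and aggregate per wave with
raking weights.  A stay-home item (days with no out-of-home trip,
same coding) supports the robustness variant.

## Weighting

Raking / iterative proportional fitting on marginal targets (age,
gender, region in declared order), converging when every weighted
margin is within 1e-6 of target; weights normalised to mean 1, optional
trim-then-renormalise.  Marginal raking (not joint-cell
poststratification) is used deliberately: only marginal population
distributions are assumed known.  IPF limits are order-independent at
convergence, but iteration counts are not, so the variable order is
fixed by configuration and logged.  Survey responses are raked per
wave; GSM aggregation applies the margins as subgroup shares since
device-level attributes exist only as group labels.

## Harmonisation and comparison

Weeks are Monday-start ISO weeks; weekly levels are means of available
daily values with a min-4-days completeness rule.  Every channel's
weekly level series becomes 100·(vₜ − v_b)/v_b against the common
baseline week 2020-03-23 (the first survey field week) — exactly 0 at
the baseline, invariant to channel rescaling, and related across
alternative baselines b′ by the affine identity
100·((1+r/100)/(1+r_{b′}/100) − 1), which the tests assert numerically.
Weekly series are matched to waves by field week; a centred 7-day
moving average is available as a robustness variant that writes
additional smoothed outputs without touching the raw ones.

Comparison statistics: Pearson r with a two-sided t-test
(t = r√(n−2)/√(1−r²), n = 22 waves), OLS trend lines with residual SE,
a time-fixed-effects OLS (channel + subgroup + interaction + wave
dummies, reference levels dropped; rank deficiency raises an error
naming aliased terms) and a two-group/two-period DiD computed from cell
means, with the standard error taken from the equivalent OLS
interaction.  Wave-level aggregates are treated as fixed observations;
no autocorrelation-robust or clustered errors are attempted.  OLS is
fitted via statsmodels; the DiD cell-means route is independent of it
and the two are cross-checked to 1e-10 in tests.

In the pipeline's DiD, treated = the lockdown regions, control = the
rest; pre = wave weeks from 2020-09-07 up to the lockdown start
(2020-11-03), post = wave weeks inside the lockdown window (to
2020-12-13), on the region-level baseline-relative series of each
channel.

## What the generator does and does not emulate

Emulated: one shared latent trend across channels; stringency-driven
suppression with category heterogeneity; seasonal shape; subgroup
differences (age multipliers, employment-gated work trips); GSM
coarseness, sparse event sampling and partial coverage; GPS opt-in
subsampling and the CMR baseline construction; survey recall noise,
desirability bias, item nonresponse, attrition, quota-style margins and
raking.  Not emulated: real geography and road networks, household
structure, multi-SIM devices/roaming, differential privacy noise in
published CMR files, holiday effects, weekday/weekend activity
structure, or the recruitment mechanics of access panels.  Passing
recovery tests therefore show the *pipeline* is faithful, not that real
instruments agree; with real inputs (a CMR CSV, an event log, a
response file) the same code applies but the error structure is the
real world's.

## Numerical conventions and scales

Chosen once for the package: ROG of a single-tower day is exactly 0
(explicit check, not floating arithmetic); empty aggregates propagate
as missing (NaN), never 0 or ±inf; medians of even counts average the
two central order statistics; the 500 m share uses strict inequality;
percent change against a zero baseline is missing; composite/GPS means
with missing components follow the rules above.  Default problem sizes
— 500 persons, 63 ISO weeks (2019-12-30..2021-03-14, covering the CMR
baseline window and all 22 waves), ~2.5 M GSM events — keep a full run
around half a minute while leaving every estimate comfortably away from
small-sample degeneracy; statistical tests in the suite use smaller
worlds sized to their Monte-Carlo tolerances.

## Known limitations

The desirability mechanism only shifts codes downward; the attrition
refreshment pool is finite (tiny populations can exhaust it, shrinking
late waves); trend-magnitude comparisons between channels depend on
free observation parameters (tower scatter, α blend), so only their
signs and orderings — not their exact sizes — are meaningful; and the
time-fixed-effects design requires the compared channels to share
subgroup labels, which the pipeline guarantees only for survey vs GSM.
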