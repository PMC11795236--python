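# Methods

## The procedure

The pipeline classifies each county-day of a study period for three
hazards and merges the flags into a dense event calendar.

**Weekly climatology.** For each county, baseline daily mean
temperatures are binned by week-of-year, defined as fixed 7-day blocks
of the day-of-year: `week = floor((doy − 1)/7) + 1`, capped at 52.
Days 365/366 join week 52 and leap days keep their natural day-of-year,
so the binning is deterministic and leap-safe. The warm-day threshold
for a (county, week) is the 85th percentile — linear interpolation
between order statistics, the common default; the method is
configurable — of **all** baseline daily values in the bin (about 210
values for a 30-year baseline). The alternative reading, a percentile
over the ~30 per-year weekly means, is available via
`use_weekly_means=True`; the daily-value reading is the default because
the warm-day definition is applied to daily values and a ~210-value
bin gives a far better-resolved tail than a 30-value one.

**Warm-day classification.** A county-day is anomalously warm iff
`tmean ≥ p85` (inclusive — a value exactly at the threshold is "at or
above the 85th percentile") **and** `tmean > 24 °C` (strict — 24.0 °C
does not exceed the cutoff). Both comparisons are applied as stated;
the asymmetry is deliberate and tested.

**Burn zone disasters.** Fire severity is the disjunction
(structures ≥ 1 | civilian deaths ≥ 1 | FEMA declaration); community
overlap — intersection with any population-density cell of
≥ 250 people/km², boundary inclusive — is a *fire-level* property, not
per-county. Disaster fires flag every overlapped county from ignition
through containment **inclusive**, so a single-county fire contributes
exactly `containment − ignition + 1` county-days. Footprints are either
explicit county lists (exact) or planar polygons; polygon–county
overlap is decided by sampling a regular grid (default 200×200) over
the footprint's bounding box and testing sampled interior points
against county polygons. This avoids exact polygon clipping in the
core; the approximation can miss slivers narrower than the sampling
pitch, which the synthetic geometries (unit-square counties, boxy
footprints) never produce. Coordinates are assumed pre-projected and
planar; densities in people/km² are taken as given.

**Outage episodes.** Counties first pass reliability filters:
reporting fraction ≥ 0.5 and customer coverage ≥ 0.5, both inclusive.
Within a reliable county, readings with
`customers_out > 0.5% × customers_total` (strict) form exceedance
runs; any non-exceeding reading ends a run, and a timestamp gap of
more than one reporting interval counts as service restored
(missing-as-restored is the conservative choice; a `gap_tolerance`
knob, default 0, exists for sensitivity analysis). Because readings
are interval-censored, a run's duration is right-extended by one
reporting interval: eight consecutive hourly exceedances = 8 h, which
qualifies. Episodes flag **every** calendar date whose [00:00, 24:00)
window intersects the episode's [start, end) span — the mapping of a
multi-day episode to days is not uniquely determined by the definition
"an outage affecting >0.5 % for 8+ h"; flagging all intersected days
is the reading adopted, and the per-day-8h alternative can be composed
from the episode table if needed. Timestamps are treated as local;
no timezone arithmetic is applied at daily resolution.

A note on monotonicity: raising either outage threshold never adds
flagged *days* (the flagged-day set shrinks), and raising `min_hours`
never adds *episodes*. Raising the customer threshold can, however,
split one long run into several shorter runs that each still qualify,
so episode **count** is not monotone in the customer threshold — the
test suite asserts the set-shrinkage form.

**Co-occurrence.** The calendar is dense over roster × study dates.
PO is *not assessable* in counties without reliable outage data: their
`po` flag is missing, they can never enter a PO-involving category,
and every PO-involving percentage uses the reliable-county count as
its denominator (day-share percentages use the full grid, matching the
published convention). The eight categories partition the calendar;
pair categories exclude the triple day. Pair counts are reported
exclusive of the triple as the headline (the four exclusive
multi-event counts then sum to the total number of co-occurring
county-days); inclusive pair counts are also emitted since published
pair figures may follow either convention. Printed percentages use
half-up rounding at the printed precision.

**SVI correlation.** Spearman's ρ is the Pearson correlation of
average ranks (standard tie handling; the source of the scores does
not prescribe one). Each category's correlation is restricted to
*affected* counties — those with ≥ 1 day of that category — matching
the per-panel sample sizes of the published scatter plots; an
all-county mode is available. Categories with fewer than two usable
counties, or with zero rank variance, are flagged not estimable rather
than erroring. No p-values are attached: with a handful of affected
counties the coefficient is descriptive. Quartile strata are
`svi > 0.75` and `svi < 0.25`, both strict (the bottom stratum is
defined by symmetry with the published "> .75" top stratum); boundary
scores fall in neither.

## The synthetic-data generator

The generator emulates the pipeline's inputs, not the physical
processes behind them:

- **Temperatures** are a per-county seasonal sinusoid (default mean
  15 °C, amplitude 8 °C, peak near mid-July) plus i.i.d. Gaussian noise
  (default σ = 2 °C), for both baseline and study periods. Planted warm
  days are forced to `max(p85, 24 °C) + 1.5 °C` (margin configurable),
  where `p85` comes from the *generated* baseline; all other study days
  are clamped strictly below the larger of the two thresholds, so the
  planted set is exactly the detectable set. The clamp is a generator
  guarantee (toggleable for stress tests), not a property of real data.
- **Fires** come from blueprints (dates, severity fields, county
  footprint, community flag); by default the generator adds two decoys
  exercising the classifier's failure branches (severity without
  community, community without severity). Blueprints can opt into
  polygon footprints: counties are laid out as unit squares on a line
  and the footprint is a union of interior boxes, so spatial overlap
  recovers the blueprint's county list exactly.
- **Outages** are hourly (configurable) customers-out traces with
  background jitter capped strictly below the 0.5 % threshold, planted
  episodes at stated fraction/duration, and default sub-threshold
  decoys (0.4 % for 24 h; 2 % for 7 h) placed away from planted
  windows. Same-county plants must be separated by at least one
  reporting interval — otherwise adjacent plants would merge into one
  run and the truth ledger would no longer be exact; the configuration
  validator enforces this. Counties with a reporting fraction below 1
  have that share of non-planted readings dropped at random.
- **SVI** scores are uniform draws (independent mode) or a strictly
  monotone affine map of per-county planted event-day counts into
  [0.05, 0.95] plus bounded jitter (increasing/decreasing modes), so
  the downstream correlation sign is known and, with zero jitter and
  distinct counts, |ρ| = 1 exactly. Explicit per-county values can
  override the modes.

The **truth ledger** records the planted warm days, disaster fires and
their county-days, qualifying outage days (plants under 0.5 % or 8 h,
or in unreliable counties, are excluded), and the reliable-county set.
Parameter-recovery tests assert that the detectors reproduce the
ledger exactly. Everything is driven by `numpy` generators seeded from
`(seed, stream)` pairs, so identical configurations give byte-identical
outputs.

What passing tests on synthetic data do **not** show: the generator has
no spatial temperature correlation, no raster-to-county aggregation
error, no realistic fire-spread geometry or daily perimeter growth, no
utility-feed quirks beyond random reporting gaps, and its exact-truth
clamping removes the borderline cases that dominate uncertainty in
real classifications. Results on real inputs inherit none of the
generator's exactness guarantees.

## Reference scenario and problem sizes

`california_county_day_config()` builds a 58-county, 1981–2010
baseline, 2018–2019 study configuration whose planted events encode the
published statewide accounting for California: 2004 warm county-days
across 56 counties, 1131 burn zone disaster days across 33 counties
(63 county-days with two simultaneous fires), 597 long-outage days
across 24 of 38 reliable counties, exclusive co-occurrences
144 / 29 / 10 / 1 (total 184), one triple-event day on 2018-08-10, and
SVI scores spanning [0, 1] with median 0.5 and mean 0.573 among the 20
counties without reliable outage data. The placement of planted days
within each county's calendar is arbitrary (contiguous blocks, chosen
deterministically); the statewide tallies are the point. The published
per-category Spearman coefficients and the exceedance-day median/IQR
depend on the original joint county-level data and are not encoded.

`scripts/acceptance.py` runs this scenario end-to-end (~5 s on one
core: ~636k baseline temperature rows, ~1.0M outage readings, a
42,340-row calendar). The test suite's parameter-recovery block uses
nine randomized configurations of 6–12 counties with a full 30-year
baseline and ~20 planted events per hazard; the oracle-equivalence
blocks compare 100 random climatology bins, 100 random outage series
(≤ 500 readings) and 100 random rank-correlation inputs against
brute-force reimplementations at 1e-12.

## Numerical and degenerate-input choices

- Percentile level accepted on (0, 100]; 100 returns the bin maximum.
- Temperature plausibility range defaults to [−60, 60] °C and is
  configurable where synthetic stress inputs need to exceed it.
- Empty inputs: an empty exceedance-day summary and an empty episode
  table are ordinary results, not errors; an episode ending exactly at
  midnight does not flag the following day.
- Duplicate (county, date) temperature rows, non-increasing outage
  timestamps, out-of-range fractions and unknown configuration keys are
  rejected with messages naming the offenders.
- The event calendar stores `po` as a nullable boolean; "false" and
  "not assessable" are distinct states and tabulation never conflates
  them.
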