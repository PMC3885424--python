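# Methods notes

This note records the models, conventions and numerical choices behind each
stage of the pipeline, the assumptions of the synthetic generator, and what
the test suite does and does not establish about real telemetry data.

## Monitoring windows and the Residency Index

A tag's monitoring window runs from release to the earlier of (release +
estimated battery life) and the array's last service date. `potential_days`
is counted in whole calendar days with the release day as day 0, floored at
one day, so a 432-day array deployment gives 432 potential days regardless
of battery headroom. The Residency Index divides distinct detected calendar
days by `potential_days`. Using battery-capped potential days (rather than
days-to-last-detection) as the denominator makes RI comparable across sharks
whose tags outlived the receiver arrays.

## Behaviour classification

The four occurrence categories overlap as stated informally (a resident also
re-appears after month-long gaps at coastal arrays), so the classifier
evaluates them in fixed precedence: resident → pseudo-resident → transient →
passer-by. Conventions:

- "Month" means calendar month; the resident rule needs ≥10 distinct
  detected months inside every 365-day block counted from release, with a
  final partial block exempt unless it spans ≥10 calendar months.
- The pseudo-resident rule needs ≥3 calendar months with ≥5 detected days
  inside a single 365-day block.
- "One month" for gap rules is 31 days: transient requires a re-detection
  after a >31-day gap (measured between successive detected days, or from
  release); passer-by requires no detection after day 31 post-release.
- The RI boundary is strict on both sides (resident > 0.30, pseudo-resident
  < 0.30); a shark at exactly 0.30 falls through to the gap rules.
- The rules as stated are not exhaustive (e.g. a shark detected continuously
  to day 40 and never again matches none of them); passer-by is the final
  fallback so classification is total. These leftovers are patterns the
  category system never contemplated, and the label should be read as
  "no sustained use of the array".

## Diel statistics

Day is [06:00, 18:00) and night [18:00, 06:00) on a fixed-UTC-offset local
clock (default +11:00; no daylight-saving logic, since the study region does
not observe it and detection timestamps are stored in UTC). The test is the
two-cell Pearson goodness-of-fit against equal expectation with no
continuity correction; for counts (d, n) the statistic is (d−n)²/(d+n) on
1 df. This convention reproduces the full published p-value column of the
study's diel table; the table's printed χ² statistics are internally
inconsistent with their own p-values under any standard two-cell test and
are therefore not treated as reproducible. p-values print as three decimals,
with "<0.001" below 0.001.

## Visits, transitions, distances

Visit merging uses a 30-minute gap threshold by default (configurable);
published per-station visit durations are means over such visits, with
single-detection visits floored at 1 minute. Great-circle distances use the
haversine formula on a 6371.0 km sphere. Maximum linear distance is the
largest pairwise distance over the set of detected receivers plus the
release point, so a shark detected once far from its tagging site reports
that displacement.

## Argos filtering

The plausibility rule keeps classes 3/2/1 unconditionally and appends them
to the anchor pool; drops class Z (no coordinates); and keeps classes 0/A/B
only within vmax × elapsed-time of the most recent anchor at or before the
fix. Choices the rule's informal statement leaves open:

- *Which* previous anchor: the most recent one, which maximises power and
  matches the intent of "a realistic swimming distance".
- Kept 0/A/B fixes do **not** become anchors — a coarse fix should not
  vouch for a later coarse fix.
- Elapsed time is floored at one minute to avoid division artefacts.
- The published accuracy bracket for classes 0/A/B reads "1,500 to 3000 km";
  this is presumed a misprint for metres and the generator's error scales
  are configured in metres (class 3: 250 m … 0/A/B: 3000 m).

Note the filter's power depends on anchor recency: with only a stale capture
location as anchor, 3.5 km h⁻¹ × weeks admits almost anything. Acoustic
detections supply dense anchors for array-associated sharks.

## Bathymetric correction

A daily position whose grid cell's seafloor is shallower than the day's
maximum dive depth relocates to the nearest (great-circle) cell at least
that deep within a search radius (default 100 km, capped by the position's
CI radius when present); infeasible points are flagged and left in place.
This nearest-valid-cell rule is a deliberate simplification of
likelihood-reweighting approaches: it satisfies the physical constraint,
is idempotent, and never moves a point farther than the search radius.

## 3D kernel utilisation distributions

Positions and depths are projected to a local azimuthal-equidistant tangent
plane (km; depth in km, positive down). The KDE is product-Gaussian with a
*diagonal* bandwidth matrix: each axis gets a univariate two-stage direct
plug-in bandwidth (normal-reference ψ₈ → ψ̂₆ → ψ̂₄ → h, with binned kernel
functional estimates on 451 bins), or the d=3 normal-scale rule as the
fallback/alternative. A full unconstrained plug-in matrix is out of scope;
the diagonal restriction is the important part for telemetry data, because
the depth axis needs a bandwidth three orders of magnitude smaller than the
horizontal axes. Degenerate axes are floored at 10⁻³ of the largest spread.

Evaluation is by linear binning onto a 64³ grid padded by 3 bandwidths per
axis, Gaussian smoothing of the bin counts, and renormalisation to unit mass
on the grid. The α% volume is the highest-density region: cells are ranked
by density and accumulated until their mass reaches α; the volume is the
cell count times the cell volume. On a 20 000-point standard trivariate
normal sample the 95% volume lands within a few percent of the analytic
91.5 km³ (ball of radius √χ²₀.₉₅,₃).

## Synthetic generator

The generator emulates the study's observation process with its stated
parameters: transmitter delays drawn i.i.d. uniform from the tag's
programmed window (50–130, 40–80 or 30–90 s, tied to 696/835/1448-day
battery lives), detection ranges of 400–800 m, Argos class error scales of
250/500/1500/3000 m with class Z carrying no coordinates, and dive profiles
mixing ≤40 m shallow occupancy with episodic deep dives (default uniform
100–1136 m, capped at 1200 m) over a temperature profile decaying from 27 °C
at the surface toward 4.5 °C at depth.

Movement is a first-order correlated random walk on the tangent plane
(innovation scale 0.6 km per 15-min step, persistence 0.5) with OU-style
attraction (0.06 per step) toward a switching target. The study describes
occurrence patterns, not a movement model, so the four regimes are bout
schedules chosen to produce those patterns on a 7-receiver, 22-km array over
a 400-day default window: residents stay on-array throughout;
pseudo-residents alternate ~8-day on-array bouts with ~30-day excursions
(time share ≈ 0.2, keeping RI below 0.3 while accumulating ≥5-day months);
transients leave after a few days and return only every 50–80 days;
passers-by depart within the first 4–8 days at ~12 km/day with a hard
outward floor on radial distance, which makes "no position in range after
day 30" a construction guarantee rather than a probabilistic one.

Detection probability decays logistically with distance (p = 0.5 at half the
maximum range, slope rmax/8), truncated to exactly zero beyond the maximum
range; each ping can be heard by at most its nearest receiver, a fair
simplification at 3.7-km receiver spacing with ≤0.8-km range.

What the generator does *not* emulate: diel or seasonal behaviour, currents
and SST structure, receiver outages and detection-efficiency weather
dependence, tag failure, or inter-individual variability in movement
parameters. Passing recovery tests therefore show the estimators are
faithful to their definitions under the assumed observation process — not
that real sharks are this well behaved. In particular the synthetic
residents are detected on ~95% of days, more detectable than the field
residents (RI ≈ 0.36–0.59), so recovery rates here are an upper bound.

## Problem sizes and determinism

Defaults were chosen so a full run is interactive: regime recovery uses 20
seeds × 4 regimes × 400 days (≈ 25 s), the filter/brute-force cross-check
1000 instances of ≤200 fixes, and the Gaussian KUD check 20 000 points on a
64³ grid. All randomness flows through `numpy.random.default_rng` seeded
from the configuration; identical config + seed gives bit-identical outputs,
and the pipeline writes a manifest (version, seed, config hash) sufficient
to reproduce any run.

## Known limitations

- The resident/pseudo-resident month rules are sensitive to how year-blocks
  are drawn; sharks near category boundaries can flip label with a single
  detected day.
- The speed filter cannot reject outliers when anchors are sparse (see
  above); it is a plausibility screen, not a state-space model.
- The KUD assumes independent points; strongly autocorrelated tracks will
  undersmooth relative to their effective sample size.
- The bathymetric correction moves points to cell centres, so its output
  resolution is the grid resolution.
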