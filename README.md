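# tigertrack

Analysis pipeline for multi-platform shark telemetry: passive acoustic
detections, Argos satellite fixes, and archival depth–temperature records,
of the kind collected for tiger sharks (*Galeocerdo cuvier*) on reef
receiver arrays across the Coral Sea. The package quantifies reef fidelity
and migration: how often a tagged shark is present at a receiver array, which
of four occurrence categories its detection history falls into, whether its
visits are biased by time of day, how it moves between stations, which of its
satellite positions are physically plausible, and how much three-dimensional
space it uses.

It is written for movement ecologists working with the standard observation
processes of biotelemetry — duty-cycled acoustic transmitters heard by
moored receivers within a few hundred metres, Argos location classes with
accuracy from <250 m (class 3) to kilometres (0/A/B) or nothing (Z), and
pop-up archival tags — and it ships a seeded synthetic generator that
emulates all of them, so every stage can be tested against known ground
truth.

## Methods at a glance

- **Residency Index.** `RI = D / P`, where `D` is the number of distinct
  calendar days with at least one detection and `P` the number of days the
  tag could possibly have been detected (its estimated battery life — 696,
  835 or 1448 days depending on the 50–130 / 40–80 / 30–90 s delay
  configuration — capped by the array's last service date).
- **Behaviour classification** into four categories, evaluated in precedence
  order: *resident* (detected in ≥10 calendar months of every year of
  monitoring and RI > 0.30), *pseudo-resident* (≥5 detected days in each of
  ≥3 months of a year, RI < 0.30), *transient* (re-detected after a gap of
  more than a month), *passer-by* (never detected after the first month).
- **Diel bias.** Detections split into day (06:00–17:59) and night
  (18:00–05:59) on a fixed-offset local clock; the two-cell equal-expectation
  Pearson test, `X² = (d − n)²/(d + n)` with one degree of freedom.
- **Movement networks.** Detections merge into station visits (30-min gap
  rule), giving directed receiver-to-receiver transition counts, detection
  proportions per station, and maximum great-circle (haversine, R = 6371 km)
  distance between detection sites.
- **Argos plausibility filter.** Classes 3/2/1 kept unconditionally; class Z
  dropped; classes 0/A/B kept only within a maximum swimming speed of
  3.5 km h⁻¹ of the most recent prior anchor (kept class 1–3 fix, capture
  location, or acoustic detection).
- **Bathymetric correction.** A geolocated daily position over seafloor
  shallower than that day's maximum dive depth is relocated to the nearest
  grid cell deep enough, within a search radius capped by the position's
  confidence radius.
- **3D kernel utilisation distributions.** Product-Gaussian KDE over
  (easting, northing, depth) in km with per-axis direct plug-in bandwidths;
  the α% activity space is the highest-density region holding α of the
  probability mass, reported in km³.

## Worked example

Simulate a pseudo-resident shark monitored for 120 days on a 7-receiver,
22-km lagoon array, with three gross Argos outliers injected, then run the
whole pipeline:

```bash
tigertrack simulate --regime pseudo_resident --duration-days 120 --seed 42 \
    --argos-outliers 3 --out-dir demo
tigertrack run --detections demo/detections.csv --receivers demo/receivers.csv \
    --tags demo/tags.csv --argos demo/argos.csv \
    --depth-series demo/depth_series.csv --out-dir demo/out
```

`demo/out/residency_summary.csv`:

```
tag_id  potential_days  days_monitored  days_detected  n_detections  mean_gap_days  residency_index  behaviour
T001    120             85              23             883           3.86           0.1917           pseudo_resident
```

The shark was detectable for 120 days, last heard on day 85, and present on
23 distinct days (RI = 23/120 = 0.19): repeated monthly use of the array but
well under the 30% residency bar, hence *pseudo-resident* — which is exactly
the regime that was simulated. `demo/out/diel.csv` shows 454 day vs 429
night detections (X² = 0.71, p = 0.400: no diel bias, as expected from a
generator with no diel behaviour), and `demo/out/argos_filtered.csv` records
that all 4 class-Z fixes were dropped and all 3 injected 500-km outliers are
among the 7 speed-rejected fixes, while the 43 class-1–3 fixes were kept.

Per-stage subcommands (`residency`, `diel`, `network`, `filter-argos`,
`track`, `kud`) run any stage standalone on the same CSV dialects; see
`tigertrack --help`.

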