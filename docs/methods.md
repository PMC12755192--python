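# Methods

## Scope and model of the data

The unit record is a *fix*: one individual, one UTC instant, one WGS84
lon/lat. Tracks are assumed accurate enough that position error is small
against hourly displacements (GPS-class tags); Argos-class error models are
out of scope. All timestamps are resolved to UTC on ingest; naive stamps are
interpreted as UTC by default (the common biologging-export convention),
overridable per study.

## Cleaning

Exact duplicate rows collapse; among distinct fixes sharing a timestamp the
first in file order wins (deterministic, no averaging of conflicting
positions). An optional per-movement-mode speed ceiling removes fixes whose
implied speeds to *both* temporal neighbours exceed the limit, iterating to
a fixed point: a single mislocated fix inflates two adjacent speeds, so the
two-sided rule deletes the outlier and spares genuinely fast but sustained
movement. The filter is off by default — cleaning beyond duplicates is
study-specific — and every removal is counted by reason.

## Regularisation

Each individual's fixes are snapped to grids of 1 h, 24 h and 7 d. The grid
is anchored at the first fix (not clock-rounded), which maximises retained
fixes and is deterministic. Per target, the temporally nearest *unused* fix
within ± tolerance is selected, earlier fix winning ties; targets without a
qualifying fix are explicit gap markers. Positions are never interpolated:
a fabricated location would bias every downstream hull and displacement.
Default tolerances — 15 min (hourly), 6 h (daily), 1 d (weekly) — are ≤
interval/4, bounding the displacement error a loose match could introduce;
all are configurable. Nearest-fix selection (rather than continuous-time
interpolation or state-space smoothing) is a deliberate design choice;
scale-insensitive continuous-time estimators are a known alternative and a
listed limitation.

## Distance kernel

"Straight-line distance" is realised as the haversine great-circle distance
on a sphere of radius 6,371,000 m. Inputs are geographic coordinates, so a
planar Euclidean treatment would be biased at track scale; full ellipsoidal
geodesics would buy < 0.5% accuracy at real cost in speed and determinism.
One degree of equator is 111,194.93 m under this kernel.

## Windowing

Daily, monthly and annual windows are calendar-aligned in *local solar
time*: the track's mean longitude, at 15°/h, is rounded to a whole-hour UTC
offset. Aligning in UTC would split the biological night for most of the
globe. Weekly windows are consecutive 7-day blocks from the first fix (there
is no natural calendar week for an animal). Feed mapping: daily and weekly
windows are cut from the hourly track; monthly and annual windows, and the
daily displacement series, come from the daily track — this bounds the
O(n²) pairwise scans (≤ 366² per annual window) and matches each metric's
grain.

## Trait definitions and numerical choices

- **Displacement**: per consecutive pair of grid slots that both carry a
  fix. Pairs spanning a gap marker are skipped, so holes never masquerade as
  long steps.
- **Maximum displacement**: maximum over all unordered fix pairs in the
  window (a capacity measure; the pairwise set contains the consecutive
  set, so it is never below the largest step).
- **Range size (95% MCP)**: points are projected to a Lambert azimuthal
  equal-area plane centred on their arithmetic lon/lat centroid — equal-area
  is the property that matters for hull areas, and per-window centring keeps
  distortion negligible at home-range scale. The ⌈0.95·n⌉ points nearest the
  projected centroid are retained (the classic centroid-peeling MCP; ties
  broken by input order for determinism) and the convex-hull area is
  reported in km². Fewer than three non-collinear retained points give
  area 0.
- **Intensity of use**: sum of gap-free consecutive displacements divided by
  √(95% MCP area). Undefined for degenerate (zero-area) hulls — perfectly
  collinear or stationary windows yield no estimate, logged, rather than an
  infinity.
- **Diurnality**: each gap-free hourly step is classified day/night by the
  solar elevation at its *start* fix (geometric horizon, 0°; the threshold
  is configurable, e.g. −6° for civil twilight). With Md, Mn the summed
  day/night displacements and Hd, Hn the day/night step counts, the index is
  (Md/Hd − Mn/Hn)/(Md/Hd + Mn/Hn): a contrast of movement *rates*, which
  conditions on day length — long summer days do not by themselves make an
  animal diurnal. Tracks with no day or no night exposure (polar seasons)
  yield no estimate. Solar elevation uses the standard low-precision
  NOAA-style solar position algorithm (mean elements since J2000, two-term
  equation of centre); its few-hundredths-of-a-degree error is far below
  what a day/night classifier needs.

## Minimum-data thresholds

Windowed estimates require a minimum fix count per window, and summaries a
minimum estimate count per individual (all configurable):

| rule | default | basis |
|---|---|---|
| monthly range size | ≥ 14 daily fixes | published analysis rule |
| daily displacement summary | ≥ 30 estimates | published 30-days-of-data rule |
| daily windows (other traits) | ≥ 18 hourly fixes | package default (75% coverage) |
| weekly windows | ≥ 120 hourly fixes | package default (~71% coverage) |
| annual windows | ≥ 200 daily fixes | package default |
| diurnality | ≥ 720 classified steps | package default (~30 days) |
| other summaries | ≥ 20 estimates | package default |
| diurnality summary | ≥ 1 | whole-track trait: one value per individual |

Thresholds govern *summaries and windowed estimates*, never the raw
estimate tier: an individual with 29 daily displacements keeps its 29
within-individual rows and simply gets no individual-tier summary.

## Aggregation

Individual summaries: arithmetic mean, median and 5th/95th percentiles by
linear interpolation between order statistics (position h = (n−1)p + 1, the
common statistical-software default), and cv = sample sd (n−1) / mean,
undefined (blank) for zero mean or a single estimate. Species statistics are
unweighted means of individual statistics — the species 95th percentile is
the mean of individual 95th percentiles — so tracking effort does not weight
the species value. Database assembly enforces referential integrity between
tiers and fails loudly, listing offending keys.

## Location privacy

Individual rows report only a *diffused* mean coordinate: the spherical
(unit-vector) mean of the fixes — antimeridian-safe — snapped to the centre
of a grid cell of ~1, 100 or 10,000 km². Cells are latitude bands of height
s/111.32° split into longitude intervals of width s/(111.32·cos φ_band)°,
origin (0°, 0°). The construction is idempotent (cell centres map to
themselves) and near-equal-area away from the poles: measured cell areas are
within 0.3% of nominal below 60° latitude (the tests enforce 5%); |lat| >
89° is rejected. Tracking dates are reported exactly; coarsening dates for
restricted studies would be a caller-side decision.

## Synthetic deployments

The generator emulates the statistical structure the metrics assume: hourly
(or coarser) fixes from a correlated random walk with gamma step lengths
(defaults shape 2, scale 250 m → 500 m mean hourly step, a realistic
mid-size terrestrial mammal), wrapped-Cauchy turning persistence, a
day-activity multiplier applied when the step starts in daylight (same
solar classifier as the trait code, so recovery is self-consistent),
optional directed migration legs, independent fix drops (gaps) and Gaussian
tangent-plane location noise. Closed forms accompany it: mean step
k·θ·(h_d·δ + h_n), diurnality (δ−1)/(δ+1), and for uncorrelated walks the
RMS net displacement √(m·k(k+1)θ²) over m steps.

What it does *not* emulate — and therefore what passing tests cannot show —
includes home-range attraction (real residency produces bounded, not
diffusive, ranges), behavioural state switching, spatially autocorrelated
location error, tag-dependent fix-success patterns (gaps here are
independent), and habitat responses. Recovery results demonstrate the
*pipeline's* correctness, not the ecological validity of any real dataset.

## Problem sizes

The test suite and the reproduction script use deployments of up to 5
species × 10 individuals × 90 days at 1 h (~106k fixes; the full build runs
in ~25 s on one core), 10,000-step walks for mean-step recovery, 60-day ×
5-seed simulations for diurnality recovery, and 200 random point sets for
hull-oracle equivalence — sizes chosen so Monte-Carlo error sits well inside
the asserted tolerances.

## Known limitations

- Nearest-fix resampling retains sampling-scale sensitivity; traits from
  coarser tags are not directly comparable to 1 h traits.
- MCP range size is known to overestimate with outliers and ignores use
  intensity inside the hull; kernel/autocorrelated estimators are
  deliberately out of scope for this standardised first suite.
- The solar-time window offset is a whole-hour approximation of local solar
  time; tracks spanning > ~7.5° of longitude blur window edges slightly.
- Species aggregation assumes individuals are exchangeable samples of the
  species; no phylogenetic or study-effect structure is modelled.
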