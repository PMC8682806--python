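# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic data generator does and does
not emulate, and the numerical conventions used throughout.

## Synthetic environmental forcing

Real assessments of this kind drive the transport and dispersion models
with historical reanalysis (hourly ~0.25° winds, 3-hourly ~1/12° ocean
state).  A desk-scale, fully testable artifact must emulate those inputs
statistically.  Each forcing variable is generated as

    x_t = mean + e_t,      e_t = phi * e_{t-1} + sqrt(1 - phi^2) * sigma * w_t,

a stationary AR(1) process in time (default lag-1 autocorrelation
phi = 0.9 at the 3-hourly step, marginal sd sigma) whose innovations
`w_t` are white in time but smoothed in space with a Gaussian kernel
(default 1 grid cell) and renormalised to unit marginal variance, so the
configured sd is the *marginal* sd of every cell's series.  Smoothing
uses wrap-around boundaries so the renormalisation factor is uniform;
the generated fields are therefore statistically homogeneous, unlike real
reanalysis, which has coasts, jets and diurnal cycles.  Current and wind
vectors are capped (3 and 40 m/s) by rescaling the vector, preserving
direction.

Seasonal mean states encode the region's known circulation reversal:
"summer" flow points south-east — mostly along the channel axis with a
small shoreward component (current (0.01, -0.12) m/s, wind
(0.5, -3.5) m/s) — and "winter" flow points north (current (0, 0.12),
wind (0.5, 3.5)).  These defaults were fixed so that summer spills run
south along the coast, reaching the southern gulf arm within three weeks,
and winter spills run north: the qualitative seasonal contrast the
analysis is about.  Spring/autumn are weak transitional states.

What passing tests on this generator show: the downstream stages respond
correctly to forcing with realistic persistence, smoothness and seasonal
structure.  What they do not show: skill against any historical spill,
since no real coastline, tides (excluded by design), wave turbulence or
mesoscale variability is present.

The domain is an idealised "Red Sea channel": water between two
north-south coasts (40°E and 43°E) from 11°N to 21°N, with an
east-opening arm at 11.5-12.5°N standing in for the gulf so that a second
fishery region and an outside-the-channel port exist.  The spill source
sits 0.2° off the eastern coast at 15.15°N, mirroring the real tanker's
position a few kilometres off the Yemeni coast near the Salif port.

Population is a Gaussian-kernel mixture around configurable hotspots,
restricted to land cells and rounded by the largest-remainder rule so the
grid sum equals the requested total exactly.

## Spill transport

Forward-Euler Lagrangian stepping with dt <= 15 min at module level (the
desk-scale pipeline uses 30-60 min, which the constant-forcing oracle
shows is still within 0.1% of the closed-form displacement for the speeds
involved).  Per step, a floating particle moves by

    (current + windage * wind) * dt  +  Gaussian jump, var = 2 D dt per axis,

converted to degrees with the local metres-per-degree factors
(111,320 m/deg latitude; x cos(lat) for longitude).  Windage is drawn
per particle from U[1%, 4%] at release and held constant — the standard
operational range for light surface oil.  Horizontal diffusivity defaults
to 10 m²/s (1e5 cm²/s), a common operational value.

Particles are released uniformly over the release window (default 7 days;
24 h variant available).  A particle whose step would land on the land
mask anchors at its last water position and never moves again (no
refloating; this is the minimal shoreline interaction).  A particle
leaving the forcing domain freezes and is excluded from concentration
accounting but still counted, so floating + beached + out-of-domain is
conserved.

Each simulation also runs an equal-sized *uncertainty ensemble*: currents
and windage scaled by a factor drawn per simulation from U[1.0, 1.5] and
diffusivity doubled.  Operational trajectory models produce such an
ensemble under "extreme-condition" parameter settings whose envelope is
read as a ~90% trajectory region; the exact perturbation scheme is not
published, so this explicit stand-in is documented here.  The convex hull
of all uncertainty-particle locations across all simulations is the
uncertainty region; by construction it contains 100% of those locations.

Surface concentrations: each particle carries an equal share (1/n) of a
per-simulation surface-thickness budget; within a simulation, values
falling in the same rounded-coordinate cell add, and across simulations
the per-cell mean divides by the number of simulations (zero for
simulations that never touched the cell).  Cells never touched by any
simulation are absent, not zero.  Rounding is round-half-even at 3
decimals (~100 m) or 2 decimals (~1.1 km); the desk-scale pipeline uses 2.
Because the absolute spilled volume is uncertain, fields are converted to
percentile ranks among exposed cells: rank = 100 x (fraction of exposed
cells with value <= x), ties sharing the highest rank, which makes the
field invariant under any strictly increasing rescaling of the thickness
proxy.  Bilinear interpolation between the four surrounding cell centres
(absent neighbours = 0) evaluates the field at asset locations; queries
outside the exposed bounding box raise a domain error.

Weekly outputs are end-of-week snapshots.  For "reached by week k"
accounting (fisheries, desalination) the pipeline uses the cumulative
per-cell maximum over weeks <= k, since a snapshot footprint can shrink
as floating oil moves on while "reached" cannot.

## Oil fate

The cargo is a three-component stand-in for a light crude: 55% light
(k = 0.026 /h), 25% medium (k = 0.002 /h), 20% heavy (k = 0), each
depleting first-order with the multiplicative modifier

    f(U, SST) = (1 + 0.045 U) * Q10^((SST - 15)/10),   Q10 = 2,

which captures the wind- and temperature-dependence of evaporation with
two interpretable knobs.  The k values were calibrated once so that about
half the cargo (51% at U = 5 m/s, SST = 29 °C) evaporates in the first
24 h — the behaviour expected of a light crude in a warm sea — and are
not adjusted anywhere else.  The per-step update is the exact exponential
decrement, so a single component reproduces 1 - exp(-lambda t) to machine
precision at any step size.  Bulk density is derived from the two cargo
figures: 150,000 t / 1.1e6 bbl = 136.36 kg/bbl.

Clean-up (optimistic): a skimmer at 14 bbl/h and 100% efficiency; in-situ
burning over 70,000 m² at 50% efficiency consuming 3.5 mm of slick per
burn-minute; and dispersant over 15% of the cargo at 20% efficiency.
Burning is episodic: a pooled slick burns out minutes after ignition, so
the model applies `burn_minutes_per_day` (default 4) of consumption per
day, which sizes six-day burn recovery to the historical large-spill
response totals that these parameters were drawn from — a continuous burn
at that area and rate would consume the entire cargo in about a day,
which no response achieves.  Dispersant transfers its
fraction x efficiency of the initial cargo linearly over the first 48 h.
All removals draw proportionally from the surviving components and are
capped by the floating mass; compartments conserve total mass to 1e-9.
With proportional removal, the floating fraction under clean-up can never
exceed the evaporation-only floating fraction under identical weather;
the two differ by ~3 percentage points at 144 h under the defaults —
clean-up removes a small share of a spill this size in six days.

Monte Carlo: each draw fixes one (wind speed, SST) pair
(wind ~ N(5, 2) truncated at 0, SST ~ N(29, 1) by default), emulating
variation of spill date; bands are 2.5th/97.5th sample percentiles per
time step.  Weathering runs are capped at 144 h because the model omits
biodegradation and photo-oxidation, which dominate later.

## Atmospheric dispersion

Emission rate = cargo mass (µg) x conversion rate / release duration.
The evaporative conversion rate defaults to 0.008 µg-PM2.5/µg-oil with a
combustion add-on of 0.05 for burning spills; both are placeholders with
a 25%-of-mean default sd for the Monte Carlo, because the measured
conversion rates this quantity is based on are published elsewhere and
are user-configurable here.

The transport model is a deliberately simple single-layer Lagrangian
cloud replacing a full meteorological dispersion system: equal-mass
particles released evenly over the emission window, advected hourly by
the 10 m wind plus isotropic Gaussian turbulence (sigma = 0.5 m/s), and
assumed well mixed through a fixed 800 m boundary layer.  Hourly binned
mass / (cell area x mixing depth) gives ground-level concentration;
daily averages are kept per release day and the headline field is the
24-h average ending when the release stops, averaged over an ensemble of
start times spread through the season (default 8; paper-scale would be
every 3 h).  The model keeps the computational structure of the full
system — particle counts, 144 h runs, start-time ensembles, 24-h
averaging — without vertical profiles, deposition or chemistry.
Emission is from the fixed spill site only.  Mass is audited exactly:
in-domain + out-of-domain = emitted, with no losses.

Concentration is linear in conversion rate and cargo mass, which the
health stage exploits: uncertainty draws rescale the field instead of
re-running transport.

## Health impacts

Default exposure-response is log-linear in 24-h PM2.5 (the standard form
in the short-term hospitalisation literature), IR(0) = 0; a linear form
is available.  The bundled slope presets are calibrated to a published
occupational-exposure anchor — 1,600 µg/m³ corresponding to a 530%
(460-590%) increased risk — giving slope = 100 x (6.3^(1/160) - 1)
= 1.1567% per 10 µg/m³ with CI [1.0823, 1.2147]; the primary-source
coefficients are cited in that literature but not redistributable, so
users supply their own to reproduce a specific study.  Two alternative
presets (a steeper elderly-population slope, a shallower short-term
mortality slope) exercise the sensitivity interface.

Population-weighted IR averages pointwise IR over cells at or above the
exposure threshold (10 µg/m³), weighted by population, i.e. risk *among
the exposed*; if no populated cell is exposed the scenario reports 0.
Person-days sum population x days at or above threshold over the release
days (exposure duration equals release duration).

Uncertainty propagation samples the per-10 relative risk
RR ~ N(1 + slope/100, sd) with sd = ln(RR_upper/RR_lower)/(2 z_0.975),
and the conversion rate ~ N(mean, sd); both propagate into IR *and*
person-days (the split is not fully specified upstream; propagating both
is the conservative choice and is switchable).  Two truncation rules are
applied and documented separately: sampled negative slopes/rates are
floored at zero per draw (`truncate_draws`, default on), and a negative
2.5th percentile of the IR draws is reported as a lower bound of exactly
0 with a `possibly_null` flag.  All quantile estimates everywhere in the
package use linear-interpolation sample quantiles (numpy default, R
type 7).

## Supply impacts

* Port exposure: bilinear percentile at the port; "directly impacted"
  means >= the 90th percentile among exposed cells.  Any positive
  concentration marks an asset as "reached" (used for desalination),
  a deliberately conservative reading of port disruption.
* Desalination: plants without their own capacity share their country's
  configured capacity equally (conservation is exact); disrupted capacity
  divided by per-country per-capita daily use gives population
  equivalents.  Per-capita use is a config value (defaults 0.075 m³ for
  the low-income coast, 0.25 m³ for the high-income coast).
* Fuel: mean and 95% quantile interval of a short monthly import series
  (n = 5 by default).  Price spike: percent change of the median price
  across fuel types between two dates.
* Food aid: (sum of disrupted ports' aid shares) x mean of the monthly
  people-targeted series, with the UI as share x series quantiles
  (multiplying the share into the quantiles is identical to taking
  quantiles of the scaled series here, and is the documented order).
* Fisheries: share of a region's gridded annual yield in cells reached by
  the spill, with cells below the 10th percentile of surface
  concentration excluded by default to drop trace amounts (no-threshold
  and 20th-percentile variants for sensitivity).  Thresholds apply to the
  percentile-transformed cumulative reach field, so
  loss(p20) <= loss(p10) <= loss(none) on any field and the no-threshold
  weekly series is monotone by construction.

## Orchestration and problem sizes

`run_pipeline` executes environment -> transport -> fate -> dispersion ->
health -> impacts for the 2 x 2 x 2 scenario matrix and writes a manifest
with per-stage seeds (sha256 of "seed:stage", below 2^31) and output
checksums; identical config and seed reproduce identical checksums.

Module-level defaults match the full-scale study design (1,000
simulations x 1,000 particles, 1,000 Monte Carlo draws, 2,500 dispersion
particles).  The pipeline's `RunConfig` defaults are the package's
desk-scale working sizes — 30 simulations x 120 particles at 30-min
steps on a 0.25° grid with 2-decimal concentration rounding, 300 fate
draws, 600 dispersion particles x 6 start times, 400 health draws —
chosen as the smallest ensembles that preserve every structural feature
of the analysis (weekly fields, hulls, seasonal contrast, the 8-scenario
table) while a complete run finishes in about a minute on one CPU.
Asset-level contact (a specific port meeting a specific 1.1 km beach
cell) is genuinely stochastic at these sizes and varies with the seed,
exactly as individual trajectories do.

## Known limitations

No tides, wave turbulence, emulsification, dissolution, refloating or
shoreline chemistry in transport; no biodegradation or photo-oxidation in
weathering (hence the 144 h cap); no vertical meteorology, deposition or
VOC speciation in dispersion; no baseline hospitalisation rates (results
are relative risks, not case counts); no port-closure durations or price
forecasting; synthetic forcing is homogeneous and the coastline is
idealised, so absolute magnitudes of exposure and disruption are
illustrative, while the oracle-checked mechanics (kinematics,
conservation, ranking, interval conventions) are exact.
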