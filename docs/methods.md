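# Methods

## The random encounter model

The REM treats a population of unmarked animals as independent movers
encountering static detectors. For a camera whose sensor covers a sector of
radius `r` and full angle `θ`, the expected contact rate with animals at
density `D` moving at mean speed `V` is `ρ = D·V·r·(2+θ)/π`: the factor
`r(2+θ)/π` is the sector's mean profile width averaged over approach
directions. Inverting gives the estimator implemented in `remcam.rem`:

    D = (y/t) · π / (V · r · (2 + θ))

with `y/t` the independent-event rate per camera-hour. The estimator
assumes (i) cameras placed randomly with respect to movement, (ii) animals
moving independently of cameras and of each other, and (iii) speed and
detection-zone estimates that refer to the same population and time window
as the events. Groups are handled by counting one event per contact by
default (`per_individual=True` counts pictured individuals instead);
treating grouped animals as independent inflates variance but not bias.

Units are fixed internally — km, hours, radians — and converted exactly
once at the I/O boundary (`r_units: m`, `theta_units: deg` in parameter
files). A radius of 0.5 km or more is rejected outright as a
metres-for-kilometres mistake rather than silently absorbed.

## Independent events

A contact ends when the animal leaves the field of view, so repeated
triggers of a lingering animal must collapse to one event. The package's
operational rule is a chained time gap: a trigger joins the current event
if it follows the previous trigger by less than `gap_min` (default 15
minutes, the analyst's knob; the comparison is always to the previous
trigger, not the run's first, so run length does not affect the rule).
Merging is idempotent and keeps the first trigger's timestamp.

## Day/night windows and effort

Night is the half-open clock window [18:00, 06:00), so the day/night
partition is exhaustive and no timestamp is double-counted. Effort is
computed from deployment intervals as the exact overlap with the daily
window — 12 h per full camera-day for night — and night-only estimates pair
night effort with the night speed `V_n`, keeping the `V·t` product's
"distance walked during surveyed time" semantics. Timestamps are naive
local datetimes (camera-stamped); there is no timezone arithmetic.

## Variance and intervals

The encounter rate is the ratio of totals Σy/Σt (invariant to splitting a
camera's record), with variance from resampling cameras with replacement
(default 10,000 replicates, seeded; the variance uses the replicate sample
with ddof 1). An exhaustive-enumeration oracle over all `n^n` resamples
backs the bootstrap in tests. Parameter uncertainty is propagated to first
order: `CV²(D) = CV²(y/t) + CV²(V) + CV²(r) + (θ/(2+θ))²·CV²(θ)`, the
standard result for a product of independent factors; the angle enters
through its elasticity `θ/(2+θ)` (≈0.30 at θ = 50°, which is why a 1%
radius error moves `D` by 1% but a 1% angle error by only 0.3%). The
default 95% interval is lognormal, `D·exp(±1.96·√ln(1+CV²))`, chosen
because it keeps bounds positive for a strictly positive quantity; a
normal interval is available (`ci="normal"`) and both are cheap to report.
Tests require the delta CV to match a 10⁶-draw Monte-Carlo propagation
within 2% for CVs ≤ 0.15; beyond that the first-order expansion degrades.

## Field parameters

Detection radius is the mean first-trigger distance of frontal approaches
(standard error of that mean). The detection angle is the circular
difference between the circular means of left- and right-side bearings
from paired perpendicular approaches, resolved into (0°, 180°]; compass
bearings are averaged as unit vectors because trial protocols routinely
straddle north. The angle's standard error combines the two mean-bearing
standard errors in quadrature — a choice, since the two sides are measured
independently. Bearing dispersion is computed from wrapped residuals,
adequate for the tightly clustered bearings these trials produce.

Speed is distance along the path per unit time (odometer semantics, not
net displacement). Each follow contributes one rate per window — km moved
inside the window over hours inside it, with segments crossing the
18:00/06:00 boundary split pro-rata by time — and the pride is the
replication unit: hours within a follow are autocorrelated, so the group
standard error is taken across pride-level rates. Follows shorter than
24 h are excluded.

## Reference densities

Census reference density for a habitat is `D_ref = Σ N_i·p_i / A`, with
`N_i` the known female count of pride `i` and `p_i` the fraction of its
75% kernel home range inside the habitat polygon.

* **UD fitting.** Bivariate Gaussian KDE with a single isotropic reference
  bandwidth `h = √((var(x)+var(y))/2)·n^(−1/6)` on a regular grid (cell
  `h/4` by default; the grid pads the points by 3 bandwidths so effectively
  all kernel mass is on the grid before normalisation). Grid-cell
  sensitivity is tested: halving the cell moves the Gaussian isopleth area
  by under 1%.
* **Isopleths.** Cells are accumulated in decreasing density order until
  the cumulative mass reaches the level; the area is cell count × cell
  area and the region is polygonised for overlap computations. Reference-
  bandwidth smoothing adds the kernel variance `h²` to the data variance,
  inflating isopleth areas by roughly a factor `1 + n^(−1/3)` (about 10% at
  n = 1000) — the known oversmoothing cost of the reference rule, and the
  reason the closed-form Gaussian check carries a 10% band.
* **Buffer width.** `w` is half the mean home-range diameter,
  operationalised as the circular-equivalent radius of the mean 75% area,
  `w = √(ā/π)`; this reproduces the published per-stratum buffer widths
  from the published mean areas exactly at one decimal, which is why it is
  the default over the mean-of-radii alternative (also offered). The 95%
  limits on `w` come from the mean ± 1.96·SE of per-pride radii (t
  quantile optional at small n).
* **Effective area.** Convex hull of the camera locations ("joining the
  outer camera locations"; concave hulls are under-specified), buffered
  outward by `w` (64 arc segments per quadrant, keeping the circular-arc
  area error below ~10⁻⁴), intersected with the habitat polygon. Density
  CIs recompute `A` at the `w` limits; a larger buffer gives a larger area
  and smaller density, so the endpoints swap.

Cameras are assigned to habitats by point-in-polygon, first containing
polygon in file order for boundary points; cameras outside all polygons are
excluded with a warning.

## The simulator

`remcam.simulate` generates every pipeline input from known truth on a
toroidal arena (the torus preserves uniform density exactly; no edge
effects). Animals are independent movers at constant speed; the default
movement is straight-line, for which the gas-model rate above is exact, and
a correlated walk (heading increments of sd `turning_sd·√dt`) is available
for realism checks.

Detection is computed exactly along each linear path segment: the segment's
intersection with the detection disc is solved in closed form, and the
sector condition is then evaluated at 128 points along the clipped chord
(resolution ~`2r/128`, far below the detection radius). A detection fires
on each outside→inside transition; an animal must exit before it can
trigger again, resting inside a zone yields one event however long, and an
animal starting inside a zone at time zero counts once. Because detection
is segment-exact, the event stream of straight-line movers is independent
of `dt`; `dt` only discretises correlated-walk headings, and tests check
that halving it leaves correlated-walk event rates unchanged within
Monte-Carlo error.

The placement-bias scenario emulates shade-seeking at camera trees: during
day hours each animal makes, with hazard `q` per day-hour, an excursion to
the nearest camera — recorded as one contact — and rests for `rest_h`
(truncated at nightfall) before resuming. The excursion interrupts rather
than displaces the underlying walk (the animal resumes from where it
paused), so the spatial distribution stays exactly uniform at every
instant and night movement is unbiased by construction; an implementation
that leaves animals at cameras at nightfall would depress the night
encounter rate and contaminate the very estimate the scenario is meant to
validate. With `q = 0` the scenario reduces bit-for-bit to the unbiased
simulation. `q` and `rest_h` are scenario knobs, not estimates of any real
attraction strength.

What the simulator does *not* emulate: pride cohesion or territoriality,
landscape resistance, detection distance varying with vegetation or
season, imperfect detection inside the zone, or classification error.
Passing recovery tests therefore show the estimator and its variance
machinery are correct under the model's own assumptions — not that those
assumptions hold in any particular field system.

## Validation scales

The recovery experiments use 5 animals/km² (500 on a 10 × 10 km torus),
0.2 km/h, 10 m / 50° zones, a 5 × 5 camera grid and 2,000 h, averaged over
200 seeded replicates (mean estimate within 5% of truth; mean per-camera
rate within 3 SE of the analytic rate). The bias contrast uses 320 animals
on 8 × 8 km, 16 cameras, 480 h, `q = 0.1`, 2 h rests, 100 replicates:
all-events estimates exceed truth, night-only 95% CIs cover truth in ≥90%
of replicates, and all-events percent error exceeds night-only error in
every habitat stratum. Smaller versions of both run in the module tests.

## Numerical and degenerate-input choices

* Ratio-of-totals rates require positive total effort; a camera with zero
  effort and nonzero events is invalid. Bootstrap variance needs ≥2
  cameras (single-camera strata report a point estimate flagged as having
  no resampling variance).
* All points identical → zero reference bandwidth → error; fewer than 5
  observation points → no UD; collinear camera points → no hull.
* Isopleth ties (uniform densities) resolve by cell index order — area is
  unaffected.
* Bootstrap replicates whose resampled effort is zero (possible only when
  some cameras have zero effort) are discarded.
* Validation is fail-fast with row-addressed messages; `permissive=True`
  logs and skips bad rows. Every stochastic output records its seed.

## Known limitations

* The 15-minute independence gap is a surrogate for "the animal left the
  field of view"; no image-based check is possible here.
* Observer-vehicle odometer distances stand in for the animals' own path
  length, as in the source field protocol.
* The delta method assumes independent multiplicative errors; correlations
  between speed and encounter rate (both behaviour-driven) are not
  modelled.
* Reference densities inherit the oversmoothing of reference-bandwidth
  KDEs and the convex-hull/buffer operationalisation of "area effectively
  sampled"; both choices are documented rather than estimated.
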