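# Methods

## Trajectory cleaning

Reverse-GPS localizations carry a per-fix horizontal positional SD.  Cleaning
applies, in order: (1) a recursive ground-speed filter at 100 m/s, (2) a
positional-SD filter at 150 m, (3) a running median over 5 fixes.

**Speed filter semantics.**  Speeds are incoming-segment speeds (distance
from the immediately preceding fix divided by the time delta).  Each pass
removes *every* fix whose incoming speed strictly exceeds the threshold and
passes repeat until stable; a single sequential pass leaves "ghost" spikes
when several bad fixes alternate with good ones (an alternating
0 ↔ 2 km teleport at 10-s cadence collapses, correctly, to its first fix).
One consequence: when a spike's return segment is itself faster than the
threshold, the fix after the spike is removed too.  All thresholds are
strict: exactly 100 m/s and exactly 150 m survive.  Duplicate timestamps are
resolved at ingest in favour of the lower SD.

**Median smoother edges.**  The centred window shrinks symmetrically at the
track ends (the first/last fix are untouched, the second/penultimate use a
window of 3), so length, timestamps and SDs are preserved.

## Departure classification

The four-criterion decision tree is implemented exactly as stated in the
package docs, with these conventions where a choice had to be made:

* *Boundary conventions*: a last fix on the core-area boundary counts as
  inside (not departed); the westward sector [225°, 315°] is inclusive;
  "> 2 h", "< 90°" are strict.
* *Bearings* are planar compass bearings, `atan2(Δx, Δy)` with 0° = +y
  (north), clockwise.  Zero-length segments contribute no bearing (the
  smoother can emit coincident fixes in slow foraging stretches).
* *Departure instant*: the analysis needs flight initiation, not last
  contact.  The departure time is the first fix of the terminal directed
  segment, found by walking backwards from the last fix while segment speed
  exceeds the 5 m/s transit threshold and successive bearings turn < 90°.
* *Insufficient data*: fewer than 3 fixes in the final 20-min window yields
  a rejection with its own reason code rather than a guess.
* *Cut-off date*: the empirical inverse-CDF 95th percentile of departure
  dates (smallest date with cumulative fraction ≥ 0.95).  Proportions count
  departures on/before the cut-off against non-departing tags still
  localized at the cut-off.

## Environmental covariates

All timestamps are UTC.  Covariates at time *t*:

* **min_to_sunset** — signed minutes to the *nearest* sunset (negative
  before).  Sunset is computed from standard NOAA solar geometry (sun centre
  at −0.833° altitude, one refinement pass); tests check it against an
  independent USNO low-precision ephemeris with bisection and the two agree
  within seconds year-round at the study latitude.  Nearest-sunset keeps the
  covariate within roughly ±12 h, matching how available times spread around
  evening departures.
* **min_to_hightide** — signed minutes to the closest high tide.  High tides
  are local maxima of the (station-lagged, +30 min) 10-min water-level
  series after a ~1-h centred rolling mean (the semidiurnal crest is flat
  relative to gauge noise), with an 8-h minimum peak separation.  An exact
  midpoint between tides resolves to the upcoming tide (−P/2), keeping the
  covariate in [−P/2, +P/2] for tidal period P ≈ 745 min.
* **cloud** — okta (0–8) at the nearest 10-min stamp.
* **rain** — the value of the hour containing *t*, in 0.1 mm/h as recorded.
* **d_pressure** — P(hour of *t*) − P(hour of *t* − 1 h), hourly records
  matched by flooring; differencing recorded values avoids inventing
  unrecorded pressures by interpolation.
* **wind_assist** — full-drift wind assistance: wind speed times the cosine
  of the angle between the blow-to direction and the intended track bearing
  (default 262°, the approximate Griend→Wash bearing; per-bird final
  bearings are available as an option).  Wind direction is meteorological
  (FROM) and converted internally.  No airspeed correction: |assistance| ≤
  wind speed, with equality on the track axis.

## Selection model

For each of *n* events: 1 used row (weight 1) plus 30 available rows
(weight 1000) drawn uniformly without replacement from the 10-min grid over
[t − 96 h, t).  The weighted binomial log-likelihood
Σ wᵢ [yᵢηᵢ − log(1 + e^ηᵢ)] is maximized by penalized IRLS
(statsmodels `GLMGam`): linear terms for wind assistance, cloud, pressure
change, rain and season (two-level indicator, earliest season reference;
dropped with a warning in single-season designs), plus cubic B-spline
smooths (basis dimension k = 10) for minutes-to-sunset and
minutes-to-high-tide.

* **Smoothing parameter**: a shared penalty chosen by generalized
  cross-validation over a 9-point log grid from 10⁻² to 10⁶.  On designs
  like these GCV selects a near-unpenalized fit; the grid search is
  deterministic and cheap (9 refits).  A fixed penalty can be supplied via
  `GAMSpec.alpha`.
* **RSF curves**: exp of the partial predictor for one covariate, intercept
  and other terms excluded, min–max scaled to [0, 1] over the evaluation
  grid.  Peaks are the argmax of the fitted smooth on a 1-min grid; a flat
  or boundary-peaked smooth warns.
* **Bootstrap**: the resampling unit is the event — a used time together
  with a freshly sampled available set — preserving the design hierarchy;
  B = 100 refits at the point fit's penalty (re-selecting the penalty per
  replicate would measure tuning variability as well as sampling
  variability).  CIs are 2.5/97.5 empirical percentiles.
* **Weighting**: multiplying the available weight beyond 1000 changes
  coefficients by < 1% (tested), i.e. the estimates sit at the
  infinitely-weighted limit where the logistic fit estimates the RSF.
* Smooths are ordinary (non-cyclic) splines over the observed range; the
  available-sample-size sensitivity analysis refits at n ∈ {5, 10, 20, 30,
  50, 100} and flags < 10% relative coefficient change between successive n.

## Synthetic-data generator

The generator defines the desk-scale study conditions:

* **Tide**: amplitude-1 cosine at the 745-min semidiurnal lunar period with
  2 cm Gaussian noise at 10-min cadence.  Only high-tide *times* matter
  downstream, so a noisy sinusoid stands in for a real gauge record.
* **Weather (hourly)**: AR(1) pressure around 1013 mb (φ = 0.9, innovation
  0.4 mb); AR(1) wind speed around 7 m/s truncated at 0; circular
  random-walk wind direction (20°/h steps); a two-state wet/dry rain chain
  (P(wet|dry) = 0.05, P(wet|wet) = 0.75, ≈ 17% wet hours, exponential wet
  intensities) matching the mostly-dry availability described for the study
  site.  **Cloud**: bounded ±1 random walk on integer okta 0–8 at 10-min
  cadence.
* **Tracks**: residents are centre-pulled random walks (150 m steps)
  confined to a 12 × 12 km core polygon, sampled hourly all season and
  detected throughout.  Departers forage at full fix cadence (60 s) for an
  hour, then fly a straight 18 m/s leg on bearing 262° until well inside the
  sea polygon (≥ 25 min of flight, so the terminal straightness window
  contains flight only); localizations and detections then stop.
  Pass-throughs enter just outside the eastern core boundary already at
  flight speed.  Every fix gets isotropic Gaussian error (default 25 m,
  a plausible array accuracy) and carries that SD.  Flight speed 18 m/s is a
  plausible knot transit speed, safely under the 100 m/s filter.
* **Departure times**: drawn from an explicit selection function
  η(t) = 0.3·windassist − 0.2·cloud + Gaussian bumps (height 2.0 log-odds)
  of width 90 min centred +108 min after sunset and width 120 min centred
  −238 min before high tide; sampling is independent across birds over the
  10-min grid (ties allowed).  The linear coefficients and peak locations
  mirror the effect sizes the analysis is designed to detect; the bump
  heights and widths are generator choices fixed once.

**What the generator does not emulate**: receiver-network geometry and its
spatially varying error, behaviourally realistic foraging (tide-driven
movement), tag failure/mortality, correlated departures (flocking), or real
gauge/station series.  Passing tests therefore demonstrate correctness of
the pipeline's logic and estimator — not that the ecological effect sizes
of any real system are recoverable at any given sample size.

## Problem sizes and numerical choices

The test suite and the reproduction script use desk-scale sizes chosen to
give stable statistical checks: classifier fidelity on 23–40 tags per
scenario; selection recovery at 500 events × (1 + 30) rows; null
calibration over 100 replicates of 40-event designs (fixed penalty 1.0);
bootstrap demonstrations at B = 1–100.  At 500 events the fit recovers the
wind coefficient within ±0.1 and both smooth peaks within ±60 min of truth;
at 34 events (the worked example) the tide smooth is only weakly identified
and its bootstrap CI spans most of the tidal cycle — an honest small-sample
property, not a defect.

Degenerate inputs are errors, not guesses: empty tracks pass through
filters but cannot be classified; designs without both response values,
flat tide series, times outside environmental coverage, and polygons too
small for the requested walk all raise with context.  Constant covariates
are dropped from the GAM with a warning.  Spline bases are evaluated with
grids clamped a relative 1e-9 inside the fitted range to avoid
out-of-knots errors at the boundary.

## Known limitations

* The speed filter's simultaneous-removal rule can delete one good fix
  after a large spike (see above); with 10-s cadence data this is a
  negligible loss and guarantees no surviving super-threshold segment.
* Smoothing-penalty selection is a shared-penalty grid search, not
  per-smooth optimization; per-smooth penalties can be fixed manually.
* The season indicator enters linearly (two levels); designs with more than
  two seasons would treat year as a trend, not factors.
* Sunset accuracy degrades above ~66° latitude (polar day/night raises).
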