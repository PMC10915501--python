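# knotflight

Departure-time analysis of red knot (*Calidris canutus islandica*) relocation
flights across the North Sea — a tested reimplementation of the full analysis
pipeline for regional reverse-GPS (time-of-arrival) tracking data, from raw
localizations to a fitted resource selection function over departure times.

## The problem

Red knots overwintering in the Dutch Wadden Sea sometimes relocate to the UK,
a ~250 km non-stop flight over open water.  A regional tracking array records
localizations (planar x/y, with per-fix positional SD) and raw detections for
hundreds of tagged birds.  The analysis asks two questions:

1. **Who departed?**  A rule-based decision tree classifies westward
   relocation-flight departures: no detections more than 2 h after the last
   localization; last fix outside the core tracking area; a straight final
   20 min of track (consecutive bearing changes < 90°); last fix over the sea
   heading westward (bearing in [225°, 315°]).  Tracks entering the array
   already in directed flight are excluded (take-off unobserved).  A
   95th-percentile cut-off date restricts the departed/remaining accounting
   to tags still active.

2. **When do they choose to go?**  A use-availability resource selection
   function: for every used departure time, 30 available times are sampled
   from the preceding 96 h, and a binomial GAM with logit link contrasts them
   with weights 1 (used) / 1000 (available) — the infinitely-weighted
   logistic-regression device of Fithian & Hastie.  Wind assistance (full
   drift: the along-track wind component), cloud cover (okta), 1-h pressure
   change and rain enter linearly; minutes-to-sunset and minutes-to-high-tide
   enter as penalized cubic B-spline smooths.  The RSF for a covariate is
   `exp(partial predictor)` without the intercept, min–max scaled to [0, 1];
   smooth peaks carry case-bootstrap CIs.

Because the real tracking data are not bundled, the package ships a
first-class synthetic-data generator (`knotflight.simulate`) that emulates
the study system — resident / departing / pass-through tracks with Gaussian
localization error, semidiurnal tides, autocorrelated weather, and departure
times drawn from a known selection function — so every stage is verifiable
against ground truth.

## Worked example

The `analysis/` scripts run the whole pipeline on a simulated season
(58 residents, 34 departers, 2 pass-throughs, Sep–Nov):

```bash
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_detect_departures.py
python analysis/04_annotate.py
python analysis/05_fit_rsf.py
python analysis/06_bootstrap_sensitivity.py
```

Output of steps 03–05 (seed 1):

```
34 departures classified, 60 rejections
label agreement: 94/94
95% cut-off 2019-11-17: 33 departed vs 58 remaining -> 36.3% departed
...
design: 1054 rows (34 used, 1020 available)
linear coefficients:
  wind_assist  beta=+0.251  se=0.053  p=0.000
  cloud        beta=-0.163  se=0.106  p=0.123
  d_pressure   beta=+0.329  se=0.531  p=0.535
  rain         beta=+0.056  se=0.091  p=0.536
smooth peaks (min): {'min_to_sunset': 105, 'min_to_hightide': 379}
```

Reading: every one of the 94 simulated tags is classified correctly (the
34 true departers recovered, residents and pass-throughs rejected with reason
codes).  The fitted tailwind preference (+0.25 per m/s) recovers the
generator's truth (+0.3) in sign and size; pressure and rain are correctly
non-significant.  At only 34 events the tide smooth is weakly identified —
its point peak lands away from the true −238 min and the bootstrap CI
(step 06) spans most of the tidal cycle, a small-sample caveat the
500-event recovery tests in `tests/` do not share.

The same stages are available as a CLI (`knotflight simulate|preprocess|
detect-departures|annotate|fit-rsf|report`) and as library functions.

## Layout

```
src/knotflight/      library: simulate, tracks, departures, environment,
                     rsf, io, config, pipeline, cli
analysis/            numbered drivers for the worked example (writes results/)
tests/               pytest suite incl. acceptance-level checks
scripts/acceptance.py  headline-number reproduction
docs/methods.md      model, assumptions, parameter choices, limitations
```
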