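# reeftrack

Fine-scale movement analysis for geopositioning acoustic telemetry of
reef fish.

Hyperbolic (time-difference-of-arrival) positioning arrays produce
near-continuous fix streams for tagged fish moving across a seascape of
point reefs. `reeftrack` implements the full analysis chain such studies
need:

- **Position-error calibration** — surveyed receivers are positioned by
  the system too, so their deviations from truth give an empirical map
  from the unitless per-fix precision score (HPE) to metric error:
  `2DRMS = 2 sqrt(MSE_x + MSE_y)` per 1-unit HPE bin, with an OLS line
  through the bin midpoints. Fixes above the 95th HPE percentile are
  excluded first; calibrated errors are thresholded at 10 m (movement
  analyses) or 5 m (fine-scale distance-to-reef).
- **Reef association** — nearest-reef assignment (2-D Euclidean), visit
  events (fix within 20 m of its nearest reef), reef switches
  (transitions between visit events at different reefs), average days
  per reef = days tracked / (switches + 1), "super-switcher"
  classification (< 2 days per reef), and height above bottom from a
  bathymetry raster.
- **Release-reef residency** — a native Kaplan–Meier estimator
  `S(t) = prod (1 - d_i/n_i)` with Greenwood variance and
  complementary-log-log confidence bands; departures are first visits to
  another reef or emigration from the array, other fates right-censor.
  Under exponential decay `S(t) = exp(-t R_E)`, site fidelity over an
  interval `t_SF` converts to median residency via
  `t_50 = t_SF ln(0.5)/ln(SF)`.
- **Home range** — movement-based kernel density from Brownian-bridge
  modelled steps: position at fractional time `a` in a step is normal
  with mean `(1-a) p_i + a p_{i+1}` and variance `a(1-a) dt sigma^2`
  per axis (`sigma^2 = 0.14 m^2/s`, max step delay 1500 s, 1-m cells),
  time-weighted over steps, in 2-D (bivariate kernels, areas) or 3-D
  (trivariate kernels, volumes). The home range is the smallest cell set
  holding 95% of the probability mass.
- **Covariates** — hourly model-ready tables: UTC hour, day of year,
  lunar phase (Moon−Sun ecliptic elongation / pi on a [0, 2) scale),
  nautical dawn/dusk intervals, NDBC buoy meteorology and
  receiver-logged bottom temperature.
- **Synthetic studies** — a seeded generator for seascapes (reefs with
  minimum spacing, receiver grids, sloping bathymetry), reef-attracted
  Ornstein–Uhlenbeck fish with diel activity, reef switching, and
  exponential emigration, plus a positioning-error observation layer
  whose HPE score is linearly related to true error — so the entire
  chain is testable closed-loop against known truth.

## Worked example

```python
import reeftrack as rt

study = rt.simulate_study(rt.SimConfig(seed=11, n_fish=50,
                                       study_days=90.0, truth_dt_s=30.0))

model = rt.HpeCalibration(study.receiver_fixes).fit()
print(model.summary())
```

```
HPE calibration (receiver 2DRMS regression)
--------------------------------------------
slope             0.5032  m per HPE unit
intercept         0.2105  m
HPE cutoff       27.9944  (95th pct exclusion)
R^2               0.9977
bins            27
```

The generator's observation model uses `2DRMS = 0.5 * HPE + 0.3`, so the
fitted slope/intercept recover the configured truth. Continuing:

```python
fixes = model.apply(study.positions)
kept, report = rt.filter_positions(fixes, 10.0)
print(report)

visits = rt.detect_visits(kept, study.seascape.reefs)
records = rt.build_residency_records(visits, study.fates,
                                     study.truth.release_reef,
                                     study.release_time, study.last_time)
km = rt.KaplanMeier.from_records(records).fit()
print(km.median_)
```

```
filter at 10 m: kept 1048584/1246991 (84.1%)
median residency: 3.09335 d (95% CI 1.76941-4.78884 d)
```

The median release-reef residency of ~3 days matches the configured
departure process: switching at 0.2/d plus emigration at ln2/43 per day
gives a true median of `ln 2 / 0.216 = 3.2` days, inside the estimated
CI. Home ranges come from the same filtered fixes:

```python
hr = rt.windowed_home_range(kept[kept.fish_id == "F00"], window="1D")
print(rt.median_windowed_home_range(hr))
```

```
fish_id
F00    611.5
Name: area_m2, dtype: float64
```

A command-line interface mirrors the library:
`reeftrack simulate|calibrate|filter|metrics|residency|fidelity|homerange`.

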