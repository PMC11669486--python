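# upriver

Analysis pipeline for the upriver spawning migration of radio-tracked adult
chum salmon (*Oncorhynchus keta*), built around an autumn telemetry design on
a ~157 km river: fish are tagged at a downstream weir, located daily by VHF
receiver, and scored against the thermal performance of their absolute
aerobic scope (AAS).

The package is aimed at movement ecologists and fish physiologists who need
the whole chain — from raw planar fixes to thermal-performance summaries —
as tested, reusable components:

* **River chainage** (`upriver.river`) — snap planar (UTM-like) fixes onto a
  mainstem-plus-tributaries river network and measure along-river distance
  (chainage, km upstream of release) with a tree metric.
* **Fate classification** (`upriver.fates`) — decision rules assigning each
  track to *located at spawning site* (stationary >2 days within 1 km,
  tributary entry, or tributary recapture), *censoring of tracking*
  (tracked then lost, tag-package release, main-river recapture) or *not
  located*, plus cohort summary rates.
* **Right-censored arrival estimation** (`upriver.survival`) — the
  product-limit (Kaplan–Meier) estimator with Greenwood variance and
  log-scale confidence bands, median extraction (including the undefined
  "NA" bound under heavy censoring) and the two-sample log-rank test,
  applied to both days-to-arrival and kilometres-to-arrival,

  S(t) = ∏_{tᵢ ≤ t} (1 − dᵢ/nᵢ).

* **Segmented regression** (`upriver.segmented`) — broken-stick fit
  y = β₀ + β₁x + β₂(x−ψ)₊ of last-point distance against tracking days,
  with profile search plus Muggeo refinement for the break point ψ, AIC/BIC
  comparison against a single line, and a Davies-type bound for the
  existence of the break.
* **Hierarchical trajectory model** (`upriver.trajectory`) — distance since
  migration start modelled as a penalized cubic-spline population smooth
  f(t) plus per-fish random intercepts and slopes and AR(1) within-fish
  residuals (lag-1 coefficient φ), fitted by profiled REML; supports
  population prediction with pointwise intervals and inverse
  time-to-chainage queries.
* **Thermal performance** (`upriver.thermal`) — the two-part AAS curve

  AAS(T) = S·exp(−((T−T_opt)/2σ)²) for T ≤ T_opt,
  AAS(T) = S·(1 − ((T−T_opt)/(T_opt−T_crit,max))²) for T > T_opt,

  calibrated from the published optimum and >90 % retention window
  (T_opt = 17.6 °C, window 12.8–20.8 °C), hourly exposure reconstruction,
  occupancy summaries, resting-metabolic-rate economics
  (B_RMR = a·e^{dT}) and uniform warming scenarios.
* **Synthetic data** (`upriver.synth`) — a generator reproducing the study's
  statistical structure (seasonal temperature decline with diurnal cycling,
  saturating distance–time trajectories with 6–22 km·day⁻¹ individual
  speeds, daily fixes with AR(1) positional noise, tag-package release
  after 2–10 days, logger-vs-river offsets of −0.1 ± 0.7 °C) with stored
  ground truth, so every stage is testable without field data.
* **Pipeline & CLI** (`upriver.pipeline`, `upriver` console script) —
  config-driven orchestration with a single seed, per-stage substreams and
  a run manifest that logs every exclusion.

## Worked example

```python
import upriver as u

# thermal performance curve from the published optimum and window
curve = u.calibrate_curve(17.6, 12.8, 20.8, 0.9)
print(curve.sigma, curve.T_crit_max)      # 7.3939  27.719  (°C)

# maintenance-cost change across the optimal window
cost = u.cost_metrics(u.RMRModel(), 12.8, 20.8)
print(cost.ratio_percent, cost.daily_diff_kj)   # 202.2  45.24

# synthetic 18-fish October cohort, tracked end to end
cfg = u.SynthConfig(seed=42, n_fish=18, p_signal_loss=0.0,
                    p_tag_package=0.0, p_october=1.0)
river = u.generate_river(cfg)
temps = u.generate_temperature_series([2021], cfg)
cohort = u.generate_cohort(river, temps, cfg)
fixes = u.snap_track(cohort.tracks, river)
fates = u.classify_cohort(fixes)          # 16 located, 2 censored

data = u.filter_tracking_data(fixes, fates)
fit = u.fit_trajectory_model(data)
print(fit.phi)                            # 0.564   (generated with 0.56)
print(fit.predict(10.0))                  # 105.3 km at day 10
print(fit.time_to_chainage(100.0))        # 9.22 days to 100 km

time_df, dist_df = u.censored_sample_from_fates(fates)
km = u.km_fit(time_df["value"], time_df["event"])
print(km.median())                        # median 6.0 days (95% CI 6.0–14.0)

exposure = u.reconstruct_exposure(temps, "2021-10-01 09:00", 10.0)
summary = u.exposure_summary(exposure, curve)
print(summary.prop_in_window)             # 1.000 — an early-October migrant
print(summary.prop_below_topt_in_window)  # 0.932   stays in the cold half
```

The numbers above are what these calls print: the cost of maintenance
roughly doubles (202 %) from the cold to the warm edge of the optimal
window, an extra ≈45 kJ·kg⁻¹·day⁻¹; the fitted trajectory model recovers
the generator's AR(1) coefficient (0.56) and its mean curve reaching
~100 km around day 10; and a fish departing 1 October spends essentially
its whole 10-day journey inside the aerobic-scope window, mostly on the
energetically cheaper cold side.

The same analysis runs from the shell:

```bash
upriver all --seed 1 --out runs/demo
```

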