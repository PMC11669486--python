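# Methods

This note documents the models, numerical choices and known limitations of
the `upriver` package; the README gives the user-facing overview.

## River geometry and chainage

The river is represented as a tree: one mainstem polyline (planar metres,
UTM-like; geographic conversion is out of scope and inputs must be
pre-projected) plus optional tributaries attached at known junction
chainages. Chainage is the cumulative along-channel distance in km,
upstream-positive, with 0 at the release point. A telemetry fix is snapped
to the orthogonally nearest segment over all parts (shapely's
point-to-linestring projection); ties are broken by lower part id, then
lower chainage, and a fix whose runner-up part lies within 50 m of the best
offset is flagged ambiguous, since assignment near tributary mouths is
genuinely uncertain at telemetry accuracy. Distance between two fixes is
the tree metric: absolute chainage difference on a common part, otherwise
via the junction(s). Braided channels and flow-direction inference are not
supported.

## Fate classification

Each track is classified *located* / *censoring* / *not located* with the
sub-outcomes used in the cohort summary table. "Stopped at a spawning
site" is operationalised on the terminal segment of the track: the fish is
located if every fix from some day onward stays within 1 km of the
segment's **median** chainage, the segment spans strictly more than 2 days,
and it lies more than 1 km upriver of release. The median (rather than the
first fix of the segment) is the stop-position estimate because a single
noisy fix should not break stationarity; with km-scale positional noise
this raises category agreement with generator truth from ~87 % to ~98 %.
Tributary entry or tributary recapture/tag retrieval also count as located.
Censoring requires at least three fixes including release over at least two
days, or a recapture in the main river, or a tag-package release while the
fish was still migrating. Everything else — next-day signal loss, never
leaving the release area, downstream tag recovery — is not located.
Contradictory annotations (a tributary outcome together with a downstream
recovery) are rejected with a diagnostic rather than silently resolved.

For survival analysis, located fish contribute events at their stop day and
stop chainage; censored fish contribute right-censored observations at the
last fix, except that a carcass found upriver of the last fix replaces the
censored distance (the fish demonstrably got at least that far). Not
located fish carry no usable migration record and are excluded.

Rates are printed the way cohort tables print them: recapture rate to one
decimal percent, habitat proportions to the nearest integer percent.

## Product-limit estimation and the log-rank test

The Kaplan–Meier estimator, Greenwood variance and the two-sample log-rank
test are implemented directly (the package treats them as core machinery,
with an external survival library used only as a test oracle). Ties between
an event and a censoring at the same value follow the standard convention
that events precede censorings. Confidence bands use the log (cumulative
hazard) transform, S·exp(±z·σ̂) with σ̂² = Σ d/(n(n−d)), matching the
default of the survival toolchain this design is usually analysed with; a
log-log variant is available via `ci_transform="loglog"`. The median is
the smallest value with S ≤ 0.5 and its CI bounds are the intersections of
the bands with 0.5 — under heavy late censoring the upper band never
crosses 0.5 and the bound is reported as NaN, reproducing the "NA" upper
bounds typical of small telemetry samples. The log-rank statistic sums
observed-minus-expected group-A events over distinct event values with the
hypergeometric variance, referred to χ²₁; since only the ordering of values
enters, time- and distance-to-event samples are interchangeable.

## Segmented regression and the Davies-type bound

Last-point distance vs days is fitted as y = β₀ + β₁x + β₂(x−ψ)₊. The
break point ψ is profiled: a 50-point grid between the 10th and 90th
percentiles of x, a 10× denser pass **plus the interior data points
themselves** (the SSE profile is piecewise smooth with kinks exactly at
data x values, and the minimiser frequently sits on a kink), then
Muggeo-style linearisation (working covariate −1{x>ψ}, update
ψ ← ψ + γ̂/β̂₂, max 30 iterations, tolerance 1e-8) with a keep-best guard so
the returned ψ never has larger SSE than any visited candidate. If no
interior candidate improves on the straight line the fit degenerates to
linear and is flagged. Standard errors come from the delta method on the
converged linearised design; 95 % CIs are ±1.96·SE (bootstrap CIs were
considered and left out — the symmetric normal intervals match how such
tables are usually printed). `slope2` is the second-segment slope β₁+β₂;
the raw difference β₂ is exposed as `slope_diff` because both
parameterisations appear in the literature.

AIC/BIC compare Gaussian likelihoods with 3 (line: intercept, slope,
variance) vs 5 (plus slope difference and break point) parameters.

The Davies-type test evaluates the Wald statistic for β₂ = 0 at K = 10
equally spaced interior candidates — under the null ψ does not exist, so
the supremum M of the squared statistics is referred to the bound
p ≤ P(t²_ν > M) + V·f_{t_ν}(√M)/2, where V is the total variation of the
signed statistic across candidates and f_{t_ν} is the t density with the
residual degrees of freedom. Using the t (rather than Gaussian) tail and
density keeps the bound conservative at the small n of telemetry designs
(empirically ≤ 7 % rejections at α = 5 % over 1000 null replicates, where
the Gaussian form reached 8 %). The bound is truncated at 1.

## Hierarchical trajectory model

Distance since the start of upriver migration is modelled as

d_ij = f(t_ij) + a_i + c_i·t_ij + e_ij,

with f a cubic B-spline smooth (8 interior knots by default) carrying a
second-difference penalty, (a_i, c_i) independent per-fish random
intercepts and slopes, and e_ij AR(1) within fish with coefficient φ
(correlation φ^{Δt} at a gap of Δt days). Knots are uniform and
*unclamped* (the knot vector extends three spacings beyond the domain), so
the penalty null space maps exactly onto straight lines: driving the
smoothing variance to zero provably collapses f to a line, and the basis
is defined out to 1.5× the observed time range so predictions beyond the
data are possible with honestly widening intervals.

Estimation: the smooth's wiggly part is treated as a random effect, so its
penalty weight is a variance component. The residual variance is profiled
out analytically and the REML criterion is maximised over the three log
variance ratios and φ (Fisher-z scale) jointly by Nelder-Mead, initialised
from an independent-residual fit plus the lag-1 moment autocorrelation of
its within-fish residuals. An alternating scheme that re-estimates φ from
BLUP-residual autocorrelation was implemented first and rejected: the
BLUPs absorb part of the correlated noise, the moment fixed point is
biased towards zero (on synthetic cohorts it settled at φ ≈ 0.12 where the
REML criterion itself was maximised near 0.7), and the criterion is the
better arbiter. Coefficient uncertainty uses the Bayesian posterior
covariance σ̂²(CᵀR⁻¹C + P)⁻¹ of the full penalized system, which yields
pointwise prediction intervals that widen away from the data.
`time_to_chainage` inverts the population curve on a 0.01-day grid, by
default after an isotonic (cumulative-maximum) projection — monotonicity
is not enforced in fitting itself. Information criteria for φ free vs
φ = 0 are exposed (`compare_ar_structures`); the full model-selection
ladder over random-effect structures is out of scope.

Finite-sample behaviour: with per-fish effects absorbing noise, φ̂ carries
a negative bias of order 1/T (T = fixes per fish), analogous to the
Nickell bias in panel autoregressions — about −0.1 at T = 10 under φ = 0,
and roughly offset at moderate positive φ. Parameter-recovery tests are
therefore run at the study's own scale (18 fish, daily fixes) and judge
medians across seeds, not single fits.

### Data filtering before fitting

Mirroring the field protocol: fixes after a tracking gap longer than 3
days are dropped (and everything following the gap, since re-acquired
segments no longer resolve daily speed); the initial stay at the release
site is removed, with the *last* stationary fix retained as t = 0 so the
trajectory keeps its d ≈ 0 anchor (movement began during the following
interval — a deliberate reading of "rebase to movement start", which would
otherwise leave no origin point); fish spawning in the lower basin
(< 30 km), fish whose tag surfaced there, not-located fish, and fish left
with fewer than three points are excluded, each with a recorded reason.
Two further rules matter numerically: for located fish the at-site stop
fix itself is excluded (migration ceased during the preceding interval, so
the fix — capped at the spawning site — injects a systematic kink that
inflated φ̂ by ≈ +0.3 on synthetic nulls), and a terminal stationary
segment (within 2 km of its median for more than 2 days) is truncated for
*every* fish, catching station-keeping plateaus whose fate label missed
them. Start of upriver migration is the first fix ≥ 1 km upstream of
release (configurable).

## Thermal exposure and aerobic scope

The AAS thermal performance curve is the standard two-part form: a
Gaussian limb below the optimum and an inverted-quadratic limb above,
continuous at T_opt and floored at zero above T_crit,max (the quadratic
goes negative; a scope cannot). Rather than taking S, σ and T_crit,max
from a supplementary source, the default curve is calibrated in closed
form from the printed optimum and >90 % retention window:

σ = (T_opt − lower)/(2√(−ln q)),  T_crit,max = T_opt + (upper − T_opt)/√(1−q),

giving σ = 7.3939 °C and T_crit,max = 27.719 °C for
(17.6, 12.8, 20.8, q = 0.9); S defaults to 1 so AAS is reported relative
to its maximum. The retention window inverts both limbs in closed form and
is cross-checked by bisection to 1e-6 °C at construction time.

Exposure reconstruction returns the hourly river-gauge temperatures over
[departure, departure + duration); gaps of at most 2 h are linearly
interpolated, longer gaps rejected. High-frequency body-logger records are
downsampled to hourly within-hour means ("sample" mode keeps the first
observation instead). Scenario exposure uses the fixed-gauge series for
the whole journey, justified by the small logger-vs-gauge differences; no
spatial temperature gradient is modelled.

Occupancy (time in / below / above the retention window, and the
below/above-T_opt split inside it) treats consecutive hourly samples as a
piecewise-linear temperature path and integrates band crossings exactly
along each chord. Pure sample counting at hourly resolution aliases badly
when a band edge is nearly tangent to the diurnal cycle — for a 24-h
sinusoid of amplitude 5 °C around 17.6 °C the lower window edge at 12.8 °C
sits near the nightly minimum and point counting misses the arcsine
occupancy by ~0.035, while the interpolating estimator is within 0.002 —
so interpolation is the default, with `method="sample"` available. The
five proportions partition unity by construction.

Maintenance-cost economics use B_RMR = a·e^{dT} (defaults a = 0.707
mgO₂·kg⁻¹·min⁻¹, d = 0.088 °C⁻¹) with an oxycaloric equivalent of
14.1 J·mgO₂⁻¹ and 1440-minute days: the window-edge ratio is
100·e^{d·(20.8−12.8)} ≈ 202 % and the daily difference ≈ 45.2
kJ·kg⁻¹·day⁻¹. Warming scenarios are uniform additive shifts; the RMR
increase under a shift ΔT is the closed form 100·(e^{dΔT}−1), i.e. 19.2 %
at +2 °C and 42.2 % at +4 °C.

## Synthetic-data generator

The generator defines the study conditions for every recovery test.

*River*: a gently meandering mainstem of 157 km (vertex spacing 0.5 km,
≤ 1 km always) with section boundaries at 21 km (lower/narrow) and 54 km
(narrow/middle) and two tributaries joining at 40 and 75 km.

*Temperature*: per year, hourly over 1 Oct–30 Nov,
T = 16.0 − 0.1·day + 1.0·sin(diurnal, peak 15:00) + year offset + AR(1)
noise (SD 0.3 °C, ρ 0.8), rounded to the 0.1 °C gauge resolution. Year
offsets (−0.4 … +0.9 °C for 2016–2021, warmest 2019/2021) keep
early-October daily means inside the 12.8–20.8 °C window with the crossing
below it around 1 November.

*Cohort*: departure dates fall in October with probability 0.7 (else
1–20 November); a fraction stays 1–3 days at the release site before
migrating. The latent trajectory is
d_i(t) = (D_max + b0_i)(1 − e^{−t/τ}) + b1_i·t with D_max = 160 km and
τ = 10.2 d, so the mean curve reaches ~100 km at day 10 with an initial
speed of 15.7 km·day⁻¹, the centre of the observed 6–22 km·day⁻¹ band;
b0 ~ N(0, 3 km) is kept small because all fish share a release point (the
field model's random-intercept contribution was essentially nil), b1 ~
N(0, 2.5 km·day⁻¹) carries the speed heterogeneity, initial speeds are
clipped into the band and b1 floored so latent paths stay non-decreasing
over the 20-day season. Spawning targets are month-dependent
(October N(85, 25) km, November N(45, 15) km, truncated to [15, 155]),
reflecting the earlier-run-farther-up pattern, without any claim of
fidelity to the true target distribution — which the source design does
not report. Observed positions are latent + stationary AR(1) noise
(φ = 0.56, SD 0.5 km — positional error of 0.1–0.2 km plus projection
slack) mapped back onto the river line; fates arise mechanistically from
whichever comes first of arrival (confirmed if observed stationary for
more than 2 days), scheduled tag-package release (48 % of fish, uniform
integer day 2–10), or signal loss (30 % of fish, half of losses on day 1).
Logger fish record hourly body temperature = river temperature +
N(−0.1, 0.7) °C. Every fish keeps its truth record, including the noise
series, so estimators can be scored without re-deriving anything.

What the generator does **not** emulate: sub-daily movement (holding,
diel activity), flow- or temperature-dependent speed, spatial temperature
gradients along the river, detection-probability structure, or mortality
processes. Passing recovery tests therefore demonstrates that the
estimators recover their own modelling assumptions at the study's scale —
not that those assumptions hold in any particular river.

## Problem sizes and tolerances

Tests and the acceptance script run at the study's own scale: cohorts of
18 modelled fish (or the full 48 with all fate mechanisms active), 20-seed
medians for trajectory recovery (φ within ±0.15 of 0.56, mean curve within
±10 km of 100 km at day 10), 200 random censored samples against a
brute-force product-limit oracle, 1000-replicate null calibrations for the
log-rank test (size within [0.03, 0.07]) and the Davies bound (≤ 0.07),
0.001-resolution break-point grids, 10⁵-point dense-sampling projection
oracles (agreement ≤ 1 m), and ≥ 10⁴-hour logger comparisons (±0.03 °C).
The full suite runs in a few minutes on one CPU; the acceptance script in
well under a minute.

## Known limitations

* The trajectory model's REML surface can be multimodal in φ at very small
  residual variance; two optimiser starts mitigate but do not prove global
  optimality.
* φ̂ carries the 1/T finite-sample bias discussed above; at daily tracking
  of ~1–2 weeks this is material under φ = 0 and recovery claims are
  median-across-seeds statements.
* Kaplan–Meier medians and the segmented fit are data-dependent estimates:
  on synthetic cohorts they vary with the seed, and no attempt is made to
  pin them to any particular published estimate.
* The Davies bound is an upper bound: it is conservative, and its power is
  correspondingly below that of an exact test.
* Fate classification assumes annotations are trustworthy; there is no
  modelling of detection failure vs death.
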