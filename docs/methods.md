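# Methods

## Dose model

The quantity estimated throughout is the inhaled dose (personal air
pollution exposure, PAPE) of a pollutant over a period: the time integral
of concentration multiplied by minute ventilation, `PAPE = SZ · V'm/1000`,
with `SZ` the trapezoidal aggregation of the concentration samples in
concentration·minutes and `V'm` in L/min (the 1/1000 converts to m³/min).
The aggregation refuses sampling gaps of 10 minutes or more: a trapezoid
across an unobserved gap of that size would silently invent exposure.
Doses are reported in μg for particulate matter and in mixing-ratio volume
units for gases (ppm·m³ for CO₂, ppb·m³ for tVOC); converting gas doses to
mass would need molar-volume assumptions the pipeline deliberately avoids.

Minute ventilation comes from a published power-law model in heart rate,
respiratory rate, age, sex (1 = man, 2 = woman) and forced vital capacity,
with log-linear coefficients (−8.75, 1.72, 0.611, 0.298, −0.206, 0.614).
Wrist pulse rate is used verbatim as the heart-rate input, with no
correction factor, mirroring how the wearable protocol uses its pulse
oximeter. The model is evaluated at every normalized node (3 per minute)
rather than once per segment — finer granularity avoids aggregation bias
when ventilation and concentration co-vary; a per-segment-median mode
exists for sensitivity analyses (`vm_series(per_segment_median=True)`).

The comparator Standard Method is `C_std · V'm_tab/1000 · T` with a fixed
monitoring station's daily concentration `C_std`, the sex-tabulated
ventilation for a light activity level (15.14 L/min men, 13.26 L/min
women; METs roughly 2–4, matching a protocol of brisk walking, standing
and sitting), and `T = 35 min` (seven static points of five minutes).

## Preprocessing

Environmental records (one per 24 s) are linearly resampled to 1 Hz;
linear interpolation is also the stated normalization flavour downstream,
so no higher-order scheme is introduced anywhere (and no overshoot is
possible — every interpolated value is bracketed by its neighbours).
Physiological streams (10 Hz) are block-averaged to 1 Hz first so that one
representation feeds everything downstream. Sessions are segmented on the
arrive/leave timestamps of the seven static points; windows are half-open
`[arrive, leave)` so adjacent segments never double-count a sample. Each
segment is then length-normalized onto an even grid of 3 samples per
minute covering the segment's span with both endpoints included (a
5-minute dwell → 15 nodes); the endpoint-inclusive convention is a
package decision — the protocol fixes only the 3/min density. Gaps larger
than three nominal sampling periods are logged, never silently imputed.

## Environmental factor and session dose

For each static point the 15 concentration nodes are collapsed to five
per-minute means, and the segment dose is the per-minute sum
`Σ z̄ₘ · v̄ₘ/1000 · 1 min` — the trapezoidal integral of the minute-mean
step profile over the full dwell. This makes the constant-input reduction
exact: constant concentration `c` and ventilation `v` give exactly
`c·v/1000·35 μg` per session, the same closed form as the Standard Method.
An alternative `env_factor="nodes"` mode trapezoids the node grid directly
(its span is 299 s, marginally under the nominal dwell). The session dose
`ID_NEW` sums the seven static points only: the emulated protocol collects
no physiological data during walking transits, so transit doses are
reported separately and never mixed into the headline total. CO and NO₂
never rise above the 20 ppb detection limit in the emulated campaign and
are excluded from dose tables. All arithmetic is at full precision;
2-decimal rounding happens only at report boundaries.

## Statistical comparison

`MethodComparison(id_new, id_std).fit()` returns sample means and SDs
(n−1), the mean difference and its percentage of the Standard Method mean,
a 95% t-interval on the per-participant differences oriented as
(std − new) — the orientation used in the reference report, printed with
its mirror to avoid sign confusion — a two-sided paired t-test, and the
Pearson correlation of the pairs. The location battery runs Shapiro–Wilk
per point, a Friedman test across the seven points with participants as
complete blocks, and on rejection all 21 pairwise Wilcoxon signed-rank
post hocs with Bonferroni adjustment (the post hoc family is a package
choice; the adjustment never decreases a p-value). Morning/afternoon
pairs use the Wilcoxon signed-rank test; respiratory rate across
participants uses Kruskal–Wallis.

The packaged reference dataset (20 participants, both dose columns plus
the printed inputs of the Standard Method) supports two checks: the paired
analysis reproduces its published summary statistics, and every Standard
Method dose re-derives from its own row's inputs to the printed 2-decimal
rounding.

## Synthetic sessions

The generator emulates the walking campaign's structure: seven 5-minute
static points joined by transits (6 min by default, ≈77 min per session),
environmental samples every 24 s, physiology at 10 Hz. Each channel draws
AR(1) fluctuations around its point's configured median (spreads are IQRs,
converted to Gaussian σ by 1/1.349; lag-1 coefficient 0.8 environmental,
0.95 physiological — the temporal autocorrelation is a stand-in, the
emulated study reports only medians and IQRs). Default medians follow the
published per-point summaries: indoor CO₂ ≈1010 ppm vs ≈620 ppm outdoors,
indoor tVOC high, PM low indoors and 20–26 μg/m³ outdoors. Afternoon
sessions multiply PM/tVOC by 1.35 and shift CO₂ by −40 ppm — directions
match the campaign's findings, magnitudes are configuration, not claims.
PM size fractions are ordered record-wise (pm1 ≤ pm2.5 ≤ pm10) by a
cumulative maximum; CO/NO₂ are left-censored at the 20 ppb detection limit
with explicit flag columns; GPS positions interpolate straight lines
between waypoint coordinates (sufficient for GeoJSON export, no
map-matching). Cohort profiles draw sex with probability 0.7 male (the
pilot cohort was 14/6), ages centred at 25.5 y with a 15% admixture of
30–60 y participants, sex-specific heights and weights near the cohort
medians, and FVC from a linear per-sex height/age reference — a labelled
stand-in for a full spirometry reference, overridable via its coefficient
table.

What the generator does **not** emulate: sensor drift and calibration
error, the accelerometry-to-RR derivation chain (RR is generated
directly), atmospheric dispersion, GPS noise, and real pollution's heavy
tails and plume events. Passing tests therefore demonstrate the pipeline's
arithmetic, contracts and statistical calibration under controlled
regimes — not field accuracy of any sensor.

`simulate_point_summaries` generates per-participant per-point summary
values directly (participant random effect σ=30 plus residual σ=25 around
a 620 ppm base) for Monte Carlo studies of the test battery; the
calibration suite uses it at the study's scale (20 participants, 7 points)
for 1000 null replicates and 100 replicates with the +390 ppm indoor CO₂
offset observed between the laboratory and the street.

## Numerical and design choices

- All randomness flows through `numpy.random.Generator` with explicit
  seeds; identical (profile, config, seed) triples are byte-identical
  end-to-end, and the pipeline manifest records seed, config hash and
  SHA-256 of every output.
- Interpolated values never overshoot their bracketing inputs (linear
  everywhere); length normalization conserves the trapezoidal integral of
  smooth signals to within 2%.
- The statsmodels-style Model/Results split is applied where estimation
  actually happens (the paired comparison); the deterministic pipeline
  stages are plain functions over typed containers.
- Degenerate inputs fail fast with named locations: single-record streams,
  non-monotone timestamps, PM-ordering violations on load, plan intervals
  outside the stream span, incomplete Friedman blocks, non-positive
  ventilation inputs.

## Limitations

- The ventilation model is used, not re-fitted; its published error
  (median ≈1.2%, wide IQR) propagates into every personalized dose.
- Gas doses remain in volume units; no deposition or uptake modelling.
- The Standard Method comparator inherits the fixed station's single daily
  value; day-to-day station variability is an input, not a model output.
- Transit (dynamic) doses are computed for concentrations only and are not
  part of the headline totals, because the emulated protocol has no
  physiology while walking.
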