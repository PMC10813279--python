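# Methods

This note documents the models implemented in `circalight`, their default
parameters, the design choices made where conventions diverge, and what the
synthetic-data tests do and do not demonstrate about real recordings.

## Data model

The unit of analysis is an `EpochSeries`: equally spaced, timezone-naive
1-min epochs with channels for activity (PIM counts), wrist temperature
(°C), illuminance (lx) and blue-light irradiance (μW/cm²), plus a per-epoch
validity mask and optional diary events. Timestamps are local clock time
throughout because every output of interest (acrophases, onsets, exposure
windows) is a clock time; recording weeks are assumed not to cross DST
transitions. Masked epochs are excluded from every mean and variance; gaps
in the input grid are filled with masked epochs so spacing stays uniform.
Non-wear is **not** inferred — only explicit mask columns or grid gaps
create masks, matching field protocols where diaries are used to clean data.

Daily profiles are 48 clock-aligned 30-min bins. Binning is
pool-then-mean by default (all unmasked epochs of all days pooled per bin),
which is robust to partial days; per-day-first averaging is a switch.
Log-transformed exposure uses `log10(max(x, floor))` with floor
0.01 μW/cm² — below the lowest hygiene threshold (0.1), so the floor only
rescues device zeros and cannot shift any value in the analysed range.

## Cosinor

Single-component, fixed 24-h period, fitted by OLS in the linearised form
`M + β·cos(ωt) + γ·sin(ωt)`; amplitude `A = √(β²+γ²)`, acrophase reported as
the clock time of the fitted peak (`atan2(γ, β)/ω mod 24`), which matches
how actigraphy software prints phases (hh:mm) rather than negative degrees.
The zero-amplitude test is the F statistic
`((SSE₀−SSE₁)/2)/(SSE₁/(n−3))` against the intercept-only model. Degenerate
constant input returns amplitude 0 with p = 1 by convention. Requirements:
≥ 4 points spanning more than half a period. Multi-component and
non-24-h-period fits are out of scope.

## Non-parametric indices

IS and IV follow the classical definitions on hourly means
(`IS = N·Σ_h(x̄_h−x̄)²/(24·Σ_i(x_i−x̄)²)`,
`IV = N·Σ(Δx)²/((N−1)·Σ(x_i−x̄)²)`); a raw-epoch basis is available behind a
flag but hourly is the field default and the one used everywhere here.
Hours with no unmasked epoch are dropped and IV differences then span the
gap — adequate for short masked stretches, biased for long ones. M10/L5 are
found by exhaustive sliding-window search (10 h / 5 h) over the wrap-around
mean daily profile at epoch resolution, ties broken to the earliest clock
onset, which makes the reported hh:mm onsets deterministic. Zero-variance
input raises an explicit error rather than propagating NaN. CFI is the mean
of IS, `(2−IV)/2` clipped to [0, 1], and RA; RA is defined as 0 when
M10 + L5 = 0. Whether M10/L5 should be computed per day and averaged is
genuinely open in the literature; the mean-profile convention is the default
and the per-day path can be built from the per-day profile helper.

## Sleep scoring

The per-minute discriminant uses the published 1-min-epoch weight set
(106, 54, 58, 76, 230, 74, 67; factor 0.001; sleep iff D < 1) with
zero-padding at the boundaries. Raw PIM counts are device-scaled by a
`scale` parameter (default 1000) because the discriminant's coefficients
presume counts of a particular magnitude and no public calibration exists
for this device class; the default is chosen so that the synthetic
generator's wake-level activity scores wake and its sleep-level activity
scores sleep. Webster-style wake rescoring exists behind a flag but is off
by default. Nights are diary-anchored; sleep onset is the first run of ≥ 5
consecutive sleep minutes (configurable), and TST/WASO are counted on
[onset, waketime) so that TST + WASO equals that span exactly. Sleep phase
is the clock midpoint of bedtime and waketime, the convention consistent
with how group means of bedtime/waketime and sleep phase relate in published
cohort tables. A night with no qualifying sleep run is returned with an
explicit `scorable=False` status, never as zeros.

## Light hygiene

The mEDI conversion is the scalar D65 relation 1 lx mEDI = 1.3262 mW/m² =
0.13262 μW/cm² of melanopic irradiance. Full spectral CIE S 026 computation
is out of scope. The consensus anchors 250 / 10 / 1 lx convert to 33.155 /
1.3262 / 0.13262 μW/cm²; the **reference curve uses the conventionally
printed values 33 / 1.33 / 0.1** so that the indices are anchored to the
published thresholds, while the conversion functions return exact values.

The reference curve is an explicit reconstruction — recommendation documents
specify thresholds, not a 24-h waveform — assembled from configurable
segments: a daytime half-sine arc `P·sin(π(t−6)/14)` on [06:00, 20:00) with
`P = 33/sin(3π/14) ≈ 52.93` chosen so the arc crosses the 33 μW/cm² daytime
target at 09:00 and 17:00; a cosine evening ramp from the 1.33 pre-bed
ceiling at 20:00 to the 0.1 sleep plateau at 23:00; the plateau until 05:00;
and a cosine morning ramp back to the day arc. A pure half-sine would fall
to zero at 06:00 and 20:00, which would make the curve discontinuous against
the evening ramp and drop it below the sleep plateau; the day arc is
therefore clipped from below at the pre-bed ceiling, the minimal change that
keeps the template continuous, everywhere ≥ the sleep plateau, and equal to
the pre-bed ceiling at the start of the night window. A flat-day
(`plateau`) preset ships as a named alternative.

NEI/DDI integrate the participant's 48-bin mean profile against the curve by
rectangle quadrature — bin width 0.5 h, reference evaluated at bin midpoints
— over 20:00–05:00 (18 bins, wrapping midnight, half-open at 05:00) and
06:00–20:00 (28 bins) respectively. Rectangle quadrature is exact for the
data (already bin means); the only discretization error comes from curve
curvature within a bin, bounded by max-slope × bin-width and verified
against a 1-second quadrature oracle in the tests. Missing bins contribute
zero and are reported, never imputed. Indices default to the mean-profile
mode; per-day computation with averaging is available.

## Association layer

Per-bin association is Pearson r between the outcome and the binned
log10-floored blue exposure across participants (for a single predictor,
linear-regression slope and r carry identical information up to scale;
Spearman is available behind a flag). p-values use the t transform with
n−2 df; bins with fewer than 4 complete pairs are flagged not evaluable.
BH-FDR at q = 0.1 is applied within the 48-bin family only. The r(t) course
is summarised by the same cosinor machinery, giving the clock time of
strongest association and a zero-amplitude test.

Group CI windows use per-group t-based CIs on bin means (each group's own
variance, no pooling); the window is the maximal circular run of bins with
disjoint CIs, ties broken to the earliest start scanning clockwise from
12:00 so evening windows crossing midnight stay contiguous. The threshold
curve reported inside the window is the upper CI bound of the lower-mean
group. `compare_correlations` implements the independent-groups Fisher z
test only (the genotype strata are independent samples). Note: applying the
standard formula to the printed stratum correlations (−0.659 with n = 22 vs
0.049 with n = 28) gives z ≈ −2.76; published software sometimes reports
slightly different values when fed unrounded inputs. The adjusted
association wrapper is routine OLS on z-scored outcome/predictor with
dummy-coded covariates; it reproduces table structure, not a novel method.

## Synthetic cohort

The generator emulates the structure of a week-long, 1-min Arctic
actigraphy study at the spring equinox. Defaults are anchored to printed
cohort statistics: wrist-temperature MESOR 31.99 °C, amplitude 1.4 °C,
acrophase 02:45; bedtime 22:35 and waketime 06:51 with 0.9 h between-subject
and 0.25 h nightly SD; BMI 24.2 ± 4.6 kg/m²; 82% female; 39% native
population; G-allele carrier frequency 0.44. Photoperiod comes from the
standard solar-declination formula with a −0.833° horizon (latitude 66.9°,
day-of-year 80 by default), returning polar-day/night sentinels above the
polar circle.

Blue light is a daylight half-sine envelope scaled by an individual
lognormal midday peak (median 25 μW/cm²), plus lognormal indoor evening
light while awake, plus a planted evening excess
`β·(BMI−25)·w(t)` with `w` a raised cosine peaking at 23:30 (half-width
2.5 h), optionally restricted to G-allele carriers; the total is truncated
at zero. β defaults to 0.08 μW/cm² per BMI unit, derived from the printed
NEI–BMI correlation (r ≈ 0.42 with NEI SD ≈ 2.2 and BMI SD 4.6 implies a
slope ≈ 0.2 μW/cm²·h per BMI unit, which the 2.5-h weight integral converts
to ≈ 0.08 at the irradiance level). Activity is a diurnal wake level with
hour-to-hour lognormal modulation (which produces realistic IS ≈ 0.56 and
IV ≈ 1.0), near-zero sleep activity, and Poisson-placed nocturnal wake
bouts whose spikes the sleep scorer picks up as WASO. Wrist temperature is
a cosinor with a carrier-specific MESOR slope on BMI (−0.05 °C per unit,
matching the printed correlation through the same SD argument). Leptin and
cortisol are linear models on BMI and the participant's *realized* WASO,
DDI and blue-light M10 onset, with Gaussian noise — so the hormone
associations flow through the actual analysis pipeline, not through stored
covariates. (The generated leptin–WASO association is positive, following
the textual description of that association; distributional forms are
simulator choices, declared not measured.)

What the synthetic tests show: that every estimator recovers what this
generative model plants, at calibrated error rates. What they do not show:
robustness to device artifacts, non-wear, irregular schedules, shift work,
seasonal light regimes other than the configured photoperiod, or any
physiological feedback between sleep, light and metabolism — the generator
is first-order by design.

## Problem sizes and numerical choices

Tests and the acceptance script use: 7 d × 1-min series for recovery checks;
1000 hourly-resolution white-noise replicates for F-test calibration (band
3.5–6.5% at α = 0.05); 200 replicates for the IV benchmark (2 ± 0.3); 100
replicates at n = 200 participants (profile-level generation) for r-chart
planted-effect recovery (acrophase within ±30 min of 23:30, power ≥ 90%)
and for the stratified carrier/non-carrier check; 200–300 replicates at
n = 60 for null calibration; and a 5-participant, 2-day cohort for the
byte-identical determinism contract. Profile-level planting is used for the
replicated r-chart checks because they exercise the statistical layer;
minute-level planted effects are verified separately on single cohort
realizations. The end-to-end cohort runs use 40 participants × 7 days.

All randomness is routed through `numpy.random.Generator` seeded from a
single integer (`SeedSequence.spawn` for substreams). Ties in window
searches break to the earliest clock time; equality thresholds use absolute
tolerances around 1e-12 relative to data scale; SVG output is stripped of
dates and hashed deterministically so identical runs are byte-identical.

## Known limitations

- The reference-curve waveform between the anchor thresholds is a
  reconstruction; published index values computed with a different waveform
  would differ by a smooth-shape term even at identical anchors.
- IS/IV on gappy data treat dropped hours as adjacent.
- The Cole-family scale parameter is device-specific and uncalibrated
  against polysomnography here.
- The CI-window detector assumes approximately normal bin means within
  groups; heavy-tailed exposure distributions (lognormal evening light)
  make the log10 transform advisable, and the pipeline applies it.
- Cohort-level values printed in the source study (group means, specific
  correlations) are not reproducible without the original non-public data;
  the package reproduces the *methods* and validates them on planted truth.
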