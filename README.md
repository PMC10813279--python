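# circalight

Circadian rhythmometry, actigraphic sleep scoring and **blue-light hygiene
indices** for epoch-level wrist-wearable data, with a time-resolved
correlation layer linking light exposure to metabolic outcomes.

The package targets studies in which participants wear a multichannel
actigraph (motor activity in PIM counts, wrist skin temperature, illuminance
and blue-light irradiance at 1-min epochs) for about a week, and the analysis
asks *when* in the day light exposure relates to markers such as BMI, leptin
or cortisol. Because field cohorts of this kind are rarely public, a
first-class synthetic-cohort generator with planted ground truth ships with
the package, so every stage of the pipeline is testable end to end.

## What it computes

**Parametric rhythm metrics.** Fixed-period single-component cosinor
`y(t) = M + A·cos(2πt/τ − φ)` per channel: MESOR `M`, amplitude `A`,
acrophase as the clock time of the fitted peak, and a zero-amplitude F-test
with (2, n−3) degrees of freedom.

**Non-parametric metrics.** Inter-daily stability (IS), intra-daily
variability (IV) on hourly means, M10/L5 window means with onsets by
exhaustive wrap-around search at epoch resolution, relative amplitude
RA = (M10−L5)/(M10+L5), and the circadian function index
CFI = (IS + clip((2−IV)/2) + RA)/3.

**Sleep.** Per-minute sleep/wake scoring with the classical 7-epoch weighted
window (weights 106, 54, 58, 76, 230, 74, 67; sleep iff D < 1) inside
diary-anchored rest intervals; per-night bedtime, wake time, time in bed,
sleep onset/latency, total sleep time, efficiency, WASO and sleep phase
(clock midpoint of bedtime and waketime).

**Light hygiene.** The melanopic-EDI conversion (1 lx mEDI ↔ 0.13262 μW/cm²
under D65, so the consensus recommendations 250 / 10 / 1 lx map to ≈33 /
1.33 / 0.1 μW/cm²), a continuous recommendation-anchored 24-h reference
curve, and the two scalar indices integrated against it:

- `DDI_bl` — daytime deficit: area of exposure *below* the curve, 06:00–20:00;
- `NEI_bl` — nocturnal excess: area *above* the curve, 20:00–05:00;

both in μW/cm²·h over the participant's 48-bin (30-min) mean daily profile.

**Association layer.** Per-bin Pearson correlation of an outcome with binned
log10 blue-light exposure ("r-chart"), Benjamini–Hochberg FDR at q = 0.1
across the 48-bin family, a cosinor fit to r(t) locating the clock time of
strongest association, detection of the maximal clock window where two
groups' 95% CIs separate, genotype-stratified r-charts, the Fisher z test
for comparing independent correlations, and a covariate-adjusted OLS wrapper.

## Worked example

```bash
python analysis/04_time_resolved_association.py --seed 1 --n 40
```

simulates a 40-participant cohort in which higher-BMI MTNR1B G-allele
carriers receive extra evening blue light peaking at 23:30, runs the full
pipeline and prints:

```
BMI r-chart: acrophase 00:15, zero-amplitude p = 0.0000, 9 bins FDR-significant
BMI-group CI window: 22.5 h → 2.0 h (7 bins)
NEI–BMI in G-carriers: r = 0.766 (n=22); non-carriers: r = 0.564 (n=18); Fisher z = 1.08, p = 0.282
```

Reading: the cosinor fit to the 48 per-bin correlations places the strongest
BMI–exposure association just after midnight, within ~45 min of the planted
23:30 peak at this cohort size; the 95% CIs of the BMI<25 and BMI≥25 groups
separate from 22:30 to 02:00; the carrier-stratum correlation is recovered,
while the non-carrier value and the carrier/non-carrier contrast reflect a
single small-n realization (the null stratum averages r ≈ 0 and the
calibrated behaviour over replicates is asserted in
`tests/test_acceptance.py`).

The other drivers (`analysis/01…03`) generate the cohort, the per-participant
index table (`results/participant_indices.csv`) and the light-hygiene
summaries. Programmatic use:

```python
from circalight import (SimConfig, simulate_cohort, fit_cosinor,
                        nonparametric_indices, ReferenceCurve,
                        bin_daily_profile, light_indices)

cohort = simulate_cohort(SimConfig(n_participants=10, seed=1))
series, meta = cohort.participants[0]
print(fit_cosinor(series, "wrist_temp"))
prof = bin_daily_profile(series, "blue")
print(light_indices(prof, ReferenceCurve()))
```

There is also a CLI: `circalight run --n 20 --seed 1 --out runs/demo`.

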