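# synseed

Quantification toolkit for α-synuclein (α-SYN) seeding studies in
neurodegeneration research: scoring of RT-QuIC seeded-amplification assays,
bespoke fluorescence-microscopy measurements, ordinal cohort statistics, and
size-exclusion chromatography (SEC) fraction profiling — plus synthetic-data
generators with exact ground truth so every stage can be validated without
any external dataset.

## Who this is for

Labs using real-time quaking-induced conversion (RT-QuIC) to measure the
seeding activity of misfolded α-SYN in brain lysates or biofluids, and
analysts correlating those readouts with neuropathology covariates (Braak
stage, Thal phase, CAA score, APOE4 allele count) across autopsy cohorts.

## The quantities at the core

**Kinetic scoring.** Each well of a plate run yields a thioflavin-T (ThT)
fluorescence time series F(t) sampled every 30 min over 60 h. The plate
threshold pools the first 10 cycles of all wells:

    threshold = mean(pool) + 25 · SD(pool)

Per well, `t_cross` is the earliest grid time with F(t) ≥ threshold, the
protein aggregation rate is `PAR = 1 / t_cross` (1/h, 0 if no crossing), and
`MaxFL` is the mean fluorescence over the last 10 cycles (the plateau). A
biological sample is the mean of its replicate wells and is positive when at
least half its replicates crossed. Batch reproducibility is summarized as
CV% = 100·SD/mean, intra- and inter-batch.

**Image quantification.** FRET-positive α-SYN inclusions are segmented by
thresholding, morphological closing with a 10-px square element, and
8-connected labelling, keeping regions with eccentricity < 0.8 and area in
[4, 1000] px; region intensity is the raw pixel sum. Neurite length per
nucleus passes both channels through the contrast filter
`z = tanh(m(x − b) + 0.5)` (m = 2, b = 0.4 on the TUJ1 channel), detects
nuclei by erosion + size-filtered components, subtracts the dilated nuclei
from the binarized neurite channel, skeletonizes, and divides total skeleton
length by the nucleus count.

**Cohort statistics.** Analyte levels (α-SYN, tau, Aβ40, Aβ42, APOE in
TBS/TBSX/FA extraction fractions) enter covariate-adjusted linear models on
identity/√/log scales. Skewed RT-QuIC outcomes are ordinalized at data
percentiles (PAR: 50/75th → 3 levels; MaxFL: 25/50/75th → 4 levels) and fit
with proportional-odds logistic regression
P(Y ≤ j | x) = logistic(α_j − βᵀx), reporting OR = exp(β) with Wald 95% CIs.
Bonferroni families give per-test thresholds (e.g. 12 tests → 0.0042,
16 tests → 0.0031). Group comparisons dispatch Mann–Whitney U /
Kruskal–Wallis for n > 8 per group and t test / one-way ANOVA otherwise.

**SEC profiling.** Per-fraction amounts over the collected range (#18–#56,
0.8 ml/fraction) are converted to percent-of-total, peaks are interior local
maxima (plateaus reported at their lowest fraction), and apparent molecular
weight is interpolated log-linearly between calibration markers.

## Worked example

```python
from synseed import simulate, kinetics

presets = [simulate.DEFAULT_PRESETS[k]
           for k in ("AD/APOE4-", "AD+LB/APOE4-", "control/APOE4-")]
plate, truth = simulate.simulate_plate(presets, samples_per_group=3, rng_seed=42)
well_df, sample_df = kinetics.score_plate(plate)

print(round(well_df["threshold"].iloc[0], 1))
print(sample_df.groupby("group")[["PAR_mean_per_h", "MaxFL_mean_AU"]].mean().round(4))
```

prints

```
20150.2
                PAR_mean_per_h  MaxFL_mean_AU
group
AD+LB/APOE4-            0.0714    170656.0284
AD/APOE4-               0.0352     83518.4665
control/APOE4-          0.0000      9975.8525
```

The threshold (20 150 AU) is the pooled 10-cycle baseline mean (~10 000 AU)
plus 25 standard deviations of read noise. Lewy-body co-pathology curves
cross roughly twice as fast as pure-AD curves (PAR 0.071 vs 0.035 per hour,
i.e. ~14 h vs ~28 h to threshold) and plateau twice as high, while flat
controls never cross (PAR 0) and stay at the optical baseline.

The same pipelines are scriptable from the shell:

```bash
synseed simulate curves --seed 42 --out run/
synseed rtquic score --curves run/plate.csv --layout run/layout.csv --out scored/
synseed images neurites --red red.tif --blue blue.tif --out neur/
synseed sec profile --table sec.csv --calibration cal.csv --out secout/
```

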