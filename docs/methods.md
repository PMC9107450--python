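# Methods

## Kinetic-curve model and scoring

Seeded-amplification curves are modelled as a four-parameter logistic

    F(t) = baseline + amplitude / (1 + exp(−k·(t − t50))) + ε,   ε ~ N(0, σ²)

on the plate-reader grid t = 0, 0.5, …, 59.5 h (120 cycles of 30 min).
The logistic is a modelling convenience, not a claim about ThT aggregation
kinetics: it has two interpretable shape parameters (t50 locates the lag,
amplitude the plateau) and both scoring statistics depend only on threshold
crossing and plateau level, which any sigmoid reproduces. Alternative forms
can be substituted by generating series externally and wrapping them in a
`PlateRun`.

Scoring choices:

- **Threshold pool.** One threshold per run: all wells' first 10 cycles are
  pooled and the threshold is pool mean + 25 sample SD (ddof = 1). A
  zero-variance pool is legal (threshold = mean). Runs spanning several
  physical plates (built with `multi_plate=True`) are treated as one run and
  pool across plates.
- **Crossing resolution.** `t_cross` is the first on-grid time with
  F ≥ threshold; the 0.5 h cycle is the assay's native resolution, so no
  interpolation by default (a linear-interpolation flag exists but is off).
- **Negative wells** carry PAR = 0 rather than a missing value so that
  sample averaging is defined and negatives plot at zero rate; the
  alternative (`negative_par="exclude"`) averages crossing wells only.
- **Invalid baselines.** A well at or above threshold at the first cycle is
  flagged and excluded from sample aggregation — it contributes no kinetics,
  only a warning. A sample with only invalid wells is marked unevaluable.
- **Sample positivity** requires at least half of the valid replicates to
  cross; a tie at exactly half counts as positive.
- **CV%** uses the sample SD over the mean; a zero mean yields an undefined
  CV reported as absent (negative controls with near-zero signal produce
  legitimately huge CVs — an expected property, asserted in tests, not an
  error).

## Image quantification

Both measurements operate on single 2-D 8-bit channels (floats on the same
0–255 scale are accepted).

**Contrast filter.** Min–max rescale to [0,1], linear map y = m(x−b)+0.5,
tanh, then min–max renormalization to [0,255]. The map is strictly monotone
before renormalization, so segmentation thresholds see the same pixel
ordering. Defaults m = 2, b = 0.4 (the neurite-channel setting). A constant
image has a degenerate rescale and maps to zeros with a warning.

**Inclusions.** Binarize (Otsu by default — parameter-free and standard; a
fixed level can be supplied when acquisition settings are constant), close
with a `close_width`×`close_width` square element (default 10), label with
8-connectivity, and keep regions with eccentricity < 0.8 (from the
same-second-moments ellipse) and area in [4, 1000] px, both bounds
inclusive. "Width 10 pixels" is read as a 10×10 element. Region intensity is
summed over the *raw* image so the filter chain never alters reported
intensities.

**Nuclei.** Grey-scale erosion (square element, default width 3), threshold,
and components of ≥ 50 px (both config-exposed; the source protocol states
neither). Touching nuclei merge — no watershed splitting — so counts are
exact only for separated nuclei, which the synthetic scenes guarantee.

**Neurites.** The dilated nucleus mask (default width 5) is subtracted from
the binarized neurite channel before skeletonization. Skeleton length
supports two conventions: `pixel` (default; one unit per skeleton pixel,
the plain summation) and `geodesic` (orthogonal steps 1, diagonal steps √2).
The pixel count under-measures oblique structures — a 45° line of Euclidean
length √2·N contains only N+1 pixels, a ~29% shortfall — so all comparisons
against Euclidean ground truth use the geodesic mode, and users measuring
curved neurites should prefer it; the pixel mode is retained as the simplest
convention and for backward comparability.

**Inclusion-positive cells.** No cell-body segmentation is performed; a
nucleus is called inclusion-positive when a kept inclusion centroid lies
within a configurable radius (default 20 px) of the nucleus centroid. This
proximity rule is a stated stand-in for whatever cell delineation a given
lab uses.

## Cohort statistics

- **Transforms**: identity, square root, natural log, with domain checks
  that name offending rows; inverses provided for report back-transformation.
  The per-variable assignment is configuration (default: √ for α-SYN
  outcomes, identity elsewhere).
- **Ordinalization** computes quantiles on the analysis set itself with the
  linear-interpolation convention (numpy default); other conventions shift
  level boundaries, which is why the choice is pinned and documented. Level
  j covers (q_{j−1}, q_j]; a value tied with a cutpoint falls to the lower
  level. PAR → 3 levels at the 50/75th percentiles; MaxFL → 4 levels at the
  25/50/75th.
- **Linear models** are OLS with Wald 95% CIs; rank-deficient designs are
  rejected with the most collinear column pair named.
- **Proportional-odds models** maximize the cumulative-logit likelihood
  P(Y ≤ j|x) = logistic(α_j − βᵀx) (statsmodels `OrderedModel`, BFGS);
  OR = exp(β); Wald CIs from the observed information. Wald (not profile)
  intervals match the symmetric ±1.96·SE style of the reporting format.
  Convergence failures are surfaced on the fit object. In tests the fit is
  cross-checked against an independent hand-written likelihood maximized by
  Nelder–Mead, to 1e-4 on the coefficient.
- **Bonferroni families**: per-test level α/m, rounded to 4 decimals for
  table annotation (12 tests → 0.0042, 16 → 0.0031).
- **Group comparisons** are two-sided throughout and dispatch on the
  smallest group: n ≤ 8 uses t test / one-way ANOVA (rank tests are
  underpowered there), larger groups use Mann–Whitney U / Kruskal–Wallis.
  Post-hoc pairwise decomposition (Dunn, Sidak) is out of scope; the family
  correction is Bonferroni via `m_tests`.

## SEC profiling

Percent-of-total is computed over the collected fraction range only
(matching the denominator of the plotted profiles) and is invariant to
rescaling raw amounts. Peaks are interior strict local maxima within a
±`window` neighbourhood; plateaus are reported once at their lowest
fraction; endpoints are never peaks. Molecular weight is interpolated
linearly in log10(kDa) against fraction index, and queries outside the
marker range are refused rather than extrapolated. Group comparison of
replicate profiles always runs on the percent scale, per fraction, with a
Bonferroni family across fractions by default.

## Synthetic-data generators: what they emulate, and what they do not

All generators are deterministic under a seed (NumPy `default_rng`).

- **Plates**: group presets encode the qualitative structure of brain-lysate
  assays — controls flat at an optical baseline of 10 000 AU with 400 AU
  read noise; Lewy-body co-pathology earlier (t50 ≈ 16–18 h) and higher
  (150 000–200 000 AU) than pure AD (t50 ≈ 34–35 h, ~80 000–90 000 AU);
  APOE4 carriage raising the plateau within seeding-positive groups.
  Replicate wells share a sample's drawn parameters and differ only in read
  noise. Not emulated: drifting baselines, mid-run evaporation artifacts,
  multi-phasic curves, or cross-well contamination — so passing tests show
  the scoring arithmetic is right, not that real plates are this clean.
- **Cohorts**: covariates use plausible autopsy-cohort marginals (age
  uniform 55–100, sex Bernoulli(½), CAA 0–4, Braak concentrated at IV–VI,
  Thal at 4–5, APOE4 count 0–2); outcomes come from the exact
  cumulative-logit model the estimator assumes, which is the point — the
  coverage experiment (200 cohorts, n = 500, β = 0.8) validates the
  estimator, not the model's fit to real brains.
- **Scenes**: hard-rasterized geometry (inclusive-distance disks, 1-px
  Bresenham polylines, no anti-aliasing) with additive Gaussian noise and
  8-bit clipping after noise. Objects are spaced so a 10-px closing cannot
  merge them. Not emulated: out-of-focus blur, uneven illumination,
  overlapping cells, true fiber morphology.
- **SEC**: Gaussian mixtures over the fraction index, clipped at zero.

## Validation problem sizes

Rendered-scene recovery uses 50 scenes of 300×300 px (25 inclusion scenes,
25 neurite scenes); the kinetics oracle uses 100 random noiseless wells on
the 120-cycle grid; the ordinal coverage experiment uses 200 cohorts of
n = 500; the end-to-end positivity experiment uses 43 samples × 3 wells.
These sizes give stable pass/fail behaviour while keeping the default suite
fast on a single CPU.

## Known limitations

- No kinetic model fitting (rate constants, lag-phase models): scoring is
  exactly threshold, PAR and MaxFL.
- No watershed nucleus splitting, 3-D stacks, or spectral unmixing.
- No chromatogram deconvolution or peak-area fitting for SEC.
- The proportional-odds fit assumes a common slope across thresholds
  (no test of the proportionality assumption is provided).
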