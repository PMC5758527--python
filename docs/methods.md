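# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `pearlclim`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Morphometric indices and population aggregation

The convexity index is SCI = 100·W/L; the integrated variant is
SCI_I = 100·W/√(π·L·H), taking the sagittal area as π·L·H. A true ellipse
area would carry a factor ¼; omitting it only rescales the index by the
constant 2, and the conventional form is kept so the two indices satisfy the
exact identity SCI_I = SCI·√(L/(π·H)), which the property tests assert.

Shells shorter than 50 mm are excluded before any aggregation, to suppress
ontogenetic (juvenile allometry) effects; the boundary L = 50 mm is
retained (strict-less exclusion). Populations are aggregated as the
arithmetic mean of per-shell indices — not the index of mean dimensions,
which differs whenever shells are not proportional — with
s.e.m. = sd(ddof=1)/√n, undefined for n = 1. Sample-size floors (≥ 11
shells for recent samples, ≥ 5 for museum/historical ones) flag rather than
drop populations; flagged samples are excluded from inter-population
inference only. Collections from 1950 onward count as "recent". Lowland
sub-analyses take altitude < 200 m, mountain > 300 m; the 200–300 m band
belongs to neither.

## Population-level statistics

Group comparisons of population mean SCI use the pooled-variance Student
t-test (df = n₁+n₂−2), matching the degrees of freedom convention of the
original analysis. Normality is checked with a Lilliefors-corrected
Kolmogorov–Smirnov test whose p-value is Monte-Carlo: 10⁴ null samples at
the observed n (seeded, cached per n), with the +1 continuity correction —
closed-form Lilliefors p approximations are only approximate, and the null
table is exact up to Monte-Carlo error. The statistic itself is
cross-checked against `statsmodels`' implementation in a test.

The width ANCOVA fits mean width ~ mean length × group on population means
with Sum (effects) coding and Type III sums of squares, then simplifies to
the minimal adequate model by sequential exclusion at α = 0.05 — the
interaction first, then the least significant main effect, refitting after
each removal. Populations are unweighted (whether the original models
weighted by sample size is unstated; unweighted is assumed). The
separate-slopes model compares period-specific lines of mean SCI on
latitude against a single common line by an F-test with 2 numerator degrees
of freedom; it is implemented with explicit design matrices (numpy least
squares) because null-uniformity and power tests run it hundreds of times.

## Climate predictors

The grid is CRU-TS-like: regular 0.5° cells, monthly mean air temperature
in °C, consecutive calendar years; readers exist for long-format CSV and
NetCDF (scipy engine, netCDF3-classic). Point-to-cell lookup uses half-open
cell bounds [south, north) × [west, east): points exactly on an edge belong
to the north/east neighbour.

Summer is June–August (boreal convention; the source analysis does not list
months). MST_k averages the summer months of the k calendar years strictly
before the collection year — the collection year itself is excluded, since
shell material laid down in the collection season cannot yet reflect that
summer. Winter for a window year y spans December of y−1 through February
of y, so the seasonal battery needs one extra lead-in December. Degree-day
quantities use the monthly approximation: a month whose mean exceeds the
base contributes (T−base)·days (effective temperature sum) or its day count
(growing-season length). February is always 28 days; the leap-year bias is
below 0.1% and the convention is deterministic. Missing grid months
propagate as missing site values with an explicit reason — never silently
interpolated.

## Calibration, validation, spatial checks

Both calibrations are ordinary least squares with n ≥ 5 and a non-constant
predictor, reporting Pearson r, F(1, n−2) = t² of the slope, two-sided p
and residual sd. Predictor selection ranks the candidate battery by |r|
against mean SCI, breaking ties alphabetically and excluding constant or
all-missing candidates.

Cross-validation uses a seeded uniform random partition into k = 5
near-equal folds (remainders spread one per fold); each fold is predicted
from the line fitted on the others. Accuracy measures, per fold and pooled
over all held-out points: MAPE = mean(|ŷ−y|/y)·100; Tofallis's relative
accuracy measure, implemented as the mean absolute natural-log accuracy
ratio mean(|ln(ŷ/y)|) (the cited measure is log-ratio based and this form
matches the reported magnitude ≤ 0.04); min-max accuracy =
mean(min(y,ŷ)/max(y,ŷ)). With k = n the procedure is leave-one-out and
partition-independent, which a test asserts.

Moran's I uses inverse great-circle-distance weights w_ij = 1/d_ij (km,
haversine), unstandardized — the default of the GIS environment the
original analysis ran in. Pair distances are floored at 1 km so duplicate
coordinates cannot produce infinite weights (with a warning). The
expectation is −1/(n−1); variance and z follow the normality assumption;
the reported p is two-sided normal. The normal approximation's tail
probabilities agree with a permutation oracle to about ±0.02 on average at
n = 49 (the acceptance test measures this); individual null datasets can
deviate by up to ~0.05 because the exact permutation null is mildly skewed,
with skewness depending on the kurtosis of the values — a limitation of the
normality assumption itself, shared by any implementation of it.

Outlier handling exposes both mechanisms used in practice: an explicit
identifier exclusion list (always removed — this is how the six
anomalous-by-local-topography mountain samples are reproduced), and
automatic flagging at |externally studentized residual| > 2.5, which only
removes when auto-exclusion is requested. The threshold 2.5 is a common
convention; the original analysis states none.

## Growth

Ring series are cumulative lengths at successive annual rings, strictly
increasing, protocol minimum 16 rings (flagged, not enforced, so short
series remain usable). Ford–Walford regresses L_{t+1} on L_t and requires
slope b ∈ (0,1); K = −ln b, L∞ = a/(1−b). On noiseless Bertalanffy data the
recovery is exact for any K and L∞, which a property test asserts across
the parameter range. When b falls outside (0,1) (non-asymptotic growth),
the fallback fits annual increments against ln(age) — increment at age 1 is
the first ring length; non-positive increments are excluded with a warning.
Ages invert the growth curve, t = −ln(1−L/L∞)/K, undefined at L ≥ L∞.
Whether the original growth constants were fitted on cumulative lengths or
increments is not fully specified; the recursive (cumulative) Ford–Walford
form is primary here, the increment-format reader converting by cumulative
sum.

## Thresholds and projection

From the per-population mean SCIs of the two status groups: A₂ and A₄ are
the unweighted declining and viable group means, s.e.m. is taken over the
declining group, A₁ = A₂ + 1.96·s.e.m. (1.96 hard-coded as the printed
normal 95% multiplier, not a t quantile), A₃ = (A₂+A₄)/2. The derivation
requires A₄ < A₂ (separable groups) and enforces A₄ < A₃ ≤ A₂ ≤ A₁; a zero
s.e.m. collapses A₁ onto A₂ with a warning. Classification is continuous
with boundaries inclusive on the cool side: SCI ≤ A₃ viable,
A₃ < SCI ≤ A₁ declining, SCI > A₁ unsuitable (the published two-decimal
"28.37 / 28.38" gap is a rounding artifact, not a real interval). No lower
viability bound exists: the species is cold-adapted.

Projection computes each masked cell's period MST as the mean over all
summer months of the period (identical to the mean of per-year summer means
for complete data — asserted in a test), applies the calibration, and
classifies. Any missing month makes the cell no-data. Area shares are
weighted by cos(latitude of cell centre), making them proportional to true
area on the sphere; shares over the three suitability classes sum to 1 for
fully covered masks. Reconstruction applies the temperature calibration to
the 20-year window ending the year before each target year, and the
longevity calibration to the result; years lacking the lead-in are dropped
with a warning.

## Synthetic world

The generator's defaults define the study conditions and were chosen once:

| parameter | default | rationale |
|---|---|---|
| populations | 49 recent (1984–2013) + 13 historical (1901–1940) | survey layout |
| shells per sample | 11–40 recent, 5–15 historical | sample-size floors |
| grid | 0.5°, 45–70°N, 1881–2013 | range span; 20-yr lead-in before 1901 |
| summer profile | 18 °C at 45°N, −0.28 °C/° latitude | spans ~11–18 °C MST₂₀ |
| warming trend | 0.10 °C/decade | 20th-century magnitude |
| interannual sd | 0.8 °C, independent per month and cell | station-grid variability |
| seasonal amplitude | 9 °C, cosine peaking in July | boreal annual cycle |
| population SCI noise | sd 1.1 | back-solved so fitted r ≈ 0.76 at n = 49 |
| longevity noise | sd 29 yr at n = 30 | back-solved to r ≈ −0.80 |
| shell length | lognormal, mean 80, sd 10 mm | adult size distribution |
| H/L ratio | 0.50 ± 0.03; width noise 5% | allometric covariation |
| status rule | viable iff true mean SCI ≤ 28.37 | threshold structure |
| growth | K = −0.01 + 0.006·MST (± 0.004), L∞ ∈ [95,140] mm, 20 rings, ring noise 0.3 mm | K in 0.05–0.10/yr, rising with temperature |

The monthly sinusoid is centred so the June–August mean equals the target
summer profile exactly at zero noise, giving closed-form oracles for the
window arithmetic. All randomness flows from the single `WorldSpec.seed`
through independent child streams per product, so outputs are byte-identical
given the spec and products are independently regenerable. Status labels
are assigned from the *true* (pre-shell-noise) population mean, one
population per grid cell at most (keeping Moran's I free of duplicate
coordinates).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: real European geography, coastlines or the actual
range polygon; spatially correlated climate noise; non-thermal drivers of
convexity (water chemistry, host-fish availability, habitat degradation);
and sub-grid thermal heterogeneity of mountain streams, the known cause of
anomalous mountain-valley samples. A structural consequence of the shared
latitudinal gradient is that all thermal predictors in the synthetic
battery are nearly collinear (they tie within ~0.01 in |r|), so "MST beats
the alternatives" is verified on a constructed noisy-proxy battery, not on
the world generator; on real data that ranking is an empirical finding, not
a guarantee.

## Problem sizes and numerical conventions

Simulation-based tests use the original sample sizes (n = 49 and n = 30)
with 200–500 replicates, and the world tests a 0.5° grid over 45–70°N with
a narrowed longitude band — the statistical structure is unchanged and the
full suite stays fast. Scenario grids in the analysis drivers are uniform
warming offsets (+1.0/+1.8/+3.7 °C) on the late-century baseline — a
stand-in for downscaled scenario products that preserves the classification
arithmetic being exercised. Tie-breaks and degenerate inputs are handled
explicitly throughout: constant predictors, constant correlation vectors
and non-separable status groups raise typed errors; identical group means
give t = 0, p = 1; predictor-ranking ties break alphabetically; the
classifier's class codes are monotone in SCI so a warming perturbation can
only keep or worsen a cell's class (property-tested).

## Known limitations

* The suitability model is temperature-only by design; it inherits the
  source analysis's deliberate exclusion of host fish, water chemistry and
  habitat covariates.
* Degree-day quantities are monthly approximations; daily-resolution ETS
  would differ near the base-temperature crossings.
* The Moran z-test's normality assumption is only ±0.05-accurate against
  the exact permutation null at n ≈ 50 (see above).
* Scenario handling resamples supplied grids by nearest neighbour and does
  no downscaling or bias correction.
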