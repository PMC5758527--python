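# pearlclim

Climate-suitability analysis for freshwater pearl mussel (*Margaritifera
margaritifera*) populations, built on a shell-morphometric temperature proxy.

The freshwater pearl mussel is a critically endangered, cold-adapted,
extremely long-lived bivalve of oligotrophic European rivers. Its shell
convexity — the width-to-length ratio — increases in warmer water because
higher temperature accelerates shell growth and widens the annual growth
increments. `pearlclim` implements the full analysis chain that turns this
observation into a continental climate-suitability model, for ecologists and
conservation modellers who want to re-run, probe or extend the approach on
their own shell and climate data.

## The model

The shell convexity index of a shell with length *L*, height *H* and width
*W* (mm) is

    SCI   = 100 · W / L
    SCI_I = 100 · W / √(π · L · H)      (integrated variant)

Population means of per-shell SCI (shells < 5 cm excluded) are the unit of
all inference. The analysis chain is:

1. **Temperature calibration.** Ordinary least squares of population mean
   SCI on MST₂₀, the mean June–August air temperature of the 20 years before
   sample collection, extracted from a 0.5° monthly grid:
   `SCI = a + b · MST₂₀` (reference coefficients a = 18.207, b = 0.666).
   Validated by seeded 5-fold cross-validation (MAPE, Tofallis's
   log-accuracy-ratio, min-max accuracy), Moran's *I* with inverse
   great-circle-distance weights, and studentized-residual outlier flagging.
   MST₂₀ is selected against a battery of alternatives (other window
   lengths, seasonal/annual/monthly means, degree-day sums, growing-season
   length).
2. **Growth and longevity.** Von Bertalanffy constants from annual ring
   series via the Ford–Walford regression `L_{t+1} = a + b·L_t`
   (K = −ln b, L∞ = a/(1−b)); maximum age by inverting the growth curve at
   the longest shell; longevity calibration
   `A_max = 632.846 − 19.122 · SCI`.
3. **Suitability thresholds.** From the viable (A₄) and declining (A₂)
   group means: A₃ = (A₂+A₄)/2 separates viable from declining, and
   A₁ = A₂ + 1.96·s.e.m. (the 95% upper bound of the declining mean)
   separates declining from unsuitable. Reference values: 28.37 and 30.04.
4. **Projection.** The calibration applied per grid cell of a range mask for
   any 20-year period or warming scenario; cells classified
   viable / declining / unsuitable; area shares weighted by cos(latitude);
   per-site SCI and A_max series reconstructed over 1901–2010.

A synthetic-world generator (`pearlclim.synthetic`) reproduces the
statistical structure of the original survey — latitudinal temperature
gradient with a 20th-century warming trend, calibration-driven population
means, allometric shell covariation, Bertalanffy ring series — so that every
stage is testable without the original data.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
world and write their tables to `results/`:

```
python analysis/01_simulate_world.py        # world: shells, climate, rings, mask
python analysis/02_shell_morphometry.py     # filtering, aggregation, group tests
python analysis/03_climate_calibration.py   # predictor battery, OLS, CV, Moran
python analysis/04_growth_longevity.py      # Ford-Walford, K vs SCI, age model
python analysis/05_thresholds_projection.py # thresholds, maps, reconstruction
```

Output of a run with the default seed (42):

```
viable (26) vs declining (23): t=-11.57, df=47, p=2.4e-15
calibration: SCI = 17.736 + 0.703 x MST20 (r=0.82, F(1,47)=95.7, p=6.5e-13, n=49)
5-fold CV: MAPE=3.18%, Tofallis=0.0318, min-max=0.969
mean K vs mean SCI (n=9): rho=0.75, p=0.02
thresholds: viable <= 28.47 < declining <= 30.57 < unsuitable
viable share 48.3% (1901-1920) -> 35.3% (1991-2010) -> 0.0% (extreme scenario)
```

Read: the declining populations are convexer (higher SCI) than the viable
ones; the fitted calibration recovers the generative slope 0.666 within its
standard error; cross-validation errors are a few percent; growth constants
rise with convexity; and under the warming trend the viable share of the
range contracts, collapsing under an extreme late-century scenario. The same
stages are available as `pearlclim` CLI subcommands
(`simulate | morpho | climate-extract | calibrate | growth | thresholds |
map | reconstruct | run`) for use on real CSV/NetCDF inputs.

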