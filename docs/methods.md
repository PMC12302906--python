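# Methods

This document describes the statistical model, the fitting procedure, the
synthetic-data generators, and the numerical choices made in `fieldfit`.

## The gene model

For one gene, log2 expression of sample *i* (clock time `c_i` in hours,
plant age `a_i` in days) is modelled as

```
y_i = b0 + b_age·a_i + b_cos·cos(2πc_i/24) + b_sin·sin(2πc_i/24)
    + x_i·(b_e + b_e_age·a_i + b_e_cos·cos(2πc_i/24) + b_e_sin·sin(2πc_i/24))
    + ε_i
```

where `x_i` is a scalar environmental input derived from the temperature or
irradiance trace preceding the sample.  The first row is a
clock-plus-development baseline; the second lets the environmental response
itself depend on age and time of day.

### The environmental input

`x_i` is the mean, over the half-open window `[t_i − D − T, t_i − D)` of the
environmental trace sampled on its native grid (step ≤ 0.5 h), of

```
gate(clock(s)) · clip(E(s); θ_lo, θ_hi)
gate(c) = (1 − γ) + γ·((1 + cos(2π(c − φ)/24)) / 2)^w
```

Seven nonlinear parameters shape it:

| parameter | meaning | units / range | default search |
|---|---|---|---|
| `T` | look-back window length | h, `T + D ≤ 72` | grid {3, 6, 12, 24} |
| `D` | lag between window end and sampling | h | grid {0, 6} |
| `φ` | clock time of peak responsiveness | h, wraps mod 24 | grid {0, 6, 12, 18} |
| `γ` | gate depth (0 = ungated) | [0, 1] | grid {0, 1} |
| `w` | gate sharpness | > 0 | fixed 2 at grid stage |
| `θ_lo, θ_hi` | clipping bounds on `E` | variable units | data range |

The 72-h cap is enforced throughout: samples must have at least 72 h of
trace history, and window/lag combinations beyond it are rejected.  Window
means are computed with prefix sums over the concatenated environmental
traces of a study (`EnvStack`), so evaluating a candidate parameter point
across hundreds of samples costs O(samples), not O(samples × window).

### Linear stage: adaptive group lasso + BIC

Given `x`, the 8 linear coefficients are grouped — intercept+age `{b0,
b_age}` treated as always-in baseline, clock pair `{b_cos, b_sin}`, and the
environmental quadruple `{b_e, b_e_age, b_e_cos, b_e_sin}` — and selected by
adaptive group lasso: a ridge pilot (penalty 1e-4) sets per-group weights
`1/‖pilot_g‖`, then FISTA with the group soft-threshold prox solves the
path `λ ∈ λ_max·logspace(0, −4, 10)`.  Each path solution is scored by

```
BIC = n·log(RSS/n) + df·log(n),   df = 1 + #nonzero coefficients
```

and the best BIC is kept.  `λ = 0` is special-cased as ordinary least
squares.  The solver works on the Gram matrix (`p = 8`), so its cost is
independent of `n` after one `X'X` product; the hot loops are compiled with
numba.  A fitted model whose environmental group is entirely zero is
reported as predictor "neither".

### Nonlinear stage

The 7 nonlinear parameters are optimized per gene and per candidate
variable by a coarse grid (the defaults above, ~40 points after removing
gate-parameter aliases at `γ = 0`; grids are configurable where a finer
search is wanted) followed by Nelder–Mead refinement from the best grid
point.  The simplex works on transformed coordinates — `log T`, `√D`, `φ`
wrapped, `logit γ`, `log w`, clipping midpoint and log half-width — so box
constraints become unconstrained and scale is roughly balanced.  During
exploration the inner group-lasso solver runs at looser tolerance; the
winning point is refit at full precision.  Grid-stage design matrices for a
fixed sample pool are precomputed once and shared across subsampling
replicates (`grid_env_inputs`), which makes the composition experiment
tractable.

### Predictor choice

The temperature- and radiation-driven fits are compared by BIC; the lower
criterion wins.  Near-ties (|ΔBIC| < 1e-8) resolve to "neither" when both
candidates zeroed the environmental group, otherwise to the sparser model,
otherwise to temperature.  Any winner with a zero environmental group is
"neither".

## Synthetic data generators

The generators provide ground-truthed studies at the structure of the
investigation: a chamber design that decouples the two candidate drivers,
and field-like data in which they are confounded.

### Chamber design

5 photoperiods {0, 8, 12, 16, 24} h × light temperature 20–40 °C × dark
temperature 15–35 °C (1 °C steps), keeping pairs with different
temperatures and collapsing the irrelevant phase for constant-light and
constant-dark conditions: 73 conditions.  Environmental traces are square
waves; plants acclimate 3 days and are sampled on day 4 at 8 clock times
(1.5, 4.5, …, 22.5 h) for each of 2 cultivars — 1168 planned samples.
Pooled over the design, corr(temperature, irradiance) ≈ 0.37, and the full
temperature range occurs in both light and dark phases, which is what lets
the fit distinguish thermal from radiative drive.

### Field weather

Synthetic field temperature is a diel sinusoid peaking at 14 h whose
amplitude is scaled by a daily lognormal "weather" factor (σ = 0.4); the
same factor scales the irradiance half-sinusoid (daylight 5–19 h) **and**
shifts the daily mean temperature (+3 °C per unit anomaly), so clear days
are both brighter and warmer — the solar/thermal coupling that makes the
two candidate drivers nearly exchangeable in field data
(corr(temperature, irradiance) ≈ 0.65–0.85 across seeds).  A non-solar
AR(1) component (sd 0.4 °C, ρ = 0.95 per 0.5-h step) adds the independent
temperature variability that remains.

### Noise model and why day-level effects exist

Gene truth is the model above plus iid Gaussian noise **and a day-level
(field) or chamber-run-level (chamber) random effect** shared by all
samples of a day/run (sd 0.5 and 0.3 log2 units respectively).  The shared
effect is not a tuning convenience: under iid noise alone, at any usable
signal-to-noise ratio, BIC separates the two predictors unless their
sample-level inputs are nearly perfectly collinear, and no weather model
with independent temperature variability produces that.  Real studies
sample one plant per time point, so biological and batch state is shared
within a sampling day; that covariance suppresses information in exactly
the day-anomaly dimension that separates temperature from irradiance in
the field, while chamber data — where the drivers are decoupled by design —
remain informative.  With these defaults, driver-identification accuracy
on development seeds is ~1.0 for chamber-trained models and ~0.78 for
field-trained ones.

Environmental truth genes gate to the photoperiod (φ ~ N(13 h, 3 h)), as
light/heat-response pathways do; effect sizes are scaled to a target SNR
(default 6) against the reference sample set.

Scope and limitations: the generators produce log2-scale expression
directly (no count layer, no library-size variation), square-wave chamber
traces (no ramping), a single growth season, and random effects that are
gene-independent across genes.  Passing the package's end-to-end checks on
these data demonstrates that the estimation machinery recovers truth under
the intended confounding structure; it does not validate the biological
model against real field measurements.

## Descriptive statistics

* **Diel amplitude** — a cubic smoothing spline through the 8 clock-time
  values, penalized as `spar = 0.3` in the standard spline
  parameterization (`λ = r·256^(3·spar−1)` with `r` the ratio of the
  traces of the basis Gram and curvature matrices, on a unit-scaled
  abscissa; matches R's `smooth.spline`), evaluated on a 1.5-h grid;
  amplitude is max − min.  Oscillating genes: amplitude ≥ 2 log2 units.
* **Expression filter** — grand mean log2(rpm+1) > 1.
* **Cultivar DEGs** — paired t-test across shared sampling times within a
  condition, Benjamini–Hochberg correction, q < 0.05; cultivar-specific
  genes (difference > 2, other cultivar < 0.5) excluded first.
* **Temperature screen** — per-gene Pearson r of expression with air
  temperature pooled over samples, thresholded at |r| > 0.5.

## Sample QC

* **Plate-swap detection** — lasso regression of nominal temperature on the
  standardized expression matrix, trained leave-one-plate-out
  (regularization by 5-fold CV within the training plates); plates with
  held-out MAE ≥ 1.5× the median plate MAE are flagged.  The flag factor is
  deliberately liberal because a swap corrupts the *training labels* of
  every fold and lifts all plates' errors.  Flagged plates are then paired
  by exhaustive search over partial pairings, each pair scored by its
  post-exchange MAE and each unpaired plate by its current MAE, so a pair
  is proposed only when exchanging annotations genuinely lowers total
  error.  A correction is accepted when a second prediction round on the
  re-annotated study proposes no pairs.
* **Genotype concordance** — per-sample proportion of called
  cultivar-diagnostic SNPs matching the nominal cultivar: ≥ 0.7 pass,
  ≤ 0.3 swap candidate, in between (or no calls) discard.

## Experiment and thresholds

The training-composition experiment subsamples pools (chamber, field, or
mixed half-and-half) at sizes {64, 128, 256, 512} with replicates, fits
every gene per subsample, and records the predictor choice and the MAE on
held-out field samples.  Fixed thresholds: poor prediction MAE ≥ 5 log2
units; a gene's choice is "consistent" when ≥ 80 % of replicates agree;
genome-wide impact converts exemplar-level selections to gene counts via
the co-expression cluster table (466 exemplars, 15 907 member genes).

## Determinism

All randomness flows from `numpy.random.SeedSequence` substreams with
explicit spawn keys (generator seed, pool/size/replicate indices), so every
entry point — generators, experiment, pipeline, `scripts/acceptance.py` —
reproduces byte-identical output from one integer seed.
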