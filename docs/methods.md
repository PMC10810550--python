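# Methods

## Count model

Monthly fire counts are treated as gamma–Poisson mixtures: `Y_i ~ NB(mu_i,
phi)` with pmf

    p(y; mu, phi) = Γ(y+phi) / (Γ(phi) Γ(y+1)) · (mu/(mu+phi))^y · (phi/(mu+phi))^phi

so `Var(Y) = mu + mu^2/phi` and `phi → ∞` recovers the Poisson. The mean is
log-linear in rainfall (mm), maximum temperature (°C) and an annual harmonic
pair `sin(2πt/12), cos(2πt/12)` of the month index `t = 1..n`. The harmonic
period is configurable but defaults to 12 because the data are monthly with
an annual cycle. Covariates are deliberately left unstandardised so fitted
coefficients are directly interpretable on the natural units (per mm, per
°C). There is no additive error term inside the link: all extra-Poisson
variation is carried by the dispersion parameter, which keeps the likelihood
well-defined and matches what standard NB-GLM software estimates.

### Maximum-likelihood fit

`fit_nb` maximises the NB likelihood (statsmodels' NB2 parameterisation,
`alpha = 1/phi`), reports standard errors from the observed information at
the optimum (delta method for `phi`), and flags optimizer non-convergence
rather than raising. The package's own `nb_log_pmf`/`nb_loglik` are
implemented independently via log-gamma functions and are used in tests to
re-score the optimum, so the two routes check each other.

### Bayesian fit

`fit_bnb` targets the posterior

    p(alpha, nu | y) ∝ NB-likelihood(alpha, nu) · Π_m N(alpha_m; 0, sd²) · Gamma(nu; shape, rate)

with defaults `sd = 10` (weakly informative on the raw covariate scale),
`shape = rate = 0.01` (vague on the dispersion). Sampling is an
affine-invariant ensemble (emcee) over `(alpha_0..alpha_4, log nu)` — the
Jacobian of the log transform is included — using an 80/20 mix of
differential-evolution and snooker moves, which mix far better than stretch
moves on this correlated six-parameter posterior. Walkers are initialised
in a tight ball around the posterior mode (Nelder–Mead from the ML
estimate), which shortens warmup without changing the target; with a very
tight prior the mode-finding step keeps the start inside the prior mass,
where an MLE start would strand the ensemble. Defaults: 16 walkers, 1000
warmup steps, 4000 retained steps thinned by 4 (16 000 kept draws).
Walkers are treated as chains for split-R̂ and ESS (arviz); runs with any
R̂ > 1.01 are reported as non-converged, and the CLI refuses their summary
without `--force`. On a 240-month reference series the defaults give
R̂ ≤ 1.007 across seeds.

### Predictions and intervals

Point predictions are `exp(x'beta)` for the ML fit and the posterior
average of `exp(x'alpha)` for the Bayesian fit. Predictive counts for the
Bayesian model default to a **single posterior-predictive draw** (one
randomly chosen posterior draw generating one NB count per row) when
computing performance metrics — this is the study's scoring convention and
is deliberately noisy; a posterior-mean mode exists for users who want the
usual point forecast. Prediction intervals are central quantile intervals:
plug-in NB quantiles at `(mu_hat, phi_hat)` for the ML fit (estimation
uncertainty ignored, hence approximate and slightly narrow), and pooled
posterior-predictive quantiles for the Bayesian fit. Credible intervals in
summaries are central 95% quantile intervals, not HPD.

## Synthetic generator

The generator emulates a Kenyan-style monthly series:

- **Maximum temperature** ~ truncated normal, mean 29.18 °C, sd 2.29 °C,
  support [23.43, 34.82] °C (the observed range of the real series).
- **Rainfall** = 312.692 − 7.83·tmax + U(−75, +75) mm, clipped at 0 by
  default (physical floor; flag to disable). The ±75 mm bound is of the
  order of the observed rainfall sd (51.69 mm); the exact residual bounds
  of the original rainfall regression are not recoverable, so this is a
  fixed package default, logged in every run manifest.
- **Counts**: linear predictor with coefficients (7.69, 0.002, −0.09,
  0.83, −0.05) — the Bayesian estimates from the real data, the only
  printed set — then, in the default `residual_uniform` mode,
  `max(0, round(exp(eta) + U(−50, +50)))` with rounding half away from
  zero. The ±50 bound reproduces the observed training RMSE scale
  (uniform sd ≈ 28.9). Long-run mean counts land near 230/month, the
  scale of the real data (mean 277).

Two properties of this construction matter for interpretation. First, the
nominal dispersion θ **never enters** `residual_uniform` generation, so
scenarios differing only in θ yield byte-identical series at a fixed seed —
the simulation study's near-identical summary rows across θ are a property
of the generator, not of the models. Whether that was intended originally
is unknowable, so a genuine `nb_sample` mode (counts drawn from
NB(exp(eta), θ)) is provided and used for all parameter-recovery and
calibration tests. Second, uniform additive noise on the count scale makes
small-mean months have large *relative* errors, which produces the
systematic ≈ −4% to −7% percent bias both models show on test data: it is a
retransformation artifact of the generator, not an estimator defect.

What the generator does **not** emulate: temporal autocorrelation beyond
the deterministic seasonal cycle, decadal trend shifts, outliers, zero
months, or any spatial structure. Passing tests therefore show estimator
correctness under the stated data-generating process, not robustness to
real-data complications.

Seeding: a master seed (default 76568) plus `(n, replicate_id)` feed a
`SeedSequence`, giving independent substreams per replicate and exact
within-implementation determinism; stream equality across libraries or
versions is not promised.

## Evaluation conventions

- **Split**: sequential, train = first `floor(0.8 n)` months (n=60 → 48/12;
  n=218 → 174/44, hence correlation tests with 42 degrees of freedom).
- **MASE**: forecast MAE divided by the training series' in-sample one-step
  naive MAE (non-seasonal scaling).
- **Percent bias**: `100 · mean((y − ŷ)/y)`; negative means
  over-prediction. Zero actuals raise by default; an epsilon policy
  (denominator 0.5) is used inside the study harness where simulated test
  months can rarely be zero.
- **Aggregation over replicates**: arithmetic means, with the full
  per-replicate table retained so medians or distributions can be
  recomputed.
- Replicate-level fit failures are logged and excluded; more than 20%
  failures in any scenario × model cell aborts the study loudly.

## Problem sizes

The package's own reference runs use desk-scale sizes chosen to keep the
full loop reproducible on a single core in minutes: 100 replicates for the
headline θ=1.5, n=60 scenario in `scripts/acceptance.py` (short chains:
12 walkers, 300 warmup, 300 thinned-by-2 kept steps), 10 replicates per
cell for the full 16-scenario grid in `analysis/03_simulation_study.py`,
and n=5000 single datasets for parameter-recovery and
Bayesian-vs-ML-agreement checks. Replicate counts are parameters
everywhere; scaling up changes Monte-Carlo error, not structure.

## FIRMS aggregation

Hotspot CSVs use the standard MCD14DL column set; rows with unparseable
dates, out-of-range coordinates or negative FRP are dropped and counted.
The default type filter keeps code 0 ("presumed vegetation fire") only,
since those are the fires the modelling targets; `--types` widens it.
Calendar months come from `acq_date` as recorded (no time-zone
conversion). Months without retained detections are absent rather than
zero-filled — the real aggregated series never had an empty month, so the
choice is documented rather than exercised. Climate enters as an
already-monthly `year,month,rainfall,tmin,tmax` table; raster extraction
and spatial cropping are upstream GIS concerns, out of scope here.

## Known limitations

- The ML prediction intervals ignore parameter uncertainty; at small n they
  under-cover slightly. The Bayesian intervals do not share this defect.
- The single-draw Bayesian scoring convention inflates the Bayesian arm's
  RMSE/MASE relative to mean prediction by construction; comparisons
  between the two models' error metrics under that convention mix
  predictive-noise and estimation-error components.
- Ensemble walkers are correlated chains, so R̂/ESS computed across walkers
  are somewhat optimistic diagnostics; thinning mitigates this.
- The generator's dispersion-inertness in its default mode means the
  scenario grid's θ axis only exercises the fitted models' own dispersion
  estimates, not genuinely different data regimes; use `nb_sample` mode for
  dispersion-sensitive experiments.
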