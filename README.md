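# firefreq

Modelling the monthly frequency of vegetation fires from climate covariates,
with over-dispersed count regression. The package grew out of the question of
forecasting satellite-detected fire counts in Kenya (MODIS/FIRMS hotspots,
2000–2018) from monthly rainfall and maximum temperature, and compares a
maximum-likelihood Negative Binomial (NB) regression against its Bayesian
counterpart (BNB) in a Monte-Carlo simulation study.

It is written for statisticians and fire-ecology analysts who need

- a **synthetic generator** of monthly climate/fire-count series with known
  structure (truncated-normal temperature, temperature-driven rainfall,
  seasonal log-link NB counts),
- **both NB estimators** with predictions and 90% prediction intervals,
- a **simulation harness** that scores the two models by RMSE, MASE and
  percent bias over replicated scenarios,
- a **FIRMS aggregation stage** turning raw hotspot CSVs plus a monthly
  climate table into the modelling table.

## The model

Monthly fire counts $Y_i$ are modelled as gamma–Poisson (Negative Binomial)
with mean $\mu_i$ and dispersion $\phi$ (variance $\mu_i + \mu_i^2/\phi$):

$$Y_i \sim \mathrm{NB}(\mu_i, \phi), \qquad
\log \mu_i = \beta_0 + \beta_1\,\mathrm{rain}_i + \beta_2\,\mathrm{tmax}_i
+ \beta_3 \sin\!\tfrac{2\pi t_i}{12} + \beta_4 \cos\!\tfrac{2\pi t_i}{12}$$

The harmonic pair absorbs annual seasonality. The ML fit maximises the NB
likelihood; the Bayesian fit samples the posterior under independent
$\mathcal N(0, 10^2)$ coefficient priors and a $\mathrm{Gamma}(0.01, 0.01)$
dispersion prior, using an affine-invariant ensemble sampler with
differential-evolution moves, and reports split-$\widehat R$ / ESS
diagnostics. Forecast quality is scored on a sequential 80:20 split with
RMSE, MASE (scaled by the training series' one-step naive MAE) and percent
bias $100\cdot\overline{(y - \hat y)/y}$.

## Worked example

```python
import numpy as np
from firefreq import synthetic as syn, models as m, evaluation as ev

scen = syn.ScenarioConfig(n=240, theta=1.5, master_seed=76568)
series = syn.generate_series(scen, replicate_id=0)
split = ev.sequential_split(series, 0.8)
train = m.ModelData.from_series(split.train)
test = m.ModelData.from_series(split.test)

nb = m.fit_nb(train)
print(nb.summary_frame().round(3))
```

yields (192 training months):

```
      term  estimate     se  ci_lower  ci_upper
 intercept     7.822  0.204     7.422     8.222
  rainfall     0.001  0.000     0.001     0.002
  max_temp    -0.092  0.007    -0.105    -0.079
     sin12     0.826  0.019     0.788     0.864
     cos12    -0.045  0.019    -0.083    -0.008
dispersion    33.695  4.696    24.490    42.900
```

The coefficients recover the generator's values (7.69, 0.002, −0.09, 0.83,
−0.05): a strong annual cycle (`sin12` ≈ 0.83) and fewer fires in hotter
months once season is controlled for. The Bayesian fit
(`m.fit_bnb(train, rng=np.random.default_rng(1))`) returns posterior means
within a fraction of a posterior SD of these estimates, and
`m.prediction_interval(fit, test, level=0.9)` gives 90% intervals whose
empirical test coverage here is 0.92 for both models.

The same steps, with narrative output and CSV artifacts under `results/`,
are packaged as numbered drivers:

```bash
python analysis/01_simulate.py          # replicate series CSVs
python analysis/02_fit_models.py        # NB + BNB fits, intervals, correlation tests
python analysis/03_simulation_study.py  # 16-scenario model comparison -> table1.csv
python analysis/04_aggregate_fires.py   # FIRMS fixture -> monthly modelling table
```

A `firefreq` command-line interface wraps the same stages
(`firefreq simulate|fit|study|aggregate`, each writing a reproducibility
manifest); see `firefreq --help`.

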