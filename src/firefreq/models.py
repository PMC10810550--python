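"""Maximum-likelihood and Bayesian negative-binomial regression.

Both models share the same mean structure on the log link:

    log(mu_i) = b0 + b1 * rainfall_i + b2 * max_temp_i
                + b3 * sin(2*pi*t_i/12) + b4 * cos(2*pi*t_i/12)

with counts y_i ~ NB(mu_i, phi) in the gamma-Poisson parameterisation
(variance mu + mu^2/phi).  The ML fit estimates (b, phi) by maximising the
NB likelihood; the Bayesian fit samples the posterior under independent
N(0, sd^2) coefficient priors and a Gamma(shape, rate) dispersion prior.

The harmonic pair carries annual seasonality for monthly data; the period
is configurable.  Extra-Poisson variation is carried entirely by the
dispersion parameter — there is no additive error term inside the link.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .exceptions import (
    ConfigurationError,
    DataFormatError,
    DiagnosticsError,
    FitError,
)
from .synthetic import SimulatedSeries

__all__ = [
    "ModelData",
    "NBFit",
    "PriorSpec",
    "SamplerSettings",
    "BNBPosterior",
    "harmonic_features",
    "nb_log_pmf",
    "nb_loglik",
    "fit_nb",
    "fit_bnb",
    "predict_mean",
    "posterior_predictive_draw",
    "prediction_interval",
    "PredictionSet",
]

TERM_NAMES = ["intercept", "rainfall", "max_temp", "sin12", "cos12"]
PARAM_NAMES = ["alpha0", "alpha1", "alpha2", "alpha3", "alpha4", "nu"]


def harmonic_features(time, period: int = 12) -> tuple[np.ndarray, np.ndarray]:
    """Sine/cosine pseudo-covariates sin(2*pi*t/period), cos(2*pi*t/period)."""
    if period < 2:
        raise ConfigurationError(f"period must be >= 2, got {period}")
    t = np.asarray(time, dtype=float)
    ang = 2.0 * np.pi * t / period
    return np.sin(ang), np.cos(ang)


@dataclass
class ModelData:
    """Design container for the NB regressions.

    Columns of the design matrix X are (1, rainfall, max_temp, sin, cos).
    """

    y: np.ndarray
    rainfall: np.ndarray
    max_temp: np.ndarray
    time: np.ndarray
    sin_term: np.ndarray
    cos_term: np.ndarray

    def __post_init__(self) -> None:
        lens = {
            len(self.y),
            len(self.rainfall),
            len(self.max_temp),
            len(self.time),
            len(self.sin_term),
            len(self.cos_term),
        }
        if len(lens) != 1:
            raise DataFormatError("model data vectors must share one length")
        y = np.asarray(self.y)
        if np.any(y < 0) or not np.allclose(y, np.round(y)):
            raise DataFormatError("counts must be nonnegative integers")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def X(self) -> np.ndarray:
        return np.column_stack(
            [
                np.ones(len(self)),
                self.rainfall,
                self.max_temp,
                self.sin_term,
                self.cos_term,
            ]
        )

    @classmethod
    def from_series(cls, series: SimulatedSeries, period: int = 12) -> "ModelData":
        s, c = harmonic_features(series.time, period)
        return cls(
            y=np.asarray(series.fire_count, dtype=float),
            rainfall=np.asarray(series.rainfall, dtype=float),
            max_temp=np.asarray(series.max_temp, dtype=float),
            time=np.asarray(series.time, dtype=int),
            sin_term=s,
            cos_term=c,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, period: int = 12) -> "ModelData":
        missing = [c for c in ("time", "max_temp", "rainfall", "fire_count") if c not in frame]
        if missing:
            raise DataFormatError(f"modelling table missing columns: {missing}")
        return cls.from_series(SimulatedSeries.from_frame(frame), period=period)


def nb_log_pmf(y, mu, phi) -> np.ndarray | float:
    """Log pmf of the gamma-Poisson negative binomial.

    log p(y; mu, phi) = lgamma(y+phi) - lgamma(phi) - lgamma(y+1)
                        + y*log(mu/(mu+phi)) + phi*log(phi/(mu+phi))
    """
    y_arr = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(y_arr < 0) or not np.allclose(y_arr, np.round(y_arr)):
        raise DataFormatError("y must be nonnegative integers")
    if np.any(mu <= 0) or np.any(phi <= 0):
        raise ConfigurationError("mu and phi must be strictly positive")
    out = (
        gammaln(y_arr + phi)
        - gammaln(phi)
        - gammaln(y_arr + 1.0)
        + y_arr * (np.log(mu) - np.log(mu + phi))
        + phi * (np.log(phi) - np.log(mu + phi))
    )
    return out if out.ndim else float(out)


def nb_loglik(beta, phi: float, data: ModelData) -> float:
    """NB log-likelihood of the log-link regression at (beta, phi)."""
    eta = data.X @ np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise FitError("nonfinite linear predictor")
    return float(np.sum(nb_log_pmf(data.y, np.exp(eta), phi)))


@dataclass
class NBFit:
    """Maximum-likelihood NB regression result."""

    beta: np.ndarray
    phi: float
    se: np.ndarray          # SEs of (beta..., phi)
    loglik: float
    converged: bool
    message: str = ""

    def summary_frame(self) -> pd.DataFrame:
        """Coefficient table with Wald 95% intervals, dispersion last."""
        est = np.concatenate([self.beta, [self.phi]])
        terms = TERM_NAMES + ["dispersion"]
        z = stats.norm.ppf(0.975)
        return pd.DataFrame(
            {
                "term": terms,
                "estimate": est,
                "se": self.se,
                "ci_lower": est - z * self.se,
                "ci_upper": est + z * self.se,
            }
        )


def fit_nb(data: ModelData) -> NBFit:
    """ML fit of the log-link NB regression (dispersion estimated freely).

    Backed by statsmodels' NB2 likelihood (alpha = 1/phi); standard errors
    come from the observed information at the optimum.
    """
    import statsmodels.api as sm

    n, k = len(data), 5
    if n <= k:
        raise FitError(f"need n > {k} observations, got {n}")
    if np.all(data.y == 0):
        raise FitError("all counts are zero; NB mean model is degenerate")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.NegativeBinomial(data.y, data.X, loglike_method="nb2")
        try:
            res = model.fit(disp=0, maxiter=200, method="bfgs")
            if not res.mle_retvals.get("converged", False):
                res = model.fit(disp=0, maxiter=500, method="nm",
                                start_params=res.params)
        except Exception as exc:  # noqa: BLE001 — surfaced as FitError
            raise FitError(f"NB fit failed: {exc}") from exc
    params = np.asarray(res.params, dtype=float)
    beta, alpha = params[:k], params[k]
    if alpha <= 0:
        alpha = 1e-8
    phi = 1.0 / alpha
    bse = np.asarray(res.bse, dtype=float)
    # delta method: phi = 1/alpha  =>  se(phi) = se(alpha)/alpha^2
    se = np.concatenate([bse[:k], [bse[k] / alpha**2]])
    converged = bool(res.mle_retvals.get("converged", False))
    message = "" if converged else str(res.mle_retvals)
    return NBFit(
        beta=beta,
        phi=float(phi),
        se=se,
        loglik=float(res.llf),
        converged=converged,
        message=message,
    )


@dataclass(frozen=True)
class PriorSpec:
    """Priors of the Bayesian NB: alpha_m ~ N(0, sd^2), nu ~ Gamma(shape, rate).

    Defaults are weakly informative on the raw covariate scale
    (covariates are not standardised, so posterior coefficients are
    directly comparable to the ML estimates).
    """

    coef_prior_sd: float = 10.0
    disp_shape: float = 0.01
    disp_rate: float = 0.01

    def __post_init__(self) -> None:
        if min(self.coef_prior_sd, self.disp_shape, self.disp_rate) <= 0:
            raise ConfigurationError("all prior hyperparameters must be > 0")


@dataclass(frozen=True)
class SamplerSettings:
    """Ensemble-sampler run configuration.

    ``n_walkers`` parallel walkers are treated as chains for diagnostics;
    after ``n_warmup`` discarded steps, ``n_keep`` thinned steps per walker
    are retained.  Defaults keep 16 x 1000 = 16000 draws, thinned by 4 to
    tame walker autocorrelation.
    """

    n_walkers: int = 16
    n_warmup: int = 1000
    n_keep: int = 1000
    thin: int = 4
    rhat_threshold: float = 1.01

    def __post_init__(self) -> None:
        # the ensemble moves need at least 2 * ndim = 12 walkers
        if self.n_walkers < 12 or self.n_walkers % 2:
            raise ConfigurationError("n_walkers must be an even number >= 12")
        if min(self.n_warmup, self.n_keep, self.thin) < 1:
            raise ConfigurationError("warmup, keep and thin must be >= 1")


@dataclass
class BNBPosterior:
    """Posterior draws of (alpha0..alpha4, nu) with convergence diagnostics.

    ``chains`` has shape (n_chains, n_draws_per_chain, 6); ``draws`` is the
    pooled (n_total, 6) matrix.
    """

    chains: np.ndarray
    rhat: dict[str, float]
    ess: dict[str, float]
    rhat_threshold: float = 1.01

    @property
    def draws(self) -> np.ndarray:
        return self.chains.reshape(-1, self.chains.shape[-1])

    @property
    def n_draws(self) -> int:
        return self.chains.shape[0] * self.chains.shape[1]

    @property
    def converged(self) -> bool:
        return all(v <= self.rhat_threshold for v in self.rhat.values())

    def failing_parameters(self) -> list[str]:
        return [p for p, v in self.rhat.items() if v > self.rhat_threshold]

    def posterior_mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def posterior_sd(self) -> np.ndarray:
        return self.draws.std(axis=0, ddof=1)

    def to_frame(self) -> pd.DataFrame:
        n_chain, n_draw, _ = self.chains.shape
        chain_idx = np.repeat(np.arange(n_chain), n_draw)
        iter_idx = np.tile(np.arange(n_draw), n_chain)
        frame = pd.DataFrame(self.draws, columns=PARAM_NAMES)
        frame.insert(0, "iter", iter_idx)
        frame.insert(0, "chain", chain_idx)
        return frame

    def summary_frame(self) -> pd.DataFrame:
        """Posterior mean, sd and central 95% credible intervals."""
        q = np.quantile(self.draws, [0.025, 0.975], axis=0)
        return pd.DataFrame(
            {
                "term": TERM_NAMES + ["dispersion"],
                "estimate": self.posterior_mean(),
                "se": self.posterior_sd(),
                "ci_lower": q[0],
                "ci_upper": q[1],
                "rhat": [self.rhat[p] for p in PARAM_NAMES],
            }
        )


def _log_posterior_factory(data: ModelData, priors: PriorSpec):
    """Vectorised log posterior over (alpha0..4, log nu) walker positions."""
    X, y = data.X, data.y
    sd = priors.coef_prior_sd
    shape, rate = priors.disp_shape, priors.disp_rate

    def log_post(params: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(params)
        beta = p[:, :5]
        log_nu = p[:, 5]
        nu = np.exp(log_nu)
        eta = X @ beta.T                      # (n, walkers)
        out = np.full(p.shape[0], -np.inf)
        ok = np.all(np.isfinite(eta), axis=0) & (eta.max(axis=0) < 500) & (nu > 0)
        if np.any(ok):
            mu = np.exp(eta[:, ok])
            nu_ok = nu[ok]
            ll = (
                gammaln(y[:, None] + nu_ok)
                - gammaln(nu_ok)
                - gammaln(y + 1.0)[:, None]
                + y[:, None] * (np.log(mu) - np.log(mu + nu_ok))
                + nu_ok * (np.log(nu_ok) - np.log(mu + nu_ok))
            ).sum(axis=0)
            lp = (
                -0.5 * np.sum(beta[ok] ** 2, axis=1) / sd**2
                + shape * log_nu[ok]          # gamma prior + log-nu Jacobian
                - rate * nu_ok
            )
            out[ok] = ll + lp
        return out if params.ndim == 2 else out[0]

    return log_post


def fit_bnb(
    data: ModelData,
    priors: PriorSpec | None = None,
    settings: SamplerSettings | None = None,
    rng: np.random.Generator | None = None,
    check_convergence: bool = False,
) -> BNBPosterior:
    """Sample the Bayesian NB posterior with an affine-invariant ensemble.

    Walkers start in a tight ball around the posterior mode (located by a
    derivative-free search started from the ML estimate), which shortens
    warmup without changing the posterior target.  ``check_convergence=True``
    raises DiagnosticsError when any rhat exceeds the threshold.
    """
    import emcee
    from scipy import optimize

    priors = priors or PriorSpec()
    settings = settings or SamplerSettings()
    rng = rng if rng is not None else np.random.default_rng()

    try:
        mle = fit_nb(data)
        center = np.concatenate([mle.beta, [np.log(max(mle.phi, 1e-3))]])
    except FitError:
        center = np.zeros(6)
    center = np.clip(center, -20, 20)

    ndim = 6
    log_post = _log_posterior_factory(data, priors)
    # MAP start: with informative priors the MLE can sit far from the
    # posterior mass, so recentre on the posterior mode
    opt = optimize.minimize(
        lambda p: -log_post(p[None, :])[0], center,
        method="Nelder-Mead", options={"maxiter": 2000},
    )
    if np.isfinite(opt.fun):
        center = opt.x
    scale = 1e-4 * np.maximum(1.0, np.abs(center))
    p0 = center + scale * rng.standard_normal((settings.n_walkers, ndim))
    sampler = emcee.EnsembleSampler(
        settings.n_walkers, ndim, log_post, vectorize=True,
        moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
    )
    # emcee draws from a legacy RandomState; seed it from our generator
    sampler._random = np.random.RandomState(int(rng.integers(2**31 - 1)))
    n_steps = settings.n_warmup + settings.n_keep * settings.thin
    sampler.run_mcmc(p0, n_steps, progress=False, skip_initial_state_check=True)
    chain = sampler.get_chain(discard=settings.n_warmup, thin=settings.thin)
    # (steps, walkers, dim) -> (walkers, steps, dim); nu on natural scale
    chains = np.transpose(chain, (1, 0, 2)).copy()
    chains[:, :, 5] = np.exp(chains[:, :, 5])

    rhat, ess = _diagnostics(chains)
    post = BNBPosterior(
        chains=chains, rhat=rhat, ess=ess, rhat_threshold=settings.rhat_threshold
    )
    if check_convergence and not post.converged:
        raise DiagnosticsError(
            "MCMC did not converge; rhat > "
            f"{settings.rhat_threshold} for {post.failing_parameters()}"
        )
    return post


def _diagnostics(chains: np.ndarray) -> tuple[dict[str, float], dict[str, float]]:
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(
            {name: chains[:, :, i] for i, name in enumerate(PARAM_NAMES)}
        )
        rhat_ds = az.rhat(ds)
        ess_ds = az.ess(ds)
    rhat = {p: float(rhat_ds[p].values) for p in PARAM_NAMES}
    ess = {p: float(ess_ds[p].values) for p in PARAM_NAMES}
    return rhat, ess


def _require_design(newdata: ModelData) -> np.ndarray:
    if not isinstance(newdata, ModelData):
        raise DataFormatError("newdata must be a ModelData instance")
    return newdata.X


def predict_mean(fit, newdata: ModelData) -> np.ndarray:
    """Predicted mean counts: exp(X beta) for an ML fit, the posterior
    average of exp(X alpha) for a Bayesian posterior."""
    X = _require_design(newdata)
    if isinstance(fit, NBFit):
        return np.exp(X @ fit.beta)
    if isinstance(fit, BNBPosterior):
        etas = X @ fit.draws[:, :5].T        # (n, draws)
        return np.exp(etas).mean(axis=1)
    raise DataFormatError(f"cannot predict from {type(fit).__name__}")


def _nb_rvs(mu: np.ndarray, phi, rng: np.random.Generator) -> np.ndarray:
    p = phi / (phi + mu)
    return rng.negative_binomial(phi, p, size=mu.shape)


def posterior_predictive_draw(
    posterior: BNBPosterior,
    newdata: ModelData,
    rng: np.random.Generator,
    mode: str = "single_draw",
) -> np.ndarray:
    """Posterior-predictive counts.

    ``single_draw`` picks one posterior draw at random and simulates one NB
    count per row (the convention used for the performance metrics);
    ``per_draw`` returns the full (n_draws, n_rows) predictive matrix.
    """
    if posterior.n_draws < 1:
        raise FitError("posterior contains no draws")
    X = _require_design(newdata)
    if mode == "single_draw":
        idx = int(rng.integers(posterior.n_draws))
        d = posterior.draws[idx]
        mu = np.exp(X @ d[:5])
        return _nb_rvs(mu, d[5], rng)
    if mode == "per_draw":
        etas = np.exp(X @ posterior.draws[:, :5].T)     # (n, draws)
        nus = posterior.draws[:, 5]
        return _nb_rvs(etas.T, nus[:, None], rng)
    raise ConfigurationError(f"unknown predictive mode {mode!r}")


@dataclass
class PredictionSet:
    """Point predictions with a central predictive interval."""

    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    draws: np.ndarray | None = None


def prediction_interval(
    fit,
    newdata: ModelData,
    level: float = 0.9,
    rng: np.random.Generator | None = None,
) -> PredictionSet:
    """Central predictive interval at the given probability.

    ML fit: plug-in NB quantiles at ((1-level)/2, 1-(1-level)/2) using
    (mu_hat, phi_hat) — estimation uncertainty is ignored, so the interval
    is approximate.  Posterior: the same quantiles of the pooled
    posterior-predictive draws.
    """
    if not 0 < level < 1:
        raise ConfigurationError(f"level must be in (0, 1), got {level}")
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    mean = predict_mean(fit, newdata)
    if isinstance(fit, NBFit):
        p = fit.phi / (fit.phi + mean)
        lower = stats.nbinom.ppf(lo_q, fit.phi, p)
        upper = stats.nbinom.ppf(hi_q, fit.phi, p)
        return PredictionSet(mean=mean, lower=lower, upper=upper, level=level)
    if isinstance(fit, BNBPosterior):
        rng = rng if rng is not None else np.random.default_rng()
        draws = posterior_predictive_draw(fit, newdata, rng, mode="per_draw")
        lower = np.quantile(draws, lo_q, axis=0)
        upper = np.quantile(draws, hi_q, axis=0)
        return PredictionSet(mean=mean, lower=lower, upper=upper, level=level, draws=draws)
    raise DataFormatError(f"cannot build intervals from {type(fit).__name__}")
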