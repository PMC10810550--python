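"""Sequential splitting, forecast metrics and the simulation-study harness.

Metric conventions
------------------
RMSE            sqrt(mean squared error), on the count scale.
MASE            forecast MAE scaled by the in-sample one-step naive MAE of
                the *training* series (non-seasonal scaling).
percent bias    100 * mean((actual - predicted) / actual); negative values
                mean over-prediction on average.

The study harness generates replicate series per scenario, splits each
sequentially 80:20, fits the ML and Bayesian NB models on the training
segment, and averages the per-replicate metrics.  The Bayesian model's
test predictions default to a single posterior-predictive draw; a
posterior-mean mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import models as m
from . import synthetic as syn
from .exceptions import ConfigurationError, MetricError, StudyError

__all__ = [
    "SplitSeries",
    "MetricsRecord",
    "CorrelationTest",
    "sequential_split",
    "rmse",
    "mase",
    "percent_bias",
    "interval_coverage",
    "correlation_test",
    "run_simulation_study",
    "summarize_study",
    "TABLE1_COLUMNS",
]

logger = logging.getLogger(__name__)

TABLE1_COLUMNS = [
    "theta", "n",
    "BNB_bias", "NB_bias",
    "BNB_mase", "NB_mase",
    "BNB_rmse1", "NB_rmse1",
    "BNB_rmse2", "NB_rmse2",
]


@dataclass
class SplitSeries:
    """Temporally ordered train/test partition of a series."""

    train: syn.SimulatedSeries
    test: syn.SimulatedSeries
    ratio: float


def sequential_split(series: syn.SimulatedSeries, ratio: float = 0.8) -> SplitSeries:
    """First floor(ratio*n) rows train, remainder test; no shuffling."""
    if not 0 < ratio < 1:
        raise ConfigurationError(f"ratio must be in (0, 1), got {ratio}")
    n = len(series)
    if n < 5:
        raise ConfigurationError(f"series too short to split (n={n})")
    n_train = int(np.floor(ratio * n))
    if n_train < 1 or n_train >= n:
        raise ConfigurationError(f"degenerate split: n={n}, ratio={ratio}")

    def _seg(lo, hi):
        return syn.SimulatedSeries(
            time=series.time[lo:hi],
            max_temp=series.max_temp[lo:hi],
            rainfall=series.rainfall[lo:hi],
            fire_count=series.fire_count[lo:hi],
        )

    return SplitSeries(train=_seg(0, n_train), test=_seg(n_train, n), ratio=ratio)


def _aligned(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise MetricError(f"length mismatch: {a.shape} vs {p.shape}")
    if a.size < 1:
        raise MetricError("empty vectors")
    return a, p


def rmse(actual, predicted) -> float:
    a, p = _aligned(actual, predicted)
    return float(np.sqrt(np.mean((a - p) ** 2)))


def mase(actual_test, predicted_test, actual_train) -> float:
    """MAE of the forecasts over the in-sample one-step naive MAE."""
    a, p = _aligned(actual_test, predicted_test)
    train = np.asarray(actual_train, dtype=float)
    if train.size < 2:
        raise MetricError("need >= 2 training points for the naive scale")
    scale = float(np.mean(np.abs(np.diff(train))))
    if scale == 0:
        raise MetricError("constant training series: naive MAE is zero")
    return float(np.mean(np.abs(a - p)) / scale)


def percent_bias(actual, predicted, zero_policy: str = "error", eps: float = 0.5) -> float:
    """100 * mean((actual - predicted)/actual).

    ``zero_policy='error'`` rejects zero actuals; ``'epsilon'`` replaces
    them by ``eps`` in the denominator.
    """
    a, p = _aligned(actual, predicted)
    if np.any(a == 0):
        if zero_policy == "error":
            raise MetricError("zero actual values make percent bias undefined")
        if zero_policy != "epsilon":
            raise ConfigurationError(f"unknown zero_policy {zero_policy!r}")
        a = np.where(a == 0, eps, a)
    return float(100.0 * np.mean((a - p) / a))


def interval_coverage(actual, prediction_set: m.PredictionSet) -> float:
    """Fraction of actual values inside [lower, upper]."""
    a = np.asarray(actual, dtype=float)
    if a.shape != np.asarray(prediction_set.lower).shape:
        raise MetricError("actual and interval lengths differ")
    inside = (a >= prediction_set.lower) & (a <= prediction_set.upper)
    return float(np.mean(inside))


@dataclass
class CorrelationTest:
    """Pearson correlation with its t statistic (df = n - 2)."""

    r: float
    t: float
    df: int
    p: float


def correlation_test(actual, predicted) -> CorrelationTest:
    a, p = _aligned(actual, predicted)
    if a.size < 3:
        raise MetricError("need >= 3 pairs for a correlation test")
    if np.std(a) == 0 or np.std(p) == 0:
        raise MetricError("zero variance: correlation undefined")
    r = float(np.corrcoef(a, p)[0, 1])
    df = a.size - 2
    denom = max(1.0 - r * r, np.finfo(float).tiny)
    t = r * np.sqrt(df / denom)
    p_val = float(2 * stats.t.sf(abs(t), df))
    return CorrelationTest(r=r, t=float(t), df=df, p=p_val)


@dataclass
class MetricsRecord:
    """One aggregated table row: scenario x model."""

    theta: float
    n: int
    model: str
    bias_pct: float
    mase: float
    rmse_train: float
    rmse_test: float
    n_replicates: int = 0
    n_excluded: int = 0


def _replicate_metrics(
    series: syn.SimulatedSeries,
    model: str,
    split_ratio: float,
    priors: m.PriorSpec,
    sampler: m.SamplerSettings,
    bnb_prediction: str,
    rng: np.random.Generator,
) -> dict[str, float]:
    split = sequential_split(series, split_ratio)
    train = m.ModelData.from_series(split.train)
    test = m.ModelData.from_series(split.test)
    if model == "nb":
        fit = m.fit_nb(train)
        pred_train = m.predict_mean(fit, train)
        pred_test = m.predict_mean(fit, test)
    elif model == "bnb":
        post = m.fit_bnb(train, priors=priors, settings=sampler, rng=rng)
        pred_train = m.predict_mean(post, train)
        if bnb_prediction == "single_draw":
            pred_test = m.posterior_predictive_draw(post, test, rng, mode="single_draw")
        elif bnb_prediction == "posterior_mean":
            pred_test = m.predict_mean(post, test)
        else:
            raise ConfigurationError(f"unknown bnb_prediction {bnb_prediction!r}")
    else:
        raise ConfigurationError(f"unknown model {model!r}")
    return {
        "bias_pct": percent_bias(test.y, pred_test, zero_policy="epsilon"),
        "mase": mase(test.y, pred_test, train.y),
        "rmse_train": rmse(train.y, pred_train),
        "rmse_test": rmse(test.y, pred_test),
    }


def run_simulation_study(
    grid: list[syn.ScenarioConfig],
    tn: syn.TruncNormalSpec | None = None,
    rain: syn.RainfallModelSpec | None = None,
    count: syn.CountModelSpec | None = None,
    models: tuple[str, ...] = ("nb", "bnb"),
    split_ratio: float = 0.8,
    priors: m.PriorSpec | None = None,
    sampler: m.SamplerSettings | None = None,
    bnb_prediction: str = "single_draw",
    max_failure_rate: float = 0.2,
    return_replicates: bool = False,
):
    """Run the full scenario x replicate x model study.

    Returns aggregated ``MetricsRecord`` rows (means over replicates); with
    ``return_replicates=True`` also the long per-replicate DataFrame.
    Replicate-level fit failures are logged and excluded; a scenario with
    more than ``max_failure_rate`` failures for a model aborts the study.
    """
    if not grid:
        raise ConfigurationError("empty scenario grid")
    tn = tn or syn.TruncNormalSpec()
    rain = rain or syn.RainfallModelSpec()
    count = count or syn.CountModelSpec()
    priors = priors or m.PriorSpec()
    sampler = sampler or m.SamplerSettings()

    records: list[MetricsRecord] = []
    rep_rows: list[dict] = []
    for scenario in grid:
        for model in models:
            per_rep: list[dict[str, float]] = []
            failures = 0
            for rep in range(scenario.n_replicates):
                series = syn.generate_series(scenario, tn, rain, count, replicate_id=rep)
                # metric/sampling stream independent of the generator stream
                rep_rng = np.random.default_rng(
                    np.random.SeedSequence(
                        [scenario.master_seed, scenario.n, rep, 2_000_001]
                    )
                )
                try:
                    vals = _replicate_metrics(
                        series, model, split_ratio, priors, sampler,
                        bnb_prediction, rep_rng,
                    )
                except Exception as exc:  # noqa: BLE001 — excluded, reported
                    failures += 1
                    logger.warning(
                        "replicate excluded (theta=%s n=%s rep=%s model=%s): %s",
                        scenario.theta, scenario.n, rep, model, exc,
                    )
                    continue
                per_rep.append(vals)
                rep_rows.append(
                    {"theta": scenario.theta, "n": scenario.n,
                     "replicate": rep, "model": model, **vals}
                )
            if failures > max_failure_rate * scenario.n_replicates:
                raise StudyError(
                    f"{failures}/{scenario.n_replicates} replicates failed for "
                    f"model={model} theta={scenario.theta} n={scenario.n}"
                )
            if not per_rep:
                raise StudyError(
                    f"no surviving replicates for model={model} "
                    f"theta={scenario.theta} n={scenario.n}"
                )
            agg = {k: float(np.mean([v[k] for v in per_rep])) for k in per_rep[0]}
            records.append(
                MetricsRecord(
                    theta=scenario.theta, n=scenario.n, model=model,
                    bias_pct=agg["bias_pct"], mase=agg["mase"],
                    rmse_train=agg["rmse_train"], rmse_test=agg["rmse_test"],
                    n_replicates=len(per_rep), n_excluded=failures,
                )
            )
    if return_replicates:
        return records, pd.DataFrame(rep_rows)
    return records


def summarize_study(records: list[MetricsRecord]) -> pd.DataFrame:
    """Wide summary table, one row per (theta, n), paired model columns."""
    if not records:
        raise ConfigurationError("no records to summarize")
    by_cell: dict[tuple[float, int], dict[str, MetricsRecord]] = {}
    for rec in records:
        by_cell.setdefault((rec.theta, rec.n), {})[rec.model] = rec
    rows = []
    for (theta, n), cell in sorted(by_cell.items()):
        missing = {"nb", "bnb"} - set(cell)
        if missing:
            raise StudyError(
                f"missing model arm {sorted(missing)} for theta={theta}, n={n}"
            )
        nb, bnb = cell["nb"], cell["bnb"]
        rows.append(
            {
                "theta": theta, "n": n,
                "BNB_bias": bnb.bias_pct, "NB_bias": nb.bias_pct,
                "BNB_mase": bnb.mase, "NB_mase": nb.mase,
                "BNB_rmse1": bnb.rmse_train, "NB_rmse1": nb.rmse_train,
                "BNB_rmse2": bnb.rmse_test, "NB_rmse2": nb.rmse_test,
            }
        )
    return pd.DataFrame(rows, columns=TABLE1_COLUMNS)
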