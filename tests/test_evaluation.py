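"""Sequential split, forecast metrics, and the simulation-study harness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from firefreq import evaluation as ev
from firefreq import models as m
from firefreq import synthetic as syn
from firefreq.exceptions import ConfigurationError, MetricError, StudyError


def series_of(counts):
    n = len(counts)
    return syn.SimulatedSeries(
        time=np.arange(1, n + 1),
        max_temp=np.full(n, 29.0),
        rainfall=np.full(n, 84.0),
        fire_count=np.asarray(counts, dtype=int),
    )


class TestSequentialSplit:
    @pytest.mark.parametrize(
        "n,ratio,expected",
        [(60, 0.8, (48, 12)), (218, 0.8, (174, 44)), (10, 0.85, (8, 2))],
    )
    def test_floor_rule_sizes(self, n, ratio, expected):
        split = ev.sequential_split(series_of(np.ones(n)), ratio)
        assert (len(split.train), len(split.test)) == expected

    def test_partition_preserves_order(self, small_series):
        split = ev.sequential_split(small_series, 0.8)
        rejoined = np.concatenate([split.train.fire_count, split.test.fire_count])
        assert np.array_equal(rejoined, small_series.fire_count)
        assert split.train.time[-1] + 1 == split.test.time[0]

    def test_too_short_series_rejected(self):
        with pytest.raises(ConfigurationError):
            ev.sequential_split(series_of([1, 2, 3]), 0.8)

    def test_invalid_ratio_rejected(self, small_series):
        with pytest.raises(ConfigurationError):
            ev.sequential_split(small_series, 1.2)


class TestRmse:
    def test_hand_computed_value(self):
        assert ev.rmse([1, 2, 3], [1, 2, 5]) == pytest.approx(np.sqrt(4 / 3))

    def test_perfect_prediction_is_zero(self):
        assert ev.rmse([4, 5, 6], [4, 5, 6]) == 0.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(c=st.floats(0.1, 100), seed=st.integers(0, 1000))
    def test_positive_homogeneity(self, c, seed):
        rng = np.random.default_rng(seed)
        a, p = rng.uniform(1, 50, 10), rng.uniform(1, 50, 10)
        assert ev.rmse(c * a, c * p) == pytest.approx(c * ev.rmse(a, p), rel=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(MetricError):
            ev.rmse([1, 2], [1])


class TestMase:
    def test_perfect_prediction_is_zero(self):
        assert ev.mase([10, 20], [10, 20], [1, 2, 3]) == 0.0

    def test_hand_computed_value(self):
        # naive in-sample MAE of (1,2,3) is 1; forecast MAE is 1
        assert ev.mase([10, 20], [11, 19], [1, 2, 3]) == pytest.approx(1.0)

    def test_scale_invariance(self):
        base = ev.mase([10, 20], [11, 19], [1, 2, 3])
        assert ev.mase([100, 200], [110, 190], [10, 20, 30]) == pytest.approx(base)

    def test_constant_training_series_rejected(self):
        with pytest.raises(MetricError):
            ev.mase([1, 2], [1, 2], [5, 5, 5])


class TestPercentBias:
    def test_perfect_prediction_is_zero(self):
        assert ev.percent_bias([10, 20], [10, 20]) == 0.0

    def test_overprediction_is_negative(self):
        assert ev.percent_bias([100], [110]) == pytest.approx(-10.0)

    def test_scale_invariance(self):
        assert ev.percent_bias([50, 100], [60, 90]) == pytest.approx(
            ev.percent_bias([500, 1000], [600, 900])
        )

    def test_zero_actual_policy(self):
        with pytest.raises(MetricError):
            ev.percent_bias([0, 10], [1, 10])
        val = ev.percent_bias([0, 10], [1, 10], zero_policy="epsilon", eps=0.5)
        assert np.isfinite(val)


class TestIntervalCoverage:
    def test_all_inside(self):
        pset = m.PredictionSet(mean=np.full(5, 10.0), lower=np.zeros(5),
                               upper=np.full(5, 20.0), level=0.9)
        assert ev.interval_coverage(np.full(5, 10.0), pset) == 1.0

    def test_partial_coverage(self):
        pset = m.PredictionSet(mean=np.full(10, 5.0), lower=np.zeros(10),
                               upper=np.full(10, 9.0), level=0.9)
        actual = np.array([1.0] * 9 + [50.0])
        assert ev.interval_coverage(actual, pset) == pytest.approx(0.9)


class TestCorrelationTest:
    def _pair_with_correlation(self, r, n, seed=0):
        """Construct a sample with exactly the requested Pearson r."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        z = z - z.mean()
        z -= x * (x @ z) / (x @ x)
        z /= z.std()
        y = r * x + np.sqrt(1 - r**2) * z
        return x, y

    def test_perfect_linear_pairs(self):
        res = ev.correlation_test([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.r == pytest.approx(1.0)

    @pytest.mark.parametrize("r,expected_t", [(0.32, 2.19), (-0.07, -0.45)])
    def test_t_statistic_closed_form_at_df_42(self, r, expected_t):
        x, y = self._pair_with_correlation(r, 44)
        res = ev.correlation_test(x, y)
        assert res.df == 42
        assert res.r == pytest.approx(r, abs=1e-9)
        assert res.t == pytest.approx(expected_t, abs=0.01)

    def test_p_value_matches_t_reference(self):
        from scipy import stats

        x, y = self._pair_with_correlation(0.32, 44)
        res = ev.correlation_test(x, y)
        assert res.p == pytest.approx(2 * stats.t.sf(abs(res.t), 42), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(MetricError):
            ev.correlation_test([1, 1, 1, 1], [1, 2, 3, 4])


@pytest.fixture(scope="module")
def tiny_study():
    """Full 16-cell grid, 1 replicate, short chains: structure checks."""
    grid = syn.scenario_grid([1.5, 5.0, 10.0, 100.0], [60, 120, 240, 360],
                             n_replicates=1, master_seed=76568)
    sampler = m.SamplerSettings(n_walkers=12, n_warmup=150, n_keep=80)
    return ev.run_simulation_study(grid, sampler=sampler, return_replicates=True)


class TestStudyHarness:
    def test_full_grid_yields_32_aggregated_records(self, tiny_study):
        records, reps = tiny_study
        assert len(records) == 32
        assert len(reps) == 32
        assert set(reps["model"]) == {"nb", "bnb"}

    def test_fixed_seed_rerun_is_identical(self):
        grid = syn.scenario_grid([1.5], [60], n_replicates=1, master_seed=76568)
        sampler = m.SamplerSettings(n_walkers=12, n_warmup=100, n_keep=50)
        out = [
            ev.summarize_study(ev.run_simulation_study(grid, sampler=sampler)).to_csv()
            for _ in range(2)
        ]
        assert out[0] == out[1]

    def test_theta_insensitivity_of_residual_mode_generator(self):
        # residual-perturbation generation never consumes theta, so metrics
        # at fixed (n, seed) match across dispersion scenarios
        sampler = m.SamplerSettings(n_walkers=12, n_warmup=150, n_keep=80)
        vals = {}
        for theta in (1.5, 100.0):
            grid = syn.scenario_grid([theta], [60], n_replicates=2, master_seed=76568)
            records = ev.run_simulation_study(grid, sampler=sampler)
            vals[theta] = {(r.model): (r.mase, r.bias_pct, r.rmse_test)
                           for r in records}
        for model in ("nb", "bnb"):
            a, b = np.array(vals[1.5][model]), np.array(vals[100.0][model])
            assert np.all(np.abs(a - b) <= 0.05 * np.abs(a))

    def test_test_rmse_decreases_with_sample_size(self):
        # longer series -> better-estimated model -> lower test error
        # posterior-mean BNB predictions: isolates estimation error from
        # predictive-draw noise so the direction is visible at few replicates
        grid = syn.scenario_grid([1.5], [60, 360], n_replicates=3, master_seed=76568)
        sampler = m.SamplerSettings(n_walkers=12, n_warmup=200, n_keep=100)
        records = ev.run_simulation_study(grid, sampler=sampler,
                                          bnb_prediction="posterior_mean")
        by = {(r.model, r.n): r.rmse_test for r in records}
        assert by[("nb", 360)] < by[("nb", 60)]
        assert by[("bnb", 360)] < by[("bnb", 60)]

    def test_failures_are_excluded_and_reported(self, monkeypatch):
        grid = syn.scenario_grid([1.5], [60], n_replicates=5, master_seed=1)
        calls = {"n": 0}
        real_fit = m.fit_nb

        def flaky_fit(data):
            calls["n"] += 1
            if calls["n"] == 2:
                raise ConfigurationError("synthetic failure")
            return real_fit(data)

        monkeypatch.setattr(ev.m, "fit_nb", flaky_fit)
        records = ev.run_simulation_study(grid, models=("nb",))
        assert records[0].n_excluded == 1
        assert records[0].n_replicates == 4

    def test_excessive_failures_abort_study(self, monkeypatch):
        grid = syn.scenario_grid([1.5], [60], n_replicates=3, master_seed=1)

        def always_fail(data):
            raise ConfigurationError("synthetic failure")

        monkeypatch.setattr(ev.m, "fit_nb", always_fail)
        with pytest.raises(StudyError):
            ev.run_simulation_study(grid, models=("nb",))


class TestSummarizeStudy:
    def test_wide_table_shape_and_columns(self, tiny_study):
        records, _ = tiny_study
        table = ev.summarize_study(records)
        assert table.shape == (16, 10)
        assert list(table.columns) == ev.TABLE1_COLUMNS

    def test_csv_round_trip_preserves_values(self, tiny_study, tmp_path):
        records, _ = tiny_study
        table = ev.summarize_study(records)
        path = tmp_path / "table1.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, table, check_exact=False, rtol=1e-12)

    def test_missing_model_arm_rejected(self, tiny_study):
        records, _ = tiny_study
        nb_only = [r for r in records if r.model == "nb"]
        with pytest.raises(StudyError):
            ev.summarize_study(nb_only)
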