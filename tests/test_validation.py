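"""Error curves, cross-validation, transfer and distribution sharpening."""

import numpy as np
import pandas as pd
import pytest

from fetalclock.errors import EmptySummaryError, InsufficientDataError
from fetalclock.model import Status, TrainConfig
from fetalclock.simulate import SimulationConfig, simulate_cohort
from fetalclock.validation import (
    compile_week_distribution,
    fit_baseline_polynomial,
    forecast_error_curve,
    half_interval_95,
    interval_error_curve,
    plot_error_curves,
    run_crossvalidation,
    single_visit_error_curve,
    transfer_evaluation,
)


class TestHalfInterval95:
    def test_degenerate_zero_errors(self):
        assert half_interval_95(np.zeros(100)) == 0.0

    def test_standard_normal_analytic_value(self, rng):
        draws = rng.standard_normal(100_000)
        assert half_interval_95(draws) == pytest.approx(1.96, abs=0.02)

    def test_matches_sort_and_index_oracle(self, rng):
        for n in (25, 100, 999):
            e = rng.normal(2.0, 5.0, size=n)
            s = np.sort(e)

            def quantile(q):  # linear interpolation between order statistics
                h = (n - 1) * q
                lo = int(np.floor(h))
                return s[lo] + (h - lo) * (s[min(lo + 1, n - 1)] - s[lo])

            expected = (quantile(0.975) - quantile(0.025)) / 2.0
            assert half_interval_95(e) == pytest.approx(expected, rel=1e-12)

    def test_insufficient_sample(self):
        with pytest.raises(InsufficientDataError):
            half_interval_95(np.zeros(19))


class PerfectIntervalStub:
    """Oracle estimator: looks up the true GA of each scan by its biometry."""

    method_label = "perfect"

    def __init__(self, df):
        self._truth = {
            tuple(np.round(row, 9)): t
            for row, t in zip(
                df[["hc_mm", "ac_mm", "fl_mm"]].to_numpy(), df["true_ga_days"]
            )
        }

    def _lookup(self, B):
        return np.array([self._truth[tuple(np.round(r, 9))] for r in np.atleast_2d(B)])

    def estimate_interval_batch(self, B1, B2):
        g1, g2 = self._lookup(B1), self._lookup(B2)
        status = np.full(len(g1), Status.OK.value)
        return g2 - g1, g1, g2, status


class TestIntervalErrorCurve:
    def test_perfect_estimator_gives_zero_half_widths(self, medium_test_cohort):
        df = medium_test_cohort.to_dataframe()
        summary = interval_error_curve(PerfectIntervalStub(df), medium_test_cohort,
                                       min_bin_n=20)
        hw = summary.frame.half_width_95_days.dropna()
        assert len(hw) > 0
        assert np.allclose(hw, 0.0, atol=1e-9)
        assert summary.n_refused == 0

    def test_eligible_pairs_match_census_oracle(self, medium_results, medium_test_cohort):
        summary = interval_error_curve(medium_results, medium_test_cohort)
        df = medium_test_cohort.to_dataframe().sort_values(["fetus_id", "visit_index"])
        count = 0
        for _, g in df.groupby("fetus_id"):
            t = g.true_ga_days.to_numpy()
            for a in range(len(t)):
                for b in range(a + 1, len(t)):
                    if 28.0 <= t[b] - t[a] <= 70.0:
                        count += 1
        assert summary.n_eligible == count
        assert summary.n_evaluated + summary.n_refused + summary.n_out_of_support == count

    def test_empty_gap_range_raises(self, medium_test_cohort):
        with pytest.raises(EmptySummaryError):
            interval_error_curve(None, medium_test_cohort, gap_range=(1.0, 2.0))

    def test_small_bias_on_default_simulation(self, medium_results, medium_test_cohort):
        summary = interval_error_curve(medium_results, medium_test_cohort)
        assert abs(summary.pooled_bias()) < 1.0


class TestSingleVisitErrorCurve:
    def test_conservation_of_eligible_scans(self, medium_results, medium_test_cohort):
        s = single_visit_error_curve(medium_results, medium_test_cohort)
        assert s.n_evaluated + s.n_refused + s.n_out_of_support == s.n_eligible

    def test_single_visit_no_better_than_two_visits(self, medium_cohort):
        """Where method B answers at all, its curve sits above method A:
        one blinded scan cannot beat two."""
        from fetalclock.model import GestationalClockModel
        from tests.conftest import MEDIUM_TRAIN

        # a low-heterogeneity population where refusals are not universal
        cfg = SimulationConfig(n_fetuses=800, seed=31, sigma_rho=0.012)
        cohort = simulate_cohort(cfg)
        res = GestationalClockModel(cohort, MEDIUM_TRAIN).fit()
        test = simulate_cohort(cfg.replace(n_fetuses=400, seed=32))
        sA = interval_error_curve(res, test, min_bin_n=30)
        sB = single_visit_error_curve(res, test, min_bin_n=30)
        assert sB.n_evaluated >= 100
        pooled_a = sA.pooled_half_width()
        pooled_b = sB.pooled_half_width()
        assert pooled_b > pooled_a


class TestForecastErrorCurve:
    def test_triple_census_matches_brute_force(self, medium_results, medium_test_cohort):
        s = forecast_error_curve(medium_results, medium_test_cohort, horizon_days=42.0)
        df = medium_test_cohort.to_dataframe().sort_values(["fetus_id", "visit_index"])
        count = 0
        for _, g in df.groupby("fetus_id"):
            t = g.true_ga_days.to_numpy()
            for j in range(1, len(t) - 1):
                for k in range(j + 1, len(t)):
                    if abs(t[k] - t[j] - 42.0) <= 7.0:
                        count += 1
        assert s.n_eligible == count

    def test_forecast_errors_centred(self, medium_results, medium_test_cohort):
        s = forecast_error_curve(medium_results, medium_test_cohort)
        assert abs(np.mean(s.errors)) < 1.5


class TestBaseline:
    def test_recovers_ga_on_clean_cohort(self, clean_cohort):
        df = clean_cohort.to_dataframe()
        base = fit_baseline_polynomial(df)
        err = base.predict_ga(df) - df.nominal_ga_days.to_numpy()
        assert np.sqrt(np.mean(err**2)) < 1.0

    def test_single_scan_error_degrades_with_ga(self, medium_cohort):
        df = medium_cohort.to_dataframe()
        base = fit_baseline_polynomial(df)
        test = simulate_cohort(SimulationConfig(n_fetuses=600, seed=41)).to_dataframe()
        err = base.predict_ga(test) - test.true_ga_days.to_numpy()
        ga = test.nominal_ga_days.to_numpy()
        hw20 = half_interval_95(err[(ga >= 140) & (ga < 154)])
        hw29 = half_interval_95(err[(ga >= 196) & (ga < 210)])
        assert hw29 > hw20
        # degradation pattern on the scale reported for conventional dating
        assert 6.0 < hw20 < 14.0
        assert 10.0 < hw29 < 20.0

    def test_interval_interface_never_refuses(self, medium_cohort, medium_test_cohort):
        base = fit_baseline_polynomial(medium_cohort.to_dataframe())
        s = interval_error_curve(base, medium_test_cohort)
        assert s.n_refused == 0
        assert s.method == "baseline"


class TestWeekDistribution:
    def test_week_selection_convention(self):
        n = 300
        df = pd.DataFrame(
            {
                "fetus_id": [f"F{i}" for i in range(n)],
                "visit_index": 1,
                "nominal_ga_days": np.linspace(181.0, 189.5, n),
                "hc_mm": np.full(n, 230.0),
                "ac_mm": np.full(n, 210.0),
                "fl_mm": np.full(n, 45.0),
            }
        )
        dist = compile_week_distribution(df, 26, clock="nominal", min_n=10)
        lo, hi = 182.0, 189.0
        expected = int(((df.nominal_ga_days >= lo) & (df.nominal_ga_days < hi)).sum())
        assert dist.n == expected

    def test_true_clock_sharper_than_nominal(self, medium_cohort):
        dn = compile_week_distribution(medium_cohort, 26, clock="nominal")
        dt = compile_week_distribution(medium_cohort, 26, clock="true")
        assert np.mean([dt.sd_mm[k] / dn.sd_mm[k] for k in dt.sd_mm]) < 1.0

    def test_insufficient_scans_raise(self, small_cohort):
        with pytest.raises(EmptySummaryError):
            compile_week_distribution(small_cohort, 26, clock="nominal", min_n=10**6)


class TestCrossValidation:
    def test_each_fetus_tested_exactly_once_and_pooling_law(self, small_cohort):
        cfg = TrainConfig(series_length=96, scans_per_day=5.0)
        cv = run_crossvalidation(small_cohort, 3, config=cfg, seed=5, min_bin_n=30)
        tested = [set() for _ in range(cv.n_folds)]
        for fid, k in cv.fold_of_fetus.items():
            tested[k - 1].add(fid)
        all_ids = {f.fetus_id for f in small_cohort}
        assert set().union(*tested) == all_ids
        assert sum(len(t) for t in tested) == len(all_ids)
        assert len(cv.pooled.errors) == sum(len(s.errors) for s in cv.fold_summaries)

    def test_pooled_summary_equals_concatenation(self, small_cohort):
        cfg = TrainConfig(series_length=96, scans_per_day=5.0)
        cv = run_crossvalidation(small_cohort, 3, config=cfg, seed=5, min_bin_n=30)
        manual = np.sort(np.concatenate([s.errors for s in cv.fold_summaries]))
        assert np.allclose(np.sort(cv.pooled.errors), manual)


class TestTransfer:
    def test_null_transfer_differences_are_sampling_noise(
        self, medium_results, medium_test_cohort
    ):
        same_again = simulate_cohort(SimulationConfig(n_fetuses=300, seed=99))
        tr = transfer_evaluation(medium_results, medium_test_cohort, same_again,
                                 min_bin_n=30)
        assert tr.max_abs_diff_days < 3.5

    def test_comparison_table_covers_headline_weeks(self, medium_results,
                                                    medium_test_cohort):
        same_again = simulate_cohort(SimulationConfig(n_fetuses=300, seed=99))
        tr = transfer_evaluation(medium_results, medium_test_cohort, same_again,
                                 min_bin_n=30)
        assert tr.comparison.week.between(20, 29).all()
        assert (tr.comparison.abs_diff >= 0).all()


def test_plot_error_curves_writes_file(tmp_path, medium_results, medium_test_cohort):
    s = interval_error_curve(medium_results, medium_test_cohort)
    out = tmp_path / "curves.png"
    plot_error_curves([s], out)
    assert out.exists() and out.stat().st_size > 0
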