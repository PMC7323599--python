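"""Supervectors, diffusion embedding and clock refinement."""

import numpy as np
import pytest
from scipy import stats

from fetalclock.errors import (
    DegenerateDataError,
    EmbeddingQualityError,
    InsufficientDataError,
)
from fetalclock.manifold import (
    Supervectors,
    build_supervectors,
    diffusion_embedding,
    refine_training_clock,
    standardize,
)
from fetalclock.model import GestationalClockModel
from fetalclock.sampling import thin_to_uniform
from tests.conftest import SMALL_TRAIN


def _standardized_sample(cohort, scans_per_day=6.0, ga_range=(98, 294), seed=0):
    sample = thin_to_uniform(cohort, scans_per_day, ga_range, seed=seed)
    return standardize(sample)


class TestStandardize:
    def test_zero_mean_unit_variance(self, small_cohort):
        sample, params = _standardized_sample(small_cohort)
        Z = sample.frame[["hc_std", "ac_std", "fl_std"]].to_numpy()
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(Z.std(axis=0), 1.0, atol=1e-9)

    def test_stored_params_reproduce_training_standardization(self, small_cohort):
        sample, params = _standardized_sample(small_cohort)
        X = sample.frame[["hc_mm", "ac_mm", "fl_mm"]].to_numpy()
        Z = sample.frame[["hc_std", "ac_std", "fl_std"]].to_numpy()
        assert np.allclose(params.apply(X), Z)
        assert np.allclose(params.invert(Z), X)

    def test_constant_measure_is_degenerate(self, small_cohort):
        sample = thin_to_uniform(small_cohort, 6.0, (98, 294), seed=0)
        sample.frame["hc_mm"] = 123.0
        with pytest.raises(DegenerateDataError):
            standardize(sample)


class TestBuildSupervectors:
    def test_window_count_and_dimension(self, small_cohort):
        sample, _ = _standardized_sample(small_cohort)
        c = 64
        sv = build_supervectors(sample, c)
        assert sv.n_windows == sample.n_scans - c + 1
        assert sv.X.shape == (sv.n_windows, 3 * c)

    def test_single_window_at_boundary(self, small_cohort):
        sample, _ = _standardized_sample(small_cohort)
        sv = build_supervectors(sample, sample.n_scans)
        assert sv.n_windows == 1

    def test_insufficient_data_error_names_sizes(self, small_cohort):
        sample, _ = _standardized_sample(small_cohort)
        with pytest.raises(InsufficientDataError, match=str(sample.n_scans)):
            build_supervectors(sample, sample.n_scans + 1)

    def test_center_ga_is_mean_of_members(self, small_cohort):
        sample, _ = _standardized_sample(small_cohort)
        sv = build_supervectors(sample, 32)
        ga = sample.frame["nominal_ga_days"].to_numpy()
        assert sv.center_ga_days[5] == pytest.approx(ga[5:37].mean())


class TestDiffusionEmbedding:
    def test_markov_spectrum(self, clean_cohort):
        sample, _ = _standardized_sample(clean_cohort)
        sv = build_supervectors(sample, 64)
        emb = diffusion_embedding(sv, n_components=6)
        assert np.all(np.diff(emb.eigenvalues) <= 1e-12)
        assert np.all(emb.eigenvalues > 0)
        assert np.all(emb.eigenvalues <= 1.0)

    def test_principal_coordinate_tracks_time_on_clean_data(self, clean_cohort):
        sample, _ = _standardized_sample(clean_cohort)
        sv = build_supervectors(sample, 64)
        emb = diffusion_embedding(sv, n_components=6)
        rho = stats.spearmanr(emb.coords[:, 0], sv.center_ga_days).statistic
        assert rho >= 0.999

    def test_order_equivariance(self, clean_cohort):
        sample, _ = _standardized_sample(clean_cohort)
        sv = build_supervectors(sample, 64)
        keep = slice(0, 300)  # dense eigensolver path
        base = Supervectors(X=sv.X[keep], center_ga_days=sv.center_ga_days[keep], c=sv.c)
        perm = np.random.default_rng(0).permutation(base.n_windows)
        permuted = Supervectors(
            X=base.X[perm], center_ga_days=base.center_ga_days[perm], c=base.c
        )
        e1 = diffusion_embedding(base, n_components=3)
        e2 = diffusion_embedding(permuted, n_components=3)
        assert np.allclose(e1.eigenvalues, e2.eigenvalues, atol=1e-9)
        assert np.allclose(e1.coords[perm, 0], e2.coords[:, 0], atol=1e-6)


class TestClockRefinement:
    def _refine(self, cohort, c=128, spd=6.0, **kw):
        sample, _ = _standardized_sample(cohort, scans_per_day=spd)
        sv = build_supervectors(sample, c)
        emb = diffusion_embedding(sv)
        return sample, refine_training_clock(emb, sv, sample, **kw)

    def test_nothing_to_correct_on_clean_cohort(self, clean_cohort):
        sample, ref = self._refine(clean_cohort)
        nominal = sample.frame["nominal_ga_days"].to_numpy()
        rms = np.sqrt(np.mean((ref.refined_ga_days - nominal) ** 2))
        assert rms < 0.5

    def test_refined_clock_beats_nominal(self, medium_results):
        true = medium_results.train_true_ga
        rms_ref = np.sqrt(np.mean((medium_results.refined_ga_days - true) ** 2))
        rms_nom = np.sqrt(np.mean((medium_results.train_nominal_ga - true) ** 2))
        assert rms_ref < rms_nom

    def test_clock_recovery_correlation(self, medium_results):
        true = medium_results.train_true_ga
        corr_ref = np.corrcoef(medium_results.refined_ga_days, true)[0, 1]
        corr_nom = np.corrcoef(medium_results.train_nominal_ga, true)[0, 1]
        assert corr_ref > 0.99
        assert stats.spearmanr(medium_results.refined_ga_days, true).statistic > 0.99
        # refined clock must not lose the ordering information nominal GA has
        assert corr_ref > corr_nom - 0.005

    def test_calibration_stays_inside_support(self, small_cohort):
        _, ref = self._refine(small_cohort)
        lo, hi = ref.ga_support
        assert np.all(ref.window_ga_days >= lo - 1e-9)
        assert np.all(ref.window_ga_days <= hi + 1e-9)

    def test_quality_gate_raises_when_threshold_unreachable(self, small_cohort):
        with pytest.raises(EmbeddingQualityError):
            self._refine(small_cohort, min_spearman=1.01)

    def test_flank_law(self, medium_results):
        cfg = medium_results.config
        flank = cfg.series_length / (2.0 * cfg.scans_per_day)
        lo, hi = medium_results.ga_support
        expected_lo = cfg.ga_range_days[0] + flank
        expected_hi = cfg.ga_range_days[1] - flank
        assert lo == pytest.approx(expected_lo, abs=0.2 * flank + 2.0)
        assert hi == pytest.approx(expected_hi, abs=0.2 * flank + 2.0)


class TestTrajectoryCoordinate:
    def test_zero_mean(self, medium_results):
        assert np.mean(medium_results.trajectory_coord) == pytest.approx(0.0, abs=1e-9)

    def test_recovers_growth_rate_factor(self, medium_results, medium_latents):
        import pandas as pd

        per = (
            pd.DataFrame(
                {"fid": medium_results.train_fetus_ids,
                 "d": medium_results.trajectory_coord}
            )
            .groupby("fid")["d"].mean()
        )
        rho = medium_latents.set_index("fetus_id").rho.loc[per.index]
        assert abs(stats.spearmanr(per, rho).statistic) >= 0.6

    def test_variance_collapses_without_heterogeneity(self, clean_results, medium_results):
        # clean cohort: no growth-rate or time-zero spread, so the trajectory
        # coordinate is measurement-noise floor only
        assert np.std(clean_results.trajectory_coord) < 0.3 * np.std(
            medium_results.trajectory_coord
        )


class TestModelLifecycle:
    def test_fit_is_deterministic(self, small_cohort):
        r1 = GestationalClockModel(small_cohort, SMALL_TRAIN).fit()
        r2 = GestationalClockModel(small_cohort, SMALL_TRAIN).fit()
        assert np.array_equal(r1.refined_ga_days, r2.refined_ga_days)
        assert np.array_equal(r1.trajectory_coord, r2.trajectory_coord)
        assert r1.ga_support == r2.ga_support

    def test_save_load_round_trip(self, tmp_path, small_results, small_cohort):
        path = tmp_path / "model.mgam.npz"
        small_results.save(path)
        from fetalclock.model import GestationalClockResults

        back = GestationalClockResults.load(path)
        B = small_cohort.to_dataframe()[["hc_mm", "ac_mm", "fl_mm"]].to_numpy()[:10]
        ga1, st1, sp1, hw1 = small_results.estimate_single_batch(B)
        ga2, st2, sp2, hw2 = back.estimate_single_batch(B)
        np.testing.assert_array_equal(st1, st2)
        np.testing.assert_array_equal(ga1, ga2)
        np.testing.assert_array_equal(sp1, sp2)

    def test_summary_mentions_support_and_series_length(self, small_results):
        text = small_results.summary()
        assert "series length" in text
        assert str(small_results.config.series_length) in text
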