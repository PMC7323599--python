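"""Validation protocols: error curves, cross-validation, transfer testing.

Accuracy is always referred to *exactly known facts* about each fetus --
the time intervals between its visits -- never to the LMP-based dates:

* **method A**: the estimator sees two blinded scans of a test fetus and
  must recover the interval separating them;
* **method B**: the estimator sees one blinded scan and must estimate
  gestational age; the reference is the two-visit anchored estimate, which
  is deduced from the exactly known elapsed time between two visits;
* **method C**: the estimator sees two blinded scans and must forecast the
  time to a subsequent scan.

The accuracy currency is the 95% half-interval, (q97.5 - q2.5)/2 of the
signed error distribution, reported per 7-day bin of (LMP-based) first-scan
gestational age.  Estimators only ever receive biometry arrays, so test
nominal ages are structurally blinded; they are used solely to form
ground-truth intervals and bin labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from sklearn.preprocessing import PolynomialFeatures, StandardScaler

from .cohort import Cohort, week_bin
from .errors import (
    DegenerateDataError,
    EmptySummaryError,
    InsufficientDataError,
)
from .model import GestationalClockResults, Status, TrainConfig
from .sampling import kfold_split

#: Default reporting bins: gestational weeks 17-33.
DEFAULT_WEEKS = tuple(range(17, 34))
#: Headline evaluation window, 20-30 weeks in days.
HEADLINE_WINDOW_DAYS = (140.0, 210.0)
#: Eligible intervisit gaps: 4-10 weeks.
DEFAULT_GAP_RANGE_DAYS = (28.0, 70.0)
#: Minimum sample in a bin before a half-interval is reported.
MIN_BIN_N = 50


def half_interval_95(errors) -> float:
    """Half-width of the 95% interval of a signed error sample (days).

    (97.5th - 2.5th percentile) / 2, quantiles by linear interpolation.
    """
    e = np.asarray(errors, dtype=float)
    if e.size < 20:
        raise InsufficientDataError(f"need >= 20 errors for a 95% half-interval, got {e.size}")
    q_lo, q_hi = np.quantile(e, [0.025, 0.975], method="linear")
    return float((q_hi - q_lo) / 2.0)


@dataclass
class ErrorSummary:
    """Per-GA-bin 95% half-interval curve plus the raw error sample.

    ``frame`` has one row per reported week with columns
    ``week, n, half_width_95_days, bias_days, refusals, out_of_support``.
    The raw signed errors (and their first-scan GA and gap) are retained so
    curves can be pooled or re-stratified without re-running the estimator.
    """

    method: str
    weeks: tuple[int, ...]
    frame: pd.DataFrame
    errors: np.ndarray
    first_ga_days: np.ndarray
    gap_days: np.ndarray
    n_eligible: int
    n_refused: int
    n_out_of_support: int

    @property
    def n_evaluated(self) -> int:
        return len(self.errors)

    def pooled_half_width(self, ga_window=HEADLINE_WINDOW_DAYS) -> float:
        lo, hi = ga_window
        mask = (self.first_ga_days >= lo) & (self.first_ga_days < hi)
        return half_interval_95(self.errors[mask])

    def pooled_bias(self, ga_window=HEADLINE_WINDOW_DAYS) -> float:
        lo, hi = ga_window
        mask = (self.first_ga_days >= lo) & (self.first_ga_days < hi)
        return float(np.mean(self.errors[mask]))


def _summarize(
    method: str,
    errors: np.ndarray,
    first_ga: np.ndarray,
    gaps: np.ndarray,
    statuses: np.ndarray,
    weeks=DEFAULT_WEEKS,
    min_bin_n: int = MIN_BIN_N,
) -> ErrorSummary:
    """Bin signed errors by week; all four arrays have one entry per
    eligible unit (``errors`` is NaN where the unit was not evaluated)."""
    statuses = np.asarray(statuses)
    ok = statuses == Status.OK.value
    refused = statuses == Status.NEEDS_MORE_DATA.value
    out_sup = statuses == Status.OUT_OF_SUPPORT.value
    rows = []
    for w in weeks:
        lo, hi = week_bin(w)
        in_bin = (first_ga >= lo) & (first_ga < hi)
        e = errors[in_bin & ok]
        n_ok = len(e)
        rows.append(
            {
                "week": w,
                "n": n_ok,
                "half_width_95_days": half_interval_95(e)
                if n_ok >= max(min_bin_n, 20)
                else np.nan,
                "bias_days": float(np.mean(e)) if n_ok else np.nan,
                "refusals": int(np.sum(in_bin & refused)),
                "out_of_support": int(np.sum(in_bin & out_sup)),
            }
        )
    frame = pd.DataFrame(rows)
    return ErrorSummary(
        method=method,
        weeks=tuple(weeks),
        frame=frame,
        errors=errors[ok],
        first_ga_days=first_ga[ok],
        gap_days=gaps[ok],
        n_eligible=len(statuses),
        n_refused=int(refused.sum()),
        n_out_of_support=int(out_sup.sum()),
    )


def _as_frame(cohort) -> pd.DataFrame:
    df = cohort.to_dataframe() if isinstance(cohort, Cohort) else pd.DataFrame(cohort)
    return df.sort_values(["fetus_id", "visit_index"], kind="mergesort").reset_index(drop=True)


def _ground_truth_ga(df: pd.DataFrame) -> np.ndarray:
    """True GA where simulated; nominal otherwise (for interval ground truth)."""
    if "true_ga_days" in df.columns and df["true_ga_days"].notna().all():
        return df["true_ga_days"].to_numpy(dtype=float)
    return df["nominal_ga_days"].to_numpy(dtype=float)


def _eligible_pairs(df: pd.DataFrame, gap_range) -> tuple[np.ndarray, np.ndarray]:
    """All within-fetus ordered scan pairs whose true gap lies in range."""
    lo, hi = gap_range
    truth = _ground_truth_ga(df)
    firsts, seconds = [], []
    for _, g in df.groupby("fetus_id", sort=True):
        idx = g.index.to_numpy()
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                gap = truth[idx[b]] - truth[idx[a]]
                if lo <= gap <= hi:
                    firsts.append(idx[a])
                    seconds.append(idx[b])
    return np.asarray(firsts, dtype=int), np.asarray(seconds, dtype=int)


def interval_error_curve(
    estimator,
    cohort,
    weeks=DEFAULT_WEEKS,
    gap_range=DEFAULT_GAP_RANGE_DAYS,
    min_bin_n: int = MIN_BIN_N,
) -> ErrorSummary:
    """Method A: recover the exactly known interval between two blinded scans.

    All within-fetus pairs with a gap of 4-10 weeks are eligible; the signed
    error is (estimated - actual) interval, binned by the first scan's
    LMP-based gestational age.  Refused and out-of-support pairs are
    excluded from the curve but counted.
    """
    df = _as_frame(cohort)
    i1, i2 = _eligible_pairs(df, gap_range)
    if len(i1) == 0:
        raise EmptySummaryError("no eligible scan pairs in the requested gap range")
    B = df[["hc_mm", "ac_mm", "fl_mm"]].to_numpy(dtype=float)
    truth = _ground_truth_ga(df)
    delta, _, _, status = estimator.estimate_interval_batch(B[i1], B[i2])
    actual = truth[i2] - truth[i1]
    first_ga = df["nominal_ga_days"].to_numpy(dtype=float)[i1]
    errors = np.asarray(delta, dtype=float) - actual
    return _summarize(
        getattr(estimator, "method_label", "A"),
        errors,
        first_ga,
        actual,
        np.asarray(status),
        weeks=weeks,
        min_bin_n=min_bin_n,
    )


def single_visit_error_curve(
    results: GestationalClockResults,
    cohort,
    weeks=DEFAULT_WEEKS,
    gap_range=DEFAULT_GAP_RANGE_DAYS,
    min_bin_n: int = MIN_BIN_N,
) -> ErrorSummary:
    """Method B: single-visit GA vs the two-visit anchored estimate.

    Each scan with a subsequent partner 4-10 weeks later is eligible.  The
    error is (single-visit estimate) - (anchored estimate), where the anchor
    uses the exactly known elapsed time between the two visits.  Refusals
    are excluded from the curve and counted.
    """
    df = _as_frame(cohort)
    i1, i2 = _eligible_pairs(df, gap_range)
    if len(i1) == 0:
        raise EmptySummaryError("no eligible scans with a partner visit")
    # keep one partner per first scan: the earliest eligible subsequent visit
    keep = ~pd.Series(i1).duplicated().to_numpy()
    i1, i2 = i1[keep], i2[keep]
    B = df[["hc_mm", "ac_mm", "fl_mm"]].to_numpy(dtype=float)
    truth = _ground_truth_ga(df)
    elapsed = truth[i2] - truth[i1]
    single_ga, s_status, _, _ = results.estimate_single_batch(B[i1])
    anchor_ga, a_status = results.anchored_first_ga_batch(B[i1], B[i2], elapsed)
    status = np.where(
        np.asarray(a_status) == Status.OUT_OF_SUPPORT.value,
        Status.OUT_OF_SUPPORT.value,
        np.asarray(s_status),
    )
    errors = np.asarray(single_ga) - np.asarray(anchor_ga)
    first_ga = df["nominal_ga_days"].to_numpy(dtype=float)[i1]
    return _summarize("B", errors, first_ga, elapsed, status, weeks=weeks, min_bin_n=min_bin_n)


def forecast_error_curve(
    results: GestationalClockResults,
    cohort,
    horizon_days: float = 42.0,
    weeks=DEFAULT_WEEKS,
    horizon_tol_days: float = 7.0,
    min_bin_n: int = MIN_BIN_N,
) -> ErrorSummary:
    """Method C: forecast the time from the second visit to a subsequent scan.

    Eligible units are consecutive scan triples (a, b, c) of one fetus whose
    actual elapsed time b->c lies within ``horizon_tol_days`` of the stated
    horizon.  The signed error is (predicted - actual) elapsed days, binned
    by the second scan's LMP-based gestational age.
    """
    df = _as_frame(cohort)
    truth = _ground_truth_ga(df)
    ia, ib, ic = [], [], []
    for _, g in df.groupby("fetus_id", sort=True):
        idx = g.index.to_numpy()
        for j in range(1, len(idx) - 1):
            for k in range(j + 1, len(idx)):
                actual = truth[idx[k]] - truth[idx[j]]
                if abs(actual - horizon_days) <= horizon_tol_days:
                    ia.append(idx[j - 1]); ib.append(idx[j]); ic.append(idx[k])
    if not ia:
        raise EmptySummaryError("no eligible scan triples near the forecast horizon")
    ia, ib, ic = (np.asarray(v, dtype=int) for v in (ia, ib, ic))
    B = df[["hc_mm", "ac_mm", "fl_mm"]].to_numpy(dtype=float)
    predicted, status = results.forecast_time_batch(B[ia], B[ib], B[ic])
    actual = truth[ic] - truth[ib]
    second_ga = df["nominal_ga_days"].to_numpy(dtype=float)[ib]
    errors = np.asarray(predicted) - actual
    return _summarize("C", errors, second_ga, actual, np.asarray(status),
                      weeks=weeks, min_bin_n=min_bin_n)


# ---------------------------------------------------------------------------
# Conventional polynomial baseline


class PolynomialBaseline:
    """Conventional biometric dating: polynomial regression of GA on biometry.

    A stand-in for chart/formula-based single-scan dating: nominal
    (LMP-based) GA regressed on polynomial features of (HC, AC, FL) over the
    training scans.  Exposes the same batch estimation interface as the
    manifold results so every error curve applies unchanged; it never
    refuses.
    """

    method_label = "baseline"

    def __init__(self, scaler, poly, reg, ga_range):
        self._scaler, self._poly, self._reg = scaler, poly, reg
        self._ga_range = ga_range

    def predict_ga(self, data) -> np.ndarray:
        if isinstance(data, pd.DataFrame):
            X = data[["hc_mm", "ac_mm", "fl_mm"]].to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(data, dtype=float))
        Z = self._poly.transform(self._scaler.transform(X))
        lo, hi = self._ga_range
        return np.clip(self._reg.predict(Z), lo - 30.0, hi + 30.0)

    def estimate_single_batch(self, biometry_mm):
        ga = self.predict_ga(biometry_mm)
        status = np.full(len(ga), Status.OK.value)
        zeros = np.zeros(len(ga))
        return ga, status, zeros, zeros

    def estimate_interval_batch(self, first_mm, second_mm):
        g1 = self.predict_ga(first_mm)
        g2 = self.predict_ga(second_mm)
        status = np.full(len(g1), Status.OK.value)
        return g2 - g1, g1, g2, status


def fit_baseline_polynomial(train_scans, degree: int = 3) -> PolynomialBaseline:
    """Fit the conventional polynomial dating baseline on training scans."""
    df = _as_frame(train_scans)
    df = df[df["nominal_ga_days"].notna()]
    X = df[["hc_mm", "ac_mm", "fl_mm"]].to_numpy(dtype=float)
    y = df["nominal_ga_days"].to_numpy(dtype=float)
    scaler = StandardScaler().fit(X)
    poly = PolynomialFeatures(degree=degree, include_bias=False).fit(scaler.transform(X))
    Z = poly.transform(scaler.transform(X))
    if Z.shape[0] <= Z.shape[1]:
        raise DegenerateDataError(
            f"rank-deficient polynomial design: {Z.shape[0]} scans for "
            f"{Z.shape[1]} features"
        )
    # least-squares fit tolerates the near-collinearity of noiseless biometry
    reg = LinearRegression().fit(Z, y)
    return PolynomialBaseline(scaler, poly, reg, (float(y.min()), float(y.max())))


# ---------------------------------------------------------------------------
# Distribution sharpening (growth-chart view)


@dataclass
class WeekDistribution:
    """Per-measure distribution of biometry among scans of one GA week."""

    week: int
    clock: str
    n: int
    sd_mm: dict
    histograms: dict  # measure -> (counts, bin_edges)


def compile_week_distribution(
    cohort,
    week: int,
    clock: str = "nominal",
    results: GestationalClockResults | None = None,
    n_hist_bins: int = 30,
    min_n: int = 200,
) -> WeekDistribution:
    """Biometry distributions among scans assigned to one gestational week.

    ``clock`` selects the timeline used for the assignment: the nominal
    (LMP-based) age, the true age (simulation only), or the model's refined
    clock (requires ``results``).  Sharper (smaller-SD) distributions under
    the refined clock indicate less timing blur in growth charts.
    """
    df = _as_frame(cohort)
    if clock == "nominal":
        ga = df["nominal_ga_days"].to_numpy(dtype=float)
    elif clock == "true":
        ga = df["true_ga_days"].to_numpy(dtype=float)
    elif clock in ("refined", "estimated"):
        if results is None:
            raise EmptySummaryError("refined clock requires a trained results object")
        ga = results.refined_clock_for(df)
    else:
        raise EmptySummaryError(f"unknown clock {clock!r}")
    lo, hi = week_bin(week)
    mask = (ga >= lo) & (ga < hi)
    n = int(mask.sum())
    if n < min_n:
        raise EmptySummaryError(f"only {n} scans in week {week} under the {clock} clock")
    sd, hist = {}, {}
    for col in ("hc_mm", "ac_mm", "fl_mm"):
        v = df.loc[mask, col].to_numpy(dtype=float)
        sd[col] = float(np.std(v, ddof=1))
        hist[col] = np.histogram(v, bins=n_hist_bins)
    return WeekDistribution(week=week, clock=clock, n=n, sd_mm=sd, histograms=hist)


# ---------------------------------------------------------------------------
# Cross-validation and transfer


@dataclass
class CrossvalResult:
    n_folds: int
    fold_summaries: list
    pooled: ErrorSummary
    fold_of_fetus: dict


def run_crossvalidation(
    cohort,
    n_folds: int,
    config: TrainConfig | None = None,
    seed: int = 0,
    weeks=DEFAULT_WEEKS,
    gap_range=DEFAULT_GAP_RANGE_DAYS,
    min_bin_n: int = MIN_BIN_N,
) -> CrossvalResult:
    """N-fold participant-level train-and-test with pooled method-A errors.

    Fetuses are split into N folds; each fold is held out once while a model
    is trained on the rest, and the held-out fetuses' interval errors are
    computed with their nominal ages blinded.  Raw errors are pooled across
    folds, so every fetus contributes test results exactly once.
    """
    config = config or TrainConfig()
    df = _as_frame(cohort)
    ss = np.random.SeedSequence([seed, n_folds])
    split_seed, *fold_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_folds + 1)]
    assignment = kfold_split(df, n_folds, seed=split_seed)
    fold_col = df["fetus_id"].map(assignment.fold_of_fetus)
    from .model import GestationalClockModel

    summaries = []
    for k in range(1, n_folds + 1):
        train_df = df[fold_col != k]
        test_df = df[fold_col == k]
        res = GestationalClockModel(train_df, config=config.replace(seed=fold_seeds[k - 1])).fit()
        summaries.append(
            interval_error_curve(res, test_df, weeks=weeks, gap_range=gap_range,
                                 min_bin_n=min_bin_n)
        )
    pooled = pool_summaries(summaries, method="A", weeks=weeks, min_bin_n=min_bin_n)
    return CrossvalResult(
        n_folds=n_folds,
        fold_summaries=summaries,
        pooled=pooled,
        fold_of_fetus=dict(assignment.fold_of_fetus),
    )


def pool_summaries(summaries, method="pooled", weeks=DEFAULT_WEEKS,
                   min_bin_n: int = MIN_BIN_N) -> ErrorSummary:
    """Concatenate raw error samples from several summaries and re-bin."""
    errors = np.concatenate([s.errors for s in summaries])
    first_ga = np.concatenate([s.first_ga_days for s in summaries])
    gaps = np.concatenate([s.gap_days for s in summaries])
    statuses = np.full(len(errors), Status.OK.value)
    out = _summarize(method, errors, first_ga, gaps, statuses, weeks=weeks,
                     min_bin_n=min_bin_n)
    out.n_eligible = sum(s.n_eligible for s in summaries)
    out.n_refused = sum(s.n_refused for s in summaries)
    out.n_out_of_support = sum(s.n_out_of_support for s in summaries)
    return out


@dataclass
class TransferResult:
    summary_a: ErrorSummary
    summary_b: ErrorSummary
    comparison: pd.DataFrame  # week, half_width_a, half_width_b, abs_diff

    @property
    def max_abs_diff_days(self) -> float:
        return float(self.comparison["abs_diff"].max())


def transfer_evaluation(
    results: GestationalClockResults,
    test_cohort_a,
    cohort_b,
    weeks=DEFAULT_WEEKS,
    gap_range=DEFAULT_GAP_RANGE_DAYS,
    min_bin_n: int = MIN_BIN_N,
    ga_window=HEADLINE_WINDOW_DAYS,
) -> TransferResult:
    """Generalisability check: identical evaluation on two test populations.

    ``results`` was trained on population A only; the same method-A curve is
    computed on held-out A fetuses and on population B, and the per-bin
    absolute half-interval differences are reported over the headline window.
    """
    sa = interval_error_curve(results, test_cohort_a, weeks=weeks, gap_range=gap_range,
                              min_bin_n=min_bin_n)
    sb = interval_error_curve(results, cohort_b, weeks=weeks, gap_range=gap_range,
                              min_bin_n=min_bin_n)
    lo_w = int(ga_window[0] // 7)
    hi_w = int(ga_window[1] // 7)
    fa = sa.frame.set_index("week")["half_width_95_days"]
    fb = sb.frame.set_index("week")["half_width_95_days"]
    rows = []
    for w in weeks:
        if lo_w <= w < hi_w and np.isfinite(fa.get(w, np.nan)) and np.isfinite(fb.get(w, np.nan)):
            rows.append({"week": w, "half_width_a": fa[w], "half_width_b": fb[w],
                         "abs_diff": abs(fa[w] - fb[w])})
    if not rows:
        raise EmptySummaryError("no common reported bins between the two populations")
    return TransferResult(summary_a=sa, summary_b=sb, comparison=pd.DataFrame(rows))


def plot_error_curves(summaries, path=None, title="Gestational-age estimation accuracy"):
    """Half-interval curves by week for several methods (Fig-2-style layout)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for s in summaries:
        f = s.frame.dropna(subset=["half_width_95_days"])
        ax.plot(f["week"], f["half_width_95_days"], marker="o", label=s.method)
    ax.set_xlabel("LMP-based gestational age at first scan (weeks)")
    ax.set_ylabel("95% half-interval (days)")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


__all__ = [
    "DEFAULT_WEEKS",
    "HEADLINE_WINDOW_DAYS",
    "DEFAULT_GAP_RANGE_DAYS",
    "MIN_BIN_N",
    "ErrorSummary",
    "WeekDistribution",
    "CrossvalResult",
    "TransferResult",
    "PolynomialBaseline",
    "half_interval_95",
    "interval_error_curve",
    "single_visit_error_curve",
    "forecast_error_curve",
    "fit_baseline_polynomial",
    "compile_week_distribution",
    "run_crossvalidation",
    "pool_summaries",
    "transfer_evaluation",
    "plot_error_curves",
]
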