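"""Gestational-clock model and results, statsmodels-style.

:class:`GestationalClockModel` is built from a longitudinal biometry cohort
and a :class:`TrainConfig`; ``fit()`` runs the full training pipeline
(time-uniform thinning -> standardization -> supervector windows ->
diffusion embedding -> clock calibration and refinement -> trajectory
strata) and returns a :class:`GestationalClockResults`, which carries the
trained artifact and exposes the blinded estimation protocols:

* ``estimate_single``  -- gestational age from one scan's biometry (with a
  refusal mode when the answer is sensitive to the growth trajectory);
* ``estimate_interval`` -- the time separating two scans of one fetus;
* ``forecast_time``     -- the time from a second visit to a later scan;
* ``forecast_biometry`` -- expected measurements a given time ahead.

None of the estimation paths sees a test scan's nominal gestational age:
they accept raw biometry only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._version import __version__ as _pkg_version
from .cohort import BiometrySample, Cohort
from .errors import ConfigError, FetalClockError, InvalidMeasurementError
from .manifold import (
    STD_COLUMNS,
    Standardization,
    build_supervectors,
    diffusion_embedding,
    extract_trajectory_coordinate,
    refine_training_clock,
    standardize,
)
from .sampling import thin_to_uniform

MODEL_FORMAT_VERSION = 1


class Status(str, Enum):
    OK = "OK"
    NEEDS_MORE_DATA = "NEEDS_MORE_DATA"
    OUT_OF_SUPPORT = "OUT_OF_SUPPORT"


@dataclass(frozen=True)
class GAEstimate:
    """Single-visit gestational-age estimate."""

    ga_days: float | None
    status: Status
    sensitivity_spread_days: float
    half_width_95_days: float

    def __post_init__(self):
        if (self.ga_days is not None) != (self.status is Status.OK):
            raise ValueError("ga_days must be present iff status is OK")


@dataclass(frozen=True)
class IntervalEstimate:
    """Estimated time interval between two scans of one fetus."""

    delta_days: float | None
    ga_first_days: float | None
    ga_second_days: float | None
    status: Status


@dataclass(frozen=True)
class ForecastResult:
    """Forecast of a subsequent visit's timing and/or biometry."""

    predicted_elapsed_days: float | None
    status: Status
    predicted_biometry: BiometrySample | None = None


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    ``series_length`` (c) is the number of consecutive scans concatenated
    into one supervector; at ``scans_per_day`` pooled density a window spans
    c / scans_per_day days, and the accessible gestational-age range shrinks
    by about half a window on each flank.
    """

    series_length: int = 1024
    scans_per_day: float = 20.0
    ga_range_days: tuple[float, float] = (98.0, 294.0)
    bandwidth_factor: float = 1.0
    n_components: int = 8
    n_strata: int = 5
    k_neighbors: int = 50
    min_stratum_neighbors: int = 4
    refusal_threshold_days: float = 7.0
    min_clock_spearman: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.series_length < 2:
            raise ConfigError("series_length must be >= 2")
        if self.n_strata < 1:
            raise ConfigError("n_strata must be >= 1")

    def replace(self, **kw) -> "TrainConfig":
        return dataclasses.replace(self, **kw)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, FetalClockError):
                exc.args = (f"[stage: {name}] {exc.args[0] if exc.args else ''}",)
            return False

    return _Ctx()


class GestationalClockModel:
    """Unfitted model: a cohort plus training configuration."""

    def __init__(self, cohort, config: TrainConfig | None = None, **overrides):
        if isinstance(cohort, Cohort):
            self.data = cohort.to_dataframe()
        else:
            self.data = pd.DataFrame(cohort).copy()
        cfg = config or TrainConfig()
        if overrides:
            cfg = cfg.replace(**overrides)
        self.config = cfg

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: TrainConfig | None = None, **kw):
        return cls(df, config=config, **kw)

    @classmethod
    def from_csv(cls, path, config: TrainConfig | None = None, **kw):
        from .cohort import read_cohort

        return cls(read_cohort(path), config=config, **kw)

    def fit(self, seed: int | None = None) -> "GestationalClockResults":
        cfg = self.config if seed is None else self.config.replace(seed=seed)
        with _stage("thin_to_uniform"):
            sample = thin_to_uniform(
                self.data, cfg.scans_per_day, cfg.ga_range_days, seed=cfg.seed
            )
        with _stage("standardize"):
            sample, std = standardize(sample)
        with _stage("build_supervectors"):
            sv = build_supervectors(sample, cfg.series_length)
        with _stage("diffusion_embedding"):
            emb = diffusion_embedding(
                sv, bandwidth_factor=cfg.bandwidth_factor, n_components=cfg.n_components
            )
        with _stage("refine_training_clock"):
            ref = refine_training_clock(emb, sv, sample, min_spearman=cfg.min_clock_spearman)
        with _stage("extract_trajectory_coordinate"):
            traj = extract_trajectory_coordinate(emb, ref)

        frame = sample.frame.reset_index(drop=True)
        res = GestationalClockResults(
            config=cfg,
            standardization=std,
            train_fetus_ids=frame["fetus_id"].to_numpy(dtype=object),
            train_nominal_ga=frame["nominal_ga_days"].to_numpy(dtype=float),
            train_true_ga=frame["true_ga_days"].to_numpy(dtype=float)
            if "true_ga_days" in frame
            else np.full(len(frame), np.nan),
            train_X_std=frame[list(STD_COLUMNS)].to_numpy(dtype=float),
            eigenvalues=emb.eigenvalues,
            clock_component=ref.clock_component,
            clock_spearman=ref.clock_spearman,
            calibration_x=ref.calibration_x,
            calibration_y=ref.calibration_y,
            window_clock_u=ref.window_clock_u,
            projection_p=ref.projection_p,
            refined_ga_days=ref.refined_ga_days,
            trajectory_coord=traj,
            ga_support=ref.ga_support,
            curve_grid=ref.curve_grid,
            curve_values=ref.curve_values,
            curve_resid_sd=ref.curve_resid_sd,
            variance_components=dict(ref.variance_components),
        )
        res._finalize()
        return res


@dataclass
class GestationalClockResults:
    """Trained gestational-clock artifact with estimation methods."""

    config: TrainConfig
    standardization: Standardization
    train_fetus_ids: np.ndarray
    train_nominal_ga: np.ndarray
    train_true_ga: np.ndarray
    train_X_std: np.ndarray
    eigenvalues: np.ndarray
    clock_component: int
    clock_spearman: float
    calibration_x: np.ndarray
    calibration_y: np.ndarray
    window_clock_u: np.ndarray
    projection_p: np.ndarray
    refined_ga_days: np.ndarray
    trajectory_coord: np.ndarray
    ga_support: tuple[float, float]
    curve_grid: np.ndarray
    curve_values: np.ndarray
    curve_resid_sd: np.ndarray
    variance_components: dict
    stratum_edges: np.ndarray = field(default=None)
    stratum_labels: np.ndarray = field(default=None)
    stratum_table_grid: np.ndarray = field(default=None)
    stratum_table: np.ndarray = field(default=None)
    version: str = _pkg_version

    # -- fitting finalization ------------------------------------------------

    def _finalize(self) -> None:
        """Derive strata and the per-stratum forecast tables."""
        S = self.config.n_strata
        t = self.trajectory_coord
        if S > 1:
            qs = np.quantile(t, np.linspace(0, 1, S + 1)[1:-1])
            self.stratum_edges = np.asarray(qs, dtype=float)
        else:
            self.stratum_edges = np.array([], dtype=float)
        self.stratum_labels = np.searchsorted(self.stratum_edges, t).astype(np.int32)
        self._build_stratum_tables()

    def _build_stratum_tables(self) -> None:
        """Stratum-conditional GA along the mean trajectory, tabulated.

        For on-curve points at a 1-day grid of developmental age, compute the
        stratum-conditional GA candidates with the same neighbour machinery
        used at estimation time, monotonize, and fill gaps; the inverse of
        this table turns a target GA back into a developmental age for
        biometry forecasting.
        """
        step = max(1.0, float(self.curve_grid[1] - self.curve_grid[0]))
        gp = np.arange(self.curve_grid[0], self.curve_grid[-1] + 1e-9, step)
        Xg = np.column_stack(
            [np.interp(gp, self.curve_grid, self.curve_values[:, k]) for k in range(3)]
        )
        cand, _, counts, valid = self._candidates_batch(Xg, gp)
        S = max(self.config.n_strata, 1)
        table = np.empty((S, len(gp)))
        for s in range(S):
            col = np.where(valid[:, s], cand[:, s], np.nan)
            if np.all(np.isnan(col)):
                col = gp.copy()
            else:
                good = np.flatnonzero(~np.isnan(col))
                col = np.interp(np.arange(len(gp)), good, col[good])
            table[s] = np.maximum.accumulate(col)
        self.stratum_table_grid = gp
        self.stratum_table = table

    # -- internal estimation machinery --------------------------------------

    @property
    def _tree(self) -> cKDTree:
        tree = getattr(self, "_tree_cache", None)
        if tree is None:
            tree = cKDTree(self.train_X_std)
            self._tree_cache = tree
        return tree

    def _standardize_input(self, biometry) -> np.ndarray:
        B = np.atleast_2d(np.asarray(
            biometry.as_array() if isinstance(biometry, BiometrySample) else biometry,
            dtype=float,
        ))
        if B.shape[1] != 3:
            raise InvalidMeasurementError(f"expected (n, 3) biometry, got shape {B.shape}")
        if not np.all(np.isfinite(B)) or np.any(B <= 0):
            raise InvalidMeasurementError("biometry must be finite and strictly positive")
        return self.standardization.apply(B)

    def _project(self, Xstd: np.ndarray) -> np.ndarray:
        from .manifold import project_onto_trajectory

        p, _ = project_onto_trajectory(
            Xstd, self.curve_grid, self.curve_values, self.curve_resid_sd
        )
        return p

    def _candidates_batch(self, Xstd: np.ndarray, P: np.ndarray):
        """Stratum-conditional GA candidates at each query point.

        For each query, the ``k`` nearest training scans in standardized
        biometry space are binned by trajectory stratum; within each stratum
        a locally weighted linear regression of refined GA on projected
        developmental age is evaluated at the query's projection.  Returns
        (candidates (n, S), mean weighted sq. residual (n, S),
        neighbour counts (n, S), validity mask (n, S)).
        """
        n = Xstd.shape[0]
        k = min(self.config.k_neighbors, len(self.train_X_std))
        S = max(self.config.n_strata, 1)
        dist, idx = self._tree.query(Xstd, k=k, workers=1)
        dist = np.atleast_2d(dist)
        idx = np.atleast_2d(idx)
        h = np.median(dist, axis=1, keepdims=True) + 1e-9
        W = np.exp(-((dist / h) ** 2))
        labels = self.stratum_labels[idx]  # (n, k)
        x = self.projection_p[idx]
        y = self.refined_ga_days[idx]

        cand = np.full((n, S), np.nan)
        resid = np.full((n, S), np.inf)
        counts = np.zeros((n, S), dtype=np.int32)
        valid = np.zeros((n, S), dtype=bool)
        lo, hi = self.ga_support
        for s in range(S):
            M = labels == s
            counts[:, s] = M.sum(axis=1)
            Ws = np.where(M, W, 0.0)
            Sw = Ws.sum(axis=1)
            ok = (counts[:, s] >= self.config.min_stratum_neighbors) & (Sw > 1e-12)
            if not np.any(ok):
                continue
            Swi = np.where(Sw > 1e-12, Sw, 1.0)
            xc = (Ws * x).sum(axis=1) / Swi
            yc = (Ws * y).sum(axis=1) / Swi
            vx = (Ws * (x - xc[:, None]) ** 2).sum(axis=1) / Swi
            cxy = (Ws * (x - xc[:, None]) * (y - yc[:, None])).sum(axis=1) / Swi
            vy = (Ws * (y - yc[:, None]) ** 2).sum(axis=1) / Swi
            slope = np.where(vx > 1e-6, cxy / np.maximum(vx, 1e-6), 0.0)
            slope = np.clip(slope, 0.0, 3.0)
            c_s = yc + slope * (P - xc)
            r_s = np.maximum(vy - slope**2 * vx, 0.0)
            cand[:, s] = np.clip(c_s, lo - 10.0, hi + 10.0)
            resid[:, s] = np.where(ok, r_s, np.inf)
            valid[:, s] = ok
        return cand, resid, counts, valid

    def _support_status(self, P: np.ndarray) -> np.ndarray:
        """True where the projection falls outside the accessible GA range."""
        lo, hi = self.ga_support
        edge = max(1.0, float(self.curve_grid[1] - self.curve_grid[0]))
        return (P <= lo + edge) | (P >= hi - edge)

    @staticmethod
    def _weighted_median(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
        """Row-wise weighted median; NaN values must carry zero weight."""
        v = np.where(np.isnan(values), np.inf, values)
        order = np.argsort(v, axis=1)
        v_sorted = np.take_along_axis(v, order, axis=1)
        w_sorted = np.take_along_axis(weights, order, axis=1)
        cw = np.cumsum(w_sorted, axis=1)
        half = cw[:, -1:] / 2.0
        pick = (cw >= half).argmax(axis=1)
        return v_sorted[np.arange(len(v)), pick]

    # -- batch estimation (arrays in, arrays out) ----------------------------

    def estimate_single_batch(self, biometry_mm: np.ndarray):
        """Vectorized single-visit estimation; see :meth:`estimate_single`."""
        X = self._standardize_input(biometry_mm)
        P = self._project(X)
        cand, _, counts, valid = self._candidates_batch(X, P)
        any_valid = valid.any(axis=1)
        w = np.where(valid, counts, 0).astype(float)
        ga = self._weighted_median(cand, np.where(w.sum(axis=1, keepdims=True) > 0, w, 1.0))
        cmin = np.min(np.where(valid, cand, np.inf), axis=1)
        cmax = np.max(np.where(valid, cand, -np.inf), axis=1)
        spread = np.where(any_valid, cmax - cmin, np.inf)
        out_sup = self._support_status(P) | ~any_valid
        refuse = ~out_sup & (spread > self.config.refusal_threshold_days)
        status = np.where(out_sup, Status.OUT_OF_SUPPORT.value,
                          np.where(refuse, Status.NEEDS_MORE_DATA.value, Status.OK.value))
        sm = self.variance_components.get("sigma_meas_days", 1.0)
        wsum = np.maximum(w.sum(axis=1), 1e-12)
        cmean = np.nansum(np.where(valid, cand, 0.0) * w, axis=1) / wsum
        cvar = np.nansum(np.where(valid, (cand - cmean[:, None]) ** 2, 0.0) * w, axis=1) / wsum
        half = 1.96 * np.sqrt(sm**2 + cvar)
        ga = np.where(status == Status.OK.value, ga, np.nan)
        return ga, status, np.where(np.isfinite(spread), spread, np.nan), half

    def _joint_stratum(self, valid1, valid2, resid1, resid2, counts1, counts2):
        """Stratum best explaining both scans; deterministic tie-breaks."""
        both = valid1 & valid2
        score = np.where(both, resid1 + resid2, np.inf)
        n = score.shape[0]
        total_counts = counts1 + counts2
        # argmin on (score, -counts, stratum index)
        order = np.lexsort(
            (np.arange(score.shape[1])[None, :].repeat(n, 0),
             -total_counts,
             score),
            axis=1,
        )
        s_star = order[:, 0]
        has_joint = both.any(axis=1)
        return s_star, has_joint

    def estimate_interval_batch(self, first_mm: np.ndarray, second_mm: np.ndarray):
        """Vectorized two-visit interval estimation; see :meth:`estimate_interval`."""
        X1 = self._standardize_input(first_mm)
        X2 = self._standardize_input(second_mm)
        P1, P2 = self._project(X1), self._project(X2)
        c1, r1, n1, v1 = self._candidates_batch(X1, P1)
        c2, r2, n2, v2 = self._candidates_batch(X2, P2)
        s_star, has_joint = self._joint_stratum(v1, v2, r1, r2, n1, n2)
        rows = np.arange(len(s_star))
        ga1 = c1[rows, s_star]
        ga2 = c2[rows, s_star]
        out_sup = self._support_status(P1) | self._support_status(P2)
        # fallback: stratum-free estimate when no stratum explains both scans
        if np.any(~has_joint):
            fb1 = self._stratum_free_ga(P1[~has_joint])
            fb2 = self._stratum_free_ga(P2[~has_joint])
            ga1 = ga1.copy(); ga2 = ga2.copy()
            ga1[~has_joint] = fb1
            ga2[~has_joint] = fb2
        delta = ga2 - ga1
        status = np.where(out_sup, Status.OUT_OF_SUPPORT.value,
                          np.where(has_joint, Status.OK.value,
                                   Status.NEEDS_MORE_DATA.value))
        bad = status == Status.OUT_OF_SUPPORT.value
        delta = np.where(bad, np.nan, delta)
        ga1 = np.where(bad, np.nan, ga1)
        ga2 = np.where(bad, np.nan, ga2)
        return delta, ga1, ga2, status

    def _stratum_free_ga(self, P: np.ndarray) -> np.ndarray:
        """All-strata fallback: interpolate the pooled stratum table mean."""
        mean_map = self.stratum_table.mean(axis=0)
        return np.interp(P, self.stratum_table_grid, mean_map)

    def forecast_time_batch(self, first_mm, second_mm, subsequent_mm):
        """Vectorized method-C timing forecast; see :meth:`forecast_time`."""
        X1 = self._standardize_input(first_mm)
        X2 = self._standardize_input(second_mm)
        X3 = self._standardize_input(subsequent_mm)
        P1, P2, P3 = self._project(X1), self._project(X2), self._project(X3)
        c1, r1, n1, v1 = self._candidates_batch(X1, P1)
        c2, r2, n2, v2 = self._candidates_batch(X2, P2)
        c3, _, _, v3 = self._candidates_batch(X3, P3)
        s_star, has_joint = self._joint_stratum(v1, v2, r1, r2, n1, n2)
        rows = np.arange(len(s_star))
        ga2 = c2[rows, s_star]
        ga3 = c3[rows, s_star]
        v3_star = v3[rows, s_star]
        need_fb = ~has_joint | ~v3_star
        if np.any(need_fb):
            ga2 = ga2.copy(); ga3 = ga3.copy()
            ga2[need_fb] = self._stratum_free_ga(P2[need_fb])
            ga3[need_fb] = self._stratum_free_ga(P3[need_fb])
        elapsed = ga3 - ga2
        out_sup = (self._support_status(P2) | self._support_status(P3)
                   | self._support_status(P1))
        status = np.where(out_sup, Status.OUT_OF_SUPPORT.value,
                          np.where(need_fb, Status.NEEDS_MORE_DATA.value,
                                   Status.OK.value))
        elapsed = np.where(status == Status.OUT_OF_SUPPORT.value, np.nan, elapsed)
        return elapsed, status

    def anchored_first_ga_batch(self, first_mm, second_mm, elapsed_days):
        """Two-visit anchored GA of the first scan, given the exact interval.

        The known elapsed time identifies the fetus's developmental rate
        (p2 - p1) / elapsed; dividing the first scan's developmental age by
        that rate anchors its gestational age without any LMP input.
        """
        X1 = self._standardize_input(first_mm)
        X2 = self._standardize_input(second_mm)
        P1, P2 = self._project(X1), self._project(X2)
        elapsed = np.asarray(elapsed_days, dtype=float)
        dp = P2 - P1
        ok = (dp > 1e-6) & (elapsed > 0)
        rate = np.where(ok, dp / np.where(elapsed > 0, elapsed, 1.0), 1.0)
        ga = np.where(ok, P1 / rate, np.nan)
        out_sup = self._support_status(P1) | self._support_status(P2)
        status = np.where(out_sup | ~ok, Status.OUT_OF_SUPPORT.value, Status.OK.value)
        ga = np.where(status == Status.OK.value, ga, np.nan)
        return ga, status

    # -- public single-sample API --------------------------------------------

    def estimate_single(self, biometry: BiometrySample) -> GAEstimate:
        """Estimate gestational age from a single blinded scan.

        Candidate ages are computed per growth-trajectory stratum; when they
        disagree by more than the refusal threshold the estimate would not
        beat typical LMP-based dating and ``NEEDS_MORE_DATA`` is returned.
        """
        ga, status, spread, half = self.estimate_single_batch(biometry.as_array())
        st = Status(status[0])
        return GAEstimate(
            ga_days=float(ga[0]) if st is Status.OK else None,
            status=st,
            sensitivity_spread_days=float(spread[0]) if np.isfinite(spread[0]) else float("nan"),
            half_width_95_days=float(half[0]),
        )

    def estimate_interval(
        self, first: BiometrySample, second: BiometrySample
    ) -> IntervalEstimate:
        """Estimate the time interval separating two blinded scans.

        Jointly selects the trajectory stratum that best explains both scans
        and differences the two stratum-consistent age estimates; exactly
        antisymmetric under swapping the scans.
        """
        delta, ga1, ga2, status = self.estimate_interval_batch(
            first.as_array(), second.as_array()
        )
        st = Status(status[0])
        none_if = lambda v: None if not np.isfinite(v) else float(v)
        return IntervalEstimate(
            delta_days=none_if(delta[0]),
            ga_first_days=none_if(ga1[0]),
            ga_second_days=none_if(ga2[0]),
            status=st,
        )

    def forecast_time(
        self,
        first: BiometrySample,
        second: BiometrySample,
        subsequent: BiometrySample,
    ) -> ForecastResult:
        """Forecast the elapsed time from the second visit to a later scan."""
        elapsed, status = self.forecast_time_batch(
            first.as_array(), second.as_array(), subsequent.as_array()
        )
        st = Status(status[0])
        return ForecastResult(
            predicted_elapsed_days=float(elapsed[0]) if np.isfinite(elapsed[0]) else None,
            status=st,
        )

    def forecast_biometry(
        self, first: BiometrySample, second: BiometrySample, elapsed_days: float
    ) -> ForecastResult:
        """Forecast biometry ``elapsed_days`` after the second visit.

        Inverts the fetus's stratum-conditional clock: find the
        developmental age whose stratum GA equals GA(second) + elapsed and
        read the mean trajectory there.
        """
        if elapsed_days <= 0:
            raise ConfigError("elapsed_days must be positive")
        X1 = self._standardize_input(first.as_array())
        X2 = self._standardize_input(second.as_array())
        P1, P2 = self._project(X1), self._project(X2)
        c1, r1, n1, v1 = self._candidates_batch(X1, P1)
        c2, r2, n2, v2 = self._candidates_batch(X2, P2)
        s_star, has_joint = self._joint_stratum(v1, v2, r1, r2, n1, n2)
        s = int(s_star[0])
        ga2 = float(c2[0, s]) if has_joint[0] else float(self._stratum_free_ga(P2)[0])
        target = ga2 + float(elapsed_days)
        tmap = self.stratum_table[s] if has_joint[0] else self.stratum_table.mean(axis=0)
        if not (tmap[0] <= target <= tmap[-1]) or self._support_status(P2)[0]:
            return ForecastResult(predicted_elapsed_days=None, status=Status.OUT_OF_SUPPORT)
        p_target = float(np.interp(target, tmap, self.stratum_table_grid))
        xs = np.array(
            [np.interp(p_target, self.curve_grid, self.curve_values[:, k]) for k in range(3)]
        )
        mm = self.standardization.invert(xs)
        status = Status.OK if has_joint[0] else Status.NEEDS_MORE_DATA
        return ForecastResult(
            predicted_elapsed_days=float(elapsed_days),
            status=status,
            predicted_biometry=BiometrySample(*[float(v) for v in mm]),
        )

    # -- refined clock for external scans ------------------------------------

    def refined_clock_for(self, df: pd.DataFrame) -> np.ndarray:
        """Refined gestational age for scans with nominal GA (days).

        Applies the population recalibration (nominal -> window clock via
        the training sample's monotone relation) and blends it with each
        scan's trajectory projection, exactly as for training scans.  Used
        to recompile growth distributions under the improved clock.
        """
        nominal = df["nominal_ga_days"].to_numpy(dtype=float)
        order = np.argsort(self.train_nominal_ga, kind="mergesort")
        u = np.interp(nominal, self.train_nominal_ga[order], self.window_clock_u[order])
        X = self._standardize_input(df[["hc_mm", "ac_mm", "fl_mm"]].to_numpy(dtype=float))
        p = self._project(X)
        from .manifold import combine_clocks

        rng = (float(self.window_clock_u.min()), float(self.window_clock_u.max()))
        return combine_clocks(u, p, self.variance_components, u_range=rng)

    # -- reporting & persistence ---------------------------------------------

    @property
    def n_train_scans(self) -> int:
        return len(self.train_nominal_ga)

    def summary(self) -> str:
        vc = self.variance_components
        lo, hi = self.ga_support
        lines = [
            "Gestational clock model",
            "=" * 64,
            f"training scans (after thinning) : {self.n_train_scans}",
            f"series length c                 : {self.config.series_length}",
            f"pooled density                  : {self.config.scans_per_day:g} scans/day",
            f"accessible GA support           : {lo:.1f} - {hi:.1f} d "
            f"({lo / 7:.1f} - {hi / 7:.1f} wk)",
            f"clock eigencoordinate           : #{self.clock_component} "
            f"(|Spearman| vs window GA = {self.clock_spearman:.4f})",
            f"leading eigenvalues             : "
            + ", ".join(f"{v:.4f}" for v in self.eigenvalues[:4]),
            f"est. time-zero SD               : {vc['sigma_tau_days']:.2f} d",
            f"est. growth-rate SD             : {vc['sigma_rho']:.4f}",
            f"est. per-scan measurement noise : {vc['sigma_meas_days']:.2f} d (GA-equivalent)",
            f"trajectory strata               : {self.config.n_strata}",
            f"refusal threshold               : {self.config.refusal_threshold_days:g} d",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialize to a single archive (JSON metadata + dense arrays)."""
        meta = {
            "format_version": MODEL_FORMAT_VERSION,
            "package_version": self.version,
            "config": dataclasses.asdict(self.config),
            "ga_support": list(self.ga_support),
            "variance_components": self.variance_components,
            "clock_component": self.clock_component,
            "clock_spearman": self.clock_spearman,
        }
        np.savez_compressed(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            std_mean=self.standardization.mean,
            std_scale=self.standardization.scale,
            train_fetus_ids=self.train_fetus_ids.astype(str),
            train_nominal_ga=self.train_nominal_ga,
            train_true_ga=self.train_true_ga,
            train_X_std=self.train_X_std,
            eigenvalues=self.eigenvalues,
            calibration_x=self.calibration_x,
            calibration_y=self.calibration_y,
            window_clock_u=self.window_clock_u,
            projection_p=self.projection_p,
            refined_ga_days=self.refined_ga_days,
            trajectory_coord=self.trajectory_coord,
            curve_grid=self.curve_grid,
            curve_values=self.curve_values,
            curve_resid_sd=self.curve_resid_sd,
            stratum_edges=self.stratum_edges,
            stratum_labels=self.stratum_labels,
            stratum_table_grid=self.stratum_table_grid,
            stratum_table=self.stratum_table,
        )

    @classmethod
    def load(cls, path) -> "GestationalClockResults":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            if meta["format_version"] != MODEL_FORMAT_VERSION:
                raise ConfigError(
                    f"unsupported model format {meta['format_version']!r}"
                )
            cfg_d = meta["config"]
            cfg_d["ga_range_days"] = tuple(cfg_d["ga_range_days"])
            cfg = TrainConfig(**cfg_d)
            res = cls(
                config=cfg,
                standardization=Standardization(
                    mean=z["std_mean"], scale=z["std_scale"]
                ),
                train_fetus_ids=z["train_fetus_ids"].astype(object),
                train_nominal_ga=z["train_nominal_ga"],
                train_true_ga=z["train_true_ga"],
                train_X_std=z["train_X_std"],
                eigenvalues=z["eigenvalues"],
                clock_component=int(meta["clock_component"]),
                clock_spearman=float(meta["clock_spearman"]),
                calibration_x=z["calibration_x"],
                calibration_y=z["calibration_y"],
                window_clock_u=z["window_clock_u"],
                projection_p=z["projection_p"],
                refined_ga_days=z["refined_ga_days"],
                trajectory_coord=z["trajectory_coord"],
                ga_support=tuple(meta["ga_support"]),
                curve_grid=z["curve_grid"],
                curve_values=z["curve_values"],
                curve_resid_sd=z["curve_resid_sd"],
                variance_components=meta["variance_components"],
                stratum_edges=z["stratum_edges"],
                stratum_labels=z["stratum_labels"].astype(np.int32),
                stratum_table_grid=z["stratum_table_grid"],
                stratum_table=z["stratum_table"],
                version=meta["package_version"],
            )
        return res


def fit_manifold_model(cohort, config: TrainConfig | None = None, **kw):
    """Train a gestational clock on a cohort; convenience wrapper."""
    return GestationalClockModel(cohort, config=config, **kw).fit()


__all__ = [
    "Status",
    "GAEstimate",
    "IntervalEstimate",
    "ForecastResult",
    "TrainConfig",
    "GestationalClockModel",
    "GestationalClockResults",
    "fit_manifold_model",
]
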