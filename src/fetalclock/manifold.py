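"""Geometric learning core: supervectors, diffusion embedding, clock refinement.

The training sample is a pooled, time-ordered, density-uniform set of scans.
Sliding windows of ``c`` consecutive standardized (HC, AC, FL) triplets are
concatenated into *supervectors* (dimension 3c); a diffusion-map embedding of
the supervectors recovers the slow one-dimensional structure of the data --
gestational time -- without trusting the noisy nominal timestamps beyond
their ordering.  A monotone calibration maps the principal embedding
coordinate to absolute gestational age through a population-level fit, so
individual time-zero errors average out.

The per-scan *refined clock* then combines two complementary readings of a
scan's age:

* the **window clock** ``u`` -- the calibrated embedding coordinate averaged
  over every window the scan participates in (a smooth, population-level
  recalibration of the nominal ordering, still carrying the pregnancy's
  time-zero offset), and
* the **trajectory projection** ``p`` -- the developmental age at which the
  population mean trajectory through standardized biometry space passes
  closest to the scan's own measurements (free of time-zero error, but
  carrying the fetus's growth-rate deviation and measurement noise),

weighted by variance components estimated from the training cohort itself.
The scan-level offset ``p - u`` is the second, growth-trajectory degree of
freedom the estimator conditions on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats
from scipy.sparse.linalg import eigsh
from sklearn.isotonic import IsotonicRegression
from sklearn.metrics import pairwise_distances
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import (
    DegenerateDataError,
    EmbeddingQualityError,
    InsufficientDataError,
    NumericalError,
)
from .sampling import UniformSample

STD_COLUMNS = ("hc_std", "ac_std", "fl_std")
MM_COLUMNS = ("hc_mm", "ac_mm", "fl_mm")

#: Within this distance of the accessible-range flanks the trajectory
#: projection clamps against the grid ends; its weight is tapered to zero
#: there and the region is excluded from the variance-component fit.
FLANK_TAPER_DAYS = 20.0


# ---------------------------------------------------------------------------
# Standardization


@dataclass(frozen=True)
class Standardization:
    """Per-measure location/scale learned on the training sample."""

    mean: np.ndarray  # (3,)
    scale: np.ndarray  # (3,)

    def apply(self, biometry_mm: np.ndarray) -> np.ndarray:
        return (np.asarray(biometry_mm, dtype=float) - self.mean) / self.scale

    def invert(self, standardized: np.ndarray) -> np.ndarray:
        return np.asarray(standardized, dtype=float) * self.scale + self.mean


def standardize(sample: UniformSample) -> tuple[UniformSample, Standardization]:
    """Zero-mean, unit-variance scaling of each measure over the sample.

    Returns a copy of the sample with ``*_std`` columns added, plus the
    parameters for reuse on test data.
    """
    if sample.n_scans == 0:
        raise DegenerateDataError("cannot standardize an empty sample")
    X = sample.biometry_matrix()
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    if np.any(scale < 1e-12):
        bad = [MM_COLUMNS[i] for i in np.flatnonzero(scale < 1e-12)]
        raise DegenerateDataError(f"zero variance in measure(s): {bad}")
    params = Standardization(mean=mean, scale=scale)
    frame = sample.frame.copy()
    frame[list(STD_COLUMNS)] = params.apply(X)
    out = UniformSample(
        frame=frame,
        scans_per_day=sample.scans_per_day,
        ga_range=sample.ga_range,
        shortfall_bins=list(sample.shortfall_bins),
    )
    return out, params


# ---------------------------------------------------------------------------
# Supervectors


@dataclass
class Supervectors:
    """Sliding-window concatenations of standardized scans.

    Window ``j`` covers sample rows ``j .. j+c-1`` in nominal-GA order, so
    there are exactly ``M - c + 1`` windows of dimension ``3c``.
    """

    X: np.ndarray  # (n_windows, 3c)
    center_ga_days: np.ndarray  # (n_windows,)
    c: int

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    def member_range(self, j: int) -> tuple[int, int]:
        """Half-open row range [start, stop) of window ``j`` in the sample."""
        return j, j + self.c

    def windows_of_scan(self, i: int) -> tuple[int, int]:
        """Half-open window range [first, last+1) containing sample row ``i``."""
        first = max(0, i - self.c + 1)
        last = min(i, self.n_windows - 1)
        return first, last + 1


def build_supervectors(sample: UniformSample, c: int) -> Supervectors:
    """Concatenate ``c`` consecutive standardized triplets per window."""
    missing = [col for col in STD_COLUMNS if col not in sample.frame.columns]
    if missing:
        raise DegenerateDataError("sample must be standardized before windowing")
    M = sample.n_scans
    if M < c:
        raise InsufficientDataError(f"need at least c={c} scans, sample has M={M}")
    Xs = sample.frame[list(STD_COLUMNS)].to_numpy(dtype=float)
    ga = sample.frame["nominal_ga_days"].to_numpy(dtype=float)
    n_win = M - c + 1
    windows = np.lib.stride_tricks.sliding_window_view(Xs, (c, 3))[:, 0]  # (n_win, c, 3)
    X = windows.reshape(n_win, 3 * c).copy()
    cs = np.concatenate([[0.0], np.cumsum(ga)])
    center = (cs[c:] - cs[:-c]) / c
    return Supervectors(X=X, center_ga_days=center, c=c)


# ---------------------------------------------------------------------------
# Diffusion embedding


@dataclass
class DiffusionEmbedding:
    """Leading nontrivial eigencoordinates of the diffusion operator."""

    eigenvalues: np.ndarray  # (k,), non-increasing, in (0, 1]
    coords: np.ndarray  # (n_windows, k)
    bandwidth: float
    n_components: int

    @property
    def n_windows(self) -> int:
        return self.coords.shape[0]


#: Below this many supervectors a dense symmetric eigensolve is used; above,
#: ARPACK with a fixed permutation-invariant start vector.
_DENSE_EIG_LIMIT = 800


def diffusion_embedding(
    supervectors: Supervectors,
    bandwidth_factor: float = 1.0,
    n_components: int = 8,
) -> DiffusionEmbedding:
    """Density-normalized (alpha=1) diffusion-map embedding.

    Pairwise Euclidean distances between supervectors feed a Gaussian kernel
    with bandwidth ``bandwidth_factor x median pairwise distance``; the
    kernel is density-normalized to decouple geometry from residual sampling
    density, symmetrized into the conjugate of the Markov operator, and its
    leading nontrivial eigenvectors are returned with eigenvalues sorted in
    non-increasing order.  Signs are fixed so each coordinate correlates
    positively with the window-center nominal GA.
    """
    X = supervectors.X
    n = X.shape[0]
    if n < n_components + 2:
        raise InsufficientDataError(
            f"need at least n_components+2={n_components + 2} supervectors, got {n}"
        )
    if not np.all(np.isfinite(X)):
        raise NumericalError("supervectors contain non-finite values")
    D = pairwise_distances(X, metric="euclidean")
    if not np.all(np.isfinite(D)):
        raise NumericalError("non-finite pairwise distances")
    med = float(np.median(D))
    eps = bandwidth_factor * med
    if eps <= 0:
        raise DegenerateDataError("all supervectors identical; zero kernel bandwidth")

    K = D  # reuse buffer
    np.square(K, out=K)
    K /= -(eps**2)
    np.exp(K, out=K)
    q = K.sum(axis=1)
    K /= q[:, None]
    K /= q[None, :]
    d1 = K.sum(axis=1)
    sqrt_d1 = np.sqrt(d1)
    K /= sqrt_d1[:, None]
    K /= sqrt_d1[None, :]
    # K is now the symmetric conjugate of the Markov operator
    k_eig = n_components + 1
    try:
        if n <= _DENSE_EIG_LIMIT:
            vals, vecs = sla.eigh(K, subset_by_index=(n - k_eig, n - 1))
        else:
            v0 = np.full(n, 1.0 / np.sqrt(n))
            vals, vecs = eigsh(K, k=k_eig, which="LA", v0=v0)
    except Exception as exc:  # pragma: no cover - solver failure path
        raise NumericalError(f"eigen-solver failure on {n} supervectors: {exc!r}") from exc
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    # drop the trivial constant mode (eigenvalue 1, eigenvector ~ sqrt(d1))
    vals = np.clip(vals[1:], 0.0, 1.0)
    phi = vecs[:, 1:] / sqrt_d1[:, None]
    phi /= np.sqrt(np.mean(phi**2, axis=0, keepdims=True))  # unit-RMS convention
    center = supervectors.center_ga_days
    for k in range(phi.shape[1]):
        r = np.corrcoef(phi[:, k], center)[0, 1]
        if np.isfinite(r) and r < 0:
            phi[:, k] = -phi[:, k]
    return DiffusionEmbedding(
        eigenvalues=vals, coords=phi, bandwidth=eps, n_components=n_components
    )


# ---------------------------------------------------------------------------
# Clock refinement


@dataclass
class ClockRefinement:
    """Per-scan manifold clock and its calibration artifacts."""

    clock_component: int
    clock_spearman: float
    calibration_x: np.ndarray  # monotone coordinate knots
    calibration_y: np.ndarray  # GA days at the knots
    window_ga_days: np.ndarray  # calibrated clock per window
    window_clock_u: np.ndarray  # per scan: window-averaged clock
    projection_p: np.ndarray  # per scan: developmental age from biometry
    refined_ga_days: np.ndarray  # per scan: combined clock
    ga_support: tuple[float, float]
    curve_grid: np.ndarray  # (G,) GA grid
    curve_values: np.ndarray  # (G, 3) mean standardized trajectory
    curve_resid_sd: np.ndarray  # (3,)
    variance_components: dict = field(default_factory=dict)


def _per_scan_clock(window_vals: np.ndarray, M: int, c: int) -> np.ndarray:
    """Per-scan clock from a per-window quantity.

    Interior scans take the window value interpolated at their rank (window
    ``j`` is centred at rank ``j + (c-1)/2``); this matches averaging over
    all member windows for a locally linear clock.  Scans on the flanks,
    whose member windows are one-sided (a plain member-window average would
    be biased toward the interior by up to half a window span), are
    extrapolated linearly using the edge slope of the window clock.
    """
    n_win = len(window_vals)
    centers = np.arange(n_win) + (c - 1) / 2.0
    i = np.arange(M, dtype=float)
    u = np.interp(i, centers, window_vals)
    k = max(min(20, n_win), n_win // 20)
    if n_win >= 2:
        s_lo = np.polyfit(centers[:k], window_vals[:k], 1)[0]
        s_hi = np.polyfit(centers[-k:], window_vals[-k:], 1)[0]
        low = i < centers[0]
        high = i > centers[-1]
        u[low] = window_vals[0] + s_lo * (i[low] - centers[0])
        u[high] = window_vals[-1] + s_hi * (i[high] - centers[-1])
    return u


def fit_mean_trajectory(
    u: np.ndarray, Xs: np.ndarray, grid_step: float = 0.25, frac: float = 0.06
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smooth mean standardized-biometry trajectory along the clock.

    Returns (grid, values (G,3), per-measure residual SD).  LOWESS with a
    short span; ``delta`` aggregation keeps it linear-time in the sample.
    """
    lo, hi = float(np.min(u)), float(np.max(u))
    grid = np.arange(lo, hi + grid_step, grid_step)
    vals = np.empty((len(grid), Xs.shape[1]))
    resid_sd = np.empty(Xs.shape[1])
    span = hi - lo
    for k in range(Xs.shape[1]):
        sm = lowess(Xs[:, k], u, frac=frac, it=1, delta=0.005 * span, return_sorted=True)
        vals[:, k] = np.interp(grid, sm[:, 0], sm[:, 1])
        resid_sd[k] = np.std(Xs[:, k] - np.interp(u, sm[:, 0], sm[:, 1]))
    resid_sd = np.maximum(resid_sd, 1e-6)
    return grid, vals, resid_sd


def project_onto_trajectory(
    X: np.ndarray, grid: np.ndarray, curve: np.ndarray, resid_sd: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Developmental age of each scan: closest point on the mean trajectory.

    Distances are weighted by inverse residual variance per measure; the
    discrete minimum is refined by parabolic interpolation.  Returns
    (projected age, weighted squared residual at the optimum).
    """
    W = 1.0 / resid_sd**2
    # (n, G) weighted squared distances
    D2 = np.zeros((X.shape[0], len(grid)))
    for k in range(X.shape[1]):
        D2 += W[k] * (X[:, k, None] - curve[None, :, k]) ** 2
    j = np.argmin(D2, axis=1)
    p = grid[j].astype(float)
    resid = D2[np.arange(len(j)), j]
    interior = (j > 0) & (j < len(grid) - 1)
    if np.any(interior):
        ji = j[interior]
        dl = D2[interior, ji - 1]
        dm = D2[interior, ji]
        dr = D2[interior, ji + 1]
        denom = dl - 2 * dm + dr
        shift = np.where(denom > 1e-12, 0.5 * (dl - dr) / np.maximum(denom, 1e-12), 0.0)
        step = grid[1] - grid[0]
        p[interior] = grid[ji] + np.clip(shift, -1.0, 1.0) * step
    return p, resid


def estimate_variance_components(
    fetus_ids: np.ndarray,
    u: np.ndarray,
    p: np.ndarray,
    bin_width_days: float = 14.0,
    flank_trim_days: float = FLANK_TAPER_DAYS,
) -> dict:
    """Method-of-moments noise decomposition of the offset d = p - u.

    Conditional on age, the offset is (rho - 1)*t - tau + measurement noise,
    so its variance follows Var(d | u) = sigma_tau^2 + sigma_rho^2 u^2 +
    sigma_meas^2(u).  Measurement noise is estimated from within-fetus
    residuals around each fetus's own linear offset trend (time-zero and
    growth-rate effects cancel there); the remaining binned variance of d is
    regressed on u^2 to separate the growth-rate spread (slope) from the
    time-zero spread (intercept).  Only the training cohort's own grouping
    is used -- no ground truth.
    """
    d = p - u
    n = len(d)
    if n < 30:
        total = float(np.var(d)) if n else 1.0
        half = float(np.sqrt(max(total / 2.0, 1.0)))
        return {"sigma_tau_days": half, "sigma_rho": 0.0,
                "sigma_meas_days": half, "n_fetuses_used": 0}

    # per-scan measurement-noise proxy: residual from the fetus's own trend
    frame = pd.DataFrame({"fid": fetus_ids, "u": u, "d": d})
    resid = np.full(n, np.nan)
    n_fetuses_used = 0
    for _, g in frame.groupby("fid", sort=True):
        if len(g) < 3:
            continue
        uu = g["u"].to_numpy()
        dd = g["d"].to_numpy()
        sxx = float(np.sum((uu - uu.mean()) ** 2))
        if sxx < 1e-9:
            continue
        b = float(np.sum((uu - uu.mean()) * (dd - dd.mean())) / sxx)
        r = dd - (dd.mean() + b * (uu - uu.mean()))
        # inflate by k/(k-2) so squared residuals are unbiased for the noise
        resid[g.index] = r * np.sqrt(len(g) / max(len(g) - 2, 1))
        n_fetuses_used += 1

    # flank windows suffer asymmetric averaging and projection clamping at
    # the grid edges, which collapses the offset variance there; exclude them
    lo_u, hi_u = u.min() + flank_trim_days, u.max() - flank_trim_days
    interior = (u >= lo_u) & (u <= hi_u)
    bins = np.floor((u - u.min()) / bin_width_days).astype(int)
    rows = []
    for b in np.unique(bins[interior]):
        m = (bins == b) & interior
        if m.sum() < 20:
            continue
        meas_var = float(np.nanmean(resid[m] ** 2)) if np.any(np.isfinite(resid[m])) else 0.0
        rows.append((float(np.mean(u[m] ** 2)), float(np.var(d[m])) - meas_var,
                     float(np.nanmean(resid[m] ** 2)), int(m.sum())))
    if len(rows) < 3 or n_fetuses_used < 10:
        total = float(np.var(d))
        half = float(np.sqrt(max(total / 2.0, 1.0)))
        return {"sigma_tau_days": half, "sigma_rho": 0.0,
                "sigma_meas_days": half, "n_fetuses_used": n_fetuses_used}
    u2 = np.array([r[0] for r in rows])
    v = np.array([r[1] for r in rows])
    wts = np.array([r[3] for r in rows], dtype=float)
    # weighted least squares of Var(d) - meas on u^2
    W = wts / wts.sum()
    u2c = u2 - np.sum(W * u2)
    vc = v - np.sum(W * v)
    beta = float(np.sum(W * u2c * vc) / max(np.sum(W * u2c**2), 1e-12))
    sigma_rho_sq = max(beta, 0.0)
    alpha = float(np.sum(W * v) - sigma_rho_sq * np.sum(W * u2))
    sigma_meas_sq = max(float(np.nanmean(resid**2)), 1e-4)
    sigma_tau_sq = max(alpha, 1.0)
    return {
        "sigma_tau_days": float(np.sqrt(sigma_tau_sq)),
        "sigma_rho": float(np.sqrt(sigma_rho_sq)),
        "sigma_meas_days": float(np.sqrt(sigma_meas_sq)),
        "n_fetuses_used": int(n_fetuses_used),
    }


def refine_training_clock(
    embedding: DiffusionEmbedding,
    supervectors: Supervectors,
    sample: UniformSample,
    min_spearman: float = 0.9,
) -> ClockRefinement:
    """Calibrate the embedding into a per-scan gestational clock.

    The eigencoordinate most (rank-)correlated with the window-center
    nominal GA is calibrated by isotonic regression -- a population-level
    monotone fit through which individual time-zero errors average out.
    Each scan's window clock ``u`` is the mean calibrated value over its
    member windows; its projection ``p`` is the age at which the mean
    trajectory best matches its own biometry; the refined clock blends the
    two with inverse-variance weights from the training cohort's estimated
    noise components.
    """
    center = supervectors.center_ga_days
    rhos = [abs(stats.spearmanr(embedding.coords[:, k], center).statistic)
            for k in range(embedding.coords.shape[1])]
    clock_k = int(np.argmax(rhos))
    sp = float(rhos[clock_k])
    if sp < min_spearman:
        raise EmbeddingQualityError(
            f"principal coordinate vs center GA Spearman {sp:.3f} < {min_spearman}"
        )
    coord = embedding.coords[:, clock_k]
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(coord, center)
    window_ga = iso.predict(coord)

    M = sample.n_scans
    u = _per_scan_clock(window_ga, M, supervectors.c)
    ga_support = (float(np.min(window_ga)), float(np.max(window_ga)))

    Xs = sample.frame[list(STD_COLUMNS)].to_numpy(dtype=float)
    grid, curve, resid_sd = fit_mean_trajectory(u, Xs)
    p, _ = project_onto_trajectory(Xs, grid, curve, resid_sd)

    vc = estimate_variance_components(sample.frame["fetus_id"].to_numpy(), u, p)
    refined = combine_clocks(u, p, vc)

    return ClockRefinement(
        clock_component=clock_k,
        clock_spearman=sp,
        calibration_x=np.asarray(iso.X_thresholds_, dtype=float),
        calibration_y=np.asarray(iso.y_thresholds_, dtype=float),
        window_ga_days=window_ga,
        window_clock_u=u,
        projection_p=p,
        refined_ga_days=refined,
        ga_support=ga_support,
        curve_grid=grid,
        curve_values=curve,
        curve_resid_sd=resid_sd,
        variance_components=vc,
    )


def combine_clocks(u: np.ndarray, p: np.ndarray, vc: dict,
                   u_range: tuple[float, float] | None = None) -> np.ndarray:
    """Inverse-variance blend of the window clock and trajectory projection.

    The projection weight is tapered to zero within ``FLANK_TAPER_DAYS`` of
    the accessible-range flanks, where projection clamping makes it biased.
    """
    var_u = max(vc["sigma_tau_days"] ** 2, 1e-2)
    var_p = vc["sigma_meas_days"] ** 2 + (vc["sigma_rho"] * u) ** 2
    lo, hi = u_range if u_range is not None else (float(np.min(u)), float(np.max(u)))
    ramp = np.clip(np.minimum(u - lo, hi - u) / FLANK_TAPER_DAYS, 0.0, 1.0)
    w_u = 1.0 / var_u
    w_p = ramp / np.maximum(var_p, 1e-2)
    return (w_u * u + w_p * p) / (w_u + w_p)


def extract_trajectory_coordinate(
    embedding: DiffusionEmbedding,
    refinement: ClockRefinement,
    decorrelation_threshold: float = 0.3,
) -> np.ndarray:
    """Per-scan growth-trajectory coordinate, centred to zero mean.

    The coordinate is the scan's developmental-age offset from the window
    clock, ``p - u``: fetuses growing faster than average sit ahead of their
    nominal-ordered peers and accumulate positive offsets, so per-fetus
    means of this coordinate track the growth-rate factor.  A secondary
    eigencoordinate decorrelated from the clock (|Spearman| below the
    threshold) would carry the same information if the window population
    resolved it; it is kept as a diagnostic fallback because window
    averaging over a pooled population dilutes fetus-level signal.
    """
    d = refinement.projection_p - refinement.window_clock_u
    return d - float(np.mean(d))


__all__ = [
    "STD_COLUMNS",
    "MM_COLUMNS",
    "Standardization",
    "Supervectors",
    "DiffusionEmbedding",
    "ClockRefinement",
    "standardize",
    "build_supervectors",
    "diffusion_embedding",
    "refine_training_clock",
    "extract_trajectory_coordinate",
    "fit_mean_trajectory",
    "project_onto_trajectory",
    "estimate_variance_components",
]
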