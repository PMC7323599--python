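"""Time-uniform thinning of pooled scans and participant-level k-fold splits.

Both real longitudinal studies and the simulator produce scan densities
that vary over gestational age (visit windows, monthly clinic peaks).  The
training protocol removes scans at random from over-supplied one-day bins
until the pooled sample is uniform in time, and splits cohorts into folds by
*fetus*, never by scan, so no participant is ever tested more than once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import ConfigError

logger = logging.getLogger(__name__)


@dataclass
class UniformSample:
    """Pooled scans thinned to a target density, sorted by nominal GA.

    ``frame`` has one row per retained scan with at least the columns
    ``fetus_id, visit_index, nominal_ga_days, hc_mm, ac_mm, fl_mm`` (plus
    ``true_ga_days`` when simulated).  ``shortfall_bins`` lists the day bins
    that could not reach the target count.
    """

    frame: pd.DataFrame
    scans_per_day: float
    ga_range: tuple[float, float]
    shortfall_bins: list[int] = field(default_factory=list)

    @property
    def n_scans(self) -> int:
        return len(self.frame)

    def biometry_matrix(self) -> np.ndarray:
        return self.frame[["hc_mm", "ac_mm", "fl_mm"]].to_numpy(dtype=float)


def _as_frame(cohort) -> pd.DataFrame:
    if isinstance(cohort, Cohort):
        return cohort.to_dataframe()
    return cohort.copy()


def thin_to_uniform(
    cohort,
    scans_per_day: float,
    ga_range: tuple[float, float],
    seed: int | np.random.Generator = 0,
) -> UniformSample:
    """Thin pooled scans to a uniform-in-time density.

    Day bins are half-open intervals [d, d+1) anchored at integer days from
    GA zero.  Within each bin, scans beyond the target count are removed
    uniformly at random; under-supplied bins keep all their scans and are
    recorded (with a logged warning when more than 5% of bins fall short).
    Deterministic given ``seed``.
    """
    lo, hi = ga_range
    if not (lo < hi):
        raise ConfigError(f"empty ga_range {ga_range}")
    if scans_per_day <= 0:
        raise ConfigError("scans_per_day must be positive")
    per_bin = int(round(scans_per_day))  # bins are exactly one day wide

    df = _as_frame(cohort)
    df = df[df["nominal_ga_days"].notna()].copy()
    df = df[(df["nominal_ga_days"] >= lo) & (df["nominal_ga_days"] < hi)]
    # stable, reproducible ordering before any random choice
    df = df.sort_values(["nominal_ga_days", "fetus_id", "visit_index"], kind="mergesort")
    df = df.reset_index(drop=True)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    day = np.floor(df["nominal_ga_days"].to_numpy()).astype(int)
    keep_idx: list[np.ndarray] = []
    shortfall: list[int] = []
    for b in range(int(np.floor(lo)), int(np.ceil(hi))):
        members = np.flatnonzero(day == b)
        if len(members) > per_bin:
            members = np.sort(rng.choice(members, size=per_bin, replace=False))
        elif len(members) < per_bin:
            shortfall.append(b)
        keep_idx.append(members)
    keep = np.concatenate(keep_idx) if keep_idx else np.array([], dtype=int)
    out = df.iloc[np.sort(keep)].reset_index(drop=True)

    n_bins = int(np.ceil(hi)) - int(np.floor(lo))
    if n_bins and len(shortfall) > 0.05 * n_bins:
        logger.warning(
            "thin_to_uniform: %d of %d day bins below target density %d",
            len(shortfall), n_bins, per_bin,
        )
    return UniformSample(frame=out, scans_per_day=scans_per_day,
                         ga_range=(float(lo), float(hi)), shortfall_bins=shortfall)


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of fetuses into ``n_folds`` folds (indices 1..N)."""

    n_folds: int
    fold_of_fetus: dict[str, int]

    def fold_ids(self, fold: int) -> list[str]:
        return sorted(f for f, k in self.fold_of_fetus.items() if k == fold)


def kfold_split(cohort, n_folds: int, seed: int = 0) -> FoldAssignment:
    """Randomly partition fetuses (never scans) into folds of near-equal size.

    Reproducible given ``seed``; fold sizes differ by at most one.
    """
    if isinstance(cohort, Cohort):
        ids = sorted(f.fetus_id for f in cohort)
    else:
        ids = sorted(pd.unique(_as_frame(cohort)["fetus_id"]))
    if not (2 <= n_folds <= len(ids)):
        raise ConfigError(
            f"n_folds must be in [2, {len(ids)}] for {len(ids)} fetuses, got {n_folds}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    chunks = np.array_split(order, n_folds)
    fold_of = {}
    for k, chunk in enumerate(chunks, start=1):
        for idx in chunk:
            fold_of[ids[idx]] = k
    return FoldAssignment(n_folds=n_folds, fold_of_fetus=fold_of)


__all__ = ["UniformSample", "FoldAssignment", "thin_to_uniform", "kfold_split"]
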