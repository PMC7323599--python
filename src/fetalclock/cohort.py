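"""Domain types and I/O for longitudinal fetal-biometry cohorts.

A *cohort* is a set of fetuses, each with a time-ordered list of ultrasound
scans.  Each scan records the three standard biometric measures -- head
circumference (HC), abdominal circumference (AC) and femur length (FL), in
millimetres, each already averaged over triplicate acquisitions -- together
with the nominal, last-menstrual-period (LMP) based gestational age in days.
Simulated cohorts additionally carry the true (conception-anchored)
gestational age, which real data never has.

Gestational age is measured in **days** throughout the package; "week w"
denotes the half-open day interval [7w, 7w+7).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DuplicateScanError,
    InvalidMeasurementError,
    ParseError,
    SchemaError,
)

DAYS_PER_WEEK = 7.0

#: Required CSV columns, in canonical order.
REQUIRED_COLUMNS = (
    "fetus_id",
    "visit_index",
    "nominal_ga_days",
    "hc_mm",
    "ac_mm",
    "fl_mm",
)
OPTIONAL_COLUMNS = ("true_ga_days", "population_label")


def weeks_to_days(weeks: float) -> float:
    return weeks * DAYS_PER_WEEK


def days_to_weeks(days: float) -> float:
    return days / DAYS_PER_WEEK


def week_bin(week: int) -> tuple[float, float]:
    """Day interval [7w, 7w+7) denoted by gestational week ``week``."""
    return (7.0 * week, 7.0 * (week + 1))


def average_triplicates(m1: float, m2: float, m3: float) -> float:
    """Arithmetic mean of triplicate measurements of one structure.

    Each biometric parameter is acquired three times from separately obtained
    images; the scan-level value used throughout the package is their mean.
    """
    vals = (m1, m2, m3)
    for v in vals:
        if not (isinstance(v, (int, float)) and math.isfinite(v)) or v <= 0:
            raise InvalidMeasurementError(
                f"triplicate values must be finite and positive, got {vals!r}"
            )
    return (m1 + m2 + m3) / 3.0


@dataclass(frozen=True)
class BiometrySample:
    """One scan's (HC, AC, FL) triplet in millimetres."""

    hc_mm: float
    ac_mm: float
    fl_mm: float

    def __post_init__(self):
        for name in ("hc_mm", "ac_mm", "fl_mm"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise InvalidMeasurementError(f"{name} must be finite and > 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.hc_mm, self.ac_mm, self.fl_mm], dtype=float)


@dataclass(frozen=True)
class Scan:
    """A single ultrasound visit.

    ``nominal_ga_days`` may be ``None`` for blinded test scans: the validation
    protocols deliberately withhold all timing information from the estimator.
    """

    fetus_id: str
    visit_index: int
    biometry: BiometrySample
    nominal_ga_days: float | None = None
    true_ga_days: float | None = None

    def __post_init__(self):
        if self.visit_index < 1:
            raise ValueError(f"visit_index must be >= 1, got {self.visit_index}")
        for name in ("nominal_ga_days", "true_ga_days"):
            v = getattr(self, name)
            if v is not None and not (0 < v < 310):
                raise ValueError(f"{name} must be in (0, 310) days, got {v}")


@dataclass
class FetusRecord:
    """A fetus's scans, sorted by visit index."""

    fetus_id: str
    scans: list[Scan]
    population_label: str = ""

    def __post_init__(self):
        self.scans = sorted(self.scans, key=lambda s: s.visit_index)
        seen = set()
        for s in self.scans:
            if s.visit_index in seen:
                raise DuplicateScanError(
                    f"fetus {self.fetus_id!r}: duplicate visit_index {s.visit_index}"
                )
            seen.add(s.visit_index)


@dataclass
class Cohort:
    """A population of fetuses."""

    fetuses: list[FetusRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        ids = [f.fetus_id for f in self.fetuses]
        if len(ids) != len(set(ids)):
            raise DuplicateScanError("fetus_ids must be unique within a cohort")

    @property
    def n_fetuses(self) -> int:
        return len(self.fetuses)

    @property
    def n_scans(self) -> int:
        return sum(len(f.scans) for f in self.fetuses)

    def __iter__(self):
        return iter(self.fetuses)

    def subset(self, fetus_ids) -> "Cohort":
        wanted = set(fetus_ids)
        return Cohort(
            fetuses=[f for f in self.fetuses if f.fetus_id in wanted],
            provenance=self.provenance,
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for f in self.fetuses:
            for s in f.scans:
                rows.append(
                    {
                        "fetus_id": f.fetus_id,
                        "visit_index": s.visit_index,
                        "nominal_ga_days": np.nan
                        if s.nominal_ga_days is None
                        else s.nominal_ga_days,
                        "hc_mm": s.biometry.hc_mm,
                        "ac_mm": s.biometry.ac_mm,
                        "fl_mm": s.biometry.fl_mm,
                        "true_ga_days": np.nan if s.true_ga_days is None else s.true_ga_days,
                        "population_label": f.population_label,
                    }
                )
        cols = list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)
        return pd.DataFrame(rows, columns=cols)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "Cohort":
        fetuses = []
        for fid, grp in df.groupby("fetus_id", sort=True):
            scans = []
            label = ""
            for _, row in grp.iterrows():
                nominal = row.get("nominal_ga_days", np.nan)
                true = row.get("true_ga_days", np.nan)
                label = str(row.get("population_label", "") or "")
                scans.append(
                    Scan(
                        fetus_id=str(fid),
                        visit_index=int(row["visit_index"]),
                        biometry=BiometrySample(
                            float(row["hc_mm"]), float(row["ac_mm"]), float(row["fl_mm"])
                        ),
                        nominal_ga_days=None if pd.isna(nominal) else float(nominal),
                        true_ga_days=None if pd.isna(true) else float(true),
                    )
                )
            fetuses.append(FetusRecord(fetus_id=str(fid), scans=scans, population_label=label))
        return cls(fetuses=fetuses, provenance=provenance)


def read_cohort(path) -> Cohort:
    """Read a cohort from CSV (UTF-8, comma separated, '.' decimal).

    Required columns: ``fetus_id, visit_index, nominal_ga_days, hc_mm, ac_mm,
    fl_mm``; optional: ``true_ga_days, population_label``.  An absent nominal
    gestational age is encoded as an empty field.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    numeric_cols = ["visit_index", "nominal_ga_days", "hc_mm", "ac_mm", "fl_mm"]
    if "true_ga_days" in raw.columns:
        numeric_cols.append("true_ga_days")
    df = raw.copy()
    for col in numeric_cols:
        stripped = raw[col].str.strip()
        parsed = pd.to_numeric(stripped, errors="coerce")
        bad = parsed.isna() & (stripped != "")
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ParseError(
                f"non-numeric value {raw[col][bad.idxmax()]!r} in column {col!r} at line {row}",
                row=row,
            )
        optional = col in ("nominal_ga_days", "true_ga_days")
        if not optional and (stripped == "").any():
            row = int((stripped == "").idxmax()) + 2
            raise ParseError(f"empty value in required column {col!r} at line {row}", row=row)
        df[col] = parsed
    dupes = df.duplicated(subset=["fetus_id", "visit_index"])
    if dupes.any():
        r = df[dupes].iloc[0]
        raise DuplicateScanError(
            f"duplicate scan for fetus {r['fetus_id']!r} visit {int(r['visit_index'])}"
        )
    if "true_ga_days" not in df.columns:
        df["true_ga_days"] = np.nan
    if "population_label" not in df.columns:
        df["population_label"] = ""
    return Cohort.from_dataframe(df, provenance=str(path))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as CSV; round-trips bit-identically through read_cohort."""
    df = cohort.to_dataframe()
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Structural validation


@dataclass(frozen=True)
class ValidationRules:
    """Configurable plausibility bounds and visit-window rules.

    The scheduled visit windows are 14-18, 19-23, 24-28, 29-33, 34-38 and
    39-42 weeks of (LMP-based) gestation, after an initial dating scan at
    less than 14 weeks that carries no HC/AC/FL biometry.
    """

    hc_bounds_mm: tuple[float, float] = (50.0, 450.0)
    ac_bounds_mm: tuple[float, float] = (50.0, 450.0)
    fl_bounds_mm: tuple[float, float] = (5.0, 90.0)
    first_window_start_days: float = 98.0  # 14 weeks
    last_window_end_days: float = 301.0  # end of week 42


@dataclass(frozen=True)
class Finding:
    code: str
    fetus_id: str
    visit_index: int | None
    message: str


def validate_cohort(cohort: Cohort, rules: ValidationRules | None = None) -> list[Finding]:
    """Structural validation; returns findings (never raises).

    Checks each scan's nominal GA against the study visit windows, nominal GA
    monotonicity within a fetus, and biometry plausibility bounds.
    """
    rules = rules or ValidationRules()
    findings: list[Finding] = []
    bounds = {
        "hc_mm": rules.hc_bounds_mm,
        "ac_mm": rules.ac_bounds_mm,
        "fl_mm": rules.fl_bounds_mm,
    }
    for fetus in cohort:
        prev_nominal = None
        for scan in fetus.scans:
            ga = scan.nominal_ga_days
            if ga is not None:
                if ga < rules.first_window_start_days:
                    findings.append(
                        Finding(
                            "before_first_window",
                            fetus.fetus_id,
                            scan.visit_index,
                            f"nominal GA {ga:.1f} d precedes the first biometry "
                            f"window at {rules.first_window_start_days:.0f} d",
                        )
                    )
                elif ga >= rules.last_window_end_days:
                    findings.append(
                        Finding(
                            "after_last_window",
                            fetus.fetus_id,
                            scan.visit_index,
                            f"nominal GA {ga:.1f} d beyond the last visit window",
                        )
                    )
                if prev_nominal is not None and ga <= prev_nominal:
                    findings.append(
                        Finding(
                            "non_increasing_nominal_ga",
                            fetus.fetus_id,
                            scan.visit_index,
                            f"nominal GA {ga:.1f} d does not increase "
                            f"(previous {prev_nominal:.1f} d)",
                        )
                    )
                prev_nominal = ga
            for name, (lo, hi) in bounds.items():
                v = getattr(scan.biometry, name)
                if not (lo <= v <= hi):
                    findings.append(
                        Finding(
                            "biometry_out_of_bounds",
                            fetus.fetus_id,
                            scan.visit_index,
                            f"{name}={v:.1f} outside [{lo:.0f}, {hi:.0f}] mm",
                        )
                    )
    return findings


__all__ = [
    "DAYS_PER_WEEK",
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "BiometrySample",
    "Scan",
    "FetusRecord",
    "Cohort",
    "Finding",
    "ValidationRules",
    "average_triplicates",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "weeks_to_days",
    "days_to_weeks",
    "week_bin",
]
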