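"""Population mean growth curves for HC, AC and FL.

The curves are smooth quadratic polynomials of true gestational age fitted
through anchor points chosen to approximate published second/third-trimester
biometry centiles (HC ~175 mm at 20 weeks rising to ~280 mm at 30 weeks,
FL ~33 mm to ~57 mm over the same span).  Only the realistic shape and
spread matter for the simulator; the anchors are configuration, not
hard-coded constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DomainError

MEASURES = ("hc", "ac", "fl")

#: Anchor points (true GA days, mm) per measure used for the default curves.
DEFAULT_ANCHORS: dict[str, tuple[tuple[float, float], ...]] = {
    "hc": ((98.0, 98.0), (140.0, 175.0), (210.0, 280.0)),
    "ac": ((98.0, 80.0), (140.0, 150.0), (210.0, 255.0)),
    "fl": ((98.0, 14.0), (140.0, 33.0), (210.0, 57.0)),
}

#: Widest true-GA span the default curves must support: nominal scheduling
#: covers [98, 294] d, time-zero offsets reach +-14 d and growth-rate
#: dilation stretches developmental age by up to ~10%.
DEFAULT_DOMAIN = (84.0, 345.0)


@dataclass(frozen=True)
class GrowthCurveSet:
    """Mean biometry curves mm = f(true GA days), one per measure.

    ``coefficients`` maps each measure to polynomial coefficients in
    :func:`numpy.polyval` order (highest degree first).  Each curve must be
    strictly increasing and positive on ``domain``.
    """

    coefficients: dict[str, np.ndarray]
    domain: tuple[float, float] = DEFAULT_DOMAIN

    def __post_init__(self):
        missing = [m for m in MEASURES if m not in self.coefficients]
        if missing:
            raise ConfigError(f"curves missing measure(s): {missing}")
        lo, hi = self.domain
        grid = np.linspace(lo, hi, 512)
        for m in MEASURES:
            vals = np.polyval(self.coefficients[m], grid)
            if not np.all(np.diff(vals) > 0):
                raise ConfigError(f"curve for {m!r} is not strictly increasing on {self.domain}")
            if not np.all(vals > 0):
                raise ConfigError(f"curve for {m!r} is not positive on {self.domain}")

    @classmethod
    def from_anchors(
        cls,
        anchors: dict[str, tuple[tuple[float, float], ...]] | None = None,
        domain: tuple[float, float] = DEFAULT_DOMAIN,
    ) -> "GrowthCurveSet":
        anchors = anchors or DEFAULT_ANCHORS
        coeffs = {}
        for m, pts in anchors.items():
            t = np.array([p[0] for p in pts], dtype=float)
            y = np.array([p[1] for p in pts], dtype=float)
            coeffs[m] = np.polyfit(t, y, deg=len(pts) - 1)
        return cls(coefficients=coeffs, domain=domain)

    @classmethod
    def default(cls) -> "GrowthCurveSet":
        return cls.from_anchors()

    @classmethod
    def linear_toy(cls) -> "GrowthCurveSet":
        """f(t) = t for every measure; useful for identity-curve checks."""
        one = np.array([1.0, 0.0])
        return cls(coefficients={m: one for m in MEASURES}, domain=(1.0, 400.0))

    def value(self, measure: str, true_ga_days) -> np.ndarray | float:
        return mean_biometry(measure, true_ga_days, self)

    def derivative(self, measure: str, true_ga_days) -> np.ndarray | float:
        """Growth velocity d(mm)/d(day); used by the forecasting oracle."""
        self._check(measure, true_ga_days)
        dcoef = np.polyder(self.coefficients[measure])
        return np.polyval(dcoef, true_ga_days)

    def _check(self, measure: str, t) -> None:
        if measure not in self.coefficients:
            raise ConfigError(f"unknown measure {measure!r}")
        t = np.asarray(t, dtype=float)
        lo, hi = self.domain
        if np.any(t < lo) or np.any(t > hi):
            raise DomainError(
                f"true GA outside supported range [{lo:.0f}, {hi:.0f}] d for {measure!r}"
            )


def mean_biometry(measure: str, true_ga_days, curves: GrowthCurveSet) -> np.ndarray | float:
    """Population mean measurement (mm) at a true gestational age (days).

    Deterministic, strictly increasing in GA and differentiable.  ``measure``
    is one of ``"hc"``, ``"ac"``, ``"fl"`` (case-insensitive).
    """
    measure = measure.lower()
    curves._check(measure, true_ga_days)
    out = np.polyval(curves.coefficients[measure], np.asarray(true_ga_days, dtype=float))
    if np.ndim(true_ga_days) == 0:
        return float(out)
    return out


__all__ = ["MEASURES", "DEFAULT_ANCHORS", "DEFAULT_DOMAIN", "GrowthCurveSet", "mean_biometry"]
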