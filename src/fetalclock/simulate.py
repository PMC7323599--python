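"""Synthetic longitudinal cohorts with known ground truth.

The generator emulates the statistical structure a gestational-age estimator
must overcome in a well-dated, healthy singleton cohort:

* **time-zero error** -- each pregnancy's LMP-based clock is offset from the
  true (conception-anchored) clock by tau_i ~ N(0, sigma_tau_days^2);
* **growth-rate heterogeneity** -- each fetus develops at its own rate
  rho_i ~ N(1, sigma_rho^2) (truncated to (0.7, 1.3)), acting as a *time
  dilation*: the biometric state at true age t is the population mean state
  at developmental age rho_i * t;
* **measurement noise** -- each recorded measure carries multiplicative
  noise (1 + eps), eps ~ N(0, cv_noise^2), on the triplicate-mean value;
* **visit schedule** -- a first biometry visit at 14-18 weeks (nominal
  clock, as clinics schedule by LMP) followed by visits every 5 weeks within
  1 week either side, capped at 42 weeks; every fetus receives 5-7 scans
  with consecutive gaps in [28, 42] days;
* **calendar clustering** -- scan dates cluster at roughly monthly clinic
  days; the strength is ``monthly_peak_weight`` (0 disables it).

Same seed and config give a bit-identical cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import ConfigError, UndefinedFractionError
from .growth import MEASURES, GrowthCurveSet, mean_biometry

#: Hard truncation for time-zero offsets: keeps nominal GA < 310 d and true
#: GA inside the default curve domain; 14 d is ~3.1 sigma at the default SD.
TAU_CLIP_DAYS = 14.0
RHO_BOUNDS = (0.7, 1.3)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults are calibrated so that (a) roughly a quarter of a conventional
    single-scan dating error stems from time-zero error with the remaining
    three quarters from growth-rate differences, and (b) a polynomial
    single-scan baseline degrades across 20-30 weeks on the scale reported
    for state-of-the-art biometric dating (9-18 days).
    """

    n_fetuses: int = 100
    sigma_tau_days: float = 4.5
    sigma_rho: float = 0.035
    cv_noise: float = 0.02
    first_visit_window_days: tuple[float, float] = (98.0, 126.0)
    intervisit_days: float = 35.0
    intervisit_jitter_days: float = 7.0
    max_nominal_days: float = 294.0
    max_visits: int = 7
    monthly_peak_weight: float = 0.3
    peak_period_days: float = 30.44
    population_label: str = "simulated"
    seed: int = 0
    curves: GrowthCurveSet = field(default_factory=GrowthCurveSet.default)

    def __post_init__(self):
        if self.n_fetuses < 1:
            raise ConfigError("n_fetuses must be >= 1")
        for name in ("sigma_tau_days", "sigma_rho", "cv_noise", "monthly_peak_weight"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        lo, hi = self.first_visit_window_days
        if not (0 < lo < hi):
            raise ConfigError("invalid first_visit_window_days")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def _visit_schedule(rng: np.random.Generator, lmp_date: float,
                    cfg: SimulationConfig) -> np.ndarray:
    """Nominal-GA visit times (days) for one fetus.

    Visits are scheduled on the nominal (LMP) clock.  Calendar clustering
    pulls each proposed date toward the nearest clinic day; gaps are then
    re-clipped into [28, 42] d so the protocol invariants always hold.
    """
    lo, hi = cfg.first_visit_window_days
    gap_lo = cfg.intervisit_days - cfg.intervisit_jitter_days
    gap_hi = cfg.intervisit_days + cfg.intervisit_jitter_days
    w, period = cfg.monthly_peak_weight, cfg.peak_period_days

    def pull(t: float) -> float:
        if w <= 0:
            return 0.0
        date = lmp_date + t
        offset = (date + period / 2.0) % period - period / 2.0  # signed dist to peak
        return float(np.clip(-w * offset, -7.0, 7.0))

    t = rng.uniform(lo, hi)
    t = float(np.clip(t + pull(t), lo, hi))
    visits = [t]
    while visits[-1] <= cfg.max_nominal_days - gap_lo and len(visits) < cfg.max_visits:
        prev = visits[-1]
        t = prev + rng.uniform(gap_lo, gap_hi)
        upper = min(prev + gap_hi, cfg.max_nominal_days)
        t = float(np.clip(t + pull(t), prev + gap_lo, upper))
        visits.append(t)
    return np.asarray(visits)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a synthetic cohort; reproducible given ``config.seed``.

    Each scan records both the nominal GA (true + tau_i) presented to any
    estimator and the true GA kept as ground truth.  Independent child
    generators drive tau, rho, the schedule, calendar placement and
    measurement noise, so switching one source off (e.g. ``sigma_rho=0``)
    leaves all other draws unchanged -- the basis of the paired variance
    decomposition below.
    """
    cohort, _ = simulate_cohort_with_latents(config)
    return cohort


def simulate_cohort_with_latents(
    config: SimulationConfig,
) -> tuple[Cohort, pd.DataFrame]:
    """As :func:`simulate_cohort`, also returning the per-fetus latents.

    The second element is a table with columns ``fetus_id, tau_days, rho,
    lmp_date`` -- the ground-truth time-zero offset, growth-rate factor and
    LMP calendar date (days, arbitrary origin) -- for recovery checks that
    real data could never support.
    """
    ss = np.random.SeedSequence(config.seed)
    g_tau, g_rho, g_sched, g_cal, g_noise = (np.random.default_rng(s) for s in ss.spawn(5))

    curves = config.curves
    dom_lo, dom_hi = curves.domain
    rows: list[dict] = []
    latents: list[dict] = []
    for i in range(config.n_fetuses):
        fid = f"F{i:05d}"
        tau = float(np.clip(g_tau.normal(0.0, config.sigma_tau_days),
                            -TAU_CLIP_DAYS, TAU_CLIP_DAYS))
        rho = float(np.clip(g_rho.normal(1.0, config.sigma_rho), *RHO_BOUNDS))
        lmp_date = float(g_cal.uniform(0.0, 365.25))
        latents.append(dict(fetus_id=fid, tau_days=tau, rho=rho, lmp_date=lmp_date))
        nominal = _visit_schedule(g_sched, lmp_date, config)
        true = nominal - tau
        dev_age = np.clip(rho * true, dom_lo, dom_hi)  # edge saturation, ~1e-6 of scans
        eps = g_noise.normal(0.0, config.cv_noise, size=(len(nominal), len(MEASURES)))
        for j, (n_ga, t_ga) in enumerate(zip(nominal, true)):
            mm = {
                f"{m}_mm": mean_biometry(m, dev_age[j], curves) * (1.0 + eps[j, k])
                for k, m in enumerate(MEASURES)
            }
            rows.append(
                dict(
                    fetus_id=fid,
                    visit_index=j + 1,
                    nominal_ga_days=n_ga,
                    true_ga_days=t_ga,
                    population_label=config.population_label,
                    **mm,
                )
            )
    df = pd.DataFrame(rows)
    cohort = Cohort.from_dataframe(df, provenance=f"simulated(seed={config.seed})")
    return cohort, pd.DataFrame(latents)


def variance_decomposition(config: SimulationConfig, baseline=None) -> float:
    """Fraction of single-scan dating error variance due to time-zero error.

    Runs two paired simulations sharing all random draws -- one with only
    the time-zero offset active (growth-rate heterogeneity and measurement
    noise switched off), one as configured -- applies a conventional
    single-scan baseline dating estimator to every scan, and returns
    ``Var(error | time-zero only) / Var(error | everything on)``.

    The error is the discrepancy between the chart-style estimate and the
    pregnancy's LMP-based (nominal) age: conventional dating is calibrated
    against the LMP clock, so its total error decomposes into the time-zero
    offset of that clock plus growth-rate scatter plus measurement noise.

    ``baseline`` maps a biometry table to GA days (any object with a
    ``predict_ga(df) -> ndarray`` method or a bare callable).  When omitted,
    a polynomial baseline is fitted to a separate cohort simulated at the
    same configuration.
    """
    if baseline is None:
        from .validation import fit_baseline_polynomial

        fit_seed = int(np.random.SeedSequence([config.seed, 0xBA5E]).generate_state(1)[0]
                       % (2**31))
        fit_cohort = simulate_cohort(config.replace(seed=fit_seed))
        baseline = fit_baseline_polynomial(fit_cohort.to_dataframe())
    predict = baseline.predict_ga if hasattr(baseline, "predict_ga") else baseline

    def errors(cfg: SimulationConfig) -> np.ndarray:
        df = simulate_cohort(cfg).to_dataframe()
        return np.asarray(predict(df), dtype=float) - df["nominal_ga_days"].to_numpy()

    err_off = errors(config.replace(sigma_rho=0.0, cv_noise=0.0))
    err_on = errors(config)
    var_on = float(np.var(err_on))
    if var_on < 1e-12:
        raise UndefinedFractionError("total error variance is zero; fraction undefined")
    return float(np.var(err_off)) / var_on


__all__ = [
    "simulate_cohort_with_latents",
    "SimulationConfig",
    "simulate_cohort",
    "variance_decomposition",
    "TAU_CLIP_DAYS",
    "RHO_BOUNDS",
]
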