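"""Dual-Kinetics Ratkowsky thermal performance curves.

The square-root (Ratkowsky) model describes microbial process rates as
linear in temperature on the sqrt scale above a low intercept Tmin.  The
Dual-Kinetics (DK) extension multiplies that line by an exponential
deviation term,

    growth:       sqrt(G) = a * (T - Tmin) * (1 - exp(b * (T - Tmax)))
    respiration:  sqrt(R) = a * (T - Tmin) * (1 + exp(b * (T - Tmax)))

so that growth declines to zero at a high intercept Tmax while
respiration accelerates around a tipping point.  Calibration is two-stage:
(1) ordinary least squares of sqrt(rate) on T over the low temperature
range (default 0-25 degC), where the exponential term is negligible,
yielding the slope ``a`` and ``t_min = -intercept/slope``; (2) nonlinear
least squares over the full screening range with ``a`` and ``t_min`` held
fixed, yielding ``b`` and ``t_max``.  Derived indices: the optimum Topt
(growth) / tipping point Ttp (respiration) from the zero of the curve's
derivative, and Q10 over 10-20 degC from the square-root line.

All fitting and goodness-of-fit statistics operate on the sqrt(rate)
scale, where the model is formulated and residuals are closest to
homoscedastic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import (
    AssayTooSparseError,
    DegenerateFitError,
    FitFailureError,
    IngestionError,
    NoOptimumError,
    UndefinedQ10Error,
)

__all__ = [
    "Process",
    "RateObservation",
    "ThermalAssay",
    "ThermalTraits",
    "fit_low_range",
    "fit_full",
    "fit_assay",
    "evaluate_sqrt_rate",
    "evaluate_rate",
    "derive_critical_temperature",
    "compute_q10",
    "solve_b_from_tcrit",
    "read_assays_csv",
    "traits_to_frame",
]

#: screening temperatures used throughout: 0-45 degC in 5 degC steps
SCREENING_TEMPERATURES = tuple(float(t) for t in range(0, 50, 5))

DEFAULT_LOW_RANGE = (0.0, 25.0)
DEFAULT_Q10_INTERVAL = (10.0, 20.0)

# stage-2 search box; hits on the t_max bound are flagged, not hidden
B_BOUNDS = (1e-3, 2.0)
B_START = 0.2
T_MAX_UPPER = 80.0


class Process(str, Enum):
    """Microbial process measured in the temperature-screening assay."""

    BACTERIAL_GROWTH = "bacterial_growth"
    FUNGAL_GROWTH = "fungal_growth"
    RESPIRATION = "respiration"

    @property
    def is_growth(self) -> bool:
        return self is not Process.RESPIRATION


@dataclass(frozen=True)
class RateObservation:
    """One measured rate at one screening temperature.

    Rates are in ug C per g dry soil per hour.  Negative readings
    (instrument noise near zero) must be truncated before construction;
    :func:`read_assays_csv` does this and counts the truncations.
    """

    soil_id: str
    process: Process
    temperature_c: float
    rate: float
    replicate: int = 1

    def __post_init__(self):
        if self.rate < 0:
            raise IngestionError(
                f"negative rate {self.rate} for {self.soil_id}/{self.process.value}"
            )
        if not -10.0 <= self.temperature_c <= 60.0:
            raise IngestionError(
                f"temperature {self.temperature_c} degC outside [-10, 60]"
            )
        if self.replicate < 1:
            raise IngestionError("replicate index must be >= 1")


@dataclass(frozen=True)
class ThermalAssay:
    """All rate observations for one soil x process screening."""

    soil_id: str
    process: Process
    observations: tuple[RateObservation, ...]

    def __post_init__(self):
        for obs in self.observations:
            if obs.soil_id != self.soil_id or obs.process != self.process:
                raise IngestionError(
                    f"observation {obs} does not belong to assay "
                    f"{self.soil_id}/{self.process.value}"
                )
        temps = self.temperatures()
        if len(temps) < 5:
            raise AssayTooSparseError(
                f"{self.soil_id}/{self.process.value}: only {len(temps)} distinct "
                "temperatures; need >= 5"
            )
        low = [t for t in temps if DEFAULT_LOW_RANGE[0] <= t <= DEFAULT_LOW_RANGE[1]]
        if len(low) < 3:
            raise AssayTooSparseError(
                f"{self.soil_id}/{self.process.value}: only {len(low)} distinct "
                "temperatures in the low range [0, 25]; need >= 3"
            )

    def temperatures(self) -> tuple[float, ...]:
        return tuple(sorted({o.temperature_c for o in self.observations}))

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(temperature, rate) arrays, one entry per observation."""
        t = np.array([o.temperature_c for o in self.observations], dtype=float)
        r = np.array([o.rate for o in self.observations], dtype=float)
        return t, r


@dataclass(frozen=True)
class ThermalTraits:
    """Fitted DK-Ratkowsky parameters plus derived thermal indices.

    ``t_crit`` is Topt for growth processes and Ttp for respiration.
    ``a`` has units (ug C g^-1 h^-1)^(1/2) per degC, ``b`` is per degC.
    """

    soil_id: str
    process: Process
    a: float
    b: float
    t_min: float
    t_max: float
    t_crit: float | None = None
    q10: float | None = None
    r2: float | None = None
    low_range: tuple[float, float] = DEFAULT_LOW_RANGE
    t_max_at_bound: bool = False
    diagnostics: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.a <= 0:
            raise DegenerateFitError(
                f"{self.soil_id}/{self.process.value}: slope a={self.a} must be > 0"
            )
        if self.b <= 0:
            raise DegenerateFitError(
                f"{self.soil_id}/{self.process.value}: shape b={self.b} must be > 0"
            )
        if self.t_min >= self.t_max:
            raise DegenerateFitError(
                f"{self.soil_id}/{self.process.value}: t_min {self.t_min} >= "
                f"t_max {self.t_max}"
            )
        if self.t_crit is not None:
            if not self.t_min < self.t_crit:
                raise DegenerateFitError(
                    f"{self.soil_id}/{self.process.value}: t_crit {self.t_crit} "
                    f"must exceed t_min {self.t_min}"
                )
            if self.process.is_growth and not self.t_crit < self.t_max:
                raise DegenerateFitError(
                    f"{self.soil_id}/{self.process.value}: growth t_crit "
                    f"{self.t_crit} must lie below t_max {self.t_max}"
                )


def _sqrt_model(t, a, t_min, b, t_max, is_growth):
    """Unclamped sqrt-scale DK model (may be negative outside support)."""
    t = np.asarray(t, dtype=float)
    sign = -1.0 if is_growth else 1.0
    return a * (t - t_min) * (1.0 + sign * np.exp(b * (t - t_max)))


def evaluate_sqrt_rate(traits: ThermalTraits, temperature_c) -> np.ndarray | float:
    """Sqrt-scale model value, clamped at zero where the expression is negative."""
    v = _sqrt_model(
        temperature_c, traits.a, traits.t_min, traits.b, traits.t_max,
        traits.process.is_growth,
    )
    return np.maximum(v, 0.0) if np.ndim(v) else max(float(v), 0.0)


def evaluate_rate(traits: ThermalTraits, temperature_c) -> np.ndarray | float:
    """Process rate (ug C g^-1 h^-1) at a temperature.

    Defined as max(sqrt-model, 0)^2: zero below t_min and, for growth,
    above t_max.  Total over all real temperatures.
    """
    v = evaluate_sqrt_rate(traits, temperature_c)
    return v * v


def fit_low_range(
    assay: ThermalAssay,
    low_range: tuple[float, float] = DEFAULT_LOW_RANGE,
) -> tuple[float, float]:
    """Stage 1: OLS of sqrt(rate) on T over the low temperature range.

    Returns ``(a, t_min)`` with ``a`` the slope and ``t_min`` the x-axis
    intercept ``-intercept/slope``.  Replicates enter individually.
    """
    t, r = assay.arrays()
    mask = (t >= low_range[0]) & (t <= low_range[1])
    if len(np.unique(t[mask])) < 3:
        raise AssayTooSparseError(
            f"{assay.soil_id}/{assay.process.value}: fewer than 3 distinct "
            f"temperatures in low range {low_range}"
        )
    slope, intercept = np.polyfit(t[mask], np.sqrt(r[mask]), 1)
    if slope <= 0:
        raise DegenerateFitError(
            f"{assay.soil_id}/{assay.process.value}: non-positive low-range "
            f"slope {slope:.4g}"
        )
    return float(slope), float(-intercept / slope)


def fit_full(
    assay: ThermalAssay,
    a: float,
    t_min: float,
) -> tuple[float, float, float, bool]:
    """Stage 2: fit (b, t_max) over the full range with (a, t_min) fixed.

    Minimizes sum((sqrt(rate) - model)^2) on the sqrt scale.  Returns
    ``(b, t_max, r2, t_max_at_bound)``; r2 is computed on the sqrt scale
    over all observations.  ``t_max_at_bound`` flags solutions pinned at
    the upper search bound (no measurable high-temperature signal).
    """
    if a <= 0:
        raise DegenerateFitError(f"stage-2 requires a > 0, got {a}")
    t, r = assay.arrays()
    y = np.sqrt(r)
    is_growth = assay.process.is_growth
    t_obs_max = float(t.max())
    t_max_bounds = (t_obs_max - 5.0, T_MAX_UPPER)
    x0 = (B_START, t_obs_max + 5.0)

    def residuals(p):
        return _sqrt_model(t, a, t_min, p[0], p[1], is_growth) - y

    sol = optimize.least_squares(
        residuals,
        x0=x0,
        bounds=([B_BOUNDS[0], t_max_bounds[0]], [B_BOUNDS[1], t_max_bounds[1]]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    if not sol.success:
        raise FitFailureError(
            f"{assay.soil_id}/{assay.process.value}: stage-2 optimizer failed "
            f"({sol.message})",
            residual_norm=float(np.linalg.norm(sol.fun)),
        )
    b, t_max = float(sol.x[0]), float(sol.x[1])
    bound_tol = 1e-6 * (t_max_bounds[1] - t_max_bounds[0])
    at_bound = abs(t_max - t_max_bounds[1]) <= bound_tol
    # with no measurable high-temperature signal the deviation term is a
    # ridge (b -> lower bound is equivalent to t_max -> upper bound);
    # report t_max pinned at the search bound and flag it
    max_dev = float(np.exp(b * (t.max() - t_max)))
    if max_dev < 1e-4 or b <= B_BOUNDS[0] * (1 + 1e-9):
        at_bound = True
        t_max = t_max_bounds[1]

    ss_res = float(np.sum(sol.fun**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return b, t_max, r2, at_bound


def _dk_derivative_root_fn(t, t_min, b, t_max):
    """Zero of d(sqrt G)/dT: exp(b(T - t_max)) * (1 + b(T - t_min)) - 1."""
    return math.exp(b * (t - t_max)) * (1.0 + b * (t - t_min)) - 1.0


def derive_critical_temperature(traits: ThermalTraits) -> float:
    """Topt (growth) / Ttp (respiration) from the derivative condition.

    Solves exp(b(T - t_max)) * (1 + b(T - t_min)) = 1 on (t_min, t_max)
    by bracketed root search to 1e-8 degC.  For respiration, whose own DK
    curve is monotone, the same growth-form condition is applied to the
    fitted respiration parameters (a policy, overridable by supplying
    t_crit directly when constructing traits).
    """
    t_min, b, t_max = traits.t_min, traits.b, traits.t_max
    lo = t_min + 1e-9 * max(1.0, abs(t_min))
    hi = t_max - 1e-12 * max(1.0, abs(t_max))
    f_lo = _dk_derivative_root_fn(lo, t_min, b, t_max)
    f_hi = _dk_derivative_root_fn(hi, t_min, b, t_max)
    if f_lo * f_hi > 0:
        raise NoOptimumError(
            f"{traits.soil_id}/{traits.process.value}: derivative condition has "
            f"no sign change on ({lo:.3f}, {hi:.3f}) "
            f"(f(lo)={f_lo:.3g}, f(hi)={f_hi:.3g})"
        )
    root = optimize.brentq(
        _dk_derivative_root_fn, lo, hi, args=(t_min, b, t_max), xtol=1e-8
    )
    return float(root)


def solve_b_from_tcrit(t_min: float, t_crit: float, t_max: float) -> float:
    """Invert the derivative condition: b such that t_crit is the optimum.

    Requires t_min < t_crit < t_max and (t_crit - t_min) > (t_max - t_crit);
    otherwise no positive b satisfies the condition.
    """
    beta = t_crit - t_min
    gamma = t_max - t_crit
    if beta <= 0 or gamma <= 0:
        raise NoOptimumError(f"need t_min < t_crit < t_max, got {t_min}, {t_crit}, {t_max}")
    if beta <= gamma:
        raise NoOptimumError(
            f"no positive b places the optimum at {t_crit}: requires "
            f"(t_crit - t_min) > (t_max - t_crit), got {beta:.3g} <= {gamma:.3g}"
        )

    def f(b):
        return (1.0 + b * beta) * math.exp(-b * gamma) - 1.0

    # f(0)=0 with f'(0)=beta-gamma>0; f -> -1 as b -> inf: unique positive root
    hi = 1e-3
    while f(hi) > 0 and hi < 1e3:
        hi *= 2.0
    if f(hi) > 0:
        raise NoOptimumError("failed to bracket b")
    return float(optimize.brentq(f, 1e-12, hi, xtol=1e-12))


def compute_q10(
    traits: ThermalTraits,
    interval: tuple[float, float] = DEFAULT_Q10_INTERVAL,
) -> float:
    """Temperature sensitivity over ``interval`` from the square-root line.

    Q10 = ((hi - t_min) / (lo - t_min))^2, the rate-scale ratio of the
    sqrt-linear model (default interval 10-20 degC).
    """
    lo, hi = interval
    if traits.t_min >= lo:
        raise UndefinedQ10Error(
            f"{traits.soil_id}/{traits.process.value}: t_min {traits.t_min} >= "
            f"interval lower bound {lo}"
        )
    return float(((hi - traits.t_min) / (lo - traits.t_min)) ** 2)


def fit_assay(
    assay: ThermalAssay,
    low_range: tuple[float, float] = DEFAULT_LOW_RANGE,
    q10_interval: tuple[float, float] = DEFAULT_Q10_INTERVAL,
) -> ThermalTraits:
    """Run the full two-stage calibration and derive all trait indices."""
    a, t_min = fit_low_range(assay, low_range)
    b, t_max, r2, at_bound = fit_full(assay, a, t_min)
    diagnostics = {}
    t_obs_max = max(assay.temperatures())
    if t_max <= t_obs_max - 20.0:
        diagnostics["implausible_t_max"] = (
            f"t_max {t_max:.2f} far below max screening temperature {t_obs_max:.1f}"
        )
    base = ThermalTraits(
        soil_id=assay.soil_id,
        process=assay.process,
        a=a, b=b, t_min=t_min, t_max=t_max,
        r2=r2, low_range=low_range, t_max_at_bound=at_bound,
        diagnostics=diagnostics,
    )
    t_crit = derive_critical_temperature(base)
    q10 = compute_q10(base, q10_interval)
    return replace(base, t_crit=t_crit, q10=q10)


# ---------------------------------------------------------------------------
# I/O

ASSAY_COLUMNS = ["soil_id", "process", "temperature_c", "replicate", "rate"]


def read_assays_csv(path) -> tuple[list[ThermalAssay], int]:
    """Read screening assays from CSV (soil_id, process, temperature_c,
    replicate, rate); returns the assays and the count of negative rates
    truncated to zero at ingestion."""
    df = pd.read_csv(path)
    missing = set(ASSAY_COLUMNS) - set(df.columns)
    if missing:
        raise IngestionError(f"{path}: missing columns {sorted(missing)}")
    n_truncated = int((df["rate"] < 0).sum())
    df["rate"] = df["rate"].clip(lower=0.0)
    assays = []
    for (soil_id, proc), grp in df.groupby(["soil_id", "process"], sort=True):
        obs = tuple(
            RateObservation(
                soil_id=str(soil_id),
                process=Process(proc),
                temperature_c=float(row.temperature_c),
                rate=float(row.rate),
                replicate=int(row.replicate),
            )
            for row in grp.itertuples()
        )
        assays.append(ThermalAssay(str(soil_id), Process(proc), obs))
    return assays, n_truncated


def traits_to_frame(traits: Iterable[ThermalTraits]) -> pd.DataFrame:
    """Tabulate fitted traits (one row per soil x process)."""
    rows = []
    for tr in traits:
        rows.append(
            {
                "soil_id": tr.soil_id,
                "process": tr.process.value,
                "a": tr.a,
                "b": tr.b,
                "t_min": tr.t_min,
                "t_max": tr.t_max,
                "t_crit": tr.t_crit,
                "q10": tr.q10,
                "r2": tr.r2,
                "low_range_lo": tr.low_range[0],
                "low_range_hi": tr.low_range[1],
                "t_max_at_bound": tr.t_max_at_bound,
            }
        )
    return pd.DataFrame(rows)
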