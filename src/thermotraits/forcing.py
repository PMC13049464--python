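"""Field forcing: sparse plot measurements -> hourly temperature/moisture.

Field campaigns record soil temperature (5 cm depth) and moisture (% of
pore-volume saturation) twice a week, in the early afternoon.  Upscaling
lab temperature relationships to annual budgets needs hourly forcing, so
this module:

1. inverts each afternoon reading through a symmetric diurnal sinusoid to
   a daily mean (the reading is taken near the daily maximum, not at the
   mean), with the daily temperature range modeled as a linear function
   of the daily mean, range = alpha + beta * mean;
2. linearly interpolates daily means across gaps between measurement
   days, and expands every day to 24 hourly values;
3. interpolates moisture at daily resolution (held constant within a
   day — soil moisture varies far more slowly than temperature);
4. classifies dates into the dry/wet season calendar;
5. applies the DAYCENT moisture rate modifier omega(W) in [0, 1];
6. summarizes plot climate (soil MAT, maximum soil temperature, seasonal
   statistics).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ConfigError, CoverageError, IngestionError, UncoveredDateError

__all__ = [
    "LandUse",
    "Treatment",
    "Season",
    "FieldRecord",
    "DiurnalModelParams",
    "MoistureFunctionParams",
    "SeasonWindows",
    "ForcingHourly",
    "PlotClimateSummary",
    "classify_season",
    "derive_daily_means",
    "expand_diurnal",
    "moisture_modifier",
    "build_hourly_forcing",
    "summarize_plot_climate",
    "read_field_csv",
    "field_records_to_frame",
]


class LandUse(str, Enum):
    CROP = "crop"
    FOREST = "forest"


class Treatment(str, Enum):
    CONTROL = "control"
    OTC = "otc"           # open-top chamber, passive warming
    SHELTER = "shelter"   # rain-exclusion roof, drought


class Season(str, Enum):
    DRY = "dry"
    WET = "wet"


@dataclass(frozen=True)
class FieldRecord:
    """One dated plot-level temperature/moisture measurement."""

    date: dt.date
    plot_id: str
    land_use: LandUse
    treatment: Treatment
    block: str
    soil_temp_c: float
    moisture_pct_sat: float

    def __post_init__(self):
        if not 0.0 <= self.moisture_pct_sat <= 100.0:
            raise IngestionError(
                f"{self.plot_id} {self.date}: moisture {self.moisture_pct_sat} "
                "% outside [0, 100]"
            )
        if not -10.0 <= self.soil_temp_c <= 70.0:
            raise IngestionError(
                f"{self.plot_id} {self.date}: temperature {self.soil_temp_c} "
                "degC outside [-10, 70]"
            )


@dataclass(frozen=True)
class DiurnalModelParams:
    """Symmetric diurnal sinusoid with mean-dependent amplitude.

    range(mean) = max(0, alpha + beta * mean); the maximum is attained at
    ``peak_hour`` and field readings are taken at ``measurement_hour``
    (2-4 pm window -> default 15:00, near the 14:00 peak).
    """

    alpha: float = 8.0      # degC, range intercept
    beta: float = 0.2       # dimensionless, range slope vs daily mean
    peak_hour: float = 14.0
    measurement_hour: float = 15.0


@dataclass(frozen=True)
class MoistureFunctionParams:
    """DAYCENT moisture rate-modifier constants (fine-textured soils).

    omega(s) = ((s - c2)/(c1 - c2))^(c4(c2-c1)/(c1-c3)) *
               ((s - c3)/(c1 - c3))^c4

    with s the relative saturation.  Field moisture recorded as % of
    pore-volume saturation maps directly to s = W/100 (``input="saturation"``,
    the default); volumetric water content maps via porosity,
    s = W/(100*phi) (``input="volumetric"``).
    """

    porosity_phi: float = 0.5
    c1: float = 0.6
    c2: float = 1.27
    c3: float = 0.0012
    c4: float = 2.84
    input: str = "saturation"  # or "volumetric"

    def __post_init__(self):
        if not (self.c3 < self.c1 < self.c2):
            raise ConfigError(
                f"moisture constants must satisfy c3 < c1 < c2, got "
                f"c3={self.c3}, c1={self.c1}, c2={self.c2}"
            )
        if self.c4 <= 0:
            raise ConfigError(f"c4 must be > 0, got {self.c4}")
        if not 0.0 < self.porosity_phi < 1.0:
            raise ConfigError(f"porosity {self.porosity_phi} outside (0, 1)")
        if self.input not in ("saturation", "volumetric"):
            raise ConfigError(f"unknown moisture input kind {self.input!r}")


# season calendar of the monomodal-rainfall study year (sampling at the
# end of the second dry spell); endpoints inclusive
DEFAULT_DRY_WINDOWS = (
    (dt.date(2018, 2, 8), dt.date(2018, 5, 26)),
    (dt.date(2019, 1, 21), dt.date(2019, 2, 10)),
)
DEFAULT_WET_WINDOW = (dt.date(2018, 5, 27), dt.date(2019, 1, 20))

#: modeled year: 365 days ending just before soil sampling
DEFAULT_YEAR_START = dt.date(2018, 2, 8)
DEFAULT_YEAR_DAYS = 365


@dataclass(frozen=True)
class SeasonWindows:
    """Dry/wet season calendar as inclusive date intervals."""

    dry_windows: tuple[tuple[dt.date, dt.date], ...] = DEFAULT_DRY_WINDOWS
    wet_window: tuple[dt.date, dt.date] = DEFAULT_WET_WINDOW

    def all_windows(self) -> list[tuple[dt.date, dt.date, Season]]:
        wins = [(a, b, Season.DRY) for a, b in self.dry_windows]
        wins.append((*self.wet_window, Season.WET))
        return sorted(wins)

    def validate_partition(self, start: dt.date, n_days: int) -> None:
        """Check the windows jointly cover [start, start+n_days) w/o overlap."""
        wins = self.all_windows()
        for (a1, b1, _), (a2, b2, _) in zip(wins, wins[1:]):
            if a2 <= b1:
                raise ConfigError(f"season windows overlap: {(a1, b1)} and {(a2, b2)}")
        missing = [
            d for d in (start + dt.timedelta(days=i) for i in range(n_days))
            if not any(a <= d <= b for a, b, _ in wins)
        ]
        if missing:
            raise ConfigError(
                f"season windows leave {len(missing)} modeled days uncovered "
                f"(first: {missing[0]})"
            )


def classify_season(date: dt.date, windows: SeasonWindows | None = None) -> Season:
    """Dry/wet membership of a date; window endpoints are inclusive."""
    windows = windows or SeasonWindows()
    for a, b, season in windows.all_windows():
        if a <= date <= b:
            return season
    raise UncoveredDateError(f"{date} outside all season windows")


# ---------------------------------------------------------------------------
# diurnal model

def _phase(hour: float, peak_hour: float) -> float:
    """cos term of the sinusoid: 1 at peak_hour, -1 twelve hours away."""
    return math.cos(2.0 * math.pi * (hour - peak_hour) / 24.0)


def expand_diurnal(daily_mean: float, params: DiurnalModelParams) -> np.ndarray:
    """24 hourly temperatures for one day.

    T(h) = mean + (range/2) * cos(2*pi*(h - peak_hour)/24) with
    range = max(0, alpha + beta*mean); the arithmetic mean of the 24
    values equals ``daily_mean`` exactly and the maximum sits at
    ``peak_hour``.
    """
    rng = max(0.0, params.alpha + params.beta * daily_mean)
    hours = np.arange(24.0)
    return daily_mean + 0.5 * rng * np.cos(
        2.0 * np.pi * (hours - params.peak_hour) / 24.0
    )


def invert_afternoon_reading(observed: float, params: DiurnalModelParams) -> float:
    """Solve mean + (range(mean)/2)*phase(measurement_hour) = observed.

    The reading near the daily peak overstates the daily mean; this
    inverts the sinusoid for the mean by bracketed root search.
    """
    phase = _phase(params.measurement_hour, params.peak_hour)

    def f(mean):
        rng = max(0.0, params.alpha + params.beta * mean)
        return mean + 0.5 * rng * phase - observed

    lo, hi = observed - 60.0, observed + 60.0
    if f(lo) * f(hi) > 0:
        raise ConfigError(
            f"diurnal inversion not solvable for observed={observed} with "
            f"alpha={params.alpha}, beta={params.beta} (beta pathological?)"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def derive_daily_means(
    records: Sequence[FieldRecord],
    params: DiurnalModelParams,
    year_start: dt.date = DEFAULT_YEAR_START,
    n_days: int = DEFAULT_YEAR_DAYS,
) -> pd.DataFrame:
    """Daily mean temperature and daily moisture for one plot-year.

    Each afternoon reading is inverted through the sinusoid to a daily
    mean; gaps between measurement days are filled by linear
    interpolation (values held at the nearest measurement beyond the
    first/last measurement day).  Returns a frame indexed by date with
    columns ``temp_mean``, ``moisture_pct_sat``, ``measured`` (bool).
    """
    if len({r.plot_id for r in records}) != 1:
        raise IngestionError("derive_daily_means expects records from exactly one plot")
    recs = sorted(records, key=lambda r: r.date)
    if len({r.date for r in recs}) < 2:
        raise IngestionError("need measurements on at least 2 distinct dates")

    meas_dates = np.array([(r.date - year_start).days for r in recs], dtype=float)
    means = np.array([invert_afternoon_reading(r.soil_temp_c, params) for r in recs])
    moist = np.array([r.moisture_pct_sat for r in recs], dtype=float)

    days = np.arange(n_days, dtype=float)
    temp_mean = np.interp(days, meas_dates, means)
    moisture = np.interp(days, meas_dates, moist)
    measured = np.isin(days, meas_dates)
    index = pd.to_datetime([year_start + dt.timedelta(days=int(d)) for d in days])
    return pd.DataFrame(
        {"temp_mean": temp_mean, "moisture_pct_sat": moisture, "measured": measured},
        index=index,
    )


# ---------------------------------------------------------------------------
# moisture rate modifier

def moisture_modifier(
    moisture_pct: np.ndarray | float,
    params: MoistureFunctionParams | None = None,
) -> np.ndarray | float:
    """DAYCENT moisture rate modifier, clamped to [0, 1].

    ``moisture_pct`` is % pore-volume saturation by default (s = W/100);
    with ``params.input == "volumetric"`` it is volumetric water content
    in %, mapped through porosity (s = W/(100*phi)).  omega = 0 for
    s <= c3 and omega = 1 at s = c1 by construction.
    """
    p = params or MoistureFunctionParams()
    w = np.asarray(moisture_pct, dtype=float)
    scalar = w.ndim == 0
    w = np.atleast_1d(w)
    s = w / 100.0 if p.input == "saturation" else w / (100.0 * p.porosity_phi)

    omega = np.zeros_like(s)
    ok = s > p.c3
    exp1 = p.c4 * (p.c2 - p.c1) / (p.c1 - p.c3)
    f1 = ((s[ok] - p.c2) / (p.c1 - p.c2)) ** exp1
    f2 = ((s[ok] - p.c3) / (p.c1 - p.c3)) ** p.c4
    omega[ok] = f1 * f2
    omega = np.clip(omega, 0.0, 1.0)
    return float(omega[0]) if scalar else omega


# ---------------------------------------------------------------------------
# hourly forcing

@dataclass(frozen=True)
class ForcingHourly:
    """Gap-filled hourly forcing for one plot-year.

    ``frame`` is indexed by hourly timestamps and carries ``temp_c``,
    ``moisture_pct_sat`` and a boolean ``measured_day`` provenance flag.
    """

    plot_id: str
    frame: pd.DataFrame = field(compare=False)

    def __post_init__(self):
        n = len(self.frame)
        if n == 0 or n % 24 != 0:
            raise CoverageError(
                f"{self.plot_id}: forcing has {n} hours, not a whole number of days"
            )
        m = self.frame["moisture_pct_sat"]
        if (m < 0).any() or (m > 100).any():
            raise CoverageError(f"{self.plot_id}: moisture outside [0, 100]")

    @property
    def n_days(self) -> int:
        return len(self.frame) // 24

    def daily_means(self) -> pd.Series:
        return self.frame["temp_c"].groupby(self.frame.index.floor("D")).mean()


def build_hourly_forcing(
    records: Sequence[FieldRecord],
    params: DiurnalModelParams | None = None,
    year_start: dt.date = DEFAULT_YEAR_START,
    n_days: int = DEFAULT_YEAR_DAYS,
) -> ForcingHourly:
    """Full plot-year hourly forcing from sparse field records."""
    params = params or DiurnalModelParams()
    daily = derive_daily_means(records, params, year_start, n_days)
    plot_id = records[0].plot_id

    temps = np.concatenate([expand_diurnal(m, params) for m in daily["temp_mean"]])
    moisture = np.repeat(daily["moisture_pct_sat"].to_numpy(), 24)
    measured = np.repeat(daily["measured"].to_numpy(), 24)
    index = pd.date_range(
        start=pd.Timestamp(year_start), periods=n_days * 24, freq="h"
    )
    frame = pd.DataFrame(
        {"temp_c": temps, "moisture_pct_sat": moisture, "measured_day": measured},
        index=index,
    )
    return ForcingHourly(plot_id=plot_id, frame=frame)


# ---------------------------------------------------------------------------
# climate summary

@dataclass(frozen=True)
class PlotClimateSummary:
    plot_id: str
    soil_mat_c: float       # mean of modeled daily means over the year
    soil_maxt_c: float      # maximum modeled hourly temperature
    season_stats: dict      # season -> {temp_mean, temp_sd, moist_mean, moist_sd}


def summarize_plot_climate(
    forcing: ForcingHourly,
    windows: SeasonWindows | None = None,
    expected_days: int = DEFAULT_YEAR_DAYS,
) -> PlotClimateSummary:
    """Soil MAT, maximum soil temperature and per-season statistics."""
    windows = windows or SeasonWindows()
    if forcing.n_days < expected_days:
        start = forcing.frame.index[0].date()
        have = {ts.date() for ts in forcing.frame.index.floor("D").unique()}
        missing = [
            start + dt.timedelta(days=i)
            for i in range(expected_days)
            if start + dt.timedelta(days=i) not in have
        ]
        raise CoverageError(
            f"{forcing.plot_id}: incomplete year, missing {len(missing)} days "
            f"(first: {missing[0] if missing else '?'})"
        )
    daily_t = forcing.daily_means()
    daily_m = forcing.frame["moisture_pct_sat"].groupby(
        forcing.frame.index.floor("D")
    ).mean()
    soil_mat = float(daily_t.mean())
    soil_maxt = float(forcing.frame["temp_c"].max())

    seasons = pd.Series(
        [classify_season(ts.date(), windows).value for ts in daily_t.index],
        index=daily_t.index,
    )
    stats = {}
    for season in (Season.DRY, Season.WET):
        mask = seasons == season.value
        stats[season.value] = {
            "temp_mean": float(daily_t[mask].mean()),
            "temp_sd": float(daily_t[mask].std(ddof=1)),
            "moist_mean": float(daily_m[mask].mean()),
            "moist_sd": float(daily_m[mask].std(ddof=1)),
        }
    return PlotClimateSummary(
        plot_id=forcing.plot_id,
        soil_mat_c=soil_mat,
        soil_maxt_c=soil_maxt,
        season_stats=stats,
    )


# ---------------------------------------------------------------------------
# I/O

FIELD_COLUMNS = [
    "date", "plot_id", "land_use", "treatment", "block",
    "soil_temp_c", "moisture_pct_sat",
]


def read_field_csv(path) -> list[FieldRecord]:
    """Read field records from CSV (ISO-8601 dates)."""
    df = pd.read_csv(path)
    missing = set(FIELD_COLUMNS) - set(df.columns)
    if missing:
        raise IngestionError(f"{path}: missing columns {sorted(missing)}")
    return [
        FieldRecord(
            date=dt.date.fromisoformat(str(row.date)),
            plot_id=str(row.plot_id),
            land_use=LandUse(row.land_use),
            treatment=Treatment(row.treatment),
            block=str(row.block),
            soil_temp_c=float(row.soil_temp_c),
            moisture_pct_sat=float(row.moisture_pct_sat),
        )
        for row in df.itertuples()
    ]


def field_records_to_frame(records: Iterable[FieldRecord]) -> pd.DataFrame:
    records = list(records)
    return pd.DataFrame(
        {
            "date": [r.date.isoformat() for r in records],
            "plot_id": [r.plot_id for r in records],
            "land_use": [r.land_use.value for r in records],
            "treatment": [r.treatment.value for r in records],
            "block": [r.block for r in records],
            "soil_temp_c": [r.soil_temp_c for r in records],
            "moisture_pct_sat": [r.moisture_pct_sat for r in records],
        }
    )
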