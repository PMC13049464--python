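"""Synthetic assay and field data with the structure the analysis assumes.

The generator emulates a two-land-use (cropland, forest) climate
manipulation experiment: three treatments (control, open-top-chamber
warming, rain shelter) x three blocks per land use.  Its defaults encode
the study conditions:

* thermal trait priors anchored to the observed index ranges — bacterial
  Topt 33-38 degC and Tmax 47-49 degC, fungal Topt 36-40 and Tmax 47-50,
  respiration tipping point 32-40 degC — with Tmin either drawn from a
  land-use-dependent range (warmer land use -> higher Tmin) or linked
  linearly to the plot's modeled mean annual soil temperature;
* temperature-screening assays at the ten temperatures 0-45 degC in
  5 degC steps, technical duplicates, multiplicative Gaussian noise on
  the sqrt(rate) scale (default CV 5 %);
* twice-weekly field series over the monomodal-rainfall season calendar,
  per-season means/SDs of afternoon soil temperature and moisture
  (cropland dry/wet 41.8 +/- 5.2 / 26.7 +/- 5.1 degC, forest 29.8 +/- 3.7 /
  21.9 +/- 3.4 degC; moisture 6.1 +/- 4.3 / 30.5 +/- 12.7 % vs
  10.5 +/- 3.8 / 37.2 +/- 14.0 %), OTC warming of the cropland dry season
  by +3.9 degC, shelter drying of the forest wet season to 30.4 %
  saturation, and AR(1) temporal correlation (rho = 0.5) so interpolation
  is exercised on serially dependent records.

All randomness flows through explicit integer seeds; per-plot streams mix
the seed with a CRC32 of the plot label so plots differ under one seed
but are individually reproducible.
"""

from __future__ import annotations

import datetime as dt
import math
import zlib
from dataclasses import dataclass, field as dc_field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .forcing import (
    DEFAULT_YEAR_DAYS,
    DEFAULT_YEAR_START,
    DiurnalModelParams,
    FieldRecord,
    LandUse,
    Season,
    SeasonWindows,
    Treatment,
    classify_season,
    derive_daily_means,
)
from .ratkowsky import (
    SCREENING_TEMPERATURES,
    Process,
    RateObservation,
    ThermalAssay,
    ThermalTraits,
    compute_q10,
    evaluate_sqrt_rate,
    solve_b_from_tcrit,
)

__all__ = [
    "SyntheticScenarioConfig",
    "SyntheticWorld",
    "sample_true_traits",
    "simulate_assay",
    "simulate_field_year",
    "generate_world",
]


# trait priors per process: critical-temperature and Tmax ranges from the
# observed index distributions; Tmin ranges per land use (cropland runs
# ~2-7 degC warmer, and communities there carry higher Tmin)
DEFAULT_TRAIT_PRIORS: dict[str, dict] = {
    Process.BACTERIAL_GROWTH.value: {
        "t_crit_range": (33.0, 38.0),
        "t_max_range": (47.0, 49.0),
        "t_min_range": {"crop": (-1.5, 1.5), "forest": (-4.5, -1.5)},
        "t_min_ref": -1.5,       # Tmin at the reference MAT (mat-linked mode)
        "t_min_mat_slope": 0.25,  # degC Tmin per degC soil MAT
        "t_min_sd": 0.6,
        "rate_scale": {"crop": 0.20, "forest": 0.25},  # ug C g-1 h-1 at Topt
    },
    Process.FUNGAL_GROWTH.value: {
        "t_crit_range": (36.0, 40.0),
        "t_max_range": (47.0, 50.0),
        "t_min_range": {"crop": (-1.5, 1.5), "forest": (-4.5, -1.5)},
        "t_min_ref": -1.5,
        "t_min_mat_slope": 0.25,
        "t_min_sd": 0.6,
        "rate_scale": {"crop": 0.14, "forest": 0.18},
    },
    Process.RESPIRATION.value: {
        "t_crit_range": (32.0, 40.0),
        "t_max_range": (48.0, 55.0),
        "t_min_range": {"crop": (-6.5, -4.0), "forest": (-5.0, -2.5)},
        "t_min_ref": -5.0,
        "t_min_mat_slope": 0.0,  # no Tmin-MAT relationship for respiration
        "t_min_sd": 0.6,
        "rate_scale": {"crop": 1.2, "forest": 1.8},
    },
}

#: reference MAT (degC) at which mat-linked Tmin equals t_min_ref
DEFAULT_MAT_REF = 22.0

# per-season afternoon-measurement climates and treatment effects
DEFAULT_FIELD_EFFECTS: dict[str, dict] = {
    "crop": {
        "dry": {"temp_mean": 41.8, "temp_sd": 5.2, "moist_mean": 6.1, "moist_sd": 4.3},
        "wet": {"temp_mean": 26.7, "temp_sd": 5.1, "moist_mean": 30.5, "moist_sd": 12.7},
        "offsets": {
            "otc": {"temp": {"dry": 3.9, "wet": 1.0}},
            "shelter": {"temp": {"dry": -1.2}, "moist_mean": {"wet": 28.0}},
        },
    },
    "forest": {
        "dry": {"temp_mean": 29.8, "temp_sd": 3.7, "moist_mean": 10.5, "moist_sd": 3.8},
        "wet": {"temp_mean": 21.9, "temp_sd": 3.4, "moist_mean": 37.2, "moist_sd": 14.0},
        "offsets": {
            "otc": {"temp": {"dry": 2.0, "wet": 0.8}},
            "shelter": {"moist_mean": {"wet": 30.4}},
        },
    },
}


@dataclass(frozen=True)
class SyntheticScenarioConfig:
    """Generator settings for one land-use x treatment scenario."""

    land_use: LandUse = LandUse.CROP
    treatment: Treatment = Treatment.CONTROL
    n_blocks: int = 3
    seed: int = 0
    assay_noise_cv: float = 0.05
    ar1_rho: float = 0.5
    trait_priors: Mapping[str, dict] = dc_field(
        default_factory=lambda: DEFAULT_TRAIT_PRIORS
    )
    field_effects: Mapping[str, dict] = dc_field(
        default_factory=lambda: DEFAULT_FIELD_EFFECTS
    )
    mat_ref: float = DEFAULT_MAT_REF
    season_windows: SeasonWindows = dc_field(default_factory=SeasonWindows)
    year_start: dt.date = DEFAULT_YEAR_START
    n_days: int = DEFAULT_YEAR_DAYS

    def __post_init__(self):
        if self.assay_noise_cv < 0:
            raise ConfigError("assay_noise_cv must be >= 0")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ConfigError("ar1_rho must be in [0, 1)")
        for proc, prior in self.trait_priors.items():
            lo_c, hi_c = prior["t_crit_range"]
            lo_x, hi_x = prior["t_max_range"]
            for lu, (lo_n, hi_n) in prior["t_min_range"].items():
                if not (hi_n < lo_c and lo_c <= hi_c and lo_x <= hi_x):
                    raise ConfigError(
                        f"{proc}/{lu}: trait ranges must be ordered "
                        "t_min < t_crit and within-range lo <= hi"
                    )
        self.season_windows.validate_partition(self.year_start, self.n_days)


def _plot_rng(seed: int, label: str, salt: int = 0) -> np.random.Generator:
    """Deterministic per-plot stream: seed mixed with a CRC32 of the label."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode()), salt])
    )


def sample_true_traits(
    config: SyntheticScenarioConfig,
    process: Process,
    seed: int,
    soil_mat_c: float | None = None,
    plot_label: str = "",
) -> ThermalTraits:
    """Draw a ground-truth trait set from the configured priors.

    t_crit and t_max are uniform within the process's observed range.
    Tmin comes from the land-use range, or — when ``soil_mat_c`` is given
    — from the linear Tmin-vs-MAT model
    ``t_min_ref + slope * (MAT - mat_ref) + noise``, which builds the
    trait-adaptation gradient into the world.  ``b`` is then solved from
    the derivative condition so t_crit is exactly the curve's optimum,
    and ``a`` is set so the curve's rate at t_crit matches the configured
    process rate scale.
    """
    prior = config.trait_priors[process.value]
    rng = _plot_rng(seed, f"{plot_label}|{process.value}", salt=1)
    t_crit = float(rng.uniform(*prior["t_crit_range"]))
    t_max = float(rng.uniform(*prior["t_max_range"]))
    if soil_mat_c is None:
        t_min = float(rng.uniform(*prior["t_min_range"][config.land_use.value]))
    else:
        t_min = float(
            prior["t_min_ref"]
            + prior["t_min_mat_slope"] * (soil_mat_c - config.mat_ref)
            + rng.normal(0.0, prior["t_min_sd"])
        )
    if not t_min < t_crit < t_max:
        raise ConfigError(
            f"{process.value}: sampled traits not ordered "
            f"({t_min=}, {t_crit=}, {t_max=})"
        )
    b = solve_b_from_tcrit(t_min, t_crit, t_max)
    gamma = t_max - t_crit
    sign = -1.0 if process.is_growth else 1.0
    sqrt_ref = (t_crit - t_min) * (1.0 + sign * math.exp(-b * gamma))
    rate_scale = prior["rate_scale"][config.land_use.value]
    a = math.sqrt(rate_scale) / sqrt_ref
    traits = ThermalTraits(
        soil_id=plot_label or "synthetic",
        process=process,
        a=a, b=b, t_min=t_min, t_max=t_max, t_crit=t_crit,
    )
    return replace(traits, q10=compute_q10(traits))


def simulate_assay(
    traits: ThermalTraits,
    n_replicates: int = 2,
    noise_cv: float = 0.05,
    seed: int = 0,
    temperatures: Sequence[float] = SCREENING_TEMPERATURES,
) -> ThermalAssay:
    """Screening assay from a known trait set.

    Rates at each screening temperature follow the DK model with
    multiplicative Gaussian noise on the sqrt(rate) scale
    (sqrt_noisy = sqrt_model * (1 + cv * z)), truncated at zero.
    """
    if noise_cv < 0:
        raise ConfigError("noise_cv must be >= 0")
    rng = _plot_rng(seed, f"{traits.soil_id}|{traits.process.value}", salt=2)
    obs = []
    for t in temperatures:
        sqrt_true = evaluate_sqrt_rate(traits, t)
        for rep in range(1, n_replicates + 1):
            sqrt_noisy = sqrt_true * (1.0 + noise_cv * rng.standard_normal())
            obs.append(
                RateObservation(
                    soil_id=traits.soil_id,
                    process=traits.process,
                    temperature_c=float(t),
                    rate=max(sqrt_noisy, 0.0) ** 2,
                    replicate=rep,
                )
            )
    return ThermalAssay(traits.soil_id, traits.process, tuple(obs))


def _measurement_dates(year_start: dt.date, n_days: int) -> list[dt.date]:
    """Twice-weekly schedule: alternating 3- and 4-day gaps, last day pinned."""
    dates, offset, step_idx = [], 0, 0
    while offset < n_days:
        dates.append(year_start + dt.timedelta(days=offset))
        offset += (3, 4)[step_idx % 2]
        step_idx += 1
    last = year_start + dt.timedelta(days=n_days - 1)
    if dates[-1] != last:
        dates.append(last)
    return dates


def simulate_field_year(
    config: SyntheticScenarioConfig,
    plot_id: str,
    seed: int,
    block: str = "b1",
) -> list[FieldRecord]:
    """Twice-weekly afternoon temperature/moisture records for one plot-year.

    Values are drawn around the per-season means with AR(1)-correlated
    deviations; treatment effects enter as configured temperature offsets
    and moisture mean overrides.  Moisture is clamped to [0, 100] %.
    """
    effects = config.field_effects[config.land_use.value]
    offsets = effects.get("offsets", {}).get(config.treatment.value, {})
    rng = _plot_rng(seed, plot_id, salt=3)
    rho = config.ar1_rho
    innov = math.sqrt(1.0 - rho * rho)
    z_t, z_m = rng.standard_normal(), rng.standard_normal()
    records = []
    for date in _measurement_dates(config.year_start, config.n_days):
        season = classify_season(date, config.season_windows).value
        base = effects[season]
        z_t = rho * z_t + innov * rng.standard_normal()
        z_m = rho * z_m + innov * rng.standard_normal()
        temp_mean = base["temp_mean"] + offsets.get("temp", {}).get(season, 0.0)
        moist_mean = offsets.get("moist_mean", {}).get(season, base["moist_mean"])
        temp = temp_mean + base["temp_sd"] * z_t
        moist = moist_mean + base["moist_sd"] * z_m
        records.append(
            FieldRecord(
                date=date,
                plot_id=plot_id,
                land_use=config.land_use,
                treatment=config.treatment,
                block=block,
                soil_temp_c=float(np.clip(temp, -10.0, 70.0)),
                moisture_pct_sat=float(np.clip(moist, 0.0, 100.0)),
            )
        )
    return records


@dataclass(frozen=True)
class SyntheticWorld:
    """Complete synthetic experiment: field series, true traits, assays."""

    field_records: list[FieldRecord]
    true_traits: dict[tuple[str, Process], ThermalTraits]
    assays: list[ThermalAssay]
    plot_meta: dict[str, dict]


def generate_world(
    seed: int,
    n_blocks: int = 3,
    assay_noise_cv: float = 0.05,
    link_tmin_to_mat: bool = True,
    diurnal_params: DiurnalModelParams | None = None,
    **config_overrides,
) -> SyntheticWorld:
    """Full two-land-use x three-treatment x n-block experiment.

    Field years are generated first; each plot's modeled soil MAT (via
    the diurnal inversion of its own records) then drives the mat-linked
    Tmin draw, so the world carries a built-in Tmin-vs-MAT slope.  Assays
    are simulated from the resulting true traits.
    """
    diurnal_params = diurnal_params or DiurnalModelParams()
    field_records: list[FieldRecord] = []
    true_traits: dict[tuple[str, Process], ThermalTraits] = {}
    assays: list[ThermalAssay] = []
    plot_meta: dict[str, dict] = {}

    for land_use in (LandUse.CROP, LandUse.FOREST):
        for treatment in (Treatment.CONTROL, Treatment.OTC, Treatment.SHELTER):
            config = SyntheticScenarioConfig(
                land_use=land_use,
                treatment=treatment,
                n_blocks=n_blocks,
                seed=seed,
                assay_noise_cv=assay_noise_cv,
                **config_overrides,
            )
            for blk in range(1, n_blocks + 1):
                plot_id = f"{land_use.value}-{treatment.value}-b{blk}"
                block = f"{land_use.value}-b{blk}"
                records = simulate_field_year(config, plot_id, seed, block=block)
                field_records.extend(records)
                daily = derive_daily_means(
                    records, diurnal_params, config.year_start, config.n_days
                )
                soil_mat = float(daily["temp_mean"].mean())
                plot_meta[plot_id] = {
                    "land_use": land_use.value,
                    "treatment": treatment.value,
                    "block": block,
                    "soil_mat_c": soil_mat,
                }
                for process in Process:
                    traits = sample_true_traits(
                        config,
                        process,
                        seed,
                        soil_mat_c=soil_mat if link_tmin_to_mat else None,
                        plot_label=plot_id,
                    )
                    true_traits[(plot_id, process)] = traits
                    assays.append(
                        simulate_assay(
                            traits,
                            n_replicates=2,
                            noise_cv=assay_noise_cv,
                            seed=seed,
                        )
                    )
    return SyntheticWorld(field_records, true_traits, assays, plot_meta)
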