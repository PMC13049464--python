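"""Pipeline orchestration: fit -> forcing -> budgets -> scenarios -> regressions.

Runs the whole analysis for a multi-plot experiment and writes tabular
outputs plus a JSON manifest into a run directory.  Each stage is a
plain function over in-memory objects so tests and scripts can call any
slice of the pipeline; the CLI wraps `run_pipeline`.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .budget import (
    AnnualBudget,
    ReferenceRates,
    budgets_to_frame,
    integrate_annual_budget,
    reference_rates_from_traits,
    scenario_decompose,
)
from .errors import ConfigError, IngestionError, ThermoTraitsError
from .forcing import (
    DEFAULT_YEAR_DAYS,
    DEFAULT_YEAR_START,
    DiurnalModelParams,
    FieldRecord,
    ForcingHourly,
    MoistureFunctionParams,
    SeasonWindows,
    Treatment,
    build_hourly_forcing,
    field_records_to_frame,
    read_field_csv,
    summarize_plot_climate,
)
from .ratkowsky import (
    Process,
    ThermalAssay,
    ThermalTraits,
    fit_assay,
    read_assays_csv,
    traits_to_frame,
)
from .synth import generate_world

__all__ = [
    "RunConfig",
    "TraitRegressionResult",
    "run_pipeline",
    "trait_climate_regression",
    "stage_fit",
    "stage_forcing",
    "stage_budgets",
    "stage_scenarios",
    "stage_regressions",
]

logger = logging.getLogger("thermotraits")


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, loadable from YAML."""

    out_dir: str = "runs/latest"
    seed: int = 0
    # either CSV paths ...
    assay_csv: str | None = None
    field_csv: str | None = None
    # ... or synthesize inputs
    synth: bool = True
    n_blocks: int = 3
    assay_noise_cv: float = 0.05
    # model parameters
    diurnal: DiurnalModelParams = dc_field(default_factory=DiurnalModelParams)
    moisture: MoistureFunctionParams = dc_field(default_factory=MoistureFunctionParams)
    season_windows: SeasonWindows = dc_field(default_factory=SeasonWindows)
    bulk_density: float = 1.1
    depth_m: float = 0.10
    low_range: tuple[float, float] = (0.0, 25.0)
    q10_interval: tuple[float, float] = (10.0, 20.0)
    year_start: dt.date = DEFAULT_YEAR_START
    n_days: int = DEFAULT_YEAR_DAYS

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        kwargs = {}
        if "diurnal" in raw:
            kwargs["diurnal"] = DiurnalModelParams(**raw.pop("diurnal"))
        if "moisture" in raw:
            kwargs["moisture"] = MoistureFunctionParams(**raw.pop("moisture"))
        if "season_windows" in raw:
            sw = raw.pop("season_windows")
            kwargs["season_windows"] = SeasonWindows(
                dry_windows=tuple(
                    (dt.date.fromisoformat(a), dt.date.fromisoformat(b))
                    for a, b in sw["dry_windows"]
                ),
                wet_window=(
                    dt.date.fromisoformat(sw["wet_window"][0]),
                    dt.date.fromisoformat(sw["wet_window"][1]),
                ),
            )
        if "year_start" in raw:
            kwargs["year_start"] = dt.date.fromisoformat(raw.pop("year_start"))
        for key in ("low_range", "q10_interval"):
            if key in raw:
                kwargs[key] = tuple(raw.pop(key))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(raw)
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


@dataclass(frozen=True)
class TraitRegressionResult:
    """OLS of one thermal trait against one plot-climate predictor."""

    trait: str
    predictor: str
    process: str
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def trait_climate_regression(
    traits_df: pd.DataFrame,
    climate_df: pd.DataFrame,
    trait: str,
    predictor: str,
    process: Process | str,
) -> TraitRegressionResult:
    """Regress a fitted trait on a plot-climate variable across plots.

    Ordinary least squares; two-sided p-value for slope = 0, unadjusted.
    """
    proc = process.value if isinstance(process, Process) else process
    sub = traits_df[traits_df["process"] == proc][["soil_id", trait]]
    merged = sub.merge(
        climate_df[["plot_id", predictor]], left_on="soil_id", right_on="plot_id"
    ).dropna(subset=[trait, predictor])
    if len(merged) < 3:
        raise IngestionError(
            f"regression {trait} ~ {predictor} ({proc}): need >= 3 plots, "
            f"have {len(merged)}"
        )
    x = merged[predictor].to_numpy(dtype=float)
    y = merged[trait].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ConfigError(
            f"regression {trait} ~ {predictor}: predictor has zero variance"
        )
    res = stats.linregress(x, y)
    return TraitRegressionResult(
        trait=trait,
        predictor=predictor,
        process=proc,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(merged),
    )


# ---------------------------------------------------------------------------
# stages

def stage_fit(
    assays: Sequence[ThermalAssay], config: RunConfig
) -> dict[tuple[str, Process], ThermalTraits]:
    """Two-stage DK fit + indices for every assay."""
    fitted = {}
    for assay in assays:
        fitted[(assay.soil_id, assay.process)] = fit_assay(
            assay, low_range=config.low_range, q10_interval=config.q10_interval
        )
    return fitted


def stage_forcing(
    field_records: Sequence[FieldRecord], config: RunConfig
) -> tuple[dict[str, ForcingHourly], pd.DataFrame]:
    """Hourly forcing and climate summary per plot."""
    by_plot: dict[str, list[FieldRecord]] = {}
    for rec in field_records:
        by_plot.setdefault(rec.plot_id, []).append(rec)
    forcings, rows = {}, []
    for plot_id, recs in sorted(by_plot.items()):
        labels = {(r.land_use, r.treatment, r.block) for r in recs}
        if len(labels) > 1:
            raise IngestionError(
                f"plot label {plot_id!r} reused across distinct plots "
                f"{sorted(t[2] for t in labels)}; refusing to pool them"
            )
        forcing = build_hourly_forcing(
            recs, config.diurnal, config.year_start, config.n_days
        )
        summary = summarize_plot_climate(
            forcing, config.season_windows, expected_days=config.n_days
        )
        forcings[plot_id] = forcing
        row = {
            "plot_id": plot_id,
            "land_use": recs[0].land_use.value,
            "treatment": recs[0].treatment.value,
            "block": recs[0].block,
            "soil_mat_c": summary.soil_mat_c,
            "soil_maxt_c": summary.soil_maxt_c,
        }
        for season, st in summary.season_stats.items():
            for k, v in st.items():
                row[f"{season}_{k}"] = v
        rows.append(row)
    return forcings, pd.DataFrame(rows)


def stage_budgets(
    forcings: Mapping[str, ForcingHourly],
    traits: Mapping[tuple[str, Process], ThermalTraits],
    climate_df: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Annual budget per plot from its own traits and forcing."""
    meta = climate_df.set_index("plot_id")
    budgets = []
    for plot_id, forcing in forcings.items():
        plot_traits = {p: traits[(plot_id, p)] for p in Process}
        refs = reference_rates_from_traits(
            plot_traits, config.bulk_density, config.depth_m
        )
        label = (
            "control"
            if meta.loc[plot_id, "treatment"] == Treatment.CONTROL.value
            else "treatment"
        )
        budgets.append(
            integrate_annual_budget(
                forcing, plot_traits, refs, config.moisture,
                scenario=label, expected_days=config.n_days,
            )
        )
    df = budgets_to_frame(budgets)
    return df.merge(
        climate_df[["plot_id", "land_use", "treatment", "block"]], on="plot_id"
    )


def stage_scenarios(
    forcings: Mapping[str, ForcingHourly],
    traits: Mapping[tuple[str, Process], ThermalTraits],
    climate_df: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Counterfactual decomposition for every treated plot.

    Each OTC/shelter plot is paired with the control plot of its own
    block and land use; reference rates are taken from the control plot.
    """
    meta = climate_df.set_index("plot_id")
    controls = {
        (row["land_use"], row["block"]): plot_id
        for plot_id, row in meta.iterrows()
        if row["treatment"] == Treatment.CONTROL.value
    }
    rows = []
    for plot_id, row in meta.iterrows():
        if row["treatment"] == Treatment.CONTROL.value:
            continue
        key = (row["land_use"], row["block"])
        if key not in controls:
            raise IngestionError(
                f"{plot_id}: no control plot for block {row['block']} "
                f"in {row['land_use']}"
            )
        control_id = controls[key]
        control_traits = {p: traits[(control_id, p)] for p in Process}
        treat_traits = {p: traits[(plot_id, p)] for p in Process}
        refs = reference_rates_from_traits(
            control_traits, config.bulk_density, config.depth_m
        )
        scen = scenario_decompose(
            forcings[control_id], forcings[plot_id],
            control_traits, treat_traits, refs, config.moisture,
        )
        for label, budget in scen.items():
            rows.append(
                {
                    "treatment_plot": plot_id,
                    "control_plot": control_id,
                    "land_use": row["land_use"],
                    "treatment": row["treatment"],
                    "block": row["block"],
                    "scenario": label,
                    "cum_growth": budget.cum_growth,
                    "cum_respiration": budget.cum_respiration,
                    "cue": budget.cue,
                }
            )
    return pd.DataFrame(rows)


TRAIT_COLUMNS = ("t_min", "t_crit", "t_max", "q10")
PREDICTOR_COLUMNS = ("soil_mat_c", "soil_maxt_c")


def stage_regressions(
    traits_df: pd.DataFrame, climate_df: pd.DataFrame
) -> pd.DataFrame:
    """All trait x predictor OLS regressions pooled across plots."""
    rows = []
    for process in Process:
        for trait in TRAIT_COLUMNS:
            for predictor in PREDICTOR_COLUMNS:
                res = trait_climate_regression(
                    traits_df, climate_df, trait, predictor, process
                )
                rows.append(dataclasses.asdict(res))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_inputs(
    config: RunConfig, out_dir: Path | None = None
) -> tuple[list[ThermalAssay], list[FieldRecord], dict]:
    """Load assay + field CSVs, or synthesize and (optionally) persist them."""
    info: dict = {}
    if config.synth:
        world = generate_world(
            seed=config.seed,
            n_blocks=config.n_blocks,
            assay_noise_cv=config.assay_noise_cv,
            diurnal_params=config.diurnal,
        )
        info["source"] = "synthetic"
        info["n_plots"] = len(world.plot_meta)
        if out_dir is not None:
            inputs = out_dir / "inputs"
            inputs.mkdir(parents=True, exist_ok=True)
            rows = []
            for assay in world.assays:
                for o in assay.observations:
                    rows.append(
                        {
                            "soil_id": o.soil_id,
                            "process": o.process.value,
                            "temperature_c": o.temperature_c,
                            "replicate": o.replicate,
                            "rate": o.rate,
                        }
                    )
            pd.DataFrame(rows).to_csv(inputs / "assays.csv", index=False)
            field_records_to_frame(world.field_records).to_csv(
                inputs / "field.csv", index=False
            )
            info["assay_csv_sha256"] = _sha256(inputs / "assays.csv")
            info["field_csv_sha256"] = _sha256(inputs / "field.csv")
        return world.assays, world.field_records, info
    if not config.assay_csv or not config.field_csv:
        raise ConfigError("synth=false requires assay_csv and field_csv paths")
    assay_path, field_path = Path(config.assay_csv), Path(config.field_csv)
    for p in (assay_path, field_path):
        if not p.exists():
            raise ConfigError(f"input file not found: {p}")
    assays, n_truncated = read_assays_csv(assay_path)
    if n_truncated:
        logger.info("truncated %d negative assay rates to 0", n_truncated)
    records = read_field_csv(field_path)
    info.update(
        source="files",
        negative_rates_truncated=n_truncated,
        assay_csv_sha256=_sha256(assay_path),
        field_csv_sha256=_sha256(field_path),
    )
    return assays, records, info


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Writes traits.csv, climate.csv, budgets.csv, scenarios.csv,
    regressions.csv, run.log and manifest.json.  Deterministic given the
    config and seed (log timestamps aside).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    timings: dict[str, float] = {}

    def timed(name, fn, *args):
        t0 = time.perf_counter()
        logger.info("stage %s: start", name)
        try:
            result = fn(*args)
        except ThermoTraitsError as exc:
            logger.error("stage %s failed: %s", name, exc)
            raise
        timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s: done in %.3f s", name, timings[name])
        return result

    try:
        assays, records, input_info = timed("load", load_inputs, config, out_dir)
        traits = timed("fit", stage_fit, assays, config)
        traits_df = traits_to_frame(traits.values())
        forcings, climate_df = timed("forcing", stage_forcing, records, config)
        budgets_df = timed(
            "budgets", stage_budgets, forcings, traits, climate_df, config
        )
        scenarios_df = timed(
            "scenarios", stage_scenarios, forcings, traits, climate_df, config
        )
        regressions_df = timed("regress", stage_regressions, traits_df, climate_df)

        float_fmt = "%.10g"
        traits_df.to_csv(out_dir / "traits.csv", index=False, float_format=float_fmt)
        climate_df.to_csv(out_dir / "climate.csv", index=False, float_format=float_fmt)
        budgets_df.to_csv(out_dir / "budgets.csv", index=False, float_format=float_fmt)
        scenarios_df.to_csv(
            out_dir / "scenarios.csv", index=False, float_format=float_fmt
        )
        regressions_df.to_csv(
            out_dir / "regressions.csv", index=False, float_format=float_fmt
        )
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": _config_to_jsonable(config),
            "inputs": input_info,
            "timings_s": timings,
            "outputs": sorted(
                p.name for p in out_dir.glob("*.csv")
            ),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out_dir


def _config_to_jsonable(config: RunConfig) -> dict:
    def convert(v):
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            return {f.name: convert(getattr(v, f.name)) for f in dataclasses.fields(v)}
        if isinstance(v, dt.date):
            return v.isoformat()
        if isinstance(v, tuple):
            return [convert(x) for x in v]
        return v

    return {
        f.name: convert(getattr(config, f.name)) for f in dataclasses.fields(RunConfig)
    }
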