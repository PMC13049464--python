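"""Integrate annual microbial C budgets per plot.

Combines each plot's fitted temperature relationships (as normalized rate
modifiers), the DAYCENT moisture modifier, and its hourly forcing into
cumulative annual bacterial + fungal growth and respiration per m2 of
soil (top 10 cm), plus the resulting carbon use efficiency.
"""

from pathlib import Path

from thermotraits.forcing import read_field_csv
from thermotraits.pipeline import RunConfig, stage_budgets, stage_fit, stage_forcing
from thermotraits.ratkowsky import read_assays_csv

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    cfg = RunConfig()
    assays, _ = read_assays_csv(RESULTS / "data" / "assays.csv")
    records = read_field_csv(RESULTS / "data" / "field.csv")
    traits = stage_fit(assays, cfg)
    forcings, climate_df = stage_forcing(records, cfg)
    budgets_df = stage_budgets(forcings, traits, climate_df, cfg)
    budgets_df.to_csv(RESULTS / "budgets.csv", index=False)

    print("annual budgets (g C m-2 y-1), mean over blocks:")
    print(
        budgets_df.groupby(["land_use", "treatment"])[
            ["cum_growth", "cum_respiration", "cue"]
        ].mean().round(3)
    )
    print(f"wrote budgets.csv -> {RESULTS}")


if __name__ == "__main__":
    main()
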