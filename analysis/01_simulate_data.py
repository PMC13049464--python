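"""Generate the synthetic experiment dataset.

Builds the two-land-use x three-treatment x three-block world: twice-weekly
field temperature/moisture series over the modeled year and temperature-
screening assays (10 temperatures x 2 duplicates) for bacterial growth,
fungal growth and respiration in every plot.  Writes the same CSV dialects
the ingestion code reads, so later steps exercise the full I/O path.
"""

from pathlib import Path

import pandas as pd

from thermotraits.forcing import field_records_to_frame
from thermotraits.synth import generate_world

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    world = generate_world(seed=SEED)

    rows = [
        {
            "soil_id": o.soil_id,
            "process": o.process.value,
            "temperature_c": o.temperature_c,
            "replicate": o.replicate,
            "rate": o.rate,
        }
        for assay in world.assays
        for o in assay.observations
    ]
    pd.DataFrame(rows).to_csv(OUT / "assays.csv", index=False)
    field_records_to_frame(world.field_records).to_csv(OUT / "field.csv", index=False)
    pd.DataFrame(
        [{"plot_id": p, **m} for p, m in world.plot_meta.items()]
    ).to_csv(OUT / "plots.csv", index=False)

    n_dates = len({r.date for r in world.field_records})
    print(f"seed {SEED}: {len(world.plot_meta)} plots, "
          f"{len(world.assays)} assays ({len(rows)} rate observations), "
          f"{n_dates} field measurement dates per plot")
    print(f"wrote assays.csv, field.csv, plots.csv -> {OUT}")


if __name__ == "__main__":
    main()
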