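import datetime as dt

import numpy as np
import pandas as pd
import pytest

from thermotraits.forcing import ForcingHourly
from thermotraits.ratkowsky import (
    Process,
    RateObservation,
    ThermalAssay,
    ThermalTraits,
)


def make_traits(
    process=Process.BACTERIAL_GROWTH,
    a=0.1,
    b=0.25,
    t_min=-5.0,
    t_max=48.0,
    t_crit=None,
    soil_id="toy",
):
    return ThermalTraits(
        soil_id=soil_id, process=process, a=a, b=b,
        t_min=t_min, t_max=t_max, t_crit=t_crit,
    )


def make_assay(soil_id, process, temps, rates, replicate=1):
    obs = tuple(
        RateObservation(soil_id, process, float(t), float(r), replicate)
        for t, r in zip(temps, rates)
    )
    return ThermalAssay(soil_id, process, obs)


def constant_forcing(
    plot_id="plot", temp_c=20.0, moisture_pct=60.0, n_days=365,
    start=dt.date(2018, 2, 8),
):
    """Hourly forcing with constant temperature and moisture."""
    index = pd.date_range(pd.Timestamp(start), periods=n_days * 24, freq="h")
    frame = pd.DataFrame(
        {
            "temp_c": np.full(len(index), float(temp_c)),
            "moisture_pct_sat": np.full(len(index), float(moisture_pct)),
            "measured_day": np.ones(len(index), dtype=bool),
        },
        index=index,
    )
    return ForcingHourly(plot_id=plot_id, frame=frame)


@pytest.fixture
def growth_traits():
    """Growth curve with a round-number parameter set used across tests."""
    return make_traits()


@pytest.fixture
def respiration_traits():
    return make_traits(
        process=Process.RESPIRATION, a=0.1, b=0.2, t_min=-5.0, t_max=40.0
    )
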