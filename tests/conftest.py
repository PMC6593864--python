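import dataclasses

import numpy as np
import pandas as pd
import pytest

from heatlag.synthetic_data import default_scenario


def scaled_scenario(seed, n_herds=25, cows_per_herd=40, years=(2004, 2007),
                    n_stations=5, milk=None, scs=None):
    """Shrunk copy of the shipped default scenario (~10k records) for fast
    tests; per-trait effect fields can be overridden via dicts."""
    scen = default_scenario(seed=seed)
    scen = dataclasses.replace(
        scen, n_herds=n_herds, cows_per_herd=cows_per_herd,
        years=tuple(years), n_stations=n_stations,
    )
    if milk:
        scen = dataclasses.replace(scen, milk=dataclasses.replace(scen.milk, **milk))
    if scs:
        scen = dataclasses.replace(scen, scs=dataclasses.replace(scen.scs, **scs))
    return scen


def make_weather(n_days=30, stations=("S1",), start="2020-06-01",
                 t=20.0, rh=70.0):
    """Hand-size weather table; t may be scalar or per-day array."""
    dates = np.arange(np.datetime64(start, "D"),
                      np.datetime64(start, "D") + np.timedelta64(n_days, "D"))
    frames = []
    for s in stations:
        frames.append(pd.DataFrame({
            "station_id": s,
            "date": dates,
            "tavg_c": np.broadcast_to(np.asarray(t, float), (n_days,)).copy(),
            "rh_pct": np.broadcast_to(np.asarray(rh, float), (n_days,)).copy(),
        }))
    return pd.concat(frames, ignore_index=True)


def make_testday(n=3, herd="H1", start="2020-06-20", milk=25.0, scc=100_000.0,
                 dim0=60, calving_year=2019, age_months=24):
    dates = np.arange(np.datetime64(start, "D"),
                      np.datetime64(start, "D") + np.timedelta64(n, "D"))
    return pd.DataFrame({
        "cow_id": [f"C{i}" for i in range(n)],
        "herd_id": herd,
        "test_date": dates,
        "dim": np.arange(dim0, dim0 + n),
        "milk_kg": milk,
        "scc": scc,
        "calving_year": calving_year,
        "age_months": age_months,
    })


@pytest.fixture
def tiny_mapping():
    return pd.DataFrame({"herd_id": ["H1"], "station_id": ["S1"]})
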