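"""Synthetic weather series and dairy test-day records with a known,
lagged, piecewise-linear heat-stress effect.

The generator emulates the structure the fixed-effects test-day model
assumes: for each cow, monthly test-day observations over the first
lactation (days in milk 6-305) with additive herd, calving-year, calendar
month, age-group, and lactation-curve effects, plus a hinge-shaped
heat-stress term acting at a configurable lag,

    y = baseline + herd + year + month + age + curve(DIM)
        + slope * max(THI(test_date - lag) - bp, 0) + e,      e ~ N(0, sd^2)

so that every downstream stage (lag scan, least-squares means, segmented
regression) can be validated by recovering the parameters that generated
the data.  The realized draws of each effect (and the hinge term) are
centred over the generated records; fixed effects are identified only up to
contrasts, so centring is a pure reparameterization that pins the sample
mean of the response at ``baseline_mean``.

Weather is a sinusoidal seasonal cycle per station with AR(1) daily
temperature noise and seasonal humidity, over a north-south station
gradient wide enough that binned THI spans roughly 4-84 with the classes
18-82 well populated.

SCS is generated on the score scale (Gaussian residuals) and transformed
back to a somatic cell count, with the count floored at 1,000 cells/mL as
recording systems do — hence a minimum attainable score of
``log2(0.01) + 3 = -3.64``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records_io import (
    DIM_MAX,
    DIM_MIN,
    ValidationError,
    assign_age_group,
    bin_thi,
    compute_thi,
    scc_to_scs,
    scs_to_scc,
)

#: minimum recordable somatic cell count, cells/mL (score floor -3.64)
SCC_FLOOR = 1_000.0

#: age-at-first-calving distribution, months 18..35 (unnormalized weights)
_AGE_VALUES = np.arange(18, 36)
_AGE_WEIGHTS = np.array(
    [1, 2, 4, 8, 14, 16, 14, 10, 7, 5, 3, 2, 1.5, 1, 0.8, 0.6, 0.5, 0.4]
)


@dataclass
class EffectSpec:
    """True generating parameters for one trait."""

    true_lag_days: int            # days between THI exposure and test day
    bp: float                     # THI breakpoint (index units)
    slope: float                  # response change per THI unit above bp
    herd_sd: float
    year_sd: float
    month_amplitude: float        # signed seasonal amplitude, peak in August
    age_effects: tuple            # one additive effect per age group
    residual_sd: float
    baseline_mean: float          # population mean of the response
    curve_exp_coef: float         # lactation curve: c1*exp(-c2*dim) + c3*dim
    curve_exp_rate: float
    curve_linear: float

    def __post_init__(self):
        if self.residual_sd < 0:
            raise ValidationError("residual_sd must be non-negative")
        if not 0 <= int(self.true_lag_days) <= 14:
            raise ValidationError("true_lag_days must be in [0, 14]")

    def lactation_curve(self, dim):
        """Smooth DIM effect: fast transient plus linear trend."""
        d = np.asarray(dim, dtype=float)
        return (self.curve_exp_coef * np.exp(-self.curve_exp_rate * d)
                + self.curve_linear * d)


@dataclass
class Scenario:
    """Sizes, seed and per-trait effect specifications for one simulation."""

    n_herds: int
    cows_per_herd: int
    years: tuple                  # (first calving year, last calving year)
    n_stations: int
    seed: int
    milk: EffectSpec
    scs: EffectSpec
    test_interval_days: int = 30
    test_jitter_days: int = 5

    def __post_init__(self):
        for name in ("n_herds", "cows_per_herd", "n_stations"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.seed is None:
            raise ValidationError("scenario seed is mandatory")

    @classmethod
    def from_dict(cls, raw: dict, seed: int | None = None) -> "Scenario":
        raw = dict(raw)
        if seed is not None:
            raw["seed"] = seed
        if "seed" not in raw:
            raise ValidationError("scenario seed is mandatory")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown scenario key(s): {sorted(unknown)}")
        for trait in ("milk", "scs"):
            spec = dict(raw[trait])
            spec["age_effects"] = tuple(spec["age_effects"])
            raw[trait] = EffectSpec(**spec)
        raw["years"] = tuple(raw["years"])
        return cls(**raw)


def load_scenario(source, seed: int | None = None) -> Scenario:
    """Load a scenario from a YAML file, or ``"default"`` for the shipped one."""
    if source == "default":
        text = (resources.files("heatlag") / "scenarios" / "default.yaml").read_text()
    else:
        text = Path(source).read_text()
    return Scenario.from_dict(yaml.safe_load(text), seed=seed)


def default_scenario(seed: int) -> Scenario:
    return load_scenario("default", seed=seed)


# ---------------------------------------------------------------------------
# weather


def _station_mapping(scenario: Scenario) -> pd.DataFrame:
    herds = [f"H{h:04d}" for h in range(scenario.n_herds)]
    stations = [f"S{h % scenario.n_stations:02d}" for h in range(scenario.n_herds)]
    return pd.DataFrame({"herd_id": herds, "station_id": stations})


def simulate_weather(scenario: Scenario) -> pd.DataFrame:
    """Daily weather per station over the scenario years (plus margins).

    Stations sit on a north-south gradient: winter mean temperature from
    -14 to +2 deg C, summer mean from 20 to 28 deg C, peaking around late
    July, with AR(1) daily noise (phi 0.55, marginal sd 2.3 deg C).
    Humidity is seasonal around 70% (summer-humid), anticorrelated with the
    temperature anomaly, clipped to [25, 100].
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(scenario.seed), 1]))
    y0, y1 = scenario.years
    start = np.datetime64(f"{y0}-01-01", "D") - np.timedelta64(50, "D")
    end = np.datetime64(f"{y1 + 1}-12-31", "D")
    dates = np.arange(start, end + np.timedelta64(1, "D"))
    nd = dates.size
    doy = ((dates - dates.astype("datetime64[Y]").astype("datetime64[D]"))
           .astype(int) + 1)
    season = np.cos(2.0 * np.pi * (doy - 208) / 365.25)   # +1 in late July
    phi, t_sd, rh_sd = 0.55, 2.3, 5.5
    frames = []
    for s in range(scenario.n_stations):
        u = 0.5 if scenario.n_stations == 1 else s / (scenario.n_stations - 1)
        t_winter = -14.0 + 16.0 * u
        t_summer = 20.0 + 8.0 * u
        mid = 0.5 * (t_winter + t_summer)
        amp = 0.5 * (t_summer - t_winter)
        innov = rng.normal(0.0, t_sd * np.sqrt(1.0 - phi * phi), size=nd)
        noise = np.empty(nd)
        noise[0] = rng.normal(0.0, t_sd)
        for i in range(1, nd):
            noise[i] = phi * noise[i - 1] + innov[i]
        # daily-mean anomalies are physically bounded; truncate at 3 sd
        t = mid + amp * season + np.clip(noise, -3.0 * t_sd, 3.0 * t_sd)
        # hot anomalies tend to be dry (clear-sky) days: anticorrelated noise
        rh = np.clip(70.0 + 8.0 * season - 1.5 * noise
                     + rng.normal(0.0, rh_sd, size=nd), 25.0, 100.0)
        frames.append(pd.DataFrame({
            "station_id": f"S{s:02d}",
            "date": dates,
            "tavg_c": t,
            "rh_pct": rh,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# test days


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean()


def simulate_testdays(scenario: Scenario, weather: pd.DataFrame):
    """Monthly test-day records with hidden truth.

    Returns ``(testday, truth)`` where ``truth`` records the generating lag,
    breakpoint, and slope per trait for recovery harnesses.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(scenario.seed), 2]))
    y0, y1 = scenario.years
    n_cows = scenario.n_herds * scenario.cows_per_herd

    herd_idx = np.repeat(np.arange(scenario.n_herds), scenario.cows_per_herd)
    calving_year = rng.integers(y0, y1 + 1, size=n_cows)
    year_start = np.array([np.datetime64(f"{y}-01-01", "D") for y in range(y0, y1 + 1)])
    is_leap = np.array([365 + int(y % 4 == 0 and (y % 100 != 0 or y % 400 == 0))
                        for y in range(y0, y1 + 1)])
    cy = calving_year - y0
    calving_date = (year_start[cy]
                    + rng.integers(0, is_leap[cy]).astype("timedelta64[D]"))
    age_months = rng.choice(_AGE_VALUES, size=n_cows,
                            p=_AGE_WEIGHTS / _AGE_WEIGHTS.sum())

    # monthly test schedule: first test at DIM 6-35, then ~30 +/- jitter days
    max_tests = 2 + (DIM_MAX - DIM_MIN) // max(
        scenario.test_interval_days - scenario.test_jitter_days, 1)
    first = rng.integers(DIM_MIN, DIM_MIN + 30, size=(n_cows, 1))
    gaps = rng.integers(
        scenario.test_interval_days - scenario.test_jitter_days,
        scenario.test_interval_days + scenario.test_jitter_days + 1,
        size=(n_cows, max_tests - 1),
    )
    dim = np.concatenate([first, gaps], axis=1).cumsum(axis=1)
    keep = dim <= DIM_MAX
    cow_of = np.repeat(np.arange(n_cows), keep.sum(axis=1))
    dim = dim[keep]
    n = dim.size

    test_date = calving_date[cow_of] + dim.astype("timedelta64[D]")
    herd = herd_idx[cow_of]
    mapping = _station_mapping(scenario)
    station_of_herd = herd % scenario.n_stations

    # per-station daily continuous THI, indexed by day offset
    wdates = weather["date"].to_numpy().astype("datetime64[D]")
    wstart = wdates.min()
    thi_all = compute_thi(weather["tavg_c"].to_numpy(dtype=float),
                          weather["rh_pct"].to_numpy(dtype=float))
    thi_by_station = {}
    for sid, idx in weather.groupby("station_id").indices.items():
        off = (wdates[idx] - wstart).astype(np.int64)
        arr = np.full(int(off.max()) + 1, np.nan)
        arr[off] = thi_all[idx]
        thi_by_station[int(sid[1:])] = (arr, wstart)

    def lagged_thi(lag: int) -> np.ndarray:
        out = np.empty(n)
        s_codes = station_of_herd
        for s, (arr, start) in thi_by_station.items():
            m = s_codes == s
            off = (test_date[m] - start).astype(np.int64) - lag
            if off.min() < 0 or off.max() >= arr.size or np.isnan(arr[off]).any():
                raise ValidationError(
                    f"weather does not cover test_date - {lag} for station S{s:02d}")
            out[m] = arr[off]
        return out

    month = pd.DatetimeIndex(test_date).month.to_numpy()
    age_group = assign_age_group(age_months)
    n_years = y1 - y0 + 1

    responses = {}
    truth = {}
    for trait in ("milk", "scs"):
        spec: EffectSpec = getattr(scenario, trait)
        herd_eff = rng.normal(0.0, spec.herd_sd, size=scenario.n_herds)
        year_eff = rng.normal(0.0, spec.year_sd, size=n_years)
        month_eff = spec.month_amplitude * np.cos(2.0 * np.pi * (np.arange(1, 13) - 8) / 12.0)
        age_eff = np.asarray(spec.age_effects, dtype=float)
        hinge = np.maximum(lagged_thi(spec.true_lag_days) - spec.bp, 0.0)
        y = (spec.baseline_mean
             + _center(herd_eff[herd])
             + _center(year_eff[calving_year[cow_of] - y0])
             + _center(month_eff[month - 1])
             + _center(age_eff[age_group[cow_of] - 1])
             + _center(spec.lactation_curve(dim))
             + spec.slope * _center(hinge)
             + rng.normal(0.0, spec.residual_sd, size=n))
        responses[trait] = y
        truth[trait] = {"true_lag_days": int(spec.true_lag_days),
                        "bp": float(spec.bp), "slope": float(spec.slope)}

    milk = np.maximum(responses["milk"], 0.2)
    scs = np.maximum(responses["scs"], scc_to_scs(SCC_FLOOR))
    scc = scs_to_scc(scs)

    testday = pd.DataFrame({
        "cow_id": np.char.add("C", np.char.zfill(cow_of.astype(str), 7)),
        "herd_id": mapping["herd_id"].to_numpy()[herd],
        "test_date": test_date,
        "dim": dim.astype(np.int64),
        "milk_kg": milk,
        "scc": scc,
        "calving_year": calving_year[cow_of],
        "age_months": age_months[cow_of],
    })
    testday["scs"] = scs
    return testday, truth


def simulate_scenario(scenario: Scenario):
    """Full in-memory simulation: (testday, weather, mapping, truth)."""
    weather = simulate_weather(scenario)
    testday, truth = simulate_testdays(scenario, weather)
    return testday, weather, _station_mapping(scenario), truth


def write_scenario(scenario: Scenario, out_dir) -> dict:
    """Simulate and write testday.csv, weather.csv, herd_station.csv, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    testday, weather, mapping, truth = simulate_scenario(scenario)
    paths = {
        "testday": out / "testday.csv",
        "weather": out / "weather.csv",
        "herd_station": out / "herd_station.csv",
        "truth": out / "truth.json",
    }
    testday.drop(columns=["scs"]).to_csv(paths["testday"], index=False,
                                         float_format="%.10g")
    weather.to_csv(paths["weather"], index=False, float_format="%.10g")
    mapping.to_csv(paths["herd_station"], index=False)
    truth_doc = {"scenario": _scenario_dict(scenario), "truth": truth}
    paths["truth"].write_text(json.dumps(truth_doc, indent=2))
    return {k: str(v) for k, v in paths.items()}


def _scenario_dict(scenario: Scenario) -> dict:
    doc = dataclasses.asdict(scenario)
    doc["years"] = list(scenario.years)
    for trait in ("milk", "scs"):
        doc[trait]["age_effects"] = list(doc[trait]["age_effects"])
    return doc
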