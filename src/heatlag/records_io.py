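"""Domain tables, transforms, and the lagged weather join.

Tables are exchanged between modules as plain :class:`pandas.DataFrame`
objects with fixed column schemas:

``testday.csv``
    ``cow_id, herd_id, test_date, dim, milk_kg, scc, calving_year, age_months``
``weather.csv``
    ``station_id, date, tavg_c, rh_pct``
``herd_station.csv``
    ``herd_id, station_id``

The somatic cell score (SCS) is the log2 transform of the somatic cell
count, ``SCS = log2(SCC / 100000) + 3``.  The temperature-humidity index
(THI) is the NRC form

    ``THI = 1.8 t + 32 - (0.55 - 0.0055 rh) * (1.8 t - 26)``

with ``t`` the mean daily temperature in deg C and ``rh`` the mean daily
relative humidity in percent.  At ``rh = 100`` the humidity correction
vanishes and THI equals the temperature in deg F.  (The index is often
typeset with the minus sign between ``32`` and the humidity term dropped;
the subtraction form above is the one that preserves that identity and is
the one used throughout this package.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TESTDAY_COLUMNS = [
    "cow_id", "herd_id", "test_date", "dim", "milk_kg", "scc",
    "calving_year", "age_months",
]
WEATHER_COLUMNS = ["station_id", "date", "tavg_c", "rh_pct"]
MAPPING_COLUMNS = ["herd_id", "station_id"]

#: days-in-milk window retained for analysis: 300 one-day classes
DIM_MIN, DIM_MAX = 6, 305

#: age-at-calving groups, months (inclusive bounds): 18-20, 21, 22-35
AGE_GROUP_BOUNDS = ((18, 20), (21, 21), (22, 35))

#: reference count of the SCS transform, cells/mL
SCS_REFERENCE_SCC = 100_000.0

MAX_LAG_DAYS = 14

_MISSING = np.iinfo(np.int32).min


class ValidationError(ValueError):
    """An input value violates a documented domain invariant."""


class SchemaError(ValueError):
    """An input file lacks a required column."""


class IntegrityError(ValueError):
    """An input table violates a uniqueness constraint."""


class WeatherCoverageError(ValueError):
    """A required (station, date) weather observation is absent."""


# ---------------------------------------------------------------------------
# scalar/array transforms


def compute_thi(t, rh):
    """Temperature-humidity index from mean temperature and humidity.

    Parameters
    ----------
    t : float or array-like
        Mean daily temperature, deg C.
    rh : float or array-like
        Mean daily relative humidity, percent, in [0, 100].
    """
    t_arr = np.asarray(t, dtype=float)
    rh_arr = np.asarray(rh, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValidationError("t: temperature must be finite")
    if not np.all(np.isfinite(rh_arr)):
        raise ValidationError("rh: relative humidity must be finite")
    if np.any((rh_arr < 0.0) | (rh_arr > 100.0)):
        raise ValidationError("rh: relative humidity outside [0, 100]")
    thi = 1.8 * t_arr + 32.0 - (0.55 - 0.0055 * rh_arr) * (1.8 * t_arr - 26.0)
    if np.isscalar(t) and np.isscalar(rh):
        return float(thi)
    return thi


def bin_thi(thi):
    """Integer THI class via round-half-away-from-zero.

    Binning the observed index range [4, 84] yields 81 one-unit classes.
    """
    arr = np.asarray(thi, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("thi: non-finite value cannot be binned")
    out = np.trunc(arr + np.copysign(0.5, arr)).astype(np.int64)
    if np.isscalar(thi):
        return int(out)
    return out


def scc_to_scs(scc):
    """Somatic cell score from somatic cell count (cells/mL)."""
    arr = np.asarray(scc, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0.0):
        raise ValidationError("scc: somatic cell count must be positive")
    out = np.log2(arr / SCS_REFERENCE_SCC) + 3.0
    if np.isscalar(scc):
        return float(out)
    return out


def scs_to_scc(scs):
    """Inverse of :func:`scc_to_scs`."""
    arr = np.asarray(scs, dtype=float)
    out = SCS_REFERENCE_SCC * np.exp2(arr - 3.0)
    if np.isscalar(scs):
        return float(out)
    return out


def assign_age_group(age_months, bounds=AGE_GROUP_BOUNDS):
    """Map age at first calving (months) to its class label (1..len(bounds)).

    The default grouping is 18-20, 21, and 22-35 months; the boundaries are
    configurable because finer groupings are common in national evaluations.
    """
    arr = np.asarray(age_months, dtype=np.int64)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for label, (lo, hi) in enumerate(bounds, start=1):
        out[(arr >= lo) & (arr <= hi)] = label
    if np.any(out < 0):
        bad = np.unique(arr[out < 0])
        raise ValidationError(
            f"age_months: values outside the configured groups: {bad.tolist()[:10]}"
        )
    if np.isscalar(age_months):
        return int(out)
    return out


# ---------------------------------------------------------------------------
# file readers


def _require_columns(frame: pd.DataFrame, columns, name: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")


def _reject(frame: pd.DataFrame, bad: np.ndarray, reason: str, name: str) -> pd.DataFrame:
    n_bad = int(np.sum(bad))
    if n_bad:
        logger.warning("%s: rejected %d row(s): %s", name, n_bad, reason)
        frame = frame.loc[~bad]
    return frame


def read_weather(path) -> pd.DataFrame:
    wx = pd.read_csv(path)
    _require_columns(wx, WEATHER_COLUMNS, "weather")
    wx = wx.copy()
    wx["date"] = pd.to_datetime(wx["date"]).values.astype("datetime64[D]")
    t = pd.to_numeric(wx["tavg_c"], errors="coerce")
    rh = pd.to_numeric(wx["rh_pct"], errors="coerce")
    wx = _reject(wx, (~np.isfinite(t)).to_numpy(), "non-finite temperature", "weather")
    rh = pd.to_numeric(wx["rh_pct"], errors="coerce")
    wx = _reject(
        wx, (~np.isfinite(rh) | (rh < 0) | (rh > 100)).to_numpy(),
        "relative humidity outside [0, 100]", "weather",
    )
    dup = wx.duplicated(subset=["station_id", "date"])
    if dup.any():
        key = wx.loc[dup, ["station_id", "date"]].iloc[0].tolist()
        raise IntegrityError(f"weather: duplicate (station_id, date), first {key}")
    return wx.reset_index(drop=True)


def read_testday(path) -> pd.DataFrame:
    td = pd.read_csv(path)
    _require_columns(td, TESTDAY_COLUMNS, "testday")
    td = td.copy()
    td["test_date"] = pd.to_datetime(td["test_date"]).values.astype("datetime64[D]")
    dim = pd.to_numeric(td["dim"], errors="coerce")
    td = _reject(
        td, (~np.isfinite(dim) | (dim < DIM_MIN) | (dim > DIM_MAX)).to_numpy(),
        f"days in milk outside [{DIM_MIN}, {DIM_MAX}]", "testday",
    )
    milk = pd.to_numeric(td["milk_kg"], errors="coerce")
    td = _reject(td, (~np.isfinite(milk) | (milk <= 0)).to_numpy(),
                 "non-positive milk yield", "testday")
    scc = pd.to_numeric(td["scc"], errors="coerce")
    td = _reject(td, (~np.isfinite(scc) | (scc <= 0)).to_numpy(),
                 "non-positive somatic cell count", "testday")
    lo = AGE_GROUP_BOUNDS[0][0]
    hi = AGE_GROUP_BOUNDS[-1][1]
    age = pd.to_numeric(td["age_months"], errors="coerce")
    td = _reject(td, (~np.isfinite(age) | (age < lo) | (age > hi)).to_numpy(),
                 f"age at calving outside [{lo}, {hi}] months", "testday")
    td = td.reset_index(drop=True)
    td["dim"] = td["dim"].astype(np.int64)
    td["scs"] = scc_to_scs(td["scc"].to_numpy(dtype=float))
    return td


def read_mapping(path) -> pd.DataFrame:
    mp = pd.read_csv(path)
    _require_columns(mp, MAPPING_COLUMNS, "herd_station")
    dup = mp.duplicated(subset=["herd_id"])
    if dup.any():
        raise IntegrityError(
            f"herd_station: herd(s) mapped to multiple stations: "
            f"{mp.loc[dup, 'herd_id'].unique().tolist()[:10]}"
        )
    return mp.reset_index(drop=True)


def read_tables(testday_path, weather_path, mapping_path):
    """Read and validate the three input tables.

    Rows violating row-level invariants (humidity range, DIM window,
    positivity of milk and SCC) are rejected with counts logged; structural
    problems (missing columns, duplicate keys) raise.
    """
    return (
        read_testday(testday_path),
        read_weather(weather_path),
        read_mapping(mapping_path),
    )


# ---------------------------------------------------------------------------
# lagged THI join


@dataclass
class ModelTable:
    """Test-day records joined to the THI class of ``test_date - lag_days``.

    ``frame`` columns: ``herd, year, month, age_group, dim_class, thi_class``
    plus the responses ``milk`` and ``scs``.
    """

    frame: pd.DataFrame
    lag_days: int


class ThiLookup:
    """Per-station daily THI classes indexed by day offset.

    Built once from a weather table and a herd->station mapping; repeated
    lagged joins (one per candidate lag) then reduce to integer indexing.
    """

    def __init__(self, weather: pd.DataFrame, mapping: pd.DataFrame):
        self.station_of = dict(zip(mapping["herd_id"], mapping["station_id"]))
        thi_class = bin_thi(compute_thi(
            weather["tavg_c"].to_numpy(dtype=float),
            weather["rh_pct"].to_numpy(dtype=float),
        ))
        dates = weather["date"].to_numpy().astype("datetime64[D]")
        self._start: dict = {}
        self._classes: dict = {}
        for sid, idx in weather.groupby("station_id").indices.items():
            d = dates[idx]
            start = d.min()
            off = (d - start).astype(np.int64)
            arr = np.full(int(off.max()) + 1, _MISSING, dtype=np.int64)
            arr[off] = thi_class[idx]
            self._start[sid] = start
            self._classes[sid] = arr

    def classes_for(self, testday: pd.DataFrame, lag_days: int) -> np.ndarray:
        herd_ids = testday["herd_id"].to_numpy()
        test_dates = testday["test_date"].to_numpy().astype("datetime64[D]")
        stations = pd.Series(herd_ids).map(self.station_of)
        if stations.isna().any():
            bad = pd.unique(pd.Series(herd_ids)[stations.isna()])
            raise ValidationError(f"herds without a station mapping: {bad.tolist()[:10]}")
        out = np.full(len(testday), _MISSING, dtype=np.int64)
        missing: list = []
        for sid, ridx in stations.groupby(stations).indices.items():
            arr = self._classes.get(sid)
            if arr is None:
                missing.extend((sid, str(d)) for d in test_dates[ridx][:5])
                continue
            off = (test_dates[ridx] - self._start[sid]).astype(np.int64) - lag_days
            ok = (off >= 0) & (off < arr.size)
            vals = np.where(ok, arr[np.clip(off, 0, arr.size - 1)], _MISSING)
            bad = vals == _MISSING
            if bad.any():
                for o in off[bad][:10]:
                    missing.append((sid, str(self._start[sid] + np.timedelta64(int(o), "D"))))
            out[ridx] = vals
        if missing:
            raise WeatherCoverageError(
                f"weather coverage gap at lag {lag_days}; first missing "
                f"(station, date) keys: {missing[:10]}"
            )
        return out


def join_lagged_thi(
    testday: pd.DataFrame,
    weather: pd.DataFrame,
    mapping: pd.DataFrame,
    lag_days: int,
    lookup: ThiLookup | None = None,
) -> ModelTable:
    """Attach the THI class observed ``lag_days`` before each test day.

    Row count and responses are preserved; a missing (station, date) pair is
    a hard error — gaps are never imputed, because silent filling would
    misattribute exposure to the wrong lag.
    """
    if not 0 <= int(lag_days) <= MAX_LAG_DAYS:
        raise ValidationError(f"lag_days must be in [0, {MAX_LAG_DAYS}], got {lag_days}")
    if lookup is None:
        lookup = ThiLookup(weather, mapping)
    thi_class = lookup.classes_for(testday, int(lag_days))
    test_dates = pd.DatetimeIndex(testday["test_date"])
    if "scs" in testday.columns:
        scs = testday["scs"].to_numpy(dtype=float)
    else:
        scs = scc_to_scs(testday["scc"].to_numpy(dtype=float))
    frame = pd.DataFrame({
        "herd": testday["herd_id"].to_numpy(),
        "year": testday["calving_year"].to_numpy(),
        "month": test_dates.month.to_numpy(),
        "age_group": assign_age_group(testday["age_months"].to_numpy()),
        "dim_class": testday["dim"].to_numpy(),
        "thi_class": thi_class,
        "milk": testday["milk_kg"].to_numpy(dtype=float),
        "scs": scs,
    })
    return ModelTable(frame=frame, lag_days=int(lag_days))
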