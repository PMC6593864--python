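"""AIC scan over exposure lags 0-14 days, replicated over herd subsets.

Herds are partitioned at random into ``k`` subsets (every cow of a herd
stays with its herd).  Within each subset the test-day model is fitted once
without any THI term (the basic model) and once per candidate lag with the
THI classes of ``test_date - lag``; the lag minimizing the mean AIC across
subsets is selected.  The across-subset spread gives the standard error,
SE = SD / sqrt(k), and a normal 95% interval mean +/- 1.96 SE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fixed_effects_model import (
    DEFAULT_ALIAS_TOL,
    build_design,
    extend_with_factor,
    fit_ols,
)
from .records_io import ThiLookup, ValidationError, join_lagged_thi

logger = logging.getLogger(__name__)

BASIC_LABEL = "basic"
DEFAULT_LAGS = tuple(range(15))

_Z95 = 1.959963984540054


@dataclass
class LagScanResult:
    """Per-(subset, lag) AICs, across-subset summary, and the selected lag."""

    per_fit: pd.DataFrame        # subset, lag, aic, delta_aic_vs_basic
    summary: pd.DataFrame        # lag, mean_aic, se, ci_lo, ci_hi, delta...
    selected_lag: int
    basic_preferred: bool        # basic model beats every lag on mean AIC
    assignment: pd.Series        # herd_id -> subset
    trait: str


def split_subsets(testday: pd.DataFrame, k: int = 5, seed: int = 0) -> pd.Series:
    """Random herd-atomic partition into ``k`` subsets.

    Each herd is assigned uniformly at random (multinomial, not balanced),
    so subset sizes vary; all records of a herd share its subset.
    """
    herds = np.unique(testday["herd_id"].to_numpy())
    if len(herds) < k:
        raise ValidationError(f"need at least k={k} herds, found {len(herds)}")
    rng = np.random.default_rng(seed)
    return pd.Series(rng.integers(0, k, size=len(herds)), index=herds, name="subset")


def _summarize(per_fit: pd.DataFrame, k: int) -> pd.DataFrame:
    rows = []
    for lag, grp in per_fit.groupby("lag", sort=False):
        aics = grp["aic"].to_numpy()
        mean = aics.mean()
        se = aics.std(ddof=1) / np.sqrt(len(aics)) if len(aics) > 1 else 0.0
        rows.append({
            "lag": lag,
            "mean_aic": mean,
            "se": se,
            "ci_lo": mean - _Z95 * se,
            "ci_hi": mean + _Z95 * se,
            "delta_aic_vs_basic": grp["delta_aic_vs_basic"].mean(),
        })
    return pd.DataFrame(rows)


def scan_lags(
    testday: pd.DataFrame,
    weather: pd.DataFrame,
    mapping: pd.DataFrame,
    trait: str = "milk",
    lags=DEFAULT_LAGS,
    k: int = 5,
    seed: int = 0,
    alias_tol: float = DEFAULT_ALIAS_TOL,
    lookup: ThiLookup | None = None,
    assignment: pd.Series | None = None,
) -> LagScanResult:
    """Fit the basic model and one model per lag in every herd subset.

    The non-THI design block is built once per subset and only the THI
    indicator columns are rebuilt per lag; results are identical to
    independent fits.  Ties in mean AIC resolve to the smaller lag.
    """
    if trait not in ("milk", "scs"):
        raise ValidationError(f"trait must be 'milk' or 'scs', got {trait!r}")
    lags = sorted(int(l) for l in lags)
    if not lags or lags[0] < 0 or lags[-1] > 14:
        raise ValidationError(f"lags must be a non-empty subset of 0..14: {lags}")
    if lookup is None:
        lookup = ThiLookup(weather, mapping)
    if assignment is None:
        assignment = split_subsets(testday, k=k, seed=seed)
    subset_of = testday["herd_id"].map(assignment).to_numpy()

    rows = []
    for s in range(k):
        sub = testday.loc[subset_of == s]
        if len(sub) == 0:
            raise ValidationError(f"subset {s} is empty")
        try:
            table0 = join_lagged_thi(sub, weather, mapping, 0, lookup=lookup)
            y = table0.frame[trait].to_numpy()
            base_design = build_design(table0.frame, include_thi=False,
                                       alias_tol=alias_tol)
            fit_basic = fit_ols(base_design, y)
            rows.append({"subset": s, "lag": BASIC_LABEL,
                         "aic": fit_basic.aic, "delta_aic_vs_basic": 0.0})
            for lag in lags:
                thi = (table0.frame["thi_class"].to_numpy() if lag == 0
                       else lookup.classes_for(sub, lag))
                design = extend_with_factor(base_design, thi)
                fit = fit_ols(design, y)
                rows.append({"subset": s, "lag": lag, "aic": fit.aic,
                             "delta_aic_vs_basic": fit.aic - fit_basic.aic})
        except Exception as exc:
            raise type(exc)(f"subset {s}: {exc}") from exc

    per_fit = pd.DataFrame(rows)
    summary = _summarize(per_fit, k)
    lag_rows = summary[summary["lag"] != BASIC_LABEL]
    means = lag_rows["mean_aic"].to_numpy()
    selected = int(lag_rows["lag"].to_numpy()[int(np.argmin(means))])
    basic_mean = float(
        summary.loc[summary["lag"] == BASIC_LABEL, "mean_aic"].iloc[0])
    basic_preferred = bool(basic_mean < means.min())
    logger.info("lag scan (%s): selected lag %d (mean AIC %.1f; basic %.1f)",
                trait, selected, means.min(), basic_mean)
    return LagScanResult(per_fit=per_fit, summary=summary, selected_lag=selected,
                         basic_preferred=basic_preferred,
                         assignment=assignment, trait=trait)


def summarize_scan(result: LagScanResult) -> pd.DataFrame:
    """Report rows: one per lag (and one basic row) with mean AIC, SE, CI."""
    return result.summary.copy()
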