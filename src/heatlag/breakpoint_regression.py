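"""Heat-stress threshold estimation from per-class least-squares means.

The exposure-response threshold is the breakpoint BP of a continuous
segmented (hinge) regression on the THI-class LSMs y*:

    y* = c + e              when x <= BP
    y* = c + b (x - BP) + e when x >  BP

i.e. flat below the breakpoint and linear above it, continuous at BP (the
implied upper-segment intercept is a = c - b BP).  BP is profiled on a
0.1-unit grid over the interior of the filtered class range, with (c, b)
solved exactly by two-parameter least squares at each candidate; ties take
the smallest BP.

Only well-populated THI classes enter the fit (strictly more than
``min_count`` records), mirroring the instability of LSMs in sparse
extreme classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records_io import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MIN_COUNT = 20_000
GRID_STEP = 0.1
INTERIOR_EXCLUDE = 2     # classes excluded from the BP grid at each end

_NO_BP_SLOPE_TOL = 1e-12


@dataclass
class BreakpointFit:
    """Constrained segmented regression estimate on class LSMs."""

    bp: float            # breakpoint, THI units (nan if no_breakpoint)
    c: float             # plateau level below bp, response units
    b: float             # slope above bp, response units per THI
    a: float             # implied upper-segment intercept, c - b*bp
    rss: float
    n_classes: int
    fitted: pd.DataFrame  # thi_class, lsm, fitted
    no_breakpoint: bool = False


def filter_thi_classes(lsm: pd.DataFrame, min_count: int = DEFAULT_MIN_COUNT,
                       min_classes: int = 4) -> pd.DataFrame:
    """Retain classes with strictly more than ``min_count`` records."""
    out = lsm.loc[lsm["count"] > min_count].reset_index(drop=True)
    dropped = len(lsm) - len(out)
    if dropped:
        logger.info("class filter (count > %d): dropped %d of %d classes",
                    min_count, dropped, len(lsm))
    if len(out) < min_classes:
        raise ValidationError(
            f"only {len(out)} THI classes exceed {min_count} records; "
            f"segmented model unidentifiable")
    return out


def pool_lsms(per_subset_lsms, min_subsets: int = 3) -> pd.DataFrame:
    """Pool per-subset LSM tables: unweighted class means, summed counts.

    Classes present in fewer than ``min_subsets`` subsets are dropped (and
    logged); the reported SE is the across-subset SD / sqrt(m).
    """
    stacked = pd.concat(per_subset_lsms, ignore_index=True)
    g = stacked.groupby("thi_class")
    pooled = pd.DataFrame({
        "thi_class": np.array(sorted(g.groups)),
        "lsm": g["lsm"].mean().to_numpy(),
        "se": (g["lsm"].std(ddof=1) / np.sqrt(g["lsm"].count())).to_numpy(),
        "count": g["count"].sum().to_numpy(),
        "n_subsets": g["lsm"].count().to_numpy(),
    })
    thin = pooled["n_subsets"] < min_subsets
    if thin.any():
        logger.info("pooling: dropped %d class(es) present in < %d subsets: %s",
                    int(thin.sum()), min_subsets,
                    pooled.loc[thin, "thi_class"].tolist()[:10])
        pooled = pooled.loc[~thin].reset_index(drop=True)
    if len(pooled) == 0:
        raise ValidationError("no THI class present in enough subsets to pool")
    return pooled.drop(columns=["n_subsets"])


def fit_segmented(lsm: pd.DataFrame, grid_step: float = GRID_STEP,
                  interior_exclude: int = INTERIOR_EXCLUDE,
                  weights: np.ndarray | None = None) -> BreakpointFit:
    """Zero-slope-below-threshold hinge fit to class LSMs.

    ``weights`` (optional) enables inverse-variance weighting by the LSM
    standard errors; the default is ordinary (unweighted) least squares.
    """
    x = lsm["thi_class"].to_numpy(dtype=float)
    y = lsm["lsm"].to_numpy(dtype=float)
    if len(x) < 4:
        raise ValidationError("segmented fit needs at least 4 THI classes")
    if np.any(np.diff(x) <= 0):
        raise ValidationError("THI classes must be strictly increasing")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    lo = x[interior_exclude]
    hi = x[-interior_exclude - 1]
    if hi <= lo:
        raise ValidationError("too few classes for an interior breakpoint grid")
    grid = lo + grid_step * np.arange(int(round((hi - lo) / grid_step)) + 1)

    # z = max(x - BP, 0) per candidate; profile (c, b) by exact 2x2 solves
    z = np.maximum(x[None, :] - grid[:, None], 0.0)
    sw = w.sum()
    swy = float(w @ y)
    swyy = float(w @ (y * y))
    sz = z @ w
    szz = (z * z) @ w
    szy = z @ (w * y)
    det = sw * szz - sz * sz
    safe = det > 1e-12 * np.maximum(sw * szz, 1.0)
    c_hat = np.where(safe, (szz * swy - sz * szy) / np.where(det == 0, 1, det),
                     swy / sw)
    b_hat = np.where(safe, (sw * szy - sz * swy) / np.where(det == 0, 1, det), 0.0)
    rss = swyy - 2 * (c_hat * swy + b_hat * szy) \
        + c_hat ** 2 * sw + 2 * c_hat * b_hat * sz + b_hat ** 2 * szz
    i = int(np.argmin(rss))   # ascending grid: ties resolve to smallest BP

    bp, c, b = float(grid[i]), float(c_hat[i]), float(b_hat[i])
    fitted_vals = c + b * np.maximum(x - bp, 0.0)
    fitted = pd.DataFrame({"thi_class": x, "lsm": y, "fitted": fitted_vals})
    if abs(b) < _NO_BP_SLOPE_TOL:
        logger.info("segmented fit: slope ~ 0, flagging no-breakpoint")
        return BreakpointFit(bp=float("nan"), c=c, b=0.0, a=c,
                             rss=float(rss[i]), n_classes=len(x),
                             fitted=fitted, no_breakpoint=True)
    return BreakpointFit(bp=bp, c=c, b=b, a=c - b * bp, rss=float(rss[i]),
                         n_classes=len(x), fitted=fitted)
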