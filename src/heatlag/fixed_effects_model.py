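"""Sparse fixed-effects least squares for the test-day model.

The model regresses a test-day response (milk yield or SCS) on purely
categorical fixed effects: herd, calving year, calendar month of the test
day, age-at-calving group, one-day days-in-milk classes, and — unless the
"basic" model is requested — one class per integer THI value at a chosen
exposure lag:

    y = herd + year + month + age_group + dim_class [+ thi_class] + e

All factors are reference-coded against their first (sorted) level, on top
of an explicit intercept.  The normal equations are formed from a sparse
indicator matrix; aliased columns are detected by a pivoted-in-place
Cholesky sweep and dropped deterministically (first-seen columns kept).

AIC uses the full Gaussian likelihood with the residual variance profiled
out:

    AIC = n log(2 pi rss / n) + n + 2 (rank + 1)

(the ``+1`` counts the residual variance).  Only AIC *differences* between
models fitted to the same records are interpreted, and those are invariant
to the additive convention.

Least-squares means (LSMs) for a factor level are the fitted response at
that level with every other factor averaged over its observed levels with
equal weight (the classical GLM/LSMEANS convention).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import solve_triangular

from .records_io import ModelTable, ValidationError

logger = logging.getLogger(__name__)

BASIC_FACTORS = ("herd", "year", "month", "age_group", "dim_class")
THI_FACTOR = "thi_class"

#: relative pivot tolerance below which a design column is declared aliased
DEFAULT_ALIAS_TOL = 1e-10

#: relative RSS below which a fit is flagged as degenerate (AIC undefined)
_DEGENERATE_RSS_RTOL = 1e-12

INTERCEPT = ("(intercept)", "")


@dataclass
class DesignMatrix:
    """Reference-coded sparse indicator design with aliasing resolved."""

    X: sp.csr_matrix                      # all assembled columns
    Xk: sp.csr_matrix                     # retained (non-aliased) columns
    columns: list                         # (factor, level) per assembled column
    kept: np.ndarray                      # bool mask over assembled columns
    R: np.ndarray                         # upper Cholesky factor of kept gram
    gram: np.ndarray                      # dense gram of all assembled columns
    factor_levels: dict                   # factor -> list of observed levels
    level_counts: dict                    # factor -> np.ndarray of level counts
    alias_tol: float

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def rank(self) -> int:
        return int(self.kept.sum())

    @property
    def dropped(self) -> list:
        return [c for c, k in zip(self.columns, self.kept) if not k]


@dataclass
class FitResult:
    """One least-squares fit: labelled coefficients, RSS, rank, AIC."""

    design: DesignMatrix | None
    beta_kept: np.ndarray | None
    rss: float
    n: int
    rank: int
    sigma2_hat: float
    aic: float
    degenerate: bool = False

    @property
    def coefficients(self) -> pd.Series:
        """Coefficients labelled ``factor=level``; aliased columns are 0."""
        full = np.zeros(len(self.design.columns))
        full[self.design.kept] = self.beta_kept
        labels = [f"{f}={lv}" if f != INTERCEPT[0] else f
                  for f, lv in self.design.columns]
        return pd.Series(full, index=labels)


def _cholesky_keep(gram: np.ndarray, tol: float):
    """In-place Cholesky with column dropping.

    Columns whose pivot falls below ``tol * max(diag, 1)`` are aliased
    (linear combinations of earlier columns) and skipped; the first-seen
    column of every dependent set is kept.
    """
    p = gram.shape[0]
    R = np.zeros((p, p))
    keep = np.zeros(p, dtype=bool)
    for j in range(p):
        rj = R[:j, j]
        d = gram[j, j] - rj @ rj
        if d <= tol * max(gram[j, j], 1.0):
            continue
        keep[j] = True
        R[j, j] = math.sqrt(d)
        if j + 1 < p:
            R[j, j + 1:] = (gram[j, j + 1:] - rj @ R[:j, j + 1:]) / R[j, j]
    return R[np.ix_(keep, keep)], keep


def _factor_codes(values: np.ndarray):
    levels, codes = np.unique(values, return_inverse=True)
    return levels, codes.astype(np.int64)


def _assemble(n: int, blocks):
    """CSR indicator matrix from (offset, codes) blocks plus an intercept."""
    rows = [np.arange(n, dtype=np.int64)]
    cols = [np.zeros(n, dtype=np.int64)]
    for offset, codes in blocks:
        mask = codes > 0
        rows.append(np.nonzero(mask)[0].astype(np.int64))
        cols.append(offset + codes[mask] - 1)
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    data = np.ones(r.size)
    ncols = max(int(c.max()) + 1, 1)
    return sp.csr_matrix((data, (r, c)), shape=(n, ncols))


def _finalize(X, columns, factor_levels, level_counts, alias_tol) -> DesignMatrix:
    gram = (X.T @ X).toarray()
    R, kept = _cholesky_keep(gram, alias_tol)
    dropped = [c for c, k in zip(columns, kept) if not k]
    if dropped:
        logger.info("design: dropped %d aliased column(s): %s",
                    len(dropped), dropped[:10])
    Xk = X[:, np.nonzero(kept)[0]].tocsr()
    return DesignMatrix(X=X, Xk=Xk, columns=columns, kept=kept, R=R,
                        gram=gram, factor_levels=factor_levels,
                        level_counts=level_counts, alias_tol=alias_tol)


def build_design(
    table,
    include_thi: bool = True,
    factors=None,
    alias_tol: float = DEFAULT_ALIAS_TOL,
) -> DesignMatrix:
    """Build the reference-coded indicator design for the test-day model.

    ``include_thi=False`` yields the basic (no heat-stress) model.  A factor
    with a single observed level carries no information beyond the intercept
    and is absorbed into it with a warning.
    """
    frame = table.frame if isinstance(table, ModelTable) else table
    if factors is None:
        factors = list(BASIC_FACTORS) + ([THI_FACTOR] if include_thi else [])
    n = len(frame)
    columns = [INTERCEPT]
    blocks = []
    factor_levels: dict = {}
    level_counts: dict = {}
    offset = 1
    for f in factors:
        if frame[f].isna().any():
            raise ValidationError(f"factor {f}: null class labels")
        levels, codes = _factor_codes(frame[f].to_numpy())
        factor_levels[f] = list(levels)
        level_counts[f] = np.bincount(codes, minlength=len(levels))
        if len(levels) == 1:
            logger.warning("factor %s has a single level; absorbed into intercept", f)
            continue
        blocks.append((offset, codes))
        columns.extend((f, lv) for lv in levels[1:])
        offset += len(levels) - 1
    X = _assemble(n, blocks)
    return _finalize(X, columns, factor_levels, level_counts, alias_tol)


def extend_with_factor(
    base: DesignMatrix,
    values: np.ndarray,
    factor: str = THI_FACTOR,
) -> DesignMatrix:
    """Append one categorical factor to an existing design.

    Reuses the cached gram of the base columns so that a lag scan rebuilds
    only the THI block; the result is identical to :func:`build_design` on
    the augmented table (see the equivalence test).
    """
    levels, codes = _factor_codes(np.asarray(values))
    counts = np.bincount(codes, minlength=len(levels))
    factor_levels = dict(base.factor_levels)
    factor_levels[factor] = list(levels)
    level_counts = dict(base.level_counts)
    level_counts[factor] = counts
    columns = list(base.columns)
    if len(levels) == 1:
        logger.warning("factor %s has a single level; absorbed into intercept", factor)
        return _finalize(base.X, columns, factor_levels, level_counts, base.alias_tol)
    n = base.n
    mask = codes > 0
    T = sp.csr_matrix(
        (np.ones(int(mask.sum())), (np.nonzero(mask)[0], codes[mask] - 1)),
        shape=(n, len(levels) - 1),
    )
    X = sp.hstack([base.X, T], format="csr")
    columns.extend((factor, lv) for lv in levels[1:])
    p0 = base.gram.shape[0]
    pt = len(levels) - 1
    gram = np.empty((p0 + pt, p0 + pt))
    gram[:p0, :p0] = base.gram
    cross = (base.X.T @ T).toarray()
    gram[:p0, p0:] = cross
    gram[p0:, :p0] = cross.T
    gram[p0:, p0:] = np.diag(counts[1:].astype(float))
    R, kept = _cholesky_keep(gram, base.alias_tol)
    Xk = X[:, np.nonzero(kept)[0]].tocsr()
    return DesignMatrix(X=X, Xk=Xk, columns=columns, kept=kept, R=R,
                        gram=gram, factor_levels=factor_levels,
                        level_counts=level_counts, alias_tol=base.alias_tol)


def fit_ols(design: DesignMatrix, y) -> FitResult:
    """Least-squares fit via the Cholesky factor of the retained gram."""
    y = np.asarray(y, dtype=float)
    n = design.n
    rank = design.rank
    if y.shape != (n,):
        raise ValidationError(f"response length {y.shape} != {n} rows")
    if n <= rank:
        raise ValidationError(f"model unidentifiable: n={n} <= rank={rank}")
    Xty = design.Xk.T @ y
    z = solve_triangular(design.R, Xty, trans="T", lower=False)
    beta = solve_triangular(design.R, z, lower=False)
    resid = y - design.Xk @ beta
    rss = float(resid @ resid)
    yty = float(y @ y)
    degenerate = rss <= _DEGENERATE_RSS_RTOL * max(yty, 1.0)
    fit = FitResult(design=design, beta_kept=beta, rss=rss, n=n, rank=rank,
                    sigma2_hat=rss / n, aic=np.nan, degenerate=degenerate)
    fit.aic = compute_aic(fit)
    return fit


def compute_aic(fit: FitResult) -> float:
    """Gaussian AIC with profiled residual variance.

    ``AIC = n log(2 pi rss / n) + n + 2 (rank + 1)``.  A perfect
    (zero-RSS) fit has no defined AIC; it is flagged and ``-inf`` returned
    so that degenerate saturated fits sort first but are recognizable.
    """
    if fit.degenerate or fit.rss <= 0.0:
        return -math.inf
    return (fit.n * math.log(2.0 * math.pi * fit.rss / fit.n)
            + fit.n + 2.0 * (fit.rank + 1))


def compute_lsm(fit: FitResult, factor: str = THI_FACTOR) -> pd.DataFrame:
    """Least-squares means for every observed level of ``factor``.

    LSM(level) = intercept + coef(factor=level) + for every other factor the
    unweighted mean of its level effects (reference level contributing 0;
    aliased columns contribute 0).  Standard errors come from the same
    linear contrast and the coefficient covariance with the unbiased
    residual variance rss / (n - rank).

    Returns a frame with columns ``[factor, "lsm", "se", "count"]``, one row
    per observed level; unobserved levels are never extrapolated.
    """
    design = fit.design
    if factor not in design.factor_levels:
        raise ValidationError(f"factor {factor} not present in the fit")
    levels = design.factor_levels[factor]
    kept_cols = [design.columns[i] for i in np.nonzero(design.kept)[0]]
    pk = len(kept_cols)
    base = np.zeros(pk)
    pos_of = {}
    for i, (f, lv) in enumerate(kept_cols):
        if f == INTERCEPT[0]:
            base[i] = 1.0
        elif f == factor:
            pos_of[lv] = i
        else:
            base[i] = 1.0 / len(design.factor_levels[f])
    C = np.tile(base[:, None], (1, len(levels)))
    for j, lv in enumerate(levels):
        i = pos_of.get(lv)
        if i is not None:
            C[i, j] = C[i, j] + 1.0
    lsm = C.T @ fit.beta_kept
    sigma2 = fit.rss / (fit.n - fit.rank) if fit.n > fit.rank else 0.0
    W = solve_triangular(design.R, C, trans="T", lower=False)
    se = np.sqrt(sigma2 * np.sum(W * W, axis=0))
    return pd.DataFrame({
        factor: levels,
        "lsm": lsm,
        "se": se,
        "count": design.level_counts[factor].astype(np.int64),
    })
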