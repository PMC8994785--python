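"""Coherence-versus-fidelity correlation statistics.

Descriptive only: product-moment (Pearson) correlation coefficients and
ordinary least-squares lines between scan-table columns, optionally
stratified by the relative-orientation angle beta, mirroring how
coherence measures are compared against the compass anisotropy.  No
hypothesis testing is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationResult", "pearson_fit", "correlate_scan"]

logger = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    """Raised when either variable has zero variance."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    slope: float
    intercept: float
    n: int
    x_id: str = "x"
    y_id: str = "y"

    def as_dict(self) -> dict:
        return {
            "x": self.x_id, "y": self.y_id, "n": self.n,
            "R": self.r, "slope": self.slope, "intercept": self.intercept,
        }


def pearson_fit(
    x: Sequence[float], y: Sequence[float], x_id: str = "x", y_id: str = "y"
) -> CorrelationResult:
    """Pearson R and the least-squares line y = slope*x + intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-d arrays, n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined: a variable has zero variance"
        )
    fit = stats.linregress(x, y)
    return CorrelationResult(
        r=float(fit.rvalue), slope=float(fit.slope),
        intercept=float(fit.intercept), n=int(x.size), x_id=x_id, y_id=y_id,
    )


def correlate_scan(
    table: pd.DataFrame,
    x_column: str,
    y_column: str,
    beta_bin_edges: Optional[Sequence[float]] = None,
) -> tuple[CorrelationResult, Optional[list[dict]]]:
    """Correlate two scan-table columns, optionally per beta stratum.

    Rows with non-finite entries in either column are dropped (count
    logged).  ``beta_bin_edges`` in degrees; default when stratifying is 12
    bins of 15 degrees.  Strata with fewer than 2 points or zero variance
    are reported with R = None.
    """
    for col in (x_column, y_column):
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in scan table")
    x = table[x_column].to_numpy(dtype=float)
    y = table[y_column].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("dropped %d rows with non-finite entries", n_dropped)
    overall = pearson_fit(x[ok], y[ok], x_column, y_column)

    if beta_bin_edges is None:
        return overall, None
    if "beta" not in table.columns:
        raise KeyError("beta stratification requires a 'beta' column")
    edges = np.asarray(beta_bin_edges, dtype=float)
    beta = table["beta"].to_numpy(dtype=float)[ok]
    xs, ys = x[ok], y[ok]
    strata = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (beta >= lo) & (beta < hi if hi < edges[-1] else beta <= hi)
        rec: dict = {"beta_lo": float(lo), "beta_hi": float(hi),
                     "n": int(sel.sum())}
        try:
            res = pearson_fit(xs[sel], ys[sel], x_column, y_column)
            rec.update(R=res.r, slope=res.slope, intercept=res.intercept)
        except (ValueError, UndefinedCorrelationError):
            rec.update(R=None, slope=None, intercept=None)
        strata.append(rec)
    return overall, strata


def default_beta_edges() -> np.ndarray:
    """12 strata of 15 degrees covering [0, 180]."""
    return np.linspace(0.0, 180.0, 13)
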