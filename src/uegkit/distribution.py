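"""Dynamic-range summaries of per-gene quantile-rank distributions.

Each gene's distribution of within-sample percentile ranks across the
compendium is summarized by its empirical percentiles on a grid (Q5 ... Q95
by default), its median (Q50), its interquartile range (IQR = Q75 - Q25,
the expression-variability measure) and its adjusted Fisher-Pearson sample
skewness

    Skew = n / ((n-1)(n-2)) * sum(((x - mean) / s)^3),

with s the sample (ddof=1) standard deviation. Negative skewness means the
mass sits toward the high-expression end, the signature of a ubiquitously
expressed gene.

Percentiles use linear interpolation between order statistics (numpy's
default, Hyndman-Fan type 7); the choice matters because the downstream
cluster boundaries depend on it, so it is fixed and documented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_GRID = tuple(range(5, 100, 5))


def skewness(values, axis: int = -1) -> np.ndarray | float:
    """Adjusted Fisher-Pearson sample skewness along *axis*.

    Requires n >= 3 and positive spread; degenerate inputs yield NaN with a
    warning rather than an error, since never-expressed genes legitimately
    have constant (all-zero) rank rows.
    """
    x = np.asarray(values, dtype=float)
    n = x.shape[axis]
    if n < 3:
        return np.full(x.sum(axis=axis).shape, np.nan) if x.ndim > 1 else float("nan")
    mean = x.mean(axis=axis, keepdims=True)
    s = x.std(axis=axis, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z3 = ((x - mean) / s) ** 3
        out = n / ((n - 1) * (n - 2)) * z3.sum(axis=axis)
    bad = ~np.isfinite(np.squeeze(s, axis=axis))
    if np.any(bad):
        logger.debug("skewness undefined (zero spread) for %d row(s)", int(np.sum(bad)))
    out = np.where(np.squeeze(s, axis=axis) > 0, out, np.nan)
    return float(out) if out.ndim == 0 else out


@dataclass
class DynamicRangeMatrix:
    """Per-gene percentile vectors plus distribution summaries.

    ``percentiles`` holds one row per gene with columns ``q05 ... q95`` (for
    the default grid); ``summary`` holds q50, iqr, skewness and n.
    """

    percentiles: pd.DataFrame
    summary: pd.DataFrame
    grid: tuple
    n: int

    @property
    def gene_ids(self) -> list[str]:
        return list(self.percentiles.index)

    def to_frame(self) -> pd.DataFrame:
        summary = self.summary
        if "q50" in self.percentiles.columns:
            summary = summary.drop(columns="q50")
        return pd.concat([self.percentiles, summary], axis=1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DynamicRangeMatrix":
        # grid columns are the leading strictly increasing q<percentile> run;
        # a later q50 (grid without 50) belongs to the summary instead
        pcols: list[str] = []
        for c in df.columns:
            if not (c.startswith("q") and c[1:].isdigit()):
                break
            if pcols and int(c[1:]) <= int(pcols[-1][1:]):
                break
            pcols.append(c)
        grid = tuple(int(c[1:]) for c in pcols)
        summary = df[[c for c in ("q50", "iqr", "skewness", "n") if c in df.columns]]
        if "q50" not in summary.columns and "q50" in pcols:
            summary = summary.assign(q50=df["q50"])
        n = int(df["n"].iloc[0]) if "n" in df.columns else 0
        return cls(df[pcols], summary, grid, n)


class DynamicRangeSummarizer(TransformerMixin, BaseEstimator):
    """Transform gene rows into their empirical-percentile vectors.

    Parameters
    ----------
    grid : sequence of percentiles, strictly increasing, within (0, 100).
    """

    def __init__(self, grid=DEFAULT_GRID):
        self.grid = grid

    def _validate_grid(self):
        grid = tuple(self.grid)
        if any(not (0 < g < 100) for g in grid):
            raise ValueError("grid percentiles must lie in (0, 100)")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("grid must be strictly increasing")
        return grid

    def fit(self, X, y=None):
        self.grid_ = self._validate_grid()
        X = np.asarray(X, dtype=float)
        if X.shape[1] < 2:
            raise ValueError("at least 2 samples are required for percentiles")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        index = None
        if isinstance(X, pd.DataFrame):
            index, X = X.index, X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("percentile vectors require finite input")
        pct = np.percentile(X, list(self.grid_), axis=1).T
        cols = [f"q{g:02d}" for g in self.grid_]
        if index is not None:
            return pd.DataFrame(pct, index=index, columns=cols)
        return pct


def dynamic_range(
    qmatrix: ExpressionMatrix,
    grid=DEFAULT_GRID,
    on_raw: bool = False,
) -> DynamicRangeMatrix:
    """Summarize each gene's rank distribution into a dynamic-range vector.

    By default this operates on quantile ranks (relative expression); pass a
    TPM/RPKM matrix with ``on_raw=True`` to summarize raw normalized values
    instead (skewness and IQR then live on that scale).
    """
    if on_raw:
        qmatrix.require_unit("TPM", "RPKM")
    else:
        qmatrix.require_unit("quantile")
    n = qmatrix.n_samples
    if n < 2:
        raise ValueError("dynamic_range requires at least 2 samples")
    summarizer = DynamicRangeSummarizer(grid=grid)
    pct = summarizer.fit_transform(qmatrix.values)
    arr = qmatrix.values.to_numpy(dtype=float)
    q25, q50, q75 = np.percentile(arr, [25, 50, 75], axis=1)
    skew = skewness(arr, axis=1) if n >= 3 else np.full(arr.shape[0], np.nan)
    summary = pd.DataFrame(
        {"q50": q50, "iqr": q75 - q25, "skewness": skew, "n": n},
        index=qmatrix.values.index,
    )
    return DynamicRangeMatrix(
        percentiles=pct, summary=summary, grid=tuple(grid), n=n
    )
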