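"""Sample-wise quantile transformation of normalized expression.

Within each sample, every nonzero expression value x_j is replaced by

    Q_j = |{i : 0 < x_i <= x_j}| / |{i : 0 < x_i}|

and zeros stay exactly zero. Ties share the maximum rank (the "<=" count),
so the largest detected gene in a sample always maps to exactly 1. The
denominator is the sample's own count of detected genes, so transcriptome
size varies by sample. This is a within-sample rank transform, not the
cross-sample quantile normalization that maps columns onto a shared
reference distribution.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


class QuantileRankTransformer(TransformerMixin, BaseEstimator):
    """Stateless per-column rank transform (genes × samples orientation).

    Each column is transformed independently in O(n log n) by sorting; a
    quadratic reference implementation lives in the test suite as the oracle.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[0]
        return self

    def transform(self, X) -> np.ndarray:
        index = columns = None
        if isinstance(X, pd.DataFrame):
            index, columns = X.index, X.columns
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2D genes × samples matrix")
        if X.size and X.min() < 0:
            raise ValueError("expression values must be non-negative")
        out = np.zeros_like(X, dtype=float)
        n_empty = 0
        for j in range(X.shape[1]):
            col = X[:, j]
            nz = col > 0
            n = int(nz.sum())
            if n == 0:
                n_empty += 1
                continue
            out[nz, j] = rankdata(col[nz], method="max") / n
        if n_empty:
            logger.warning(
                "%d sample(s) had no detected genes; their ranks are all zero",
                n_empty,
            )
        if index is not None:
            return pd.DataFrame(out, index=index, columns=columns)
        return out


def quantile_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Apply the sample-wise quantile transform to a TPM or RPKM matrix."""
    matrix.require_unit("TPM", "RPKM")
    ranks = QuantileRankTransformer().fit_transform(matrix.values)
    return ExpressionMatrix(ranks, "quantile")
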