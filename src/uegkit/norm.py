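"""Transcript collapse, TPM/RPKM normalization and reference-gene QC.

TPM_g = 1e6 * (c_g / l_g) / sum_i(c_i / l_i), per sample.
RPKM_g = 1e9 * c_g / (l_g * N), N the sample's total count.

A sample is low quality when any lowly expressed internal reference gene
measures exactly zero in it; such samples are removed before specificity
analysis. The conventional human reference trio is GUSB/HPRT1/HMBS, but any
gene list may be supplied (the synthetic compendium plants its own).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import ExpressionMatrix, QCReport, validate_lengths

logger = logging.getLogger(__name__)

#: Conventional lowly expressed internal reference genes used for sample QC.
DEFAULT_REFERENCE_GENES = ("GUSB", "HPRT1", "HMBS")


class CountNormalizer(TransformerMixin, BaseEstimator):
    """Length/depth normalization of read counts to TPM or RPKM.

    scikit-learn style transformer over genes × samples count frames. The
    transform is stateless; ``fit`` only validates the length table against
    the input's gene IDs.

    Parameters
    ----------
    lengths : pandas.Series
        Gene ID → length in base pairs.
    method : {"tpm", "rpkm"}
    """

    def __init__(self, lengths=None, method: str = "tpm"):
        self.lengths = lengths
        self.method = method

    def fit(self, X: pd.DataFrame, y=None):
        if self.method not in ("tpm", "rpkm"):
            raise ValueError(f"method must be 'tpm' or 'rpkm', got {self.method!r}")
        if self.lengths is None:
            raise ValueError("a gene-length table is required")
        lengths = validate_lengths(pd.Series(self.lengths))
        missing = X.index.difference(lengths.index)
        if len(missing):
            raise KeyError(f"missing gene length for {missing[0]!r}")
        self.lengths_ = lengths.reindex(X.index)
        self.n_features_in_ = X.shape[0]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "lengths_")
        counts = X.to_numpy(dtype=float)
        lens = self.lengths_.reindex(X.index).to_numpy()[:, None]
        if self.method == "tpm":
            rate = counts / lens
            denom = rate.sum(axis=0, keepdims=True)
            out = _safe_scale(rate, denom, 1e6)
        else:
            depth = counts.sum(axis=0, keepdims=True)
            out = _safe_scale(counts / lens, depth, 1e9)
        return pd.DataFrame(out, index=X.index, columns=X.columns)


def _safe_scale(num: np.ndarray, denom: np.ndarray, scale: float) -> np.ndarray:
    zero_cols = denom == 0
    if zero_cols.any():
        logger.warning(
            "%d all-zero sample column(s) kept as zeros through normalization",
            int(zero_cols.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = scale * num / denom
    out[:, zero_cols.ravel()] = 0.0
    return out


def collapse_to_genes(matrix: ExpressionMatrix, id_map: pd.Series) -> ExpressionMatrix:
    """Collapse transcript rows to genes, taking the per-sample maximum.

    Rows absent from *id_map* are dropped (with a logged count), mirroring
    lossy transcript → gene ID conversion.
    """
    id_map = pd.Series(id_map)
    mapped = matrix.values.index.intersection(id_map.index)
    if len(mapped) == 0:
        raise ValueError("no matrix row IDs found in the transcript→gene map")
    dropped = matrix.n_genes - len(mapped)
    if dropped:
        logger.info("collapse_to_genes: dropped %d unmapped transcript rows", dropped)
    sub = matrix.values.loc[mapped]
    genes = id_map.reindex(mapped)
    collapsed = sub.groupby(genes.to_numpy()).max()
    collapsed.index.name = matrix.values.index.name
    return ExpressionMatrix(collapsed, matrix.unit)


def tpm_normalize(counts: ExpressionMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Transcripts-per-million normalization of a counts matrix."""
    counts.require_unit("counts")
    out = CountNormalizer(lengths=lengths, method="tpm").fit_transform(counts.values)
    return ExpressionMatrix(out, "TPM")


def rpkm_normalize(counts: ExpressionMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Reads-per-kilobase-per-million normalization of a counts matrix."""
    counts.require_unit("counts")
    out = CountNormalizer(lengths=lengths, method="rpkm").fit_transform(counts.values)
    return ExpressionMatrix(out, "RPKM")


def qc_filter(
    matrix: ExpressionMatrix, ref_genes
) -> tuple[ExpressionMatrix, QCReport]:
    """Remove samples in which any reference gene measures exactly zero."""
    ref_genes = list(ref_genes)
    missing = [g for g in ref_genes if g not in matrix.values.index]
    if missing:
        raise KeyError(f"reference gene(s) absent from matrix: {missing}")
    ref = matrix.values.loc[ref_genes]
    zero = ref.to_numpy() == 0
    removed_mask = zero.any(axis=0)
    samples = np.asarray(matrix.sample_ids)
    removed = [str(s) for s in samples[removed_mask]]
    kept = [str(s) for s in samples[~removed_mask]]
    if not kept:
        raise ValueError("QC filter removed every sample")
    flags = {
        s: [g for g, z in zip(ref_genes, zero[:, j]) if z]
        for j, s in enumerate(samples)
        if removed_mask[j]
    }
    report = QCReport(kept=kept, removed=removed, reference_genes=ref_genes, flags=flags)
    return matrix.subset_samples(kept), report
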