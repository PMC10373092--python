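"""Core in-memory containers for expression compendia.

Everything downstream operates on a genes × samples orientation. A matrix
always carries its unit (``counts``, ``TPM``, ``RPKM`` or ``quantile``) so
that operations can refuse inputs produced at the wrong pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Units an :class:`ExpressionMatrix` may declare.
UNITS = ("counts", "TPM", "RPKM", "quantile")


@dataclass
class ExpressionMatrix:
    """A genes × samples expression matrix with a declared unit.

    Parameters
    ----------
    values
        Non-negative matrix with gene IDs as the index and sample IDs as
        columns. Both must be unique.
    unit
        One of :data:`UNITS`.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene IDs in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample IDs in expression matrix")
        arr = self.values.to_numpy()
        if arr.size and np.nanmin(arr) < 0:
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_unit(self, *units: str) -> None:
        """Raise ``ValueError`` unless the declared unit is one of *units*."""
        if self.unit not in units:
            raise ValueError(
                f"operation requires unit in {units}, got {self.unit!r}"
            )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.unit)


@dataclass
class QCReport:
    """Outcome of the reference-gene sample filter."""

    kept: list[str]
    removed: list[str]
    reference_genes: list[str]
    #: per-sample mapping to the list of reference genes measured at zero
    flags: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kept": self.kept,
            "removed": self.removed,
            "reference_genes": self.reference_genes,
            "flags": self.flags,
            "n_kept": len(self.kept),
            "n_removed": len(self.removed),
        }


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-annotation frame and return it indexed by sample ID.

    Required columns: ``tissue_group``, ``source_type``, ``study_id``; the
    sample ID is either the index or a ``sample_id`` column.
    """
    ann = annotation.copy()
    if "sample_id" in ann.columns:
        ann = ann.set_index("sample_id")
    required = {"tissue_group", "source_type", "study_id"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    if ann.index.has_duplicates:
        raise ValueError("duplicate sample IDs in annotation")
    return ann


def validate_lengths(lengths: pd.Series) -> pd.Series:
    """Check a gene-length table (gene ID → length in bp)."""
    lengths = pd.Series(lengths)
    if lengths.index.has_duplicates:
        raise ValueError("duplicate gene IDs in length table")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"non-positive gene length for {bad!r}")
    return lengths.astype(float)
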