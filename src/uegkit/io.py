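"""Readers and writers for the plain-text formats the pipeline consumes.

Dense matrices travel as TSV/CSV with a header row of sample IDs and a first
column of gene IDs; sparse matrices as MatrixMarket with ``.rows``/``.cols``
ID sidecars. All auxiliary tables (lengths, ID maps, annotations, gene lists)
are TSV.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import ExpressionMatrix, validate_annotation, validate_lengths


def read_matrix(path: str, unit: str, sep: str | None = None) -> ExpressionMatrix:
    """Read a dense genes × samples matrix from TSV/CSV."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df, unit)


def write_matrix(matrix: ExpressionMatrix, path: str, sep: str = "\t") -> None:
    matrix.values.to_csv(path, sep=sep, index_label="gene_id")


def read_mtx(path: str, unit: str) -> ExpressionMatrix:
    """Read a MatrixMarket matrix with ``<path>.rows`` / ``<path>.cols`` sidecars."""
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    base = str(path)
    genes = _read_id_file(base + ".rows")
    samples = _read_id_file(base + ".cols")
    df = pd.DataFrame(np.asarray(mat, dtype=float), index=genes, columns=samples)
    return ExpressionMatrix(df, unit)


def write_mtx(matrix: ExpressionMatrix, path: str) -> None:
    scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(matrix.values.to_numpy()))
    # mmwrite appends .mtx when the suffix is missing
    actual = str(path) if str(path).endswith(".mtx") else str(path) + ".mtx"
    _write_id_file(actual + ".rows", matrix.gene_ids)
    _write_id_file(actual + ".cols", matrix.sample_ids)


def _read_id_file(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def _write_id_file(path: str, ids) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(str(i) for i in ids) + "\n")


def read_lengths(path: str) -> pd.Series:
    """Read a gene-length TSV (columns: gene_id, length)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="length")
    return validate_lengths(s)


def write_lengths(lengths: pd.Series, path: str) -> None:
    pd.DataFrame({"gene_id": lengths.index, "length": lengths.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_id_map(path: str) -> pd.Series:
    """Read a transcript → gene map TSV (columns: transcript_id, gene_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="gene_id")


def read_annotation(path: str) -> pd.DataFrame:
    """Read a sample-annotation TSV (sample_id, tissue_group, source_type, study_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_annotation(df)


def write_annotation(annotation: pd.DataFrame, path: str) -> None:
    annotation.to_csv(path, sep="\t", index_label="sample_id")


def read_gene_list(path: str) -> list[str]:
    """Read a candidate gene list: one ID per line, ``#`` comments allowed."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.append(line)
    return genes


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
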