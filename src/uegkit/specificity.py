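"""Detection calls, global expression specificity φ and summary tables.

Global expression specificity of a gene is the fraction of transcriptomes in
which it is called expressed at a stated detection threshold:

    φ_g = (# transcriptomes expressing g) / (# transcriptomes),

so φ = 1 marks a ubiquitously expressed gene and φ near 0 a specifically
expressed one. Detection is inclusive (value >= threshold); the four
conventional presets are TPM >= 0.1 (the GTEx choice), TPM >= 1.0,
RPKM >= 0.3 and RPKM >= 1.0.

Tissue-based specificity is the classical stratified variant: a tissue
counts as expressing a gene when at least 80% of its annotated samples
detect it, and the statistic is the fraction of expressing tissues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, validate_annotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionThreshold:
    """A minimum normalized expression value for calling a gene expressed."""

    unit: str
    value: float

    def __post_init__(self):
        if self.unit not in ("TPM", "RPKM"):
            raise ValueError(f"threshold unit must be TPM or RPKM, got {self.unit!r}")
        if not self.value > 0:
            raise ValueError("threshold value must be positive")

    @property
    def name(self) -> str:
        return f"{self.unit}:{self.value:g}"

    @classmethod
    def parse(cls, text: str) -> "DetectionThreshold":
        unit, value = text.split(":")
        return cls(unit=unit.strip(), value=float(value))


#: The four conventional detection-threshold presets.
PRESET_THRESHOLDS = (
    DetectionThreshold("TPM", 0.1),
    DetectionThreshold("TPM", 1.0),
    DetectionThreshold("RPKM", 0.3),
    DetectionThreshold("RPKM", 1.0),
)


@dataclass
class DetectionMatrix:
    """Boolean expressed/not-expressed calls at a named threshold."""

    values: pd.DataFrame  # bool, genes × samples
    threshold: DetectionThreshold

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def detect(matrix: ExpressionMatrix, threshold: DetectionThreshold) -> DetectionMatrix:
    """Call each gene expressed in each sample when value >= threshold."""
    matrix.require_unit(threshold.unit)
    calls = matrix.values >= threshold.value
    return DetectionMatrix(values=calls, threshold=threshold)


def global_specificity(detection: DetectionMatrix) -> pd.Series:
    """Per-gene φ: the row mean of the detection matrix."""
    if detection.values.shape[1] < 1:
        raise ValueError("at least one sample is required")
    phi = detection.values.mean(axis=1)
    phi.name = f"phi@{detection.threshold.name}"
    return phi


def tissue_specificity(
    detection: DetectionMatrix,
    annotation: pd.DataFrame,
    tissue_expressed_frac: float = 0.8,
) -> pd.Series:
    """Fraction of annotated tissue groups expressing each gene.

    A tissue expresses a gene when at least ``tissue_expressed_frac`` of its
    samples detect it (inclusive >=). Only annotated samples participate.
    """
    ann = validate_annotation(annotation)
    missing = ann.index.difference(detection.values.columns)
    if len(missing):
        raise KeyError(f"annotated sample(s) absent from detection matrix: {list(missing)[:5]}")
    groups = ann.groupby("tissue_group").groups
    groups = {t: list(s) for t, s in groups.items() if len(s) > 0}
    if not groups:
        raise ValueError("no non-empty tissue groups in annotation")
    expressing = pd.DataFrame(
        {
            t: detection.values[samples].mean(axis=1) >= tissue_expressed_frac
            for t, samples in groups.items()
        }
    )
    ts = expressing.mean(axis=1)
    ts.name = "tissue_specificity"
    return ts


def transcriptome_sizes(detection: DetectionMatrix) -> tuple[pd.Series, dict]:
    """Per-sample expressed-gene counts, with median and central-80% interval."""
    sizes = detection.values.sum(axis=0)
    sizes.name = f"size@{detection.threshold.name}"
    summary = {
        "median": float(np.median(sizes)) if len(sizes) else float("nan"),
        "p10": float(np.percentile(sizes, 10)) if len(sizes) else float("nan"),
        "p90": float(np.percentile(sizes, 90)) if len(sizes) else float("nan"),
        "n_genes": int(detection.values.shape[0]),
        "n_samples": int(detection.values.shape[1]),
    }
    return sizes, summary


DEFAULT_BREAKPOINTS = (0.2, 0.4, 0.6, 0.8)


def interval_labels(breakpoints=DEFAULT_BREAKPOINTS) -> list[str]:
    bp = sorted(breakpoints)
    edges = [0.0, *bp, 1.0]
    return [f"{lo:g}-{hi:g}" for lo, hi in zip(edges[:-1], edges[1:])][::-1]


def _assign_interval(phi: np.ndarray, breakpoints) -> np.ndarray:
    """Interval index per gene, 0 = top interval.

    The top interval is closed on its lower edge (phi >= top breakpoint,
    matching the inclusive ">= 0.8" convention); lower intervals take
    (lower, upper], with [0, lowest] at the bottom.
    """
    bp = sorted(breakpoints)
    edges = [0.0, *bp, 1.0]
    k = len(edges) - 1  # number of intervals
    out = np.empty(phi.shape, dtype=int)
    out.fill(k - 1)
    top = bp[-1]
    for rank in range(k):
        if rank == 0:
            mask = phi >= top
        else:
            lo, hi = edges[k - 1 - rank], edges[k - rank]
            mask = (phi > lo) & (phi <= hi) & (phi < top)
        out[mask] = rank
    return out


def interval_table(
    phi: pd.Series,
    breakpoints=DEFAULT_BREAKPOINTS,
    gene_sets: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Count genes per specificity interval, per optional named gene set.

    Returns one row per set (plus ``all_genes``) with per-interval counts,
    percentages, the set total and a ``missing`` tally for set members not
    present in *phi*.
    """
    arr = phi.to_numpy(dtype=float)
    if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
        raise ValueError("phi values must lie in [0, 1]")
    labels = interval_labels(breakpoints)
    sets: dict[str, list[str]] = {"all_genes": list(phi.index)}
    if gene_sets:
        sets.update({k: list(v) for k, v in gene_sets.items()})
    rows = []
    for name, members in sets.items():
        present = [g for g in members if g in phi.index]
        n_missing = len(members) - len(present)
        idx = _assign_interval(phi.loc[present].to_numpy(dtype=float), breakpoints)
        counts = np.bincount(idx, minlength=len(labels)) if present else np.zeros(len(labels), int)
        total = int(counts.sum())
        row = {"set": name}
        for lab, c in zip(labels, counts):
            row[f"n[{lab}]"] = int(c)
            row[f"pct[{lab}]"] = 100.0 * c / total if total else 0.0
        row["total"] = total
        row["missing"] = n_missing
        rows.append(row)
    return pd.DataFrame(rows).set_index("set")


def specificity_table(
    matrices: dict[str, ExpressionMatrix],
    thresholds=PRESET_THRESHOLDS,
    annotation: pd.DataFrame | None = None,
    tissue_expressed_frac: float = 0.8,
    tissue_threshold: DetectionThreshold = DetectionThreshold("TPM", 0.1),
) -> pd.DataFrame:
    """One row per gene: φ at each applicable threshold, plus tissue specificity.

    *matrices* maps unit name ("TPM"/"RPKM") to the normalized matrix;
    thresholds whose unit has no matrix are skipped with a log message.
    """
    cols = {}
    for thr in thresholds:
        if thr.unit not in matrices:
            logger.info("no %s matrix supplied; skipping threshold %s", thr.unit, thr.name)
            continue
        cols[f"phi@{thr.name}"] = global_specificity(detect(matrices[thr.unit], thr))
    table = pd.DataFrame(cols)
    if annotation is not None:
        det = detect(matrices[tissue_threshold.unit], tissue_threshold)
        ann = validate_annotation(annotation)
        ann = ann.loc[ann.index.intersection(det.values.columns)]
        table["tissue_specificity"] = tissue_specificity(
            det, ann, tissue_expressed_frac
        )
    table.index.name = "gene_id"
    return table
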