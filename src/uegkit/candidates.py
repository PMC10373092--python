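"""Candidate-gene evaluation: ubiquity combined with group-restricted repression.

A disallowed gene is a ubiquitously expressed gene that is selectively
repressed in one or a few cell types (the classic examples being LDHA and
SLC16A1 in pancreatic islet beta cells). Given a candidate list, this module
reports each gene's global specificity, variability, dynamic range and
per-tissue-group detection rates, and assigns a verdict:

- ``constitutive``:        φ@TPM:0.1 >= 0.8 and IQR <= 0.2
- ``variable_ubiquitous``: φ@TPM:0.1 >= 0.8 and IQR > 0.2
- ``restricted``:          φ@TPM:0.1 < 0.8
- ``not_found``:           gene absent from the compendium

Constitutive genes whose detection rate drops below ``repressed_rate_cut``
in some group are additionally flagged with those groups — the signature of
candidate disallowance worth following up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import validate_annotation
from .distribution import DynamicRangeMatrix
from .specificity import DetectionMatrix

logger = logging.getLogger(__name__)

VERDICTS = ("constitutive", "variable_ubiquitous", "restricted", "not_found")


def per_group_detection(
    detection: DetectionMatrix,
    annotation: pd.DataFrame,
    genes: list[str],
) -> pd.DataFrame:
    """Gene × tissue-group detection-rate matrix.

    Unknown genes yield all-NaN rows (reported as ``not_found`` downstream,
    not an error).
    """
    ann = validate_annotation(annotation)
    ann = ann.loc[ann.index.intersection(detection.values.columns)]
    groups = {t: list(s) for t, s in ann.groupby("tissue_group").groups.items()}
    if not groups:
        raise ValueError("annotation covers no tissue group")
    rates = pd.DataFrame(index=list(genes), columns=sorted(groups), dtype=float)
    present = [g for g in genes if g in detection.values.index]
    for t in sorted(groups):
        sub = detection.values.loc[present, groups[t]]
        rates.loc[present, t] = sub.mean(axis=1).to_numpy()
    missing = set(genes) - set(present)
    if missing:
        logger.info("%d candidate gene(s) not found in the matrix", len(missing))
    return rates


@dataclass
class CandidateReport:
    """Per-candidate metrics, verdicts and repressed-group flags."""

    table: pd.DataFrame  # per gene: phi cols, iqr, skewness, verdict, flags
    group_rates: pd.DataFrame
    dynamic_ranges: pd.DataFrame


def evaluate_candidates(
    genes: list[str],
    spec_table: pd.DataFrame,
    drm: DynamicRangeMatrix,
    group_rates: pd.DataFrame,
    phi_column: str = "phi@TPM:0.1",
    ueg_cut: float = 0.8,
    iqr_cut: float = 0.2,
    repressed_rate_cut: float = 0.5,
) -> CandidateReport:
    """Assign a verdict to each candidate and flag repressed groups.

    Thresholds deliberately reuse the module-wide ubiquity cut (0.8) and
    low-variability band (0.2) so that verdicts agree with the five-way
    category scheme and the LoVarUEG gate.
    """
    rows = []
    for g in genes:
        row: dict = {"gene_id": g}
        if g not in spec_table.index or g not in drm.summary.index:
            row.update(verdict="not_found", phi=np.nan, iqr=np.nan, skewness=np.nan)
            row["repressed_groups"] = ""
            rows.append(row)
            continue
        phi = float(spec_table.loc[g, phi_column])
        iqr = float(drm.summary.loc[g, "iqr"])
        row["phi"] = phi
        for c in spec_table.columns:
            row[c] = float(spec_table.loc[g, c])
        row["iqr"] = iqr
        row["skewness"] = float(drm.summary.loc[g, "skewness"])
        if phi >= ueg_cut:
            row["verdict"] = "constitutive" if iqr <= iqr_cut else "variable_ubiquitous"
        else:
            row["verdict"] = "restricted"
        flagged = []
        if phi >= ueg_cut and g in group_rates.index:
            r = group_rates.loc[g]
            flagged = [t for t in group_rates.columns if r[t] < repressed_rate_cut]
        row["repressed_groups"] = ",".join(map(str, flagged))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("gene_id")
    present = [g for g in genes if g in drm.percentiles.index]
    return CandidateReport(
        table=table,
        group_rates=group_rates,
        dynamic_ranges=drm.percentiles.loc[present],
    )
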