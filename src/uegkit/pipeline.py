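"""End-to-end orchestration: counts → TPM → QC → ranks → φ → clusters → LoVarUEGs.

The pipeline is driven by a validated config mapping with sections
``input``, ``thresholds``, ``grid``, ``clustering``, ``categories``,
``lovar``, ``output`` and ``seed``; unknown keys anywhere raise before any
computation. Every stage writes its artifact under the output directory and
the run closes with a JSON manifest (package version, seed, thresholds,
stage outputs).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from . import io as ueg_io
from .candidates import evaluate_candidates, per_group_detection
from .cluster import (
    CategoryAssignment,
    ClusterResult,
    LoVarSet,
    assign_categories,
    cluster_genes,
    select_lovar,
)
from .containers import ExpressionMatrix, QCReport
from .distribution import DEFAULT_GRID, DynamicRangeMatrix, dynamic_range
from .norm import qc_filter, rpkm_normalize, tpm_normalize
from .quantile import quantile_transform
from .simulate import SimConfig, candidate_config, demo_config, generate, qc_reference_genes
from .specificity import DetectionThreshold, detect, specificity_table, transcriptome_sizes

logger = logging.getLogger(__name__)

_SECTION_KEYS = {
    "input": {"preset", "counts", "lengths", "annotation", "ref_genes", "candidates"},
    "thresholds": None,  # list of "UNIT:value" strings
    "grid": None,  # list of percentiles
    "clustering": {"method", "damping", "preference", "n_clusters"},
    "categories": {"ueg_cut", "seg_cut"},
    "lovar": {"iqr_cut", "outlier_rule", "z_cut", "fold_cap_pct"},
    "output": {"dir"},
    "seed": None,
}


def validate_config(config: dict) -> dict:
    """Reject unknown keys before any computation; fill defaults."""
    unknown = set(config) - set(_SECTION_KEYS)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for section, allowed in _SECTION_KEYS.items():
        if allowed is None or section not in config:
            continue
        sub = config[section]
        if not isinstance(sub, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        extra = set(sub) - allowed
        if extra:
            raise ValueError(f"unknown key(s) in config section {section!r}: {sorted(extra)}")
    cfg = dict(config)
    cfg.setdefault("input", {"preset": "demo"})
    cfg.setdefault("thresholds", ["TPM:0.1", "TPM:1.0"])
    cfg.setdefault("grid", list(DEFAULT_GRID))
    cfg.setdefault("clustering", {})
    cfg.setdefault("categories", {})
    cfg.setdefault("lovar", {})
    cfg.setdefault("output", {})
    cfg.setdefault("seed", 0)
    if "output" in cfg and cfg["output"].get("dir") is None:
        cfg["output"] = {**cfg["output"], "dir": None}
    return cfg


@dataclass
class PipelineResult:
    """All in-memory artifacts of one run."""

    tpm: ExpressionMatrix
    qc_report: QCReport
    ranks: ExpressionMatrix
    spec_table: pd.DataFrame
    drm: DynamicRangeMatrix
    clusters: ClusterResult
    categories: CategoryAssignment
    lovar: LoVarSet
    sizes_summary: dict
    truth: object | None = None
    candidate_report: object | None = None
    manifest: dict = field(default_factory=dict)


def _load_inputs(input_cfg: dict, seed: int):
    preset = input_cfg.get("preset")
    if preset is not None:
        maker = {"demo": demo_config, "candidates": candidate_config}.get(preset)
        if maker is None:
            raise ValueError(f"unknown preset {preset!r}")
        counts, lengths, annotation, truth = generate(maker(seed=seed))
        ref_genes = input_cfg.get("ref_genes") or qc_reference_genes(truth)
        candidates = input_cfg.get("candidates")
        if candidates is None and preset == "candidates":
            candidates = truth.gene_ids("disallowed")
        return counts, lengths, annotation, ref_genes, candidates, truth
    for key in ("counts", "lengths"):
        if key not in input_cfg:
            raise ValueError(f"config input section needs {key!r} (or a preset)")
    counts = ueg_io.read_matrix(input_cfg["counts"], unit="counts")
    lengths = ueg_io.read_lengths(input_cfg["lengths"])
    annotation = (
        ueg_io.read_annotation(input_cfg["annotation"])
        if "annotation" in input_cfg
        else None
    )
    ref_genes = input_cfg.get("ref_genes")
    candidates = input_cfg.get("candidates")
    if isinstance(candidates, str):
        candidates = ueg_io.read_gene_list(candidates)
    return counts, lengths, annotation, ref_genes, candidates, None


def run_pipeline(config: dict) -> PipelineResult:
    """Run every stage and (optionally) write the artifacts plus a manifest."""
    cfg = validate_config(config)
    seed = int(cfg["seed"])
    thresholds = [DetectionThreshold.parse(t) for t in cfg["thresholds"]]
    counts, lengths, annotation, ref_genes, candidates, truth = _load_inputs(
        cfg["input"], seed
    )

    units_needed = {t.unit for t in thresholds}
    matrices: dict[str, ExpressionMatrix] = {}
    tpm = tpm_normalize(counts, lengths)
    matrices["TPM"] = tpm
    if "RPKM" in units_needed:
        matrices["RPKM"] = rpkm_normalize(counts, lengths)

    if ref_genes:
        tpm, qc_report = qc_filter(tpm, ref_genes)
        matrices = {
            u: m.subset_samples(qc_report.kept) for u, m in matrices.items()
        }
        matrices["TPM"] = tpm
    else:
        qc_report = QCReport(
            kept=list(tpm.sample_ids), removed=[], reference_genes=[], flags={}
        )

    spec = specificity_table(matrices, thresholds, annotation=annotation)
    ranks = quantile_transform(tpm)
    drm = dynamic_range(ranks, grid=tuple(cfg["grid"]))
    _, sizes_summary = transcriptome_sizes(detect(tpm, thresholds[0]))

    clus_cfg = dict(cfg["clustering"])
    method = clus_cfg.pop("method", "affinity")
    clus_cfg = {k: v for k, v in clus_cfg.items() if v is not None}
    clusters = cluster_genes(drm, spec, method=method, seed=seed, **clus_cfg)
    categories = assign_categories(clusters, **cfg["categories"])
    lovar = select_lovar(clusters, categories, drm, raw=tpm, **cfg["lovar"])

    candidate_report = None
    if candidates and annotation is not None:
        det = detect(matrices["TPM"], thresholds[0])
        rates = per_group_detection(det, annotation, list(candidates))
        candidate_report = evaluate_candidates(list(candidates), spec, drm, rates)

    result = PipelineResult(
        tpm=tpm,
        qc_report=qc_report,
        ranks=ranks,
        spec_table=spec,
        drm=drm,
        clusters=clusters,
        categories=categories,
        lovar=lovar,
        sizes_summary=sizes_summary,
        truth=truth,
        candidate_report=candidate_report,
    )
    out_dir = cfg["output"].get("dir")
    if out_dir:
        result.manifest = _write_outputs(result, out_dir, cfg, thresholds)
    return result


def _write_outputs(result: PipelineResult, out_dir: str, cfg: dict, thresholds) -> dict:
    ueg_io.ensure_dir(out_dir)
    stage_outputs = {}

    def _save(name: str, writer) -> None:
        path = f"{out_dir}/{name}"
        writer(path)
        stage_outputs[name.split(".")[0]] = path

    _save("tpm.tsv", lambda p: ueg_io.write_matrix(result.tpm, p))
    _save(
        "qc_report.json",
        lambda p: open(p, "w").write(json.dumps(result.qc_report.to_dict(), indent=1)),
    )
    _save("quantile.tsv", lambda p: ueg_io.write_matrix(result.ranks, p))
    _save(
        "specificity.tsv",
        lambda p: result.spec_table.to_csv(p, sep="\t", index_label="gene_id"),
    )
    _save(
        "dynamic_range.tsv",
        lambda p: result.drm.to_frame().to_csv(p, sep="\t", index_label="gene_id"),
    )
    clusters_df = pd.DataFrame(
        {
            "cluster_id": result.clusters.labels,
            "category": result.categories.gene_category,
        }
    )
    _save(
        "clusters.tsv", lambda p: clusters_df.to_csv(p, sep="\t", index_label="gene_id")
    )
    _save(
        "cluster_summary.tsv",
        lambda p: result.clusters.medians.assign(
            category=result.categories.cluster_category
        ).to_csv(p, sep="\t"),
    )
    lovar_df = pd.DataFrame({"gene_id": result.lovar.selected})
    _save("lovar.tsv", lambda p: lovar_df.to_csv(p, sep="\t", index=False))
    if result.candidate_report is not None:
        _save(
            "candidates.tsv",
            lambda p: result.candidate_report.table.to_csv(p, sep="\t"),
        )

    manifest = {
        "package": "uegkit",
        "version": __version__,
        "seed": cfg["seed"],
        "thresholds": [t.name for t in thresholds],
        "grid": list(cfg["grid"]),
        "n_clusters": result.clusters.n_clusters,
        "transcriptome_size": result.sizes_summary,
        "lovar_removed_fraction": result.lovar.removed_fraction,
        "stage_outputs": stage_outputs,
    }
    with open(f"{out_dir}/manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def run_from_yaml(path: str) -> PipelineResult:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    return run_pipeline(config)
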