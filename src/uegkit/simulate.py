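"""Synthetic transcriptome compendia with known ground truth.

The generator emulates the statistical structure a UEG analysis assumes in a
real compendium: a bimodal specificity landscape (ubiquitous high- and
low-expressed genes versus tissue-restricted ones), moderately specific
genes in between, disallowed genes (ubiquitous but repressed in one tissue),
planted QC reference genes, library-size and batch variation, and detection
dropout concentrated at low expression. Every gene carries a truth record so
parameter recovery is testable without any download.

Mechanism, per gene class: a baseline mean count is drawn log-normally;
specifically expressed genes receive that mean only in their assigned
tissues; disallowed genes receive it everywhere except the repressed tissue,
where it is scaled by a repression factor. Per-sample library-size and batch
factors multiply all genes, observed counts are Poisson (negative binomial
by flag), and an independent Bernoulli dropout then zeroes observations with
probability logistic-decreasing in log10 of the scaled mean — low-expressed
genes are the ones detection thresholds overlook. QC reference genes are
guaranteed positive in good samples; a configured fraction of planted bad
samples has one reference gene zeroed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import ExpressionMatrix

#: Gene classes the generator plants.
GENE_CLASSES = ("ueg_high", "ueg_low", "msg", "seg", "disallowed", "qc_ref")


@dataclass
class DropoutModel:
    """Detection-dropout curve: p(x) = max_rate * expit(-steepness*(x - midpoint)).

    x is log10 of the scaled Poisson mean; steepness 0 gives the constant
    rate max_rate / 2; max_rate 0 disables dropout.
    """

    midpoint: float = 0.5
    steepness: float = 3.0
    max_rate: float = 0.95

    def rate(self, mean: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            x = np.log10(np.where(mean > 0, mean, 1.0))
        p = self.max_rate * expit(-self.steepness * (x - self.midpoint))
        return np.where(mean > 0, p, 0.0)


@dataclass
class SimConfig:
    """Study conditions for one synthetic compendium.

    Class counts and log-normal (natural-log) location/scale of baseline mean
    counts define the expression landscape; the demo preset plants 2000 genes
    over 4 tissues x 25 samples.
    """

    n_tissues: int = 4
    samples_per_tissue: int | tuple = 25
    n_ueg_high: int = 600
    n_ueg_low: int = 400
    n_msg: int = 381
    n_seg: int = 600
    n_disallowed: int = 16
    n_qc_ref: int = 3
    class_lognorm: dict = field(
        default_factory=lambda: {
            "ueg_high": (np.log(5000.0), 0.8),
            "ueg_low": (np.log(4.0), 0.3),
            "msg": (np.log(100.0), 0.6),
            "seg": (np.log(5.0), 0.5),
            "disallowed": (np.log(55.0), 0.12),
            "qc_ref": (np.log(50.0), 0.2),
        }
    )
    seg_tissue_breadth: int = 1
    msg_tissue_breadth: tuple = (2, 3)  # inclusive range, drawn per gene
    disallowed_split: tuple = (9, 3, 4)  # stable : variable : restricted weights
    disallowed_restricted_breadth: int | None = None  # default ~40% of tissues
    repression_factor: float = 0.02
    ueg_high_variable_fraction: float = 0.25
    variable_noise_sigma: float = 1.6
    dropout: DropoutModel = field(default_factory=DropoutModel)
    library_sigma: float = 0.25
    n_batches: int = 5
    batch_sigma: float = 0.15
    bad_sample_fraction: float = 0.05
    length_range: tuple = (500, 10_000)
    nb_dispersion: float | None = None  # None = Poisson
    seed: int = 0

    def validate(self) -> None:
        if self.n_tissues < 2:
            raise ValueError("at least 2 tissues are required")
        counts = [self.n_ueg_high, self.n_ueg_low, self.n_msg, self.n_seg,
                  self.n_disallowed, self.n_qc_ref]
        if any(c < 0 for c in counts):
            raise ValueError("gene-class counts must be >= 0")
        spt = self.tissue_sample_counts()
        if any(s < 1 for s in spt):
            raise ValueError("each tissue needs at least one sample")
        if not 0 <= self.bad_sample_fraction <= 1:
            raise ValueError("bad_sample_fraction must lie in [0, 1]")
        if not 0 <= self.dropout.max_rate <= 1:
            raise ValueError("dropout max_rate must lie in [0, 1]")
        if not 0 <= self.repression_factor:
            raise ValueError("repression_factor must be >= 0")
        if not (1 <= self.seg_tissue_breadth <= self.n_tissues):
            raise ValueError("seg_tissue_breadth out of range")

    def tissue_sample_counts(self) -> list[int]:
        if isinstance(self.samples_per_tissue, int):
            return [self.samples_per_tissue] * self.n_tissues
        spt = list(self.samples_per_tissue)
        if len(spt) != self.n_tissues:
            raise ValueError("samples_per_tissue length must equal n_tissues")
        return [int(s) for s in spt]

    @property
    def n_genes(self) -> int:
        return (self.n_ueg_high + self.n_ueg_low + self.n_msg + self.n_seg
                + self.n_disallowed + self.n_qc_ref)

    @property
    def n_samples(self) -> int:
        return sum(self.tissue_sample_counts())

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


def demo_config(seed: int = 0, **overrides) -> SimConfig:
    """The default demo compendium: 4 tissues x 25 samples, 2000 genes."""
    return SimConfig(seed=seed).replace(**overrides)


def candidate_config(seed: int = 0, **overrides) -> SimConfig:
    """The bundled candidate-evaluation scenario.

    Eight tissues keep a fully repressed tissue small enough (12.5% of
    samples) that a classic disallowed gene stays ubiquitous overall; 16
    disallowed genes are planted as 9 stable + 3 variable + 7-of-16
    non-constitutive overall (3 variable + 4 restricted).
    """
    cfg = SimConfig(
        n_tissues=8,
        samples_per_tissue=25,
        n_ueg_high=400,
        n_ueg_low=200,
        n_msg=200,
        n_seg=300,
        n_disallowed=16,
        n_qc_ref=3,
        seed=seed,
    )
    return cfg.replace(**overrides)


@dataclass
class TruthTable:
    """Planted ground truth for one generated compendium.

    ``genes``: one row per gene — class, subclass, baseline mean, noise
    sigma, repressed tissue (disallowed only) and per-tissue presence
    probability columns ``presence_<tissue>``. ``bad_samples`` lists the
    planted low-quality sample IDs (one QC reference gene zeroed).
    """

    genes: pd.DataFrame
    bad_samples: list[str]
    config: SimConfig

    def gene_ids(self, gene_class: str, subclass: str | None = None) -> list[str]:
        sel = self.genes["gene_class"] == gene_class
        if subclass is not None:
            sel &= self.genes["subclass"] == subclass
        return list(self.genes.index[sel])


def _allocate(n: int, weights) -> list[int]:
    """Largest-remainder allocation of n items over integer weights."""
    w = np.asarray(weights, dtype=float)
    if w.sum() == 0:
        return [0] * len(w)
    exact = n * w / w.sum()
    base = np.floor(exact).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(exact - base))
    base[order[:rem]] += 1
    return base.tolist()


def _gene_level_draws(config: SimConfig, rng: np.random.Generator):
    """Everything determined per gene: ids, classes, means, presence, lengths."""
    tissues = [f"tissue_{i:02d}" for i in range(config.n_tissues)]
    ids, classes, subclasses = [], [], []
    spec = [
        ("ueg_high", config.n_ueg_high, "UHG"),
        ("ueg_low", config.n_ueg_low, "ULG"),
        ("msg", config.n_msg, "MSG"),
        ("seg", config.n_seg, "SEG"),
        ("disallowed", config.n_disallowed, "DAG"),
        ("qc_ref", config.n_qc_ref, "QCR"),
    ]
    for cls, n, prefix in spec:
        ids += [f"{prefix}{i:05d}" for i in range(n)]
        classes += [cls] * n
        subclasses += ["stable"] * n
    classes = np.array(classes)
    subclasses = np.array(subclasses, dtype=object)
    n_genes = len(ids)

    lo_l, hi_l = config.length_range
    lengths = np.exp(rng.uniform(np.log(lo_l), np.log(hi_l), size=n_genes))
    lengths = np.maximum(1, np.round(lengths)).astype(int)

    baseline = np.empty(n_genes)
    for cls, _, _ in spec:
        sel = classes == cls
        loc, scale = config.class_lognorm[cls]
        baseline[sel] = rng.lognormal(loc, scale, size=int(sel.sum()))

    # subclass structure
    hi = np.flatnonzero(classes == "ueg_high")
    n_var = int(round(config.ueg_high_variable_fraction * len(hi)))
    if n_var:
        subclasses[rng.choice(hi, size=n_var, replace=False)] = "variable"
    da = np.flatnonzero(classes == "disallowed")
    n_stable, n_variable, n_restricted = _allocate(len(da), config.disallowed_split)
    da_shuffled = rng.permutation(da)
    subclasses[da_shuffled[:n_stable]] = "stable"
    subclasses[da_shuffled[n_stable:n_stable + n_variable]] = "variable"
    subclasses[da_shuffled[n_stable + n_variable:]] = "restricted"

    # Variable-ubiquitous candidates need rank headroom: plant them at the
    # center of the high-expression block on the TPM scale (ranks follow
    # count/length, so the gene's own length is compensated); the sample-level
    # noise then sweeps their percentile rank across the block.
    da_var = np.flatnonzero((classes == "disallowed") & (subclasses == "variable"))
    if len(da_var):
        loc_hi, _ = config.class_lognorm["ueg_high"]
        mean_log_len = (np.log(lo_l) + np.log(hi_l)) / 2.0
        baseline[da_var] = np.exp(
            loc_hi - mean_log_len + np.log(lengths[da_var])
            + 0.25 * rng.standard_normal(len(da_var))
        )

    noise_sigma = np.zeros(n_genes)
    noise_sigma[subclasses == "variable"] = config.variable_noise_sigma

    # per-tissue mean design
    presence = np.ones((n_genes, config.n_tissues))
    mean_design = baseline[:, None] * np.ones((1, config.n_tissues))
    lo_b, hi_b = config.msg_tissue_breadth
    r_breadth = config.disallowed_restricted_breadth
    if r_breadth is None:
        r_breadth = max(1, int(round(0.4 * config.n_tissues)))
    repressed = np.full(n_genes, "", dtype=object)
    for g in range(n_genes):
        cls, sub = classes[g], subclasses[g]
        if cls == "seg" or (cls == "disallowed" and sub == "restricted"):
            breadth = config.seg_tissue_breadth if cls == "seg" else r_breadth
            on = rng.choice(config.n_tissues, size=breadth, replace=False)
            mask = np.zeros(config.n_tissues, dtype=bool)
            mask[on] = True
            presence[g, ~mask] = 0.0
            mean_design[g, ~mask] = 0.0
        elif cls == "msg":
            breadth = int(rng.integers(lo_b, hi_b + 1))
            on = rng.choice(config.n_tissues, size=breadth, replace=False)
            mask = np.zeros(config.n_tissues, dtype=bool)
            mask[on] = True
            presence[g, ~mask] = 0.0
            mean_design[g, ~mask] = 0.0
        elif cls == "disallowed" and sub == "stable":
            t = int(rng.integers(config.n_tissues))
            repressed[g] = tissues[t]
            mean_design[g, t] *= config.repression_factor

    genes = pd.DataFrame(
        {
            "gene_class": classes,
            "subclass": subclasses,
            "baseline_mean": baseline,
            "noise_sigma": noise_sigma,
            "repressed_tissue": repressed,
            **{f"presence_{t}": presence[:, j] for j, t in enumerate(tissues)},
        },
        index=pd.Index(ids, name="gene_id"),
    )
    return tissues, genes, mean_design, lengths


def _sample_counts(
    config: SimConfig,
    genes: pd.DataFrame,
    mean_design: np.ndarray,
    tissues: list[str],
    rng: np.random.Generator,
):
    """Everything determined per sample: factors, counts, dropout, QC truth."""
    spt = config.tissue_sample_counts()
    tissue_of = np.repeat(np.arange(config.n_tissues), spt)
    n_samples = len(tissue_of)
    sample_ids = [f"S{i:05d}" for i in range(n_samples)]

    lib = rng.lognormal(0.0, config.library_sigma, size=n_samples)
    batch_of = rng.integers(config.n_batches, size=n_samples)
    batch_fac = rng.lognormal(0.0, config.batch_sigma, size=config.n_batches)
    factor = lib * batch_fac[batch_of]

    mean = mean_design[:, tissue_of] * factor[None, :]
    sig = genes["noise_sigma"].to_numpy()
    noisy = sig > 0
    if noisy.any():
        mean[noisy] = mean[noisy] * rng.lognormal(
            0.0, np.broadcast_to(sig[noisy, None], (noisy.sum(), n_samples))
        )

    if config.nb_dispersion:
        shape = 1.0 / config.nb_dispersion
        lam = np.where(mean > 0, rng.gamma(shape, 1.0, size=mean.shape), 0.0)
        counts = rng.poisson(lam * mean / shape)
    else:
        counts = rng.poisson(mean)

    qc_mask = (genes["gene_class"] == "qc_ref").to_numpy()
    drop_p = config.dropout.rate(mean)
    drop = rng.random(mean.shape) < drop_p
    drop[qc_mask] = False  # reference genes are exempt
    counts = np.where(drop, 0, counts)
    counts[qc_mask] = np.maximum(counts[qc_mask], 1)

    n_bad = int(np.floor(config.bad_sample_fraction * n_samples))
    bad_idx = rng.choice(n_samples, size=n_bad, replace=False) if n_bad else np.array([], int)
    qc_rows = np.flatnonzero(qc_mask)
    if n_bad and len(qc_rows):
        which = rng.integers(len(qc_rows), size=n_bad)
        counts[qc_rows[which], bad_idx] = 0
    bad_samples = sorted(sample_ids[i] for i in bad_idx)

    annotation = pd.DataFrame(
        {
            "tissue_group": [tissues[t] for t in tissue_of],
            "source_type": rng.choice(["in_vivo", "in_vitro"], size=n_samples),
            "study_id": [f"study_{b:02d}" for b in batch_of],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return counts, annotation, bad_samples


def generate(
    config: SimConfig, _sample_seed: int | None = None
) -> tuple[ExpressionMatrix, pd.Series, pd.DataFrame, TruthTable]:
    """Generate one compendium: (counts matrix, gene lengths, annotation, truth).

    Deterministic for a fixed config (the seed lives in the config). Gene-
    and sample-level randomness use separate streams so that Monte-Carlo
    re-sampling of the same gene population is possible (see
    :func:`expected_phi`); ``_sample_seed`` overrides only the sample stream.
    """
    config.validate()
    rng_gene = np.random.default_rng(config.seed)
    rng_sample = np.random.default_rng(
        config.seed + 1_000_003 if _sample_seed is None else _sample_seed
    )
    tissues, genes, mean_design, lengths = _gene_level_draws(config, rng_gene)
    counts, annotation, bad_samples = _sample_counts(
        config, genes, mean_design, tissues, rng_sample
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(counts.astype(float), index=genes.index, columns=annotation.index),
        "counts",
    )
    length_s = pd.Series(lengths, index=genes.index, name="length")
    truth = TruthTable(genes=genes, bad_samples=bad_samples, config=config)
    return matrix, length_s, annotation, truth


def qc_reference_genes(truth: TruthTable) -> list[str]:
    """The planted QC reference gene IDs of a generated compendium."""
    return truth.gene_ids("qc_ref")


def expected_phi(
    config: SimConfig,
    threshold=None,
    n_mc: int = 2500,
    mc_seed: int = 777_001,
) -> pd.Series:
    """Expected per-gene detection proportion under the study conditions.

    With ``threshold=None`` a closed design composition is returned:
    phi_g = sum_t w_t * presence(g,t) * (1 - dropout(log10 mean(g,t))),
    i.e. tissue-weighted presence thinned by the dropout curve — exact when
    expression is high enough that count-level zeros and the normalization
    sum are negligible. With a :class:`DetectionThreshold` the coupling of
    TPM values across genes has no closed form, so a labeled high-rep Monte
    Carlo (its own seed, ``n_mc`` samples per tissue) regenerates the same
    gene population and measures per-tissue detection rates directly.
    """
    config.validate()
    spt = np.asarray(config.tissue_sample_counts(), dtype=float)
    weights = spt / spt.sum()
    if threshold is None:
        rng_gene = np.random.default_rng(config.seed)
        tissues, genes, mean_design, _ = _gene_level_draws(config, rng_gene)
        keep = 1.0 - config.dropout.rate(mean_design)
        phi = ((mean_design > 0) * keep * weights[None, :]).sum(axis=1)
        qc = (genes["gene_class"] == "qc_ref").to_numpy()
        phi[qc] = 1.0  # reference genes are guaranteed positive
        return pd.Series(phi, index=genes.index, name="expected_phi")

    from .norm import tpm_normalize, rpkm_normalize
    from .specificity import detect

    mc_cfg = config.replace(
        samples_per_tissue=[int(n_mc)] * config.n_tissues, bad_sample_fraction=0.0
    )
    counts, lengths, annotation, truth = generate(mc_cfg, _sample_seed=mc_seed)
    norm = tpm_normalize if threshold.unit == "TPM" else rpkm_normalize
    det = detect(norm(counts, lengths), threshold)
    tissue_of = annotation["tissue_group"]
    phi = np.zeros(counts.n_genes)
    for j, t in enumerate(f"tissue_{i:02d}" for i in range(config.n_tissues)):
        cols = tissue_of.index[tissue_of == t]
        phi += weights[j] * det.values[cols].mean(axis=1).to_numpy()
    return pd.Series(phi, index=counts.values.index, name=f"expected_phi@{threshold.name}")
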