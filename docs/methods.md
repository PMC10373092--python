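# Methods

## Model and rationale

`uegkit` characterizes ubiquitously expressed genes (UEGs) directly from a
large, heterogeneous collection of transcriptomes, without stratifying
samples into tissues first. Three statistics carry the analysis:

**Global expression specificity.** For a detection threshold t (a minimum
normalized expression value), a gene g is *expressed* in sample j when
x_gj ≥ t, and

    φ_g = (# samples expressing g) / (# samples).

φ = 1 marks a UEG; φ near 0 marks a specifically expressed gene (SEG).
Detection is inclusive (≥). Four conventional presets ship: TPM ≥ 0.1 (the
GTEx choice, and the default because it is the most sensitive to lowly
expressed genes), TPM ≥ 1.0, RPKM ≥ 0.3 and RPKM ≥ 1.0. φ is monotone
non-increasing in the threshold, which the tests assert genewise.

The classical tissue-stratified variant is also provided for comparison: a
tissue *expresses* a gene when ≥ 80% of its annotated samples detect it
(inclusive ≥, computed only over annotated samples), and tissue specificity
is the fraction of expressing tissues.

**Sample-wise quantile ranks.** To compare expression patterns across
samples with different depths, platforms and batches, each sample's nonzero
values are replaced by their within-sample rank fraction among nonzero
values,

    Q_j(x) = |{i : 0 < x_i ≤ x_j}| / |{i : 0 < x_i}|   (x_j > 0; else 0).

Ties take the maximum rank (the ≤ count) — no midranks — so the largest
detected gene in every sample maps to exactly 1 and zeros are preserved
exactly. The denominator is the sample's own detected-gene count, so
transcriptome size legitimately varies by sample. This is a within-sample
transform; it is *not* cross-sample quantile normalization to a shared
reference distribution. The implementation sorts (O(n log n) per sample);
the test suite keeps a quadratic double-loop as the independent oracle.

**Dynamic ranges.** A gene's distribution of quantile ranks across the
compendium is summarized by its empirical percentiles Q5…Q95 (step 5, 19
points — enough shape resolution for clustering without inflating the
feature dimension; configurable), its median Q50, its interquartile range
IQR = Q75 − Q25 (the expression-variability measure, computed on ranks, not
raw TPM), and the adjusted Fisher–Pearson sample skewness

    Skew = n/((n−1)(n−2)) · Σ((x − x̄)/s)³,   s = sample SD (ddof 1).

Negative skewness indicates mass at the high-expression end — the UEG
signature — and skewness is strongly anti-correlated with φ. Percentiles use
linear interpolation between order statistics (Hyndman–Fan type 7, numpy's
default); the choice is fixed and documented because cluster boundaries
depend on it. Skewness is computed on quantile ranks by default (consistent
with the relative-expression framing); `dynamic_range(..., on_raw=True)`
exposes the raw-scale alternative.

## Clustering and the five categories

Genes are clustered by distribution *shape*: affinity propagation on the
Q5…Q95 vectors with negative squared-Euclidean similarity, preference at the
median similarity, damping 0.9 (escalated up to 3 times toward 0.99 on
non-convergence, then a hard error with diagnostics). Affinity propagation
picks the number of clusters itself and names an exemplar gene per cluster.
Seeded k-means (10 restarts, k supplied or borrowed from the affinity
solution) is available for sensitivity comparison; within-cluster
homogeneity (mean distance to exemplar, or to centroid for k-means) is the
comparison statistic. The affinity-beats-kmeans comparison is a soft check:
it is computed and warned about, never a hard failure, because on trivially
tight fixtures a centroid is by construction at least as close as any
exemplar.

Each cluster receives one of five categories from its median φ at the two
TPM thresholds; first matching rule wins, in this order:

1. median φ@1.0 ≥ 0.8 → **UEGs@1.0**
2. median φ@0.1 ≥ 0.8 → **UEGs@0.1** (ubiquitous only at the sensitive threshold)
3. median φ@0.1 ≤ 0.3 → **SEGs@0.1**
4. median φ@1.0 ≤ 0.3 → **SEGs@1.0**
5. otherwise → **MSG** (moderately specific)

The rule order (UEG rules before SEG rules; strict before sensitive for
UEGs, sensitive before strict for SEGs) resolves the ambiguity in the
five-way scheme's prose definition and reproduces the expected concentration
of each category across specificity intervals; it is regression-locked by
the tests. Cut-offs 0.8/0.3 are parameters.

**Interval tables.** Gene counts per specificity interval use a closed top
bin [0.8, 1.0] (matching the inclusive "φ ≥ 0.8" convention), half-open
(lower, upper] bins below it, and [0, 0.2] at the bottom; a literal
all-half-open reading would double-assign φ = 0.8, so top-bin precedence is
the documented policy.

**LoVarUEGs.** Candidate internal reference genes are the members of
UEG-category clusters whose median rank IQR lies in the low-variability band
(≤ 0.2), minus per-cluster outliers. The outlier rule (no canonical
definition exists) defaults to a robust z-score — |z| > 3 on
log10((Q95+ε)/(Q5+ε)) of *raw* TPM within each source cluster, ε = 10⁻³ —
removing genes whose raw-scale fold range contradicts their rank-scale
stability; a percentile-cap rule is available by configuration.

**Candidate (disallowed-gene) evaluation.** A disallowed gene is a UEG
selectively repressed in one or a few cell types. For a candidate list the
package reports φ per threshold, IQR, skewness, the dynamic range and
per-tissue-group detection rates, and assigns: *constitutive*
(φ@0.1 ≥ 0.8, IQR ≤ 0.2), *variable_ubiquitous* (φ@0.1 ≥ 0.8, IQR > 0.2),
*restricted* (φ@0.1 < 0.8) or *not_found*. Constitutive genes with a group
detection rate < 0.5 are flagged with those groups — the disallowance
signature. The verdict thresholds deliberately reuse the category cut (0.8)
and the low-variability band (0.2) so all modules agree; the repressed-group
cut (0.5) is an explicit documented stand-in for what is otherwise an
inspection call, and is configurable.

## Preprocessing

Transcript-level rows collapse to genes by the per-sample **maximum** over a
transcript→gene map; unmapped rows are dropped with a logged count
(mirroring lossy ID conversion), and an empty intersection is a hard error.
TPM_g = 10⁶·(c_g/l_g)/Σᵢ(cᵢ/lᵢ) per sample; RPKM_g = 10⁹·c_g/(l_g·N) with N
the column sum. All-zero sample columns pass through normalization as zeros
with a warning. Sample QC removes any sample in which any of a set of lowly
expressed internal reference genes measures exactly zero; the conventional
human trio GUSB/HPRT1/HMBS is the symbolic default, and the synthetic
compendium plants its own three reference genes. Matrices carry a declared
unit (counts/TPM/RPKM/quantile) and operations reject wrong-unit inputs.

## The synthetic compendium

The generator emulates the structure the analysis assumes — it is the
package's study condition, not a tuning knob. Per gene class, a baseline
mean count is drawn log-normally (natural-log location/scale):

| class      | n (demo) | loc        | scale | pattern |
|------------|----------|------------|-------|---------|
| ueg_high   | 600      | ln 5000    | 0.8   | all tissues; 25% get sample-level noise σ=1.6 ("variable") |
| ueg_low    | 400      | ln 4       | 0.3   | all tissues, low expression |
| msg        | 381      | ln 100     | 0.6   | 2–3 of 4 tissues |
| seg        | 600      | ln 5       | 0.5   | 1 tissue |
| disallowed | 16       | ln 55      | 0.12  | 9 stable (one tissue repressed ×0.02), 3 variable, 4 restricted |
| qc_ref     | 3        | ln 50      | 0.2   | all tissues, guaranteed positive |

Demo conditions: 4 tissues × 25 samples, 2000 genes; library-size factors
lognormal(σ=0.25), 5 batches with lognormal(σ=0.15) factors, 5% planted bad
samples (one reference gene zeroed), gene lengths log-uniform in
[500, 10⁴] bp so TPM and RPKM orderings differ. Counts are Poisson of the
scaled means (negative binomial by flag; Poisson is the default for the
analytic tractability of the expectation oracle). Detection dropout then
zeroes an observation with probability max_rate·expit(−k·(log10 μ − m))
(defaults max_rate 0.95, steepness k = 3, midpoint m = 0.5 in log10 counts),
concentrating missingness at low expression — the reason lowly expressed
UEGs are overlooked by stringent thresholds.

Design notes on the class parameters, chosen from the detection arithmetic
before any testing and then left alone:

- The disallowed baseline window is narrow (ln 55 ± 0.12) because the class
  must satisfy two constraints at once: detected in ≥ 90% of samples outside
  the repressed tissue, while 2% of its mean falls below the sensitive
  detection threshold inside it.
- "Variable-ubiquitous" genes are planted at the center of the
  high-expression block *on the TPM scale* (the gene's own length is
  compensated) with sample-level lognormal noise σ = 1.6 (~25-fold swings):
  rank variability requires headroom — a variable gene parked below the
  high-expression block cannot move through the ranks no matter how much its
  counts vary.
- The bundled candidate scenario uses 8 tissues (12.5% of samples per
  tissue): with 4 equal tissues, fully repressing one tissue caps φ at 0.75,
  so no classic disallowed gene could remain ubiquitous (φ ≥ 0.8). Its 16
  candidates split 9 stable + 3 variable + 4 restricted, i.e. 7 of 16
  non-constitutive.

The truth table records class, subclass, baseline mean, noise σ, per-tissue
presence and the repressed tissue, plus the planted bad-sample IDs.
Generation is deterministic for a fixed config; gene-level and sample-level
randomness use separate streams so the expectation oracle can resample the
same gene population.

**Expectation oracle.** `expected_phi` returns, per gene, the expected
detection proportion. With no threshold it is the closed design composition
Σ_t w_t · presence(g,t) · (1 − dropout(log10 μ_gt)), exact when means are
high enough that count-level zeros are negligible. At a TPM threshold no
closed form exists — a gene's TPM depends on every other gene's counts
through the per-sample normalizing sum — so a labeled high-replication Monte
Carlo (own seed, default 2500 samples per tissue) regenerates the same gene
population and measures per-tissue detection rates directly.

**Recovery calibration.** The φ-recovery experiment (2000 genes × 400
samples) compares the estimate against the oracle with the *exact* central
99.73% binomial interval — the ±3 SE analogue computed from binomial
quantiles — because the normal-approximation band collapses below one
sample's granularity as φ → 0 or 1, where no discrete estimate could pass.
The experiment runs without the shared-batch factor (batch σ = 0; per-sample
library variation and dropout remain): with only 5 shared batches, samples
are not exchangeable and the binomial reference understates the variance of
φ̂. The demo preset itself keeps its batch structure.

## What the synthetic data does and does not show

The generator reproduces the bimodal specificity landscape, the
specificity–skewness anti-correlation, the variance structure of stable
versus variable UEGs, dropout at low expression, library/batch scale
effects, planted QC failures and the disallowed-gene repression pattern. It
does **not** model: gene–gene correlation beyond shared scale factors,
isoform structure, length biases within a gene class, annotation errors,
single-cell sparsity, or real batch effects beyond multiplicative factors.
Passing tests therefore demonstrate the correctness and internal consistency
of the statistics and the recoverability of planted structure — not that any
particular real compendium would yield particular gene lists. Scale is also
deliberately modest (2000 genes, 100–400 samples) so the whole suite runs on
a laptop; headline counts from real compendia (tens of thousands of genes
and profiles) are not reproduced at this scale.

One structural consequence worth knowing: a gene detected in fewer than 25%
of samples has rank Q25 = Q75 = 0 and hence IQR exactly 0. Strict SEGs are
therefore *not* high-IQR genes; the variability contrast between stable UEGs
and specific genes is better read from the full dynamic-range width
(Q95 − Q5), and the tests do so.

## Numerical choices and degenerate inputs

- Ties in ranks: maximum rank, per the ≤ definition; no midranks.
- Samples with zero detected genes: all-zero rank column, logged warning.
- Skewness: NaN (with warning) for n < 3 or zero spread; never an error —
  never-expressed genes legitimately have constant rank rows.
- TPM of an all-zero column: zeros (0/0 defined as 0), logged.
- Affinity propagation non-convergence: damping escalates 0.9 → toward 0.99
  over 3 retries, then a hard error.
- Robust z-score with MAD = 0 within a cluster: no outliers flagged there.
- Config validation (pipeline and simulator) rejects unknown keys and
  invariant violations before any computation.

## Known limitations

- The candidate verdict thresholds are explicit stand-ins for what is, in
  practice, an inspection call; they are configurable and documented rather
  than claimed optimal.
- Affinity propagation is O(n²) in genes; beyond ~10⁴ genes k-means mode or
  sub-sampling is advisable.
- Tissue specificity uses hard 80% detection cuts; no uncertainty is
  propagated.
- Uneven tissue representation is first-class in the simulator but no
  reweighting of φ is implemented.
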