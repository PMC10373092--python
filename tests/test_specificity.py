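import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

import uegkit as uk
from conftest import make_matrix


def tpm(values, **kw):
    return make_matrix(values, unit="TPM", **kw)


THR = uk.DetectionThreshold("TPM", 0.1)


class TestDetect:
    def test_threshold_is_inclusive(self):
        det = uk.detect(tpm([[0.1]]), THR)
        assert det.values.iloc[0, 0]

    def test_zero_never_expressed(self):
        det = uk.detect(tpm([[0.0]]), uk.DetectionThreshold("TPM", 1e-9))
        assert not det.values.iloc[0, 0]

    def test_raising_threshold_monotone(self, rng):
        m = tpm(rng.random((20, 10)) * 3)
        lo = uk.detect(m, uk.DetectionThreshold("TPM", 0.1)).values
        hi = uk.detect(m, uk.DetectionThreshold("TPM", 1.0)).values
        assert not (hi & ~lo).any().any()

    def test_unit_mismatch_is_error(self):
        with pytest.raises(ValueError, match="unit"):
            uk.detect(tpm([[1.0]]), uk.DetectionThreshold("RPKM", 0.3))


class TestGlobalSpecificity:
    def test_four_of_five(self):
        m = tpm([[1, 1, 1, 1, 0]])
        assert uk.global_specificity(uk.detect(m, THR)).iloc[0] == pytest.approx(0.8)

    def test_ueg_end_is_one(self):
        m = tpm([[1, 1, 1]])
        assert uk.global_specificity(uk.detect(m, THR)).iloc[0] == 1.0

    def test_binomial_recovery_of_planted_presence(self):
        # gene present with probability 0.65 per sample; phi must land inside
        # the exact central 99% binomial interval at n=1000
        rng = np.random.default_rng(42)
        n = 1000
        present = rng.random(n) < 0.65
        m = tpm(present[None, :].astype(float))
        phi = uk.global_specificity(uk.detect(m, THR)).iloc[0]
        lo, hi = binom.ppf(0.005, n, 0.65) / n, binom.isf(0.005, n, 0.65) / n
        assert lo <= phi <= hi

    def test_oracle_equivalence_on_small_matrices(self, rng):
        for _ in range(10):
            X = rng.random((rng.integers(2, 20), rng.integers(1, 20)))
            det = uk.detect(tpm(X), uk.DetectionThreshold("TPM", 0.5))
            phi = uk.global_specificity(det)
            # brute-force loop count
            for i, g in enumerate(det.gene_ids):
                count = sum(1 for j in range(X.shape[1]) if X[i, j] >= 0.5)
                assert phi.loc[g] == pytest.approx(count / X.shape[1])


class TestTissueSpecificity:
    def _annotation(self, groups):
        return pd.DataFrame(
            {
                "sample_id": [s for ss in groups.values() for s in ss],
                "tissue_group": [t for t, ss in groups.items() for _ in ss],
                "source_type": "in_vivo",
                "study_id": "s",
            }
        )

    def test_two_of_four_tissues(self):
        # one sample per tissue: detection == tissue expression
        m = tpm([[1, 1, 0, 0]], samples=["a", "b", "c", "d"])
        ann = self._annotation({"t1": ["a"], "t2": ["b"], "t3": ["c"], "t4": ["d"]})
        ts = uk.tissue_specificity(uk.detect(m, THR), ann)
        assert ts.iloc[0] == pytest.approx(0.5)

    def test_detected_everywhere_is_one(self):
        m = tpm([[1, 1, 1, 1]], samples=list("abcd"))
        ann = self._annotation({"t1": ["a", "b"], "t2": ["c", "d"]})
        assert uk.tissue_specificity(uk.detect(m, THR), ann).iloc[0] == 1.0

    def test_eighty_percent_rule_inclusive(self):
        # 4 of 5 samples detected = exactly 80% -> tissue counts as expressing
        m = tpm([[1, 1, 1, 1, 0]], samples=list("abcde"))
        ann = self._annotation({"t1": list("abcde")})
        assert uk.tissue_specificity(uk.detect(m, THR), ann).iloc[0] == 1.0
        # 3 of 5 (60%) does not
        m2 = tpm([[1, 1, 1, 0, 0]], samples=list("abcde"))
        assert uk.tissue_specificity(uk.detect(m2, THR), ann).iloc[0] == 0.0

    def test_only_annotated_samples_count(self):
        m = tpm([[1, 0]], samples=["a", "b"])
        ann = self._annotation({"t1": ["a"]})
        assert uk.tissue_specificity(uk.detect(m, THR), ann).iloc[0] == 1.0


class TestTranscriptomeSizes:
    def test_all_zero_sample(self):
        sizes, _ = uk.transcriptome_sizes(uk.detect(tpm([[0], [0]]), THR))
        assert sizes.iloc[0] == 0

    def test_everything_at_threshold(self):
        sizes, summary = uk.transcriptome_sizes(uk.detect(tpm([[0.1], [0.1]]), THR))
        assert sizes.iloc[0] == 2
        assert summary["median"] == 2

    def test_planted_counts_recovered_without_dropout(self):
        lognorm = {c: (np.log(2000.0), 0.3) for c in
                   ("ueg_high", "ueg_low", "msg", "seg", "disallowed", "qc_ref")}
        cfg = uk.demo_config(
            seed=5, n_ueg_high=50, n_ueg_low=0, n_msg=0, n_seg=50,
            n_disallowed=0, n_qc_ref=0, samples_per_tissue=5,
            class_lognorm=lognorm,  # high means: no count-level zeros
            dropout=uk.DropoutModel(max_rate=0.0), bad_sample_fraction=0.0,
        )
        counts, lengths, ann, truth = uk.generate(cfg)
        det = uk.detect(uk.tpm_normalize(counts, lengths), THR)
        sizes, _ = uk.transcriptome_sizes(det)
        presence = truth.genes[[f"presence_{t}" for t in sorted(ann["tissue_group"].unique())]]
        for s in sizes.index:
            t = ann.loc[s, "tissue_group"]
            # high-mean genes present in this tissue are all detected
            assert sizes[s] == presence[f"presence_{t}"].sum()


class TestIntervalTable:
    def test_all_ones_in_top_interval(self):
        phi = pd.Series(1.0, index=[f"g{i}" for i in range(10)])
        table = uk.interval_table(phi)
        assert table.loc["all_genes", "n[0.8-1]"] == 10
        assert table.loc["all_genes", "pct[0.8-1]"] == 100.0

    def test_phi_exactly_08_in_top_interval(self):
        table = uk.interval_table(pd.Series({"g": 0.8}))
        assert table.loc["all_genes", "n[0.8-1]"] == 1

    def test_lower_edges_half_open(self):
        phi = pd.Series({"a": 0.2, "b": 0.200001, "c": 0.0})
        table = uk.interval_table(phi)
        assert table.loc["all_genes", "n[0-0.2]"] == 2  # 0.2 and 0.0
        assert table.loc["all_genes", "n[0.2-0.4]"] == 1

    def test_empty_gene_set_row_of_zeros(self):
        phi = pd.Series({"g": 0.5})
        table = uk.interval_table(phi, gene_sets={"empty": []})
        assert table.loc["empty", "total"] == 0

    def test_missing_members_tallied(self):
        phi = pd.Series({"g": 0.5})
        table = uk.interval_table(phi, gene_sets={"s": ["g", "absent"]})
        assert table.loc["s", "missing"] == 1
        assert table.loc["s", "total"] == 1

    def test_rows_sum_to_present_gene_count(self, rng):
        phi = pd.Series(rng.random(100), index=[f"g{i}" for i in range(100)])
        sets = {"half": [f"g{i}" for i in range(0, 100, 2)] + ["nope"]}
        table = uk.interval_table(phi, gene_sets=sets)
        ncols = [c for c in table.columns if c.startswith("n[")]
        assert table.loc["half", ncols].sum() == 50
        assert table.loc["all_genes", ncols].sum() == 100


class TestThresholdMonotonicity:
    def test_phi_monotone_in_threshold(self, rng):
        m = tpm(rng.random((50, 20)) * 3)
        phi_lo = uk.global_specificity(uk.detect(m, uk.DetectionThreshold("TPM", 0.1)))
        phi_hi = uk.global_specificity(uk.detect(m, uk.DetectionThreshold("TPM", 1.0)))
        assert (phi_hi <= phi_lo).all()
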