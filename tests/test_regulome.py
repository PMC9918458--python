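"""Consensus peaks, TSS assignment, genomic categories, core program."""

import numpy as np
import pandas as pd
import pytest

from oracles import per_base_consensus
from trendsig import regulome
from trendsig.errors import ValidationError
from trendsig.genemodel import GeneModel
from trendsig.regulome import CATEGORIES
from trendsig.synthdata import gen_chip_replicates, gen_gene_model


def _peaks(intervals, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom,
                         "start": [s for s, _ in intervals],
                         "end": [e for _, e in intervals]})


class TestConsensusPeaks:
    def test_two_of_three_rule(self):
        reps = [_peaks([(100, 200)]), _peaks([(150, 250)]),
                _peaks([(400, 500)])]
        cons = regulome.consensus_peaks(reps, min_support=2)
        assert cons[["start", "end"]].to_numpy().tolist() == [[100, 250]]

    def test_identical_peak_in_all_reps(self):
        reps = [_peaks([(100, 200)])] * 3
        cons = regulome.consensus_peaks(reps)
        assert cons[["start", "end"]].to_numpy().tolist() == [[100, 200]]

    def test_same_replicate_overlap_does_not_count_twice(self):
        reps = [_peaks([(100, 200), (150, 260)]), _peaks([(500, 600)])]
        cons = regulome.consensus_peaks(reps, min_support=2)
        assert cons.empty

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(12)
        for trial in range(5):
            reps_iv = []
            for _ in range(3):
                starts = rng.integers(0, 99_000, size=30)
                reps_iv.append([(int(s), int(s + rng.integers(200, 1200)))
                                for s in starts])
            cons = regulome.consensus_peaks([_peaks(iv) for iv in reps_iv],
                                            min_support=2)
            expected = per_base_consensus(reps_iv, 101_000, min_support=2)
            assert cons[["start", "end"]].to_numpy().tolist() == \
                [list(t) for t in expected]

    def test_output_sorted_disjoint(self):
        rng = np.random.default_rng(13)
        reps = [_peaks([(int(s), int(s) + 300)
                        for s in rng.integers(0, 50_000, size=40)])
                for _ in range(3)]
        cons = regulome.consensus_peaks(reps)
        starts = cons["start"].to_numpy()
        ends = cons["end"].to_numpy()
        assert (starts[1:] >= ends[:-1]).all()

    def test_monotone_in_min_support(self):
        rng = np.random.default_rng(14)
        reps = [_peaks([(int(s), int(s) + 500)
                        for s in rng.integers(0, 30_000, size=20)])
                for _ in range(3)]
        sizes = [len(regulome.consensus_peaks(reps, min_support=k))
                 for k in (1, 2, 3)]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_min_support_exceeding_reps_rejected(self):
        with pytest.raises(ValidationError):
            regulome.consensus_peaks([_peaks([(1, 2)])], min_support=2)


def _toy_model():
    """One '+' gene with TSS 10000 and one '-' gene with TSS 49999."""
    transcripts = pd.DataFrame({
        "gene_id": ["GP", "GM"], "transcript_id": ["GP.t1", "GM.t1"],
        "chrom": ["chr1", "chr1"], "start": [10_000, 40_000],
        "end": [20_000, 50_000], "strand": ["+", "-"],
        "cds_start": [11_000, 41_000], "cds_end": [19_000, 49_000],
    })
    exons = pd.DataFrame({
        "transcript_id": ["GP.t1", "GP.t1", "GM.t1", "GM.t1"],
        "chrom": "chr1",
        "start": [10_000, 15_000, 40_000, 46_000],
        "end": [12_000, 20_000, 44_000, 50_000],
        "strand": ["+", "+", "-", "-"],
    })
    return GeneModel(transcripts=transcripts, exons=exons,
                     chrom_sizes={"chr1": 100_000})


class TestAssignPeaks:
    model = _toy_model()

    def test_upstream_peak_within_window_is_target(self):
        ann, targets = regulome.assign_peaks_to_genes(
            _peaks([(7000, 7200)]), self.model)
        assert ann.loc[0, "gene_id"] == "GP"
        assert ann.loc[0, "signed_distance"] == -2900
        assert "GP" in targets

    def test_peak_just_outside_window_not_target(self):
        ann, targets = regulome.assign_peaks_to_genes(
            _peaks([(13_000, 13_200)]), self.model)  # midpoint 13100, d=3100
        assert ann.loc[0, "gene_id"] == "GP"
        assert not ann.loc[0, "within_window"]
        assert targets == set()

    def test_minus_strand_signed_distance(self):
        # anchor 2900 bp downstream (left) of the '-' TSS at 49999
        ann, targets = regulome.assign_peaks_to_genes(
            _peaks([(46_999, 47_199)]), self.model)
        assert ann.loc[0, "gene_id"] == "GM"
        assert ann.loc[0, "signed_distance"] == 49_999 - 47_099
        assert "GM" in targets

    def test_unplaced_chromosome_excluded(self):
        ann, targets = regulome.assign_peaks_to_genes(
            _peaks([(100, 200)], chrom="chrZ"), self.model)
        assert ann.loc[0, "gene_id"] == "unplaced"
        assert targets == set()

    def test_window_monotonicity(self):
        peaks = _peaks([(5000, 5400), (13_000, 13_200), (47_000, 47_400)])
        sizes = [len(regulome.assign_peaks_to_genes(peaks, self.model,
                                                    tss_window=w)[1])
                 for w in (1000, 3000, 10_000)]
        assert sizes[0] <= sizes[1] <= sizes[2]

    def test_synthetic_targets_match_truth(self):
        model = gen_gene_model(12, n_chroms=2, chrom_len=900_000, seed=20)
        reps, truth = gen_chip_replicates(model, model.gene_ids[:8],
                                          reproducible_frac=0.6,
                                          n_noise_peaks=12, seed=21)
        cons = regulome.consensus_peaks(reps, min_support=2)
        _, targets = regulome.assign_peaks_to_genes(cons, model)
        assert targets == set(truth.peak_targets)


class TestGenomicDistribution:
    model = _toy_model()

    def _category(self, pos):
        dist = regulome.genomic_distribution(_peaks([(pos - 50, pos + 50)]),
                                             self.model)
        return dist.idxmax()

    def test_tss_beats_exon(self):
        # inside first exon AND within the TSS window
        assert self._category(11_000) == "TSS"

    def test_exon_and_intron_and_utr(self):
        assert self._category(16_000) == "exon"       # CDS part of exon 2
        assert self._category(13_500) == "intron"
        assert self._category(19_500) == "three_prime_UTR"

    def test_downstream_and_distal(self):
        assert self._category(21_000) == "downstream"  # past '+' TES
        assert self._category(30_000) == "distal_intergenic"

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(15)
        peaks = _peaks([(int(p), int(p) + 100)
                        for p in rng.integers(0, 90_000, size=60)])
        dist = regulome.genomic_distribution(peaks, self.model)
        assert dist.sum() == pytest.approx(1.0, abs=1e-9)
        assert set(dist.index) == set(CATEGORIES)

    def test_matches_per_anchor_oracle(self):
        """Exhaustive check against an independent per-base category map."""
        m = self.model
        tss_w, down_w = 3000, 3000
        base_cat = {}

        def oracle(pos):
            if abs(pos - 10_000) <= tss_w or abs(pos - 49_999) <= tss_w:
                return "TSS"
            in_utr5 = 10_000 <= pos < 11_000 or 49_000 <= pos < 50_000
            in_utr3 = 19_000 <= pos < 20_000 or 40_000 <= pos < 41_000
            in_exon = (10_000 <= pos < 12_000 or 15_000 <= pos < 20_000
                       or 40_000 <= pos < 44_000 or 46_000 <= pos < 50_000)
            in_body = 10_000 <= pos < 20_000 or 40_000 <= pos < 50_000
            in_down = (20_000 <= pos < 23_000) or (37_000 <= pos < 40_000)
            if in_utr5:
                return "five_prime_UTR"
            if in_utr3:
                return "three_prime_UTR"
            if in_exon:
                return "exon"
            if in_body:
                return "intron"
            if in_down:
                return "downstream"
            return "distal_intergenic"

        rng = np.random.default_rng(16)
        anchors = rng.integers(0, 60_000, size=200)
        peaks = _peaks([(int(a) - 10, int(a) + 10) for a in anchors])
        dist = regulome.genomic_distribution(peaks, m)
        expected = pd.Series([oracle(int(a)) for a in anchors]) \
            .value_counts(normalize=True)
        for cat in CATEGORIES:
            assert dist[cat] == pytest.approx(expected.get(cat, 0.0),
                                              abs=1e-9)


class TestThresholdDeg:
    def test_strict_threshold(self):
        t = pd.DataFrame({"gene_id": ["a", "b", "c"],
                          "log2fc": [1, 1, 1],
                          "fdr": [0.01, 0.05, 0.049]})
        assert regulome.threshold_deg(t, 0.05) == {"a", "c"}

    def test_empty_table(self):
        t = pd.DataFrame({"gene_id": [], "log2fc": [], "fdr": []})
        assert regulome.threshold_deg(t) == set()

    def test_duplicates_keep_min(self):
        t = pd.DataFrame({"gene_id": ["a", "a"], "log2fc": [1, 1],
                          "fdr": [0.9, 0.01]})
        assert regulome.threshold_deg(t) == {"a"}


class TestCoreProgram:
    def test_hand_example(self):
        prog = regulome.core_program({"A", "B", "C"}, {"B", "C", "D"},
                                     {"C", "B", "E"})
        assert prog.core == {"B", "C"}
        assert prog.venn["core"] == 2

    def test_empty_input_empty_core(self):
        assert regulome.core_program(set(), {"A"}, {"A"}).core == frozenset()

    def test_venn_regions_sum_to_union(self):
        rng = np.random.default_rng(17)
        pool = [f"g{i}" for i in range(50)]
        a = set(rng.choice(pool, 20, replace=False))
        b = set(rng.choice(pool, 25, replace=False))
        c = set(rng.choice(pool, 15, replace=False))
        prog = regulome.core_program(a, b, c)
        assert sum(prog.venn.values()) == prog.union_size
        assert prog.core <= a and prog.core <= b and prog.core <= c
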