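"""Replicate concordance, common/specific labels, level comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest

import meriptools as mt
from meriptools.compare import (
    AMBIGUOUS,
    COMMON,
    SPECIFIC_A,
    SPECIFIC_B,
    classify_genes,
    classify_peaks,
    concordant,
    subsample_control,
)
from meriptools.peaks import Peak
from meriptools.transcriptome import TranscriptModel


def peak(tx, start, end, fe=4.0, q=1e-3):
    return Peak(tx, start, end, fe, q)


class TestConcordant:
    def test_half_overlap_boundary_not_concordant(self):
        # overlap 50 nt == 50% of the shorter peak (100 nt): strict >, fails
        assert concordant([peak("t1", 100, 200)], [peak("t1", 150, 300)]) == []

    def test_majority_overlap_union_emitted(self):
        out = concordant([peak("t1", 100, 200)], [peak("t1", 120, 210)], tissue="A")
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (100, 210)
        assert out[0].tissue == "A"

    def test_identical_peaks(self):
        out = concordant([peak("t1", 50, 150)], [peak("t1", 50, 150)])
        assert (out[0].start, out[0].end) == (50, 150)

    def test_symmetric_in_replicate_order(self):
        r1 = [peak("t1", 0, 200), peak("t1", 500, 700), peak("t2", 10, 110)]
        r2 = [peak("t1", 50, 260), peak("t2", 40, 150)]
        fwd = concordant(r1, r2)
        rev = concordant(r2, r1)
        assert [(c.transcript_id, c.start, c.end) for c in fwd] == [
            (c.transcript_id, c.start, c.end) for c in rev
        ]

    def test_each_peak_used_at_most_once(self):
        # one rep-2 peak overlaps two rep-1 peaks; best overlap wins
        r1 = [peak("t1", 0, 100), peak("t1", 80, 200)]
        r2 = [peak("t1", 60, 190)]
        out = concordant(r1, r2)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (60, 200)

    def test_different_transcripts_never_match(self):
        assert concordant([peak("t1", 0, 100)], [peak("t2", 0, 100)]) == []

    def test_log2_fe_is_replicate_mean(self):
        out = concordant([peak("t1", 0, 100, fe=4.0)], [peak("t1", 0, 100, fe=16.0)])
        assert out[0].log2_fe == pytest.approx(3.0)  # mean of 2 and 4


def _pattern_outcome(a1, a2, b1, b2):
    """Run the classifier on one replicate-presence pattern of a single
    locus and return the set of (tissue, label) pairs emitted."""
    iv = peak("t1", 100, 300)
    reps_a = [[iv] if a1 else [], [iv] if a2 else []]
    reps_b = [[iv] if b1 else [], [iv] if b2 else []]
    conc_a = concordant(reps_a[0], reps_a[1], tissue="A")
    conc_b = concordant(reps_b[0], reps_b[1], tissue="B")
    out = classify_peaks(conc_a, conc_b, reps_a, reps_b)
    return {(pc.peak.tissue, pc.label) for pc in out}


class TestClassifyPeaks:
    def test_present_everywhere_is_common(self):
        assert _pattern_outcome(1, 1, 1, 1) == {("A", COMMON), ("B", COMMON)}

    def test_one_tissue_only_is_specific(self):
        assert _pattern_outcome(1, 1, 0, 0) == {("A", SPECIFIC_A)}
        assert _pattern_outcome(0, 0, 1, 1) == {("B", SPECIFIC_B)}

    def test_single_other_replicate_is_ambiguous(self):
        assert _pattern_outcome(1, 1, 1, 0) == {("A", AMBIGUOUS)}
        assert _pattern_outcome(1, 1, 0, 1) == {("A", AMBIGUOUS)}

    def test_no_concordant_peak_nothing_emitted(self):
        for a1, a2 in [(1, 0), (0, 1), (0, 0)]:
            assert _pattern_outcome(a1, a2, 1, 0) == set()

    def test_every_concordant_peak_gets_exactly_one_label(self):
        for bits in itertools.product([0, 1], repeat=4):
            out = _pattern_outcome(*bits)
            expected_n = (bits[0] & bits[1]) + (bits[2] & bits[3])
            assert len(out) == expected_n


def _models():
    return [
        TranscriptModel("g1", "t1", "lncRNA", 2000),
        TranscriptModel("g2", "t2", "lncRNA", 2000),
        TranscriptModel("g3", "t3", "lncRNA", 2000),
    ]


def _classified(tx, label, start=0, end=200, fe=2.0, tissue="A"):
    c = mt.ConcordantPeak(tx, start, end, (1e-3, 1e-3), fe, tissue)
    return mt.PeakClassification(c, label)


class TestClassifyGenes:
    def test_common_peak_takes_precedence(self):
        out = classify_genes(
            [_classified("t1", COMMON), _classified("t1", SPECIFIC_A, start=500, end=700)],
            _models(),
        )
        assert out[0].label == "CMR" and out[0].n_peaks == 2

    def test_specific_only_gene_is_smr(self):
        out = classify_genes([_classified("t2", SPECIFIC_B, tissue="B")], _models())
        assert out[0].gene_id == "g2" and out[0].label == "SMR_B"

    def test_specific_in_both_tissues_is_mixed(self):
        out = classify_genes(
            [_classified("t1", SPECIFIC_A), _classified("t1", SPECIFIC_B, start=500, end=700, tissue="B")],
            _models(),
        )
        assert out[0].label == "mixed"

    def test_peakless_gene_reported_unmethylated(self):
        out = classify_genes(
            [_classified("t1", COMMON)], _models(), gene_universe=["g1", "g2", "g3"]
        )
        labels = {g.gene_id: g.label for g in out}
        assert labels == {"g1": "CMR", "g2": "unmethylated", "g3": "unmethylated"}

    def test_ambiguous_peaks_excluded(self):
        out = classify_genes([_classified("t1", AMBIGUOUS)], _models())
        assert out == []

    def test_gene_fe_is_mean_of_peak_fes(self):
        out = classify_genes(
            [_classified("t1", COMMON, fe=1.0), _classified("t1", COMMON, start=500, end=700, fe=3.0)],
            _models(),
        )
        assert out[0].gene_log2_fe == pytest.approx(2.0)


class TestCompareLevels:
    def test_identical_sets_maximal_p(self):
        m1, m2, p = mt.compare_levels([1.0, 2.0, 3.0] * 10, [1.0, 2.0, 3.0] * 10)
        assert m1 == m2 and p > 0.9

    def test_shifted_sample_detected(self):
        rng = np.random.default_rng(0)
        base = rng.normal(2.0, 0.5, size=100)
        m1, m2, p = mt.compare_levels(base + 1.0, base)
        assert m1 - m2 == pytest.approx(1.0)
        assert p < 0.01

    def test_small_sample_exact_p_matches_permutation_oracle(self):
        x, y = [1.0, 5.0, 7.0], [2.0, 3.0, 4.0]
        pooled = x + y
        n = len(x)
        obs = sum(sorted(pooled).index(v) + 1 for v in x)
        perms = [
            sum(sorted(pooled).index(pooled[i]) + 1 for i in comb)
            for comb in itertools.combinations(range(6), n)
        ]
        mean = np.mean(perms)
        p_exact = np.mean([abs(w - mean) >= abs(obs - mean) - 1e-12 for w in perms])
        _, _, p = mt.compare_levels(x, y)
        assert p == pytest.approx(p_exact)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            mt.compare_levels([], [1.0])


class TestSubsampleControl:
    def test_draw_count_and_determinism(self):
        cmr = list(np.random.default_rng(1).normal(3, 1, 50))
        smr = list(np.random.default_rng(2).normal(2, 1, 20))
        a = subsample_control(cmr, smr, draws=10, seed=7)
        b = subsample_control(cmr, smr, draws=10, seed=7)
        assert len(a) == 10
        pd.testing.assert_frame_equal(a, b)

    def test_null_draws_have_zero_median_difference(self):
        values = list(np.random.default_rng(3).normal(0, 1, 40))
        out = subsample_control(values, values, draws=5, seed=1)
        assert np.allclose(out["median_smr"], np.median(values))
        assert np.abs(out["median_cmr_sample"] - np.median(values)).max() < 1.0

    def test_smaller_cmr_set_rejected(self):
        with pytest.raises(ValueError):
            subsample_control([1.0], [1.0, 2.0])


class TestExpressionVsMethylation:
    def _setup(self, rho_sign):
        genes = [f"g{i}" for i in range(20)]
        fpkm = np.linspace(1, 20, 20)
        fe = -fpkm if rho_sign < 0 else np.random.default_rng(0).normal(size=20)
        expr = pd.DataFrame({"gene_id": genes + ["u1", "u2"],
                             "fpkm": list(fpkm) + [0.1, 0.2]})
        gm = [mt.GeneMethylation(g, 1, float(f), "CMR") for g, f in zip(genes, fe)]
        return expr, gm

    def test_perfect_monotone_negative_correlation(self):
        expr, gm = self._setup(-1)
        out = mt.expression_vs_methylation(expr, gm)
        assert out["spearman_rho"] == pytest.approx(-1.0)
        assert out["median_fpkm_methylated"] > out["median_fpkm_unmethylated"]

    def test_rho_matches_rank_formula(self):
        expr, gm = self._setup(0)
        out = mt.expression_vs_methylation(expr, gm)
        # Spearman via the closed-form rank-difference formula (no ties)
        fpkm_ranks = pd.Series([e for e in expr["fpkm"][:20]]).rank().to_numpy()
        fe_ranks = pd.Series([g.gene_log2_fe for g in gm]).rank().to_numpy()
        d2 = ((fpkm_ranks - fe_ranks) ** 2).sum()
        n = 20
        rho = 1 - 6 * d2 / (n * (n**2 - 1))
        assert out["spearman_rho"] == pytest.approx(rho)

    def test_too_few_methylated_genes_rejected(self):
        expr = pd.DataFrame({"gene_id": ["g0", "g1"], "fpkm": [1.0, 2.0]})
        gm = [mt.GeneMethylation("g0", 1, 1.0, "CMR")]
        with pytest.raises(ValueError):
            mt.expression_vs_methylation(expr, gm)
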