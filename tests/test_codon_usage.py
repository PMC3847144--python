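from collections import Counter

import numpy as np
import pytest

from xenosig import codon_usage as cu
from xenosig.genetic_code import (
    degenerate_codons,
    rscu_chi2_df,
    synonymous_families,
)


def equal_usage_counts(per_codon=2):
    """Each degenerate codon used equally often within its family."""
    return Counter({c: per_codon for c in degenerate_codons()})


def random_counts(rng, lo=0, hi=30):
    return Counter({c: int(rng.integers(lo, hi)) for c in degenerate_codons()})


class TestRSCU:
    def test_equal_usage_gives_one_everywhere(self):
        table = cu.rscu(equal_usage_counts())
        assert all(v == pytest.approx(1.0) for v in table.rscu.values())

    def test_phe_three_to_one_example(self):
        table = cu.rscu(Counter({"TTT": 3, "TTC": 1}))
        assert table.rscu["TTT"] == pytest.approx(1.5)
        assert table.rscu["TTC"] == pytest.approx(0.5)

    def test_absent_amino_acid_marked_missing(self):
        table = cu.rscu(Counter({"TTT": 3}))
        assert np.isnan(table.rscu["GGG"])  # no Gly counted
        assert table.aa_counts["G"] == 0

    def test_matches_per_family_oracle(self):
        rng = np.random.default_rng(0)
        counts = random_counts(rng, lo=1)
        table = cu.rscu(counts)
        for aa, codons in synonymous_families().items():
            total = sum(counts[c] for c in codons)
            for c in codons:
                assert table.rscu[c] == pytest.approx(len(codons) * counts[c] / total)

    def test_family_mean_is_one_for_present_amino_acids(self):
        rng = np.random.default_rng(1)
        table = cu.rscu(random_counts(rng))
        for aa, codons in synonymous_families().items():
            if table.aa_counts[aa] > 0:
                mean = np.mean([table.rscu[c] for c in codons])
                assert mean == pytest.approx(1.0)


class TestChi2:
    def test_df_computed_from_code_table(self):
        fams = synonymous_families()
        assert rscu_chi2_df() == sum(len(v) for v in fams.values()) - len(fams) == 41

    def test_gene_matching_reference_scores_zero(self):
        ref = cu.rscu(Counter({"TTT": 30, "TTC": 10}))
        result = cu.rscu_chi2_test(Counter({"TTT": 3, "TTC": 1}), ref)
        assert result.chi2 == pytest.approx(0.0)
        assert result.df == 41
        assert result.p == pytest.approx(1.0)

    def test_toy_hand_summation(self):
        ref = cu.rscu(Counter({"TTT": 3, "TTC": 1, "CAA": 1, "CAG": 1}))
        gene = Counter({"TTT": 1, "TTC": 3, "CAA": 2})
        result = cu.rscu_chi2_test(gene, ref)
        # Phe: expected (3, 1); Gln: expected (1, 0) over CAA, CAG -> CAG cell
        # has expectation 1 with observation 0
        expect = (1 - 3) ** 2 / 3 + (3 - 1) ** 2 / 1 + (2 - 1) ** 2 / 1 + (0 - 1) ** 2 / 1
        assert result.chi2 == pytest.approx(expect)
        assert result.effective_df == 2

    def test_invariant_under_reference_scaling(self):
        rng = np.random.default_rng(2)
        counts = random_counts(rng, lo=1)
        gene = random_counts(rng, lo=0, hi=5)
        r1 = cu.rscu_chi2_test(gene, cu.rscu(counts))
        r2 = cu.rscu_chi2_test(gene, cu.rscu(Counter({c: 7 * n for c, n in counts.items()})))
        assert r1.chi2 == pytest.approx(r2.chi2)

    def test_null_calibration_with_fixed_df(self, small_genome):
        """Genes drawn from the genome's model reject at roughly alpha."""
        ref = cu.rscu(cu.count_codons(small_genome))
        ps = [cu.rscu_chi2_test(cu.count_codons(g), ref).p for g in small_genome]
        rate = np.mean(np.array(ps) < 0.05)
        assert rate <= 0.12


class TestCAI:
    def test_max_codon_gene_scores_one(self):
        rng = np.random.default_rng(3)
        ref = cu.rscu(random_counts(rng, lo=1))
        gene = Counter()
        for aa, codons in synonymous_families().items():
            best = max(codons, key=lambda c: ref.rscu[c])
            gene[best] = 5
        result = cu.cai(gene, ref)
        assert result.cai == pytest.approx(1.0)
        assert result.cai_obs == pytest.approx(result.cai_max)

    def test_rare_codon_two_fold_ratio(self):
        ref = cu.rscu(Counter({"TTT": 4, "TTC": 1}))  # RSCU 1.6 / 0.4
        result = cu.cai(Counter({"TTC": 7}), ref)
        assert result.cai == pytest.approx(0.4 / 1.6)

    def test_bounded_and_obs_below_max(self):
        rng = np.random.default_rng(4)
        ref = cu.rscu(random_counts(rng, lo=1))
        for _ in range(200):
            gene = random_counts(rng, lo=0, hi=8)
            if sum(gene.values()) == 0:
                continue
            r = cu.cai(gene, ref)
            assert 0.0 <= r.cai <= 1.0
            assert r.cai_obs <= r.cai_max + 1e-12

    def test_matches_occurrence_oracle(self):
        rng = np.random.default_rng(5)
        ref = cu.rscu(random_counts(rng, lo=1))
        gene = random_counts(rng, lo=0, hi=6)
        obs, mx, n = 0.0, 0.0, 0
        for aa, codons in synonymous_families().items():
            fam_max = max(ref.rscu[c] for c in codons)
            for c in codons:
                obs += gene[c] * ref.rscu[c]
                mx += gene[c] * fam_max
                n += gene[c]
        r = cu.cai(gene, ref)
        assert r.cai == pytest.approx((obs / n) / (mx / n))

    def test_absent_reference_amino_acid_skipped_with_warning(self):
        ref = cu.rscu(Counter({"TTT": 4, "TTC": 1}))
        with pytest.warns(UserWarning, match="absent"):
            r = cu.cai(Counter({"TTC": 1, "GGG": 5}), ref)
        assert r.n_codons == 1


class TestCAIDeviation:
    def test_threshold_rule(self):
        s = cu.GenomeCAISummary(mean=0.7, dispersion=0.05, n_genes=100)
        assert cu.cai_deviation_flag(0.7 + 1.6 * 0.05, s)
        assert not cu.cai_deviation_flag(0.7 + 1.4 * 0.05, s)

    def test_flag_rate_matches_empirical_quantile(self, small_genome):
        ref = cu.rscu(cu.count_codons(small_genome))
        vals = np.array([cu.cai(cu.count_codons(g), ref).cai for g in small_genome])
        s = cu.genome_cai_summary(vals)
        flags = np.array([cu.cai_deviation_flag(v, s) for v in vals])
        outside = np.abs(vals - s.mean) > 1.5 * s.dispersion
        assert (flags == outside).all()

    def test_zero_dispersion_raises(self):
        s = cu.GenomeCAISummary(mean=0.7, dispersion=0.0, n_genes=10)
        with pytest.raises(ValueError):
            cu.cai_deviation_flag(0.8, s)


class TestCAIVariants:
    def test_geometric_mean_still_scores_one_for_max_gene(self):
        rng = np.random.default_rng(6)
        ref = cu.rscu(random_counts(rng, lo=1))
        gene = Counter()
        for aa, codons in synonymous_families().items():
            gene[max(codons, key=lambda c: ref.rscu[c])] = 3
        r = cu.cai(gene, ref, mean="geometric")
        assert r.cai == pytest.approx(1.0)

    def test_geometric_differs_from_arithmetic_on_biased_gene(self):
        ref = cu.rscu(Counter({"TTT": 9, "TTC": 1, "CAA": 5, "CAG": 5}))
        gene = Counter({"TTC": 3, "CAA": 2})
        arith = cu.cai(gene, ref).cai
        geom = cu.cai(gene, ref, mean="geometric").cai
        assert arith != pytest.approx(geom)
        assert 0 < geom <= 1

    def test_genome_level_max_is_occurrence_independent(self):
        rng = np.random.default_rng(7)
        ref = cu.rscu(random_counts(rng, lo=1))
        g1 = Counter({"TTT": 10})
        g2 = Counter({"TTT": 1})
        r1 = cu.cai(g1, ref, max_weighting="genome")
        r2 = cu.cai(g2, ref, max_weighting="genome")
        assert r1.cai_max == pytest.approx(r2.cai_max)


class TestGenomeReference:
    def test_pooled_equals_direct_rscu(self, small_genome):
        ref = cu.genome_reference(small_genome, method="pooled")
        direct = cu.rscu(cu.count_codons(small_genome))
        assert ref.rscu == direct.rscu

    def test_mean_reference_preserves_family_normalisation(self, small_genome):
        ref = cu.genome_reference(small_genome[:30], method="mean")
        for aa, codons in synonymous_families().items():
            vals = [ref.rscu[c] for c in codons]
            if not any(np.isnan(v) for v in vals):
                assert np.mean(vals) == pytest.approx(1.0, abs=1e-9)
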