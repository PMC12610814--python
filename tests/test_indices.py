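"""RSCU, SCUO, homozygosity, ENC, CAI and the 1-CAI expression proxy."""

import math

import numpy as np
import pytest

from plastcub import (CodonCountTable, cai, count_codons, enc_expected,
                      enc_observed, family_homozygosity, milc, profile_gene,
                      profile_genes, relative_adaptiveness, rscu, scuo)

from oracles import bf_homozygosity, bf_rscu, bf_scuo, random_count_table


def uniform_counts(code, per_codon=100):
    return CodonCountTable({c: per_codon for c in code.codon_to_aa})


def one_codon_per_aa(code, per_codon=100):
    return CodonCountTable({fam[0]: per_codon for fam in code.families.values()})


class TestRSCU:
    def test_uniform_usage_gives_all_ones(self, code):
        vec = rscu(uniform_counts(code), code)
        assert len(vec.values) == 59
        assert all(v == pytest.approx(1.0) for v in vec.values.values())

    def test_leucine_hand_computation(self, code):
        """{UUA:4, UUG:2, rest 0} -> X=(4,2,.5,.5,.5,.5), RSCU(UUA)=3."""
        vec = rscu(CodonCountTable({"UUA": 4, "UUG": 2}), code)
        assert vec["UUA"] == pytest.approx(3.0)
        assert vec["UUG"] == pytest.approx(1.5)
        assert vec["CUU"] == pytest.approx(0.375)
        assert "CUU" in vec.zero_substituted
        assert "UUA" not in vec.zero_substituted

    def test_unobserved_family_is_uniform(self, code):
        """A family never used gets 0.5 everywhere -> RSCU 1 by symmetry."""
        vec = rscu(CodonCountTable({"AUG": 10}), code)
        for c in code.families["L"]:
            assert vec[c] == pytest.approx(1.0)

    def test_empty_table_errors(self, code):
        with pytest.raises(ValueError):
            rscu(CodonCountTable({}), code)

    def test_family_sums_equal_degeneracy_on_random_tables(self, code, rng):
        """sum_j RSCU_ij = n_i for every family, any input."""
        for _ in range(20):
            counts = CodonCountTable(random_count_table(rng, code.families))
            vec = rscu(counts, code)
            for aa, codons in code.multi_codon_families.items():
                assert vec.family_sum(aa) == pytest.approx(len(codons))


class TestSCUO:
    def test_single_codon_certainty(self, code):
        """A 2-fold family used as (1,0) has zero entropy -> SCUO_i = 1."""
        _, per = scuo(CodonCountTable({"UUU": 1}), code)
        assert per["F"] == pytest.approx(1.0)

    def test_equal_usage_zero_order(self, code):
        _, per = scuo(CodonCountTable({"UUU": 3, "UUC": 3}), code)
        assert per["F"] == pytest.approx(0.0)

    def test_asymmetric_two_fold_entropy(self, code):
        """p=(0.75,0.25): H ~ 0.8113, SCUO_i ~ 0.1887."""
        _, per = scuo(CodonCountTable({"UUU": 3, "UUC": 1}), code)
        assert per["F"] == pytest.approx(0.18872187, abs=1e-6)

    def test_no_multicodon_family_flagged_nan(self, code):
        value, per = scuo(CodonCountTable({"AUG": 5, "UGG": 2}), code)
        assert math.isnan(value) and per == {}

    def test_bounded_in_unit_interval(self, code, rng):
        for _ in range(10):
            value, per = scuo(
                CodonCountTable(random_count_table(rng, code.families)), code)
            assert 0.0 <= value <= 1.0
            assert all(0.0 <= v <= 1.0 for v in per.values())


class TestHomozygosity:
    @pytest.mark.parametrize("counts,expected", [
        ((3, 1), 0.5),
        ((2, 2), 1 / 3),
        ((100, 0), 1.0),
    ])
    def test_direct_arithmetic(self, counts, expected):
        assert family_homozygosity(counts) == pytest.approx(expected)

    @pytest.mark.parametrize("counts", [(1, 0), (0, 0), (1,)])
    def test_small_families_unusable(self, counts):
        assert family_homozygosity(counts) is None

    def test_equal_pair_of_ones_unusable(self):
        """(1,1) gives F=0, which is unusable for the ENC harmonic mean."""
        assert family_homozygosity((1, 1)) is None


class TestENC:
    def test_one_codon_per_amino_acid_is_20(self, code):
        enc, raw = enc_observed(one_codon_per_aa(code), code)
        assert enc == pytest.approx(20.0)
        assert raw == pytest.approx(20.0)

    def test_equal_usage_caps_at_61(self, code):
        enc, raw = enc_observed(uniform_counts(code), code)
        assert enc == 61.0
        assert raw > 61.0  # finite-sample estimator exceeds 61 before capping

    def test_missing_3fold_class_imputed(self, code):
        """Without Ile the 3-fold class average is (F2+F4)/2."""
        counts = {fam[0]: 50 for aa, fam in code.families.items()
                  if aa != "I"}
        enc, _ = enc_observed(CodonCountTable(counts), code)
        assert enc == pytest.approx(20.0)  # all F=1, imputed F3=1

    def test_missing_2fold_class_undefined(self, code):
        counts = {code.families[aa][0]: 50 for aa in ("L", "V", "I")}
        enc, _ = enc_observed(CodonCountTable(counts), code)
        assert math.isnan(enc)

    @pytest.mark.parametrize("gc3,expected", [
        (0.5, 60.5), (0.0, 31.0), (1.0, 32.0)])
    def test_expected_curve_closed_form(self, gc3, expected):
        assert enc_expected(gc3) == pytest.approx(expected)

    def test_expected_curve_near_symmetry(self):
        """The 29/(s^2+(1-s)^2) term is symmetric about 0.5; the linear
        GC3 term offsets the two branches by exactly 2d."""
        for d in (0.1, 0.25, 0.4):
            assert enc_expected(0.5 + d) - enc_expected(0.5 - d) == \
                pytest.approx(2 * d)

    def test_expected_curve_domain_error(self):
        with pytest.raises(ValueError):
            enc_expected(1.2)


class TestCAI:
    def test_reference_maximal_codons_give_one(self, code):
        ref = rscu(CodonCountTable({"UUA": 8, "UUG": 2, "GCU": 9, "GCA": 3}),
                   code)
        gene = CodonCountTable({"UUA": 5, "GCU": 5})
        assert cai(gene, ref) == pytest.approx(1.0)

    def test_two_codon_geometric_mean(self, code):
        """w = (1, 0.25) used once each -> CAI = sqrt(0.25) = 0.5."""
        w = {"UUA": 1.0, "UUG": 0.25}
        gene = CodonCountTable({"UUA": 1, "UUG": 1})
        assert cai(gene, w) == pytest.approx(0.5)

    def test_self_reference_uniform_gene_is_one(self, code):
        gene = uniform_counts(code)
        ref = rscu(gene, code)
        assert cai(gene, ref) == pytest.approx(1.0)

    def test_empty_reference_errors(self, code):
        with pytest.raises(ValueError):
            cai(CodonCountTable({"UUA": 1}), {})

    def test_milc_is_exact_complement(self):
        assert milc(1.0) == 0.0
        assert milc(0.3) == pytest.approx(0.7)


class TestOracleEquivalence:
    def test_formula_oracles_agree_on_100_random_tables(self, code):
        """RSCU, SCUO and F agree with brute-force formulas to 1e-12."""
        rng = np.random.default_rng(4242)
        for _ in range(100):
            raw = random_count_table(rng, code.families)
            if not raw:
                continue
            counts = CodonCountTable(raw)
            vec = rscu(counts, code)
            ours_scuo, ours_per = scuo(counts, code)
            bf_vec = bf_rscu(raw, code.families)
            bf_val, bf_per = bf_scuo(raw, code.families)
            for c in code.analyzable_codons:
                assert vec[c] == pytest.approx(bf_vec[c], abs=1e-12)
            if math.isnan(ours_scuo):
                assert math.isnan(bf_val)
            else:
                assert ours_scuo == pytest.approx(bf_val, abs=1e-12)
            for aa, codons in code.multi_codon_families.items():
                x = counts.family_counts(code, aa)
                ours_f = family_homozygosity(x)
                bf_f = bf_homozygosity(x)
                if ours_f is None:
                    assert bf_f is None
                else:
                    assert ours_f == pytest.approx(bf_f, abs=1e-12)


class TestProfiles:
    def test_profile_fields_consistent(self, uniform_profiles):
        for p in uniform_profiles[:10]:
            assert p.milc == pytest.approx(1.0 - p.cai)
            assert 20.0 <= p.enc_obs <= 61.0 or math.isnan(p.enc_obs)
            assert 0.0 <= p.scuo <= 1.0
            assert 0.0 <= p.pr2_x <= 1.0 and 0.0 <= p.pr2_y <= 1.0

    def test_single_gene_self_reference(self, code):
        seq = "ATG" + "TTAGCT" * 60 + "TAA"
        p = profile_gene(seq, code)
        assert p.cai == pytest.approx(1.0)  # own maximal codons only

    def test_unknown_reference_rejected(self, uniform_set):
        with pytest.raises(ValueError):
            profile_genes(uniform_set, reference="mystery")
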