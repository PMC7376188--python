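"""Frequencies, diversity statistics, HWE and LD testing."""

import numpy as np
import pytest

from strmps.genotyping import GenotypeCall
from strmps.nomenclature import SequenceAllele, allele_from_sequence
from strmps.locus_model import FlankVariant
from strmps.popgen import (
    FrequencyTable,
    HaplotypeTable,
    allele_frequencies,
    bonferroni,
    effective_alleles,
    flank_variant_frequencies,
    genetic_diversity,
    haplotype_diversity,
    hwe_test,
    ld_test,
    locus_parameters,
    pair_count,
    pic,
    rmp,
)


def _cohort_calls(locus, genotype_by_sample):
    return [GenotypeCall(sample, locus, tuple(alleles),
                         tuple([500] * len(alleles)),
                         acr=0.9 if len(alleles) == 2 else None)
            for sample, alleles in genotype_by_sample.items()]


def _sexes(n_female=54, n_male=53):
    sexes = {f"F{i:03d}": "female" for i in range(n_female)}
    sexes.update({f"M{i:03d}": "male" for i in range(n_male)})
    return sexes


class TestAlleleFrequencies:
    def test_x_locus_denominator_is_2f_plus_m(self, loci):
        """One male variant among 54 females + 53 males: 1/161 = 0.0062."""
        cfg = loci["DXS8378"]
        ref = allele_from_sequence("DXS8378", "ATAG" * 10, cfg)
        var = SequenceAllele("DXS8378", ref.structure,
                             (FlankVariant("substitution", 9402257, alt="G"),))
        sexes = _sexes()
        genotypes = {s: (ref,) for s in sexes}
        genotypes["M000"] = (var,)
        table = allele_frequencies(_cohort_calls("DXS8378", genotypes), cfg,
                                   sexes)
        assert table.denominator == 161
        assert round(table.frequency(var), 4) == 0.0062

    def test_autosomal_denominator_is_2n(self, loci):
        """One variant chromosome among 107 individuals: 1/214 = 0.0047."""
        cfg = loci["D6S1043"]
        ref = allele_from_sequence("D6S1043", "ATCT" * 12, cfg)
        var = SequenceAllele("D6S1043", ref.structure,
                             (FlankVariant("substitution", 91740273, alt="A"),))
        sexes = _sexes()
        genotypes = {s: (ref,) for s in sexes}
        genotypes["F000"] = (ref, var)
        table = allele_frequencies(_cohort_calls("D6S1043", genotypes), cfg,
                                   sexes)
        assert table.denominator == 214
        assert round(table.frequency(var), 4) == 0.0047

    def test_y_locus_counts_males_only(self, loci):
        cfg = loci["DYS390"]
        a = allele_from_sequence(
            "DYS390", "TAGA" * 4 + "CAGA" + "TAGA" * 10 + "CAGA" * 9, cfg)
        sexes = _sexes()
        calls = [GenotypeCall(s, "DYS390", (a,), (500,))
                 for s in sexes if s.startswith("M")]
        table = allele_frequencies(calls, cfg, sexes)
        assert table.denominator == 53
        assert table.frequency(a) == 1.0

    def test_missing_sex_excluded_with_warning(self, loci):
        cfg = loci["DXS8378"]
        a = allele_from_sequence("DXS8378", "ATAG" * 10, cfg)
        calls = [GenotypeCall("S1", "DXS8378", (a,), (500,)),
                 GenotypeCall("S2", "DXS8378", (a,), (500,))]
        with pytest.warns(UserWarning, match="no sex"):
            table = allele_frequencies(calls, cfg, {"S1": "female"})
        assert table.denominator == 2

    def test_counts_are_exact_rationals(self):
        table = FrequencyTable.from_counts("L", {"a": 3, "b": 1})
        assert table.denominator == 4
        assert np.isclose(table.p.sum(), 1.0, atol=1e-12)


class TestFlankVariantFrequencies:
    def test_carrier_chromosomes_over_y_denominator(self, loci):
        """Variant carried by alleles with counts 7 + 15 + 1 among 53 males
        has frequency 23/53 = 0.4340."""
        cfg = loci["Y-GATA-H4"]
        sub = FlankVariant("substitution", 16631756, alt="G")
        pool = {n: SequenceAllele(
            "Y-GATA-H4",
            allele_from_sequence("Y-GATA-H4", "TCTA" * n, cfg).structure,
            (sub,)) for n in (10, 11, 12)}
        plain = allele_from_sequence("Y-GATA-H4", "TCTA" * 9, cfg)
        sexes = {f"M{i:03d}": "male" for i in range(53)}
        carriers = [pool[10]] * 7 + [pool[11]] * 15 + [pool[12]] * 1
        alleles = carriers + [plain] * (53 - len(carriers))
        calls = [GenotypeCall(s, "Y-GATA-H4", (a,), (500,))
                 for s, a in zip(sorted(sexes), alleles)]
        df = flank_variant_frequencies(calls, cfg, sexes)
        assert len(df) == 1
        row = df.iloc[0]
        assert (row["count"], row["denominator"]) == (23, 53)
        assert row["frequency"] == 0.4340

    def test_variant_on_every_chromosome(self, loci):
        cfg = loci["DXS8378"]
        sub = FlankVariant("substitution", 9402257, alt="G")
        a = SequenceAllele(
            "DXS8378",
            allele_from_sequence("DXS8378", "ATAG" * 10, cfg).structure,
            (sub,))
        sexes = _sexes(2, 1)
        calls = _cohort_calls("DXS8378", {s: (a,) for s in sexes})
        df = flank_variant_frequencies(calls, cfg, sexes)
        assert df.iloc[0]["frequency"] == 1.0

    def test_repeat_region_variants_not_counted(self, loci):
        cfg = loci["DYS448"]
        deletion = FlankVariant.parse("22,218,995–22,219,000 DEL")
        a = SequenceAllele(
            "DYS448",
            allele_from_sequence(
                "DYS448", "AGAGAT" * 11 + "N" * 36 + "AGAGAT" * 8, cfg
            ).structure,
            (deletion,))
        sexes = {"M1": "male"}
        calls = [GenotypeCall("M1", "DYS448", (a,), (500,))]
        df = flank_variant_frequencies(calls, cfg, sexes)
        assert df.empty

    def test_planted_frequency_recovered(self, loci):
        """A variant planted at 0.20 lands inside its binomial 99% interval."""
        from scipy.stats import binom

        cfg = loci["D6S1043"]
        ref = allele_from_sequence("D6S1043", "ATCT" * 12, cfg)
        var = SequenceAllele("D6S1043", ref.structure,
                             (FlankVariant("substitution", 91740273, alt="A"),))
        rng = np.random.default_rng(42)
        n = 200
        sexes = {f"S{i:03d}": "female" for i in range(n)}
        calls = []
        for s in sorted(sexes):
            pair = tuple(var if rng.random() < 0.2 else ref for _ in range(2))
            alleles = tuple(sorted(set(pair), key=id)) if pair[0] is not pair[1] \
                else (pair[0],)
            calls.append(GenotypeCall(
                s, "D6S1043", alleles, (500,) * len(alleles),
                acr=0.9 if len(alleles) == 2 else None))
        df = flank_variant_frequencies(calls, cfg, sexes)
        count = int(df.iloc[0]["count"]) if len(df) else 0
        lo, hi = binom.ppf([0.005, 0.995], 2 * n, 0.2)
        assert lo <= count <= hi


class TestDiversity:
    def test_two_allele_worked_value(self):
        table = FrequencyTable.from_counts("DYS391", {"10": 47, "11": 6})
        assert round(genetic_diversity(table), 4) == 0.2046

    def test_single_allele_diversity_zero(self):
        table = FrequencyTable.from_counts("L", {"a": 50})
        assert genetic_diversity(table) == 0.0

    def test_uniform_alleles_limit(self):
        p = np.full(4, 0.25)
        assert genetic_diversity(p, n=10**9) == pytest.approx(0.75, abs=1e-6)

    def test_undefined_below_two(self):
        with pytest.raises(ValueError):
            genetic_diversity(np.array([1.0]), n=1)

    def test_haplotype_diversity_worked_value(self):
        counts = {f"h{i}": 1 for i in range(48)}
        counts.update({"h48": 2, "h49": 3})
        table = HaplotypeTable.from_counts(counts)
        assert table.n == 53
        assert round(haplotype_diversity(table), 4) == 0.9971
        assert table.singleton_fraction == pytest.approx(0.96)

    def test_all_distinct_haplotypes_give_exactly_one(self):
        table = HaplotypeTable.from_counts({f"h{i}": 1 for i in range(20)})
        assert haplotype_diversity(table) == pytest.approx(1.0, abs=1e-12)

    def test_single_haplotype_diversity_zero(self):
        table = HaplotypeTable.from_counts({"h": 10})
        assert haplotype_diversity(table) == 0.0

    @pytest.mark.parametrize("p,expected", [
        ((0.25, 0.25, 0.25, 0.25), 4.0),
        ((0.5, 0.5), 2.0),
    ])
    def test_effective_alleles(self, p, expected):
        assert effective_alleles(np.array(p)) == pytest.approx(expected)

    def test_effective_alleles_bounded_by_allele_count(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            k = rng.integers(2, 8)
            p = rng.dirichlet(np.ones(k))
            ae = effective_alleles(p)
            assert 1.0 <= ae <= k + 1e-12


class TestLocusParameters:
    def test_biallelic_closed_forms(self, loci):
        table = FrequencyTable.from_counts("D7S820", {"a": 500000, "b": 500000})
        calls = [GenotypeCall(f"S{i}", "D7S820", ("a", "b"), (500, 500),
                              acr=1.0) for i in range(10)]
        par = locus_parameters(table, calls)
        assert par.hexp == pytest.approx(0.5, abs=1e-5)
        assert par.rmp == pytest.approx(0.375)
        assert par.dp == pytest.approx(0.625)
        assert par.hobs == 1.0

    def test_dp_complements_rmp_exactly(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            p = rng.dirichlet(np.ones(rng.integers(2, 9)))
            counts = np.maximum(1, (p * 1000).astype(int))
            table = FrequencyTable.from_counts(
                "L", {f"a{i}": int(c) for i, c in enumerate(counts)})
            par = locus_parameters(table)
            assert par.dp + par.rmp == 1.0

    def test_pic_below_large_n_heterozygosity(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            p = rng.dirichlet(np.ones(rng.integers(2, 9)))
            assert pic(p) <= 1.0 - np.sum(p * p) + 1e-12

    def test_hexp_equals_gene_diversity_estimator(self, loci):
        table = FrequencyTable.from_counts("L", {"a": 30, "b": 20, "c": 10})
        par = locus_parameters(table)
        assert par.hexp == genetic_diversity(table.p, n=table.denominator)

    def test_empty_genotype_set_rejected(self):
        table = FrequencyTable.from_counts("L", {"a": 10})
        with pytest.raises(ValueError, match="empty genotype"):
            locus_parameters(table, [GenotypeCall("S", "L",
                                                  flags=frozenset({"no_call"}))])


class TestHweTest:
    def test_exact_proportions_give_high_p(self):
        genotypes = ([("A", "A")] * 25 + [("A", "B")] * 50 + [("B", "B")] * 25)
        assert hwe_test(genotypes) > 0.9

    def test_monomorphic_locus_trivial(self):
        with pytest.warns(UserWarning, match="monomorphic"):
            assert hwe_test([("A", "A")] * 30) == 1.0

    def test_extreme_heterozygote_excess_rejected(self):
        genotypes = [("A", "B")] * 60
        assert hwe_test(genotypes) < 0.01

    def test_monte_carlo_agrees_with_enumeration(self):
        rng = np.random.default_rng(12)
        alleles = rng.choice(3, size=(40, 2), p=[0.5, 0.3, 0.2])
        genotypes = [tuple(sorted(map(str, row))) for row in alleles]
        p_exact = hwe_test(genotypes)
        p_mc = hwe_test(genotypes, seed=5, n_perm=20000, max_enum_states=0)
        se = np.sqrt(p_exact * (1 - p_exact) / 20000)
        assert abs(p_mc - p_exact) < 5 * se + 1e-4


class TestLdTest:
    def test_duplicated_locus_floor_p(self):
        rng = np.random.default_rng(4)
        genos = [tuple(sorted(rng.choice(["A", "B", "C"], 2)))
                 for _ in range(60)]
        assert ld_test(genos, genos, seed=1, n_perm=999) == 1 / 1000

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            ld_test([("A", "A")], [("A", "A"), ("A", "B")])

    @pytest.mark.parametrize("n,expected", [(26, 325), (94, 4371), (120, 7140)])
    def test_pair_count(self, n, expected):
        assert pair_count(n) == expected

    def test_bonferroni_exact(self):
        assert bonferroni(0.05, 7140) == 0.05 / 7140
        assert bonferroni(0.05, 26) == 0.05 / 26
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)
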