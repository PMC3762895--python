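"""Genotype algebra: ordering, segregation, inheritance, fitness, summaries."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aedesrr.genetics import (
    GENOTYPE_LABELS,
    allele_frequencies,
    build_inheritance_tensor,
    composite_ld,
    enumerate_genotypes,
    fitness_vector,
    gamete_distribution,
    genotype_by_label,
    inheritance_tensor_exact,
    viability_vector,
)


def brute_force_offspring_dist(mother, father):
    """Independent oracle: enumerate the 16 equiprobable gamete pairings.

    Each parent contributes one of its two alleles at each locus; the four
    maternal gamete choices cross the four paternal ones, each with
    probability 1/16 exactly.
    """
    def alleles(count):
        return ["T"] * count + ["w"] * (2 - count)

    dist = {}
    mk, ma = alleles(mother.n_K), alleles(mother.n_A)
    fk, fa = alleles(father.n_K), alleles(father.n_A)
    for gk_m in mk:
        for ga_m in ma:
            for gk_f in fk:
                for ga_f in fa:
                    n_K = (gk_m == "T") + (gk_f == "T")
                    n_A = (ga_m == "T") + (ga_f == "T")
                    dist[(n_K, n_A)] = dist.get((n_K, n_A), Fraction(0)) + Fraction(1, 16)
    return dist


class TestGenotypeEnumeration:
    def test_order_and_endpoints(self):
        genos = enumerate_genotypes()
        assert len(genos) == 9
        assert genos[0].label == "KKAA" and (genos[0].n_K, genos[0].n_A) == (2, 2)
        assert genos[8].label == "kkaa" and (genos[8].n_K, genos[8].n_A) == (0, 0)
        assert [g.index for g in genos] == list(range(1, 10))

    def test_bijection_with_allele_counts(self):
        pairs = {(g.n_K, g.n_A) for g in enumerate_genotypes()}
        assert pairs == {(k, a) for k in range(3) for a in range(3)}

    def test_labels_exported(self):
        assert GENOTYPE_LABELS == (
            "KKAA", "KkAA", "kkAA", "KKAa", "KkAa", "kkAa", "KKaa", "Kkaa", "kkaa",
        )

    def test_lookup_by_label(self):
        assert genotype_by_label("KkAa").index == 5
        with pytest.raises(KeyError):
            genotype_by_label("XXyy")


class TestGameteDistribution:
    @pytest.mark.parametrize(
        "label, expected",
        [
            ("KKAA", {"KA": 1}),
            ("KkAa", {"KA": Fraction(1, 4), "Ka": Fraction(1, 4),
                      "kA": Fraction(1, 4), "ka": Fraction(1, 4)}),
            ("Kkaa", {"Ka": Fraction(1, 2), "ka": Fraction(1, 2)}),
        ],
    )
    def test_examples(self, label, expected):
        dist = gamete_distribution(genotype_by_label(label))
        for gamete, p in expected.items():
            assert dist[gamete] == p
        assert sum(dist.values()) == 1

    def test_all_distributions_normalized_exactly(self):
        for g in enumerate_genotypes():
            assert sum(gamete_distribution(g).values()) == Fraction(1)


class TestInheritanceTensor:
    def test_matches_gamete_pairing_enumeration_exactly(self):
        """Tensor equals the 16-pairing oracle for all 81 parent pairs."""
        exact = inheritance_tensor_exact()
        genos = enumerate_genotypes()
        for m, mother in enumerate(genos):
            for n, father in enumerate(genos):
                oracle = brute_force_offspring_dist(mother, father)
                for i, child in enumerate(genos):
                    assert exact[i][m][n] == oracle.get((child.n_K, child.n_A), 0)

    def test_float_conversion_is_exact(self):
        exact = inheritance_tensor_exact()
        tensor = build_inheritance_tensor()
        for i in range(9):
            for m in range(9):
                for n in range(9):
                    assert tensor[i, m, n] == float(exact[i][m][n])

    def test_normalization_and_parental_symmetry(self):
        tensor = build_inheritance_tensor()
        assert np.array_equal(tensor.sum(axis=0), np.ones((9, 9)))
        assert np.array_equal(tensor, tensor.transpose(0, 2, 1))

    def test_forced_and_double_heterozygote_crosses(self):
        tensor = build_inheritance_tensor()
        i_KkAa, i_KKAA, i_kkaa = 4, 0, 8
        assert tensor[i_KkAa, i_KKAA, i_kkaa] == 1.0
        assert tensor[i_kkaa, i_KkAa, i_KkAa] == 1.0 / 16.0


class TestFitness:
    def test_no_cost_is_all_ones(self):
        assert np.array_equal(fitness_vector(0.0, 0.0), np.ones(9))

    def test_double_heterozygote_value(self):
        w = fitness_vector(0.2, 0.1)
        assert w[4] == pytest.approx((1 - 0.05) * (1 - 0.10))  # KkAa

    def test_lethal_fk_cost(self):
        w = fitness_vector(1.0, 0.0)
        assert w[0] == 0.0  # KKAA
        assert w[8] == 1.0  # kkaa

    @pytest.mark.parametrize("bad", [-0.1, 1.5, float("nan")])
    def test_costs_outside_unit_interval_rejected(self, bad):
        with pytest.raises(ValueError, match="c_K"):
            fitness_vector(bad, 0.0)
        with pytest.raises(ValueError, match="c_A"):
            fitness_vector(0.0, bad)

    @given(
        c=st.floats(0.0, 1.0), d=st.floats(0.0, 0.5),
        locus=st.sampled_from(["K", "A"]),
    )
    def test_componentwise_non_increasing_in_each_cost(self, c, d, locus):
        c2 = min(c + d, 1.0)
        if locus == "K":
            lo, hi = fitness_vector(c2, 0.3), fitness_vector(c, 0.3)
        else:
            lo, hi = fitness_vector(0.3, c2), fitness_vector(0.3, c)
        assert np.all(lo <= hi + 1e-12)
        assert hi[8] == 1.0  # wild type never pays a cost


class TestViability:
    def test_only_fk_free_genotypes_viable(self):
        gamma = viability_vector()
        assert list(gamma) == [0, 0, 1, 0, 0, 1, 0, 0, 1]
        assert gamma[5] == 1.0  # kkAa
        assert gamma[6] == 0.0  # KKaa
        assert gamma.sum() == 3


class TestAlleleFrequencies:
    def test_examples(self):
        wild = np.zeros(9); wild[8] = 5.0
        assert allele_frequencies(wild) == (0.0, 0.0)
        het = np.zeros(9); het[4] = 2.0
        assert allele_frequencies(het) == (0.5, 0.5)
        mix = np.zeros(9); mix[0] = 3.0; mix[8] = 3.0
        assert allele_frequencies(mix) == (0.5, 0.5)

    def test_empty_or_negative_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            allele_frequencies(np.zeros(9))
        with pytest.raises(ValueError, match="nonnegative"):
            allele_frequencies(-np.ones(9))

    @given(
        mothers=st.lists(st.floats(0.0, 100.0), min_size=9, max_size=9),
        fathers=st.lists(st.floats(0.0, 100.0), min_size=9, max_size=9),
    )
    def test_mendelian_conservation_through_the_tensor(self, mothers, fathers):
        """Offspring allele frequencies equal the parental gamete-pool mean.

        Without selection, the tensor must conserve allele frequencies: the
        offspring pool generated from mothers (by density) and fathers (by
        frequency) has K and A frequencies equal to the average of the two
        parental pool frequencies.
        """
        F = np.asarray(mothers)
        M = np.asarray(fathers)
        if F.sum() <= 0 or M.sum() <= 0:
            return
        tensor = build_inheritance_tensor()
        offspring = np.einsum("imn,m,n->i", tensor, F, M / M.sum())
        fK_off, fA_off = allele_frequencies(offspring)
        fK_m, fA_m = allele_frequencies(F)
        fK_f, fA_f = allele_frequencies(M)
        assert fK_off == pytest.approx((fK_m + fK_f) / 2, abs=1e-9)
        assert fA_off == pytest.approx((fA_m + fA_f) / 2, abs=1e-9)


class TestCompositeLD:
    def test_product_distribution_has_zero_ld(self):
        only_het = np.zeros(9); only_het[4] = 10.0
        assert composite_ld(only_het) == pytest.approx(0.0, abs=1e-15)

    def test_maximal_coupling(self):
        mix = np.zeros(9); mix[0] = 1.0; mix[8] = 1.0
        assert composite_ld(mix) == pytest.approx(0.5)

    @pytest.mark.parametrize("pos", range(9))
    def test_monomorphic_population_has_zero_ld(self, pos):
        c = np.zeros(9); c[pos] = 7.0
        assert composite_ld(c) == pytest.approx(0.0, abs=1e-15)
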