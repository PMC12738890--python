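"""Diversity, FST/Nm, Smouse-Peakall distance, AMOVA and Nei distance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tiliapop.genotype_core import MISSING, GenotypeDataset
from tiliapop.popgen_stats import (
    NEI_INFINITE_DISTANCE,
    allele_frequencies,
    amova,
    diversity_per_locus,
    fis,
    genotypic_distance_matrix,
    global_fst,
    nei_distance,
    nm_from_fst,
    pairwise_fst,
    population_summary,
    squared_genotypic_distance,
)


def _dataset(pop_genotypes: dict[str, list[list[tuple[int, int]]]], n_loci=None):
    """Build a dataset from {pop: [per-individual list of genotype tuples]}."""
    individuals, populations, calls = [], [], []
    for pop, genos in pop_genotypes.items():
        for k, g in enumerate(genos):
            individuals.append(f"{pop}{k}")
            populations.append(pop)
            calls.append(list(g))
    loci = [f"L{j+1}" for j in range(len(calls[0]))]
    return GenotypeDataset(individuals, populations, loci, np.array(calls))


class TestFrequenciesAndDiversity:
    def test_direct_count(self):
        ds = _dataset({"P": [[(180, 180)], [(180, 182)]]})
        f = allele_frequencies(ds, "P", "L1")
        assert f[180] == 0.75 and f[182] == 0.25

    def test_monomorphic(self):
        ds = _dataset({"P": [[(180, 180)], [(180, 180)]]})
        assert allele_frequencies(ds, "P", "L1").to_dict() == {180: 1.0}

    def test_missing_aware_denominator(self):
        ds = _dataset({"P": [[(180, 180)], [(180, 182)], [(MISSING, MISSING)]]})
        f = allele_frequencies(ds, "P", "L1")
        assert f[180] == pytest.approx(3 / 4)

    def test_all_missing_raises(self):
        ds = _dataset({"P": [[(MISSING, MISSING)]]})
        with pytest.raises(ValueError):
            allele_frequencies(ds, "P", "L1")

    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.5, 0.5], (2, 2.0, np.log(2), 0.5)),
            ([1.0], (1, 1.0, 0.0, 0.0)),
            ([0.7, 0.2, 0.1], (3, 1 / 0.54, 0.8018185525, 0.46)),
        ],
    )
    def test_per_locus_formulas(self, p, expected):
        na, ne, i_, ho, he = diversity_per_locus(np.array(p))
        assert (na, ne) == pytest.approx(expected[:2])
        assert i_ == pytest.approx(expected[2], abs=1e-6)
        assert he == pytest.approx(expected[3])

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8).map(
            lambda v: np.array(v) / np.sum(v)
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_diversity_invariants(self, p):
        """Ne <= Na; He = 1 - 1/Ne; I >= ln(Ne), equality iff uniform."""
        na, ne, i_, _, he = diversity_per_locus(p)
        assert ne <= na + 1e-9
        assert he == pytest.approx(1 - 1 / ne)
        assert i_ >= np.log(ne) - 1e-9


class TestFis:
    @pytest.mark.parametrize("ho,he,expected", [(0.5, 0.5, 0.0), (0.0, 0.5, 1.0)])
    def test_examples(self, ho, he, expected):
        assert fis(ho, he) == pytest.approx(expected)

    def test_per_locus_formula_value(self):
        assert fis(0.329, 0.458) == pytest.approx(0.2817, abs=1e-4)

    def test_monomorphic_undefined(self):
        assert np.isnan(fis(0.0, 0.0))


class TestPopulationSummary:
    def test_monomorphic_dataset(self):
        ds = _dataset({"P": [[(180, 180), (200, 200)], [(180, 180), (200, 200)]]})
        row = population_summary(ds).per_population.loc["P"]
        assert row["Na"] == 1 and row["Ne"] == 1
        assert row["I"] == 0 and row["Ho"] == 0 and row["He"] == 0
        assert row["He_se"] == 0

    def test_se_across_two_loci(self):
        # He 0.4 and 0.6 -> mean 0.5, SE = sd/sqrt(2) = 0.1
        summary = pd.Series([0.4, 0.6])
        assert summary.std(ddof=1) / np.sqrt(2) == pytest.approx(0.1)
        ds = _dataset(
            {
                "P": [
                    [(1, 1), (1, 1)], [(1, 1), (1, 2)], [(1, 2), (1, 2)],
                    [(1, 2), (2, 2)], [(2, 2), (2, 2)],
                ]
            }
        )
        per_locus = population_summary(ds).per_locus
        row = population_summary(ds).per_population.loc["P"]
        expect_se = per_locus["He"].std(ddof=1) / np.sqrt(2)
        assert row["He_se"] == pytest.approx(expect_se)

    def test_fixture_summary_regression(self, study_fixture):
        """Regression lock on the seeded fixture's summary values."""
        row = population_summary(study_fixture).per_population.loc["TS"]
        assert row["Na"] == pytest.approx(4.8667, abs=1e-3)
        assert row["He"] == pytest.approx(0.6490, abs=1e-3)
        assert row["Ho"] == pytest.approx(0.6513, abs=1e-3)


class TestFstAndNm:
    def test_identical_frequencies_zero(self):
        genos = [[(1, 2)], [(1, 1)], [(2, 2)]]
        ds = _dataset({"A": genos, "B": genos})
        assert pairwise_fst(ds).fst.loc["A", "B"] == pytest.approx(0.0)

    def test_fixed_alternate_alleles_one(self):
        ds = _dataset({"A": [[(1, 1)]] * 3, "B": [[(2, 2)]] * 3})
        assert pairwise_fst(ds).fst.loc["A", "B"] == pytest.approx(1.0)

    def test_hand_computed_case(self):
        # p=(0.8,0.2) vs (0.2,0.8): HS=0.32, HT=0.5 -> FST=0.36
        a = [[(1, 1)]] * 3 + [[(1, 2)]] * 2  # freq(1)=0.8
        b = [[(2, 2)]] * 3 + [[(1, 2)]] * 2
        ds = _dataset({"A": a, "B": b})
        assert pairwise_fst(ds).fst.loc["A", "B"] == pytest.approx(0.36)

    def test_wc_estimator_agrees_on_strong_differentiation(self):
        ds = _dataset({"A": [[(1, 1)]] * 5, "B": [[(2, 2)]] * 5})
        assert pairwise_fst(ds, "wc").fst.loc["A", "B"] == pytest.approx(1.0)

    def test_wc_near_zero_for_identical(self):
        rng = np.random.default_rng(7)
        genos = [
            [tuple(sorted(rng.integers(1, 4, 2)))] for _ in range(100)
        ]
        ds = _dataset({"A": genos, "B": [list(g) for g in genos]})
        assert abs(pairwise_fst(ds, "wc").fst.loc["A", "B"]) < 0.03

    def test_global_fst_matches_pairwise_for_two_pops(self, study_fixture):
        sub = study_fixture.subset_populations(["TS", "LU"])
        assert global_fst(sub) == pytest.approx(
            pairwise_fst(sub).fst.loc["TS", "LU"]
        )

    @pytest.mark.parametrize(
        "fst,expected,tol",
        [(0.2, 1.0, 1e-12), (0.25, 0.75, 1e-12), (1.0, 0.0, 1e-12)],
    )
    def test_nm_formula(self, fst, expected, tol):
        assert nm_from_fst(fst) == pytest.approx(expected, abs=tol)

    def test_nm_undefined_for_nonpositive(self):
        assert np.isnan(nm_from_fst(0.0)) and np.isnan(nm_from_fst(-0.1))

    @given(st.floats(0.001, 0.999), st.floats(0.001, 0.999))
    @settings(max_examples=50, deadline=None)
    def test_nm_strictly_decreasing(self, a, b):
        if a == b:
            return
        lo, hi = sorted([a, b])
        assert nm_from_fst(lo) > nm_from_fst(hi)


class TestSquaredGenotypicDistance:
    def _oracle(self, g1, g2):
        states = sorted(set(g1) | set(g2))
        c1 = np.array([list(g1).count(s) for s in states])
        c2 = np.array([list(g2).count(s) for s in states])
        return 0.5 * np.sum((c1 - c2) ** 2)

    def test_all_pair_classes_match_oracle_exhaustively(self):
        """d2 in {0,1,2,3,4} over every genotype pair on a 4-letter alphabet."""
        alleles = [1, 2, 3, 4]
        genotypes = list(itertools.combinations_with_replacement(alleles, 2))
        seen = set()
        for g1 in genotypes:
            for g2 in genotypes:
                d = squared_genotypic_distance(g1, g2)
                assert d == self._oracle(g1, g2)
                seen.add(d)
        assert seen == {0, 1, 2, 3, 4}

    @pytest.mark.parametrize(
        "g1,g2,expected",
        [((1, 1), (1, 1), 0), ((1, 1), (1, 2), 1), ((1, 2), (3, 4), 2),
         ((1, 1), (2, 3), 3), ((1, 1), (2, 2), 4)],
    )
    def test_named_classes(self, g1, g2, expected):
        assert squared_genotypic_distance(g1, g2) == expected

    def test_missing_rejected(self):
        with pytest.raises(ValueError):
            squared_genotypic_distance((MISSING, MISSING), (1, 1))

    def test_multilocus_matrix_skips_missing_locus(self):
        ds = _dataset(
            {"P": [[(1, 1), (5, 5)], [(2, 2), (MISSING, MISSING)]]}
        )
        d2 = genotypic_distance_matrix(ds)
        assert d2[0, 1] == 4  # only locus 1 contributes


class TestAmova:
    def test_df_bookkeeping_on_study_subset(self, study_fixture):
        am_pops = ["TS", "LU", "YDS", "ZS", "LS", "DGL", "MPS", "DXG"]
        table = amova(study_fixture, n_permutations=49, seed=0, populations=am_pops)
        assert (table.df_among, table.df_within, table.df_total) == (7, 176, 183)

    def test_label_order_invariance(self, tiny_dataset):
        t1 = amova(tiny_dataset, 199, seed=3)
        shuffled = tiny_dataset.subset_populations(["B", "A"])
        t2 = amova(shuffled, 199, seed=3)
        assert t1.var_among == pytest.approx(t2.var_among)
        assert t1.var_within == pytest.approx(t2.var_within)

    def test_permutation_p_reproducible(self, tiny_dataset):
        p1 = amova(tiny_dataset, 199, seed=11).p_value
        p2 = amova(tiny_dataset, 199, seed=11).p_value
        assert p1 == p2

    def test_identical_populations_null(self):
        rng = np.random.default_rng(0)
        genos = [
            [tuple(sorted(rng.integers(1, 5, 2))) for _ in range(3)]
            for _ in range(20)
        ]
        ds = _dataset({"A": genos, "B": list(genos)})
        table = amova(ds, 199, seed=1)
        # the unbiased among-component fluctuates around zero under the null
        assert abs(table.var_among) < 0.15 * table.var_total + 1e-9
        assert table.p_value > 0.05

    def test_percentage_and_component_identities(self, study_fixture):
        table = amova(study_fixture, 49, seed=0, populations=["TS", "LU", "YDS"])
        pa, pw = table.percentages()
        assert pa + pw == pytest.approx(100.0)
        assert table.var_total == pytest.approx(table.var_among + table.var_within)

    def test_requires_permutations(self, tiny_dataset):
        with pytest.raises(ValueError):
            amova(tiny_dataset, 0, seed=0)


class TestNeiDistance:
    def test_identical_populations_zero(self):
        genos = [[(1, 2)], [(1, 1)], [(2, 2)], [(1, 2)], [(1, 1)], [(1, 2)]]
        ds = _dataset({"A": genos, "B": list(genos)})
        d = nei_distance(ds)
        assert d.values[0, 1] == pytest.approx(0.0, abs=0.02)

    def test_disjoint_alleles_sentinel(self):
        ds = _dataset({"A": [[(1, 1)]] * 3, "B": [[(2, 2)]] * 3})
        assert nei_distance(ds).values[0, 1] == NEI_INFINITE_DISTANCE

    def test_bias_correction_vanishes_at_large_n(self):
        """Both pops at p=(0.5,0.5): D -> 0 as n grows."""
        rng = np.random.default_rng(42)
        genos = [
            [tuple(sorted(rng.integers(1, 3, 2)))] for _ in range(2000)
        ]
        ds = _dataset({"A": genos, "B": [list(g) for g in genos]})
        assert nei_distance(ds).values[0, 1] < 1e-3

    def test_matrix_properties(self, study_fixture):
        d = nei_distance(study_fixture)
        assert np.allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)
        assert np.all(d.values >= 0)
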