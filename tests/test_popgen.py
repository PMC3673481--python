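"""F-statistics, diversity and test machinery against independent oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seapop.core import GenotypeTable, PairwiseMatrix
from seapop.popgen import (
    allelic_richness,
    classical_mds,
    expected_het,
    fis_wc,
    g_test_differentiation,
    ld_test,
    one_way_anova,
    pairwise_theta,
    theta_wc,
    welch_t,
)
from conftest import random_table


def table_from_genotypes(pop_genotypes: dict[str, list[list[tuple[int, int]]]]) -> GenotypeTable:
    """Build a table from {site: [per-individual locus genotype list]}."""
    ids, sites, rows = [], [], []
    for site, inds in pop_genotypes.items():
        for k, g in enumerate(inds):
            ids.append(f"{site}_{k + 1}")
            sites.append(site)
            rows.append(np.array(g))
    L = rows[0].shape[0]
    return GenotypeTable(
        ids, np.array(sites, dtype=object), np.stack(rows).astype(np.int32),
        [f"LOC{j + 1}" for j in range(L)],
    )


def wc84_oracle(genotypes_by_pop: list[list[tuple[int, int]]]) -> float:
    """Direct transcription of the Weir-Cockerham (1984) single-locus
    theta formulas, written independently of the package's vectorised
    implementation: explicit loops over alleles and populations."""
    pops = [[g for g in pop if g[0] != 0] for pop in genotypes_by_pop]
    pops = [p for p in pops if len(p)]
    r = len(pops)
    n = [len(p) for p in pops]
    nbar = sum(n) / r
    nc = (sum(n) - sum(x**2 for x in n) / sum(n)) / (r - 1)
    alleles = sorted({a for p in pops for g in p for a in g})
    A, BB, CC = 0.0, 0.0, 0.0
    for al in alleles:
        p_i = [sum(g.count(al) for g in pop) / (2 * len(pop)) for pop in pops]
        h_i = [
            sum(1 for g in pop if al in g and g[0] != g[1]) / len(pop) for pop in pops
        ]
        pbar = sum(ni * pi for ni, pi in zip(n, p_i)) / (r * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h_i)) / (r * nbar)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p_i)) / ((r - 1) * nbar)
        a = (nbar / nc) * (
            s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
        A += a
        BB += b
        CC += c
    return A / (A + BB + CC)


class TestThetaWC:
    def test_fixed_differences_give_theta_one(self):
        pops = {
            "A": [[(101, 101)]] * 20,
            "B": [[(102, 102)]] * 20,
        }
        res = theta_wc(table_from_genotypes(pops))
        assert res.multilocus == pytest.approx(1.0)

    def test_monomorphic_locus_is_skipped(self):
        pops = {
            "A": [[(101, 101), (150, 150)]] * 5,
            "B": [[(101, 102), (150, 150)]] * 5,
        }
        res = theta_wc(table_from_genotypes(pops))
        assert "LOC2" in res.skipped
        assert np.isnan(res.per_locus["LOC2"])
        assert np.isfinite(res.multilocus)

    def test_matches_independent_wc84_transcription(self):
        rng = np.random.default_rng(42)
        # 2 pops x 5 diploids, biallelic, several random fixtures
        for trial in range(6):
            popa = [[tuple(rng.choice([101, 102], 2))] for _ in range(5)]
            popb = [[tuple(rng.choice([101, 102], 2, p=[0.8, 0.2]))] for _ in range(5)]
            alleles = {a for g in popa + popb for a in g[0]}
            if len(alleles) < 2:
                continue
            table = table_from_genotypes({"A": popa, "B": popb})
            res = theta_wc(table)
            expected = wc84_oracle([[g[0] for g in popa], [g[0] for g in popb]])
            assert res.multilocus == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_allele_relabeling_and_pop_order(self):
        table = random_table(n_sites=3, n_per_site=15, n_loci=4, seed=5)
        base = theta_wc(table).multilocus
        relabeled = GenotypeTable(
            table.individual_ids,
            table.sites.copy(),
            np.where(table.genotypes > 0, 700 - table.genotypes, 0),
            table.locus_names,
        )
        assert theta_wc(relabeled).multilocus == pytest.approx(base, abs=1e-12)
        order = np.argsort(table.sites, kind="stable")[::-1]
        reordered = table.subset_individuals(order)
        assert theta_wc(reordered).multilocus == pytest.approx(base, abs=1e-12)


class TestPairwiseTheta:
    def test_15_sites_yield_105_pairs(self):
        table = random_table(n_sites=15, n_per_site=6, n_loci=3, seed=6)
        fst = pairwise_theta(table)
        n = fst.n
        assert n * (n - 1) // 2 == 105
        assert np.allclose(fst.values, fst.values.T)

    def test_duplicated_population_has_near_zero_theta(self):
        rng = np.random.default_rng(7)
        geno = rng.integers(100, 104, size=(30, 5, 2))
        table = GenotypeTable(
            [f"A_{i}" for i in range(15)] + [f"B_{i}" for i in range(15)],
            np.array(["A"] * 15 + ["B"] * 15, dtype=object),
            np.concatenate([geno[:15], geno[:15]]).astype(np.int32),
            [f"LOC{j}" for j in range(5)],
        )
        fst = pairwise_theta(table)
        assert fst.values[0, 1] <= 0.0 + 1e-12

    def test_matches_theta_restricted_to_pair(self):
        table = random_table(n_sites=4, n_per_site=10, n_loci=4, seed=8)
        fst = pairwise_theta(table)
        labels = fst.labels
        sub = table.subset_sites([labels[1], labels[3]])
        expected = theta_wc(sub).multilocus
        assert fst.values[1, 3] == pytest.approx(expected, abs=1e-12)


class TestExpectedHet:
    def test_monomorphic_is_zero(self):
        table = table_from_genotypes({"A": [[(101, 101)]] * 6, "B": [[(101, 101)]] * 6})
        he = expected_het(table)
        assert np.allclose(he.to_numpy(), 0.0)

    def test_unbiased_correction_at_even_split(self):
        # 25 diploids, alleles 50/50: He = (50/49) * 0.5
        inds = [[(101, 102)]] * 25
        he = expected_het(table_from_genotypes({"A": inds, "B": inds}))
        assert he.loc["A", "LOC1"] == pytest.approx(50 / 49 * 0.5, abs=1e-12)

    def test_matches_hand_formula(self):
        pops = {"A": [[(101, 102)], [(101, 101)], [(102, 103)]]}
        he = expected_het(table_from_genotypes(pops | {"B": [[(101, 101)]]}))
        # counts: 101 x3, 102 x2, 103 x1; n = 3
        p = np.array([3, 2, 1]) / 6
        expected = 6 / 5 * (1 - np.sum(p**2))
        assert he.loc["A", "LOC1"] == pytest.approx(expected, abs=1e-12)


class TestAllelicRichness:
    def test_full_sample_recovers_observed_count(self):
        pops = {"A": [[(101, 102)], [(103, 101)]], "B": [[(101, 101)], [(101, 101)]]}
        table = table_from_genotypes(pops)
        ar = allelic_richness(table, g=4)
        assert ar.loc["A", "LOC1"] == pytest.approx(3.0, abs=1e-12)

    def test_monomorphic_is_one(self):
        table = table_from_genotypes({"A": [[(101, 101)]] * 5, "B": [[(101, 101)]] * 5})
        ar = allelic_richness(table, g=2)
        assert np.allclose(ar.to_numpy(), 1.0)

    def test_matches_exhaustive_enumeration(self):
        # allele copies (5, 3, 2) in 10 gene copies, rarefy to g = 4
        copies = [101] * 5 + [102] * 3 + [103] * 2
        genotypes = [
            [(copies[2 * i], copies[2 * i + 1])] for i in range(5)
        ]
        table = table_from_genotypes({"A": genotypes, "B": [[(101, 101)]] * 2})
        ar = allelic_richness(table, g=4)
        counts = [len(set(sub)) for sub in itertools.combinations(copies, 4)]
        assert ar.loc["A", "LOC1"] == pytest.approx(np.mean(counts), abs=1e-12)

    def test_g_below_two_rejected(self, small_table):
        with pytest.raises(ValueError):
            allelic_richness(small_table, g=1)


class TestFis:
    def test_hwe_fixture_has_fis_near_zero(self):
        rng = np.random.default_rng(9)
        geno = rng.integers(101, 105, size=(500, 8, 2)).astype(np.int32)
        table = GenotypeTable(
            [f"A_{i}" for i in range(500)],
            np.array(["A"] * 500, dtype=object),
            geno,
            [f"LOC{j}" for j in range(8)],
        )
        res = fis_wc(table, n_bootstrap=300, n_permutations=99, seed=1)
        assert abs(res.per_site["A"]) < 0.05
        assert res.ci.loc["A", "lo"] <= 0.0 <= res.ci.loc["A", "hi"]

    def test_all_homozygotes_give_fis_one(self):
        inds = [[(101, 101)]] * 10 + [[(102, 102)]] * 10
        table = table_from_genotypes({"A": inds})
        res = fis_wc(table, n_bootstrap=200, n_permutations=99, seed=1)
        assert res.per_site["A"] == pytest.approx(1.0)
        assert res.single_locus


class TestGTest:
    def test_fixed_pops_hit_permutation_floor(self):
        pops = {"A": [[(101, 101)]] * 20, "B": [[(102, 102)]] * 20}
        res = g_test_differentiation(table_from_genotypes(pops), n_permutations=199, seed=2)
        assert res.per_locus_p["LOC1"] == pytest.approx(1 / 200)

    def test_g_statistic_matches_hand_calculation(self):
        # 2 sites x 2 alleles with allele counts 30/10 vs 10/30
        a_inds = [[(101, 101)]] * 15 + [[(102, 102)]] * 5
        b_inds = [[(101, 101)]] * 5 + [[(102, 102)]] * 15
        res = g_test_differentiation(
            table_from_genotypes({"A": a_inds, "B": b_inds}), n_permutations=99, seed=3
        )
        obs = np.array([[30, 10], [10, 30]], float)
        exp = obs.sum(1, keepdims=True) * obs.sum(0, keepdims=True) / obs.sum()
        g_hand = 2 * np.sum(obs * np.log(obs / exp))
        assert res.per_locus_g["LOC1"] == pytest.approx(g_hand, abs=1e-9)

    def test_null_type_one_error_controlled(self):
        # identical allele distributions: rejection rate at 0.05 stays near nominal
        rng = np.random.default_rng(4)
        rejections = 0
        n_rep = 120
        for rep in range(n_rep):
            geno = rng.integers(101, 104, size=(40, 1, 2)).astype(np.int32)
            table = GenotypeTable(
                [f"A_{i}" for i in range(20)] + [f"B_{i}" for i in range(20)],
                np.array(["A"] * 20 + ["B"] * 20, dtype=object),
                geno,
                ["LOC1"],
            )
            res = g_test_differentiation(table, n_permutations=99, seed=rep)
            rejections += res.per_locus_p["LOC1"] <= 0.05
        assert rejections / n_rep <= 0.10  # binomial slack around 0.05


class TestLdTest:
    def test_duplicated_locus_is_detected(self):
        rng = np.random.default_rng(5)
        g = rng.integers(101, 104, size=(47, 1, 2))
        geno = np.concatenate([g, g], axis=1).astype(np.int32)
        table = GenotypeTable(
            [f"A_{i}" for i in range(47)],
            np.array(["A"] * 47, dtype=object),
            geno,
            ["L1", "L2"],
        )
        p = ld_test(table, ("L1", "L2"), "A", n_permutations=199, seed=6)
        assert p == pytest.approx(1 / 200)

    def test_monomorphic_locus_skipped(self):
        geno = np.zeros((10, 2, 2), int)
        geno[:, 0] = (101, 101)
        geno[:, 1, 0] = np.arange(10) % 2 + 101
        geno[:, 1, 1] = 101
        table = GenotypeTable(
            [f"A_{i}" for i in range(10)],
            np.array(["A"] * 10, dtype=object),
            geno.astype(np.int32),
            ["L1", "L2"],
        )
        assert ld_test(table, ("L1", "L2"), "A", n_permutations=99, seed=7) is None

    def test_independent_loci_type_one_error(self):
        rng = np.random.default_rng(8)
        rejections = 0
        n_rep = 120
        for rep in range(n_rep):
            geno = rng.integers(101, 104, size=(30, 2, 2)).astype(np.int32)
            table = GenotypeTable(
                [f"A_{i}" for i in range(30)],
                np.array(["A"] * 30, dtype=object),
                geno,
                ["L1", "L2"],
            )
            p = ld_test(table, ("L1", "L2"), "A", n_permutations=99, seed=rep)
            rejections += p is not None and p <= 0.05
        assert rejections / n_rep <= 0.10


class TestClassicalMds:
    def test_line_configuration_recovered_in_one_dimension(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        D = np.abs(x[:, None] - x[None, :])
        m = PairwiseMatrix(list("abcd"), D)
        coords, eig = classical_mds(m, k=1)
        rec = np.abs(coords.to_numpy()[:, 0][:, None] - coords.to_numpy()[:, 0][None, :])
        np.testing.assert_allclose(rec, D, atol=1e-10)

    def test_equilateral_triangle(self):
        D = np.ones((3, 3)) - np.eye(3)
        coords, _ = classical_mds(PairwiseMatrix(list("abc"), D), k=2)
        c = coords.to_numpy()
        d = np.linalg.norm(c[:, None] - c[None, :], axis=2)
        np.testing.assert_allclose(d[~np.eye(3, dtype=bool)], 1.0, atol=1e-10)

    def test_euclidean_round_trip_3d(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(9, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords, _ = classical_mds(PairwiseMatrix([f"s{i}" for i in range(9)], D), k=3)
        c = coords.to_numpy()
        rec = np.linalg.norm(c[:, None] - c[None, :], axis=2)
        np.testing.assert_allclose(rec, D, atol=1e-8)

    def test_agrees_with_skbio_pcoa(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(7, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords, _ = classical_mds(PairwiseMatrix([f"s{i}" for i in range(7)], D), k=2)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D), number_of_dimensions=2)
        np.testing.assert_allclose(
            np.abs(coords.to_numpy()), np.abs(ref.samples.to_numpy()), atol=1e-8
        )


class TestAnovaAndWelch:
    def test_anova_df_for_15_sites_by_60_loci(self):
        rng = np.random.default_rng(12)
        values = pd.DataFrame(rng.normal(size=(15, 60)))
        res = one_way_anova(values)
        assert res.df == (14, 885)
        assert res.p > 0.001

    def test_anova_matches_textbook_two_group(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        res = one_way_anova(pd.DataFrame([a, b]))
        f_ref, p_ref = stats.f_oneway(a, b)
        assert res.F == pytest.approx(f_ref)
        assert res.p == pytest.approx(p_ref)

    def test_welch_identical_samples(self):
        res = welch_t(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(13)
        a, b = rng.normal(size=12), rng.normal(1.0, 2.0, size=20)
        res = welch_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)
        # equal variance, equal n limit: df = 2n - 2
        res2 = welch_t(np.array([1.0, 2, 3, 4]), np.array([5.0, 6, 7, 8]))
        assert res2.df == pytest.approx(6.0)
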