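import math

import numpy as np
import pytest

from sealpop.datatypes import SequenceAlignment
from sealpop.diversity import (bonferroni_alpha, find_duplicate_genotypes,
                               haplotype_frequencies, heterozygosity,
                               hwe_test, ld_test, rarefied_allelic_richness,
                               richness_difference_test,
                               site_mean_heterozygosity)
from sealpop.synthetic import (IslandModelSpec, simulate_island_genotypes,
                               simulate_mtdna_haplotypes)
from tests.conftest import make_genotypes


class TestHeterozygosity:
    def test_monomorphic_locus_zero(self):
        ds = make_genotypes([[(1, 1)], [(1, 1)], [(1, 1)]])
        s = heterozygosity(ds)[0]
        assert s.h_obs == 0.0
        assert s.h_exp == 0.0
        assert not s.polymorphic

    def test_unbiased_h_exp_direct_formula(self):
        # two heterozygotes carrying four distinct alleles: p_k = 1/4 each,
        # H_e = (2n/(2n-1)) (1 - sum p^2) = (4/3)(1 - 4/16) = 1.0
        ds = make_genotypes([[(1, 2)], [(3, 4)]])
        s = heterozygosity(ds)[0]
        assert s.h_obs == 1.0
        assert s.h_exp == pytest.approx(1.0)
        # two distinct homozygotes: p = 1/2 each, H_e = (4/3)(1/2) = 2/3
        ds2 = make_genotypes([[(1, 1)], [(2, 2)]])
        s2 = heterozygosity(ds2)[0]
        assert s2.h_obs == 0.0
        assert s2.h_exp == pytest.approx(2 / 3)

    def test_all_heterozygous(self):
        ds = make_genotypes([[(1, 2)], [(1, 2)], [(1, 2)], [(1, 2)]])
        assert heterozygosity(ds)[0].h_obs == 1.0

    def test_allele_counts_sum_to_2n(self):
        ds = make_genotypes([[(1, 2)], [(2, 3)], [(0, 0)]])
        s = heterozygosity(ds)[0]
        assert s.n == 2
        assert sum(s.allele_counts.values()) == 2 * s.n

    def test_unbiased_estimator_calibration(self):
        # mean of the unbiased H_e over HWE replicates approaches
        # 1 - sum p^2 evaluated at the true frequencies
        p = np.array([0.5, 0.3, 0.2])
        target = 1 - np.sum(p ** 2)
        rng = np.random.default_rng(42)
        n = 10
        estimates = []
        for _ in range(400):
            calls = rng.choice(3, size=(n, 1, 2), p=p) + 1
            ds = make_genotypes(calls.tolist())
            estimates.append(heterozygosity(ds)[0].h_exp)
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - target) < 2 * se

    def test_site_means_over_polymorphic_loci(self):
        ds = make_genotypes(
            [[(1, 1), (1, 2)], [(1, 1), (1, 2)]], sites=["A", "A"])
        means = site_mean_heterozygosity(heterozygosity(ds))
        assert means.loc[0, "n_polymorphic_loci"] == 1
        assert means.loc[0, "mean_h_obs"] == 1.0


def exact_hwe_two_allele_p(pairs: np.ndarray) -> float:
    """Full-enumeration exact HWE p for a two-allele genotype array.

    Enumerates every genotype configuration compatible with the observed
    allele counts and sums the conditional probabilities of those no more
    probable than the observed array.
    """
    n = len(pairs)
    m1 = int(np.sum(pairs == 1))
    m2 = 2 * n - m1

    def prob(n12: int) -> float:
        n11 = (m1 - n12) // 2
        n22 = (m2 - n12) // 2
        return (math.factorial(n) * 2 ** n12 * math.factorial(m1)
                * math.factorial(m2)
                / (math.factorial(2 * n) * math.factorial(n11)
                   * math.factorial(n12) * math.factorial(n22)))

    feasible = [h for h in range(min(m1, m2) + 1)
                if (m1 - h) % 2 == 0 and (m2 - h) >= 0 and (m2 - h) % 2 == 0]
    obs_h = int(np.sum(pairs[:, 0] != pairs[:, 1]))
    p_obs = prob(obs_h)
    return sum(prob(h) for h in feasible if prob(h) <= p_obs + 1e-12)


class TestHweTest:
    def test_extreme_heterozygote_excess_rejected(self):
        ds = make_genotypes([[(1, 2)]] * 50)
        res = hwe_test(ds, "siteA", "L1", n_perm=2000, seed=1)
        assert res.p_value < 0.01
        # all-heterozygote array is the extreme of the excess direction
        assert res.extra["p_homozygote_excess"] > 0.95

    def test_monomorphic_undefined(self):
        ds = make_genotypes([[(1, 1)]] * 10)
        assert hwe_test(ds, "siteA", "L1").p_value is None

    def test_monte_carlo_matches_full_enumeration_small_n(self):
        # n=3 with two alleles admits complete enumeration of the null
        for rows, seed in [([[(1, 2)], [(1, 2)], [(1, 1)]], 5),
                           ([[(1, 1)], [(2, 2)], [(1, 2)]], 6),
                           ([[(1, 2)], [(1, 2)], [(1, 2)]], 7)]:
            ds = make_genotypes(rows)
            n_perm = 4000
            res = hwe_test(ds, "siteA", "L1", n_perm=n_perm, seed=seed)
            exact = exact_hwe_two_allele_p(ds.calls[:, 0, :])
            se = math.sqrt(exact * (1 - exact) / n_perm)
            assert abs(res.p_value - exact) <= 2 * se + 2 / n_perm

    def test_seed_deterministic(self):
        ds = make_genotypes([[(1, 1)], [(1, 2)], [(2, 2)], [(1, 2)], [(1, 1)]])
        p1 = hwe_test(ds, "siteA", "L1", n_perm=500, seed=9).p_value
        p2 = hwe_test(ds, "siteA", "L1", n_perm=500, seed=9).p_value
        assert p1 == p2


class TestLdTest:
    def test_perfect_dependence_minimal_p(self):
        rng = np.random.default_rng(0)
        genos = rng.choice([(1, 1), (1, 2), (2, 2)], size=30)
        rows = [[tuple(g), tuple(g)] for g in genos]  # locus duplicated
        ds = make_genotypes(rows)
        res = ld_test(ds, "siteA", ("L1", "L2"), n_perm=499, seed=2)
        # only permutations reproducing the pairing can tie the observed G
        assert res.p_value < 0.02

    def test_monomorphic_locus_undefined(self):
        rows = [[(1, 1), (1, 2)], [(1, 1), (2, 2)], [(1, 1), (1, 1)]]
        ds = make_genotypes(rows)
        assert ld_test(ds, "siteA", ("L1", "L2")).p_value is None

    def test_individual_order_invariance(self):
        rng = np.random.default_rng(3)
        rows = [[tuple(sorted(rng.integers(1, 4, 2))),
                 tuple(sorted(rng.integers(1, 4, 2)))] for _ in range(20)]
        ds = make_genotypes(rows)
        res1 = ld_test(ds, "siteA", ("L1", "L2"), n_perm=299, seed=4)
        perm = rng.permutation(20)
        ds2 = make_genotypes([rows[i] for i in perm])
        res2 = ld_test(ds2, "siteA", ("L1", "L2"), n_perm=299, seed=4)
        assert res1.statistic == pytest.approx(res2.statistic)
        # null stream is canonicalized, so p is exactly order-invariant
        assert res1.p_value == res2.p_value


class TestBonferroni:
    def test_hwe_family_reproduces_printed_alpha(self):
        assert bonferroni_alpha(0.05, 9 * 11, sig_figs=1) == 0.0005

    def test_ld_family_reproduces_printed_alpha(self):
        assert bonferroni_alpha(0.05, 36 * 11, sig_figs=1) == 0.0001

    def test_single_test_identity(self):
        assert bonferroni_alpha(0.05, 1) == 0.05


class TestRarefaction:
    def _dataset(self, seed=0):
        spec = IslandModelSpec(n_sites=2, n_per_site=30, n_loci=5,
                               n_alleles_per_locus=8, target_fst=0.05,
                               seed=seed)
        return simulate_island_genotypes(spec)

    def test_full_sample_size_exact_no_variability(self):
        ds = self._dataset()
        curves = rarefied_allelic_richness(ds, [30], n_reps=50, seed=1)
        for c in curves.values():
            observed = np.mean([
                len(np.unique(ds.calls[ds.by_site()[c.unit], j, :]))
                for j in range(ds.n_loci)])
            assert c.mean_richness[0] == pytest.approx(observed)
            assert c.sd_richness[0] == 0.0

    def test_matches_hypergeometric_closed_form(self):
        # exact closed form for subsampling N of n individuals: an allele
        # carried by t_a individuals is absent from the subsample with
        # probability C(n - t_a, N) / C(n, N); the gene-level form (2N of
        # 2n gene copies) is only an approximation, checked loosely below
        ds = self._dataset(seed=3)
        site = ds.site_names()[0]
        idx = ds.by_site()[site]
        n, n_std, n_reps = len(idx), 10, 2000
        curves = rarefied_allelic_richness(ds, [n_std], n_reps=n_reps, seed=2)
        c = curves[site]
        exact, gene_level = [], []
        for j in range(ds.n_loci):
            calls = ds.calls[idx, j, :]
            alleles, counts = np.unique(calls, return_counts=True)
            carriers = [int(np.sum((calls == a).any(axis=1))) for a in alleles]
            exact.append(sum(
                1 - math.comb(n - t, n_std) / math.comb(n, n_std)
                for t in carriers))
            gene_level.append(sum(
                1 - math.comb(2 * n - ca, 2 * n_std)
                / math.comb(2 * n, 2 * n_std) for ca in counts))
        target = float(np.mean(exact))
        se = c.sd_richness[0] / math.sqrt(n_reps)
        assert abs(c.mean_richness[0] - target) <= 3 * se + 1e-9
        assert abs(c.mean_richness[0] - float(np.mean(gene_level))) < 0.05

    def test_single_individual_bound(self):
        ds = self._dataset()
        curves = rarefied_allelic_richness(ds, [1], n_reps=100, seed=4)
        for c in curves.values():
            assert 1.0 <= c.mean_richness[0] <= 2.0

    def test_monotone_in_n(self):
        ds = self._dataset(seed=5)
        curves = rarefied_allelic_richness(ds, [5, 10, 20, 30],
                                           n_reps=400, seed=6)
        for c in curves.values():
            assert np.all(np.diff(c.mean_richness) >= -1e-9)

    def test_oversized_n_skipped_as_nan(self):
        ds = self._dataset()
        curves = rarefied_allelic_richness(ds, [30, 40], n_reps=10, seed=7)
        for c in curves.values():
            assert math.isnan(c.mean_richness[1])

    def test_region_pooling_never_below_max_member(self):
        ds = self._dataset(seed=8)
        sites = ds.site_names()
        per_site = rarefied_allelic_richness(ds, [20], n_reps=400, seed=9)
        pooled = rarefied_allelic_richness(
            ds, [20], n_reps=400, seed=9, pooling="region",
            regions={s: "all" for s in sites})
        best_site = max(per_site[s].mean_richness[0] for s in sites)
        assert pooled["all"].mean_richness[0] >= best_site - 0.05


class TestRichnessDifference:
    def _contrast_dataset(self):
        rng = np.random.default_rng(12)
        rows_a = [[tuple(sorted(rng.integers(1, 16, 2))) for _ in range(4)]
                  for _ in range(20)]
        rows_b = [[tuple(sorted(rng.integers(1, 4, 2))) for _ in range(4)]
                  for _ in range(20)]
        return make_genotypes(rows_a + rows_b, sites=["A"] * 20 + ["B"] * 20)

    def test_unit_against_itself_null(self):
        ds = self._contrast_dataset()
        # compare a site with a shuffled copy of itself via pooled labels
        rows = [[tuple(c) for c in ind] for ind in ds.calls[:20].tolist()]
        ds_self = make_genotypes(rows + rows, sites=["A"] * 20 + ["B"] * 20)
        res = richness_difference_test(ds_self, "A", "B", n_std=10,
                                       n_reps=40, n_perm=99, seed=13)
        assert res.p_value > 0.5

    def test_strong_allele_pool_contrast_rejected(self):
        ds = self._contrast_dataset()
        res = richness_difference_test(ds, "A", "B", n_std=15,
                                       n_reps=40, n_perm=199, seed=14)
        assert res.p_value < 0.01

    def test_p_respects_floor(self):
        ds = self._contrast_dataset()
        res = richness_difference_test(ds, "A", "B", n_std=10,
                                       n_reps=20, n_perm=99, seed=15)
        assert res.p_value >= 1 / (1 + 99)


class TestHaplotypeFrequencies:
    def test_single_haplotype(self):
        aln = SequenceAlignment(ids=["a", "b", "c"], sites=["X", "X", "Y"],
                                sequences=["ACGT"] * 3)
        table = haplotype_frequencies(aln)
        assert list(table.index) == ["H1"]
        assert table.loc["H1", "X"] == 2
        assert table.loc["H1", "Y"] == 1

    def test_saimaa_like_concentration(self):
        aln = simulate_mtdna_haplotypes(
            {"Saimaa": 22, "Other": 10}, shared_pool=4, private_pool=1,
            divergence=2, seq_length=200, saimaa_like=["Saimaa"], seed=3)
        table = haplotype_frequencies(aln)
        assert table["Saimaa"].max() >= 21

    def test_reordering_invariance(self):
        rng = np.random.default_rng(5)
        seqs = ["ACGT", "ACGA", "ACGT", "TCGT"]
        aln = SequenceAlignment(ids=list("abcd"), sites=["X"] * 4,
                                sequences=seqs)
        n1 = len(haplotype_frequencies(aln))
        perm = rng.permutation(4)
        aln2 = SequenceAlignment(ids=[aln.ids[i] for i in perm],
                                 sites=["X"] * 4,
                                 sequences=[seqs[i] for i in perm])
        assert len(haplotype_frequencies(aln2)) == n1

    def test_ambiguous_columns_excluded_listwise(self):
        aln = SequenceAlignment(ids=["a", "b"], sites=["X", "X"],
                                sequences=["ACNT", "ACAT"])
        table = haplotype_frequencies(aln)
        assert len(table) == 1  # they differ only at the masked column


class TestDuplicateScreen:
    def test_identical_genotypes_flagged(self):
        row = [(1, 2)] * 9
        ds = make_genotypes([row, row])
        assert find_duplicate_genotypes(ds) == [("ind1", "ind2", 0)]

    def test_one_allele_difference_flagged(self):
        a = [(1, 2)] + [(3, 3)] * 8
        b = [(1, 1)] + [(3, 3)] * 8
        ds = make_genotypes([a, b])
        assert find_duplicate_genotypes(ds) == [("ind1", "ind2", 1)]

    def test_two_mismatches_not_flagged(self):
        a = [(1, 2), (1, 2)] + [(3, 3)] * 7
        b = [(1, 1), (1, 1)] + [(3, 3)] * 7
        ds = make_genotypes([a, b])
        assert find_duplicate_genotypes(ds) == []
        assert find_duplicate_genotypes(ds, max_mismatch=2) == \
            [("ind1", "ind2", 2)]

    def test_missing_loci_skipped_in_comparison(self):
        a = [(1, 2), (0, 0)]
        b = [(1, 2), (5, 6)]
        ds = make_genotypes([a, b])
        assert find_duplicate_genotypes(ds) == [("ind1", "ind2", 0)]
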