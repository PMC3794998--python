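import numpy as np
import pytest
from scipy.stats import spearmanr

from sealpop.differentiation import (amova, avg_pairwise_differences,
                                     fst_permutation_test,
                                     weir_cockerham_fst)
from sealpop.distances import DistanceMatrix, pairwise_genotype_distances
from sealpop.synthetic import IslandModelSpec, simulate_island_genotypes
from tests.conftest import make_genotypes


def wc_two_pop_one_locus_oracle(calls_1, calls_2):
    """Direct evaluation of the published variance-component formulas.

    Independent implementation for a 2-population single-locus case:
    returns (sum_a, sum_b, sum_c) over alleles.
    """
    pops = [np.asarray(calls_1), np.asarray(calls_2)]
    r = 2
    n = np.array([len(p) for p in pops], dtype=float)
    nbar = n.mean()
    nc = (r * nbar - (n ** 2).sum() / (r * nbar)) / (r - 1)
    alleles = np.unique(np.concatenate([p.reshape(-1) for p in pops]))
    sa = sb = sc = 0.0
    for al in alleles:
        p = np.array([np.mean(pop == al) for pop in pops])
        h = np.array([np.mean((pop[:, 0] != pop[:, 1])
                              & ((pop[:, 0] == al) | (pop[:, 1] == al)))
                      for pop in pops])
        pbar = (n * p).sum() / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * h).sum() / (r * nbar)
        sa += (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - hbar / 4) / (nbar - 1))
        sb += (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - (2 * nbar - 1) / (4 * nbar) * hbar)
        sc += hbar / 2
    return sa, sb, sc


class TestWeirCockerham:
    def test_complete_fixation_theta_one(self):
        rows = [[(1, 1), (3, 3)]] * 5 + [[(2, 2), (4, 4)]] * 5
        ds = make_genotypes(rows, sites=["A"] * 5 + ["B"] * 5)
        assert weir_cockerham_fst(ds) == pytest.approx(1.0)

    def test_duplicated_sites_theta_nonpositive(self):
        rng = np.random.default_rng(8)
        block = [[tuple(sorted(rng.integers(1, 6, 2))) for _ in range(5)]
                 for _ in range(12)]
        ds = make_genotypes(block + block, sites=["A"] * 12 + ["B"] * 12)
        theta = weir_cockerham_fst(ds)
        assert theta <= 0.0
        assert theta == pytest.approx(0.0, abs=0.1)

    def test_matches_hand_component_oracle(self):
        # 2 sites, 1 locus, n = (4, 4); component values frozen from the
        # independent per-allele evaluation below
        calls_1 = [(1, 1), (1, 2), (2, 2), (1, 1)]
        calls_2 = [(2, 2), (2, 2), (1, 2), (2, 2)]
        ds = make_genotypes([[g] for g in calls_1 + calls_2],
                            sites=["A"] * 4 + ["B"] * 4)
        theta, comps = weir_cockerham_fst(ds, return_components=True)
        sa, sb, sc = wc_two_pop_one_locus_oracle(calls_1, calls_2)
        assert comps["a"] == pytest.approx(sa)
        assert comps["b"] == pytest.approx(sb)
        assert comps["c"] == pytest.approx(sc)
        assert theta == pytest.approx(sa / (sa + sb + sc))
        # frozen numbers: per-allele a=0.08854167, b=0.08333, c=0.125 (x2)
        assert comps["a"] == pytest.approx(2 * 0.0885416667)
        assert theta == pytest.approx(0.2982456, abs=1e-6)

    def test_ratio_of_sums_not_mean_of_ratios(self):
        # a second locus with no among-site signal pulls theta down via
        # the summed denominators, not by averaging a 0 ratio
        calls_1 = [(1, 1), (1, 2), (2, 2), (1, 1)]
        calls_2 = [(2, 2), (2, 2), (1, 2), (2, 2)]
        null_locus = [(1, 2)] * 8  # identical everywhere
        rows = [[g, n] for g, n in zip(calls_1 + calls_2, null_locus)]
        ds = make_genotypes(rows, sites=["A"] * 4 + ["B"] * 4)
        sa, sb, sc = wc_two_pop_one_locus_oracle(calls_1, calls_2)
        sa2, sb2, sc2 = wc_two_pop_one_locus_oracle(null_locus[:4],
                                                    null_locus[4:])
        expected = (sa + sa2) / (sa + sb + sc + sa2 + sb2 + sc2)
        assert weir_cockerham_fst(ds) == pytest.approx(expected)

    def test_missing_data_pairwise_deletion(self):
        rows = [[(1, 1), (0, 0)]] * 4 + [[(2, 2), (0, 0)]] * 4
        ds = make_genotypes(rows, sites=["A"] * 4 + ["B"] * 4)
        assert weir_cockerham_fst(ds) == pytest.approx(1.0)

    def test_no_informative_locus_nan(self):
        ds = make_genotypes([[(1, 1)]] * 4, sites=["A", "A", "B", "B"])
        assert np.isnan(weir_cockerham_fst(ds))


class TestFstPermutation:
    def test_fixed_difference_minimal_p(self):
        rows = [[(1, 1), (3, 3)]] * 10 + [[(2, 2), (4, 4)]] * 10
        ds = make_genotypes(rows, sites=["A"] * 10 + ["B"] * 10)
        res = fst_permutation_test(ds, ("A", "B"), n_perm=999, seed=3)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_seed_deterministic(self, two_site_dataset):
        r1 = fst_permutation_test(two_site_dataset, ("A", "B"),
                                  n_perm=199, seed=11)
        r2 = fst_permutation_test(two_site_dataset, ("A", "B"),
                                  n_perm=199, seed=11)
        assert r1.p_value == r2.p_value


def brute_force_amova_components(values, labels):
    """SS decomposition by explicit pair enumeration (test oracle)."""
    labels = list(labels)
    n = len(labels)
    groups = sorted(set(labels))
    d2 = np.asarray(values, dtype=float) ** 2
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i, lab in enumerate(labels) if lab == g]
        ss_within += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
    ss_among = ss_total - ss_within
    k = len(groups)
    sizes = np.array([labels.count(g) for g in groups], dtype=float)
    n0 = (n - (sizes ** 2).sum() / n) / (k - 1)
    sigma_w = ss_within / (n - k)
    sigma_a = (ss_among / (k - 1) - sigma_w) / n0
    return ss_among, ss_within, sigma_a, sigma_w


class TestAmova:
    def _toy(self):
        rng = np.random.default_rng(17)
        values = rng.integers(1, 9, size=(6, 6)).astype(float)
        values = np.triu(values, 1)
        values = values + values.T
        labels = ["A", "A", "B", "B", "C", "C"]
        return DistanceMatrix(ids=[f"i{k}" for k in range(6)],
                              values=values, metric="toy"), labels

    def test_components_match_brute_force(self):
        dm, labels = self._toy()
        res = amova(dm, labels, n_perm=0)
        ss_a, ss_w, sig_a, sig_w = brute_force_amova_components(dm.values,
                                                                labels)
        assert res.ss_among == pytest.approx(ss_a)
        assert res.ss_within == pytest.approx(ss_w)
        assert res.sigma_among == pytest.approx(sig_a)
        assert res.sigma_within == pytest.approx(sig_w)
        assert res.phi_st == pytest.approx(sig_a / (sig_a + sig_w))
        assert res.pct_among + res.pct_within == pytest.approx(100.0)

    def test_degenerate_all_zero_distances(self):
        dm = DistanceMatrix(ids=list("abcd"), values=np.zeros((4, 4)),
                            metric="toy")
        res = amova(dm, ["A", "A", "B", "B"], n_perm=10, seed=0)
        assert res.sigma_among == 0.0
        assert res.sigma_within == 0.0
        assert (res.pct_among, res.pct_within) == (0.0, 100.0)
        assert any("zero total variance" in f for f in res.flags)

    def test_saturated_structure_phi_one(self):
        values = np.full((4, 4), 5.0)
        np.fill_diagonal(values, 0.0)
        values[0, 1] = values[1, 0] = 0.0
        values[2, 3] = values[3, 2] = 0.0
        dm = DistanceMatrix(ids=list("abcd"), values=values, metric="toy")
        res = amova(dm, ["A", "A", "B", "B"], n_perm=0)
        assert res.sigma_within == 0.0
        assert res.phi_st == pytest.approx(1.0)

    def test_singleton_site_excluded_with_flag(self):
        dm, labels = self._toy()
        labels = ["A", "A", "B", "B", "C", "D"]
        with pytest.warns(UserWarning, match="singleton"):
            res = amova(dm, labels, n_perm=0)
        assert any("singleton" in f for f in res.flags)
        assert res.df_among == 1  # only A and B retained

    def test_permutation_p_floor_and_determinism(self):
        dm, labels = self._toy()
        r1 = amova(dm, labels, n_perm=99, seed=5)
        r2 = amova(dm, labels, n_perm=99, seed=5)
        assert r1.p_value == r2.p_value
        assert r1.p_value >= 1 / 100

    def test_phi_tracks_theta_across_drift_levels(self):
        # ordering agreement between the distance-based and the
        # variance-component estimators over a simulated F gradient
        thetas, phis = [], []
        for i, f in enumerate([0.02, 0.05, 0.1, 0.2, 0.35]):
            spec = IslandModelSpec(n_sites=2, n_per_site=25, n_loci=6,
                                   n_alleles_per_locus=6, target_fst=f,
                                   seed=100 + i)
            ds = simulate_island_genotypes(spec)
            thetas.append(weir_cockerham_fst(ds))
            dm = pairwise_genotype_distances(ds, metric="allele_count_diff")
            phis.append(amova(dm, ds.sites, n_perm=0).phi_st)
        rho = spearmanr(thetas, phis).statistic
        assert rho > 0.9
        assert np.all(np.sign(thetas) == np.sign(phis))


class TestAvgPairwiseDifferences:
    def test_all_identical_zero(self):
        dm = DistanceMatrix(ids=list("abcd"), values=np.zeros((4, 4)),
                            metric="toy")
        within, between = avg_pairwise_differences(dm, ["A", "A", "B", "B"])
        assert within["A"] == 0.0
        assert between.loc["A", "B"] == 0.0

    def test_hand_enumeration_two_sites_of_two(self):
        values = np.array([
            [0, 2, 5, 7],
            [2, 0, 4, 6],
            [5, 4, 0, 3],
            [7, 6, 3, 0]], dtype=float)
        dm = DistanceMatrix(ids=list("abcd"), values=values, metric="toy")
        within, between = avg_pairwise_differences(dm, ["A", "A", "B", "B"])
        assert within["A"] == 2.0
        assert within["B"] == 3.0
        assert between.loc["A", "B"] == pytest.approx((5 + 7 + 4 + 6) / 4)
        assert between.loc["B", "A"] == between.loc["A", "B"]

    def test_singleton_site_nan_within(self):
        dm = DistanceMatrix(ids=list("abc"), values=np.zeros((3, 3)),
                            metric="toy")
        within, _ = avg_pairwise_differences(dm, ["A", "A", "B"])
        assert np.isnan(within["B"])
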