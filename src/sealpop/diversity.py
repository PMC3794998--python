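"""Within-site diversity statistics for microsatellite and mtDNA data.

Covers observed/unbiased-expected heterozygosity, Monte-Carlo exact
Hardy–Weinberg tests, genotypic linkage-disequilibrium tests, Bonferroni
family corrections, individual-subsampling rarefaction of allelic
richness, per-site haplotype frequency tallies, and the one-mismatch
duplicate-genotype screen used to detect resampled individuals from shed
skin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeDataset, PermutationTestResult, SequenceAlignment, MISSING, permutation_p
from .distances import _locus_allele_diff


@dataclass
class SiteLocusSummary:
    """Heterozygosity summary for one site x locus cell."""

    site: str
    locus: str
    n: int                      # genotyped individuals
    allele_counts: dict[int, int]
    h_obs: float | None
    h_exp: float | None         # Nei unbiased, needs n >= 2
    polymorphic: bool
    hwe_p: float | None = None


def _site_locus_calls(ds: GenotypeDataset, site: str, locus: str) -> np.ndarray:
    """Non-missing (n, 2) allele array for one site x locus cell."""
    j = ds.loci.index(locus)
    idx = ds.by_site()[site]
    calls = ds.calls[idx, j, :]
    return calls[~(calls == MISSING).all(axis=1)]


def heterozygosity(ds: GenotypeDataset) -> list[SiteLocusSummary]:
    """Observed and unbiased expected heterozygosity per site x locus.

    H_o is the fraction of genotyped individuals that are heterozygous;
    H_e is Nei's unbiased estimator ``(2n / (2n - 1)) (1 - sum p_k^2)``,
    computed only when n >= 2. Cells with no genotyped individual are
    returned with ``n = 0`` and None statistics so callers can exclude
    them from means.
    """
    out: list[SiteLocusSummary] = []
    for site in ds.site_names():
        for locus in ds.loci:
            calls = _site_locus_calls(ds, site, locus)
            n = len(calls)
            if n == 0:
                out.append(SiteLocusSummary(site, locus, 0, {}, None, None,
                                            False))
                continue
            alleles, counts = np.unique(calls, return_counts=True)
            freqs = counts / counts.sum()
            h_obs = float(np.mean(calls[:, 0] != calls[:, 1]))
            if n >= 2:
                h_exp = float((2 * n / (2 * n - 1)) * (1 - np.sum(freqs ** 2)))
            else:
                h_exp = None
            out.append(SiteLocusSummary(
                site=site, locus=locus, n=n,
                allele_counts={int(a): int(c) for a, c in zip(alleles, counts)},
                h_obs=h_obs, h_exp=h_exp, polymorphic=len(alleles) >= 2))
    return out


def site_mean_heterozygosity(summaries: list[SiteLocusSummary]) -> pd.DataFrame:
    """Per-site mean H_o / H_e over polymorphic loci, plus locus counts."""
    rows = []
    for site in dict.fromkeys(s.site for s in summaries):
        cell = [s for s in summaries if s.site == site
                and s.polymorphic and s.h_exp is not None]
        rows.append({
            "site": site,
            "n_polymorphic_loci": len(cell),
            "mean_h_obs": float(np.mean([s.h_obs for s in cell])) if cell else np.nan,
            "mean_h_exp": float(np.mean([s.h_exp for s in cell])) if cell else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test (Monte-Carlo)


def _genotype_log_prob(pairs: np.ndarray) -> float:
    """Log conditional probability of a genotype array given allele counts.

    For n diploid genotypes with h heterozygotes, genotype counts n_ab and
    allele counts m_a: P = n! 2^h prod(m_a!) / ((2n)! prod(n_ab!)).
    """
    n = len(pairs)
    ordered = np.sort(pairs, axis=1)
    _, geno_counts = np.unique(ordered, axis=0, return_counts=True)
    _, allele_counts = np.unique(pairs, return_counts=True)
    h = int(np.sum(pairs[:, 0] != pairs[:, 1]))
    logp = (math.lgamma(n + 1) + h * math.log(2)
            + sum(math.lgamma(m + 1) for m in allele_counts)
            - math.lgamma(2 * n + 1)
            - sum(math.lgamma(c + 1) for c in geno_counts))
    return logp


def hwe_test(ds: GenotypeDataset, site: str, locus: str,
             n_perm: int = 1000, seed: int = 0) -> PermutationTestResult:
    """Monte-Carlo exact test of Hardy–Weinberg proportions in one cell.

    The statistic is the conditional probability of the observed genotype
    array given its allele counts; the null is generated by randomly
    re-pairing the observed allele pool (each pairing drawn uniformly),
    and the two-sided exact-style p-value counts replicates with
    probability <= the observed one, using the (1 + b)/(1 + n_perm) rule.
    ``extra["p_homozygote_excess"]`` carries the one-sided p in the
    direction of homozygote excess (fewer heterozygotes than the null).

    Returns a result with ``p_value=None`` when the cell is monomorphic
    (the test is undefined) or has fewer than 3 genotyped individuals.
    """
    pairs = _site_locus_calls(ds, site, locus)
    n = len(pairs)
    if n < 3 or len(np.unique(pairs)) < 2:
        return PermutationTestResult(statistic=float("nan"), p_value=None,
                                     n_perm=0, seed=seed, name="hwe")
    obs_logp = _genotype_log_prob(pairs)
    obs_het = int(np.sum(pairs[:, 0] != pairs[:, 1]))

    pool = pairs.reshape(-1)
    rng = np.random.default_rng(seed)
    b_two = b_hom = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool).reshape(n, 2)
        if _genotype_log_prob(perm) <= obs_logp + 1e-12:
            b_two += 1
        if int(np.sum(perm[:, 0] != perm[:, 1])) <= obs_het:
            b_hom += 1
    return PermutationTestResult(
        statistic=obs_logp, p_value=permutation_p(b_two, n_perm),
        n_perm=n_perm, seed=seed, name="hwe",
        extra={"n": n, "n_het": obs_het,
               "p_homozygote_excess": permutation_p(b_hom, n_perm)})


# ---------------------------------------------------------------------------
# Linkage disequilibrium (genotypic G test by permutation)


def _g_statistic(a_codes: np.ndarray, b_codes: np.ndarray) -> float:
    """Log-likelihood-ratio G for independence of two categorical vectors."""
    ka, kb = a_codes.max() + 1, b_codes.max() + 1
    table = np.bincount(a_codes * kb + b_codes,
                        minlength=ka * kb).reshape(ka, kb).astype(float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    return float(2.0 * terms.sum())


def _genotype_codes(calls: np.ndarray) -> np.ndarray:
    """Map (n, 2) unordered allele pairs to integer genotype categories."""
    ordered = np.sort(calls, axis=1)
    _, codes = np.unique(ordered, axis=0, return_inverse=True)
    return codes


def ld_test(ds: GenotypeDataset, site: str, locus_pair: tuple[str, str],
            n_perm: int = 1000, seed: int = 0) -> PermutationTestResult:
    """Genotypic linkage-disequilibrium permutation test within one site.

    The statistic is the G log-likelihood ratio for independence of the
    two-locus genotype contingency table; the null permutes one locus's
    genotypes among individuals, breaking any between-locus association
    while preserving both single-locus genotype distributions. Undefined
    (``p_value=None``) when either locus is monomorphic in the site.
    """
    la, lb = locus_pair
    ja, jb = ds.loci.index(la), ds.loci.index(lb)
    idx = ds.by_site()[site]
    calls_a = ds.calls[idx, ja, :]
    calls_b = ds.calls[idx, jb, :]
    ok = ~((calls_a == MISSING).all(axis=1) | (calls_b == MISSING).all(axis=1))
    calls_a, calls_b = calls_a[ok], calls_b[ok]
    if len(calls_a) < 3 or len(np.unique(calls_a)) < 2 \
            or len(np.unique(calls_b)) < 2:
        return PermutationTestResult(statistic=float("nan"), p_value=None,
                                     n_perm=0, seed=seed, name="ld")
    codes_a = _genotype_codes(calls_a)
    codes_b = _genotype_codes(calls_b)
    obs = _g_statistic(codes_a, codes_b)
    rng = np.random.default_rng(seed)
    # sorted copies make the null stream invariant to individual input
    # order; random pairings of sorted codes are exchangeable with random
    # pairings of the originals
    sorted_a = np.sort(codes_a)
    sorted_b = np.sort(codes_b)
    b = 0
    for _ in range(n_perm):
        if _g_statistic(sorted_a, rng.permutation(sorted_b)) >= obs - 1e-12:
            b += 1
    return PermutationTestResult(
        statistic=obs, p_value=permutation_p(b, n_perm), n_perm=n_perm,
        seed=seed, name="ld", extra={"n": len(codes_a), "site": site,
                                     "loci": locus_pair})


# ---------------------------------------------------------------------------
# Bonferroni correction


def bonferroni_alpha(family_alpha: float, n_tests: int,
                     sig_figs: int | None = None) -> float:
    """Bonferroni-adjusted per-test significance level.

    ``sig_figs`` rounds the returned value to that many significant
    figures for reporting (e.g. 0.05 / 99 -> 0.0005 at 1 sig fig); the
    unrounded value should be used for actual decisions.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    alpha = family_alpha / n_tests
    if sig_figs is not None:
        if alpha == 0:
            return 0.0
        digits = sig_figs - 1 - math.floor(math.log10(abs(alpha)))
        alpha = round(alpha, digits)
    return alpha


# ---------------------------------------------------------------------------
# Rarefied allelic richness


@dataclass
class RarefactionCurve:
    """Mean allelic richness at standardized sample sizes for one unit."""

    unit: str
    sizes: list[int]
    mean_richness: list[float]
    sd_richness: list[float]
    n_reps: int
    seed: int
    sample_size: int


def _mean_alleles_per_locus(calls: np.ndarray) -> float:
    """Mean number of distinct alleles per locus over non-missing genotypes."""
    per_locus = []
    for j in range(calls.shape[1]):
        col = calls[:, j, :]
        col = col[~(col == MISSING).all(axis=1)]
        if len(col) == 0:
            continue  # locus absent from the subsample: renormalize over the rest
        per_locus.append(len(np.unique(col)))
    if not per_locus:
        return float("nan")
    return float(np.mean(per_locus))


def rarefied_allelic_richness(ds: GenotypeDataset, n_values: list[int],
                              n_reps: int = 1000, seed: int = 0,
                              pooling: str = "site",
                              regions: dict[str, str] | None = None,
                              ) -> dict[str, RarefactionCurve]:
    """Allelic richness standardized to sample size by subsampling genotypes.

    For each unit (site, or region when ``pooling="region"`` with a
    site → region map) and each standardized size N, individuals are drawn
    without replacement ``n_reps`` times; each draw's richness is the mean
    over loci of the number of distinct alleles among the subsample's
    non-missing genotypes. Sizes exceeding a unit's sample size are
    skipped with a warning entry (NaN mean).
    """
    if pooling not in ("site", "region"):
        raise ValueError("pooling must be 'site' or 'region'")
    units: dict[str, np.ndarray] = {}
    if pooling == "site":
        units = ds.by_site()
    else:
        if regions is None:
            raise ValueError("region pooling requires a site -> region map")
        for site, idx in ds.by_site().items():
            region = regions[site]
            units[region] = np.concatenate([units.get(region, np.empty(0, int)),
                                            idx]).astype(int)
    curves: dict[str, RarefactionCurve] = {}
    for u, (unit, idx) in enumerate(units.items()):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 40, u])
        means, sds, sizes = [], [], []
        for n_std in n_values:
            if n_std > len(idx):
                sizes.append(int(n_std))
                means.append(float("nan"))
                sds.append(float("nan"))
                continue
            if n_std == len(idx):
                reps = np.array([_mean_alleles_per_locus(ds.calls[idx])])
            else:
                reps = np.array([
                    _mean_alleles_per_locus(
                        ds.calls[rng.choice(idx, size=n_std, replace=False)])
                    for _ in range(n_reps)])
            sizes.append(int(n_std))
            means.append(float(np.nanmean(reps)))
            sds.append(float(np.nanstd(reps, ddof=0)) if len(reps) > 1 else 0.0)
        curves[unit] = RarefactionCurve(unit=unit, sizes=sizes,
                                        mean_richness=means, sd_richness=sds,
                                        n_reps=n_reps, seed=seed,
                                        sample_size=len(idx))
    return curves


def richness_difference_test(ds: GenotypeDataset, unit_a: str, unit_b: str,
                             n_std: int, n_reps: int = 100,
                             n_perm: int = 199, seed: int = 0,
                             ) -> PermutationTestResult:
    """Permutation test for a difference in rarefied allelic richness.

    The observed statistic is |Â_N(a) − Â_N(b)| at the standardized size
    ``n_std`` (each Â_N a mean over ``n_reps`` subsample draws). The null
    pools the two units' individuals and re-splits them at the observed
    sample sizes before recomputing the difference. Two-sided p with the
    (1 + b)/(1 + n_perm) rule.
    """
    by_site = ds.by_site()
    idx_a, idx_b = by_site[unit_a], by_site[unit_b]
    if n_std > min(len(idx_a), len(idx_b)):
        raise ValueError(
            f"standardized size {n_std} exceeds a unit sample size")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 41])

    def richness(idx: np.ndarray) -> float:
        if n_std == len(idx):
            return _mean_alleles_per_locus(ds.calls[idx])
        reps = [_mean_alleles_per_locus(
            ds.calls[rng.choice(idx, size=n_std, replace=False)])
            for _ in range(n_reps)]
        return float(np.nanmean(reps))

    obs = abs(richness(idx_a) - richness(idx_b))
    pooled = np.concatenate([idx_a, idx_b])
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        diff = abs(richness(perm[:len(idx_a)]) - richness(perm[len(idx_a):]))
        if diff >= obs - 1e-12:
            b += 1
    return PermutationTestResult(
        statistic=obs, p_value=permutation_p(b, n_perm), n_perm=n_perm,
        seed=seed, name="richness_difference",
        extra={"units": (unit_a, unit_b), "n_std": n_std})


# ---------------------------------------------------------------------------
# Haplotype frequencies


def haplotype_frequencies(aln: SequenceAlignment) -> pd.DataFrame:
    """Tally unique haplotypes per site over fully-resolved columns.

    Columns where any sequence carries N or a gap are excluded listwise
    (the same positions for every sequence), then haplotypes are keyed by
    exact identity of the remaining string. Returns a counts DataFrame
    (rows = global haplotype ids ordered by total frequency, columns =
    sites) whose ``attrs["haplotype_sequences"]`` maps id -> sequence.
    """
    if aln.n_sequences == 0:
        raise ValueError("empty alignment")
    arr = np.array([list(s) for s in aln.sequences])
    keep = ~np.any((arr == "N") | (arr == "-"), axis=0)
    reduced = ["".join(row) for row in arr[:, keep]]

    order: dict[str, int] = {}
    for seq in reduced:
        order.setdefault(seq, len(order))
    counts = pd.crosstab(
        pd.Series([order[s] for s in reduced], name="hap"),
        pd.Series(aln.sites, name="site"))
    counts = counts.reindex(columns=aln.site_names(), fill_value=0)
    totals = counts.sum(axis=1)
    counts = counts.loc[totals.sort_values(ascending=False, kind="stable").index]
    seq_by_first = {v: k for k, v in order.items()}
    counts.index = [f"H{i + 1}" for i in range(len(counts))]
    counts.attrs["haplotype_sequences"] = {
        f"H{i + 1}": seq_by_first[old]
        for i, old in enumerate(totals.sort_values(
            ascending=False, kind="stable").index)}
    return counts


# ---------------------------------------------------------------------------
# Duplicate-genotype screen (one-mismatch model)


def find_duplicate_genotypes(ds: GenotypeDataset, max_mismatch: int = 1
                             ) -> list[tuple[str, str, int]]:
    """Flag genotype pairs differing by at most ``max_mismatch`` alleles.

    Mismatches are counted per allele over mutually non-missing loci
    (per locus: 2 minus the multiset intersection of the two allele
    pairs). The default one-mismatch model flags putative resamples of
    the same individual. Pairs with no comparable locus are never
    flagged.
    """
    flagged: list[tuple[str, str, int]] = []
    calls = ds.calls
    missing = ds.missing_mask
    for i in range(ds.n_individuals):
        for j in range(i + 1, ds.n_individuals):
            usable = ~(missing[i] | missing[j])
            if not usable.any():
                continue
            mm = 0
            for k in np.flatnonzero(usable):
                mm += _locus_allele_diff(calls[i, k], calls[j, k])
                if mm > max_mismatch:
                    break
            if mm <= max_mismatch:
                flagged.append((ds.individuals[i], ds.individuals[j], mm))
    return flagged
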