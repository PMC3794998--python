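"""Between-site genetic structure.

* Weir & Cockerham (1984) θ — the moment estimator of F_ST built from
  per-allele, per-locus variance components a (among populations),
  b (among individuals within populations) and c (within individuals) —
  with a label-permutation significance test.
* One-level AMOVA (Excoffier–Smouse–Quattro) on a pairwise distance
  matrix: squared distances are partitioned into among- and within-site
  sums of squares, variance components and Φ_ST, with significance by
  permuting individuals among sites.
* Average pairwise differences within and between sites, uncorrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeDataset, PermutationTestResult, MISSING, permutation_p
from .distances import DistanceMatrix


# ---------------------------------------------------------------------------
# Weir–Cockerham theta


def _wc_locus_components(per_site_calls: list[np.ndarray]
                         ) -> tuple[float, float, float]:
    """Summed per-allele components (a, b, c) for one locus.

    ``per_site_calls`` holds the non-missing (n_i, 2) allele arrays of
    each population at this locus; populations with fewer than one
    genotyped individual must already be dropped by the caller.
    """
    r = len(per_site_calls)
    n = np.array([len(c) for c in per_site_calls], dtype=float)
    nbar = n.mean()
    if nbar <= 1 or r < 2:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - np.sum(n ** 2) / (r * nbar)) / (r - 1)
    alleles = np.unique(np.concatenate([c.reshape(-1) for c in per_site_calls]))
    # per-site allele frequencies P and heterozygote frequencies H,
    # vectorized over alleles: shape (r, n_alleles)
    P = np.stack([(c[:, :, None] == alleles).sum(axis=(0, 1)) / (2 * len(c))
                  for c in per_site_calls])
    H = np.stack([
        (((c[:, 0] != c[:, 1])[:, None])
         & ((c[:, 0][:, None] == alleles) | (c[:, 1][:, None] == alleles))
         ).mean(axis=0)
        for c in per_site_calls])
    pbar = (n[:, None] * P).sum(axis=0) / (r * nbar)
    s2 = (n[:, None] * (P - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n[:, None] * H).sum(axis=0) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar)
                             - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def _theta_grouped(calls: np.ndarray, groups: list[np.ndarray]
                   ) -> tuple[float, dict]:
    """Multi-locus θ from a calls array and per-group row indices."""
    a_tot = b_tot = c_tot = 0.0
    informative = 0
    for j in range(calls.shape[1]):
        per_site = []
        for idx in groups:
            g = calls[idx, j, :]
            g = g[~(g == MISSING).all(axis=1)]
            if len(g) >= 1:
                per_site.append(g)
        if len(per_site) < 2:
            continue
        if len(np.unique(np.concatenate([g.reshape(-1) for g in per_site]))) < 2:
            continue  # monomorphic across the selected sites
        a, b, c = _wc_locus_components(per_site)
        if a + b + c != 0:
            informative += 1
        a_tot, b_tot, c_tot = a_tot + a, b_tot + b, c_tot + c
    if informative == 0 or (a_tot + b_tot + c_tot) == 0:
        theta = float("nan")
    else:
        theta = a_tot / (a_tot + b_tot + c_tot)
    return theta, {"a": a_tot, "b": b_tot, "c": c_tot,
                   "informative_loci": informative}


def weir_cockerham_fst(ds: GenotypeDataset,
                       sites: tuple[str, str] | list[str] | None = None,
                       return_components: bool = False):
    """Multi-locus Weir–Cockerham θ across the given sites (default: all).

    θ is the ratio of sums Σa / Σ(a+b+c) over alleles and loci (not an
    average of per-locus ratios), which stabilizes loci with little
    polymorphism. Missing genotypes are dropped per locus (pairwise
    deletion); loci leaving fewer than two populations with data, or
    monomorphic overall, contribute nothing. Returns NaN when no locus is
    informative.
    """
    use_sites = list(sites) if sites is not None else ds.site_names()
    if len(use_sites) < 2:
        raise ValueError("need at least 2 sites")
    by_site = ds.by_site()
    theta, comps = _theta_grouped(ds.calls, [by_site[s] for s in use_sites])
    if return_components:
        return theta, comps
    return theta


def pairwise_fst_table(ds: GenotypeDataset, n_perm: int = 1000,
                       seed: int = 0) -> pd.DataFrame:
    """θ and permutation p for every pair of sites with >= 2 members."""
    sites = [s for s, idx in ds.by_site().items() if len(idx) >= 2]
    rows = []
    for i, sa in enumerate(sites):
        for sb in sites[i + 1:]:
            res = fst_permutation_test(ds, (sa, sb), n_perm=n_perm,
                                       seed=seed + i)
            rows.append({"site_a": sa, "site_b": sb,
                         "theta": res.statistic, "p_value": res.p_value,
                         "n_perm": res.n_perm})
    return pd.DataFrame(rows)


def fst_permutation_test(ds: GenotypeDataset, site_pair: tuple[str, str],
                         n_perm: int = 1000, seed: int = 0
                         ) -> PermutationTestResult:
    """One-sided permutation test of θ > 0 between two sites.

    The null shuffles individuals between the two sites at their observed
    sample sizes; p counts permuted θ >= observed θ with the
    (1 + b)/(1 + n_perm) rule.
    """
    sa, sb = site_pair
    by_site = ds.by_site()
    idx = np.concatenate([by_site[sa], by_site[sb]])
    n_a = len(by_site[sa])
    calls = ds.calls[idx]
    n = len(idx)
    theta_obs, _ = _theta_grouped(calls, [np.arange(n_a), np.arange(n_a, n)])
    if not np.isfinite(theta_obs):
        return PermutationTestResult(statistic=float("nan"), p_value=None,
                                     n_perm=0, seed=seed, name="fst",
                                     extra={"reason": "no informative locus"})
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        theta_perm, _ = _theta_grouped(calls, [perm[:n_a], perm[n_a:]])
        if np.isfinite(theta_perm) and theta_perm >= theta_obs - 1e-12:
            b += 1
    return PermutationTestResult(
        statistic=theta_obs, p_value=permutation_p(b, n_perm),
        n_perm=n_perm, seed=seed, name="fst",
        extra={"sites": site_pair, "n": (n_a, len(idx) - n_a)})


# ---------------------------------------------------------------------------
# AMOVA


@dataclass
class AmovaResult:
    """One-level AMOVA decomposition with permutation significance."""

    sigma_among: float
    sigma_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    p_value: float | None
    n_perm: int
    seed: int | None
    marker: str = ""
    flags: list[str] = field(default_factory=list)


def _amova_ss(d2: np.ndarray, group_indices: list[np.ndarray]
              ) -> tuple[float, float]:
    """(SS_total, SS_within) from a squared-distance matrix."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for idx in group_indices:
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return float(ss_total), float(ss_within)


def amova(dm: DistanceMatrix, labels: list[str], n_perm: int = 16000,
          seed: int = 0, marker: str = "") -> AmovaResult:
    """One-level analysis of molecular variance on a distance matrix.

    Squared pairwise distances are decomposed into among-site and
    within-site sums of squares; σ²_within = SS_within / (N − k),
    σ²_among = (MS_among − σ²_within) / n₀ with the standard unequal-size
    coefficient n₀ = (N − Σn_g²/N)/(k − 1); Φ_ST = σ²_a / (σ²_a + σ²_b).
    Significance permutes individuals among sites at fixed sizes and
    counts Φ_perm >= Φ_obs. Sites with a single member are excluded with
    a warning recorded in ``flags``. Negative σ²_among is reported as
    computed, not truncated.
    """
    if len(labels) != dm.n:
        raise ValueError("one label per matrix row required")
    labels = list(labels)
    groups: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    flags = []
    kept = {g: np.asarray(v) for g, v in groups.items() if len(v) >= 2}
    dropped = sorted(set(groups) - set(kept))
    if dropped:
        flags.append(f"singleton sites excluded: {dropped}")
        warnings.warn(flags[-1], stacklevel=2)
    if len(kept) < 2:
        raise ValueError("AMOVA needs >= 2 sites with >= 2 members")
    keep_idx = np.concatenate(list(kept.values()))
    keep_idx.sort()
    remap = {old: new for new, old in enumerate(keep_idx)}
    d2 = dm.values[np.ix_(keep_idx, keep_idx)] ** 2
    group_indices = [np.array([remap[i] for i in v]) for v in kept.values()]
    sizes = np.array([len(v) for v in group_indices], dtype=float)
    n_tot, k = int(sizes.sum()), len(group_indices)
    df_among, df_within = k - 1, n_tot - k
    n0 = (n_tot - np.sum(sizes ** 2) / n_tot) / (k - 1)

    def decompose(gidx: list[np.ndarray]):
        ss_total, ss_within = _amova_ss(d2, gidx)
        ss_among = ss_total - ss_within
        sigma_w = ss_within / df_within
        sigma_a = (ss_among / df_among - sigma_w) / n0
        total = sigma_a + sigma_w
        phi = sigma_a / total if total > 0 else float("nan")
        return ss_among, ss_within, sigma_a, sigma_w, phi

    ss_among, ss_within, sigma_a, sigma_w, phi = decompose(group_indices)
    total = sigma_a + sigma_w
    if total > 0:
        pct_among = 100.0 * sigma_a / total
        pct_within = 100.0 * sigma_w / total
    else:  # fully degenerate matrix: all-zero distances
        flags.append("zero total variance; percentages set by convention")
        pct_among, pct_within = 0.0, 100.0
        phi = float("nan")

    p_value: float | None = None
    if n_perm > 0 and np.isfinite(phi):
        rng = np.random.default_rng(seed)
        starts = np.cumsum([0] + [len(g) for g in group_indices])
        b = 0
        n_kept = len(keep_idx)
        for _ in range(n_perm):
            perm = rng.permutation(n_kept)
            gidx = [perm[starts[i]:starts[i + 1]]
                    for i in range(len(group_indices))]
            phi_perm = decompose(gidx)[4]
            if np.isfinite(phi_perm) and phi_perm >= phi - 1e-12:
                b += 1
        p_value = permutation_p(b, n_perm)

    return AmovaResult(
        sigma_among=sigma_a, sigma_within=sigma_w,
        pct_among=pct_among, pct_within=pct_within, phi_st=phi,
        df_among=df_among, df_within=df_within,
        ss_among=ss_among, ss_within=ss_within,
        p_value=p_value, n_perm=n_perm, seed=seed, marker=marker,
        flags=flags)


# ---------------------------------------------------------------------------
# Average pairwise differences


def avg_pairwise_differences(dm: DistanceMatrix, labels: list[str]
                             ) -> tuple[pd.Series, pd.DataFrame]:
    """Mean pairwise distance within each site and between site pairs.

    Within-site means average over unordered within-site pairs (NaN for
    singleton sites); between-site entries average over all cross pairs,
    uncorrected for within-site diversity.
    """
    if len(labels) != dm.n:
        raise ValueError("one label per matrix row required")
    sites = list(dict.fromkeys(labels))
    idx = {s: np.array([i for i, lab in enumerate(labels) if lab == s])
           for s in sites}
    within = {}
    for s in sites:
        ii = idx[s]
        if len(ii) < 2:
            within[s] = float("nan")
        else:
            sub = dm.values[np.ix_(ii, ii)]
            within[s] = float(sub[np.triu_indices(len(ii), 1)].mean())
    between = pd.DataFrame(np.nan, index=sites, columns=sites)
    for i, sa in enumerate(sites):
        for sb in sites[i + 1:]:
            m = float(dm.values[np.ix_(idx[sa], idx[sb])].mean())
            between.loc[sa, sb] = between.loc[sb, sa] = m
    return pd.Series(within, name="within"), between
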