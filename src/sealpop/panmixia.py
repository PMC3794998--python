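"""Hudson–Boos–Kaplan K_ST test of panmixia between pairs of sites.

For two sampling sites with pairwise genetic distances between
individuals, K_i is the mean distance within site i, K_S the
sample-size-weighted average of the K_i, and K_T the mean distance over
all pairs regardless of site. The statistic K_ST = 1 − K_S/K_T is near
zero under panmixia and grows as within-site pairs become more similar
than between-site pairs. Significance comes from permuting site labels
over individuals at fixed sample sizes (one-sided: large K_ST rejects);
small problems are enumerated exhaustively instead of sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .datatypes import permutation_p
from .distances import DistanceMatrix

EXHAUSTIVE_LIMIT = 20_000  # label arrangements at or below this are enumerated


@dataclass
class KstResult:
    """K_ST decomposition and (optionally) its permutation p-value."""

    site_pair: tuple[str, str]
    n_per_site: tuple[int, int]
    k_within: tuple[float, float]   # K_1, K_2
    k_s: float
    k_t: float
    k_st: float | None              # None when K_T == 0 (degenerate)
    p_value: float | None = None
    n_perm: int = 0
    exhaustive: bool = False
    seed: int | None = None
    metric: str = ""
    degenerate: bool = False


def _kst_from_mask(values: np.ndarray, in_a: np.ndarray,
                   weights: str) -> tuple[float, float, float, float, float]:
    """(K_1, K_2, K_S, K_T, K_ST) for a boolean site-A membership mask."""
    n = values.shape[0]
    n1 = int(in_a.sum())
    n2 = n - n1
    iu = np.triu_indices(n, 1)
    k_t = float(values[iu].mean())
    a_idx = np.flatnonzero(in_a)
    b_idx = np.flatnonzero(~in_a)
    sub_a = values[np.ix_(a_idx, a_idx)]
    sub_b = values[np.ix_(b_idx, b_idx)]
    k1 = float(sub_a[np.triu_indices(n1, 1)].mean())
    k2 = float(sub_b[np.triu_indices(n2, 1)].mean())
    if weights == "sample_size":
        w1, w2 = n1 / n, n2 / n
    elif weights == "hbk":
        w1, w2 = (n1 - 1) / (n - 2), (n2 - 1) / (n - 2)
    else:
        raise ValueError("weights must be 'sample_size' or 'hbk'")
    k_s = w1 * k1 + w2 * k2
    k_st = 1.0 - k_s / k_t if k_t > 0 else float("nan")
    return k1, k2, k_s, k_t, k_st


def _prepare(dm: DistanceMatrix, labels: list[str]
             ) -> tuple[np.ndarray, str, str]:
    if len(labels) != dm.n:
        raise ValueError("one label per matrix row required")
    sites = list(dict.fromkeys(labels))
    if len(sites) != 2:
        raise ValueError(f"exactly 2 site labels required, got {sites}")
    counts = {s: labels.count(s) for s in sites}
    small = [s for s, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"site(s) {small} have fewer than 2 members")
    in_a = np.array([lab == sites[0] for lab in labels])
    return in_a, sites[0], sites[1]


def kst_statistic(dm: DistanceMatrix, labels: list[str],
                  weights: str = "sample_size") -> KstResult:
    """Compute K_1, K_2, K_S, K_T and K_ST for a two-site labelling.

    ``weights="sample_size"`` weights K_i by n_i/Σn_j; ``"hbk"`` selects
    the (n_i − 1)-weighted variant found in parts of the literature.
    A matrix whose pooled mean distance K_T is zero makes the statistic
    undefined; the result is returned flagged ``degenerate`` (panmixia
    trivially non-rejectable) rather than raising.
    """
    in_a, site_a, site_b = _prepare(dm, labels)
    k1, k2, k_s, k_t, k_st = _kst_from_mask(dm.values, in_a, weights)
    degenerate = k_t == 0
    return KstResult(
        site_pair=(site_a, site_b),
        n_per_site=(int(in_a.sum()), int((~in_a).sum())),
        k_within=(k1, k2), k_s=k_s, k_t=k_t,
        k_st=None if degenerate else float(k_st),
        metric=dm.metric, degenerate=degenerate)


def kst_permutation_test(dm: DistanceMatrix, labels: list[str],
                         n_perm: int = 5000, seed: int = 0,
                         weights: str = "sample_size") -> KstResult:
    """One-sided permutation test of panmixia via K_ST.

    Site labels are permuted over individuals at fixed sample sizes; p
    counts permuted K_ST >= observed with the (1 + b)/(1 + n_perm) rule.
    When the number of distinct label arrangements C(n, n1) is at most
    20,000 the null is enumerated exhaustively and p is the exact
    fraction of arrangements at least as extreme (observed included).
    """
    result = kst_statistic(dm, labels, weights=weights)
    if result.degenerate:
        result.p_value = 1.0
        return result
    in_a, _, _ = _prepare(dm, labels)
    n = dm.n
    n1 = int(in_a.sum())
    obs = result.k_st
    values = dm.values

    n_arrangements = comb(n, n1)
    if n_arrangements <= EXHAUSTIVE_LIMIT:
        count = 0
        for subset in combinations(range(n), n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(subset)] = True
            k_st = _kst_from_mask(values, mask, weights)[4]
            if k_st >= obs - 1e-12:
                count += 1
        result.p_value = count / n_arrangements
        result.n_perm = n_arrangements
        result.exhaustive = True
        result.seed = seed
        return result

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1 for Monte-Carlo mode")
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=n1, replace=False)] = True
        k_st = _kst_from_mask(values, mask, weights)[4]
        if k_st >= obs - 1e-12:
            b += 1
    result.p_value = permutation_p(b, n_perm)
    result.n_perm = n_perm
    result.seed = seed
    return result


# ---------------------------------------------------------------------------
# All-pairs screen and panmictic grouping


def panmixia_screen(dm: DistanceMatrix, labels: list[str],
                    n_perm: int = 5000, seed: int = 0, alpha: float = 0.05,
                    weights: str = "sample_size",
                    ) -> tuple[pd.DataFrame, list[set[str]]]:
    """Pairwise K_ST tests over all usable site pairs + panmictic groups.

    Pairs whose p-value exceeds ``alpha`` (panmixia not rejected) become
    edges of a graph over sites; the returned groups are its connected
    components, mirroring how sites "connected by a line" are read as one
    panmictic unit. Raw per-pair p-values are used for the decisions (no
    multiplicity correction); a Bonferroni-adjusted decision column is
    reported alongside for comparison. Sites with fewer than 2 members
    are skipped and listed with a reason.
    """
    if len(labels) != dm.n:
        raise ValueError("one label per matrix row required")
    sites = list(dict.fromkeys(labels))
    counts = {s: labels.count(s) for s in sites}
    usable = [s for s in sites if counts[s] >= 2]
    skipped = [(s, "fewer than 2 members") for s in sites if counts[s] < 2]

    n_tests = comb(len(usable), 2)
    adj_alpha = alpha / n_tests if n_tests else alpha
    rows = []
    edges: list[tuple[str, str]] = []
    for i, sa in enumerate(usable):
        for j, sb in enumerate(usable[i + 1:], start=i + 1):
            idx = [k for k, lab in enumerate(labels) if lab in (sa, sb)]
            sub = dm.submatrix(idx)
            sub_labels = [labels[k] for k in idx]
            res = kst_permutation_test(sub, sub_labels, n_perm=n_perm,
                                       seed=seed + 1000 * i + j,
                                       weights=weights)
            panmictic = res.p_value is not None and res.p_value > alpha
            rows.append({
                "site_a": sa, "site_b": sb,
                "k_st": res.k_st, "p_value": res.p_value,
                "panmictic": panmictic,
                "panmictic_bonferroni": (res.p_value is not None
                                         and res.p_value > adj_alpha),
                "exhaustive": res.exhaustive, "n_perm": res.n_perm,
                "metric": dm.metric,
            })
            if panmictic:
                edges.append((sa, sb))
    for s, reason in skipped:
        rows.append({"site_a": s, "site_b": None, "k_st": None,
                     "p_value": None, "panmictic": None,
                     "panmictic_bonferroni": None, "exhaustive": None,
                     "n_perm": 0, "metric": dm.metric, "skipped": reason})

    # connected components over the panmixia graph (union-find)
    parent = {s: s for s in usable}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    groups: dict[str, set[str]] = {}
    for s in usable:
        groups.setdefault(find(s), set()).add(s)
    return pd.DataFrame(rows), sorted(groups.values(), key=lambda g: sorted(g))


def write_panmixia_graph(table: pd.DataFrame, path, fmt: str = "dot") -> None:
    """Export the panmixia graph (edges = pairs whose test did not reject).

    ``fmt="dot"`` writes Graphviz DOT; ``"edges"`` writes a plain
    tab-separated edge list (site_a, site_b, K_ST, p).
    """
    pairs = table.dropna(subset=["site_b"]) if "site_b" in table else table
    edges = pairs[pairs["panmictic"].fillna(False).astype(bool)]
    with open(path, "w") as fh:
        if fmt == "dot":
            fh.write("graph panmixia {\n")
            sites = sorted(set(pairs["site_a"]) | set(pairs["site_b"].dropna()))
            for s in sites:
                fh.write(f'  "{s}";\n')
            for _, row in edges.iterrows():
                fh.write(f'  "{row.site_a}" -- "{row.site_b}" '
                         f'[label="p={row.p_value:.3g}"];\n')
            fh.write("}\n")
        elif fmt == "edges":
            fh.write("site_a\tsite_b\tk_st\tp_value\n")
            for _, row in edges.iterrows():
                fh.write(f"{row.site_a}\t{row.site_b}\t{row.k_st:.6g}\t"
                         f"{row.p_value:.6g}\n")
        else:
            raise ValueError("fmt must be 'dot' or 'edges'")
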