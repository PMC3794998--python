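"""Pairwise genetic distances between individuals.

Two families feed the downstream differentiation and panmixia tests:

* **Tamura–Nei (1993) + Γ** distances between aligned mtDNA haplotypes.
  The model allows unequal base frequencies and distinguishes the two
  transition types (A<->G among purines, C<->T among pyrimidines) from
  transversions; among-site rate variation follows a gamma distribution
  with shape ``alpha``, applied through the continuous-gamma correction
  ``a * (w**(-1/a) - 1)`` in place of ``-log(w)``.

* **Microsatellite genotype distances.** Two integer schemes over
  unordered diploid allele pairs: a 0–4 single-locus scheme summed over
  loci (the distance that drives the panmixia permutation test), and the
  number-of-different-alleles scheme ``2 - |multiset intersection|``
  summed over loci (the distance that drives the microsatellite AMOVA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datatypes import GenotypeDataset, SequenceAlignment, MISSING


class SaturationError(ValueError):
    """Observed divergence too high for the distance formula (log/power
    argument fell to or below zero)."""


class CoverageError(ValueError):
    """No comparable (mutually non-missing) positions or loci."""


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix tagged with its metric."""

    ids: list[str]
    values: np.ndarray
    metric: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n},{n})")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.values < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.all(np.diag(self.values) == 0):
            raise ValueError("diagonal must be exactly zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, indices) -> "DistanceMatrix":
        idx = np.asarray(list(indices))
        return DistanceMatrix(
            ids=[self.ids[i] for i in idx],
            values=self.values[np.ix_(idx, idx)].copy(),
            metric=self.metric,
            parameters=dict(self.parameters),
        )


# ---------------------------------------------------------------------------
# Tamura–Nei + gamma sequence distance


def _pair_counts(seq_a: str, seq_b: str) -> tuple[dict[str, int], int, int, int, int]:
    """Count comparable sites, base composition and change classes.

    Positions where either sequence shows N or a gap are excluded
    pairwise. Returns (pooled base counts, n_sites, transitions_AG,
    transitions_CT, transversions).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    counts = {b: 0 for b in "ACGT"}
    n_sites = ts_ag = ts_ct = tv = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue  # N, '-' and any ambiguity code: excluded pairwise
        n_sites += 1
        counts[x] += 1
        counts[y] += 1
        if x == y:
            continue
        pair = frozenset((x, y))
        if pair == frozenset("AG"):
            ts_ag += 1
        elif pair == frozenset("CT"):
            ts_ct += 1
        else:
            tv += 1
    return counts, n_sites, ts_ag, ts_ct, tv


def _gamma_log(w: float, alpha: float | None) -> float:
    """-log(w), or its continuous-gamma analogue a*(w^(-1/a) - 1)."""
    if alpha is None or math.isinf(alpha):
        return -math.log(w)
    return alpha * (w ** (-1.0 / alpha) - 1.0)


def tn93_gamma_distance(seq_a: str, seq_b: str, alpha: float | None,
                        pair_label: str = "") -> float:
    """Tamura–Nei (1993) distance with continuous-gamma rate variation.

    Parameters
    ----------
    seq_a, seq_b : str
        Equal-length aligned sequences over A/C/G/T/N/-; N and gaps are
        excluded pairwise. Ambiguity codes are not interpreted.
    alpha : float or None
        Gamma shape of among-site rate variation (>0). ``None`` or
        ``inf`` gives the uncorrected TN93 distance.
    pair_label : str
        Used only to identify the pair in error messages.

    Returns
    -------
    float
        Expected substitutions per site.

    Raises
    ------
    CoverageError
        If no position is comparable.
    SaturationError
        If observed divergence exceeds what the formula can invert.
    """
    if alpha is not None and not math.isinf(alpha) and alpha <= 0:
        raise ValueError("gamma shape alpha must be > 0")
    counts, n, ts_ag, ts_ct, tv = _pair_counts(seq_a, seq_b)
    if n == 0:
        raise CoverageError(
            f"no comparable sites for pair {pair_label or '(unnamed)'}")
    total = 2 * n
    gA, gC, gG, gT = (counts[b] / total for b in "ACGT")
    gR, gY = gA + gG, gC + gT
    p1, p2, q = ts_ag / n, ts_ct / n, tv / n

    if p1 == 0 and p2 == 0 and q == 0:
        return 0.0

    # degenerate compositions: fall back to the defined sub-terms only
    k1 = 2 * gA * gG / gR if gR > 0 else 0.0
    k2 = 2 * gT * gC / gY if gY > 0 else 0.0
    k3 = 2 * (gR * gY
              - (gA * gG * gY / gR if gR > 0 else 0.0)
              - (gT * gC * gR / gY if gY > 0 else 0.0))

    def checked(w: float) -> float:
        if w <= 0:
            raise SaturationError(
                f"saturated divergence for pair {pair_label or '(unnamed)'}"
                f" (P1={p1:.4f}, P2={p2:.4f}, Q={q:.4f})")
        return w

    d = 0.0
    if k1 > 0:
        w1 = checked(1.0 - p1 / k1 - q / (2 * gR))
        d += k1 * _gamma_log(w1, alpha)
    elif p1 > 0:
        raise SaturationError(
            f"A/G transitions observed but purine composition degenerate "
            f"for pair {pair_label or '(unnamed)'}")
    if k2 > 0:
        w2 = checked(1.0 - p2 / k2 - q / (2 * gY))
        d += k2 * _gamma_log(w2, alpha)
    elif p2 > 0:
        raise SaturationError(
            f"C/T transitions observed but pyrimidine composition degenerate "
            f"for pair {pair_label or '(unnamed)'}")
    if gR > 0 and gY > 0:
        w3 = checked(1.0 - q / (2 * gR * gY))
        d += k3 * _gamma_log(w3, alpha)
    elif q > 0:
        raise SaturationError(
            f"transversions observed but one base class absent for pair "
            f"{pair_label or '(unnamed)'}")
    return max(d, 0.0)


def pairwise_sequence_distances(aln: SequenceAlignment,
                                alpha: float | None,
                                rate_categories: int | None = 4,
                                cap_saturated: float | None = None,
                                ) -> DistanceMatrix:
    """TN93+Γ distance matrix over all sequence pairs of an alignment.

    Base frequencies are estimated per pair from the two sequences being
    compared. ``rate_categories`` is recorded as metadata only: the
    pairwise correction is the continuous-gamma closed form, the discrete
    approximation being a likelihood-phylogenetics device.

    ``cap_saturated`` substitutes the given value for saturated pairs
    instead of raising; by default saturation raises, since a silent cap
    would distort the downstream permutation statistics.
    """
    if aln.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    n = aln.n_sequences
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            label = f"{aln.ids[i]}/{aln.ids[j]}"
            try:
                d = tn93_gamma_distance(
                    aln.sequences[i], aln.sequences[j], alpha, pair_label=label)
            except SaturationError:
                if cap_saturated is None:
                    raise
                d = cap_saturated
            values[i, j] = values[j, i] = d
    return DistanceMatrix(
        ids=list(aln.ids), values=values, metric="tn93_gamma",
        parameters={"alpha": alpha, "rate_categories": rate_categories})


# ---------------------------------------------------------------------------
# Microsatellite genotype distances


def _single_locus_genotype_distance(a: np.ndarray, b: np.ndarray) -> int:
    """0–4 single-locus distance over unordered diploid genotypes.

    With arbitrary alleles i, j, k, l: 0 for (ii,ii) or (ij,ij); 1 for
    (ii,ij) or (ij,ik); 2 for (ij,kl); 3 for (ii,jk); 4 for (ii,jj).
    """
    sa, sb = frozenset(a.tolist()), frozenset(b.tolist())
    shared = len(sa & sb)
    hom_a, hom_b = len(sa) == 1, len(sb) == 1
    if sa == sb:
        return 0
    if hom_a and hom_b:
        return 4                       # (ii, jj)
    if hom_a or hom_b:
        return 1 if shared else 3      # (ii,ij) vs (ii,jk)
    return 1 if shared else 2          # (ij,ik) vs (ij,kl)


def _locus_allele_diff(a: np.ndarray, b: np.ndarray) -> int:
    """Number of different alleles at one locus: 2 - |multiset intersect|."""
    a1, a2 = int(a[0]), int(a[1])
    b1, b2 = int(b[0]), int(b[1])
    best = 0
    # multiset intersection of two 2-element multisets, by matching
    if a1 == b1:
        best = 1 + (a2 == b2)
    if a1 == b2:
        best = max(best, 1 + (a2 == b1))
    if a2 == b1:
        best = max(best, 1 + (a1 == b2))
    if a2 == b2:
        best = max(best, 1 + (a1 == b1))
    return 2 - best


def _sum_over_loci(g_a: np.ndarray, g_b: np.ndarray, per_locus) -> int:
    g_a = np.asarray(g_a)
    g_b = np.asarray(g_b)
    if g_a.shape != g_b.shape or g_a.ndim != 2 or g_a.shape[1] != 2:
        raise ValueError("genotypes must share shape (n_loci, 2)")
    usable = ~(((g_a == MISSING).all(axis=1)) | ((g_b == MISSING).all(axis=1)))
    if not usable.any():
        raise CoverageError("no mutually non-missing loci")
    return int(sum(per_locus(g_a[i], g_b[i]) for i in np.flatnonzero(usable)))


def genotype_distance(g_a: np.ndarray, g_b: np.ndarray) -> int:
    """Multi-locus genotype distance: the 0–4 scheme summed over loci.

    Loci where either genotype is missing are skipped; raises
    :class:`CoverageError` when no locus is comparable.
    """
    return _sum_over_loci(g_a, g_b, _single_locus_genotype_distance)


def allele_count_diff_distance(g_a: np.ndarray, g_b: np.ndarray) -> int:
    """Number of different alleles summed over comparable loci."""
    return _sum_over_loci(g_a, g_b, _locus_allele_diff)


_GENOTYPE_METRICS = {
    "genotype_smouse_peakall": genotype_distance,
    "allele_count_diff": allele_count_diff_distance,
}


def pairwise_genotype_distances(ds: GenotypeDataset,
                                metric: str = "genotype_smouse_peakall",
                                ) -> DistanceMatrix:
    """Pairwise distance matrix over all individuals of a genotype dataset."""
    try:
        fn = _GENOTYPE_METRICS[metric]
    except KeyError:
        raise ValueError(
            f"unknown genotype metric {metric!r}; "
            f"choose from {sorted(_GENOTYPE_METRICS)}") from None
    n = ds.n_individuals
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = fn(ds.calls[i], ds.calls[j])
    return DistanceMatrix(ids=list(ds.individuals), values=values,
                          metric=metric, parameters={"n_loci": ds.n_loci})
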