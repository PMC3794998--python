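"""Core containers shared by every analysis stage.

Genotypes are diploid multi-locus calls with integer allele codes; a
missing call always blanks the whole genotype at a locus, never a single
allele, so every downstream statistic can use pairwise/per-locus deletion
without half-called states. Sequences are equal-length aligned mtDNA
haplotypes carrying their trimming window. Telemetry tracks are
time-ordered Argos-quality positions anchored at the animal's capture
(breeding) site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Sequence

import numpy as np

MISSING = 0  # allele code reserved for "whole genotype missing"

VALID_BASES = frozenset("ACGTN-")


class FormatError(ValueError):
    """Malformed input file or record."""


@dataclass
class GenotypeDataset:
    """Diploid multi-locus genotypes with per-individual site/group labels.

    Parameters
    ----------
    individuals : list of str
        Unique individual ids, in input order.
    sites : list of str
        Sampling-site label per individual (breeding site).
    loci : list of str
        Ordered locus names, shared by all individuals.
    calls : ndarray of shape (n_individuals, n_loci, 2), dtype int
        Unordered allele pairs; positive integer allele codes, with
        ``(0, 0)`` marking a missing genotype at that locus.
    groups : list of str, optional
        Higher-level label (subspecies/region) per individual; defaults
        to the site label.
    """

    individuals: list[str]
    sites: list[str]
    loci: list[str]
    calls: np.ndarray
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, m = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, m, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {m}, 2)")
        if len(self.sites) != n:
            raise ValueError("one site label per individual required")
        if self.groups is None:
            self.groups = list(self.sites)
        elif len(self.groups) != n:
            raise ValueError("one group label per individual required")
        if (self.calls < 0).any():
            raise ValueError("allele codes must be positive (0 = missing)")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, j = np.argwhere(half)[0]
            raise ValueError(
                f"half-called genotype at individual {self.individuals[i]!r}, "
                f"locus {self.loci[j]!r}; missing must blank both alleles")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci); True where the genotype is missing."""
        return (self.calls == MISSING).all(axis=2)

    def site_names(self) -> list[str]:
        """Distinct site labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.sites:
            seen.setdefault(s)
        return list(seen)

    def subset(self, indices: Sequence[int]) -> "GenotypeDataset":
        idx = list(indices)
        return GenotypeDataset(
            individuals=[self.individuals[i] for i in idx],
            sites=[self.sites[i] for i in idx],
            loci=list(self.loci),
            calls=self.calls[idx].copy(),
            groups=[self.groups[i] for i in idx],
        )

    def by_site(self) -> dict[str, np.ndarray]:
        """Map site label -> integer indices of its members (input order)."""
        out: dict[str, list[int]] = {}
        for i, s in enumerate(self.sites):
            out.setdefault(s, []).append(i)
        return {k: np.asarray(v) for k, v in out.items()}


@dataclass
class SequenceAlignment:
    """Equal-length aligned haplotype sequences with site labels.

    ``window`` is the 1-based inclusive [start, end] slice retained after
    trimming, recorded on the original coordinate system.
    """

    ids: list[str]
    sites: list[str]
    sequences: list[str]
    window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")
        if len(self.sites) != len(self.ids):
            raise ValueError("one site label per sequence required")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise FormatError(f"unequal sequence lengths: {sorted(lengths)}")
        for sid, seq in zip(self.ids, self.sequences):
            bad = set(seq.upper()) - VALID_BASES
            if bad:
                raise FormatError(
                    f"sequence {sid!r} has unsupported symbols {sorted(bad)}")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def site_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sites:
            seen.setdefault(s)
        return list(seen)


@dataclass
class TelemetryRecord:
    """A single Argos-derived position (and optional hourly dry-time value)."""

    timestamp: datetime
    lat: float
    lon: float
    dry_fraction: float | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} out of range [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} out of range [-180, 180]")
        if self.dry_fraction is not None and not 0.0 <= self.dry_fraction <= 1.0:
            raise ValueError("dry_fraction must be in [0, 1]")


@dataclass
class TelemetryTrack:
    """Time-ordered positions for one animal, anchored at its capture site."""

    animal_id: str
    capture_site: tuple[float, float]  # (lat, lon)
    records: list[TelemetryRecord]
    sex: str | None = None
    age: float | None = None
    filter_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: r.timestamp)
        for a, b in zip(self.records, self.records[1:]):
            if a.timestamp == b.timestamp:
                raise ValueError(
                    f"duplicate timestamp {a.timestamp} in track "
                    f"{self.animal_id!r}")

    @property
    def n_records(self) -> int:
        return len(self.records)

    def timestamps(self) -> list[datetime]:
        return [r.timestamp for r in self.records]


@dataclass
class PermutationTestResult:
    """Observed statistic + permutation null summary, shared by all tests."""

    statistic: float
    p_value: float | None
    n_perm: int
    seed: int | None
    name: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def is_defined(self) -> bool:
        return self.p_value is not None and np.isfinite(self.statistic)


def permutation_p(n_as_extreme: int, n_perm: int) -> float:
    """(1 + b) / (1 + n_perm) permutation p-value.

    ``b`` counts null replicates at least as extreme as the observed
    statistic; the +1 terms count the observed arrangement itself, so the
    attainable minimum is 1/(1+n_perm) and p never reaches 0.
    """
    return (1 + n_as_extreme) / (1 + n_perm)
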