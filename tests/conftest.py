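from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from sealpop.datatypes import GenotypeDataset, TelemetryRecord, TelemetryTrack
from sealpop.distances import DistanceMatrix


def make_genotypes(rows, loci=None, sites=None):
    """Build a GenotypeDataset from a list of per-individual locus pairs.

    ``rows`` is a list of lists of (a, b) allele tuples, one inner list
    per individual; (0, 0) marks a missing genotype.
    """
    n = len(rows)
    m = len(rows[0])
    calls = np.array(rows, dtype=np.int64)
    return GenotypeDataset(
        individuals=[f"ind{i + 1}" for i in range(n)],
        sites=sites or ["siteA"] * n,
        loci=loci or [f"L{j + 1}" for j in range(m)],
        calls=calls,
    )


@pytest.fixture
def two_site_dataset():
    """4 individuals, 2 sites, 2 loci; no missing data."""
    return make_genotypes(
        [[(1, 1), (2, 3)],
         [(1, 2), (2, 2)],
         [(3, 3), (1, 1)],
         [(3, 4), (1, 2)]],
        sites=["A", "A", "B", "B"])


@pytest.fixture
def worked_kst_matrix():
    """Two sites of two: within-site distances 1, all between-site 3.

    Full pair enumeration gives K_1 = K_2 = 1, K_S = 1,
    K_T = (1 + 1 + 4*3) / 6 = 7/3 and K_ST = 1 - 3/7 = 4/7.
    """
    values = np.full((4, 4), 3.0)
    np.fill_diagonal(values, 0.0)
    values[0, 1] = values[1, 0] = 1.0
    values[2, 3] = values[3, 2] = 1.0
    dm = DistanceMatrix(ids=["a1", "a2", "b1", "b2"], values=values,
                        metric="toy")
    labels = ["A", "A", "B", "B"]
    return dm, labels


def make_track(positions, start=None, step_hours=6.0, animal_id="seal01",
               capture_site=None):
    """Track from a list of (lat, lon) at a fixed time step."""
    start = start or datetime(2007, 1, 1, tzinfo=timezone.utc)
    records = [
        TelemetryRecord(timestamp=start + timedelta(hours=i * step_hours),
                        lat=lat, lon=lon)
        for i, (lat, lon) in enumerate(positions)]
    return TelemetryTrack(animal_id=animal_id,
                          capture_site=capture_site or positions[0],
                          records=records)
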