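"""Readers and writers for the formats the pipeline touches.

* GenePop genotype files (diploid, 2- or 3-digit allele coding, one POP
  block per sampling site). Both the classic ``id , 0101 0202`` dialect
  and the whitespace-separated variant are accepted; files are always
  written back in 3-digit comma dialect, so one read→write pass
  normalizes a file and the round trip is byte-stable thereafter.
* Aligned FASTA with an optional 1-based inclusive trimming window and
  ``site=`` tokens in headers (or a separate id→site table).
* Telemetry and hourly-haulout CSV tables.

Result tables written elsewhere in the package share `write_table`,
which prepends a comment line carrying the package version and seed.
"""

from __future__ import annotations

import logging
import re
import warnings
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .datatypes import (FormatError, GenotypeDataset, SequenceAlignment,
                        TelemetryRecord, TelemetryTrack, MISSING)

logger = logging.getLogger("sealpop.io")

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


# ---------------------------------------------------------------------------
# GenePop


def _split_genepop_line(line: str) -> tuple[str, list[str]]:
    """Return (individual id, genotype fields) for one data line."""
    if "," in line:
        ident, _, rest = line.partition(",")
        return ident.strip(), rest.split()
    fields = line.split()
    return fields[0], fields[1:]


def _decode_genotype(field: str, width: int, path: str, lineno: int) -> tuple[int, int]:
    if len(field) != 2 * width or not field.isdigit():
        raise FormatError(
            f"{path}:{lineno}: malformed genotype field {field!r} "
            f"(expected {2 * width} digits)")
    a, b = int(field[:width]), int(field[width:])
    if (a == 0) != (b == 0):
        raise FormatError(
            f"{path}:{lineno}: half-called genotype {field!r}; "
            "missing data must blank both alleles")
    return a, b


def read_genepop(path: str | Path) -> GenotypeDataset:
    """Read a GenePop file into a :class:`GenotypeDataset`.

    One POP block per sampling site; the site is named from the last
    individual label of its block (the GenePop convention) or, if that
    label repeats an earlier site name or is blank, from the block index.
    ``00``/``000`` allele codes decode to missing; 2- and 3-digit coding
    are auto-detected but must not be mixed within a file.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: truncated GenePop file")

    # header: title line, then locus names (one per line, or comma-joined)
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        loci.extend(tok.strip() for tok in lines[i].split(",") if tok.strip())
        i += 1
    if not loci:
        raise FormatError(f"{path}: no locus names before first POP")
    if i == len(lines):
        raise FormatError(f"{path}: no POP block found")

    width: int | None = None
    blocks: list[list[tuple[str, list[tuple[int, int]]]]] = []
    for lineno0 in range(i, len(lines)):
        line = lines[lineno0]
        lineno = lineno0 + 1
        if not line.strip():
            continue
        if _POP_RE.match(line):
            blocks.append([])
            continue
        ident, fields = _split_genepop_line(line)
        if len(fields) != len(loci):
            raise FormatError(
                f"{path}:{lineno}: individual {ident!r} has {len(fields)} "
                f"genotype fields, expected {len(loci)} loci")
        w = len(fields[0]) // 2
        if w not in (2, 3):
            raise FormatError(
                f"{path}:{lineno}: allele coding must be 2 or 3 digits, "
                f"got field {fields[0]!r}")
        if width is None:
            width = w
        elif w != width:
            raise FormatError(
                f"{path}:{lineno}: mixed allele-code widths "
                f"({w}-digit after {width}-digit)")
        calls = [_decode_genotype(f, width, str(path), lineno) for f in fields]
        blocks[-1].append((ident, calls))

    individuals: list[str] = []
    sites: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    used_sites: set[str] = set()
    for b, block in enumerate(blocks):
        if not block:
            raise FormatError(f"{path}: empty POP block #{b + 1}")
        site = block[-1][0]
        if not site or site in used_sites:
            site = f"pop{b + 1}"
        used_sites.add(site)
        for ident, calls in block:
            individuals.append(ident)
            sites.append(site)
            rows.append(calls)

    calls = np.array(rows, dtype=np.int64)
    return GenotypeDataset(individuals=individuals, sites=sites,
                           loci=loci, calls=calls)


def write_genepop(ds: GenotypeDataset, path: str | Path,
                  title: str = "sealpop genotypes") -> None:
    """Write a dataset in normalized 3-digit comma dialect, one POP per site."""
    if (ds.calls > 999).any():
        raise ValueError("allele codes above 999 cannot use 3-digit coding")
    out = [title]
    out.extend(ds.loci)
    for site, idx in ds.by_site().items():
        out.append("POP")
        for k in idx:
            fields = " ".join(f"{a:03d}{b:03d}" for a, b in ds.calls[k])
            ident = ds.individuals[k]
            # the last label of a block names the site on re-read
            if k == idx[-1]:
                ident = site
            out.append(f"{ident} , {fields}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# FASTA alignments


def read_fasta_alignment(path: str | Path,
                         window: tuple[int, int] | None = None,
                         site_table: dict[str, str] | None = None,
                         ) -> SequenceAlignment:
    """Read an aligned FASTA file, optionally trimming to a window.

    ``window`` is 1-based inclusive ``(start, end)`` — e.g. ``(90, 564)``
    keeps positions 90..564, i.e. ``end - start + 1`` columns. Site
    labels come from a ``site=`` token in the description or from
    ``site_table`` (id → site); records with neither get site
    ``"unknown"``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        raise FormatError(
            f"{path}: records are not aligned (lengths {sorted(lengths)})")
    length = lengths.pop()
    if window is not None:
        start, end = window
        if not (1 <= start <= end <= length):
            raise ValueError(
                f"window [{start}, {end}] out of bounds for length {length}")

    ids, sites, seqs = [], [], []
    for rec in records:
        ids.append(rec.id)
        m = re.search(r"site=(\S+)", rec.description)
        if m:
            sites.append(m.group(1))
        elif site_table and rec.id in site_table:
            sites.append(site_table[rec.id])
        else:
            sites.append("unknown")
        seq = str(rec.seq)
        if window is not None:
            seq = seq[window[0] - 1:window[1]]
        seqs.append(seq)
    return SequenceAlignment(ids=ids, sites=sites, sequences=seqs,
                             window=window)


def write_fasta_alignment(aln: SequenceAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, site, seq in zip(aln.ids, aln.sites, aln.sequences):
            fh.write(f">{sid} site={site}\n{seq}\n")


# ---------------------------------------------------------------------------
# Telemetry / haulout CSV


def _parse_timestamp(value: str) -> datetime:
    ts = pd.Timestamp(value)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return ts.tz_convert("UTC").to_pydatetime()


def read_telemetry_csv(path: str | Path,
                       capture_sites: dict[str, tuple[float, float]] | None = None,
                       lenient: bool = False) -> list[TelemetryTrack]:
    """Read a telemetry table into one track per animal.

    Expected columns ``animal_id,timestamp,lat,lon`` with optional
    ``dry_fraction``, ``capture_lat``, ``capture_lon``; ISO-8601
    timestamps, normalized to UTC (naive values are taken as UTC).
    Rows are sorted by time within each animal; duplicate timestamps
    collapse to the first occurrence with a warning. A bad row raises
    unless ``lenient`` is set, in which case it is dropped and reported.

    ``capture_sites`` (animal_id → (lat, lon)) overrides or supplies the
    capture anchor; otherwise the first (earliest) position is used.
    """
    df = pd.read_csv(path, comment="#", dtype={"animal_id": str})
    required = {"animal_id", "timestamp", "lat", "lon"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}")

    rows: dict[str, list[TelemetryRecord]] = {}
    anchors: dict[str, tuple[float, float]] = {}
    errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            ts = _parse_timestamp(row["timestamp"])
            dry = row.get("dry_fraction")
            dry = None if dry is None or pd.isna(dry) else float(dry)
            rec = TelemetryRecord(timestamp=ts, lat=float(row["lat"]),
                                  lon=float(row["lon"]), dry_fraction=dry)
        except (ValueError, TypeError) as exc:
            msg = f"{path}: row {idx + 2}: {exc}"
            if not lenient:
                raise FormatError(msg) from exc
            errors.append(msg)
            continue
        aid = str(row["animal_id"])
        rows.setdefault(aid, []).append(rec)
        if aid not in anchors and {"capture_lat", "capture_lon"} <= set(df.columns) \
                and not pd.isna(row["capture_lat"]):
            anchors[aid] = (float(row["capture_lat"]), float(row["capture_lon"]))
    for msg in errors:
        logger.warning("dropped %s", msg)

    tracks = []
    for aid, recs in rows.items():
        recs.sort(key=lambda r: r.timestamp)
        deduped, seen = [], set()
        for r in recs:
            if r.timestamp in seen:
                warnings.warn(
                    f"animal {aid}: duplicate timestamp {r.timestamp} "
                    "collapsed to first occurrence", stacklevel=2)
                continue
            seen.add(r.timestamp)
            deduped.append(r)
        if capture_sites and aid in capture_sites:
            anchor = capture_sites[aid]
        else:
            anchor = anchors.get(aid, (deduped[0].lat, deduped[0].lon))
        tracks.append(TelemetryTrack(animal_id=aid, capture_site=anchor,
                                     records=deduped))
    tracks.sort(key=lambda t: t.animal_id)
    return tracks


def write_telemetry_csv(tracks: list[TelemetryTrack], path: str | Path) -> None:
    rows = []
    for t in tracks:
        for r in t.records:
            rows.append({
                "animal_id": t.animal_id,
                "timestamp": r.timestamp.astimezone(timezone.utc).isoformat(),
                "lat": r.lat, "lon": r.lon,
                "dry_fraction": r.dry_fraction,
                "capture_lat": t.capture_site[0],
                "capture_lon": t.capture_site[1],
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_haulout_csv(path: str | Path) -> pd.DataFrame:
    """Hourly dry-time table: animal_id,timestamp,dry_fraction (UTC hours)."""
    df = pd.read_csv(path, comment="#", dtype={"animal_id": str})
    required = {"animal_id", "timestamp", "dry_fraction"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    bad = ~df["dry_fraction"].between(0, 1)
    if bad.any():
        raise FormatError(
            f"{path}: dry_fraction outside [0,1] at row {bad.idxmax() + 2}")
    return df.sort_values(["animal_id", "timestamp"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Distance matrices


def write_distance_matrix(dm, path: str | Path) -> None:
    """Square CSV with id header row/column and a metadata comment line."""
    import json as _json

    from .distances import DistanceMatrix  # local import avoids a cycle
    assert isinstance(dm, DistanceMatrix)
    with open(path, "w") as fh:
        fh.write(f"# metric={dm.metric} "
                 f"parameters={_json.dumps(dm.parameters, default=str)}\n")
        fh.write("id," + ",".join(dm.ids) + "\n")
        for i, row_id in enumerate(dm.ids):
            fh.write(row_id + "," +
                     ",".join(f"{float(v):.17g}" for v in dm.values[i])
                     + "\n")


def read_distance_matrix(path: str | Path):
    from .distances import DistanceMatrix
    lines = Path(path).read_text().splitlines()
    m = re.match(r"#\s*metric=(\S+)", lines[0])
    if not m:
        raise FormatError(f"{path}: missing metric comment line")
    metric = m.group(1)
    params = {}
    pm = re.search(r"parameters=(\{.*\})", lines[0])
    if pm:
        import json as _json
        params = _json.loads(pm.group(1))
    ids = lines[1].split(",")[1:]
    values = np.array([[float(v) for v in line.split(",")[1:]]
                       for line in lines[2:2 + len(ids)]])
    return DistanceMatrix(ids=ids, values=values, metric=metric,
                          parameters=params)


# ---------------------------------------------------------------------------
# Result tables


def write_table(df: pd.DataFrame, path: str | Path,
                seed: int | None = None) -> None:
    """Write a result CSV with a version/seed provenance comment line."""
    from . import __version__
    with open(path, "w") as fh:
        fh.write(f"# sealpop {__version__} seed={seed}\n")
        df.to_csv(fh, index=False)
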