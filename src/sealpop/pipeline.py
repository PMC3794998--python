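"""End-to-end orchestration: simulate/load -> QC -> diversity ->
differentiation -> panmixia -> telemetry, from a single config.

Every stochastic stage receives a deterministic sub-seed derived from the
run seed, logged in the manifest, so a rerun with the same config and
seed reproduces every output table byte for byte. The duplicate-genotype
screen runs before all genetic stages and drops flagged resamples,
keeping the first-seen genotype (optionally the one with fewest missing
loci).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import GenotypeDataset, SequenceAlignment, TelemetryTrack
from . import diversity, differentiation, panmixia, telemetry
from .distances import pairwise_genotype_distances, pairwise_sequence_distances
from .io_formats import (read_fasta_alignment, read_genepop,
                         read_haulout_csv, read_telemetry_csv, write_table)
from .synthetic import (IslandModelSpec, MovementRegimeSpec,
                        simulate_island_genotypes, simulate_mtdna_haplotypes,
                        simulate_track)

logger = logging.getLogger("sealpop.pipeline")

DEFAULT_PARAMS = {
    "amova_n_perm": 16000,
    "pairwise_n_perm": 1000,
    "kst_n_perm": 5000,
    "telemetry_n_perm": 10000,
    "hwe_n_perm": 1000,
    "alpha": 0.05,
    "bonferroni_sig_figs": 1,
    "std_n": 20,
    "rarefaction_reps": 1000,
    "vmax": 2.0,
    "duplicate_max_mismatch": 1,
    "keep_fewest_missing": False,
}


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    seed: int = 0
    output_dir: str = "sealpop_out"
    inputs: dict = field(default_factory=dict)     # genepop/fasta/telemetry paths
    simulate: dict = field(default_factory=dict)   # island/mtdna/tracks specs
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params)
        self.params = merged

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({
            "seed": self.seed, "output_dir": self.output_dir,
            "inputs": self.inputs, "simulate": self.simulate,
            "params": self.params}, sort_keys=True))


def _sub_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _resolve_genotypes(config: RunConfig) -> GenotypeDataset | None:
    if "genepop" in config.inputs:
        return read_genepop(config.inputs["genepop"])
    if "island" in config.simulate:
        spec_kwargs = dict(config.simulate["island"])
        spec_kwargs.setdefault("seed", _sub_seed(config.seed, "island"))
        return simulate_island_genotypes(IslandModelSpec(**spec_kwargs))
    return None


def _resolve_alignments(config: RunConfig) -> dict[str, tuple[SequenceAlignment, float]]:
    """region name -> (alignment, gamma shape alpha)."""
    out: dict[str, tuple[SequenceAlignment, float]] = {}
    for entry in config.inputs.get("fasta", []):
        window = tuple(entry["window"]) if "window" in entry else None
        aln = read_fasta_alignment(entry["path"], window=window)
        out[entry.get("region", Path(entry["path"]).stem)] = (
            aln, float(entry.get("alpha", 0.25103)))
    for region, entry in config.simulate.get("mtdna", {}).items():
        kwargs = dict(entry)
        alpha = float(kwargs.pop("alpha", 0.25103))
        kwargs.setdefault("seed", _sub_seed(config.seed, f"mtdna:{region}"))
        out[region] = (simulate_mtdna_haplotypes(**kwargs), alpha)
    return out


def _resolve_tracks(config: RunConfig) -> list[TelemetryTrack]:
    if "telemetry" in config.inputs:
        return read_telemetry_csv(config.inputs["telemetry"])
    tracks = []
    spec = config.simulate.get("tracks")
    if spec:
        n_animals = int(spec.get("n_animals", 5))
        base = {k: v for k, v in spec.items() if k != "n_animals"}
        for i in range(n_animals):
            kwargs = dict(base)
            kwargs["animal_id"] = f"seal{i + 1:02d}"
            kwargs["seed"] = _sub_seed(config.seed, f"track:{i}")
            tracks.append(simulate_track(MovementRegimeSpec(**kwargs)))
    return tracks


def deduplicate_genotypes(ds: GenotypeDataset, max_mismatch: int = 1,
                          keep_fewest_missing: bool = False
                          ) -> tuple[GenotypeDataset, list[tuple[str, str, int]]]:
    """Drop putative resampled individuals flagged by the one-mismatch screen.

    From each flagged cluster one genotype is retained: the first by
    input order, or with ``keep_fewest_missing`` the member with the
    fewest missing loci (ties by input order).
    """
    flagged = diversity.find_duplicate_genotypes(ds, max_mismatch=max_mismatch)
    if not flagged:
        return ds, []
    pos = {ind: i for i, ind in enumerate(ds.individuals)}
    parent = {ind: ind for ind in ds.individuals}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, _ in flagged:
        parent[find(a)] = find(b)
    clusters: dict[str, list[str]] = {}
    for ind in ds.individuals:
        clusters.setdefault(find(ind), []).append(ind)
    missing_counts = ds.missing_mask.sum(axis=1)
    keep: set[str] = set()
    for members in clusters.values():
        members.sort(key=lambda m: pos[m])
        if keep_fewest_missing:
            members.sort(key=lambda m: (missing_counts[pos[m]], pos[m]))
        keep.add(members[0])
    idx = [i for i, ind in enumerate(ds.individuals) if ind in keep]
    return ds.subset(idx), flagged


ALL_STAGES = ("diversity", "differentiation", "panmixia", "telemetry",
              "haulout")


def run_pipeline(config: RunConfig, stages: tuple[str, ...] | None = None
                 ) -> dict:
    """Execute all runnable stages and write result tables + a manifest.

    ``stages`` restricts execution to a subset of
    diversity/differentiation/panmixia/telemetry/haulout; the duplicate
    screen always precedes any genetic stage. Stages without inputs are
    skipped; a stage failure aborts its dependents but the manifest still
    records partial completion. Returns the manifest dict.
    """
    if stages is None:
        stages = ALL_STAGES
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    p = config.params
    manifest: dict = {
        "package": "sealpop", "version": __version__, "seed": seed,
        "stages": {}, "tables": [], "inputs": {
            k: _digest(Path(v)) for k, v in config.inputs.items()
            if isinstance(v, str) and Path(v).exists()},
    }

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            entry = {"seed": _sub_seed(seed, name)}
            try:
                result = fn(entry["seed"])
                entry["status"] = "ok"
                entry.update(result or {})
            except Exception as exc:  # noqa: BLE001 - manifest must record failures
                entry["status"] = "failed"
                entry["error"] = str(exc)
                logger.exception("stage %s failed", name)
            entry["seconds"] = round(time.perf_counter() - t0, 3)
            manifest["stages"][name] = entry
            return entry
        return deco

    def emit(df: pd.DataFrame, name: str, stage_seed: int) -> None:
        path = outdir / name
        write_table(df, path, seed=stage_seed)
        manifest["tables"].append(name)

    genetic_requested = bool(
        {"diversity", "differentiation", "panmixia"} & set(stages))
    genotypes = _resolve_genotypes(config) if genetic_requested else None
    alignments = _resolve_alignments(config) if genetic_requested else {}
    tracks = _resolve_tracks(config) if "telemetry" in stages else []

    if genotypes is not None:
        @stage("duplicate_screen")
        def _dup(stage_seed):
            nonlocal genotypes
            genotypes, flagged = deduplicate_genotypes(
                genotypes, max_mismatch=p["duplicate_max_mismatch"],
                keep_fewest_missing=p["keep_fewest_missing"])
            logger.info("duplicate screen: %d flagged pairs, %d retained",
                        len(flagged), genotypes.n_individuals)
            return {"flagged_pairs": [list(f) for f in flagged],
                    "n_retained": genotypes.n_individuals}

    if genotypes is not None and "diversity" in stages:
        @stage("diversity")
        def _div(stage_seed):
            summaries = diversity.heterozygosity(genotypes)
            rows = []
            for s in summaries:
                hwe_p = None
                if s.polymorphic and s.n >= 3:
                    hwe_p = diversity.hwe_test(
                        genotypes, s.site, s.locus,
                        n_perm=p["hwe_n_perm"], seed=stage_seed).p_value
                rows.append({"site": s.site, "locus": s.locus, "n": s.n,
                             "h_obs": s.h_obs, "h_exp": s.h_exp,
                             "polymorphic": s.polymorphic, "hwe_p": hwe_p})
            emit(pd.DataFrame(rows), "heterozygosity.csv", stage_seed)

            sizes = sorted({min(p["std_n"], genotypes.n_individuals), 5})
            curves = diversity.rarefied_allelic_richness(
                genotypes, sizes, n_reps=p["rarefaction_reps"],
                seed=stage_seed)
            crows = [{"site": c.unit, "n_std": n, "mean_richness": m,
                      "sd_richness": sd, "n_reps": c.n_reps}
                     for c in curves.values()
                     for n, m, sd in zip(c.sizes, c.mean_richness,
                                         c.sd_richness)]
            emit(pd.DataFrame(crows), "rarefaction.csv", stage_seed)
            n_sites = len(genotypes.site_names())
            return {"adjusted_alpha_hwe": diversity.bonferroni_alpha(
                p["alpha"], genotypes.n_loci * n_sites,
                p["bonferroni_sig_figs"])}

    if genotypes is not None and "differentiation" in stages:
        @stage("differentiation")
        def _diff(stage_seed):
            table = differentiation.pairwise_fst_table(
                genotypes, n_perm=p["pairwise_n_perm"], seed=stage_seed)
            emit(table, "fst_pairwise.csv", stage_seed)
            amova_rows = []
            dm = pairwise_genotype_distances(genotypes,
                                             metric="allele_count_diff")
            res = differentiation.amova(dm, genotypes.sites,
                                        n_perm=p["amova_n_perm"],
                                        seed=stage_seed,
                                        marker="microsatellites")
            amova_rows.append(vars(res))
            for region, (aln, alpha) in alignments.items():
                dm_seq = pairwise_sequence_distances(aln, alpha)
                res = differentiation.amova(dm_seq, aln.sites,
                                            n_perm=p["amova_n_perm"],
                                            seed=stage_seed, marker=region)
                amova_rows.append(vars(res))
            df = pd.DataFrame(amova_rows)
            df["flags"] = df["flags"].map("; ".join)
            emit(df, "amova.csv", stage_seed)
            return {"n_pairs": len(table)}

    if genotypes is not None and "panmixia" in stages:
        @stage("panmixia")
        def _pan(stage_seed):
            frames = []
            dm = pairwise_genotype_distances(genotypes)
            table, groups = panmixia.panmixia_screen(
                dm, genotypes.sites, n_perm=p["kst_n_perm"],
                seed=stage_seed, alpha=p["alpha"])
            table["marker"] = "microsatellites"
            frames.append(table)
            all_groups = {"microsatellites": [sorted(g) for g in groups]}
            for region, (aln, alpha) in alignments.items():
                dm_seq = pairwise_sequence_distances(aln, alpha)
                table, groups = panmixia.panmixia_screen(
                    dm_seq, aln.sites, n_perm=p["kst_n_perm"],
                    seed=stage_seed, alpha=p["alpha"])
                table["marker"] = region
                frames.append(table)
                all_groups[region] = [sorted(g) for g in groups]
            emit(pd.concat(frames, ignore_index=True), "panmixia.csv",
                 stage_seed)
            return {"panmictic_groups": all_groups}

    if tracks:
        @stage("telemetry")
        def _tel(stage_seed):
            filtered = [telemetry.speed_filter(t, v_max=p["vmax"])
                        for t in tracks]
            emit(telemetry.seasonal_table(
                filtered, n_perm=p["telemetry_n_perm"], seed=stage_seed),
                "telemetry_seasonal.csv", stage_seed)
            emit(telemetry.monthly_localization(filtered),
                 "telemetry_monthly.csv", stage_seed)
            removed = sum(len(f.filter_log) for f in filtered)
            return {"n_tracks": len(filtered), "n_removed_fixes": removed}

    if "haulout" in config.inputs and "haulout" in stages:
        @stage("haulout")
        def _haul(stage_seed):
            df = read_haulout_csv(config.inputs["haulout"])
            rows = []
            for aid, grp in df.groupby("animal_id"):
                series = pd.Series(grp["dry_fraction"].to_numpy(),
                                   index=pd.DatetimeIndex(grp["timestamp"]),
                                   name=aid)
                s = telemetry.haulout_summary(series)
                for h, m, r, e in zip(s.hours, s.mean_dry, s.range_dry,
                                      s.exceedance):
                    rows.append({"animal_id": aid, "hour": h, "mean_dry": m,
                                 "range_dry": r, "exceedance": e,
                                 "longest_wet_bout_hours":
                                     s.longest_wet_bout_hours,
                                 "min_dry_minutes": s.min_dry_minutes})
            emit(pd.DataFrame(rows), "haulout.csv", stage_seed)
            return {"n_animals": df["animal_id"].nunique()}

    failed = [k for k, v in manifest["stages"].items()
              if v["status"] == "failed"]
    manifest["status"] = "failed" if failed else "ok"
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
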