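"""End-to-end orchestration: reads -> database -> metrics -> structures ->
families -> ranked candidates -> correlation tables.

Every stage is a pure function of (inputs, config, seed); rerunning with
the same config and inputs reproduces the artifacts byte for byte.  The
run manifest records tool version, a config hash, and per-stage record
counts so a result can be traced back to its inputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from . import __version__
from . import distfam, poolmetrics, rankcorr, rnastructure, seqio
from .errors import ConfigurationError
from .seqio import ReadRecord, SequenceRecord


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    Defaults mirror the published selection's settings: 18-22 nt variable
    regions, true-selected rule (2 rounds / cluster 3), sequence families
    at edit distance 1, structure families at tree distance 3-6, scoring
    windows 1-3 / 1-8 / 3-8 / 6-8, folding at 30 degrees C without GU or
    lonely pairs.
    """

    reads: Sequence[str] = ()
    barcodes: Mapping[str, int] = field(default_factory=dict)
    flank5: str = seqio.FLANK5_DNA
    flank3: str = seqio.FLANK3_DNA
    max_mismatch: int = 0
    min_length: int = 18
    max_length: int = 22
    round0_label: int = 0
    min_rounds: int = 2
    min_cluster: int = 3
    sequence_threshold: int = 1
    structure_threshold_range: tuple[int, int] = (3, 6)
    orphan_min_reads: int = 100
    windows: Sequence[tuple[int, int]] = rankcorr.DEFAULT_WINDOWS
    fold_engine: str = "builtin"  # builtin | external | none
    temperature_c: float = 30.0
    allow_gu: bool = False
    allow_lonely_pairs: bool = False
    internalization: str | None = None
    out_dir: str | None = None
    seed: int = 0

    def fold_config(self) -> rnastructure.FoldConfig:
        return rnastructure.FoldConfig(
            temperature_c=self.temperature_c,
            allow_gu=self.allow_gu,
            allow_lonely_pairs=self.allow_lonely_pairs,
        )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "windows" in raw:
            raw["windows"] = [_parse_window(w) for w in raw["windows"]]
        if "structure_threshold_range" in raw:
            lo, hi = _parse_window(raw["structure_threshold_range"])
            raw["structure_threshold_range"] = (lo, hi)
        if "barcodes" in raw and isinstance(raw["barcodes"], str):
            raw["barcodes"] = _read_barcode_tsv(raw["barcodes"])
        return cls(**raw)


def _parse_window(w) -> tuple[int, int]:
    if isinstance(w, str):
        a, b = w.replace("-", ":").split(":")
        return (int(a), int(b))
    a, b = w
    return (int(a), int(b))


def _read_barcode_tsv(path: str | Path) -> dict[str, int]:
    barcodes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            barcode, rnd = line.split()[:2]
            barcodes[barcode.upper()] = int(rnd)
    return barcodes


@dataclass
class PipelineResult:
    """In-memory artifacts of one run."""

    records: list[SequenceRecord]
    pools: list[seqio.RoundPool]
    summaries: list[poolmetrics.RoundSummary]
    enrichment_fit: poolmetrics.EnrichmentCurveFit | None
    true_selected: list[SequenceRecord]
    sequence_families: list[distfam.Family]
    structure_families: list[distfam.Family]
    profiles: dict[int, rankcorr.EnrichmentProfile]
    candidates: rankcorr.CandidateSet
    correlation_table: object | None
    manifest: dict


def _validate(config: PipelineConfig) -> None:
    if config.fold_engine not in ("builtin", "external", "none"):
        raise ConfigurationError(f"unknown fold engine: {config.fold_engine}")
    if config.min_length > config.max_length:
        raise ConfigurationError("min_length exceeds max_length")
    for path in config.reads:
        if not Path(path).exists():
            raise ConfigurationError(f"reads file not found: {path}")
    if config.internalization and not Path(config.internalization).exists():
        raise ConfigurationError(
            f"internalization table not found: {config.internalization}")


def run_from_reads(
    reads: Iterable[ReadRecord],
    config: PipelineConfig,
) -> PipelineResult:
    """Run the analysis on an in-memory read stream (post file loading)."""
    manifest: dict = {
        "tool": "selexkit", "version": __version__,
        "config_hash": config.config_hash(), "stages": {},
    }

    def stage(name: str, **counts) -> None:
        manifest["stages"][name] = {"time": round(time.time() - t0, 3), **counts}

    # --- preprocess ---------------------------------------------------
    t0 = time.time()
    assigned, rejected_bc = seqio.demultiplex_reads(reads, config.barcodes)
    per_round_regions: dict[int, list[str]] = {}
    n_extract_rejected = 0
    for rnd, round_reads in assigned.items():
        regions = []
        for read in round_reads:
            res = seqio.extract_variable_region(
                read, config.flank5, config.flank3, config.max_mismatch,
                (config.min_length, config.max_length))
            if res.ok:
                regions.append(res.variable_region)
            else:
                n_extract_rejected += 1
        per_round_regions[rnd] = regions
    pools = seqio.merge_pools([
        seqio.collapse_to_unique(regions, rnd)
        for rnd, regions in sorted(per_round_regions.items())
    ])
    records = seqio.build_database(pools)
    stage("preprocess",
          assigned=sum(len(v) for v in assigned.values()),
          rejected_barcode=len(rejected_bc),
          rejected_extraction=n_extract_rejected,
          unique_sequences=len(records))

    # --- metrics ------------------------------------------------------
    t0 = time.time()
    summaries = [poolmetrics.pool_enrichment_stats(p) for p in pools]
    fit = None
    points = [(s.round_label, s.enrichment) for s in summaries]
    if len(points) >= 4:
        try:
            fit = poolmetrics.fit_enrichment_midpoint(points)
        except poolmetrics.FitError:
            fit = None
    stage("metrics", rounds=len(summaries))

    # --- true-selected filter -----------------------------------------
    t0 = time.time()
    kept, _ = poolmetrics.filter_true_selected(
        records, config.min_rounds, config.min_cluster,
        round0_label=config.round0_label)
    stage("filter", true_selected=len(kept))

    # --- folding ------------------------------------------------------
    t0 = time.time()
    if config.fold_engine != "none":
        fold_cfg = config.fold_config()
        for rec in kept:
            if rec.structure is not None:
                continue
            if config.fold_engine == "builtin":
                rec.structure = rnastructure.fold_sequence(rec.full_rna, fold_cfg)
            else:
                rec.structure = rnastructure.fold_external(rec.full_rna, fold_cfg)
    stage("fold", folded=len(kept) if config.fold_engine != "none" else 0)

    # --- families -----------------------------------------------------
    t0 = time.time()
    seq_fams, struct_fams = distfam.call_families(
        kept,
        sequence_threshold=config.sequence_threshold,
        structure_threshold_range=config.structure_threshold_range,
        with_structures=config.fold_engine != "none",
    )
    stage("families", sequence=len(seq_fams), structure=len(struct_fams))

    # --- ranking ------------------------------------------------------
    t0 = time.time()
    totals = rankcorr.round_totals(records)
    selection_rounds = sorted(set(totals) - {config.round0_label})
    profiles = rankcorr.normalize_read_counts(kept, selection_rounds, totals)
    rankcorr.score_windows(profiles, config.windows, selection_rounds)
    candidates = rankcorr.select_representatives(
        kept, seq_fams, struct_fams, profiles,
        windows=config.windows, orphan_min_reads=config.orphan_min_reads)
    stage("rank", candidates=len(candidates.all_ids))

    # --- correlation --------------------------------------------------
    table = None
    if config.internalization:
        t0 = time.time()
        measurements = _read_internalization(config.internalization)
        table = rankcorr.correlate_internalization(
            {i: profiles[i] for i in candidates.all_ids if i in profiles},
            measurements, windows=config.windows, rounds=selection_rounds)
        stage("correlate", cells=len(table))

    return PipelineResult(
        records=records, pools=pools, summaries=summaries, enrichment_fit=fit,
        true_selected=kept, sequence_families=seq_fams,
        structure_families=struct_fams, profiles=profiles,
        candidates=candidates, correlation_table=table, manifest=manifest,
    )


def _read_internalization(path: str | Path) -> dict[int, float]:
    import pandas as pd

    frame = pd.read_csv(path)
    if "id" not in frame.columns or "fold_internalization" not in frame.columns:
        raise ConfigurationError(
            "internalization table needs 'id' and 'fold_internalization' columns")
    return dict(zip(frame["id"].astype(int), frame["fold_internalization"].astype(float)))


def write_artifacts(result: PipelineResult, config: PipelineConfig,
                    out_dir: str | Path) -> dict[str, Path]:
    """Serialize a result into the artifact directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rounds = seqio.database_rounds(result.records)
    paths["db"] = out / "db.csv"
    seqio.write_database(result.records, paths["db"], rounds)

    paths["summary"] = out / "summary.csv"
    poolmetrics.summaries_to_frame(result.summaries).to_csv(paths["summary"], index=False)

    if result.true_selected:
        graph = distfam.build_distance_graph(
            result.true_selected, "edit", config.sequence_threshold)
        paths["edges"] = out / "edges.csv"
        distfam.edges_to_frame(graph).to_csv(paths["edges"], index=False)

    paths["db_labeled"] = out / "db.labeled.csv"
    seqio.write_database(result.true_selected, paths["db_labeled"], rounds)

    paths["candidates"] = out / "candidates.csv"
    rankcorr.profiles_to_frame(
        {i: result.profiles[i] for i in result.candidates.all_ids
         if i in result.profiles},
        config.windows).to_csv(paths["candidates"], index=False)

    if result.correlation_table is not None:
        paths["tables"] = out / "tables.csv"
        result.correlation_table.to_csv(paths["tables"], index=False)

    paths["manifest"] = out / "run_manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    return paths


def run_full_pipeline(config: PipelineConfig) -> PipelineResult:
    """Load read files, run every stage, and write artifacts if configured."""
    _validate(config)

    def read_stream():
        for path in config.reads:
            yield from seqio.read_sequence_file(path)

    result = run_from_reads(read_stream(), config)
    if config.out_dir:
        write_artifacts(result, config, config.out_dir)
    return result
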