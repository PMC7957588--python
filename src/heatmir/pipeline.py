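"""End-to-end pipeline orchestration.

Stages run in order - preprocess (clean/collapse/annotate), identify
(known / new member / novel), diffexpr (TPM, DEM calls, nine-type
classification), targets (rule-based site scan over significant DEMs),
integrate (negative-regulation network) - and write flat TSV/FASTA
outputs plus a JSON manifest into a run directory.  Rerunning with the
same config and inputs is byte-identical except for the manifest
timestamp.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import LIBRARIES, PipelineConfig
from .diffexpr import dem_table, tpm_matrix
from .fold import engine_id
from .genome import GenomeIndex
from .identify import (
    MiRNARecord,
    identify_mirnas,
    parse_catalog,
    records_table,
)
from .io import read_fasta, read_tsv, write_fasta, write_tsv
from .network import build_network, edges_table, family_summary, write_edge_list
from .preprocess import (
    LibraryStats,
    NCRNA_CLASSES,
    ReferenceSets,
    SequenceTag,
    annotate,
    clean_reads,
    collapse,
    length_stats,
    stats_table,
    tags_to_fasta,
)
from .targets import scan, sites_table

log = logging.getLogger("heatmir")

STAGES = ("preprocess", "identify", "diffexpr", "targets", "integrate")


@dataclass
class PipelineResult:
    config: PipelineConfig
    stats: list[LibraryStats] = field(default_factory=list)
    tags: list[SequenceTag] = field(default_factory=list)
    records: list[MiRNARecord] = field(default_factory=list)
    hairpin_report: pd.DataFrame = field(default_factory=pd.DataFrame)
    expression: pd.DataFrame = field(default_factory=pd.DataFrame)
    dem: pd.DataFrame = field(default_factory=pd.DataFrame)
    sites: pd.DataFrame = field(default_factory=pd.DataFrame)
    edges: list = field(default_factory=list)
    totals: dict[str, int] = field(default_factory=dict)


def _validate(config: PipelineConfig, until: str) -> None:
    required = [
        ("genome", config.genome),
        ("annotation", config.annotation),
        ("ncrna_dir", config.ncrna_dir),
        ("focal_catalog", config.focal_catalog),
        ("foreign_catalog", config.foreign_catalog),
    ]
    if STAGES.index(until) >= STAGES.index("targets"):
        required.append(("transcripts", config.transcripts))
    if until == "integrate":
        required.append(("deg_table", config.deg_table))
    missing = [name for name, path in required if not path]
    missing += [
        name
        for name, path in required
        if path and not Path(path).exists()
    ]
    for lib in LIBRARIES:
        if lib not in config.fastq:
            missing.append(f"fastq[{lib}]")
        elif not Path(config.fastq[lib]).exists():
            missing.append(f"fastq[{lib}]")
    if missing:
        raise FileNotFoundError(
            f"missing or nonexistent inputs: {sorted(set(missing))}"
        )
    if config.ncrna_dir:
        for cls in NCRNA_CLASSES:
            if not (Path(config.ncrna_dir) / f"{cls}.fa").exists():
                raise FileNotFoundError(
                    f"missing ncRNA reference class file {cls}.fa"
                )


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    until: str = "integrate",
) -> PipelineResult:
    """Execute the pipeline up to stage ``until`` and write all outputs.

    Inputs are validated before any computation; a stage failure leaves
    earlier outputs in place.  The run manifest records the package
    version, folding-engine identity, seed, config digest and per-stage
    record counts.
    """
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    _validate(config, until)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.folding_engine = engine_id()
    config.to_yaml(outdir / "config.yaml")
    result = PipelineResult(config=config)
    manifest: dict = {
        "heatmir_version": __version__,
        "folding_engine": config.folding_engine,
        "seed": config.seed,
        "config_digest": config.digest(),
        "stages": {},
    }

    # ---- preprocess ---------------------------------------------------
    log.info("stage preprocess")
    genome_index = GenomeIndex(read_fasta(config.genome))
    refs = ReferenceSets.from_paths(
        config.ncrna_dir, config.annotation, genome_index
    )
    reads_per_library: dict[str, list[str]] = {}
    for lib in LIBRARIES:
        clean, stats = clean_reads(config.fastq[lib], config, lib)
        reads_per_library[lib] = clean
        result.stats.append(stats)
        log.info(
            "library %s: %d raw -> %d clean (%s)",
            lib, stats.raw_reads, stats.clean_reads, stats.discarded,
        )
    result.totals = {
        s.library_id: s.clean_reads for s in result.stats
    }
    result.tags = collapse(reads_per_library)
    log.info("collapsed to %d unique tags", len(result.tags))
    # ncRNA classes are annotated before known-miRNA matching; genomic
    # classes (repeat / mRNA fragment) afterwards, inside identify
    annotate(result.tags, refs, classes=NCRNA_CLASSES)
    manifest["stages"]["preprocess"] = {
        "raw_reads": {s.library_id: s.raw_reads for s in result.stats},
        "clean_reads": dict(result.totals),
        "discarded": {
            s.library_id: s.discarded for s in result.stats
        },
        "unique_tags": len(result.tags),
    }
    if until == "preprocess":
        _finish_stats(result, outdir)
        _write_manifest(manifest, outdir)
        return result

    # ---- identify -----------------------------------------------------
    log.info("stage identify")
    focal = parse_catalog(config.focal_catalog)
    foreign = parse_catalog(config.foreign_catalog)
    result.records, result.hairpin_report = identify_mirnas(
        result.tags, focal, foreign, genome_index, config, refs=refs
    )
    _finish_stats(result, outdir)  # breakdown now includes genomic classes
    counts = records_table(result.records, LIBRARIES)
    write_tsv(outdir / "mirnas.tsv", counts)
    if not result.hairpin_report.empty:
        write_tsv(outdir / "hairpin_report.tsv", result.hairpin_report)
    write_fasta(
        outdir / "mature.fa",
        [(r.mirna_id, r.mature_sequence) for r in result.records],
    )
    write_fasta(
        outdir / "precursors.fa",
        [
            (r.mirna_id, r.precursor.precursor_sequence)
            for r in result.records
            if r.precursor is not None
        ],
    )
    by_class = counts["class"].value_counts().to_dict() if len(counts) else {}
    log.info("identified miRNAs by class: %s", by_class)
    manifest["stages"]["identify"] = {
        "mirna_records": len(result.records),
        "by_class": by_class,
        "hairpin_loci_evaluated": int(len(result.hairpin_report)),
    }
    if until == "identify":
        _write_manifest(manifest, outdir)
        return result

    # ---- diffexpr -----------------------------------------------------
    log.info("stage diffexpr")
    result.expression = tpm_matrix(counts, result.totals)
    write_tsv(outdir / "expression.tsv", result.expression)
    result.dem = dem_table(counts, config, result.totals)
    write_tsv(outdir / "dem.tsv", result.dem)
    n_sig = int(
        (
            result.dem["significant_tolerant"]
            | result.dem["significant_sensitive"]
        ).sum()
    ) if len(result.dem) else 0
    log.info("%d significant DEMs", n_sig)
    manifest["stages"]["diffexpr"] = {
        "mirnas_tested": len(result.dem),
        "significant_dems": n_sig,
        "pattern_types": result.dem["pattern_type"]
        .value_counts()
        .to_dict()
        if len(result.dem)
        else {},
    }
    if until == "diffexpr":
        _write_manifest(manifest, outdir)
        return result

    # ---- targets ------------------------------------------------------
    log.info("stage targets")
    transcripts = read_fasta(config.transcripts)
    dem_ids = set(
        result.dem.loc[
            result.dem["significant_tolerant"]
            | result.dem["significant_sensitive"],
            "mirna_id",
        ]
    ) if len(result.dem) else set()
    mirna_seqs = {
        r.mirna_id: r.mature_sequence
        for r in result.records
        if r.mirna_id in dem_ids
    }
    hits = scan(sorted(mirna_seqs.items()), transcripts, config)
    result.sites = sites_table(hits, mirna_seqs, transcripts)
    write_tsv(outdir / "target_sites.tsv", result.sites)
    n_genes = (
        result.sites["transcript_id"].nunique() if len(result.sites) else 0
    )
    log.info("%d accepted sites in %d genes", len(result.sites), n_genes)
    manifest["stages"]["targets"] = {
        "dems_scanned": len(mirna_seqs),
        "accepted_sites": int(len(result.sites)),
        "target_genes": int(n_genes),
    }
    if until == "targets":
        _write_manifest(manifest, outdir)
        return result

    # ---- integrate ----------------------------------------------------
    log.info("stage integrate")
    deg = read_tsv(config.deg_table)
    families = {r.mirna_id: r.family for r in result.records}
    result.edges = build_network(
        result.dem, result.sites, deg, config, families
    )
    write_tsv(outdir / "edges.tsv", edges_table(result.edges))
    write_tsv(outdir / "edge_families.tsv", family_summary(result.edges))
    write_edge_list(outdir / "network.edgelist", result.edges)
    log.info("%d negative-regulation edges", len(result.edges))
    manifest["stages"]["integrate"] = {
        "edges": len(result.edges),
        "dem_nodes": len({e.mirna_id for e in result.edges}),
        "gene_nodes": len({e.gene_id for e in result.edges}),
    }
    _write_manifest(manifest, outdir)
    return result


def _finish_stats(result: PipelineResult, outdir: Path) -> None:
    stats = [
        length_stats(result.tags, s.library_id, base=s)
        for s in result.stats
    ]
    write_tsv(outdir / "library_stats.tsv", stats_table(stats))
    write_fasta(outdir / "tags.fa", tags_to_fasta(result.tags))


def _write_manifest(manifest: dict, outdir: Path) -> None:
    manifest["written_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
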