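"""Read cleaning, tag collapsing, hierarchical annotation and length stats.

A raw small-RNA read is ``insert + 3' adapter + filler``.  Cleaning removes
the adapter, then discards low-quality, poly-A, and out-of-range inserts
(18-30 nt retained).  Surviving reads collapse to unique *tags* carrying
per-library counts - the atom of all downstream counting.  Tags are then
annotated against known non-miRNA RNA classes and genomic features with a
fixed priority, and only ``candidate_sRNA`` tags continue to miRNA
identification.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .genome import GenomeIndex, Hit
from .io import iter_fastq, read_fasta, read_gff

#: annotation priority; the first matching class wins
ANNOTATION_PRIORITY = (
    "rRNA", "scRNA", "snoRNA", "snRNA", "tRNA",
    "repeat", "mRNA_fragment", "candidate_sRNA",
)
NCRNA_CLASSES = ("rRNA", "scRNA", "snoRNA", "snRNA", "tRNA")
GENOMIC_CLASSES = ("repeat", "mRNA_fragment")

DISCARD_REASONS = ("low_quality", "poly_a", "too_short", "too_long")


@dataclass
class SequenceTag:
    """A unique cleaned sRNA sequence with per-library counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)
    annotation: str = "candidate_sRNA"
    genome_hits: list[Hit] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __post_init__(self) -> None:
        if not 18 <= len(self.sequence) <= 30:
            raise ValueError(
                f"tag length {len(self.sequence)} outside 18-30 nt"
            )


@dataclass
class LibraryStats:
    library_id: str
    raw_reads: int = 0
    clean_reads: int = 0
    discarded: dict[str, int] = field(default_factory=dict)
    mapped_fraction: float = 0.0
    length_histogram: dict[int, int] = field(default_factory=dict)
    ratio_24_21: float | None = None
    annotation_breakdown: dict[str, tuple[int, int]] = field(
        default_factory=dict
    )


# ----------------------------------------------------------------------
# cleaning


def _trim_adapter(seq: str, adapter: str, min_overlap: int) -> str:
    """Remove the 3' adapter: full occurrence first, else a suffix of the
    read matching a prefix of the adapter (>= min_overlap nt)."""
    pos = seq.find(adapter)
    if pos >= 0:
        return seq[:pos]
    max_ov = min(len(seq), len(adapter) - 1)
    for ov in range(max_ov, min_overlap - 1, -1):
        if seq.endswith(adapter[:ov]):
            return seq[: len(seq) - ov]
    return seq


def clean_reads(
    fastq_path: str | Path,
    config: PipelineConfig,
    library_id: str,
) -> tuple[list[str], LibraryStats]:
    """Clean one FASTQ library; returns surviving inserts and partial stats.

    Filters, in order: any base below ``min_quality`` within the first
    ``quality_cycles`` cycles; adapter trimming; poly-A discard
    (>= ``polya_fraction`` A after trimming); insert length outside
    [``min_tag_len``, ``max_tag_len``].
    """
    stats = LibraryStats(library_id=library_id)
    stats.discarded = {reason: 0 for reason in DISCARD_REASONS}
    clean: list[str] = []
    qmin = chr(config.min_quality + 33)
    reader = iter_fastq(fastq_path)
    idx = -1
    while True:
        idx += 1
        try:
            title, seq, qual = next(reader)
        except StopIteration:
            break
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ record {idx}: {exc}"
            ) from exc
        stats.raw_reads += 1
        if min(qual[: config.quality_cycles], default="~") < qmin:
            stats.discarded["low_quality"] += 1
            continue
        insert = _trim_adapter(
            seq.upper(), config.adapter, config.min_adapter_overlap
        )
        if (
            insert
            and insert.count("A") / len(insert) >= config.polya_fraction
        ):
            stats.discarded["poly_a"] += 1
            continue
        if len(insert) < config.min_tag_len:
            stats.discarded["too_short"] += 1
            continue
        if len(insert) > config.max_tag_len:
            stats.discarded["too_long"] += 1
            continue
        clean.append(insert)
    stats.clean_reads = len(clean)
    return clean, stats


# ----------------------------------------------------------------------
# collapsing


def collapse(reads_per_library: dict[str, list[str]]) -> list[SequenceTag]:
    """Collapse clean reads into unique tags keyed by exact sequence."""
    counts: dict[str, Counter] = defaultdict(Counter)
    order: dict[str, None] = {}
    for lib, reads in reads_per_library.items():
        for seq in reads:
            counts[seq][lib] += 1
            order.setdefault(seq, None)
    return [
        SequenceTag(sequence=seq, counts=dict(counts[seq])) for seq in order
    ]


# ----------------------------------------------------------------------
# annotation


class ReferenceSets:
    """Reference material for tag annotation.

    ncRNA classes are per-class FASTA files matched by exact (sense)
    substring; exon/intron and repeat features come from the annotation GFF
    and are matched through genomic hits.
    """

    def __init__(
        self,
        ncrna: dict[str, dict[str, str]],
        annotation: pd.DataFrame | None,
        genome_index: GenomeIndex | None,
    ):
        missing = [c for c in NCRNA_CLASSES if c not in ncrna]
        if missing:
            raise ValueError(f"missing ncRNA reference class(es): {missing}")
        self._ncrna_seqs = {
            cls: list(seqs.values()) for cls, seqs in ncrna.items()
        }
        self.genome_index = genome_index
        self._features: dict[str, list[tuple[str, int, int]]] = {
            "repeat": [],
            "mRNA_fragment": [],
        }
        if annotation is not None:
            for row in annotation.itertuples(index=False):
                start0, end0 = int(row.start) - 1, int(row.end)  # to half-open
                if row.type in ("repeat_region", "repeat"):
                    self._features["repeat"].append((row.seqid, start0, end0))
                elif row.type in ("exon", "intron"):
                    self._features["mRNA_fragment"].append(
                        (row.seqid, start0, end0)
                    )

    @classmethod
    def from_paths(
        cls,
        ncrna_dir: str | Path,
        annotation_path: str | Path | None,
        genome_index: GenomeIndex | None,
    ) -> "ReferenceSets":
        ncrna = {
            c: read_fasta(Path(ncrna_dir) / f"{c}.fa") for c in NCRNA_CLASSES
        }
        ann = read_gff(annotation_path) if annotation_path else None
        return cls(ncrna, ann, genome_index)

    def matches_ncrna(self, cls_name: str, tag: str) -> bool:
        return any(tag in ref for ref in self._ncrna_seqs[cls_name])

    def overlaps_feature(self, cls_name: str, hits: list[Hit], length: int
                         ) -> bool:
        for chrom, start, _ in hits:
            for fchrom, fstart, fend in self._features[cls_name]:
                if fchrom == chrom and start < fend and start + length > fstart:
                    return True
        return False


def annotate(
    tags: list[SequenceTag],
    refs: ReferenceSets,
    classes: tuple[str, ...] = ANNOTATION_PRIORITY,
) -> list[SequenceTag]:
    """Assign each tag the first matching class in priority order.

    ``classes`` restricts the stages applied (the pipeline runs the ncRNA
    stages before known-miRNA matching and the genomic stages after it, so
    catalogued miRNAs overlapping annotated exons are not discarded as
    degradation fragments).  Tags already annotated are left untouched.
    Genomic hits are computed here when a genome index is available.
    """
    for tag in tags:
        if refs.genome_index is not None and not tag.genome_hits:
            tag.genome_hits = refs.genome_index.find(tag.sequence)
        if tag.annotation != "candidate_sRNA":
            continue
        for cls_name in classes:
            if cls_name == "candidate_sRNA":
                continue
            if cls_name in NCRNA_CLASSES:
                if refs.matches_ncrna(cls_name, tag.sequence):
                    tag.annotation = cls_name
                    break
            elif cls_name in GENOMIC_CLASSES:
                if refs.overlaps_feature(
                    cls_name, tag.genome_hits, len(tag.sequence)
                ):
                    tag.annotation = cls_name
                    break
    return tags


# ----------------------------------------------------------------------
# statistics


def length_stats(
    tags: list[SequenceTag],
    library_id: str,
    base: LibraryStats | None = None,
) -> LibraryStats:
    """Count-weighted length histogram, 24/21-nt ratio, mapping rate and
    annotation breakdown for one library."""
    stats = base if base is not None else LibraryStats(library_id=library_id)
    hist = {length: 0 for length in range(18, 31)}
    mapped = 0
    total = 0
    breakdown: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for tag in tags:
        n = tag.counts.get(library_id, 0)
        if n == 0:
            continue
        total += n
        hist[len(tag.sequence)] += n
        if tag.genome_hits:
            mapped += n
        breakdown[tag.annotation][0] += n
        breakdown[tag.annotation][1] += 1
    stats.length_histogram = hist
    stats.ratio_24_21 = hist[24] / hist[21] if hist[21] else None
    stats.mapped_fraction = mapped / total if total else 0.0
    stats.annotation_breakdown = {
        cls: (v[0], v[1]) for cls, v in breakdown.items()
    }
    return stats


def stats_table(all_stats: list[LibraryStats]) -> pd.DataFrame:
    """LibraryStats rows -> TSV-ready table."""
    rows = []
    for s in all_stats:
        row: dict = {
            "library": s.library_id,
            "raw": s.raw_reads,
            "clean": s.clean_reads,
            "mapped_fraction": round(s.mapped_fraction, 4),
        }
        for length in range(18, 31):
            row[f"len{length}"] = s.length_histogram.get(length, 0)
        row["ratio_24_21"] = (
            round(s.ratio_24_21, 4) if s.ratio_24_21 is not None else "NA"
        )
        rows.append(row)
    return pd.DataFrame(rows)


def tags_to_fasta(tags: list[SequenceTag]) -> list[tuple[str, str]]:
    """Collapsed tags as FASTA records with count-bearing headers."""
    return [
        (f"tag{i}_x{tag.total}", tag.sequence)
        for i, tag in enumerate(tags, start=1)
    ]
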