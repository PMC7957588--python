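"""miRNA identification: known catalog matching, new members of known
families, and novel miRNA calling via precursor excision, folding and the
five structural criteria.

The five criteria applied to a candidate precursor hairpin:

1. miR-5p and miR-3p come from opposite stem arms, with more than 16
   matched nucleotide pairs in their duplex and an arm-length difference
   of at most 4 nt.
2. The most abundant read from each arm pairs in the duplex with a 2-nt
   3' overhang at both ends.
3. At most one asymmetric bulge in the duplex, no larger than 2 nt.
4. The most abundant arm read reaches the support threshold (>= 10 reads)
   in at least one library.
5. MFE below -0.2 kcal/mol/nt and MFEI above 0.85, where
   MFEI = (|MFE| / length * 100) / GC%.

Criterion verdicts are reported separately for the MFE and MFEI clauses of
criterion 5 so single-clause failures stay diagnosable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._seq import gc_fraction
from .config import PipelineConfig
from .fold import fold, pair_table
from .genome import GenomeIndex, Hit
from .preprocess import SequenceTag

CRITERIA = ("c1", "c2", "c3", "c4", "mfe", "mfei")


@dataclass
class ArmRead:
    """Most abundant read on one precursor arm."""

    sequence: str
    start: int  # 0-based offset within the precursor window
    counts: dict[str, int]

    @property
    def end(self) -> int:  # half-open
        return self.start + len(self.sequence)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class DuplexInfo:
    matched_pairs: int = 0
    size_difference: int = 0
    overhangs: tuple[int | None, int | None] = (None, None)
    asymmetric_bulges: list[int] = field(default_factory=list)


@dataclass
class HairpinCandidate:
    """An excised precursor window with structure and criterion verdicts."""

    precursor_sequence: str
    locus: tuple[str, int, int, str]  # chrom, start, end (0-based ho), strand
    structure: str
    mfe: float
    arm5p: ArmRead | None = None
    arm3p: ArmRead | None = None
    duplex: DuplexInfo = field(default_factory=DuplexInfo)
    criterion_verdicts: dict[str, bool] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.precursor_sequence)

    @property
    def mfe_per_nt(self) -> float:
        return self.mfe / self.length

    @property
    def gc(self) -> float:
        return gc_fraction(self.precursor_sequence)

    @property
    def mfei(self) -> float:
        """Minimal folding energy index, reported as a positive magnitude."""
        gc_pct = self.gc * 100
        return abs(self.mfe_per_nt * 100) / gc_pct if gc_pct else 0.0

    @property
    def passed(self) -> bool:
        return bool(self.criterion_verdicts) and all(
            self.criterion_verdicts.values()
        )


@dataclass
class MiRNARecord:
    mirna_id: str
    mature_sequence: str
    arm: str  # '5p' | '3p' | '' for catalog matches without a precursor
    mirna_class: str  # 'known' | 'new_member' | 'novel'
    family: str
    counts: dict[str, int]
    precursor: HairpinCandidate | None = None
    ambiguous: bool = False


# ----------------------------------------------------------------------
# catalogs


def parse_catalog(path: str | Path) -> list[tuple[str, str, str]]:
    """Mature-miRNA FASTA with ``id family species`` headers ->
    [(id, family, sequence)].  A missing family field is derived from the
    id by stripping the species prefix and arm/letter suffixes."""
    entries = []
    with open(path) as fh:
        name = None
        family = ""
        chunks: list[str] = []
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    entries.append((name, family, "".join(chunks)))
                fields = line[1:].split()
                name = fields[0]
                family = fields[1] if len(fields) > 1 else _family_of(name)
                chunks = []
            elif line:
                chunks.append(line.upper().replace("U", "T"))
        if name is not None:
            entries.append((name, family, "".join(chunks)))
    return entries


def _family_of(mirna_id: str) -> str:
    m = re.search(r"(miR[A-Za-z]*\d+)", mirna_id)
    return m.group(1) if m else mirna_id


# ----------------------------------------------------------------------
# known miRNAs


def terminal_shift_match(tag: str, mature: str, max_shift: int) -> bool:
    """True iff ``tag`` equals ``mature`` up to terminal shifts of at most
    ``max_shift`` nt at each end (isomiR tolerance); the overlapping region
    must match exactly and internal mismatches are never allowed."""
    for offset in range(-max_shift, max_shift + 1):
        # tag position i aligns mature position offset + i
        shift3 = offset + len(tag) - len(mature)
        if abs(shift3) > max_shift:
            continue
        lo = max(0, -offset)
        hi = min(len(tag), len(mature) - offset)
        if hi - lo <= 0:
            continue
        if tag[lo:hi] == mature[offset + lo : offset + hi]:
            return True
    return False


def match_known(
    tags: list[SequenceTag],
    catalog: list[tuple[str, str, str]],
    config: PipelineConfig,
) -> tuple[list[MiRNARecord], set[str]]:
    """Assign tags to focal-species catalog entries.

    A tag is assigned iff identical to a mature sequence or identical after
    shifting either terminus by at most ``isomir_shift`` nt; counts of all
    assigned tags are summed per entry.  A tag matching several entries is
    counted for each and the records are flagged ambiguous.
    """
    if not catalog:
        raise ValueError("focal catalog is empty")
    records: dict[str, MiRNARecord] = {}
    assigned: set[str] = set()
    tag_entry_count: dict[str, int] = {}
    for tag in tags:
        matches = [
            (mid, family, mature)
            for mid, family, mature in catalog
            if terminal_shift_match(tag.sequence, mature, config.isomir_shift)
        ]
        if not matches:
            continue
        assigned.add(tag.sequence)
        tag_entry_count[tag.sequence] = len(matches)
        for mid, family, mature in matches:
            rec = records.setdefault(
                mid,
                MiRNARecord(
                    mirna_id=mid,
                    mature_sequence=mature,
                    arm="",
                    mirna_class="known",
                    family=family,
                    counts={},
                ),
            )
            for lib, n in tag.counts.items():
                rec.counts[lib] = rec.counts.get(lib, 0) + n
            if len(matches) > 1:
                rec.ambiguous = True
    return list(records.values()), assigned


# ----------------------------------------------------------------------
# homology to foreign catalogs


def homology_mismatches(
    seq_a: str, seq_b: str, max_len_diff: int = 2
) -> int | None:
    """Minimum mismatch count over ungapped alignments with the shorter
    sequence fully contained in the longer; None if the length difference
    exceeds ``max_len_diff``."""
    short, long_ = sorted((seq_a, seq_b), key=len)
    diff = len(long_) - len(short)
    if diff > max_len_diff:
        return None
    best: int | None = None
    for off in range(diff + 1):
        mm = sum(
            1 for a, b in zip(short, long_[off : off + len(short)]) if a != b
        )
        if best is None or mm < best:
            best = mm
    return best


def best_foreign_match(
    sequence: str,
    catalog: list[tuple[str, str, str]],
    config: PipelineConfig,
) -> tuple[str, str] | None:
    """(entry id, family) of the closest foreign mature within the
    homology tolerance, or None."""
    best: tuple[int, str, str] | None = None
    for mid, family, mature in catalog:
        mm = homology_mismatches(sequence, mature)
        if mm is None or mm > config.homology_mismatches:
            continue
        if best is None or mm < best[0]:
            best = (mm, mid, family)
    return (best[1], best[2]) if best else None


# ----------------------------------------------------------------------
# precursor excision


def excise_precursor(
    genome_index: GenomeIndex,
    hit: Hit,
    tag_length: int,
    config: PipelineConfig,
) -> list[tuple[str, tuple[str, int, int, str]]]:
    """Candidate precursor windows around a mapped tag.

    Windows extend the tag by each configured (upstream, downstream) flank
    layout in tag orientation, clipped to the contig, and are kept when
    their length is within [precursor_min_len, precursor_max_len].
    Minus-strand windows are reverse-complemented.
    """
    chrom, start, strand = hit
    end = start + tag_length
    contig_len = genome_index.contig_length(chrom)
    windows: list[tuple[str, tuple[str, int, int, str]]] = []
    seen: set[tuple[int, int]] = set()
    for up, down in config.window_layouts:
        if strand == "+":
            w_start, w_end = start - up, end + down
        else:
            w_start, w_end = start - down, end + up
        w_start, w_end = max(0, w_start), min(contig_len, w_end)
        if (w_start, w_end) in seen:
            continue
        seen.add((w_start, w_end))
        if not (
            config.precursor_min_len
            <= w_end - w_start
            <= config.precursor_max_len
        ):
            continue
        seq = genome_index.fetch(chrom, w_start, w_end, strand)
        windows.append((seq, (chrom, w_start, w_end, strand)))
    return windows


# ----------------------------------------------------------------------
# hairpin evaluation


def _read_arm(pt: list[int], start: int, end: int) -> str | None:
    """Arm of a read from its paired positions: '5p' (partners downstream),
    '3p' (partners upstream), or None for loop-spanning/unpaired reads."""
    down = sum(1 for i in range(start, end) if pt[i] > i)
    up = sum(1 for i in range(start, end) if -1 < pt[i] < i)
    if down >= 3 and up < 3:
        return "5p"
    if up >= 3 and down < 3:
        return "3p"
    return None


def _duplex_geometry(
    pt: list[int], arm5: ArmRead, arm3: ArmRead
) -> DuplexInfo:
    info = DuplexInfo()
    info.size_difference = abs(len(arm5.sequence) - len(arm3.sequence))
    pairs = [
        (i, pt[i])
        for i in range(arm5.start, arm5.end)
        if arm3.start <= pt[i] < arm3.end
    ]
    info.matched_pairs = len(pairs)
    if not pairs:
        return info
    # overhang at the (5p 5' end / 3p 3' end) side of the duplex
    i0, j0 = pairs[0]
    ov_a = (arm3.end - 1 - j0) - (i0 - arm5.start)
    info.overhangs = (ov_a, None)
    # other side: the 3p-read 5'-most base paired into the 5p read
    for j in range(arm3.start, arm3.end):
        if arm5.start <= pt[j] < arm5.end:
            ov_b = (arm5.end - 1 - pt[j]) - (j - arm3.start)
            info.overhangs = (ov_a, ov_b)
            break
    # asymmetric bulges between consecutive duplex pairs
    for (ia, ja), (ib, jb) in zip(pairs, pairs[1:]):
        gap5 = ib - ia - 1
        gap3 = ja - jb - 1
        if gap5 != gap3:
            info.asymmetric_bulges.append(abs(gap5 - gap3))
    return info


def evaluate_hairpin(
    window_seq: str,
    locus: tuple[str, int, int, str],
    reads: list[tuple[str, int, dict[str, int]]],
    config: PipelineConfig,
) -> HairpinCandidate:
    """Fold a precursor window and score the five criteria.

    ``reads`` are (sequence, 0-based offset within window, per-library
    counts); the most abundant read per arm defines that arm's mature
    product.  Reads spanning the terminal loop disqualify their arm.
    """
    for seq, off, _ in reads:
        if off < 0 or off + len(seq) > len(window_seq):
            raise ValueError(
                f"read at offset {off} (len {len(seq)}) not within the "
                f"{len(window_seq)}-nt precursor window"
            )
        if window_seq[off : off + len(seq)] != seq:
            raise ValueError(
                f"read sequence at offset {off} disagrees with the window"
            )
    structure, mfe = fold(window_seq)
    cand = HairpinCandidate(
        precursor_sequence=window_seq,
        locus=locus,
        structure=structure,
        mfe=mfe,
    )
    pt = pair_table(structure)
    arms: dict[str, ArmRead] = {}
    for seq, off, counts in reads:
        arm = _read_arm(pt, off, off + len(seq))
        if arm is None:
            continue
        candidate = ArmRead(sequence=seq, start=off, counts=dict(counts))
        incumbent = arms.get(arm)
        if (
            incumbent is None
            or (candidate.total, candidate.sequence)
            > (incumbent.total, incumbent.sequence)
        ):
            arms[arm] = candidate
    cand.arm5p = arms.get("5p")
    cand.arm3p = arms.get("3p")

    v: dict[str, bool] = {}
    if cand.arm5p and cand.arm3p:
        info = _duplex_geometry(pt, cand.arm5p, cand.arm3p)
        cand.duplex = info
        v["c1"] = (
            info.matched_pairs > config.min_matched_pairs
            and info.size_difference <= config.max_size_difference
        )
        v["c2"] = all(
            ov == config.overhang_len for ov in info.overhangs
        ) and None not in info.overhangs
        v["c3"] = (
            len(info.asymmetric_bulges) <= config.max_asymmetric_bulges
            and all(
                b <= config.max_bulge_size for b in info.asymmetric_bulges
            )
        )
    else:
        v["c1"] = v["c2"] = v["c3"] = False
    arm_reads = [a for a in (cand.arm5p, cand.arm3p) if a is not None]
    v["c4"] = any(
        max(a.counts.values(), default=0) >= config.min_arm_reads
        for a in arm_reads
    )
    v["mfe"] = cand.mfe_per_nt < config.max_mfe_per_nt
    v["mfei"] = cand.mfei > config.min_mfei
    cand.criterion_verdicts = v
    return cand


# ----------------------------------------------------------------------
# locus clustering and novel miRNA calling


@dataclass
class Locus:
    """A cluster of genomically adjacent tag hits on one strand."""

    chrom: str
    strand: str
    start: int
    end: int
    hits: list[tuple[SequenceTag, int]] = field(default_factory=list)
    # each entry: (tag, hit start on forward strand)


def cluster_loci(
    tags: list[SequenceTag], config: PipelineConfig
) -> list[Locus]:
    """Group mapped tags into loci by merging hits separated by at most
    ``locus_cluster_gap`` nt on the same contig and strand."""
    placed: list[tuple[str, str, int, int, SequenceTag]] = []
    for tag in tags:
        for chrom, start, strand in tag.genome_hits:
            placed.append((chrom, strand, start, start + len(tag.sequence), tag))
    placed.sort(key=lambda x: (x[0], x[1], x[2], x[3], x[4].sequence))
    loci: list[Locus] = []
    for chrom, strand, start, end, tag in placed:
        cur = loci[-1] if loci else None
        if (
            cur is not None
            and cur.chrom == chrom
            and cur.strand == strand
            and start - cur.end <= config.locus_cluster_gap
        ):
            cur.end = max(cur.end, end)
            cur.hits.append((tag, start))
        else:
            loci.append(
                Locus(chrom=chrom, strand=strand, start=start, end=end,
                      hits=[(tag, start)])
            )
    return loci


def _window_reads(
    locus: Locus, w_locus: tuple[str, int, int, str]
) -> list[tuple[str, int, dict[str, int]]]:
    """Locus tags positioned inside a window, as window-relative reads."""
    _, w_start, w_end, strand = w_locus
    reads = []
    seen: set[tuple[str, int]] = set()
    for tag, start in locus.hits:
        end = start + len(tag.sequence)
        if start < w_start or end > w_end:
            continue
        if strand == "+":
            off = start - w_start
        else:
            off = w_end - end
        if (tag.sequence, off) in seen:
            continue
        seen.add((tag.sequence, off))
        reads.append((tag.sequence, off, tag.counts))
    return reads


def evaluate_locus(
    locus: Locus,
    genome_index: GenomeIndex,
    config: PipelineConfig,
) -> tuple[HairpinCandidate | None, list[HairpinCandidate]]:
    """Excise windows around the locus anchor tag, evaluate each, and pick
    the best candidate: the lowest-MFE window passing all criteria, else
    (for reporting) the window passing the most criteria."""
    anchor_tag, anchor_start = max(
        locus.hits, key=lambda h: (h[0].total, h[0].sequence)
    )
    hit = (locus.chrom, anchor_start, locus.strand)
    evaluated: list[HairpinCandidate] = []
    for window_seq, w_locus in excise_precursor(
        genome_index, hit, len(anchor_tag.sequence), config
    ):
        reads = _window_reads(locus, w_locus)
        if not reads:
            continue
        evaluated.append(
            evaluate_hairpin(window_seq, w_locus, reads, config)
        )
    passing = [c for c in evaluated if c.passed]
    if passing:
        best = min(passing, key=lambda c: (c.mfe, c.locus))
    elif evaluated:
        best = max(
            evaluated,
            key=lambda c: (sum(c.criterion_verdicts.values()), -c.mfe),
        )
    else:
        best = None
    return best, evaluated


def cluster_families(
    sequences: list[str], max_mismatches: int
) -> list[int]:
    """Single-linkage clustering of mature sequences at a mismatch radius;
    returns a family index per sequence."""
    n = len(sequences)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            mm = homology_mismatches(sequences[i], sequences[j])
            if mm is not None and mm <= max_mismatches:
                parent[find(i)] = find(j)
    roots: dict[int, int] = {}
    labels = []
    for i in range(n):
        r = find(i)
        labels.append(roots.setdefault(r, len(roots)))
    return labels


def _arm_records(
    prefix: str,
    family: str,
    mirna_class: str,
    cand: HairpinCandidate,
) -> list[MiRNARecord]:
    recs = []
    for arm_name, arm in (("5p", cand.arm5p), ("3p", cand.arm3p)):
        if arm is None:
            continue
        recs.append(
            MiRNARecord(
                mirna_id=f"{prefix}-{arm_name}",
                mature_sequence=arm.sequence,
                arm=arm_name,
                mirna_class=mirna_class,
                family=family,
                counts=dict(arm.counts),
                precursor=cand,
            )
        )
    return recs


def call_novel(
    passing: list[HairpinCandidate],
    config: PipelineConfig,
) -> list[MiRNARecord]:
    """Emit novel miRNA records (both arms when both carry reads) from
    per-locus best candidates, deduplicated by mature sequence, with
    families formed by single-linkage clustering of matures."""
    candidates = sorted(passing, key=lambda c: c.locus)
    records: list[MiRNARecord] = []
    seen_matures: set[str] = set()
    for idx, cand in enumerate(candidates, start=1):
        prefix = f"novel-miR{idx:03d}"
        for rec in _arm_records(prefix, "", "novel", cand):
            if rec.mature_sequence in seen_matures:
                continue
            seen_matures.add(rec.mature_sequence)
            records.append(rec)
    labels = cluster_families(
        [r.mature_sequence for r in records], config.family_mismatches
    )
    for rec, label in zip(records, labels):
        rec.family = f"novel-fam{label + 1:03d}"
    return records


# ----------------------------------------------------------------------
# orchestration


def identify_mirnas(
    tags: list[SequenceTag],
    focal_catalog: list[tuple[str, str, str]],
    foreign_catalog: list[tuple[str, str, str]],
    genome_index: GenomeIndex,
    config: PipelineConfig,
    refs=None,
) -> tuple[list[MiRNARecord], pd.DataFrame]:
    """Full classification of candidate tags into known miRNAs, new
    members of known families, and novel miRNAs.

    Known-catalog matching runs before exon/intron- and repeat-based
    removal (performed here through ``refs`` when given) so catalogued
    miRNAs overlapping annotated features are not discarded.  Returns the
    miRNA records and the per-locus hairpin report.
    """
    candidates = [t for t in tags if t.annotation == "candidate_sRNA"]
    known, assigned = match_known(candidates, focal_catalog, config)

    remaining = [t for t in candidates if t.sequence not in assigned]
    if refs is not None:
        from .preprocess import GENOMIC_CLASSES, annotate

        annotate(remaining, refs, classes=GENOMIC_CLASSES)
        remaining = [
            t for t in remaining if t.annotation == "candidate_sRNA"
        ]
    for t in remaining:
        if not t.genome_hits:
            t.genome_hits = genome_index.find(t.sequence)
    mapped = [t for t in remaining if t.genome_hits]

    loci = cluster_loci(mapped, config)
    new_member_records: list[MiRNARecord] = []
    novel_pass: list[HairpinCandidate] = []
    report_rows: list[dict] = []
    n_new = 0
    for locus in loci:
        best, _ = evaluate_locus(locus, genome_index, config)
        if best is None:
            continue
        foreign = None
        for arm in (best.arm5p, best.arm3p):
            if arm is not None and foreign is None:
                foreign = best_foreign_match(
                    arm.sequence, foreign_catalog, config
                )
        status = "rejected"
        if best.passed and foreign is not None:
            mid, family = foreign
            recs = [
                r
                for r in _arm_records(
                    f"N-{family}-{n_new + 1}", family, "new_member", best
                )
                if r.mature_sequence
                not in {x.mature_sequence for x in new_member_records}
            ]
            if recs:
                n_new += 1
            new_member_records.extend(recs)
            status = "new_member"
        elif best.passed:
            novel_pass.append(best)
            status = "novel"
        chrom, start, end, strand = best.locus
        row = {
            "locus": f"{chrom}:{start + 1}-{end}:{strand}",
            "length": best.length,
            "mfe": best.mfe,
            "mfe_per_nt": round(best.mfe_per_nt, 4),
            "mfei": round(best.mfei, 4),
            "gc": round(best.gc, 4),
            "status": status,
        }
        row.update({c: best.criterion_verdicts.get(c, False) for c in CRITERIA})
        row["verdict"] = best.passed
        report_rows.append(row)

    novel_records = call_novel(novel_pass, config)
    records = known + new_member_records + novel_records
    report = pd.DataFrame(report_rows)
    return records, report


def records_table(records: list[MiRNARecord], libraries) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {
            "mirna_id": rec.mirna_id,
            "class": rec.mirna_class,
            "family": rec.family,
            "arm": rec.arm,
            "mature": rec.mature_sequence,
            "ambiguous": rec.ambiguous,
        }
        for lib in libraries:
            row[f"count_{lib}"] = rec.counts.get(lib, 0)
        rows.append(row)
    return pd.DataFrame(rows)
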