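"""Synthetic study generator with machine-readable ground truth.

Builds every input the pipeline consumes - genome, annotation, ncRNA
references, miRNA catalogs, four FASTQ libraries (tolerant/sensitive
genotype x normal/high temperature), transcripts and a gene-level DEG
table - around planted features whose expected downstream behaviour is
recorded in a :class:`SyntheticTruth`:

* compliant precursor hairpins that must be recovered as novel miRNAs,
  and decoy hairpins violating exactly one acceptance criterion each;
* hairpins homologous to a foreign catalog entry (new family members);
* catalogued mature miRNAs planted as plain genomic inserts;
* per-miRNA library counts realising all nine expression-pattern types;
* target sites obeying or violating each of the six target rules; and
* anti-correlated, concordant and below-cutoff DEG partners.

Hairpins are designed by explicit reverse-complement arm construction
with controlled defects and then *verified with the same folding engine
and criterion evaluator the pipeline uses*, redrawing until the intended
verdict pattern is reproduced, so folding-engine disagreement cannot
silently break the ground truth.  All randomness flows from one integer
seed; identical seeds give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import random_seq, revcomp
from .config import CONTRASTS, LIBRARIES, PipelineConfig
from .diffexpr import PATTERN_GRID
from .fold import duplex_mfe, perfect_duplex_mfe
from .identify import evaluate_hairpin, homology_mismatches

DECOY_LABELS = ("c1", "c2", "c3", "c4", "mfe", "mfei")

#: designed per-library counts for one genotype, (NT, HT)
RESPONSE_TEMPLATES = {
    "induced": (60, 600),
    "repressed": (600, 60),
    "unchanged": (400, 400),
}
ON_OFF_TEMPLATES = {"induced": (0, 400), "repressed": (400, 0)}

#: inverse of the nine-type grid
TYPE_RESPONSES = {v: k for k, v in PATTERN_GRID.items()}


class PlacementError(RuntimeError):
    """A planted feature could not be constructed/placed within bounds."""


# ----------------------------------------------------------------------
# truth containers


@dataclass
class PlantedHairpin:
    name: str
    violated_criterion: str  # 'none' or one of DECOY_LABELS
    role: str  # 'novel' | 'new_member' | 'decoy'
    precursor: str
    chrom: str = ""
    start: int = 0  # 0-based, half-open on the forward strand
    end: int = 0
    arm5p: str = ""
    arm3p: str = ""
    arm5p_offset: int = 0  # offsets within the precursor
    arm3p_offset: int = 0


@dataclass
class PlantedMiRNA:
    mirna_id: str
    sequence: str
    mirna_class: str  # 'known' | 'new_member' | 'novel'
    family: str
    arm: str = ""
    hairpin: str = ""  # PlantedHairpin name for hairpin-borne miRNAs


@dataclass
class PlantedSite:
    mirna_id: str
    transcript_id: str
    start: int  # 1-based window start on the transcript
    intended: dict[str, bool] = field(default_factory=dict)


@dataclass
class SyntheticTruth:
    seed: int
    planted_hairpins: list[PlantedHairpin] = field(default_factory=list)
    planted_mirnas: list[PlantedMiRNA] = field(default_factory=list)
    #: mirna_id -> {"counts": {lib: n}, "pattern_type": str}
    expression_design: dict[str, dict] = field(default_factory=dict)
    planted_target_sites: list[PlantedSite] = field(default_factory=list)
    #: rows gene_id/contrast/log2fc/direction
    deg_design: list[dict] = field(default_factory=list)
    expected_edges: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def mirna_by_id(self, mirna_id: str) -> PlantedMiRNA:
        for m in self.planted_mirnas:
            if m.mirna_id == mirna_id:
                return m
        raise KeyError(mirna_id)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text())
        truth = cls(seed=raw["seed"])
        truth.planted_hairpins = [
            PlantedHairpin(**h) for h in raw["planted_hairpins"]
        ]
        truth.planted_mirnas = [
            PlantedMiRNA(**m) for m in raw["planted_mirnas"]
        ]
        truth.expression_design = raw["expression_design"]
        truth.planted_target_sites = [
            PlantedSite(**s) for s in raw["planted_target_sites"]
        ]
        truth.deg_design = raw["deg_design"]
        truth.expected_edges = raw["expected_edges"]
        truth.warnings = raw["warnings"]
        return truth


# ----------------------------------------------------------------------
# hairpin construction


def _counts(n: int = 100) -> dict[str, int]:
    # dummy abundances used only during construction-time verification
    return {lib: n for lib in LIBRARIES}


def _verify(
    core: str,
    a5: int,
    m5: str,
    a3: int,
    m3: str,
    config: PipelineConfig,
) -> dict[str, bool]:
    cand = evaluate_hairpin(
        core,
        ("design", 0, len(core), "+"),
        [(m5, a5, _counts()), (m3, a3, _counts())],
        config,
    )
    return cand.criterion_verdicts


def _expected_pattern(violation: str) -> dict[str, bool]:
    # c4 decoys are structurally compliant; their violation is expression
    if violation in ("none", "c4"):
        structural = None
    elif violation == "c3b":  # bulge-count variant of criterion 3
        structural = "c3"
    else:
        structural = violation
    return {c: (c != structural) for c in ("c1", "c2", "c3", "mfe", "mfei")}


def _non_pairing_base(rng: np.random.Generator, opposite: str) -> str:
    """A base that neither Watson-Crick- nor wobble-pairs ``opposite``."""
    forbidden = {
        "A": {"T"}, "C": {"G"}, "G": {"C", "T"}, "T": {"A", "G"},
    }[opposite]
    choices = sorted(set("ACGT") - forbidden - {""})
    return str(rng.choice(choices))


def design_hairpin(
    rng: np.random.Generator,
    violation: str,
    config: PipelineConfig,
    max_tries: int = 400,
) -> tuple[str, int, str, int, str]:
    """Design a precursor realising ``violation`` ('none', 'c1', 'c2',
    'c3', 'c4', 'mfe' or 'mfei') and verify it with the pipeline's own
    evaluator; returns (core, arm5_offset, arm5, arm3_offset, arm3).

    The base geometry is a fully complementary stem
    ``ext + arm5 + loop + revcomp(arm5) + revcomp(ext)`` whose arm reads
    carry the canonical 2-nt 3' overhangs; defects are then introduced:

    * c1 - three 1x1 symmetric internal loops drop the duplex to 16 pairs;
    * c2 - the 3p read window is shifted by 1 nt (3-nt overhangs);
    * c3 - a single 3-nt asymmetric bulge in the 3p arm;
    * c3b - two 1-nt asymmetric bulges (the count clause of criterion 3);
    * c4 - structurally compliant (the violation is low read support);
    * mfe - an A/U- and wobble-rich stem too weak for -0.2 kcal/mol/nt,
      in a low-GC context so the MFEI clause still passes;
    * mfei - a moderately weak stem at normal GC, below -0.2 kcal/mol/nt
      but with MFEI under 0.85.
    """
    if violation not in ("none", "c1", "c2", "c3", "c3b", "c4", "mfe",
                         "mfei"):
        raise ValueError(f"unknown violation {violation!r}")
    expected = _expected_pattern(violation)
    for _ in range(max_tries):
        spacer_a = spacer_b = ""
        if violation == "mfe":
            # weak A/U stem diluted by unpaired A-rich spacers: the
            # energy density stays above -0.2 kcal/mol/nt while the low
            # GC keeps MFEI passing
            ext = "".join(rng.choice(["A", "T"], size=2))
            loop = "".join(rng.choice(["A", "C"], size=14, p=[0.85, 0.15]))
            m5 = "".join(rng.choice(["A", "T"], size=21, p=[0.45, 0.55]))
            spacer_a = "".join(
                rng.choice(["A", "C"], size=20, p=[0.9, 0.1])
            )
            spacer_b = "".join(
                rng.choice(["A", "C"], size=20, p=[0.9, 0.1])
            )
        elif violation == "mfei":
            # wobble-weakened stem in a C-rich (high-GC, unstructured)
            # context: the energy clause passes but MFEI falls short
            ext = random_seq(rng, 2, gc=0.6)
            loop = "".join(rng.choice(["C", "A"], size=10, p=[0.7, 0.3]))
            m5 = random_seq(rng, 21, gc=0.6)
            spacer_a = "".join(
                rng.choice(["C", "A"], size=15, p=[0.85, 0.15])
            )
            spacer_b = "".join(
                rng.choice(["C", "A"], size=15, p=[0.85, 0.15])
            )
        else:
            ext = random_seq(rng, 12, gc=0.55)
            loop = "".join(rng.choice(["A", "C"], size=9))
            m5 = random_seq(rng, 21, gc=0.55)
        e = len(ext)
        arm3_full = revcomp(m5)
        if violation == "mfe":
            # a few G-U wobbles soften the A/U stem further
            arm3_list = list(arm3_full)
            convertible = [i for i, b in enumerate(arm3_list) if b == "A"]
            n_wob = min(len(convertible), 4)
            for i in rng.choice(convertible, size=n_wob, replace=False):
                arm3_list[i] = "G"
            arm3_full = "".join(arm3_list)
        elif violation == "mfei":
            # many wobbles: keeps pairing but drops |MFE| under the MFEI bar
            arm3_list = list(arm3_full)
            convertible = [
                i for i in range(3, 18) if arm3_list[i] in "AC"
            ]
            n_wob = min(len(convertible), 9)
            for i in rng.choice(convertible, size=n_wob, replace=False):
                arm3_list[i] = "G" if arm3_list[i] == "A" else "T"
            arm3_full = "".join(arm3_list)
        elif violation == "c1":
            # 1x1 symmetric internal loops at three interior duplex
            # positions: mutate the partner base of arm5 position k
            arm3_list = list(arm3_full)
            for k in (6, 10, 16):
                arm3_list[20 - k] = _non_pairing_base(rng, m5[k])
            arm3_full = "".join(arm3_list)

        if violation == "c3":
            # single asymmetric bulge of 3 nt (size clause)
            bulge = "".join(rng.choice(["A", "C"], size=3))
            arm3_seq = arm3_full[:10] + bulge + arm3_full[10:]
        elif violation == "c3b":
            # two 1-nt asymmetric bulges (count clause)
            b1 = "".join(rng.choice(["A", "C"], size=1))
            b2 = "".join(rng.choice(["A", "C"], size=1))
            arm3_seq = (
                arm3_full[:6] + b1 + arm3_full[6:14] + b2 + arm3_full[14:]
            )
        else:
            arm3_seq = arm3_full

        core = (
            spacer_a + ext + m5 + loop + arm3_seq + revcomp(ext) + spacer_b
        )
        a5 = len(spacer_a) + e
        # 3p read: 2 nt in from the arm start, through 2 nt of the stem
        # extension = the canonical 2-nt 3' overhang geometry
        arm_start = len(spacer_a) + e + 21 + len(loop)
        if violation == "c3":
            a3 = arm_start + 2
            m3 = core[a3 : a3 + 24]
        elif violation == "c3b":
            a3 = arm_start + 2
            m3 = core[a3 : a3 + 23]
        elif violation == "c2":
            a3 = arm_start + 3
            m3 = core[a3 : a3 + 21]
        else:
            a3 = arm_start + 2
            m3 = core[a3 : a3 + 21]
        try:
            verdicts = _verify(core, a5, m5, a3, m3, config)
        except ValueError:
            continue
        got = {c: verdicts[c] for c in expected}
        if got == expected:
            return core, a5, m5, a3, m3
    raise PlacementError(
        f"could not construct a hairpin with violation={violation!r} "
        f"after {max_tries} attempts"
    )


# ----------------------------------------------------------------------
# expression design


def design_counts(pattern_type: str, scale: float = 1.0,
                  on_off: bool = False) -> dict[str, int]:
    """Per-library designed counts realising a pattern type.

    ``on_off`` uses the zero-baseline variant for the tolerant genotype's
    response (a miRNA expressed in only one sample).
    """
    resp_tol, resp_sen = TYPE_RESPONSES[pattern_type]
    counts: dict[str, int] = {}
    for genotype, resp in (("tolerant", resp_tol), ("sensitive", resp_sen)):
        treated, control = CONTRASTS[genotype]
        if on_off and genotype == "tolerant" and resp in ON_OFF_TEMPLATES:
            nt, ht = ON_OFF_TEMPLATES[resp]
        else:
            nt, ht = RESPONSE_TEMPLATES[resp]
        counts[control] = int(round(nt * scale))
        counts[treated] = int(round(ht * scale))
    return counts


# ----------------------------------------------------------------------
# genome assembly


@dataclass
class GenomeBundle:
    """Generated genome-side material handed to the library generator."""

    contigs: dict[str, str]
    annotation: pd.DataFrame
    ncrna: dict[str, dict[str, str]]  # class -> {id: sequence}
    focal_catalog: list[tuple[str, str, str]]  # (id, family, mature)
    foreign_catalog: list[tuple[str, str, str]]
    exon_intervals: list[tuple[int, int]]
    repeat_intervals: list[tuple[int, int]]
    truth: SyntheticTruth


@dataclass
class _HairpinSpec:
    role: str  # 'novel' | 'new_member' | 'decoy'
    violation: str
    pattern_type: str
    on_off: bool = False


def _distinct(seq: str, existing: list[str], min_mm: int = 3) -> bool:
    for other in existing:
        mm = homology_mismatches(seq, other)
        if mm is not None and mm < min_mm:
            return False
    return True


def generate_genome(
    n_compliant_hairpins: int,
    decoy_violations: int | list[str],
    genome_length: int,
    gc_content: float,
    seed: int,
    config: PipelineConfig | None = None,
    n_known: int = 12,
    n_new_members: int = 3,
    chrom: str = "chr1",
) -> GenomeBundle:
    """Generate the genome, annotation, ncRNA references and catalogs.

    ``decoy_violations`` is either a list of criterion labels (one decoy
    each) or an integer cycling through all labels.  Compliant hairpins
    and new-member hairpins are engine-verified to pass every criterion;
    each decoy is verified to violate exactly its recorded criterion.
    Raises :class:`PlacementError` when loci cannot be placed.
    """
    config = config or PipelineConfig()
    if not 0 < gc_content < 1:
        raise ValueError("gc_content must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if isinstance(decoy_violations, int):
        decoy_violations = [
            DECOY_LABELS[i % len(DECOY_LABELS)]
            for i in range(decoy_violations)
        ]
    truth = SyntheticTruth(seed=seed)

    # --- plan hairpins and their expression patterns -------------------
    types_cycle = list(PATTERN_GRID.values())
    specs: list[_HairpinSpec] = []
    for i in range(n_compliant_hairpins):
        specs.append(
            _HairpinSpec(
                role="novel",
                violation="none",
                pattern_type=types_cycle[i % 9],
            )
        )
    nm_types = ["I", "IV", "II"]
    for i in range(n_new_members):
        specs.append(
            _HairpinSpec(
                role="new_member",
                violation="none",
                pattern_type=nm_types[i % len(nm_types)],
            )
        )
    for label in decoy_violations:
        if label not in DECOY_LABELS:
            raise ValueError(f"unknown decoy criterion {label!r}")
        specs.append(
            _HairpinSpec(role="decoy", violation=label, pattern_type="I")
        )

    # --- known catalog -------------------------------------------------
    known_types = types_cycle + ["I", "IV", "IX"]
    matures: list[str] = []
    focal: list[tuple[str, str, str]] = []
    for i in range(n_known):
        for _ in range(200):
            m = random_seq(rng, 21, gc=0.5)
            if _distinct(m, matures, min_mm=config.isomir_shift + 3):
                break
        else:
            raise PlacementError("could not draw distinct known matures")
        matures.append(m)
        mid = f"gma-miR{100 + i}"
        focal.append((mid, f"miR{100 + i}", m))
        if i < len(known_types):
            pattern = known_types[i]
            on_off = pattern == "II"  # the 'only expressed under HT' case
            truth.planted_mirnas.append(
                PlantedMiRNA(
                    mirna_id=mid,
                    sequence=m,
                    mirna_class="known",
                    family=f"miR{100 + i}",
                )
            )
            truth.expression_design[mid] = {
                "counts": design_counts(pattern, on_off=on_off),
                "pattern_type": pattern,
            }

    # --- ncRNA references ---------------------------------------------
    ncrna: dict[str, dict[str, str]] = {}
    for cls in ("rRNA", "scRNA", "snoRNA", "snRNA", "tRNA"):
        ncrna[cls] = {
            f"{cls}-{k + 1}": random_seq(rng, 320, gc=0.5) for k in range(2)
        }

    # --- progressive contig assembly with in-context verification ------
    # Each hairpin is embedded between background margins and immediately
    # re-evaluated through the pipeline's own locus machinery (including
    # the mirror locus arising from the reverse-complement arm), with
    # redraws until the intended accept/reject outcome holds in context.
    margin = 200
    parts: list[str] = [random_seq(rng, margin, gc=gc_content)]
    cursor = margin
    tail = parts[0]
    ann_rows: list[tuple] = []
    foreign: list[tuple[str, str, str]] = []
    built: list[tuple[_HairpinSpec, PlantedHairpin]] = []

    def _append(seq: str) -> int:
        nonlocal cursor, tail
        start_pos = cursor
        parts.append(seq)
        cursor += len(seq)
        tail = (tail + seq)[-160:]
        return start_pos

    for idx, spec in enumerate(specs):
        if spec.role == "decoy":
            scale5, scale3 = (
                (0.005, 0.0025) if spec.violation == "c4" else (1.0, 0.3)
            )
        else:
            scale5, scale3 = 1.0, 0.3
        counts5 = design_counts(
            spec.pattern_type, scale=scale5, on_off=spec.on_off
        )
        counts3 = design_counts(
            spec.pattern_type, scale=scale3, on_off=spec.on_off
        )
        right_bg = random_seq(rng, margin, gc=gc_content)
        placed = None
        for _ in range(60):
            core, a5, m5, a3, m3 = design_hairpin(rng, spec.violation, config)
            if not (_distinct(m5, matures) and _distinct(m3, matures)):
                continue
            context = tail + core + right_bg
            if _context_ok(
                context, counts5, counts3, m5, m3,
                compliant=(spec.role != "decoy"), config=config,
            ):
                placed = (core, a5, m5, a3, m3)
                break
        if placed is None:
            raise PlacementError(
                f"could not place hairpin {idx} "
                f"(role={spec.role}, violation={spec.violation})"
            )
        core, a5, m5, a3, m3 = placed
        matures.extend([m5, m3])
        start_pos = _append(core)
        _append(right_bg)
        if spec.role == "novel":
            name = f"hp-novel{idx + 1:03d}"
        elif spec.role == "new_member":
            name = f"hp-newmem{idx + 1:03d}"
        else:
            name = f"hp-decoy-{spec.violation}"
        hp = PlantedHairpin(
            name=name,
            violated_criterion=(
                "none" if spec.role != "decoy" else spec.violation
            ),
            role=spec.role,
            precursor=core,
            chrom=chrom,
            start=start_pos,
            end=start_pos + len(core),
            arm5p=m5,
            arm3p=m3,
            arm5p_offset=a5,
            arm3p_offset=a3,
        )
        built.append((spec, hp))
        truth.planted_hairpins.append(hp)
        ann_rows.append(
            (chrom, "heatmir_synthetic", "miRNA_primary_transcript",
             start_pos + 1, start_pos + len(core), ".", "+", ".",
             f"ID={name}")
        )
        if spec.role == "decoy":
            truth.expression_design[f"{name}-5p"] = {
                "counts": counts5, "pattern_type": spec.pattern_type,
            }
            truth.expression_design[f"{name}-3p"] = {
                "counts": counts3, "pattern_type": spec.pattern_type,
            }
            continue
        mirna_class = "novel" if spec.role == "novel" else "new_member"
        family = ""
        if spec.role == "new_member":
            fam_no = 200 + len(foreign)
            family = f"miR{fam_no}"
            # foreign homolog: the 5p mature with 2 internal substitutions
            foreign_seq = list(m5)
            for ppos in (5, 13):
                foreign_seq[ppos] = str(
                    rng.choice(sorted(set("ACGT") - {m5[ppos]}))
                )
            foreign.append(
                (f"ath-miR{fam_no}", family, "".join(foreign_seq))
            )
        for arm_name, mat, arm_counts in (
            ("5p", m5, counts5), ("3p", m3, counts3),
        ):
            mirna_id = f"{name}-{arm_name}"
            truth.planted_mirnas.append(
                PlantedMiRNA(
                    mirna_id=mirna_id,
                    sequence=mat,
                    mirna_class=mirna_class,
                    family=family,
                    arm=arm_name,
                    hairpin=name,
                )
            )
            truth.expression_design[mirna_id] = {
                "counts": arm_counts,
                "pattern_type": spec.pattern_type,
            }

    # decoy foreign entries that match nothing
    for j in range(3):
        for _ in range(200):
            m = random_seq(rng, 21, gc=0.5)
            if _distinct(m, matures):
                break
        foreign.append((f"osa-miR{900 + j}", f"miR{900 + j}", m))

    # guard: novel matures must stay outside the foreign-homology radius
    foreign_seqs = [s for _, _, s in foreign]
    for m in truth.planted_mirnas:
        if m.mirna_class == "novel":
            for fs in foreign_seqs:
                mm = homology_mismatches(m.sequence, fs)
                if mm is not None and mm <= config.homology_mismatches:
                    raise PlacementError(
                        f"novel mature {m.mirna_id} collides with the "
                        "foreign catalog"
                    )

    # --- known matures, exons and repeats ------------------------------
    for mid, _, m in focal:
        start_pos = _append(m)
        _append(random_seq(rng, margin, gc=gc_content))
        ann_rows.append(
            (chrom, "heatmir_synthetic", "mature_miRNA_insert",
             start_pos + 1, start_pos + len(m), ".", "+", ".", f"ID={mid}")
        )
    exon_intervals: list[tuple[int, int]] = []
    repeat_intervals: list[tuple[int, int]] = []
    for length in (400, 400, 350):
        start_pos = _append(random_seq(rng, length, gc=gc_content))
        _append(random_seq(rng, margin, gc=gc_content))
        exon_intervals.append((start_pos, start_pos + length))
        ann_rows.append(
            (chrom, "heatmir_synthetic", "exon", start_pos + 1,
             start_pos + length, ".", "+", ".",
             f"ID=exon{len(exon_intervals)}")
        )
    for length in (300, 300):
        start_pos = _append(random_seq(rng, length, gc=gc_content))
        _append(random_seq(rng, margin, gc=gc_content))
        repeat_intervals.append((start_pos, start_pos + length))
        ann_rows.append(
            (chrom, "heatmir_synthetic", "repeat_region", start_pos + 1,
             start_pos + length, ".", "+", ".",
             f"ID=repeat{len(repeat_intervals)}")
        )
    if cursor > genome_length:
        raise PlacementError(
            f"genome_length {genome_length} too small; need >= {cursor}"
        )
    parts.append(random_seq(rng, genome_length - cursor, gc=gc_content))
    contigs = {chrom: "".join(parts)}
    annotation = pd.DataFrame(
        ann_rows,
        columns=[
            "seqid", "source", "type", "start", "end",
            "score", "strand", "phase", "attributes",
        ],
    )

    # final verification: each planted mature occurs exactly once on '+'
    text = contigs[chrom]
    for m in truth.planted_mirnas:
        if text.count(m.sequence) != 1:
            raise PlacementError(
                f"mature {m.mirna_id} does not occur exactly once"
            )

    return GenomeBundle(
        contigs=contigs,
        annotation=annotation,
        ncrna=ncrna,
        focal_catalog=focal,
        foreign_catalog=foreign,
        exon_intervals=exon_intervals,
        repeat_intervals=repeat_intervals,
        truth=truth,
    )


def _context_ok(
    context: str,
    counts5: dict[str, int],
    counts3: dict[str, int],
    m5: str,
    m3: str,
    compliant: bool,
    config: PipelineConfig,
) -> bool:
    """Run the pipeline's locus evaluation on a candidate hairpin embedded
    in its real flanking sequence.

    A compliant hairpin must yield at least one passing locus, and every
    passing locus (the reverse-complement mirror locus may legitimately
    pass too - an RNase-III duplex is strand-symmetric) must report
    exactly the designed arm sequences, so downstream mature-sequence
    deduplication collapses them.  A decoy must yield no passing locus.
    """
    from .genome import GenomeIndex
    from .identify import cluster_loci, evaluate_locus
    from .preprocess import SequenceTag

    index = GenomeIndex({"ctx": context})
    tags = []
    for seq, counts in ((m5, counts5), (m3, counts3)):
        tag = SequenceTag(sequence=seq, counts=dict(counts))
        tag.genome_hits = index.find(seq)
        if not tag.genome_hits:
            return False
        tags.append(tag)
    passing = []
    for locus in cluster_loci(tags, config):
        best, _ = evaluate_locus(locus, index, config)
        if best is not None and best.passed:
            passing.append(best)
    if not compliant:
        return not passing
    if not passing:
        return False
    designed = {m5, m3}
    for cand in passing:
        arms = {
            arm.sequence
            for arm in (cand.arm5p, cand.arm3p)
            if arm is not None
        }
        if arms != designed:
            return False
    return True


# ----------------------------------------------------------------------
# read libraries


#: split of the dirty (discarded-by-cleaning) read fraction
DIRTY_SPLIT = {
    "adapter_only": 0.20,
    "low_quality": 0.25,
    "poly_a": 0.20,
    "short": 0.25,
    "long": 0.10,
}
#: split of the clean non-miRNA background
BACKGROUND_SPLIT = {
    "ncrna": 0.40,
    "exon": 0.25,
    "repeat": 0.15,
    "random": 0.20,
}


def generate_libraries(
    bundle: GenomeBundle,
    depth_per_library: int,
    noise_rate: float,
    seed: int,
    config: PipelineConfig | None = None,
) -> dict[str, list[tuple[str, str, str]]]:
    """Four FASTQ libraries realising the expression design.

    Each raw read is ``insert + adapter``; miRNA inserts are sampled
    per-library with Poisson counts at the designed means, a
    ``noise_rate`` fraction of reads exercises every cleaning filter
    (adapter-only, low-quality, poly-A, <18 nt, >30 nt), and the
    remaining depth is clean background (ncRNA/exon/repeat fragments and
    unmappable random tags).  Returns {library: [(title, seq, qual)]}.
    """
    config = config or PipelineConfig()
    truth = bundle.truth
    designed_types = {
        d["pattern_type"] for d in truth.expression_design.values()
    }
    missing = set(PATTERN_GRID.values()) - designed_types
    if missing:
        raise ValueError(
            f"expression design does not cover pattern types {sorted(missing)}"
        )
    rng = np.random.default_rng(seed)
    adapter = config.adapter
    genome = next(iter(bundle.contigs.values()))
    ncrna_refs = [
        seq for cls in bundle.ncrna.values() for seq in cls.values()
    ]
    mirna_ids = sorted(truth.expression_design)
    seq_of = {m.mirna_id: m.sequence for m in truth.planted_mirnas}
    for hp in truth.planted_hairpins:
        if hp.role == "decoy":
            seq_of[f"{hp.name}-5p"] = hp.arm5p
            seq_of[f"{hp.name}-3p"] = hp.arm3p

    libraries: dict[str, list[tuple[str, str, str]]] = {}
    for lib in LIBRARIES:
        design = {
            mid: truth.expression_design[mid]["counts"].get(lib, 0)
            for mid in mirna_ids
        }
        designed_sum = sum(design.values())
        n_dirty = int(round(depth_per_library * noise_rate))
        if designed_sum + n_dirty > depth_per_library:
            truth.warnings.append(
                f"library {lib}: depth {depth_per_library} too low for the "
                f"designed counts ({designed_sum}) plus noise ({n_dirty}); "
                "fold changes may not reach significance"
            )
        inserts: list[str] = []
        quals: list[str | None] = []  # None = default high quality
        for mid in mirna_ids:
            n = int(rng.poisson(design[mid]))
            inserts.extend([seq_of[mid]] * n)
            quals.extend([None] * n)
        # dirty classes
        dirty_counts = rng.multinomial(
            n_dirty, list(DIRTY_SPLIT.values())
        )
        for kind, n in zip(DIRTY_SPLIT, dirty_counts):
            for _ in range(n):
                if kind == "adapter_only":
                    inserts.append("")
                    quals.append(None)
                elif kind == "low_quality":
                    ins = random_seq(rng, 21, gc=0.5)
                    q = ["I"] * (len(ins) + len(adapter))
                    q[int(rng.integers(0, min(25, len(q))))] = "#"
                    inserts.append(ins)
                    quals.append("".join(q))
                elif kind == "poly_a":
                    inserts.append("A" * int(rng.integers(20, 25)))
                    quals.append(None)
                elif kind == "short":
                    inserts.append(
                        random_seq(rng, int(rng.integers(10, 17)), gc=0.5)
                    )
                    quals.append(None)
                else:  # long
                    inserts.append(random_seq(rng, 35, gc=0.5))
                    quals.append(None)
        # clean background
        n_background = max(
            0, depth_per_library - len(inserts)
        )
        bg_counts = rng.multinomial(
            n_background, list(BACKGROUND_SPLIT.values())
        )
        for kind, n in zip(BACKGROUND_SPLIT, bg_counts):
            for _ in range(n):
                length = int(rng.integers(20, 25))
                if kind == "ncrna":
                    ref = ncrna_refs[int(rng.integers(0, len(ncrna_refs)))]
                    start = int(rng.integers(0, len(ref) - length))
                    inserts.append(ref[start : start + length])
                elif kind == "exon" and bundle.exon_intervals:
                    lo, hi = bundle.exon_intervals[
                        int(rng.integers(0, len(bundle.exon_intervals)))
                    ]
                    start = int(rng.integers(lo, hi - length))
                    inserts.append(genome[start : start + length])
                elif kind == "repeat" and bundle.repeat_intervals:
                    lo, hi = bundle.repeat_intervals[
                        int(rng.integers(0, len(bundle.repeat_intervals)))
                    ]
                    start = int(rng.integers(lo, hi - length))
                    inserts.append(genome[start : start + length])
                else:
                    inserts.append(random_seq(rng, length, gc=0.5))
                quals.append(None)
        order = rng.permutation(len(inserts))
        records = []
        for serial, j in enumerate(order, start=1):
            ins = inserts[j]
            seq = ins + adapter
            qual = quals[j] if quals[j] is not None else "I" * len(seq)
            records.append((f"{lib}_r{serial}", seq, qual))
        libraries[lib] = records
    return libraries


# ----------------------------------------------------------------------
# transcripts, target sites and DEGs


_SITE_RULE_POSITIONS = {
    # miRNA positions (1-based) turned into non-pairing bases per rule
    "none": [],
    "r1": [13, 15, 17, 19, 21],  # weighted total 5 > 4
    "r2": [14, 15, 16],          # run of 3 adjacent non-matches
    "r3": [5, 6],                # adjacent non-matches inside 2-12
    "r4": [10],                  # non-match at a central position
    "r5": [2, 4, 6],             # 3 > 2.5 within positions 1-12
    "r6": [13, 15, 17, 19],      # r1-r5 pass, duplex energy degraded
}
_SITE_RULE_INTENDED = {
    "none": {},
    "r1": {"r1": False},
    "r2": {"r2": False},
    "r3": {"r3": False},
    "r4": {"r4": False},
    "r5": {"r1": True, "r5": False},
    "r6": {"r6": False},
}


def _site_sequence(
    rng: np.random.Generator,
    mature: str,
    violation: str,
    config: PipelineConfig,
    max_tries: int = 60,
) -> tuple[str, dict[str, bool]]:
    """Target-site window realising a rule violation (or none).

    The window is the reverse complement of the mature with non-pairing
    substitutions at the rule's positions; the r6 case is re-drawn until
    the duplex-MFE ratio actually drops below the threshold while rules
    1-5 still pass.
    """
    length = len(mature)
    perfect = perfect_duplex_mfe(mature)
    for _ in range(max_tries):
        site = list(revcomp(mature))
        for k in _SITE_RULE_POSITIONS[violation]:
            site[length - k] = _non_pairing_base(rng, mature[k - 1])
        site_seq = "".join(site)
        ratio = (
            abs(duplex_mfe(mature, site_seq)) / abs(perfect)
            if perfect
            else 0.0
        )
        intended = {f"r{i}": True for i in range(1, 6)}
        intended.update(_SITE_RULE_INTENDED[violation])
        intended["r6"] = ratio >= config.min_mfe_ratio
        if violation == "r6" and intended["r6"]:
            continue  # substitutions not destabilising enough; redraw
        if violation == "none" and not intended["r6"]:
            raise PlacementError("perfect site fails the energy rule")
        return site_seq, intended
    raise PlacementError(
        f"could not realise target-site violation {violation!r}"
    )


def generate_transcripts_and_degs(
    bundle: GenomeBundle,
    n_transcripts: int,
    seed: int,
    config: PipelineConfig | None = None,
    transcript_length: int = 500,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Transcripts with planted target sites and the matching DEG table.

    Plants, for selected differentially expressed miRNAs: fully
    compliant sites wired to anti-correlated DEGs (expected network
    edges, including one gene shared by two miRNAs), a concordant DEG
    and a below-cutoff DEG (expected non-edges), and one site violating
    each of the six target rules.  Truth entries are appended to
    ``bundle.truth``.
    """
    config = config or PipelineConfig()
    truth = bundle.truth
    rng = np.random.default_rng(seed)
    genes = [f"gene{i + 1:03d}" for i in range(n_transcripts)]
    transcripts = {
        g: random_seq(rng, transcript_length, gc=0.45) for g in genes
    }

    def mirna_with_type(mirna_class: str, pattern: str) -> PlantedMiRNA:
        for m in truth.planted_mirnas:
            design = truth.expression_design.get(m.mirna_id)
            if (
                m.mirna_class == mirna_class
                and design
                and design["pattern_type"] == pattern
                and (m.arm in ("", "5p"))
            ):
                return m
        raise PlacementError(
            f"no planted {mirna_class} miRNA of type {pattern}"
        )

    mir_up = mirna_with_type("known", "I")      # induced in both genotypes
    mir_down = mirna_with_type("known", "IV")   # repressed in both
    mir_novel = mirna_with_type("novel", "I")

    def plant(
        mirna: PlantedMiRNA, gene: str, start: int, violation: str
    ) -> None:
        site_seq, intended = _site_sequence(
            rng, mirna.sequence, violation, config
        )
        if start - 1 + len(site_seq) > len(transcripts[gene]):
            raise PlacementError(
                f"transcript {gene} shorter than the site window"
            )
        t = transcripts[gene]
        transcripts[gene] = (
            t[: start - 1] + site_seq + t[start - 1 + len(site_seq) :]
        )
        truth.planted_target_sites.append(
            PlantedSite(
                mirna_id=mirna.mirna_id,
                transcript_id=gene,
                start=start,
                intended=intended,
            )
        )

    deg_rows: list[dict] = []

    def deg(gene: str, contrast: str, log2fc: float) -> None:
        deg_rows.append(
            {
                "gene_id": gene,
                "contrast": contrast,
                "log2fc": round(log2fc, 3),
                "direction": "up" if log2fc > 0 else "down",
            }
        )

    # anti-correlated partners -> expected edges
    plant(mir_up, genes[0], 101, "none")
    deg(genes[0], "tolerant", -2.0)
    deg(genes[0], "sensitive", -2.0)
    plant(mir_down, genes[1], 101, "none")
    deg(genes[1], "tolerant", 1.8)
    deg(genes[1], "sensitive", 1.8)
    # one gene targeted by two DEMs simultaneously (tolerant contrast)
    plant(mir_up, genes[2], 101, "none")
    plant(mir_novel, genes[2], 201, "none")
    deg(genes[2], "tolerant", -1.5)
    truth.expected_edges = [
        {"mirna_id": mir_up.mirna_id, "gene_id": genes[0],
         "contrast": "tolerant"},
        {"mirna_id": mir_up.mirna_id, "gene_id": genes[0],
         "contrast": "sensitive"},
        {"mirna_id": mir_down.mirna_id, "gene_id": genes[1],
         "contrast": "tolerant"},
        {"mirna_id": mir_down.mirna_id, "gene_id": genes[1],
         "contrast": "sensitive"},
        {"mirna_id": mir_up.mirna_id, "gene_id": genes[2],
         "contrast": "tolerant"},
        {"mirna_id": mir_novel.mirna_id, "gene_id": genes[2],
         "contrast": "tolerant"},
    ]
    # concordant pair: same directions, must never become an edge
    plant(mir_up, genes[3], 101, "none")
    deg(genes[3], "tolerant", 2.0)
    deg(genes[3], "sensitive", 2.0)
    # below the >1.5-fold DEG cutoff
    plant(mir_down, genes[4], 101, "none")
    deg(genes[4], "tolerant", 0.4)
    # one site violating each target rule, all wired anti-correlated
    for j, rule in enumerate(("r1", "r2", "r3", "r4", "r5", "r6")):
        gene = genes[5 + j]
        plant(mir_up, gene, 101, rule)
        deg(gene, "tolerant", -1.5)
        deg(gene, "sensitive", -1.5)
    # background DEGs without any target site
    for j in range(11, min(n_transcripts, 17)):
        deg(genes[j], "tolerant", float(rng.uniform(-2.5, 2.5)))

    deg_table = pd.DataFrame(deg_rows)
    return transcripts, deg_table


# ----------------------------------------------------------------------
# fixture bundles


FIXTURE_PRESETS: dict[str, dict] = {
    # small enough for unit tests, still covering all nine pattern types
    "tiny": dict(
        n_compliant=3, decoys=["c2"], genome_length=30_000, gc=0.45,
        n_known=9, n_new_members=1, depth=20_000, noise=0.2,
        n_transcripts=12,
    ),
    # the full study-shaped fixture: 20 hairpin loci (11 compliant novel,
    # 3 new members, 6 single-criterion decoys), 4 x 100k reads
    "demo": dict(
        n_compliant=11, decoys=list(DECOY_LABELS), genome_length=50_000,
        gc=0.45, n_known=12, n_new_members=3, depth=100_000, noise=0.25,
        n_transcripts=50,
    ),
}


def make_fixture(
    preset: str,
    seed: int,
    outdir: str | Path,
    config: PipelineConfig | None = None,
) -> tuple[PipelineConfig, SyntheticTruth]:
    """Write a complete input bundle for one preset and seed.

    Returns a :class:`PipelineConfig` whose input paths point at the
    written files, plus the ground truth (also stored as truth.json).
    Identical seeds produce byte-identical files.
    """
    from .io import write_fasta, write_fastq, write_gff, write_tsv

    if preset not in FIXTURE_PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; choose from {sorted(FIXTURE_PRESETS)}"
        )
    p = FIXTURE_PRESETS[preset]
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "ncrna").mkdir(exist_ok=True)

    bundle = generate_genome(
        p["n_compliant"], p["decoys"], p["genome_length"], p["gc"],
        seed=seed, config=config, n_known=p["n_known"],
        n_new_members=p["n_new_members"],
    )
    libraries = generate_libraries(
        bundle, p["depth"], p["noise"], seed=seed + 1, config=config
    )
    transcripts, deg_table = generate_transcripts_and_degs(
        bundle, p["n_transcripts"], seed=seed + 2, config=config
    )

    write_fasta(outdir / "genome.fa", bundle.contigs.items())
    write_gff(outdir / "annotation.gff3", bundle.annotation)
    for cls, seqs in bundle.ncrna.items():
        write_fasta(outdir / "ncrna" / f"{cls}.fa", seqs.items())
    write_fasta(
        outdir / "focal_catalog.fa",
        [(f"{mid} {fam} gma", seq) for mid, fam, seq in bundle.focal_catalog],
    )
    write_fasta(
        outdir / "foreign_catalog.fa",
        [
            (f"{mid} {fam} {mid.split('-')[0]}", seq)
            for mid, fam, seq in bundle.foreign_catalog
        ],
    )
    fastq_paths = {}
    for lib, records in libraries.items():
        path = outdir / f"reads_{lib}.fastq"
        write_fastq(path, records)
        fastq_paths[lib] = str(path)
    write_fasta(outdir / "transcripts.fa", transcripts.items())
    write_tsv(outdir / "deg.tsv", deg_table)
    bundle.truth.to_json(outdir / "truth.json")

    run_config = PipelineConfig.from_dict(config.to_dict())
    run_config.genome = str(outdir / "genome.fa")
    run_config.annotation = str(outdir / "annotation.gff3")
    run_config.ncrna_dir = str(outdir / "ncrna")
    run_config.focal_catalog = str(outdir / "focal_catalog.fa")
    run_config.foreign_catalog = str(outdir / "foreign_catalog.fa")
    run_config.transcripts = str(outdir / "transcripts.fa")
    run_config.deg_table = str(outdir / "deg.tsv")
    run_config.fastq = fastq_paths
    run_config.seed = seed
    return run_config, bundle.truth
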