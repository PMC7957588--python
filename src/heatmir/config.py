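"""Pipeline configuration.

Every tunable read by any stage lives here, with defaults anchored to the
thresholds of the study design this pipeline implements: tag length 18-30 nt,
DEM fold change >= 2 at p < 0.05, hairpin MFE < -0.2 kcal/mol/nt and
MFEI > 0.85, arm-read support >= 10, target rules (<= 4 mismatches with G-U
as 0.5, <= 2.5 in positions 1-12, duplex-MFE ratio >= 0.75) and the
>1.5-fold DEG cutoff for network integration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: library identifiers, fixed order: (genotype, condition)
LIBRARIES = ("NF1NT", "NF1HT", "YF1NT", "YF1HT")
LIBRARY_META = {
    "NF1NT": {"genotype": "tolerant", "condition": "NT"},
    "NF1HT": {"genotype": "tolerant", "condition": "HT"},
    "YF1NT": {"genotype": "sensitive", "condition": "NT"},
    "YF1HT": {"genotype": "sensitive", "condition": "HT"},
}
#: HT-vs-NT contrast per genotype: (treated, control)
CONTRASTS = {
    "tolerant": ("NF1HT", "NF1NT"),
    "sensitive": ("YF1HT", "YF1NT"),
}

#: Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class PipelineConfig:
    """All tunables of the pipeline; defaults are the study's thresholds."""

    # --- input paths (filled per run) ---
    genome: str = ""
    annotation: str = ""
    ncrna_dir: str = ""          # directory of per-class ncRNA FASTAs
    focal_catalog: str = ""      # mature miRNAs of the focal species
    foreign_catalog: str = ""    # mature miRNAs of other species
    transcripts: str = ""
    deg_table: str = ""
    fastq: dict[str, str] = field(default_factory=dict)  # library -> path

    # --- preprocessing ---
    adapter: str = DEFAULT_ADAPTER
    min_adapter_overlap: int = 8
    min_quality: int = 20          # Phred floor in the first quality_cycles
    quality_cycles: int = 25
    min_tag_len: int = 18
    max_tag_len: int = 30
    polya_fraction: float = 0.8    # >= this fraction of A => poly-A discard

    # --- miRNA identification ---
    isomir_shift: int = 2          # terminal-shift tolerance for known match
    homology_mismatches: int = 2   # foreign-catalog tolerance (new members)
    family_mismatches: int = 2     # single-linkage clustering radius
    precursor_min_len: int = 60
    precursor_max_len: int = 400
    # (upstream, downstream) flank layouts tried around a mapped tag
    window_layouts: tuple[tuple[int, int], ...] = (
        (15, 60), (60, 15), (40, 40), (15, 120), (120, 15),
    )
    locus_cluster_gap: int = 40    # max gap (nt) merging tag hits into loci
    min_matched_pairs: int = 16    # criterion 1: duplex pairs must exceed this
    max_size_difference: int = 4   # criterion 1: |len(5p) - len(3p)|
    overhang_len: int = 2          # criterion 2: 3' overhang at both ends
    max_asymmetric_bulges: int = 1  # criterion 3
    max_bulge_size: int = 2        # criterion 3
    min_arm_reads: int = 10        # criterion 4 support threshold
    max_mfe_per_nt: float = -0.2   # criterion 5: MFE/length must be below
    min_mfei: float = 0.85         # criterion 5: MFEI must exceed

    # --- target prediction ---
    max_target_score: float = 4.0      # rule 1
    max_adjacent_mismatches: int = 2   # rule 2
    seed_region: tuple[int, int] = (2, 12)   # rule 3 (1-based, inclusive)
    central_positions: tuple[int, int] = (10, 11)  # rule 4
    max_seed_score: float = 2.5        # rule 5 over positions 1-12
    min_mfe_ratio: float = 0.75        # rule 6 (inclusive)
    gu_strict: bool = True  # G-U is a non-match for rules 2-4 (0.5 for 1/5)

    # --- differential expression ---
    fc_threshold: float = 2.0
    alpha: float = 0.05
    pseudocount: float = 1.0  # added to both raw counts when either is zero

    # --- integration ---
    deg_fc_cutoff: float = 1.5  # gene |fold change| must exceed this

    # --- misc ---
    seed: int = 0
    folding_engine: str = ""  # filled at run time from heatmir.fold

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_layouts"] = [list(w) for w in self.window_layouts]
        d["seed_region"] = list(self.seed_region)
        d["central_positions"] = list(self.central_positions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "window_layouts" in d:
            d["window_layouts"] = tuple(tuple(w) for w in d["window_layouts"])
        for key in ("seed_region", "central_positions"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
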