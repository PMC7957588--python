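"""Rule-based miRNA target-site prediction.

Transcripts are scanned with ungapped, antiparallel windows of the miRNA
length (the pattern-matching style of plant target predictors; bulged
sites are out of scope because position-indexed rules are ill-defined
under gaps).  Positions are numbered 1..L from the miRNA 5' end; miRNA
position 1 pairs the 3'-most base of the site window.  Six rules decide
acceptance:

r1  weighted mismatch total <= 4 (G-U wobble counts 0.5)
r2  no more than 2 adjacent non-matches anywhere
r3  no adjacent non-matches within positions 2-12
r4  positions 10 and 11 both Watson-Crick matches
r5  weighted total over positions 1-12 <= 2.5
r6  duplex MFE at least 75% of the perfect-complement duplex MFE

With the default ``gu_strict`` setting a G-U pair is a non-match for the
adjacency/position rules (r2-r4) while contributing only 0.5 to the
numeric totals of r1/r5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import encode_seq
from .config import PipelineConfig
from .fold import duplex_mfe, perfect_duplex_mfe

MATCH, GU, MISMATCH = 0, 1, 2

RULES = ("r1", "r2", "r3", "r4", "r5", "r6")

#: pair-state lookup indexed [miRNA base, target base] (A=0 C=1 G=2 T/U=3)
PAIR_TABLE = np.full((4, 4), MISMATCH, dtype=np.uint8)
for _m, _t in ((0, 3), (1, 2), (2, 1), (3, 0)):  # Watson-Crick
    PAIR_TABLE[_m, _t] = MATCH
PAIR_TABLE[2, 3] = GU  # miRNA G : target U
PAIR_TABLE[3, 2] = GU  # miRNA U : target G


@dataclass
class DuplexScore:
    """Position-resolved scoring of one miRNA x transcript window."""

    mirna_id: str
    transcript_id: str
    start: int  # 1-based on the transcript
    length: int
    pair_states: np.ndarray  # index 0 = miRNA position 1
    total_score: float
    window_1_12_score: float
    max_adjacent_run: int
    rule_verdicts: dict[str, bool]
    duplex_mfe: float = 0.0
    perfect_mfe: float = 0.0
    mfe_ratio: float = 0.0

    @property
    def end(self) -> int:
        return self.start + self.length - 1

    @property
    def accepted(self) -> bool:
        return all(self.rule_verdicts.values())


def pair_states(mirna: str, site: str) -> np.ndarray:
    """Per-position pair states of an ungapped antiparallel duplex.

    ``mirna`` and ``site`` are both 5'->3' and must have equal length;
    miRNA position k (1-based) pairs the site's base L-k+1 positions from
    its 5' end (i.e. the k-th base from the site's 3' end).
    """
    if len(mirna) != len(site):
        raise ValueError(
            f"miRNA ({len(mirna)} nt) and site ({len(site)} nt) differ"
        )
    m = encode_seq(mirna)
    s = encode_seq(site)[::-1]
    if (m > 3).any() or (s > 3).any():
        raise ValueError("non-ACGTU character in miRNA or site")
    return PAIR_TABLE[m, s]


def _scores(states: np.ndarray) -> tuple[float, float]:
    total = float((states == MISMATCH).sum() + 0.5 * (states == GU).sum())
    head = states[:12]
    head_score = float(
        (head == MISMATCH).sum() + 0.5 * (head == GU).sum()
    )
    return total, head_score


def _max_run(mask: np.ndarray) -> int:
    best = run = 0
    for flag in mask:
        run = run + 1 if flag else 0
        best = max(best, run)
    return best


def apply_rules(
    states: np.ndarray, config: PipelineConfig | None = None
) -> dict[str, bool]:
    """Verdicts for rules r1-r5 from pair states alone (r6 needs energies)."""
    config = config or PipelineConfig()
    total, head = _scores(states)
    nonmatch = (
        states != MATCH if config.gu_strict else states == MISMATCH
    )
    lo, hi = config.seed_region  # 1-based inclusive
    seed = nonmatch[lo - 1 : hi]
    p10, p11 = config.central_positions
    central = states[[p10 - 1, p11 - 1]]
    return {
        "r1": total <= config.max_target_score,
        "r2": _max_run(nonmatch) <= config.max_adjacent_mismatches,
        "r3": not (seed[:-1] & seed[1:]).any(),
        "r4": bool((central == MATCH).all())
        if config.gu_strict
        else bool((central != MISMATCH).all()),
        "r5": head <= config.max_seed_score,
    }


def mfe_ratio(
    mirna: str, site: str, config: PipelineConfig | None = None
) -> tuple[float, float, float, bool]:
    """(duplex MFE, perfect MFE, ratio, r6 verdict) for a miRNA and a site.

    The ratio compares magnitudes of the (negative) energies; the >=75%
    threshold is inclusive, so an exact tie passes.
    """
    config = config or PipelineConfig()
    d = duplex_mfe(mirna, site)
    p = perfect_duplex_mfe(mirna)
    ratio = abs(d) / abs(p) if p != 0 else 0.0
    return d, p, ratio, ratio >= config.min_mfe_ratio


def evaluate_site(
    mirna_id: str,
    mirna: str,
    transcript_id: str,
    transcript: str,
    start: int,
    config: PipelineConfig | None = None,
) -> DuplexScore:
    """Full DuplexScore of one window (``start`` 1-based on transcript)."""
    config = config or PipelineConfig()
    site = transcript[start - 1 : start - 1 + len(mirna)]
    states = pair_states(mirna, site)
    verdicts = apply_rules(states, config)
    d, p, ratio, r6 = mfe_ratio(mirna, site, config)
    verdicts["r6"] = r6
    total, head = _scores(states)
    nonmatch = states != MATCH if config.gu_strict else states == MISMATCH
    return DuplexScore(
        mirna_id=mirna_id,
        transcript_id=transcript_id,
        start=start,
        length=len(mirna),
        pair_states=states,
        total_score=total,
        window_1_12_score=head,
        max_adjacent_run=_max_run(nonmatch),
        rule_verdicts=verdicts,
        duplex_mfe=d,
        perfect_mfe=p,
        mfe_ratio=round(ratio, 4),
    )


# ----------------------------------------------------------------------
# vectorised scan


def _state_matrix(m_enc: np.ndarray, t_enc: np.ndarray) -> np.ndarray:
    """Pair states for every window: shape (n_windows, L), column k-1 =
    miRNA position k."""
    length = len(m_enc)
    windows = np.lib.stride_tricks.sliding_window_view(t_enc, length)
    return PAIR_TABLE[m_enc[None, :], windows[:, ::-1]]


def _rule_masks(states: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Boolean acceptance of r1-r5 per window (vectorised)."""
    mm = states == MISMATCH
    gu = states == GU
    total = mm.sum(axis=1) + 0.5 * gu.sum(axis=1)
    head = mm[:, :12].sum(axis=1) + 0.5 * gu[:, :12].sum(axis=1)
    nonmatch = (states != MATCH) if config.gu_strict else mm
    run_limit = config.max_adjacent_mismatches
    # a run of run_limit + 1 consecutive non-matches anywhere fails r2
    runs = np.ones(states.shape[0], dtype=bool)
    length = states.shape[1]
    for s in range(max(0, length - run_limit)):
        runs &= ~nonmatch[:, s : s + run_limit + 1].all(axis=1)
    lo, hi = config.seed_region
    seed = nonmatch[:, lo - 1 : hi]
    r3 = ~(seed[:, :-1] & seed[:, 1:]).any(axis=1)
    p10, p11 = config.central_positions
    central = states[:, [p10 - 1, p11 - 1]]
    r4 = (
        (central == MATCH).all(axis=1)
        if config.gu_strict
        else (central != MISMATCH).all(axis=1)
    )
    return (
        (total <= config.max_target_score)
        & runs
        & r3
        & r4
        & (head <= config.max_seed_score)
    )


def scan(
    mirnas: list[tuple[str, str]],
    transcripts: dict[str, str],
    config: PipelineConfig | None = None,
) -> list[DuplexScore]:
    """All accepted target sites of each miRNA on each transcript.

    Every window of each transcript is evaluated; windows passing r1-r5
    are then checked for r6 with the duplex-MFE engine, and sites passing
    all six rules are returned.  Overlapping accepted windows are all
    reported; the best-scoring site per (miRNA, transcript) is flagged
    downstream in :func:`sites_table`.
    """
    config = config or PipelineConfig()
    out: list[DuplexScore] = []
    encoded = {tid: encode_seq(seq) for tid, seq in transcripts.items()}
    for mirna_id, mirna in mirnas:
        m_enc = encode_seq(mirna)
        length = len(m_enc)
        for tid, t_enc in encoded.items():
            if len(t_enc) < length:
                continue
            states = _state_matrix(m_enc, t_enc)
            candidates = np.flatnonzero(_rule_masks(states, config))
            for w in candidates:
                score = evaluate_site(
                    mirna_id, mirna, tid, transcripts[tid],
                    int(w) + 1, config,
                )
                if score.accepted:
                    out.append(score)
    return out


def alignment_strings(mirna: str, site: str) -> tuple[str, str, str]:
    """(miRNA 5'->3', pair symbols, site 3'->5') for report output."""
    states = pair_states(mirna, site)
    symbols = "".join("|o."[s] for s in states)
    return mirna, symbols, site[::-1]


def sites_table(
    sites: list[DuplexScore],
    mirna_seqs: dict[str, str],
    transcripts: dict[str, str],
) -> pd.DataFrame:
    rows = []
    for s in sites:
        mirna = mirna_seqs[s.mirna_id]
        window = transcripts[s.transcript_id][s.start - 1 : s.end]
        mir_str, sym, site_rev = alignment_strings(mirna, window)
        row = {
            "mirna_id": s.mirna_id,
            "transcript_id": s.transcript_id,
            "start": s.start,
            "end": s.end,
            "total_score": s.total_score,
            "score_1_12": s.window_1_12_score,
            "mfe_ratio": s.mfe_ratio,
        }
        row.update(s.rule_verdicts)
        row["mirna_5p3p"] = mir_str
        row["pairing"] = sym
        row["site_3p5p"] = site_rev
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    # flag the best-scoring site per miRNA/transcript pair
    best = (
        df.sort_values(
            ["total_score", "mfe_ratio", "start"],
            ascending=[True, False, True],
        )
        .groupby(["mirna_id", "transcript_id"], sort=False)
        .head(1)
        .index
    )
    df["is_best"] = df.index.isin(best)
    return df.sort_values(["mirna_id", "transcript_id", "start"]).reset_index(
        drop=True
    )
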