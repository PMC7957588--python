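"""TPM normalisation, differential expression of unreplicated tag
libraries, nine-type expression-pattern classification, and the
2^-ddCt qPCR utility.

Expression is normalised as TPM = count / total clean tags * 1e6.  With a
single library per condition the p-value comes from an Audic-Claverie
exact test on the raw counts conditional on library totals: given count x
in library A (total N_A), the null predictive distribution of the count y
in library B (total N_B) is negative binomial with x + 1 successes and
success probability N_A / (N_A + N_B); the two-sided p-value doubles the
smaller tail.  A miRNA is differentially expressed when fold change >= 2
(either direction) and p < 0.05; no multiple-testing correction is
applied to the calls (a Benjamini-Hochberg column is emitted for
information only).

Pattern types I-IX place each miRNA on the 3x3 grid of HT-vs-NT responses
(induced / repressed / unchanged) in the tolerant and sensitive genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import CONTRASTS, LIBRARIES, LIBRARY_META, PipelineConfig

RESPONSES = ("induced", "repressed", "unchanged")

#: (tolerant response, sensitive response) -> type label.
#: Anchored on: induced in both -> I; repressed in both -> IV;
#: no response in either -> IX.  The remaining six cells are this
#: package's convention (the source figure is not machine-readable).
PATTERN_GRID: dict[tuple[str, str], str] = {
    ("induced", "induced"): "I",
    ("induced", "unchanged"): "II",
    ("unchanged", "induced"): "III",
    ("repressed", "repressed"): "IV",
    ("repressed", "unchanged"): "V",
    ("unchanged", "repressed"): "VI",
    ("induced", "repressed"): "VII",
    ("repressed", "induced"): "VIII",
    ("unchanged", "unchanged"): "IX",
}


@dataclass
class DEMRecord:
    mirna_id: str
    contrast: tuple[str, str]  # (treated, control) library ids
    count_a: int
    count_b: int
    tpm_a: float
    tpm_b: float
    fold_change: float  # treated / control, pseudocount-adjusted
    p_value: float
    significant: bool
    direction: str  # 'induced' | 'repressed' | 'unchanged'
    on_off: bool  # expressed in only one of the two libraries


# ----------------------------------------------------------------------
# TPM


def tpm_matrix(
    counts: pd.DataFrame, totals: dict[str, int]
) -> pd.DataFrame:
    """TPM columns for each library count column.

    ``counts`` holds one ``count_<lib>`` column per library; ``totals``
    are the per-library clean-tag totals.  TPM = count / total * 1e6.
    """
    out = counts.copy()
    for lib, total in totals.items():
        if total <= 0:
            raise ValueError(f"library {lib} has non-positive total {total}")
        out[f"tpm_{lib}"] = out[f"count_{lib}"] / total * 1e6
    return out


# ----------------------------------------------------------------------
# Audic-Claverie test


def audic_claverie_pvalue(
    x: int | np.ndarray,
    y: int | np.ndarray,
    total_x: int,
    total_y: int,
) -> np.ndarray:
    """Two-sided Audic-Claverie p-value(s) for tag counts x vs y.

    Conditional on x with library totals (N_x, N_y), the null predictive
    law of y is NB(x + 1, N_x / (N_x + N_y)).  Two-sided via doubling the
    smaller of the two tails (capped at 1).
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    p_success = total_x / (total_x + total_y)
    lower = stats.nbinom.cdf(y, x + 1, p_success)
    upper = stats.nbinom.sf(y - 1, x + 1, p_success)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def call_dem(
    matrix: pd.DataFrame,
    contrast: tuple[str, str],
    config: PipelineConfig | None = None,
    totals: dict[str, int] | None = None,
) -> list[DEMRecord]:
    """Differential-expression calls for one (treated, control) contrast.

    Fold change is computed on TPM; when either raw count is zero the
    pseudocount is added to both raw counts first, so on/off miRNAs get a
    finite fold change and are flagged ``on_off``.  Significance requires
    max(FC, 1/FC) >= fc_threshold and p < alpha.
    """
    config = config or PipelineConfig()
    treated, control = contrast
    for lib in contrast:
        if f"count_{lib}" not in matrix.columns:
            raise ValueError(f"contrast names unknown library {lib!r}")
    if totals is None:
        totals = {
            lib: int(matrix[f"count_{lib}"].sum()) for lib in contrast
        }
    n_t, n_c = totals[treated], totals[control]
    records = []
    counts_t = matrix[f"count_{treated}"].to_numpy()
    counts_c = matrix[f"count_{control}"].to_numpy()
    # condition on the lexicographically first library so that swapping
    # the contrast direction yields the identical p-value
    if min(contrast) == treated:
        pvals = audic_claverie_pvalue(counts_t, counts_c, n_t, n_c)
    else:
        pvals = audic_claverie_pvalue(counts_c, counts_t, n_c, n_t)
    for i, row in enumerate(matrix.itertuples(index=False)):
        ct, cc = int(counts_t[i]), int(counts_c[i])
        if ct == 0 and cc == 0:
            fc = 1.0
        elif ct == 0 or cc == 0:
            fc = ((ct + config.pseudocount) / n_t) / (
                (cc + config.pseudocount) / n_c
            )
        else:
            fc = (ct / n_t) / (cc / n_c)
        p = float(pvals[i])
        sig = max(fc, 1 / fc) >= config.fc_threshold and p < config.alpha
        direction = "unchanged"
        if sig:
            direction = "induced" if fc > 1 else "repressed"
        records.append(
            DEMRecord(
                mirna_id=getattr(row, "mirna_id"),
                contrast=contrast,
                count_a=ct,
                count_b=cc,
                tpm_a=ct / n_t * 1e6,
                tpm_b=cc / n_c * 1e6,
                fold_change=fc,
                p_value=p,
                significant=sig,
                direction=direction,
                on_off=(ct == 0) != (cc == 0),
            )
        )
    return records


# ----------------------------------------------------------------------
# nine-type classification


def classify_type(
    response_tolerant: str, response_sensitive: str
) -> str:
    """Pattern type I-IX from the two genotype responses."""
    key = (response_tolerant, response_sensitive)
    if key not in PATTERN_GRID:
        raise ValueError(f"unknown response pair {key}")
    return PATTERN_GRID[key]


def dem_table(
    matrix: pd.DataFrame,
    config: PipelineConfig | None = None,
    totals: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Both genotype contrasts, significance, and pattern types.

    Returns one row per miRNA with per-contrast fold changes/p-values, a
    BH-adjusted column per contrast (informational), each genotype's
    response, and the pattern type.
    """
    config = config or PipelineConfig()
    if totals is None:
        totals = {
            lib: int(matrix[f"count_{lib}"].sum()) for lib in LIBRARIES
        }
    per_genotype: dict[str, list[DEMRecord]] = {}
    for genotype, contrast in CONTRASTS.items():
        per_genotype[genotype] = call_dem(matrix, contrast, config, totals)
    rows = []
    for i in range(len(matrix)):
        rec_t = per_genotype["tolerant"][i]
        rec_s = per_genotype["sensitive"][i]
        row = {"mirna_id": rec_t.mirna_id}
        for tag, rec in (("tolerant", rec_t), ("sensitive", rec_s)):
            row[f"fc_{tag}"] = round(rec.fold_change, 4)
            row[f"p_{tag}"] = rec.p_value
            row[f"significant_{tag}"] = rec.significant
            row[f"direction_{tag}"] = rec.direction
            row[f"on_off_{tag}"] = rec.on_off
        row["pattern_type"] = classify_type(
            rec_t.direction, rec_s.direction
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    for tag in ("tolerant", "sensitive"):
        df[f"padj_{tag}"] = _benjamini_hochberg(df[f"p_{tag}"].to_numpy())
    return df


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    n = len(pvals)
    if n == 0:
        return pvals
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ----------------------------------------------------------------------
# qPCR utility


def ddct(ct_table: pd.DataFrame) -> dict[str, float]:
    """Relative expression by the 2^-ddCt method.

    ``ct_table`` columns: sample ('test' | 'calibrator'), gene ('target'
    | 'control'), replicate, ct.  Returns the point estimate
    2^-((Ct_target,test - Ct_control,test) - (Ct_target,cal -
    Ct_control,cal)) with replicate dispersion propagated in quadrature.
    """
    cells: dict[tuple[str, str], np.ndarray] = {}
    for (sample, gene), grp in ct_table.groupby(["sample", "gene"]):
        values = grp["ct"].to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError(f"non-finite Ct in {(sample, gene)}")
        cells[(sample, gene)] = values
    for key in (
        ("test", "target"), ("test", "control"),
        ("calibrator", "target"), ("calibrator", "control"),
    ):
        if key not in cells:
            raise ValueError(f"missing Ct cell {key}")
    means = {k: v.mean() for k, v in cells.items()}
    sds = {k: v.std(ddof=1) if len(v) > 1 else 0.0 for k, v in cells.items()}
    dct_test = means[("test", "target")] - means[("test", "control")]
    dct_cal = means[("calibrator", "target")] - means[("calibrator", "control")]
    ddct_value = dct_test - dct_cal
    sd = float(np.sqrt(sum(s**2 for s in sds.values())))
    return {
        "ddct": float(ddct_value),
        "relative_expression": float(2.0 ** (-ddct_value)),
        "sd_ddct": sd,
        "low": float(2.0 ** (-(ddct_value + sd))),
        "high": float(2.0 ** (-(ddct_value - sd))),
    }


def library_metadata() -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"library": lib, **LIBRARY_META[lib]}
            for lib in LIBRARIES
        ]
    )
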