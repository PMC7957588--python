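"""miRNA-target negative-regulation network construction.

Joins the differential-expression calls, the predicted target sites, and
a gene-level differential-expression (DEG) table into edges
DEM -> DEG that satisfy, within one genotype's HT-vs-NT contrast:

* the miRNA is a significant DEM,
* at least one accepted target site falls in the gene's transcript,
* the gene's |fold change| exceeds the DEG cutoff (default >1.5-fold),
* the two directions are opposite (negative regulation).

The DEG table is taken as provided (genes are not re-called here); its
columns are gene_id, contrast ('tolerant' | 'sensitive'), log2fc,
direction ('up' | 'down').
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .config import PipelineConfig


@dataclass(frozen=True)
class RegulationEdge:
    mirna_id: str
    family: str
    gene_id: str
    contrast: str  # genotype label of the satisfying contrast
    mirna_direction: str  # 'induced' | 'repressed'
    gene_direction: str  # 'up' | 'down'
    gene_log2fc: float
    n_sites: int


_OPPOSITE = {("induced", "down"), ("repressed", "up")}


def build_network(
    dem: pd.DataFrame,
    sites: pd.DataFrame,
    deg: pd.DataFrame,
    config: PipelineConfig | None = None,
    families: dict[str, str] | None = None,
) -> list[RegulationEdge]:
    """Negative-regulation edges from DEM calls, target sites and DEGs.

    ``dem`` is the table from :func:`heatmir.diffexpr.dem_table`;
    ``sites`` the accepted-site table (mirna_id, transcript_id, ...);
    ``deg`` the gene-level table described in the module docstring.
    Transcript ids and gene ids must share a namespace.  Many-to-many
    relations are allowed; an edge records which contrast satisfied it.
    """
    config = config or PipelineConfig()
    families = families or {}
    log2_cutoff = math.log2(config.deg_fc_cutoff)
    edges: list[RegulationEdge] = []
    if sites.empty or dem.empty or deg.empty:
        return edges
    site_counts = (
        sites.groupby(["mirna_id", "transcript_id"]).size().to_dict()
    )
    if not set(sites["transcript_id"]) & set(deg["gene_id"]):
        warnings.warn(
            "no overlap between target transcript ids and DEG gene ids; "
            "empty network",
            stacklevel=2,
        )
        return edges
    deg_by_key = {
        (row.gene_id, row.contrast): row
        for row in deg.itertuples(index=False)
    }
    for dem_row in dem.itertuples(index=False):
        for genotype in ("tolerant", "sensitive"):
            if not getattr(dem_row, f"significant_{genotype}"):
                continue
            mirna_dir = getattr(dem_row, f"direction_{genotype}")
            for (mirna_id, transcript_id), n_sites in site_counts.items():
                if mirna_id != dem_row.mirna_id:
                    continue
                deg_row = deg_by_key.get((transcript_id, genotype))
                if deg_row is None:
                    continue
                if abs(deg_row.log2fc) <= log2_cutoff:
                    continue
                if (mirna_dir, deg_row.direction) not in _OPPOSITE:
                    continue
                edges.append(
                    RegulationEdge(
                        mirna_id=mirna_id,
                        family=families.get(mirna_id, ""),
                        gene_id=transcript_id,
                        contrast=genotype,
                        mirna_direction=mirna_dir,
                        gene_direction=deg_row.direction,
                        gene_log2fc=float(deg_row.log2fc),
                        n_sites=int(n_sites),
                    )
                )
    edges.sort(
        key=lambda e: (e.mirna_id, e.gene_id, e.contrast)
    )
    return edges


def edges_table(edges: list[RegulationEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": e.mirna_id,
                "family": e.family,
                "gene_id": e.gene_id,
                "contrast": e.contrast,
                "mirna_direction": e.mirna_direction,
                "gene_direction": e.gene_direction,
                "gene_log2fc": e.gene_log2fc,
                "n_sites": e.n_sites,
            }
            for e in edges
        ]
    )


def family_summary(edges: list[RegulationEdge]) -> pd.DataFrame:
    """Edges collapsed per miRNA family (members sharing a family label)."""
    df = edges_table(edges)
    if df.empty:
        return df
    return (
        df.groupby("family")
        .agg(
            n_members=("mirna_id", "nunique"),
            n_genes=("gene_id", "nunique"),
            n_edges=("gene_id", "size"),
        )
        .reset_index()
    )


def write_edge_list(path, edges: list[RegulationEdge]) -> None:
    """Plain edge list (miRNA<TAB>gene) for network-visualisation tools."""
    with open(path, "w") as fh:
        for e in edges:
            fh.write(f"{e.mirna_id}\t{e.gene_id}\n")
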