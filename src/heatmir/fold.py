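"""Thin wrapper around the RNA secondary-structure engine.

All thermodynamic predictions in the package go through this module so the
engine identity (and hence the provenance of every MFE number) is recorded
in one place.  MFE values are engine- and version-dependent: two engines
agree on what is a hairpin but rarely on the second decimal of its energy,
so reports always carry :func:`engine_id`.
"""

from __future__ import annotations

from functools import lru_cache

from ._seq import revcomp, to_rna

try:
    import RNA  # ViennaRNA python bindings
except ImportError as exc:  # pragma: no cover - environment misconfiguration
    raise ImportError(
        "No RNA folding engine available. Install the ViennaRNA python "
        "bindings (package 'ViennaRNA') or configure an equivalent engine "
        "exposing fold()/duplexfold()."
    ) from exc


def engine_id() -> str:
    """Identity string of the folding engine, recorded in run manifests."""
    version = getattr(RNA, "__version__", "unknown")
    return f"ViennaRNA-{version}"


@lru_cache(maxsize=100_000)
def fold(sequence: str) -> tuple[str, float]:
    """Predict the MFE secondary structure of a single strand.

    Parameters
    ----------
    sequence : str
        Nucleotide sequence (DNA or RNA alphabet).

    Returns
    -------
    (structure, mfe) : (str, float)
        Dot-bracket string of the same length and the minimum free energy
        in kcal/mol (<= 0), rounded to 0.01 kcal/mol for determinism.
    """
    structure, mfe = RNA.fold(to_rna(sequence))
    return structure, round(float(mfe), 2)


@lru_cache(maxsize=100_000)
def duplex_mfe(seq_a: str, seq_b: str) -> float:
    """MFE (kcal/mol) of the intermolecular duplex of two strands."""
    duplex = RNA.duplexfold(to_rna(seq_a), to_rna(seq_b))
    return round(float(duplex.energy), 2)


def perfect_duplex_mfe(mirna: str) -> float:
    """MFE of a miRNA bound to its exact reverse complement."""
    return duplex_mfe(mirna, revcomp(mirna))


def pair_table(structure: str) -> list[int]:
    """0-based pairing partners for a dot-bracket string (-1 = unpaired)."""
    # RNA.ptable is 1-based with length in slot 0
    pt = RNA.ptable(structure)
    return [p - 1 if p > 0 else -1 for p in pt[1:]]
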