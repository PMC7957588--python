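"""Small sequence helpers shared across the pipeline.

Sequences are stored in the DNA alphabet (A, C, G, T) throughout; they are
converted to RNA only at the folding-engine boundary.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")

#: integer encoding used by the vectorised target scanner (T and U collapse)
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet; U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def _build_encoder() -> np.ndarray:
    table = np.full(256, 255, dtype=np.uint8)
    for base, idx in BASE_INDEX.items():
        table[ord(base)] = idx
        table[ord(base.lower())] = idx
    return table


_ENCODER = _build_encoder()


def encode_seq(seq: str) -> np.ndarray:
    """Encode a DNA/RNA string as uint8 codes A=0 C=1 G=2 T/U=3 (other=255)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODER[raw]


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random DNA sequence with expected GC content ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
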