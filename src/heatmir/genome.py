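"""Exact-match genome index for short tags.

Tags are mapped by exact occurrence on either strand (a seed k-mer lookup
followed by full-length verification).  At the scale this pipeline targets
no heuristic aligner is needed, and exact matching keeps the mapping rule
auditable: a tag maps iff its sequence (or reverse complement) occurs in
the genome; all hits are recorded.
"""

from __future__ import annotations

from collections import defaultdict

from ._seq import revcomp

#: genomic hit: (chromosome, 0-based start, strand)
Hit = tuple[str, int, str]


class GenomeIndex:
    """Seed-and-verify exact substring index over a set of contigs."""

    def __init__(self, contigs: dict[str, str], k: int = 12):
        self.k = k
        self.contigs = {name: seq.upper() for name, seq in contigs.items()}
        self._seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.contigs.items():
            for i in range(len(seq) - k + 1):
                self._seeds[seq[i : i + k]].append((name, i))

    def find(self, tag: str) -> list[Hit]:
        """All exact occurrences of ``tag`` on both strands, sorted."""
        if len(tag) < self.k:
            raise ValueError(
                f"tag shorter than index seed ({len(tag)} < {self.k})"
            )
        hits: list[Hit] = []
        for strand, query in (("+", tag.upper()), ("-", revcomp(tag))):
            for name, i in self._seeds.get(query[: self.k], ()):
                if self.contigs[name][i : i + len(query)] == query:
                    hits.append((name, i, strand))
        return sorted(set(hits))

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end) clipped to the contig; '-' strand is
        reverse-complemented."""
        seq = self.contigs[chrom][max(0, start) : end]
        return revcomp(seq) if strand == "-" else seq

    def contig_length(self, chrom: str) -> int:
        return len(self.contigs[chrom])
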