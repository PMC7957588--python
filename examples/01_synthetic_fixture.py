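"""Generate a synthetic small RNA-seq study with planted ground truth.

Builds the complete input bundle for a four-library heat-stress design
(tolerant/sensitive genotype x normal/high temperature): genome with
planted miRNA hairpins and single-criterion decoys, ncRNA references,
miRNA catalogs, FASTQ reads, transcripts with planted target sites, and
a DEG table.
"""

from heatmir.synthetic import make_fixture

config, truth = make_fixture("tiny", seed=7, outdir="scratch/example_fixture")

print(f"planted hairpin loci: {len(truth.planted_hairpins)}")
for hp in truth.planted_hairpins:
    print(
        f"  {hp.name:18s} role={hp.role:10s} "
        f"violates={hp.violated_criterion:4s} "
        f"{hp.chrom}:{hp.start + 1}-{hp.end}"
    )
print(f"planted miRNAs: {len(truth.planted_mirnas)} "
      f"(known + new members + novel arms)")
print(f"planted target sites: {len(truth.planted_target_sites)}")
print(f"expected negative-regulation edges: {len(truth.expected_edges)}")
# Every entry above is recoverable from the written FASTA/FASTQ/GFF/TSV
# files; decoy loci must be rejected by the hairpin criteria downstream.
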