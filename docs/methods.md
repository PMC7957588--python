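# Methods

This note documents the models and procedures implemented in `heatmir`,
the defaults and why they were chosen, what the synthetic benchmark does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Study design and data model

The pipeline targets an unreplicated 2×2 small RNA-seq design: two
genotypes (heat-**tolerant**, heat-**sensitive**) under two conditions
(**NT** normal temperature, **HT** high temperature), one library each
(`NF1NT`, `NF1HT`, `YF1NT`, `YF1HT`). The atom of all counting is the
*sequence tag*: a unique cleaned read sequence (18–30 nt, DNA alphabet)
with per-library counts. All genomic coordinates are 0-based half-open
internally and 1-based inclusive in GFF3 output; minus-strand sequences
are reverse-complemented at extraction.

## Read cleaning

Order of filters, each read counted under exactly one outcome so that
`raw = clean + Σ discarded(reason)` holds exactly:

1. **Quality** — discard if any base in the first 25 cycles is below
   Phred 20. The thresholds are configurable; "low quality" is not
   standardised across instruments, and this rule is a common strict
   choice for short inserts where early cycles carry the insert.
2. **Adapter trimming** — remove the 3′ adapter (default TruSeq small
   RNA, `TGGAATTCTCGGGTGCCAAGG`) at its first full occurrence, else the
   longest read-suffix matching an adapter prefix of ≥8 nt.
3. **Poly-A** — discard inserts that are ≥80% adenine after trimming.
   "Poly-A tag" has no universal definition; the fraction is exposed in
   the config.
4. **Length** — keep 18–30 nt inclusive.

Cleaning is idempotent: re-cleaning clean inserts changes nothing.

## Tag annotation

Tags receive exactly one class by a fixed priority:
rRNA → scRNA → snoRNA → snRNA → tRNA → repeat → mRNA fragment →
candidate sRNA. Non-coding classes match by exact sense-strand substring
against per-class reference FASTAs; repeat and exon/intron classes match
through exact-match genome hits overlapping annotated intervals.
Known-miRNA catalog matching runs *before* the repeat/exon stages so a
catalogued miRNA that happens to overlap an annotated exon is not
discarded as a degradation fragment; only the remaining tags are subject
to genomic-feature removal. Mapping is exact substring search (12-mer
seed + verification) on both strands with all hits recorded — at the
scale this pipeline targets a heuristic aligner would add dependencies
without adding correctness, and exact matching keeps "maps" auditable.

## miRNA classes

- **Known**: tag equals a focal-catalog mature, or equals it after
  shifting either terminus by ≤2 nt (isomiR tolerance; internal
  mismatches never allowed). Counts of all matching tags are summed per
  catalog entry; a tag matching several entries counts for each and the
  records are flagged ambiguous.
- **New member of a known family**: an unassigned tag within ≤2
  ungapped mismatches of another species' mature (length difference
  ≤2), whose genomic locus folds into a hairpin passing all criteria
  below. The family label is inherited; both arms are reported when
  both carry reads.
- **Novel**: everything else that maps and passes the hairpin criteria.
  Novel families are single-linkage clusters of mature sequences at ≤2
  mismatches.

### Precursor excision and locus handling

Mapped candidate tags are clustered into loci per (contig, strand) with
a 40-nt merge gap, so the two arms of one hairpin form one locus. Around
the most abundant (anchor) tag, candidate windows extend by the flank
layouts (15, 60), (60, 15), (40, 40), (15, 120), (120, 15) nt
(upstream, downstream in tag orientation), clipped to the contig and
kept if 60–400 nt. Among windows passing all criteria the lowest-MFE one
is retained. A hairpin locus also produces a mirror locus on the
opposite strand (the reverse complement of a hairpin is a hairpin, and
an RNase-III duplex with 2-nt 3′ overhangs is strand-symmetric); records
are therefore deduplicated by mature sequence, which collapses mirrors
exactly.

### The five acceptance criteria

Evaluated on the folded window (ViennaRNA MFE structure; the engine
identity and version are recorded in every run manifest because MFE
values are engine-dependent). The most abundant read per arm defines
that arm; reads spanning the terminal loop disqualify their arm.

1. Duplex between the two arm reads has **more than 16** matched pairs
   (strict inequality) and the arm lengths differ by ≤4 nt.
2. Both duplex ends show exactly **2-nt 3′ overhangs**, measured from
   the read termini to the pairing partner of the opposite read's
   5′-most paired base.
3. At most **one asymmetric bulge**, each ≤2 nt. Symmetric internal
   loops (equal unpaired bases on both strands) are not bulges.
4. The most abundant arm read reaches **≥10 reads in at least one
   library**. The criterion is deliberately read as a minimum-support
   threshold (a maximum-support reading would reject every
   well-expressed miRNA); the threshold is configurable.
5. **MFE < −0.2 kcal/mol/nt** and **MFEI > 0.85**, with
   MFEI = (|MFE|/length × 100)/GC% computed on magnitudes so reported
   values are positive. The two clauses are reported as separate
   verdicts (`mfe`, `mfei`) for diagnosability.

## Differential expression

**Normalisation**: TPM = count / total clean tags × 10⁶, so TPM summed
over *all* clean tags of a library is 10⁶ by construction (miRNA-only
sums are ≤10⁶).

**Test**: with one library per condition, an Audic–Claverie exact test
conditional on library totals. Given count *x* in a library of total
*N₁*, the null predictive distribution of the count *y* in a library of
total *N₂* is negative binomial with *x*+1 successes and success
probability *N₁/(N₁+N₂)*; the two-sided p-value doubles the smaller
tail (capped at 1). The test conditions on the lexicographically first
library of the contrast so that swapping contrast direction yields the
identical p-value (the raw test is asymmetric in *x* and *y*). Under a
simulated equal-proportion null the rejection rate at α = 0.05 is
within binomial error of 0.05 (checked in the acceptance suite).

**Calling**: significant iff max(FC, 1/FC) ≥ 2 and *p* < 0.05, fold
change on TPM. When either raw count is zero, a pseudocount of 1 raw
count is added to both sides first, making on/off miRNAs representable;
they carry an `on_off` flag rather than a separate type. No multiple-
testing correction is applied to the calls, mirroring the stated
thresholds; a Benjamini–Hochberg column is emitted for information.

**Nine types**: each miRNA's response per genotype is induced /
repressed / unchanged (reusing the DEM verdicts). The 3×3 grid is
anchored by three fixed points — (induced, induced) = I,
(repressed, repressed) = IV, (unchanged, unchanged) = IX — and the
remaining six cells follow this package's enumeration:
II = (induced, unchanged), III = (unchanged, induced),
V = (repressed, unchanged), VI = (unchanged, repressed),
VII = (induced, repressed), VIII = (repressed, induced). Only the three
anchors are externally fixed; the rest is a documented convention of
this implementation.

**qPCR utility**: 2^−ΔΔCt with replicate means; the dispersion of the
four cells is propagated in quadrature and reported as a low/high range.

## Target prediction

Ungapped antiparallel windows only — the position-indexed rules are
ill-defined under gaps, so bulged target sites are out of scope.
Positions are 1-based from the miRNA 5′ end; position *k* pairs the
site's *k*-th base from its 3′ end. Rules:

- r1: weighted total ≤ 4, G-U wobble counting 0.5;
- r2: no run of >2 consecutive non-matches;
- r3: no two consecutive non-matches with both positions in 2–12;
- r4: positions 10 and 11 both Watson–Crick;
- r5: weighted total over positions 1–12 ≤ 2.5;
- r6: |duplex MFE| ≥ 0.75 × |perfect-complement duplex MFE|, inclusive.

G-U is a *non-match* for r2–r4 while contributing 0.5 to the r1/r5
totals; the lenient alternative (G-U acceptable everywhere but the
totals) is exposed as `gu_strict=False`. Windows slide by 1 nt; all
accepted windows are reported with the best-scoring site flagged (no
non-maximum suppression). The scanner is vectorised (per-window pair
states via a 4×4 lookup table); rule verdicts r1–r5 are recomputable
from pair states alone, and the test suite holds the scanner equal,
window for window, to an independent naive re-implementation.

## Network integration

An edge requires, within one genotype's HT-vs-NT contrast: a
significant DEM; ≥1 accepted site in the gene's transcript; gene
|fold change| > 1.5 (strict) from the supplied DEG table; and opposite
directions. The DEG table is an input (genes are not re-called); it
carries a `contrast` column because opposition is evaluated per
contrast. Edges record the satisfying contrast; a per-family rollup is
also emitted. The >1.5-fold cutoff applies to the gene side only — the
miRNA side already passed the stricter ≥2-fold DEM threshold.

## The synthetic benchmark

The generator builds every pipeline input around planted features and
records the intended downstream outcome of each in a JSON truth file.
Design choices:

- **Hairpins** are built by explicit reverse-complement arm design:
  `ext + arm + loop + revcomp(arm) + revcomp(ext)` with the arm reads
  placed in the canonical 2-nt 3′-overhang register. Decoys introduce
  exactly one defect: three 1×1 symmetric internal loops (duplex drops
  to 16 pairs, criterion 1); a 1-nt read-register shift (3-nt
  overhangs, criterion 2); one 3-nt asymmetric bulge or two 1-nt
  bulges (criterion 3, size and count clauses); designed counts below
  the support threshold (criterion 4); a weak A/U + wobble stem in a
  low-GC context (MFE clause fails, MFEI still passes); a
  wobble-weakened stem in a C-rich context (MFE passes, MFEI fails).
- **Verification, not assumption**: every hairpin is embedded in its
  actual flanking genome sequence and re-evaluated through the
  pipeline's own excision/folding/criterion code (including the mirror
  locus), with redraws until the intended accept/reject outcome holds.
  The ground truth is therefore robust to folding-engine behaviour on
  any seed.
- **Expression design**: per-genotype response templates
  induced = (60, 600), repressed = (600, 60), unchanged = (400, 400)
  reads (NT, HT), with an on/off variant (0, 400) exercising the
  pseudocount path; 3p arms are scaled to 0.3× their 5p arm. The
  templates put every designed call far from the FC = 2 and α = 0.05
  boundaries, so Poisson sampling noise cannot flip a designed verdict
  at the default depths (100k reads/library for the `demo` preset,
  20k for `tiny`). Per-library miRNA counts are sampled Poisson at the
  designed means; a noise fraction (25% demo / 20% tiny) exercises
  every cleaning filter, and the remaining depth is clean background
  (ncRNA, exon and repeat fragments, unmappable random tags).
- **Targets and DEGs**: planted sites include fully compliant sites
  wired to anti-correlated DEGs (expected edges, including one gene
  shared by two miRNAs), a concordant and a below-cutoff DEG (expected
  non-edges), and one site violating each of the six rules. The
  rule-6 site is re-drawn until the engine-measured duplex ratio
  actually falls below 0.75 with rules 1–5 passing.

**What the benchmark does not emulate**: sequencing-error models,
quality-score distributions beyond a single low-quality spike,
expression dispersion beyond Poisson, isomiR spectra, bulged target
sites, genome-scale repeat structure, or multi-locus miRNA families at
realistic densities. Passing the truth-recovery tests therefore
demonstrates correctness of the decision logic under its stated rules,
not performance on real sequencing data.

## Numerical conventions and degenerate inputs

- MFE values are rounded to 0.01 kcal/mol; folding results are cached.
- Thresholds at boundaries: FC = 2 is significant (≥); 16 duplex pairs
  fail criterion 1 (strictly more than 16); duplex ratio exactly 0.75
  passes rule 6 (≥); gene fold change exactly 1.5 is excluded (>).
- A library histogram with no 21-nt tags reports the 24/21 ratio as
  undefined (`NA`), not an exception.
- An all-unpairable sequence folds to zero energy and no structure;
  candidate evaluation then fails the energy criteria rather than
  erroring.
- Ties among arm reads with equal counts break lexicographically;
  among passing windows, by (MFE, locus); both make reruns
  byte-identical.
- All randomness flows from integer seeds through
  `numpy.random.default_rng`; identical seed and config give
  byte-identical fixture files and byte-identical DEM/edge tables.

## Problem sizes

Default test/benchmark sizes — `tiny`: 30-kb genome, 5 hairpin loci,
9 catalog miRNAs, 4 × 20k reads, 12 transcripts; `demo`: 50-kb genome,
20 hairpin loci (11 compliant novel, 3 new-member, 6 decoys), 12
catalog miRNAs, 4 × 100k reads, 50 transcripts of 500 nt. These sizes
exercise all nine pattern types, all criterion decoys and all six
target rules while keeping a full end-to-end run near ten seconds on
one core.
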