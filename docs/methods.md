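# Methods

## Coordinate model

All internal coordinates are 0-based half-open on a named contig with an
explicit strand; GTF I/O converts to/from 1-based inclusive at the boundary.
The Ensembl GTF dialect is assumed: `CDS` features exclude the stop codon,
and an explicit `stop_codon` feature takes precedence over derivation. When
no `stop_codon` feature exists, the stop is derived by walking 3 exonic
bases transcript-downstream of the CDS 3′ end; a stop codon split across an
exon junction is stored as the genomic interval from its first to its last
base with a flag, which is safe because every distance in the package is an
exonic walk, never a genomic subtraction. Transcripts with zero exons,
overlapping exons or mixed strands among features are rejected, not
repaired.

All distances labelled `distance_to_stop` are **spliced** distances: the
number of exonic bases between the base immediately after the stop codon and
the intron donor, counted along the query transcript's mature mRNA. This is
the quantity the EJC/ribosome geometry of the 55-nt NMD rule refers to; the
raw genomic distance is reported alongside for comparison. A donor
immediately after the stop codon has distance 0 and is still a 3UI.

## Reference curation

High-confidence references require a numeric transcript support level ≤ 2
(parsed from the leading integer of the attribute; "NA" and absent fail) and
an APPRIS tag mapping to `principal`, `alternative:1` or `alternative:2`.
Two indices are built from the **full** annotation, not the curated subset
(the curated subset is only the matching target set): the set of every
reference junction, and the set of donor/acceptor positions of *coding
introns* — introns whose genomic span lies between a transcript's start and
stop codon in transcript order. Introns wholly within the 5′ UTR are not
treated as coding by default (`include_utr5` flips this); the concern is
introns that an early PTC would relocate into the 3′ UTR, and 5′ UTR introns
cannot play that role. A CDS-bearing reference whose stop codon cannot be
derived is skipped for the boundary index only, with a warning.

## Matching and classification

A reference is a candidate for a query when they share chromosome and
strand and the first base of the reference's start codon lies in a query
exon. The CDS chain test compares, as exact coordinate pairs, the query and
reference introns contained in the genomic span of the reference CDS; an
intron of either transcript that overlaps the span without being contained
in it fails the match (intron retention across the CDS boundary is a
different chain, not a matching one). Query introns whose donor lies
transcript-downstream of the last stop-codon base are the 3UIs of that
(query, reference) pair; a pairing whose stop codon is swallowed by a query
intron is skipped as unmeasurable.

Per record, `co3UI` means the intron's donor **or** acceptor position
(side-matched) appears in the coding-boundary index; `e3UI` otherwise;
`novel` means the exact (donor, acceptor) pair appears in no reference
junction. A transcript matched by several references yields one record per
(intron, reference) pair; the per-intron summary demotes an intron to co3UI
if *any* pairing does, and a transcript counts as e3UI-containing only when
all of its 3UIs are e3UI under all matched references. The maximal-distance
flag marks the record achieving the transcript's largest stop distance,
breaking ties towards the most 3′ (transcript-downstream) intron. Output is
sorted and invariant to input transcript order; queries with no match are
listed in a skipped log rather than raising.

## Merge filtering

Overlap categories per query, with precedence `identical > fragment >
overlapping_novel > contained_utr > contained_intronic > intergenic` across
references (a transcript is kept if any reference legitimizes it):
`identical` is an exact same-strand exon chain; `fragment` is a contiguous
sub-chain with matching internal junctions and boundary exons contained in
the reference (single-exon queries inside a reference exon count);
containment tests ignore strand, identity/fragment require the same strand
(an antisense copy is not a fragment of a reference). The filter keeps
categories {identical, overlapping_novel} with TPM strictly > 1 in at least
one sample. The exact fragment semantics of assembler merge tools are not
published; this definition is the documented approximation, and it is
deliberately conservative — anything dropped here could never yield a
trustworthy 3UI call.

## Expression filters

Gene TPM is the sum of member-transcript TPMs from the same quantification;
the transcript/gene fraction is undefined where gene TPM is 0. *Expressed* =
TPM > 1 and fraction > 0.25, both strict, as the thresholds are printed.
*Broadly expressed* = expressed in ≥ 10% of either condition's samples —
the count threshold is the ceiling (10% of 25 samples ⇒ ≥ 3), so the rule is
attainable in small cohorts — and every junction of the transcript has at
least one supporting read summed across samples (aggregate rather than
per-sample coverage; a per-expressing-sample variant would be stricter and
is easy to add, but junction evidence is fundamentally a detection question,
not a per-sample quantification one).

## PSO statistics

PSO = 1 − PSI elementwise on an rMATS-style inclusion table (values outside
[0, 1] are errors, missing values propagate). Per-sample class averages are
unweighted means over non-missing events. Expression normalization is the
median-of-ratios method: per-sample factors are medians of count ratios to
per-gene geometric means, using only genes with nonzero counts in every
sample. Note that scaling one sample's counts by c rescales the per-gene
geometric means too, so all factors shift (by c^(1−1/m) for the scaled
sample and c^(−1/m) for the rest with m samples); the two-sample doubled
case gives (1/√2, √2).

Spearman correlations are tie-aware rank Pearson with the two-sided t
approximation (scipy), on pairwise-complete observations; fewer than 4
complete pairs or a zero-variance vector yield a missing result (not 0 — a
constant vector carries no rank information and 0 would be a fabricated
null). BH adjustment is applied over genes within each (condition, class)
stratum by default; a global family is available. Conditions are compared
per gene with the Fisher r-to-z test for independent correlations, the
standard default among the comparison variants for two independent groups;
groups need n > 3 and |r| < 1.

## The synthetic-data generator

The generator emulates the data flows the pipeline ingests: an Ensembl-style
reference GTF (CDS, start/stop codons, TSL/APPRIS attributes), an exon-only
assembly GTF, a genome FASTA, Salmon-style TPM tables, featureCounts-style
junction counts and rMATS-style PSI tables, plus a truth table that tests
treat as the single source of ground truth.

Per gene, a transcript-order plan (5′ UTR 150 nt; coding exons of 120 nt
separated by 90-nt introns; stop codon; a planted UTR intron at a chosen
spliced distance; 150 nt tail) is laid out on either strand; minus-strand
genes are exact mirror images of the forward layout. Class construction: an
annotated e3UI adds a reference isoform carrying the same post-stop intron;
a novel e3UI adds none; a co3UI adds a readthrough reference isoform whose
CDS extends across the intron, making it a coding intron. Decoys (reference
fragments, intron-contained single exons, antisense overlaps) exercise the
merge filter and strand handling. The genome is random sequence at GC 0.42
with GT..AG planted at every intron (strand-aware), ATG/TAA at the codons;
planted intron lengths are ≥ 60 nt by default. Default cohort: 25 normal and
25 cancer samples; PSI is Beta-distributed (concentration 20) with mean 0.60
in normal, shifted −0.10 for e3UIs and +0.05 for co3UIs in cancer (e3UIs
over-spliced, co3UIs more retained in cancer). A regulator gene's expression
is coupled to the per-sample mean e3UI PSO through a Gaussian copula on the
PSO ranks (Pearson coefficient 2·sin(πρ/6) to hit a Spearman target),
targeting ρ = −0.34 in normal and 0.11 in cancer samples — the UPF1-like
study conditions. Background genes are drawn independently of PSO so that
size-factor estimation has a stable reference. One seed determines every
byte of output.

What the generator does **not** emulate: read-level noise and alignment
artifacts, assembler fragmentation beyond the planted decoy types,
soft-clipped or non-canonical junctions (unless planted), overlapping gene
loci, PSI estimation uncertainty correlated with depth, and library-size
differences between samples. Passing round-trip tests therefore demonstrates
the correctness of the annotation-comparison logic and statistics, not
robustness to upstream assembly or quantification error.

## Problem sizes and numerical choices

The test suite uses 20 fixtures of 50 genes for round-trip concordance, 500
random small loci (≤ 4 query introns, ≤ 3 references) for brute-force oracle
equivalence, 5 seeds for mirror symmetry, and 100 replicates at n = 100
samples per condition for correlation recovery; the acceptance script uses 5
fixtures of 50 genes and the same 100-replicate recovery. These sizes give
stable statistics while keeping a full run in seconds. Closed-form
statistical checks are asserted to 1e-9. The recovery criterion uses the
95% Fisher interval around the planted ρ; Spearman's sampling variance is
slightly larger than the 1/(n−3) Pearson value, so nominal coverage is ~94%,
comfortably above the ≥ 90/100 requirement without tuning.

## Known limitations

* GTF only (no GFF3), Ensembl attribute dialect; no liftover or BAM input.
* CDS for 3UI-containing transcripts is always inherited from the matched
  reference; no de-novo ORF prediction.
* Canonicality is the binary GT-AG statistic; GC-AG/AT-AC minor-class
  introns are reported via their dinucleotides but counted non-canonical.
* The naive I/(I+S) PSI estimator is a labelled convenience, not an rMATS
  replacement.
* The Fisher-z comparison assumes independent groups; paired or overlapping
  designs need a different variant.
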