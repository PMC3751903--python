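# Methods

chimerakit detects chimeric transcripts — gene fusions, partial tandem
duplications (PTDs) and internal tandem duplications (ITDs) — from de novo
transcriptome-assembly contigs. It consumes contig-to-genome alignments
(PSL), read-to-contig alignments (SAM/BAM), gene models (genePredExt) and
region annotations (BED), and optionally read-to-genome alignments for
relative-coverage estimation. This note documents the model, the defaults
and why they are what they are, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Event model

A chimeric transcript lacks a collinear mapping to a single reference gene
model. Three types are characterized:

* **Fusion** — parts of two distinct genes joined in one transcript. No
  requirement that the junction uses annotated exon boundaries.
* **PTD** — a tandem duplication whose both edges coincide with annotated
  exon boundaries; its signature is a non-canonical exon junction (NCEJ)
  from the end of an exon back to the start of the same or an upstream
  exon. Circular transcripts produce the identical junction and cannot be
  distinguished locally; since poly(A)-selected libraries deplete circles,
  NCEJ events are labeled PTD.
* **ITD** — a tandem duplication with at least one edge off any exon
  boundary, typically sub-exonic, possibly with a few inserted bases
  between the copies (the FLT3-style insert).

## Stage 1 — alignment selection and candidate identification

For contig C with alignment set A(C), subsets are scored as

    score(A) = quality(A) + inclusion(A) − overlap(A) − size(A)

where inclusion is the fraction of contig positions aligned in ≥1 member,
overlap the fraction aligned in ≥2, size the member count, and quality the
sum of per-alignment qualities. **Quality** is defined here as
`(matches − mismatches) / (matches + mismatches)`, clamped to [0, 1]: it is
monotone in both the alignment score and percent identity, aligner-agnostic,
and independent of how much of the contig the alignment covers. Coverage is
deliberately excluded from quality — it is what the inclusion term measures;
folding coverage into quality makes the piece qualities of any split pair
sum to ≈1, so no pair could ever outscore a single alignment covering half
the contig, and split candidates would be unreachable.

Selection is heuristic: if one gap-free alignment has inclusion > 0.95
(`case1_inclusion_min`), the contig is non-chimeric (Case I). Otherwise
alignments are grouped transitively by pairwise contig overlap > 0.10 of
contig length (`overlap_group_min`), and the score-optimal combination
taking at most one member per group is chosen — exhaustively when the
search space is small (≤4096 combinations, always true at realistic
alignment counts per contig), otherwise best-quality-per-group. A chosen
set of one alignment with significant query gaps is Case II (potential
gap-candidate), a pair is Case III (potential split-candidate), more is
Case IV (not characterized). Within a group, members within 0.05 of the
top quality (`multimap_quality_window`) are kept as alternates and mark the
resulting candidates multi-mapping. Alignments to mitochondrial sequence
({chrM, chrMT, MT, M}, configurable) are discarded.

**Query gaps** are maximal runs of unaligned contig positions, including
contig edges. Gaps ≥ 4 nt (`min_gap_length`; the smallest reported ITDs are
4 nt) in a host alignment with quality ≥ 0.90 and inclusion ≥ 0.90 are
realigned twice with Smith–Waterman local alignment
(match +1 / mismatch −1 / gap open −2 / gap extend −1, via
Bio.Align.PairwiseAligner): first against the contig with the gap excised
(duplication; the excision guarantees the gap cannot match itself), then —
for internal gaps only — against the reverse complement of the genomic
window between the mates of the gap-flanking bases (inversion). Success
requires ≥ 90% of the gap aligned at ≥ 95% identity; these thresholds are
this package's choice, as no published criteria exist. When both succeed,
duplication wins (shorter explanatory distance) and the conflict is
recorded.

**Topology labels.** Ordered by contig coordinate, an alignment pair is
interchromosomal (different chromosomes), inversion (different strands),
duplication (same chromosome and strand, genomic intervals overlap),
eversion (same chromosome and strand, genome order reversed relative to
contig order), or read_through (same chromosome and strand, collinear order,
disjoint — deletion-style intrachromosomal junctions). read_through is an
addition that keeps the labeling total; it participates in fusion calling
only.

Candidate **breakpoints** are the genomic mates of the junction-flanking
contig bases; for tandem duplications they are the first and last genomic
positions of the duplicated segment. Internally all coordinates are 0-based
half-open; prediction output is 1-based inclusive.

## Stages 1.2–1.3 — grouping and annotation

Meta-assemblies represent one event with several contigs, so candidates are
grouped single-linkage: same chromosome pair, same orientation signature
(strand pair + contig order of the genomic pieces), both breakpoints within
10 nt (`group_tolerance_nt`; the source method states no value — 10 nt
absorbs junction-homology ambiguity without merging distinct events).
Breakpoints match an exon boundary when within `boundary_tolerance`
(default 0, exact — PTD calling hinges on this) of any exon start/end of
any transcript. A gene overlaps a candidate piece if any exon intersects
any alignment block; intron-only overlap does not count, since contigs are
transcript-derived.

## Stage 2 — read support

Junction homology makes the exact breakpoint ambiguous, so support is
computed over a contig search region P: the overlap of the two alignments
±1 nt for split candidates (two junction-flanking bases when abutting), or
the region between the two copies for gap duplications. At each p in P,
R(p) counts mismatch-free reads (NM = 0 and a pure-match CIGAR — junction
evidence must be exact) overlapping p by ≥ `min_flank` = 5 nt on each side.
Reported support is min over p of R(p), guaranteeing at least that many
junction-spanning reads wherever the true breakpoint lies in P. For reads
mapping to several contigs, score(r, C) = |C(r) ∩ E(C)| / |C(r)| with E(C)
the event's contig group; reads with score ≥ 0.5 support strongly. Reads
are counted per alignment record (a pair contributes up to 2).

## Stage 3 — filters

Ten filters, all evaluated without short-circuit so review output lists
every violation. Defaults: contig in > 3 groups; multi-mapping; homopolymer
gap (every base of the realigned gap identical); breakpoints in repeats
(off by default); breakpoints in structural RNA; either alignment identity
< 99.0%; pair inclusion < 0.9 (union coverage — the overlapped positions
are counted once); strong support < 5 reads; contig-coordinate alignment
overlap > 75 nt; poly(A) artifact (an alignment piece covering only a
leading T-run or trailing A-run of ≥ 8 nt at ≥ 90% base content; run length
and purity are this package's choice).

## Stage 4 — prediction

Typing applies the event model above to candidates that pass filtering:
fusions from split candidates (any topology) whose pieces overlap only
distinct genes and are genomically disjoint — if either piece overlaps both
genes (read-through ambiguity) no fusion is called; PTD/long-ITD from
split candidates with duplication or eversion topology within one gene,
separated by whether both breakpoints sit on exon boundaries; short ITDs
from gap-duplication candidates, with boundary-consistent gap duplications
routed to PTD. One prediction is emitted per candidate group; distinct
breakpoint pairs (fusion isoforms) are distinct predictions. ITD
`inserted_bases` = gap length − realigned duplication length.

An optional post-filter aligns each predicted contig to user-provided
wild-type transcript sequences and removes predictions whose contig aligns
collinearly and near-full-length (coverage ≥ 95%, identity ≥ 98%; pairwise
local alignments are monotone by construction) to any single transcript.

## Stage 5 — relative coverage

C is the event's read-to-contig support. Two genomic flank regions A and B
are built from alignment blocks, cut from the far end or extended along
annotated exons until each totals 2 × read length (truncated-and-flagged at
gene ends). For fusions, A and B flank the breakpoint on the gene-A and
gene-B sides. For tandem duplications, A and B extend *outward* from the
duplicated segment's edges: inside the segment, total depth carries the
extra chimeric copy, which the W formula corrects for but which would
distort the T denominator.

Read-to-genome depth at each region position s (reads overlapping s by ≥
q = 5 nt on each side; mismatches tolerated) is partitioned as
T = DW + T1 + T2: DW counts reads spanning, with ≥ q nt on both sides, a
wild-type splice junction or genomic adjacency the chimera destroys
(fusions only; a tandem duplication destroys no wild-type junction), T2
counts reads at positions inside the duplicated segment, T1 the rest. The
wild-type depth estimate assumes a single extra copy of any duplicated
region:

    W(r,s) = DW(r,s) + I1(r,s)·(T1(r,s) − C) + I2(r,s)·(T2(r,s) − 2C)

with I_j(r,s) = 1 iff T_j(r,s) > 0. Negative intermediate values are
clamped at 0 and flagged (chimeric support exceeding locus coverage).
W(r) = max_s W(r,s); T(r) = max over positions attaining W(r) of T(r,s);
starred values average A and B. Seven depths (C, W(A), T(A), W(B), T(B),
W(*), T(*)) and six ratios C/W(r), C/T(r) are reported; a ratio with a
non-positive denominator is reported as infinity, not an error. For
duplications the starred averages are the headline values; for fusions the
two sides measure different genes and are read separately.

The DW/T1/T2 assignment rule is operational — the read classes are defined
by what sequence a read represents, not by an algorithm — and is validated
against the generator's truth labels only.

## Synthetic-data generator

`simulate` builds everything the pipeline consumes, emulating an idealized
experiment:

* **Genome**: random sequence, 2 chromosomes, non-overlapping plus-strand
  genes with 3–6 exons of 120–400 nt and introns of 60–300 nt; deterministic
  under a fixed seed.
* **Events**: fusions join 5′ exons of one gene to 3′ exons of another;
  PTDs duplicate whole exon runs (edges on boundaries by construction);
  ITDs duplicate 10–30 nt sub-exonic segments with 0–3 inserted bases
  (inserts capped at segment length / 10 so the realignment's 90%-aligned
  criterion reflects the duplication, not the insert). Products < 200 nt
  are discarded. Two generator properties ensure the truth table is
  meaningful: ITD junctions are kept ≥ 150 nt (two read lengths) from
  transcript ends, since closer junctions cannot be covered by read
  fragments or assembled and are undetectable by construction; and events
  whose breakpoint pair falls within 25 nt of an existing event's are
  rejected — such twins are one event to the grouping stage by definition.
* **Reads**: error-free paired-end reads; per-transcript coverage either
  fixed, or drawn from a two-component log-normal mixture
  (weight 0.65 on LN(μ=3.0, σ=0.8), 0.35 on LN(μ=4.5, σ=1.0)), chosen to
  give a median near 30× with a long right tail, typical of deeply
  sequenced transcriptomes. Defaults: 75 nt reads, 114 nt mean fragment —
  mates overlap, as in short-fragment libraries. `simulate_reads_tiled`
  places single reads at even spacing for exact per-position depth; it is
  used where a check targets an estimator rather than sampling behavior.
* **Ideal alignments**: the PSL and SAM records a perfect aligner would
  emit — two split alignments for fusion contigs and PTD junction contigs
  (PTDs are emitted as 2-read-length junction contigs around the NCEJ,
  exercising the short-junction-contig pathway), one gapped alignment for
  ITD contigs (the second copy plus insert is the query gap), a single
  spliced alignment for wild-type contigs, spliced read-to-genome records
  for wild-type reads, and clipped-at-the-junction records for chimeric
  reads.

What the generator does **not** emulate: sequencing errors and quality
scores, assembly fragmentation and misassembly, alignment ambiguity from
genomic repeats and paralogy, minus-strand genes (minus-strand *alignments*
are exercised by the PSL and inversion-realignment tests), intronic or
intergenic transcription, and isoform mixtures beyond one wild-type
transcript per gene. Passing tests therefore demonstrate correctness of the
pipeline's logic on well-formed inputs, not robustness to the aligner- and
assembler-specific failure modes that dominate errors on real data (e.g.
support undercounting on very short contigs).

## Problem sizes and determinism

The test suite and the acceptance script use a 20-gene genome with 10
events per type at 30× coverage for end-to-end recovery (matched events
allow 10 nt of breakpoint slack — junction homology, e.g. an inserted base
equal to the base preceding the segment, legitimately shifts the reported
breakpoint); 200 random contigs for the alignment-set oracle; 500 random
layouts for the read-support oracle; and 60× mixtures at chimeric fractions
0.1/0.25/0.5 for relative-coverage recovery. All randomness flows from
explicit seeds; identical inputs and configuration give byte-identical
outputs.

## Known limitations

* Case IV contigs (three or more selected alignments) are labeled and
  dropped, not characterized.
* The grouping tolerance and multimap quality window are heuristics; no
  data-driven calibration is attempted.
* Relative coverage assumes one extra copy of duplicated regions and is a
  local metric: highly expressed isoforms that skip the involved exons
  bias it downward.
* The wild-type collinear post-filter scales as contigs × transcripts
  pairwise alignments; for transcriptome-scale references an indexed
  aligner should replace it.
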