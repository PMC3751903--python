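# chimerakit

Detection and characterization of chimeric transcripts — gene fusions,
partial tandem duplications (PTDs) and internal tandem duplications
(ITDs) — from de novo transcriptome-assembly contigs.

Chimeric transcripts matter clinically: in acute myeloid leukemia, MLL
PTDs, FLT3 ITDs and PML/RARA fusions carry prognostic and treatment
information, and the expression of a chimera *relative to its wild-type
transcript* can itself be prognostic. Fusion callers are plentiful;
tools that also call tandem duplications from RNA-seq and report relative
chimeric expression are not. chimerakit works downstream of any assembler
and aligner whose outputs can be converted to PSL and SAM/BAM: it never
maps reads itself, so short-fragment libraries (fragment < 2 × read
length) are not a problem.

## Method

The pipeline has five stages:

1. **Detect** — for each contig, choose the alignment subset A\*(C)
   approximately maximizing
   `score(A) = quality(A) + inclusion(A) − overlap(A) − size(A)`
   (inclusion/overlap are the fractions of contig positions aligned in ≥1 /
   ≥2 members). A single gapped alignment is a *gap-candidate*: its query
   gap is locally realigned against the gap-masked contig (duplication) and
   against the reverse complement of the flanked genomic window
   (inversion). An alignment pair is a *split-candidate*, labeled with its
   topology: interchromosomal, inversion, eversion, duplication, or
   read-through. Candidates are grouped across meta-assembly contigs and
   annotated with genes, exon-boundary matches, and repeat/structural-RNA
   overlaps.
2. **Support** — over a breakpoint search region P on the contig, count
   mismatch-free reads overlapping each position with ≥ 5 nt flanks; report
   the minimum (so at least that many reads span the breakpoint wherever it
   lies in P). Multi-mapped reads support strongly only when ≥ half their
   mappings land in the event's contig group.
3. **Filter** — ten independent filters (group count, multi-mapping,
   homopolymer, repeats, structural RNA, identity ≥ 99%, inclusion ≥ 0.9,
   ≥ 5 strong reads, alignment overlap ≤ 75 nt, poly(A) artifacts), all
   reported, none short-circuited.
4. **Predict** — fusions from split-candidates spanning two disjoint
   genes; PTDs from duplication/eversion junction contigs within one gene
   with both breakpoints on annotated exon boundaries (the non-canonical
   exon junction, NCEJ); ITDs when at least one breakpoint is off-boundary,
   including short ITDs assembled in full and detected through gapped
   alignments. An optional post-filter removes contigs that align
   collinearly to a single wild-type transcript.
5. **Relcov** (optional) — with read-to-genome alignments, estimate
   wild-type depth in two breakpoint-flanking regions A and B (each cut or
   extended to 2 × read length) via
   `W(r,s) = DW + I1·(T1 − C) + I2·(T2 − 2C)` and report
   C, W(A), T(A), W(B), T(B), W(\*), T(\*) and the six ratios C/W(r),
   C/T(r) — the chimera's expression relative to total and wild-type
   transcription at its own locus.

A synthetic-data module generates genomes, events, reads (log-normal
mixture coverage), and the PSL/SAM fixtures a perfect aligner would
produce, so the entire pipeline is testable offline. See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate a 12-gene genome with two events of each type at 30× coverage,
then run the pipeline on the synthetic fixtures:

```bash
chimerakit simulate --out-dir sim --n-genes 12 \
    --fusions 2 --ptds 2 --itds 2 --coverage 30 --seed 5
# 6 events, 3412 reads -> sim

chimerakit run --contigs sim/contigs.fa --psl sim/contigs.psl \
    --read-to-contig sim/reads_to_contigs.sam --genes sim/genes.gpd \
    --genome sim/genome.fa --out-dir out
# 6 predictions -> out/predictions.tsv
```

Selected columns of `out/predictions.tsv`:

| event_type | contig_id | genes | chrom_a | breakpoint_a | chrom_b | breakpoint_b | exon_boundary_match | strong_support |
|---|---|---|---|---|---|---|---|---|
| ITD | ctg_ev005 | G004 | chr1 | 7599 | chr1 | 7625 | neither | 22 |
| ITD | ctg_ev006 | G010 | chr2 | 7962 | chr2 | 7987 | neither | 25 |
| PTD | ctg_ev004 | G007 | chr2 | 1998 | chr2 | 265 | both | 29 |
| PTD | ctg_ev003 | G012 | chr2 | 11731 | chr2 | 10222 | both | 36 |
| fusion | ctg_ev002 | G003,G009 | chr2 | 5481 | chr1 | 5434 | both | 21 |
| fusion | ctg_ev001 | G005,G011 | chr2 | 8746 | chr1 | 8887 | both | 39 |

All six implanted events are recovered: the two ITD rows report sub-exonic
duplications (both breakpoints off exon boundaries, `neither`), the PTD
rows report exon-run duplications whose breakpoints sit exactly on exon
boundaries (`both`, and breakpoint_a > breakpoint_b — the junction runs
backward along the genome), and the fusion rows join two genes.
`strong_support` is the minimum number of mismatch-free junction-spanning
reads (~30× simulated coverage, thinned by the 5 nt flank requirement and
sampling). Breakpoints are 1-based inclusive in the TSV; the `sim/truth.tsv`
table written by the simulator lists the implanted coordinates for
comparison.

Each stage is also independently invokable (`chimerakit detect / support /
filter / predict`) with JSON intermediates between stages, and everything
is importable as a library (`import chimerakit`).

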