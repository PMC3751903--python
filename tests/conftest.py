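"""Shared fixture builders for the test suite.

Everything is generated programmatically; no data files are stored.
"""

from __future__ import annotations

import numpy as np
import pytest

from chimerakit.align_select import Candidate, GapRealignment, QueryGap
from chimerakit.candidates import CandidateAnnotation
from chimerakit.formats import ContigAlignment, GeneModel, ReadAlignment, compute_quality
from chimerakit.support import ReadSupport


def make_aln(
    blocks,
    contig_length=100,
    chrom="chr1",
    strand="+",
    quality=None,
    contig_id="c1",
    mismatches=0,
    percent_identity=100.0,
):
    """ContigAlignment from (contig_start, genome_start, length) blocks."""
    matches = sum(n for _, _, n in blocks) - mismatches
    if quality is None:
        quality = compute_quality(matches, mismatches)
    return ContigAlignment(
        contig_id=contig_id,
        contig_length=contig_length,
        chrom=chrom,
        strand=strand,
        blocks=list(blocks),
        matches=matches,
        mismatches=mismatches,
        quality=quality,
        percent_identity=percent_identity,
    )


def make_split_candidate(
    piece_a=((0, 60), "chr1", 1000, "+"),
    piece_b=((50, 100), "chr2", 5000, "+"),
    contig_length=100,
    contig_id="c1",
    topology=None,
    multimapping=False,
    percent_identity=100.0,
):
    """Split candidate from two ((cstart, cend), chrom, gstart, strand) pieces."""
    (ca, cb), chrom_a, ga, strand_a = piece_a
    (cc, cd), chrom_b, gb, strand_b = piece_b
    aln_a = make_aln(
        [(ca, ga, cb - ca)], contig_length, chrom_a, strand_a,
        contig_id=contig_id, percent_identity=percent_identity,
    )
    aln_b = make_aln(
        [(cc, gb, cd - cc)], contig_length, chrom_b, strand_b,
        contig_id=contig_id, percent_identity=percent_identity,
    )
    from chimerakit.align_select import classify_topology, _split_breakpoints

    topo = topology or classify_topology(aln_a, aln_b)
    bps = _split_breakpoints(aln_a, aln_b)
    overlap = max(0, min(cb, cd) - max(ca, cc))
    return Candidate(
        contig_id=contig_id,
        kind="split",
        topology=topo,
        alignment_pair=(aln_a, aln_b),
        breakpoints=bps,
        multimapping=multimapping,
        contig_overlap_nt=overlap,
        contig_length=contig_length,
        inclusion=(cb - ca + cd - cc - overlap) / contig_length,
        piece_intervals=[(ca, cb), (cc, cd)],
        duplicated_segment=(
            (chrom_a, min(b[1] for b in bps), max(b[1] for b in bps) + 1)
            if topo in ("duplication", "eversion") and chrom_a == chrom_b
            else None
        ),
    )


def make_gap_candidate(
    copy1=(10, 30),
    gap=(45, 64),
    contig_length=120,
    chrom="chr1",
    genome_offset=1000,
    contig_id="c1",
    gap_sequence="",
    realigned_sequence="",
    inserted_bases=0,
):
    """Gap-duplication candidate: copy1 interval + gap (inclusive coords)."""
    host = make_aln(
        [(0, genome_offset, gap[0]), (gap[1] + 1, genome_offset + gap[0], contig_length - gap[1] - 1)],
        contig_length,
        chrom,
        contig_id=contig_id,
    )
    g_first = genome_offset + copy1[0]
    g_last = genome_offset + copy1[1] - 1
    realn = GapRealignment(
        kind="duplication",
        target_interval=copy1,
        identity=100.0,
        aligned_fraction=1.0,
        realigned_sequence=realigned_sequence,
    )
    qgap = QueryGap(contig_id, gap[0], gap[1], gap_sequence)
    return Candidate(
        contig_id=contig_id,
        kind="gap",
        topology="duplication",
        alignment_pair=(host, realn),
        breakpoints=[(chrom, g_first, "+"), (chrom, g_last, "+")],
        contig_length=contig_length,
        inclusion=1.0,
        gap=qgap,
        piece_intervals=[copy1, (gap[0], gap[1] + 1)],
        duplicated_segment=(chrom, g_first, g_last + 1),
        inserted_bases=inserted_bases,
    )


def make_reads(intervals, target="c1", mismatch=False, prefix="r"):
    return [
        ReadAlignment(
            read_id=f"{prefix}{i}",
            target_id=target,
            target_start=s,
            target_end=e,
            has_mismatch=mismatch,
        )
        for i, (s, e) in enumerate(intervals)
    ]


def clean_annotation(**kw):
    defaults = dict(
        genes_a=["GA"],
        genes_b=["GB"],
        exon_boundary_match="both",
        repeat_overlap=False,
        segdup_overlap=False,
        struct_rna_overlap=False,
    )
    defaults.update(kw)
    return CandidateAnnotation(**defaults)


def clean_support(total=20, strong=20, region=(49, 61)):
    return ReadSupport(region_P=region, total_support=total, strong_support=strong)


def write_pipeline_inputs(
    dirpath,
    seed=7,
    n_genes=20,
    counts=None,
    coverage=30.0,
    read_length=75,
):
    """Write a complete synthetic input set for the file-based pipeline.

    Returns (paths dict, genome, events).
    """
    import os

    from chimerakit import formats, simulate

    counts = counts or {"fusion": 10, "PTD": 10, "ITD": 10}
    genome = simulate.simulate_genome(n_chroms=2, n_genes=n_genes, seed=seed)
    events = simulate.simulate_events(
        genome, counts, seed=seed + 1, read_length=read_length
    )
    used = {g for ev in events for g in ev.gene_ids}
    wildtype = [g for g in genome.genes if g.gene_id not in used]
    alignments, contigs = simulate.synthesize_alignments(genome, events, wildtype)
    transcripts = {ev.event_id: ev.transcript for ev in events}
    reads = simulate.simulate_reads(
        transcripts,
        {tid: coverage for tid in transcripts},
        read_length=read_length,
        seed=seed + 2,
        chimeric_ids=set(transcripts),
    )
    paths = {
        "genome": os.path.join(dirpath, "genome.fa"),
        "genes": os.path.join(dirpath, "genes.gpd"),
        "contigs": os.path.join(dirpath, "contigs.fa"),
        "psl": os.path.join(dirpath, "contigs.psl"),
        "r2c": os.path.join(dirpath, "reads_to_contigs.sam"),
        "out": os.path.join(dirpath, "out"),
    }
    formats.write_fasta(genome.sequences, paths["genome"])
    formats.write_genepredext(genome.genes, paths["genes"])
    formats.write_fasta(contigs, paths["contigs"])
    formats.write_psl(alignments, paths["psl"])
    sam_records = []
    for ev in events:
        sam_records.extend(
            simulate.reads_to_contig_records(ev, reads, read_length=read_length)
        )
    refs = [(cid, len(seq)) for cid, seq in sorted(contigs.items())]
    formats.write_sam(sam_records, refs, paths["r2c"])
    return paths, genome, events


def match_prediction_to_truth(pred, events, tolerance=10):
    """True prediction iff type matches and breakpoints agree within the
    grouping tolerance (junction homology makes exact positions ambiguous)."""
    pb = sorted((c, p) for c, p, _ in pred.breakpoints)
    for ev in events:
        if pred.event_type != ev.event_type:
            continue
        tb = sorted(ev.breakpoints)
        if all(
            c1 == c2 and abs(p1 - p2) <= tolerance
            for (c1, p1), (c2, p2) in zip(pb, tb)
        ):
            return ev
    return None


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def two_exon_gene():
    return GeneModel(
        gene_id="GX",
        transcript_id="TX",
        chrom="chr1",
        strand="+",
        exons=[(1000, 1200), (1500, 1800), (2100, 2400)],
    )
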