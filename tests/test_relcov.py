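"""Flank regions, depth partitioning, and the relative-coverage formula."""

import math

import pytest

from chimerakit.formats import GeneModel, ReadAlignment
from chimerakit.predict import classify_event
from chimerakit.relcov import (
    DepthPartition,
    FlankRegion,
    depth_partition,
    flanking_regions,
    relative_coverage,
)

from conftest import clean_annotation, make_gap_candidate, make_split_candidate


# ---------------------------------------------------------------------------
# flank regions
# ---------------------------------------------------------------------------


def _fusion_candidate(len_a=400, len_b=400):
    return make_split_candidate(
        piece_a=((0, len_a), "chr1", 1000, "+"),
        piece_b=((len_a, len_a + len_b), "chr2", 5000, "+"),
        contig_length=len_a + len_b,
    )


def test_long_blocks_cut_to_twice_read_length():
    cand = _fusion_candidate()
    a, b = flanking_regions(cand, 75)
    assert a.total_length == 150 and b.total_length == 150
    # region A keeps the block end adjacent to the breakpoint (1399)
    assert a.blocks == [(1250, 1400)]
    # region B starts at its breakpoint (5000)
    assert b.blocks == [(5000, 5150)]
    assert not a.truncated and not b.truncated


def test_split_blocks_trimmed_from_far_end():
    cand = make_split_candidate(
        piece_a=((0, 230), "chr1", 1000, "+"),
        piece_b=((230, 630), "chr2", 5000, "+"),
        contig_length=630,
    )
    # side A: exon blocks of 200 + 30, junction after the 30 nt block:
    # the region keeps the 30 nt block plus 120 nt of the other
    cand.alignment_pair[0].blocks[:] = [(0, 1000, 200), (200, 1400, 30)]
    a, _ = flanking_regions(cand, 75)
    assert a.total_length == 150
    assert a.blocks == [(1080, 1200), (1400, 1430)]


def test_short_terminal_region_truncated_and_flagged():
    cand = make_split_candidate(
        piece_a=((0, 80), "chr1", 1000, "+"),
        piece_b=((80, 480), "chr2", 5000, "+"),
        contig_length=480,
    )
    a, b = flanking_regions(cand, 75, gene_models=[])
    assert a.total_length == 80 and a.truncated
    assert b.total_length == 150 and not b.truncated


def test_region_extends_along_gene_model():
    gene = GeneModel(
        gene_id="GA", transcript_id="TA", chrom="chr1", strand="+",
        exons=[(500, 700), (1000, 1080)],
    )
    cand = make_split_candidate(
        piece_a=((0, 80), "chr1", 1000, "+"),  # covers only the 80 nt exon
        piece_b=((80, 480), "chr2", 5000, "+"),
        contig_length=480,
    )
    a, _ = flanking_regions(cand, 75, gene_models=[gene])
    assert a.total_length == 150
    assert a.blocks == [(630, 700), (1000, 1080)]
    assert not a.truncated


def test_duplication_regions_extend_outward_from_segment():
    cand = make_gap_candidate(
        copy1=(100, 120), gap=(120, 139), contig_length=400, genome_offset=1000
    )
    gene = GeneModel(
        gene_id="GA", transcript_id="TA", chrom="chr1", strand="+",
        exons=[(700, 1400)],
    )
    # duplicated genomic segment is [1100, 1120)
    a, b = flanking_regions(cand, 75, gene_models=[gene])
    assert all(e <= 1100 for _, e in a.blocks)
    assert all(s >= 1120 for s, _ in b.blocks)
    assert a.total_length == 150 and b.total_length == 150


def test_invalid_read_length_raises():
    with pytest.raises(ValueError):
        flanking_regions(_fusion_candidate(), 0)


# ---------------------------------------------------------------------------
# relative-coverage formula (closed-form checks)
# ---------------------------------------------------------------------------


def _uniform_partition(label, chrom, start, length, dw=0, t1=0, t2=0):
    region = FlankRegion(label=label, chrom=chrom, blocks=[(start, start + length)])
    part = DepthPartition(region=region)
    for s in range(start, start + length):
        if dw:
            part.dw[s] = dw
        if t1:
            part.t1[s] = t1
        if t2:
            part.t2[s] = t2
    return part


def test_uniform_t1_closed_form():
    """C=5 with T1=15 everywhere: W = 15-5 = 10, C/W* = 0.5, C/T* = 1/3."""
    pa = _uniform_partition("A", "chr1", 100, 50, t1=15)
    pb = _uniform_partition("B", "chr1", 300, 50, t1=15)
    rc = relative_coverage(5, pa, pb)
    assert rc.W_star == 10 and rc.T_star == 15
    assert rc.ratios["C_over_W_star"] == pytest.approx(0.5)
    assert rc.ratios["C_over_T_star"] == pytest.approx(1 / 3)
    assert rc.W_A == rc.W_B == 10 and rc.T_A == rc.T_B == 15


def test_duplicated_segment_t2_closed_form():
    """C=5 at a T2=20 position: W = 20 - 2*5 = 10."""
    pa = _uniform_partition("A", "chr1", 100, 50, t2=20)
    pb = _uniform_partition("B", "chr1", 300, 50, t1=15)
    rc = relative_coverage(5, pa, pb)
    assert rc.W_A == 10.0
    assert rc.T_A == 20.0


def test_dw_only_positions_report_full_depth_as_wildtype():
    pa = _uniform_partition("A", "chr1", 100, 50, dw=12)
    pb = _uniform_partition("B", "chr1", 300, 50, dw=12)
    rc = relative_coverage(5, pa, pb)
    assert rc.W_star == 12 and rc.T_star == 12


def test_negative_w_clamped_and_flagged():
    pa = _uniform_partition("A", "chr1", 100, 10, t1=3)
    pb = _uniform_partition("B", "chr1", 300, 10, t1=3)
    rc = relative_coverage(10, pa, pb)
    assert rc.W_star == 0.0 and rc.clamped
    assert math.isinf(rc.ratios["C_over_W_star"])


def test_w_never_exceeds_t(rng):
    for _ in range(50):
        pa = _uniform_partition(
            "A", "chr1", 0, 20,
            dw=int(rng.integers(0, 5)),
            t1=int(rng.integers(0, 20)),
            t2=int(rng.integers(0, 20)),
        )
        pb = _uniform_partition("B", "chr1", 100, 20, t1=int(rng.integers(0, 20)))
        C = int(rng.integers(0, 10))
        rc = relative_coverage(C, pa, pb)
        for part, (w, t) in ((pa, (rc.W_A, rc.T_A)), (pb, (rc.W_B, rc.T_B))):
            assert w <= t or t == 0
    # W equals T when T1 = T2 = 0 (pure wild-type evidence)
    pa = _uniform_partition("A", "chr1", 0, 20, dw=9)
    pb = _uniform_partition("B", "chr1", 100, 20, dw=9)
    rc = relative_coverage(4, pa, pb)
    assert rc.W_star == rc.T_star == 9


# ---------------------------------------------------------------------------
# depth partition classification
# ---------------------------------------------------------------------------


def _tile_reads(chrom, start, end, depth, read_len=40):
    """Reads tiling [start, end) with ~uniform coverage `depth`."""
    reads = []
    k = 0
    step = max(1, read_len // depth)
    pos = start - read_len
    while pos < end:
        for _ in range(max(1, depth * step // read_len)):
            reads.append(
                ReadAlignment(f"t{k}", chrom, pos, pos + read_len, False)
            )
            k += 1
        pos += step
    return reads


def test_uniform_coverage_without_duplication_is_all_t1():
    cand = _fusion_candidate()
    ann = clean_annotation(genes_a=["GA"], genes_b=["GB"], exon_boundary_match="neither")
    pred = classify_event(cand, ann)
    region = FlankRegion(label="A", chrom="chr1", blocks=[(1250, 1400)])
    reads = [
        ReadAlignment(f"r{i}", "chr1", s, s + 60, False)
        for i, s in enumerate(range(1100, 1400, 4))
    ]
    part = depth_partition(region, pred, reads, q=5)
    some = [s for s in region.positions() if part.total(s) > 0]
    assert some
    for s in some:
        assert part.t2.get(s, 0) == 0
        assert part.total(s) == part.t1.get(s, 0) + part.dw.get(s, 0)


def test_positions_inside_duplicated_segment_accrue_t2():
    cand = make_gap_candidate(
        copy1=(100, 120), gap=(120, 139), contig_length=400, genome_offset=1000
    )
    ann = clean_annotation(genes_a=["GA"], genes_b=["GA"], exon_boundary_match="neither")
    pred = classify_event(cand, ann)
    seg = pred.duplicated_segment  # (chr1, 1100, 1120)
    region = FlankRegion(label="A", chrom="chr1", blocks=[(1090, 1130)])
    reads = [
        ReadAlignment(f"r{i}", "chr1", s, s + 60, False)
        for i, s in enumerate(range(1000, 1130, 3))
    ]
    part = depth_partition(region, pred, reads, q=5, junction_at_end=True)
    for s in region.positions():
        if seg[1] <= s < seg[2]:
            assert part.t1.get(s, 0) == 0
            assert part.t2.get(s, 0) > 0
        else:
            assert part.t2.get(s, 0) == 0


def test_fusion_reads_spanning_destroyed_junction_are_dw():
    cand = _fusion_candidate()
    ann = clean_annotation(genes_a=["GA"], genes_b=["GB"], exon_boundary_match="neither")
    pred = classify_event(cand, ann)
    bp_a = pred.breakpoints[0][1]  # 1399
    region = FlankRegion(label="A", chrom="chr1", blocks=[(1250, 1400)])
    spanning = [
        ReadAlignment(f"w{i}", "chr1", bp_a - 30, bp_a + 31, False)
        for i in range(4)
    ]
    stopping = [
        ReadAlignment(f"c{i}", "chr1", bp_a - 59, bp_a + 1, False)
        for i in range(4)
    ]
    part = depth_partition(region, pred, spanning + stopping, q=5)
    s = bp_a - 10
    assert part.dw.get(s, 0) == 4  # wild-type-only junction spanners
    assert part.t1.get(s, 0) == 4  # chimera-compatible reads
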