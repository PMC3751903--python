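"""Alignment-set metrics, selection, topology, query gaps, gap realignment."""

import itertools

import numpy as np
import pytest

from chimerakit.align_select import (
    SelectionParams,
    alignment_set_metrics,
    classify_topology,
    detect_contig,
    find_query_gaps,
    group_by_overlap,
    make_candidates,
    realign_gap,
    select_alignment_sets,
)
from chimerakit.align_select import QueryGap
from chimerakit.simulate import revcomp, _random_seq

from conftest import make_aln


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def test_single_full_coverage_alignment_metrics():
    a = make_aln([(0, 1000, 100)], 100, quality=1.0)
    m = alignment_set_metrics([a], 100)
    assert (m.quality, m.inclusion, m.overlap, m.size) == (1.0, 1.0, 0.0, 1)
    assert m.score == 1.0


def test_two_overlapping_alignments_metrics():
    a = make_aln([(0, 1000, 60)], 100, quality=0.9)
    b = make_aln([(40, 5000, 60)], 100, quality=0.9)
    m = alignment_set_metrics([a, b], 100)
    assert m.quality == pytest.approx(1.8)
    assert m.inclusion == pytest.approx(1.0)
    assert m.overlap == pytest.approx(0.2)
    assert m.size == 2
    assert m.score == pytest.approx(0.6)


def test_empty_set_raises():
    with pytest.raises(ValueError):
        alignment_set_metrics([], 100)


def _random_alignment_set(rng, contig_length):
    n = int(rng.integers(1, 6))
    alns = []
    for _ in range(n):
        start = int(rng.integers(0, contig_length - 10))
        length = int(rng.integers(5, contig_length - start + 1))
        alns.append(
            make_aln(
                [(start, int(rng.integers(0, 10000)), length)],
                contig_length,
                quality=float(rng.random()),
            )
        )
    return alns


def test_metrics_match_per_position_brute_force(rng):
    """inclusion/overlap equal an independent per-position tally (numpy)."""
    for _ in range(200):
        contig_length = int(rng.integers(20, 201))
        alns = _random_alignment_set(rng, contig_length)
        m = alignment_set_metrics(alns, contig_length)
        tally = np.zeros(contig_length, dtype=int)
        for a in alns:
            for c, _, n in a.blocks:
                tally[c : c + n] += 1
        assert m.inclusion == pytest.approx((tally >= 1).mean())
        assert m.overlap == pytest.approx((tally >= 2).mean())
        assert m.quality == pytest.approx(sum(a.quality for a in alns))
        assert m.score == pytest.approx(
            m.quality + m.inclusion - m.overlap - m.size
        )
        assert 0 <= m.overlap <= m.inclusion <= 1


# ---------------------------------------------------------------------------
# query gaps
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "blocks,contig_length,expected",
    [
        ([(0, 0, 40), (60, 100, 40)], 100, [(40, 59)]),
        ([(10, 0, 90)], 100, [(0, 9)]),  # edge gap at the contig start
        ([(0, 0, 100)], 100, []),
        ([(0, 0, 10), (20, 50, 10)], 40, [(10, 19), (30, 39)]),
    ],
)
def test_find_query_gaps(blocks, contig_length, expected):
    a = make_aln(blocks, contig_length)
    gaps = find_query_gaps(a, contig_length)
    assert [(g.start, g.end) for g in gaps] == expected


def test_query_gap_positions_are_exactly_the_unaligned_set(rng):
    for _ in range(50):
        contig_length = int(rng.integers(20, 120))
        alns = _random_alignment_set(rng, contig_length)
        a = alns[0]
        gaps = find_query_gaps(a, contig_length)
        gap_positions = set()
        for g in gaps:
            gap_positions.update(range(g.start, g.end + 1))
        assert gap_positions == set(range(contig_length)) - a.aligned_positions()


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


def test_case_i_high_inclusion_gap_free():
    a = make_aln([(0, 0, 99)], 100, quality=1.0)
    case, sets, flags = select_alignment_sets([a], 100)
    assert case == "I"


def test_case_iii_pair_selected_over_noise():
    """Two high-quality, low-overlap alignments jointly covering the contig
    win over partially overlapping lower-quality alternatives."""
    good1 = make_aln([(0, 1000, 52)], 100, quality=1.0, chrom="chr1")
    good2 = make_aln([(52, 9000, 48)], 100, quality=1.0, chrom="chr2")
    # middle alignments overlap each other (> threshold) but each good
    # alignment by at most the threshold, so they form their own group
    noise = [
        make_aln([(45, 3000, 17)], 100, quality=0.6),
        make_aln([(44, 4000, 17)], 100, quality=0.5),
        make_aln([(43, 6000, 17)], 100, quality=0.7),
    ]
    case, sets, flags = select_alignment_sets([good1, *noise, good2], 100)
    assert case == "III"
    chosen = sets[0]
    assert {a.genome_start for a in chosen} == {1000, 9000}


def test_case_iv_three_disjoint_groups():
    thirds = [
        make_aln([(0, 1000, 33)], 100, quality=1.0),
        make_aln([(33, 5000, 33)], 100, quality=1.0),
        make_aln([(66, 9000, 34)], 100, quality=1.0),
    ]
    case, sets, flags = select_alignment_sets(thirds, 100)
    assert case == "IV"
    assert make_candidates("c1", 100, case, sets, flags) == []


def test_multimap_window_marks_sets():
    a1 = make_aln([(0, 1000, 50)], 100, quality=1.0)
    a2 = make_aln([(0, 3000, 50)], 100, quality=0.97)  # within 0.05 window
    b = make_aln([(50, 9000, 50)], 100, quality=1.0, chrom="chr2")
    case, sets, flags = select_alignment_sets([a1, a2, b], 100)
    assert case == "III"
    assert all(flags)
    assert len(sets) == 2  # the alternate pairing is kept as a parallel set


def _enumerate_partition_subsets(alignments, groups):
    """All subsets taking at most one member per overlap group."""
    options = [[None] + g for g in groups]
    for combo in itertools.product(*options):
        chosen = [i for i in combo if i is not None]
        if chosen:
            yield chosen


def test_selection_score_matches_partition_restricted_enumeration(rng):
    """The chosen set's score equals the max over all subsets respecting the
    overlap partition (exhaustive oracle, <=6 alignments)."""
    params = SelectionParams()
    for _ in range(100):
        contig_length = int(rng.integers(30, 150))
        alns = _random_alignment_set(rng, contig_length)
        groups = group_by_overlap(alns, contig_length, params.overlap_group_min)
        best = max(
            alignment_set_metrics([alns[i] for i in chosen], contig_length).score
            for chosen in _enumerate_partition_subsets(alns, groups)
        )
        case, sets, flags = select_alignment_sets(alns, contig_length, params)
        if case == "I":
            continue  # shortcut bypasses score maximization by design
        got = alignment_set_metrics(sets[0], contig_length).score
        assert got == pytest.approx(best)


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "a_kw,b_kw,expected",
    [
        (dict(chrom="chr1"), dict(chrom="chr2"), "interchromosomal"),
        (dict(strand="+"), dict(strand="-"), "inversion"),
        (
            dict(blocks=[(0, 5000, 50)]),
            dict(blocks=[(50, 4800, 50)]),
            "eversion",
        ),
        (
            dict(blocks=[(0, 5000, 100)]),
            dict(blocks=[(50, 5000, 100)]),
            "duplication",
        ),
        (
            dict(blocks=[(0, 4800, 50)]),
            dict(blocks=[(50, 5000, 50)]),
            "read_through",
        ),
    ],
)
def test_classify_topology(a_kw, b_kw, expected):
    defaults = dict(blocks=[(0, 5000, 50)], contig_length=150, chrom="chr1", strand="+")
    a = make_aln(**{**defaults, **a_kw})
    b_defaults = dict(blocks=[(50, 5100, 50)], contig_length=150, chrom="chr1", strand="+")
    b = make_aln(**{**b_defaults, **b_kw})
    assert classify_topology(a, b) == expected


def test_topology_is_total_and_single_valued(rng):
    labels = {"interchromosomal", "inversion", "eversion", "duplication", "read_through"}
    for _ in range(200):
        a = make_aln(
            [(0, int(rng.integers(0, 1000)), 50)],
            120,
            chrom=f"chr{int(rng.integers(1, 3))}",
            strand="+-"[int(rng.integers(0, 2))],
        )
        b = make_aln(
            [(60, int(rng.integers(0, 1000)), 50)],
            120,
            chrom=f"chr{int(rng.integers(1, 3))}",
            strand="+-"[int(rng.integers(0, 2))],
        )
        assert classify_topology(a, b) in labels


def test_minus_strand_eversion_orientation():
    # on '-' alignments, contig order ascending maps to descending genome,
    # so ascending genome order is the reversed (everted) layout
    a = make_aln([(0, 4800, 50)], 120, strand="-")
    b = make_aln([(60, 5000, 50)], 120, strand="-")
    assert classify_topology(a, b) == "eversion"
    a2 = make_aln([(0, 5000, 50)], 120, strand="-")
    b2 = make_aln([(60, 4800, 50)], 120, strand="-")
    assert classify_topology(a2, b2) == "read_through"


# ---------------------------------------------------------------------------
# gap realignment
# ---------------------------------------------------------------------------


def test_realign_gap_finds_exact_duplication(rng):
    prefix = _random_seq(rng, 40)
    dup = _random_seq(rng, 20)
    suffix = _random_seq(rng, 40)
    contig = prefix + dup + dup + suffix
    host = make_aln([(0, 0, 60), (80, 60, 40)], len(contig))
    gap = QueryGap("c1", 60, 79, dup)
    r = realign_gap(contig, gap, host)
    assert r is not None and r.kind == "duplication"
    assert r.target_interval == (40, 60)
    assert r.identity == pytest.approx(100.0)


def test_realign_gap_finds_inversion(rng):
    genome = _random_seq(rng, 400)
    contig = genome[0:100] + revcomp(genome[120:160]) + genome[200:260]
    host = make_aln([(0, 0, 100), (140, 200, 60)], len(contig))
    gap = QueryGap("c1", 100, 139, contig[100:140])

    def fetch(chrom, s, e):
        return genome[s:e]

    r = realign_gap(contig, gap, host, genome_fetcher=fetch)
    assert r is not None and r.kind == "inversion"
    g0, g1 = r.target_interval
    assert (g0, g1) == (120, 160)


def test_realign_gap_random_sequence_matches_nothing(rng):
    contig = _random_seq(rng, 60) + _random_seq(rng, 30) + _random_seq(rng, 60)
    host = make_aln([(0, 0, 60), (90, 60, 60)], 150)
    gap = QueryGap("c1", 60, 89, contig[60:90])
    r = realign_gap(contig, gap, host, genome_fetcher=lambda c, s, e: "T" * (e - s))
    assert r is None


def test_realign_gap_never_matches_itself(rng):
    """The gap is excised from the duplication target, so a gap with no
    second copy elsewhere cannot 'find itself'."""
    prefix = _random_seq(rng, 50)
    unique = _random_seq(rng, 25)
    suffix = _random_seq(rng, 50)
    contig = prefix + unique + suffix
    host = make_aln([(0, 0, 50), (75, 50, 50)], len(contig))
    gap = QueryGap("c1", 50, 74, unique)
    r = realign_gap(contig, gap, host)
    assert r is None


def test_realign_gap_out_of_range_raises():
    with pytest.raises(ValueError):
        realign_gap("ACGT", QueryGap("c1", 2, 10, ""), make_aln([(0, 0, 4)], 4))


# ---------------------------------------------------------------------------
# candidate construction
# ---------------------------------------------------------------------------


def test_split_candidate_requires_inclusion_above_min():
    a = make_aln([(0, 1000, 52)], 100, chrom="chr1")
    b = make_aln([(52, 9000, 43)], 100, chrom="chr2")  # joint inclusion 0.95
    cands = make_candidates("c1", 100, "III", [[a, b]], [False])
    assert len(cands) == 1 and cands[0].kind == "split"
    b_low = make_aln([(52, 9000, 30)], 100, chrom="chr2")  # inclusion 0.82
    assert make_candidates("c1", 100, "III", [[a, b_low]], [False]) == []


def test_gap_candidate_duplication_topology(rng):
    prefix = _random_seq(rng, 100)
    dup = _random_seq(rng, 20)
    suffix = _random_seq(rng, 100)
    contig = prefix + dup + dup + suffix
    host = make_aln([(0, 500, 120), (140, 620, 100)], len(contig))
    cands = make_candidates(
        "c1", len(contig), "II", [[host]], [False], contig_sequence=contig
    )
    assert len(cands) == 1
    c = cands[0]
    assert c.kind == "gap" and c.topology == "duplication"
    # duplicated segment: genomic span of the first copy
    assert c.duplicated_segment == ("chr1", 600, 620)
    assert c.breakpoints == [("chr1", 600, "+"), ("chr1", 619, "+")]


def test_mitochondrial_alignments_dropped():
    a = make_aln([(0, 1000, 52)], 100, chrom="chrM")
    b = make_aln([(52, 9000, 48)], 100, chrom="chr2")
    assert make_candidates("c1", 100, "III", [[a, b]], [False]) == []
    assert (
        detect_contig("c1", [a, b], 100) == []
    )


def test_candidate_inherits_multimapping_flag():
    a = make_aln([(0, 1000, 52)], 100, chrom="chr1")
    b = make_aln([(52, 9000, 48)], 100, chrom="chr2")
    (cand,) = make_candidates("c1", 100, "III", [[a, b]], [True])
    assert cand.multimapping
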