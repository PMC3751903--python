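"""Alignment-set selection and candidate identification (pipeline stage 1.1).

For each assembled contig we hold a set of contig-to-genome alignments
A(C) and must decide which subset best explains the contig. The score of a
subset is

    score(A) = quality(A) + inclusion(A) - overlap(A) - size(A)

where quality is the sum of member qualities (each in [0, 1]), inclusion is
the fraction of contig positions covered by at least one member, overlap the
fraction covered by more than one, and size the member count. Selection
yields one of four cases: a single gap-free alignment (non-chimeric), a
single gapped alignment (potential gap-candidate), a pair (potential
split-candidate), or more than two (not characterized).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

from Bio import Align
from Bio.Seq import reverse_complement

from .formats import MITO_NAMES, ContigAlignment

# Topology labels. The four canonical labels plus read_through for
# same-chromosome, same-strand, collinear-order disjoint pairs
# (deletion-style intrachromosomal junctions), keeping classification total.
INTERCHROMOSOMAL = "interchromosomal"
INVERSION = "inversion"
EVERSION = "eversion"
DUPLICATION = "duplication"
READ_THROUGH = "read_through"


@dataclass
class SelectionParams:
    case1_inclusion_min: float = 0.95
    overlap_group_min: float = 0.10  # fraction of contig length
    multimap_quality_window: float = 0.05
    min_gap_length: int = 4
    gap_quality_min: float = 0.90
    gap_inclusion_min: float = 0.90
    split_inclusion_min: float = 0.90
    realign_min_fraction: float = 0.90
    realign_min_identity: float = 95.0
    discard_mito: bool = True
    mito_names: frozenset = MITO_NAMES
    exhaustive_limit: int = 4096


@dataclass
class AlignmentSetMetrics:
    quality: float
    inclusion: float
    overlap: float
    size: int
    score: float


@dataclass
class QueryGap:
    """A maximal run of unaligned contig positions; start/end inclusive."""

    contig_id: str
    start: int
    end: int
    gap_sequence: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GapRealignment:
    kind: str  # duplication | inversion
    target_interval: Tuple[int, int]  # contig coords (dup) or genome coords (inv)
    identity: float
    aligned_fraction: float
    chrom: Optional[str] = None  # inversion target chromosome
    realigned_sequence: str = ""
    conflict: bool = False  # both duplication and inversion succeeded


@dataclass
class Candidate:
    contig_id: str
    kind: str  # gap | split
    topology: str
    alignment_pair: tuple  # (ContigAlignment, ContigAlignment | GapRealignment)
    breakpoints: List[Tuple[str, int, str]]  # (chrom, 0-based position, strand)
    multimapping: bool = False
    contig_overlap_nt: int = 0
    contig_length: int = 0
    inclusion: float = 0.0
    gap: Optional[QueryGap] = None
    # contig intervals of the two pieces, used for read-support regions
    piece_intervals: List[Tuple[int, int]] = field(default_factory=list)
    # duplicated segment in genome coordinates (PTD/ITD)
    duplicated_segment: Optional[Tuple[str, int, int]] = None
    inserted_bases: int = 0
    group_ids: List[int] = field(default_factory=list)

    @property
    def id(self) -> str:
        bp = ";".join(f"{c}:{p}:{s}" for c, p, s in self.breakpoints)
        return f"{self.contig_id}|{self.kind}|{self.topology}|{bp}"


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def alignment_set_metrics(
    alignments: Sequence[ContigAlignment], contig_length: int
) -> AlignmentSetMetrics:
    """Per-position tally of inclusion/overlap plus summed quality and size."""
    if not alignments:
        raise ValueError("metrics undefined for an empty alignment set")
    if contig_length <= 0:
        raise ValueError("contig_length must be positive")
    counts = [0] * contig_length
    for a in alignments:
        for pos in a.aligned_positions():
            counts[pos] += 1
    covered = sum(1 for c in counts if c >= 1)
    multi = sum(1 for c in counts if c >= 2)
    quality = sum(a.quality for a in alignments)
    inclusion = covered / contig_length
    overlap = multi / contig_length
    size = len(alignments)
    return AlignmentSetMetrics(
        quality=quality,
        inclusion=inclusion,
        overlap=overlap,
        size=size,
        score=quality + inclusion - overlap - size,
    )


def pairwise_overlap_fraction(
    a: ContigAlignment, b: ContigAlignment, contig_length: int
) -> float:
    """Fraction of contig positions aligned in both a and b."""
    return len(a.aligned_positions() & b.aligned_positions()) / contig_length


# ---------------------------------------------------------------------------
# query gaps
# ---------------------------------------------------------------------------


def find_query_gaps(
    alignment: ContigAlignment, contig_length: int, contig_sequence: str = ""
) -> List[QueryGap]:
    """Maximal runs of unaligned contig positions, including contig edges."""
    aligned = alignment.aligned_positions()
    gaps: List[QueryGap] = []
    start = None
    for pos in range(contig_length):
        if pos not in aligned:
            if start is None:
                start = pos
        elif start is not None:
            gaps.append(_make_gap(alignment.contig_id, start, pos - 1, contig_sequence))
            start = None
    if start is not None:
        gaps.append(
            _make_gap(alignment.contig_id, start, contig_length - 1, contig_sequence)
        )
    return gaps


def _make_gap(contig_id: str, i: int, j: int, seq: str) -> QueryGap:
    return QueryGap(
        contig_id=contig_id,
        start=i,
        end=j,
        gap_sequence=seq[i : j + 1] if seq else "",
    )


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


def group_by_overlap(
    alignments: Sequence[ContigAlignment],
    contig_length: int,
    overlap_group_min: float,
) -> List[List[int]]:
    """Transitive grouping of alignments by pairwise contig overlap."""
    n = len(alignments)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    positions = [a.aligned_positions() for a in alignments]
    for i in range(n):
        for j in range(i + 1, n):
            ov = len(positions[i] & positions[j]) / contig_length
            if ov > overlap_group_min:
                parent[find(i)] = find(j)
    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: min(g))


def select_alignment_sets(
    alignments: Sequence[ContigAlignment],
    contig_length: int,
    params: Optional[SelectionParams] = None,
) -> Tuple[str, List[List[ContigAlignment]], List[bool]]:
    """Choose the alignment subset(s) best explaining the contig.

    Returns ``(case, sets, multimap_flags)`` where case is one of
    ``'I'``/``'II'``/``'III'``/``'IV'``, each set is an alignment subset to
    process further, and the per-set flag marks multi-mapping (another
    alignment within the quality window could substitute for a member).
    """
    if not alignments:
        raise ValueError("select_alignment_sets requires at least one alignment")
    params = params or SelectionParams()

    # Case I shortcut: a single high-inclusion alignment without a
    # significant query gap is non-chimeric.
    for a in alignments:
        m = alignment_set_metrics([a], contig_length)
        if m.inclusion > params.case1_inclusion_min:
            gaps = [
                g
                for g in find_query_gaps(a, contig_length)
                if g.length >= params.min_gap_length
            ]
            if not gaps:
                return ("I", [[a]], [False])

    groups = group_by_overlap(alignments, contig_length, params.overlap_group_min)

    # Within each group, the top-quality member plus any within the quality
    # window are kept; more than one kept member marks multi-mapping.
    kept_per_group: List[List[int]] = []
    multimap_per_group: List[bool] = []
    for g in groups:
        best_q = max(alignments[i].quality for i in g)
        kept = [
            i
            for i in g
            if alignments[i].quality >= best_q - params.multimap_quality_window
        ]
        kept.sort(key=lambda i: (-alignments[i].quality, i))
        kept_per_group.append(kept)
        multimap_per_group.append(len(kept) > 1)

    # Choose the scoring-optimal combination: at most one member per group,
    # at least one member overall. Exhaustive over all group members when
    # the search space is small; otherwise best quality per group.
    n_combos = 1
    for g in groups:
        n_combos *= len(g) + 1
    best_choice = None
    best_score = None
    if n_combos <= params.exhaustive_limit:
        options = [[None] + g for g in groups]
        for combo in itertools.product(*options):
            chosen = [i for i in combo if i is not None]
            if not chosen:
                continue
            m = alignment_set_metrics([alignments[i] for i in chosen], contig_length)
            key = (m.score, sum(alignments[i].quality for i in chosen))
            if best_score is None or key > best_score:
                best_score = key
                best_choice = chosen
    if best_choice is None:
        # fallback: highest-quality member of every group
        best_choice = [kept[0] for kept in kept_per_group]

    group_of = {}
    for gi, g in enumerate(groups):
        for i in g:
            group_of[i] = gi
    chosen_groups = sorted({group_of[i] for i in best_choice})

    n = len(best_choice)
    case = "II" if n == 1 else ("III" if n == 2 else "IV")

    # Expand multi-mapping alternates into parallel sets: for each chosen
    # group, the chosen member plus any kept (within-quality-window) members.
    sets: List[List[ContigAlignment]] = []
    flags: List[bool] = []
    alternates = []
    for gi in chosen_groups:
        chosen_member = next(i for i in best_choice if group_of[i] == gi)
        alts = [chosen_member] + [i for i in kept_per_group[gi] if i != chosen_member]
        alternates.append(alts)
    mm = any(len(a) > 1 for a in alternates)
    for combo in itertools.product(*alternates):
        ordered = sorted(combo, key=lambda i: alignments[i].contig_start)
        sets.append([alignments[i] for i in ordered])
        flags.append(mm)
        if len(sets) >= 16:  # cap the multi-mapping expansion
            break

    if case == "II":
        # single-alignment set; re-check for Case I (no significant gap)
        single = sets[0][0]
        gaps = [
            g
            for g in find_query_gaps(single, contig_length)
            if g.length >= params.min_gap_length
        ]
        if not gaps and alignment_set_metrics([single], contig_length).inclusion > params.case1_inclusion_min:
            case = "I"
    return (case, sets, flags)


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------


def classify_topology(aln_a: ContigAlignment, aln_b: ContigAlignment) -> str:
    """Label the geometric relation between two contig pieces on the genome.

    The pair must be ordered by contig coordinate (aln_a first on the
    contig). Every ordered pair receives exactly one label.
    """
    if aln_a.chrom != aln_b.chrom:
        return INTERCHROMOSOMAL
    if aln_a.strand != aln_b.strand:
        return INVERSION
    a_start, a_end = aln_a.genome_interval
    b_start, b_end = aln_b.genome_interval
    if a_start < b_end and b_start < a_end:
        return DUPLICATION
    # disjoint, same chrom + strand: eversion iff genome order is reversed
    # relative to contig order (strand-aware)
    if aln_a.strand == "+":
        return EVERSION if b_end <= a_start else READ_THROUGH
    return EVERSION if a_end <= b_start else READ_THROUGH


# ---------------------------------------------------------------------------
# gap realignment
# ---------------------------------------------------------------------------


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def _best_local(query: str, target: str):
    """Best local alignment of query vs target -> (identity%, fraction, t0, t1)."""
    if not query or not target:
        return None
    aligner = _local_aligner()
    try:
        aln = aligner.align(query, target)[0]
    except (IndexError, ValueError):
        return None
    q_blocks, t_blocks = aln.aligned[0], aln.aligned[1]
    matches = 0
    aligned_len = 0
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        aligned_len += qe - qs
        matches += sum(
            1 for k in range(qe - qs) if query[qs + k].upper() == target[ts + k].upper()
        )
    if aligned_len == 0:
        return None
    identity = 100.0 * matches / aligned_len
    fraction = (q_blocks[-1][1] - q_blocks[0][0]) / len(query)
    q_span = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    t_span = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    return identity, fraction, t_span, q_span


def realign_gap(
    contig_sequence: str,
    gap: QueryGap,
    host_alignment: ContigAlignment,
    genome_fetcher: Optional[Callable[[str, int, int], str]] = None,
    params: Optional[SelectionParams] = None,
) -> Optional[GapRealignment]:
    """Attempt the two gap realignments: duplication, then inversion.

    Duplication: the gap sequence is locally aligned against the contig with
    the gap excised (so the gap can never align to itself). Inversion (only
    for internal gaps): the gap is aligned against the reverse complement of
    the genomic window between the mates of the gap-flanking bases. A
    successful duplication takes precedence; a simultaneous inversion hit is
    recorded as a conflict.
    """
    params = params or SelectionParams()
    i, j = gap.start, gap.end
    if i < 0 or j >= len(contig_sequence) or i > j:
        raise ValueError(f"gap [{i},{j}] outside contig of length {len(contig_sequence)}")
    gap_seq = contig_sequence[i : j + 1]

    dup = None
    masked = contig_sequence[:i] + contig_sequence[j + 1 :]
    hit = _best_local(gap_seq, masked)
    if hit is not None:
        identity, fraction, (t0, t1), _ = hit
        if fraction >= params.realign_min_fraction and identity >= params.realign_min_identity:
            # map masked coordinates back to contig coordinates
            c0 = t0 if t0 < i else t0 + (j - i + 1)
            c1 = t1 if t1 <= i else t1 + (j - i + 1)
            dup = GapRealignment(
                kind=DUPLICATION,
                target_interval=(c0, c1),
                identity=identity,
                aligned_fraction=fraction,
                realigned_sequence=gap_seq,
            )

    inv = None
    internal = i > 0 and j < len(contig_sequence) - 1
    if internal and genome_fetcher is not None:
        gi = host_alignment.genome_position(i - 1)
        gj = host_alignment.genome_position(j + 1)
        if gi is not None and gj is not None:
            lo, hi = min(gi, gj), max(gi, gj) + 1
            window = genome_fetcher(host_alignment.chrom, lo, hi)
            hit = _best_local(gap_seq, reverse_complement(window))
            if hit is not None:
                identity, fraction, (t0, t1), _ = hit
                if (
                    fraction >= params.realign_min_fraction
                    and identity >= params.realign_min_identity
                ):
                    # flip back to forward-genome coordinates
                    g1 = hi - t0
                    g0 = hi - t1
                    inv = GapRealignment(
                        kind=INVERSION,
                        target_interval=(g0, g1),
                        identity=identity,
                        aligned_fraction=fraction,
                        chrom=host_alignment.chrom,
                        realigned_sequence=gap_seq,
                    )

    if dup is not None:
        if inv is not None:
            dup.conflict = True
        return dup
    return inv


# ---------------------------------------------------------------------------
# candidate construction
# ---------------------------------------------------------------------------


def _split_breakpoints(
    first: ContigAlignment, second: ContigAlignment
) -> List[Tuple[str, int, str]]:
    """Breakpoints of a split candidate: the genomic mates of the junction-
    flanking contig bases (last base of the first piece, first base of the
    second)."""
    bp_a = first.genome_position(first.contig_end - 1)
    bp_b = second.genome_position(second.contig_start)
    return [
        (first.chrom, int(bp_a), first.strand),
        (second.chrom, int(bp_b), second.strand),
    ]


def _contig_overlap_nt(a: ContigAlignment, b: ContigAlignment) -> int:
    s = max(a.contig_start, b.contig_start)
    e = min(a.contig_end, b.contig_end)
    return max(0, e - s)


def make_candidates(
    contig_id: str,
    contig_length: int,
    case: str,
    sets: Sequence[Sequence[ContigAlignment]],
    multimap_flags: Sequence[bool],
    contig_sequence: str = "",
    genome_fetcher: Optional[Callable[[str, int, int], str]] = None,
    params: Optional[SelectionParams] = None,
) -> List[Candidate]:
    """Turn selected alignment sets into gap-/split-candidates.

    Case II sets go through gap realignment; Case III sets become split
    candidates when their joint inclusion passes the minimum. Alignments to
    mitochondrial sequence are discarded by default.
    """
    params = params or SelectionParams()
    out: List[Candidate] = []
    if case in ("I", "IV"):
        return out
    for aln_set, mm in zip(sets, multimap_flags):
        if params.discard_mito and any(a.chrom in params.mito_names for a in aln_set):
            continue
        if case == "II" and len(aln_set) == 1:
            out.extend(
                _gap_candidates(
                    contig_id,
                    contig_length,
                    aln_set[0],
                    mm,
                    contig_sequence,
                    genome_fetcher,
                    params,
                )
            )
        elif case == "III" and len(aln_set) == 2:
            cand = _split_candidate(
                contig_id, contig_length, aln_set[0], aln_set[1], mm, params
            )
            if cand is not None:
                out.append(cand)
    return out


def _gap_candidates(
    contig_id: str,
    contig_length: int,
    aln: ContigAlignment,
    multimapping: bool,
    contig_sequence: str,
    genome_fetcher,
    params: SelectionParams,
) -> List[Candidate]:
    metrics = alignment_set_metrics([aln], contig_length)
    if aln.quality < params.gap_quality_min:
        return []
    if metrics.inclusion < params.gap_inclusion_min:
        return []
    out: List[Candidate] = []
    for gap in find_query_gaps(aln, contig_length, contig_sequence):
        if gap.length < params.min_gap_length:
            continue
        if not contig_sequence:
            continue
        re_aln = realign_gap(contig_sequence, gap, aln, genome_fetcher, params)
        if re_aln is None:
            continue
        if re_aln.kind == DUPLICATION:
            c0, c1 = re_aln.target_interval
            g_first = aln.genome_position(c0)
            g_last = aln.genome_position(c1 - 1)
            if g_first is None or g_last is None:
                continue
            lo, hi = min(g_first, g_last), max(g_first, g_last)
            breakpoints = [
                (aln.chrom, lo, aln.strand),
                (aln.chrom, hi, aln.strand),
            ]
            duplicated = (aln.chrom, lo, hi + 1)
            topology = DUPLICATION
            inserted = max(0, gap.length - (c1 - c0))
            pieces = [(c0, c1), (gap.start, gap.end + 1)]
        else:
            g0, g1 = re_aln.target_interval
            breakpoints = [
                (re_aln.chrom, g0, aln.strand),
                (re_aln.chrom, g1 - 1, aln.strand),
            ]
            duplicated = None
            topology = INVERSION
            inserted = 0
            pieces = [(gap.start, gap.end + 1), (gap.start, gap.end + 1)]
        out.append(
            Candidate(
                contig_id=contig_id,
                kind="gap",
                topology=topology,
                alignment_pair=(aln, re_aln),
                breakpoints=breakpoints,
                multimapping=multimapping,
                contig_overlap_nt=0,
                contig_length=contig_length,
                inclusion=min(1.0, metrics.inclusion + gap.length / contig_length),
                gap=gap,
                piece_intervals=pieces,
                duplicated_segment=duplicated,
                inserted_bases=inserted,
            )
        )
    return out


def _split_candidate(
    contig_id: str,
    contig_length: int,
    first: ContigAlignment,
    second: ContigAlignment,
    multimapping: bool,
    params: SelectionParams,
) -> Optional[Candidate]:
    metrics = alignment_set_metrics([first, second], contig_length)
    if metrics.inclusion <= params.split_inclusion_min:
        return None
    topology = classify_topology(first, second)
    breakpoints = _split_breakpoints(first, second)
    duplicated = None
    if topology in (DUPLICATION, EVERSION):
        lo = min(bp[1] for bp in breakpoints)
        hi = max(bp[1] for bp in breakpoints)
        duplicated = (first.chrom, lo, hi + 1)
    return Candidate(
        contig_id=contig_id,
        kind="split",
        topology=topology,
        alignment_pair=(first, second),
        breakpoints=breakpoints,
        multimapping=multimapping or first.multimapping or second.multimapping,
        contig_overlap_nt=_contig_overlap_nt(first, second),
        contig_length=contig_length,
        inclusion=metrics.inclusion,
        piece_intervals=[first.contig_interval, second.contig_interval],
        duplicated_segment=duplicated,
    )


def detect_contig(
    contig_id: str,
    alignments: Sequence[ContigAlignment],
    contig_length: int,
    contig_sequence: str = "",
    genome_fetcher=None,
    params: Optional[SelectionParams] = None,
) -> List[Candidate]:
    """Run selection + candidate construction for one contig."""
    params = params or SelectionParams()
    usable = list(alignments)
    if params.discard_mito:
        usable = [a for a in usable if a.chrom not in params.mito_names]
    if not usable:
        return []
    case, sets, flags = select_alignment_sets(usable, contig_length, params)
    return make_candidates(
        contig_id,
        contig_length,
        case,
        sets,
        flags,
        contig_sequence=contig_sequence,
        genome_fetcher=genome_fetcher,
        params=params,
    )
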