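"""Breakpoint search regions and read-to-contig support (pipeline stage 2).

Sequence homology around a chimeric junction can make the exact breakpoint
position ambiguous, so support is computed over a search region P on the
contig. At each position p in P, R(p) counts mismatch-free reads that
overlap p with at least ``min_flank`` bases on each side; the reported
support is min over p of R(p), guaranteeing that at least that many read
alignments span the breakpoint wherever it lies within P.

Reads mapping to several contigs are down-weighted: a read strongly supports
an event when at least half of its mapped contigs belong to the event's
contig group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Set, Tuple

from .align_select import Candidate
from .formats import ReadAlignment


@dataclass
class ReadSupport:
    region_P: Tuple[int, int]  # contig interval, 0-based half-open
    total_support: int
    strong_support: int
    min_flank: int = 5

    def __post_init__(self) -> None:
        assert 0 <= self.strong_support <= self.total_support


def breakpoint_region(candidate: Candidate) -> Tuple[int, int]:
    """Contig search region P for the candidate's breakpoint.

    Split candidates: the contig-coordinate overlap of the two alignments,
    extended by 1 nt on each side (abutting alignments degenerate to the two
    junction-flanking bases). Gap-duplication candidates: the region between
    the two copies of the duplicated sequence.
    """
    if candidate.kind == "split":
        (s1, e1), (s2, e2) = candidate.piece_intervals
        ov_start, ov_end = max(s1, s2), min(e1, e2)
        if ov_start > ov_end:  # disjoint pieces: span the uncovered junction
            ov_start, ov_end = ov_end, ov_start
        lo = max(0, ov_start - 1)
        hi = min(candidate.contig_length, ov_end + 1)
        return (lo, hi)
    # gap candidate
    if candidate.topology == "duplication":
        copies = sorted(candidate.piece_intervals)
        lo, hi = copies[0][1], copies[1][0]
        if lo < hi:
            return (lo, hi)
        pos = max(1, min(candidate.contig_length - 1, lo))
        return (pos - 1, pos + 1)
    # inversion gap: the gap itself plus one flanking base each side
    gap = candidate.gap
    lo = max(0, gap.start - 1)
    hi = min(candidate.contig_length, gap.end + 2)
    return (lo, hi)


def support_score(
    read_contigs: Set[str], event_contigs: Set[str]
) -> Tuple[float, bool]:
    """score(r, C) = |C(r) n E(C)| / |C(r)|; strong iff score >= 0.5."""
    if not read_contigs:
        raise ValueError("read maps to no contigs")
    score = len(read_contigs & event_contigs) / len(read_contigs)
    return score, score >= 0.5


def _qualifies(read: ReadAlignment, p: int, min_flank: int) -> bool:
    """Read covers p with >= min_flank aligned bases strictly on each side."""
    return (
        read.target_start <= p - min_flank
        and read.target_end - 1 >= p + min_flank
    )


def read_support(
    candidate: Candidate,
    read_alignments: Iterable[ReadAlignment],
    min_flank: int = 5,
    read_contig_sets: Optional[Dict[str, Set[str]]] = None,
    event_contigs: Optional[Set[str]] = None,
) -> ReadSupport:
    """Compute total and strong read support over the search region.

    ``read_alignments`` are read-to-contig records for the candidate's
    contig, already restricted to that contig. ``read_contig_sets`` maps a
    read id to the set of contigs it maps to anywhere; when omitted, every
    read is assumed to map uniquely (strong support equals total support).
    """
    lo, hi = breakpoint_region(candidate)
    if hi <= lo:
        raise ValueError(f"malformed candidate: empty search region [{lo},{hi})")
    if event_contigs is None:
        event_contigs = {candidate.contig_id}

    clean = [r for r in read_alignments if not r.has_mismatch]
    total_min = None
    strong_min = None
    for p in range(lo, hi):
        total = 0
        strong = 0
        for r in clean:
            if not _qualifies(r, p, min_flank):
                continue
            total += 1
            if read_contig_sets is None:
                strong += 1
            else:
                contigs = read_contig_sets.get(r.read_id, {r.target_id})
                _, is_strong = support_score(contigs, event_contigs)
                if is_strong:
                    strong += 1
        total_min = total if total_min is None else min(total_min, total)
        strong_min = strong if strong_min is None else min(strong_min, strong)
    return ReadSupport(
        region_P=(lo, hi),
        total_support=int(total_min),
        strong_support=int(strong_min),
        min_flank=min_flank,
    )
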