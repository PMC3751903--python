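"""Chimeric-vs-wild-type relative coverage (optional pipeline stage 5).

For a predicted event, two genomic flank regions A and B are built from the
contig-to-genome alignment blocks on each side of the breakpoint, cut or
extended along the annotated transcript so each region totals twice the read
length. Read-to-genome depth T(r,s) at each position s (reads overlapping s
by at least q nt) is partitioned into

    T(r,s) = DW(r,s) + T1(r,s) + T2(r,s)

where DW counts reads from sequence present only in wild-type transcripts,
T1 reads from sequence present once in both, and T2 reads from sequence
present once in wild type but twice in the chimera. Assuming a single extra
copy of any duplicated region, the wild-type depth estimate is

    W(r,s) = DW(r,s) + I1(r,s) * (T1(r,s) - C) + I2(r,s) * (T2(r,s) - 2C)

with I_j(r,s) = 1 iff T_j(r,s) > 0, and C the chimeric junction depth (the
read-to-contig support). W(r) = max_s W(r,s); T(r) = max over s' with
W(r,s') = W(r) of T(r,s'); starred values average A and B. The headline
report is the seven depths and the six ratios C/W(r), C/T(r).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .formats import GeneModel, ReadAlignment
from .predict import FUSION, EventPrediction


@dataclass
class FlankRegion:
    label: str  # 'A' or 'B'
    chrom: str
    blocks: List[Tuple[int, int]]  # genome intervals, 0-based half-open
    truncated: bool = False

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    def positions(self) -> Iterable[int]:
        for s, e in self.blocks:
            yield from range(s, e)


@dataclass
class DepthPartition:
    region: FlankRegion
    dw: Dict[int, int] = field(default_factory=dict)
    t1: Dict[int, int] = field(default_factory=dict)
    t2: Dict[int, int] = field(default_factory=dict)

    def total(self, s: int) -> int:
        return self.dw.get(s, 0) + self.t1.get(s, 0) + self.t2.get(s, 0)


@dataclass
class RelativeCoverage:
    C: float
    W_A: float
    T_A: float
    W_B: float
    T_B: float
    W_star: float
    T_star: float
    ratios: Dict[str, float] = field(default_factory=dict)
    clamped: bool = False

    def as_dict(self) -> dict:
        out = {
            "C": self.C,
            "W_A": self.W_A,
            "T_A": self.T_A,
            "W_B": self.W_B,
            "T_B": self.T_B,
            "W_star": self.W_star,
            "T_star": self.T_star,
        }
        out.update(self.ratios)
        return out


# ---------------------------------------------------------------------------
# flank regions
# ---------------------------------------------------------------------------


def _trim_blocks_toward_junction(
    blocks: List[Tuple[int, int]], target: int, junction_at_end: bool
) -> Tuple[List[Tuple[int, int]], int]:
    """Keep up to ``target`` nt of blocks adjacent to the junction side.

    ``junction_at_end=True`` means the breakpoint sits at the high end of the
    block chain (trim from the front); otherwise at the low end.
    """
    ordered = sorted(blocks)
    if junction_at_end:
        ordered = ordered[::-1]
    kept: List[Tuple[int, int]] = []
    remaining = target
    for s, e in ordered:
        if remaining <= 0:
            break
        size = e - s
        take = min(size, remaining)
        if junction_at_end:
            kept.append((e - take, e))
        else:
            kept.append((s, s + take))
        remaining -= take
    return sorted(kept), remaining


def _extend_along_gene(
    kept: List[Tuple[int, int]],
    remaining: int,
    gene_models: Sequence[GeneModel],
    chrom: str,
    junction_at_end: bool,
    edge: Optional[int] = None,
) -> Tuple[List[Tuple[int, int]], int]:
    """Extend away from the junction along annotated exon structure."""
    if remaining <= 0 or (not kept and edge is None):
        return kept, remaining
    exons: List[Tuple[int, int]] = []
    for gm in gene_models:
        if gm.chrom == chrom:
            exons.extend(gm.exons)
    exons = sorted(set(exons))
    if junction_at_end:
        # far end is the low end: walk exons leftward from kept[0]
        edge = kept[0][0] if kept else edge
        for s, e in reversed(exons):
            if remaining <= 0:
                break
            hi = min(e, edge)
            if hi <= s:
                continue
            take = min(hi - s, remaining)
            kept.insert(0, (hi - take, hi))
            remaining -= take
            edge = hi - take
    else:
        edge = kept[-1][1] if kept else edge
        for s, e in exons:
            if remaining <= 0:
                break
            lo = max(s, edge)
            if lo >= e:
                continue
            take = min(e - lo, remaining)
            kept.append((lo, lo + take))
            remaining -= take
            edge = lo + take
    # merge abutting intervals
    merged: List[Tuple[int, int]] = []
    for s, e in sorted(kept):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged, remaining


def flanking_regions(
    candidate,
    read_length: int,
    gene_models: Sequence[GeneModel] = (),
) -> Tuple[FlankRegion, FlankRegion]:
    """Build flank regions A and B, each totalling 2 x read_length.

    Blocks adjacent to the breakpoint are kept; far ends are cut, or
    extended along annotated exons when the alignment is too short. A region
    that cannot reach the target length is flagged truncated.
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    target = 2 * read_length

    if candidate.duplicated_segment is not None:
        # Tandem duplication: the regions represent the wild-type context and
        # extend outward from the duplicated segment's edges (inside the
        # segment, total depth is inflated by the extra chimeric copy, which
        # the W formula corrects but which would distort T).
        chrom, seg_lo, seg_hi = candidate.duplicated_segment
        all_blocks = []
        for piece in candidate.alignment_pair:
            blocks = getattr(piece, "blocks", None)
            if blocks:
                all_blocks.extend((g, g + n) for _, g, n in blocks)
        sides = [
            (chrom, [(s, min(e, seg_lo)) for s, e in all_blocks if s < seg_lo]),
            (chrom, [(max(s, seg_hi), e) for s, e in all_blocks if e > seg_hi]),
        ]
        junction_flags = [True, False]  # A ends at seg_lo, B starts at seg_hi
        edges = [seg_lo, seg_hi]
    else:
        first, second = candidate.alignment_pair
        sides = [
            (first.chrom, [(g, g + n) for _, g, n in first.blocks]),
            (second.chrom, [(g, g + n) for _, g, n in second.blocks]),
        ]
        # junction position on each side: genomic mate of the junction base
        junction_flags = []
        edges = []
        for (chrom, pos, _strand), (c, blocks) in zip(candidate.breakpoints, sides):
            lo = min(s for s, _ in blocks)
            hi = max(e for _, e in blocks)
            junction_flags.append(abs(pos - (hi - 1)) <= abs(pos - lo))
            edges.append(pos)

    regions = []
    for label, (chrom, blocks), junction_at_end, edge in zip(
        "AB", sides, junction_flags, edges
    ):
        blocks = [(s, e) for s, e in blocks if e > s]
        # dedupe overlapping piece blocks
        merged: List[Tuple[int, int]] = []
        for s, e in sorted(blocks):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        kept, remaining = _trim_blocks_toward_junction(merged, target, junction_at_end)
        if remaining > 0:
            kept, remaining = _extend_along_gene(
                kept, remaining, gene_models, chrom, junction_at_end, edge=edge
            )
        regions.append(
            FlankRegion(
                label=label, chrom=chrom, blocks=kept, truncated=remaining > 0
            )
        )
    return regions[0], regions[1]


# ---------------------------------------------------------------------------
# depth partition
# ---------------------------------------------------------------------------


def _read_covers(read: ReadAlignment, s: int, q: int) -> bool:
    """Read overlaps position s by >= q nt on each side (inclusive of s)."""
    for bs, be in read.blocks:
        if bs <= s < be:
            return s - read.target_start + 1 >= q and read.target_end - s >= q
    return False


def _spans_destroyed_adjacency(
    read: ReadAlignment, breakpoint: int, q: int, junction_at_end: bool
) -> bool:
    """Wild-type-only read: covers the breakpoint and continues >= q nt past
    it into sequence the chimera replaces (possibly through a splice)."""
    inside = any(bs <= breakpoint < be for bs, be in read.blocks)
    if not inside:
        return False
    if junction_at_end:
        aligned_past = sum(
            max(0, be - max(bs, breakpoint + 1)) for bs, be in read.blocks
        )
        aligned_before = sum(
            max(0, min(be, breakpoint + 1) - bs) for bs, be in read.blocks
        )
    else:
        aligned_past = sum(
            max(0, min(be, breakpoint) - bs) for bs, be in read.blocks
        )
        aligned_before = sum(
            max(0, be - max(bs, breakpoint)) for bs, be in read.blocks
        )
    return aligned_past >= q and aligned_before >= q


def depth_partition(
    region: FlankRegion,
    event: EventPrediction,
    read_alignments: Iterable[ReadAlignment],
    q: int = 5,
    junction_at_end: Optional[bool] = None,
) -> DepthPartition:
    """Partition read-to-genome depth at each region position into DW/T1/T2.

    T2 accrues at positions inside the event's duplicated genomic segment;
    DW accrues from reads that span a wild-type adjacency the chimera
    destroys (fusions only — a tandem duplication destroys no wild-type
    junction); T1 otherwise.
    """
    part = DepthPartition(region=region)
    dup = event.duplicated_segment
    is_fusion = event.event_type == FUSION
    if junction_at_end is None:
        junction_at_end = region.label == "A"
    bp_index = 0 if region.label == "A" else 1
    bp = event.breakpoints[bp_index][1] if event.breakpoints else None

    reads = [
        r
        for r in read_alignments
        if r.target_id == region.chrom or r.target_id == ""
    ]
    for s in region.positions():
        for r in reads:
            if not _read_covers(r, s, q):
                continue
            if is_fusion and bp is not None and _spans_destroyed_adjacency(
                r, bp, q, junction_at_end
            ):
                part.dw[s] = part.dw.get(s, 0) + 1
            elif dup is not None and dup[1] <= s < dup[2]:
                part.t2[s] = part.t2.get(s, 0) + 1
            else:
                part.t1[s] = part.t1.get(s, 0) + 1
    return part


# ---------------------------------------------------------------------------
# relative coverage
# ---------------------------------------------------------------------------


def _ratio(c: float, denom: float) -> float:
    if denom > 0:
        return c / denom
    return math.inf


def relative_coverage(
    C: float, partition_a: DepthPartition, partition_b: DepthPartition
) -> RelativeCoverage:
    """Combine the chimeric depth C with the two flank partitions."""
    clamped = False
    per_region: Dict[str, Tuple[float, float]] = {}
    for part in (partition_a, partition_b):
        best_w = None
        best_t = None
        for s in part.region.positions():
            dw = part.dw.get(s, 0)
            t1 = part.t1.get(s, 0)
            t2 = part.t2.get(s, 0)
            w = dw
            if t1 > 0:
                w += t1 - C
            if t2 > 0:
                w += t2 - 2 * C
            if w < 0:
                w = 0.0
                clamped = True
            t = dw + t1 + t2
            if best_w is None or w > best_w:
                best_w, best_t = w, t
            elif w == best_w:
                best_t = max(best_t, t)
        if best_w is None:
            best_w, best_t = 0.0, 0.0
        per_region[part.region.label] = (float(best_w), float(best_t))

    w_a, t_a = per_region.get("A", (0.0, 0.0))
    w_b, t_b = per_region.get("B", (0.0, 0.0))
    w_star = (w_a + w_b) / 2
    t_star = (t_a + t_b) / 2
    ratios = {
        "C_over_W_A": _ratio(C, w_a),
        "C_over_T_A": _ratio(C, t_a),
        "C_over_W_B": _ratio(C, w_b),
        "C_over_T_B": _ratio(C, t_b),
        "C_over_W_star": _ratio(C, w_star),
        "C_over_T_star": _ratio(C, t_star),
    }
    return RelativeCoverage(
        C=float(C),
        W_A=w_a,
        T_A=t_a,
        W_B=w_b,
        T_B=t_b,
        W_star=w_star,
        T_star=t_star,
        ratios=ratios,
        clamped=clamped,
    )
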