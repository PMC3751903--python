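"""Candidate grouping and annotation (pipeline stages 1.2 and 1.3).

Meta-assemblies represent one event with several contigs, so candidates are
grouped by genomic location and alignment orientation before filtering.
Each candidate is then annotated with overlapping genes, exon-boundary
matches of its breakpoints, and overlaps with repeat / segmental-duplication
/ structural-RNA regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from intervaltree import IntervalTree

from .align_select import Candidate
from .formats import AnnotatedRegion, GeneModel


@dataclass
class CandidateGroup:
    group_id: int
    members: List[Candidate]
    representative_breakpoints: List[Tuple[str, int, str]] = field(default_factory=list)
    orientation_signature: tuple = ()

    @property
    def contig_ids(self) -> Set[str]:
        return {c.contig_id for c in self.members}


@dataclass
class CandidateAnnotation:
    genes_a: List[str]
    genes_b: List[str]
    exon_boundary_match: str  # both | one | neither
    breakpoint_boundary_flags: Tuple[bool, bool] = (False, False)
    repeat_overlap: bool = False
    segdup_overlap: bool = False
    struct_rna_overlap: bool = False
    transcription_direction_maintained: Optional[bool] = None


def orientation_signature(candidate: Candidate) -> tuple:
    """(strand_a, strand_b, contig order of the genomic pieces)."""
    (chrom_a, pos_a, strand_a), (chrom_b, pos_b, strand_b) = candidate.breakpoints
    if (chrom_a, pos_a) <= (chrom_b, pos_b):
        order = "ab"
    else:
        order = "ba"
    return (strand_a, strand_b, order)


def _chrom_pair(candidate: Candidate) -> tuple:
    return tuple(sorted(bp[0] for bp in candidate.breakpoints))


def _sorted_breakpoints(candidate: Candidate) -> list:
    return sorted((bp[0], bp[1]) for bp in candidate.breakpoints)


def _groupable(a: Candidate, b: Candidate, tolerance_nt: int) -> bool:
    if _chrom_pair(a) != _chrom_pair(b):
        return False
    if orientation_signature(a) != orientation_signature(b):
        return False
    for (ca, pa), (cb, pb) in zip(_sorted_breakpoints(a), _sorted_breakpoints(b)):
        if ca != cb or abs(pa - pb) > tolerance_nt:
            return False
    return True


def group_candidates(
    candidates: Sequence[Candidate], tolerance_nt: int = 10
) -> List[CandidateGroup]:
    """Single-linkage clustering of candidates on the grouping predicate.

    Two candidates join a group iff they share the chromosome pair and
    orientation signature and both breakpoints lie within ``tolerance_nt``.
    Group membership is recorded on each candidate (``group_ids``) so the
    per-contig group count is available to filter 1.
    """
    n = len(candidates)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if _groupable(candidates[i], candidates[j], tolerance_nt):
                parent[find(i)] = find(j)

    by_root: Dict[int, List[int]] = {}
    for i in range(n):
        by_root.setdefault(find(i), []).append(i)

    groups: List[CandidateGroup] = []
    for gid, indices in enumerate(sorted(by_root.values(), key=lambda ix: min(ix))):
        members = [candidates[i] for i in indices]
        rep = members[0].breakpoints
        group = CandidateGroup(
            group_id=gid,
            members=members,
            representative_breakpoints=list(rep),
            orientation_signature=orientation_signature(members[0]),
        )
        for m in members:
            if gid not in m.group_ids:
                m.group_ids.append(gid)
        groups.append(group)
    return groups


def groups_per_contig(groups: Sequence[CandidateGroup]) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for g in groups:
        for contig in g.contig_ids:
            counts[contig] = counts.get(contig, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


class GeneIndex:
    """Interval index over gene-model exons for fast overlap queries."""

    def __init__(self, gene_models: Sequence[GeneModel]):
        self.trees: Dict[str, IntervalTree] = {}
        self.boundaries: Dict[str, List[int]] = {}
        self.by_gene: Dict[str, List[GeneModel]] = {}
        for gm in gene_models:
            tree = self.trees.setdefault(gm.chrom, IntervalTree())
            for s, e in gm.exons:
                tree.addi(s, e, gm)
            self.boundaries.setdefault(gm.chrom, []).extend(gm.exon_boundaries())
            self.by_gene.setdefault(gm.gene_id, []).append(gm)

    def genes_overlapping(self, chrom: str, start: int, end: int) -> Set[str]:
        tree = self.trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data.gene_id for iv in tree.overlap(start, end)}

    def gene_strands(self, gene_ids) -> Dict[str, str]:
        return {
            g: self.by_gene[g][0].strand for g in gene_ids if g in self.by_gene
        }

    def matches_boundary(self, chrom: str, pos: int, tolerance: int = 0) -> bool:
        return any(
            abs(pos - b) <= tolerance for b in self.boundaries.get(chrom, ())
        )


class RegionIndex:
    def __init__(self, regions: Sequence[AnnotatedRegion]):
        self.trees: Dict[Tuple[str, str], IntervalTree] = {}
        for r in regions:
            self.trees.setdefault((r.region_class, r.chrom), IntervalTree()).addi(
                r.start, r.end, r
            )

    def contains(self, region_class: str, chrom: str, pos: int) -> bool:
        tree = self.trees.get((region_class, chrom))
        return bool(tree is not None and tree.overlap(pos, pos + 1))


def _piece_genes(
    candidate: Candidate, index: GeneIndex
) -> Tuple[Set[str], Set[str], List[str], List[str]]:
    """Gene sets overlapping the two genomic pieces of the candidate."""
    first = candidate.alignment_pair[0]
    genes_blocks = []
    if candidate.kind == "split":
        pieces = candidate.alignment_pair
        for aln in pieces:
            genes = set()
            for _, g, n in aln.blocks:
                genes |= index.genes_overlapping(aln.chrom, g, g + n)
            genes_blocks.append(genes)
        strands = [pieces[0].strand, pieces[1].strand]
        chroms = [pieces[0].chrom, pieces[1].chrom]
    else:
        # gap candidate: both pieces live on the host alignment's chromosome
        for chrom, pos, _ in candidate.breakpoints:
            genes_blocks.append(index.genes_overlapping(chrom, pos, pos + 1))
        # widen with the host alignment's gene overlap when a breakpoint
        # falls between exons
        host_genes = set()
        for _, g, n in first.blocks:
            host_genes |= index.genes_overlapping(first.chrom, g, g + n)
        genes_blocks = [gb | host_genes if not gb else gb for gb in genes_blocks]
        strands = [first.strand, first.strand]
        chroms = [first.chrom, first.chrom]
    return genes_blocks[0], genes_blocks[1], strands, chroms


def annotate_candidate(
    candidate: Candidate,
    gene_index: GeneIndex,
    region_index: Optional[RegionIndex] = None,
    boundary_tolerance: int = 0,
) -> CandidateAnnotation:
    """Assign genes, exon-boundary matches, and region overlaps."""
    genes_a, genes_b, strands, _ = _piece_genes(candidate, gene_index)

    flags = []
    for chrom, pos, _ in candidate.breakpoints:
        flags.append(gene_index.matches_boundary(chrom, pos, boundary_tolerance))
    n_match = sum(flags)
    match_label = {2: "both", 1: "one", 0: "neither"}[n_match]

    repeat = segdup = srna = False
    if region_index is not None:
        for chrom, pos, _ in candidate.breakpoints:
            repeat = repeat or region_index.contains("repeat", chrom, pos)
            segdup = segdup or region_index.contains(
                "segmental_duplication", chrom, pos
            )
            srna = srna or region_index.contains("struct_rna", chrom, pos)

    direction = None
    if genes_a and genes_b and not (genes_a & genes_b):
        strand_map = gene_index.gene_strands(genes_a | genes_b)
        sense_a = {strand_map.get(g) == strands[0] for g in genes_a if g in strand_map}
        sense_b = {strand_map.get(g) == strands[1] for g in genes_b if g in strand_map}
        if len(sense_a) == 1 and len(sense_b) == 1:
            direction = sense_a == sense_b

    return CandidateAnnotation(
        genes_a=sorted(genes_a),
        genes_b=sorted(genes_b),
        exon_boundary_match=match_label,
        breakpoint_boundary_flags=(flags[0], flags[1]),
        repeat_overlap=repeat,
        segdup_overlap=segdup,
        struct_rna_overlap=srna,
        transcription_direction_maintained=direction,
    )
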