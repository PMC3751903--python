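"""Event typing and the wild-type collinear post-filter (pipeline stage 4).

Typing rules:

* fusion — split candidate, any topology, whose two alignments overlap only
  distinct genes and do not overlap each other in the genome. Fusion
  breakpoints need not fall on annotated exon boundaries.
* PTD — split candidate with eversion or duplication topology whose
  alignments overlap one common gene and whose breakpoints both match
  annotated exon boundaries (the non-canonical exon junction signature;
  circular transcripts produce the same junction and are labeled PTD).
* long ITD — as PTD, but at least one breakpoint off any exon boundary.
* short ITD — gap candidate with duplication topology and at least one
  off-boundary breakpoint; a gap-duplication whose breakpoints both sit on
  exon boundaries is routed to PTD instead.

The post-filter drops predictions whose contig aligns full-length and
collinearly to any single wild-type transcript (cDNA-to-genome misalignment
false positives).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import Align

from .align_select import DUPLICATION, EVERSION, Candidate
from .candidates import CandidateAnnotation

FUSION = "fusion"
PTD = "PTD"
ITD = "ITD"


@dataclass
class EventPrediction:
    event_type: str
    candidate: Candidate
    genes: List[str]
    breakpoints: List[Tuple[str, int, str]]
    exon_boundary_match: str
    duplicated_segment: Optional[Tuple[str, int, int]] = None
    inserted_bases: int = 0
    direction_maintained: Optional[bool] = None
    total_support: int = 0
    strong_support: int = 0
    group_id: Optional[int] = None
    relative_coverage: Optional[dict] = None

    @property
    def contig_id(self) -> str:
        return self.candidate.contig_id


def _genomically_disjoint(candidate: Candidate) -> bool:
    a, b = candidate.alignment_pair
    if a.chrom != b.chrom:
        return True
    a0, a1 = a.genome_interval
    b0, b1 = b.genome_interval
    return a1 <= b0 or b1 <= a0


def classify_event(
    candidate: Candidate, annotation: CandidateAnnotation
) -> Optional[EventPrediction]:
    """Type a filtered candidate as fusion, PTD, or ITD; None when untyped."""
    genes_a, genes_b = set(annotation.genes_a), set(annotation.genes_b)
    shared = genes_a & genes_b
    boundary = annotation.exon_boundary_match

    common = dict(
        candidate=candidate,
        breakpoints=list(candidate.breakpoints),
        exon_boundary_match=boundary,
        duplicated_segment=candidate.duplicated_segment,
        inserted_bases=candidate.inserted_bases,
    )

    if candidate.kind == "split":
        if genes_a and genes_b and not shared and _genomically_disjoint(candidate):
            return EventPrediction(
                event_type=FUSION,
                genes=sorted(genes_a | genes_b),
                direction_maintained=annotation.transcription_direction_maintained,
                **common,
            )
        if shared and candidate.topology in (EVERSION, DUPLICATION):
            event_type = PTD if boundary == "both" else ITD
            return EventPrediction(
                event_type=event_type, genes=sorted(shared), **common
            )
        return None

    # gap candidate
    if candidate.topology == DUPLICATION:
        genes = sorted(shared or (genes_a | genes_b))
        event_type = PTD if boundary == "both" else ITD
        return EventPrediction(event_type=event_type, genes=genes, **common)
    return None


# ---------------------------------------------------------------------------
# wild-type collinear post-filter
# ---------------------------------------------------------------------------


def _collinear_to(
    contig_seq: str,
    transcript_seq: str,
    min_coverage: float,
    min_identity: float,
) -> bool:
    """Does the contig align full-length + collinearly to this transcript?

    A pairwise local alignment is monotone by construction, so collinearity
    reduces to coverage and identity thresholds.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    try:
        aln = aligner.align(contig_seq, transcript_seq)[0]
    except (IndexError, ValueError):
        return False
    q_blocks, t_blocks = aln.aligned[0], aln.aligned[1]
    if not len(q_blocks):
        return False
    matches = 0
    aligned_len = 0
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        aligned_len += qe - qs
        matches += sum(
            1
            for k in range(qe - qs)
            if contig_seq[qs + k].upper() == transcript_seq[ts + k].upper()
        )
    coverage = aligned_len / len(contig_seq)
    identity = matches / aligned_len if aligned_len else 0.0
    return coverage >= min_coverage and identity >= min_identity


def wildtype_collinear_filter(
    predictions: Sequence[EventPrediction],
    transcript_sequences: Dict[str, str],
    contig_sequences: Dict[str, str],
    min_coverage: float = 0.95,
    min_identity: float = 0.98,
) -> List[EventPrediction]:
    """Drop predictions whose contig is explainable by one wild-type transcript.

    Skipped (all predictions retained) when no transcripts are provided.
    """
    if not transcript_sequences:
        return list(predictions)
    surviving: List[EventPrediction] = []
    verdict_cache: Dict[str, bool] = {}
    for pred in predictions:
        contig_seq = contig_sequences.get(pred.contig_id, "")
        if not contig_seq:
            surviving.append(pred)
            continue
        if pred.contig_id not in verdict_cache:
            verdict_cache[pred.contig_id] = any(
                _collinear_to(contig_seq, tseq, min_coverage, min_identity)
                for tseq in transcript_sequences.values()
            )
        if not verdict_cache[pred.contig_id]:
            surviving.append(pred)
    return surviving
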