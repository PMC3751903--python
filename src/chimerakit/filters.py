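"""The ten candidate filters (pipeline stage 3).

Filters address repetitive-sequence artifacts (1-5), alignment confidence
(6-7), junction read evidence (8), and common false-positive sources:
homology-driven co-assembly (9) and poly(A)-tail misalignment (10). All ten
are evaluated without short-circuiting so review output lists every
violation. Defaults follow extensive manual-review experience on deeply
sequenced human datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

from .align_select import Candidate, GapRealignment
from .candidates import CandidateAnnotation
from .support import ReadSupport

FILTER_NAMES = {
    1: "max_groups_per_contig",
    2: "multimapping",
    3: "homopolymer",
    4: "repeat_breakpoints",
    5: "struct_rna",
    6: "percent_identity",
    7: "inclusion",
    8: "strong_read_support",
    9: "contig_overlap",
    10: "polya",
}


@dataclass
class FilterConfig:
    max_groups_per_contig: int = 3
    reject_multimapping: bool = True
    reject_homopolymer: bool = True
    reject_repeat_breakpoints: bool = False  # breakpoints in repeats allowed
    reject_struct_rna: bool = True
    min_percent_identity: float = 99.0
    min_inclusion: float = 0.9
    min_strong_reads: int = 5
    max_contig_overlap_nt: int = 75
    reject_polya: bool = True
    polya_min_run: int = 8
    polya_min_content: float = 0.9


@dataclass
class FilterResult:
    passed: bool
    failures: List[int] = field(default_factory=list)
    reasons: List[str] = field(default_factory=list)


def is_homopolymer_gap(candidate: Candidate) -> bool:
    """True iff a gap-candidate's realigned gap portion is a single-base run."""
    if candidate.kind != "gap":
        return False
    realn = candidate.alignment_pair[1]
    seq = ""
    if isinstance(realn, GapRealignment):
        seq = realn.realigned_sequence
    if not seq and candidate.gap is not None:
        seq = candidate.gap.gap_sequence
    return bool(seq) and len(set(seq.upper())) == 1


def _terminal_run(seq: str, base: str, min_run: int, min_content: float) -> bool:
    return len(seq) >= min_run and seq.upper().count(base) / len(seq) >= min_content


def is_polya_artifact(
    candidate: Candidate,
    contig_sequence: str,
    min_run: int = 8,
    min_content: float = 0.9,
) -> bool:
    """True iff one contig piece covers only a leading T-run or trailing A-run.

    Poly(A) tails retained in assembled contigs misalign to the genome; the
    signature is an alignment piece confined to a terminal homopolymeric run.
    """
    if not contig_sequence:
        return False
    n = len(contig_sequence)
    for start, end in candidate.piece_intervals:
        piece = contig_sequence[start:end]
        if start == 0 and _terminal_run(piece, "T", min_run, min_content):
            return True
        if end >= n and _terminal_run(piece, "A", min_run, min_content):
            return True
    return False


def apply_filters(
    candidate: Candidate,
    annotation: CandidateAnnotation,
    support: ReadSupport,
    config: Optional[FilterConfig] = None,
    contig_sequence: str = "",
    group_count: int = 1,
) -> FilterResult:
    """Evaluate all ten filters; every violated filter id is reported."""
    if support is None:
        raise ValueError("candidate is missing read-support data")
    config = config or FilterConfig()
    failures: List[int] = []
    reasons: List[str] = []

    def fail(fid: int, reason: str) -> None:
        failures.append(fid)
        reasons.append(f"{FILTER_NAMES[fid]}: {reason}")

    if group_count > config.max_groups_per_contig:
        fail(1, f"contig in {group_count} groups > {config.max_groups_per_contig}")
    if config.reject_multimapping and candidate.multimapping:
        fail(2, "candidate is multi-mapping")
    if config.reject_homopolymer and is_homopolymer_gap(candidate):
        fail(3, "realigned gap is a homopolymer run")
    if config.reject_repeat_breakpoints and annotation.repeat_overlap:
        fail(4, "breakpoint inside annotated repeat")
    if config.reject_struct_rna and annotation.struct_rna_overlap:
        fail(5, "breakpoint inside structural RNA region")

    identities = []
    for piece in candidate.alignment_pair:
        pid = getattr(piece, "percent_identity", None)
        if pid is None:
            pid = getattr(piece, "identity", None)
        if pid is not None:
            identities.append(pid)
    if any(pid < config.min_percent_identity for pid in identities):
        low = min(identities)
        fail(6, f"alignment identity {low:.1f}% < {config.min_percent_identity}%")

    if candidate.inclusion < config.min_inclusion:
        fail(7, f"inclusion {candidate.inclusion:.3f} < {config.min_inclusion}")
    if support.strong_support < config.min_strong_reads:
        fail(
            8,
            f"{support.strong_support} strong reads < {config.min_strong_reads}",
        )
    if candidate.contig_overlap_nt > config.max_contig_overlap_nt:
        fail(
            9,
            f"alignments overlap {candidate.contig_overlap_nt} nt > "
            f"{config.max_contig_overlap_nt}",
        )
    if config.reject_polya and is_polya_artifact(
        candidate, contig_sequence, config.polya_min_run, config.polya_min_content
    ):
        fail(10, "alignment piece covers only a terminal poly(A)/poly(T) run")

    return FilterResult(passed=not failures, failures=failures, reasons=reasons)
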