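"""End-to-end orchestration of the detection pipeline.

Stages run in order: detect (alignment selection + candidate creation +
grouping + annotation), support (read-to-contig evidence), filter, predict
(event typing + optional wild-type post-filter), and optional relcov
(chimeric vs wild-type coverage from read-to-genome alignments). Each stage
writes a reviewable JSON intermediate; the final output is a deterministic
prediction TSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from . import formats
from .align_select import (
    Candidate,
    ContigAlignment,
    GapRealignment,
    QueryGap,
    SelectionParams,
    detect_contig,
)
from .candidates import (
    CandidateAnnotation,
    GeneIndex,
    RegionIndex,
    annotate_candidate,
    group_candidates,
    groups_per_contig,
)
from .filters import FilterConfig, FilterResult, apply_filters
from .predict import EventPrediction, classify_event, wildtype_collinear_filter
from .relcov import depth_partition, flanking_regions, relative_coverage
from .support import ReadSupport, read_support

log = logging.getLogger("chimerakit")


@dataclass
class PipelineConfig:
    contigs_fasta: str = ""
    psl: str = ""
    read_to_contig: str = ""
    genes: str = ""
    genome_fasta: str = ""
    repeats_bed: str = ""
    segdup_bed: str = ""
    structrna_bed: str = ""
    transcripts_fasta: str = ""
    read_to_genome: str = ""
    out_dir: str = "chimerakit_out"
    read_length: int = 75
    min_flank: int = 5
    group_tolerance_nt: int = 10
    boundary_tolerance: int = 0
    enable_relcov: bool = False
    relcov_q: int = 5
    seed: int = 0
    selection: SelectionParams = field(default_factory=SelectionParams)
    filters: FilterConfig = field(default_factory=FilterConfig)

    def validate(self) -> None:
        required = {
            "contigs_fasta": self.contigs_fasta,
            "psl": self.psl,
            "read_to_contig": self.read_to_contig,
            "genes": self.genes,
        }
        for name, path in required.items():
            if not path:
                raise FileNotFoundError(f"missing required input: {name}")
            if not os.path.exists(path):
                raise FileNotFoundError(f"{name}: no such file: {path}")
        if self.enable_relcov and not self.read_to_genome:
            raise FileNotFoundError(
                "relcov stage enabled but no read-to-genome alignments provided"
            )


@dataclass
class CandidateRecord:
    candidate: Candidate
    annotation: Optional[CandidateAnnotation] = None
    support: Optional[ReadSupport] = None
    filter_result: Optional[FilterResult] = None
    group_id: Optional[int] = None
    group_count: int = 1


# ---------------------------------------------------------------------------
# stages (pure functions of in-memory inputs)
# ---------------------------------------------------------------------------


def stage_detect(
    alignments: Sequence[ContigAlignment],
    contig_sequences: Dict[str, str],
    gene_index: GeneIndex,
    region_index: Optional[RegionIndex] = None,
    genome_fetcher=None,
    selection: Optional[SelectionParams] = None,
    group_tolerance_nt: int = 10,
    boundary_tolerance: int = 0,
) -> List[CandidateRecord]:
    """Stage 1: candidate identification, grouping, and annotation."""
    selection = selection or SelectionParams()
    by_contig: Dict[str, List[ContigAlignment]] = {}
    for a in alignments:
        by_contig.setdefault(a.contig_id, []).append(a)

    candidates: List[Candidate] = []
    for contig_id in sorted(by_contig):
        alns = by_contig[contig_id]
        seq = contig_sequences.get(contig_id, "")
        clen = alns[0].contig_length
        candidates.extend(
            detect_contig(
                contig_id,
                alns,
                clen,
                contig_sequence=seq,
                genome_fetcher=genome_fetcher,
                params=selection,
            )
        )

    groups = group_candidates(candidates, tolerance_nt=group_tolerance_nt)
    counts = groups_per_contig(groups)
    group_of: Dict[int, int] = {}
    for g in groups:
        for m in g.members:
            group_of[id(m)] = g.group_id

    records: List[CandidateRecord] = []
    for cand in candidates:
        ann = annotate_candidate(
            cand, gene_index, region_index, boundary_tolerance=boundary_tolerance
        )
        records.append(
            CandidateRecord(
                candidate=cand,
                annotation=ann,
                group_id=group_of.get(id(cand)),
                group_count=counts.get(cand.contig_id, 1),
            )
        )
    return records


def build_read_index(
    read_alignments,
) -> Tuple[Dict[str, list], Dict[str, Set[str]]]:
    """Split read-to-contig records per contig and map read -> contig set."""
    per_contig: Dict[str, list] = {}
    contig_sets: Dict[str, Set[str]] = {}
    for r in read_alignments:
        per_contig.setdefault(r.target_id, []).append(r)
        contig_sets.setdefault(r.read_id, set()).add(r.target_id)
    return per_contig, contig_sets


def stage_support(
    records: Sequence[CandidateRecord],
    reads_per_contig: Dict[str, list],
    read_contig_sets: Dict[str, Set[str]],
    min_flank: int = 5,
) -> None:
    """Stage 2: attach read support to every candidate (in place)."""
    # event contig sets: contigs sharing a group
    group_contigs: Dict[int, Set[str]] = {}
    for rec in records:
        if rec.group_id is not None:
            group_contigs.setdefault(rec.group_id, set()).add(
                rec.candidate.contig_id
            )
    for rec in records:
        event_contigs = group_contigs.get(rec.group_id, {rec.candidate.contig_id})
        rec.support = read_support(
            rec.candidate,
            reads_per_contig.get(rec.candidate.contig_id, []),
            min_flank=min_flank,
            read_contig_sets=read_contig_sets,
            event_contigs=event_contigs,
        )


def stage_filter(
    records: Sequence[CandidateRecord],
    config: FilterConfig,
    contig_sequences: Dict[str, str],
) -> None:
    """Stage 3: evaluate the ten filters on every supported candidate."""
    for rec in records:
        rec.filter_result = apply_filters(
            rec.candidate,
            rec.annotation,
            rec.support,
            config=config,
            contig_sequence=contig_sequences.get(rec.candidate.contig_id, ""),
            group_count=rec.group_count,
        )
        if not rec.filter_result.passed:
            log.info(
                "candidate %s failed filters: %s",
                rec.candidate.id,
                "; ".join(rec.filter_result.reasons),
            )


def stage_predict(
    records: Sequence[CandidateRecord],
    transcript_sequences: Optional[Dict[str, str]] = None,
    contig_sequences: Optional[Dict[str, str]] = None,
) -> List[EventPrediction]:
    """Stage 4: type passing candidates; one prediction per candidate group.

    Distinct breakpoint pairs (fusion isoforms) fall in distinct groups and
    therefore stay distinct predictions.
    """
    best_per_group: Dict[tuple, EventPrediction] = {}
    for rec in records:
        if rec.filter_result is None or not rec.filter_result.passed:
            continue
        pred = classify_event(rec.candidate, rec.annotation)
        if pred is None:
            continue
        pred.total_support = rec.support.total_support
        pred.strong_support = rec.support.strong_support
        pred.group_id = rec.group_id
        key = (pred.event_type, rec.group_id)
        prev = best_per_group.get(key)
        if prev is None or pred.strong_support > prev.strong_support:
            best_per_group[key] = pred
    predictions = sorted(
        best_per_group.values(),
        key=lambda p: (p.event_type, p.breakpoints[0][0], p.breakpoints[0][1]),
    )
    if transcript_sequences:
        predictions = wildtype_collinear_filter(
            predictions, transcript_sequences, contig_sequences or {}
        )
    return predictions


def stage_relcov(
    predictions: Sequence[EventPrediction],
    genome_reads,
    gene_models,
    read_length: int = 75,
    q: int = 5,
) -> None:
    """Stage 5: attach relative-coverage estimates (in place)."""
    reads = list(genome_reads)
    by_chrom: Dict[str, list] = {}
    for r in reads:
        by_chrom.setdefault(r.target_id, []).append(r)
    for pred in predictions:
        region_a, region_b = flanking_regions(
            pred.candidate, read_length, gene_models
        )
        part_a = depth_partition(
            region_a, pred, by_chrom.get(region_a.chrom, []), q=q
        )
        part_b = depth_partition(
            region_b, pred, by_chrom.get(region_b.chrom, []), q=q
        )
        rc = relative_coverage(pred.total_support, part_a, part_b)
        pred.relative_coverage = rc.as_dict()


# ---------------------------------------------------------------------------
# serialization of intermediates
# ---------------------------------------------------------------------------


def record_to_jsonable(rec: CandidateRecord) -> dict:
    return dataclasses.asdict(rec)


def _aln_from_dict(d: dict) -> ContigAlignment:
    d = dict(d)
    d["blocks"] = [tuple(b) for b in d["blocks"]]
    return ContigAlignment(**d)


def record_from_jsonable(d: dict) -> CandidateRecord:
    c = dict(d["candidate"])
    pair = c.pop("alignment_pair")
    first = _aln_from_dict(pair[0])
    if c["kind"] == "split":
        second = _aln_from_dict(pair[1])
    else:
        p = dict(pair[1])
        p["target_interval"] = tuple(p["target_interval"])
        second = GapRealignment(**p)
    gap = c.pop("gap")
    c["gap"] = QueryGap(**gap) if gap else None
    c["alignment_pair"] = (first, second)
    c["breakpoints"] = [tuple(bp) for bp in c["breakpoints"]]
    c["piece_intervals"] = [tuple(p) for p in c["piece_intervals"]]
    if c.get("duplicated_segment"):
        c["duplicated_segment"] = tuple(c["duplicated_segment"])
    cand = Candidate(**c)
    ann = d.get("annotation")
    annotation = None
    if ann:
        ann = dict(ann)
        ann["breakpoint_boundary_flags"] = tuple(ann["breakpoint_boundary_flags"])
        annotation = CandidateAnnotation(**ann)
    sup = d.get("support")
    support = None
    if sup:
        sup = dict(sup)
        sup["region_P"] = tuple(sup["region_P"])
        support = ReadSupport(**sup)
    fr = d.get("filter_result")
    filter_result = FilterResult(**fr) if fr else None
    return CandidateRecord(
        candidate=cand,
        annotation=annotation,
        support=support,
        filter_result=filter_result,
        group_id=d.get("group_id"),
        group_count=d.get("group_count", 1),
    )


def save_records(records: Sequence[CandidateRecord], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([record_to_jsonable(r) for r in records], fh, indent=1)


def load_records(path: str) -> List[CandidateRecord]:
    with open(path) as fh:
        return [record_from_jsonable(d) for d in json.load(fh)]


def predictions_to_rows(predictions: Sequence[EventPrediction]) -> List[dict]:
    rows = []
    for p in predictions:
        (chrom_a, bp_a, strand_a), (chrom_b, bp_b, strand_b) = p.breakpoints
        row = dict(
            event_type=p.event_type,
            contig_id=p.contig_id,
            genes=p.genes,
            chrom_a=chrom_a,
            breakpoint_a=bp_a,
            strand_a=strand_a,
            chrom_b=chrom_b,
            breakpoint_b=bp_b,
            strand_b=strand_b,
            topology=p.candidate.topology,
            exon_boundary_match=p.exon_boundary_match,
            total_support=p.total_support,
            strong_support=p.strong_support,
            filter_failures="",
        )
        if p.relative_coverage:
            rc = p.relative_coverage
            row.update(
                relcov_C=rc["C"],
                relcov_W_star=rc["W_star"],
                relcov_T_star=rc["T_star"],
                relcov_C_over_W_star=rc["C_over_W_star"],
                relcov_C_over_T_star=rc["C_over_T_star"],
            )
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> List[EventPrediction]:
    """Run all stages from files per the config; write intermediates + TSV."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    logging.basicConfig(
        filename=os.path.join(config.out_dir, "chimerakit.log"),
        level=logging.INFO,
        force=True,
    )

    contig_sequences = formats.read_fasta(config.contigs_fasta)
    alignments = formats.read_psl(config.psl)
    gene_models = formats.read_annotations(config.genes, "genepredext")
    regions = []
    for path, cls in (
        (config.repeats_bed, "repeat"),
        (config.segdup_bed, "segmental_duplication"),
        (config.structrna_bed, "struct_rna"),
    ):
        if path:
            regions.extend(formats.read_annotations(path, "bed", region_class=cls))
    gene_index = GeneIndex(gene_models)
    region_index = RegionIndex(regions) if regions else None
    genome_fetcher = None
    if config.genome_fasta:
        genome = formats.read_fasta(config.genome_fasta)
        genome_fetcher = formats.dict_fetcher(genome)

    records = stage_detect(
        alignments,
        contig_sequences,
        gene_index,
        region_index,
        genome_fetcher=genome_fetcher,
        selection=config.selection,
        group_tolerance_nt=config.group_tolerance_nt,
        boundary_tolerance=config.boundary_tolerance,
    )
    save_records(records, os.path.join(config.out_dir, "stage1_candidates.json"))

    reads = list(formats.read_bam(config.read_to_contig, mode="read_to_contig"))
    per_contig, contig_sets = build_read_index(reads)
    stage_support(records, per_contig, contig_sets, min_flank=config.min_flank)
    save_records(records, os.path.join(config.out_dir, "stage2_support.json"))

    stage_filter(records, config.filters, contig_sequences)
    save_records(records, os.path.join(config.out_dir, "stage3_filtered.json"))

    transcripts = (
        formats.read_fasta(config.transcripts_fasta)
        if config.transcripts_fasta
        else None
    )
    predictions = stage_predict(records, transcripts, contig_sequences)

    if config.enable_relcov:
        genome_reads = formats.read_bam(config.read_to_genome, mode="read_to_genome")
        stage_relcov(
            predictions,
            genome_reads,
            gene_models,
            read_length=config.read_length,
            q=config.relcov_q,
        )

    rows = predictions_to_rows(predictions)
    formats.write_predictions(rows, os.path.join(config.out_dir, "predictions.tsv"))
    return predictions
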