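"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open. Conversion to the 1-based
inclusive convention happens only at the prediction-output boundary.

Supported formats: PSL (BLAT 21-column, headered or headerless), UCSC
genePredExt, BED4+, SAM/BAM via pysam, and the tab-separated prediction
report defined by this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Sequence, Tuple

import pysam

MITO_NAMES = frozenset({"chrM", "chrMT", "MT", "M"})

PSL_HEADER_PREFIXES = ("psLayout", "match", "-----", "\t")


class ParseError(ValueError):
    """Raised when an input file does not conform to its declared dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ContigAlignment:
    """One contig-to-genome alignment.

    ``blocks`` is an ordered list of ``(contig_start, genome_start, length)``
    triples in forward-contig coordinates (minus-strand PSL queries are
    flipped at parse time). ``quality`` is the aligner-agnostic score
    ``(matches - mismatches) / contig_length`` clamped to [0, 1].
    """

    contig_id: str
    contig_length: int
    chrom: str
    strand: str  # '+' or '-'
    blocks: List[Tuple[int, int, int]]
    matches: int
    mismatches: int
    quality: float
    percent_identity: float
    target_length: int = 0
    multimapping: bool = False

    # -- convenience geometry -------------------------------------------------

    @property
    def contig_start(self) -> int:
        return self.blocks[0][0]

    @property
    def contig_end(self) -> int:
        c, _, n = self.blocks[-1]
        return c + n

    @property
    def contig_interval(self) -> Tuple[int, int]:
        return (self.contig_start, self.contig_end)

    @property
    def genome_start(self) -> int:
        return min(g for _, g, _ in self.blocks)

    @property
    def genome_end(self) -> int:
        return max(g + n for _, g, n in self.blocks)

    @property
    def genome_interval(self) -> Tuple[int, int]:
        return (self.genome_start, self.genome_end)

    def aligned_positions(self) -> set:
        """Set of contig positions covered by any block."""
        out: set = set()
        for c, _, n in self.blocks:
            out.update(range(c, c + n))
        return out

    def genome_position(self, contig_pos: int) -> Optional[int]:
        """Genomic coordinate mapped to ``contig_pos``, or None if unaligned.

        Respects strand: on '-' alignments consecutive forward-contig
        positions map to decreasing genome positions within a block.
        """
        for c, g, n in self.blocks:
            if c <= contig_pos < c + n:
                off = contig_pos - c
                if self.strand == "+":
                    return g + off
                return g + (n - 1 - off)
        return None


@dataclass
class GeneModel:
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]  # 0-based half-open, sorted, non-overlapping

    def exon_boundaries(self) -> List[int]:
        """Genomic coordinates of exon edges (first and last base of each exon)."""
        out = []
        for s, e in self.exons:
            out.append(s)
            out.append(e - 1)
        return out

    @property
    def span(self) -> Tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass
class AnnotatedRegion:
    chrom: str
    start: int
    end: int
    region_class: str  # repeat | segmental_duplication | struct_rna
    name: str = ""


@dataclass
class ReadAlignment:
    """A read aligned to a contig or chromosome.

    ``blocks`` carries the aligned target intervals (split by N/D CIGAR
    operations) so junction-spanning logic can see splice structure; for a
    gapless alignment it is the single ``(target_start, target_end)`` pair.
    """

    read_id: str
    target_id: str
    target_start: int
    target_end: int
    has_mismatch: bool
    mate_id: Optional[str] = None
    blocks: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.blocks:
            self.blocks = [(self.target_start, self.target_end)]


# ---------------------------------------------------------------------------
# PSL
# ---------------------------------------------------------------------------


def _is_psl_header(line: str) -> bool:
    return line.startswith(PSL_HEADER_PREFIXES) or not line[:1].isdigit()


def compute_quality(matches: int, mismatches: int, contig_length: int = 0) -> float:
    """Aligner-agnostic alignment quality in [0, 1].

    ``(matches - mismatches) / (matches + mismatches)``: monotone in both
    the alignment score and percent identity, and independent of how much of
    the contig the alignment covers (coverage is what the inclusion term of
    the set score measures).
    """
    del contig_length
    aligned = matches + mismatches
    if aligned <= 0:
        return 0.0
    return min(1.0, max(0.0, (matches - mismatches) / aligned))


def read_psl(path: str) -> List[ContigAlignment]:
    """Parse a BLAT 21-column PSL file (with or without header lines).

    Minus-strand query coordinates are normalized to forward-contig
    coordinates, so downstream code sees a single convention. Trailing
    columns beyond 21 are ignored.
    """
    out: List[ContigAlignment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if _is_psl_header(line):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 21:
                raise ParseError(
                    f"{path}:{lineno}: expected >=21 PSL columns, got {len(fields)}"
                )
            try:
                aln = _parse_psl_fields(fields)
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed PSL line: {exc}") from exc
            out.append(aln)
    return out


def _parse_psl_fields(f: Sequence[str]) -> ContigAlignment:
    matches = int(f[0])
    mismatches = int(f[1])
    rep_matches = int(f[2])
    strand = f[8]
    qname = f[9]
    qsize = int(f[10])
    tname = f[13]
    tsize = int(f[14])
    block_count = int(f[17])
    sizes = [int(x) for x in f[18].rstrip(",").split(",") if x]
    qstarts = [int(x) for x in f[19].rstrip(",").split(",") if x]
    tstarts = [int(x) for x in f[20].rstrip(",").split(",") if x]
    if not (len(sizes) == len(qstarts) == len(tstarts) == block_count):
        raise ValueError("block arrays disagree with blockCount")
    # PSL for translated alignments uses 2-char strands; keep query strand only
    qstrand = strand[0]
    blocks: List[Tuple[int, int, int]] = []
    for sz, qs, ts in zip(sizes, qstarts, tstarts):
        if qstrand == "-":
            # PSL minus-strand qStarts are in reverse-complement coordinates
            qs = qsize - (qs + sz)
        blocks.append((qs, ts, sz))
    blocks.sort(key=lambda b: b[0])
    total_matches = matches + rep_matches
    aligned = total_matches + mismatches
    pid = 100.0 * total_matches / aligned if aligned else 0.0
    return ContigAlignment(
        contig_id=qname,
        contig_length=qsize,
        chrom=tname,
        strand=qstrand,
        blocks=blocks,
        matches=total_matches,
        mismatches=mismatches,
        quality=compute_quality(total_matches, mismatches, qsize),
        percent_identity=pid,
        target_length=tsize,
    )


def write_psl(alignments: Sequence[ContigAlignment], path: str) -> None:
    """Write alignments as headerless 21-column PSL (inverse of read_psl)."""
    with open(path, "w") as fh:
        for a in alignments:
            blocks = sorted(a.blocks, key=lambda b: b[0])
            if a.strand == "-":
                psl_blocks = sorted(
                    ((a.contig_length - (c + n), g, n) for c, g, n in blocks),
                    key=lambda b: b[0],
                )
            else:
                psl_blocks = blocks
            qstart = blocks[0][0]
            qend = blocks[-1][0] + blocks[-1][2]
            tstart = min(g for _, g, _ in blocks)
            tend = max(g + n for _, g, n in blocks)
            sizes = ",".join(str(n) for _, _, n in psl_blocks) + ","
            qstarts = ",".join(str(c) for c, _, _ in psl_blocks) + ","
            tstarts = ",".join(str(g) for _, g, _ in psl_blocks) + ","
            row = [
                a.matches, a.mismatches, 0, 0, 0, 0, 0, 0,
                a.strand, a.contig_id, a.contig_length, qstart, qend,
                a.chrom, a.target_length or tend, tstart, tend,
                len(psl_blocks), sizes, qstarts, tstarts,
            ]
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# annotations: genePredExt and BED
# ---------------------------------------------------------------------------


def read_annotations(path: str, kind: str, region_class: str = "repeat"):
    """Read gene models (``kind='genepredext'``) or regions (``kind='bed'``).

    BED records get ``region_class`` (repeat, segmental_duplication or
    struct_rna) attached; start/end stay 0-based half-open.
    """
    if kind == "genepredext":
        return _read_genepredext(path)
    if kind == "bed":
        return _read_bed(path, region_class)
    raise ValueError(f"unknown annotation kind: {kind!r}")


def _read_genepredext(path: str) -> List[GeneModel]:
    out: List[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            # genePredExt: name chrom strand txStart txEnd cdsStart cdsEnd
            # exonCount exonStarts exonEnds score name2 ...
            if len(f) < 10:
                raise ParseError(f"{path}:{lineno}: expected >=10 genePredExt columns")
            exon_count = int(f[7])
            starts = [int(x) for x in f[8].rstrip(",").split(",") if x]
            ends = [int(x) for x in f[9].rstrip(",").split(",") if x]
            if len(starts) != exon_count or len(ends) != exon_count:
                raise ParseError(
                    f"{path}:{lineno}: exonCount {exon_count} disagrees with "
                    f"exonStarts/exonEnds lengths"
                )
            gene_id = f[11] if len(f) > 11 and f[11] else f[0]
            out.append(
                GeneModel(
                    gene_id=gene_id,
                    transcript_id=f[0],
                    chrom=f[1],
                    strand=f[2],
                    exons=list(zip(starts, ends)),
                )
            )
    return out


def write_genepredext(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            tx_start, tx_end = g.span
            starts = ",".join(str(s) for s, _ in g.exons) + ","
            ends = ",".join(str(e) for _, e in g.exons) + ","
            row = [
                g.transcript_id, g.chrom, g.strand, tx_start, tx_end,
                tx_start, tx_end, len(g.exons), starts, ends, 0, g.gene_id,
                "cmpl", "cmpl", ",".join("0" for _ in g.exons) + ",",
            ]
            fh.write("\t".join(str(x) for x in row) + "\n")


def _read_bed(path: str, region_class: str) -> List[AnnotatedRegion]:
    out: List[AnnotatedRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) == 1:
                f = line.split()
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            start, end = int(f[1]), int(f[2])
            if start >= end:
                raise ParseError(f"{path}:{lineno}: BED start >= end")
            out.append(
                AnnotatedRegion(
                    chrom=f[0],
                    start=start,
                    end=end,
                    region_class=region_class,
                    name=f[3] if len(f) > 3 else "",
                )
            )
    return out


# ---------------------------------------------------------------------------
# SAM/BAM
# ---------------------------------------------------------------------------


def _record_has_mismatch(rec: "pysam.AlignedSegment") -> bool:
    """A read counts as mismatch-free only with NM=0 and a pure-match CIGAR."""
    try:
        if rec.get_tag("NM") > 0:
            return True
    except KeyError:
        pass
    for op, _ in rec.cigartuples or []:
        # 1=I, 2=D, 3=N, 4=S, 5=H: indels, splices and clips disqualify
        if op in (1, 2, 4, 5):
            return True
    return False


def _record_blocks(rec: "pysam.AlignedSegment") -> List[Tuple[int, int]]:
    blocks = rec.get_blocks()
    # merge abutting blocks (pysam splits on I as well as N/D)
    merged: List[Tuple[int, int]] = []
    for s, e in blocks:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def read_bam(
    path: str,
    mode: str = "read_to_contig",
    region: Optional[Tuple[str, int, int]] = None,
) -> Iterator[ReadAlignment]:
    """Iterate mapped records of a SAM/BAM file as ReadAlignments.

    ``mode`` is informational (read_to_contig vs read_to_genome); both use
    the same record model. Region queries require an index (BAM only).
    """
    del mode
    save = pysam.set_verbosity(0)
    try:
        af = pysam.AlignmentFile(path, require_index=False, check_sq=False)
    finally:
        pysam.set_verbosity(save)
    try:
        if region is not None:
            if not af.has_index():
                raise OSError(f"{path}: region query requires an index")
            it = af.fetch(region[0], region[1], region[2])
        else:
            it = af.fetch(until_eof=True)
        for rec in it:
            if rec.is_unmapped:
                continue
            yield ReadAlignment(
                read_id=rec.query_name,
                target_id=rec.reference_name,
                target_start=rec.reference_start,
                target_end=rec.reference_end,
                has_mismatch=_record_has_mismatch(rec),
                mate_id=rec.query_name if rec.is_paired else None,
                blocks=_record_blocks(rec),
            )
    finally:
        af.close()


def write_sam(
    reads: Sequence[dict],
    references: Sequence[Tuple[str, int]],
    path: str,
) -> None:
    """Write simple single-end SAM records.

    Each read dict needs: read_id, target_id, target_start, cigar, seq;
    optional: nm (default 0), flag (default 0).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in references],
    }
    ref_index = {name: i for i, (name, _) in enumerate(references)}
    recs = sorted(reads, key=lambda r: (ref_index[r["target_id"]], r["target_start"]))
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for r in recs:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r["read_id"]
            a.query_sequence = r["seq"]
            a.flag = r.get("flag", 0)
            a.reference_id = ref_index[r["target_id"]]
            a.reference_start = r["target_start"]
            a.mapping_quality = 60
            a.cigarstring = r["cigar"]
            a.set_tag("NM", r.get("nm", 0))
            out.write(a)


# ---------------------------------------------------------------------------
# prediction report
# ---------------------------------------------------------------------------

PREDICTION_COLUMNS = [
    "event_type",
    "contig_id",
    "genes",
    "chrom_a",
    "breakpoint_a",
    "strand_a",
    "chrom_b",
    "breakpoint_b",
    "strand_b",
    "topology",
    "exon_boundary_match",
    "total_support",
    "strong_support",
    "filter_failures",
    "relcov_C",
    "relcov_W_star",
    "relcov_T_star",
    "relcov_C_over_W_star",
    "relcov_C_over_T_star",
]


def write_predictions(events: Sequence[dict], path: str) -> None:
    """Write the tab-separated prediction report.

    Breakpoints are converted to 1-based inclusive coordinates. Rows sort
    deterministically by (event_type, chrom, breakpoint, contig).
    """
    rows = []
    for ev in events:
        row = dict(ev)
        for key in ("breakpoint_a", "breakpoint_b"):
            if row.get(key) not in (None, ""):
                row[key] = int(row[key]) + 1  # 0-based -> 1-based inclusive
        rows.append(row)
    rows.sort(
        key=lambda r: (
            str(r.get("event_type", "")),
            str(r.get("chrom_a", "")),
            int(r.get("breakpoint_a", 0) or 0),
            str(r.get("contig_id", "")),
        )
    )
    with open(path, "w") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for row in rows:
            fh.write(
                "\t".join(_fmt_field(row.get(c)) for c in PREDICTION_COLUMNS) + "\n"
            )


def _fmt_field(v) -> str:
    if v is None or v == "":
        return "."
    if isinstance(v, float):
        return f"{v:.6g}"
    if isinstance(v, (list, tuple, set)):
        return ",".join(str(x) for x in sorted(v))
    return str(v)


def read_predictions(path: str) -> List[dict]:
    """Inverse of write_predictions (breakpoints back to 0-based)."""
    out: List[dict] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for raw in fh:
            fields = raw.rstrip("\n").split("\t")
            row = dict(zip(header, fields))
            for key in ("breakpoint_a", "breakpoint_b"):
                if row.get(key) not in (None, ".", ""):
                    row[key] = int(row[key]) - 1
                else:
                    row[key] = None
            out.append(row)
    return out


# ---------------------------------------------------------------------------
# FASTA helpers
# ---------------------------------------------------------------------------


def read_fasta(path: str) -> dict:
    """Load a FASTA file into an id -> sequence dict (uppercased)."""
    seqs: dict = {}
    name = None
    chunks: List[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks).upper()
    return seqs


def write_fasta(seqs: dict, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def dict_fetcher(sequences: dict):
    """Wrap a chrom -> sequence dict as a fetch-by-interval callable."""

    def fetch(chrom: str, start: int, end: int) -> str:
        return sequences[chrom][max(0, start) : end]

    return fetch
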