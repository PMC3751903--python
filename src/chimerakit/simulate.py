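"""Synthetic genomes, chimeric events, reads, and ideal alignment fixtures.

The generator emulates an RNA-seq experiment over a small multi-gene genome:
multi-exon gene models on random sequence, simulated fusion / PTD / ITD
transcripts, paired-end reads with per-transcript coverage drawn from a
two-component log-normal mixture, and the PSL / SAM files a perfect
assembler-plus-aligner would produce for each chimeric contig and read.
Every stage of the detection pipeline is therefore testable without any
external aligner or reference download.

Simulated transcripts shorter than 200 nt are discarded, mirroring standard
practice for assembly-based detection (contigs below typical assembler
output length are not observable).
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .formats import ContigAlignment, GeneModel, compute_quality

BASES = np.array(list("ACGT"))

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


@dataclass
class SyntheticGenome:
    sequences: Dict[str, str]
    genes: List[GeneModel]
    seed: int

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][max(0, start) : end]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def simulate_genome(
    n_chroms: int = 2,
    n_genes: int = 20,
    exon_length: Tuple[int, int] = (120, 400),
    intron_length: Tuple[int, int] = (60, 300),
    n_exons: Tuple[int, int] = (3, 6),
    intergenic: Tuple[int, int] = (200, 500),
    seed: int = 0,
) -> SyntheticGenome:
    """Random multi-chromosome genome with non-overlapping multi-exon genes.

    Fixed seed gives byte-identical output. Genes are laid out left to right
    with intergenic spacers; all genes are on the '+' strand.
    """
    if n_chroms <= 0:
        raise ValueError("n_chroms must be positive")
    if n_genes < 0:
        raise ValueError("n_genes must be non-negative")
    rng = np.random.default_rng(seed)
    per_chrom = [n_genes // n_chroms] * n_chroms
    for i in range(n_genes % n_chroms):
        per_chrom[i] += 1

    genes: List[GeneModel] = []
    sequences: Dict[str, str] = {}
    gi = 0
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        pos = int(rng.integers(intergenic[0], intergenic[1] + 1))
        for _ in range(per_chrom[ci]):
            k = int(rng.integers(n_exons[0], n_exons[1] + 1))
            exons = []
            for ei in range(k):
                if ei > 0:
                    pos += int(rng.integers(intron_length[0], intron_length[1] + 1))
                elen = int(rng.integers(exon_length[0], exon_length[1] + 1))
                exons.append((pos, pos + elen))
                pos += elen
            gi += 1
            genes.append(
                GeneModel(
                    gene_id=f"G{gi:03d}",
                    transcript_id=f"T{gi:03d}",
                    chrom=chrom,
                    strand="+",
                    exons=exons,
                )
            )
            pos += int(rng.integers(intergenic[0], intergenic[1] + 1))
        sequences[chrom] = _random_seq(rng, pos)
    return SyntheticGenome(sequences=sequences, genes=genes, seed=seed)


# ---------------------------------------------------------------------------
# transcript coordinate maps
# ---------------------------------------------------------------------------


class TranscriptMap:
    """Transcript <-> genome coordinate map for a (plus-strand) gene model."""

    def __init__(self, gene: GeneModel):
        self.gene = gene
        self.cum = [0]
        for s, e in gene.exons:
            self.cum.append(self.cum[-1] + (e - s))
        self.length = self.cum[-1]

    def t2g(self, t: int) -> int:
        ei = bisect_right(self.cum, t) - 1
        ei = min(ei, len(self.gene.exons) - 1)
        s, _ = self.gene.exons[ei]
        return s + (t - self.cum[ei])

    def genome_blocks(self, t0: int, t1: int) -> List[Tuple[int, int]]:
        """Genome intervals covered by transcript interval [t0, t1)."""
        blocks = []
        for (s, e), c0, c1 in zip(self.gene.exons, self.cum, self.cum[1:]):
            lo, hi = max(t0, c0), min(t1, c1)
            if lo < hi:
                blocks.append((s + (lo - c0), s + (hi - c0)))
        return blocks

    def sequence(self, genome: SyntheticGenome, t0: int = 0, t1: Optional[int] = None) -> str:
        t1 = self.length if t1 is None else t1
        return "".join(
            genome.fetch(self.gene.chrom, s, e) for s, e in self.genome_blocks(t0, t1)
        )


def transcript_sequence(genome: SyntheticGenome, gene: GeneModel) -> str:
    return TranscriptMap(gene).sequence(genome)


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------


@dataclass
class SimulatedEvent:
    """A simulated chimeric transcript plus its truth record.

    ``parts`` is the chimera layout: ("gene", gene_id, t0, t1) entries are
    transcript intervals of a source gene; ("insert", seq) entries are
    literal inserted bases.
    """

    event_id: str
    event_type: str  # fusion | PTD | ITD
    gene_ids: List[str]
    parts: List[tuple]
    transcript: str
    breakpoints: List[Tuple[str, int]]  # truth (chrom, 0-based position)
    duplicated_segment: Optional[Tuple[str, int, int]] = None
    inserted_bases: int = 0
    coverage: float = 0.0
    contig_id: str = ""
    contig_window: Tuple[int, int] = (0, 0)  # chimera-coordinate window
    junction: int = 0  # chimera coordinate of the chimeric junction

    @property
    def contig_sequence(self) -> str:
        w0, w1 = self.contig_window
        return self.transcript[w0:w1]


def _parts_sequence(parts: Sequence[tuple], genome: SyntheticGenome) -> str:
    chunks = []
    for part in parts:
        if part[0] == "insert":
            chunks.append(part[1])
        else:
            _, gene_id, t0, t1 = part
            chunks.append(TranscriptMap(genome.gene(gene_id)).sequence(genome, t0, t1))
    return "".join(chunks)


def _make_fusion(genome: SyntheticGenome, ga: GeneModel, gb: GeneModel, rng) -> dict:
    ma, mb = TranscriptMap(ga), TranscriptMap(gb)
    k1 = int(rng.integers(1, len(ga.exons)))
    k2 = int(rng.integers(1, len(gb.exons)))
    t_a = ma.cum[k1]
    t_b = mb.cum[len(gb.exons) - k2]
    parts = [("gene", ga.gene_id, 0, t_a), ("gene", gb.gene_id, t_b, mb.length)]
    return dict(
        event_type="fusion",
        gene_ids=[ga.gene_id, gb.gene_id],
        parts=parts,
        breakpoints=[
            (ga.chrom, ga.exons[k1 - 1][1] - 1),
            (gb.chrom, gb.exons[len(gb.exons) - k2][0]),
        ],
        junction=t_a,
    )


def _make_ptd(genome: SyntheticGenome, gene: GeneModel, rng) -> dict:
    m = TranscriptMap(gene)
    n = len(gene.exons)
    a = int(rng.integers(0, n))
    b = int(rng.integers(a, n))
    parts = [("gene", gene.gene_id, 0, m.cum[b + 1]), ("gene", gene.gene_id, m.cum[a], m.length)]
    return dict(
        event_type="PTD",
        gene_ids=[gene.gene_id],
        parts=parts,
        breakpoints=[
            (gene.chrom, gene.exons[b][1] - 1),
            (gene.chrom, gene.exons[a][0]),
        ],
        duplicated_segment=(gene.chrom, gene.exons[a][0], gene.exons[b][1]),
        junction=m.cum[b + 1],
    )


def _make_itd(
    genome: SyntheticGenome,
    gene: GeneModel,
    rng,
    seg_range: Tuple[int, int] = (10, 30),
    max_insert: int = 3,
    end_margin: int = 150,
) -> Optional[dict]:
    # The junction needs flanking transcript sequence on both sides to be
    # assemblable and coverable by read fragments, so duplications are kept
    # at least ``end_margin`` from the transcript ends.
    m = TranscriptMap(gene)
    candidates = []
    for ei, (s, e) in enumerate(gene.exons):
        lo_t = max(m.cum[ei] + 2, end_margin)
        hi_t = min(m.cum[ei + 1] - 2, m.length - end_margin) - seg_range[1]
        if hi_t > lo_t:
            candidates.append((ei, s, e, lo_t, hi_t))
    if not candidates:
        return None
    ei, s, e, lo_t, hi_t = candidates[int(rng.integers(0, len(candidates)))]
    seg = int(rng.integers(seg_range[0], seg_range[1] + 1))
    x_t0 = int(rng.integers(lo_t, hi_t))
    x_g = s + (x_t0 - m.cum[ei])
    ins_max = min(max_insert, seg // 10)
    ins_len = int(rng.integers(0, ins_max + 1)) if ins_max > 0 else 0
    ins_seq = _random_seq(rng, ins_len) if ins_len else ""
    x_t = x_t0
    y_t = x_t + seg
    parts = [("gene", gene.gene_id, 0, y_t)]
    if ins_seq:
        parts.append(("insert", ins_seq))
    parts.append(("gene", gene.gene_id, x_t, m.length))
    return dict(
        event_type="ITD",
        gene_ids=[gene.gene_id],
        parts=parts,
        breakpoints=[(gene.chrom, x_g), (gene.chrom, x_g + seg - 1)],
        duplicated_segment=(gene.chrom, x_g, x_g + seg),
        inserted_bases=ins_len,
        junction=y_t + ins_len,
    )


def _distinct(
    breakpoints: Sequence[Tuple[str, int]],
    events: Sequence["SimulatedEvent"],
    min_separation: int = 25,
) -> bool:
    """Simulated events must be distinguishable: no two may share (near-)
    identical breakpoint pairs, or they would legitimately merge into one
    prediction downstream."""
    new = sorted(breakpoints)
    for ev in events:
        old = sorted(ev.breakpoints)
        if all(
            c1 == c2 and abs(p1 - p2) < min_separation
            for (c1, p1), (c2, p2) in zip(new, old)
        ):
            return False
    return True


def simulate_events(
    genome: SyntheticGenome,
    counts: Dict[str, int],
    seed: int = 0,
    read_length: int = 75,
    min_length: int = 200,
) -> List[SimulatedEvent]:
    """Simulate fusion / PTD / ITD transcripts with truth records.

    Fusions join 5' exons of one gene to 3' exons of another; PTDs duplicate
    whole exon runs (both edges on exon boundaries); ITDs duplicate
    sub-exonic segments, optionally with up to 3 inserted bases between the
    copies. Products shorter than ``min_length`` are discarded. Long
    duplications are later represented by short junction contigs, so each
    PTD records a contig window of 2 x read_length around the junction.
    """
    rng = np.random.default_rng(seed)
    events: List[SimulatedEvent] = []
    gene_pool = list(genome.genes)
    rng.shuffle(gene_pool)
    pool_iter = iter(gene_pool)

    def next_genes(k: int) -> Optional[List[GeneModel]]:
        picked = []
        for _ in range(k):
            g = next(pool_iter, None)
            if g is None:
                # pool exhausted: sample with replacement
                g = genome.genes[int(rng.integers(0, len(genome.genes)))]
            picked.append(g)
        if k == 2 and picked[0].gene_id == picked[1].gene_id:
            return None
        return picked

    idx = 0
    for etype, maker, arity in (
        ("fusion", _make_fusion, 2),
        ("PTD", _make_ptd, 1),
        ("ITD", _make_itd, 1),
    ):
        wanted = counts.get(etype, counts.get(etype.lower(), 0))
        made = 0
        attempts = 0
        while made < wanted and attempts < 20 * max(1, wanted):
            attempts += 1
            genes = next_genes(arity)
            if genes is None:
                continue
            spec = maker(genome, *genes, rng)
            if spec is None:
                continue
            if not _distinct(spec["breakpoints"], events):
                continue
            transcript = _parts_sequence(spec["parts"], genome)
            if len(transcript) < min_length:
                continue
            idx += 1
            junction = spec["junction"]
            if spec["event_type"] == "PTD":
                w0 = max(0, junction - 2 * read_length)
                w1 = min(len(transcript), junction + 2 * read_length)
            else:
                w0, w1 = 0, len(transcript)
            ev = SimulatedEvent(
                event_id=f"ev{idx:03d}",
                event_type=spec["event_type"],
                gene_ids=spec["gene_ids"],
                parts=spec["parts"],
                transcript=transcript,
                breakpoints=spec["breakpoints"],
                duplicated_segment=spec.get("duplicated_segment"),
                inserted_bases=spec.get("inserted_bases", 0),
                contig_id=f"ctg_ev{idx:03d}",
                contig_window=(w0, w1),
                junction=junction,
            )
            events.append(ev)
            made += 1
    return events


# ---------------------------------------------------------------------------
# coverage model
# ---------------------------------------------------------------------------


@dataclass
class CoverageModel:
    """Two-component log-normal mixture for per-transcript read coverage.

    Defaults give a median near 30x with a long right tail, a shape typical
    of deeply sequenced transcriptomes.
    """

    mu1: float = 3.0
    sigma1: float = 0.8
    mu2: float = 4.5
    sigma2: float = 1.0
    weight: float = 0.65  # mixing weight of component 1

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        comp1 = rng.random(n) < self.weight
        out = np.where(
            comp1,
            rng.lognormal(self.mu1, self.sigma1, n),
            rng.lognormal(self.mu2, self.sigma2, n),
        )
        return out

    def cdf(self, x: float) -> float:
        if x <= 0:
            return 0.0

        def phi(z: float) -> float:
            return 0.5 * (1 + math.erf(z / math.sqrt(2)))

        lx = math.log(x)
        return self.weight * phi((lx - self.mu1) / self.sigma1) + (
            1 - self.weight
        ) * phi((lx - self.mu2) / self.sigma2)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


@dataclass
class SimulatedRead:
    read_id: str
    source_id: str  # transcript or event id the read came from
    start: int  # fragment-relative alignment on the source sequence
    end: int
    sequence: str
    mate: int  # 1 or 2
    chimeric: bool = False


def simulate_reads(
    transcripts: Dict[str, str],
    coverages: Dict[str, float],
    read_length: int = 75,
    mean_fragment: int = 114,
    sd_fragment: int = 10,
    seed: int = 0,
    chimeric_ids: Optional[set] = None,
) -> List[SimulatedRead]:
    """Error-free paired-end reads at the requested per-transcript coverage.

    Fragment lengths are normal(mean, sd) clipped to [read_length, |T|];
    mates overlap when the fragment is shorter than two read lengths, as in
    short-fragment libraries. Each read is labeled with its source
    transcript so downstream depth partitions can be checked against truth.
    """
    if mean_fragment < read_length:
        raise ValueError("mean_fragment must be >= read_length")
    rng = np.random.default_rng(seed)
    chimeric_ids = chimeric_ids or set()
    reads: List[SimulatedRead] = []
    for tid in sorted(transcripts):
        seq = transcripts[tid]
        cov = coverages.get(tid, 0.0)
        tlen = len(seq)
        if cov <= 0 or tlen < read_length:
            continue
        n_frags = int(round(cov * tlen / (2 * read_length)))
        for k in range(n_frags):
            flen = int(round(rng.normal(mean_fragment, sd_fragment)))
            flen = max(read_length, min(tlen, flen))
            start = int(rng.integers(0, tlen - flen + 1))
            frag = seq[start : start + flen]
            r1 = frag[:read_length]
            r2 = frag[-read_length:]
            is_chimeric = tid in chimeric_ids
            reads.append(
                SimulatedRead(
                    read_id=f"{tid}:{k}",
                    source_id=tid,
                    start=start,
                    end=start + read_length,
                    sequence=r1,
                    mate=1,
                    chimeric=is_chimeric,
                )
            )
            reads.append(
                SimulatedRead(
                    read_id=f"{tid}:{k}",
                    source_id=tid,
                    start=start + flen - read_length,
                    end=start + flen,
                    sequence=r2,
                    mate=2,
                    chimeric=is_chimeric,
                )
            )
    return reads


def simulate_reads_tiled(
    transcripts: Dict[str, str],
    coverages: Dict[str, float],
    read_length: int = 75,
    chimeric_ids: Optional[set] = None,
) -> List[SimulatedRead]:
    """Single-end reads tiled at even spacing for exact per-position depth.

    Every position (away from the transcript edges) is covered by almost
    exactly ``coverage`` reads, so depth summaries carry no sampling-extremum
    noise; useful when checking estimators rather than sampling behavior.
    """
    chimeric_ids = chimeric_ids or set()
    reads: List[SimulatedRead] = []
    for tid in sorted(transcripts):
        seq = transcripts[tid]
        cov = coverages.get(tid, 0.0)
        tlen = len(seq)
        if cov <= 0 or tlen < read_length:
            continue
        span = tlen - read_length
        n = int(round(cov * span / read_length)) + 1
        for k in range(n):
            start = round(k * span / max(1, n - 1)) if n > 1 else 0
            reads.append(
                SimulatedRead(
                    read_id=f"{tid}:t{k}",
                    source_id=tid,
                    start=start,
                    end=start + read_length,
                    sequence=seq[start : start + read_length],
                    mate=1,
                    chimeric=tid in chimeric_ids,
                )
            )
    return reads


def write_fastq(reads: Sequence[SimulatedRead], path_r1: str, path_r2: str) -> None:
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for r in reads:
            fh = f1 if r.mate == 1 else f2
            seq = r.sequence if r.mate == 1 else revcomp(r.sequence)
            fh.write(f"@{r.read_id}/{r.mate}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# ideal alignments
# ---------------------------------------------------------------------------


def _perfect_alignment(
    contig_id: str,
    contig_length: int,
    chrom: str,
    blocks: List[Tuple[int, int, int]],
) -> ContigAlignment:
    matches = sum(n for _, _, n in blocks)
    return ContigAlignment(
        contig_id=contig_id,
        contig_length=contig_length,
        chrom=chrom,
        strand="+",
        blocks=blocks,
        matches=matches,
        mismatches=0,
        quality=compute_quality(matches, 0, contig_length),
        percent_identity=100.0,
        target_length=0,
    )


def _piece_blocks(
    genome: SyntheticGenome,
    gene_id: str,
    t0: int,
    t1: int,
    contig_offset: int,
) -> Tuple[str, List[Tuple[int, int, int]]]:
    m = TranscriptMap(genome.gene(gene_id))
    blocks = []
    c = contig_offset
    for g0, g1 in m.genome_blocks(t0, t1):
        blocks.append((c, g0, g1 - g0))
        c += g1 - g0
    return m.gene.chrom, blocks


def wildtype_contig_alignment(
    genome: SyntheticGenome, gene: GeneModel, contig_id: Optional[str] = None
) -> ContigAlignment:
    m = TranscriptMap(gene)
    chrom, blocks = _piece_blocks(genome, gene.gene_id, 0, m.length, 0)
    return _perfect_alignment(contig_id or f"ctg_{gene.transcript_id}", m.length, chrom, blocks)


def event_contig_alignments(
    event: SimulatedEvent, genome: SyntheticGenome
) -> List[ContigAlignment]:
    """The contig-to-genome alignments a perfect aligner would report.

    Fusions and PTD junction contigs yield two split alignments; ITDs yield
    one gapped alignment whose query gap is the second copy (plus any
    inserted bases).
    """
    w0, w1 = event.contig_window
    clen = w1 - w0
    cid = event.contig_id

    if event.event_type == "fusion":
        (_, ga, a0, a1), (_, gb, b0, b1) = event.parts
        chrom_a, blocks_a = _piece_blocks(genome, ga, a0, a1, 0)
        chrom_b, blocks_b = _piece_blocks(genome, gb, b0, b1, a1 - a0)
        return [
            _perfect_alignment(cid, clen, chrom_a, blocks_a),
            _perfect_alignment(cid, clen, chrom_b, blocks_b),
        ]

    if event.event_type == "PTD":
        (_, g, _, p1_end), (_, _, p2_start, _) = event.parts
        junction = event.junction
        # piece 1: transcript interval ending at the junction
        t1_lo = p1_end - (junction - w0)
        chrom, blocks1 = _piece_blocks(genome, g, t1_lo, p1_end, 0)
        # piece 2: transcript interval starting back at the duplicated run
        t2_hi = p2_start + (w1 - junction)
        _, blocks2 = _piece_blocks(genome, g, p2_start, t2_hi, junction - w0)
        return [
            _perfect_alignment(cid, clen, chrom, blocks1),
            _perfect_alignment(cid, clen, chrom, blocks2),
        ]

    # ITD: single gapped alignment; second copy + insert is the query gap
    parts = event.parts
    gene_id = parts[0][1]
    y_t = parts[0][3]
    x_t = parts[-1][2]
    L = parts[-1][3]
    seg = y_t - x_t
    ins = event.inserted_bases
    chrom, blocks_a = _piece_blocks(genome, gene_id, 0, y_t, 0)
    _, blocks_b = _piece_blocks(genome, gene_id, y_t, L, y_t + ins + seg)
    return [_perfect_alignment(cid, clen, chrom, blocks_a + blocks_b)]


def reads_to_contig_records(
    event: SimulatedEvent, reads: Sequence[SimulatedRead], read_length: int = 75
) -> List[dict]:
    """SAM records of chimeric reads onto the event contig.

    Only reads that fall entirely inside the contig window are kept (a
    perfect aligner would clip boundary reads, disqualifying them from
    mismatch-free support anyway).
    """
    w0, w1 = event.contig_window
    out = []
    for r in reads:
        if r.source_id != event.event_id:
            continue
        if r.start < w0 or r.end > w1:
            continue
        out.append(
            dict(
                read_id=f"{r.read_id}/{r.mate}",
                target_id=event.contig_id,
                target_start=r.start - w0,
                cigar=f"{r.end - r.start}M",
                seq=r.sequence,
                nm=0,
            )
        )
    return out


def _chimera_part_spans(event: SimulatedEvent) -> List[Tuple[int, int, tuple]]:
    spans = []
    pos = 0
    for part in event.parts:
        if part[0] == "insert":
            plen = len(part[1])
        else:
            plen = part[3] - part[2]
        spans.append((pos, pos + plen, part))
        pos += plen
    return spans


def _blocks_to_cigar(
    blocks: List[Tuple[int, int]], lead_clip: int, tail_clip: int
) -> str:
    ops = []
    if lead_clip:
        ops.append(f"{lead_clip}S")
    prev_end = None
    for s, e in blocks:
        if prev_end is not None and s > prev_end:
            ops.append(f"{s - prev_end}N")
        ops.append(f"{e - s}M")
        prev_end = e
    if tail_clip:
        ops.append(f"{tail_clip}S")
    return "".join(ops)


def read_to_genome_record(
    read: SimulatedRead,
    genome: SyntheticGenome,
    event: Optional[SimulatedEvent] = None,
    wildtype_gene: Optional[GeneModel] = None,
) -> Optional[dict]:
    """Genome alignment of one read: spliced for wild-type reads, clipped at
    chimeric junctions for event reads (the longer side stays aligned)."""
    if wildtype_gene is not None:
        m = TranscriptMap(wildtype_gene)
        blocks = m.genome_blocks(read.start, read.end)
        if not blocks:
            return None
        return dict(
            read_id=f"{read.read_id}/{read.mate}",
            target_id=wildtype_gene.chrom,
            target_start=blocks[0][0],
            cigar=_blocks_to_cigar(blocks, 0, 0),
            seq=read.sequence,
            nm=0,
        )

    assert event is not None
    spans = _chimera_part_spans(event)
    overlaps = []
    for lo, hi, part in spans:
        o0, o1 = max(read.start, lo), min(read.end, hi)
        if o0 < o1 and part[0] == "gene":
            overlaps.append((o1 - o0, lo, hi, part, o0, o1))
    if not overlaps:
        return None
    overlaps.sort(key=lambda x: (-x[0], x[1]))
    _, lo, hi, part, o0, o1 = overlaps[0]
    _, gene_id, t0, _ = part
    m = TranscriptMap(genome.gene(gene_id))
    blocks = m.genome_blocks(t0 + (o0 - lo), t0 + (o1 - lo))
    if not blocks:
        return None
    lead_clip = o0 - read.start
    tail_clip = read.end - o1
    return dict(
        read_id=f"{read.read_id}/{read.mate}",
        target_id=m.gene.chrom,
        target_start=blocks[0][0],
        cigar=_blocks_to_cigar(blocks, lead_clip, tail_clip),
        seq=read.sequence,
        nm=0,
    )


def synthesize_alignments(
    genome: SyntheticGenome,
    events: Sequence[SimulatedEvent],
    wildtype_genes: Sequence[GeneModel] = (),
) -> Tuple[List[ContigAlignment], Dict[str, str]]:
    """Ideal contig-to-genome alignments + contig sequences for all contigs.

    Returns the PSL-ready alignment list and a contig_id -> sequence dict
    covering event contigs and full-length wild-type contigs.
    """
    alignments: List[ContigAlignment] = []
    contigs: Dict[str, str] = {}
    for ev in events:
        alignments.extend(event_contig_alignments(ev, genome))
        contigs[ev.contig_id] = ev.contig_sequence
    for gene in wildtype_genes:
        aln = wildtype_contig_alignment(genome, gene)
        alignments.append(aln)
        contigs[aln.contig_id] = transcript_sequence(genome, gene)
    return alignments, contigs
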