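"""Strand-aware read classification, antisense readthrough detection, and
splice-acceptor disruption consequence prediction.

Reads are single stranded intervals (no split/junction reads); readthrough
is called from coverage geometry on the strand of the tail-to-tail flank,
not from transcript assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from epitrio.io_formats import GeneModel, GenomicInterval
from epitrio.trioscan import TrioCall

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StrandedRead:
    interval: GenomicInterval


@dataclass
class GeneReadCounts:
    gene_id: str
    sense: int
    antisense: int


@dataclass
class ReadthroughCall:
    trio: TrioCall
    antisense_fraction_f2: float
    contiguous_with_r3: bool
    sense_antisense_ratio_f2: Optional[float]  # antisense/sense; None if no sense
    is_readthrough: bool


@dataclass
class SpliceConsequence:
    variant_pos: int
    hit: str  # "acceptor_minus1" | "acceptor_minus2" | "none"
    affected_intron: Optional[int]  # 1-based, transcription order
    predicted: str  # "terminal_exon_skipped_polyA_lost" | "internal_exon_skipped" | "none"
    note: str = ""


def classify_reads(
    reads: Sequence[StrandedRead],
    genes: Sequence[GeneModel],
    orientation: str = "forward",
) -> tuple[dict[str, GeneReadCounts], int]:
    """Count sense/antisense reads per gene body; returns (counts, intergenic).

    A read overlapping a gene body counts sense when strands match (after
    applying the library orientation), antisense otherwise; reads spanning
    several genes count toward each.
    """
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"unknown orientation {orientation!r}")
    counts = {g.gene_id: GeneReadCounts(g.gene_id, 0, 0) for g in genes}
    intergenic = 0
    multi = 0
    for read in reads:
        iv = read.interval
        strand = iv.strand
        if orientation == "reverse":
            strand = "-" if strand == "+" else "+"
        hits = [g for g in genes if iv.overlaps(g.interval)]
        if not hits:
            intergenic += 1
            continue
        if len(hits) > 1:
            multi += 1
        for g in hits:
            if strand == g.strand:
                counts[g.gene_id].sense += 1
            else:
                counts[g.gene_id].antisense += 1
    if multi:
        logger.info("classify_reads: %d reads overlapped multiple genes", multi)
    return counts, intergenic


def _coverage(
    reads: Sequence[StrandedRead],
    span: GenomicInterval,
    strand: str,
    orientation: str = "forward",
) -> np.ndarray:
    """Per-base coverage on one strand over a half-open span."""
    cov = np.zeros(len(span), dtype=np.int64)
    for read in reads:
        iv = read.interval
        if iv.chrom != span.chrom:
            continue
        s = iv.strand
        if orientation == "reverse":
            s = "-" if s == "+" else "+"
        if s != strand:
            continue
        lo = max(iv.start, span.start)
        hi = min(iv.end, span.end)
        if lo < hi:
            cov[lo - span.start : hi - span.start] += 1
    return cov


def detect_readthrough(
    reads: Sequence[StrandedRead],
    trio: TrioCall,
    genes: Sequence[GeneModel],
    min_depth: int = 5,
    min_fraction: float = 0.5,
    min_ratio: float = 1.0,
    orientation: str = "forward",
) -> ReadthroughCall:
    """Call antisense readthrough from the tail-to-tail flank across the
    middle gene of a trio.

    Coverage is computed on the tail flank's strand. The antisense fraction
    is the share of middle-gene body bases at depth >= min_depth on that
    strand; contiguity requires a single covered run with at least one
    covered base on each side of the overlap junction, reaching from inside
    the tail flank's body into the middle gene. The call is positive when
    contiguity holds, the fraction reaches min_fraction, and the
    antisense/sense coverage ratio over the middle gene reaches min_ratio.
    """
    by_id = {g.gene_id: g for g in genes}
    try:
        middle = by_id[trio.middle]
    except KeyError:
        raise ValueError(f"trio middle gene {trio.middle!r} not in annotation")
    # the tail-to-tail flank sits 3' of the middle gene in transcription order
    tail_id = trio.right if middle.strand == "+" else trio.left
    if tail_id not in by_id:
        raise ValueError(f"trio lacks its tail-to-tail flank {tail_id!r}")
    tail = by_id[tail_id]
    anti_strand = tail.strand

    span_start = min(middle.interval.start, tail.interval.start)
    span_end = max(middle.interval.end, tail.interval.end)
    span = GenomicInterval(middle.chrom, span_start, span_end, "+")
    anti_cov = _coverage(reads, span, anti_strand, orientation)
    sense_cov = _coverage(reads, span, middle.strand, orientation)

    mid_lo = middle.interval.start - span_start
    mid_hi = middle.interval.end - span_start
    covered = anti_cov >= min_depth
    frac = float(np.mean(covered[mid_lo:mid_hi]))

    # junction = boundary of the tail/middle overlap interior to the middle gene
    if middle.strand == "+":
        junction = tail.interval.start  # overlap is [tail.start, middle.end)
    else:
        junction = tail.interval.end  # overlap is [middle.start, tail.end)
    j = junction - span_start
    contiguous = False
    if 0 < j < len(covered) and covered[j - 1] and covered[j]:
        # walk the single run containing the junction
        lo = j
        while lo > 0 and covered[lo - 1]:
            lo -= 1
        hi = j
        while hi < len(covered) and covered[hi]:
            hi += 1
        run = GenomicInterval(span.chrom, span_start + lo, span_start + hi, "+")
        contiguous = (
            run.overlap_length(tail.interval) > 0
            and run.overlap_length(middle.interval) > 0
        )

    anti_total = int(anti_cov[mid_lo:mid_hi].sum())
    sense_total = int(sense_cov[mid_lo:mid_hi].sum())
    ratio = (anti_total / sense_total) if sense_total > 0 else None
    ratio_ok = ratio is None and anti_total > 0 or (ratio is not None and ratio >= min_ratio)
    return ReadthroughCall(
        trio=trio,
        antisense_fraction_f2=frac,
        contiguous_with_r3=contiguous,
        sense_antisense_ratio_f2=ratio,
        is_readthrough=bool(contiguous and frac >= min_fraction and ratio_ok),
    )


def acceptor_disruption(gene: GeneModel, variant_pos: int) -> SpliceConsequence:
    """Predict the consequence of a variant at a canonical splice acceptor.

    For each intron (transcription order) the acceptor dinucleotide is the
    last two intronic bases before the downstream exon. A hit on the
    terminal exon's acceptor predicts terminal-exon skipping with loss of
    the polyA signal; other introns predict internal exon skipping.
    """
    if len(gene.exons) < 2:
        raise ValueError(f"gene {gene.gene_id} needs >= 2 exons")
    iv = gene.interval
    if not (iv.start <= variant_pos < iv.end):
        return SpliceConsequence(
            variant_pos, "none", None, "none", note="variant outside gene span"
        )
    exons = gene.exons_transcription_order()
    n_introns = len(exons) - 1
    for k in range(n_introns):
        downstream = exons[k + 1]
        if gene.strand == "+":
            minus1 = downstream.start - 1
            minus2 = downstream.start - 2
        else:
            minus1 = downstream.end
            minus2 = downstream.end + 1
        hit = None
        if variant_pos == minus1:
            hit = "acceptor_minus1"
        elif variant_pos == minus2:
            hit = "acceptor_minus2"
        if hit:
            terminal = k + 1 == n_introns
            return SpliceConsequence(
                variant_pos,
                hit,
                k + 1,
                "terminal_exon_skipped_polyA_lost" if terminal
                else "internal_exon_skipped",
            )
    return SpliceConsequence(variant_pos, "none", None, "none")
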