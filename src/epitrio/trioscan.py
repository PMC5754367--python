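"""Sense-antisense gene-pair and trio scanning.

Finds tail-to-tail and head-to-head sense-antisense gene pairs (SAGPs) from
transcript-level intervals and assembles reverse-forward-reverse (R1F2R3)
and forward-reverse-forward (F1R2F1) trios in which the head-to-head pair
shares a bidirectional-promoter CpG island.

Geometry conventions (0-based half-open): a plus-strand gene's 3' end is
its ``end`` and 5' end its ``start``; mirrored for minus strand. Only
end-to-end partial overlaps qualify — containment is excluded from both
pair geometries.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from epitrio.io_formats import GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

DEFAULT_PROMOTER_WINDOW = 1000


@dataclass
class SagpPair:
    gene_a: GeneModel  # plus-strand member
    gene_b: GeneModel  # minus-strand member
    geometry: str  # "tail_to_tail" | "head_to_head"
    overlap: Optional[GenomicInterval] = None  # None for proximal head-to-head
    gap: Optional[int] = None  # set for proximal divergent pairs

    @property
    def gene_ids(self) -> tuple[str, str]:
        return (self.gene_a.gene_id, self.gene_b.gene_id)


@dataclass
class TrioCall:
    pattern: str  # "R1F2R3" | "F1R2F1"
    left: str  # flank gene id, genomic order
    middle: str
    right: str
    shared_island: GenomicInterval
    promoter_window: int
    joint_overlap: int  # island bases shared with both promoter windows


def _is_tail_to_tail(plus: GeneModel, minus: GeneModel) -> bool:
    p, m = plus.interval, minus.interval
    if p.chrom != m.chrom:
        return False
    # overlap must contain both 3' ends: strict partial overlap, plus gene
    # to the left. Containment fails the chained inequality.
    return p.start < m.start <= p.end <= m.end and p.end > m.start


def _is_head_to_head_overlap(plus: GeneModel, minus: GeneModel) -> bool:
    p, m = plus.interval, minus.interval
    if p.chrom != m.chrom:
        return False
    # overlap must contain both 5' ends: minus gene to the left.
    return m.start < p.start <= m.end <= p.end and m.end > p.start


def _divergent_gap(plus: GeneModel, minus: GeneModel) -> Optional[int]:
    """Gap between a divergent non-overlapping minus/plus gene pair."""
    p, m = plus.interval, minus.interval
    if p.chrom != m.chrom or m.end > p.start:
        return None
    return p.start - m.end


def find_tail_to_tail(genes: Sequence[GeneModel]) -> list[SagpPair]:
    """All tail-to-tail SAGPs among the given genes."""
    pairs = []
    plus = [g for g in genes if g.strand == "+"]
    minus = [g for g in genes if g.strand == "-"]
    for p in plus:
        for m in minus:
            if _is_tail_to_tail(p, m):
                pairs.append(
                    SagpPair(
                        gene_a=p,
                        gene_b=m,
                        geometry="tail_to_tail",
                        overlap=GenomicInterval(
                            p.chrom, m.interval.start, p.interval.end, "+"
                        ),
                    )
                )
    return pairs


def find_head_to_head(
    genes: Sequence[GeneModel],
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
) -> list[SagpPair]:
    """All head-to-head SAGPs: 5'-overlapping, or divergent non-overlapping
    with a gap of at most ``promoter_window`` (proximal head-to-head)."""
    pairs = []
    plus = [g for g in genes if g.strand == "+"]
    minus = [g for g in genes if g.strand == "-"]
    for p in plus:
        for m in minus:
            if _is_head_to_head_overlap(p, m):
                pairs.append(
                    SagpPair(
                        gene_a=p,
                        gene_b=m,
                        geometry="head_to_head",
                        overlap=GenomicInterval(
                            p.chrom, p.interval.start, m.interval.end, "+"
                        ),
                    )
                )
            else:
                gap = _divergent_gap(p, m)
                if gap is not None and gap <= promoter_window:
                    pairs.append(
                        SagpPair(gene_a=p, gene_b=m, geometry="head_to_head", gap=gap)
                    )
    return pairs


def promoter_interval(gene: GeneModel, window: int) -> GenomicInterval:
    """TSS +/- window, clipped at 0."""
    tss = gene.tss
    return GenomicInterval(
        gene.chrom, max(0, tss - window), tss + window + 1, gene.strand
    )


def _joint_island_overlap(
    island: GenomicInterval, prom_a: GenomicInterval, prom_b: GenomicInterval
) -> int:
    oa = island.overlap_length(prom_a)
    ob = island.overlap_length(prom_b)
    if oa == 0 or ob == 0:
        return 0
    return min(oa, ob)


def find_trios(
    genes: Sequence[GeneModel],
    islands: Sequence[GenomicInterval],
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
) -> list[TrioCall]:
    """Assemble trios from tail-to-tail pairs, a head-to-head flank, and a
    CpG island overlapping both promoter windows of the head-to-head pair.

    R1F2R3: plus-strand middle gene, minus-strand flanks; F1R2F1 is the
    strand mirror. Each trio is reported once, with the island of maximal
    joint overlap.
    """
    genes = _dedupe(genes)
    t2t = find_tail_to_tail(genes)
    h2h = find_head_to_head(genes, promoter_window)

    # index head-to-head partners by gene id for the trio assembly loop
    head_partners: dict[str, list[GeneModel]] = {}
    for hh in h2h:
        head_partners.setdefault(hh.gene_a.gene_id, []).append(hh.gene_b)
        head_partners.setdefault(hh.gene_b.gene_id, []).append(hh.gene_a)

    trios: list[TrioCall] = []
    seen: set[tuple[str, str, str]] = set()
    for pair in t2t:
        plus_gene, minus_gene = pair.gene_a, pair.gene_b
        for middle, tail_flank in ((plus_gene, minus_gene), (minus_gene, plus_gene)):
            for head_flank in head_partners.get(middle.gene_id, []):
                if head_flank.gene_id == tail_flank.gene_id:
                    continue
                if head_flank.strand == middle.strand:
                    continue  # antisense criterion
                prom_mid = promoter_interval(middle, promoter_window)
                prom_head = promoter_interval(head_flank, promoter_window)
                best = None
                best_overlap = 0
                for island in islands:
                    jo = _joint_island_overlap(island, prom_mid, prom_head)
                    if jo > best_overlap:
                        best, best_overlap = island, jo
                if best is None:
                    continue
                ordered = sorted(
                    (head_flank, middle, tail_flank), key=lambda g: g.interval.start
                )
                if ordered[1].gene_id != middle.gene_id:
                    continue  # middle gene must sit between the flanks
                key = tuple(g.gene_id for g in ordered)
                if key in seen:
                    continue
                seen.add(key)
                trios.append(
                    TrioCall(
                        pattern="R1F2R3" if middle.strand == "+" else "F1R2F1",
                        left=ordered[0].gene_id,
                        middle=ordered[1].gene_id,
                        right=ordered[2].gene_id,
                        shared_island=best,
                        promoter_window=promoter_window,
                        joint_overlap=best_overlap,
                    )
                )
    return trios


def _dedupe(genes: Sequence[GeneModel]) -> list[GeneModel]:
    seen: set[str] = set()
    out = []
    dup = 0
    for g in genes:
        if g.gene_id in seen:
            dup += 1
            continue
        seen.add(g.gene_id)
        out.append(g)
    if dup:
        logger.warning("find_trios: %d duplicate gene ids dropped", dup)
    return out


def summarize_patterns(trios: Sequence[TrioCall]) -> dict[str, int]:
    counts = Counter(t.pattern for t in trios)
    return {"R1F2R3": counts.get("R1F2R3", 0), "F1R2F1": counts.get("F1R2F1", 0)}


def write_pairs_tsv(path, pairs: Sequence[SagpPair]) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("gene_plus\tgene_minus\tgeometry\toverlap_start\toverlap_end\tgap\n")
        for p in pairs:
            ostart = p.overlap.start if p.overlap else "NA"
            oend = p.overlap.end if p.overlap else "NA"
            gap = p.gap if p.gap is not None else "NA"
            fh.write(
                f"{p.gene_a.gene_id}\t{p.gene_b.gene_id}\t{p.geometry}\t"
                f"{ostart}\t{oend}\t{gap}\n"
            )


def write_trios_tsv(path, trios: Sequence[TrioCall]) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(
            "pattern\tleft\tmiddle\tright\tisland_chrom\tisland_start\t"
            "island_end\tjoint_overlap\n"
        )
        for t in trios:
            fh.write(
                f"{t.pattern}\t{t.left}\t{t.middle}\t{t.right}\t"
                f"{t.shared_island.chrom}\t{t.shared_island.start}\t"
                f"{t.shared_island.end}\t{t.joint_overlap}\n"
            )
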