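"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open; conversions to and from
1-based conventions (GFF3) happen only at the parse/serialize boundary.
Strand is mandatory internally; strandless BED input defaults to "+".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed row in an input file (carries the line number)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open stranded genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GeneModel:
    """A gene with its transcript interval and ordered exon list.

    ``tss``/``tes`` are single base positions mirrored by strand: the TSS of
    a minus-strand gene is ``interval.end - 1``.
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.interval.chrom or exon.strand != self.interval.strand:
                raise ValueError(
                    f"gene {self.gene_id}: exon chrom/strand mismatch"
                )
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ValueError(
                    f"gene {self.gene_id}: exon [{exon.start},{exon.end}) "
                    f"outside gene span"
                )
            if prev_end is not None and exon.start < prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = exon.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    def exons_transcription_order(self) -> list[GenomicInterval]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, columns: int = 6) -> list[GenomicInterval]:
    """Read a BED3 or BED6 file into intervals.

    Strand defaults to "+" for 3-column input (logged once per file).
    """
    if columns not in (3, 6):
        raise ValueError(f"columns must be 3 or 6, got {columns}")
    intervals: list[GenomicInterval] = []
    defaulted = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < columns:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {columns} fields, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if columns == 6:
                strand = fields[5]
            else:
                strand = "+"
                defaulted = True
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if defaulted:
        logger.warning("%s: strandless BED input, strand defaulted to '+'", path)
    return intervals


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval],
              columns: int = 6) -> None:
    with open(path, "w", newline="\n") as fh:
        for iv in intervals:
            if columns == 3:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Gene models (GFF3 subset / BED12)
# ---------------------------------------------------------------------------

def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gene_models(path: str | Path, dialect: str = "gff3") -> list[GeneModel]:
    """Read gene models from a GFF3 subset (gene/exon rows) or BED12.

    GFF3 is 1-based inclusive and converted to internal 0-based half-open.
    """
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'gff3' or 'bed12')")


def _read_gff3(path: str | Path) -> list[GeneModel]:
    genes: dict[str, GenomicInterval] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 fields")
            chrom, _source, ftype, start1, end1, _score, strand, _phase, attr = fields[:9]
            try:
                start = int(start1) - 1  # 1-based inclusive -> 0-based half-open
                end = int(end1)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            attrs = _parse_gff3_attributes(attr)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ParseError(f"{path}:{lineno}: gene row lacks ID attribute")
                genes[gid] = GenomicInterval(chrom, start, end, strand)
                order.append(gid)
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise ParseError(f"{path}:{lineno}: exon row lacks Parent attribute")
                exons.setdefault(parent, []).append(
                    GenomicInterval(chrom, start, end, strand)
                )
    models = []
    for gid in order:
        exon_list = sorted(exons.get(gid, []), key=lambda e: e.start)
        models.append(GeneModel(gid, genes[gid], exon_list))
    return models


def _read_bed12(path: str | Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 BED12 fields")
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            name, strand = fields[3], fields[5]
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != len(offsets):
                raise ParseError(
                    f"{path}:{lineno}: blockSizes/blockStarts length mismatch"
                )
            interval = GenomicInterval(chrom, start, end, strand)
            exon_list = [
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(offsets, sizes)
            ]
            models.append(GeneModel(name, interval, exon_list))
    return models


def write_gff3(path: str | Path, genes: Sequence[GeneModel]) -> None:
    """Serialize gene models as a GFF3 subset; 0-based half-open -> 1-based."""
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            iv = gene.interval
            fh.write(
                f"{iv.chrom}\tepitrio\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={gene.gene_id}\n"
            )
            for i, exon in enumerate(gene.exons, start=1):
                fh.write(
                    f"{exon.chrom}\tepitrio\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{exon.strand}\t.\tID={gene.gene_id}.e{i};Parent={gene.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Beta-matrix TSV
# ---------------------------------------------------------------------------

def read_beta_matrix(path: str | Path):
    """Read a beta-matrix TSV (probe_id, chrom, pos, one column per subject).

    Returns a :class:`epitrio.methylome.BetaMatrix` with probes sorted by
    (chrom, pos); empty cells become missing values.
    """
    import numpy as np
    import pandas as pd

    from epitrio.methylome import BetaMatrix

    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    expected = ["probe_id", "chrom", "pos"]
    if list(df.columns[:3]) != expected:
        raise ParseError(
            f"{path}: header must start with {expected}, got {list(df.columns[:3])}"
        )
    if df["probe_id"].duplicated().any():
        dups = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValueError(f"{path}: duplicate probe ids {dups}")
    subjects = list(df.columns[3:])
    values = df[subjects].to_numpy(dtype=float)  # empty cells -> NaN
    finite = values[np.isfinite(values)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        raise ValueError(f"{path}: beta values must lie in [0, 1]")
    return BetaMatrix(
        probe_ids=df["probe_id"].tolist(),
        chroms=df["chrom"].tolist(),
        positions=df["pos"].astype(int).tolist(),
        subjects=subjects,
        values=values.T,  # subjects x probes
    ).sorted_by_position()


def write_beta_matrix(path: str | Path, matrix) -> None:
    import numpy as np

    with open(path, "w", newline="\n") as fh:
        fh.write("probe_id\tchrom\tpos\t" + "\t".join(matrix.subjects) + "\n")
        for j in range(matrix.n_probes):
            cells = []
            for i in range(matrix.n_subjects):
                v = matrix.values[i, j]
                cells.append("" if not np.isfinite(v) else format(v, ".6g"))
            fh.write(
                f"{matrix.probe_ids[j]}\t{matrix.chroms[j]}\t"
                f"{matrix.positions[j]}\t" + "\t".join(cells) + "\n"
            )
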