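"""Synthetic data generation for every pipeline stage.

Generates a trio locus with a bidirectional-promoter CpG island, bisulfite
clone populations with a planted mono-allelic epimutation tagged by a SNP,
control cohorts of beta values with planted rare heterozygous carriers,
stranded read sets with optional antisense readthrough, decoy-rich gene
annotations with planted trios, and pedigree variant tables with one
planted segregating splice-acceptor variant. All generators are
deterministic given a seed: identical configs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from epitrio.io_formats import (
    GeneModel,
    GenomicInterval,
    write_bed,
    write_beta_matrix,
    write_gff3,
)
from epitrio.methylome import BetaMatrix
from epitrio.segregation import VariantRecord, write_status_tsv, write_variant_tsv


@dataclass
class SimulationConfig:
    seed: int = 0
    # locus geometry (coordinates on a synthetic chromosome)
    chrom: str = "chrS"
    n_cpg: int = 32
    island_span: tuple[int, int] = (1400, 1863)
    snp_alleles: tuple[str, str] = ("G", "T")  # (epiallele tag, other)
    # clone parameters
    n_clones_per_allele: int = 30
    conversion_efficiency: float = 0.99
    base_error_rate: float = 0.0
    # cohort parameters
    n_controls: int = 1040
    n_cases: int = 3
    n_planted_carriers: int = 1
    block_size: int = 8
    n_flank_probes: int = 6
    uu_shape: tuple[float, float] = (2.0, 18.0)  # Beta params, mean 0.1
    pm_shape: tuple[float, float] = (50.0, 50.0)  # mean 0.5
    mm_shape: tuple[float, float] = (18.0, 2.0)  # mean 0.9
    # read parameters
    n_reads: int = 10000
    readthrough_frac: float = 0.0
    read_length: int = 100
    readthrough_read_length: int = 150
    # annotation parameters
    n_planted_r1f2r3: int = 50
    n_planted_f1r2f1: int = 10
    n_decoy_trios: int = 500
    # variant parameters
    n_decoy_variants: int = 100
    pedigree: dict[str, str] = field(
        default_factory=lambda: {
            "S1": "carrier", "S2": "carrier", "S3": "carrier",
            "S4": "non_carrier", "S5": "non_carrier", "S6": "non_carrier",
        }
    )

    @classmethod
    def from_file(cls, path: str | Path, seed: Optional[int] = None
                  ) -> "SimulationConfig":
        """Parse a flat key=value config file; unknown keys are rejected."""
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                kwargs[key] = _parse_value(key, value)
        cfg = cls(**kwargs)
        if seed is not None:
            cfg.seed = seed
        return cfg


def _parse_value(key: str, value: str):
    if key == "chrom":
        return value
    if key == "pedigree":
        return dict(item.split(":") for item in value.split(","))
    if "," in value:
        parts = [p.strip() for p in value.split(",")]
        if key == "snp_alleles":
            return tuple(parts)
        return tuple(float(p) if "." in p else int(p) for p in parts)
    try:
        return int(value)
    except ValueError:
        return float(value)


@dataclass
class TruthRecord:
    planted_carriers: list[str] = field(default_factory=list)
    planted_epimutation_allele: Optional[str] = None
    planted_trios: list[dict] = field(default_factory=list)
    planted_variant: Optional[dict] = None
    snp_offset: Optional[int] = None
    block_probes: list[str] = field(default_factory=list)
    acceptor_positions: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", newline="\n") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class SyntheticLocus:
    reference_seq: str  # island region sequence (epigram reference)
    region: GenomicInterval
    snp_offset: int
    snp_alleles: tuple[str, str]
    genes: list[GeneModel]  # R1, F2, R3
    island: GenomicInterval
    truth: TruthRecord


# ---------------------------------------------------------------------------
# locus
# ---------------------------------------------------------------------------

_R1_SPAN = (100, 1550)
_F2_SPAN = (1500, 3500)
_R3_SPAN = (3400, 4900)


def _trio_gene_models(chrom: str, offset: int = 0, mirror: bool = False,
                      prefix: str = "") -> list[GeneModel]:
    """The canonical trio cassette; ``mirror`` flips every strand to produce
    the forward-reverse-forward configuration."""
    def strand(s: str) -> str:
        if not mirror:
            return s
        return "-" if s == "+" else "+"

    def iv(lo: int, hi: int, s: str) -> GenomicInterval:
        return GenomicInterval(chrom, lo + offset, hi + offset, strand(s))

    r1 = GeneModel(
        prefix + ("F1a" if mirror else "R1"),
        iv(*_R1_SPAN, "-"),
        [iv(100, 400, "-"), iv(1300, 1550, "-")],
    )
    f2 = GeneModel(
        prefix + ("R2" if mirror else "F2"),
        iv(*_F2_SPAN, "+"),
        [iv(1500, 1900, "+"), iv(2600, 3500, "+")],
    )
    # six exons so the splice-acceptor logic has an intron 5
    r3_exons = [
        iv(3400, 3600, "-"), iv(3700, 3850, "-"), iv(3950, 4100, "-"),
        iv(4200, 4350, "-"), iv(4450, 4600, "-"), iv(4700, 4900, "-"),
    ]
    r3 = GeneModel(prefix + ("F1b" if mirror else "R3"), iv(*_R3_SPAN, "-"), r3_exons)
    return [r1, f2, r3]


def _island_sequence(rng: np.random.Generator, length: int, n_cpg: int,
                     ) -> tuple[str, list[int], int]:
    """Random sequence with exactly n_cpg CpGs plus a methylation-neutral
    SNP slot. Returns (seq, cpg_offsets, snp_offset)."""
    if n_cpg * 3 + 6 > length and n_cpg > 0:
        raise ValueError("island too short for requested CpG count")
    seq = list(rng.choice(list("ACGT"), size=length, p=[0.3, 0.2, 0.2, 0.3]))
    # scrub accidental CpGs
    for i in range(length - 1):
        if seq[i] == "C" and seq[i + 1] == "G":
            seq[i + 1] = "A"
    # plant CpGs evenly across the island, spaced >= 3 apart
    cpg_offsets: list[int] = []
    if n_cpg > 0:
        slots = np.linspace(2, length - 4, n_cpg).astype(int)
        for p in slots:
            p = int(p)
            seq[p], seq[p + 1] = "C", "G"
            if p + 2 < length and seq[p + 2] == "G" and seq[p + 1] == "C":
                pass  # unreachable, kept for clarity
            cpg_offsets.append(p)
        # planting may have created a new CpG just before a planted C; scrub
        for p in cpg_offsets:
            if p >= 1 and seq[p - 1] == "C":
                seq[p - 1] = "A"
    # rescan: planting G at p+1 could pair with a following C? (G then C is
    # not a CpG); but a planted C at p with pre-existing G at p-1 is fine.
    # choose a SNP slot away from CpGs and their G partners, with neighbors
    # that keep both alleles CpG-neutral
    blocked = set(cpg_offsets) | {p + 1 for p in cpg_offsets}
    snp_offset = None
    for i in range(1, length - 1):
        if i in blocked or (i - 1) in blocked or (i + 1) in blocked:
            continue
        if seq[i - 1] != "C" and seq[i + 1] != "G":
            snp_offset = i
            break
    if snp_offset is None:
        raise ValueError("no methylation-neutral SNP slot available")
    return "".join(seq), cpg_offsets, snp_offset


def gen_locus(config: SimulationConfig) -> SyntheticLocus:
    """Generate the trio locus: reference sequence, gene models, island."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.island_span
    island = GenomicInterval(config.chrom, lo, hi, "+")
    seq, cpgs, snp_offset = _island_sequence(rng, hi - lo, config.n_cpg)
    genes = _trio_gene_models(config.chrom)
    # make the SNP slot carry the tag allele in the reference
    seq = seq[:snp_offset] + config.snp_alleles[0] + seq[snp_offset + 1:]
    r3 = genes[2]
    exons_tx = r3.exons_transcription_order()
    acceptor = {  # acceptor -1/-2 of intron 5 (downstream exon = terminal)
        "minus1": exons_tx[-1].end,
        "minus2": exons_tx[-1].end + 1,
    }
    truth = TruthRecord(
        planted_epimutation_allele=config.snp_alleles[0],
        snp_offset=snp_offset,
        planted_trios=[{"pattern": "R1F2R3",
                        "genes": [g.gene_id for g in genes]}],
        acceptor_positions=acceptor,
    )
    return SyntheticLocus(
        reference_seq=seq,
        region=island,
        snp_offset=snp_offset,
        snp_alleles=config.snp_alleles,
        genes=genes,
        island=island,
        truth=truth,
    )


def write_locus(locus: SyntheticLocus, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "reference.fa", "w", newline="\n") as fh:
        fh.write(f">{locus.region.chrom}:{locus.region.start}-{locus.region.end}\n")
        fh.write(locus.reference_seq + "\n")
    with open(outdir / "reference.config", "w", newline="\n") as fh:
        fh.write(f"chrom={locus.region.chrom}\n")
        fh.write(f"start={locus.region.start}\n")
        fh.write(f"end={locus.region.end}\n")
        fh.write(f"snp_offset={locus.snp_offset}\n")
        fh.write(f"snp_alleles={locus.snp_alleles[0]},{locus.snp_alleles[1]}\n")
    write_gff3(outdir / "genes.gff3", locus.genes)
    write_bed(outdir / "island.bed", [locus.island], columns=3)
    locus.truth.to_json(outdir / "truth_locus.json")


# ---------------------------------------------------------------------------
# clones
# ---------------------------------------------------------------------------

def gen_clones(
    locus: SyntheticLocus,
    config: SimulationConfig,
    allele_states: Optional[dict[str, Sequence[float]]] = None,
) -> list[tuple[str, str]]:
    """Simulate bisulfite clone sequences as (clone_id, sequence) pairs.

    ``allele_states`` maps allele name ("tag"/"other") to per-CpG
    methylation probabilities; the default plants a fully methylated tag
    allele and fully unmethylated other allele (the mono-allelic
    epimutation). Unmethylated CpG cytosines and converted non-CpG
    cytosines read T; conversion failures leave C.
    """
    rng = np.random.default_rng(config.seed + 1)
    seq = locus.reference_seq
    cpgs, noncpg = [], []
    for i, b in enumerate(seq):
        if b == "C":
            if i + 1 < len(seq) and seq[i + 1] == "G":
                cpgs.append(i)
            else:
                noncpg.append(i)
    if allele_states is None:
        allele_states = {
            "tag": [1.0] * len(cpgs),
            "other": [0.0] * len(cpgs),
        }
    clones = []
    for allele_name, allele_base in (
        ("tag", locus.snp_alleles[0]),
        ("other", locus.snp_alleles[1]),
    ):
        probs = np.asarray(allele_states[allele_name], dtype=float)
        for k in range(config.n_clones_per_allele):
            chars = list(seq)
            chars[locus.snp_offset] = allele_base
            meth = rng.random(len(cpgs)) < probs
            for j, p in enumerate(cpgs):
                chars[p] = "C" if meth[j] else "T"
            conv = rng.random(len(noncpg)) < config.conversion_efficiency
            for j, p in enumerate(noncpg):
                chars[p] = "T" if conv[j] else "C"
            if config.base_error_rate > 0:
                protected = set(cpgs) | set(noncpg) | {locus.snp_offset}
                errs = rng.random(len(chars)) < config.base_error_rate
                for p in np.flatnonzero(errs):
                    if int(p) not in protected:
                        chars[p] = str(rng.choice(list("ACGT")))
            clones.append((f"{allele_name}_clone{k + 1:03d}", "".join(chars)))
    return clones


def write_clones(clones: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for clone_id, seq in clones:
            fh.write(f">{clone_id}\n{seq}\n")


# ---------------------------------------------------------------------------
# beta cohorts
# ---------------------------------------------------------------------------

def gen_beta_cohort(
    config: SimulationConfig,
) -> tuple[BetaMatrix, BetaMatrix, list[str], TruthRecord]:
    """Simulate (controls, cases, block probe list, truth).

    Block probes inside the island draw from the UU shape for non-carriers
    and the PM shape for carriers; flanking probes draw from the MM shape
    for everyone (the hypomethylated island surrounded by hypermethylated
    sites). Cases are carriers by construction.
    """
    rng = np.random.default_rng(config.seed + 2)
    lo, hi = config.island_span
    block_pos = np.linspace(lo + 5, hi - 5, config.block_size).astype(int)
    n_left = config.n_flank_probes // 2
    n_right = config.n_flank_probes - n_left
    flank_pos = [lo - 400 + 60 * i for i in range(n_left)] + [
        hi + 100 + 60 * i for i in range(n_right)
    ]
    positions = sorted(set(flank_pos) | set(int(p) for p in block_pos))
    probe_ids = [f"cg{p:08d}" for p in positions]
    block_probes = [f"cg{int(p):08d}" for p in sorted(block_pos)]
    block_cols = [positions.index(int(p)) for p in sorted(block_pos)]

    def draw(shape: tuple[float, float], size) -> np.ndarray:
        return np.clip(rng.beta(shape[0], shape[1], size=size), 0.0, 1.0)

    def cohort(n: int, prefix: str, carrier_rows: Sequence[int]) -> np.ndarray:
        values = np.empty((n, len(positions)))
        for j in range(len(positions)):
            if j in block_cols:
                values[:, j] = draw(config.uu_shape, n)
            else:
                values[:, j] = draw(config.mm_shape, n)
        for i in carrier_rows:
            for j in block_cols:
                values[i, j] = draw(config.pm_shape, 1)[0]
        return values

    n_ctrl = config.n_controls
    carrier_rows = sorted(
        rng.choice(n_ctrl, size=config.n_planted_carriers, replace=False).tolist()
    ) if config.n_planted_carriers else []
    ctrl_subjects = [f"ctrl{i + 1:05d}" for i in range(n_ctrl)]
    controls = BetaMatrix(
        probe_ids=list(probe_ids),
        chroms=[config.chrom] * len(positions),
        positions=positions,
        subjects=ctrl_subjects,
        values=cohort(n_ctrl, "ctrl", carrier_rows),
    )
    case_subjects = [f"case{i + 1:03d}" for i in range(config.n_cases)]
    cases = BetaMatrix(
        probe_ids=list(probe_ids),
        chroms=[config.chrom] * len(positions),
        positions=positions,
        subjects=case_subjects,
        values=cohort(config.n_cases, "case", list(range(config.n_cases))),
    )
    truth = TruthRecord(
        planted_carriers=[ctrl_subjects[i] for i in carrier_rows],
        block_probes=block_probes,
    )
    return controls, cases, block_probes, truth


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def gen_reads(
    locus: SyntheticLocus, config: SimulationConfig
) -> list[GenomicInterval]:
    """Simulate stranded read intervals over the trio locus.

    Sense reads fall inside each gene's exclusive body (outside the overlap
    regions, so a readthrough-free library has zero antisense coverage over
    the middle gene); readthrough reads tile the tail flank's strand from
    its body across the junction through the middle gene into the head
    flank's promoter-proximal exon.
    """
    rng = np.random.default_rng(config.seed + 3)
    r1, f2, r3 = locus.genes
    chrom = config.chrom
    n_rt = int(round(config.n_reads * config.readthrough_frac))
    n_sense = config.n_reads - n_rt
    reads: list[GenomicInterval] = []

    # exclusive sense regions (single intervals by construction)
    exclusive = [
        (r1, GenomicInterval(chrom, r1.interval.start, f2.interval.start, r1.strand)),
        (f2, GenomicInterval(chrom, r1.interval.end, r3.interval.start, f2.strand)),
        (r3, GenomicInterval(chrom, f2.interval.end, r3.interval.end, r3.strand)),
    ]
    lengths = np.array([len(region) for _, region in exclusive], dtype=float)
    alloc = np.floor(n_sense * lengths / lengths.sum()).astype(int)
    alloc[0] += n_sense - alloc.sum()
    L = config.read_length
    for (gene, region), count in zip(exclusive, alloc):
        if count <= 0:
            continue
        max_start = len(region) - L
        if max_start <= 0:
            raise ValueError("read_length exceeds exclusive gene region")
        starts = region.start + rng.integers(0, max_start + 1, size=count)
        for s in np.sort(starts):
            reads.append(GenomicInterval(chrom, int(s), int(s) + L, gene.strand))

    if n_rt > 0:
        # span: head flank's promoter-proximal exon through the tail flank
        head_exon = r1.exons_transcription_order()[0]
        span_lo = head_exon.start
        span_hi = r3.interval.end
        Lr = config.readthrough_read_length
        starts = np.linspace(span_lo, span_hi - Lr, n_rt).astype(int)
        for s in starts:
            reads.append(GenomicInterval(chrom, int(s), int(s) + Lr, r3.strand))
    return reads


# ---------------------------------------------------------------------------
# annotation scan fixtures
# ---------------------------------------------------------------------------

_SLOT = 10000
_ISLAND_R1F2R3 = (1300, 1763)
_ISLAND_F1R2F1 = (3250, 3713)


def gen_annotation(
    config: SimulationConfig,
) -> tuple[list[GeneModel], list[GenomicInterval], TruthRecord]:
    """Planted trios among decoys, each decoy violating exactly one trio
    predicate (same-strand flank, missing island, or no 3' overlap)."""
    genes: list[GeneModel] = []
    islands: list[GenomicInterval] = []
    truth = TruthRecord()
    chrom = "chrA"
    slot = 0

    def add_cassette(prefix: str, mirror: bool, island_span: Optional[tuple[int, int]],
                     violation: Optional[str] = None) -> list[GeneModel]:
        offset = slot * _SLOT + 100
        cassette = _trio_gene_models(chrom, offset=offset, mirror=mirror,
                                     prefix=prefix)
        if violation == "same_strand_flank":
            head = cassette[0]
            flipped = "-" if head.strand == "+" else "+"
            cassette[0] = GeneModel(
                head.gene_id,
                GenomicInterval(chrom, head.interval.start, head.interval.end,
                                flipped),
                [GenomicInterval(chrom, e.start, e.end, flipped)
                 for e in head.exons],
            )
        elif violation == "no_tail_overlap":
            tail = cassette[2]
            shift = 2000
            cassette[2] = GeneModel(
                tail.gene_id,
                GenomicInterval(chrom, tail.interval.start + shift,
                                tail.interval.end + shift, tail.strand),
                [GenomicInterval(chrom, e.start + shift, e.end + shift,
                                 tail.strand) for e in tail.exons],
            )
        genes.extend(cassette)
        if island_span is not None:
            islands.append(
                GenomicInterval(chrom, island_span[0] + offset,
                                island_span[1] + offset, "+")
            )
        return cassette

    for i in range(config.n_planted_r1f2r3):
        cassette = add_cassette(f"t{slot:04d}_", False, _ISLAND_R1F2R3)
        truth.planted_trios.append(
            {"pattern": "R1F2R3", "genes": [g.gene_id for g in cassette]}
        )
        slot += 1
    for i in range(config.n_planted_f1r2f1):
        cassette = add_cassette(f"t{slot:04d}_", True, _ISLAND_F1R2F1)
        truth.planted_trios.append(
            {"pattern": "F1R2F1", "genes": [g.gene_id for g in cassette]}
        )
        slot += 1
    violations = ["same_strand_flank", "missing_island", "no_tail_overlap"]
    for i in range(config.n_decoy_trios):
        violation = violations[i % 3]
        island = None if violation == "missing_island" else _ISLAND_R1F2R3
        add_cassette(f"d{slot:04d}_", False, island, violation=violation)
        slot += 1
    return genes, islands, truth


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

_DAMAGE_CYCLE = ["missense", "nonsense", "splice_site", "frameshift_indel"]


def gen_variants(
    config: SimulationConfig,
    planted_pos: Optional[int] = None,
    planted_maf: float = 0.0001,
) -> tuple[list[VariantRecord], dict[str, str], TruthRecord]:
    """One planted segregating splice-acceptor variant among decoys.

    Decoys cycle through violations: too common, non-damaging class, het in
    a non-carrier, and absent from all samples.
    """
    status = dict(config.pedigree)
    carriers = [s for s, st in status.items() if st == "carrier"]
    non_carriers = [s for s, st in status.items() if st == "non_carrier"]
    if not carriers or not non_carriers:
        raise ValueError("pedigree needs at least one carrier and one non-carrier")
    rng = np.random.default_rng(config.seed + 4)
    samples = list(status)
    if planted_pos is None:
        planted_pos = 3601  # acceptor -1 of the default locus tail gene, 1-based
    planted = VariantRecord(
        chrom=config.chrom,
        pos=planted_pos,
        ref="G",
        alt="T",
        consequence="splice_site",
        max_maf=planted_maf,
        genotypes={
            s: "het" if status[s] == "carrier" else "hom_ref" for s in samples
        },
    )
    variants = [planted]
    bases = "ACGT"
    for i in range(config.n_decoy_variants):
        kind = i % 4
        pos = int(rng.integers(1, 5_000_000))
        ref = bases[rng.integers(0, 4)]
        alt = bases[(bases.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
        if kind == 0:  # common variant, otherwise perfect pattern
            genos = {s: "het" if status[s] == "carrier" else "hom_ref"
                     for s in samples}
            consequence = _DAMAGE_CYCLE[i % 4]
            maf = float(0.002 + 0.01 * rng.random())
        elif kind == 1:  # non-damaging class
            genos = {s: "het" if status[s] == "carrier" else "hom_ref"
                     for s in samples}
            consequence = "other"
            maf = float(0.0005 * rng.random())
        elif kind == 2:  # het leaks into a non-carrier
            leak = non_carriers[int(rng.integers(0, len(non_carriers)))]
            genos = {s: "het" if (status[s] == "carrier" or s == leak)
                     else "hom_ref" for s in samples}
            consequence = _DAMAGE_CYCLE[i % 4]
            maf = float(0.0005 * rng.random())
        else:  # hom_ref everywhere
            genos = {s: "hom_ref" for s in samples}
            consequence = _DAMAGE_CYCLE[i % 4]
            maf = float(0.0005 * rng.random())
        variants.append(
            VariantRecord(
                chrom=f"chr{1 + i % 22}",
                pos=pos,
                ref=ref,
                alt=alt,
                consequence=consequence,
                max_maf=maf,
                genotypes=genos,
            )
        )
    truth = TruthRecord(
        planted_variant={
            "chrom": planted.chrom, "pos": planted.pos,
            "ref": planted.ref, "alt": planted.alt,
        }
    )
    return variants, status, truth


# ---------------------------------------------------------------------------
# convenience writers
# ---------------------------------------------------------------------------

def write_cohort(outdir: str | Path, controls: BetaMatrix, cases: BetaMatrix,
                 block_probes: Sequence[str], truth: TruthRecord) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_beta_matrix(outdir / "controls.tsv", controls)
    write_beta_matrix(outdir / "cases.tsv", cases)
    with open(outdir / "block_probes.txt", "w", newline="\n") as fh:
        fh.write("\n".join(block_probes) + "\n")
    truth.to_json(outdir / "truth_cohort.json")


def write_annotation(outdir: str | Path, genes: Sequence[GeneModel],
                     islands: Sequence[GenomicInterval],
                     truth: TruthRecord) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gff3(outdir / "annotation.gff3", genes)
    write_bed(outdir / "islands.bed", islands, columns=3)
    truth.to_json(outdir / "truth_annotation.json")


def write_variants(outdir: str | Path, variants: Sequence[VariantRecord],
                   status: dict[str, str], truth: TruthRecord) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = list(status)
    write_variant_tsv(outdir / "variants.tsv", variants, samples=samples)
    write_status_tsv(outdir / "status.tsv", status)
    truth.to_json(outdir / "truth_variants.json")
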