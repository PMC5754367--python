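"""Bisulfite clone epigram analysis.

Calls per-clone, per-CpG methylation from cloned bisulfite amplicon
sequences, estimates conversion efficiency from non-CpG cytosines, filters
clones at the strict >95% conversion threshold, tags alleles by a
methylation-neutral SNP, and calls mono-allelic epimutations.

Clones are consumed pre-aligned: each clone sequence must have the same
length as the reference region, reported on the bisulfite top strand.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from epitrio.io_formats import GenomicInterval

logger = logging.getLogger(__name__)

CONVERSION_QC_THRESHOLD = 0.95  # pass requires strictly greater

MISSING = -1  # sentinel for a CpG call that is neither C nor T


@dataclass
class RegionReference:
    """The assayed region: sequence, CpG layout and optional tagging SNP."""

    seq: str
    region: GenomicInterval
    cpg_positions: list[int]
    noncpg_c_positions: list[int]
    snp_offset: Optional[int] = None
    snp_alleles: Optional[tuple[str, str]] = None  # (epiallele tag, other)

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)


@dataclass
class CloneCall:
    clone_id: str
    meth_calls: list[int]  # 1 methylated, 0 unmethylated, MISSING
    conversion_rate: float
    allele: str  # "tag", "other", "unassigned"
    passed_qc: bool

    def methylation_fraction(self) -> Optional[float]:
        valid = [c for c in self.meth_calls if c != MISSING]
        return sum(valid) / len(valid) if valid else None


@dataclass
class Epigram:
    """QC-passed clone calls plus per-allele methylation summaries."""

    clones: list[CloneCall]
    reference: RegionReference
    n_failed_qc: int = 0
    allele_fractions: dict[str, float] = field(default_factory=dict)
    allele_counts: dict[str, int] = field(default_factory=dict)


def build_reference(
    seq: str,
    region: GenomicInterval,
    snp_offset: Optional[int] = None,
    snp_alleles: Optional[tuple[str, str]] = None,
) -> RegionReference:
    """Enumerate CpG and non-CpG cytosines in a single left-to-right scan.

    A cytosine at the last position counts as non-CpG. The tagging SNP may
    not coincide with a CpG cytosine (the tag must be methylation-neutral).
    """
    seq = seq.upper()
    if len(seq) != len(region):
        raise ValueError(
            f"sequence length {len(seq)} != region length {len(region)}"
        )
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence contains non-ACGTN characters")
    cpg, noncpg = [], []
    for i, base in enumerate(seq):
        if base != "C":
            continue
        if i + 1 < len(seq) and seq[i + 1] == "G":
            cpg.append(i)
        else:
            noncpg.append(i)
    if snp_offset is not None:
        if not 0 <= snp_offset < len(seq):
            raise ValueError(f"snp_offset {snp_offset} outside region")
        if snp_offset in cpg:
            raise ValueError(
                "snp_offset coincides with a CpG cytosine; the allele tag "
                "must be methylation-neutral"
            )
    return RegionReference(seq, region, cpg, noncpg, snp_offset, snp_alleles)


def call_clone(clone_id: str, clone_seq: str, ref: RegionReference) -> CloneCall:
    """Call methylation and conversion for one pre-aligned clone.

    At CpG cytosines: C -> methylated, T -> unmethylated, else missing.
    At non-CpG cytosines: T counts converted, C unconverted, else ignored.
    QC passes only when conversion_rate is strictly greater than 0.95.
    """
    clone_seq = clone_seq.upper()
    if len(clone_seq) != len(ref.seq):
        raise ValueError(
            f"clone {clone_id}: length {len(clone_seq)} != reference "
            f"length {len(ref.seq)}"
        )
    meth = []
    for p in ref.cpg_positions:
        base = clone_seq[p]
        meth.append(1 if base == "C" else 0 if base == "T" else MISSING)
    converted = unconverted = 0
    for p in ref.noncpg_c_positions:
        base = clone_seq[p]
        if base == "T":
            converted += 1
        elif base == "C":
            unconverted += 1
    total = converted + unconverted
    if total == 0:
        raise ValueError(
            f"clone {clone_id}: no assessable non-CpG cytosines, "
            "conversion QC indeterminate"
        )
    rate = converted / total
    allele = "unassigned"
    if ref.snp_offset is not None and ref.snp_alleles is not None:
        base = clone_seq[ref.snp_offset]
        if base == ref.snp_alleles[0]:
            allele = "tag"
        elif base == ref.snp_alleles[1]:
            allele = "other"
    return CloneCall(
        clone_id=clone_id,
        meth_calls=meth,
        conversion_rate=rate,
        allele=allele,
        passed_qc=rate > CONVERSION_QC_THRESHOLD,
    )


def assemble_epigram(
    clone_calls: Sequence[CloneCall], ref: RegionReference
) -> Epigram:
    """Drop QC-failed clones and compute per-allele methylation fractions."""
    passed = [c for c in clone_calls if c.passed_qc]
    n_failed = len(clone_calls) - len(passed)
    if not passed:
        raise ValueError("all clones failed conversion QC")
    if n_failed:
        logger.info("assemble_epigram: dropped %d clones failing QC", n_failed)
    fractions: dict[str, float] = {}
    counts: dict[str, int] = {}
    for group in ("tag", "other", "unassigned"):
        members = [c for c in passed if c.allele == group]
        if not members:
            continue
        calls = [v for c in members for v in c.meth_calls if v != MISSING]
        counts[group] = len(members)
        if calls:
            fractions[group] = sum(calls) / len(calls)
    return Epigram(
        clones=passed,
        reference=ref,
        n_failed_qc=n_failed,
        allele_fractions=fractions,
        allele_counts=counts,
    )


def call_monoallelic_epimutation(
    epigram: Epigram,
    hyper_min: float = 0.9,
    hypo_max: float = 0.1,
    min_clones_per_allele: int = 3,
) -> str:
    """Call a mono-allelic epimutation from an allele-tagged epigram.

    Returns the tagging allele name ("tag"/"other") whose methylation
    fraction is >= hyper_min while the opposite allele is <= hypo_max and
    both alleles carry >= min_clones_per_allele clones; "none" when both
    alleles are <= hypo_max; "indeterminate" otherwise.
    """
    frac = epigram.allele_fractions
    counts = epigram.allele_counts
    if "tag" not in frac or "other" not in frac:
        raise ValueError("epigram has no clones assigned to both alleles")
    enough = (
        counts.get("tag", 0) >= min_clones_per_allele
        and counts.get("other", 0) >= min_clones_per_allele
    )
    f_tag, f_other = frac["tag"], frac["other"]
    if enough and f_tag >= hyper_min and f_other <= hypo_max:
        return "tag"
    if enough and f_other >= hyper_min and f_tag <= hypo_max:
        return "other"
    if f_tag <= hypo_max and f_other <= hypo_max:
        return "none"
    return "indeterminate"


def read_clone_fasta(path) -> list[tuple[str, str]]:
    """Read clone sequences; FASTA headers carry clone ids."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_epigram_tsv(path, epigram: Epigram) -> None:
    ref = epigram.reference
    header = ["clone_id", "allele", "conversion_rate"] + [
        f"cpg_{p}" for p in ref.cpg_positions
    ]
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for clone in epigram.clones:
            cells = [
                clone.clone_id,
                clone.allele,
                format(clone.conversion_rate, ".4f"),
            ] + ["" if v == MISSING else str(v) for v in clone.meth_calls]
            fh.write("\t".join(cells) + "\n")
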