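"""Variant prioritization: damage-class/rarity filtering and co-segregation
with epimutation carrier status.

Variant tables are TSV (chrom, pos, ref, alt, consequence, max_maf, then one
genotype column per sample); carrier status maps are 2-column TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

DAMAGE_CLASSES = frozenset(
    {"nonsense", "splice_site", "frameshift_indel", "missense"}
)
CONSEQUENCE_CLASSES = DAMAGE_CLASSES | {"other"}
GENOTYPES = frozenset({"hom_ref", "het", "hom_alt", "missing"})
DEFAULT_MAF_MAX = 0.001


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based, as in variant tables
    ref: str
    alt: str
    consequence: str
    max_maf: float
    genotypes: dict[str, str]  # sample id -> genotype

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if not 0.0 <= self.max_maf <= 1.0:
            raise ValueError(f"max_maf must lie in [0, 1], got {self.max_maf}")
        bad = {g for g in self.genotypes.values()} - GENOTYPES
        if bad:
            raise ValueError(f"unknown genotypes {sorted(bad)}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def filter_variants(
    variants: Sequence[VariantRecord],
    maf_max: float = DEFAULT_MAF_MAX,
    classes: frozenset[str] = DAMAGE_CLASSES,
) -> list[VariantRecord]:
    """Keep likely-damaging rare variants.

    A variant survives when its consequence is in ``classes`` and its
    maximum population MAF is <= maf_max (variants strictly above the
    threshold are removed; the boundary value is kept).
    """
    return [
        v for v in variants
        if v.consequence in classes and v.max_maf <= maf_max
    ]


def cosegregate(
    variants: Sequence[VariantRecord],
    status: dict[str, str],
    model: str = "het_in_carriers",
    strict_missing: bool = True,
) -> list[VariantRecord]:
    """Keep variants co-segregating with epimutation carrier status.

    Under the default dominant-het model a variant survives when it is het
    in every carrier and hom_ref in every non-carrier. Missing genotypes
    fail the variant in strict mode (default) and are ignored in lenient
    mode.
    """
    if model != "het_in_carriers":
        raise ValueError(f"unsupported model {model!r}")
    bad = set(status.values()) - {"carrier", "non_carrier"}
    if bad:
        raise ValueError(f"unknown status values {sorted(bad)}")
    carriers = [s for s, st in status.items() if st == "carrier"]
    non_carriers = [s for s, st in status.items() if st == "non_carrier"]
    if not carriers:
        raise ValueError("status map contains no carriers")
    if not non_carriers:
        raise ValueError("status map contains no non-carriers")

    kept = []
    for v in variants:
        missing_samples = [s for s in status if s not in v.genotypes]
        if missing_samples:
            raise ValueError(
                f"variant {v.key}: no genotype for samples {missing_samples}"
            )
        ok = True
        for s in carriers:
            g = v.genotypes[s]
            if g == "missing":
                if strict_missing:
                    ok = False
                    break
                continue
            if g != "het":
                ok = False
                break
        if ok:
            for s in non_carriers:
                g = v.genotypes[s]
                if g == "missing":
                    if strict_missing:
                        ok = False
                        break
                    continue
                if g != "hom_ref":
                    ok = False
                    break
        if ok:
            kept.append(v)
    return kept


# ---------------------------------------------------------------------------
# TSV plumbing
# ---------------------------------------------------------------------------

_FIXED_COLUMNS = ["chrom", "pos", "ref", "alt", "consequence", "max_maf"]


def read_variant_tsv(path: str | Path) -> list[VariantRecord]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_FIXED_COLUMNS)] != _FIXED_COLUMNS:
            raise ValueError(
                f"{path}: header must start with {_FIXED_COLUMNS}"
            )
        samples = header[len(_FIXED_COLUMNS):]
        records = []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            genos = dict(zip(samples, fields[len(_FIXED_COLUMNS):]))
            records.append(
                VariantRecord(
                    chrom=fields[0],
                    pos=int(fields[1]),
                    ref=fields[2],
                    alt=fields[3],
                    consequence=fields[4],
                    max_maf=float(fields[5]),
                    genotypes=genos,
                )
            )
    return records


def write_variant_tsv(path: str | Path, variants: Sequence[VariantRecord],
                      samples: Sequence[str] | None = None) -> None:
    if samples is None:
        samples = sorted(variants[0].genotypes) if variants else []
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(_FIXED_COLUMNS + list(samples)) + "\n")
        for v in variants:
            row = [
                v.chrom, str(v.pos), v.ref, v.alt, v.consequence,
                format(v.max_maf, "g"),
            ] + [v.genotypes[s] for s in samples]
            fh.write("\t".join(row) + "\n")


def read_status_tsv(path: str | Path) -> dict[str, str]:
    status = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("sample"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            status[fields[0]] = fields[1]
    return status


def write_status_tsv(path: str | Path, status: dict[str, str]) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("sample\tstatus\n")
        for sample, st in status.items():
            fh.write(f"{sample}\t{st}\n")
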