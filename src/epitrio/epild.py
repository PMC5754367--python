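"""Epi-linkage disequilibrium between adjacent CpG probes.

Methylation categories (UU/PM/MM) are treated as unphased two-allele
"epigenotypes" with dosages 0/1/2, making classical two-locus LD machinery
applicable: an EM haplotype-frequency estimator and the phase-free composite
haplotype method (covariance-based composite disequilibrium with
Hardy-Weinberg-departure-corrected denominator). Runs of adjacent probe
pairs in high r-squared form epi-haplotype blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from epitrio.methylome import BetaMatrix, dosage_matrix


@dataclass(frozen=True)
class EpiGenotypePair:
    subject_id: str
    g1: int
    g2: int

    def __post_init__(self) -> None:
        if self.g1 not in (0, 1, 2) or self.g2 not in (0, 1, 2):
            raise ValueError("dosages must lie in {0, 1, 2}")


@dataclass
class EpiLDResult:
    probe_a: str
    probe_b: str
    n: int
    hap_freqs: Optional[dict[str, float]] = None  # keys UU, UM, MU, MM
    pA: Optional[float] = None
    pB: Optional[float] = None
    D: Optional[float] = None
    r2_em: Optional[float] = None
    delta_comp: Optional[float] = None
    dA: Optional[float] = None
    dB: Optional[float] = None
    r2_chm: Optional[float] = None
    loglik: Optional[float] = None
    converged: bool = False


@dataclass
class EpiHaploBlock:
    probe_ids: list[str]
    min_r2: float

    def __post_init__(self) -> None:
        if len(self.probe_ids) < 2:
            raise ValueError("a block spans at least 2 probes")


def _genotype_counts(pairs: Sequence[EpiGenotypePair]) -> np.ndarray:
    counts = np.zeros((3, 3))
    for p in pairs:
        counts[p.g1, p.g2] += 1
    return counts


def _loglik(counts: np.ndarray, h: np.ndarray) -> float:
    """Multinomial log-likelihood of the 3x3 genotype table given haplotype
    frequencies h = (hUU, hUM, hMU, hMM) under random haplotype pairing."""
    hUU, hUM, hMU, hMM = h
    probs = np.array(
        [
            [hUU**2, 2 * hUU * hUM, hUM**2],
            [2 * hUU * hMU, 2 * (hMM * hUU + hMU * hUM), 2 * hUM * hMM],
            [hMU**2, 2 * hMU * hMM, hMM**2],
        ]
    )
    mask = counts > 0
    with np.errstate(divide="ignore"):
        logp = np.where(probs > 0, np.log(np.maximum(probs, 1e-300)), -np.inf)
    return float(np.sum(counts[mask] * logp[mask]))


def em_ld(
    pairs: Sequence[EpiGenotypePair],
    tol: float = 1e-10,
    max_iter: int = 1000,
    probe_a: str = "A",
    probe_b: str = "B",
) -> EpiLDResult:
    """Two-locus haplotype EM from unphased epigenotype dosage pairs.

    Initializes at linkage-equilibrium products of the observed allele
    frequencies; the E-step apportions double heterozygotes between cis and
    trans phase; iteration stops when the log-likelihood improves by less
    than ``tol``. D and r-squared come from the converged frequencies; with
    a monomorphic locus r-squared is left undefined (None), never forced
    to 0.
    """
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    counts = _genotype_counts(pairs)
    pA = float((counts[1, :].sum() + 2 * counts[2, :].sum()) / (2 * n))
    pB = float((counts[:, 1].sum() + 2 * counts[:, 2].sum()) / (2 * n))

    result = EpiLDResult(probe_a=probe_a, probe_b=probe_b, n=n, pA=pA, pB=pB)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return result  # monomorphic: r2 undefined

    # haplotype order: UU, UM, MU, MM
    h = np.array([(1 - pA) * (1 - pB), (1 - pA) * pB, pA * (1 - pB), pA * pB])
    n11 = counts[1, 1]
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        cis = h[3] * h[0]
        trans = h[2] * h[1]
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        cUU = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0] + w * n11
        cUM = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2] + (1 - w) * n11
        cMU = 2 * counts[2, 0] + counts[1, 0] + counts[2, 1] + (1 - w) * n11
        cMM = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2] + w * n11
        h = np.array([cUU, cUM, cMU, cMM]) / (2 * n)
        ll = _loglik(counts, h)
        if ll - prev_ll < -1e-9:
            raise AssertionError("EM log-likelihood decreased")
        if abs(ll - prev_ll) < tol:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll

    D = float(h[3] - pA * pB)
    denom = pA * (1 - pA) * pB * (1 - pB)
    result.hap_freqs = {"UU": h[0], "UM": h[1], "MU": h[2], "MM": h[3]}
    result.D = D
    result.r2_em = float(D * D / denom)
    result.loglik = float(prev_ll)
    result.converged = converged
    return result


def chm_ld(
    pairs: Sequence[EpiGenotypePair],
    probe_a: str = "A",
    probe_b: str = "B",
) -> EpiLDResult:
    """Composite haplotype method on dosage pairs.

    delta_comp = cov(g1, g2)/2 (1/n normalization); dA/dB are within-locus
    Hardy-Weinberg-style departures freq(g=2) - p^2; r2_chm divides
    delta_comp^2 by the departure-corrected heterozygosity product.
    """
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    g1 = np.array([p.g1 for p in pairs], dtype=float)
    g2 = np.array([p.g2 for p in pairs], dtype=float)
    pA = float(g1.mean() / 2)
    pB = float(g2.mean() / 2)
    result = EpiLDResult(probe_a=probe_a, probe_b=probe_b, n=n, pA=pA, pB=pB)
    delta = float(np.mean(g1 * g2) - g1.mean() * g2.mean()) / 2.0
    dA = float(np.mean(g1 == 2) - pA * pA)
    dB = float(np.mean(g2 == 2) - pB * pB)
    result.delta_comp = delta
    result.dA = dA
    result.dB = dB
    denom = (pA * (1 - pA) + dA) * (pB * (1 - pB) + dB)
    if denom > 0:
        result.r2_chm = float(delta * delta / denom)
    return result


def pairs_from_dosages(
    subjects: Sequence[str], g1: Iterable[float], g2: Iterable[float]
) -> list[EpiGenotypePair]:
    """Build genotype pairs, excluding subjects missing at either probe."""
    out = []
    for s, a, b in zip(subjects, g1, g2):
        if math.isnan(a) or math.isnan(b):
            continue
        out.append(EpiGenotypePair(s, int(a), int(b)))
    return out


def adjacent_ld_profile(
    matrix: BetaMatrix, method: str = "both"
) -> list[EpiLDResult]:
    """Epi-LD over every consecutive probe pair of a (sorted) beta matrix."""
    if method not in ("em", "chm", "both"):
        raise ValueError(f"unknown method {method!r}")
    matrix = matrix.sorted_by_position()
    if matrix.n_probes < 2:
        raise ValueError("need at least 2 probes")
    dosages = dosage_matrix(matrix)
    profile: list[EpiLDResult] = []
    for j in range(matrix.n_probes - 1):
        a, b = matrix.probe_ids[j], matrix.probe_ids[j + 1]
        pairs = pairs_from_dosages(matrix.subjects, dosages[:, j], dosages[:, j + 1])
        if len(pairs) < 2:
            profile.append(EpiLDResult(probe_a=a, probe_b=b, n=len(pairs)))
            continue
        if method == "chm":
            res = chm_ld(pairs, probe_a=a, probe_b=b)
        else:
            res = em_ld(pairs, probe_a=a, probe_b=b)
            if method == "both":
                comp = chm_ld(pairs, probe_a=a, probe_b=b)
                res.delta_comp = comp.delta_comp
                res.dA, res.dB = comp.dA, comp.dB
                res.r2_chm = comp.r2_chm
        profile.append(res)
    return profile


def build_blocks(
    profile: Sequence[EpiLDResult], r2_min: float = 0.8, metric: str = "em"
) -> list[EpiHaploBlock]:
    """Maximal runs of adjacent pairs with defined r-squared >= r2_min.

    An undefined r-squared (monomorphic pair) breaks a run. The boundary is
    inclusive: r2 == r2_min keeps the pair in the block.
    """
    attr = "r2_em" if metric == "em" else "r2_chm"
    blocks: list[EpiHaploBlock] = []
    run: list[EpiLDResult] = []

    def flush() -> None:
        if run:
            probes = [run[0].probe_a] + [r.probe_b for r in run]
            blocks.append(
                EpiHaploBlock(probes, min(getattr(r, attr) for r in run))
            )
            run.clear()

    prev_b: Optional[str] = None
    for res in profile:
        r2 = getattr(res, attr)
        if r2 is None or r2 < r2_min or (prev_b is not None and res.probe_a != prev_b):
            flush()
        if r2 is not None and r2 >= r2_min:
            run.append(res)
        prev_b = res.probe_b
    flush()
    return blocks


def write_ld_tsv(path, profile: Sequence[EpiLDResult]) -> None:
    cols = [
        "probeA", "probeB", "n", "pA", "pB", "D",
        "r2_em", "delta_comp", "r2_chm", "converged",
    ]

    def fmt(x) -> str:
        if x is None:
            return "NA"
        if isinstance(x, bool):
            return str(int(x))
        if isinstance(x, float):
            return format(x, ".6g")
        return str(x)

    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in profile:
            fh.write(
                "\t".join(
                    fmt(v)
                    for v in (
                        r.probe_a, r.probe_b, r.n, r.pA, r.pB, r.D,
                        r.r2_em, r.delta_comp, r.r2_chm, r.converged,
                    )
                )
                + "\n"
            )


def write_r2_matrix(path, matrix: BetaMatrix, method: str = "em") -> None:
    """Square adjacent-pair r-squared matrix (off-by-one band filled)."""
    profile = adjacent_ld_profile(matrix, method="both")
    ids = matrix.sorted_by_position().probe_ids
    n = len(ids)
    grid = [["NA"] * n for _ in range(n)]
    for i in range(n):
        grid[i][i] = "1"
    attr = "r2_em" if method == "em" else "r2_chm"
    for k, res in enumerate(profile):
        r2 = getattr(res, attr)
        val = "NA" if r2 is None else format(r2, ".6g")
        grid[k][k + 1] = grid[k + 1][k] = val
    with open(path, "w", newline="\n") as fh:
        fh.write("probe\t" + "\t".join(ids) + "\n")
        for i in range(n):
            fh.write(ids[i] + "\t" + "\t".join(grid[i]) + "\n")
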