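"""Methylation-array analysis: probe-level case/control scans, ENCODE-style
beta categorization, control-cohort carrier screening, and epimutation
allele-frequency estimation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

# Categorization boundaries: beta <= 0.2 is fully unmethylated, beta >= 0.6
# fully methylated, strictly between is partially methylated.
UU_MAX = 0.2
MM_MIN = 0.6


class EpiCategory(Enum):
    """Categorical methylation state with a dosage encoding 0/1/2."""

    UU = 0  # fully unmethylated
    PM = 1  # partially methylated (one of the two alleles)
    MM = 2  # fully methylated

    @property
    def dosage(self) -> int:
        return self.value


@dataclass
class BetaMatrix:
    """Subjects x probes methylation beta values in [0, 1] (NaN = missing)."""

    probe_ids: list[str]
    chroms: list[str]
    positions: list[int]
    subjects: list[str]
    values: np.ndarray  # shape (n_subjects, n_probes)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subjects), len(self.probe_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.probe_ids)} probes"
            )
        if len({*self.probe_ids}) != len(self.probe_ids):
            raise ValueError("duplicate probe ids")
        if len({*self.subjects}) != len(self.subjects):
            raise ValueError("duplicate subject ids")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def sorted_by_position(self) -> "BetaMatrix":
        order = sorted(
            range(self.n_probes), key=lambda j: (self.chroms[j], self.positions[j])
        )
        return BetaMatrix(
            probe_ids=[self.probe_ids[j] for j in order],
            chroms=[self.chroms[j] for j in order],
            positions=[self.positions[j] for j in order],
            subjects=list(self.subjects),
            values=self.values[:, order],
        )

    def probe_index(self, probe_id: str) -> int:
        try:
            return self.probe_ids.index(probe_id)
        except ValueError:
            raise KeyError(f"probe {probe_id!r} not in matrix") from None


@dataclass
class MvpRecord:
    """Per-probe methylation variation position statistics."""

    probe_id: str
    chrom: str
    pos: int
    delta_beta: float
    t_stat: Optional[float]
    p_value: Optional[float]
    p_bonferroni: Optional[float]
    flagged_hyper: bool
    flagged_hypo: bool

    @property
    def flagged(self) -> bool:
        return self.flagged_hyper or self.flagged_hypo


@dataclass
class CarrierReport:
    block_probes: list[str]
    carriers: list[str]
    n_subjects: int
    excluded_subjects: list[str] = field(default_factory=list)
    allele_frequency_estimate: float = 0.0
    allele_frequency_upper_bound: float = 0.0


def categorize_beta(beta: float) -> Optional[EpiCategory]:
    """Map a beta value onto {UU, PM, MM}; missing (NaN) propagates as None."""
    if beta is None or (isinstance(beta, float) and math.isnan(beta)):
        return None
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    if beta <= UU_MAX:
        return EpiCategory.UU
    if beta >= MM_MIN:
        return EpiCategory.MM
    return EpiCategory.PM


def dosage_matrix(matrix: BetaMatrix) -> np.ndarray:
    """Vectorized categorization to dosages (float array, NaN = missing)."""
    v = matrix.values
    out = np.full(v.shape, np.nan)
    with np.errstate(invalid="ignore"):
        out[v <= UU_MAX] = 0.0
        out[(v > UU_MAX) & (v < MM_MIN)] = 1.0
        out[v >= MM_MIN] = 2.0
    return out


def mvp_scan(
    cases: BetaMatrix,
    controls: BetaMatrix,
    delta_threshold: float = 0.3,
) -> list[MvpRecord]:
    """Per-probe case-vs-control scan on the shared probe set.

    Reports the signed mean difference (case - control), a Welch two-sample
    t statistic with two-sided p, and Bonferroni correction over the probes
    actually tested. Probes are flagged hyper at delta >= threshold and hypo
    at delta <= -threshold.
    """
    case_index = {p: j for j, p in enumerate(cases.probe_ids)}
    shared = [p for p in controls.probe_ids if p in case_index]
    if not shared:
        raise ValueError("empty probe intersection between cases and controls")
    n_dropped = (cases.n_probes - len(shared)) + (controls.n_probes - len(shared))
    if n_dropped:
        logger.warning("mvp_scan: %d probes outside the shared set dropped", n_dropped)

    records: list[MvpRecord] = []
    tested: list[int] = []
    for k, probe in enumerate(shared):
        jc = case_index[probe]
        jo = controls.probe_index(probe)
        x = cases.values[:, jc]
        y = controls.values[:, jo]
        x = x[np.isfinite(x)]
        y = y[np.isfinite(y)]
        if x.size == 0 or y.size == 0:
            continue  # untested and unreported: no group mean available
        delta = float(x.mean() - y.mean())
        t_stat = p_value = None
        if x.size >= 2 and y.size >= 2:
            res = stats.ttest_ind(x, y, equal_var=False)
            t_stat, p_value = float(res.statistic), float(res.pvalue)
            tested.append(len(records))
        records.append(
            MvpRecord(
                probe_id=probe,
                chrom=controls.chroms[jo],
                pos=controls.positions[jo],
                delta_beta=delta,
                t_stat=t_stat,
                p_value=p_value,
                p_bonferroni=None,
                flagged_hyper=delta >= delta_threshold,
                flagged_hypo=delta <= -delta_threshold,
            )
        )
    m = len(tested)
    for i in tested:
        records[i].p_bonferroni = min(1.0, m * records[i].p_value)
    return records


def detect_carriers(
    cohort: BetaMatrix,
    block_probes: Sequence[str],
    rule: str = "all-non-UU",
    max_missing_fraction: float = 0.5,
) -> CarrierReport:
    """Screen a cohort for subjects matching the epimutation block signature.

    Default rule: a subject is a carrier iff every non-missing block probe
    categorizes non-UU (beta > 0.2). The strict "all-PM" rule additionally
    requires every block probe to be partially methylated. Subjects missing
    more than ``max_missing_fraction`` of block probes are excluded.
    """
    if not block_probes:
        raise ValueError("block_probes must be non-empty")
    if rule not in ("all-non-UU", "all-PM"):
        raise ValueError(f"unknown rule {rule!r}")
    cols = [cohort.probe_index(p) for p in block_probes]
    block = cohort.values[:, cols]

    carriers: list[str] = []
    excluded: list[str] = []
    for i, subject in enumerate(cohort.subjects):
        row = block[i]
        finite = np.isfinite(row)
        if finite.sum() < len(cols) * (1.0 - max_missing_fraction):
            excluded.append(subject)
            continue
        vals = row[finite]
        if rule == "all-non-UU":
            ok = bool(np.all(vals > UU_MAX))
        else:
            ok = bool(np.all((vals > UU_MAX) & (vals < MM_MIN)))
        if ok:
            carriers.append(subject)
    if excluded:
        logger.warning(
            "detect_carriers: %d subjects excluded for missingness", len(excluded)
        )
    n_eval = cohort.n_subjects - len(excluded)
    est, bound = allele_frequency(len(carriers), n_eval) if n_eval else (0.0, 0.0)
    return CarrierReport(
        block_probes=list(block_probes),
        carriers=carriers,
        n_subjects=n_eval,
        excluded_subjects=excluded,
        allele_frequency_estimate=est,
        allele_frequency_upper_bound=bound,
    )


def _ceil_one_significant_figure(x: float) -> float:
    if x <= 0.0:
        return 0.0
    exponent = math.floor(math.log10(x))
    mantissa = x / 10**exponent
    # guard against float noise turning e.g. 5.000000001 into 6
    if abs(mantissa - round(mantissa)) < 1e-9:
        mantissa = round(mantissa)
    return math.ceil(mantissa) * 10.0**exponent


def allele_frequency(
    n_carriers: int, n_subjects: int, zygosity: str = "heterozygous"
) -> tuple[float, float]:
    """Epimutation allele frequency under a heterozygous-carrier model.

    Returns ``(estimate, upper_bound)`` where estimate = carriers / (2N) and
    the bound is the estimate rounded up at one significant figure — the
    "not higher than" style ceiling (0 when there are no carriers).
    """
    if zygosity != "heterozygous":
        raise ValueError(f"unsupported zygosity {zygosity!r}")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not 0 <= n_carriers <= n_subjects:
        raise ValueError("n_carriers must lie in [0, n_subjects]")
    estimate = n_carriers / (2 * n_subjects)
    return estimate, _ceil_one_significant_figure(estimate)
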