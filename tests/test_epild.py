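"""Epi-LD tests, including an EM-independent likelihood-grid oracle.

The oracle maximizes the multinomial genotype likelihood directly over
haplotype frequencies. Because every E-step allocation of a double
heterozygote assigns exactly one methylated allele at each locus, the
maximum-likelihood haplotype frequencies always carry the observed allele
frequencies as marginals; the simplex search therefore reduces to a 1-D
grid over the MM-haplotype frequency within its feasible interval, refined
around the coarse argmax. No EM step is involved.
"""

import numpy as np
import pytest

from epitrio.epild import (
    EpiGenotypePair,
    EpiLDResult,
    adjacent_ld_profile,
    build_blocks,
    chm_ld,
    em_ld,
    pairs_from_dosages,
)
from epitrio.methylome import BetaMatrix


def pairs_from_counts(counts: dict[tuple[int, int], int]) -> list[EpiGenotypePair]:
    out = []
    i = 0
    for (g1, g2), n in counts.items():
        for _ in range(n):
            out.append(EpiGenotypePair(f"s{i}", g1, g2))
            i += 1
    return out


def _loglik_at(counts33: np.ndarray, h: np.ndarray) -> float:
    hUU, hUM, hMU, hMM = h
    probs = np.array(
        [
            [hUU**2, 2 * hUU * hUM, hUM**2],
            [2 * hUU * hMU, 2 * (hMM * hUU + hMU * hUM), 2 * hUM * hMM],
            [hMU**2, 2 * hMU * hMM, hMM**2],
        ]
    )
    mask = counts33 > 0
    with np.errstate(divide="ignore"):
        return float(
            np.sum(counts33[mask] * np.log(np.maximum(probs[mask], 1e-300)))
        )


def grid_oracle_r2(pairs, step=1e-3):
    """Likelihood-grid maximizer over haplotype frequencies (EM-free)."""
    counts = np.zeros((3, 3))
    for p in pairs:
        counts[p.g1, p.g2] += 1
    n = counts.sum()
    pA = (counts[1, :].sum() + 2 * counts[2, :].sum()) / (2 * n)
    pB = (counts[:, 1].sum() + 2 * counts[:, 2].sum()) / (2 * n)
    lo = max(0.0, pA + pB - 1.0)
    hi = min(pA, pB)

    def ll(d):
        h = np.array([1 - pA - pB + d, pB - d, pA - d, d])
        return _loglik_at(counts, h)

    grid = np.arange(lo, hi + step / 2, step)
    coarse = grid[int(np.argmax([ll(d) for d in grid]))]
    fine = np.arange(max(lo, coarse - step), min(hi, coarse + step) + 1e-9, step / 200)
    d_hat = fine[int(np.argmax([ll(d) for d in fine]))]
    D = d_hat - pA * pB
    return D * D / (pA * (1 - pA) * pB * (1 - pB))


def random_genotype_table(rng, n=50):
    """Sample dosage pairs from random haplotype frequencies under random
    pairing; resample until both loci are polymorphic."""
    while True:
        h = rng.dirichlet([1.0, 1.0, 1.0, 1.0])
        haps = rng.choice(4, size=(n, 2), p=h)  # 0=UU 1=UM 2=MU 3=MM
        g1 = (haps >= 2).sum(axis=1)
        g2 = (haps % 2).sum(axis=1)
        if 0 < g1.sum() < 2 * n and 0 < g2.sum() < 2 * n:
            return [EpiGenotypePair(f"s{i}", int(a), int(b))
                    for i, (a, b) in enumerate(zip(g1, g2))]


class TestEmLd:
    def test_perfect_ld_closed_form(self):
        pairs = pairs_from_counts({(0, 0): 50, (2, 2): 50})
        r = em_ld(pairs)
        assert r.pA == r.pB == 0.5
        assert r.hap_freqs["UU"] == pytest.approx(0.5)
        assert r.hap_freqs["MM"] == pytest.approx(0.5)
        assert r.D == pytest.approx(0.25)
        assert r.r2_em == pytest.approx(1.0)

    def test_monomorphic_undefined_not_zero(self):
        r = em_ld(pairs_from_counts({(2, 2): 10}))
        assert r.r2_em is None

    def test_mixed_table_matches_grid_oracle(self):
        pairs = pairs_from_counts({(0, 0): 30, (1, 1): 40, (2, 2): 30})
        r = em_ld(pairs)
        assert r.r2_em == pytest.approx(grid_oracle_r2(pairs), abs=1e-3)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="2 subjects"):
            em_ld([EpiGenotypePair("a", 0, 0)])

    def test_hap_freqs_sum_to_one(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            r = em_ld(random_genotype_table(rng))
            assert sum(r.hap_freqs.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(v >= -1e-12 for v in r.hap_freqs.values())
            assert -1e-9 <= r.r2_em <= 1 + 1e-9

    def test_r2_invariant_to_locus_swap_and_relabel(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            pairs = random_genotype_table(rng)
            r = em_ld(pairs)
            swapped = [EpiGenotypePair(p.subject_id, p.g2, p.g1) for p in pairs]
            relabeled = [
                EpiGenotypePair(p.subject_id, 2 - p.g1, 2 - p.g2) for p in pairs
            ]
            assert em_ld(swapped).r2_em == pytest.approx(r.r2_em, abs=1e-9)
            assert em_ld(relabeled).r2_em == pytest.approx(r.r2_em, abs=1e-9)

    def test_single_double_het_goes_cis(self):
        pairs = pairs_from_counts({(0, 0): 99, (1, 1): 1})
        r = em_ld(pairs)
        assert r.r2_em == pytest.approx(1.0, abs=1e-6)


class TestChmLd:
    def test_perfect_ld_hand_computed(self):
        # cov(g1,g2) = E[g1 g2] - E[g1]E[g2] = 2 - 1 = 1; delta = 1/2
        # dA = freq(g1=2) - pA^2 = 0.5 - 0.25 = 0.25; denominator = 0.25
        pairs = pairs_from_counts({(0, 0): 50, (2, 2): 50})
        r = chm_ld(pairs)
        assert r.delta_comp == pytest.approx(0.5)
        assert r.dA == pytest.approx(0.25)
        assert r.dB == pytest.approx(0.25)
        assert r.r2_chm == pytest.approx(1.0)

    def test_independent_loci_near_zero(self):
        rng = np.random.default_rng(7)
        g1 = rng.integers(0, 3, size=20000)
        g2 = rng.integers(0, 3, size=20000)
        pairs = [EpiGenotypePair(f"s{i}", int(a), int(b))
                 for i, (a, b) in enumerate(zip(g1, g2))]
        assert chm_ld(pairs).r2_chm == pytest.approx(0.0, abs=0.01)

    def test_monomorphic_undefined(self):
        r = chm_ld(pairs_from_counts({(2, 2): 10}))
        assert r.r2_chm is None

    def test_matches_em_under_random_pairing(self):
        rng = np.random.default_rng(8)
        pairs = random_genotype_table(rng, n=10000)
        r_em = em_ld(pairs)
        r_chm = chm_ld(pairs)
        assert r_chm.r2_chm == pytest.approx(r_em.r2_em, abs=0.02)


class TestAdjacentProfile:
    def _matrix(self, values, positions=None):
        values = np.asarray(values, dtype=float)
        n_subj, n_probes = values.shape
        return BetaMatrix(
            probe_ids=[f"cg{j}" for j in range(n_probes)],
            chroms=["chr1"] * n_probes,
            positions=positions or list(range(100, 100 + n_probes)),
            subjects=[f"s{i}" for i in range(n_subj)],
            values=values,
        )

    def test_concordant_block_all_r2_one(self):
        # 30 carriers (PM everywhere) + 70 non-carriers (UU everywhere)
        values = np.vstack([np.full((30, 8), 0.5), np.full((70, 8), 0.05)])
        profile = adjacent_ld_profile(self._matrix(values), method="both")
        assert len(profile) == 7
        for res in profile:
            assert res.r2_em == pytest.approx(1.0, abs=1e-6)
            assert res.r2_chm == pytest.approx(1.0, abs=1e-6)

    def test_shuffled_probes_identical_output(self):
        rng = np.random.default_rng(9)
        values = rng.uniform(size=(40, 5))
        m = self._matrix(values)
        shuffled = BetaMatrix(
            probe_ids=list(reversed(m.probe_ids)),
            chroms=list(m.chroms),
            positions=list(reversed(m.positions)),
            subjects=list(m.subjects),
            values=m.values[:, ::-1],
        )
        a = adjacent_ld_profile(m, method="both")
        b = adjacent_ld_profile(shuffled, method="both")
        assert [(r.probe_a, r.probe_b, r.r2_em) for r in a] == [
            (r.probe_a, r.probe_b, r.r2_em) for r in b
        ]

    def test_two_probes_one_result(self):
        values = np.vstack([np.full((10, 2), 0.5), np.full((10, 2), 0.05)])
        profile = adjacent_ld_profile(self._matrix(values))
        assert len(profile) == 1

    def test_single_probe_errors(self):
        with pytest.raises(ValueError, match="2 probes"):
            adjacent_ld_profile(self._matrix(np.full((5, 1), 0.5)))

    def test_missing_pairs_excluded(self):
        values = np.vstack([np.full((20, 2), 0.5), np.full((20, 2), 0.05)])
        values[0, 0] = np.nan
        profile = adjacent_ld_profile(self._matrix(values))
        assert profile[0].n == 39


class TestBuildBlocks:
    def _res(self, a, b, r2):
        return EpiLDResult(probe_a=a, probe_b=b, n=10, r2_em=r2)

    def test_single_run_of_eight(self):
        profile = [self._res(f"p{i}", f"p{i+1}", 1.0) for i in range(7)]
        (block,) = build_blocks(profile, r2_min=0.8)
        assert block.probe_ids == [f"p{i}" for i in range(8)]
        assert block.min_r2 == 1.0

    def test_run_splitting(self):
        r2s = [1.0, 1.0, 0.1, 1.0]
        profile = [self._res(f"p{i}", f"p{i+1}", r) for i, r in enumerate(r2s)]
        blocks = build_blocks(profile, r2_min=0.8)
        assert [len(b.probe_ids) for b in blocks] == [3, 2]

    def test_all_undefined_no_blocks(self):
        profile = [self._res(f"p{i}", f"p{i+1}", None) for i in range(5)]
        assert build_blocks(profile) == []

    def test_boundary_inclusive(self):
        profile = [self._res("a", "b", 0.8)]
        assert len(build_blocks(profile, r2_min=0.8)) == 1

    def test_empty_profile(self):
        assert build_blocks([]) == []


def test_em_loglik_monotone_guard_runs():
    # the EM asserts per-iteration monotonicity internally; a batch of random
    # tables exercises that assertion
    rng = np.random.default_rng(10)
    for _ in range(50):
        em_ld(random_genotype_table(rng))


def test_pairs_from_dosages_excludes_missing():
    pairs = pairs_from_dosages(
        ["a", "b", "c"], [0.0, float("nan"), 2.0], [1.0, 1.0, float("nan")]
    )
    assert [p.subject_id for p in pairs] == ["a"]
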