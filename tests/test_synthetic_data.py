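import json

import numpy as np
import pytest
from scipy import stats

from epitrio import epigram as eg
from epitrio import methylome as me
from epitrio import segregation as sg
from epitrio import trioscan as ts
from epitrio.antisense import StrandedRead, detect_readthrough
from epitrio.synthetic_data import (
    SimulationConfig,
    gen_annotation,
    gen_beta_cohort,
    gen_clones,
    gen_locus,
    gen_reads,
    gen_variants,
    write_clones,
    write_cohort,
    write_locus,
)


class TestGenLocus:
    def test_island_contains_requested_cpgs(self, locus, default_config):
        ref = eg.build_reference(
            locus.reference_seq, locus.region, locus.snp_offset,
            locus.snp_alleles,
        )
        assert ref.n_cpg == default_config.n_cpg == 32

    def test_determinism(self, default_config):
        a = gen_locus(default_config)
        b = gen_locus(SimulationConfig(seed=default_config.seed))
        assert a.reference_seq == b.reference_seq
        assert a.snp_offset == b.snp_offset

    def test_zero_cpg_degenerate(self):
        locus = gen_locus(SimulationConfig(seed=1, n_cpg=0))
        assert "CG" not in locus.reference_seq

    def test_trio_predicates_satisfied(self, locus):
        trios = ts.find_trios(locus.genes, [locus.island])
        assert len(trios) == 1
        assert trios[0].pattern == "R1F2R3"

    def test_snp_slot_is_neutral(self, locus):
        # neither allele at the SNP offset creates or destroys a CpG
        for allele in locus.snp_alleles:
            seq = (locus.reference_seq[: locus.snp_offset] + allele
                   + locus.reference_seq[locus.snp_offset + 1:])
            assert seq.count("CG") == locus.reference_seq.count("CG")

    def test_write_locus_deterministic_bytes(self, tmp_path, default_config):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_locus(gen_locus(default_config), d1)
        write_locus(gen_locus(SimulationConfig(seed=default_config.seed)), d2)
        for name in ("reference.fa", "genes.gff3", "island.bed"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


class TestGenClones:
    def test_full_conversion_forced(self, locus):
        cfg = SimulationConfig(seed=3, conversion_efficiency=1.0)
        ref = eg.build_reference(locus.reference_seq, locus.region,
                                 locus.snp_offset, locus.snp_alleles)
        for cid, seq in gen_clones(locus, cfg):
            assert eg.call_clone(cid, seq, ref).conversion_rate == 1.0

    def test_clone_count(self, locus):
        cfg = SimulationConfig(seed=3, n_clones_per_allele=30)
        assert len(gen_clones(locus, cfg)) == 60

    def test_qc_pass_rate_matches_binomial_tail(self):
        """Pass rate of the >0.95 filter vs the exact binomial tail."""
        cfg = SimulationConfig(seed=4, conversion_efficiency=0.90,
                               n_clones_per_allele=500)
        locus = gen_locus(cfg)
        ref = eg.build_reference(locus.reference_seq, locus.region,
                                 locus.snp_offset, locus.snp_alleles)
        n_c = len(ref.noncpg_c_positions)
        calls = [eg.call_clone(cid, s, ref) for cid, s in gen_clones(locus, cfg)]
        observed = np.mean([c.passed_qc for c in calls])
        # P[Binomial(n_c, 0.90) > 0.95 * n_c]
        threshold = int(np.floor(0.95 * n_c))
        expected = float(stats.binom.sf(threshold, n_c, 0.90))
        se = np.sqrt(expected * (1 - expected) / 1000)
        assert observed == pytest.approx(expected, abs=max(4 * se, 0.01))

    def test_determinism(self, locus):
        cfg = SimulationConfig(seed=5)
        assert gen_clones(locus, cfg) == gen_clones(locus, cfg)

    def test_planted_allele_recovered(self, locus, default_config):
        ref = eg.build_reference(locus.reference_seq, locus.region,
                                 locus.snp_offset, locus.snp_alleles)
        calls = [eg.call_clone(cid, s, ref)
                 for cid, s in gen_clones(locus, default_config)]
        epi = eg.assemble_epigram(calls, ref)
        assert eg.call_monoallelic_epimutation(epi) == "tag"


class TestGenBetaCohort:
    def test_planted_carrier_recovered(self):
        cfg = SimulationConfig(seed=6)
        controls, cases, block, truth = gen_beta_cohort(cfg)
        rep = me.detect_carriers(controls, block)
        assert rep.carriers == truth.planted_carriers
        assert len(rep.carriers) == 1

    def test_zero_planted(self):
        cfg = SimulationConfig(seed=6, n_planted_carriers=0)
        controls, _, block, truth = gen_beta_cohort(cfg)
        assert truth.planted_carriers == []
        assert me.detect_carriers(controls, block).carriers == []

    def test_cases_are_carriers(self):
        cfg = SimulationConfig(seed=6, n_cases=3)
        _, cases, block, _ = gen_beta_cohort(cfg)
        rep = me.detect_carriers(cases, block)
        assert len(rep.carriers) == 3

    def test_deterministic_tsv_bytes(self, tmp_path):
        for d in ("a", "b"):
            cfg = SimulationConfig(seed=7, n_controls=40)
            write_cohort(tmp_path / d, *gen_beta_cohort(cfg))
        assert (tmp_path / "a" / "controls.tsv").read_bytes() == (
            tmp_path / "b" / "controls.tsv"
        ).read_bytes()

    def test_flanks_hypermethylated(self):
        cfg = SimulationConfig(seed=8, n_controls=100)
        controls, _, block, _ = gen_beta_cohort(cfg)
        flank_cols = [j for j, p in enumerate(controls.probe_ids)
                      if p not in block]
        assert np.nanmean(controls.values[:, flank_cols]) > 0.8


class TestGenReads:
    def test_zero_readthrough(self, locus):
        cfg = SimulationConfig(seed=9, readthrough_frac=0.0)
        reads = [StrandedRead(iv) for iv in gen_reads(locus, cfg)]
        (trio,) = ts.find_trios(locus.genes, [locus.island])
        call = detect_readthrough(reads, trio, locus.genes)
        assert call.antisense_fraction_f2 == 0.0
        assert not call.is_readthrough

    def test_half_readthrough_detected(self, locus):
        cfg = SimulationConfig(seed=9, readthrough_frac=0.5, n_reads=10000)
        reads = [StrandedRead(iv) for iv in gen_reads(locus, cfg)]
        (trio,) = ts.find_trios(locus.genes, [locus.island])
        call = detect_readthrough(reads, trio, locus.genes)
        assert call.is_readthrough

    def test_empty(self, locus):
        cfg = SimulationConfig(seed=9, n_reads=0)
        assert gen_reads(locus, cfg) == []

    def test_read_count(self, locus):
        cfg = SimulationConfig(seed=9, n_reads=1000, readthrough_frac=0.25)
        assert len(gen_reads(locus, cfg)) == 1000


class TestGenAnnotation:
    def test_planted_recovery_exact(self):
        cfg = SimulationConfig(seed=10, n_planted_r1f2r3=5,
                               n_planted_f1r2f1=2, n_decoy_trios=30)
        genes, islands, truth = gen_annotation(cfg)
        trios = ts.find_trios(genes, islands)
        assert ts.summarize_patterns(trios) == {"R1F2R3": 5, "F1R2F1": 2}
        found = {tuple(sorted((t.left, t.middle, t.right))) for t in trios}
        planted = {tuple(sorted(t["genes"])) for t in truth.planted_trios}
        assert found == planted

    def test_zero_planted(self):
        cfg = SimulationConfig(seed=10, n_planted_r1f2r3=0,
                               n_planted_f1r2f1=0, n_decoy_trios=30)
        genes, islands, _ = gen_annotation(cfg)
        assert ts.find_trios(genes, islands) == []

    def test_determinism(self, tmp_path):
        from epitrio.synthetic_data import write_annotation

        for d in ("a", "b"):
            cfg = SimulationConfig(seed=11, n_planted_r1f2r3=3,
                                   n_planted_f1r2f1=1, n_decoy_trios=6)
            write_annotation(tmp_path / d, *gen_annotation(cfg))
        assert (tmp_path / "a" / "annotation.gff3").read_bytes() == (
            tmp_path / "b" / "annotation.gff3"
        ).read_bytes()

    def test_each_decoy_class_violates_one_predicate(self):
        cfg = SimulationConfig(seed=12, n_planted_r1f2r3=0,
                               n_planted_f1r2f1=0, n_decoy_trios=3)
        genes, islands, _ = gen_annotation(cfg)
        # decoys still form partial structures: pairs exist, trios do not
        assert ts.find_trios(genes, islands) == []
        assert len(ts.find_tail_to_tail(genes)) >= 1


class TestGenVariants:
    def test_pipeline_recovers_planted(self):
        cfg = SimulationConfig(seed=13)
        variants, status, truth = gen_variants(cfg)
        kept = sg.cosegregate(sg.filter_variants(variants), status)
        assert len(kept) == 1
        assert kept[0].pos == truth.planted_variant["pos"]

    def test_common_planted_filtered_out(self):
        cfg = SimulationConfig(seed=13)
        variants, status, _ = gen_variants(cfg, planted_maf=0.002)
        kept = sg.cosegregate(sg.filter_variants(variants), status)
        assert kept == []

    def test_determinism(self, tmp_path):
        from epitrio.synthetic_data import write_variants

        for d in ("a", "b"):
            write_variants(tmp_path / d, *gen_variants(SimulationConfig(seed=14)))
        assert (tmp_path / "a" / "variants.tsv").read_bytes() == (
            tmp_path / "b" / "variants.tsv"
        ).read_bytes()

    def test_pedigree_without_carriers_rejected(self):
        cfg = SimulationConfig(seed=13, pedigree={"S1": "non_carrier"})
        with pytest.raises(ValueError, match="carrier"):
            gen_variants(cfg)


class TestConfig:
    def test_from_file_round_trip(self, tmp_path):
        p = tmp_path / "sim.cfg"
        p.write_text(
            "n_cpg = 16\nconversion_efficiency = 0.97\n"
            "snp_alleles = G,T\nn_controls = 50\n"
        )
        cfg = SimulationConfig.from_file(p, seed=42)
        assert cfg.n_cpg == 16
        assert cfg.conversion_efficiency == 0.97
        assert cfg.seed == 42

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "sim.cfg"
        p.write_text("bogus = 1\n")
        with pytest.raises(ValueError, match="unknown config key"):
            SimulationConfig.from_file(p)

    def test_truth_serialization(self, tmp_path, locus):
        locus.truth.to_json(tmp_path / "t.json")
        data = json.loads((tmp_path / "t.json").read_text())
        assert data["planted_epimutation_allele"] == "G"
        assert data["snp_offset"] == locus.snp_offset
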