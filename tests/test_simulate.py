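"""Synthetic-cohort generator: determinism, decoy accounting, scenarios."""

import hashlib
import math

import numpy as np
import pytest

from ntdburden import (
    Pedigree,
    apply_filter_cascade,
    compound_het_scan,
    prioritize_by_segregation,
    read_ped,
    read_vcf,
    segregate,
)
from ntdburden.errors import ConfigurationError
from ntdburden.simulate import (
    DECOY_BENIGN_MISSENSE,
    DECOY_COMMON,
    DECOY_QC_FAIL,
    DECOY_SYNONYMOUS,
    DecoyFractions,
    SimulationConfig,
    evaluate_type1_power,
    simulate_cohort,
    simulate_family_variants,
)


def small_config(**overrides):
    defaults = dict(seed=42, n_genes=40)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestSimulateCohort:
    def test_default_cohort_composition(self):
        config = SimulationConfig()
        assert config.n_cases == 61  # 18 familial affected + 43 trio probands
        cohort = simulate_cohort(small_config())
        familial = [
            f for f in cohort.pedigree.family_ids if not f.startswith("CTRL")
        ]
        assert len(familial) == 8 + 43
        assert len(cohort.control_sample_ids) == 188

    def test_deterministic_under_seed(self):
        a = simulate_cohort(small_config())
        b = simulate_cohort(small_config())
        assert a.truth_table.equals(b.truth_table)
        assert [r.key for r in a.case_records] == [r.key for r in b.case_records]
        assert a.case_records == b.case_records

    def test_written_files_byte_identical_under_seed(self, tmp_path):
        ha, hb = [], []
        for name, acc in (("a", ha), ("b", hb)):
            cohort = simulate_cohort(small_config(n_genes=10)).write(tmp_path / name)
            for path in (cohort.vcf_path, cohort.ped_path, cohort.truth_path):
                acc.append(hashlib.sha256(path.read_bytes()).hexdigest())
        assert ha == hb

    def test_different_seed_changes_output(self):
        a = simulate_cohort(small_config())
        b = simulate_cohort(small_config(seed=43))
        assert not a.truth_table.equals(b.truth_table)

    def test_total_qualifying_count_near_poisson_expectation(self):
        config = SimulationConfig(
            seed=1, n_genes=100, base_rate=1e-6,
            decoy_fractions=DecoyFractions(0, 0, 0), polyphen_mix=1.0,
        )
        cohort = simulate_cohort(config)
        lam_total = sum(
            config.base_rate * n * length * 2
            for length in cohort.gene_lengths.values()
            for n in (config.n_cases, config.n_controls)
        )
        observed = len(cohort.truth_table)
        assert abs(observed - lam_total) <= 4 * math.sqrt(lam_total)

    def test_no_decoys_means_everything_survives_cascade(self):
        config = small_config(
            decoy_fractions=DecoyFractions(0, 0, 0), polyphen_mix=1.0
        )
        cohort = simulate_cohort(config)
        for records, ped in (
            (cohort.case_records, cohort.pedigree),
            (cohort.control_records, None),
        ):
            kept, funnel = apply_filter_cascade(records, ped)
            assert funnel.total_removed == 0
            assert len(kept) == len(records)

    def test_zero_rate_no_decoys_is_empty(self):
        cohort = simulate_cohort(
            small_config(base_rate=0.0, decoy_fractions=DecoyFractions(0, 0, 0))
        )
        assert cohort.case_records == []
        assert cohort.control_records == []
        assert len(cohort.truth_table) == 0

    def test_funnel_removals_match_truth_labels_exactly(self):
        cohort = simulate_cohort(small_config(seed=5))
        truth = cohort.truth_table
        for cohort_name, records, ped in (
            ("case", cohort.case_records, cohort.pedigree),
            ("control", cohort.control_records, None),
        ):
            sub = truth[truth.cohort == cohort_name]
            _, funnel = apply_filter_cascade(records, ped)
            expected = {
                "consequence": (sub.label == DECOY_SYNONYMOUS).sum(),
                "frequency": (sub.label == DECOY_COMMON).sum(),
                "genotype_qc": (sub.label == DECOY_QC_FAIL).sum(),
                "impact": (sub.label == DECOY_BENIGN_MISSENSE).sum(),
            }
            for stage in funnel.stages:
                assert stage.removed_count == expected[stage.stage_name]

    def test_qc_decoys_violate_exactly_one_named_rule(self):
        from ntdburden.qc_filtering import FilterConfig

        config = small_config(
            seed=9, decoy_fractions=DecoyFractions(0, 0, 0.4)
        )
        cohort = simulate_cohort(config)
        truth = cohort.truth_table
        qc_rows = truth[truth.label == DECOY_QC_FAIL]
        assert set(qc_rows.qc_rule) <= {"gq", "fwd", "rev", "fraction"}
        by_key = {
            r.key: r for r in cohort.case_records + cohort.control_records
        }
        fc = FilterConfig()
        for _, row in qc_rows.iterrows():
            rec = by_key[(row.chrom, row.pos, row.ref, row.alt)]
            (entry,) = rec.genotypes
            checks = {
                "gq": entry.gq >= fc.min_gq,
                "fwd": entry.alt_fwd > fc.min_strand_reads,
                "rev": entry.alt_rev > fc.min_strand_reads,
                "fraction": entry.alt_fraction > fc.min_alt_fraction,
            }
            assert checks[row.qc_rule] is False
            del checks[row.qc_rule]
            assert all(checks.values())

    def test_enriched_gene_must_exist(self):
        with pytest.raises(ConfigurationError, match="not in the simulated"):
            simulate_cohort(small_config(enriched_genes={"NOPE": 3.0}))

    def test_written_cohort_round_trips_through_readers(self, tmp_path):
        cohort = simulate_cohort(small_config(n_genes=10)).write(tmp_path)
        records = list(read_vcf(cohort.vcf_path))
        ped = read_ped(cohort.ped_path)
        assert len(records) == len(cohort.case_records) + len(
            cohort.control_records
        )
        assert len(ped) == len(cohort.pedigree)
        roster = {g.sample_id for g in records[0].genotypes}
        assert roster == {i.sample_id for i in ped.individuals}


class TestFamilyScenarios:
    def test_shared_scenario_segregates_true(self):
        records, members = simulate_family_variants("multiplex2", "shared_by_affected")
        ped = Pedigree(members)
        (res,) = segregate(records[0], ped)
        assert res.shared_by_all_affected is True
        assert res.transmitting_parent  # carried by the unaffected mother

    def test_unshared_scenario_dropped_by_prioritization(self):
        records, members = simulate_family_variants("multiplex3", "unshared")
        ped = Pedigree(members)
        assert prioritize_by_segregation(records, ped) == []

    def test_de_novo_scenario_sets_flag(self):
        records, members = simulate_family_variants("trio", "de_novo")
        ped = Pedigree(members)
        (res,) = segregate(records[0], ped)
        assert res.de_novo_flag is True
        assert res.shared_by_all_affected is True

    def test_compound_het_scenario_yields_one_trans_pair(self):
        records, members = simulate_family_variants("trio", "compound_het")
        ped = Pedigree(members)
        proband_pairs = [
            p for p in compound_het_scan(records, ped) if p.sample_id == "FAM001_p1"
        ]
        assert len(proband_pairs) == 1
        assert proband_pairs[0].phase_support.value == "confirmed_trans"

    def test_all_scenario_genotypes_pass_qc(self):
        from ntdburden.qc_filtering import FilterConfig, passes_genotype_qc

        for scenario in ("shared_by_affected", "de_novo", "compound_het"):
            records, _ = simulate_family_variants("trio", scenario)
            for rec in records:
                for g in rec.genotypes:
                    if g.allele_state.carries_alt:
                        assert passes_genotype_qc(g, FilterConfig())

    def test_impossible_scenarios_raise(self):
        with pytest.raises(ConfigurationError, match="2 affected"):
            simulate_family_variants("trio", "unshared")
        with pytest.raises(ConfigurationError, match="unknown scenario"):
            simulate_family_variants("trio", "linked")


class TestEvaluate:
    def test_report_fractions_and_shapes(self):
        config = small_config(
            n_genes=60, enriched_genes={"GENE0001": 10.0}
        )
        report = evaluate_type1_power(config, n_replicates=2, alphas=[0.05])
        assert 0.0 <= report.empirical_type1[0.05] <= 1.0
        assert report.n_null_gene_tests == 59 * 2
        assert set(report.empirical_power) == {"GENE0001"}
        assert report.mean_rate_ratio["GENE0001"] > 0.0
        frame = report.to_frame()
        assert set(frame.metric) == {"type1", "power", "rate_ratio"}

    def test_power_increases_with_rate_ratio(self):
        """Stronger enrichment is detected more often at the same threshold."""
        base = 6 / (18.5 * 61 * 3000 * 2)
        hi = SimulationConfig(
            seed=5, n_genes=20, base_rate=base,
            enriched_genes={"GENE0001": 18.5},
        )
        lo = SimulationConfig(
            seed=5, n_genes=20, base_rate=base,
            enriched_genes={"GENE0001": 2.0},
        )
        p_hi = evaluate_type1_power(hi, n_replicates=15, alphas=[]).empirical_power
        p_lo = evaluate_type1_power(lo, n_replicates=15, alphas=[]).empirical_power
        assert p_hi["GENE0001"] > p_lo["GENE0001"]

    def test_requires_null_genes_for_type1(self):
        config = small_config(
            n_genes=1, enriched_genes={"GENE0001": 2.0}
        )
        with pytest.raises(ConfigurationError, match="null genes"):
            evaluate_type1_power(config, n_replicates=1, alphas=[0.05])
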