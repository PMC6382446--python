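"""Filter-cascade rules, funnel accounting, and oracle equivalence.

The independent oracle re-evaluates every published filtering rule as a
flat boolean expression per record, with no shared code with the cascade.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ntdburden import (
    AlleleState,
    Consequence,
    FilterConfig,
    GenotypeEntry,
    ImpactClass,
    PolyPhenCategory,
    VariantRecord,
    apply_filter_cascade,
    consequence_filter,
    frequency_filter,
    impact_class,
    passes_genotype_qc,
    replication_filter,
)
from ntdburden.qc_filtering import PolyphenRule


def brute_force_keep(record: VariantRecord) -> bool:
    """Independent flat evaluation of the published filtering rules."""
    if record.consequence.value in ("synonymous", "noncoding"):
        return False
    for freq in record.pop_freqs.values():
        if freq > 0.01:
            return False
    any_pass = False
    for g in record.genotypes:
        if g.allele_state.value not in ("het", "hom_alt"):
            continue
        ok = (
            g.depth > 0
            and g.gq >= 99
            and g.alt_fwd > 3
            and g.alt_rev > 3
            and (g.alt_fwd + g.alt_rev) / g.depth > 0.15
        )
        if ok:
            any_pass = True
    if not any_pass:
        return False
    if record.consequence.value in ("stop_gained", "frameshift", "splice"):
        return True
    return (
        record.consequence.value == "missense"
        and record.polyphen_category.value == "probably_damaging"
    )


def make_record(
    pos,
    consequence=Consequence.MISSENSE,
    polyphen=PolyPhenCategory.PROBABLY_DAMAGING,
    freqs=None,
    genotypes=None,
    gene="G1",
):
    return VariantRecord(
        chrom="1", pos=pos, ref="A", alt="C", gene=gene,
        consequence=consequence, polyphen_category=polyphen,
        pop_freqs=freqs or {},
        genotypes=genotypes
        or [GenotypeEntry("S1", AlleleState.HET, 99, 5, 5, 30)],
    )


class TestStageRules:
    @pytest.mark.parametrize(
        "consequence,kept",
        [
            (Consequence.MISSENSE, True),
            (Consequence.SYNONYMOUS, False),
            (Consequence.NONCODING, False),
            (Consequence.FRAMESHIFT, True),
            (Consequence.OTHER, True),  # kept with a warning
        ],
    )
    def test_consequence_filter(self, consequence, kept):
        assert consequence_filter(make_record(1, consequence)) is kept

    @pytest.mark.parametrize(
        "freqs,kept",
        [
            ({"gnomAD": 0.002103, "EVS": 0.001157}, True),
            ({"gnomAD": 0.02}, False),
            ({}, True),  # absent everywhere = novel
            ({"gnomAD": 0.005, "ExAC": 0.011}, False),  # max over sources
            ({"gnomAD": 0.01}, True),  # removal threshold is exclusive
        ],
    )
    def test_frequency_filter(self, freqs, kept):
        assert frequency_filter(make_record(1, freqs=freqs), FilterConfig()) is kept

    @pytest.mark.parametrize(
        "gq,fwd,rev,depth,passes",
        [
            (99, 4, 4, 20, True),
            (99, 3, 10, 30, False),  # forward-strand threshold is exclusive
            (99, 10, 3, 30, False),
            (99, 4, 4, 60, False),  # fraction 0.133 <= 0.15
            (98, 10, 10, 40, False),
            (99, 5, 5, 66, True),  # fraction 0.1515 > 0.15
            (99, 4, 4, 0, False),  # zero depth undefined -> fail
        ],
    )
    def test_genotype_qc(self, gq, fwd, rev, depth, passes):
        entry = GenotypeEntry("S1", AlleleState.HET, gq, fwd, rev, max(depth, fwd + rev))
        if depth == 0:
            entry = GenotypeEntry("S1", AlleleState.HET, gq, 0, 0, 0)
        assert passes_genotype_qc(entry, FilterConfig()) is passes

    @pytest.mark.parametrize(
        "consequence,category,expected",
        [
            (Consequence.STOP_GAINED, PolyPhenCategory.UNKNOWN, ImpactClass.LOF),
            (Consequence.FRAMESHIFT, PolyPhenCategory.UNKNOWN, ImpactClass.LOF),
            (Consequence.SPLICE, PolyPhenCategory.UNKNOWN, ImpactClass.LOF),
            (
                Consequence.MISSENSE,
                PolyPhenCategory.PROBABLY_DAMAGING,
                ImpactClass.PROBABLY_DAMAGING_MISSENSE,
            ),
            (Consequence.MISSENSE, PolyPhenCategory.BENIGN, ImpactClass.OTHER),
            (Consequence.MISSENSE, PolyPhenCategory.UNKNOWN, ImpactClass.OTHER),
            (Consequence.MISSENSE, PolyPhenCategory.POSSIBLY_DAMAGING, ImpactClass.OTHER),
        ],
    )
    def test_impact_class_category_rule(self, consequence, category, expected):
        assert impact_class(make_record(1, consequence, category)) is expected

    def test_impact_class_score_cutoff_rule(self):
        config = FilterConfig(polyphen_rule=PolyphenRule.SCORE_CUTOFF)
        rec = make_record(1, Consequence.MISSENSE, PolyPhenCategory.UNKNOWN)
        rec.polyphen_score = 0.866
        assert impact_class(rec, config) is ImpactClass.PROBABLY_DAMAGING_MISSENSE
        rec.polyphen_score = 0.5
        assert impact_class(rec, config) is ImpactClass.OTHER


class TestCascade:
    def test_structured_funnel_counts(self):
        """20 synonymous + 10 common + 15 QC-failing + 30 benign + 25 good."""
        records, pos = [], 0
        for _ in range(25):
            pos += 1
            records.append(make_record(pos))
        for _ in range(20):
            pos += 1
            records.append(make_record(pos, Consequence.SYNONYMOUS))
        for _ in range(10):
            pos += 1
            records.append(make_record(pos, freqs={"gnomAD": 0.05}))
        for _ in range(15):
            pos += 1
            records.append(
                make_record(
                    pos,
                    genotypes=[GenotypeEntry("S1", AlleleState.HET, 50, 5, 5, 30)],
                )
            )
        for _ in range(30):
            pos += 1
            records.append(make_record(pos, polyphen=PolyPhenCategory.BENIGN))
        kept, funnel = apply_filter_cascade(records)
        assert len(kept) == 25
        assert [s.removed_count for s in funnel.stages] == [20, 10, 15, 30]
        assert funnel.total_input == 100
        assert funnel.total_output == 25

    def test_table1_fixture_keeps_all_five(self, filtered_table1):
        kept, funnel = filtered_table1
        assert len(kept) == 5
        assert funnel.total_removed == 0

    def test_all_synonymous_input_empties(self):
        records = [make_record(i + 1, Consequence.SYNONYMOUS) for i in range(5)]
        kept, funnel = apply_filter_cascade(records)
        assert kept == []
        assert funnel.total_output == 0

    def test_empty_input_gives_zero_funnel(self):
        kept, funnel = apply_filter_cascade([])
        assert kept == []
        assert funnel.total_input == funnel.total_output == 0

    def test_failing_carrier_cleared_on_retained_record(self):
        rec = make_record(
            1,
            genotypes=[
                GenotypeEntry("good", AlleleState.HET, 99, 5, 5, 30),
                GenotypeEntry("bad", AlleleState.HET, 10, 5, 5, 30),
            ],
        )
        (kept,), _ = apply_filter_cascade([rec])
        assert kept.genotype_of("bad").allele_state is AlleleState.MISSING
        assert kept.genotype_of("good").allele_state is AlleleState.HET

    def test_idempotent_on_own_output(self, table1_records, families_pedigree):
        kept, _ = apply_filter_cascade(table1_records, families_pedigree)
        again, funnel = apply_filter_cascade(kept, families_pedigree)
        assert again == kept
        assert funnel.total_removed == 0

    def _random_records(self, n, seed):
        rng = np.random.default_rng(seed)
        consequences = list(Consequence)
        categories = list(PolyPhenCategory)
        records = []
        for i in range(n):
            genotypes = [
                GenotypeEntry(
                    f"S{j}",
                    AlleleState(
                        str(rng.choice(["hom_ref", "het", "hom_alt", "missing"]))
                    ),
                    gq=int(rng.integers(0, 100)),
                    alt_fwd=int(rng.integers(0, 8)),
                    alt_rev=int(rng.integers(0, 8)),
                    depth=int(rng.integers(16, 60)),
                )
                for j in range(int(rng.integers(1, 4)))
            ]
            freqs = {}
            if rng.random() < 0.5:
                freqs["gnomAD"] = float(rng.choice([0.0001, 0.005, 0.02, 0.3]))
            records.append(
                VariantRecord(
                    chrom="1",
                    pos=i + 1,
                    ref="A",
                    alt="C",
                    gene=f"G{int(rng.integers(1, 20))}",
                    consequence=Consequence(str(rng.choice([c.value for c in consequences]))),
                    polyphen_category=PolyPhenCategory(
                        str(rng.choice([c.value for c in categories]))
                    ),
                    pop_freqs=freqs,
                    genotypes=genotypes,
                )
            )
        return records

    def test_oracle_equivalence_on_random_records(self):
        """Cascade output equals the independent per-record rule evaluation."""
        records = self._random_records(1000, seed=20260928)
        kept, funnel = apply_filter_cascade(records)
        expected = {r.key for r in records if brute_force_keep(r)}
        assert {r.key for r in kept} == expected
        assert funnel.total_output == len(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(0, 60))
    def test_funnel_conservation_property(self, seed, n):
        records = self._random_records(n, seed)
        kept, funnel = apply_filter_cascade(records)
        assert funnel.total_input == n
        assert funnel.total_output == len(kept)
        for prev, cur in zip(funnel.stages, funnel.stages[1:]):
            assert cur.input_count == prev.output_count
        assert funnel.total_input == funnel.total_output + funnel.total_removed

    def test_consequence_and_frequency_stages_commute(self):
        records = self._random_records(300, seed=7)
        config = FilterConfig()
        ab = [
            r
            for r in records
            if consequence_filter(r) and frequency_filter(r, config)
        ]
        ba = [
            r
            for r in records
            if frequency_filter(r, config) and consequence_filter(r)
        ]
        assert ab == ba


class TestReplicationFilter:
    def test_mips_fixture_counts(self, mips_cohort):
        records, pedigree = mips_cohort
        kept = replication_filter(records)
        affected = set(pedigree.affected_ids())
        unaffected = set(pedigree.unaffected_ids())
        case_obs = sum(1 for r in kept for s in r.carriers() if s in affected)
        ctrl_obs = sum(1 for r in kept for s in r.carriers() if s in unaffected)
        assert (case_obs, ctrl_obs) == (5, 2)

    def test_common_and_benign_records_removed(self, mips_cohort):
        records, _ = mips_cohort
        kept_keys = {r.pos for r in replication_filter(records)}
        assert 59520001 not in kept_keys  # >1% gnomAD
        assert 59521002 not in kept_keys  # benign tag
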