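"""Synthetic case-control exome cohorts with known per-gene variant rates.

The generator emulates the statistical structure the burden analysis
assumes: per-gene qualifying-variant carrier-observations are drawn as
Poisson counts with mean ``rate * n_individuals * gene_length * 2 alleles``
(enriched genes multiply the base rate by a configured rate ratio), and
decoy records — synonymous, common (>1% population frequency), QC-failing,
and benign-missense — are injected so every stage of the filter cascade
has work to do. The default cohort mirrors the study design this package
targets: 61 affected (18 familial members across 8 multiplex families plus
43 trio probands) versus 188 unrelated controls.

It deliberately does not model mutation spectra, linkage disequilibrium,
or population structure: the burden statistic sees only counts and
exposures, so those are what the generator controls exactly (a truth table
labels every emitted record).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .burden import (
    BurdenScanConfig,
    ExposureSpec,
    bonferroni_threshold,
    gene_burden_scan,
)
from .errors import ConfigurationError
from .models import (
    Affection,
    AlleleState,
    Consequence,
    GenotypeEntry,
    Individual,
    Pedigree,
    PolyPhenCategory,
    Sex,
    VariantRecord,
)
from .qc_filtering import FilterConfig, apply_filter_cascade

_BASES = np.array(["A", "C", "G", "T"])

QUALIFYING_CASE = "qualifying_case"
QUALIFYING_CONTROL = "qualifying_control"
DECOY_SYNONYMOUS = "decoy_synonymous"
DECOY_COMMON = "decoy_common"
DECOY_QC_FAIL = "decoy_qc_fail"
DECOY_BENIGN_MISSENSE = "decoy_benign_missense"


# ---------------------------------------------------------------------------
# Pedigree templates


def make_trio(family_id: str) -> list[Individual]:
    """Unaffected parents with one affected proband."""
    f, m, c = (f"{family_id}_fa", f"{family_id}_mo", f"{family_id}_p1")
    return [
        Individual(f, family_id, sex=Sex.MALE, affected=Affection.UNAFFECTED),
        Individual(m, family_id, sex=Sex.FEMALE, affected=Affection.UNAFFECTED),
        Individual(
            c, family_id, father_id=f, mother_id=m, sex=Sex.MALE,
            affected=Affection.AFFECTED, phenotype_label="MMC",
        ),
    ]


def make_multiplex(family_id: str, n_affected: int = 2) -> list[Individual]:
    """Unaffected parents with ``n_affected`` affected and one unaffected sib."""
    f, m = f"{family_id}_fa", f"{family_id}_mo"
    out = [
        Individual(f, family_id, sex=Sex.MALE, affected=Affection.UNAFFECTED),
        Individual(m, family_id, sex=Sex.FEMALE, affected=Affection.UNAFFECTED),
    ]
    for i in range(n_affected):
        out.append(
            Individual(
                f"{family_id}_p{i + 1}", family_id, father_id=f, mother_id=m,
                sex=Sex.MALE if i % 2 == 0 else Sex.FEMALE,
                affected=Affection.AFFECTED, phenotype_label="MMC",
            )
        )
    out.append(
        Individual(
            f"{family_id}_s1", family_id, father_id=f, mother_id=m,
            sex=Sex.FEMALE, affected=Affection.UNAFFECTED,
        )
    )
    return out


def make_two_generation(family_id: str) -> list[Individual]:
    """Affected mother and affected daughter (two generations)."""
    f, m = f"{family_id}_fa", f"{family_id}_mo"
    return [
        Individual(f, family_id, sex=Sex.MALE, affected=Affection.UNAFFECTED),
        Individual(
            m, family_id, sex=Sex.FEMALE, affected=Affection.AFFECTED,
            phenotype_label="myelocele",
        ),
        Individual(
            f"{family_id}_p1", family_id, father_id=f, mother_id=m,
            sex=Sex.FEMALE, affected=Affection.AFFECTED, phenotype_label="MMC",
        ),
        Individual(
            f"{family_id}_s1", family_id, father_id=f, mother_id=m,
            sex=Sex.MALE, affected=Affection.UNAFFECTED,
        ),
    ]


TEMPLATES = {
    "trio": make_trio,
    "multiplex2": lambda fid: make_multiplex(fid, 2),
    "multiplex3": lambda fid: make_multiplex(fid, 3),
    "two_generation": make_two_generation,
}


def default_family_structures() -> list[str]:
    """8 multiplex families totalling 18 affected, plus 43 trios."""
    return (
        ["multiplex2"] * 5 + ["multiplex3"] * 2 + ["two_generation"] + ["trio"] * 43
    )


@dataclass
class DecoyFractions:
    """Decoy record counts as fractions of the qualifying observation count."""

    synonymous: float = 0.25
    common: float = 0.10
    qc_fail: float = 0.05

    def __post_init__(self) -> None:
        for name in ("synonymous", "common", "qc_fail"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"decoy fraction {name}={v} outside [0,1]")


@dataclass
class SimulationConfig:
    """Full generative description of one synthetic cohort."""

    seed: int = 0
    n_controls: int = 188
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (1500, 4500)
    #: per-allele-bp qualifying-variant rate for null genes
    base_rate: float = 1.8e-6
    #: gene symbol -> rate ratio (> 0); applied to cases only
    enriched_genes: dict[str, float] = field(default_factory=dict)
    decoy_fractions: DecoyFractions = field(default_factory=DecoyFractions)
    family_structures: list[str] = field(default_factory=default_family_structures)
    #: fraction of missense records tagged probably damaging; the remainder
    #: are benign-missense decoys on top of the qualifying counts
    polyphen_mix: float = 0.75
    #: fraction of qualifying records that are LOF (rest: damaging missense)
    lof_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.n_controls <= 0 or self.n_genes <= 0:
            raise ConfigurationError("cohort and gene counts must be positive")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("bad gene_length_range")
        if self.base_rate < 0:
            raise ConfigurationError("base_rate must be >= 0")
        if not 0.0 < self.polyphen_mix <= 1.0:
            raise ConfigurationError("polyphen_mix must be in (0,1]")
        if not 0.0 <= self.lof_fraction <= 1.0:
            raise ConfigurationError("lof_fraction outside [0,1]")
        for g, ratio in self.enriched_genes.items():
            if ratio <= 0:
                raise ConfigurationError(f"rate ratio for {g} must be > 0")
        for name in self.family_structures:
            if name not in TEMPLATES:
                raise ConfigurationError(f"unknown family template {name!r}")

    @property
    def gene_symbols(self) -> list[str]:
        return [f"GENE{i + 1:04d}" for i in range(self.n_genes)]

    @property
    def n_cases(self) -> int:
        counts = {"trio": 1, "multiplex2": 2, "multiplex3": 3, "two_generation": 2}
        return sum(counts[t] for t in self.family_structures)

    def validate(self) -> None:
        symbols = set(self.gene_symbols)
        for g in self.enriched_genes:
            if g not in symbols:
                raise ConfigurationError(
                    f"enriched gene {g!r} is not in the simulated gene set"
                )


@dataclass
class SimulatedCohort:
    """In-memory cohort plus (after :meth:`write`) the emitted file paths."""

    config: SimulationConfig
    pedigree: Pedigree
    case_records: list[VariantRecord]
    control_records: list[VariantRecord]
    gene_lengths: dict[str, int]
    truth_table: pd.DataFrame
    vcf_path: Path | None = None
    ped_path: Path | None = None
    annotation_path: Path | None = None
    truth_path: Path | None = None

    @property
    def case_sample_ids(self) -> list[str]:
        return [
            i.sample_id
            for i in self.pedigree.individuals
            if not i.family_id.startswith("CTRL")
        ]

    @property
    def control_sample_ids(self) -> list[str]:
        return [
            i.sample_id
            for i in self.pedigree.individuals
            if i.family_id.startswith("CTRL")
        ]

    def write(self, out_dir: str | Path) -> "SimulatedCohort":
        """Materialize VCF/PED/annotation-sidecar/truth files under out_dir."""
        from . import io_formats

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        roster = self.case_sample_ids + self.control_sample_ids
        records = sorted(
            self.case_records + self.control_records, key=lambda r: (r.chrom, r.pos)
        )
        filled = [_fill_hom_ref(r, roster) for r in records]
        self.vcf_path = io_formats.write_vcf(
            filled, out_dir / "cohort.vcf", samples=roster
        )
        self.ped_path = io_formats.write_ped(self.pedigree, out_dir / "cohort.ped")
        self.truth_path = out_dir / "truth.tsv"
        self.truth_table.to_csv(self.truth_path, sep="\t", index=False)
        self.annotation_path = out_dir / "annotations.tsv"
        _write_annotation_sidecar(filled, self.annotation_path)
        return self


def _fill_hom_ref(record: VariantRecord, roster: Sequence[str]) -> VariantRecord:
    """Give every roster sample an explicit call (hom-ref where absent)."""
    present = {g.sample_id for g in record.genotypes}
    rec = record.copy()
    for sid in roster:
        if sid not in present:
            rec.genotypes.append(
                GenotypeEntry(
                    sample_id=sid, allele_state=AlleleState.HOM_REF,
                    gq=99, alt_fwd=0, alt_rev=0, depth=30,
                )
            )
    order = {sid: i for i, sid in enumerate(roster)}
    rec.genotypes.sort(key=lambda g: order.get(g.sample_id, len(order)))
    return rec


def _write_annotation_sidecar(records: Iterable[VariantRecord], path: Path) -> None:
    rows = []
    for r in records:
        row = {
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "gene": r.gene,
            "transcript": r.transcript,
            "cdna_change": r.cdna_change,
            "protein_change": r.protein_change,
            "consequence": r.consequence.value,
            "polyphen_category": r.polyphen_category.value,
            "polyphen_score": "" if r.polyphen_score is None else r.polyphen_score,
        }
        for src, f in r.pop_freqs.items():
            row[f"freq_{src}"] = f
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cohort generation


def _build_pedigree(config: SimulationConfig) -> Pedigree:
    individuals: list[Individual] = []
    for i, template in enumerate(config.family_structures):
        individuals.extend(TEMPLATES[template](f"FAM{i + 1:03d}"))
    for j in range(config.n_controls):
        fid = f"CTRL{j + 1:04d}"
        individuals.append(
            Individual(f"{fid}_c", fid, affected=Affection.UNAFFECTED)
        )
    return Pedigree(individuals)


def _passing_genotype(
    rng: np.random.Generator, sample_id: str, state: AlleleState = AlleleState.HET
) -> GenotypeEntry:
    depth = int(rng.integers(20, 61))
    alt = int(np.clip(rng.binomial(depth, 0.5), 9, depth))
    return GenotypeEntry(
        sample_id=sample_id, allele_state=state,
        gq=99, alt_fwd=alt // 2, alt_rev=alt - alt // 2, depth=depth,
    )


_QC_RULES = ("gq", "fwd", "rev", "fraction")


def _failing_genotype(
    rng: np.random.Generator, sample_id: str, rule: str
) -> GenotypeEntry:
    """A carrier genotype violating exactly the named QC rule."""
    if rule == "gq":
        g = _passing_genotype(rng, sample_id)
        return replace(g, gq=int(rng.integers(0, 99)))
    if rule == "fwd":
        return GenotypeEntry(sample_id, AlleleState.HET, 99, 3, 10, 30)
    if rule == "rev":
        return GenotypeEntry(sample_id, AlleleState.HET, 99, 10, 2, 30)
    if rule == "fraction":
        # 4+4 alt reads of 60: per-strand passes, fraction 0.133 <= 0.15
        return GenotypeEntry(sample_id, AlleleState.HET, 99, 4, 4, 60)
    raise ValueError(rule)


def _draw_positions(
    rng: np.random.Generator, start: int, length: int, n: int
) -> np.ndarray:
    return rng.choice(np.arange(start, start + length), size=n, replace=False)


class _VariantFactory:
    """Stateful helper assigning unique positions and building records."""

    def __init__(self, rng: np.random.Generator, config: SimulationConfig):
        self.rng = rng
        self.config = config
        lo, hi = config.gene_length_range
        self.lengths = {
            g: int(rng.integers(lo, hi + 1)) for g in config.gene_symbols
        }
        self.starts = {}
        cursor = 1_000_000
        for g in config.gene_symbols:
            self.starts[g] = cursor
            cursor += self.lengths[g] + 1_000
        self.used: dict[str, set[int]] = {g: set() for g in config.gene_symbols}

    def position(self, gene: str) -> int:
        length, start = self.lengths[gene], self.starts[gene]
        while True:
            pos = int(self.rng.integers(start, start + length))
            if pos not in self.used[gene]:
                self.used[gene].add(pos)
                return pos

    def alleles(self) -> tuple[str, str]:
        ref, alt = self.rng.choice(4, size=2, replace=False)
        return str(_BASES[ref]), str(_BASES[alt])

    def record(
        self,
        gene: str,
        consequence: Consequence,
        carriers: list[GenotypeEntry],
        polyphen_category: PolyPhenCategory = PolyPhenCategory.UNKNOWN,
        polyphen_score: float | None = None,
        pop_freqs: dict[str, float] | None = None,
    ) -> VariantRecord:
        ref, alt = self.alleles()
        return VariantRecord(
            chrom="1",
            pos=self.position(gene),
            ref=ref,
            alt=alt,
            gene=gene,
            consequence=consequence,
            polyphen_category=polyphen_category,
            polyphen_score=polyphen_score,
            pop_freqs=pop_freqs or {},
            genotypes=carriers,
        )


def _qualifying_consequence(
    rng: np.random.Generator, config: SimulationConfig
) -> tuple[Consequence, PolyPhenCategory, float | None]:
    if rng.random() < config.lof_fraction:
        csq = Consequence(
            str(rng.choice(["stop_gained", "frameshift", "splice"]))
        )
        return csq, PolyPhenCategory.UNKNOWN, None
    score = float(np.round(rng.uniform(0.85, 1.0), 3))
    return Consequence.MISSENSE, PolyPhenCategory.PROBABLY_DAMAGING, score


def _rare_freqs(rng: np.random.Generator) -> dict[str, float]:
    if rng.random() < 0.5:
        return {}  # novel: absent from every database
    return {"gnomAD": float(np.round(rng.uniform(1e-5, 5e-3), 7))}


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate one cohort; deterministic for a fixed config (incl. seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pedigree = _build_pedigree(config)
    factory = _VariantFactory(rng, config)
    affected = pedigree.affected_ids()
    controls = [i.sample_id for i in pedigree.individuals
                if i.family_id.startswith("CTRL")]
    if len(affected) != config.n_cases:
        raise ConfigurationError("family structures inconsistent with n_cases")

    case_records: list[VariantRecord] = []
    control_records: list[VariantRecord] = []
    truth_rows: list[dict] = []

    def emit(rec: VariantRecord, cohort: str, label: str, rate: float,
             qc_rule: str = "") -> None:
        (case_records if cohort == "case" else control_records).append(rec)
        truth_rows.append(
            {
                "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
                "alt": rec.alt, "gene": rec.gene, "cohort": cohort,
                "label": label, "true_rate": rate, "qc_rule": qc_rule,
            }
        )

    n_qual = {"case": 0, "control": 0}
    missense_count = 0
    for gene in config.gene_symbols:
        length = factory.lengths[gene]
        ratio = config.enriched_genes.get(gene, 1.0)
        for cohort, samples, rate in (
            ("case", affected, config.base_rate * ratio),
            ("control", controls, config.base_rate),
        ):
            mean = rate * len(samples) * length * 2
            k = int(rng.poisson(mean))
            n_qual[cohort] += k
            for _ in range(k):
                csq, cat, score = _qualifying_consequence(rng, config)
                if csq is Consequence.MISSENSE:
                    missense_count += 1
                carrier = str(rng.choice(samples))
                emit(
                    factory.record(
                        gene, csq, [_passing_genotype(rng, carrier)],
                        polyphen_category=cat, polyphen_score=score,
                        pop_freqs=_rare_freqs(rng),
                    ),
                    cohort, QUALIFYING_CASE if cohort == "case"
                    else QUALIFYING_CONTROL, rate,
                )

    # decoys, proportional to the realized qualifying counts
    genes = config.gene_symbols
    for cohort, samples in (("case", affected), ("control", controls)):
        base = n_qual[cohort]
        d = config.decoy_fractions
        for label, frac in (
            (DECOY_SYNONYMOUS, d.synonymous),
            (DECOY_COMMON, d.common),
            (DECOY_QC_FAIL, d.qc_fail),
        ):
            n = int(rng.poisson(frac * base))
            for _ in range(n):
                gene = str(rng.choice(genes))
                carrier = str(rng.choice(samples))
                if label == DECOY_SYNONYMOUS:
                    rec = factory.record(
                        gene, Consequence.SYNONYMOUS,
                        [_passing_genotype(rng, carrier)],
                        pop_freqs=_rare_freqs(rng),
                    )
                    emit(rec, cohort, label, 0.0)
                elif label == DECOY_COMMON:
                    rec = factory.record(
                        gene, Consequence.MISSENSE,
                        [_passing_genotype(rng, carrier)],
                        polyphen_category=PolyPhenCategory.PROBABLY_DAMAGING,
                        polyphen_score=float(np.round(rng.uniform(0.85, 1.0), 3)),
                        pop_freqs={
                            "gnomAD": float(np.round(rng.uniform(0.02, 0.2), 5))
                        },
                    )
                    emit(rec, cohort, label, 0.0)
                else:
                    rule = str(rng.choice(_QC_RULES))
                    csq, cat, score = _qualifying_consequence(rng, config)
                    rec = factory.record(
                        gene, csq, [_failing_genotype(rng, carrier, rule)],
                        polyphen_category=cat, polyphen_score=score,
                        pop_freqs=_rare_freqs(rng),
                    )
                    emit(rec, cohort, label, 0.0, qc_rule=rule)

    # benign missense: sized so probably-damaging/missense ~ polyphen_mix
    if config.polyphen_mix < 1.0 and missense_count:
        n_benign_total = rng.poisson(
            missense_count * (1.0 - config.polyphen_mix) / config.polyphen_mix
        )
        for _ in range(int(n_benign_total)):
            cohort = "case" if rng.random() < len(affected) / (
                len(affected) + len(controls)
            ) else "control"
            samples = affected if cohort == "case" else controls
            gene = str(rng.choice(genes))
            rec = factory.record(
                gene, Consequence.MISSENSE,
                [_passing_genotype(rng, str(rng.choice(samples)))],
                polyphen_category=PolyPhenCategory.BENIGN,
                polyphen_score=float(np.round(rng.uniform(0.0, 0.4), 3)),
                pop_freqs=_rare_freqs(rng),
            )
            emit(rec, cohort, DECOY_BENIGN_MISSENSE, 0.0)

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene", "cohort", "label",
            "true_rate", "qc_rule",
        ],
    )
    return SimulatedCohort(
        config=config,
        pedigree=pedigree,
        case_records=case_records,
        control_records=control_records,
        gene_lengths=dict(factory.lengths),
        truth_table=truth,
    )


# ---------------------------------------------------------------------------
# Family scenarios


FAMILY_SCENARIOS = ("shared_by_affected", "unshared", "de_novo", "compound_het")


def simulate_family_variants(
    structure: str | list[Individual],
    scenario: str,
    seed: int = 0,
) -> tuple[list[VariantRecord], list[Individual]]:
    """Emit genotypes realizing one segregation scenario exactly.

    ``shared_by_affected``: every affected member carries (plus one
    transmitting unaffected parent where present); ``unshared``: exactly one
    affected carries, other affected are genotyped non-carriers;
    ``de_novo``: the first affected carries, both its genotyped parents do
    not; ``compound_het``: two variants of one gene, one inherited from each
    parent. All emitted carrier genotypes pass QC.
    """
    if scenario not in FAMILY_SCENARIOS:
        raise ConfigurationError(f"unknown scenario {scenario!r}")
    members = (
        TEMPLATES[structure]("FAM001") if isinstance(structure, str) else structure
    )
    rng = np.random.default_rng(seed)
    affected = [m for m in members if m.affected is Affection.AFFECTED]
    if not affected:
        raise ConfigurationError("structure has no affected member")
    by_id = {m.sample_id: m for m in members}
    proband = affected[0]

    def genotype(sid: str, carrier: bool) -> GenotypeEntry:
        if carrier:
            return _passing_genotype(rng, sid)
        return GenotypeEntry(sid, AlleleState.HOM_REF, 99, 0, 0, 30)

    def record(carrier_ids: set[str], pos: int, gene: str = "FAMGENE") -> VariantRecord:
        return VariantRecord(
            chrom="2", pos=pos, ref="G", alt="T", gene=gene,
            consequence=Consequence.STOP_GAINED,
            genotypes=[genotype(m.sample_id, m.sample_id in carrier_ids)
                       for m in members],
        )

    if scenario == "shared_by_affected":
        carriers = {m.sample_id for m in affected}
        mother = by_id.get(proband.mother_id)
        if mother is not None and mother.affected is not Affection.AFFECTED:
            carriers.add(mother.sample_id)  # transmitting unaffected parent
        return [record(carriers, 5_000_000)], members
    if scenario == "unshared":
        if len(affected) < 2:
            raise ConfigurationError("unshared scenario needs >= 2 affected")
        return [record({proband.sample_id}, 5_000_000)], members
    if scenario == "de_novo":
        if not (proband.father_id and proband.mother_id):
            raise ConfigurationError("de_novo scenario needs both parents")
        return [record({proband.sample_id}, 5_000_000)], members
    # compound_het
    if not (proband.father_id and proband.mother_id):
        raise ConfigurationError("compound_het scenario needs both parents")
    rec_a = record({proband.sample_id, proband.father_id}, 5_000_000)
    rec_b = record({proband.sample_id, proband.mother_id}, 5_000_400)
    return [rec_a, rec_b], members


# ---------------------------------------------------------------------------
# Evaluation: type-I error, power, rate-ratio recovery


@dataclass
class EvaluationReport:
    n_replicates: int
    alphas: list[float]
    n_null_gene_tests: int
    #: alpha -> fraction of null gene-replicates with p < alpha
    empirical_type1: dict[float, float]
    #: enriched gene -> fraction of replicates significant at the
    #: Bonferroni threshold
    empirical_power: dict[str, float]
    #: enriched gene -> mean estimated case/control rate ratio
    mean_rate_ratio: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": "type1", "key": f"{a:g}", "value": v}
            for a, v in self.empirical_type1.items()
        ]
        rows += [
            {"metric": "power", "key": g, "value": v}
            for g, v in self.empirical_power.items()
        ]
        rows += [
            {"metric": "rate_ratio", "key": g, "value": v}
            for g, v in self.mean_rate_ratio.items()
        ]
        return pd.DataFrame(rows)


def evaluate_type1_power(
    config: SimulationConfig,
    n_replicates: int = 10,
    alphas: Sequence[float] = (0.05,),
    filter_config: FilterConfig | None = None,
    scan_config: BurdenScanConfig | None = None,
) -> EvaluationReport:
    """Simulate replicates, run the full cascade + burden scan, and measure
    empirical type-I error (null genes), power and mean estimated rate
    ratio (enriched genes).

    Genes never observed in either cohort count as p = 1. Replicate r uses
    seed ``config.seed + r``.
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    null_genes = [
        g for g in config.gene_symbols if g not in config.enriched_genes
    ]
    if alphas and not null_genes:
        raise ConfigurationError("type-I evaluation needs null genes")
    # the replicate loop would re-flag the same Poisson-tail outliers every
    # replicate, so the misalignment warning heuristic defaults off here
    scan_config = scan_config or BurdenScanConfig(misalignment_warn_quantile=0.0)
    filter_config = filter_config or FilterConfig()
    exposure = ExposureSpec(n_cases=config.n_cases, n_controls=config.n_controls)
    alpha_bonf = bonferroni_threshold(
        scan_config.alpha, scan_config.n_genes_bonferroni
    )
    pseudo = scan_config.zero_control_pseudocount or 0.5

    null_exceed = {a: 0 for a in alphas}
    power_hits = {g: 0 for g in config.enriched_genes}
    ratio_sums = {g: 0.0 for g in config.enriched_genes}

    for r in range(n_replicates):
        rep_config = replace(config, seed=config.seed + r)
        cohort = simulate_cohort(rep_config)
        case_f, _ = apply_filter_cascade(
            cohort.case_records, cohort.pedigree, filter_config
        )
        ctrl_f, _ = apply_filter_cascade(cohort.control_records, None, filter_config)
        results = {
            res.gene: res
            for res in gene_burden_scan(
                case_f, ctrl_f, exposure, config=scan_config
            )
        }
        for g in null_genes:
            p = results[g].p_value if g in results else 1.0
            for a in alphas:
                if p < a:
                    null_exceed[a] += 1
        for g in config.enriched_genes:
            res = results.get(g)
            if res is not None and res.p_value < alpha_bonf:
                power_hits[g] += 1
            k_case = res.case_count if res is not None else 0
            k_ctrl = res.control_count if res is not None else 0
            rate_case = k_case / exposure.case_alleles
            rate_ctrl = max(k_ctrl, pseudo) / exposure.control_alleles
            ratio_sums[g] += rate_case / rate_ctrl

    n_null_tests = len(null_genes) * n_replicates
    return EvaluationReport(
        n_replicates=n_replicates,
        alphas=list(alphas),
        n_null_gene_tests=n_null_tests,
        empirical_type1={
            a: null_exceed[a] / n_null_tests for a in alphas
        },
        empirical_power={
            g: power_hits[g] / n_replicates for g in config.enriched_genes
        },
        mean_rate_ratio={
            g: ratio_sums[g] / n_replicates for g in config.enriched_genes
        },
    )
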