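"""Candidate-gene prioritization and family segregation analysis.

Candidate variants are those falling in a merged candidate-gene list
(mouse neural-tube-defect genes plus folate-pathway genes) that survive the
filter cascade and are not previously published. Within each family, a
variant is prioritized when it is shared by every genotyped affected
member; unaffected carriers are recorded as a penetrance annotation, and
per-sample compound-heterozygote pairs are scanned with trio-based phase
assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

from .models import (
    Affection,
    AlleleState,
    ImpactClass,
    Individual,
    Pedigree,
    PhaseSupport,
    VariantRecord,
)
from .qc_filtering import FilterConfig, impact_class


@dataclass
class CandidateGeneList:
    """Union of tagged source lists; symbol -> set of source tags."""

    entries: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.entries

    def tags(self, symbol: str) -> set[str]:
        return self.entries.get(symbol.upper(), set())


def merge_gene_lists(
    *lists: Sequence[tuple[str, str]],
) -> CandidateGeneList:
    """Merge tagged symbol lists into one candidate list.

    Commutative and associative; a symbol present in several lists carries
    the union of its tags.
    """
    merged = CandidateGeneList()
    for tagged in lists:
        for symbol, tag in tagged:
            merged.entries.setdefault(symbol.upper(), set()).add(tag)
    return merged


def select_candidate_variants(
    records: Iterable[VariantRecord],
    gene_list: CandidateGeneList,
    config: FilterConfig | None = None,
) -> dict[ImpactClass, list[VariantRecord]]:
    """Restrict cascade-filtered records to candidate genes, split by impact.

    Returns a mapping with keys ``ImpactClass.LOF`` and
    ``ImpactClass.PROBABLY_DAMAGING_MISSENSE``.
    """
    out: dict[ImpactClass, list[VariantRecord]] = {
        ImpactClass.LOF: [],
        ImpactClass.PROBABLY_DAMAGING_MISSENSE: [],
    }
    for rec in records:
        if rec.gene and rec.gene in gene_list:
            cls = impact_class(rec, config)
            if cls in out:
                out[cls].append(rec)
    return out


def remove_published(
    records: Iterable[VariantRecord],
    published: set[tuple[str, str]],
) -> list[VariantRecord]:
    """Drop records matching a previously published (gene, cdna_change).

    A published entry with an empty cdna_change excludes every variant in
    that gene.
    """
    published_norm = {(g.upper(), c) for g, c in published}
    gene_level = {g for g, c in published_norm if not c}
    out = []
    for rec in records:
        gene = rec.gene.upper()
        if gene in gene_level:
            continue
        if (gene, rec.cdna_change) in published_norm:
            continue
        out.append(rec)
    return out


@dataclass
class SegregationResult:
    """Per-family segregation summary for one variant."""

    variant: VariantRecord
    family_id: str
    shared_by_all_affected: bool
    affected_carriers: list[str] = field(default_factory=list)
    unaffected_carriers: list[str] = field(default_factory=list)
    transmitting_parent: str = ""
    de_novo_flag: bool = False
    uninformative: bool = False  # no genotyped affected member
    incomplete: bool = False  # >=1 affected member not genotyped


def _genotyped(variant: VariantRecord, sample_id: str) -> bool:
    g = variant.genotype_of(sample_id)
    return g is not None and g.allele_state is not AlleleState.MISSING


def _carries(variant: VariantRecord, sample_id: str) -> bool:
    g = variant.genotype_of(sample_id)
    return g is not None and g.allele_state.carries_alt


def segregate(
    variant: VariantRecord, pedigree: Pedigree
) -> list[SegregationResult]:
    """Evaluate segregation in every family containing a carrier.

    ``shared_by_all_affected`` is judged on genotyped affected members only
    (missing genotypes do not veto sharing; the result is flagged
    ``incomplete`` instead) and requires at least one genotyped affected
    member. The transmitting parent is reported when exactly one genotyped
    parent of an affected carrier carries the variant; the de novo flag is
    set when an affected carrier's parents are both genotyped non-carriers.
    """
    carrier_ids = set(variant.carriers())
    families = sorted(
        {pedigree[s].family_id for s in carrier_ids if s in pedigree}
    )
    results = []
    for fam in families:
        members = pedigree.family(fam)
        affected = [m for m in members if m.affected is Affection.AFFECTED]
        unaffected = [m for m in members if m.affected is Affection.UNAFFECTED]
        genotyped_affected = [m for m in affected if _genotyped(variant, m.sample_id)]
        affected_carriers = [
            m.sample_id for m in affected if _carries(variant, m.sample_id)
        ]
        unaffected_carriers = [
            m.sample_id for m in unaffected if _carries(variant, m.sample_id)
        ]
        uninformative = not genotyped_affected
        shared = bool(genotyped_affected) and all(
            _carries(variant, m.sample_id) for m in genotyped_affected
        )
        transmitting = ""
        de_novo = False
        for m in affected:
            if m.sample_id not in affected_carriers:
                continue
            parents = [p for p in (m.father_id, m.mother_id) if p]
            genotyped_parents = [p for p in parents if _genotyped(variant, p)]
            carrier_parents = [p for p in genotyped_parents if _carries(variant, p)]
            if len(carrier_parents) == 1:
                transmitting = carrier_parents[0]
            if len(genotyped_parents) == 2 and not carrier_parents:
                de_novo = True
        results.append(
            SegregationResult(
                variant=variant,
                family_id=fam,
                shared_by_all_affected=shared,
                affected_carriers=affected_carriers,
                unaffected_carriers=unaffected_carriers,
                transmitting_parent=transmitting,
                de_novo_flag=de_novo,
                uninformative=uninformative,
                incomplete=len(genotyped_affected) < len(affected),
            )
        )
    return results


def prioritize_by_segregation(
    records: Iterable[VariantRecord], pedigree: Pedigree
) -> list[VariantRecord]:
    """Keep variants shared by all genotyped affected members of at least
    one carrier family."""
    out = []
    for rec in records:
        results = segregate(rec, pedigree)
        if any(r.shared_by_all_affected for r in results):
            out.append(rec)
    return out


@dataclass
class CompoundHetPair:
    """Two heterozygous variants of one gene in one carrier."""

    gene: str
    sample_id: str
    variant_a: VariantRecord
    variant_b: VariantRecord
    phase_support: PhaseSupport

    def __post_init__(self) -> None:
        if self.variant_a.key == self.variant_b.key:
            raise ValueError("compound-het pair cannot reuse one variant")


def _parental_origin(
    variant: VariantRecord, child: Individual
) -> str | None:
    """'father'/'mother' when exactly one genotyped parent carries, else None."""
    origins = []
    for role, pid in (("father", child.father_id), ("mother", child.mother_id)):
        if pid and _genotyped(variant, pid) and _carries(variant, pid):
            origins.append(role)
    if len(origins) == 1:
        return origins[0]
    return None


def compound_het_scan(
    records: Iterable[VariantRecord], pedigree: Pedigree
) -> list[CompoundHetPair]:
    """Enumerate per-sample, per-gene heterozygous variant pairs with phase.

    Phase is inferred from parental genotypes: opposite single-parent
    origins confirm a trans configuration, identical single-parent origins
    exclude it (cis), anything else stays possible. A sample with k
    heterozygous variants in one gene yields k*(k-1)/2 pairs.
    """
    by_gene_sample: dict[tuple[str, str], list[VariantRecord]] = {}
    for rec in records:
        if not rec.gene:
            continue
        for g in rec.genotypes:
            if g.allele_state is AlleleState.HET and g.sample_id in pedigree:
                by_gene_sample.setdefault(
                    (rec.gene.upper(), g.sample_id), []
                ).append(rec)
    pairs = []
    for (gene, sample_id), variants in sorted(by_gene_sample.items()):
        if len(variants) < 2:
            continue
        child = pedigree[sample_id]
        for va, vb in combinations(variants, 2):
            oa = _parental_origin(va, child)
            ob = _parental_origin(vb, child)
            if oa and ob:
                support = (
                    PhaseSupport.CONFIRMED_TRANS
                    if oa != ob
                    else PhaseSupport.EXCLUDED_CIS
                )
            else:
                support = PhaseSupport.POSSIBLE
            pairs.append(
                CompoundHetPair(
                    gene=gene,
                    sample_id=sample_id,
                    variant_a=va,
                    variant_b=vb,
                    phase_support=support,
                )
            )
    return pairs
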