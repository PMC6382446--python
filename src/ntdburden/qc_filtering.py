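"""The basic filter cascade applied identically to case and control calls.

Stages, in fixed order:

1. **consequence** — drop synonymous and noncoding variants;
2. **frequency** — drop variants whose maximum population allele frequency
   across available databases exceeds 1% (absent everywhere = novel = kept);
3. **genotype QC** — per-carrier evidence thresholds (GQ >= 99, more than 3
   alternate reads on each strand, alternate-read fraction > 0.15); a
   variant survives iff at least one relevant carrier passes, and failing
   carriers are cleared to missing;
4. **impact** — keep loss-of-function variants (stop-gained, frameshift,
   splice) and missense variants called probably damaging by PolyPhen-2.

A :class:`FilterFunnel` records per-stage input/removed/output counts so a
run is auditable.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .models import (
    LOF_CONSEQUENCES,
    AlleleState,
    Consequence,
    GenotypeEntry,
    ImpactClass,
    Pedigree,
    PolyPhenCategory,
    VariantRecord,
)

logger = logging.getLogger(__name__)


class PolyphenRule(enum.Enum):
    """How 'probably damaging' is decided for missense variants."""

    CATEGORY_TAG = "category_tag"
    SCORE_CUTOFF = "score_cutoff"


@dataclass
class FilterConfig:
    """Thresholds of the cascade; defaults reproduce the published rules.

    Strand-read and alt-fraction thresholds are exclusive (``> 3`` reads per
    strand means at least 4; fraction must strictly exceed 0.15). The
    population-frequency threshold is an exclusive removal bound: variants
    above 1% are removed, variants missing from every database are kept as
    novel.
    """

    min_gq: int = 99
    min_strand_reads: int = 3  # exclusive: require > 3 per strand
    min_alt_fraction: float = 0.15  # exclusive
    max_pop_freq: float = 0.01  # exclusive removal: drop if freq > 1%
    polyphen_rule: PolyphenRule = PolyphenRule.CATEGORY_TAG
    polyphen_score_cutoff: float = 0.80

    def __post_init__(self) -> None:
        if self.min_gq < 0:
            raise ValueError("min_gq must be >= 0")
        if not 0.0 <= self.min_alt_fraction <= 1.0:
            raise ValueError("min_alt_fraction outside [0,1]")
        if not 0.0 <= self.max_pop_freq <= 1.0:
            raise ValueError("max_pop_freq outside [0,1]")
        if not 0.0 <= self.polyphen_score_cutoff <= 1.0:
            raise ValueError("polyphen_score_cutoff outside [0,1]")


@dataclass
class FunnelStage:
    stage_name: str
    input_count: int
    removed_count: int

    @property
    def output_count(self) -> int:
        return self.input_count - self.removed_count


@dataclass
class FilterFunnel:
    """Ordered per-stage accounting of the cascade."""

    stages: list[FunnelStage] = field(default_factory=list)

    def add(self, name: str, input_count: int, removed_count: int) -> None:
        if self.stages and self.stages[-1].output_count != input_count:
            raise ValueError(
                f"funnel stage {name!r} input {input_count} != previous "
                f"output {self.stages[-1].output_count}"
            )
        self.stages.append(FunnelStage(name, input_count, removed_count))

    @property
    def total_input(self) -> int:
        return self.stages[0].input_count if self.stages else 0

    @property
    def total_output(self) -> int:
        return self.stages[-1].output_count if self.stages else 0

    @property
    def total_removed(self) -> int:
        return sum(s.removed_count for s in self.stages)

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "stage": s.stage_name,
                    "input": s.input_count,
                    "removed": s.removed_count,
                    "output": s.output_count,
                }
                for s in self.stages
            ],
            "total_input": self.total_input,
            "total_removed": self.total_removed,
            "total_output": self.total_output,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        lines = [f"{'stage':<22}{'input':>8}{'removed':>9}{'output':>8}"]
        for s in self.stages:
            lines.append(
                f"{s.stage_name:<22}{s.input_count:>8}{s.removed_count:>9}"
                f"{s.output_count:>8}"
            )
        return "\n".join(lines)


def consequence_filter(record: VariantRecord) -> bool:
    """Keep unless synonymous or noncoding. ``other`` is kept with a warning."""
    if record.consequence in (Consequence.SYNONYMOUS, Consequence.NONCODING):
        return False
    if record.consequence is Consequence.OTHER:
        logger.warning(
            "variant %s:%d has consequence 'other'; kept", record.chrom, record.pos
        )
    return True


def frequency_filter(record: VariantRecord, config: FilterConfig) -> bool:
    """Keep unless any population database reports frequency above threshold.

    Missing from every database means novel, hence kept.
    """
    if not record.pop_freqs:
        return True
    return max(record.pop_freqs.values()) <= config.max_pop_freq


def passes_genotype_qc(entry: GenotypeEntry, config: FilterConfig) -> bool:
    """Carrier-level evidence check (GQ, per-strand alt reads, alt fraction).

    Zero depth fails (the fraction is undefined).
    """
    if entry.depth <= 0:
        logger.warning("sample %s has zero depth; QC fail", entry.sample_id)
        return False
    return (
        entry.gq >= config.min_gq
        and entry.alt_fwd > config.min_strand_reads
        and entry.alt_rev > config.min_strand_reads
        and entry.alt_fraction > config.min_alt_fraction
    )


def impact_class(
    record: VariantRecord, config: FilterConfig | None = None
) -> ImpactClass:
    """Classify as LOF, probably-damaging missense, or other.

    LOF = stop-gained, frameshift, or splice. Under the default
    ``category_tag`` rule a missense variant qualifies iff its PolyPhen-2
    category is probably damaging; the ``score_cutoff`` rule instead
    compares the numeric score against ``polyphen_score_cutoff``.
    """
    config = config or FilterConfig()
    if record.consequence in LOF_CONSEQUENCES:
        return ImpactClass.LOF
    if record.consequence is Consequence.MISSENSE:
        if config.polyphen_rule is PolyphenRule.CATEGORY_TAG:
            if record.polyphen_category is PolyPhenCategory.PROBABLY_DAMAGING:
                return ImpactClass.PROBABLY_DAMAGING_MISSENSE
            if record.polyphen_category is PolyPhenCategory.UNKNOWN:
                logger.warning(
                    "missense %s:%d lacks a PolyPhen-2 category; classed other",
                    record.chrom,
                    record.pos,
                )
        else:
            if (
                record.polyphen_score is not None
                and record.polyphen_score >= config.polyphen_score_cutoff
            ):
                return ImpactClass.PROBABLY_DAMAGING_MISSENSE
    return ImpactClass.OTHER


def _relevant_samples(
    record: VariantRecord, pedigree: Pedigree | None
) -> set[str] | None:
    """Samples whose carrier evidence can rescue a record at the QC stage.

    With a pedigree containing affected members, only affected carriers
    count (the case cohort); otherwise every carrier counts (the control
    cohort, or pedigree-free runs). Returns None for "all samples".
    """
    if pedigree is None:
        return None
    affected = set(pedigree.affected_ids())
    return affected or None


def genotype_qc_filter(
    record: VariantRecord,
    config: FilterConfig,
    pedigree: Pedigree | None = None,
) -> VariantRecord | None:
    """Apply carrier-level QC; return the cleaned record or None if dropped.

    Failing carriers are set to missing on the returned copy. The record
    survives iff at least one relevant carrier (affected member when a
    pedigree with affected individuals is supplied, any carrier otherwise)
    passes QC.
    """
    relevant = _relevant_samples(record, pedigree)
    keep = False
    cleaned = record.copy()
    for entry in cleaned.genotypes:
        if not entry.allele_state.carries_alt:
            continue
        if passes_genotype_qc(entry, config):
            if relevant is None or entry.sample_id in relevant:
                keep = True
        else:
            entry.allele_state = AlleleState.MISSING
    return cleaned if keep else None


def apply_filter_cascade(
    records: Iterable[VariantRecord],
    pedigree: Pedigree | None = None,
    config: FilterConfig | None = None,
) -> tuple[list[VariantRecord], FilterFunnel]:
    """Run the four-stage cascade and return survivors plus the funnel.

    The cascade is idempotent: re-applying it to its own output removes
    nothing further.
    """
    config = config or FilterConfig()
    records = list(records)
    funnel = FilterFunnel()

    stage1 = [r for r in records if consequence_filter(r)]
    funnel.add("consequence", len(records), len(records) - len(stage1))

    stage2 = [r for r in stage1 if frequency_filter(r, config)]
    funnel.add("frequency", len(stage1), len(stage1) - len(stage2))

    stage3 = []
    for r in stage2:
        cleaned = genotype_qc_filter(r, config, pedigree)
        if cleaned is not None:
            stage3.append(cleaned)
    funnel.add("genotype_qc", len(stage2), len(stage2) - len(stage3))

    stage4 = [r for r in stage3 if impact_class(r, config) is not ImpactClass.OTHER]
    funnel.add("impact", len(stage3), len(stage3) - len(stage4))

    return stage4, funnel


def replication_filter(
    records: Iterable[VariantRecord],
    config: FilterConfig | None = None,
) -> list[VariantRecord]:
    """Targeted-resequencing filter: frequency < 1% and probably damaging.

    This is the reduced rule set used on candidate-gene resequencing data
    (no consequence-removal stage — the targets are coding — and annotation
    rather than read-level evidence decides): keep variants that pass the
    population-frequency rule and are PolyPhen-2 probably damaging missense
    or loss-of-function.
    """
    config = config or FilterConfig()
    return [
        r
        for r in records
        if frequency_filter(r, config)
        and impact_class(r, config) is not ImpactClass.OTHER
    ]
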