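"""Core domain types shared across the pipeline.

Everything that flows between modules is one of the dataclasses below: a
:class:`VariantRecord` (one ALT allele at one site, with annotations and
per-sample genotype evidence), an :class:`Individual` (one pedigree row),
or a :class:`GeneModel` (coding length used as the exposure denominator
of the burden test).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace


class Consequence(enum.Enum):
    """Functional consequence class of a variant on its gene."""

    SYNONYMOUS = "synonymous"
    NONCODING = "noncoding"
    MISSENSE = "missense"
    STOP_GAINED = "stop_gained"
    FRAMESHIFT = "frameshift"
    SPLICE = "splice"
    OTHER = "other"


#: Consequence classes treated as loss-of-function: premature stop,
#: frameshift, or splice-site disruption.
LOF_CONSEQUENCES = frozenset(
    {Consequence.STOP_GAINED, Consequence.FRAMESHIFT, Consequence.SPLICE}
)


class PolyPhenCategory(enum.Enum):
    PROBABLY_DAMAGING = "probably_damaging"
    POSSIBLY_DAMAGING = "possibly_damaging"
    BENIGN = "benign"
    UNKNOWN = "unknown"


class AlleleState(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def carries_alt(self) -> bool:
        return self in (AlleleState.HET, AlleleState.HOM_ALT)


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class ImpactClass(enum.Enum):
    LOF = "lof"
    PROBABLY_DAMAGING_MISSENSE = "probably_damaging_missense"
    OTHER = "other"


class PhaseSupport(enum.Enum):
    CONFIRMED_TRANS = "confirmed_trans"
    POSSIBLE = "possible"
    EXCLUDED_CIS = "excluded_cis"


@dataclass
class GenotypeEntry:
    """One sample's call at one variant.

    ``alt_fwd``/``alt_rev`` are strand-split alternate-read counts; the
    alternate-read fraction is derived from them and ``depth``.
    """

    sample_id: str
    allele_state: AlleleState
    gq: int = 0
    alt_fwd: int = 0
    alt_rev: int = 0
    depth: int = 0

    def __post_init__(self) -> None:
        if self.gq < 0:
            raise ValueError(f"gq must be >= 0, got {self.gq}")
        if self.alt_fwd < 0 or self.alt_rev < 0 or self.depth < 0:
            raise ValueError("read counts must be non-negative")
        if self.alt_fwd + self.alt_rev > self.depth:
            raise ValueError(
                f"alt reads ({self.alt_fwd}+{self.alt_rev}) exceed depth "
                f"({self.depth}) for sample {self.sample_id}"
            )

    @property
    def alt_fraction(self) -> float:
        """Alternate-read fraction; 0.0 when depth is zero."""
        if self.depth <= 0:
            return 0.0
        return (self.alt_fwd + self.alt_rev) / self.depth


@dataclass
class VariantRecord:
    """One normalized (bi-allelic) variant with annotations and genotypes.

    Multi-allelic VCF sites are decomposed on read, so ``alt`` is always a
    single allele. ``pop_freqs`` maps population-database names (e.g.
    ``gnomAD``, ``ExAC``, ``EVS``) to allele frequencies; absence from every
    database marks the variant as novel.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = ""
    transcript: str = ""
    cdna_change: str = ""
    protein_change: str = ""
    consequence: Consequence = Consequence.OTHER
    polyphen_category: PolyPhenCategory = PolyPhenCategory.UNKNOWN
    polyphen_score: float | None = None
    pop_freqs: dict[str, float] = field(default_factory=dict)
    genotypes: list[GenotypeEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt identical at {self.chrom}:{self.pos}")
        for src, f in self.pop_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"pop_freq[{src}]={f} outside [0,1]")
        if self.polyphen_score is not None and not 0.0 <= self.polyphen_score <= 1.0:
            raise ValueError(f"polyphen_score {self.polyphen_score} outside [0,1]")
        ids = [g.sample_id for g in self.genotypes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate sample ids at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def genotype_of(self, sample_id: str) -> GenotypeEntry | None:
        for g in self.genotypes:
            if g.sample_id == sample_id:
                return g
        return None

    def carriers(self) -> list[str]:
        """Sample ids with at least one alternate allele."""
        return [g.sample_id for g in self.genotypes if g.allele_state.carries_alt]

    def copy(self) -> "VariantRecord":
        return replace(
            self,
            pop_freqs=dict(self.pop_freqs),
            genotypes=[replace(g) for g in self.genotypes],
        )


@dataclass
class Individual:
    """One pedigree member with affection status."""

    sample_id: str
    family_id: str
    father_id: str = ""
    mother_id: str = ""
    sex: Sex = Sex.UNKNOWN
    affected: Affection = Affection.UNKNOWN
    phenotype_label: str = ""


class Pedigree:
    """Cohort-wide family structure indexed by sample and family."""

    def __init__(self, individuals: list[Individual]):
        self.individuals = list(individuals)
        self._by_id: dict[str, Individual] = {}
        for ind in self.individuals:
            if ind.sample_id in self._by_id:
                raise ValueError(f"duplicate sample id {ind.sample_id!r}")
            self._by_id[ind.sample_id] = ind
        self._validate_parents()

    def _validate_parents(self) -> None:
        dangling = []
        for ind in self.individuals:
            for pid in (ind.father_id, ind.mother_id):
                if pid and pid not in self._by_id:
                    dangling.append(pid)
                elif pid and self._by_id[pid].family_id != ind.family_id:
                    raise ValueError(
                        f"parent {pid!r} of {ind.sample_id!r} is in a "
                        f"different family"
                    )
        if dangling:
            raise ValueError(
                "dangling parent reference(s): " + ", ".join(sorted(set(dangling)))
            )

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def __getitem__(self, sample_id: str) -> Individual:
        return self._by_id[sample_id]

    def get(self, sample_id: str) -> Individual | None:
        return self._by_id.get(sample_id)

    @property
    def family_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.family_id, None)
        return list(seen)

    def family(self, family_id: str) -> list[Individual]:
        return [i for i in self.individuals if i.family_id == family_id]

    def affected_ids(self) -> list[str]:
        return [
            i.sample_id for i in self.individuals if i.affected is Affection.AFFECTED
        ]

    def unaffected_ids(self) -> list[str]:
        return [
            i.sample_id for i in self.individuals if i.affected is Affection.UNAFFECTED
        ]


@dataclass
class GeneModel:
    """Gene coding model; ``coding_length`` feeds the exposure denominator."""

    symbol: str
    transcript: str = ""
    coding_length: int = 0
    exons: list[tuple[int, int]] | None = None  # half-open, 0-based

    def __post_init__(self) -> None:
        if self.coding_length <= 0:
            raise ValueError(
                f"coding_length must be > 0 for {self.symbol}, got "
                f"{self.coding_length}"
            )
        if self.exons is not None:
            span = sum(e - s for s, e in self.exons)
            if self.coding_length > span:
                raise ValueError(
                    f"coding_length {self.coding_length} exceeds exon span "
                    f"{span} for {self.symbol}"
                )
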