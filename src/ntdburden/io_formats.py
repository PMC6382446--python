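"""Readers and writers for every external format the pipeline touches.

VCF goes through :mod:`pysam`; the non-standard parts (which FORMAT keys
hold strand-split alternate-read counts, which INFO keys hold the gene,
consequence, PolyPhen-2 and population-frequency annotations) are described
by a :class:`VcfDialect` so the pipeline can consume output from different
callers/annotators. Annotations may alternatively come from a sidecar TSV
keyed by (chrom, pos, ref, alt).

Coordinate conventions are centralized here: VCF positions are 1-based
inclusive; BED intervals are half-open 0-based.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

from .errors import ConfigurationError, PedigreeError, VcfParseError
from .models import (
    Affection,
    AlleleState,
    Consequence,
    GeneModel,
    GenotypeEntry,
    Individual,
    Pedigree,
    PolyPhenCategory,
    Sex,
    VariantRecord,
)

logger = logging.getLogger(__name__)

MISSING = "."


@dataclass
class VcfDialect:
    """Maps FORMAT/INFO keys onto :class:`GenotypeEntry`/annotation fields.

    The shipped default expects ``GQ``, ``DP``, and the standard per-allele
    strand-split depths ``ADF``/``ADR`` (Number=R: reference first), plus
    String INFO keys for the annotation columns. Frequencies are declared
    as String and parsed here so values round-trip at full printed
    precision.
    """

    gq_key: str = "GQ"
    depth_key: str = "DP"
    alt_fwd_key: str = "ADF"
    alt_rev_key: str = "ADR"
    gene_key: str = "GENE"
    transcript_key: str = "TRANSCRIPT"
    cdna_key: str = "CDNA"
    protein_key: str = "PROT"
    consequence_key: str = "CSQ_CLASS"
    polyphen_cat_key: str = "PPH2"
    polyphen_score_key: str = "PPH2_SCORE"
    #: population source name -> INFO key
    freq_keys: dict[str, str] = field(
        default_factory=lambda: {
            "gnomAD": "AF_GNOMAD",
            "ExAC": "AF_EXAC",
            "EVS": "AF_EVS",
        }
    )

    @property
    def format_keys(self) -> list[str]:
        return [self.gq_key, self.depth_key, self.alt_fwd_key, self.alt_rev_key]

    @property
    def annotation_info_keys(self) -> list[str]:
        return [
            self.gene_key,
            self.transcript_key,
            self.cdna_key,
            self.protein_key,
            self.consequence_key,
            self.polyphen_cat_key,
            self.polyphen_score_key,
            *self.freq_keys.values(),
        ]


DEFAULT_DIALECT = VcfDialect()


def _per_alt(value, alt_index: int, n_alts: int) -> str:
    """Pick the alt_index-th component of a possibly per-allele INFO value."""
    if value is None:
        return MISSING
    if isinstance(value, (tuple, list)):
        if len(value) == n_alts:
            v = value[alt_index]
        elif len(value) == 1:
            v = value[0]
        else:
            v = value[alt_index] if alt_index < len(value) else None
        return MISSING if v is None else str(v)
    return str(value)


def _parse_float(text: str) -> float | None:
    if text in ("", MISSING, "None"):
        return None
    return float(text)


def _allele_state(gt: tuple, alt_number: int) -> AlleleState:
    """Genotype state relative to one alt allele (1-based allele number)."""
    if gt is None or all(a is None for a in gt):
        return AlleleState.MISSING
    called = [a for a in gt if a is not None]
    n_alt = sum(1 for a in called if a == alt_number)
    if n_alt == 0:
        return AlleleState.HOM_REF
    if n_alt == len(called) and len(called) > 1:
        return AlleleState.HOM_ALT
    return AlleleState.HET


def _check_dialect(header: pysam.VariantHeader, dialect: VcfDialect) -> None:
    for key in dialect.format_keys:
        if key not in header.formats:
            raise ConfigurationError(
                f"dialect FORMAT key {key!r} absent from VCF header"
            )
    for key in dialect.annotation_info_keys:
        if key not in header.info:
            raise ConfigurationError(f"dialect INFO key {key!r} absent from VCF header")


def read_vcf(
    path: str | Path,
    dialect: VcfDialect = DEFAULT_DIALECT,
    annotations: dict[tuple[str, int, str, str], dict] | None = None,
) -> Iterator[VariantRecord]:
    """Stream one :class:`VariantRecord` per ALT allele per site.

    Multi-allelic sites are decomposed; per-allele INFO values (commas) are
    split accordingly. When a sidecar ``annotations`` mapping (from
    :func:`read_annotation_sidecar`) is given it overrides INFO annotations
    for matching (chrom, pos, ref, alt) keys.

    Raises
    ------
    ConfigurationError
        if a dialect key is missing from the header.
    VcfParseError
        on malformed VCF content, naming the offending position.
    """
    path = Path(path)
    save = pysam.set_verbosity(0)
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    finally:
        pysam.set_verbosity(save)
    with vf:
        if annotations is None:
            _check_dialect(vf.header, dialect)
        else:
            for key in dialect.format_keys:
                if key not in vf.header.formats:
                    raise ConfigurationError(
                        f"dialect FORMAT key {key!r} absent from VCF header"
                    )
        try:
            for site in vf:
                yield from _decompose_site(site, dialect, annotations)
        except (OSError, ValueError) as exc:
            raise VcfParseError(f"malformed VCF record in {path}: {exc}") from exc


def _decompose_site(site, dialect, annotations) -> Iterator[VariantRecord]:
    alts = site.alts or ()
    n_alts = len(alts)
    for i, alt in enumerate(alts):
        key = (site.chrom, site.pos, site.ref, alt)
        if annotations is not None:
            ann = annotations.get(key, {})
            gene = ann.get("gene", "")
            transcript = ann.get("transcript", "")
            cdna = ann.get("cdna_change", "")
            prot = ann.get("protein_change", "")
            csq = ann.get("consequence", Consequence.OTHER)
            pph_cat = ann.get("polyphen_category", PolyPhenCategory.UNKNOWN)
            pph_score = ann.get("polyphen_score")
            freqs = dict(ann.get("pop_freqs", {}))
        else:
            info = site.info
            gene = _per_alt(info.get(dialect.gene_key), i, n_alts)
            transcript = _per_alt(info.get(dialect.transcript_key), i, n_alts)
            cdna = _per_alt(info.get(dialect.cdna_key), i, n_alts)
            prot = _per_alt(info.get(dialect.protein_key), i, n_alts)
            csq_txt = _per_alt(info.get(dialect.consequence_key), i, n_alts)
            cat_txt = _per_alt(info.get(dialect.polyphen_cat_key), i, n_alts)
            score_txt = _per_alt(info.get(dialect.polyphen_score_key), i, n_alts)
            gene = "" if gene == MISSING else gene
            transcript = "" if transcript == MISSING else transcript
            cdna = "" if cdna == MISSING else cdna
            prot = "" if prot == MISSING else prot
            try:
                csq = (
                    Consequence.OTHER
                    if csq_txt == MISSING
                    else Consequence(csq_txt)
                )
                pph_cat = (
                    PolyPhenCategory.UNKNOWN
                    if cat_txt == MISSING
                    else PolyPhenCategory(cat_txt)
                )
            except ValueError as exc:
                raise VcfParseError(
                    f"bad annotation at {site.chrom}:{site.pos}: {exc}"
                ) from exc
            pph_score = _parse_float(score_txt)
            freqs = {}
            for source, info_key in dialect.freq_keys.items():
                f = _parse_float(_per_alt(info.get(info_key), i, n_alts))
                if f is not None:
                    freqs[source] = f
        genotypes = [
            _read_genotype(sample, i + 1, n_alts, dialect, site)
            for sample in site.samples.values()
        ]
        yield VariantRecord(
            chrom=site.chrom,
            pos=site.pos,
            ref=site.ref,
            alt=alt,
            gene=gene,
            transcript=transcript,
            cdna_change=cdna,
            protein_change=prot,
            consequence=csq,
            polyphen_category=pph_cat,
            polyphen_score=pph_score,
            pop_freqs=freqs,
            genotypes=genotypes,
        )


def _read_genotype(sample, alt_number, n_alts, dialect, site) -> GenotypeEntry:
    gt = sample.get("GT")
    state = _allele_state(gt, alt_number)
    if state is AlleleState.MISSING:
        return GenotypeEntry(sample_id=sample.name, allele_state=state)
    gq = sample.get(dialect.gq_key)
    dp = sample.get(dialect.depth_key)
    adf = sample.get(dialect.alt_fwd_key)
    adr = sample.get(dialect.alt_rev_key)

    def strand_count(values) -> int:
        # Number=R layout: [ref, alt1, alt2, ...]
        if values is None:
            return 0
        if isinstance(values, (tuple, list)):
            if len(values) == n_alts + 1:
                v = values[alt_number]
            elif len(values) == n_alts:
                v = values[alt_number - 1]
            else:
                v = values[0] if values else None
            return 0 if v is None else int(v)
        return int(values)

    return GenotypeEntry(
        sample_id=sample.name,
        allele_state=state,
        gq=0 if gq is None else int(gq),
        alt_fwd=strand_count(adf),
        alt_rev=strand_count(adr),
        depth=0 if dp is None else int(dp),
    )


def _build_header(
    records: Sequence[VariantRecord],
    dialect: VcfDialect,
    samples: Sequence[str] | None,
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    contigs: dict[str, None] = {}
    for rec in records:
        contigs.setdefault(rec.chrom, None)
    for contig in contigs:
        header.contigs.add(contig)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add(dialect.gq_key, 1, "Integer", "Genotype quality")
    header.formats.add(dialect.depth_key, 1, "Integer", "Read depth")
    header.formats.add(
        dialect.alt_fwd_key, "R", "Integer", "Forward-strand read depth per allele"
    )
    header.formats.add(
        dialect.alt_rev_key, "R", "Integer", "Reverse-strand read depth per allele"
    )
    descriptions = {
        dialect.gene_key: "Gene symbol",
        dialect.transcript_key: "Transcript accession",
        dialect.cdna_key: "HGVS cDNA change",
        dialect.protein_key: "HGVS protein change",
        dialect.consequence_key: "Consequence class",
        dialect.polyphen_cat_key: "PolyPhen-2 category",
        dialect.polyphen_score_key: "PolyPhen-2 score",
    }
    for source, info_key in dialect.freq_keys.items():
        descriptions[info_key] = f"{source} allele frequency"
    for info_key, desc in descriptions.items():
        header.info.add(info_key, 1, "String", desc)
    if samples is None:
        seen: dict[str, None] = {}
        for rec in records:
            for g in rec.genotypes:
                seen.setdefault(g.sample_id, None)
        samples = list(seen)
    for sample in samples:
        header.add_sample(sample)
    return header


def write_vcf(
    records: Iterable[VariantRecord],
    path: str | Path,
    dialect: VcfDialect = DEFAULT_DIALECT,
    samples: Sequence[str] | None = None,
) -> Path:
    """Write records as a bi-allelic VCF that :func:`read_vcf` round-trips.

    The sample roster defaults to the union of sample ids across records,
    in order of first appearance; samples lacking a genotype entry on a
    record are written as missing calls.
    """
    path = Path(path)
    records = list(records)
    header = _build_header(records, dialect, samples)
    roster = list(header.samples)
    gt_state = {
        AlleleState.HOM_REF: (0, 0),
        AlleleState.HET: (0, 1),
        AlleleState.HOM_ALT: (1, 1),
        AlleleState.MISSING: (None, None),
    }
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            site = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                stop=rec.pos - 1 + len(rec.ref),
                alleles=(rec.ref, rec.alt),
            )
            info = site.info
            if rec.gene:
                info[dialect.gene_key] = rec.gene
            if rec.transcript:
                info[dialect.transcript_key] = rec.transcript
            if rec.cdna_change:
                info[dialect.cdna_key] = rec.cdna_change
            if rec.protein_change:
                info[dialect.protein_key] = rec.protein_change
            info[dialect.consequence_key] = rec.consequence.value
            if rec.polyphen_category is not PolyPhenCategory.UNKNOWN:
                info[dialect.polyphen_cat_key] = rec.polyphen_category.value
            if rec.polyphen_score is not None:
                info[dialect.polyphen_score_key] = repr(rec.polyphen_score)
            for source, info_key in dialect.freq_keys.items():
                if source in rec.pop_freqs:
                    info[info_key] = repr(rec.pop_freqs[source])
            by_id = {g.sample_id: g for g in rec.genotypes}
            for sample in roster:
                entry = by_id.get(sample)
                fmt = site.samples[sample]
                if entry is None or entry.allele_state is AlleleState.MISSING:
                    fmt["GT"] = (None, None)
                    continue
                fmt["GT"] = gt_state[entry.allele_state]
                fmt[dialect.gq_key] = entry.gq
                fmt[dialect.depth_key] = entry.depth
                ref_reads = max(entry.depth - entry.alt_fwd - entry.alt_rev, 0)
                fmt[dialect.alt_fwd_key] = (ref_reads // 2, entry.alt_fwd)
                fmt[dialect.alt_rev_key] = (ref_reads - ref_reads // 2, entry.alt_rev)
            out.write(site)
    return path


# ---------------------------------------------------------------------------
# PED


_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}
_AFFECTION_CODES = {"1": Affection.UNAFFECTED, "2": Affection.AFFECTED}


def read_ped(path: str | Path) -> Pedigree:
    """Read a 6-column PED file (optional 7th free-text phenotype label).

    Affection codes: 2 -> affected, 1 -> unaffected, 0/-9 -> unknown.
    Raises :class:`PedigreeError` on dangling parent references.
    """
    individuals = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeError(
                    f"{path}:{lineno}: expected >=6 PED columns, got {len(fields)}"
                )
            fam, sid, father, mother, sex, pheno = fields[:6]
            label = fields[6] if len(fields) > 6 else ""
            individuals.append(
                Individual(
                    sample_id=sid,
                    family_id=fam,
                    father_id="" if father == "0" else father,
                    mother_id="" if mother == "0" else mother,
                    sex=_SEX_CODES.get(sex, Sex.UNKNOWN),
                    affected=_AFFECTION_CODES.get(pheno, Affection.UNKNOWN),
                    phenotype_label=label,
                )
            )
    try:
        return Pedigree(individuals)
    except ValueError as exc:
        raise PedigreeError(f"{path}: {exc}") from exc


def write_ped(pedigree: Pedigree, path: str | Path) -> Path:
    sex_out = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    aff_out = {Affection.UNAFFECTED: "1", Affection.AFFECTED: "2", Affection.UNKNOWN: "0"}
    path = Path(path)
    with open(path, "w") as fh:
        for ind in pedigree.individuals:
            cols = [
                ind.family_id,
                ind.sample_id,
                ind.father_id or "0",
                ind.mother_id or "0",
                sex_out[ind.sex],
                aff_out[ind.affected],
            ]
            if ind.phenotype_label:
                cols.append(ind.phenotype_label)
            fh.write("\t".join(cols) + "\n")
    return path


# ---------------------------------------------------------------------------
# Gene lists, gene models, annotation sidecar, published-mutation lists


def read_gene_list(path: str | Path, source_tag: str) -> list[tuple[str, str]]:
    """Read gene symbols (one per line, or TSV first column), tag them.

    Symbols are uppercased and deduplicated within the file; order of first
    appearance is preserved. An empty file yields an empty list with a
    warning.
    """
    symbols: dict[str, None] = {}
    path = Path(path)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            symbol = line.split("\t")[0].strip().upper()
            if symbol:
                symbols.setdefault(symbol, None)
    if not symbols:
        warnings.warn(f"gene list {path} is empty", stacklevel=2)
    return [(symbol, source_tag) for symbol in symbols]


def read_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Read gene coding models from TSV (symbol, transcript, coding_length)
    or BED (chrom, start, end, symbol; coding_length = end - start)."""
    path = Path(path)
    models: dict[str, GeneModel] = {}
    is_bed = path.suffix.lower() == ".bed"
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if is_bed:
                if len(fields) < 4:
                    raise ConfigurationError(
                        f"{path}:{lineno}: BED gene model needs 4 columns"
                    )
                symbol = fields[3].upper()
                length = int(fields[2]) - int(fields[1])
                model = GeneModel(symbol=symbol, coding_length=length)
            else:
                if fields[0].lower() in ("symbol", "gene"):
                    continue  # header row
                symbol = fields[0].upper()
                transcript = fields[1] if len(fields) > 1 else ""
                length = int(fields[2]) if len(fields) > 2 else 0
                model = GeneModel(
                    symbol=symbol, transcript=transcript, coding_length=length
                )
            models[symbol] = model
    return models


def read_annotation_sidecar(
    path: str | Path,
) -> dict[tuple[str, int, str, str], dict]:
    """Read a per-variant annotation TSV keyed by (chrom, pos, ref, alt).

    Columns beyond the fixed set are treated as population-frequency
    sources when named ``freq_<source>``.
    """
    out: dict[tuple[str, int, str, str], dict] = {}
    with open(Path(path)) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            freqs = {}
            for col, val in row.items():
                if col.startswith("freq_") and val not in ("", MISSING, None):
                    freqs[col[len("freq_"):]] = float(val)
            score = row.get("polyphen_score", "")
            out[key] = {
                "gene": row.get("gene", ""),
                "transcript": row.get("transcript", ""),
                "cdna_change": row.get("cdna_change", ""),
                "protein_change": row.get("protein_change", ""),
                "consequence": Consequence(row.get("consequence", "other")),
                "polyphen_category": PolyPhenCategory(
                    row.get("polyphen_category", "unknown")
                ),
                "polyphen_score": _parse_float(score),
                "pop_freqs": freqs,
            }
    return out


def read_published_mutations(path: str | Path) -> set[tuple[str, str]]:
    """Read a (gene, cdna_change) exclusion TSV; symbols uppercased."""
    published = set()
    with open(Path(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() == "gene":
                continue
            gene = fields[0].upper()
            cdna = fields[1] if len(fields) > 1 else ""
            published.add((gene, cdna))
    return published


def read_blacklist(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line gene blacklist (misalignment exclusions)."""
    genes = set()
    with open(Path(path)) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line.split("\t")[0].upper())
    return genes
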