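import pytest

from ntdburden import (
    Pedigree,
    apply_filter_cascade,
    merge_gene_lists,
    read_ped,
    read_vcf,
)
from ntdburden.fixtures import (
    FAMILIES_PED,
    FOLATE_GENES,
    GENE_MODELS,
    MOUSE_NTD_GENES,
    PUBLISHED_MUTATIONS,
    SHROOM3_DECOY_VCF,
    TABLE1_VCF,
    TABLE2_MIPS_PED,
    TABLE2_MIPS_VCF,
    TABLE2_WES_PED,
    TABLE2_WES_VCF,
    fixture_path,
)
from ntdburden.io_formats import read_gene_list, read_published_mutations


@pytest.fixture(scope="session")
def table1_records():
    return list(read_vcf(fixture_path(TABLE1_VCF)))


@pytest.fixture(scope="session")
def shroom3_decoy_records():
    return list(read_vcf(fixture_path(SHROOM3_DECOY_VCF)))


@pytest.fixture(scope="session")
def families_pedigree() -> Pedigree:
    return read_ped(fixture_path(FAMILIES_PED))


@pytest.fixture(scope="session")
def candidate_gene_list():
    return merge_gene_lists(
        read_gene_list(fixture_path(MOUSE_NTD_GENES), "mouse_ntd"),
        read_gene_list(fixture_path(FOLATE_GENES), "folate"),
    )


@pytest.fixture(scope="session")
def published_mutations():
    return read_published_mutations(fixture_path(PUBLISHED_MUTATIONS))


@pytest.fixture(scope="session")
def wes_cohort():
    records = list(read_vcf(fixture_path(TABLE2_WES_VCF)))
    pedigree = read_ped(fixture_path(TABLE2_WES_PED))
    return records, pedigree


@pytest.fixture(scope="session")
def mips_cohort():
    records = list(read_vcf(fixture_path(TABLE2_MIPS_VCF)))
    pedigree = read_ped(fixture_path(TABLE2_MIPS_PED))
    return records, pedigree


@pytest.fixture(scope="session")
def gene_models_path():
    return fixture_path(GENE_MODELS)


@pytest.fixture
def filtered_table1(table1_records, families_pedigree):
    kept, funnel = apply_filter_cascade(table1_records, families_pedigree)
    return kept, funnel
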