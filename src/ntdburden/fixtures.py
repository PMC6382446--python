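"""Paths to the packaged example data.

The two variant tables and the family pedigree encode the published
discovery results this package is validated against; the gene lists and
gene models are synthetic stand-ins at the documented sizes (see their
file headers).
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

_DATA = files("ntdburden") / "data"

TABLE1_VCF = "table1.vcf"
SHROOM3_DECOY_VCF = "shroom3_decoy.vcf"
FAMILIES_PED = "families.ped"
TABLE2_WES_VCF = "table2_wes.vcf"
TABLE2_WES_PED = "table2_wes.ped"
TABLE2_MIPS_VCF = "table2_mips.vcf"
TABLE2_MIPS_PED = "table2_mips.ped"
MOUSE_NTD_GENES = "mouse_ntd_genes.synthetic.tsv"
FOLATE_GENES = "folate_genes.synthetic.tsv"
PUBLISHED_MUTATIONS = "published_mutations.tsv"
GENE_MODELS = "gene_models.synthetic.tsv"


def fixture_path(name: str) -> Path:
    """Absolute path of a packaged data file."""
    path = Path(str(_DATA / name))
    if not path.exists():
        raise FileNotFoundError(f"no packaged fixture named {name!r}")
    return path
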