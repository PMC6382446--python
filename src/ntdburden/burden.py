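"""Per-gene exact Poisson rate-comparison burden test.

For each gene, qualifying-variant carrier-observations in the case cohort
(``k_case``) are compared against the control cohort (``k_ctrl``) on
allele-count exposures ``E = n_individuals x 2`` (optionally x gene coding
length; the length cancels exactly in the two-cohort comparison). The
control rate sets the null: ``lambda = k_ctrl * E_case / E_ctrl`` and the
reported p-value is the exact upper-tail Poisson probability
``P(X >= k_case)`` for ``X ~ Poisson(lambda)``. A doubled two-sided option
exists; the default upper tail is what reproduces published rate-burden
results. Family-wise error is controlled by Bonferroni over the number of
genes tested (default 20,389).

Counting unit: one observation per carrier individual per variant — a
variant shared by two affected individuals contributes two observations.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .models import GeneModel, VariantRecord

logger = logging.getLogger(__name__)

#: Number of genes in the exome-wide scan, used for the default Bonferroni
#: correction (0.05 / 20,389 = 2.45e-6).
DEFAULT_N_GENES = 20_389
DEFAULT_ALPHA = 0.05
PLOIDY = 2


class Tail(enum.Enum):
    UPPER = "upper"
    TWO_SIDED_DOUBLED = "two_sided_doubled"


@dataclass
class ExposureSpec:
    """Cohort sizes defining the allele-count exposures of the comparison."""

    n_cases: int
    n_controls: int
    ploidy: int = PLOIDY

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("cohort sizes must be positive")
        if self.ploidy != PLOIDY:
            raise ValueError("ploidy is fixed at 2")

    @property
    def case_alleles(self) -> int:
        return self.n_cases * self.ploidy

    @property
    def control_alleles(self) -> int:
        return self.n_controls * self.ploidy


@dataclass
class BurdenResult:
    """One gene's burden-scan row."""

    gene: str
    case_count: int
    control_count: int
    case_exposure: float
    control_exposure: float
    rate_case: float | None
    rate_control: float | None
    lam: float
    p_value: float
    alpha_bonferroni: float
    significant: bool
    excluded_reason: str = ""
    degenerate_lambda: bool = False  # k_ctrl was zero (pseudocount or p=0)


def mutation_rate(k: int, n: int, length_bp: int) -> float:
    """Per-allele-bp mutation rate: k / (n * length * 2 alleles)."""
    if n <= 0 or length_bp <= 0:
        raise ValueError("cohort size and gene length must be positive")
    if k < 0:
        raise ValueError("variant count must be non-negative")
    return k / (n * length_bp * PLOIDY)


def bonferroni_threshold(alpha: float = DEFAULT_ALPHA, n_genes: int = DEFAULT_N_GENES) -> float:
    """Family-wise significance cutoff alpha / n_genes."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0,1)")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return alpha / n_genes


def poisson_burden_p(
    k_case: int,
    k_ctrl: float,
    e_case: float,
    e_ctrl: float,
    tail: Tail = Tail.UPPER,
) -> float:
    """Exact Poisson p-value for the case count against the control rate.

    ``lambda = k_ctrl * e_case / e_ctrl``. Upper tail is ``P(X >= k_case)``;
    the doubled two-sided variant is ``min(1, 2 * min(P(X >= k), P(X <= k)))``.
    ``k_ctrl = 0`` yields ``lambda = 0`` and hence ``p = 0`` for any positive
    case count; callers wanting a guarded value should apply a pseudocount
    (see :func:`gene_burden_scan`).
    """
    if e_case <= 0 or e_ctrl <= 0:
        raise ValueError("exposures must be positive")
    if k_case < 0 or k_ctrl < 0:
        raise ValueError("counts must be non-negative")
    lam = k_ctrl * (e_case / e_ctrl)
    if lam == 0.0 and k_case > 0:
        logger.warning(
            "degenerate lambda: control count 0 gives p = 0 for k_case=%d", k_case
        )
        return 0.0
    upper = float(stats.poisson.sf(k_case - 1, lam))  # P(X >= k_case)
    if tail is Tail.UPPER:
        return upper
    lower = float(stats.poisson.cdf(k_case, lam))  # P(X <= k_case)
    return min(1.0, 2.0 * min(upper, lower))


def count_carrier_observations(
    records: Iterable[VariantRecord],
) -> dict[str, int]:
    """Per-gene carrier-observation counts (one per carrier per variant)."""
    counts: dict[str, int] = {}
    for rec in records:
        gene = rec.gene.upper()
        if not gene:
            continue
        counts[gene] = counts.get(gene, 0) + len(rec.carriers())
    return counts


def split_records_by_cohort(
    records: Iterable[VariantRecord],
    affected_ids: set[str],
    unaffected_ids: set[str],
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split a joint cohort's records into case/control views.

    Each output record keeps only the genotypes of its cohort's samples;
    records with no genotyped sample in a cohort are omitted from that
    cohort's list.
    """
    cases, controls = [], []
    for rec in records:
        for ids, bucket in ((affected_ids, cases), (unaffected_ids, controls)):
            sub = rec.copy()
            sub.genotypes = [g for g in sub.genotypes if g.sample_id in ids]
            if sub.genotypes:
                bucket.append(sub)
    return cases, controls


@dataclass
class BurdenScanConfig:
    tail: Tail = Tail.UPPER
    alpha: float = DEFAULT_ALPHA
    n_genes_bonferroni: int = DEFAULT_N_GENES
    #: added to k_ctrl only when k_ctrl == 0; set to 0 to disable
    zero_control_pseudocount: float = 0.5
    #: warn (never exclude) when a control count exceeds this quantile in a
    #: genome-scale scan; 0 disables
    misalignment_warn_quantile: float = 0.999


def gene_burden_scan(
    case_variants: Iterable[VariantRecord],
    control_variants: Iterable[VariantRecord],
    exposure: ExposureSpec,
    gene_models: Mapping[str, GeneModel] | None = None,
    blacklist: set[str] | None = None,
    config: BurdenScanConfig | None = None,
) -> list[BurdenResult]:
    """Run the per-gene burden test over both cohorts' filtered variants.

    Both inputs must already have passed the identical filter cascade. One
    result is emitted per gene with at least one qualifying observation in
    either cohort. Blacklisted genes (known misalignment artifacts) carry
    ``excluded_reason='blacklist'`` and are never significant. Per-bp rates
    are reported when the gene has a coding model; the p-value never needs
    one (gene length cancels between cohorts).
    """
    config = config or BurdenScanConfig()
    blacklist = {g.upper() for g in (blacklist or set())}
    case_counts = count_carrier_observations(case_variants)
    ctrl_counts = count_carrier_observations(control_variants)
    genes = sorted(set(case_counts) | set(ctrl_counts))
    alpha_bonf = bonferroni_threshold(config.alpha, config.n_genes_bonferroni)
    e_case = float(exposure.case_alleles)
    e_ctrl = float(exposure.control_alleles)

    # heuristic outlier flag; meaningless below genome-scan size
    if config.misalignment_warn_quantile and len(ctrl_counts) >= 1000:
        cutoff = float(
            np.quantile(list(ctrl_counts.values()), config.misalignment_warn_quantile)
        )
        for gene, k in ctrl_counts.items():
            if k > cutoff and gene not in blacklist:
                logger.warning(
                    "gene %s control count %d exceeds the %.1f%% quantile; "
                    "possible misalignment artifact (not excluded)",
                    gene,
                    k,
                    100 * config.misalignment_warn_quantile,
                )

    results = []
    for gene in genes:
        k_case = case_counts.get(gene, 0)
        k_ctrl = ctrl_counts.get(gene, 0)
        degenerate = k_ctrl == 0
        k_ctrl_eff = (
            config.zero_control_pseudocount if degenerate else float(k_ctrl)
        )
        p = poisson_burden_p(k_case, k_ctrl_eff, e_case, e_ctrl, config.tail)
        model = (gene_models or {}).get(gene)
        if model is not None:
            rate_case = mutation_rate(k_case, exposure.n_cases, model.coding_length)
            rate_ctrl = mutation_rate(
                k_ctrl, exposure.n_controls, model.coding_length
            )
        else:
            rate_case = rate_ctrl = None
        excluded = "blacklist" if gene in blacklist else ""
        results.append(
            BurdenResult(
                gene=gene,
                case_count=k_case,
                control_count=k_ctrl,
                case_exposure=e_case,
                control_exposure=e_ctrl,
                rate_case=rate_case,
                rate_control=rate_ctrl,
                lam=k_ctrl_eff * e_case / e_ctrl,
                p_value=p,
                alpha_bonferroni=alpha_bonf,
                significant=(p < alpha_bonf) and not excluded,
                excluded_reason=excluded,
                degenerate_lambda=degenerate,
            )
        )
    return results


def replication_test(
    k_case: int,
    k_ctrl: int,
    n_case: int,
    n_ctrl: int,
    tail: Tail = Tail.UPPER,
    alpha: float = DEFAULT_ALPHA,
) -> BurdenResult:
    """Single-gene test for a targeted resequencing (replication) cohort.

    Exposures are allele counts ``n x 2``; no pseudocount is applied (the
    counts are observed directly) and significance is judged at the plain
    alpha, not a Bonferroni threshold, since a single pre-specified gene is
    tested.
    """
    exposure = ExposureSpec(n_cases=n_case, n_controls=n_ctrl)
    e_case = float(exposure.case_alleles)
    e_ctrl = float(exposure.control_alleles)
    p = poisson_burden_p(k_case, k_ctrl, e_case, e_ctrl, tail)
    return BurdenResult(
        gene="",
        case_count=k_case,
        control_count=k_ctrl,
        case_exposure=e_case,
        control_exposure=e_ctrl,
        rate_case=None,
        rate_control=None,
        lam=k_ctrl * e_case / e_ctrl,
        p_value=p,
        alpha_bonferroni=alpha,
        significant=p < alpha,
        degenerate_lambda=k_ctrl == 0,
    )


def burden_results_to_frame(results: Iterable[BurdenResult]) -> pd.DataFrame:
    """Tabulate burden results for TSV/JSON reports."""
    rows = []
    for r in results:
        rows.append(
            {
                "gene": r.gene,
                "case_count": r.case_count,
                "control_count": r.control_count,
                "case_exposure": r.case_exposure,
                "control_exposure": r.control_exposure,
                "rate_case": r.rate_case,
                "rate_control": r.rate_control,
                "lambda": r.lam,
                "p_value": r.p_value,
                "alpha_bonferroni": r.alpha_bonferroni,
                "significant": r.significant,
                "excluded_reason": r.excluded_reason,
                "degenerate_lambda": r.degenerate_lambda,
            }
        )
    return pd.DataFrame(rows)
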