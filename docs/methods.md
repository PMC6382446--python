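# Methods

## Problem and model

`ntdburden` implements a rare-variant discovery analysis for small
case-control exome cohorts with a familial component, of the kind used to
search for genes underlying neural tube defects (NTD): a multi-stage
variant filter applied identically to cases and controls, candidate-gene
prioritization with family segregation, and a per-gene exact Poisson
rate-comparison ("burden") test with Bonferroni correction, plus a
replication mode for targeted resequencing of a single candidate gene.

### Filter cascade

Variants enter as annotated VCF records and pass four stages in a fixed
order (the order is fixed only for reproducible funnel accounting; the
consequence and frequency stages commute):

1. **Consequence** — synonymous and noncoding variants are removed.
   Variants with an unclassifiable consequence are kept with a warning.
2. **Population frequency** — a variant is removed when its maximum allele
   frequency over the available population databases (gnomAD, ExAC, EVS by
   default) exceeds 1%. Absence from every database marks the variant
   novel and keeps it. The threshold is exclusive (exactly 1% is kept).
3. **Genotype QC** — per-carrier read-level evidence: genotype quality
   ≥ 99, more than 3 alternate reads on each strand (i.e. ≥ 4), and an
   alternate-read fraction strictly above 0.15. Zero-depth genotypes fail
   (the fraction is undefined). A variant survives when at least one
   *relevant* carrier passes: the affected members when a pedigree with
   affected individuals is supplied (the case cohort), otherwise any
   carrier (the control cohort). Failing carriers are cleared to missing
   rather than silently retained — the variant-level decision is gated by
   carrier-level evidence.
4. **Predicted impact** — loss-of-function variants (stop-gained,
   frameshift, splice) and missense variants tagged *probably damaging* by
   PolyPhen-2 are kept; everything else is removed. For inputs lacking
   categorical tags, a numeric score cutoff (default 0.80) can substitute;
   the default cutoff sits below the smallest probably-damaging score in
   the packaged resequencing table (0.848) so both rules agree on it.

A `FilterFunnel` records input/removed/output per stage; its arithmetic is
validated as an invariant (input = output + removed at every stage, each
stage's input equals the previous stage's output), and the cascade is
idempotent on its own output.

The replication (targeted resequencing) mode uses the reduced rule set
appropriate to pre-screened coding targets: population frequency < 1% and
a probably-damaging/LOF impact call; no consequence-removal or read-level
stage.

### Segregation and compound heterozygotes

Within each family carrying a variant, the variant is *shared* when every
genotyped affected member carries it and at least one affected member is
genotyped. Affected members with missing genotypes do not veto sharing;
the result is flagged `incomplete` instead — exome coverage gaps are
routine and treating them as refutations would discard real candidates.
Unaffected carriers are reported as a penetrance annotation, the
transmitting parent is named when exactly one genotyped parent carries,
and a de novo flag is set when both parents of an affected carrier are
genotyped non-carriers. Prioritization keeps variants shared in at least
one carrier family.

The compound-heterozygote scan enumerates, per sample and gene, all pairs
of heterozygous variants (k variants give k·(k−1)/2 pairs) and assigns
phase from parental genotypes: opposite single-parent origins confirm
trans, identical single-parent origins exclude as cis, anything else is
left possible. No population-panel phasing is attempted.

### Burden test

For gene *g*, qualifying-variant **carrier-observations** are counted: one
count per carrier individual per variant, so a variant shared by two
affected individuals contributes two. This is the counting unit under
which per-gene counts, cohort sizes, and the published rate formula
*k / (n · L · 2 alleles)* are mutually consistent. With case and control
counts k₁, k₀ and allele-count exposures E₁ = 2n₁, E₀ = 2n₀ (gene length
cancels exactly between the two cohorts and is only used for reporting
per-bp rates), the null expectation for the case count is

    λ = k₀ · E₁ / E₀

and the reported p-value is the exact upper-tail Poisson probability
P(X ≥ k₁), X ~ Poisson(λ). A doubled two-sided option
min(1, 2·min(P(X ≥ k₁), P(X ≤ k₁))) is available but the upper tail is the
default: it is the convention that reproduces published rate-burden
results of this design exactly. Family-wise error is controlled by
Bonferroni over the number of genes tested (default 20,389, the size of
an exome-wide scan; configurable independently of the simulated gene
count).

Degenerate control counts (k₀ = 0 gives λ = 0 and p = 0 for any positive
case count) are guarded in the scan by a pseudocount (default 0.5 added to
k₀ only when it is zero) and flagged in the output; the raw test function
leaves the degeneracy visible. The replication test applies no
pseudocount — its counts are observed directly — and judges significance
at the plain α since a single pre-specified gene is tested.

Genes with artifactually high counts (misalignment-prone loci) are
excluded only via an explicit blacklist file. A heuristic that flags
control counts above the cross-gene 99.9th percentile warns and never
excludes, and only activates in scans of ≥ 1,000 genes — below that the
quantile merely tags ordinary Poisson tails.

## Synthetic cohorts

The generator reproduces the statistical structure the test consumes, not
sequence-level realism. Per gene and cohort, qualifying carrier-
observations are drawn Poisson with mean rate · n · L · 2; enriched genes
multiply the case rate by a configured ratio. Each observation becomes a
heterozygous variant at a unique position in its gene with read-level
evidence that passes QC. Decoy records exercise each cascade stage:
synonymous, common (frequency 2–20%), QC-failing (violating exactly one
named rule, recorded in the truth table), and benign-missense (derived
from the probably-damaging mix proportion rather than a separate knob).
Every emitted record is labelled in a truth table, which makes the funnel
exactly checkable: per-stage removals must equal the injected decoy counts
per label.

Defaults mirror the study design this package targets: 61 affected — 18
familial members across 8 multiplex families (five 2-affected, two
3-affected, one two-generation) plus 43 trio probands — versus 188
unrelated controls; gene lengths uniform on 1,500–4,500 bp (a typical
coding-length range, mean 3 kb); base qualifying-variant rate
1.8 × 10⁻⁶ per allele·bp, which puts the expected control count per gene
near 2 — the regime where the burden test is actually exercised (most
genes observed, counts small); decoy fractions 0.25 synonymous, 0.10
common, 0.05 QC-failing relative to the qualifying count; 75% of missense
tagged probably damaging; 40% of qualifying variants LOF. Family-scenario
generators (shared/unshared/de novo/compound-het) emit genotypes realizing
each segregation pattern exactly.

What the generator does **not** model: site-frequency spectra, linkage
disequilibrium, relatedness beyond the explicit pedigrees, population
stratification, sequencing-read noise beyond the QC fields, and recurrent
artifact hotspots. Passing calibration and recovery tests therefore shows
the statistics behave correctly on data satisfying the test's own
assumptions; they do not certify robustness to stratification or
batch-differential artifacts in real cohorts, which the blacklist and the
identical-filtration requirement only partially address.

## Evaluation

`evaluate_type1_power` simulates replicates (replicate r reseeds with
seed + r), runs the full cascade and scan, and reports: empirical type-I
error per α over null genes (genes unobserved in both cohorts count as
p = 1), power per enriched gene at the Bonferroni threshold, and the mean
estimated rate ratio (k₁/E₁)/(max(k₀, 0.5)/E₀). Because the test
conditions on the observed control count as if it were the true rate, it
is slightly anti-conservative at small expected control counts; with the
default generator settings the expected type-I at α = 0.05 is ≈ 0.066, and
that is what the calibration tests measure. The rate-ratio estimator is
biased upward by Jensen's inequality at small control counts; the
recovery test uses expected counts ≥ 10, where the bias stays within the
tolerated 25%.

Test problem sizes — 2,000 null genes × 10 replicates for calibration, 200
replicates for ratio recovery, 1,000 records for cascade-oracle
equivalence — keep the whole validation suite in the tens of seconds on a
single CPU while leaving binomial sampling error well inside the asserted
bands.

## Numerical and design notes

- Poisson tails come from `scipy.stats.poisson.sf`; tests cross-check them
  against an independent log-space pmf summation to 10⁻¹² over a 21×21
  count grid.
- "GQ = 99" is read as GQ ≥ 99 (capped-quality convention); ">3 reads" and
  ">0.15 fraction" are strict inequalities; "frequency > 1%" removal is a
  strict inequality. "Mutation frequency" in the QC rule is the carrier's
  alternate-read fraction — population frequency is handled by the
  separate 1% rule.
- VCF positions are 1-based inclusive; BED intervals half-open 0-based;
  conversion is centralized in `io_formats`. Multi-allelic sites are
  decomposed to one record per ALT on read. Annotation INFO fields are
  declared as VCF Strings and parsed in Python so frequencies and scores
  round-trip at full printed precision.
- Gene symbols are matched by case-insensitive exact string; no alias
  resolution.
- The packaged mouse-NTD (221) and folate-pathway (93) gene lists and the
  gene coding models are synthetic stand-ins (real anchor symbols plus
  labelled fillers) at the documented sizes; curating the historical lists
  is configuration, not code. The published-mutation exclusion list is an
  editable TSV supporting both gene-level and variant-level entries.
- Known limitations: no covariate adjustment or stratification correction;
  Bonferroni only (no FDR); no SKAT-style dispersion tests; phasing only
  from parental genotypes.
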