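# Methods

This note documents the models, defaults, numerical choices and known
limitations of the `trimedit` pipeline, and what the synthetic-data
generator does and does not emulate.

## Study design emulated

All simulated assays share one design: monocytes from `n_donors = 5` donors
exposed for 24 h to one of four conditions — naive/RPMI (reference), LPS,
BCG Denmark, BCG Bulgaria — and profiled at day 6 as macrophages
(20 samples). The expression arm adds a paired secondary 4 h LPS exposure
(day 6 vs day 6 + LPS). The methylation arm is a separate vaccinated-vs-
control cohort (`n_per_group = 60`).

## Editing-site simulation and filtering

**Coverage model.** Per site × sample read depth is negative-binomial with
mean `coverage_mean = 30` and size `coverage_dispersion = 10`
(Var = μ + μ²/k), a typical level of biological-replicate overdispersion for
bulk RNA-seq. No read-depth distribution is implied by the underlying assay
description, so this is a modelling choice.

**Editing-rate model.** Alternate (edited) counts are binomial with
probability `logistic(base + donor + condition + gene-set boost)`:
per-site baseline logits ~ N(−2.2, 0.8²) (≈ 10% median editing), donor
offsets ~ N(0, 0.15²), condition offsets default to +0.4 logits for both
BCG strains and +0.15 for LPS, and an optional per-gene-set boost applies
in BCG conditions only. Truth is planted on the logit scale because the
downstream tests are logit-scale GLMs, so recovery can be compared
coefficient-for-coefficient.

**Nuisance structure.** 2% of sites are common-SNP stand-ins with
condition-invariant alternate fraction 0.5 (heterozygote-like), which makes
the SNP filter's effect observable; 5% are non-A>G decoy mismatches; each
positional artifact flag (read-end, indel/splice, homopolymer) is set per
site at rate 2%; 5% of records draw a caller statistic below the 1.56
threshold; exactly 90% of non-SNP sites are listed in the editing-site
catalog. Positions are 1-based in TSVs; BED output is 0-based half-open.

**Filter cascade.** Per-record predicates are applied in a fixed reporting
order (caller statistic → coverage → alternate depth → positional flags →
SNP → A>G), followed by two site-level rules: detection (alt ≥ 3 and
coverage ≥ 10) in ≥ 3 samples, then catalog membership. The order only
affects attrition attribution, never the retained set, which equals the
conjunction of all predicates (verified against a brute-force oracle).
"Detected" for the recurrence rule reuses the stated detection thresholds;
whether the caller-statistic threshold applies per record or per site is
ambiguous in the workflow this mirrors, and it is applied per record here.

## Alu editing index

AEI(sample) = Σ alt / Σ (ref + alt) over the universal set (sites EDITED in
every sample), algebraically the coverage-weighted mean of per-site editing
fractions. Condition effects come from OLS of AEI on condition indicators
(reference = NAIVE) plus donor fixed effects; p-values are two-sided t
(sidedness is a package choice). Donors are fixed effects, matching an
`lm()`-style formulation, not random effects. Degenerate designs (a donor
in a single condition, rank deficiency) raise errors rather than returning
unstable estimates.

## Differential editing GLMs

Reference/alternate alleles are summed per gene per sample; only rows with
nonzero totals are emitted, and total alleles are conserved (mapped +
unmapped = input). The GLM is binomial with logit link, endog =
(sum_alt, sum_ref), covariates condition (reference NAIVE) + donor, fitted
by IRLS; Wald z tests per condition coefficient. Non-convergence after 100
iterations raises an error carrying the last deviance; |coefficient| > 15
is treated as separation.

**Gene-baseline offsets in set-level fits.** Genes differ strongly in
baseline editing (site logit sd 0.8). In a pooled condition + donor fit,
that heterogeneity leaks into the condition contrast through sample-to-
sample coverage fluctuation and inflates its nominal significance
(measured null type-I ≈ 0.10 at α = 0.05 under the generator's default
conditions). Set-level and background-adjusted fits therefore include
per-gene intercepts by default, which restores calibration (measured
≈ 0.055) without biasing the condition estimate; `gene_effects=False`
gives the plain condition + donor form. Per-gene fits need no such fix
(most genes carry one or two sites; measured null rate ≈ 0.047).

**Background adjustment.** The "set effect beyond background" is the
set × condition interaction in a joint GLM over background ∪ set rows.
With gene offsets present the set-membership main effect is collinear with
them and is dropped. The interaction estimate is mildly attenuated
(≈ 5–10%) relative to the planted per-site logit boost because summing
sites with unequal baselines within genes shrinks the pooled logit shift —
an intrinsic property of gene-level aggregation, not of the fitter.

**Multiple testing.** Per-gene q-values are Benjamini–Hochberg within each
condition contrast across tested genes (not pooled across contrasts), with
significance at q < 0.01. Genes are testable when they have editing rows in
≥ 6 samples, with no extra per-sample depth requirement. Overdispersion is
not corrected by default (plain binomial likelihood); a quasi-binomial
option (`quasi=True`, Pearson-scaled SEs) is available as a caveat handle.

## Trained-response ranking

Expression truth: a fraction 0.2 of genes is LPS-induced (+3 log2 on
restimulation); among induced genes, 16% are trained (+2 log2 extra in BCG
conditions) and 8% attenuated (−2 log2), with multiplicative log-normal
noise (log2 sd 0.1) on every measurement; these fractions echo the
~1242 / 196 / 100 proportions typical of such restimulation experiments.

Induction uses log2((post + 0.5)/(pre + 0.5)); a gene is induced when, in
the naive OR the BCG group, the geometric-mean fold change exceeds 2.5, a
paired t-test across the group's samples gives p < 0.05, and mean
post-stimulation expression is ≥ 5. The training score is the donor-mean of
(BCG induction − naive induction), BCG being the mean of the two strains;
its p-value is a paired t across donors. TRAINED/ATTENUATED require
|score| > log2(2) strictly and p < 0.05; ties in ranking break by gene id.
The paired t-test on log2 values is a deliberately simple stand-in for a
count-model DE engine: appropriate to the small paired design, but it does
not shrink dispersions and is not claimed to be equivalent to one.

Window enrichment: windows of 60 genes advancing by 10 (the step size is a
package default — small enough for a smooth trace, large enough to avoid
~1200 windows), tested per motif with a one-sided hypergeometric against
the full ranked list. Window count = floor((N − 60)/10) + 1.

## Methylation regions

DMP calling is per-probe OLS of beta on group (+ optional covariates) with
BH across probes — ordinary least squares, not an empirical-Bayes moderated
fit, which is adequate at n = 60/group and is a documented divergence from
moderated-t pipelines. DMPs require adjusted p < 0.05 AND |Δβ| ≥ 0.05.
DMRs are single-linkage chains of DMPs with inter-probe gap ≤ 1000 bp
(the default bandwidth of kernel-based DMR callers) and ≥ 2 probes; a
kernel-smoothed statistic is intentionally not reimplemented — the
clustering is the desk-scale realisation of the "clusters of DMPs"
strategy. CpG context uses the conventional distances (shore ≤ 2 kb from
an island edge, shelf ≤ 4 kb, else open sea); spans are reduced to their
midpoint. Gene assignment: nearest TSS within 1 Mb (ties to the
lexicographically smaller gene id) and promoter membership within 5 kb of
any TSS.

Simulation: background probes are spaced ~exponentially (mean 5 kb) so they
do not chain with planted regions; planted DMR probes are 200 bp apart with
group difference = planted Δβ (+0.10, −0.08, +0.07 by default) plus
N(0, 0.02) noise per probe × sample; a CpG island is placed under each
planted DMR and decoy islands elsewhere.

## Problem sizes used in validation

Replicated experiments (null calibration, recovery) run the full pipeline
on a reduced design — 200–240 sites over 80 genes, 400 methylation probes —
with all noise, coverage and effect-size parameters at their defaults;
500 replicates for null calibration of the AEI and gene-set tests, ≥ 600
fitted unit replicates for per-gene calibration, 100–200 replicates for
effect recovery. These sizes are the package's validation choices; the
class and motif recovery checks run at the full default scale (1500 genes).

## What passing tests do and do not show

The generator plants truth on exactly the scales the models estimate, with
independent binomial/Gaussian noise. Real data add what is not emulated:
read-level artifacts and mapping bias, splice structure, correlated sites,
probe cross-reactivity and cell-composition effects, and DE-engine
dispersion structure. Passing recovery tests therefore demonstrates the
correctness and calibration of the statistical machinery under its own
assumptions, not robustness to those real-data violations. Known
limitations worth repeating: no overdispersion correction by default in the
binomial GLMs, a t-test stand-in for count-model DE, midpoint-based CpG
context for wide spans, and gene-level aggregation's mild attenuation of
per-site effect sizes.
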