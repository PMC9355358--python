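# trimedit

Analysis toolkit for the quantitative core of a trained-immunity (TRIM)
multi-omics study of BCG-exposed human macrophages: A-to-I RNA editing
quantification, trained-vs-attenuated transcriptional response ranking, and
differential DNA methylation region calling — together with a synthetic-data
simulator that plants recoverable effects, so every step can be validated
without any sequencing or array data.

## The scientific problem

Exposure of monocytes to the BCG vaccine leaves a lasting epigenetic imprint
("trained immunity") that changes how the derived macrophages respond to a
later, unrelated stimulus. This package implements the bespoke statistics
such a study needs downstream of alignment and variant calling:

1. **Editing-site filtering** (`trimedit.sites`). Candidate A-to-I sites from
   a strand-aware variant caller are filtered by caller statistic (≥ 1.56),
   total coverage (≥ 10), alternate-allele depth (≥ 3), positional artifact
   flags, common-SNP removal, A>G identity on the transcribed strand,
   recurrence in ≥ 3 samples, and membership in a known-editing-site catalog.
   Each site × sample is classified EDITED / UNEDITED / INSUFFICIENT_COVERAGE
   so absence of editing is distinguished from absence of data.
2. **Alu editing index** (`trimedit.aei`). For the "universal" sites edited in
   every sample, AEI(s) = Σ alt reads / Σ (ref + alt) reads. Condition effects
   are estimated by OLS: `AEI ~ condition + donor`, reference = naive/RPMI.
3. **Differential editing** (`trimedit.diffedit`). Allele counts are summed
   per gene per sample and condition shifts in editing odds are tested with
   logit-link binomial GLMs (condition + donor, per-gene baseline offsets for
   set-level fits), with Benjamini–Hochberg control at FDR 0.01 for per-gene
   tests and a set × condition interaction model for "boost beyond
   background" contrasts.
4. **Trained-response ranking** (`trimedit.trained`). Genes induced by a
   secondary LPS exposure (paired test p < 0.05, FC > 2.5, expression ≥ 5)
   are ranked by the training score — log2 induction in BCG-macrophages
   (mean of the Denmark and Bulgaria strains) minus induction in naive
   macrophages — classified TRAINED / UNAFFECTED / ATTENUATED (p < 0.05,
   FC > 2), and scanned in sliding 60-gene windows for promoter motif
   enrichment (one-sided hypergeometric vs the ranked background).
5. **Methylation regions** (`trimedit.methylation`). Probes passing adjusted
   p < 0.05 and |Δβ| ≥ 0.05 are DMPs; DMPs within 1 kb chain into DMRs
   (≥ 2 probes), annotated by CpG island/shore/shelf context and assigned to
   genes (nearest TSS within 1 Mb; promoter within 5 kb).
6. **Simulator** (`trimedit.simulate`). Generates every input above for a
   5-donor × 4-condition design (naive/RPMI, LPS, BCG Denmark, BCG Bulgaria)
   with logit-additive editing truth, log-normal expression noise, planted
   DMRs and planted motif enrichment, all recorded in a ground-truth object.

## Worked example

The `analysis/` scripts run the whole workflow on one simulated study
(seed 0, with a +0.3 log-odds editing boost planted in the `ex_vivo` gene
set for BCG conditions):

```bash
python analysis/01_simulate.py
python analysis/02_filter_sites.py
python analysis/03_editing_index.py
python analysis/04_differential_editing.py
python analysis/05_trained_response.py
python analysis/06_methylation_dmrs.py
```

Selected output (abbreviated):

```
retained 1484 sites (29680 records)
universal sites (edited in every sample): 157

condition effects vs NAIVE (donor-controlled OLS):
  term  estimate      se   p
BCG_BG   0.09843 0.00381 0.0
BCG_DK   0.09619 0.00381 0.0
   LPS   0.03068 0.00381 0.0

ex_vivo_vs_background    BCG_BG    0.2909 0.0275 0.0000
ex_vivo_vs_background    BCG_DK    0.3233 0.0273 0.0000

300 induced genes -> 48 trained, 228 unaffected, 24 attenuated
planted trained/attenuated recovery: 72/72
25 windows scanned; ISRE minimum p = 1.09e-08 at window 0 (trained end = window 0)

20 DMPs (14 hyper / 6 hypo) -> 3 DMRs
planted DMRs recovered with exact probe membership: 3/3
```

Reading the numbers: both BCG strains raise the Alu editing index by ~0.10
over naive (the planted +0.4 logit condition effect on the proportion
scale), LPS by ~0.03; the set × condition interaction recovers the planted
+0.3 log-odds boost of the `ex_vivo` genes beyond the background response;
the trained/attenuated continuum and the planted ISRE motif at its trained
end are recovered exactly, as are the three planted DMRs (all island
context, as planted).

The same steps are exposed as CLI subcommands (`trimedit simulate`,
`filter-sites`, `aei`, `diff-editing`, `trained-genes`, `dmrs`); see
`trimedit --help`.

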