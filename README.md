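# spongescreen

A tested, reusable implementation of a ceRNA (competing endogenous RNA)
screening pipeline for transcriptomic cohorts: it identifies lncRNAs
that act as miRNA sponges dually regulating the immune-checkpoint
ligands PD-L1 (*CD274*) and PD-L2 (*PDCD1LG2*), and carries the hit
through survival, enrichment and immune-infiltration analyses.  The
package targets bioinformaticians who want each stage of such a screen
as an auditable, unit-tested function rather than a notebook, together
with a synthetic-data generator that plants known sponge structure so
the whole chain can be validated end to end.

## The screen

Given a genes × samples count matrix with tumor/normal labels:

1. **Normalisation** — values are standardised to log2(CPM + 1).
2. **Differential expression** — lncRNAs are screened tumor-vs-normal
   with a moderated t statistic (empirical-Bayes variance shrinkage,
   s̃² = (d₀s₀² + d·s²)/(d₀ + d) with (d₀, s₀²) fitted by method of
   moments on the log residual variances); genes with |log2FC| > 1 and
   BH-adjusted p < 0.05 are kept.
3. **Ligand correlation screen** — DE lncRNAs with Spearman ρ > 0.4 and
   p < 0.001 against each ligand (tumor samples) form two sets whose
   intersection yields the ligand-related candidates.
4. **Binding-prediction intersection** — lncRNA→miRNA and miRNA→mRNA
   edge tables from independent prediction sources are intersected, so
   only edges supported by every source survive.
5. **Triplet assembly** — a lncRNA–miRNA–mRNA *co-expressed competing
   triplet* requires ρ(lnc, mRNA) > 0.5 with p < 0.001, both partners
   negatively co-expressed with the shared miRNA (ρ < 0, p < 0.05), and
   both edges binding-predicted.  The candidate with the highest mean
   correlation with the two ligands is ranked as the hub.
6. **Survival** — median split on hub expression, Kaplan–Meier curves,
   log-rank test, and a univariate → multivariate Cox proportional-
   hazards screen (Efron ties; covariates entering at p < 0.05).
7. **Enrichment & immune association** — preranked GSEA (weighted
   Kolmogorov–Smirnov running sum, gene-label permutation null) of
   exhaustion-type gene sets between high/low hub groups; geometric-mean
   signature scores; Spearman association of hub expression with
   22-cell-type immune fractions and clinical factors; 2⁻ΔΔCt
   quantification for paired qPCR validation plates.

The synthetic generator (`spongescreen.simulate`) plants this exact
structure — Gaussian-copula sponge triplets over negative-binomial
counts, exponential survival with log-hazard β per SD of hub
expression, a Dirichlet immune-fraction table with one hub-coupled cell
type — and emits a truth record for recovery scoring.

## Worked example

Generate a synthetic cohort (200 tumor / 50 normal samples, 10 planted
triplets among 500 decoy prediction edges per table) and run the full
screen:

```bash
cerna simulate --outdir demo --seed 1
cerna -v run-all --config demo/pipeline_config.yaml
```

The run prints `hub candidate: LNC0001` (the planted hub) and writes
one TSV per stage under `demo/results/`.  The top of `triplets.tsv`:

```
lnc_id   mi_id    mrna_id  rho_lnc_mrna  rho_lnc_mi  rho_mi_mrna
LNC0001  MIR0001  MR0001   0.815         -0.796      -0.792
LNC0001  MIR0001  MR0002   0.836         -0.796      -0.831
LNC0002  MIR0002  MR0003   0.788         -0.707      -0.750
```

All ten planted triplets are recovered with no false triplet: the hub
lncRNA sponges its miRNA (ρ ≈ −0.8, the planted sponge strength) and
thereby tracks both ligand mRNAs.  Downstream, the survival stage
reports a log-rank χ² of 21.40 (p = 3.7e-06) between the high and low
hub-expression groups, and the multivariate Cox model retains the hub
group with HR = 2.27 (95% CI 1.59–3.24) — the planted log-hazard is
ln(1.74) per SD, which the median split dichotomises.  The immune stage
finds the planted M2-macrophage coupling (Spearman ρ = 0.468 at a target
of 0.47), and GSEA flags the hub-co-expression gene set
(ES = 0.86, NES = 1.87, adjusted p = 0.006) while leaving the random
set flat (p = 0.85).

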