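# Methods

This note documents the statistical procedures, the synthetic-data
model, the numerical choices and the known limitations of the package.
It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Screening model

The pipeline operationalises the ceRNA hypothesis: a cytoplasmic lncRNA
that shares miRNA binding sites with an mRNA can de-repress that mRNA
by competing for the shared miRNA pool.  Observationally this predicts
a positive lncRNA–mRNA correlation together with negative correlations
of both partners with the miRNA, restricted to pairs with predicted
binding.  All correlations are Spearman (rank-based), computed on tumor
samples by default — the co-expression signal of interest is variation
within the tumor cohort, not the tumor/normal contrast, which is
handled separately by the DE stage.  The tumor-only restriction is a
configuration switch (`tumor_only`), since the cohort choice for the
correlation screens is a genuinely open design point.

Screen thresholds follow the conventional cutoffs for this analysis
family and are all exposed in `PipelineConfig`: DE at |log2FC| > 1 with
BH-adjusted p < 0.05 (strict inequalities); ligand screen at ρ > 0.4,
raw p < 0.001; lncRNA–mRNA pair rule at ρ > 0.5, raw p < 0.001.  The
negative co-expression rule for the shared miRNA has no canonical
threshold; the default is ρ < 0 at nominal p < 0.05 (`neg_p_max`),
chosen because genuine sponge interactions are often weak (observed
coefficients in the −0.1 to −0.3 range) and a stricter cut would
discard them.  BH adjustment is deliberately *not* applied inside the
correlation screens — only the DE stage and the per-cell-type fraction
tests use adjusted p, the families being a single gene-class screen and
the 22 cell types of one comparison respectively.  Every output table
records which tests were adjusted together.

### Triplet assembly scope

Hub identification follows the ligand-centric route: DE lncRNAs →
ligand-correlated sets → intersection → hub by mean ligand correlation.
Triplet assembly, however, runs by default over the full DE lncRNA set
against every binding-predicted target mRNA (`triplet_candidates="de"`,
`triplet_targets="all"`), not only over the intersected candidates and
the two ligands.  Rationale: sponge triplets that do not involve the
checkpoint ligands are still valid screen output, and the synthetic
validation plants such triplets precisely to measure recovery; the
ligand-restricted behaviour is available via configuration.

## Rank statistics

`rankstats` is self-contained computation (no I/O, no randomness).
Ranks are average-tie ranks; all p-values are two-sided.

* **Spearman** — ρ is the Pearson correlation of tie-averaged ranks.
  The default p uses t = ρ√((n−2)/(1−ρ²)) on n−2 df; for n ≤ 8 an
  exhaustive permutation enumeration is available (vectorised as dot
  products of the fixed centered unit-norm rank vectors).  A constant
  input yields a flagged degenerate result, never a silent ρ = 0.
  At n = 5 the permutation distribution has probability atoms near
  0.08, so the t-approximation can differ from the exact p by more
  than 0.05 there; from n = 6 the two agree within 0.05.
* **Wilcoxon rank-sum** — exact enumeration of all C(n, n_a) rank
  assignments for n ≤ 12, otherwise a normal approximation with
  tie-corrected variance and a 0.5 continuity correction.  Exact
  two-sided p-values are extremity probabilities
  P(|T − E[T]| ≥ |t − E[T]|) under the enumerated null.
* **Wilcoxon signed-rank** — zero differences dropped; exact over all
  2^m sign patterns for m ≤ 12 non-zero pairs, else the tie-corrected
  normal approximation.
* **Kruskal–Wallis** — H with tie correction against χ² on k−1 df; for
  two groups it coincides algebraically with the squared rank-sum
  z-statistic without continuity correction (verified in tests).
* **Benjamini–Hochberg** — delegated to statsmodels' step-up
  implementation behind the `bh_adjust` surface.

## Differential expression

Counts are normalised to log2(10⁶·count/libsize + 1).  Per gene the
two-group mean difference on this scale is the reported log2FC, tested
with a moderated t: gene-wise residual variances s² (d = n₁+n₂−2 df
each) are shrunk toward a prior scale s₀² with prior df d₀, both fitted
by matching the mean and variance of log s² through digamma/trigamma
identities (the trigamma equation is inverted numerically with Brent's
method; a non-positive excess variance yields d₀ = ∞).  The moderated
statistic uses s̃² = (d₀s₀² + d·s²)/(d₀+d) on d₀+d df.  The two limits
are exact identities: d₀ = 0 reproduces the ordinary equal-variance t
test, d₀ = ∞ the pooled common-variance statistic — both serve as
oracle tests.  Genes constant in both groups are flagged with an
undefined statistic and p = 1.  No voom-style precision weights and no
covariate adjustment are applied.

## Survival

Cox proportional-hazards models are fitted with lifelines (Efron tie
handling) behind the module surface; the Newton–Raphson stopping
criterion is tightened (`precision 1e-9`, 100 steps) so estimates agree
with direct partial-likelihood maximisation to ~1e-6 even on flat
small-sample likelihoods.  Categorical covariates are reference-coded
with clinical reference levels (stage I, T1, N0, M0, G1, male, low
expression).  Wald 95% CIs are exp(β ± 1.96·se); separation-driven
infinite bounds are reported as such rather than raised, and fitter
convergence warnings (suspected monotone likelihood) are attached to
the result.  In the univariate → multivariate screen a candidate enters
the joint model when any of its levels has Wald p below `univ_p_enter`
(default 0.05; 0.1 selectable), and a candidate whose univariate fit
fails to converge is reported as non-convergent and excluded rather
than aborting the screen.

The log-rank test is computed directly from the observed-minus-expected
event tabulation with hypergeometric variance; on tie-free data it
equals the Cox score test exactly (verified in tests).  The
maximally selected cutpoint scans every observed marker value inside a
quantile band (default 10–90%) for the largest log-rank statistic; its
naive 1-df p-value is flagged as multiplicity-uncorrected.  Median
splits send values equal to the median to the *low* group — an
arbitrary but fixed tie rule recorded in output metadata.

## Enrichment and signatures

The preranked enrichment score is the weighted Kolmogorov–Smirnov
running sum: walking the ranking, set members add |score|^weight
normalised by the set's total weighted mass, non-members subtract
1/(N−N_h); the ES is the running-sum value of largest magnitude (first
occurrence on ties).  Degenerate case: when every set member has zero
weighted score the set carries no hit mass; hits are then neutral and
misses spread over all N positions.  The null permutes set membership
labels uniformly over ranked genes (preranked mode, not phenotype
permutation, because the ranking is a single log2FC vector).  NES is
sign-matched — ES divided by the mean |null ES| of the same sign — and
p = (1 + #{null at least as extreme, same sign})/(1 + #{null same
sign}), floored at 1/(n_perm+1) when no null sample matches the sign.
BH adjustment spans the sets tested in one call.  The ES is checked
bit-for-bit (to float round-off) against an independently coded loop
oracle.

Per-sample signature scores are geometric means of member counts plus a
pseudocount (default 1), computed on the counts scale; absent members
are reported, and score–expression associations delegate to the
Spearman machinery with the sample list hashed for provenance.  The
full kernel-based sample-wise enrichment algorithm (GSVA) is out of
scope; the geometric-mean score is the implemented statistic.

## qPCR arithmetic

2⁻ΔCt normalises the replicate-mean target Ct to the replicate-mean
reference-gene Ct per sample; 2⁻ΔΔCt additionally subtracts the
control-condition mean ΔCt, making the control fold changes centre at
geometric mean one.  The exponent carries the standard negative sign
(Livak convention).  Fold changes are invariant to any constant offset
in the reference gene.  No amplification-efficiency or plate-effect
correction is attempted.

## Synthetic data model

`SimConfig` defaults define the validation conditions: 200 tumor / 50
normal samples; 500 lncRNAs, 100 miRNAs, 300 mRNAs; 10 planted
triplets at sponge Spearman 0.8; hub log2FC 2; NB dispersion 0.15;
library sizes log-uniform on [5·10⁵, 2·10⁶]; true Cox log-hazard
ln(1.74) per SD of hub expression with 30% censoring; 500 decoy edges
per prediction table; M2-fraction coupling 0.47.

* **Correlation planting** — each sponge unit shares one latent
  standard Gaussian factor; the lncRNA and mRNA load +√ρ_g, the miRNA
  −√ρ_g, where ρ_g = 2·sin(π·s/6) converts the target Spearman s to
  the Gaussian-copula correlation (the bivariate-normal identity
  ρ_S = (6/π)·asin(ρ/2), inverted).  Latents pass through a per-gene
  negative-binomial quantile transform (variance m + φm²), which is
  monotone and therefore rank-preserving, so the calibration carries
  to the counts.  The first two triplets share the hub lncRNA/miRNA
  and terminate at the two designated ligand mRNAs; remaining triplets
  are disjoint positive controls.  Null genes are independent NB noise
  sampled directly (distributionally identical to the copula route).
* **Baseline expression** — null genes draw baseline CPM log-uniformly
  from [10, 5000] and planted genes from [100, 500].  The wide null
  range keeps the planted genes a small fraction of the library mass:
  otherwise their tumor up-shift inflates the per-sample library size
  and the CPM composition artifact visibly attenuates every estimated
  fold change.  Planted genes stay well-expressed so count ties do not
  erode the planted rank correlations.
* **Differential expression** — planted lncRNAs and mRNAs carry +de_lfc
  in tumor samples and planted miRNAs −de_lfc (sponge-consistent
  directions); all are recorded with signs in the truth record.
* **Survival** — times are exponential with rate λ₀·exp(β·z), λ₀ set
  to a two-year median at z = 0, z the z-scored observed hub
  log2(CPM+1); censoring is an independent exponential whose rate is
  solved by bisection so the expected censored fraction
  mean_i c/(c+λ_i) hits `censor_rate`.  Ordinal stage is drawn from a
  cumulative-logit model shifted by the hub-expression tertile
  (`stage_coupling`, default 0.8 on the log-odds scale — no canonical
  effect size exists for this association, so it is a configuration
  choice); other covariates are uncoupled.
* **Immune fractions** — the coupled cell type's fraction is a
  Beta(2, 20) marginal joined to the hub expression through the same
  Gaussian copula at the correlation mapped from `frac_coupling`; the
  remaining 21 of the 22 leukocyte types split the leftover mass by a
  Dirichlet draw, so columns sum to one exactly.
* **Interaction tables** — two sources per edge class; every planted
  edge appears in both, decoys are drawn uniformly without replacement
  and independently per source, so a source intersection retains
  decoys only at the birthday-collision rate f²/U.
* **Determinism** — every generator derives its own stream from
  (stage-index, seed) seed sequences; identical configurations are
  byte-identical on disk.

What the generator does *not* emulate: batch effects, GC/length biases,
overdispersion heterogeneity across genes, non-proportional hazards,
informative censoring, compositional correlations among uncoupled cell
types beyond the simplex constraint, and molecular subtypes beyond
Bernoulli labels.  Passing recovery tests therefore demonstrates the
pipeline's correctness under its own assumptions, not robustness to
real-data artifacts.

## Problem sizes and test design

The validation suite uses the default conditions (250 samples × 900
genes) for recovery checks; Cox recovery runs 200 replicate cohorts of
400 tumor samples; null calibrations use 1000–1500 replicates per test
statistic with cohort sizes (e.g. n = 160 for the log-rank null) at
which the asymptotic reference distributions are accurate — at n = 80
the log-rank χ² approximation alone rejects at ~6–7%.  Oracle checks
enumerate 1000 random enrichment fixtures (N ≤ 50), ten 8-subject Cox
fixtures against a grid/Brent partial-likelihood search, and 40 exact
Spearman enumerations.  These sizes were chosen so the whole suite
completes in a few minutes on a single CPU while keeping Monte-Carlo
error well inside the asserted bounds.

## Known limitations

* The moderated-t screen approximates the limma behaviour but is not a
  reimplementation (no trend fitting, no weights); on strongly
  mean-dependent variance structures the two can differ.
* Cox models assume proportional hazards; no diagnostics, stratification
  or time-varying covariates are provided.
* The maximally selected cutpoint reports no multiplicity-corrected p;
  users needing inference on the selected cut must correct externally.
* The permutation GSEA p has resolution 1/(n_perm+1) and no adaptive
  refinement.
* Gene-id normalisation handles Ensembl version suffixes and case only;
  cross-annotation aliasing is out of scope.
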