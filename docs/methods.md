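# Methods

This note documents the statistical model, the defaults and why they were
chosen, the synthetic-data generator's scope, and the numerical decisions a
maintainer would want written down.

## Study design the package assumes

Two independent case-control cohorts genotyped on the same curated panel of
biallelic SNPs: a *training* cohort used for QC and per-SNP effect
estimation, and an *evaluation* cohort on which the polygenic score is
scored and assessed. Weights never come from the evaluation cohort; the
pipeline refuses to evaluate on the training samples unless
`prs.allow_same_cohort` is set explicitly. The effect ("risk") allele of
each SNP is defined by the panel's manifest — typically the allele reported
as risk-increasing in the source literature — and is never re-oriented from
sample frequencies. This also fixes the convention for strand-ambiguous
(A/T, C/G) SNPs: the manifest is authoritative, and callers are responsible
for having resolved strand before building it.

## Quality control

- **Call rate** (samples and assays): fraction of non-missing calls;
  threshold 0.95, *inclusive* — a sample at exactly 95% passes, matching
  the usual "failed to reach 95%" exclusion phrasing.
- **MAF filter**: SNPs with minor-allele frequency below 0.01 in the
  analysis cohort (cases + controls, non-missing calls) are excluded from
  scoring. Allele frequency, not carrier frequency, is used. Note that
  case-control sampling enriches a risk allele relative to its population
  frequency by roughly `1 + w_case·(OR−1)`, so a rare large-effect variant
  sits closer to the threshold in the sample than its population frequency
  suggests.
- **Hardy–Weinberg equilibrium**: tested in controls only (a departure in
  controls indicates genotyping artifact; in cases it may be signal). The
  default method is the exact conditional test: conditioning on the
  observed allele counts, the two-sided p is the total probability of all
  heterozygote configurations no more likely than the observed one. No
  mid-p correction is applied. The χ² 1-df goodness-of-fit test is kept as
  a cross-check. The default exclusion threshold is p < 1e-6 — deliberately
  loose, catching only gross assay failure — and is explicit in config and
  logged, since typed panels rarely state one.

## Association

Per SNP, maximum-likelihood logistic regression of case status on
effect-allele dosage 0/1/2 (additive coding), optionally with age as a
linear covariate on the logit scale. Estimation is Newton–Raphson
(equivalently IRLS for this GLM) with tolerance 1e-8 and at most 100
iterations; Wald standard errors come from the inverse observed information
at the MLE. Missing genotypes (and ages, when adjusting) are excluded
pairwise per SNP rather than complete-case across the panel, matching the
per-assay framing of call rates.

Separation (complete or quasi-complete) is detected by non-convergence or
unbounded coefficient drift and reported as a non-converged result — never
a silently huge OR — and such SNPs are excluded from PRS weight sets. No
penalized fallback is used, to keep the estimator identical across SNPs.

Significance is nominal p ≤ 0.05 (boundary inclusive), with no
multiple-testing correction: model 2 is defined by nominal significance, as
is conventional for small replication panels. A Bonferroni column is
emitted in the association table for transparency but never drives
selection.

## LD and pruning

r² is the *composite* (genotype-dosage) estimator: the squared Pearson
correlation of dosage vectors over pairwise-complete samples. It requires
no phase information, is deterministic, and coincides with haplotype r²
when phase is unambiguous; an EM haplotype estimator is out of scope. An LD
*block* is a connected component of the graph with edges at r² ≥ 0.5
("moderate to strong"); components rather than cliques, because a chain of
strong pairwise LD should count as one block. Pruning keeps one SNP per
block: smallest association p, ties broken by larger |β|, then by (chrom,
pos). The tie-break chain matters only for degenerate inputs and is a
package convention.

## PRS construction and evaluation

`PRS_i = Σ_j w_j · g_ij`, with natural-log OR weights (natural log keeps
weights on the same scale as the logistic β̂). Model 1 uses all QC-passing
SNPs; model 2 the significant subset; model 3 the pruned significant
subset, so model3 ⊆ model2 ⊆ model1. Weights come from either the
unadjusted or the age-adjusted training analysis.

Missing genotypes at scoring time default to mean imputation with
2 × the effect-allele frequency among *training controls* (keeps the score
scale comparable across samples and cohorts); a per-sample renormalization
policy (`m/m_observed` rescaling) is available in config.

**Quartiles.** Cutpoints are the 25/50/75th percentiles of the control
score distribution, computed as type-6 (Weibull) sample percentiles, with
boundary ties assigned to the lower quartile. Two deliberate choices:

- *Control-based* cutpoints (configurable to `combined`): with 243
  controls this yields the characteristic 61/61/61/60 control split across
  quartiles regardless of the model being evaluated, which is the behavior
  expected of control-referenced risk stratification.
- *Type-6 percentiles*: with ties-to-lower assignment, type-6 positions
  `p(n+1)` put exactly ⌈n/4⌉ controls in each of the first three quartiles
  for n = 243 (61/61/61/60). The more common type-7 (linear) definition
  would split 61/61/60/61 instead. With continuous scores the choice only
  moves single boundary samples.

Per-quartile ORs against the bottom quartile come from a one-hot logistic
fit. Because that categorical model is saturated, the ML ORs equal the
crude cross-product ratios of each quartile-versus-reference 2×2 table and
the Wald SE is `sqrt(Σ 1/cell)` — the identity that makes published
unadjusted quartile tables exactly recomputable from their printed counts
(`quartile_table_from_counts`).

**Trend.** Logistic regression of status on the continuous PRS (plus age
if requested); the reported OR is per unit of PRS, i.e. per unit of summed
log-OR-weighted allele count, so it is *not* comparable across models with
different SNP counts — a smaller model concentrates the same risk gradient
on a shorter scale and shows a larger per-unit trend OR.

**AUC.** Mann–Whitney estimator with ties counted ½; the 95% CI uses the
DeLong structural-components variance. Equivalent to the trapezoidal area
under the empirical ROC curve.

## Synthetic-data generator

The generator emulates: two independent cohorts filled to exact
case/control quotas (defaults 1294/885 and 301/243); a ~50-SNP panel with
effect-allele frequencies from 0.1% to 50%; per-allele ORs 1.1–1.5 for
common variants and up to ~4.9 for rare ones; LD blocks of 3–4 SNPs with
dosage r² ≈ 0.85; cases older than controls (truncated-normal ages on
[20, 90] with means 50.2/42.7 and SD 10 — only the means are anchored to
the emulated design, the SD is a field-typical choice); sporadic missing
calls at 0.9% (matching a 99.1% average call rate); and optional
whole-assay dropout.

Mechanics:

- **LD** via a latent-Gaussian threshold copula on haplotypes: each
  haplotype's alleles in a block derive from one multivariate-normal draw
  thresholded at the allele-frequency quantile; dosage is the sum of two
  independent haplotypes. The latent pairwise correlation is calibrated by
  root-finding on the bivariate normal orthant probability so the *allele*
  correlation hits √(target r²); dosage correlation equals allele
  correlation because the two haplotypes are i.i.d. Infeasible
  (frequency, r²) pairs — beyond the Fréchet bound — raise a calibration
  error. For unequal within-block frequencies the pairwise-calibrated
  latent matrix is projected to the nearest correlation matrix if needed.
- **Disease** via `P(case) = logistic(α + Σ_j ln(OR_j)·g_ij [+ γ·age])`.
  α is tuned once by bisection on a 20,000-draw calibration sample so the
  population prevalence matches the configured baseline (default 10%);
  cohorts are then filled by rejection sampling until quotas are met. ORs
  are invariant to this outcome-dependent sampling; prevalence only affects
  sampling efficiency. Quotas are treated as *post-QC* cohort sizes: only
  samples whose realized call rate clears 95% are admitted, so downstream
  sample filters leave the configured sizes intact.
- **Ages**: with γ = 0 (default) ages are drawn per class after status
  assignment, reproducing the configured class means. With γ ≠ 0 a
  pre-status age is drawn for everyone from the control-class normal and
  enters the risk model, producing genuine age→risk confounding for
  adjustment experiments (class age means then emerge from the model
  rather than the config).

The preset panel (`paper_like_panel`) has 51 SNPs: 5 rare variants
(EAF 0.1–0.2%, ORs 2.6–4.9) that a 1% MAF filter removes deterministically,
one 4-SNP block at r² ≈ 0.85 containing a single causal SNP (OR 1.4) with
three tags, 7 independent causal SNPs (ORs 1.15–1.3), and 35 nulls. At the
default cohort sizes about 11 SNPs reach nominal significance in
expectation (the 4 block SNPs, most of the causal 7, and ~1.8 nulls by
chance); across seeds the realized count varies roughly 8–14. Each block
contains one causal variant with the rest tagging it — the simplest
structure consistent with a tightly linked risk locus.

What the generator does **not** emulate: genome-wide LD maps, population
structure/admixture, genotype-calling error that violates HWE, batch
effects, relatedness, or X-chromosome dosage. Passing tests therefore show
the estimators are correct under the stated model, not that real cohorts
satisfy that model.

## Problem sizes used in the test battery

Statistical acceptance checks run at sizes chosen to make their Monte Carlo
error small relative to the asserted bands: CI coverage with 500 replicates
of 2000+2000 cohorts (binomial SD ≈ 1% around 95%), type-I error with 2000
null replicates (SD ≈ 0.5% around 5%), the end-to-end null on a
20,000-sample evaluation cohort (AUC SD ≈ 0.004 around 0.5), and the exact
HWE test swept exhaustively against a rational-arithmetic enumeration
oracle for all 23,425 genotype configurations with up to 50 diploids.

## Known limitations

- PLINK *text* formats only; no `.bed`, no VCF, no multi-allelic sites.
- Wald inference throughout; no profile-likelihood or exact logistic CIs,
  which matters for very sparse quartile cells (those are flagged instead).
- The DeLong CI is symmetric on the AUC scale and can touch the [0, 1]
  boundary at extreme separation (it is clipped).
- Single-threaded; the intended scale (~50 SNPs, thousands of samples)
  needs no more.
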