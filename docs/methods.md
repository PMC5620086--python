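# Methods

## The model and its assumptions

All four mapping layers fit the same fixed-effect linear model to
line × sex observations:

```
y_kh = μ + Σ_i q_i·u_ik + Σ_{i<j} qq_ij·u_ijk + e_h
         + Σ_i qe_ih·u_ikh + Σ_{i<j} qqe_ijh·u_ijkh + ε_kh
```

The panel is assumed fully inbred (every call homozygous, no missing
data) and the lines unrelated, so no kinship correction is applied.
Genotypes are coded `u_ik = +1` for the major-allele homozygote and `−1`
for the minor homozygote; with balanced allele frequencies this makes
main-effect, epistasis (`u_ijk = u_ik·u_jk`), and sex-interaction
columns mutually orthogonal. The sex effect is coded on a ±1 contrast
(+1 female, −1 male) with a sum-to-zero constraint, so μ is the grand
mean and per-sex effects fold out as `effect ± qe`. Transcript
predictors are standardized to mean 0, SD 1 within each sex, making
effects comparable across transcripts.

The observation unit defaults to line × sex replicate means (two
observations per line): the model has no replicate term, and averaging
replicates halves the residual variance without changing any fixed
effect. Replicate-level fitting is available by passing the replicate
table's values directly.

## Two-step detection

1. **Prescreen.** Every predictor is tested alone in the model
   `[intercept, sex, locus, locus×sex]`; the locus terms are tested
   jointly (2 df F). Predictors with nominal P < 0.001 become
   candidates. This single-locus screen plays the candidate-reduction
   role of the screening stage in the original analysis workflow.
2. **Permutation calibration.** Line labels of the response are
   permuted jointly across both sex slices — each line's female/male
   pair moves together, so the sex main effect survives under the null.
   For each permutation the F statistics of *all* hygiene-passing
   predictors (not only the prescreen survivors) plus all candidate
   epistasis pairs are recomputed, and the family maximum recorded. The
   critical F is the `ceil((1−α_EW)·n_perm)`-th order statistic of the
   null maxima; experiment-wise P values use add-one smoothing,
   `P_EW = (1 + #{null maxima ≥ F}) / (n_perm + 1)`, so they are never
   exactly zero.

   Taking the maximum over the full predictor set — rather than over the
   selected candidates only — is essential: candidates are chosen for
   small nominal P, so a candidate-only null would be stochastically too
   small and the realized family-wise error would approach the prescreen
   hit rate instead of α_EW. One family (mains + pairs) per scan gives
   one critical F per scan, and the observed statistics are the same
   marginal statistics recomputed under permutation, keeping observed
   and null families exchangeable.
3. **Scans and selection.** The 1D scan compares each candidate's locus
   F with the critical F; the 2D scan tests the epistasis terms
   (`qq`, `qq×sex`, jointly 2 df) of every candidate pair, with pairs
   truncated to a budget when candidates are many. Selection is forward
   inclusion of passing terms (mains by decreasing F, then pairs),
   followed by backward elimination: the joint model is refit and the
   weakest term whose joint-context partial F falls below the critical F
   is dropped, until all scan-selected terms remain experiment-wise
   significant. Perfectly collinear survivors are resolved
   deterministically by the (chromosome, position) or lexicographic id
   order; a pair whose interaction column is linearly dependent on its
   main effects (e.g. perfectly linked loci) is treated as inestimable
   and receives F = 0. An exact zero-residual fit reports a large
   sentinel F (1e12) rather than infinity.

Significance tiers label each retained association: `high` at
−log10 P_EW ≥ 5, `report` at ≥ 3, otherwise `significant` (passed the
critical F). With 2,000 permutations the add-one estimator floors at
−log10 P_EW = 3.30, so the `report` tier is reachable and `high` would
require ≥ 100,000 permutations; the labels are kept for forward
compatibility rather than extrapolated from a fitted tail.

## Effect estimation

Reported effect sizes are posterior means from a Gibbs sampler: the full
coefficient vector is drawn from its multivariate normal conditional,
then the residual variance and one shared prior variance per term group
(q, qq, qe, qqe) from conjugate inverse-gamma conditionals with vague
hyperparameters (a = b = 0.01). Defaults are 20,000 iterations, 10%
burn-in, thinning 10; the intercept and sex effect are effectively
unshrunk (prior variance 10⁶ × Var(y)). A split-chain
potential-scale-reduction above 1.1 triggers a warning, never an error.
Frequentist F tests drive detection; the sampler only quantifies the
retained effects, mirroring the original split between permutation-based
testing and MCMC estimation.

## Variance components and heritability

`V_Q`, `V_QQ`, `V_QE`, `V_QQE` are the population (divide-by-n)
variances over observations of each term group's fitted contribution;
`V_ε = SSE/n`; `V_P` is defined as their sum, so the decomposition
identity holds to machine precision and noise-free data give `h²_T = 1`
exactly. The per-term degrees-of-freedom scaling that sometimes appears
in this decomposition is never defined unambiguously in the source
analyses; using the empirical variance of each term's contribution
reduces to `q²/V_P` under balanced ±1 coding and keeps all shares in
[0, 1] by construction. Predicted genotypic values are the model's
systematic part; `R²_Ĝ→Y` is its squared Pearson correlation with the
observed response (defined as 0, with a warning, for a constant
prediction).

## Synthetic panels: what they emulate and what they do not

The generator reproduces the *structure* of a DGRP-style resource at
configurable scale: fully homozygous biallelic SNPs on the five major
chromosome arms, a minor allele forced into at least 4 lines, two sexes,
two phenotype replicates per line × sex (defaults: 156 lines, startle
mean 20 s, replicate residual SD 3 s — scores centred well inside the
[0, 45] s assay window). Linkage is simulated by block-wise copying of a
latent haplotype with a per-line mutation probability (block size 1 =
independent SNPs). Expression is baseline + cis/trans SNP effects +
transcript-transcript effects evaluated in topological order over a
regulatory DAG + sex effect + Gaussian noise. The phenotype follows the
model equation exactly, so downstream estimates can be compared to truth.

Deliberate simplifications: no population-genetic realism (no
demography, selection, or realistic allele-frequency spectra), no
microarray noise model, no replicate-by-day batch effects, and phenotype
values are *not* clipped to [0, 45] by default — clipping would break
the linear-Gaussian structure that recovery tests rely on; it is applied
only on request, and the generator warns when the truth implies
out-of-range means. Because the truth holds genotype-only phenotype
effects, "true QTTs" in recovery scenarios are realised by mediation: a
QTS with a strong cis effect on a transcript makes that transcript a
true QTT. Passing recovery tests therefore demonstrates correctness of
the machinery under the model's own assumptions, not robustness to the
messiness of real panel data.

## Study-scale choices in the tests

The recovery scenario plants 3 QTSs (additive effect 1.0 = 1 residual
SD), 2 mediated QTTs (cis effect 2.0), and 2 transcript-regulator edges
(coefficient 1.0) in a 300-line × 200-SNP × 40-transcript panel, and is
run for 25 seeds with the default 2,000 permutations and 20,000 Gibbs
iterations. The null error-control simulation uses 200 panels of 100
lines × 200 SNPs with 200 permutations each. These sizes keep each
simulation a faithful miniature of the study design (two sexes, two
replicates, minor-allele floor) while the vectorised permutation kernel
(precomputed design moments, batched 4×4/8×8 solves across predictors
and permutations) keeps the whole suite fast.

## Numerical conventions

* Critical F: `ceil((1−α)·n_perm)`-th order statistic, so 19
  permutations are the minimum that resolves α = 0.05.
* Degenerate (zero-variance) predictors are excluded from designs with
  a warning; unknown ids raise.
* Rank-deficient joint designs raise, naming the aliased columns.
* All file writers use fixed float formats (`%.17g` for data, two
  decimals for −log10 P_EW in association tables), and all simulation
  and MCMC randomness flows from explicit seeds, so a fixed seed gives
  byte-identical outputs.

## Known limitations

* No FDR alternative to family-wise control; no REML/random-effect
  variance estimation; no kinship correction.
* The tQTT target set is the significant QTTs from the same run; there
  is no principled subsetting beyond the tier filter.
* The 2D scan covers candidate pairs only (with a budget), not all SNP
  pairs.
* Experiment-wise P values cannot fall below 1/(n_perm + 1); very strong
  signals saturate at the permutation floor rather than spreading out.
* cis/trans classification of tQTS edges by genomic distance is not
  performed; positions are carried as metadata only.
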