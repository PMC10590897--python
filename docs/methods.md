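# Methods

## Phenotype model and adjustment

Plot-level damage ratings live on the ordinal grid {1.0, 1.5, …, 4.0} but
are treated as numeric throughout: the adjustment fits a linear mixed model
by REML with genotype as a fixed effect and three variance components —
environment, genotype × environment, and replicate nested in environment.
Because genotype is the only fixed effect, the equal-environment-weight
marginal (least-squares) mean of a genotype is its fixed-effect estimate;
genotypes observed in disjoint environment subsets remain comparable through
the shared random environment effects. No ordinal link is used; with
half-point ratings and well-replicated designs the linear treatment is the
standard practice for this kind of visual score, and it keeps the adjusted
means on the interpretable 1–4 scale.

Implementation: `statsmodels` MixedLM with environment as the grouping
factor (its random intercept is the environment effect) and G×E and
replicate-within-environment as variance components. Boundary fits (a
component estimated at zero) make gradient optimizers report failure, so the
fit retries lbfgs → Powell → Nelder–Mead before declaring non-convergence;
components below 1e−10 are pinned to zero and flagged. A closed-form path
(`method="means"`, simple genotype means) exists for complete balanced
designs, where it coincides with the REML fixed effects by orthogonality; it
is also the automatic fallback when the data are balanced and noise-free,
where the REML objective is degenerate. Tolerance classes follow the fixed
thresholds: tolerant ≤ 2 < moderate ≤ 3 < susceptible; boundary values
belong to the milder class.

## VIP scoring

The PLS regression uses centered, unit-scaled dosages (scaling makes VIP
comparable across minor-allele frequencies) and the numeric adjusted score
as the response. The component count is the smallest one whose 10-fold
cross-validated RMSEP is within one standard error of the minimum; the
folds are fixed by the seed, and a fixed count can be forced. One CV pass
fits the largest model per fold and reads every smaller component count
from its nested component sequence, so the error curve costs one fit per
fold. VIP is the standard definition

    VIP_j = sqrt( p * sum_a [ SS_a * (w_ja/||w_a||)^2 ] / sum_a SS_a ),

with SS_a = (t_a' t_a) q_a^2 the response sum of squares captured by
component a. Σ_j VIP_j² = p identically, so mean(VIP²) = 1 is asserted
after every fit as an internal consistency check. The selection threshold
defaults to VIP ≥ 2.0 — the conservative cutoff recommended when predictors
far outnumber observations and are strongly collinear, as on a genotyping
chip — with the boundary kept.

## Correlation pruning

Among shortlisted SNPs, pruning is a single greedy pass in descending-VIP
order (ties broken by chromosome, then position): a SNP is kept iff its
absolute Pearson correlation with every already-kept SNP is below 0.7.
This pass is deterministic, independent of input column order, and
guarantees both that the kept set has max pairwise |r| < 0.7 and that a SNP
is only ever discarded in favor of a higher-VIP one. Zero-variance columns
are dropped with a log entry (their correlation is undefined).

## Forward stepwise classification

Candidates enter in descending-VIP order. Iteration 1 always fits the
top-VIP SNP alone. In the default `greedy` mode, every remaining candidate
is evaluated as the next addition and the accuracy-maximizing one is kept
(ties: higher VIP, then genome order); `vip-order` mode instead adds
candidates in their fixed ranking — both modes emit identical trace shapes.
The trace deliberately continues past the first non-improvement to the
iteration cap so the overfitting decline is observable; the reported best
subset is the accuracy argmax over the whole trace (earliest iteration on
ties), and the iteration where the classical "stop at no further
improvement" rule would have halted is reported separately.

Each candidate set is scored by stratified k-fold cross-validation (default
5 folds, fold assignment fixed by the seed) with out-of-fold predictions
pooled into a single confusion matrix. Stratification keeps all three
classes in every fold under the typical ~19/62/19 mix; a class with fewer
members than folds reduces the fold count with a warning, and a
single-member class (which cannot be stratified at all) is excluded from
the evaluation with a warning. The Random Forest uses 500 trees and
⌊√p⌋ features per split; determinism is within-platform (tree RNG seeded
from the master seed), not bit-identical across platforms. The SVM uses a
radial kernel with one-vs-one multi-class voting; cost
{0.01, 0.1, 1, 10, 100, 1000} and gamma {0.0001, 0.001, 0.01, 0.5, 1} are
tuned by an inner stratified grid search on the training folds only, so no
outer-fold test row ever touches the tuning.

Per-class metrics are one-vs-rest: accuracy (TP+TN)/n, precision
TP/(TP+FP), specificity TN/(TN+FP); overall accuracy is correct/n × 100%.
Precision is reported as the "–" sentinel when a class is never predicted.
Tables round to 2 decimals; full precision is kept in memory.

## Synthetic data

The generator emulates a chip-genotyped panel of inbred advanced breeding
lines screened in a multi-environment, three-replicate randomized complete
block trial. Defaults: 551 lines, 4,970 SNPs on 20 chromosomes, 9
environments × 3 replicates.

*Genotypes.* SNPs are laid out in blocks of 10 within chromosomes; within a
block, haplotype liabilities follow a compound-symmetric Gaussian copula
(correlation 0.6 by default) thresholded at each SNP's target allele
frequency, drawn uniformly from [0.05, 0.5]; blocks are independent. Lines
are fully inbred (one haplotype doubled; a heterozygosity-rate option
exists). Blocks are redrawn until every realized MAF clears the lower
bound, and columns are oriented so the counted allele is the minor one.
This is a deliberately cheap LD model: it reproduces the two features the
funnel interacts with — local correlation among markers and a MAF floor —
but not recombination-distance decay, population structure, or the
relatedness structure of a real breeding panel (lines here are exchangeable).

*Phenotypes.* The per-plot latent liability is

    intercept + Σ_q β_q · dosage_q + env + G×E + rep(env) + residual,

with independent normal draws for each component and default variances
env 0.12, G×E 0.05, rep 0.03, residual 0.10. QTL effects are scaled against
realized dosage variances to hit target shares of total liability variance
(default: one major QTL at 0.30 plus seven background QTL summing to 0.40,
spread across chromosomes with alternating signs), bringing the total to
~1.0. Ratings are the liability binned to the nearest half-point at a step
of 0.74 liability units per half-point (breakpoints at ±0.37, ±1.11,
±1.85): the binning is symmetric and unbiased (zero liability averages a
2.5 rating), and with a genetic SD of ~0.84 the tolerant/susceptible
boundaries at ±0.74 put roughly 19% of lines in each tail — a typical
screening-trial class mix. Genotype and phenotype RNG streams derive
independently from the master seed, so re-simulating phenotypes never
perturbs genotypes. Passing tests on these data demonstrate the pipeline's
mechanics (recovery, calibration, determinism), not performance on real
panels with pedigree structure, spatial field trends, or rater effects,
none of which are simulated.

## Problem sizes and numerical choices

The test and acceptance suites run the funnel at 150–500 lines and
200–1,000 SNPs with 20 replicate seeds for the stochastic properties —
sizes chosen so the whole suite completes in minutes while leaving the
tested contrasts (top-VIP recovery, small-versus-full-panel accuracy gap,
chance-level nulls) far from marginal. Replicate panels for those checks
use 3 environments and the balanced closed-form adjustment; the REML path
is exercised separately at smaller sizes. The REML convergence tolerance is
the optimizer default with a 200-iteration cap; PLS CV standard errors are
propagated from the mean squared error through the square root; single-SNP
regressions use the two-sided slope t-test with p clipped away from zero
before LOD = −log10(p).

## Known limitations

- The forward search is greedy and myopic: beyond the second iteration its
  accuracy can fall below the fixed VIP-order prefix of the same size, so
  no global optimality is claimed; the trace makes the search auditable.
- Accuracy comparisons between candidate additions reuse the same folds by
  design; they are paired comparisons, not independent estimates.
- The comparator single-marker scan fits no kinship or structure
  covariates; its LOD > 4.0 flag is descriptive, not an inferential claim.
- Missing dosages are mean-imputed per SNP for modelling; no genotype
  imputation or phasing is attempted.
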