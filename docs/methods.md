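# Methods

`bnomics` re-implements, as a tested pipeline, an integrative multi-omic
analysis of asthma control: metabolome-wide association screens across
genotype, gene-expression and CpG-methylation panels; a conditional
Gaussian Bayesian network (CGBN) learned by bootstrap consensus and scored
by cross-validated prediction of the phenotype; and joint metabolite–gene
pathway enrichment. Because the motivating 20-subject cohort is not
publicly deposited, the package ships a synthetic cohort generator that
reproduces the *structure* of such data — including a planted ground truth
— so that every stage can be validated end to end.

## The phenotype and the data model

The outcome is a binary indicator of asthma control: use of a short-acting
β2 agonist (albuterol) rescue inhaler in the preceding week (1 =
uncontrolled). Modalities are feature-by-subject matrices: metabolite LC-MS
peak areas (log-normal, analyzed on the log2 scale), expression probe
intensities (log2, quantile-normalized), CpG methylation beta values in
[0, 1] (type I and type II probe chemistries analyzed separately), and SNP
genotypes as additive dosages 0/1/2 with `-1` as the missing sentinel.
Subjects may lack whole modalities; availability masks track this.

## Quality control and screening

* Metabolites: drop features with no variation among observed values and
  features missing in strictly more than half the subjects; log2-transform.
  A correlation report lists all pairs with pairwise-complete r² above a
  threshold (default 0.9).
* Expression: drop subjects whose p95/p05 intensity ratio is ≤ 6 (poor
  signal-to-noise); log2 + quantile normalization (each column takes the
  row-means of the sorted columns, ranks preserved).
* Methylation: drop majority-missing probes and user-supplied exclusion
  lists (cross-hybridizing probes, SNP probes); for replicate arrays keep
  the one with the largest inter-quartile range; split by probe type.
* Screens: ordinary least squares of each (log) metabolite on each feature
  with covariates — age and sex for genotype and expression screens, age
  plus the first two principal components of the methylation matrix for
  the methylation screen. Genotype screens mean-impute metabolites (bias
  toward the null) and use an additive dosage coding; expression and
  methylation screens drop incomplete pairs. Two-sided t tests on the
  feature slope; Benjamini–Hochberg FDR within each screen (per probe
  type for methylation). We use plain OLS rather than moderated
  (empirical-Bayes) t statistics; an optional variance-shrinkage switch
  s̃² = (d₀s₀² + d s²)/(d₀ + d) is not enabled by default because no
  moderation parameters are available to match.
* Leverage screening: an association is flagged (and excluded from
  selection) when refitting without subjects whose hat value exceeds
  2·(params)/n pushes its p above 0.05 — the standard leverage rule; the
  threshold is configurable.
* Selection: SNPs attaining FDR < 0.20 for any metabolite, ranked by
  minimum p, then pruned for complete linkage disequilibrium (D′ = 1,
  estimated by two-locus EM over unphased genotypes) keeping the stronger
  association; the top 20 expression probes by minimum p; and, for CpGs,
  the union of the top-50 type I and top-50 type II association rows
  yields a metabolite set, from which the top two CpGs per metabolite are
  taken (deduplicated). The rank-then-prune order for SNPs is a
  documented choice; the alternative (prune-then-rank) differs only when
  a pruned SNP would have re-entered below the cutoff.

## The conditional Gaussian Bayesian network

A CGBN is a DAG mixing discrete nodes (multinomial CPTs) and continuous
nodes (per discrete-parent-configuration linear Gaussian regressions on
continuous parents). Discrete nodes cannot have continuous parents; this
CG restriction keeps every family's marginal likelihood closed-form and is
consistent with the direction of biology here (genotype → metabolite).

Family scores (all hyperparameters exposed in `ScoreConfig`):

* Discrete child, states s = 1..r, per observed parent configuration with
  counts n_s: Dirichlet–multinomial evidence
  Γ(α₀)/Γ(α₀+n) · Π_s Γ(α_s+n_s)/Γ(α_s) with a *low uniform* Dirichlet
  prior α_s = α₀/r, α₀ = 1 by default. The low total mass acts as a
  complexity penalty and keeps the learned network sparse.
* Continuous child y on continuous parents X (with intercept), per
  discrete-parent configuration: normal–inverse-gamma evidence with prior
  mean 0 (data are standardized), coefficient precision τ = 1, variance
  shape a₀ = 1 and rate b₀ = 1 — the multivariate-t marginal computed via
  Λₙ = τI + XᵀX, bₙ = b₀ + (yᵀy − μₙᵀΛₙμₙ)/2.

Structure search is an add-only greedy hill climb from the empty network:
at each step the single edge addition with the largest positive score gain
is applied, excluding cycle creators, CG violations and children already
at `max_parents` (default 3, a guard against combinatorial blowup at
20 subjects); ties break lexicographically, so learning is deterministic
given the data. Scores are cached per (child, parent-set) and only the
modified child's candidates are re-scored after each addition.

Bootstrap consensus: the subjects are resampled with replacement B times
(default 250) and a network is learned on each resample; directed-edge
frequencies are tallied. Candidate consensus thresholds are the observed
frequencies in descending order; for each, edges are inserted in
decreasing frequency (skipping cycle creators and CG violations), the
network's parameters are fitted, and the phenotype is predicted by
stratified k-fold cross-validation (default 5 folds, folds derived from
the run seed). The chosen network maximizes CV AUC, ties resolved toward
the higher threshold (sparser network).

Prediction uses only the phenotype's Markov neighborhood:
P(state | evidence) ∝ P(state | parents) · Π_children p(child | its
parents with the phenotype set to that state). Parameters are posterior
means (CPTs smoothed by the Dirichlet prior; ridge-regularized regression
coefficients with posterior-mean residual variance). Missing evidence is
filled with the fitted marginal mean/mode and flagged. AUC is the
rank-based (Mann–Whitney) probability that a random case outscores a
random control, ties credited ½.

`markov_neighborhood` defaults to children plus the children's other
parents; a flag adds the node's own parents (the full Markov blanket,
which prediction always consults). Planted-recovery experiments count
recovery on the full blanket because the learner may orient a planted SNP
as a phenotype parent — a Markov-equivalent choice used identically by
the predictor.

## Pathway enrichment

Over-representation per pathway and per side (genes, metabolites): the
upper-tail hypergeometric probability of the observed overlap against the
background universe of all pathway members. A pathway is evaluated only if
it overlaps at least one query gene *and* one query metabolite; joint
p-values combine the two sides by Fisher's method (−2Σln p ~ χ² with 4
degrees of freedom), floored at 1e-300 before logs; BH adjustment runs
over the evaluated pathways only. Wilcoxon enrichment (WEA) rank-compares
members' case/control fold differences against non-members. Topology-based
pathway impact is the matched metabolites' share of the pathway graph's
total relative betweenness centrality. The original analysis's
concentration test ("Global Test") is not reproducible from its
description; `pathway_concentration_test` is a clearly-named permutation
surrogate whose statistic is the sum of squared standardized case/control
mean differences over the pathway's members.

## Cohort table

Binary traits are compared by Pearson χ² without continuity correction —
this choice reproduces all five published binary-trait p-values from the
printed percentages — with Fisher's exact test as an automatic fallback
when an expected cell count falls below 1, or on request. Printed
percentages are converted to counts by nearest-integer rounding (half to
even); 88% of 8 is read as 7/8. Continuous variables use the two-sided
rank-sum test (the original test is unstated; these p-values are
descriptive only).

## The synthetic cohort generator

The generator emulates the study's structure: 20 subjects by default, 68
metabolites of which 2 are constant and 2 majority-missing (64 survive
QC), genome-scale SNP/expression/CpG panels at reduced width (2000 each by
default), partial modality overlap (expression ≈ 80%, methylation ≈ 65% of
subjects), scattered missingness, and correlated metabolite blocks built
from a common latent factor whose loading is chosen analytically
(λ = (target r²)^¼ gives pairwise correlation λ² and r² = λ⁴): a pair at
r² = 0.95 and a block of four at r² = 0.92, mirroring the observed
bile-acid pair and fatty-acid cluster.

The planted truth is generated in the CG-representable orientation:
planted SNPs → phenotype (logistic model on standardized dosages),
phenotype → two planted metabolites, and SNP → metabolite couplings making
those SNPs co-parents of the phenotype's children. Because the metabolite
children are Gaussian with unit residual variance given (phenotype, SNPs),
the implied conditional P(phenotype | SNPs, metabolites) is exactly
logistic; the direct SNP coefficients are adjusted analytically
(β_direct = β_target + Σ_j γ_j·b_ij) so that the *configured* effects are
what a logistic refit on the true blanket estimates. Effect-size defaults
are moderate — SNP and metabolite log-odds ±0.8, coupling 0.6 — chosen so
that good prediction requires the whole neighborhood rather than one
saturating feature, which is the regime in which a consensus-threshold
sweep is informative (and, as in the original study, the AUC-maximizing
threshold is low). One master seed feeds fixed per-modality substreams, so
adding a modality never perturbs another.

What the generator does *not* emulate: linkage-disequilibrium structure
beyond optional duplicated SNP columns, batch/plate effects beyond a
single additive term, platform-specific intensity distributions, and any
real biological pathway structure. Passing tests therefore demonstrate the
statistical machinery under the assumed generative model, not performance
on real arrays.

## Problem sizes and numerical choices

Validation runs use desk-scale sizes chosen to make the stochastic checks
stable: planted-recovery experiments use n = 200 subjects, 12 SNPs + 12
metabolites + phenotype (25 nodes), B = 100 bootstraps, fivefold CV,
three seeds; null screens use m = 2000 features at n = 100. Greedy search
accepts an edge only if the gain exceeds 1e-9; consensus AUC ties within
1e-12 go to the sparser network; the evidence rate bₙ is floored at
1e-300; p-values are floored at the smallest positive double. PCA uses
SVD on feature-centered data with the sign convention that each
component's largest-magnitude loading is positive.

## Known limitations

* At the original cohort's size (n = 20) the bootstrap tally is noisy and
  the chosen threshold varies across seeds; the package reproduces the
  procedure, not the exact published network, whose underlying data are
  unavailable.
* Methylation is analyzed on the beta scale by default (a logit/M-value
  flag is available); the original scale choice is unstated.
* The greedy search is add-only by design; remove/reverse moves exist
  behind a flag and are off by default.
* CPTs for unseen parent configurations fall back to the uniform prior;
  continuous families fall back to the prior-mean regression.
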