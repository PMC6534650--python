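# Methods

This note records the statistical model behind each stage, the parameters
that matter, the numerical choices, and what the synthetic cohorts do and
do not emulate.

## Dispersion screen

**Model.** A gene set is *aberrantly expressed* in a disorder when the
cases, viewed as points in the set's p-dimensional expression space, are
over-dispersed around the healthy-control centroid. The screen makes no
assumption that cases shift in a common direction — each case may
dysregulate different member genes with different signs — which is exactly
the situation single-gene differential expression misses.

**Robust centroid.** Location and scatter of the controls are the raw MCD
estimates: over subsets of h = ⌊α·n⌋ controls (α = 0.8), the subset whose
sample covariance (denominator h−1) has minimal determinant. No reweighting
step and no consistency correction are applied; the statistic is the plain
subset mean/covariance. This keeps the estimator elementary and exactly
reproducible, and any multiplicative bias cancels in the permutation
comparison because the null sets are fit the same way. The search is
FAST-MCD: random (p+1)-point starts, concentration steps (each step
re-selects the h points closest in Mahalanobis distance and refits; the
determinant never increases), with the best few starts run to convergence.
The implementation batches the concentration steps across starts *and*
across the permutation null's random gene sets with stacked linear algebra,
which is what makes per-set permutation affordable on one CPU. For n ≤ 20
the number of starts is raised to 100 (nearly free at that size); an
independent exhaustive enumeration over all h-subsets is provided as
`exhaustive_mcd` and the tests verify the stochastic search attains the
exact minimum for n ≤ 12. Sets with p ≥ h are skipped (singular scatter is
unavoidable); a random null set whose scatter is still singular is redrawn,
with an error after 10·N redraws.

**Statistic and null.** SSMD = Σ MD_i² over the m cases. The null is N
random gene sets of identical size drawn uniformly *without replacement*
from the analyzed-gene universe, each refit from scratch; P = M/N with
strict "greater than", so P = 0 is attainable. An (M+1)/(N+1) mode exists
for users who prefer never-zero P-values but is not the default. N defaults
to 1000; the calibration and power checks in the test suite use N = 200 and
N = 500 with problem sizes chosen so each simulation finishes in minutes
(500 null sets of 10 genes against 83 controls / 40 cases for calibration;
ten planted 20-gene sets at τ = 2 against 80 controls / 40 cases for
power). Because the null is drawn from the same universe as the tested
sets, background structure (co-expression, covariate-driven variance) is
matched automatically and the P-values stay uniform under the global null.

**ΔSSMD.** For each gene the full pipeline — MCD refit included — is re-run
on the set minus that gene; ΔSSMD_j = SSMD − SSMD_excluding_j, reported
with 100·Δ/SSMD. The contributions need not sum to 100% and can be
negative (removing a redundant, highly correlated gene can *raise* the
recomputed SSMD); the exact additive decomposition ΔSSMD_j = Σ_i z_ij²
holds only in the idealized case of a fixed identity-scatter centroid,
which the tests use as a closed-form oracle via the injectable
`center_fn` argument.

**Case subsampling.** To compare disorders with unequal case counts, the
screen is repeated on random case subsamples of a common size; the mean
significant-set count across repetitions is reported.

## Shared sets and enrichment

Significant sets from the per-disorder screens are pooled, tagged with
their source disorder, and clustered by average-linkage hierarchical
clustering on Jaccard distance 1 − |a∩b|/|a∪b|, cutting the tree at 0.3
(merges at distance ≤ 0.3 join). Average linkage is the package's choice —
the linkage is exposed as a parameter — because it is the standard
compromise for set-overlap profiles; a cluster containing sets from ≥ 2
disorders is *shared*, and the Venn tally is over exact disorder
combinations. Candidate-gene enrichment is the inclusive upper tail
P(X ≥ k) of the hypergeometric law with the analyzed-gene universe (not
the genome) as background and the candidate list intersected with that
background first. No multiple-testing correction is applied to enrichment
P-values.

## Consensus co-expression networks

Per dataset: biweight midcorrelation (median/MAD based, weights
(1−u²)²·1[|u|<1] with u = dev/(9·MAD); a gene with MAD = 0 falls back to
its Pearson transform, logged), signed adjacency ((1+cor)/2)^β with β = 5,
and the topological overlap matrix
TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij). The
consensus is the elementwise minimum after each TOM is multiplicatively
scaled so its 0.95-quantile of off-diagonal entries matches the first
dataset's (removing global connectivity differences between datasets of
different sample sizes). `scale_free_fit` reports the signed R² of the
log-log regression of bin frequency on mean connectivity over 10
**equal-width** bins — equal-width is what makes the bin frequencies
informative; with equal-count bins every frequency is identical and the
fit degenerates. It verifies approximate scale-free topology for a chosen
β rather than selecting β.

**Modules.** Average-linkage clustering of 1 − TOM with a *static* cut
(default height 0.85) and a minimum module size of 20; genes in smaller
clusters are unassigned (label 0) and labels are renumbered by decreasing
size. The static cut replaces dynamic hybrid tree cutting (no PAM-like
reassignment stage, consistent with the rest of the design being fully
specifiable). The default height was derived from the adjacency algebra at
desk scale: background gene pairs (cor ≈ 0) have signed adjacency
0.5⁵ ≈ 0.03 and TOM of the same order, so unrelated genes merge at heights
≈ 0.93–0.97, while coherent modules (within-module cor ≳ 0.5) finish
merging below ≈ 0.8; 0.85 sits in the gap. **Limitation:** within-module
TOM is diluted as the universe grows (the denominator tracks total
connectivity), so for matrices much beyond ~10³ genes the cut must be
raised toward 0.9–0.95 or the modules must be proportionally stronger;
this scale dependence is intrinsic to any static cut and is why the cut
height is a first-class parameter everywhere.

**Eigengenes and traits.** A module eigengene is the first right-singular
vector of the gene-standardized module matrix, sign-aligned so it
correlates positively with the module's mean profile, unit norm.
Associations with age, sex and per-disorder 0/1 diagnosis indicators use
Pearson correlation with two-sided P-values, BH-corrected across all
(module, trait) pairs; constant traits are reported as undefined and
excluded from the correction. A module is *shared* when significant
(q < 0.1) for at least two diagnosis indicators.

**Robustness.** When two datasets share a control pool, the shared
controls are split per repetition into disjoint halves (seeded), one half
joining each dataset, and the consensus modules are rebuilt with identical
parameters. A full-data module's stability in a repetition is the fraction
of its gene pairs still co-clustered (a pair with an unassigned gene
counts as split); the per-module median over repetitions is the summary.
With no shared controls the full-data assignment is returned with
stability 1.

## Preprocessing stand-ins

Batch correction is ordinary least-squares residualization with the source
batch as a covariate alongside age, sex and brain region (categoricals
dummy-encoded, grand mean added back so the low-expression filter remains
meaningful); it is idempotent, and a rank-deficient design raises an error
naming the collinear encoded columns (an `on_collinear="drop"` mode prunes
them instead — the projection is unchanged — which matters when one batch
contains a single brain region). Hidden expression determinants are the
top-k right-singular vectors of the gene-centered matrix; each factor is
tested for association with diagnosis by one-way ANOVA and regressed out
only when p ≥ 0.05 (factors that may carry disease signal are kept). These
are transparent linear stand-ins with the same contract as empirical-Bayes
batch correction and variational latent-factor inference, not numerical
reproductions of them. The low-expression filter removes genes with
across-sample median strictly below 2 and runs before residualization.
Per-disorder splitting pairs each disorder's cases with the controls from
the same source batch, so the two batch-II disorders share a control pool
while the gene universe stays identical across the three datasets.

## Synthetic cohorts

The generator emulates a normalized log-scale two-batch brain cohort:
baseline gene means ~ N(6, 1), gene noise SD ~ U(0.8, 1.2), batch offsets,
age/sex/brain-region effects, broad hidden factors, planted co-expression
modules (rank-1 factors with positive loadings), and planted aberrant sets
— for a fraction ρ of a disorder's cases, the residual SD of member genes
is multiplied by τ (dispersion with per-case random sign structure, no
common mean shift). Default group sizes are 47/31/25 cases with 57 + 26
controls, the shape of a two-source cortical cohort; the default gene
count is 2,000, a desk-scale stand-in for a filtered protein-coding
transcriptome; τ defaults to 2 and ρ to 1. Optional knobs plant the
cross-disorder phenomena the downstream stages detect: `shared_set_combos`
disperses one set in several disorders' cases, `module_disease_shift`
shifts a module's factor in its assigned disorders' cases so eigengenes
associate with diagnosis, and `shared_sets_overlap_modules` draws shared
sets from module gene pools so the two method families overlap. All
randomness derives from one master seed through `SeedSequence` substreams;
a fixed seed gives bit-identical cohorts.

What the generator does **not** emulate: count-level sampling noise
(negative binomial, library size — it targets the post-normalization log
scale), heavy-tailed single-sample outliers, correlated covariates
(age/sex are assigned independently of diagnosis), or realistic gene-set
topology (decoys are uniform draws). Passing tests therefore demonstrate
the statistical machinery — calibration, power against planted dispersion,
module recovery — under Gaussian conditions, not performance on raw
RNA-seq.

## Reported run

`scripts/acceptance.py` uses a 500-gene cohort with the study-shaped group
sizes, two planted sets per disorder plus three shared combinations
(τ = 2, 10-gene sets), three 30-gene modules (factor SD 2.5, disease shift
1.5) and three strong hidden factors; screens with N = 200 permutations at
P ≤ 0.01; and reports shared clusters at both P ≤ 0.01 and P ≤ 0.05. At
these cohort sizes the P ≤ 0.01 screen is genuinely underpowered for the
26-control disorders (planted sets land around P ≈ 0.03–0.06), which the
recovery percentage reflects; the larger-cohort power simulation in the
test suite recovers ≥ 80% of planted sets. The hidden-factor count is set
to the generator's nuisance dimension (3); asking for many more factors
would begin to strip genuine co-expression, the same tension latent-factor
correction faces on real data.
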