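# Methods notes

## Data model and normalization

A cohort is a genes × samples matrix with binary phenotype labels coded
−1/+1 (+1 = case / poor outcome). All activity inference operates on
per-cohort z-scores: each gene row is standardized to mean 0, sd 1 (sample
sd, ddof 1) over *all* samples of the cohort, classes pooled. Z-scores are
recomputed independently in every cohort — cohorts typically come from
different platforms, so carrying one cohort's means/sds into another would
import platform effects into the activity values. Zero-variance genes are
zeroed (with a warning) rather than dropped so the gene universe stays
aligned across cohorts.

Differential expression uses the pooled-variance two-tailed two-sample
t-test by default (deterministic degrees of freedom, the classical
microarray choice); Welch's test is available via `equal_var=False`. A gene
is a DEG at p ≤ α, default α = 0.05.

## Core-module inference

Within a pathway, DEGs are ranked by descending |t| (ties broken by gene
symbol so results are independent of input order). Prefix activities

P_j = (1/j) Σ_{i≤j} z(g_i)·sign(t(g_i))

are evaluated for j = 1 … min(#DEGs, 20) and K is the smallest j maximizing
the activity's own t statistic. The member cap of 20 reflects the intended
compact-marker regime. Numerical choices:

- The divisor is j (plain average) as printed in the defining formula; the
  sqrt(j) convention used by the CORG family is available via
  `denominator="sqrt"` since both normalizations appear in this literature.
- The arg-max uses the *signed* t: members are sign-aligned, so the
  constructed activity discriminates in the positive direction by design. In
  the degenerate case where no prefix attains a positive t, |t| decides.
- A pathway with no DEG yields no model (its activity would be identically
  zero and carries no information).

The CORG comparator searches only within the up- (t > 0) or down- (t < 0)
regulated subset, growing the prefix greedily (sum of z over sqrt(j),
negated for the down subset) and stopping at the first non-improving
addition; the subset with the larger |t| wins. PCA activities are oriented
so the inference t-score is non-negative. LLR fits per-gene class-
conditional Gaussians with a variance floor of 1e-6.

Projection onto another cohort freezes member genes, signs, divisor and any
loadings/parameters; members absent from the target are dropped with the
divisor adjusted to the survivors (a warning is emitted; a model with no
surviving member raises).

## Reproducibility score

Cscore(N) = (1/N) Σ_{i≤N} t(P_I_i)·t(P_V_i) over the top-N ranked inference
models. Sign-aligned constructions (CMI, CORG) are ranked by descending
signed t; methods whose orientation relative to the phenotype is arbitrary
(mean, median, individual genes) are ranked by descending |t| with the sign
carried into the product, so direction disagreement is still penalized. LLR
is excluded from this comparison — its activities are log-likelihood sums,
not points in the shared expression z-space the score assumes. The overall
value is the plain arithmetic mean over all ordered cohort pairs.

## Consensus feature elimination

Each elimination step fits `n_splits` × `n_folds` (default 100 × 5 = 500)
linear classifiers on stratified folds, records held-out AUCs, ranks
features by mean squared weight over the 500 weight vectors, and removes the
lowest-ranked feature; the feature set at the step with maximal mean AUC is
selected (ties go to the smaller set). The whole elimination is repeated
(default 100 times) under different split randomizations and the most
frequent exact set wins (ties: smaller set, then lexicographic).

Implementation decisions:

- Folds are stratified by class; the study cohorts this procedure targets
  are class-imbalanced, and unstratified small folds can be single-class.
- The split ensemble is drawn once per elimination run and reused at every
  step, so consecutive steps differ only in the feature set, not in the
  resampling noise. Empirically this matches per-step redrawing to within
  Monte-Carlo error while being cheaper and easier to reason about.
- AUC is the held-out (test-fold) AUC of each fit, averaged over all 500
  fits per step; AUC itself is the normalized Mann–Whitney statistic with
  ties counting 1/2.
- LDA is the Fisher discriminant w = S⁻¹(μ₊ − μ₋) with the pooled
  within-class covariance shrunk toward a scaled identity at the closed-form
  Ledoit–Wolf intensity (plus a 1e-10 ridge for exactly singular corners);
  the bias places the boundary midway between projected class means. The SVM
  option is a standard soft-margin linear SVM (C = 1 by default).
- Per-repeat seeds spawn deterministically from the master seed, so any run
  is bit-reproducible.

### Known limitation: internal-CV selection bias

The consensus weight ranking pools information from fits covering every
sample, so the features surviving to late elimination steps are those that
happen to discriminate on the dataset at hand. The mean held-out AUC at
those steps is therefore optimistically biased — on pure-noise data with 20
features and 60 samples, the maximum of the trajectory sits around 0.6–0.75
rather than 0.5, consistent with the selection-bias literature on
cross-validated feature elimination. The step-0 (all-features) AUC is
unbiased, and the *final-marker voting* is unaffected, but the reported
max-mean-AUC should be read as an internal model-selection score, not an
unbiased estimate of generalization accuracy. Unbiased accuracy in this
framework comes from the cross-cohort design itself: activities are
validated on cohorts never used for their inference.

## Pairwise validation and core assembly

For each ordered cohort pair, models are inferred on the inference cohort,
the top-`top_n` (default 100) by rank are projected onto the validation
cohort, and repeated CFE with the validation labels selects a pathway set. A
pathway inferred from cohort D is a core marker iff it is selected against
*every* validation partner of D — the strictest reading of "reproducible in
all other cohorts" — and core markers are pooled (union) over inference
cohorts, with full provenance retained so alternative poolings can be
audited. Core genes are the union of member genes of core markers, annotated
up/down per cohort by the sign of the gene's t-score; a gene with
inconsistent signs (or a zero t) across cohorts is flagged contradictory.

## Enrichment and network exploration

Enrichment of a signature (J genes, K in the reference list) against a
universe of N genes containing M reference genes uses the strict
hypergeometric tail P(X > K) (the conventional P(X ≥ K) is available via
`inclusive=True`); the enrichment rate is K/J. The recommended universe is
the genes shared by all cohorts and present in the filtered pathway
collection. No multiple-testing correction is applied across reference
lists by default.

Pathway filtering intersects each gene set with the shared cohort universe
and keeps sets of 5–200 surviving members by default ("bulky" sets several
hundred genes wide dilute activity signal and dominate enrichment
statistics); both bounds are configurable.

Hub genes are the top-k nodes of the core-gene induced subnetwork by degree
(confidence-weighted degree when edge scores exist; ties by weighted degree,
then lexicographically), k = 20 by default. Driver genes are hubs that are
also common marker genes. The optional functional-module labelling is a
greedy-modularity community heuristic intended only for display.

## Synthetic studies

The generator emulates the driver/passenger structure the method assumes:
i.i.d. Gaussian noise (sd 1; a heavier-tailed t option exists for
robustness checks), a set of driver pathways whose chosen member genes are
shifted in cases by a configured effect with signs drawn once and shared by
all cohorts, and per-cohort passenger genes — disjoint across cohorts,
sampled from non-driver pathway members — shifted only in their own cohort.
Driver pathways occupy a dedicated, mutually disjoint slice of the gene
pool, which makes "passenger-only pathway" unambiguous for
sensitivity/specificity scoring. The interaction network is a scale-free
(preferential-attachment) backbone over pathway genes with extra edges
wired to driver genes so they are planted hubs.

Defaults describe the intended study regime: 3 cohorts × 100 samples
(half cases), 1000 genes, 50 pathways of 10–20 genes, 5 driver pathways
with 5 shifted members at 0.8 sd, 25 passengers per cohort at 0.8 sd.
What the generator does *not* emulate: probe/batch effects, correlated
background expression, missing values, class-imbalanced label noise — so
passing recovery tests demonstrates correctness of the machinery under the
model's own assumptions, not robustness to real microarray artefacts.

## Problem sizes used in the shipped analyses

The test-suite and the acceptance script run the pipeline at the default
synthetic design above but with the CFE ensembles scaled to 10 splits and
10 repeats (4 × 6 for the determinism check), which reproduces the
paper-scale behaviour of the selection machinery while keeping a full
6-pair, 3-seed study in the minutes range on one CPU; single-run CFE checks
use the full 100-split ensemble. Scaling the ensembles back to
100 × 100 is a constructor argument.
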