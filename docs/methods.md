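# Methods

`rfgsea` decides, for every gene *n* in an expression matrix, whether it
plausibly participates in a biological process described by a prior gene
set.  The premise is network-based: genes taking part in one process
predict each other's expression, so a process member's best predictors
should be enriched for other (known) members.  The screen combines three
ingredients — per-target random-forest importance rankings, preranked
gene-set enrichment of the prior within each ranking, and a consensus-
cluster / differential-expression filter — and intersects their outputs
into a final candidate list.

## Per-target importance ranking

For target gene *n* with expression `y` across S samples, an ensemble of
unpruned CART regression trees is fit with the remaining N−1 genes as
predictors.  Defaults: 500 trees, every predictor examined at every
split (bagged trees, the literal "N−1 features per node" recipe; a
numeric `predictors_per_split` gives classic random-subspace forests),
bootstrap resampling of samples, and `min_samples_leaf = 5`.  The leaf
bound is the only growth limit: with no post-pruning the trees would
otherwise grow to single-sample leaves, and 5 is the long-standing
regression-tree convention.

Two importances are computed for every predictor *j*:

* **%IncMSE** — for each tree, the out-of-bag MSE after permuting
  column *j* within that tree's out-of-bag samples minus the unpermuted
  out-of-bag MSE; the score is `mean_t(d_tj) / stderr_t(d_tj)` across
  trees (the raw mean when the standard error is 0, e.g. for a predictor
  never split on, whose increase is identically 0).  The scaling matches
  the reference behaviour of the R ecosystem's permutation importance;
  `scale_importance=False` reports the raw mean.  One permutation pass
  per tree per predictor is the standard estimator; `n_permutations`
  averages repeats.  Uninformative predictors fluctuate around zero and
  are frequently negative — the screen's negative-enrichment class
  depends on exactly this behaviour.
* **IncNodePurity** — the decrease in node residual sum of squares
  summed over every split on *j* in every tree, divided by the number of
  trees; non-negative, and exactly 0 for never-used predictors.

Determinism: a root seed spawns three per-target seeds (forest,
enrichment test per score) by hashing `root_seed:gene_id` with SHA-256,
so per-gene results are independent of iteration order, of target
subsetting and of the worker count.

## Preranked enrichment of the prior

Predictors are ranked by descending score (ties broken by gene id so
orderings are platform-independent) and the prior set — restricted to
the ranked universe, minimum overlap 5 — is tested with the weighted
running-sum statistic: a hit at position *i* adds
`|score_i|^w / Σ_hits |score|^w` (w = 1), a miss subtracts
`1/(N − N_hit)`; the enrichment score ES is the signed maximum deviation
(an exact positive/negative tie resolves to the positive value, a
probability-zero event for continuous scores, and is logged).  The null
fixes the scores and redraws hit positions uniformly without
replacement.  The p-value is sign-conditional with a +1 pseudo-count —
it is conservative at finite permutation count and never exactly 0 —
and NES divides the observed ES by the mean |ES| of same-sign null
draws (NaN, with p = 1, if no null shares the sign; logged).  At least
100 permutations are required; the screen uses 1000.

The screen thresholds the **raw** per-gene p at α = 0.05, mirroring the
method it implements; Benjamini–Hochberg-adjusted companions are written
to the output table for the reader but never acted on.

Classification: a target is `%IncMSE-positive` if its %IncMSE ranking
enriches the prior significantly with ES > 0, `%IncMSE-negative` with
ES < 0 (evidence *against* membership — the prior concentrates among its
least important predictors), and the IncNodePurity flag requires
significance only (the sign split is applied to the %IncMSE arm alone;
`split_purity_by_sign` opts into the symmetric variant).

## Clustering and differential expression

Samples are consensus-clustered on the prior-gene features: 1000 draws
of 80% of samples without replacement, K-means (Euclidean, 10 greedy
k-means++ restarts) per draw, consensus(i, j) = co-clustered /
co-sampled draws.  The number of clusters is chosen from the CDF of
consensus entries on a fixed 100-bin grid: `delta(k) =
(A(k) − A(k−1))/A(k−1)`, with the smallest k whose next delta falls
below `delta_threshold` selected.  The default threshold is 0.3,
calibrated on synthetic data: splitting one clean cluster still inflates
the relative area by ≈ 0.24, while structureless data gains ≥ 0.3, so
the conventional 0.1 would never stop at the true k at this scale.  The
choice is advisory — the pipeline accepts an explicit `k` (the screen's
canonical setting is k = 2) and always writes both curves.  Final labels
cut an average-linkage tree on 1 − consensus and are renumbered by
descending cluster size.  A partition whose within-minus-between
consensus contrast falls below 0.5 is flagged low-confidence; the
threshold sits above the 0.23–0.46 range that resampled iid noise
produces (the labels are derived from the consensus matrix itself, so
some contrast is inevitable even without structure).

Differential expression between the two clusters uses a moderated
t-statistic: per-gene pooled variances are shrunk toward a scaled
inverse-chi-square prior fitted across genes by the method of moments
(`d0 = (2d − 4 + 4ud)/(ud − 2)` with `u = var(s²)/mean(s²)²`; infinite
`d0`, i.e. complete shrinkage, when the spread of variances does not
exceed sampling noise).  A plain Welch test is the fallback, and the
moderated p-values approach the pooled/Welch values as the prior
degrees of freedom vanish.  Log2 fold change is the difference of
cluster means (cluster 1 − cluster 2; inputs are already log-scale, so
no re-logging), significance requires |log2FC| > 1 **and**
BH-adjusted p < 0.05, genes constant in both groups with equal means
get p = 1, and Bonferroni is available by config.

## Candidate assembly

`final = %IncMSE-positive ∩ IncNodePurity ∩ DEGs`.  The positive and
negative %IncMSE sets are disjoint by construction, so the final list
can never contain a gene whose ranking anti-enriches the prior.  The
three-way intersection makes the screen far more conservative than any
single test: in null simulations the final fraction is ≲ α² (the DE
stage is nearly independent of the enrichment stages).

## Synthetic studies

The generator plants a single-latent-factor module: per sample,
`z ~ N(0, 1)` (group 2's mean shifted by `group_shift`, default 2),
module gene `g` reads `x = β_g z + ε` with `β_g ~ U(0.6, 1.2)` and
`ε ~ N(0, 0.5·noise_sd)`, background genes are `N(0, noise_sd)`
(default 1).  The halved module residual keeps marginal variances
comparable so nothing can be found by variance alone.  Defaults — 200
genes × 120 samples, 30-gene module, prior of 20 module genes plus 10
background decoys with round-robin validated/screened/deduced tiers —
emulate a curated, partially wrong prior.  A single factor is the
minimal structure making module genes mutually predictive; the
generator deliberately omits count-level features of RNA-seq (library
size, overdispersion, zeros) because the method consumes log-scale
values, and it omits graph-structured regulation, so passing tests show
recovery of co-expression modules, not of arbitrary network topologies.
The null generator moves every gene to the background and fills the
prior entirely with decoys, making screen-wide type-I behaviour
measurable.

## Problem sizes used in the tests

The test-suite and acceptance checks run each analysis at the largest
size a single CPU carries comfortably: enrichment exactness on 1000
random lists (N ≤ 50) against a brute-force oracle; null calibration
with 500 replicates × 1000 permutations; importance sanity on a
100-sample, 51-gene linear model over 100 seeds; and the full pipeline
(100 trees, 500 permutations) on a 120-gene × 80-sample study that
keeps the default module and prior composition, over 25 seeds.
Pre-registered calibration at those settings gives sensitivity ≥ 0.70
in 20/25 seeds with zero background contamination, and empty final
lists on null studies.

## Known limitations

* With small planted modules (≈ ≤ 15 genes) the greedy, all-features
  trees concentrate IncNodePurity on one or two predictors; the
  resulting heavy-tailed weights inflate the permutation null of the
  weighted statistic at small N and the purity arm loses power.  This is
  a small-universe artifact — at genome scale the prior is a vanishing
  fraction of the ranking — but it means the purity arm should not be
  trusted on very small expression panels.
* The raw-p thresholding across all targets is the method's own rule,
  not a multiplicity-corrected procedure; the emitted BH column
  quantifies the difference.
* The delta-area elbow is weakly informative at small sample counts;
  `chosen_k` is advisory and the consensus matrices and curves are
  always written for inspection.
* Full-feature bagging is computationally extreme at genome scale
  (N − 1 features per split, ~N forests); `predictors_per_split` and
  `workers` exist precisely for that case.
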