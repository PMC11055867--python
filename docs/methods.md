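# Methods

## The model: dynamic co-expression as a three-way interaction

Classical co-expression analysis asks whether two genes X and Y are
correlated across samples. That picture is static: in real tissue the
strength — even the sign — of a pair's co-expression can depend on the
cell's internal state. This package screens for *switch genes*: a third
gene Z whose expression level acts as a surrogate for that state, so
that the X–Y correlation changes as Z moves through its range. A
candidate is the triplet Z/{X, Y}, with {X, Y} unordered and Z distinct
from both.

### The statistic

Samples are split into `M` equal-frequency bins by ascending Z
(remainder samples go to the lowest bins; ties break by sample index).
The binned liquid-association score is

    MLA(Z/{X,Y}) = (1/M) * sum_{i=1..M}  rho_i * zbar_i

where `rho_i` is the Pearson correlation of X and Y inside bin i and
`zbar_i` is the mean of (standardized) Z in bin i. Because the bin means
of a standardized Z are symmetric around zero, a pair whose correlation
is constant in Z contributes cancelling terms and scores near 0, while a
correlation that tracks Z (e.g. +0.7 at low Z, −0.65 at high Z) scores
far from 0.

`M` defaults to 3. Terciles are the coarsest split that can express a
sign flip with a neutral middle state, and on rank-normalized data the
upper tercile of a cohort of ~100 samples starts near
Phi^-1(2/3) = 0.43 — the scale on which low/high switch states are
reported. A bin with zero within-bin variance of X or Y contributes
`rho_i = 0` with a logged warning.

### Preprocessing

The statistic assumes each gene vector is marginally normal with mean 0
and variance 1. The pipeline therefore applies, per gene:

1. optional RPKM normalization (`count * 1e9 / (length * library_size)`)
   when starting from raw counts, and a median/variance gene filter
   (thresholds explicit and configurable; constant genes are always
   dropped because they cannot be ranked);
2. a rank-based inverse-normal transform,
   `Phi^-1((rank - 0.5)/n)` with average ranks over ties — the
   (r − 0.5)/n offset is the symmetric van-der-Waerden-style convention;
3. standardization to unit sample variance (n−1 denominator throughout,
   consistent with the correlation estimators downstream).

After step 2 every gene is a permutation of the same fixed normal
scores, so Pearson correlations downstream are Gaussian rank
correlations of the raw data, and the screen is invariant to any
monotone distortion of the original expression scale.

## Significance

The screen enumerates every triplet (G·C(G−1, 2) of them), retains the
`top_k` by |MLA|, and assesses retained triplets by permuting Z across
samples (re-binning each permutation) B times.

Two p-values are available per triplet:

* **permutation** — the empirical tail `(1 + #{|MLA_b| >= |MLA|})/(B+1)`;
  exact and assumption-free, resolution-limited to 1/(B+1). Used for
  calibration experiments.
* **normal** (screening default) — a two-sided normal tail at the
  triplet's own permutation-null mean with the null SD *pooled* across
  all retained triplets. Pooling is what makes very small p-values
  estimable from a few thousand permutations; it is justified here
  because every gene vector carries identical marginal normal scores, so
  the null scale is shared to good approximation. A triplet with genuine
  structure in its (X, Y) scatter has a somewhat wider data-conditional
  permutation null than the pooled one — the pooled tail behaves like
  the parametric null of model-based liquid-association screens rather
  than the conditional permutation null. `normal_per_triplet` is
  available when the conservative conditional version is wanted.

Multiple-testing adjustment offers Bonferroni (the conservative
headline criterion, default threshold adjusted p < 0.001) and
Benjamini–Hochberg, both computed over an explicit family size that
defaults to the *total* number of triplets enumerated, not only those
retained — the conservative reading when a screen is truncated. Both
columns are always written so the two criteria can be compared; the
FDR-vs-(−log10 p) curve makes the correspondence explicit.

## Diagnostics: the switch-gene event rate

If switch roles were assigned by chance, the number of distinct Z genes
among k significant triplets drawn from a g-gene universe would have
expectation `g * (1 − (1 − 1/g)^k)`; divided by k this is the *random
event rate*. Biology concentrates regulatory control in few genes, so
the *observed* rate (distinct Z genes per significant triplet) should
fall well below it. The profile reports both, over a grid of p-value
cutoffs, with a Monte-Carlo estimate and SD alongside the closed form.
The uniform-assignment baseline is a modeling choice: it is the natural
"by chance" null, but it ignores any inhomogeneity in per-gene triplet
counts induced by truncation.

## Biological relevance

A significant triplet is called *biologically relevant* when both of
the following hold.

* **Co-enrichment.** Gene-set enrichment (right-tailed hypergeometric
  test per term, BH across tested terms, default alpha 0.05) is run on
  the union of genes in significant triplets, restricted to terms of
  ontology level > 6 — shallow terms are too generic to tie a pair to a
  concrete process. Term levels are consumed as catalog metadata
  (`level=<int>` in the GMT description field); the ontology graph is
  not traversed. The triplet passes if some enriched term contains both
  X and Y.
* **Network support.** An ARACNE-style mutual-information network is
  built over all screened genes: Gaussian-copula MI
  (`−½·ln(1 − r²)` on normal scores — consistent because the input is
  already marginally normal, and monotone in |r| so MI and |r|
  permutation tests coincide; a binned plug-in estimator is kept as a
  nonparametric cross-check), permutation p-values per edge with
  Bonferroni family = number of pairs, then data-processing-inequality
  pruning: in every triangle the weakest edge is removed if its MI is
  below (1 − tolerance) times the smaller of the other two
  (tolerance 0.15, the customary ARACNE default). Edges are undirected —
  MI is symmetric and no regulator list is consulted. The triplet passes
  if Z reaches X and Y each through at most 3 intermediate nodes
  (path length ≤ 4 edges) over surviving edges.

The per-edge permutation count B defaults to `ceil(4 * n_pairs / alpha)`
so the 1/(B+1) resolution sits below the Bonferroni threshold; one
shared permutation per replicate is used across pairs (common random
numbers — each pair's marginal null is exact).

For reporting, each verified triplet also carries its conditional
correlation profile: the per-bin Pearson r of (X, Y) and the Z range of
each bin, labelled r_low / r_mid / r_high for M = 3. Recomputing the MLA
from this profile reproduces the stored score exactly.

## Switch-gene importance

A random forest (default 10,000 trees, mtry = floor(sqrt(p)), seeded)
classifies the sample groups from switch-gene expression. Importance is
mean decrease accuracy: per tree, the drop in out-of-bag accuracy when
one gene's values are permuted among that tree's out-of-bag samples,
averaged over trees — the classical permutation importance, computed
against out-of-bag samples to avoid resubstitution optimism. (The
per-tree bootstrap is reconstructed from each tree's stored seed; the
test suite cross-checks the reconstruction against the library's own
out-of-bag votes.) Classifier performance is an ROC on out-of-bag
probabilities of a designated positive group (default: the polyp-tissue
group versus all other samples — the screen's groups are three, so the
binary contrast is an explicit choice), with trapezoidal AUC (equal to
the Mann–Whitney rank statistic under the tie handling used) and
sensitivity/specificity at a probability threshold of 0.5. Per-gene
group differences are summarized by one-way ANOVA with Tukey HSD
post-hoc pairs and the usual star convention (*, **, ***, **** at
0.05/0.01/0.001/0.0001).

## The synthetic cohort generator

The generator produces the structure the screen targets, so the whole
pipeline is exercisable and testable without any external download:

* three sample groups, default sizes 42/33/28 (a polyp cohort design:
  polyp tissue, paired turbinate tissue, control turbinate);
* background genes: independent unit-variance noise, optionally
  equicorrelated via a shared factor (`background_correlation`);
* planted triplets: Z drawn per sample with a group-dependent mean shift
  (default ±1.1 SD, mimicking a switch gene elevated in disease tissue),
  then samples stratified into equal-frequency terciles of Z and the
  pair (X, Y) generated per stratum with target correlations
  (defaults +0.70 / 0 / −0.65, the sign-flip magnitude reported for
  S100a9-type switch triplets).

Two design choices deserve emphasis:

* **Switch coupling.** X and Y each carry a `switch_coupling * Z`
  component (default 0.5); the within-stratum pair correlation of the
  residual components is solved so the *total* within-stratum
  correlation still meets the targets. A switch gene that modulates its
  targets is plausibly co-expressed with them, and without this marginal
  dependence the planted triplet would be invisible to any
  mutual-information network — the relevance stage could never confirm
  a purely conditional plant.
* **Effect modes.** `population` (default) draws the pair from a
  bivariate normal with the target correlation, so realized stratum
  correlations fluctuate around the targets (SD ≈ 0.05–0.1 at ~34
  samples per stratum) — the right mode for power studies.
  `empirical` realizes the sample correlations exactly by
  orthogonalizing the residual components within each stratum — the
  right mode for a deterministic demonstration at a prescribed effect
  size, and the one the default demo configuration uses.

Matching fixtures: an annotation catalog whose planted co-term (level
> 6) contains X, Y and — by default — Z, on the view that a switch gene
shares its targets' biological process, plus random filler terms; and a
Poisson read-count table with mean `expression·length·library/1e9`, so
RPKM re-normalization is a round trip (this requires the cohort on its
non-negative `lognormal` output scale; the default `gaussian` scale is
already "post-transform").

What the generator does **not** emulate: read-level sequencing noise,
batch or library-preparation artifacts, heavy-tailed or zero-inflated
expression, realistic gene–gene covariance beyond the single shared
factor, or group differences in any background gene. Passing tests
therefore demonstrate the statistical machinery under the assumed
structure, not robustness to everything real RNA-seq exhibits.

## Problem sizes and numerical choices

The default demonstration configuration screens a 20-gene cohort
(3,420 triplets) with one planted triplet at the default effect, B=1999
permutations, and the empirical effect mode. The size was set by a
power analysis: with ~103 samples a paper-strength effect gives
|MLA| ≈ 0.49 against a null SD ≈ 0.09 (a ~5.5 SD effect), which clears
the Bonferroni-adjusted 0.001 threshold with a family of a few thousand
triplets but cannot under families of hundreds of thousands — a
desk-scale demonstration keeps the family commensurate with the effect.
Power and calibration tests run at 150 genes (1.65M triplets ranked by
|MLA|) across 50 cohorts.

Determinism: every stochastic step is seeded from one global seed via
hashed per-stage derivation; gene input order never affects results
(canonical pair ordering, stable ties); re-running any stage with the
same configuration reproduces its outputs byte for byte. Degenerate
inputs fail loudly: constant genes, zero-variance strata, empty filter
results, single-class labels and missing stage inputs each raise a
named error, and the CLI maps input errors to exit code 2 and empty
results to 3.

## Known limitations

* The pooled-SD normal p-value is anti-conservative for triplets whose
  pair scatter is strongly non-bivariate-normal (the planted kind);
  the conservative per-triplet variant is one flag away.
* Permutation and network p-values are exchangeability arguments; group
  structure that induces within-group correlation would violate them.
* The event-rate baseline assumes uniform switch assignment.
* Enrichment treats terms independently; no term grouping or ontology
  topology is used.
* The forest stage evaluates only the switch genes handed to it; it is
  a ranking device, not a tuned classifier.
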