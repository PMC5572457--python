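# Methods

This note documents the statistical methods implemented in `chemtrans`, the
default parameters and why they were chosen, what the synthetic generator
does and does not emulate, and the numerical conventions used throughout.

## Ranked-list algebra

A transcriptional profile is a total ordering of a fixed gene universe:
rank 1 is the most up-regulated gene, rank *n* the most down-regulated.
Working with orderings rather than expression values makes profiles
comparable across platforms and normalizations.

* **Spearman footrule** `footrule_distance`: the L1 distance between rank
  vectors, a metric on permutations; 0 iff identical, n²/2 (even *n*) for a
  reversal.
* **Borda merge** `borda_merge`: sum per-gene ranks across two lists and
  re-rank ascending. Rank-sum ties are broken by lexicographic gene
  identifier, which makes the merge deterministic and symmetric in its
  inputs.
* **Prototype ranked list (PRL)** `build_prl`: hierarchically merge
  replicate profiles, always merging the pair of surviving lists with the
  smallest footrule distance (ties resolved on the lexicographically
  smallest id pair). This "closest pair first" agglomeration lets
  concordant replicates dominate the consensus while outlier replicates are
  folded in last. Consequence worth knowing: the last-merged outlier still
  receives ~50% weight in the final Borda step regardless of how many
  concordant replicates preceded it, so one discordant replicate noticeably
  dilutes a consensus — this is a property of the published aggregation
  scheme, not a bug.

## Enrichment score and transcriptional distance

* **KS/GSEA enrichment score** `enrichment_score`: walk the ranking,
  adding 1/|S| at each gene-set hit and subtracting 1/(n−|S|) at each miss;
  the score is the signed deviation of maximal absolute value, in [−1, 1].
  The implementation evaluates the running sum analytically at hit
  boundaries (O(|S|) after sorting) instead of walking all *n* ranks; tests
  verify equality with a literal brute-force walk. When several points tie
  in |value| the extremum reached earliest in the ranking wins, matching a
  left-to-right walk with a strict "greater" update; a 1e-12 tolerance in
  the arg-max collapses float-rounding noise between mathematically equal
  ties (distinct extrema differ by at least 1/(|S|(n−|S|))).
* **Transcriptional distance** `transcriptional_distance`: for profiles *a*
  and *b*, enrich the top-*p* and bottom-*p* genes of *b* in *a*:
  TES(a|b) = 1 − (ES_up − ES_down)/2, then symmetrize by averaging both
  directions. Range [0, 2]: 0 for identical rankings, ≈1 for unrelated
  ones, 2 for a reversal.
* **p (top/bottom window)**: defaults to `max(1, min(250, n // 10))` — 250
  genes at genome scale, scaled down for small universes so that 2p ≤ n
  always holds.
* **Similarity threshold 0.8**: distances below 0.8 are called
  "transcriptionally similar" throughout (network edges, signature
  positives, quadrant axes). Under the null of unrelated rankings the
  distance concentrates near 1, so 0.8 is a conservative left-tail cut.

## Transcriptional variability (TV)

TV of a drug = median of the M(M−1)/2 pairwise transcriptional distances
among its M ≥ 2 replicates (for M = 2 this is the single distance). TV is
computed within one cell line; mixing lines is rejected unless explicitly
overridden, because distance scales are not comparable across cell types.
`partition_by_tv` splits a compendium at the median TV (or a fixed value);
values exactly at the threshold go to the high/weak side.

## Networks, communities, rich clubs

* **Structural distance**: pairwise 3D similarity scores S ∈ [0, 3] (sum of
  three per-probe similarities) become distances D = 1 − S/3.
* **Density thresholding**: keep the k = floor(density · C(n, 2)) closest
  pairs (default density 5%); the k-th pair's distance becomes the network
  threshold, and pairs tied with it are all included (with a warning).
* **Affinity propagation** is implemented in-package (vectorized
  responsibility/availability message passing) so that
  `sklearn.cluster.AffinityPropagation` can serve as an *independent*
  reference in tests. Defaults: preference = median off-diagonal
  similarity, damping 0.9, max 1000 iterations, 50 stable iterations for
  convergence, seeded 1e-12 jitter to break symmetric ties. Input is
  s = −D. After convergence each cluster's exemplar is refined to the
  member maximizing within-cluster similarity.
* **Communities** with more than `min_size` (default 3) members are flagged
  reportable (strict inequality). **Rich clubs** cluster the community
  exemplars' distance submatrix once more (depth 1 by default), grouping
  communities into coarser families.

## Enrichment statistics

* **ATC / community**: exact hypergeometric upper tail P(X ≥ k) over the
  universe of annotated drugs in communities, per (community, level-L ATC
  prefix) pair, BH-adjusted across all tests. ATC level boundaries follow
  the WHO format (1/3/4/5/7 characters for levels 1–5).
* **Descriptor / rich club**: drugs are ranked by descending descriptor
  value; the club's KS enrichment score is compared to ≥ 100 random member
  sets of the same size. Empirical p = (b + 1)/(R + 1), never exactly zero;
  BH across descriptors.
* **DSEA-lite**: member drugs' rankings are merged into one consensus
  ranking and each gene set is scored against it, with size-matched random
  gene sets as the null. This is a consensus-profile simplification of drug
  set enrichment analysis, not a reimplementation of the full method.

## Coherence, PPV, signature, classifier

* **Quadrants**: thresholds on the structural and transcriptional axes
  split drug pairs into quadrant I (structurally similar only), II (both),
  III (transcriptionally similar only), IV (neither). Boundary values count
  as "similar" (≤).
* **PPV benchmark**: pairs sorted ascending by distance; cumulative
  precision of "shares a level-4 ATC code". The TV-split benchmark runs
  this separately in the low-TV and high-TV halves with a mean-of-100-
  shuffles baseline and a pointwise 95% band.
* **Consensus signature**: `build_prl` over member drug PRLs; compendium
  drugs with distance strictly below 0.8 are signature-positive. Profiles
  can be stratified at 1 µM into LOW/HIGH concentration consensuses first.
* **Balanced random forest**: 500 trees, each grown on a bootstrap of
  minority-class size drawn from both classes (true per-tree downsampling —
  sklearn's `class_weight="balanced_subsample"` reweights instead of
  resampling, hence the hand-rolled bagging loop around
  `DecisionTreeClassifier`), `m_try` = 11 features per split (≈ √128).
  Out-of-bag error is the misclassification rate of majority-vote OOB
  predictions; importances are normalized mean decrease in impurity (or a
  direct permutation importance of the vote ensemble).

## Synthetic compendium generator

Latent Gaussian score model: gene *g* in replicate *r* of drug *d* (class
*c*) gets score ρ_d·z_c[g] + (1 − ρ_d)·ε_r[g] + λ·1{carrier, HIGH}·u[g],
ranked descending with ties broken by gene id; z_c is the class prototype,
ε_r fresh noise, u the indicator of the planted signature gene set.

Defaults, chosen once up front:

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 1000 | large enough for p = 100 top/bottom windows, small enough for second-scale tests |
| `n_classes` × `drugs_per_class` | 5 × 8 | several recoverable communities of realistic size |
| `replicates_per_drug` | 4 | median-based TV needs ≥ 2; 4 gives 6 pairs |
| `responsiveness` ρ | 0.8 | concordant but noisy replicates (TV ≈ 0.15, far from the 0.8 threshold); ρ = 0 yields uniform random permutations |
| `pld_fraction` | 0.25 | enough carriers for held-out signature evaluation |
| `pld_geneset_size` | 50 | typical pathway-size gene set |
| `signature_weight` λ | 2.0 | the planted stress response dominates the class component at high concentration, reflecting the premise that the off-target response partially masks mechanism-related transcription |
| `cad_fraction` | 0.30 | carriers are a subset of CAD-flagged drugs (planted physicochemical hypothesis) |
| `n_descriptors` | 128 | LogP, pKa, a 4-column CAD-correlated hydrophobicity family (CD3–CD6), rest standard-normal nuisance |
| `simulate_concentrations` | off | when on, 25% of replicates are LOW (0.1 µM) and skip the signature bump; the rest are HIGH (10 µM) |
| structural distances | 0.3 within / 0.7 between class, σ = 0.05 | classes are structurally tight and well separated under a 5% density threshold |
| ATC | one level-4 code per class, 10% of drugs get a second code | class recovery is testable, with annotation noise |

The CAD-correlated descriptor family exists for statistical realism:
descriptor suites contain blocks of correlated lipophilicity measures, and
with only two informative columns among 128, BH correction at R = 1000
permutations cannot reach q < 0.05 (the floor is (1/1001)·128/2 ≈ 0.064);
six informative columns make the planted LogP signal detectable — this is a
property of BH arithmetic, not tuning.

**What the generator emulates**: replicate concordance structure,
mechanism classes with shared transcriptional prototypes, a
concentration-gated off-target signature, CAD-shifted descriptor
distributions, class-correlated structural distances, ATC annotation with
noise, and deterministic seeding (identical configs give bit-identical
datasets).

**What it does not emulate**: real expression-value noise models
(everything is rank-level), probe-to-gene collapsing, multiple cell lines,
batch effects, dose-response curves beyond a binary LOW/HIGH split,
realistic chemical-similarity geometry (distances are class-block
constants plus noise), or realistic descriptor covariance beyond the one
planted family.

## Numerical conventions

* Ranks are 1-based; every ranking is validated as a bijection onto 1..n.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; derived streams use distinct seed offsets or `SeedSequence`
  spawns, and seeds stay below 2³¹.
* Empirical p-values use the (b + 1)/(R + 1) convention.
* Score ties in ranking construction are broken by gene identifier; pair
  ties in merging and thresholding are broken lexicographically — every
  pipeline output is deterministic given the seed.
* BH FDR comes from `statsmodels`, hypergeometric tails from
  `scipy.stats.hypergeom` (tested against exhaustive enumeration), PCA and
  decision trees from `scikit-learn`, graph components from `networkx`.

## Limitations

* The transcriptional distance is not a metric (no triangle-inequality
  guarantee) — it is used only for thresholding and ranking.
* Affinity propagation can fail to converge on adversarial similarity
  matrices; the implementation then warns and returns the current best
  labeling.
* The PRL merge order depends on footrule ties only through deterministic
  id ordering; different replicate id schemes can change tie resolution.
* DSEA-lite scores a single consensus ranking, not the per-drug ES matrix
  of the full published method.
* TV requires ≥ 2 replicates; drugs with a single profile are silently
  excluded from TV tables (by contract).
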