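# Methods

## Model

`hetpath` predicts domain–disease associations by supervised link
prediction on a five-layer heterogeneous network. All layers are binary:
an observed link is 1, an unobserved link 0. Any confidence column in an
input edge list (e.g. a PPI combined score) is used only for thresholding
at load time (`min_weight`, inclusive ≥); no weighted matrices are kept.
The P–P and S–S layers are symmetrized from either input orientation and
their diagonals are forced to zero — a protein's self-interaction or a
disease's similarity to itself would otherwise create degenerate walk
instances (e.g. a `DSS` count fed by the pair's own edge plus a
self-similarity hop). Node indices contain exactly the labels observed in
the inputs (plus any explicitly supplied universe); no global node counts
are assumed.

### Meta-path features

The feature for pair (d, s) under meta-path Π is the number of walks from
d to s whose node types follow Π, computed as the entry of the chain
product of adjacency matrices along Π. Walks may revisit nodes: that is
the matrix-product convention, and the brute-force oracle used in tests
counts with the same convention. Products accumulate in 64-bit integers,
which is exact for any network the package realistically handles (an
overflow would need ~10^18 walks for a single pair).

The registry of meta-paths is **hard-coded**, not enumerated: the curated
set of 37 schemes (identifiers C1–C27 for lengths 2–5, scheme strings for
length 6) is not the exhaustive set of schema-valid walks — `DSSS` or
`DSDS`, for example, are valid walks but not part of the canonical set —
so fidelity to the curated list wins over generation. `parse_metapath`
lets users define extras.

RW normalization divides each commuting-matrix row by its row sum over the
**full disease universe** (not just queried candidates); this is the only
reading consistent with a row-wise normalizer, and it makes the RW value
of a pair independent of which other pairs are being scored. Zero rows map
to zero (0/0 → 0), preserving boundedness in [0, 1].

Feature sets: counts for lengths ≤ 3 / ≤ 4 / ≤ 5 / ≤ 6 give TF1/TF2/TF3/TF4
(6, 17, 27, 37 columns); Feature-I = TF3; Feature-II appends the 27
RW columns to Feature-I (54 columns, count block first, so Feature-I is a
prefix of Feature-II). Implementations may compute single rows by
vector–chain products; tests require bit-identity with the full product.

### Labels, split, leakage control

Positives come from the single-domain transfer rule: (d, s) is positive iff
some protein contains exactly the domain d and is associated with s.
Negatives are drawn uniformly without replacement from the non-positive
pairs of the candidate universe — by default the domains and diseases that
appear in the positive set, which avoids negatives dominated by isolated
nodes; no degree matching is attempted. The split is stratified by label
with per-label training size round(train_fraction · n); at the reference
scale of 666 positives + 666 negatives and fraction 2/3 this yields
888 = 444+444 training and 444 = 222+222 test pairs.

Leakage control has two modes:

- **paper** (default, protocol fidelity): the test-positive D–S edges are
  removed from the network before any feature computation; training
  positives keep their edges. Deleting an absent edge is a no-op, which
  keeps split plumbing idempotent.
- **strict**: additionally, each evaluated pair's own D–S edge is masked
  during that pair's feature computation (implemented in
  `assemble_features(mask_pair_edge=True)` via vector–chain row products on
  a one-edge-edited network, since a per-pair mask cannot be expressed as a
  single returned network).

The paper mode is knowingly optimistic for ranking and *pessimistic* for
calibration: training positives see own-edge-driven features that test
positives cannot have, so held-out probabilities shift low and F1 at the
0.5 threshold collapses even while AUC stays high. The strict mode removes
the asymmetry; on the default synthetic conditions it reaches mean AUC
≈ 0.96 / F1 ≈ 0.93 (recomputed by `scripts/acceptance.py`, never asserted
as constants). Whether training-positive edges were removed in the original
protocol is not documented; both readings are offered with paper mode as
default.

### Classifier and evaluation

The primary model is XGBoost with six tunable hyperparameters
(n_estimators, max_depth, min_child_weight, gamma, colsample_bytree,
reg_alpha); the published grid ranges are unstated, so the defaults here
are small, desk-scale ranges (3·3·2·2·2·2 = 144 combinations), fully
user-overridable — the end-to-end helper defaults to a single combination
(n_estimators 300, max_depth 5) to keep repeated studies fast. Selection is
by mean validation AUC over stratified 3-fold CV, ties broken by
first-in-grid order; everything is reproducible from one integer seed.
Baselines (random forest, SVM with probability output, Gaussian naive
Bayes) use library defaults.

AUC is the trapezoidal area over the grouped-threshold ROC curve, so tied
scores receive half credit and the value equals the Mann–Whitney pairwise
statistic (a brute-force pairwise oracle verifies this in tests). F1 is
2TP/(2TP+FN+FP) at threshold 0.5 (the threshold is a free choice; 0.5 on
predicted probability is the neutral default), defined as 0 with a warning
when the denominator vanishes.

## Synthetic study conditions

There is no public generator for this problem, so the package defines one:
the minimal mechanism that produces guilt-by-association signal is a
cluster-structured block model. Diseases are partitioned into k clusters;
similarity edges are dense within clusters (p_similarity_in_cluster) and
sparse between (p_noise_edge). Each protein belongs to one cluster, links
diseases mostly within it (p_protein_disease_in_cluster inside,
p_noise_edge outside), interacts preferentially within its cluster, and
draws its domains from its cluster's domain pool with probability 0.8.
A protein is single-domain with probability single_domain_fraction,
otherwise it carries 2 + Poisson(mean_domains_per_protein − 2) domains.
The D–S reference layer is the transfer rule applied to the generated
network — these pairs are the planted truth — plus noise edges at
p_noise_edge/10.

Defaults (chosen once as a realistic, clearly clustered small study and
not revisited): 200 domains, 400 proteins, 60 diseases, 4 clusters,
single_domain_fraction 0.35, mean_domains_per_protein 2.0,
p_protein_disease_in_cluster 0.2, p_similarity_in_cluster 0.6,
p_noise_edge 0.03, ppi_density 0.05. A full study at these sizes runs in
about a second; the reference-arithmetic demonstration uses a larger draw
(300/1200/80) so that at least 666 positives are planted.

**Signal ablation.** A naive ablation — permuting disease clusters and
re-deriving labels from the transfer rule — cannot reduce performance to
chance, because any transfer-derived positive retains a `DPS` count ≥ 1
through its generating protein regardless of cluster structure. The
implemented control therefore decouples labels from the network: the
labeled pairs are frozen from the intact draw, while features are computed
on an independently generated network (derived seed, disease clusters
permuted before the cluster-dependent layers are drawn) whose D–S layer is
replaced by exactly the selected positive pairs (test edges then removed
as usual). Under this control the truth-consistency invariant of the
generator intentionally does not apply, and a sound pipeline scores at
AUC ≈ 0.5.

**What the generator does not emulate:** real degree distributions
(SCOP/PPI networks are heavy-tailed, the block model is not), similarity
scores (binary only), multi-cluster diseases, and database noise or
ascertainment bias. Passing the recovery test shows the pipeline extracts
planted relational signal under leakage control; it does not certify
real-data performance, and the published real-data AUC/F1 values are
deliberately out of scope here.

## Numerical and degenerate-case choices

- Counts are exact int64; RW in float64; RW row sums are exact to 1e-12.
- 0/0 → 0 for RW on unreachable domains.
- Duplicate input edges collapse; absent-edge deletion is a no-op.
- Empty pair lists yield zero-row tables with full headers.
- AUC with a single class raises; F1 with zero denominator returns 0 with
  a warning.
- Grid-search ties resolve to the earliest combination in grid order.
- All randomness (generator, negative sampling, split, CV shuffling,
  classifiers) flows through integer seeds.

## Known limitations

- The registry's selection rule for which schema walks count as canonical
  is opaque (inherited from the curated list); user-defined paths are
  possible but not auto-discovered.
- Strict-mode masking costs one vector-chain pass per edge-bearing pair;
  at desk scale this is seconds, but it scales linearly in pair count.
- The negative sampler is uniform; hard negatives (same-cluster
  non-associations) would give a more demanding benchmark.
- No identifier mapping or database download tooling is included; inputs
  must already be label-consistent TSVs.
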