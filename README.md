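# hetpath

Predicting associations between protein **structural domains** and
**diseases** from the topology of a heterogeneous biological network.

Domains are the conserved, independently folding units of proteins; when a
protein is implicated in a disease, one of its domains is often the
functional culprit. Direct domain–disease annotations are scarce — the only
reliable ones come from *single-domain* proteins, whose disease links
transfer unambiguously to their one domain. `hetpath` treats the problem as
link prediction on a five-layer heterogeneous information network and learns
to generalize those transferred associations to the rest of the domain
universe.

## The method

The network is G = (H, F) with node sets **D** (domains), **P** (proteins),
**S** (diseases) and five binary adjacency layers: domain–protein membership
(A<sub>DP</sub>), protein–protein interaction (A<sub>PP</sub>),
protein–disease association (A<sub>PS</sub>), disease–disease similarity
(A<sub>SS</sub>), and the domain–disease reference layer (A<sub>DS</sub>).
Reversed orientations are transposes.

A **meta-path** is a typed node sequence from domain to disease, e.g.
`DPSS` = domain → protein → disease → disease. Its **commuting matrix** is
the product of the adjacency matrices along the path,

&nbsp;&nbsp;&nbsp;&nbsp;M(DPSS) = A<sub>DP</sub> · A<sub>PS</sub> · A<sub>SS</sub>,

whose entry M<sub>ij</sub> counts the concrete path instances (walks) from
domain *i* to disease *j*. The package ships the canonical registry of 37
meta-paths — 2 of length 2, 4 of length 3, 11 of length 4, 10 of length 5,
and 10 of length 6. Counts are optionally **RW-normalized**:
RW<sub>ij</sub> = M<sub>ij</sub> / M<sub>i</sub>, with M<sub>i</sub> the row
sum over all diseases. The standard feature sets are **Feature-I** (27 raw
counts, lengths 2–5), **Feature-II** (27 counts + 27 RW values = 54
columns), and the cumulative length sets **TF1–TF4** (6/17/27/37 columns).

Per-pair feature vectors feed a gradient-boosted tree classifier (XGBoost;
random forest, SVM and naive Bayes as baselines) tuned by grid search with
stratified 3-fold cross-validation. Labels follow the reference protocol:
transferred single-domain positives, uniformly sampled 1:1 negatives, a
stratified 2/3–1/3 split, and **leakage control** — held-out positive edges
are removed from A<sub>DS</sub> before any feature is computed. Evaluation
reports the trapezoidal AUC (tied scores get half credit) and
F1 = 2TP / (2TP + FN + FP).

Because the real inputs are large curated databases, the package includes a
seedable **synthetic generator**: a cluster-structured block model over
diseases, proteins and domains that plants domain–disease signal through
the same single-domain transfer rule, so the entire pipeline is testable
offline.

## Worked example

```bash
python examples/end_to_end.py
```

prints (seed 1, default study conditions — 200 domains, 400 proteins,
60 diseases in 4 clusters):

```
paper-style leakage (test edges removed): AUC 0.930  F1 0.010
strict leakage (every pair's own edge masked): AUC 0.957  F1 0.923
signal ablation (labels decoupled from network): AUC 0.546
```

Reading the numbers: with the reference protocol (only *test* positive
edges removed) the classifier ranks held-out positives far above negatives
(AUC 0.93) but its probabilities are miscalibrated, because training
positives still feed on their own label edge — hence the collapsed F1 at
threshold 0.5. The strict mode masks every evaluated pair's own edge,
removing that train/test asymmetry: AUC 0.957 and F1 0.923. The ablation
control — identical labels, an independently generated network — scores at
chance, confirming the features carry real structure. The other examples
(`build_network.py`, `metapath_features.py`) walk through the network
format and the commuting-matrix arithmetic on hand-checkable toys.

The same pipeline is scriptable from the shell:

```bash
hetpath full --seed 1 --preset feature2 --out runs/demo
```

## Layout

- `src/hetpath/hetnet.py` — network construction, TSV I/O, adjacency queries
- `src/hetpath/metapath.py` — registry, commuting matrices, walk-count oracle
- `src/hetpath/features.py` — RW normalization, feature tables, presets
- `src/hetpath/dataset.py` — transfer rule, negatives, splits, leakage control
- `src/hetpath/model_eval.py` — grid-search training, AUC/F1/ROC/PR
- `src/hetpath/synthetic.py` — block-model generator with planted truth
- `src/hetpath/pipeline.py`, `src/hetpath/cli.py` — orchestration and CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
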