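"""Seedable synthetic heterogeneous networks with planted domain-disease signal.

The generator emulates the statistical structure that makes meta-path
features informative in real domain/protein/disease data — guilt by
association through shared proteins and similar diseases — using a
cluster-structured block model:

* diseases are partitioned into clusters; disease-disease similarity edges
  are dense within a cluster and sparse between clusters;
* each protein belongs to one cluster and is associated mostly with
  diseases of its own cluster;
* each domain has a home cluster; proteins draw their domains mostly from
  their own cluster's pool, so a domain's proteins concentrate in one
  disease neighbourhood;
* protein-protein interactions are denser within clusters;
* the domain-disease reference layer is produced by the single-domain
  transfer rule applied to the generated network (these pairs are the
  planted truth), plus a sprinkle of noise edges.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .dataset import (
    LabeledPairSet,
    Pair,
    SplitSpec,
    build_labeled_pairs,
    leakage_controlled_network,
    sample_negatives,
    train_test_split_pairs,
    transfer_single_domain_associations,
)
from .hetnet import (
    DISEASE,
    DOMAIN,
    PROTEIN,
    HeteroNetwork,
    NodeIndex,
    _binarize,
)


@dataclass
class SyntheticConfig:
    """Network sizes and block-model probabilities.

    Defaults describe a small study with clear within-cluster signal:
    four disease clusters, about a third of proteins single-domain (the
    carriers of transferable associations), and low cross-cluster noise.
    """

    n_domains: int = 200
    n_proteins: int = 400
    n_diseases: int = 60
    n_disease_clusters: int = 4
    single_domain_fraction: float = 0.35
    mean_domains_per_protein: float = 2.0
    p_protein_disease_in_cluster: float = 0.2
    p_similarity_in_cluster: float = 0.6
    p_noise_edge: float = 0.03
    ppi_density: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_disease_clusters > self.n_diseases:
            raise ValueError("more disease clusters than diseases")
        if self.n_disease_clusters < 1:
            raise ValueError("need at least one disease cluster")
        for name in (
            "single_domain_fraction",
            "p_protein_disease_in_cluster",
            "p_similarity_in_cluster",
            "p_noise_edge",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_domains_per_protein < 1.0:
            raise ValueError("mean_domains_per_protein must be >= 1")


@dataclass
class SyntheticTruth:
    """Planted positives plus the generation bookkeeping."""

    planted_pairs: list[Pair]
    disease_clusters: dict[str, int]
    protein_clusters: dict[str, int]
    domain_clusters: dict[str, int]
    log: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("domain_id,disease_id\n")
            for d, s in self.planted_pairs:
                fh.write(f"{d},{s}\n")


def _labels(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _block_pairs(
    rng: np.random.Generator,
    groups_a: np.ndarray,
    groups_b: np.ndarray,
    p_same: float,
    p_diff: float,
    symmetric: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample edges of a (possibly rectangular) stochastic block model."""
    same = groups_a[:, None] == groups_b[None, :]
    probs = np.where(same, p_same, p_diff)
    draws = rng.random(probs.shape) < probs
    if symmetric:
        draws = np.triu(draws, k=1)
    rows, cols = np.nonzero(draws)
    return rows, cols


def generate_network(
    config: SyntheticConfig,
    permute_disease_clusters: bool = False,
) -> tuple[HeteroNetwork, SyntheticTruth]:
    """Draw one network and its planted truth from the block model.

    The planted positives are exactly the output of the single-domain
    transfer rule on the generated domain-protein and protein-disease
    layers; the D-S layer contains them plus noise edges.

    ``permute_disease_clusters`` randomly permutes the disease -> cluster
    assignment before any cluster-dependent layer is drawn; used by signal
    ablation experiments.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_disease_clusters
    dom_labels = _labels("D", config.n_domains)
    prot_labels = _labels("P", config.n_proteins)
    dis_labels = _labels("S", config.n_diseases)

    dis_cluster = np.array(
        [i * k // config.n_diseases for i in range(config.n_diseases)]
    )
    if permute_disease_clusters:
        dis_cluster = dis_cluster[rng.permutation(config.n_diseases)]
    dom_cluster = np.array(
        [i * k // config.n_domains for i in range(config.n_domains)]
    )
    prot_cluster = rng.integers(k, size=config.n_proteins)

    # S-S similarity: dense within clusters, sparse between
    ss_r, ss_c = _block_pairs(
        rng, dis_cluster, dis_cluster,
        config.p_similarity_in_cluster, config.p_noise_edge, symmetric=True,
    )

    # domain membership: single-domain proteins carry the transferable signal
    domains_by_cluster = [np.flatnonzero(dom_cluster == c) for c in range(k)]
    dp_r: list[int] = []
    dp_c: list[int] = []
    n_single = 0
    for p in range(config.n_proteins):
        if rng.random() < config.single_domain_fraction:
            n_dom = 1
            n_single += 1
        else:
            n_dom = 2 + rng.poisson(max(config.mean_domains_per_protein - 2.0, 0.0))
        pool = domains_by_cluster[prot_cluster[p]]
        chosen: set[int] = set()
        while len(chosen) < n_dom:
            if rng.random() < 0.8 and len(pool):
                d = int(pool[rng.integers(len(pool))])
            else:
                d = int(rng.integers(config.n_domains))
            chosen.add(d)
        for d in sorted(chosen):
            dp_r.append(d)
            dp_c.append(p)

    # P-S associations: mostly within the protein's cluster
    ps_r, ps_c = _block_pairs(
        rng, prot_cluster, dis_cluster,
        config.p_protein_disease_in_cluster, config.p_noise_edge, symmetric=False,
    )

    # P-P interactions: denser within clusters, thinner across
    pp_r, pp_c = _block_pairs(
        rng, prot_cluster, prot_cluster,
        min(1.0, 3.0 * config.ppi_density), config.ppi_density / 3.0,
        symmetric=True,
    )

    def build(rows, cols, shape, symmetric=False):
        mat = sp.coo_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=shape
        ).tocsr()
        if symmetric:
            mat = mat + mat.T
            mat.setdiag(0)
        return _binarize(mat)

    indices = {
        DOMAIN: NodeIndex.from_labels(DOMAIN, dom_labels),
        PROTEIN: NodeIndex.from_labels(PROTEIN, prot_labels),
        DISEASE: NodeIndex.from_labels(DISEASE, dis_labels),
    }
    adj = {
        (DOMAIN, PROTEIN): build(dp_r, dp_c, (config.n_domains, config.n_proteins)),
        (PROTEIN, PROTEIN): build(pp_r, pp_c, (config.n_proteins,) * 2, symmetric=True),
        (PROTEIN, DISEASE): build(ps_r, ps_c, (config.n_proteins, config.n_diseases)),
        (DISEASE, DISEASE): build(ss_r, ss_c, (config.n_diseases,) * 2, symmetric=True),
        (DOMAIN, DISEASE): sp.csr_matrix(
            (config.n_domains, config.n_diseases), dtype=np.int8
        ),
    }
    network = HeteroNetwork(indices, adj)

    planted = transfer_single_domain_associations(network)

    # D-S reference layer: planted pairs plus a sprinkle of noise edges
    dom_pos = indices[DOMAIN].position
    dis_pos = indices[DISEASE].position
    ds_rows = [dom_pos[d] for d, _ in planted]
    ds_cols = [dis_pos[s] for _, s in planted]
    n_noise = rng.binomial(
        config.n_domains * config.n_diseases, config.p_noise_edge / 10.0
    )
    planted_set = set(zip(ds_rows, ds_cols))
    for _ in range(int(n_noise)):
        i = int(rng.integers(config.n_domains))
        j = int(rng.integers(config.n_diseases))
        if (i, j) not in planted_set:
            ds_rows.append(i)
            ds_cols.append(j)
    adj[(DOMAIN, DISEASE)] = build(
        ds_rows, ds_cols, (config.n_domains, config.n_diseases)
    )

    truth = SyntheticTruth(
        planted_pairs=planted,
        disease_clusters={dis_labels[i]: int(c) for i, c in enumerate(dis_cluster)},
        protein_clusters={prot_labels[i]: int(c) for i, c in enumerate(prot_cluster)},
        domain_clusters={dom_labels[i]: int(c) for i, c in enumerate(dom_cluster)},
        log={
            "seed": config.seed,
            "n_single_domain_proteins": n_single,
            "n_planted_pairs": len(planted),
            "n_noise_ds_edges": int(adj[(DOMAIN, DISEASE)].nnz - len(planted)),
            "permuted_disease_clusters": permute_disease_clusters,
        },
    )
    return network, truth


@dataclass
class StudyBundle:
    """Everything one end-to-end experiment needs."""

    network: HeteroNetwork           # leakage-controlled (test edges removed)
    raw_network: HeteroNetwork       # as generated
    truth: SyntheticTruth
    pairs: LabeledPairSet            # all labeled pairs with split tags
    train: LabeledPairSet
    test: LabeledPairSet
    config: SyntheticConfig
    split: SplitSpec


def generate_study(
    config: SyntheticConfig,
    n_positives: int | None = None,
    split: SplitSpec | None = None,
    mask_mode: str = "paper",
    ablate_signal: bool = False,
) -> StudyBundle:
    """One call from config to a complete labeled, leakage-controlled study.

    Subsamples ``n_positives`` planted pairs (all of them when ``None``),
    samples 1:`negative_ratio` negatives from the non-positive universe of
    domains and diseases appearing in the positives, splits stratified by
    label, and removes the test-positive D-S edges from the network.

    ``ablate_signal=True`` is the negative control: the labeled pairs are
    kept from the intact draw, but features will be computed on an
    independently generated network whose disease clusters were permuted
    before the cluster-dependent layers were drawn, and whose D-S layer is
    replaced by the selected positive pairs.  Labels are then independent
    of the network's association structure, so a sound pipeline should
    score at chance.
    """
    split = split or SplitSpec(seed=config.seed)
    network, truth = generate_network(config)
    planted = truth.planted_pairs
    if n_positives is None:
        n_positives = len(planted)
    if n_positives > len(planted):
        raise ValueError(
            f"requested {n_positives} positives but only {len(planted)} were planted"
        )
    rng = np.random.default_rng(split.seed + 1)
    if n_positives < len(planted):
        keep = np.sort(rng.choice(len(planted), size=n_positives, replace=False))
        positives = [planted[int(i)] for i in keep]
    else:
        positives = list(planted)

    candidate_domains = sorted({d for d, _ in positives})
    candidate_diseases = sorted({s for _, s in positives})
    negatives = sample_negatives(
        positives, candidate_domains, candidate_diseases,
        ratio=split.negative_ratio, seed=split.seed + 2,
    )
    pairs = build_labeled_pairs(positives, negatives)
    train, test = train_test_split_pairs(pairs, split)

    raw = network
    if ablate_signal:
        ablated_cfg = replace(config, seed=config.seed + 10_000)
        raw, _ = generate_network(ablated_cfg, permute_disease_clusters=True)
        dom_pos = raw.indices[DOMAIN].position
        dis_pos = raw.indices[DISEASE].position
        rows = [dom_pos[d] for d, _ in positives]
        cols = [dis_pos[s] for _, s in positives]
        ds = sp.coo_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)),
            shape=(len(dom_pos), len(dis_pos)),
        )
        raw = HeteroNetwork(raw.indices, dict(raw.adj))
        raw.adj[(DOMAIN, DISEASE)] = _binarize(ds.tocsr())

    controlled = leakage_controlled_network(raw, test.positives(), mask_mode)
    tagged = LabeledPairSet(train.entries + test.entries)
    return StudyBundle(
        network=controlled,
        raw_network=raw,
        truth=truth,
        pairs=tagged,
        train=train,
        test=test,
        config=config,
        split=split,
    )


def write_study(bundle: StudyBundle, out_dir: str | Path) -> None:
    """Materialize a study as the TSV/CSV/JSON fixture directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.raw_network.to_directory(
        out / "network",
        build_options={"synthetic_seed": bundle.config.seed},
    )
    bundle.truth.to_csv(out / "truth.csv")
    bundle.pairs.to_csv(out / "pairs.csv")
    meta = {
        "config": {k: getattr(bundle.config, k) for k in vars(bundle.config)},
        "split": {
            "seed": bundle.split.seed,
            "train_fraction": bundle.split.train_fraction,
            "negative_ratio": bundle.split.negative_ratio,
        },
        "generation_log": bundle.truth.log,
    }
    (out / "study.json").write_text(json.dumps(meta, indent=1))
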