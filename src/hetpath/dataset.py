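"""Labeled pair construction, splits, and leakage control.

Positive (domain, disease) pairs come from the single-domain transfer rule:
a protein composed of exactly one structural domain carries its disease
associations over to that domain.  Negatives are sampled uniformly from
non-positive pairs at a configurable ratio (1:1 by default).  The train/test
split is stratified by label with a 2/3-1/3 default, and the held-out
positive links are removed from the network before features are computed so
a test pair's label edge cannot feed its own features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .hetnet import DISEASE, DOMAIN, PROTEIN, HeteroNetwork

Pair = tuple[str, str]


@dataclass(frozen=True)
class LabeledPair:
    domain: str
    disease: str
    label: int           # 1 = associated, 0 = not
    origin: str          # "transferred" or "sampled"
    split: str = "none"  # "train", "test" or "none"


@dataclass
class LabeledPairSet:
    """A set of labeled (domain, disease) pairs with provenance.

    Invariants: no (domain, disease) pair appears twice, and all sampled
    entries carry label 0.
    """

    entries: list[LabeledPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[Pair] = set()
        for e in self.entries:
            key = (e.domain, e.disease)
            if key in seen:
                raise ValueError(f"pair {key} appears twice")
            seen.add(key)
            if e.origin == "sampled" and e.label != 0:
                raise ValueError(f"sampled pair {key} must have label 0")

    def __len__(self) -> int:
        return len(self.entries)

    def pairs(self) -> list[Pair]:
        return [(e.domain, e.disease) for e in self.entries]

    def labels(self) -> np.ndarray:
        return np.array([e.label for e in self.entries], dtype=np.int64)

    def positives(self) -> list[Pair]:
        return [(e.domain, e.disease) for e in self.entries if e.label == 1]

    def subset(self, split: str) -> "LabeledPairSet":
        return LabeledPairSet([e for e in self.entries if e.split == split])

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.domain, e.disease, e.label, e.origin, e.split) for e in self.entries],
            columns=["domain_id", "disease_id", "label", "origin", "split"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabeledPairSet":
        frame = pd.read_csv(path, dtype={"domain_id": str, "disease_id": str})
        return cls(
            [
                LabeledPair(r.domain_id, r.disease_id, int(r.label), r.origin, r.split)
                for r in frame.itertuples()
            ]
        )


@dataclass
class SplitSpec:
    """Stratified split parameters: 2/3 train, 1:1 negatives by default."""

    train_fraction: float = 2.0 / 3.0
    negative_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.negative_ratio <= 0:
            raise ValueError("negative_ratio must be positive")


def transfer_single_domain_associations(network: HeteroNetwork) -> list[Pair]:
    """Positive pairs via the single-domain transfer rule.

    A pair (d, s) is emitted iff some protein contains exactly domain d and
    nothing else, and that protein is associated with disease s.  Duplicates
    (several single-domain proteins supporting the same pair) are collapsed;
    output is ordered by (domain, disease) index.
    """
    dp = network.adj[(DOMAIN, PROTEIN)].tocsc()
    ps = network.adj[(PROTEIN, DISEASE)].tocsr()
    domains_per_protein = np.diff(dp.indptr)
    single = np.flatnonzero(domains_per_protein == 1)
    dom_labels = network.indices[DOMAIN].labels
    dis_labels = network.indices[DISEASE].labels
    found: set[tuple[int, int]] = set()
    for p in single:
        d = int(dp.indices[dp.indptr[p]])
        for s in ps.indices[ps.indptr[p]:ps.indptr[p + 1]]:
            found.add((d, int(s)))
    return [(dom_labels[d], dis_labels[s]) for d, s in sorted(found)]


def sample_negatives(
    positives: Sequence[Pair],
    domains: Sequence[str],
    diseases: Sequence[str],
    ratio: float = 1.0,
    seed: int = 0,
) -> list[Pair]:
    """Uniform sample of non-positive pairs from domains x diseases.

    Returns round(ratio * |positives|) pairs without replacement, none of
    which is positive; deterministic for a given seed.
    """
    n_needed = int(round(ratio * len(positives)))
    domains = list(dict.fromkeys(domains))
    diseases = list(dict.fromkeys(diseases))
    universe = len(domains) * len(diseases)
    pos_set = set(positives)
    dom_set, dis_set = set(domains), set(diseases)
    n_available = universe - sum(
        1 for d, s in pos_set if d in dom_set and s in dis_set
    )
    if n_needed > n_available:
        raise ValueError(
            f"not enough non-positive pairs: need {n_needed}, have {n_available}"
        )
    rng = np.random.default_rng(seed)
    chosen: list[Pair] = []
    taken: set[Pair] = set()
    # rejection sampling; falls back to full enumeration if the universe is tight
    max_tries = 50 * max(n_needed, 1)
    tries = 0
    while len(chosen) < n_needed and tries < max_tries:
        tries += 1
        d = domains[int(rng.integers(len(domains)))]
        s = diseases[int(rng.integers(len(diseases)))]
        pair = (d, s)
        if pair in pos_set or pair in taken:
            continue
        taken.add(pair)
        chosen.append(pair)
    if len(chosen) < n_needed:
        remaining = [
            (d, s)
            for d in domains
            for s in diseases
            if (d, s) not in pos_set and (d, s) not in taken
        ]
        idx = rng.choice(len(remaining), size=n_needed - len(chosen), replace=False)
        chosen.extend(remaining[int(i)] for i in idx)
    return chosen


def build_labeled_pairs(
    positives: Sequence[Pair], negatives: Sequence[Pair]
) -> LabeledPairSet:
    entries = [LabeledPair(d, s, 1, "transferred") for d, s in positives]
    entries += [LabeledPair(d, s, 0, "sampled") for d, s in negatives]
    return LabeledPairSet(entries)


def train_test_split_pairs(
    pairs: LabeledPairSet, spec: SplitSpec
) -> tuple[LabeledPairSet, LabeledPairSet]:
    """Label-stratified split: per label, round(train_fraction * n) to train.

    With 666 positives and 666 negatives at 2/3 this gives 444+444 training
    and 222+222 test pairs.  Deterministic for a given seed; outputs are
    disjoint and their union is the input.
    """
    rng = np.random.default_rng(spec.seed)
    train: list[LabeledPair] = []
    test: list[LabeledPair] = []
    for label in (1, 0):
        members = [e for e in pairs.entries if e.label == label]
        if len(members) < 2:
            raise ValueError(f"label {label} has fewer than 2 members; cannot split")
        n_train = int(round(spec.train_fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        order = rng.permutation(len(members))
        chosen = set(order[:n_train].tolist())
        for i, e in enumerate(members):
            tag = "train" if i in chosen else "test"
            (train if tag == "train" else test).append(
                LabeledPair(e.domain, e.disease, e.label, e.origin, tag)
            )
    return LabeledPairSet(train), LabeledPairSet(test)


def leakage_controlled_network(
    network: HeteroNetwork,
    test_positives: Iterable[Pair],
    mask_mode: str = "paper",
) -> HeteroNetwork:
    """Remove held-out positive D-S links before feature computation.

    ``mask_mode="paper"`` removes exactly the test-positive edges; training
    positives keep their edges.  ``"strict"`` removes the same edges here
    and additionally expects feature assembly to zero each evaluated pair's
    own D-S edge (``assemble_features(..., mask_pair_edge=True)``), closing
    the residual self-edge shortcut for training positives.
    """
    if mask_mode not in ("paper", "strict"):
        raise ValueError(f"unknown mask_mode {mask_mode!r}")
    return network.remove_domain_disease_edges(list(test_positives))


def split_metadata(
    train: LabeledPairSet, test: LabeledPairSet, spec: SplitSpec
) -> dict:
    return {
        "seed": spec.seed,
        "train_fraction": spec.train_fraction,
        "negative_ratio": spec.negative_ratio,
        "n_train": len(train),
        "n_test": len(test),
        "n_train_positive": int(train.labels().sum()),
        "n_test_positive": int(test.labels().sum()),
    }


def write_split_metadata(path: str | Path, meta: dict) -> None:
    Path(path).write_text(json.dumps(meta, indent=1))
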