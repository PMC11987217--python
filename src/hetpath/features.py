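"""Per-pair topological feature tables from commuting matrices.

Raw features are path-instance counts; the random-walk (RW) normalization
divides each count M_ij by its row sum M_i (the domain's total outgoing
path mass), turning counts into per-domain proportions in [0, 1].  Rows
whose sum is zero stay zero.  Two standard blocks are built from the
length-2..5 registry: Feature-I (27 raw counts) and Feature-II (27 counts +
27 RW values = 54 columns).  TF1..TF4 are the cumulative count sets for
maximum meta-path lengths 3, 4, 5 and 6 (6, 17, 27 and 37 columns).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .hetnet import DISEASE, DOMAIN, HeteroNetwork
from .metapath import (
    CommutingMatrix,
    MetaPathRegistry,
    canonical_registry,
    commuting_matrix,
    commuting_row,
)

#: preset name -> (max meta-path length, feature mode)
PRESETS: dict[str, tuple[int, str]] = {
    "Feature-I": (5, "counts"),
    "Feature-II": (5, "counts+rw"),
    "TF1": (3, "counts"),
    "TF2": (4, "counts"),
    "TF3": (5, "counts"),
    "TF4": (6, "counts"),
}

ID_COLUMNS = ("domain_id", "disease_id")


def rw_normalize(cm: CommutingMatrix) -> sp.csr_matrix:
    """Row-normalize a commuting matrix: entry M_ij becomes M_ij / M_i.

    Rows are domains; the sum runs over the full disease universe.  All-zero
    rows remain all-zero (0/0 -> 0), so every output entry lies in [0, 1].
    """
    mat = cm.matrix.tocsr().astype(np.float64)
    row_sums = np.asarray(mat.sum(axis=1)).ravel()
    scale = np.divide(
        1.0, row_sums, out=np.zeros_like(row_sums), where=row_sums > 0
    )
    return sp.diags(scale) @ mat


@dataclass
class FeatureTable:
    """Aligned (pair x feature) table with provenance metadata."""

    frame: pd.DataFrame
    feature_columns: list[str]
    feature_set_name: str = "custom"
    provenance: dict = field(default_factory=dict)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.frame["domain_id"], self.frame["disease_id"]))

    def values(self) -> np.ndarray:
        return self.frame[self.feature_columns].to_numpy(dtype=np.float64)

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        self.frame.to_csv(path, index=False)
        if sidecar:
            meta = {
                "feature_set_name": self.feature_set_name,
                "n_pairs": len(self.frame),
                "feature_columns": self.feature_columns,
                **self.provenance,
            }
            Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        frame = pd.read_csv(path, dtype={"domain_id": str, "disease_id": str})
        cols = [c for c in frame.columns if c not in ID_COLUMNS]
        name, prov = "custom", {}
        sidecar = Path(str(path) + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            name = meta.pop("feature_set_name", "custom")
            meta.pop("feature_columns", None)
            meta.pop("n_pairs", None)
            prov = meta
        return cls(frame, cols, name, prov)


def registry_hash(registry: MetaPathRegistry) -> str:
    return hashlib.sha256(registry.to_json().encode()).hexdigest()[:16]


def _pair_positions(
    network: HeteroNetwork, pairs: Sequence[tuple[str, str]]
) -> tuple[np.ndarray, np.ndarray]:
    dom_ix = network.indices[DOMAIN]
    dis_ix = network.indices[DISEASE]
    rows = np.empty(len(pairs), dtype=np.int64)
    cols = np.empty(len(pairs), dtype=np.int64)
    for k, (d, s) in enumerate(pairs):
        if d not in dom_ix or s not in dis_ix:
            raise KeyError(f"unknown label in pair ({d!r}, {s!r})")
        rows[k] = dom_ix.position[d]
        cols[k] = dis_ix.position[s]
    return rows, cols


def assemble_features(
    network: HeteroNetwork,
    pairs: Sequence[tuple[str, str]],
    registry: MetaPathRegistry,
    mode: str = "counts+rw",
    feature_set_name: str = "custom",
    mask_pair_edge: bool = False,
) -> FeatureTable:
    """Compute the feature table for a list of (domain, disease) pairs.

    ``mode="counts"`` yields one column per registry path; ``"counts+rw"``
    appends the RW-normalized block, so the count block is always a prefix.
    RW values are read from the row-normalized commuting matrix, i.e. the
    denominator sums over every disease, not just the queried pairs.

    With ``mask_pair_edge=True`` each pair whose own D-S edge is present is
    scored on a network with that single edge removed (strict leakage
    control); pairs without a direct edge are unaffected.
    """
    if mode not in ("counts", "counts+rw"):
        raise ValueError(f"unknown feature mode {mode!r}")
    rows, cols = _pair_positions(network, pairs)
    paths = registry.paths()
    count_block = np.zeros((len(pairs), len(paths)), dtype=np.float64)
    rw_block = np.zeros_like(count_block) if mode == "counts+rw" else None

    ds = network.adj[(DOMAIN, DISEASE)]
    if mask_pair_edge:
        has_edge = np.asarray(ds[rows, cols]).ravel() > 0 if len(pairs) else np.array([])
    for j, path in enumerate(paths):
        cm = commuting_matrix(network, path)
        count_block[:, j] = np.asarray(cm.matrix[rows, cols]).ravel()
        if rw_block is not None:
            rw = rw_normalize(cm)
            rw_block[:, j] = np.asarray(rw[rows, cols]).ravel()
    if mask_pair_edge and len(pairs) and has_edge.any():
        dom_labels = network.indices[DOMAIN].labels
        dis_labels = network.indices[DISEASE].labels
        for k in np.flatnonzero(has_edge):
            masked = network.remove_domain_disease_edges(
                [(dom_labels[rows[k]], dis_labels[cols[k]])]
            )
            for j, path in enumerate(paths):
                row_counts = commuting_row(masked, path, int(rows[k]))
                count_block[k, j] = row_counts[cols[k]]
                if rw_block is not None:
                    total = row_counts.sum()
                    rw_block[k, j] = row_counts[cols[k]] / total if total > 0 else 0.0

    names = [p.name for p in paths]
    columns = [f"{n}_count" for n in names]
    blocks = [count_block]
    if rw_block is not None:
        columns += [f"{n}_rw" for n in names]
        blocks.append(rw_block)
    data = np.hstack(blocks) if len(pairs) else np.zeros((0, len(columns)))
    frame = pd.DataFrame(data, columns=columns)
    frame.insert(0, "disease_id", [s for _, s in pairs])
    frame.insert(0, "domain_id", [d for d, _ in pairs])
    return FeatureTable(
        frame,
        columns,
        feature_set_name,
        provenance={"registry_hash": registry_hash(registry), "mode": mode},
    )


def feature_set(
    network: HeteroNetwork,
    pairs: Sequence[tuple[str, str]],
    preset: str,
    mask_pair_edge: bool = False,
) -> FeatureTable:
    """Build one of the named feature presets (Feature-I/II, TF1..TF4)."""
    if preset not in PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
        )
    max_length, mode = PRESETS[preset]
    registry = canonical_registry(max_length)
    table = assemble_features(
        network, pairs, registry, mode=mode,
        feature_set_name=preset, mask_pair_edge=mask_pair_edge,
    )
    return table
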