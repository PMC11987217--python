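"""Global heterogeneous information network over domains, proteins and diseases.

The network G = (H, F) has three node sets (structural domains D, proteins P,
diseases S) and five undirected link layers: domain-protein membership,
protein-protein interaction, protein-disease association, disease-disease
similarity, and the domain-disease reference associations.  Each layer is
stored as a binary sparse adjacency matrix in a fixed schema orientation;
the reverse orientation is the transpose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

DOMAIN = "domain"
PROTEIN = "protein"
DISEASE = "disease"

NODE_TYPES: tuple[str, ...] = (DOMAIN, PROTEIN, DISEASE)

#: schema edge types in their canonical (stored) orientation
EDGE_TYPES: tuple[tuple[str, str], ...] = (
    (DOMAIN, PROTEIN),
    (PROTEIN, PROTEIN),
    (PROTEIN, DISEASE),
    (DISEASE, DISEASE),
    (DOMAIN, DISEASE),
)

_EDGE_FILENAMES = {
    (DOMAIN, PROTEIN): "domain_protein.tsv",
    (PROTEIN, PROTEIN): "protein_protein.tsv",
    (PROTEIN, DISEASE): "protein_disease.tsv",
    (DISEASE, DISEASE): "disease_disease.tsv",
    (DOMAIN, DISEASE): "domain_disease.tsv",
}


class SchemaError(ValueError):
    """A node or edge type outside the domain/protein/disease schema."""


class EdgeParseError(ValueError):
    """A malformed line in an edge-list file."""


def canonical_edge_type(source_type: str, target_type: str) -> tuple[str, str]:
    """Map an (source, target) pair to the stored schema orientation.

    Raises :class:`SchemaError` for pairs with no schema edge type
    (the only invalid combination of the three node types is domain-domain).
    """
    for a, b in ((source_type, target_type), (target_type, source_type)):
        if (a, b) in _EDGE_FILENAMES:
            return (a, b)
    raise SchemaError(
        f"no edge type {source_type}-{target_type} in the domain/protein/disease schema"
    )


@dataclass
class NodeIndex:
    """Ordered label <-> position mapping for one node type."""

    node_type: str
    labels: list[str] = field(default_factory=list)
    position: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_labels(cls, node_type: str, labels: Iterable[str]) -> "NodeIndex":
        if node_type not in NODE_TYPES:
            raise SchemaError(f"unknown node type {node_type!r}")
        idx = cls(node_type)
        for lab in labels:
            idx.add(lab)
        return idx

    def add(self, label: str) -> int:
        pos = self.position.get(label)
        if pos is None:
            pos = len(self.labels)
            self.labels.append(label)
            self.position[label] = pos
        return pos

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.position


@dataclass
class EdgeTable:
    """Parsed edge list for one schema edge type.

    Records are (source_label, target_label, weight) triples; the weight is
    ``None`` when the file had only two columns.  Duplicate (source, target)
    pairs are removed at load time, keeping the first occurrence.
    """

    source_type: str
    target_type: str
    records: list[tuple[str, str, float | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        canonical_edge_type(self.source_type, self.target_type)

    def __len__(self) -> int:
        return len(self.records)


def load_edge_table(
    path: str | Path,
    source_type: str,
    target_type: str,
    min_weight: float | None = None,
) -> EdgeTable:
    """Read a two- or three-column TSV edge list.

    Lines starting with ``#`` are ignored.  When ``min_weight`` is given,
    rows whose weight is below it are dropped (the threshold is inclusive,
    mirroring confidence filters such as STRING's combined_score >= 400);
    rows without a weight column are kept.
    """
    table = EdgeTable(source_type, target_type)
    seen: set[tuple[str, str]] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise EdgeParseError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated columns, got {len(parts)}"
                )
            src, tgt = parts[0].strip(), parts[1].strip()
            if not src or not tgt:
                raise EdgeParseError(f"{path}:{lineno}: empty node identifier")
            weight: float | None = None
            if len(parts) == 3:
                try:
                    weight = float(parts[2])
                except ValueError as exc:
                    raise EdgeParseError(
                        f"{path}:{lineno}: weight column is not numeric: {parts[2]!r}"
                    ) from exc
            if min_weight is not None and weight is not None and weight < min_weight:
                continue
            key = (src, tgt)
            if key in seen:
                continue
            seen.add(key)
            table.records.append((src, tgt, weight))
    return table


@dataclass
class HeteroNetwork:
    """The five-layer heterogeneous network.

    ``indices`` maps node type to its :class:`NodeIndex`; ``adj`` maps each
    canonical edge type to a binary CSR matrix of shape |source| x |target|.
    Square layers (P-P, S-S) are symmetric with zero diagonal.
    """

    indices: dict[str, NodeIndex]
    adj: dict[tuple[str, str], sp.csr_matrix]

    def n_nodes(self, node_type: str) -> int:
        return len(self.indices[node_type])

    def adjacency(self, source_type: str, target_type: str) -> sp.csr_matrix:
        """Adjacency in the requested orientation (transpose for reversed).

        The returned matrix shares storage with the network and must not be
        mutated by callers.
        """
        key = canonical_edge_type(source_type, target_type)
        mat = self.adj[key]
        if key == (source_type, target_type):
            return mat
        return mat.T.tocsr()

    def copy(self) -> "HeteroNetwork":
        indices = {
            t: NodeIndex(t, list(ix.labels), dict(ix.position))
            for t, ix in self.indices.items()
        }
        return HeteroNetwork(indices, {k: m.copy() for k, m in self.adj.items()})

    def remove_domain_disease_edges(
        self, pairs: Sequence[tuple[str, str]]
    ) -> "HeteroNetwork":
        """Return a network whose D-S matrix has the listed entries zeroed.

        Pairs that are not currently edges are ignored (deletion is
        idempotent); unknown labels raise ``KeyError``.  All other layers are
        shared unchanged and the input network is not modified.
        """
        dom_ix = self.indices[DOMAIN]
        dis_ix = self.indices[DISEASE]
        rows, cols = [], []
        for d, s in pairs:
            if d not in dom_ix:
                raise KeyError(f"unknown domain label in pair ({d!r}, {s!r})")
            if s not in dis_ix:
                raise KeyError(f"unknown disease label in pair ({d!r}, {s!r})")
            rows.append(dom_ix.position[d])
            cols.append(dis_ix.position[s])
        new = HeteroNetwork(self.indices, dict(self.adj))
        if rows:
            ds = self.adj[(DOMAIN, DISEASE)].tolil(copy=True)
            ds[rows, cols] = 0
            new.adj[(DOMAIN, DISEASE)] = _binarize(ds.tocsr())
        return new

    def domain_disease_pairs(self) -> list[tuple[str, str]]:
        """All (domain_label, disease_label) edges in the D-S layer."""
        ds = self.adj[(DOMAIN, DISEASE)].tocoo()
        dom = self.indices[DOMAIN].labels
        dis = self.indices[DISEASE].labels
        order = np.lexsort((ds.col, ds.row))
        return [(dom[ds.row[k]], dis[ds.col[k]]) for k in order]

    # ---- serialization -------------------------------------------------

    def to_directory(self, path: str | Path, build_options: Mapping | None = None) -> None:
        """Write the five edge-list TSVs plus a JSON manifest.

        Square layers are written with each undirected edge once (row < col).
        The manifest records the full node label lists so that isolated nodes
        survive a round trip.
        """
        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        for key, fname in _EDGE_FILENAMES.items():
            src_t, tgt_t = key
            mat = self.adj[key].tocoo()
            src_labels = self.indices[src_t].labels
            tgt_labels = self.indices[tgt_t].labels
            with open(out / fname, "w", encoding="utf-8") as fh:
                fh.write(f"# {src_t}\t{tgt_t}\n")
                order = np.lexsort((mat.col, mat.row))
                for k in order:
                    i, j = int(mat.row[k]), int(mat.col[k])
                    if src_t == tgt_t and i > j:
                        continue
                    fh.write(f"{src_labels[i]}\t{tgt_labels[j]}\n")
        manifest = {
            "node_counts": {t: len(self.indices[t]) for t in NODE_TYPES},
            "edge_counts": {
                "-".join(k): int(self.adj[k].nnz) for k in _EDGE_FILENAMES
            },
            "node_labels": {t: self.indices[t].labels for t in NODE_TYPES},
            "build_options": dict(build_options or {}),
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def from_directory(cls, path: str | Path) -> "HeteroNetwork":
        src = Path(path)
        with open(src / "manifest.json", "r", encoding="utf-8") as fh:
            manifest = json.load(fh)
        tables = [
            load_edge_table(src / fname, key[0], key[1])
            for key, fname in _EDGE_FILENAMES.items()
        ]
        node_labels = {
            t: labs for t, labs in manifest.get("node_labels", {}).items()
        }
        return build_network(tables, node_labels=node_labels or None)


def _binarize(mat: sp.spmatrix) -> sp.csr_matrix:
    out = mat.tocsr()
    out.eliminate_zeros()
    out.data = np.ones_like(out.data, dtype=np.int8)
    return out


def build_network(
    edge_tables: Sequence[EdgeTable],
    node_labels: Mapping[str, Sequence[str]] | None = None,
) -> HeteroNetwork:
    """Assemble a :class:`HeteroNetwork` from one edge table per layer.

    Node indices are the union of labels seen, in first-appearance order
    (optionally pre-seeded through ``node_labels``).  P-P and S-S layers are
    symmetrized from either input orientation and their diagonals forced to
    zero; all matrices are binary.  A label used under two node types is a
    schema conflict.
    """
    by_type: dict[tuple[str, str], EdgeTable] = {}
    for table in edge_tables:
        key = canonical_edge_type(table.source_type, table.target_type)
        if key in by_type:
            raise SchemaError(f"duplicate edge table for layer {'-'.join(key)}")
        by_type[key] = table
    missing = [k for k in _EDGE_FILENAMES if k not in by_type and k != (DOMAIN, DISEASE)]
    if missing:
        names = ", ".join("-".join(k) for k in missing)
        raise SchemaError(f"missing edge tables for layers: {names}")

    indices = {t: NodeIndex(t) for t in NODE_TYPES}
    if node_labels:
        for t, labs in node_labels.items():
            for lab in labs:
                indices[t].add(lab)
    owner: dict[str, str] = {
        lab: t for t in NODE_TYPES for lab in indices[t].labels
    }

    def register(label: str, node_type: str) -> int:
        prev = owner.get(label)
        if prev is not None and prev != node_type:
            raise SchemaError(
                f"label {label!r} appears as both {prev} and {node_type}"
            )
        owner[label] = node_type
        return indices[node_type].add(label)

    # first pass: fix the node universe in first-appearance order
    for key in _EDGE_FILENAMES:
        table = by_type.get(key)
        if table is None:
            continue
        src_t, tgt_t = table.source_type, table.target_type
        for s, t, _w in table.records:
            register(s, src_t)
            register(t, tgt_t)

    adj: dict[tuple[str, str], sp.csr_matrix] = {}
    for key in _EDGE_FILENAMES:
        src_t, tgt_t = key
        n, m = len(indices[src_t]), len(indices[tgt_t])
        table = by_type.get(key)
        rows: list[int] = []
        cols: list[int] = []
        if table is not None:
            flip = (table.source_type, table.target_type) != key
            for s, t, _w in table.records:
                if flip:
                    s, t = t, s
                rows.append(indices[src_t].position[s])
                cols.append(indices[tgt_t].position[t])
        mat = sp.coo_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, m)
        ).tocsr()
        if src_t == tgt_t:
            mat = mat + mat.T
            mat.setdiag(0)
        adj[key] = _binarize(mat)
    return HeteroNetwork(indices, adj)
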