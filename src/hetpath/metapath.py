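"""Meta-paths and their commuting (path-count) matrices.

A meta-path is a typed node sequence from a structural domain to a disease,
written over the alphabet D (domain), P (protein), S (disease), e.g. "DPSS"
for domain -> protein -> disease -> disease.  Its commuting matrix is the
left-to-right product of the adjacency matrices along the edge sequence;
entry (i, j) counts the walks from domain i to disease j whose node types
follow the meta-path.  Walks may revisit nodes, matching the matrix-product
convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import scipy.sparse as sp

from .hetnet import DISEASE, DOMAIN, PROTEIN, HeteroNetwork, SchemaError, canonical_edge_type

_LETTER = {"D": DOMAIN, "P": PROTEIN, "S": DISEASE}

# The canonical list of meta-paths, hard-coded rather than enumerated:
# the selection of walks used as features is a curated set (some valid
# schema walks such as DSSS are deliberately absent), so the registry
# reproduces the curated tables verbatim.  C1..C27 cover lengths 2-5; the
# ten length-6 paths carry their scheme string as identifier.
_CANONICAL: tuple[tuple[str, str], ...] = (
    ("C1", "DPS"),
    ("C2", "DSS"),
    ("C3", "DPSS"),
    ("C4", "DPPS"),
    ("C5", "DSPS"),
    ("C6", "DPDS"),
    ("C7", "DPPSS"),
    ("C8", "DPSDS"),
    ("C9", "DPDSS"),
    ("C10", "DPSPS"),
    ("C11", "DSPPS"),
    ("C12", "DSPSS"),
    ("C13", "DSDPS"),
    ("C14", "DSPDS"),
    ("C15", "DSSDS"),
    ("C16", "DPPDS"),
    ("C17", "DSSPS"),
    ("C18", "DPPDSS"),
    ("C19", "DSSPPS"),
    ("C20", "DPPSDS"),
    ("C21", "DSSPDS"),
    ("C22", "DPDSPS"),
    ("C23", "DPPSPS"),
    ("C24", "DSDPDS"),
    ("C25", "DPSSDS"),
    ("C26", "DPSPPS"),
    ("C27", "DSPDSS"),
    ("DPPDSPS", "DPPDSPS"),
    ("DPPSPDS", "DPPSPDS"),
    ("DPPSDSS", "DPPSDSS"),
    ("DPDSPPS", "DPDSPPS"),
    ("DPSPPSS", "DPSPPSS"),
    ("DPSSPDS", "DPSSPDS"),
    ("DSPDSPS", "DSPDSPS"),
    ("DSDPSDS", "DSDPSDS"),
    ("DSSPPSS", "DSSPPSS"),
    ("DSSPDSS", "DSSPDSS"),
)


@dataclass(frozen=True)
class MetaPath:
    """A validated domain -> ... -> disease typed node sequence."""

    name: str
    node_sequence: tuple[str, ...]

    @property
    def length(self) -> int:
        """Number of edges (= number of adjacency matrices multiplied)."""
        return len(self.node_sequence) - 1

    def edge_sequence(self) -> list[tuple[str, str]]:
        seq = self.node_sequence
        return [(seq[k], seq[k + 1]) for k in range(len(seq) - 1)]

    def reversed(self) -> "MetaPath":
        """The disease -> ... -> domain mirror (for transpose identities)."""
        return MetaPath(self.name[::-1], tuple(reversed(self.node_sequence)))


def parse_metapath(name: str) -> MetaPath:
    """Parse and validate a meta-path scheme string such as "DPSS".

    The sequence must start at a domain, end at a disease, have length >= 2,
    and every consecutive letter pair must be a schema edge type (the only
    impossible pair is D-D).
    """
    if not name:
        raise ValueError("empty meta-path name")
    bad = set(name) - set("DPS")
    if bad:
        raise ValueError(f"meta-path {name!r}: letters must be D/P/S, got {sorted(bad)}")
    if name[0] != "D" or name[-1] != "S":
        raise ValueError(
            f"meta-path {name!r} must start at domain (D) and end at disease (S)"
        )
    seq = tuple(_LETTER[c] for c in name)
    if len(seq) < 3:
        raise ValueError(f"meta-path {name!r} must have length >= 2")
    for a, b in zip(seq, seq[1:]):
        try:
            canonical_edge_type(a, b)
        except SchemaError as exc:
            raise ValueError(f"meta-path {name!r}: no edge type D-D") from exc
    return MetaPath(name, seq)


@dataclass(frozen=True)
class RegisteredPath:
    id: str
    path: MetaPath


class MetaPathRegistry:
    """Ordered collection of the canonical meta-paths."""

    def __init__(self, entries: Sequence[RegisteredPath]):
        names = [e.path.name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("registry path names must be unique")
        self.entries: list[RegisteredPath] = list(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[RegisteredPath]:
        return iter(self.entries)

    def paths(self) -> list[MetaPath]:
        return [e.path for e in self.entries]

    def length_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for e in self.entries:
            counts[e.path.length] = counts.get(e.path.length, 0) + 1
        return counts

    def restrict(self, max_length: int) -> "MetaPathRegistry":
        return MetaPathRegistry(
            [e for e in self.entries if e.path.length <= max_length]
        )

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "id": e.id,
                    "name": e.path.name,
                    "node_sequence": list(e.path.node_sequence),
                    "length": e.path.length,
                }
                for e in self.entries
            ],
            indent=1,
        )


def canonical_registry(max_length: int = 5) -> MetaPathRegistry:
    """The canonical meta-path registry restricted to ``max_length``.

    Per-length counts are 2 (length 2), 4 (length 3), 11 (length 4),
    10 (length 5) and 10 (length 6): 27 paths at ``max_length=5``,
    37 at ``max_length=6``.
    """
    if not 2 <= max_length <= 6:
        raise ValueError(f"max_length must be in 2..6, got {max_length}")
    entries = []
    for pid, scheme in _CANONICAL:
        path = parse_metapath(scheme)
        if path.length <= max_length:
            entries.append(RegisteredPath(pid, path))
    return MetaPathRegistry(entries)


@dataclass
class CommutingMatrix:
    """Path-instance counts for one meta-path: |D| x |S| integer matrix."""

    meta_path: MetaPath
    matrix: sp.csr_matrix

    def to_coo_tsv(self, path, domain_labels: Sequence[str], disease_labels: Sequence[str]) -> None:
        coo = self.matrix.tocoo()
        order = np.lexsort((coo.col, coo.row))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# domain_id\tdisease_id\tcount\n")
            for k in order:
                fh.write(
                    f"{domain_labels[coo.row[k]]}\t{disease_labels[coo.col[k]]}\t{int(coo.data[k])}\n"
                )


def commuting_matrix(network: HeteroNetwork, path: MetaPath) -> CommutingMatrix:
    """Chain-multiply the adjacency matrices along ``path``.

    Accumulation is in 64-bit integers; counts are exact as long as no
    intermediate entry exceeds 2**63 - 1, which holds by a wide margin for
    networks of up to ~10^4 nodes per type and the registry's path lengths.
    """
    edges = path.edge_sequence()
    mat = network.adjacency(*edges[0]).astype(np.int64)
    for a, b in edges[1:]:
        mat = mat @ network.adjacency(a, b).astype(np.int64)
    return CommutingMatrix(path, sp.csr_matrix(mat))


def commuting_row(network: HeteroNetwork, path: MetaPath, domain_index: int) -> np.ndarray:
    """One domain's row of the commuting matrix via a vector-chain product.

    Bit-identical to the corresponding row of :func:`commuting_matrix` (same
    integer arithmetic, different association order), but avoids forming the
    full matrix — used when a single pair's features must be computed on a
    locally edited network.
    """
    edges = path.edge_sequence()
    first = network.adjacency(*edges[0]).astype(np.int64)
    vec = first[domain_index, :]
    for a, b in edges[1:]:
        vec = vec @ network.adjacency(a, b).astype(np.int64)
    return np.asarray(vec.todense()).ravel()


_BRUTE_FORCE_GUARD = 10**7


def _walk_budget(network: HeteroNetwork, path: MetaPath) -> int:
    budget = 1
    for t in path.node_sequence:
        budget *= max(1, network.n_nodes(t))
    return budget


def brute_force_commuting(network: HeteroNetwork, path: MetaPath) -> np.ndarray:
    """Exhaustive walk enumeration oracle for :func:`commuting_matrix`.

    Counts concrete walks by depth-first search over node neighbourhoods —
    no matrix products — so it serves as an independent check.  Nodes may
    repeat along a walk.  Refuses networks where the product of layer sizes
    exceeds 10^7.
    """
    if _walk_budget(network, path) > _BRUTE_FORCE_GUARD:
        raise ValueError("network too large for exhaustive walk enumeration")
    seq = path.node_sequence
    adjs = [network.adjacency(a, b) for a, b in path.edge_sequence()]
    n_dom = network.n_nodes(DOMAIN)
    n_dis = network.n_nodes(DISEASE)
    counts = np.zeros((n_dom, n_dis), dtype=np.int64)

    def dfs(step: int, node: int, start: int) -> None:
        if step == len(adjs):
            counts[start, node] += 1
            return
        row = adjs[step].getrow(node)
        for nxt in row.indices:
            dfs(step + 1, int(nxt), start)

    for d in range(n_dom):
        dfs(0, d, d)
    return counts


def brute_force_path_count(
    network: HeteroNetwork, path: MetaPath, domain_label: str, disease_label: str
) -> int:
    """Number of walks from one domain to one disease along ``path``.

    Explicit depth-first enumeration (see :func:`brute_force_commuting`);
    intended as a small-network oracle, guarded against blow-up.
    """
    if _walk_budget(network, path) > _BRUTE_FORCE_GUARD:
        raise ValueError("network too large for exhaustive walk enumeration")
    d = network.indices[DOMAIN].position[domain_label]
    s = network.indices[DISEASE].position[disease_label]
    adjs = [network.adjacency(a, b) for a, b in path.edge_sequence()]

    def dfs(step: int, node: int) -> int:
        if step == len(adjs):
            return 1 if node == s else 0
        row = adjs[step].getrow(node)
        return sum(dfs(step + 1, int(nxt)) for nxt in row.indices)

    return dfs(0, d)
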