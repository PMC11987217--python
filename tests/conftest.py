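import numpy as np
import pytest

from hetpath import DISEASE, DOMAIN, PROTEIN, EdgeTable, build_network


def make_network(dp=(), pp=(), ps=(), ss=(), ds=(), node_labels=None):
    """Build a HeteroNetwork from in-memory edge lists of label pairs."""
    tables = [
        EdgeTable(DOMAIN, PROTEIN, [(a, b, None) for a, b in dp]),
        EdgeTable(PROTEIN, PROTEIN, [(a, b, None) for a, b in pp]),
        EdgeTable(PROTEIN, DISEASE, [(a, b, None) for a, b in ps]),
        EdgeTable(DISEASE, DISEASE, [(a, b, None) for a, b in ss]),
        EdgeTable(DOMAIN, DISEASE, [(a, b, None) for a, b in ds]),
    ]
    return build_network(tables, node_labels=node_labels)


def random_network(rng: np.random.Generator, max_nodes=7, max_density=0.4):
    """A small random network for oracle cross-checks."""
    n_d = int(rng.integers(2, max_nodes + 1))
    n_p = int(rng.integers(2, max_nodes + 1))
    n_s = int(rng.integers(2, max_nodes + 1))
    doms = [f"d{i}" for i in range(n_d)]
    prots = [f"p{i}" for i in range(n_p)]
    diss = [f"s{i}" for i in range(n_s)]

    def pick(a_side, b_side, symmetric=False):
        dens = rng.uniform(0.05, max_density)
        edges = []
        for i, a in enumerate(a_side):
            for j, b in enumerate(b_side):
                if symmetric and j <= i:
                    continue
                if rng.random() < dens:
                    edges.append((a, b))
        return edges

    return make_network(
        dp=pick(doms, prots),
        pp=pick(prots, prots, symmetric=True),
        ps=pick(prots, diss),
        ss=pick(diss, diss, symmetric=True),
        ds=pick(doms, diss),
        node_labels={DOMAIN: doms, PROTEIN: prots, DISEASE: diss},
    )


@pytest.fixture
def toy_network():
    """Small hand-checkable network used across modules.

    d1 is in p1 (single-domain) and p2; d2 is in p2; p1-p2 interact;
    p1-s1 and p2-s2 are protein-disease links; s1-s2 are similar;
    (d1, s1) is a reference association.
    """
    return make_network(
        dp=[("d1", "p1"), ("d1", "p2"), ("d2", "p2")],
        pp=[("p1", "p2")],
        ps=[("p1", "s1"), ("p2", "s2")],
        ss=[("s1", "s2")],
        ds=[("d1", "s1")],
    )
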