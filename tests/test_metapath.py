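import numpy as np
import pytest

from hetpath import (
    DISEASE,
    DOMAIN,
    PROTEIN,
    brute_force_commuting,
    brute_force_path_count,
    canonical_registry,
    commuting_matrix,
    parse_metapath,
)
from hetpath.metapath import MetaPath, commuting_row

from conftest import make_network, random_network


class TestParseMetaPath:
    def test_dps_parses(self):
        path = parse_metapath("DPS")
        assert path.node_sequence == (DOMAIN, PROTEIN, DISEASE)
        assert path.length == 2

    @pytest.mark.parametrize(
        "name,msg",
        [
            ("DDS", "D-D"),
            ("SPD", "start at domain"),
            ("DP", "start at domain"),   # ends at protein
            ("DS", "length"),
            ("DXS", "letters"),
            ("", "empty"),
        ],
    )
    def test_invalid_names_rejected(self, name, msg):
        with pytest.raises(ValueError, match=msg):
            parse_metapath(name)

    def test_every_canonical_scheme_is_valid(self):
        for entry in canonical_registry(6):
            reparsed = parse_metapath(entry.path.name)
            assert reparsed == entry.path


class TestCanonicalRegistry:
    @pytest.mark.parametrize("max_length,expected", [(2, 2), (3, 6), (4, 17), (5, 27), (6, 37)])
    def test_cumulative_counts(self, max_length, expected):
        assert len(canonical_registry(max_length)) == expected

    def test_per_length_breakdown(self):
        counts = canonical_registry(6).length_counts()
        assert counts == {2: 2, 3: 4, 4: 11, 5: 10, 6: 10}

    def test_identifiers_and_order(self):
        reg = canonical_registry(5)
        assert [e.id for e in reg][:3] == ["C1", "C2", "C3"]
        assert [e.id for e in reg][-1] == "C27"
        names = [e.path.name for e in reg]
        assert len(set(names)) == len(names)

    @pytest.mark.parametrize("bad", [1, 7, 0])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            canonical_registry(bad)

    def test_json_export_round_trips_lengths(self):
        import json

        payload = json.loads(canonical_registry(6).to_json())
        assert len(payload) == 37
        assert all(p["length"] == len(p["name"]) - 1 for p in payload)


class TestCommutingMatrix:
    def test_empty_network_all_zero(self):
        net = make_network(node_labels={DOMAIN: ["d1"], PROTEIN: ["p1"], DISEASE: ["s1"]})
        for entry in canonical_registry(6):
            assert commuting_matrix(net, entry.path).matrix.nnz == 0

    def test_dpps_single_walk(self):
        # d1-p1, p1-p2, p2-s1: exactly one walk d1->p1->p2->s1
        net = make_network(dp=[("d1", "p1")], pp=[("p1", "p2")], ps=[("p2", "s1")])
        cm = commuting_matrix(net, parse_metapath("DPPS"))
        assert cm.matrix[0, 0] == 1
        assert brute_force_path_count(net, parse_metapath("DPPS"), "d1", "s1") == 1

    def test_dps_counts_two_instances(self):
        net = make_network(
            dp=[("d1", "p1"), ("d1", "p2")],
            ps=[("p1", "s1"), ("p2", "s1")],
        )
        cm = commuting_matrix(net, parse_metapath("DPS"))
        assert cm.matrix[0, 0] == 2
        assert brute_force_path_count(net, parse_metapath("DPS"), "d1", "s1") == 2

    def test_dpss_walk_through_similarity(self):
        net = make_network(dp=[("d1", "p1")], ps=[("p1", "s1")], ss=[("s1", "s2")])
        assert brute_force_path_count(net, parse_metapath("DPSS"), "d1", "s2") == 1
        cm = commuting_matrix(net, parse_metapath("DPSS"))
        i = net.indices[DISEASE].position
        assert cm.matrix[0, i["s2"]] == 1

    def test_extra_ps_edge_changes_nothing_without_ss_hop(self):
        base = dict(dp=[("d1", "p1")], ps=[("p1", "s1")], ss=[("s1", "s2")])
        with_extra = dict(base, ps=[("p1", "s1"), ("p1", "s2")])
        path = parse_metapath("DPSS")
        n0 = brute_force_path_count(make_network(**base), path, "d1", "s2")
        n1 = brute_force_path_count(make_network(**with_extra), path, "d1", "s2")
        # p1-s2 adds no DPSS walk to s2 unless an s2->s2 hop existed (diagonal is 0)
        assert n0 == n1 == 1

    def test_dss_self_similarity_contributes_nothing(self):
        # only D-S edge is (d1, s1); with zero S-S diagonal, DSS[d1, s1] = 0
        net = make_network(
            dp=[("d1", "p1")], ps=[("p1", "s1")],
            ss=[("s1", "s2")], ds=[("d1", "s1")],
        )
        cm = commuting_matrix(net, parse_metapath("DSS"))
        assert cm.matrix[0, 0] == 0
        i = net.indices[DISEASE].position
        assert cm.matrix[0, i["s2"]] == 1

    def test_entries_are_integer_typed(self, toy_network):
        cm = commuting_matrix(toy_network, parse_metapath("DPPSS"))
        assert cm.matrix.dtype == np.int64

    def test_associativity_of_chain_product(self):
        rng = np.random.default_rng(11)
        net = random_network(rng)
        for entry in canonical_registry(6):
            edges = entry.path.edge_sequence()
            left = net.adjacency(*edges[0]).astype(np.int64)
            for a, b in edges[1:]:
                left = left @ net.adjacency(a, b).astype(np.int64)
            right = net.adjacency(*edges[-1]).astype(np.int64)
            for a, b in reversed(edges[:-1]):
                right = net.adjacency(a, b).astype(np.int64) @ right
            assert (left != right).nnz == 0
            assert (commuting_matrix(net, entry.path).matrix != left).nnz == 0

    def test_reversed_path_gives_transpose(self):
        rng = np.random.default_rng(5)
        net = random_network(rng)
        for entry in canonical_registry(5):
            fwd = commuting_matrix(net, entry.path).matrix
            rev_path = entry.path.reversed()
            edges = rev_path.edge_sequence()
            rev = net.adjacency(*edges[0]).astype(np.int64)
            for a, b in edges[1:]:
                rev = rev @ net.adjacency(a, b).astype(np.int64)
            assert (fwd.T != rev).nnz == 0

    def test_adding_edge_never_decreases_counts(self):
        rng = np.random.default_rng(23)
        net = random_network(rng)
        doms = net.indices[DOMAIN].labels
        prots = net.indices[PROTEIN].labels
        bigger = make_network(
            dp=[*_pairs(net, DOMAIN, PROTEIN), (doms[0], prots[-1])],
            pp=_pairs(net, PROTEIN, PROTEIN),
            ps=_pairs(net, PROTEIN, DISEASE),
            ss=_pairs(net, DISEASE, DISEASE),
            ds=_pairs(net, DOMAIN, DISEASE),
            node_labels={t: net.indices[t].labels for t in net.indices},
        )
        for entry in canonical_registry(6):
            before = commuting_matrix(net, entry.path).matrix.toarray()
            after = commuting_matrix(bigger, entry.path).matrix.toarray()
            assert (after >= before).all()

    def test_row_strategy_matches_full_product(self):
        rng = np.random.default_rng(7)
        net = random_network(rng)
        for entry in canonical_registry(6):
            full = commuting_matrix(net, entry.path).matrix.toarray()
            for d in range(net.n_nodes(DOMAIN)):
                assert (commuting_row(net, entry.path, d) == full[d]).all()


def _pairs(net, src, tgt):
    mat = net.adj[(src, tgt)].tocoo()
    s_labels = net.indices[src].labels
    t_labels = net.indices[tgt].labels
    return [
        (s_labels[i], t_labels[j])
        for i, j in zip(mat.row, mat.col)
        if src != tgt or i < j
    ]


class TestBruteForceOracle:
    def test_empty_network_counts_zero(self):
        net = make_network(node_labels={DOMAIN: ["d1"], PROTEIN: ["p1"], DISEASE: ["s1"]})
        assert brute_force_path_count(net, parse_metapath("DPSS"), "d1", "s1") == 0

    def test_guard_refuses_huge_networks(self):
        labels = {
            DOMAIN: [f"d{i}" for i in range(200)],
            PROTEIN: [f"p{i}" for i in range(200)],
            DISEASE: [f"s{i}" for i in range(200)],
        }
        net = make_network(node_labels=labels)
        with pytest.raises(ValueError, match="too large"):
            brute_force_path_count(net, parse_metapath("DPPSS"), "d0", "s0")

    def test_matches_matrix_product_on_random_networks(self):
        # a smaller, faster version of the acceptance-level sweep
        rng = np.random.default_rng(2024)
        for _ in range(5):
            net = random_network(rng)
            for entry in canonical_registry(6):
                oracle = brute_force_commuting(net, entry.path)
                product = commuting_matrix(net, entry.path).matrix.toarray()
                np.testing.assert_array_equal(oracle, product)
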