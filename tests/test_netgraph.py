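"""Network model: validation, path counting, isomorphism, serialization."""

import pytest

from ploidynet import (
    build_beaded_chain,
    count_paths,
    from_enewick,
    from_json,
    isomorphic,
    normalize,
    realize_profile,
    reticulation_inventory,
    to_dot,
    to_enewick,
    to_json,
    validate,
)
from ploidynet.netgraph import Network, NetworkError, enumerate_root_leaf_paths
from ploidynet.fixtures import random_profile


def bead_with_leaf():
    return build_beaded_chain(1)


class TestValidate:
    def test_accepts_bead_with_leaf(self):
        assert validate(bead_with_leaf()).ok

    def test_accepts_single_vertex(self):
        assert validate(Network.single_vertex("a")).ok

    def test_accepts_fig2_realization(self, worked_networks):
        assert validate(worked_networks["fig2"]).ok

    def test_reports_bad_degree_vertex(self):
        net = bead_with_leaf()
        # force an in-2/out-2 vertex
        extra = net.add_vertex("z", label="x2")
        net.add_arc("h1", extra)
        rep = validate(net)
        assert not rep.ok
        assert any(rule == "vertex-degrees" for rule, _ in rep.violations)

    def test_reports_multiple_roots(self):
        net = bead_with_leaf()
        net.add_vertex("r2")
        net.add_arc("r2", "L1")
        assert any(r == "root-count" for r, _ in validate(net).violations)

    def test_reports_cycle(self):
        net = bead_with_leaf()
        del net.g.nodes["L1"]["label"]
        net.add_arc("L1", "t1")
        assert any(r == "cyclic" for r, _ in validate(net).violations)

    def test_triple_arc_refused_on_construction(self):
        net = bead_with_leaf()
        with pytest.raises(NetworkError):
            net.add_arc("t1", "h1")

    def test_reports_unlabelled_leaf(self):
        net = bead_with_leaf()
        del net.g.nodes["L1"]["label"]
        assert any(r == "leaf-unlabelled" for r, _ in validate(net).violations)


class TestCountPaths:
    def test_single_vertex(self):
        assert count_paths(Network.single_vertex("a")) == {"a": 1}

    def test_matches_brute_force_on_small_networks(self, worked_networks):
        for name, net in worked_networks.items():
            if len(net.g) <= 14:
                assert count_paths(net) == enumerate_root_leaf_paths(net), name

    def test_fig2_counts(self, worked_networks):
        assert count_paths(worked_networks["fig2"]) == {
            "x1": 7, "x2": 6, "x3": 6, "x4": 5,
        }

    def test_simple77_core_counts(self, worked_networks):
        assert count_paths(worked_networks["core_simple77"]) == {
            "x1": 77, "x2": 1, "x3": 1, "x4": 1,
        }

    def test_mul_network_sums_over_shared_labels(self):
        net = Network(mul=True)
        for v in "rab":
            net.add_vertex(v)
        net.g.nodes["a"]["label"] = "x"
        net.g.nodes["b"]["label"] = "x"
        net.add_arc("r", "a")
        net.add_arc("r", "b")
        assert count_paths(net) == {"x": 2}


class TestReticulationInventory:
    def test_single_bead(self):
        inv = reticulation_inventory(bead_with_leaf())
        assert inv == [("h1", True)]

    def test_arcrich_core(self, worked_networks):
        # 6 bead-chain reticulations + s2', s3', s4'; the root bead is
        # opened up by s_k, so 5 reticulations remain inside beads
        inv = reticulation_inventory(worked_networks["core77"])
        assert len(inv) == 9
        assert sum(in_bead for _, in_bead in inv) == 5

    def test_fig2_reticulations(self, worked_networks):
        inv = reticulation_inventory(worked_networks["fig2"])
        assert len(inv) == 5
        assert sum(in_bead for _, in_bead in inv) == 1


class TestENewick:
    def test_bead_round_trip(self):
        net = bead_with_leaf()
        text = to_enewick(net)
        assert text.count("#H1") == 2
        assert isomorphic(net, from_enewick(text))

    def test_worked_networks_round_trip(self, worked_networks):
        for name, net in worked_networks.items():
            again = from_enewick(to_enewick(net))
            assert isomorphic(net, again), name

    def test_seeded_realizations_round_trip(self):
        for seed in range(60):
            p = random_profile(1 + seed % 6, 60, 9000 + seed)
            net = realize_profile(p)
            assert isomorphic(net, from_enewick(to_enewick(net)))

    def test_canonical_output_is_deterministic(self, worked_networks):
        net = worked_networks["fig2"]
        assert to_enewick(net) == to_enewick(from_enewick(to_enewick(net)))

    def test_hybrid_used_once_is_error(self):
        with pytest.raises(NetworkError, match="referenced once"):
            from_enewick("((x1)#H1,x2);")

    def test_unbalanced_is_error(self):
        with pytest.raises(NetworkError):
            from_enewick("((x1,x2;")


class TestJson:
    def test_round_trip(self, worked_networks):
        net = worked_networks["weak63"]
        again = from_json(to_json(net))
        assert isomorphic(net, again)
        assert count_paths(again) == count_paths(net)


class TestIsomorphic:
    def test_relabelled_vertices_are_isomorphic(self, worked_networks):
        import networkx as nx

        net = worked_networks["fig2"]
        other = net.copy()
        other.g = nx.relabel_nodes(other.g, {v: f"z{i}" for i, v in enumerate(net.g)})
        assert isomorphic(net, other)

    def test_chain_lengths_differ(self):
        assert not isomorphic(build_beaded_chain(2), build_beaded_chain(3))

    def test_leaf_labels_matter(self):
        a = build_beaded_chain(1, "x1")
        b = build_beaded_chain(1, "x2")
        assert not isomorphic(a, b)


class TestDot:
    def test_renders_squares_and_ranks(self, worked_networks):
        from ploidynet import label_core
        from ploidynet.corenet import build_B

        B = build_B(normalize([77, 1, 1, 1]))
        stamps = label_core(B)
        dot = to_dot(B, stamps)
        assert dot.startswith("digraph")
        assert "shape=square" in dot
        assert "rank=same" in dot
        # the cross-arc partners share a rank group
        assert any("sk" in line and "h1" in line and "rank=same" in line
                   for line in dot.splitlines())

    def test_single_vertex(self):
        assert "digraph" in to_dot(Network.single_vertex("a"))
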