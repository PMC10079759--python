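"""Profile-space operations: splits, unzipping, tree-based, enumeration."""

import pytest

from ploidynet import (
    count_paths,
    distance_upper_bound,
    enumerate_realizations,
    is_tree_based,
    is_tree_child,
    isomorphic,
    normalize,
    orchard_status,
    realize_profile,
    simplification_sequence,
    split,
    unzip_to_multree,
    validate,
)
from ploidynet.cherries import OrchardStatus
from ploidynet.corenet import caterpillar
from ploidynet.netgraph import Network, NetworkError
from ploidynet.profiles import ProfileError
from ploidynet.fixtures import random_profile


class TestSplit:
    def test_split_conserves_counts_and_duplicates_the_label(self):
        net = realize_profile(normalize([2, 1, 1]))
        h = next(v for v in net.reticulations() if not net.is_bead_reticulation(v))
        out = split(net, h)
        assert out.mul
        assert count_paths(out) == {"x1": 2, "x2": 1, "x3": 1}
        x1_leaves = [v for v, lab in out.leaf_labels().items() if lab == "x1"]
        assert len(x1_leaves) == 2

    def test_split_refuses_beads(self, worked_networks):
        net = worked_networks["fig2"]
        bead_ret = next(v for v in net.reticulations() if net.is_bead_reticulation(v))
        with pytest.raises(NetworkError):
            split(net, bead_ret)

    def test_split_refuses_non_cut_arc(self):
        # in a stacked pair the upper reticulation's child arc is not a cut-arc
        nets = enumerate_realizations(normalize([3]), 2)
        found = False
        for net in nets:
            rets = set(net.reticulations())
            for h in rets:
                c = next(iter(net.g.successors(h)))
                if c in rets:
                    found = True
                    with pytest.raises(NetworkError):
                        split(net, h)
        assert found


class TestUnzip:
    def test_tree_input_unchanged(self):
        t = caterpillar(["a", "b", "c"])
        out, nsplits = unzip_to_multree(t)
        assert nsplits == 0
        assert isomorphic(t, out)

    def test_fig2_unzips_conserving_counts(self, worked_networks):
        net = worked_networks["fig2"]
        tree, nsplits = unzip_to_multree(net)
        assert nsplits == len(net.reticulations())
        assert tree.reticulations() == []
        assert count_paths(tree) == count_paths(net)

    def test_conservation_on_seeded_corpus(self):
        """Label-summed path counts are invariant under full unzipping."""
        for seed in range(200):
            p = random_profile(1 + seed % 6, 30, 8000 + seed)
            net = realize_profile(p)
            tree, nsplits = unzip_to_multree(net)
            assert nsplits == len(net.reticulations())
            assert count_paths(tree) == count_paths(net)
            assert tree.reticulations() == []


class TestDistanceUpperBound:
    def test_network_against_itself(self, worked_networks):
        net = worked_networks["weak63"]
        bound = distance_upper_bound(net, net)
        assert bound == 2 * len(net.reticulations())

    def test_plugged_metric_on_trees(self):
        t1 = caterpillar(["a", "b", "c"])
        t2 = caterpillar(["b", "a", "c"])
        assert distance_upper_bound(t1, t2, tree_distance=lambda x, y: 1) == 1

    def test_profile_mismatch_raises(self, worked_networks):
        with pytest.raises(NetworkError):
            distance_upper_bound(worked_networks["fig2"], worked_networks["weak63"])

    def test_two_realizations_of_one_profile_get_a_finite_bound(self):
        from ploidynet import build_B, naive_core

        p = normalize([5, 1, 1])
        n1 = realize_profile(p, core=build_B(p))
        n2 = realize_profile(p, core=naive_core(p))
        bound = distance_upper_bound(n1, n2, tree_distance=lambda x, y: 1)
        assert bound == len(n1.reticulations()) + len(n2.reticulations()) + 1


class TestTreeBased:
    def test_trees_are_their_own_base(self):
        t = caterpillar(["a", "b", "c"])
        ok, base = is_tree_based(t)
        assert ok and isomorphic(t, base)

    def test_simple77_realization_is_tree_based(self, worked_networks):
        ok, base = is_tree_based(worked_networks["core_simple77"])
        assert ok
        assert sorted(base.leaf_labels().values()) == ["x1", "x2", "x3", "x4"]
        assert validate(base).ok
        assert base.reticulations() == []

    def test_practical_terminal_realizations_on_seeded_corpus(self):
        """Tree-basedness of N(m) built from the beaded core."""
        from ploidynet import classify

        checked = 0
        for seed in range(300):
            if checked >= 50:
                break
            p = random_profile(1 + seed % 6, 60, 600 + seed)
            term = simplification_sequence(p).terminal
            if not (term.degenerate or classify(term)["practical"]):
                continue
            checked += 1
            net = realize_profile(p)
            ok, base = is_tree_based(net)
            assert ok, p
            assert sorted(base.leaf_labels().values()) == sorted(p.labels)
        assert checked == 50


class TestTreeChild:
    def test_trees_are_tree_child(self):
        assert is_tree_child(caterpillar(["a", "b"]))

    def test_powers_of_two_ladder_is_tree_child(self):
        assert is_tree_child(realize_profile(normalize([4, 2, 1])))

    def test_stack_is_not_tree_child(self):
        stacked = [
            net for net in enumerate_realizations(normalize([3]), 2)
        ]
        assert stacked and not any(is_tree_child(net) for net in stacked)


class TestEnumerateRealizations:
    def test_two_is_uniquely_the_bead_with_leaf(self):
        nets = enumerate_realizations(normalize([2]), 1)
        assert len(nets) == 1
        net = nets[0]
        assert len(net.beads()) == 1 and count_paths(net) == {"x1": 2}

    def test_three_is_weak_orchard_but_not_orchard(self):
        nets = enumerate_realizations(normalize([3]), 2)
        assert nets
        statuses = [orchard_status(n, allow_trim=True).status for n in nets]
        assert OrchardStatus.ORCHARD not in statuses
        assert OrchardStatus.WEAK_ORCHARD in statuses

    def test_every_enumerated_network_validates_and_realizes(self):
        for comps, max_r in [((2,), 2), ((3,), 2), ((2, 1), 2)]:
            p = normalize(list(comps))
            for net in enumerate_realizations(p, max_r):
                assert validate(net).ok
                assert count_paths(net) == p.as_dict()

    def test_guards(self):
        with pytest.raises(ProfileError):
            enumerate_realizations(normalize([2, 1, 1]), 2)
        with pytest.raises(ProfileError):
            enumerate_realizations(normalize([2]), 4)
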