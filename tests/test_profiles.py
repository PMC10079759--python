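"""Profile model, classification, binary representation, simplification."""

import pytest
from hypothesis import given, settings, strategies as st

from ploidynet import (
    Case,
    binary_representation,
    classify,
    halve,
    normalize,
    simplification_sequence,
    simplify_step,
)
from ploidynet.profiles import PloidyProfile, ProfileError, read_profile_file
from ploidynet.fixtures import random_profile


class TestNormalize:
    @pytest.mark.parametrize(
        "comps,labels,exp_comps,exp_labels",
        [
            ((5, 6, 7, 6), "abcd", (7, 6, 6, 5), "cbda"),
            ((7, 6, 6, 5), None, (7, 6, 6, 5), None),
            ((1,), None, (1,), None),
        ],
    )
    def test_sorts_descending_with_stable_labels(self, comps, labels, exp_comps, exp_labels):
        labs = list(labels) if labels else None
        p = normalize(list(comps), labs)
        assert p.components == exp_comps
        if exp_labels:
            assert p.labels == tuple(exp_labels)

    def test_rejects_bad_input(self):
        with pytest.raises(ProfileError):
            normalize([0, 1])
        with pytest.raises(ProfileError):
            normalize([2, 1], ["a", "a"])
        with pytest.raises(ProfileError):
            normalize([2, 1], ["a"])

    def test_profile_invariant_enforced(self):
        with pytest.raises(ProfileError):
            PloidyProfile((1, 2), ("a", "b"))


class TestClassify:
    @pytest.mark.parametrize(
        "comps,simple,strictly,practical,arc_rich",
        [
            ((77, 1, 1, 1), True, False, True, False),
            ((77,), True, True, False, True),
            ((8,), True, True, True, False),
            ((7, 6, 6, 5), False, False, False, False),
            ((2,), True, True, True, False),
        ],
    )
    def test_flags(self, comps, simple, strictly, practical, arc_rich):
        flags = classify(normalize(list(comps)))
        assert flags == {
            "simple": simple,
            "strictly_simple": strictly,
            "practical": practical,
            "arc_rich": arc_rich,
        }


class TestBinaryRepresentation:
    @pytest.mark.parametrize("m,exp", [(77, (6, 3, 2, 0)), (1, (0,)), (12, (3, 2)), (8, (3,))])
    def test_examples(self, m, exp):
        assert binary_representation(m).exponents == exp

    @given(st.integers(min_value=1, max_value=10**6))
    @settings(max_examples=300, derandomize=True)
    def test_round_trip_and_strictly_decreasing(self, m):
        br = binary_representation(m)
        assert br.value == m
        assert all(a > b for a, b in zip(br.exponents, br.exponents[1:]))

    def test_rejects_nonpositive(self):
        with pytest.raises(ProfileError):
            binary_representation(0)


class TestSimplifyStep:
    def test_remove_insert_case(self):
        succ, step = simplify_step(normalize([7, 6, 6, 5]))
        assert succ.components == (6, 6, 5, 1)
        assert step.case is Case.REMOVE_INSERT and step.alpha == 1
        assert step.inserted_index == 4

    def test_remove_equal_case(self):
        p = PloidyProfile((6, 6, 5, 1), ("x2", "x3", "x4", "_s1"))
        succ, step = simplify_step(p)
        assert succ.components == (6, 5, 1)
        assert step.case is Case.REMOVE_EQUAL and step.alpha == 0
        assert succ.labels == ("x3", "x4", "_s1")

    def test_subtract_case(self):
        succ, step = simplify_step(normalize([10, 2, 2]))
        assert succ.components == (8, 2, 2)
        assert step.case is Case.SUBTRACT and step.alpha == 8
        assert succ.labels == ("x1", "x2", "x3")

    def test_refuses_simple_profile(self):
        with pytest.raises(ProfileError):
            simplify_step(normalize([5, 1, 1]))

    def test_insert_goes_after_last_equal_value(self):
        # alpha = 2 inserted after the existing 2s
        succ, step = simplify_step(normalize([10, 8, 2, 2]))
        assert succ.components == (8, 2, 2, 2)
        assert step.inserted_index == 4


class TestSimplificationSequence:
    @pytest.mark.parametrize(
        "comps,n_profiles,terminal",
        [
            ((7, 6, 6, 5), 4, (5, 1, 1)),
            ((5, 1, 1), 1, (5, 1, 1)),
            ((5, 3, 1), 3, (2, 1, 1)),
            ((6, 3), 3, (3,)),
            ((18, 14, 14, 10, 8, 8, 8, 4, 4, 2), None, (2,)),
        ],
    )
    def test_worked_examples(self, comps, n_profiles, terminal):
        seq = simplification_sequence(normalize(list(comps)))
        if n_profiles is not None:
            assert len(seq) == n_profiles
        assert seq.terminal.components == terminal

    def test_six_three_intermediate(self):
        seq = simplification_sequence(normalize([6, 3]))
        assert [q.components for q in seq.profiles] == [(6, 3), (3, 3), (3,)]

    def test_invariants_on_seeded_corpus(self):
        """Sum strictly decreases, order and alignment hold, only the
        terminal is simple."""
        for seed in range(500):
            p = random_profile(1 + seed % 8, 200, seed)
            seq = simplification_sequence(p)
            for q in seq.profiles:
                assert all(a >= b for a, b in zip(q.components, q.components[1:]))
                assert len(q.components) == len(q.labels) == len(set(q.labels))
            sums = [sum(q.components) for q in seq.profiles]
            assert all(a > b for a, b in zip(sums, sums[1:]))
            assert seq.terminal.simple or seq.terminal.degenerate
            for q in seq.profiles[:-1]:
                assert not (q.simple or q.degenerate)

    def test_deterministic(self):
        p = normalize([9, 7, 7, 5, 4])
        a = simplification_sequence(p)
        b = simplification_sequence(p)
        assert [q.components for q in a.profiles] == [q.components for q in b.profiles]
        assert [q.labels for q in a.profiles] == [q.labels for q in b.profiles]


class TestHalve:
    @pytest.mark.parametrize(
        "comps,exp",
        [
            ((14, 12, 12, 10), (7, 6, 6, 5)),
            ((2,), (1,)),
            ((18, 14, 14, 10, 8, 8, 8, 4, 4, 2), (9, 7, 7, 5, 4, 4, 4, 2, 2, 1)),
        ],
    )
    def test_divides_componentwise(self, comps, exp):
        assert halve(normalize(list(comps))).components == exp

    def test_rejects_odd(self):
        with pytest.raises(ProfileError):
            halve(normalize([3, 2]))


class TestProfileIO:
    def test_reads_csv_with_header(self, tmp_path):
        f = tmp_path / "p.csv"
        f.write_text("taxon,ploidy\nb,6\na,7\nc,5\n")
        p = read_profile_file(f)
        assert p.components == (7, 6, 5)
        assert p.labels == ("a", "b", "c")

    def test_reads_whitespace_columns(self, tmp_path):
        f = tmp_path / "p.txt"
        f.write_text("x1 7\nx2 6\n")
        assert read_profile_file(f).components == (7, 6)
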