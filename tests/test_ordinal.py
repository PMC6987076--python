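"""Ordinal pattern encoding, reversal pairing, and window counting."""

from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ordirr.ordinal import (
    PatternCounts,
    count_patterns,
    encode_window,
    has_tied_neighbours,
    pair_counts,
    pattern_code_sequence,
    pattern_pairs,
    reverse_pattern,
)


def naive_count(series, D=3, tau=1, stride=1):
    """Per-window reference counter, independent of the vectorized scan."""
    x = list(map(float, series))
    counts = {}
    n = 0
    for s in range(0, len(x) - (D - 1) * tau, stride):
        w = [x[s + k * tau] for k in range(D)]
        p = tuple(sorted(range(D), key=lambda i: (w[i], i)))
        counts[p] = counts.get(p, 0) + 1
        n += 1
    return counts, n


class TestEncodeWindow:
    @pytest.mark.parametrize(
        "window, expected",
        [
            ((0.1, 0.5, 0.9), (0, 1, 2)),  # monotonically increasing
            ((3, 1, 2), (1, 2, 0)),
            ((5, 5, 5), (0, 1, 2)),  # all ties -> stable index order
            ((2, 1, 3), (1, 0, 2)),
            ((0.9, 0.5, 0.1), (2, 1, 0)),
        ],
    )
    def test_examples(self, window, expected):
        assert encode_window(window) == expected

    def test_matches_sorting_definition_on_random_windows(self, rng):
        for _ in range(200):
            w = rng.standard_normal(int(rng.integers(2, 7)))
            pi = encode_window(w)
            assert all(w[pi[k]] <= w[pi[k + 1]] for k in range(len(pi) - 1))

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            encode_window((1.0, np.nan, 2.0))
        with pytest.raises(ValueError):
            encode_window((1.0,))
        with pytest.raises(ValueError):
            encode_window((1, 2, 3), tie_rule="nearest")


class TestReversePattern:
    def test_monotone_pair(self):
        assert reverse_pattern((0, 1, 2)) == (2, 1, 0)

    def test_matches_encoding_of_reversed_window(self):
        # (2,1,3) encodes to (1,0,2); its reversal (3,1,2) encodes to (1,2,0)
        assert encode_window((2, 1, 3)) == (1, 0, 2)
        assert reverse_pattern((1, 0, 2)) == encode_window((3, 1, 2)) == (1, 2, 0)

    @pytest.mark.parametrize("p", list(permutations(range(3))))
    def test_involution(self, p):
        assert reverse_pattern(reverse_pattern(p)) == p

    def test_rejects_non_permutation(self):
        with pytest.raises(ValueError):
            reverse_pattern((0, 0, 2))


class TestPatternPairs:
    def test_three_pairs_cover_six_patterns_at_D3(self):
        pairs = pattern_pairs(3)
        assert len(pairs) == 3
        members = [m for pr in pairs for m in pr.members]
        assert sorted(members) == sorted(permutations(range(3)))

    def test_D2_single_pair(self):
        (pair,) = pattern_pairs(2)
        assert pair.members == ((0, 1), (1, 0))

    @pytest.mark.parametrize("D", [2, 3, 4])
    def test_partition_property(self, D):
        pairs = pattern_pairs(D)
        members = [m for pr in pairs for m in pr.members]
        from math import factorial

        assert len(members) == len(set(members))  # each pattern in exactly one pair
        assert len(set(members)) == factorial(D)
        for pr in pairs:
            assert pr.forward != pr.reversed_  # no self-paired pattern

    def test_rejects_small_D(self):
        with pytest.raises(ValueError):
            pattern_pairs(1)


class TestCountPatterns:
    def test_monotone_ramp(self):
        pc = count_patterns(range(10))
        assert pc.counts == {(0, 1, 2): 8}
        assert pc.n_windows == 8

    def test_alternating_series_with_ties(self):
        pc = count_patterns([0, 1, 0, 1, 0, 1])
        assert pc.counts == {(0, 2, 1): 2, (1, 0, 2): 2}
        assert pc.n_windows == 4

    def test_window_count_formula(self, rng):
        for D, tau, stride in [(3, 1, 1), (3, 2, 1), (4, 1, 3), (2, 5, 2)]:
            x = rng.standard_normal(60)
            pc = count_patterns(x, D=D, tau=tau, stride=stride)
            assert pc.n_windows == len(range(0, 60 - (D - 1) * tau, stride))
        assert count_patterns(rng.standard_normal(50)).n_windows == 48

    def test_too_short_series_names_minimum(self):
        with pytest.raises(ValueError, match="at least 9"):
            count_patterns([1.0, 2.0], D=3, tau=4)

    def test_matches_naive_oracle(self, rng):
        for _ in range(50):
            x = rng.standard_normal(200)
            D = int(rng.integers(2, 5))
            tau = int(rng.integers(1, 4))
            stride = int(rng.integers(1, 4))
            pc = count_patterns(x, D=D, tau=tau, stride=stride)
            counts, n = naive_count(x, D, tau, stride)
            assert pc.counts == counts and pc.n_windows == n

    def test_counting_reversed_series_mirrors_patterns(self, rng):
        x = rng.standard_normal(300)  # continuous -> tie-free
        fwd = count_patterns(x)
        rev = count_patterns(x[::-1])
        assert rev.counts == {reverse_pattern(p): c for p, c in fwd.counts.items()}

    def test_jitter_rule_breaks_ties_reproducibly(self):
        x = np.repeat([1.0, 2.0], 20)
        a = count_patterns(x, tie_rule="jitter", rng=5)
        b = count_patterns(x, tie_rule="jitter", rng=5)
        assert a.counts == b.counts
        assert a.n_windows == 38

    def test_counts_sum_invariant_enforced(self):
        with pytest.raises(ValueError):
            PatternCounts(3, 1, {(0, 1, 2): 2}, n_windows=3)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.floats(-1e6, 1e6), min_size=10, max_size=80, unique=True
    )
)
def test_pair_class_counts_convention_invariant(values):
    """Index- and rank-convention encodings give identical pair-class counts.

    The rank encoding of a tie-free window is the inverse permutation of
    the index encoding, and its reversal pairing is tuple reversal (the
    pairing printed in the rank convention) rather than the elementwise
    complement.  Both conventions must assign every window to the same
    reversal class, so the per-class counts agree under the label
    bijection p -> invert(p).
    """
    pc = count_patterns(values)

    def invert(p):
        q = [0] * len(p)
        for rank, idx in enumerate(p):
            q[idx] = rank
        return tuple(q)

    index_class = {}  # canonical index-pair label -> count
    rank_class = {}  # canonical rank-pair label -> count
    label_map = {}  # index label -> rank label, must be consistent
    for p, c in pc.counts.items():
        idx_label = min(p, reverse_pattern(p))
        q = invert(p)
        rank_label = min(q, q[::-1])
        index_class[idx_label] = index_class.get(idx_label, 0) + c
        rank_class[rank_label] = rank_class.get(rank_label, 0) + c
        assert label_map.setdefault(idx_label, rank_label) == rank_label
    assert {label_map[k]: v for k, v in index_class.items()} == rank_class


def test_pattern_code_sequence_orders_windows(rng):
    x = rng.standard_normal(40)
    codes = pattern_code_sequence(x, D=3, tau=1, stride=1)
    assert codes.shape == (38,)
    pc = count_patterns(x)
    assert sum(pc.counts.values()) == codes.size


def test_tied_neighbour_detection():
    assert has_tied_neighbours([1.0, 1.0, 2.0])
    assert not has_tied_neighbours([1.0, 2.0, 3.0])
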