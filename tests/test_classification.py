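from collections import Counter
from fractions import Fraction
from itertools import permutations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mesotypes import (
    DensityMatrix,
    RelationshipType,
    UsageError,
    classify_all_pairs,
    classify_pair_directed,
    classify_pair_undirected,
    configuration_table,
    enumerate_configurations,
)

A = RelationshipType.ASSORTATIVE
CP = RelationshipType.CORE_PERIPHERY
D = RelationshipType.DISASSORTATIVE
SB = RelationshipType.SOURCE_BASIN
DEG = RelationshipType.DEGENERATE


def oracle_directed_type(w_rr, w_rs, w_sr, w_ss):
    """Independent transcription of the four directed inequalities."""
    hits = []
    if max(w_rs, w_sr) < min(w_rr, w_ss):
        hits.append(A)
    if min(w_rr, w_rs) > max(w_sr, w_ss):
        hits.append(CP)
    if min(w_rs, w_sr) > max(w_rr, w_ss):
        hits.append(D)
    if min(w_rr, w_sr) > max(w_rs, w_ss):
        hits.append(SB)
    return hits


def oracle_undirected_type(w_rr, w_ss, w_rs):
    hits = []
    if w_rs < min(w_rr, w_ss):
        hits.append(A)
    if min(w_rr, w_ss) < w_rs < max(w_rr, w_ss):
        hits.append(CP)
    if w_rs > max(w_rr, w_ss):
        hits.append(D)
    return hits


class TestUndirectedPairs:
    @pytest.mark.parametrize(
        "w, expected",
        [
            ((0.8, 0.5, 0.2), A),
            ((0.8, 0.2, 0.5), CP),
            ((0.5, 0.2, 0.9), D),
            ((0.5, 0.5, 0.5), DEG),
            ((0.5, 0.5, 0.2), DEG),
        ],
    )
    def test_examples(self, w, expected):
        assert classify_pair_undirected(*w).type is expected

    def test_canonical_order_enforced(self):
        with pytest.raises(UsageError):
            classify_pair_undirected(0.2, 0.8, 0.5)

    def test_configuration_labels_in_type_order(self):
        assert classify_pair_undirected(0.8, 0.5, 0.2).configuration == "U1"
        assert classify_pair_undirected(0.8, 0.2, 0.5).configuration == "U2"
        assert classify_pair_undirected(0.5, 0.2, 0.9).configuration == "U3"


class TestDirectedPairs:
    @pytest.mark.parametrize(
        "w, expected",
        [
            ((0.9, 0.1, 0.2, 0.8), A),
            ((0.9, 0.8, 0.2, 0.1), CP),
            ((0.9, 0.2, 0.8, 0.1), SB),
            ((0.2, 0.9, 0.8, 0.1), D),
            ((0.9, 0.9, 0.2, 0.1), DEG),
        ],
    )
    def test_examples(self, w, expected):
        assert classify_pair_directed(*w).type is expected

    def test_canonical_order_enforced(self):
        with pytest.raises(UsageError):
            classify_pair_directed(0.1, 0.2, 0.3, 0.9)

    def test_agrees_with_inequality_oracle_on_all_strict_orderings(self):
        for perm in permutations((Fraction(4), Fraction(3), Fraction(2), Fraction(1))):
            w_rr, w_rs, w_sr, w_ss = perm
            if w_rr < w_ss:
                continue
            hits = oracle_directed_type(*perm)
            assert len(hits) == 1
            assert classify_pair_directed(*perm).type is hits[0]

    def test_exactly_one_condition_holds_after_canonicalization(self):
        # the conditions presume the canonical labeling (r = denser block);
        # after swapping roles where needed they partition all 24 orderings
        for perm in permutations((4, 3, 2, 1)):
            w_rr, w_rs, w_sr, w_ss = perm
            if w_rr < w_ss:
                w_rr, w_ss, w_rs, w_sr = w_ss, w_rr, w_sr, w_rs
            assert len(oracle_directed_type(w_rr, w_rs, w_sr, w_ss)) == 1

    def test_relabel_swap_leaves_type_invariant(self):
        def canonical_type(w_rr, w_rs, w_sr, w_ss):
            if w_rr < w_ss:
                w_rr, w_ss, w_rs, w_sr = w_ss, w_rr, w_sr, w_rs
            return classify_pair_directed(w_rr, w_rs, w_sr, w_ss).type

        for perm in permutations((4, 3, 2, 1)):
            w_rr, w_rs, w_sr, w_ss = perm
            assert canonical_type(w_rr, w_rs, w_sr, w_ss) is canonical_type(
                w_ss, w_sr, w_rs, w_rr
            )

    def test_symmetric_offdiagonals_never_mixed_type(self):
        # a directed classification of a symmetric ω cannot be
        # core-periphery or source-basin: the mixed conditions demand the
        # two off-diagonal values fall on opposite sides of a diagonal value
        grid = [Fraction(k, 8) for k in range(9)]
        for w_rr in grid:
            for w_ss in grid:
                if w_rr < w_ss:
                    continue
                for w_c in grid:
                    t = classify_pair_directed(w_rr, w_c, w_c, w_ss).type
                    assert t in (A, D, DEG)


class TestCatalog:
    def test_directed_catalog_size_and_type_multiset(self):
        cat = enumerate_configurations(directed=True)
        assert len(cat) == 12
        assert Counter(t for _, t in cat) == {A: 2, CP: 4, D: 2, SB: 4}
        assert [label for label, _ in cat] == [f"D{i}" for i in range(1, 13)]

    def test_undirected_catalog_one_configuration_per_type(self):
        cat = enumerate_configurations(directed=False)
        assert cat == [("U1", A), ("U2", CP), ("U3", D)]

    def test_catalog_matches_brute_force_enumeration(self):
        seen = {}
        for perm in permutations((4, 3, 2, 1)):
            w_rr, w_rs, w_sr, w_ss = perm
            if w_rr < w_ss:
                continue
            pc = classify_pair_directed(*perm)
            seen[pc.configuration] = pc.type
        assert seen == dict(enumerate_configurations(directed=True))

    def test_d_labels_ordered_by_rank_vector(self):
        table = configuration_table(directed=True)
        rank_vectors = [rv for _, _, rv in table]
        assert rank_vectors == sorted(rank_vectors)
        # every rank vector keeps w_rr ranked above w_ss
        assert all(rv[0] < rv[3] for rv in rank_vectors)


class TestClassifyAllPairs:
    @staticmethod
    def _dm(entries, directed=True, labels=None, sizes=10):
        entries = [[Fraction(x).limit_denominator(10**6) for x in row] for row in entries]
        labels = labels or [str(i + 1) for i in range(len(entries))]
        return DensityMatrix(
            block_labels=labels,
            entries=entries,
            directed=directed,
            sizes={b: sizes for b in labels},
            singleton={b: False for b in labels},
        )

    def test_pair_count_is_b_choose_2(self):
        om = self._dm(
            [
                [0.9, 0.1, 0.1, 0.1],
                [0.1, 0.8, 0.1, 0.1],
                [0.1, 0.1, 0.7, 0.1],
                [0.2, 0.1, 0.1, 0.6],
            ]
        )
        assert len(classify_all_pairs(om)) == 6

    def test_single_block_yields_empty_list(self):
        om = self._dm([[0.5]])
        assert classify_all_pairs(om) == []

    def test_identical_rows_make_pair_degenerate(self):
        om = self._dm([[0.5, 0.2], [0.2, 0.5]])
        (pc,) = classify_all_pairs(om)
        assert pc.type is DEG

    def test_pair_canonicalized_by_its_own_self_densities(self):
        # block 2 denser than block 1: the classifier must swap roles
        om = self._dm([[0.1, 0.2], [0.7, 0.9]])
        (pc,) = classify_all_pairs(om)
        assert pc.pair == ("2", "1")
        # canonical view: w_rr=0.9, w_rs(2→1)=0.7, w_sr(1→2)=0.2, w_ss=0.1
        assert pc.type is CP

    def test_planted_two_block_assortative_matrix(self):
        om = self._dm([[0.8, 0.1, ], [0.05, 0.5]])
        (pc,) = classify_all_pairs(om)
        assert pc.type is A


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(
        st.fractions(min_value=0, max_value=3, max_denominator=50),
        min_size=4,
        max_size=4,
    )
)
def test_directed_classifier_always_agrees_with_oracle(ws):
    """Random rational densities: classifier = inequality oracle, ties DEGENERATE."""
    w_rr, w_rs, w_sr, w_ss = ws
    if w_rr < w_ss:
        w_rr, w_ss = w_ss, w_rr
        w_rs, w_sr = w_sr, w_rs
    pc = classify_pair_directed(w_rr, w_rs, w_sr, w_ss)
    if len({w_rr, w_rs, w_sr, w_ss}) < 4:
        assert pc.type is DEG
    else:
        assert [pc.type] == oracle_directed_type(w_rr, w_rs, w_sr, w_ss)
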