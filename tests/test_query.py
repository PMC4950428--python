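import random

import pytest

from pancdbg import (
    Interval,
    build_document_array,
    interval_sequences,
    locate_node_of_interval,
    node_sequences,
    search_pattern,
)
from conftest import build_all


class TestDocumentArray:
    def test_single_sequence(self, example):
        doc = build_document_array(example.fm, example.text)
        assert list(doc.D) == [1] * 15

    def test_two_sequences_ownership(self):
        fx = build_all(["ACGTT", "ACGCC"], 3)
        doc = build_document_array(fx.fm, fx.text)
        for i in range(1, fx.fm.n + 1):
            expected = 1 if fx.fm.sa_value(i) <= 6 else 2
            assert doc[i] == expected

    def test_equal_content_symmetric_counts(self):
        fx = build_all(["ACGTACG", "ACGTACG", "ACGTACG"], 3)
        doc = build_document_array(fx.fm, fx.text)
        counts = [list(doc.D).count(j) for j in (1, 2, 3)]
        assert counts[0] == counts[1] == counts[2]


class TestLocate:
    def test_right_maximal_zero_steps(self, example):
        ident, ell = locate_node_of_interval(
            example.fm, example.marks, example.G, Interval(2, 4)
        )
        assert (ident, ell) == (1, 0)

    def test_one_psi_step(self, example):
        # TAC-interval [13..15] maps to the ACG-interval [2..4] by Psi
        ident, ell = locate_node_of_interval(
            example.fm, example.marks, example.G, Interval(13, 15)
        )
        assert (ident, ell) == (1, 1)

    def test_bl_marked_interval(self, example):
        ident, ell = locate_node_of_interval(
            example.fm, example.marks, example.G, Interval(11, 12)
        )
        assert (ident, ell) == (3, 0)

    def test_rejects_empty(self, example):
        with pytest.raises(ValueError):
            locate_node_of_interval(
                example.fm, example.marks, example.G, Interval(5, 4)
            )


class TestSearchPattern:
    def test_multi_node_path(self, example):
        res = search_pattern(example.fm, example.marks, example.G, "ACGTACG")
        assert res.resList == [1, 3, 1]
        assert res.iv == Interval(3, 4)
        hits = sorted(
            example.fm.sa_value(i) for i in range(res.iv.lb, res.iv.rb + 1)
        )
        assert hits == [4, 8]

    def test_single_kmer(self, example):
        res = search_pattern(example.fm, example.marks, example.G, "ACG")
        assert res.resList == [1]

    def test_absent_pattern(self, example):
        res = search_pattern(example.fm, example.marks, example.G, "AAA")
        assert not res.found
        assert res.resList == []

    def test_too_short_rejected(self, example):
        with pytest.raises(ValueError):
            search_pattern(example.fm, example.marks, example.G, "AC")

    def test_separator_rejected(self, example):
        with pytest.raises(ValueError):
            search_pattern(example.fm, example.marks, example.G, "AC$")

    def test_unknown_symbol_is_empty_result(self, example):
        res = search_pattern(example.fm, example.marks, example.G, "AXG")
        assert not res.found

    def test_full_sequence_pattern(self, example):
        res = search_pattern(
            example.fm, example.marks, example.G, "ACTACGTACGTACG"
        )
        assert res.found
        assert res.resList[0] == 2  # the start node ACTA

    def test_psi_cost_bounded_by_longest_node(self):
        rng = random.Random(53)
        for _ in range(20):
            seqs = [
                "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 80)))
                for _ in range(rng.randint(1, 3))
            ]
            k = rng.randint(2, 4)
            fx = build_all(seqs, k)
            longest = max(fx.G[i].len for i in fx.G.ids())
            for s in seqs:
                for off in range(0, len(s) - k, 7):
                    w = s[off : off + k]
                    res = search_pattern(fx.fm, fx.marks, fx.G, w)
                    assert res.found
                    # offset counts characters of the node before the k-mer
                    last = fx.G[res.resList[-1]]
                    assert 0 <= res.offset <= last.len - k <= longest - k


class TestMembership:
    def test_single_sequence_counts(self, example):
        doc = build_document_array(example.fm, example.text)
        assert interval_sequences(doc, Interval(13, 15)) == [(1, 3)]

    def test_shared_kmer_both_sequences(self):
        fx = build_all(["ACGTT", "ACGCC"], 3)
        doc = build_document_array(fx.fm, fx.text)
        res = search_pattern(fx.fm, fx.marks, fx.G, "ACG")
        assert interval_sequences(doc, res.iv) == [(1, 1), (2, 1)]
        res = search_pattern(fx.fm, fx.marks, fx.G, "GCC")
        assert interval_sequences(doc, res.iv) == [(2, 1)]

    def test_empty_interval_empty_list(self, example):
        doc = build_document_array(example.fm, example.text)
        assert interval_sequences(doc, Interval(3, 2)) == []

    def test_node_sequences(self, example):
        doc = build_document_array(example.fm, example.text)
        assert node_sequences(doc, example.G, 1) == [(1, 3)]
        assert node_sequences(doc, example.G, 2) == [(1, 1)]

    def test_node_sequences_shared_node(self):
        fx = build_all(["ACGTT", "ACGCC"], 3)
        doc = build_document_array(fx.fm, fx.text)
        shared = [
            i
            for i in fx.G.ids()
            if len(node_sequences(doc, fx.G, i)) == 2
        ]
        assert shared  # the ACG node occurs in both sequences

    def test_invalid_node_rejected(self, example):
        doc = build_document_array(example.fm, example.text)
        with pytest.raises(IndexError):
            node_sequences(doc, example.G, 99)
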