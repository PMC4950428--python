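import random

import pytest
from hypothesis import given, settings, strategies as st

from pancdbg import (
    Interval,
    ReservedSymbolError,
    backward_search,
    build_fm_index,
    encode_and_concatenate,
    get_intervals,
    lf_map,
    psi,
)
from pancdbg.oracle import naive_bwt, naive_suffix_array
from conftest import (
    EXAMPLE_BWT,
    EXAMPLE_LF,
    EXAMPLE_PSI,
    EXAMPLE_SA,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestEncode:
    def test_two_records(self):
        t = encode_and_concatenate([("a", "ACG"), ("b", "AAC")])
        assert t.S == "ACG#AAC$"
        assert t.n == 8
        assert t.d == 2
        assert t.seq_starts == (1, 5)
        assert t.seq_lengths == (3, 3)

    def test_single_record_example(self):
        t = encode_and_concatenate([("x", "ACTACGTACGTACG")])
        assert t.S == "ACTACGTACGTACG$"
        assert t.n == 15
        assert t.d == 1

    def test_reserved_symbol_rejected(self):
        with pytest.raises(ReservedSymbolError):
            encode_and_concatenate([("a", "AC$G")])
        with pytest.raises(ReservedSymbolError):
            encode_and_concatenate([("a", "AC#G")])

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            encode_and_concatenate([])
        with pytest.raises(ValueError):
            encode_and_concatenate([("a", "")])

    def test_uppercasing_and_alphabet_order(self):
        t = encode_and_concatenate([("a", "acgt"), ("b", "TnA")])
        assert t.S == "ACGT#TNA$"
        assert t.alphabet == "$#ACGNT"

    def test_sentinel_invariants(self):
        t = encode_and_concatenate([("a", "AC"), ("b", "GT"), ("c", "AA")])
        assert t.S.count("$") == 1 and t.S.endswith("$")
        assert t.S.count("#") == t.d - 1
        assert t.n == sum(t.seq_lengths) + t.d


class TestBuild:
    def test_example_sa_and_bwt(self, example):
        assert list(example.fm.sa) == EXAMPLE_SA
        assert example.fm.bwt == EXAMPLE_BWT

    def test_tiny_derived(self):
        t = encode_and_concatenate([("a", "AA")])
        fm = build_fm_index(t)
        assert list(fm.sa) == [3, 2, 1]
        # BWT[i] = S[SA[i]-1] with '$' for the wrapped first suffix:
        # rows are $, A$, AA$ preceded by A, A, (wrap) -> "AA$"
        assert fm.bwt == "AA$" == naive_bwt(t.S, [3, 2, 1])

    @settings(max_examples=60, deadline=None)
    @given(st.lists(dna, min_size=1, max_size=4))
    def test_matches_naive_suffix_sort(self, seqs):
        t = encode_and_concatenate([(f"s{i}", s) for i, s in enumerate(seqs)])
        fm = build_fm_index(t)
        sa = naive_suffix_array(t.S)
        assert list(fm.sa) == sa
        assert fm.bwt == naive_bwt(t.S, sa)

    def test_many_random_vs_naive(self):
        rng = random.Random(7)
        for _ in range(200):
            d = rng.randint(1, 4)
            seqs = [
                "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 200)))
                for _ in range(d)
            ]
            t = encode_and_concatenate([(f"s{i}", s) for i, s in enumerate(seqs)])
            fm = build_fm_index(t)
            assert list(fm.sa) == naive_suffix_array(t.S)


class TestLfPsi:
    def test_example_lf_column(self, example):
        assert [lf_map(example.fm, i) for i in range(1, 16)] == EXAMPLE_LF

    def test_example_psi_column(self, example):
        assert [psi(example.fm, i) for i in range(1, 16)] == EXAMPLE_PSI

    def test_mutually_inverse(self, example):
        fm = example.fm
        for i in range(1, fm.n + 1):
            assert lf_map(fm, psi(fm, i)) == i
            assert psi(fm, lf_map(fm, i)) == i

    def test_lf_moves_one_left_in_text(self, example):
        fm = example.fm
        for i in range(1, fm.n + 1):
            p = fm.sa_value(i)
            if p == 1:
                assert lf_map(fm, i) == 1  # wraparound convention
            else:
                assert fm.sa_value(lf_map(fm, i)) == p - 1

    def test_out_of_range(self, example):
        with pytest.raises(IndexError):
            lf_map(example.fm, 0)
        with pytest.raises(IndexError):
            psi(example.fm, 16)


class TestBackwardSearch:
    def test_walkthrough_steps(self, example):
        fm = example.fm
        assert backward_search(fm, "T", Interval(2, 4)) == Interval(13, 15)
        assert backward_search(fm, "C", Interval(10, 10)) == Interval(6, 6)

    def test_absent_extension_empty(self, example):
        iv = backward_search(example.fm, "T", Interval(13, 15))
        assert iv.is_empty

    def test_unknown_symbol_empty(self, example):
        assert backward_search(example.fm, "X", Interval(1, 15)).is_empty

    def test_exhaustive_vs_naive_scan(self):
        rng = random.Random(11)
        for _ in range(12):
            d = rng.randint(1, 2)
            seqs = [
                "".join(rng.choice("ACGT") for _ in range(rng.randint(4, 30)))
                for _ in range(d)
            ]
            t = encode_and_concatenate([(f"s{i}", s) for i, s in enumerate(seqs)])
            if t.n > 64:
                continue
            fm = build_fm_index(t)
            S = t.S
            seen = set()
            for a in range(len(S)):
                for b in range(a + 1, len(S) + 1):
                    w = S[a:b]
                    if w in seen:
                        continue
                    seen.add(w)
                    iv = Interval(1, t.n)
                    for c in reversed(w):
                        iv = backward_search(fm, c, iv)
                    hits = sorted(
                        fm.sa_value(i) for i in range(iv.lb, iv.rb + 1)
                    )
                    expected = [
                        p + 1
                        for p in range(len(S))
                        if S[p : p + len(w)] == w
                    ]
                    assert hits == expected


class TestGetIntervals:
    def test_examples(self, example):
        fm = example.fm
        assert get_intervals(fm, Interval(2, 4)) == [("T", Interval(13, 15))]
        assert get_intervals(fm, Interval(13, 15)) == [
            ("C", Interval(9, 9)),
            ("G", Interval(11, 12)),
        ]
        assert get_intervals(fm, Interval(1, 1)) == [("G", Interval(10, 10))]

    def test_rejects_empty(self, example):
        with pytest.raises(ValueError):
            get_intervals(example.fm, Interval(2, 1))

    def test_partition_property(self, example):
        fm = example.fm
        for lb in range(1, fm.n + 1):
            for rb in range(lb, min(lb + 4, fm.n) + 1):
                if rb > fm.n:
                    continue
                pairs = get_intervals(fm, Interval(lb, rb))
                assert sum(iv.size for _, iv in pairs) == rb - lb + 1
                flat = sorted(
                    p for _, iv in pairs for p in range(iv.lb, iv.rb + 1)
                )
                assert len(flat) == len(set(flat))

    def test_symbols_ascending(self, example):
        fm = example.fm
        pairs = get_intervals(fm, Interval(1, fm.n))
        symbols = [c for c, _ in pairs]
        assert symbols == sorted(symbols, key=fm.text.alphabet.index)
        assert symbols[0] == "$"
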