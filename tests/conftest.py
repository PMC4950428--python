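"""Shared fixtures and the oracle-equivalence checker."""

from __future__ import annotations

import random
from dataclasses import dataclass

import pytest

from pancdbg import (
    build_document_array,
    build_fm_index,
    build_implicit,
    build_kmer_marks,
    encode_and_concatenate,
    interval_sequences,
    node_positions,
    node_string,
    reconstruct_sequence,
    search_pattern,
    to_explicit,
)
from pancdbg.oracle import oracle_compressed_dbg, oracle_node_path

# Hand-checkable reference: the worked single-sequence example, k = 3.
EXAMPLE_SEQ = "ACTACGTACGTACG"
EXAMPLE_S = EXAMPLE_SEQ + "$"
EXAMPLE_SA = [15, 12, 8, 4, 1, 13, 9, 5, 2, 14, 10, 6, 11, 7, 3]
EXAMPLE_LCP = [-1, 0, 3, 7, 2, 0, 2, 6, 1, 0, 1, 5, 0, 4, 8, -1]
EXAMPLE_BWT = "GTTT$AAAACCCGGC"
EXAMPLE_LF = [10, 13, 14, 15, 1, 2, 3, 4, 5, 6, 7, 8, 11, 12, 9]
EXAMPLE_PSI = [5, 6, 7, 8, 9, 10, 11, 12, 15, 1, 13, 14, 2, 3, 4]
EXAMPLE_BR = [0, 1, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]
EXAMPLE_BL = [0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 1, 0, 0, 0]


@dataclass
class BuiltFixture:
    sequences: list[str]
    k: int
    text: object
    fm: object
    marks: object
    G: object


def build_all(sequences: list[str], k: int) -> BuiltFixture:
    text = encode_and_concatenate(
        [(f"s{i + 1}", s) for i, s in enumerate(sequences)]
    )
    fm = build_fm_index(text)
    marks = build_kmer_marks(fm, k)
    G = build_implicit(fm, marks)
    return BuiltFixture(
        sequences=list(sequences), k=k, text=text, fm=fm, marks=marks, G=G
    )


@pytest.fixture(scope="session")
def example() -> BuiltFixture:
    return build_all([EXAMPLE_SEQ], 3)


def random_pangenome(rng: random.Random) -> tuple[list[str], int]:
    """1-4 near-identical sequences (lengths 20-200) and a k in 2..5."""
    d = rng.randint(1, 4)
    base_len = rng.randint(20, 200)
    base = "".join(rng.choice("ACGT") for _ in range(base_len))
    seqs = [base]
    for _ in range(d - 1):
        s = list(base)
        for _ in range(rng.randint(0, max(1, base_len // 20))):
            op = rng.choice("sid")
            p = rng.randrange(len(s))
            if op == "s":
                s[p] = rng.choice("ACGT")
            elif op == "i" and len(s) < 220:
                s.insert(p, rng.choice("ACGT"))
            elif op == "d" and len(s) > 20:
                del s[p]
        seqs.append("".join(s))
    k = rng.randint(2, 5)
    return seqs, k


def naive_occurrences(S: str, w: str) -> list[int]:
    out, start = [], 0
    while True:
        p = S.find(w, start)
        if p < 0:
            return out
        out.append(p + 1)
        start = p + 1


def check_oracle_equivalence(
    sequences: list[str], k: int, max_pattern_len: int = 12
) -> None:
    """Full cross-check of one fixture against the brute-force oracle.

    Covers implicit node materialization, conservation, explicit
    conversion with round-trip reconstruction, per-sequence walks, edge
    multisets, pattern search over every distinct substring of length
    k..max_pattern_len, membership counts, and non-occurring probes.
    """
    fx = build_all(sequences, k)
    fm, marks, G, text = fx.fm, fx.marks, fx.G, fx.text
    og = oracle_compressed_dbg(sequences, k)

    impl_items = {
        ident: (node_string(fm, G, ident), tuple(node_positions(fm, G, ident)))
        for ident in G.ids()
    }
    assert sorted(impl_items.values()) == sorted(og.node_items())

    # window-coverage conservation
    lhs = sum(G[i].size * (G[i].len - k + 1) for i in G.ids())
    rhs = sum(len(s) + 2 - k for s in sequences)
    assert lhs == rhs

    # identifier spaces are bijective via (string, positions)
    oracle_id = {item: i for i, item in enumerate(og.node_items())}
    to_oracle = {ident: oracle_id[item] for ident, item in impl_items.items()}
    assert len(set(to_oracle.values())) == G.N == og.num_nodes

    # suffix interval of every non-stop node is the full k-mer interval
    kmer_indices: dict[str, list[int]] = {}
    for i in range(1, fm.n + 1):
        p = fm.sa_value(i)
        kmer_indices.setdefault(text.S[p - 1 : p - 1 + k], []).append(i)
    for ident in G.ids():
        if G.is_stop(ident):
            continue
        nd = G[ident]
        suffix = node_string(fm, G, ident)[-k:]
        assert kmer_indices[suffix] == list(
            range(nd.suffix_lb, nd.suffix_lb + nd.size)
        )

    ex = to_explicit(fm, marks, G)
    for ident in G.ids():
        assert ex[ident].posList == list(impl_items[ident][1])
        if G.is_stop(ident):
            assert ex[ident].adjList == []
        else:
            assert len(ex[ident].adjList) == len(ex[ident].posList)
    for j in range(1, len(sequences) + 1):
        term = "$" if j == len(sequences) else "#"
        assert reconstruct_sequence(ex, text, fm, G, j) == sequences[j - 1] + term

    # per-sequence walks and edge multiset
    impl_walks = []
    for j in range(1, len(sequences) + 1):
        ident = ex.StartNodes[j - 1]
        pos = text.seq_starts[j - 1]
        walk = [ident]
        while ident <= G.rightMax + G.leftMax:
            node = ex[ident]
            ident = node.adjList[node.posList.index(pos)]
            pos += node.len - (k - 1)
            walk.append(ident)
        impl_walks.append([to_oracle[i] for i in walk])
    assert impl_walks == og.walks
    assert sorted(
        (to_oracle[a.id], to_oracle[b]) for a in ex.nodes for b in a.adjList
    ) == sorted(og.edges)

    # pattern search for every distinct substring of length k..12
    doc = build_document_array(fm, text)
    patterns: dict[str, int] = {}
    for s_idx, s in enumerate(sequences):
        start = text.seq_starts[s_idx]
        for ln in range(k, max_pattern_len + 1):
            for off in range(0, len(s) - ln + 1):
                w = s[off : off + ln]
                patterns.setdefault(w, start + off)
    for w, p in patterns.items():
        res = search_pattern(fm, marks, G, w)
        assert res.found
        expected_path, expected_offset = oracle_node_path(og, p, len(w), k)
        assert [to_oracle[i] for i in res.resList] == expected_path
        assert res.offset == expected_offset
        hits = sorted(
            fm.sa_value(i) for i in range(res.iv.lb, res.iv.rb + 1)
        )
        assert hits == naive_occurrences(text.S, w)
        per_seq = interval_sequences(doc, res.iv)
        expected_counts = {}
        for h in hits:
            j = text.sequence_of_position(h)
            expected_counts[j] = expected_counts.get(j, 0) + 1
        assert per_seq == sorted(expected_counts.items())

    # non-occurring probes come back empty
    rng = random.Random(len(text.S) * 31 + k)
    probes = 0
    for w in list(patterns)[:50]:
        mutated = list(w)
        mutated[rng.randrange(len(w))] = "N"
        w2 = "".join(mutated)
        if w2 not in patterns and w2 not in fx.text.S:
            assert not search_pattern(fm, marks, G, w2).found
            probes += 1
        if probes >= 10:
            break
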