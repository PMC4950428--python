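"""Brute-force ground truth used by the test suite and acceptance checks.

Everything here is deliberately naive and dictionary-based and shares no
code with the production path: a quadratic suffix sort, pairwise LCP
computation with per-occurrence separator identity, definitional k-mer
maximality scans, and an uncompressed de Bruijn graph compacted by
merging unary chains.  Separator occurrences are treated as pairwise
distinct characters throughout, mirroring the production semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

SENTINEL = "$"
SEPARATOR = "#"


def _symbol_rank(c: str) -> int:
    if c == SENTINEL:
        return 0
    if c == SEPARATOR:
        return 1
    return 2 + ord(c)


def concat(sequences: Sequence[str]) -> str:
    return SEPARATOR.join(sequences) + SENTINEL


def naive_suffix_array(S: str) -> list[int]:
    """1-based suffix array by direct sorting ($ < # < byte order)."""
    keys = [tuple(_symbol_rank(c) for c in S[i:]) for i in range(len(S))]
    return [i + 1 for i in sorted(range(len(S)), key=keys.__getitem__)]


def naive_bwt(S: str, sa: list[int]) -> str:
    return "".join(S[p - 2] if p > 1 else SENTINEL for p in sa)


def _chars_match(S: str, p: int, q: int) -> bool:
    """1-based char comparison with distinct separator occurrences."""
    a, b = S[p - 1], S[q - 1]
    if a != b:
        return False
    if a in (SENTINEL, SEPARATOR):
        return p == q
    return True


def naive_lcp_array(S: str, sa: list[int]) -> list[int]:
    """LCP[1..n+1] with LCP[1] = LCP[n+1] = -1, distinct-separator order."""
    n = len(S)
    out = [-1]
    for i in range(1, n):
        p, q = sa[i - 1], sa[i]
        ell = 0
        while p + ell <= n and q + ell <= n and _chars_match(S, p + ell, q + ell):
            ell += 1
        out.append(ell)
    out.append(-1)
    return out


def _occurrences(S: str, w: str) -> list[int]:
    """1-based start positions of w in S (w treated literally)."""
    out = []
    start = 0
    while True:
        p = S.find(w, start)
        if p < 0:
            return out
        out.append(p + 1)
        start = p + 1


def _kmer_positions(S: str, k: int) -> dict[str, list[int]]:
    """Separator-free k-mers of S and their 1-based positions."""
    table: dict[str, list[int]] = {}
    for p in range(1, len(S) - k + 2):
        w = S[p - 1 : p - 1 + k]
        if SENTINEL in w or SEPARATOR in w:
            continue
        table.setdefault(w, []).append(p)
    return table


def right_maximal_kmers(S: str, k: int) -> set[str]:
    """Separator-free k-mer repeats followed by >= 2 distinct symbols.

    Separator followers count as pairwise distinct (they end different
    sequences), so a k-mer closing two sequences is right-maximal.
    """
    out = set()
    for w, positions in _kmer_positions(S, k).items():
        if len(positions) < 2:
            continue
        followers = set()
        for p in positions:
            c = S[p + k - 1]
            followers.add((c, p) if c in (SENTINEL, SEPARATOR) else c)
        if len(followers) >= 2:
            out.add(w)
    return out


def left_maximal_kmers(S: str, k: int) -> set[str]:
    """Separator-free k-mer repeats preceded by >= 2 distinct symbols.

    A separator predecessor (sequence start) is distinct from every
    content symbol and from other separator occurrences.
    """
    out = set()
    for w, positions in _kmer_positions(S, k).items():
        if len(positions) < 2:
            continue
        preceders = set()
        for p in positions:
            c = SENTINEL if p == 1 else S[p - 2]
            preceders.add((c, p) if c in (SENTINEL, SEPARATOR) else c)
        if len(preceders) >= 2:
            out.add(w)
    return out


def naive_br_bits(S: str, k: int, sa: list[int]) -> list[int]:
    """Definitional B_r: boundaries of right-maximal k-mer intervals."""
    n = len(S)
    bits = [0] * n
    rmax = right_maximal_kmers(S, k)
    for w in rmax:
        idx = [i + 1 for i, p in enumerate(sa) if S[p - 1 : p - 1 + k] == w]
        bits[min(idx) - 1] = 1
        bits[max(idx) - 1] = 1
    return bits


def naive_bl_bits(S: str, k: int, sa: list[int]) -> list[int]:
    """Definitional B_l: right boundaries of non-right-maximal k-mer
    intervals whose following k-mer is a left-maximal repeat."""
    n = len(S)
    bits = [0] * n
    rmax = right_maximal_kmers(S, k)
    lmax = left_maximal_kmers(S, k)
    interval_rb: dict[str, int] = {}
    for i, p in enumerate(sa):
        w = S[p - 1 : p - 1 + k]
        if len(w) == k and SENTINEL not in w and SEPARATOR not in w:
            interval_rb[w] = i + 1  # ascending scan keeps the max index
    for w, rb in interval_rb.items():
        if w in rmax:
            continue
        p = sa[rb - 1]
        nxt = S[p : p + k]
        if nxt in lmax:
            bits[rb - 1] = 1
    return bits


@dataclass
class OracleGraph:
    """Compacted de Bruijn graph computed from first principles.

    Node keys are opaque integers; ``strings`` and ``positions`` describe
    each node, ``window_owner`` maps a text window position to
    ``(node, offset-in-windows)``, ``walks`` lists the per-sequence node
    visit chains, and ``edges`` is the multiset of consecutive visits.
    """

    strings: list[str]
    positions: list[list[int]]
    window_owner: dict[int, tuple[int, int]]
    walks: list[list[int]]
    edges: list[tuple[int, int]] = field(default_factory=list)

    @property
    def num_nodes(self) -> int:
        return len(self.strings)

    def node_items(self) -> list[tuple[str, tuple[int, ...]]]:
        return [
            (s, tuple(p)) for s, p in zip(self.strings, self.positions)
        ]

    def start_strings(self) -> list[str]:
        return [self.strings[w[0]] for w in self.walks]

    def stop_strings(self) -> list[str]:
        return [self.strings[w[-1]] for w in self.walks]


def oracle_compressed_dbg(sequences: Sequence[str], k: int) -> OracleGraph:
    """Uncompressed window graph per sequence, then unary-chain merging.

    Windows are the length-k substrings of each ``S^j`` followed by its
    terminator; a window containing a separator is keyed by that
    separator's text position, so such windows are unique.  Edges join
    consecutive windows of the same sequence only; nodes ``u -> v`` merge
    when ``u`` is the sole distinct predecessor of ``v`` and ``v`` the
    sole distinct successor of ``u``.
    """
    if any(len(s) < k for s in sequences):
        raise ValueError("every sequence must have length >= k")
    S = concat(sequences)
    d = len(sequences)
    # per-sequence window key lists; a key identifies an uncompressed node
    starts = []
    pos = 1
    for s in sequences:
        starts.append(pos)
        pos += len(s) + 1

    def window_key(p: int) -> object:
        w = S[p - 1 : p - 1 + k]
        for off, c in enumerate(w):
            if c in (SENTINEL, SEPARATOR):
                return (w, p + off)  # unique separator occurrence
        return w

    seq_windows: list[list[tuple[int, object]]] = []
    for j, s in enumerate(sequences):
        st = starts[j]
        wins = [(p, window_key(p)) for p in range(st, st + len(s) + 2 - k)]
        seq_windows.append(wins)

    succs: dict[object, set] = {}
    preds: dict[object, set] = {}
    occ: dict[object, list[int]] = {}
    for j, wins in enumerate(seq_windows):
        for (p, key), (_, nxt) in zip(wins, wins[1:]):
            succs.setdefault(key, set()).add(nxt)
            preds.setdefault(nxt, set()).add(key)
        for p, key in wins:
            occ.setdefault(key, []).append(p)
            succs.setdefault(key, set())
            preds.setdefault(key, set())
        # a sequence start is preceded by its own separator occurrence,
        # which never equals any real window: block merges across it
        preds[wins[0][1]].add(("^", j))

    # unary links: u -> v mergeable
    out_link: dict[object, object] = {}
    in_link: dict[object, object] = {}
    for u, sset in succs.items():
        if len(sset) == 1:
            (v,) = sset
            if len(preds[v]) == 1:
                out_link[u] = v
                in_link[v] = u

    heads = [key for key in occ if key not in in_link]
    strings: list[str] = []
    positions: list[list[int]] = []
    window_owner: dict[int, tuple[int, int]] = {}
    owner_of_key: dict[object, tuple[int, int]] = {}
    for head in heads:
        node_id = len(strings)
        chain = [head]
        while chain[-1] in out_link:
            chain.append(out_link[chain[-1]])
        first_occ = occ[head][0]
        string = S[first_occ - 1 : first_occ - 1 + k + len(chain) - 1]
        strings.append(string)
        positions.append(sorted(occ[head]))
        for off, key in enumerate(chain):
            owner_of_key[key] = (node_id, off)
    for wins in seq_windows:
        for p, key in wins:
            window_owner[p] = owner_of_key[key]

    walks: list[list[int]] = []
    edges: list[tuple[int, int]] = []
    for wins in seq_windows:
        walk = []
        i = 0
        while i < len(wins):
            node_id, off = owner_of_key[wins[i][1]]
            assert off == 0, "walk must enter nodes at their first window"
            walk.append(node_id)
            i += len(strings[node_id]) - k + 1
        walks.append(walk)
        edges.extend(zip(walk, walk[1:]))
    return OracleGraph(
        strings=strings,
        positions=positions,
        window_owner=window_owner,
        walks=walks,
        edges=edges,
    )


def oracle_window_owner(g: OracleGraph, p: int) -> str:
    """Node string owning the window starting at text position ``p``."""
    if p not in g.window_owner:
        raise ValueError(f"no window starts at position {p}")
    return g.strings[g.window_owner[p][0]]


def oracle_node_path(g: OracleGraph, p: int, m: int, k: int) -> tuple[list[int], int]:
    """Node visit chain covering windows ``p .. p+m-k`` plus final offset.

    Returns the chain of oracle node ids spelling a length-``m``
    occurrence starting at ``p`` and the number of characters preceding
    the final window inside its owning node.
    """
    last = p + m - k
    path = []
    q = p
    node_id, off = g.window_owner[q]
    path.append(node_id)
    q += len(g.strings[node_id]) - k + 1 - off
    while q <= last:
        node_id, off = g.window_owner[q]
        path.append(node_id)
        q += len(g.strings[node_id]) - k + 1
    return path, g.window_owner[last][1]
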