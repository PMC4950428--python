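"""Pattern-to-node search and per-sequence membership queries.

A pattern ``P`` with ``|P| >= k`` is searched backward on the FM-index.
The node owning its final k-mer is located by forward steps with Psi
until a node marker fires (stop node, right-maximal interval boundary
parity, or a ``B_l`` one at the interval's right boundary); the rest of
the pattern then walks predecessor nodes, collecting the node path.

Per-sequence counts use the document array: for every suffix array
position, the sequence owning that suffix.  Range-distinct queries over
its wavelet tree list the sequences containing a pattern or node with
their occurrence counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pancdbg.build import (
    ImplicitGraph,
    id_left_split,
    id_right_maximal,
    in_right_maximal,
)
from pancdbg.kmer_marks import KmerMarks
from pancdbg.text_index import (
    EMPTY_INTERVAL,
    FMIndex,
    Interval,
    PanGenomeText,
    WaveletTree,
    backward_search,
    psi,
)


@dataclass
class DocumentArray:
    """Sequence ownership of every suffix array position (1-based values)."""

    D: np.ndarray  # D[i-1] = sequence number owning SA[i]
    wt: WaveletTree
    d: int

    def __getitem__(self, i: int) -> int:
        return int(self.D[i - 1])


@dataclass
class SearchResult:
    """Node path of a pattern, its SA interval and in-node offset.

    ``resList`` lists the identifiers of the nodes covering the pattern
    in order; ``iv`` is the suffix array interval of the full pattern and
    ``offset`` the number of characters preceding the pattern's final
    k-mer inside the last node's string.
    """

    resList: list[int] = field(default_factory=list)
    iv: Interval = EMPTY_INTERVAL
    offset: int = 0

    @property
    def found(self) -> bool:
        return not self.iv.is_empty


def build_document_array(fm: FMIndex, text: PanGenomeText) -> DocumentArray:
    """D[i] = sequence owning SA[i]; terminators belong to the sequence they end."""
    starts = np.asarray(text.seq_starts, dtype=np.int64)
    sa = fm.sa  # 1-based positions
    D = np.searchsorted(starts, sa, side="right").astype(np.int64)
    wt = WaveletTree(D - 1, text.d)
    return DocumentArray(D=D, wt=wt, d=text.d)


def locate_node_of_interval(
    fm: FMIndex,
    marks: KmerMarks,
    G: ImplicitGraph,
    iv: Interval,
    d: int | None = None,
) -> tuple[int, int]:
    """Find the node owning the k-mer whose full interval chains to ``iv``.

    ``iv`` must be the interval of a string of length >= k occurring in
    ``S`` whose k-prefix is a window of a single node.  Forward steps
    with Psi drop the leading character until a node marker fires.
    Returns ``(id, ell)`` such that the node's string has exactly
    ``G[id].len - ell - k`` characters before the k-mer window that
    prefixes the queried string (for non-stop nodes ``ell`` is the
    number of Psi applications performed).
    """
    if iv.is_empty:
        raise ValueError("empty interval")
    d = G.d if d is None else d
    base = G.rightMax + G.leftMax
    i, j = iv.lb, iv.rb
    for steps in range(fm.n + 1):
        if i <= d:
            # the remaining string is a separator: stop node found
            return base + i, steps + 1 - G.k
        cur = Interval(i, j)
        if in_right_maximal(marks, cur):
            return id_right_maximal(marks, i), steps
        if marks.B_l[j] == 1:
            return id_left_split(marks, i), steps
        i, j = psi(fm, i), psi(fm, j)
    raise RuntimeError("interval does not chain to any node marker")


def _resolve_node(marks: KmerMarks, iv: Interval) -> int:
    """Node whose string ends with the k-mer prefixing the interval's string."""
    if in_right_maximal(marks, iv):
        return id_right_maximal(marks, iv.lb)
    return id_left_split(marks, iv.lb)


def search_pattern(
    fm: FMIndex,
    marks: KmerMarks,
    G: ImplicitGraph,
    P: str,
    k: int | None = None,
) -> SearchResult:
    """Locate the node path spelling pattern ``P`` (``|P| >= k``).

    Returns an empty result if ``P`` does not occur.  Otherwise
    ``resList`` holds the identifiers of the nodes whose strings cover
    ``P`` in order, ``iv`` the interval of the full pattern (occurrence
    positions are ``SA[iv.lb..iv.rb]``), and ``offset`` the number of
    characters preceding ``P``'s final k-mer in the last node.
    """
    k = G.k if k is None else k
    m = len(P)
    if m < k:
        raise ValueError(f"pattern length {m} is below k = {k}")
    if "$" in P or "#" in P:
        raise ValueError("pattern contains a reserved separator symbol")
    iv = Interval(1, fm.n)
    for c in reversed(P[m - k :]):
        iv = backward_search(fm, c, iv)
        if iv.is_empty:
            return SearchResult()
    ident, ell_found = locate_node_of_interval(fm, marks, G, iv)
    ell = G[ident].len - ell_found - k  # characters before P's k-suffix
    offset = ell
    res = [ident]
    for pos in range(m - k, 0, -1):
        iv = backward_search(fm, P[pos - 1], iv)
        if iv.is_empty:
            return SearchResult()
        if ell > 0:
            ell -= 1
        else:
            ident = _resolve_node(marks, iv)
            res.insert(0, ident)
            ell = G[ident].len - k
    return SearchResult(resList=res, iv=iv, offset=offset)


def interval_sequences(
    doc: DocumentArray, iv: Interval
) -> list[tuple[int, int]]:
    """Sequences owning suffixes in ``iv`` with occurrence counts, ascending."""
    if iv.is_empty:
        return []
    return [
        (code + 1, hi - lo)
        for code, lo, hi in doc.wt.range_distinct(iv.lb, iv.rb)
    ]


def node_sequences(
    doc: DocumentArray, G: ImplicitGraph, id: int
) -> list[tuple[int, int]]:
    """Per-sequence occurrence counts of node ``id``'s string."""
    node = G[id]
    return interval_sequences(doc, Interval(node.lb, node.lb + node.size - 1))
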