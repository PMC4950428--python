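"""Conversion of the implicit graph to the explicit splitMEM-style form.

One backward walk per sequence, starting at its stop node, recovers
position lists and visit-ordered adjacency lists.  Walks are processed
in descending text order and entries are prepended, so position lists
come out ascending and adjacency lists in visit order without sorting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pancdbg.build import (
    ImplicitGraph,
    id_left_split,
    id_right_maximal,
    in_right_maximal,
    node_string,
)
from pancdbg.kmer_marks import KmerMarks
from pancdbg.text_index import FMIndex, Interval, PanGenomeText, lf_map


@dataclass
class ExplicitNode:
    id: int
    len: int
    posList: list[int] = field(default_factory=list)
    adjList: list[int] = field(default_factory=list)


@dataclass
class ExplicitGraph:
    nodes: list[ExplicitNode]
    StartNodes: list[int]  # identifier of the start node of each sequence

    def __getitem__(self, id: int) -> ExplicitNode:
        if not 1 <= id <= len(self.nodes):
            raise IndexError(f"node identifier {id} outside 1..{len(self.nodes)}")
        return self.nodes[id - 1]

    @property
    def N(self) -> int:
        return len(self.nodes)

    def edge_count(self) -> int:
        return sum(len(nd.adjList) for nd in self.nodes)


def suffix_index_shift(G: ImplicitGraph, id: int, i: int) -> int:
    """Map index ``i`` of the node's k-suffix interval into its full interval.

    For a non-stop node with record ``(len, lb, size, suffix_lb)``, the
    suffix at index ``i`` of ``[suffix_lb..suffix_lb+size-1]`` reappears
    at index ``lb + (i - suffix_lb)``: the occurrence of the k-suffix at
    text position ``p`` corresponds to the occurrence of the full node
    string at ``p - (len - k)``, and relative order is preserved.  When
    ``len == k`` this is the identity.
    """
    node = G[id]
    if G.is_stop(id):
        raise ValueError(f"node {id} is a stop node")
    if not node.suffix_lb <= i <= node.suffix_lb + node.size - 1:
        raise IndexError(
            f"index {i} outside suffix interval "
            f"[{node.suffix_lb}..{node.suffix_lb + node.size - 1}]"
        )
    return node.lb + (i - node.suffix_lb)


def _resolve_predecessor(marks: KmerMarks, i: int) -> int:
    """Identifier of the node whose string ends with the k-mer at index ``i``."""
    if in_right_maximal(marks, Interval(i, i)):
        return id_right_maximal(marks, i)
    return id_left_split(marks, i)


def to_explicit(
    fm: FMIndex, marks: KmerMarks, G: ImplicitGraph
) -> ExplicitGraph:
    """Backward-walk every sequence to build posList/adjList/StartNodes."""
    nodes = [ExplicitNode(id=ident, len=G[ident].len) for ident in G.ids()]
    base = G.rightMax + G.leftMax
    # stop node s (suffix_lb = s) terminates at text position SA[s];
    # walk sequences in descending terminator position so prepending
    # yields ascending position lists
    order = sorted(
        range(1, G.d + 1), key=lambda s: fm.sa_value(s), reverse=True
    )
    start_by_seq: dict[int, int] = {}
    for s in order:
        ident = base + s
        term_pos = fm.sa_value(s)
        seq_j = fm.text.sequence_of_position(term_pos)
        pos = term_pos - G[ident].len + 1
        idx = G[ident].lb  # stop nodes have size 1
        while True:
            nodes[ident - 1].posList.insert(0, pos)
            c = fm.bwt[idx - 1]
            if c in ("$", "#"):
                start_by_seq[seq_j] = ident
                break
            i = lf_map(fm, idx)
            new_id = _resolve_predecessor(marks, i)
            nodes[new_id - 1].adjList.insert(0, ident)
            pos = pos - 1 - (G[new_id].len - G.k)
            idx = suffix_index_shift(G, new_id, i)
            ident = new_id
    if len(start_by_seq) != G.d:
        raise RuntimeError("explicit conversion did not reach every sequence start")
    return ExplicitGraph(
        nodes=nodes, StartNodes=[start_by_seq[j] for j in range(1, G.d + 1)]
    )


def reconstruct_sequence(
    explicit: ExplicitGraph,
    text: PanGenomeText,
    fm: FMIndex,
    G: ImplicitGraph,
    j: int,
) -> str:
    """Rebuild sequence ``j`` (with terminator) by walking the adjacency lists.

    Consecutive node strings overlap ``k - 1`` characters.  Used as a
    round-trip validation of the explicit conversion.
    """
    if not 1 <= j <= G.d:
        raise IndexError(f"sequence index {j} outside 1..{G.d}")
    k = G.k
    start = text.seq_starts[j - 1]
    ident = explicit.StartNodes[j - 1]
    if start not in explicit[ident].posList:
        raise RuntimeError(
            f"start node {ident} has no occurrence at position {start}"
        )
    out = node_string(fm, G, ident)
    pos = start
    while ident <= G.rightMax + G.leftMax:  # a stop node ends the walk
        node = explicit[ident]
        # the i-th visit of a node consumes adjList[i]; posList and adjList
        # are aligned because both were prepended in the same walk order
        visit = node.posList.index(pos)
        if visit >= len(node.adjList):
            raise RuntimeError(f"node {ident}: visit {visit} has no successor")
        nxt = explicit[node.adjList[visit]]
        pos = pos + (node.len - (k - 1))
        if pos not in nxt.posList:
            raise RuntimeError(
                f"adjacency breaks at node {node.id} -> {nxt.id}: "
                f"no visit at position {pos}"
            )
        out += node_string(fm, G, nxt.id)[k - 1 :]
        ident = nxt.id
    return out
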