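"""Implicit compressed de Bruijn graph construction (leftward extension).

Nodes are records ``(len, lb, size, suffix_lb)``: the node string is
``S[SA[lb]..SA[lb]+len-1]``, ``[lb..lb+size-1]`` its suffix array
interval, and ``[suffix_lb..suffix_lb+size-1]`` the interval of its
length-k suffix (for stop nodes, the SA index of the terminating
separator).  Construction seeds one node per right-maximal k-mer and one
stop node per sequence, then repeatedly extends each node to the left
with the generalized backward step, splitting off new nodes when the
extension is ambiguous or runs into a right-maximal k-mer.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from pancdbg.text_index import FMIndex, Interval, get_intervals
from pancdbg.kmer_marks import KmerMarks


@dataclass
class ImplicitNode:
    len: int
    lb: int
    size: int
    suffix_lb: int

    def interval(self) -> Interval:
        return Interval(self.lb, self.lb + self.size - 1)

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.len, self.lb, self.size, self.suffix_lb)


@dataclass
class ImplicitGraph:
    """Array of implicit nodes indexed by identifier 1..N.

    Identifiers 1..rightMax belong to nodes ending with a right-maximal
    k-mer (lexicographic k-mer order), the next leftMax to split nodes
    (ordered by their B_l rank), and the final d to stop nodes.
    """

    nodes: list[ImplicitNode]
    k: int
    d: int
    rightMax: int
    leftMax: int

    @property
    def N(self) -> int:
        return len(self.nodes)

    def __getitem__(self, id: int) -> ImplicitNode:
        if not 1 <= id <= len(self.nodes):
            raise IndexError(f"node identifier {id} outside 1..{len(self.nodes)}")
        return self.nodes[id - 1]

    def is_stop(self, id: int) -> bool:
        return id > self.rightMax + self.leftMax

    def ids(self) -> range:
        return range(1, len(self.nodes) + 1)


def in_right_maximal(marks: KmerMarks, iv: Interval) -> bool:
    """Is ``iv`` a subinterval of a right-maximal k-mer interval?

    False iff ``rank1(B_r, lb)`` is even and ``B_r[lb] = 0``; marked
    intervals are disjoint, so boundary parity decides membership.
    """
    if iv.is_empty:
        raise ValueError("empty interval")
    return marks.B_r.rank1(iv.lb) % 2 == 1 or marks.B_r[iv.lb] == 1


def id_right_maximal(marks: KmerMarks, lb: int) -> int:
    """Identifier of the right-maximal k-mer interval containing ``lb``."""
    return (marks.B_r.rank1(lb) + 1) // 2


def id_left_split(marks: KmerMarks, lb: int) -> int:
    """Identifier ``rightMax + rank1(B_l, lb-1) + 1`` of a split node."""
    return marks.rightMax + marks.B_l.rank1(lb - 1) + 1


def build_implicit(fm: FMIndex, marks: KmerMarks, k: int | None = None,
                   d: int | None = None,
                   trace: list[tuple] | None = None) -> ImplicitGraph:
    """Build the implicit compressed de Bruijn graph of order ``k``.

    Seeds are installed at identifiers fixed by the rank formulas, then a
    FIFO queue drives the left-extension loop.  For each dequeued node
    the one-symbol extensions of its interval are examined:

    * separator symbols are dropped (a sequence start was reached);
    * extensions whose interval lies in a right-maximal k-mer interval
      stop (the predecessor node ends there and was seeded already);
    * if the extension list had a single element the node absorbs it
      (``len + 1``, new ``lb``) and the loop continues;
    * otherwise the node string is left-maximal and every surviving
      extension spawns (or re-finds) a split node holding the full
      interval of its k-mer prefix.

    When ``trace`` is a list, construction events are appended to it as
    tuples: ``("seed"|"stop_seed", id, record)``, ``("extend", id,
    record)`` after each left-extension, ``("split", id, record)`` when a
    split node is created, and ``("halt", id, lb, rank1_Br_lb)`` when an
    extension branch stops at a right-maximal k-mer interval.
    """
    k = marks.k if k is None else k
    d = fm.text.d if d is None else d
    rightMax, leftMax = marks.rightMax, marks.leftMax
    N = rightMax + leftMax + d
    nodes: list[ImplicitNode | None] = [None] * N
    queue: deque[int] = deque()
    for ident, (ln, lb, size, suffix_lb) in enumerate(marks.seeds, start=1):
        nodes[ident - 1] = ImplicitNode(ln, lb, size, suffix_lb)
        queue.append(ident)
        if trace is not None:
            trace.append(("seed", ident, nodes[ident - 1].as_tuple()))
    for j in range(1, d + 1):
        ident = rightMax + leftMax + j
        nodes[ident - 1] = ImplicitNode(1, j, 1, j)
        queue.append(ident)
        if trace is not None:
            trace.append(("stop_seed", ident, nodes[ident - 1].as_tuple()))

    seen_split = [False] * N
    while queue:
        ident = queue.popleft()
        node = nodes[ident - 1]
        while True:
            iv = Interval(node.lb, node.lb + node.size - 1)
            pairs = get_intervals(fm, iv)
            single = len(pairs) == 1
            extended = False
            for c, sub in pairs:
                if c in ("$", "#"):
                    continue  # start of a sequence: nothing precedes
                if in_right_maximal(marks, sub):
                    if trace is not None:
                        trace.append(
                            ("halt", ident, sub.lb, marks.B_r.rank1(sub.lb))
                        )
                    continue  # a predecessor node ends with this k-mer
                if single:
                    node.lb = sub.lb
                    node.len += 1
                    extended = True
                    if trace is not None:
                        trace.append(("extend", ident, node.as_tuple()))
                else:
                    new_id = id_left_split(marks, sub.lb)
                    if not seen_split[new_id - 1]:
                        seen_split[new_id - 1] = True
                        nodes[new_id - 1] = ImplicitNode(
                            k, sub.lb, sub.size, sub.lb
                        )
                        queue.append(new_id)
                        if trace is not None:
                            trace.append(
                                ("split", new_id, nodes[new_id - 1].as_tuple())
                            )
            if not extended:
                break
    missing = [i + 1 for i, nd in enumerate(nodes) if nd is None]
    if missing:
        raise RuntimeError(
            f"implicit graph incomplete: identifiers {missing} never seeded"
        )
    return ImplicitGraph(
        nodes=nodes, k=k, d=d, rightMax=rightMax, leftMax=leftMax
    )


def node_string(fm: FMIndex, G: ImplicitGraph, id: int) -> str:
    """The string ``S[SA[lb]..SA[lb]+len-1]`` of node ``id``."""
    node = G[id]
    start = fm.sa_value(node.lb)
    return fm.text.substring(start, start + node.len - 1)


def node_positions(fm: FMIndex, G: ImplicitGraph, id: int) -> list[int]:
    """Sorted 1-based start positions of the node's string in ``S``."""
    node = G[id]
    return sorted(
        fm.sa_value(i) for i in range(node.lb, node.lb + node.size)
    )
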