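"""Level-k LCP computation from the BWT and the k-mer marking vectors.

A two-bit level array records, for every LCP position, whether the value
is below, equal to, or above ``k``.  It is filled by a breadth-first
interval walk over the wavelet tree (values appear in ascending order),
seeded so that distinct occurrences of the separator ``#`` behave like
distinct characters: no repeat may span a sequence boundary.

From the level array two bit vectors are derived:

* ``B_r`` marks the left and right boundary of every right-maximal
  k-mer interval (an lcp-interval of lcp-value ``k``).
* ``B_l`` marks positions whose k-mer is not right-maximal, is the last
  suffix of its k-mer interval, and precedes a left-maximal k-mer.

Together they provide the identifier arithmetic of the implicit
compressed de Bruijn graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pancdbg.text_index import (
    FMIndex,
    Interval,
    RankBitVector,
    get_intervals,
)


class LcpLevelArray:
    """Two-bit codes of LCP entries relative to ``k``.

    Code 0 means ``LCP < k``, 1 means ``LCP = k``, 2 means ``LCP > k``.
    Entries are 1-based; there are ``n + 1`` of them and the first and
    last are always 0 (they encode the virtual value -1).
    """

    __slots__ = ("codes", "k")

    def __init__(self, codes: np.ndarray, k: int):
        self.codes = codes
        self.k = k

    def __len__(self) -> int:
        return len(self.codes)

    def __getitem__(self, p: int) -> int:
        if not 1 <= p <= len(self.codes):
            raise IndexError(f"LCP position {p} outside 1..{len(self.codes)}")
        return int(self.codes[p - 1])


@dataclass
class KmerMarks:
    """Marking vectors and node seeds for one value of ``k``."""

    B_r: RankBitVector
    B_l: RankBitVector
    rightMax: int
    leftMax: int
    k: int
    seeds: list[tuple[int, int, int, int]]  # (len, lb, size, suffix_lb)


def _validate_k(fm: FMIndex, k: int) -> None:
    shortest = min(fm.text.seq_lengths)
    if not 2 <= k < shortest:
        raise ValueError(
            f"k must satisfy 2 <= k < min sequence length "
            f"({shortest}); got {k}"
        )


def compute_lcp_levels(fm: FMIndex, k: int, d: int | None = None) -> LcpLevelArray:
    """Fill the two-bit level array for ``k`` directly from the BWT.

    Breadth-first over string lengths 1..k+1: the interval of a string of
    length ``l`` whose right neighbour position is still unset assigns it
    the LCP value ``l - 1`` and is extended with every one-symbol left
    extension.  The ``#``-interval is replaced by its singleton positions
    ``[s..s]``, ``2 <= s <= d``, so separator occurrences never share a
    prefix: the resulting values realize the modified order in which
    distinct ``#`` occurrences are mutually distinct characters.
    """
    _validate_k(fm, k)
    n = fm.n
    d = fm.text.d if d is None else d
    codes = np.full(n + 1, 2, dtype=np.uint8)
    codes[0] = 0
    codes[n] = 0
    is_set = np.zeros(n + 2, dtype=bool)
    is_set[1] = True
    is_set[n + 1] = True

    # level-1 seeds: single-character intervals, '#' exploded to singletons
    queue: list[Interval] = []
    C = fm._C_by_code
    sigma = fm.sigma
    for code in range(sigma):
        lo = int(C[code]) + 1
        hi = int(C[code + 1]) if code + 1 < sigma else n
        if hi < lo:
            continue
        if fm.text.alphabet[code] == "#":
            queue.extend(Interval(s, s) for s in range(lo, hi + 1))
        else:
            queue.append(Interval(lo, hi))

    for level in range(1, k + 2):
        if not queue:
            break
        value = level - 1
        level_code = 0 if value < k else 1  # value == k at the last level
        nxt: list[Interval] = []
        for iv in queue:
            p = iv.rb + 1
            if is_set[p]:
                continue
            is_set[p] = True
            codes[p - 1] = level_code
            if level <= k:
                nxt.extend(sub for _, sub in get_intervals(fm, iv))
        queue = nxt
    return LcpLevelArray(codes, k)


def mark_right_maximal(
    fm: FMIndex, L: LcpLevelArray, k: int
) -> tuple[RankBitVector, list[tuple[int, int, int, int]], list[int]]:
    """Mark right-maximal k-mer intervals and seed the initial nodes.

    A maximal run ``[lb..rb]`` with boundary codes 0, interior codes >= 1
    and at least one interior code 1 is the interval of a right-maximal
    k-mer.  Both boundaries are set in ``B_r`` and a node record
    ``(k, lb, rb - lb + 1, lb)`` is seeded; identifiers follow discovery
    (= lexicographic) order, so ``id = (rank1(B_r, lb) + 1) // 2``.
    """
    n = fm.n
    bits = np.zeros(n, dtype=np.uint8)
    seeds: list[tuple[int, int, int, int]] = []
    lb = 1
    has_exact = False
    for i in range(2, n + 2):
        code = L[i]
        if code == 0:
            if has_exact:
                rb = i - 1
                bits[lb - 1] = 1
                bits[rb - 1] = 1
                seeds.append((k, lb, rb - lb + 1, lb))
            lb = i
            has_exact = False
        elif code == 1:
            has_exact = True
    queue = list(range(1, len(seeds) + 1))
    return RankBitVector(bits), seeds, queue


def mark_bl(
    fm: FMIndex, L: LcpLevelArray, B_r: RankBitVector, k: int
) -> RankBitVector:
    """Mark non-right-maximal k-mers that precede a left-maximal k-mer.

    One left-to-right scan over the BWT keeps the running C-array (so
    that after position ``q`` was consumed, ``C[c] = LF[q]`` for the last
    occurrence ``q`` of ``c``) and ``lastdiff``, the largest index where
    consecutive BWT symbols differ.  When a run of LCP >= k closes at
    ``[lb..rb]`` (the interval of some k-mer repeat) and ``lastdiff > lb``
    (the repeat is left-maximal), the LF image of the last occurrence of
    every non-separator symbol in ``BWT[lb..rb]`` is set.  Ones that fall
    inside right-maximal k-mer intervals are cleared afterwards.
    """
    n = fm.n
    sigma = fm.sigma
    alphabet = fm.text.alphabet
    separator_codes = {
        code for code, c in enumerate(alphabet) if c in ("$", "#")
    }
    bwt_codes = np.fromiter(
        (fm._code_of[c] for c in fm.bwt), dtype=np.int64, count=n
    )
    C_run = fm._C_by_code.astype(np.int64).copy()
    last_occ = np.zeros(sigma, dtype=np.int64)
    last_lf = np.zeros(sigma, dtype=np.int64)
    bits = np.zeros(n, dtype=np.uint8)
    lastdiff = 0
    lb = 1
    for i in range(1, n + 2):
        if i >= 2:
            # consume BWT[i-1]; afterwards C_run[c] == LF[i-1]
            c = int(bwt_codes[i - 2])
            C_run[c] += 1
            last_occ[c] = i - 1
            last_lf[c] = C_run[c]
            if i >= 3 and bwt_codes[i - 2] != bwt_codes[i - 3]:
                lastdiff = i - 1
        if L[i] == 0:
            rb = i - 1
            if rb > lb and lastdiff > lb:
                for c in range(sigma):
                    if c in separator_codes:
                        continue
                    if last_occ[c] >= lb:
                        bits[last_lf[c] - 1] = 1
            lb = i
    # keep only marks outside right-maximal k-mer intervals
    for p in np.flatnonzero(bits):
        pos = int(p) + 1
        if B_r.rank1(pos) % 2 == 1 or B_r[pos] == 1:
            bits[p] = 0
    return RankBitVector(bits)


def build_kmer_marks(fm: FMIndex, k: int) -> KmerMarks:
    """Run the full marking pass: level array, ``B_r``, seeds, ``B_l``."""
    L = compute_lcp_levels(fm, k)
    B_r, seeds, _ = mark_right_maximal(fm, L, k)
    B_l = mark_bl(fm, L, B_r, k)
    return KmerMarks(
        B_r=B_r,
        B_l=B_l,
        rightMax=len(seeds),
        leftMax=B_l.rank1(fm.n),
        k=k,
        seeds=seeds,
    )
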