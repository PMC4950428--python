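"""FM-index of a concatenated pan-genome.

The text is the concatenation ``S = S1 # S2 # ... # Sd $`` of ``d`` input
sequences, where ``#`` separates sequences and ``$`` terminates the text.
The index consists of the suffix array, the Burrows-Wheeler transform
stored in a rank-capable wavelet tree, and the ``C`` array of cumulative
symbol counts.  All public coordinates are 1-based and intervals are
closed, so every value can be checked against a hand-written suffix table
directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np

SENTINEL = "$"
SEPARATOR = "#"
RESERVED = frozenset((SENTINEL, SEPARATOR))


class ReservedSymbolError(ValueError):
    """An input sequence contains '$' or '#'."""


class Interval(NamedTuple):
    """Closed 1-based suffix array interval; ``lb > rb`` encodes empty."""

    lb: int
    rb: int

    @property
    def is_empty(self) -> bool:
        return self.lb > self.rb

    @property
    def size(self) -> int:
        return 0 if self.is_empty else self.rb - self.lb + 1


EMPTY_INTERVAL = Interval(1, 0)


@dataclass(frozen=True)
class PanGenomeText:
    """Concatenated pan-genome with sequence-boundary metadata.

    Attributes
    ----------
    S:
        The text ``S1#S2#...#Sd$`` as a plain string.
    names:
        Record names of the ``d`` input sequences, in file order.
    seq_lengths:
        Length of each input sequence (separators excluded).
    seq_starts:
        1-based start position of each sequence in ``S``.
    alphabet:
        Distinct symbols of ``S`` in index order: ``$`` < ``#`` < the
        remaining symbols in ascending byte order.
    """

    S: str
    names: tuple[str, ...]
    seq_lengths: tuple[int, ...]
    seq_starts: tuple[int, ...]
    alphabet: str

    @property
    def n(self) -> int:
        return len(self.S)

    @property
    def d(self) -> int:
        return len(self.seq_lengths)

    def at(self, p: int) -> str:
        """Character ``S[p]``, 1-based."""
        if not 1 <= p <= self.n:
            raise IndexError(f"position {p} outside text of length {self.n}")
        return self.S[p - 1]

    def substring(self, i: int, j: int) -> str:
        """``S[i..j]``, 1-based closed."""
        return self.S[i - 1 : j]

    def sequence(self, j: int) -> str:
        """The ``j``-th input sequence (1-based), without its terminator."""
        if not 1 <= j <= self.d:
            raise IndexError(f"sequence index {j} outside 1..{self.d}")
        start = self.seq_starts[j - 1]
        return self.S[start - 1 : start - 1 + self.seq_lengths[j - 1]]

    def sequence_of_position(self, p: int) -> int:
        """1-based index of the sequence owning text position ``p``.

        A terminator belongs to the sequence it ends ('$' to the last one).
        """
        if not 1 <= p <= self.n:
            raise IndexError(f"position {p} outside text of length {self.n}")
        for j in range(self.d - 1, -1, -1):
            if p >= self.seq_starts[j]:
                return j + 1
        raise AssertionError("unreachable")


def encode_and_concatenate(sequences: Sequence[tuple[str, str]]) -> PanGenomeText:
    """Concatenate input records into ``S = S1#...#Sd$`` with metadata.

    Sequences are uppercased.  Raises :class:`ReservedSymbolError` if a
    sequence contains '$' or '#', and :class:`ValueError` for an empty
    record list or an empty sequence.
    """
    if not sequences:
        raise ValueError("at least one input sequence is required")
    names = []
    seqs = []
    for name, seq in sequences:
        seq = seq.upper()
        if not seq:
            raise ValueError(f"record {name!r} has an empty sequence")
        if RESERVED & set(seq):
            raise ReservedSymbolError(
                f"record {name!r} contains a reserved symbol ('$' or '#')"
            )
        names.append(name)
        seqs.append(seq)
    S = SEPARATOR.join(seqs) + SENTINEL
    starts = []
    pos = 1
    for seq in seqs:
        starts.append(pos)
        pos += len(seq) + 1
    others = sorted(set(S) - RESERVED)
    alphabet = SENTINEL + (SEPARATOR if len(seqs) > 1 else "") + "".join(others)
    return PanGenomeText(
        S=S,
        names=tuple(names),
        seq_lengths=tuple(len(s) for s in seqs),
        seq_starts=tuple(starts),
        alphabet=alphabet,
    )


class RankBitVector:
    """Plain bit vector with O(1) rank1 via a cumulative-count table."""

    def __init__(self, bits: np.ndarray | Sequence[int]):
        self.bits = np.asarray(bits, dtype=np.uint8)
        self._cum = np.concatenate(
            ([0], np.cumsum(self.bits, dtype=np.int64))
        )

    def __len__(self) -> int:
        return len(self.bits)

    def __getitem__(self, i: int) -> int:
        """Bit at 1-based position ``i``."""
        return int(self.bits[i - 1])

    def rank1(self, i: int) -> int:
        """Number of ones in positions ``1..i``; ``rank1(0) = 0``."""
        if not 0 <= i <= len(self.bits):
            raise IndexError(f"rank position {i} outside 0..{len(self.bits)}")
        return int(self._cum[i])

    def ones(self) -> list[int]:
        """1-based positions of all ones."""
        return [int(p) + 1 for p in np.flatnonzero(self.bits)]


class WaveletTree:
    """Balanced binary wavelet tree over an integer code sequence.

    Codes lie in ``[0, sigma)``.  Each internal node over the code range
    ``[lo, hi)`` stores, for the subsequence routed to it, the cumulative
    count of symbols with code >= mid, which yields rank queries for any
    code in O(log sigma) time and a range-distinct traversal used by the
    generalized backward search.
    """

    def __init__(self, codes: np.ndarray, sigma: int):
        self.sigma = sigma
        self.n = len(codes)
        self._cums: dict[tuple[int, int], np.ndarray] = {}
        self._build(np.asarray(codes, dtype=np.int64), 0, sigma)

    def _build(self, codes: np.ndarray, lo: int, hi: int) -> None:
        if hi - lo <= 1 or len(codes) == 0:
            # leaves store nothing; positions there are ranks already
            return
        mid = (lo + hi) // 2
        right = codes >= mid
        self._cums[(lo, hi)] = np.concatenate(
            ([0], np.cumsum(right, dtype=np.int64))
        )
        self._build(codes[~right], lo, mid)
        self._build(codes[right], mid, hi)

    def rank(self, code: int, i: int) -> int:
        """Occurrences of ``code`` among the first ``i`` symbols (1-based)."""
        if not 0 <= code < self.sigma:
            raise ValueError(f"code {code} outside alphabet of size {self.sigma}")
        if not 0 <= i <= self.n:
            raise IndexError(f"rank position {i} outside 0..{self.n}")
        lo, hi = 0, self.sigma
        while hi - lo > 1:
            cum = self._cums.get((lo, hi))
            if cum is None:
                return 0
            mid = (lo + hi) // 2
            ones = int(cum[i])
            if code >= mid:
                i = ones
                lo = mid
            else:
                i = i - ones
                hi = mid
        return i

    def range_distinct(self, l: int, r: int) -> list[tuple[int, int, int]]:
        """Distinct codes in the (1-based, closed) range ``[l..r]``.

        Returns ``(code, rank_code(l-1), rank_code(r))`` triples in
        ascending code order; only codes occurring in the range appear.
        """
        if r < l:
            return []
        out: list[tuple[int, int, int]] = []
        self._range_distinct(l - 1, r, 0, self.sigma, out)
        return out

    def _range_distinct(
        self, a: int, b: int, lo: int, hi: int, out: list
    ) -> None:
        if a >= b:
            return
        if hi - lo == 1:
            out.append((lo, a, b))
            return
        cum = self._cums.get((lo, hi))
        if cum is None:
            return
        mid = (lo + hi) // 2
        a1, b1 = int(cum[a]), int(cum[b])
        self._range_distinct(a - a1, b - b1, lo, mid, out)
        self._range_distinct(a1, b1, mid, hi, out)


def _suffix_array_doubling(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (numpy lexsort); 1-based values.

    Correct for any integer sequence with a unique minimum at the end.
    """
    n = len(codes)
    rank = np.asarray(codes, dtype=np.int64)
    if n == 1:
        return np.array([1], dtype=np.int64)
    step = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - step] = rank[step:]
        order = np.lexsort((key2, rank))
        changed = (rank[order][1:] != rank[order][:-1]) | (
            key2[order][1:] != key2[order][:-1]
        )
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order[0]] = 0
        new_rank[order[1:]] = np.cumsum(changed)
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order.astype(np.int64) + 1
        step *= 2


@dataclass
class FMIndex:
    """Suffix array, BWT, wavelet tree and C-array of a pan-genome text."""

    text: PanGenomeText
    sa: np.ndarray  # sa[i-1] = SA[i], 1-based values
    bwt: str
    wt: WaveletTree
    C: dict[str, int]
    _code_of: dict[str, int] = field(repr=False, default_factory=dict)
    _C_by_code: np.ndarray = field(repr=False, default=None)
    _psi: np.ndarray = field(repr=False, default=None)  # psi[i-1], 1-based values

    @property
    def n(self) -> int:
        return self.text.n

    @property
    def sigma(self) -> int:
        return len(self.text.alphabet)

    def code(self, c: str) -> int | None:
        return self._code_of.get(c)

    def sa_value(self, i: int) -> int:
        """``SA[i]``, 1-based both ways."""
        if not 1 <= i <= self.n:
            raise IndexError(f"suffix array index {i} outside 1..{self.n}")
        return int(self.sa[i - 1])


def build_fm_index(text: PanGenomeText) -> FMIndex:
    """Build the FM-index (SA, BWT, wavelet tree, C-array) of ``text``."""
    code_of = {c: k for k, c in enumerate(text.alphabet)}
    codes = np.fromiter(
        (code_of[c] for c in text.S), dtype=np.int64, count=text.n
    )
    sa = _suffix_array_doubling(codes)
    sa0 = sa - 1  # 0-based positions
    bwt_codes = codes[(sa0 - 1) % text.n]
    bwt = "".join(text.alphabet[c] for c in bwt_codes)
    sigma = len(text.alphabet)
    counts = np.bincount(codes, minlength=sigma)
    C_by_code = np.concatenate(([0], np.cumsum(counts)))[:sigma]
    C = {c: int(C_by_code[k]) for c, k in code_of.items()}
    wt = WaveletTree(bwt_codes, sigma)
    # LF as an array (per-symbol stable ranking), inverted to get psi
    lf = np.empty(text.n, dtype=np.int64)
    for k in range(sigma):
        idx = np.flatnonzero(bwt_codes == k)
        lf[idx] = C_by_code[k] + np.arange(1, len(idx) + 1)
    psi_arr = np.empty(text.n, dtype=np.int64)
    psi_arr[lf - 1] = np.arange(1, text.n + 1)
    return FMIndex(
        text=text,
        sa=sa,
        bwt=bwt,
        wt=wt,
        C=C,
        _code_of=code_of,
        _C_by_code=C_by_code,
        _psi=psi_arr,
    )


def lf_map(fm: FMIndex, i: int) -> int:
    """Last-to-first mapping: index of the suffix one position earlier.

    Computed as ``C[BWT[i]] + rank_BWT[i](i)`` on the wavelet tree.
    """
    if not 1 <= i <= fm.n:
        raise IndexError(f"index {i} outside 1..{fm.n}")
    code = fm._code_of[fm.bwt[i - 1]]
    return int(fm._C_by_code[code]) + fm.wt.rank(code, i)


def psi(fm: FMIndex, i: int) -> int:
    """Inverse of the LF-mapping."""
    if not 1 <= i <= fm.n:
        raise IndexError(f"index {i} outside 1..{fm.n}")
    return int(fm._psi[i - 1])


def backward_search(fm: FMIndex, c: str, iv: Interval) -> Interval:
    """One backward search step: the ``c + omega`` interval.

    Returns an empty interval if ``c`` is not in the alphabet or the
    extended string does not occur.
    """
    code = fm._code_of.get(c)
    if code is None or iv.is_empty:
        return EMPTY_INTERVAL
    base = int(fm._C_by_code[code])
    lb = base + fm.wt.rank(code, iv.lb - 1) + 1
    rb = base + fm.wt.rank(code, iv.rb)
    if lb > rb:
        return EMPTY_INTERVAL
    return Interval(lb, rb)


def get_intervals(fm: FMIndex, iv: Interval) -> list[tuple[str, Interval]]:
    """All one-symbol left-extensions of the interval ``iv``.

    Returns ``(c, c-omega-interval)`` pairs for every symbol ``c`` (the
    separators included) such that ``c + omega`` occurs in ``S``, in
    ascending alphabet order.  The returned intervals partition ``iv``
    under the LF mapping: their sizes sum to ``iv.size``.
    """
    if iv.is_empty:
        raise ValueError("get_intervals requires a non-empty interval")
    out = []
    for code, lo_rank, hi_rank in fm.wt.range_distinct(iv.lb, iv.rb):
        base = int(fm._C_by_code[code])
        out.append(
            (fm.text.alphabet[code], Interval(base + lo_rank + 1, base + hi_rank))
        )
    return out
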