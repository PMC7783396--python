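"""Repeat screening: de novo k-mer repeat libraries and overlap-based discard.

The de novo library is built from raw (unassembled) reads: every k-mer
(default 32) is counted canonically — a k-mer and its reverse complement
share one count keyed by the lexicographically smaller — and the most
abundant ``repeat_top_n`` (default 5,000) are concatenated in rank order
into a single repeat reference. An oligo is discarded when it shares an
exact substring of at least ``repeat_overlap_min`` bases (default 28, either
strand) with any repeat reference; user-supplied known repeats (rDNA,
organellar, published families) are screened the same way and take
precedence over the de novo library when attributing the discard.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import DesignParameters, DiscardReason, Oligo, OligoStatus, encode, revcomp


class LibrarySource(enum.Enum):
    KMER_DENOVO = "kmer_denovo"
    KNOWN_FASTA = "known_fasta"


class _SuffixAutomaton:
    """Suffix automaton over a reference string.

    Supports streaming longest-match queries: for a query q, the length of
    the longest substring of q that also occurs in the reference, in O(|q|)
    after O(|reference|) construction.
    """

    def __init__(self, text: str) -> None:
        self._len = [0]
        self._link = [-1]
        self._next: List[Dict[str, int]] = [{}]
        last = 0
        for ch in text:
            cur = len(self._len)
            self._len.append(self._len[last] + 1)
            self._link.append(-1)
            self._next.append({})
            p = last
            while p != -1 and ch not in self._next[p]:
                self._next[p][ch] = cur
                p = self._link[p]
            if p == -1:
                self._link[cur] = 0
            else:
                q = self._next[p][ch]
                if self._len[p] + 1 == self._len[q]:
                    self._link[cur] = q
                else:
                    clone = len(self._len)
                    self._len.append(self._len[p] + 1)
                    self._link.append(self._link[q])
                    self._next.append(dict(self._next[q]))
                    while p != -1 and self._next[p].get(ch) == q:
                        self._next[p][ch] = clone
                        p = self._link[p]
                    self._link[q] = clone
                    self._link[cur] = clone
            last = cur

    def longest_match(self, query: str) -> int:
        best = 0
        state, length = 0, 0
        for ch in query:
            while state and ch not in self._next[state]:
                state = self._link[state]
                length = self._len[state]
            if ch in self._next[state]:
                state = self._next[state][ch]
                length += 1
            else:
                state, length = 0, 0
            if length > best:
                best = length
        return best


@dataclass
class RepeatLibrary:
    """A repeat reference used for overlap screening."""

    k: int
    entries: List[Tuple[str, int]]
    concatenated: str
    source: LibrarySource
    name: str = ""
    _automaton: Optional[_SuffixAutomaton] = field(
        default=None, repr=False, compare=False
    )

    @property
    def automaton(self) -> _SuffixAutomaton:
        if self._automaton is None:
            self._automaton = _SuffixAutomaton(self.concatenated)
        return self._automaton

    @classmethod
    def from_known_sequences(
        cls, sequences: Iterable[str], name: str = "known"
    ) -> "RepeatLibrary":
        """Treat whole repeat sequences (e.g. rDNA, published families) as
        one concatenated reference."""
        concatenated = "".join(sequences)
        return cls(k=0, entries=[], concatenated=concatenated,
                   source=LibrarySource.KNOWN_FASTA, name=name)


@dataclass
class ScreenReport:
    n_in: int
    n_discarded_known: int
    n_discarded_kmer: int
    best_overlap: Dict[str, int]
    discarded: List[Oligo]

    @property
    def n_survivors(self) -> int:
        return self.n_in - self.n_discarded_known - self.n_discarded_kmer


def _window_codes(arr: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Forward and reverse-complement integer codes of every k-window.

    Returns (canonical codes of N-free windows, all-window validity mask is
    applied internally). Codes pack 2 bits per base into uint64, so k <= 32.
    """
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    is_n = (arr == 4).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(is_n)])
    valid = (cs[k:] - cs[:-k]) == 0
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    comp = (3 - arr) & 3  # N maps arbitrarily; N windows are masked out
    a = arr & 3
    for j in range(k):
        fwd |= a[j : j + n].astype(np.uint64) << np.uint64(2 * (k - 1 - j))
        rc |= comp[j : j + n].astype(np.uint64) << np.uint64(2 * j)
    canon = np.minimum(fwd, rc)
    return canon[valid], valid


def _decode_kmer(code: int, k: int) -> str:
    return "".join("ACGT"[(code >> (2 * (k - 1 - j))) & 3] for j in range(k))


def build_kmer_repeat_library(
    reads: Iterable[str],
    params: DesignParameters,
    name: str = "denovo",
) -> RepeatLibrary:
    """Count canonical k-mers in *reads* and concatenate the top-N.

    Ranking is by count descending with lexicographic tie-break on the
    canonical k-mer, which makes the cut deterministic. K-mers containing N
    are skipped. Raises ``ValueError`` when the reads yield no valid k-mer.
    """
    k = params.kmer_k
    if not (1 <= k <= 32):
        raise ValueError("kmer_k must be in 1..32")
    chunks: List[np.ndarray] = []
    sep = np.array([4], dtype=np.uint8)  # read boundary: never part of a k-mer
    buf: List[np.ndarray] = []
    buf_len = 0
    all_codes: List[np.ndarray] = []

    def _flush() -> None:
        nonlocal buf, buf_len
        if not buf:
            return
        arr = np.concatenate(buf)
        codes, _ = _window_codes(arr, k)
        if codes.size:
            all_codes.append(codes)
        buf, buf_len = [], 0

    for read in reads:
        buf.append(encode(read))
        buf.append(sep)
        buf_len += len(read) + 1
        if buf_len >= 4_000_000:
            _flush()
    _flush()
    if not all_codes:
        raise ValueError("reads contain no valid k-mers")
    codes = np.concatenate(all_codes)
    uniq, counts = np.unique(codes, return_counts=True)
    order = np.lexsort((uniq, -counts.astype(np.int64)))
    top = order[: params.repeat_top_n]
    entries = [(_decode_kmer(int(uniq[i]), k), int(counts[i])) for i in top]
    concatenated = "".join(km for km, _ in entries)
    return RepeatLibrary(k=k, entries=entries, concatenated=concatenated,
                         source=LibrarySource.KMER_DENOVO, name=name)


def repeat_overlap(oligo: Oligo, library: RepeatLibrary) -> int:
    """Length of the longest exact substring the oligo (either strand)
    shares with the library's concatenated reference."""
    if not library.concatenated:
        return 0
    sam = library.automaton
    return max(sam.longest_match(oligo.sequence),
               sam.longest_match(revcomp(oligo.sequence)))


def screen_oligos(
    oligos: Sequence[Oligo],
    libraries: Sequence[RepeatLibrary],
    params: DesignParameters,
) -> Tuple[List[Oligo], ScreenReport]:
    """Discard oligos overlapping any repeat library by >= repeat_overlap_min bp.

    Known-repeat libraries are checked before de novo k-mer libraries so the
    recorded discard reason names the more informative class. Returns the
    surviving oligos (order preserved) and a per-oligo report.
    """
    ordered = sorted(
        libraries, key=lambda lib: lib.source is not LibrarySource.KNOWN_FASTA
    )
    survivors: List[Oligo] = []
    discarded: List[Oligo] = []
    best: Dict[str, int] = {}
    n_known = n_kmer = 0
    for oligo in oligos:
        if oligo.status is OligoStatus.DISCARDED:
            discarded.append(oligo)
            continue
        fired: Optional[LibrarySource] = None
        overlap_best = 0
        for lib in ordered:
            ov = repeat_overlap(oligo, lib)
            overlap_best = max(overlap_best, ov)
            if ov >= params.repeat_overlap_min:
                fired = lib.source
                break
        best[oligo.oligo_id] = overlap_best
        if fired is LibrarySource.KNOWN_FASTA:
            n_known += 1
            discarded.append(oligo.discarded(DiscardReason.KNOWN_REPEAT))
        elif fired is LibrarySource.KMER_DENOVO:
            n_kmer += 1
            discarded.append(oligo.discarded(DiscardReason.KMER_REPEAT))
        else:
            survivors.append(oligo)
    report = ScreenReport(
        n_in=len([o for o in oligos if o.status is not OligoStatus.DISCARDED]),
        n_discarded_known=n_known,
        n_discarded_kmer=n_kmer,
        best_overlap=best,
        discarded=discarded,
    )
    return survivors, report
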