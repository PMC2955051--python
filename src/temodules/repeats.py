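"""Enumeration of exact maximal repeats (MRs) across a sequence family.

A word ``w`` is a maximal repeat if it has two occurrences whose left
flanking letters differ and whose right flanking letters differ, sequence
boundaries acting as per-sequence unique sentinel letters.  Enumeration is
done over a suffix array with LCP intervals built on the concatenation of
the family (plus reverse-complemented copies when the reverse strand is
searched); a definition-level brute-force enumerator is provided as an
independent oracle for small inputs.

``N`` positions are treated as per-position unique letters: they break
repeats, so no reported MR contains an ambiguous base, and an ``N`` flank
always counts as a distinct letter.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from temodules.family import SequenceFamily, reverse_complement

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"


@dataclass(frozen=True, order=True)
class Occurrence:
    """One exact occurrence of a repeat word.

    ``start``/``end`` are 0-based half-open coordinates on the direct
    strand of sequence ``seq_index``.  Strand ``-`` means the reverse
    complement of the repeat word appears at this location.
    """

    seq_index: int
    start: int
    end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, seq_index: int, start: int, end: int) -> bool:
        return self.seq_index == seq_index and self.start < end and start < self.end


@dataclass(frozen=True)
class MaximalRepeat:
    """An exact repeated word with its sorted occurrence list."""

    word: str
    occurrences: tuple[Occurrence, ...]

    @property
    def length(self) -> int:
        return len(self.word)

    @property
    def count(self) -> int:
        return len(self.occurrences)

    @property
    def support(self) -> int:
        """Number of distinct sequences with at least one occurrence."""
        return len({o.seq_index for o in self.occurrences})

    def sort_key(self) -> tuple:
        first = self.occurrences[0] if self.occurrences else Occurrence(0, 0, 0)
        return (-self.length, -self.count, self.word, first.seq_index, first.start)


@dataclass
class MRList:
    """The working list L of maximal repeats.

    Sorted by decreasing word length, then decreasing occurrence count,
    then lexicographic word, then first occurrence position (determinism
    tie-breaks).
    """

    entries: list[MaximalRepeat] = field(default_factory=list)

    def sort(self) -> None:
        self.entries.sort(key=MaximalRepeat.sort_key)

    def filtered(self, min_support: int) -> list[MaximalRepeat]:
        """Entries whose remaining support reaches ``min_support``."""
        return [mr for mr in self.entries if mr.support >= min_support]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[MaximalRepeat]:
        return iter(self.entries)

    def to_tsv(self) -> str:
        """Debug dump: word, length, count, support, occurrence list."""
        lines = ["word\tlength\tcount\tsupport\toccurrences"]
        for mr in self.entries:
            occs = ";".join(
                f"{o.seq_index}:{o.start}-{o.end}{o.strand}" for o in mr.occurrences
            )
            lines.append(f"{mr.word}\t{mr.length}\t{mr.count}\t{mr.support}\t{occs}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# suffix array backend


def _suffix_array(arr: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n) with numpy sorts)."""
    n = arr.size
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = np.unique(arr, return_inverse=True)[1].astype(np.int64)
    k = 1
    while True:
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        order = np.lexsort((second, rank))
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order[0]] = 0
        diff = (rank[order[1:]] != rank[order[:-1]]) | (
            second[order[1:]] != second[order[:-1]]
        )
        new_rank[order[1:]] = np.cumsum(diff)
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


def _lcp_array(arr: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Kasai's algorithm; lcp[i] = lcp(suffix sa[i-1], suffix sa[i])."""
    n = arr.size
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    a = arr.tolist()
    sa_l = sa.tolist()
    rank_l = rank.tolist()
    h = 0
    for i in range(n):
        r = rank_l[i]
        if r > 0:
            j = sa_l[r - 1]
            while i + h < n and j + h < n and a[i + h] == a[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


def _lcp_intervals(lcp: Sequence[int]) -> Iterator[tuple[int, int, int]]:
    """Yield every lcp interval as (depth, left, right), depth >= 1."""
    n = len(lcp)
    stack: list[tuple[int, int]] = [(0, 0)]
    for i in range(1, n):
        lb = i - 1
        li = lcp[i]
        while stack[-1][0] > li:
            depth, left = stack.pop()
            if depth > 0:
                yield depth, left, i - 1
            lb = left
        if stack[-1][0] < li:
            stack.append((li, lb))
    while stack:
        depth, left = stack.pop()
        if depth > 0:
            yield depth, left, n - 1


def _augmented_sequences(
    family: SequenceFamily, include_reverse: bool
) -> list[str]:
    seqs = list(family.sequences)
    if include_reverse:
        seqs += [reverse_complement(s) for s in family.sequences]
    return seqs


def _map_occurrence(
    aug_index: int, start: int, end: int, word: str, canon: str, n: int,
    seq_lengths: Sequence[int],
) -> tuple[int, int, int, str]:
    """Map an occurrence in the augmented family back to direct-strand
    coordinates of the original family, labelling the strand relative to
    the canonical representative ``canon``."""
    if aug_index < n:
        strand = "+" if canon == word else "-"
        return aug_index, start, end, strand
    j = aug_index - n
    length = seq_lengths[j]
    strand = "-" if canon == word else "+"
    return j, length - end, length - start, strand


def _merge_canonical(
    word_occs: Iterable[tuple[str, list[tuple[int, int, int]]]],
    family: SequenceFamily,
    include_reverse: bool,
    min_support: int,
) -> MRList:
    """Canonicalize words (reverse search only), merge and deduplicate
    occurrences, filter by support, and build the sorted list L."""
    n = family.n
    lengths = [len(s) for s in family.sequences]
    merged: dict[str, dict[tuple[int, int, int], str]] = {}
    for word, occs in word_occs:
        if include_reverse:
            canon = min(word, reverse_complement(word))
        else:
            canon = word
        bucket = merged.setdefault(canon, {})
        for aug_index, start, end in occs:
            si, s, e, strand = _map_occurrence(
                aug_index, start, end, word, canon, n, lengths
            )
            key = (si, s, e)
            prev = bucket.get(key)
            if prev is None or (prev == "-" and strand == "+"):
                bucket[key] = strand
    entries = []
    for canon, bucket in merged.items():
        occurrences = tuple(
            sorted(Occurrence(si, s, e, strand) for (si, s, e), strand in bucket.items())
        )
        mr = MaximalRepeat(canon, occurrences)
        if mr.support >= min_support:
            entries.append(mr)
    result = MRList(entries)
    result.sort()
    return result


def enumerate_mrs(
    family: SequenceFamily, min_support: int = 1, include_reverse: bool = False
) -> MRList:
    """Enumerate all maximal repeats of the family.

    With ``include_reverse``, the family is augmented with its
    reverse-complemented copies before indexing; an MR and its reverse
    complement are merged under the lexicographically smaller word, with
    minus-strand occurrences mapped back onto direct-strand coordinates.
    Only MRs present in at least ``min_support`` distinct sequences are
    retained.
    """
    if not 1 <= min_support <= family.n:
        raise ValueError("min_support must be in [1, n]")
    seqs = _augmented_sequences(family, include_reverse)

    # encode: A,C,G,T -> 0..3; every N and every sentinel gets a unique code
    unique = 4
    codes: list[int] = []
    starts: list[int] = []
    pos = 0
    for seq in seqs:
        starts.append(pos)
        for ch in seq:
            code = _BASE_CODE.get(ch)
            if code is None:
                code = unique
                unique += 1
            codes.append(code)
        codes.append(unique)  # per-sequence sentinel
        unique += 1
        pos = len(codes)
    arr = np.asarray(codes, dtype=np.int64)
    sa = _suffix_array(arr)
    lcp = _lcp_array(arr, sa)
    sa_l = sa.tolist()
    lcp_l = lcp.tolist()
    arr_l = arr.tolist()

    ends = [starts[i] + len(seqs[i]) for i in range(len(seqs))]

    word_occs: list[tuple[str, list[tuple[int, int, int]]]] = []
    for depth, left, right in _lcp_intervals(lcp_l):
        # left-maximality: at least two distinct preceding letters
        bwt = set()
        for idx in range(left, right + 1):
            p = sa_l[idx]
            bwt.add(arr_l[p - 1] if p > 0 else -1)
            if len(bwt) > 1:
                break
        if len(bwt) < 2:
            continue
        p0 = sa_l[left]
        word = "".join(_CODE_BASE[c] for c in arr_l[p0 : p0 + depth])
        occs = []
        for idx in range(left, right + 1):
            p = sa_l[idx]
            ai = bisect.bisect_right(starts, p) - 1
            off = p - starts[ai]
            occs.append((ai, off, off + depth))
        word_occs.append((word, occs))

    return _merge_canonical(word_occs, family, include_reverse, min_support)


def brute_force_mrs(
    family: SequenceFamily,
    min_support: int = 1,
    include_reverse: bool = False,
    max_total: int = 2000,
) -> MRList:
    """Definition-level MR enumeration, for use as a test oracle.

    Repeated words are grown letter by letter from repeated k-mers; a word
    is reported when two occurrences have distinct left flanks and two have
    distinct right flanks (boundaries and N positions count as unique
    letters).  Refuses families above ``max_total`` nucleotides.
    """
    if family.total_length > max_total:
        raise ValueError(f"brute force capped at {max_total} nt")
    if not 1 <= min_support <= family.n:
        raise ValueError("min_support must be in [1, n]")
    seqs = _augmented_sequences(family, include_reverse)

    def left_flank(ai: int, pos: int):
        if pos == 0:
            return ("^", ai)
        ch = seqs[ai][pos - 1]
        return ("N", ai, pos - 1) if ch == "N" else ch

    def right_flank(ai: int, pos: int, k: int):
        if pos + k >= len(seqs[ai]):
            return ("$", ai)
        ch = seqs[ai][pos + k]
        return ("N", ai, pos + k) if ch == "N" else ch

    # length-1 repeated words
    cur: dict[str, list[tuple[int, int]]] = {}
    for ai, seq in enumerate(seqs):
        for pos, ch in enumerate(seq):
            if ch != "N":
                cur.setdefault(ch, []).append((ai, pos))
    cur = {w: occ for w, occ in cur.items() if len(occ) >= 2}

    word_occs: list[tuple[str, list[tuple[int, int, int]]]] = []
    k = 1
    while cur:
        nxt: dict[str, list[tuple[int, int]]] = {}
        for word, occs in cur.items():
            lefts = {left_flank(ai, pos) for ai, pos in occs}
            rights = {right_flank(ai, pos, k) for ai, pos in occs}
            if len(lefts) >= 2 and len(rights) >= 2:
                word_occs.append((word, [(ai, pos, pos + k) for ai, pos in occs]))
            for ai, pos in occs:
                if pos + k < len(seqs[ai]):
                    ch = seqs[ai][pos + k]
                    if ch != "N":
                        nxt.setdefault(word + ch, []).append((ai, pos))
        cur = {w: occ for w, occ in nxt.items() if len(occ) >= 2}
        k += 1

    return _merge_canonical(word_occs, family, include_reverse, min_support)


def prune_occurrences(
    L: MRList,
    intervals: Iterable[tuple[int, int, int]],
    min_support: int = 1,
) -> MRList:
    """Remove every MR occurrence that overlaps (shares >= 1 position with)
    any of the given ``(seq_index, start, end)`` intervals, strand-agnostic;
    drop MRs whose remaining support falls below ``min_support`` and
    re-establish the sort order."""
    raw: dict[int, list[tuple[int, int]]] = {}
    for si, s, e in intervals:
        raw.setdefault(si, []).append((s, e))
    if not raw:
        return L
    # merge per-sequence intervals so overlap reduces to one lookup
    by_seq: dict[int, list[tuple[int, int]]] = {}
    starts: dict[int, list[int]] = {}
    for si, ivs in raw.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        by_seq[si] = [(s, e) for s, e in merged]
        starts[si] = [s for s, _ in merged]

    def hits(o: Occurrence) -> bool:
        ivs = by_seq.get(o.seq_index)
        if not ivs:
            return False
        i = bisect.bisect_right(starts[o.seq_index], o.end - 1)
        return i > 0 and ivs[i - 1][1] > o.start

    entries = []
    for mr in L.entries:
        kept = tuple(o for o in mr.occurrences if not hits(o))
        if not kept:
            continue
        pruned = MaximalRepeat(mr.word, kept)
        if pruned.support >= min_support:
            entries.append(pruned)
    result = MRList(entries)
    result.sort()
    return result
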