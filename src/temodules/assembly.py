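"""Seed-and-extend assembly of flexible repeats from maximal repeats.

A flexible repeat chains maximal repeats (MRs) with variable spacers under
two constraints applied at every assembly step between the current chain A
and a candidate MR B:

* length condition: the spacer ``x`` satisfies ``|x| <= |A| * Maxratio/100``
  (A is the larger part by construction, since seed spans only grow);
* distance condition: across the supporting occurrences, spacers are
  pairwise within edit distance ``min(b_x, b_y)`` where ``b`` is the size
  of the smaller part B.

Candidate extensions are collected per orientation (``AxB`` vs ``BxA``),
turned into a compatibility graph whose edges encode the distance
condition, and accepted when a clique covering enough distinct sequences
exists (a deterministic greedy heuristic; it may miss a qualifying
clique).  Orientations, spacers and part strands are expressed in the
*module frame*: an occurrence on the reverse strand realizes the
reverse-complemented chain, so its genomic left side is the module-frame
right side and its spacers are reverse-complemented before comparison.
Support may therefore be reached by a combination of both directions.
Identical frame spacers are interchangeable in the compatibility graph,
so the implementation groups candidates by spacer equivalence class
before searching cliques — the edge rule is unchanged, only the
bookkeeping is coarser.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import edlib
import networkx as nx

from temodules.family import SequenceFamily, reverse_complement
from temodules.repeats import MaximalRepeat, MRList, Occurrence

_EPS = 1e-9

# Minimum length for the smaller partner B of an association.  With
# b = 1 the distance condition degenerates (spacers of length <= 1 are
# always mutually compatible), so single-nucleotide partners would attach
# to any chain by chance at any support level and blur module boundaries.
# Single-nucleotide MRs remain in the list and may still seed a module.
MIN_PARTNER_LENGTH = 2


def edit_distance(x: str, y: str) -> int:
    """Levenshtein distance with unit costs; empty strings allowed."""
    return _cached_edit(x, y) if x <= y else _cached_edit(y, x)


@lru_cache(maxsize=1 << 18)
def _cached_edit(x: str, y: str) -> int:
    if not x:
        return len(y)
    if not y:
        return len(x)
    return edlib.align(x, y, task="distance")["editDistance"]


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


class IntervalSet:
    """Merged, per-sequence interval collection with overlap queries."""

    def __init__(self) -> None:
        self._ivs: dict[int, list[tuple[int, int]]] = {}
        self._starts: dict[int, list[int]] = {}

    def add(self, seq_index: int, start: int, end: int) -> None:
        ivs = self._ivs.setdefault(seq_index, [])
        ivs.append((start, end))
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        self._ivs[seq_index] = [(s, e) for s, e in merged]
        self._starts[seq_index] = [s for s, _ in merged]

    def overlaps(self, seq_index: int, start: int, end: int) -> bool:
        if start >= end:
            return False
        ivs = self._ivs.get(seq_index)
        if not ivs:
            return False
        i = bisect.bisect_right(self._starts[seq_index], end - 1)
        return i > 0 and ivs[i - 1][1] > start

    def intervals(self) -> Iterable[tuple[int, int, int]]:
        for si, ivs in sorted(self._ivs.items()):
            for s, e in ivs:
                yield si, s, e


@dataclass(frozen=True)
class FlexOccurrence:
    """One realization of a flexible-repeat chain on a sequence.

    ``strand`` is '+' when the chain is realized as stored and '-' when
    the reverse-complemented chain is realized.  ``part_intervals[i]`` is
    the genomic interval of ``parts[i]`` (ascending for '+', descending
    for '-'); ``spacers`` are the module-frame spacer strings between
    consecutive parts (reverse-complemented from the genome for '-'
    occurrences).  ``history`` is the assembly audit trail: one
    ``(a_span, b_len, spacer)`` record per accepted extension step, used
    to replay the length and distance conditions.
    """

    seq_index: int
    start: int
    end: int
    strand: str
    part_intervals: tuple[tuple[int, int], ...]
    spacers: tuple[str, ...]
    history: tuple[tuple[int, int, str], ...] = ()

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class FlexibleRepeat:
    """An ordered chain of (MR word, strand) parts with its occurrences."""

    parts: tuple[tuple[str, str], ...]
    occurrences: tuple[FlexOccurrence, ...]

    @property
    def support(self) -> int:
        return len({o.seq_index for o in self.occurrences})

    @property
    def total_part_length(self) -> int:
        return sum(len(w) for w, _ in self.parts)

    @property
    def min_span(self) -> int:
        return min(o.span for o in self.occurrences)

    @staticmethod
    def single(mr_word: str, occurrences: Iterable[Occurrence]) -> "FlexibleRepeat":
        """A single-MR flexible repeat; minus-strand MR occurrences become
        minus-strand realizations of the one-part chain."""
        occs = tuple(
            FlexOccurrence(
                o.seq_index,
                o.start,
                o.end,
                o.strand,
                ((o.start, o.end),),
                (),
            )
            for o in sorted(occurrences)
        )
        return FlexibleRepeat(((mr_word, "+"),), occs)


def rc_chain(parts: tuple[tuple[str, str], ...]) -> tuple[tuple[str, str], ...]:
    """The reverse-complement chain: parts reversed, strands flipped.

    Words stay as written because under reverse search they are canonical
    representatives (a word and its reverse complement share one entry)."""
    return tuple((w, _flip(s)) for w, s in reversed(parts))


def flip_flexible(flex: FlexibleRepeat) -> FlexibleRepeat:
    """Re-express a flexible repeat on the opposite chain orientation."""
    flipped = tuple(
        replace(
            o,
            strand=_flip(o.strand),
            part_intervals=tuple(reversed(o.part_intervals)),
            spacers=tuple(reverse_complement(s) for s in reversed(o.spacers)),
            history=tuple(
                (a, b, reverse_complement(x)) for a, b, x in o.history
            ),
        )
        for o in flex.occurrences
    )
    return FlexibleRepeat(rc_chain(flex.parts), flipped)


def orient_by_first_occurrence(flex: FlexibleRepeat) -> FlexibleRepeat:
    """Reporting convention: the chain is stored in the orientation of its
    first occurrence (lowest sequence index, then position), which is
    therefore labelled direct."""
    if not flex.occurrences:
        return flex
    first = min(flex.occurrences, key=lambda o: (o.seq_index, o.start, o.end))
    if first.strand == "-":
        return flip_flexible(flex)
    return flex


@dataclass(frozen=True)
class PairCandidate:
    """A candidate association between one seed occurrence and one
    occurrence of the next MR, with the spacer between them.

    ``orientation`` and ``spacer`` are module-frame quantities: '+' means
    the next MR attaches after the chain (seed-x-B in the module frame),
    '-' before it.  ``next_strand`` is the strand the next MR word would
    take as a chain part.  ``new_start``/``new_end`` is the genomic span
    of the extended occurrence."""

    seed_index: int
    seq_index: int
    spacer: str
    flank_size: int  # b: size of the smaller part B (the next MR)
    orientation: str
    next_strand: str
    next_occ: Occurrence
    a_span: int
    new_start: int
    new_end: int

    def sort_pos(self) -> tuple:
        return (self.seq_index, self.new_start, self.new_end, self.orientation)


def _make_candidate(
    seed_index: int,
    o: FlexOccurrence,
    ob: Occurrence,
    b: int,
    genomic_side: str,
    genomic_spacer: str,
) -> PairCandidate:
    """Normalize a genomic association into the module frame."""
    if o.strand == "+":
        orientation = "+" if genomic_side == "right" else "-"
        spacer = genomic_spacer
        next_strand = ob.strand
    else:
        orientation = "-" if genomic_side == "right" else "+"
        spacer = reverse_complement(genomic_spacer)
        next_strand = _flip(ob.strand)
    if genomic_side == "right":
        new_start, new_end = o.start, ob.end
    else:
        new_start, new_end = ob.start, o.end
    return PairCandidate(
        seed_index, o.seq_index, spacer, b, orientation, next_strand,
        ob, o.span, new_start, new_end,
    )


def collect_pairs(
    seed: FlexibleRepeat,
    next_mr: MaximalRepeat,
    maxratio: float,
    family: SequenceFamily,
    blocked: Optional[IntervalSet] = None,
    consumed: Optional[set] = None,
) -> list[PairCandidate]:
    """All admissible associations of ``seed`` occurrences with occurrences
    of ``next_mr`` on the same sequence whose spacer satisfies the length
    condition ``|x| <= |A| * maxratio/100`` with A the seed occurrence
    span.  Spacers crossing a ``blocked`` interval (already covered by a
    module) and ``consumed`` MR occurrences are skipped."""
    if not 0 < maxratio <= 100:
        raise ValueError("maxratio must be in (0, 100]")
    by_seq: dict[int, list[Occurrence]] = {}
    for o in next_mr.occurrences:
        if consumed and (next_mr.word, o) in consumed:
            continue
        by_seq.setdefault(o.seq_index, []).append(o)
    out: list[PairCandidate] = []
    b = next_mr.length
    for si, occ_b in by_seq.items():
        occ_b.sort()
        seq = family.sequences[si]
        for i, a in enumerate(seed.occurrences):
            if a.seq_index != si:
                continue
            window = a.span * maxratio / 100.0 + _EPS
            for ob in occ_b:
                if ob.start >= a.end and ob.start - a.end <= window:
                    if blocked and blocked.overlaps(si, a.end, ob.start):
                        continue
                    out.append(
                        _make_candidate(i, a, ob, b, "right", seq[a.end : ob.start])
                    )
                elif ob.end <= a.start and a.start - ob.end <= window:
                    if blocked and blocked.overlaps(si, ob.end, a.start):
                        continue
                    out.append(
                        _make_candidate(i, a, ob, b, "left", seq[ob.end : a.start])
                    )
    out.sort(key=PairCandidate.sort_pos)
    return out


def build_compatibility_graph(pairs: Sequence[PairCandidate]) -> nx.Graph:
    """Graph GB over pair candidates; an edge joins two candidates of the
    same module-frame orientation (and next-part strand) whose spacers are
    within edit distance ``min(b_x, b_y)``."""
    g = nx.Graph()
    g.add_nodes_from(pairs)
    for i, p in enumerate(pairs):
        for q in pairs[i + 1 :]:
            if p.orientation != q.orientation or p.next_strand != q.next_strand:
                continue
            bound = min(p.flank_size, q.flank_size)
            if abs(len(p.spacer) - len(q.spacer)) > bound:
                continue
            if edit_distance(p.spacer, q.spacer) <= bound:
                g.add_edge(p, q)
    return g


def _greedy_clique(nodes, adj, weight, tie_key, seqs_of, min_cover):
    """Deterministic greedy clique heuristic: keep vertices whose closed
    neighborhood covers at least ``min_cover`` sequences, then repeatedly
    take the heaviest-degree vertex among those still mutually adjacent.
    Returns the clique (list of nodes); may miss a qualifying clique."""
    keep = []
    for v in nodes:
        cover = set(seqs_of(v))
        for u in adj[v]:
            cover |= seqs_of(u)
        if len(cover) >= min_cover:
            keep.append(v)
    remaining = set(keep)
    clique = []
    while remaining:
        best = min(
            remaining,
            key=lambda u: (
                -(weight(u) + sum(weight(w) for w in adj[u] & remaining)),
                tie_key(u),
            ),
        )
        clique.append(best)
        remaining = remaining & adj[best]
    return clique


def _resolve_members(
    members: list[PairCandidate], min_cover: int
) -> Optional[list[PairCandidate]]:
    """Keep at most one candidate per seed occurrence and per next
    occurrence, with pairwise-disjoint extended intervals; check that the
    survivors still cover ``min_cover`` sequences."""
    members = sorted(members, key=PairCandidate.sort_pos)
    chosen: list[PairCandidate] = []
    used_seed: set[int] = set()
    used_next: set[Occurrence] = set()
    spans = IntervalSet()
    for c in members:
        if c.seed_index in used_seed or c.next_occ in used_next:
            continue
        if spans.overlaps(c.seq_index, c.new_start, c.new_end):
            continue
        chosen.append(c)
        used_seed.add(c.seed_index)
        used_next.add(c.next_occ)
        spans.add(c.seq_index, c.new_start, c.new_end)
    if len({c.seq_index for c in chosen}) < min_cover:
        return None
    return chosen


def find_support_clique(
    gb: nx.Graph, min_sequences: int
) -> Optional[list[PairCandidate]]:
    """Clique of pair candidates covering at least ``min_sequences``
    distinct sequences, found by the documented greedy heuristic (no
    completeness guarantee); ``None`` when the heuristic finds none."""
    nodes = sorted(gb.nodes, key=PairCandidate.sort_pos)
    if not nodes:
        return None
    adj = {v: set(gb.neighbors(v)) for v in nodes}
    clique = _greedy_clique(
        nodes,
        adj,
        weight=lambda v: 1,
        tie_key=PairCandidate.sort_pos,
        seqs_of=lambda v: {v.seq_index},
        min_cover=min_sequences,
    )
    if not clique:
        return None
    return _resolve_members(clique, min_sequences)


@dataclass
class PairResult:
    ok: bool
    next_mr: Optional[MaximalRepeat] = None
    clique: Optional[list[PairCandidate]] = None


class _OccurrenceIndex:
    """Per-sequence position index over the occurrences of an MR list
    view, for windowed candidate sweeps."""

    def __init__(self, view: Sequence[MaximalRepeat]):
        self.by_start: dict[int, list[tuple[int, int, int, Occurrence]]] = {}
        self.by_end: dict[int, list[tuple[int, int, int, Occurrence]]] = {}
        for rank, mr in enumerate(view):
            for o in mr.occurrences:
                self.by_start.setdefault(o.seq_index, []).append(
                    (o.start, o.end, rank, o)
                )
                self.by_end.setdefault(o.seq_index, []).append(
                    (o.end, o.start, rank, o)
                )
        for lst in self.by_start.values():
            lst.sort()
        for lst in self.by_end.values():
            lst.sort()

    def right_of(self, seq_index: int, lo: int, hi: int):
        """Occurrences with start in [lo, hi]."""
        lst = self.by_start.get(seq_index, [])
        i = bisect.bisect_left(lst, (lo, -1, -1))
        while i < len(lst) and lst[i][0] <= hi:
            yield lst[i][2], lst[i][3]
            i += 1

    def left_of(self, seq_index: int, lo: int, hi: int):
        """Occurrences with end in [lo, hi]."""
        lst = self.by_end.get(seq_index, [])
        i = bisect.bisect_left(lst, (lo, -1, -1))
        while i < len(lst) and lst[i][0] <= hi:
            yield lst[i][2], lst[i][3]
            i += 1


def _sweep_candidates(
    seed: FlexibleRepeat,
    view: Sequence[MaximalRepeat],
    index: _OccurrenceIndex,
    start_index: int,
    maxratio: float,
    family: SequenceFamily,
    blocked: Optional[IntervalSet],
    consumed: set,
) -> dict[int, list[PairCandidate]]:
    """One pass over seed occurrences collecting, for every candidate next
    MR (rank >= start_index in the view), the admissible pair candidates.
    Equivalent to running :func:`collect_pairs` against each MR of the
    view, bucketed by view rank."""
    buckets: dict[int, list[PairCandidate]] = {}
    for i, a in enumerate(seed.occurrences):
        window = int(a.span * maxratio / 100.0 + _EPS)
        seq = family.sequences[a.seq_index]
        for rank, ob in index.right_of(a.seq_index, a.end, a.end + window):
            if rank < start_index:
                continue
            if (view[rank].word, ob) in consumed:
                continue
            if blocked and blocked.overlaps(a.seq_index, a.end, ob.start):
                continue
            buckets.setdefault(rank, []).append(
                _make_candidate(
                    i, a, ob, view[rank].length, "right", seq[a.end : ob.start]
                )
            )
        for rank, ob in index.left_of(a.seq_index, a.start - window, a.start):
            if rank < start_index:
                continue
            if (view[rank].word, ob) in consumed:
                continue
            if blocked and blocked.overlaps(a.seq_index, ob.end, a.start):
                continue
            buckets.setdefault(rank, []).append(
                _make_candidate(
                    i, a, ob, view[rank].length, "left", seq[ob.end : a.start]
                )
            )
    return buckets


def _clique_for_candidates(
    cands: list[PairCandidate], b: int, min_cover: int
) -> Optional[list[PairCandidate]]:
    """Clique search over one next-MR's candidates, grouped by spacer
    equivalence class within each (orientation, next strand) class."""
    classes: dict[tuple[str, str], dict[str, list[PairCandidate]]] = {}
    for c in cands:
        classes.setdefault((c.orientation, c.next_strand), {}).setdefault(
            c.spacer, []
        ).append(c)
    for key in sorted(classes):
        groups = classes[key]
        if len({c.seq_index for g in groups.values() for c in g}) < min_cover:
            continue
        spacers = sorted(groups)
        # adjacency between spacer classes: edit distance at most b,
        # pre-filtered by length difference
        order = sorted(range(len(spacers)), key=lambda i: (len(spacers[i]), spacers[i]))
        adj: dict[int, set[int]] = {i: set() for i in range(len(spacers))}
        for ii, gi in enumerate(order):
            for gj in order[ii + 1 :]:
                if len(spacers[gj]) - len(spacers[gi]) > b:
                    break
                if edit_distance(spacers[gi], spacers[gj]) <= b:
                    adj[gi].add(gj)
                    adj[gj].add(gi)
        seqs = [
            frozenset(c.seq_index for c in groups[spacers[i]])
            for i in range(len(spacers))
        ]
        sizes = [len(groups[spacers[i]]) for i in range(len(spacers))]
        ties = [
            min(c.sort_pos() for c in groups[spacers[i]]) for i in range(len(spacers))
        ]
        clique = _greedy_clique(
            list(range(len(spacers))),
            adj,
            weight=lambda i: sizes[i],
            tie_key=lambda i: ties[i],
            seqs_of=lambda i: seqs[i],
            min_cover=min_cover,
        )
        if not clique:
            continue
        members = [c for i in clique for c in groups[spacers[i]]]
        resolved = _resolve_members(members, min_cover)
        if resolved:
            return resolved
    return None


def build_pair(
    view: Sequence[MaximalRepeat],
    seed: FlexibleRepeat,
    start_index: int,
    min_sequences: int,
    maxratio: float,
    family: SequenceFamily,
    index: Optional[_OccurrenceIndex] = None,
    blocked: Optional[IntervalSet] = None,
    consumed: Optional[set] = None,
) -> PairResult:
    """Scan the sorted MR view from ``start_index`` for the first MR that
    associates with the seed through a qualifying clique (largest MR
    first, then most occurrences — the view order).  A composite flexible
    repeat needs support in at least two distinct sequences, so the
    effective clique coverage requirement is ``max(min_sequences, 2)``."""
    consumed = consumed if consumed is not None else set()
    if index is None:
        index = _OccurrenceIndex(view)
    min_cover = max(min_sequences, 2)
    if not seed.occurrences:
        return PairResult(False)
    buckets = _sweep_candidates(
        seed, view, index, start_index, maxratio, family, blocked, consumed
    )
    for rank in sorted(buckets):
        if view[rank].length < MIN_PARTNER_LENGTH:
            continue
        cands = buckets[rank]
        if len({c.seq_index for c in cands}) < min_cover:
            continue
        clique = _clique_for_candidates(cands, view[rank].length, min_cover)
        if clique:
            return PairResult(True, view[rank], clique)
    return PairResult(False)


def _apply_extension(
    seed: FlexibleRepeat, next_mr: MaximalRepeat, clique: list[PairCandidate]
) -> FlexibleRepeat:
    """Replace the seed by seed-x-next or next-x-seed according to the
    clique's module-frame orientation; occurrences shrink to the clique
    members.  Genomic geometry follows each occurrence's strand."""
    orientation = clique[0].orientation
    strand_b = clique[0].next_strand
    b_len = next_mr.length
    new_occs = []
    for c in sorted(clique, key=PairCandidate.sort_pos):
        o = seed.occurrences[c.seed_index]
        step = (o.span, b_len, c.spacer)
        iv = (c.next_occ.start, c.next_occ.end)
        if orientation == "+":
            intervals = o.part_intervals + (iv,)
            spacers = o.spacers + (c.spacer,)
        else:
            intervals = (iv,) + o.part_intervals
            spacers = (c.spacer,) + o.spacers
        new_occs.append(
            FlexOccurrence(
                o.seq_index,
                c.new_start,
                c.new_end,
                o.strand,
                intervals,
                spacers,
                o.history + (step,),
            )
        )
    if orientation == "+":
        parts = seed.parts + ((next_mr.word, strand_b),)
    else:
        parts = ((next_mr.word, strand_b),) + seed.parts
    return FlexibleRepeat(parts, tuple(new_occs))


def build_modules(
    L: MRList,
    min_sequences: int,
    min_size_module: int,
    maxratio: float,
    family: SequenceFamily,
    blocked: Optional[IntervalSet] = None,
    excluded_single_words: Optional[set[str]] = None,
    failed_seeds: Optional[set] = None,
) -> tuple[Optional[FlexibleRepeat], list[tuple[str, Occurrence]]]:
    """One round of module construction at the given support level.

    Seeds are tried in the sorted-list order.  The first seed that pairs
    is grown greedily at either end until no extension qualifies,
    consuming the paired MR occurrences from the list; the resulting
    chain is returned as a module candidate when every retained
    occurrence spans at least ``min_size_module`` — otherwise ``None`` is
    returned with the occurrences nevertheless consumed, ending the
    level.  A seed that pairs with nothing but itself meets the size and
    support conditions is emitted as a single-part module at its place in
    the scan ("each maximal repeat is a flexible repeat"); MRs whose word
    already belongs to a discovered module are not re-emitted this way —
    a leftover occurrence of a known module part is the business of the
    truncated-occurrence pass.

    Returns ``(flexible_repeat_or_None, consumed_occurrences)``.
    """
    if min_size_module < 1:
        raise ValueError("min_size_module must be >= 1")
    excluded = excluded_single_words or set()
    failed = failed_seeds if failed_seeds is not None else set()
    view = L.filtered(min_sequences)
    index = _OccurrenceIndex(view)
    consumed: set = set()

    chain: Optional[FlexibleRepeat] = None
    first_clique: Optional[PairResult] = None
    seed_mr: Optional[MaximalRepeat] = None
    for i, mr in enumerate(view):
        if mr.word in failed:
            continue
        seed = FlexibleRepeat.single(mr.word, mr.occurrences)
        res = PairResult(False)
        if len({o.seq_index for o in mr.occurrences}) >= 2 or min_sequences >= 2:
            res = build_pair(
                view, seed, i + 1, min_sequences, maxratio, family,
                index=index, blocked=blocked,
            )
        if res.ok:
            chain = seed
            first_clique = res
            seed_mr = mr
            break
        if mr.length >= min_size_module and mr.word not in excluded:
            flex = orient_by_first_occurrence(seed)
            used = [(mr.word, o) for o in mr.occurrences]
            return flex, used
        failed.add(mr.word)

    if chain is None:
        return None, []

    # apply the first pairing: consume the paired seed and next occurrences
    assert first_clique is not None and first_clique.next_mr is not None
    used: list[tuple[str, Occurrence]] = []
    seed_occ_list = sorted(seed_mr.occurrences)
    for c in first_clique.clique:
        used.append((seed_mr.word, seed_occ_list[c.seed_index]))
        used.append((first_clique.next_mr.word, c.next_occ))
        consumed.add((seed_mr.word, seed_occ_list[c.seed_index]))
        consumed.add((first_clique.next_mr.word, c.next_occ))
    chain = _apply_extension(chain, first_clique.next_mr, first_clique.clique)

    # extension loop: regrow from the full list until no pair qualifies
    while True:
        res = build_pair(
            view, chain, 0, min_sequences, maxratio, family,
            index=index, blocked=blocked, consumed=consumed,
        )
        if not res.ok:
            break
        for c in res.clique:
            used.append((res.next_mr.word, c.next_occ))
            consumed.add((res.next_mr.word, c.next_occ))
        chain = _apply_extension(chain, res.next_mr, res.clique)

    if chain.min_span >= min_size_module:
        return orient_by_first_occurrence(chain), used
    return None, used
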