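"""Module detection: outer support loop, partition bookkeeping, reverse
and truncated occurrence search, and the composition output.

Detection scans support levels from the family size down to one (or runs a
single user-fixed level).  At each level, module construction is repeated
until it yields nothing; every accepted module immediately claims its
intervals, the MR list is pruned of overlapping occurrences (partition
condition), and — when the reverse search is enabled — the
reverse-complemented form of the module is looked for right away so its
occurrences cannot be re-consumed by later modules.  Truncated occurrences
are attached in a second pass once all complete modules are known: they
anchor on the module's largest MR, which must be present, and contribute
fractionally (conserved MR length / total MR length).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from temodules.assembly import (
    FlexibleRepeat,
    IntervalSet,
    build_modules,
    edit_distance,
    rc_chain,
)
from temodules.family import SequenceFamily, default_min_size_module, reverse_complement
from temodules.repeats import MaximalRepeat, MRList, Occurrence, enumerate_mrs, prune_occurrences

logger = logging.getLogger(__name__)

KINDS = ("direct", "reverse", "truncated_direct", "truncated_reverse")


@dataclass(frozen=True)
class ModuleOccurrence:
    """A placed occurrence of a module on one sequence (0-based half-open)."""

    seq_index: int
    start: int
    end: int
    kind: str
    conserved_fraction: float

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class Module:
    """A module: an ordered chain of (MR word, strand) parts, its placed
    occurrences, and the assembly audit record of its complete
    occurrences."""

    id: int
    parts: tuple[tuple[str, str], ...]
    occurrences: list[ModuleOccurrence]
    support_at_discovery: int
    flex: FlexibleRepeat

    @property
    def total_mr_length(self) -> int:
        return sum(len(w) for w, _ in self.parts)

    @property
    def part_words(self) -> set[str]:
        return {w for w, _ in self.parts}

    def spacer_length_bounds(self) -> list[tuple[int, int]]:
        """Observed (min, max) spacer length per gap among the complete
        occurrences."""
        n_gaps = len(self.parts) - 1
        bounds = []
        for g in range(n_gaps):
            lens = [len(o.spacers[g]) for o in self.flex.occurrences]
            bounds.append((min(lens), max(lens)))
        return bounds


@dataclass
class DetectionParams:
    min_size_module: Optional[int] = None  # None: data-driven default
    maxratio: float = 100.0
    min_sequences: Optional[int] = None  # None: sweep n -> 1
    reverse: bool = False
    truncated: bool = False

    def validate(self, n: int) -> None:
        if self.min_size_module is not None and self.min_size_module < 1:
            raise ValueError("MinSizeModule must be >= 1")
        if not 0 < self.maxratio <= 100:
            raise ValueError("Maxratio must be in (0, 100]")
        if self.min_sequences is not None and not 1 <= self.min_sequences <= n:
            raise ValueError("MinSequences must be in [1, n]")


@dataclass
class ModuleCatalog:
    """All modules of a family with the per-sequence segmentation."""

    family: SequenceFamily
    modules: list[Module] = field(default_factory=list)
    resolved_min_size_module: int = 0
    params: Optional[DetectionParams] = None

    @property
    def m(self) -> int:
        return len(self.modules)

    def all_occurrences(self) -> Iterable[tuple[Module, ModuleOccurrence]]:
        for mod in self.modules:
            for occ in mod.occurrences:
                yield mod, occ

    def segmentation(self, seq_index: int) -> list[tuple[Optional[int], int, int, Optional[str]]]:
        """Ordered (module_id or None, start, end, kind or None) covering
        the sequence; None entries are uncovered gaps."""
        occs = sorted(
            (occ.start, occ.end, mod.id, occ.kind)
            for mod, occ in self.all_occurrences()
            if occ.seq_index == seq_index
        )
        out = []
        pos = 0
        for s, e, mid, kind in occs:
            if s > pos:
                out.append((None, pos, s, None))
            out.append((mid, s, e, kind))
            pos = e
        length = len(self.family.sequences[seq_index])
        if pos < length:
            out.append((None, pos, length, None))
        return out


def _genomic_word(word: str, strand: str) -> str:
    return word if strand == "+" else reverse_complement(word)


def _remove_occurrences(L: MRList, used: list[tuple[str, Occurrence]]) -> MRList:
    if not used:
        return L
    by_word: dict[str, set[Occurrence]] = {}
    for w, o in used:
        by_word.setdefault(w, set()).add(o)
    entries = []
    for mr in L.entries:
        rm = by_word.get(mr.word)
        if rm:
            kept = tuple(o for o in mr.occurrences if o not in rm)
            if kept:
                entries.append(MaximalRepeat(mr.word, kept))
        else:
            entries.append(mr)
    out = MRList(entries)
    out.sort()
    return out


def _find_uncovered_matches(
    seq: str, word: str, covered: IntervalSet, seq_index: int
) -> list[int]:
    """Start positions of exact matches of ``word`` not overlapping any
    covered interval (overlapping self-matches included)."""
    out = []
    p = seq.find(word)
    while p != -1:
        if not covered.overlaps(seq_index, p, p + len(word)):
            out.append(p)
        p = seq.find(word, p + 1)
    return out


def find_reverse_occurrences(
    module: Module,
    family: SequenceFamily,
    covered: IntervalSet,
    maxratio: float = 100.0,
) -> list[ModuleOccurrence]:
    """Occurrences of the reverse module (reverse-complemented parts in
    reversed order) on uncovered regions.

    Each candidate spacer, read back in the module frame, must be within
    edit distance ``min(|flanking parts|)`` of the corresponding spacer of
    at least one complete occurrence, and satisfy the length condition
    against the larger flanking part.  The returned occurrences are not
    yet claimed in ``covered``; the caller does that.
    """
    chain = rc_chain(module.parts)
    k = len(chain)
    if k == 0:
        return []
    gap_of = lambda i: k - 2 - i  # chain gap i maps to module-frame gap
    spacer_sets = [
        [o.spacers[g] for o in module.flex.occurrences] for g in range(k - 1)
    ]
    part_lens = [len(w) for w, _ in module.parts]
    found: list[ModuleOccurrence] = []
    claimed = IntervalSet()

    for si, seq in enumerate(family.sequences):
        w0 = _genomic_word(*chain[0])
        for p0 in _find_uncovered_matches(seq, w0, covered, si):
            if claimed.overlaps(si, p0, p0 + len(w0)):
                continue
            pos_end = p0 + len(w0)
            ok = True
            for i in range(1, k):
                wi = _genomic_word(*chain[i])
                g = gap_of(i - 1)
                flank_a = max(part_lens[g], part_lens[g + 1])
                flank_b = min(part_lens[g], part_lens[g + 1])
                hi = int(flank_a * maxratio / 100.0 + 1e-9)
                hit = None
                p = seq.find(wi, pos_end)
                while p != -1 and p <= pos_end + hi:
                    spacer = seq[pos_end:p]
                    frame_spacer = reverse_complement(spacer)
                    if (
                        not covered.overlaps(si, pos_end, p + len(wi))
                        and not claimed.overlaps(si, pos_end, p + len(wi))
                        and any(
                            edit_distance(frame_spacer, s) <= flank_b
                            for s in spacer_sets[g]
                        )
                    ):
                        hit = p
                        break
                    p = seq.find(wi, p + 1)
                if hit is None:
                    ok = False
                    break
                pos_end = hit + len(wi)
            if ok:
                occ = ModuleOccurrence(si, p0, pos_end, "reverse", 1.0)
                found.append(occ)
                claimed.add(si, p0, pos_end)
    return found


def find_truncated_occurrences(
    module: Module,
    family: SequenceFamily,
    covered: IntervalSet,
    maxratio: float = 100.0,
    reverse_enabled: bool = False,
) -> list[ModuleOccurrence]:
    """Partial occurrences of a module on uncovered regions.

    An occurrence anchors on an exact match of the module's largest MR
    (mandatory part); the other parts are attached greedily in their
    original relative order when found within the observed spacer-length
    bounds widened by the Maxratio slack.  The conserved fraction is the
    summed length of present parts over the module's total MR length; a
    scan that recovers every part is classified as a full (direct or
    reverse) occurrence.  Returned occurrences are not yet claimed in
    ``covered``."""
    k = len(module.parts)
    part_lens = [len(w) for w, _ in module.parts]
    total = module.total_mr_length
    anchor_idx = max(range(k), key=lambda i: (part_lens[i], -i))
    bounds = module.spacer_length_bounds()

    orientations = ["direct"] + (["reverse"] if reverse_enabled else [])
    found: list[ModuleOccurrence] = []
    claimed = IntervalSet()

    for orient in orientations:
        if orient == "direct":
            chain = module.parts
            a_idx = anchor_idx
            gap_of = lambda i: i  # gap between chain i and i+1, module frame
        else:
            chain = rc_chain(module.parts)
            a_idx = k - 1 - anchor_idx
            gap_of = lambda i: k - 2 - i
        chain_lens = [len(w) for w, _ in chain]

        def widened(g: int, attached_len: int) -> tuple[int, int]:
            lo, hi = bounds[g]
            w = int(attached_len * maxratio / 100.0 + 1e-9)
            return max(0, lo - w), hi + w

        for si, seq in enumerate(family.sequences):
            aw = _genomic_word(*chain[a_idx])
            for pa in _find_uncovered_matches(seq, aw, covered, si):
                if claimed.overlaps(si, pa, pa + len(aw)):
                    continue
                present = {a_idx: (pa, pa + len(aw))}
                # walk right of the anchor
                prev_end = pa + len(aw)
                lo_acc, hi_acc = 0, 0
                for i in range(a_idx + 1, k):
                    g = gap_of(i - 1)
                    lo, hi = widened(g, chain_lens[i])
                    lo_w, hi_w = lo_acc + lo, hi_acc + hi
                    wi = _genomic_word(*chain[i])
                    hit = None
                    p = seq.find(wi, prev_end + lo_w)
                    while p != -1 and p <= prev_end + hi_w:
                        if not covered.overlaps(si, prev_end, p + len(wi)) and not claimed.overlaps(si, prev_end, p + len(wi)):
                            hit = p
                            break
                        p = seq.find(wi, p + 1)
                    if hit is None:
                        # part missing: widen the window for the next part
                        lo_acc, hi_acc = 0, hi_w + chain_lens[i]
                    else:
                        present[i] = (hit, hit + len(wi))
                        prev_end = hit + len(wi)
                        lo_acc, hi_acc = 0, 0
                # walk left of the anchor (mirror)
                prev_start = pa
                lo_acc, hi_acc = 0, 0
                for i in range(a_idx - 1, -1, -1):
                    g = gap_of(i)
                    lo, hi = widened(g, chain_lens[i])
                    lo_w, hi_w = lo_acc + lo, hi_acc + hi
                    wi = _genomic_word(*chain[i])
                    hit = None
                    # nearest match ending within [prev_start-hi_w, prev_start-lo_w]
                    p = seq.rfind(wi, 0, prev_start - lo_w)
                    while p != -1 and p + len(wi) >= prev_start - hi_w:
                        if not covered.overlaps(si, p, prev_start) and not claimed.overlaps(si, p, prev_start):
                            hit = p
                            break
                        p = seq.rfind(wi, 0, p + len(wi) - 1)
                    if hit is None:
                        lo_acc, hi_acc = 0, hi_w + chain_lens[i]
                    else:
                        present[i] = (hit, hit + len(wi))
                        prev_start = hit
                        lo_acc, hi_acc = 0, 0

                conserved = sum(chain_lens[i] for i in present)
                frac = conserved / total
                start = min(s for s, _ in present.values())
                end = max(e for _, e in present.values())
                if frac >= 1.0:
                    kind = "direct" if orient == "direct" else "reverse"
                    frac = 1.0
                else:
                    kind = "truncated_direct" if orient == "direct" else "truncated_reverse"
                occ = ModuleOccurrence(si, start, end, kind, frac)
                found.append(occ)
                claimed.add(si, start, end)
    return found


def detect_modules(family: SequenceFamily, params: DetectionParams) -> ModuleCatalog:
    """Run the full detection loop and return the module catalog."""
    params.validate(family.n)
    min_size = params.min_size_module
    if min_size is None:
        min_size = default_min_size_module(family)
        logger.info("resolved default MinSizeModule = %d", min_size)
    catalog = ModuleCatalog(family, [], min_size, params)
    if min_size > max(len(s) for s in family.sequences):
        logger.warning(
            "MinSizeModule %d exceeds every sequence length; empty catalog",
            min_size,
        )
        return catalog

    L = enumerate_mrs(family, min_support=1, include_reverse=params.reverse)
    covered = IntervalSet()
    part_words: set[str] = set()

    if params.min_sequences is not None:
        levels = [params.min_sequences]
    else:
        levels = list(range(family.n, 0, -1))

    next_id = 1
    for level in levels:
        failed_seeds: set[str] = set()
        while True:
            flex, used = build_modules(
                L,
                level,
                min_size,
                params.maxratio,
                family,
                blocked=covered,
                excluded_single_words=part_words,
                failed_seeds=failed_seeds,
            )
            L = _remove_occurrences(L, used)
            if flex is None:
                break
            occs = [
                ModuleOccurrence(
                    o.seq_index,
                    o.start,
                    o.end,
                    "direct" if o.strand == "+" else "reverse",
                    1.0,
                )
                for o in flex.occurrences
            ]
            module = Module(next_id, flex.parts, occs, flex.support, flex)
            next_id += 1
            intervals = [(o.seq_index, o.start, o.end) for o in occs]
            for si, s, e in intervals:
                covered.add(si, s, e)
            if params.reverse:
                rev = find_reverse_occurrences(
                    module, family, covered, params.maxratio
                )
                for occ in rev:
                    module.occurrences.append(occ)
                    covered.add(occ.seq_index, occ.start, occ.end)
                    intervals.append((occ.seq_index, occ.start, occ.end))
            module.support_at_discovery = len(
                {o.seq_index for o in module.occurrences}
            )
            L = prune_occurrences(L, intervals, min_support=1)
            part_words |= module.part_words
            catalog.modules.append(module)
            logger.info(
                "module %d: %d parts, support %d, level %d",
                module.id,
                len(module.parts),
                module.support_at_discovery,
                level,
            )

    if params.truncated:
        for module in catalog.modules:
            extra = find_truncated_occurrences(
                module, family, covered, params.maxratio, params.reverse
            )
            for occ in extra:
                module.occurrences.append(occ)
                covered.add(occ.seq_index, occ.start, occ.end)

    return catalog


# ---------------------------------------------------------------------------
# verification and output


def verify_catalog(
    catalog: ModuleCatalog, maxratio: float = 100.0
) -> list[str]:
    """Post-hoc legality check; returns a list of violations (empty = ok).

    Checks the partition condition (pairwise-disjoint occurrence
    intervals), that every complete occurrence realizes its parts exactly,
    and replays the per-step length and pairwise distance conditions from
    the assembly audit trail."""
    problems: list[str] = []
    seqs = catalog.family.sequences

    per_seq: dict[int, list[tuple[int, int, int]]] = {}
    for mod, occ in catalog.all_occurrences():
        per_seq.setdefault(occ.seq_index, []).append((occ.start, occ.end, mod.id))
    for si, ivs in per_seq.items():
        ivs.sort()
        for (s1, e1, m1), (s2, e2, m2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                problems.append(
                    f"overlap on sequence {si}: module {m1} [{s1},{e1}) vs "
                    f"module {m2} [{s2},{e2})"
                )

    for mod in catalog.modules:
        for o in mod.flex.occurrences:
            for (word, strand), (s, e) in zip(mod.parts, o.part_intervals):
                expect = _genomic_word(word, strand)
                if o.strand == "-":
                    expect = reverse_complement(expect)
                if seqs[o.seq_index][s:e] != expect:
                    problems.append(
                        f"module {mod.id}: part mismatch at seq {o.seq_index} [{s},{e})"
                    )
            # module-frame spacers must read back from the genome
            for g in range(len(mod.parts) - 1):
                if o.strand == "+":
                    gs, ge = o.part_intervals[g][1], o.part_intervals[g + 1][0]
                    text = seqs[o.seq_index][gs:ge]
                else:
                    gs, ge = o.part_intervals[g + 1][1], o.part_intervals[g][0]
                    text = reverse_complement(seqs[o.seq_index][gs:ge])
                if text != o.spacers[g]:
                    problems.append(
                        f"module {mod.id}: spacer mismatch at seq {o.seq_index} gap {g}"
                    )
        n_steps = {len(o.history) for o in mod.flex.occurrences}
        if len(n_steps) > 1:
            problems.append(f"module {mod.id}: ragged assembly histories")
            continue
        for step in range(next(iter(n_steps), 0)):
            recs = [o.history[step] for o in mod.flex.occurrences]
            for a_span, b_len, spacer in recs:
                if len(spacer) > a_span * maxratio / 100.0 + 1e-9:
                    problems.append(
                        f"module {mod.id}: spacer length {len(spacer)} exceeds "
                        f"{maxratio}% of flank {a_span} at step {step}"
                    )
            for i in range(len(recs)):
                for j in range(i + 1, len(recs)):
                    ai, bi, xi = recs[i]
                    aj, bj, xj = recs[j]
                    bound = min(ai, aj, bi, bj)
                    if edit_distance(xi, xj) > bound:
                        problems.append(
                            f"module {mod.id}: spacers at step {step} exceed "
                            f"edit distance bound {bound}"
                        )
    for mod in catalog.modules:
        for occ in mod.occurrences:
            if not 0 < occ.conserved_fraction <= 1:
                problems.append(
                    f"module {mod.id}: conserved_fraction {occ.conserved_fraction}"
                )
            if (occ.conserved_fraction == 1.0) != (occ.kind in ("direct", "reverse")):
                problems.append(
                    f"module {mod.id}: kind {occ.kind} inconsistent with "
                    f"fraction {occ.conserved_fraction}"
                )
    return problems


def write_composition(catalog: ModuleCatalog, path: str | Path) -> None:
    """Write the per-sequence module composition as TSV.

    Columns: sequence_id, module_id, start (1-based), end (inclusive),
    kind, conserved_fraction."""
    lines = ["sequence_id\tmodule_id\tstart\tend\tkind\tconserved_fraction"]
    ids = catalog.family.ids
    rows = []
    for mod, occ in catalog.all_occurrences():
        rows.append(
            (occ.seq_index, occ.start, occ.end, mod.id, occ.kind, occ.conserved_fraction)
        )
    rows.sort()
    for si, s, e, mid, kind, frac in rows:
        lines.append(f"{ids[si]}\t{mid}\t{s + 1}\t{e}\t{kind}\t{frac:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")
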