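"""Synthetic TE families with known planted module architectures.

A family is built from a consensus layout ``gap0 B1 gap1 B2 ... Bk gapk``
of conserved blocks separated by spacer gaps, replicated into copies with
per-copy events: block deletion, tandem duplication, inversion
(reverse complement) and spacer point mutations.  Block interiors are
never mutated — the detection method anchors on exact repeated words, and
the planted blocks are those words; variation is carried by the spacers
and the structural events, as in real non-autonomous TE families where
conserved blocks drift apart through deletions, duplications and
inversions.

Two spacer regimes are available per gap: ``shared`` gaps are drawn once
for the consensus and point-mutated in each copy (homologous spacers, so
neighbouring blocks can assemble into one module across copies);
non-shared gaps are drawn independently per copy (no homology, which
keeps the flanking blocks in separate modules when the gaps are long).

Planted block boundaries are sharp: the bases of an independent gap that
touch a block are cycled over A/C/G/T by copy index, so no flanking base
is shared by chance across most copies and an exact repeated word never
extends beyond a block in a large copy subset — emulating the unrelated
host DNA that flanks real TE insertions.

The generated truth table records every planted block occurrence with
coordinates, orientation and status, so recovery can be scored exactly.
Generation is fully determined by the architecture's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from temodules.assembly import edit_distance
from temodules.family import SequenceFamily, reverse_complement

_BASES = "ACGT"


@dataclass(frozen=True)
class Block:
    """A planted conserved block (exact across copies unless inverted)."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GapSpec:
    """Spacer gap between consecutive blocks (or at the flanks).

    ``shared`` gaps have one consensus realization mutated per copy at the
    architecture's spacer mutation rate; independent gaps are redrawn for
    every copy."""

    min_len: int
    max_len: int
    shared: bool = False


@dataclass(frozen=True)
class TruthRow:
    """One planted block occurrence (or deletion record) in one copy."""

    copy_index: int
    block_id: str
    start: int  # -1 when deleted
    end: int
    strand: str  # '+', '-' ; '.' when deleted
    status: str  # present | duplicate | deleted


@dataclass
class PlantedArchitecture:
    """Blueprint for a synthetic family.

    ``gaps`` has ``len(blocks) + 1`` entries (flanks included).  ``events``
    maps a copy index to a tuple of ``(op, block_id)`` events with op in
    {"delete", "tandem_dup", "invert"}.  Blocks must be mutually distinct
    words: pairwise edit distance above half the largest block length.
    """

    blocks: tuple[Block, ...]
    gaps: tuple[GapSpec, ...]
    events: dict[int, tuple[tuple[str, str], ...]] = field(default_factory=dict)
    spacer_mutation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.gaps) != len(self.blocks) + 1:
            raise ValueError("need len(blocks) + 1 gap specs")
        for i, a in enumerate(self.blocks):
            for b in self.blocks[i + 1 :]:
                if edit_distance(a.seq, b.seq) <= max(a.length, b.length) / 2:
                    raise ValueError(
                        f"blocks {a.id!r} and {b.id!r} are too similar"
                    )
        ids = [b.id for b in self.blocks]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate block id")


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def make_random_blocks(
    rng: np.random.Generator,
    count: int,
    length_range: tuple[int, int] = (18, 30),
    length_ranges: Optional[list[tuple[int, int]]] = None,
    max_tries: int = 500,
) -> tuple[Block, ...]:
    """Random mutually-dissimilar blocks (one length range for all, or one
    per block)."""
    ranges = length_ranges if length_ranges is not None else [length_range] * count
    if len(ranges) != count:
        raise ValueError("need one length range per block")
    blocks: list[Block] = []
    tries = 0
    while len(blocks) < count:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not draw dissimilar blocks")
        lo, hi = ranges[len(blocks)]
        length = int(rng.integers(lo, hi + 1))
        seq = random_sequence(rng, length)
        cand = Block(f"B{len(blocks) + 1}", seq)
        if all(
            edit_distance(cand.seq, b.seq) > max(cand.length, b.length) / 2
            for b in blocks
        ):
            blocks.append(cand)
    return tuple(blocks)


def demo_architecture(
    seed: int, n_copies: int, n_blocks: int = 3
) -> PlantedArchitecture:
    """A standard planted architecture exercising every event type.

    Blocks 1 and 2 form a close pair separated by a short spacer drawn
    independently per copy (short random spacers always satisfy the
    distance condition against the smaller flanking block, so the pair
    assembles into one two-part module); the remaining blocks are
    isolated by long independent gaps (each becomes its own module).
    Copy 1 loses block 2 (the smaller member of the pair), copy 2 carries
    block 3 inverted, and copy 3 a tandem duplication of the last block.
    Copy 0 is always intact.  Detecting with MinSequences fixed at
    ``n_copies - 1`` (the pair module's support once one copy lost its
    smaller member) recovers the pair as a module with a truncated
    occurrence in the deletion copy.
    """
    if n_blocks < 3:
        raise ValueError("need at least 3 blocks")
    if n_copies < 4:
        raise ValueError("need at least 4 copies")
    rng = np.random.default_rng(seed)
    ranges = [(22, 30), (12, 16)] + [(18, 30)] * (n_blocks - 2)
    blocks = make_random_blocks(rng, n_blocks, length_ranges=ranges)
    gaps = [GapSpec(40, 60, shared=False), GapSpec(3, 8, shared=False)]
    gaps += [GapSpec(40, 65, shared=False) for _ in range(n_blocks - 1)]
    events = {
        1: (("delete", blocks[1].id),),
        2: (("invert", blocks[2].id),),
        3: (("tandem_dup", blocks[-1].id),),
    }
    return PlantedArchitecture(
        blocks, tuple(gaps), events, seed=int(rng.integers(0, 2**31 - 1))
    )


def _independent_gap(
    rng: np.random.Generator, gap: GapSpec, copy_index: int
) -> str:
    """Per-copy random gap with block-adjacent bases cycled by copy."""
    length = int(rng.integers(gap.min_len, gap.max_len + 1))
    s = random_sequence(rng, length)
    letter = _BASES[copy_index % 4]
    if length >= 1:
        s = letter + s[1:]
    if length >= 2:
        s = s[:-1] + letter
    return s


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = [b for b in _BASES if b != out[i]]
        out[i] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def generate_family(
    arch: PlantedArchitecture, n_copies: int
) -> tuple[SequenceFamily, list[TruthRow]]:
    """Realize the architecture into ``n_copies`` sequences plus the truth
    table of planted block occurrences."""
    if n_copies < 2:
        raise ValueError("n_copies must be >= 2")
    rng = np.random.default_rng(arch.seed)
    # consensus realizations for shared gaps
    consensus_gaps: dict[int, str] = {}
    for gi, gap in enumerate(arch.gaps):
        if gap.shared:
            length = int(rng.integers(gap.min_len, gap.max_len + 1))
            consensus_gaps[gi] = random_sequence(rng, length)

    records = []
    truth: list[TruthRow] = []
    for ci in range(n_copies):
        events = arch.events.get(ci, ())
        deleted = {b for op, b in events if op == "delete"}
        duplicated = {b for op, b in events if op == "tandem_dup"}
        inverted = {b for op, b in events if op == "invert"}
        parts: list[str] = []
        pos = 0

        def emit(s: str) -> None:
            nonlocal pos
            parts.append(s)
            pos += len(s)

        for bi, block in enumerate(arch.blocks):
            gap = arch.gaps[bi]
            if gap.shared:
                emit(_mutate(rng, consensus_gaps[bi], arch.spacer_mutation_rate))
            else:
                emit(_independent_gap(rng, gap, ci))
            if block.id in deleted:
                truth.append(TruthRow(ci, block.id, -1, -1, ".", "deleted"))
                continue
            strand = "-" if block.id in inverted else "+"
            seq = block.seq if strand == "+" else reverse_complement(block.seq)
            truth.append(
                TruthRow(ci, block.id, pos, pos + len(seq), strand, "present")
            )
            emit(seq)
            if block.id in duplicated:
                dup_gap = _independent_gap(rng, GapSpec(0, 4), ci)
                emit(dup_gap)
                truth.append(
                    TruthRow(ci, block.id, pos, pos + len(seq), strand, "duplicate")
                )
                emit(seq)
        last = arch.gaps[-1]
        if last.shared:
            emit(_mutate(rng, consensus_gaps[len(arch.blocks)], arch.spacer_mutation_rate))
        else:
            emit(_independent_gap(rng, last, ci))
        records.append((f"copy{ci + 1}", "".join(parts)))

    family = SequenceFamily(tuple(records))
    return family, truth


def truth_to_tsv(truth: list[TruthRow]) -> str:
    lines = ["copy_index\tblock_id\tstart\tend\tstrand\tstatus"]
    for row in truth:
        lines.append(
            f"{row.copy_index}\t{row.block_id}\t{row.start}\t{row.end}\t"
            f"{row.strand}\t{row.status}"
        )
    return "\n".join(lines) + "\n"
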