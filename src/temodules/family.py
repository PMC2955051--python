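"""Sequence I/O and alphabet utilities for TE families.

A family is an ordered set of named nucleotide sequences (the copies of one
transposable-element family).  Order is the FASTA order and is preserved by
every downstream stage.  The alphabet is {A, C, G, T, N}; lowercase input is
folded to uppercase on load.  ``N`` is accepted on input but breaks exact
repeats: a maximal repeat never contains an ambiguous position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FamilyFormatError(ValueError):
    """Raised when an input file violates the family format contract."""


@dataclass(frozen=True)
class SequenceFamily:
    """Ordered, named nucleotide sequences of one TE family.

    ``records`` is a tuple of ``(id, sequence)`` pairs in file order.
    Identifiers are unique and non-empty; sequences are uppercase strings
    over {A, C, G, T, N} of length >= 1.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise FamilyFormatError("duplicate identifier in family")
        for rid, seq in self.records:
            if not rid:
                raise FamilyFormatError("empty identifier")
            if not seq:
                raise FamilyFormatError(f"empty sequence for record {rid!r}")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.records)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(seq for _, seq in self.records)

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, index: int) -> tuple[str, str]:
        return self.records[index]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "SequenceFamily":
        """Build a family from ``(id, seq)`` pairs, validating the alphabet."""
        cleaned = []
        for rid, seq in pairs:
            up = seq.upper()
            _check_alphabet(up, rid)
            cleaned.append((rid, up))
        return cls(tuple(cleaned))

    @classmethod
    def from_sequences(cls, seqs: Sequence[str], prefix: str = "seq") -> "SequenceFamily":
        """Convenience constructor with generated ids ``seq1, seq2, ...``."""
        return cls.from_pairs((f"{prefix}{i + 1}", s) for i, s in enumerate(seqs))

    def reverse_complemented(self) -> "SequenceFamily":
        """The family with every sequence reverse-complemented."""
        return SequenceFamily(
            tuple((rid, reverse_complement(seq)) for rid, seq in self.records)
        )


def _check_alphabet(seq: str, rid: str) -> None:
    for pos, ch in enumerate(seq):
        if ch not in ALPHABET:
            raise FamilyFormatError(
                f"invalid alphabet: character {ch!r} at position {pos + 1} "
                f"of record {rid!r}"
            )


def read_fasta(path: str | Path) -> SequenceFamily:
    """Read a multi-FASTA file into a :class:`SequenceFamily`.

    Records are kept in file order; lowercase letters are folded to
    uppercase.  Raises :class:`FamilyFormatError` on an empty file, a
    duplicate identifier or a character outside {A, C, G, T, N}.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FamilyFormatError(f"no sequences in {path}")
    seen: set[str] = set()
    pairs = []
    for rec in records:
        if rec.id in seen:
            raise FamilyFormatError(f"duplicate identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FamilyFormatError(f"empty sequence for record {rec.id!r}")
        _check_alphabet(seq, rec.id)
        pairs.append((rec.id, seq))
    return SequenceFamily(tuple(pairs))


def write_fasta(family: SequenceFamily, path: str | Path, width: int = 70) -> None:
    """Write a family back to FASTA (wrapped at ``width`` columns)."""
    with open(path, "w") as handle:
        for rid, seq in family.records:
            handle.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def reverse_complement(s: str) -> str:
    """Reverse complement over {A, C, G, T, N}; N maps to N.

    An involution: applying it twice returns the input.
    """
    for ch in s:
        if ch not in ALPHABET:
            raise ValueError(f"invalid alphabet: {ch!r}")
    return s.translate(_COMPLEMENT)[::-1]


def default_min_size_module(family: SequenceFamily) -> int:
    """Data-driven default for the minimal module size.

    Returns the smallest ``x >= 1`` such that some word of size ``x`` over
    {A, C, G, T} is absent from the family, i.e. the number of distinct
    x-mers observed (direct strand, N-free) is strictly below ``4**x``.
    Always terminates because the sequences are finite.
    """
    if family.n == 0:
        raise ValueError("empty family")
    x = 1
    while True:
        seen: set[str] = set()
        full = 4**x
        for seq in family.sequences:
            for i in range(len(seq) - x + 1):
                kmer = seq[i : i + x]
                if "N" not in kmer:
                    seen.add(kmer)
            if len(seen) == full:
                break
        if len(seen) < full:
            return x
        x += 1
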