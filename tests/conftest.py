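"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import numpy as np
import pytest

from temodules import (
    DetectionParams,
    PlantedArchitecture,
    SequenceFamily,
    GapSpec,
    demo_architecture,
    detect_modules,
    generate_family,
)


def dp_edit_distance(a: str, b: str) -> int:
    """Textbook dynamic-programming Levenshtein distance (test oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


def absent_kmer_size_oracle(seqs: list[str], kmax: int = 14) -> int:
    """Smallest k with an absent k-mer, by exhaustive k-mer enumeration."""
    for k in range(1, kmax + 1):
        seen = set()
        for s in seqs:
            for i in range(len(s) - k + 1):
                w = s[i : i + k]
                if "N" not in w:
                    seen.add(w)
        if len(seen) < 4**k:
            return k
    raise AssertionError("oracle cap exceeded")


def random_family(
    rng: random.Random,
    n_seqs: int | None = None,
    length: tuple[int, int] = (20, 120),
    alphabet: str = "ACGT",
) -> SequenceFamily:
    n = n_seqs if n_seqs is not None else rng.randint(1, 5)
    seqs = [
        "".join(rng.choice(alphabet) for _ in range(rng.randint(*length)))
        for _ in range(n)
    ]
    return SequenceFamily.from_sequences(seqs)


def adversarial_families() -> list[SequenceFamily]:
    """Repeat-rich edge cases for the MR enumeration oracle check."""
    F = SequenceFamily.from_sequences
    return [
        F(["A" * 80]),
        F(["A" * 40, "T" * 40]),
        F(["AC" * 40]),
        F(["ACG" * 25, "ACG" * 20]),
        F(["GATTACA" * 8, "GATTACA" * 8]),
        F(["ACGT" * 20]),  # palindromic period
        F(["AAAATTTT" * 8]),
        F(["ACGTN" * 15]),
        F(["NNNNACGTACGTNNNN"]),
        F(["ACGTACGT", "ACGTACGT", "ACGTACGT"]),
        F(["A"]),
        F(["AN", "NA"]),
        F(["ATATATATAT", "TATATATATA"]),
        F(["AACGTT" * 10, "AACGTT" * 9 + "C"]),
    ]


@pytest.fixture(scope="session")
def planted_run():
    """One standard planted family with every event type, detected with
    the pair-support level; reused by several structural tests."""
    n_copies = 6
    arch = demo_architecture(seed=77, n_copies=n_copies, n_blocks=3)
    family, truth = generate_family(arch, n_copies)
    params = DetectionParams(
        min_size_module=15,
        min_sequences=n_copies - 1,
        reverse=True,
        truncated=True,
    )
    catalog = detect_modules(family, params)
    return arch, family, truth, params, catalog


def ward_oracle(values):
    """From-scratch Ward aggregation: at every step recompute the loss of
    inertia between clusters directly from weights and centroids (no
    Lance-Williams shortcut).  Same tie-break as the implementation."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    clusters = {
        i: (1.0 / n, np.asarray(values[i], dtype=float), i) for i in range(n)
    }  # id -> (weight, centroid, min leaf)
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                wa, ca, la = clusters[a]
                wb, cb, lb = clusters[b]
                d = wa * wb / (wa + wb) * float(np.sum((ca - cb) ** 2))
                key = (d, min(la, lb), max(la, lb), min(a, b), max(a, b))
                if best is None or key < best[0]:
                    best = (key, a, b)
        key, a, b = best
        wa, ca, la = clusters[a]
        wb, cb, lb = clusters[b]
        w = wa + wb
        merges.append((key[0], frozenset([la]), frozenset([lb])))
        clusters[next_id] = (w, (wa * ca + wb * cb) / w, min(la, lb))
        del clusters[a], clusters[b]
        next_id += 1
    return merges


def score_recovery(arch, truth, catalog, min_cover_frac: float = 0.8):
    """Compare detected occurrences against the planted truth table.

    Returns (missed_rows, orientation_errors, truncated_in_deletion_copy).
    A planted block counts as recovered when a module occurrence covers at
    least ``min_cover_frac`` of it; orientation must agree (reverse kinds
    for '-' strands)."""
    occs = [(mod.id, o) for mod, o in catalog.all_occurrences()]
    missed, orient_bad = [], []
    for row in truth:
        if row.status == "deleted":
            continue
        hits = [
            (mid, o)
            for mid, o in occs
            if o.seq_index == row.copy_index
            and o.start < row.end
            and row.start < o.end
            and min(o.end, row.end) - max(o.start, row.start)
            >= min_cover_frac * (row.end - row.start)
        ]
        if not hits:
            missed.append(row)
            continue
        want_rev = row.strand == "-"
        got_rev = any(
            o.kind in ("reverse", "truncated_reverse") for _, o in hits
        )
        if want_rev != got_rev:
            orient_bad.append((row, {o.kind for _, o in hits}))
    b1 = arch.blocks[0]
    b1row = next(
        r for r in truth if r.copy_index == 1 and r.block_id == b1.id
    )
    truncated = [
        o
        for mid, o in occs
        if o.kind.startswith("truncated")
        and o.seq_index == 1
        and o.start < b1row.end
        and b1row.start < o.end
    ]
    return missed, orient_bad, truncated
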