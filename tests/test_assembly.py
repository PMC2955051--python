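"""Flexible-repeat assembly: spacer association rules, compatibility
graph, clique heuristic and the seed-and-extend module builder."""

import itertools
import random

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from temodules import (
    DetectionParams,
    MaximalRepeat,
    Occurrence,
    SequenceFamily,
    build_compatibility_graph,
    build_modules,
    build_pair,
    collect_pairs,
    detect_modules,
    edit_distance,
    enumerate_mrs,
    find_support_clique,
)
from temodules.assembly import FlexibleRepeat, PairCandidate
from temodules.synth import random_sequence

from conftest import dp_edit_distance

import numpy as np

dna = st.text(alphabet="ACGT", min_size=0, max_size=25)


class TestEditDistance:
    @pytest.mark.parametrize(
        "x,y,d",
        [("", "ACG", 3), ("ACGT", "ACGT", 0), ("GATT", "GTAT", 2), ("", "", 0)],
    )
    def test_examples(self, x, y, d):
        assert edit_distance(x, y) == d

    @settings(derandomize=True, max_examples=150)
    @given(dna, dna)
    def test_matches_dp_oracle_and_symmetry(self, x, y):
        d = edit_distance(x, y)
        assert d == dp_edit_distance(x, y)
        assert d == edit_distance(y, x)

    @settings(derandomize=True, max_examples=50)
    @given(dna, dna, dna)
    def test_triangle_inequality(self, x, y, z):
        assert edit_distance(x, z) <= edit_distance(x, y) + edit_distance(y, z)


def _mk_candidate(spacer, flank_size, seq_index=0, seed_index=0, start=0):
    """Pair candidate with explicit spacer and smaller-part size."""
    return PairCandidate(
        seed_index=seed_index,
        seq_index=seq_index,
        spacer=spacer,
        flank_size=flank_size,
        orientation="+",
        next_strand="+",
        next_occ=Occurrence(seq_index, start + 100, start + 100 + flank_size),
        a_span=20,
        new_start=start,
        new_end=start + 100 + flank_size,
    )


def _pair_fixture(spacers, a_word="GGAAGGTTGGCCAAGGTTCC", b_word="TTCCA"):
    """Sequences 'A + spacer_i + B' plus the seed and next-MR records."""
    seqs = [a_word + x + b_word for x in spacers]
    fam = SequenceFamily.from_sequences(seqs)
    a_occs = [Occurrence(i, 0, len(a_word)) for i in range(len(spacers))]
    b_occs = [
        Occurrence(i, len(a_word) + len(x), len(a_word) + len(x) + len(b_word))
        for i, x in enumerate(spacers)
    ]
    seed = FlexibleRepeat.single(a_word, a_occs)
    next_mr = MaximalRepeat(b_word, tuple(b_occs))
    return fam, seed, next_mr


class TestSpacerAssociationCases:
    """The four canonical association situations between two MRs."""

    def test_short_spacer_is_admissible(self):
        # spacer shorter than the smaller MR: always associable
        fam, seed, next_mr = _pair_fixture(["ACG", "ACG"])
        pairs = collect_pairs(seed, next_mr, 100.0, fam)
        assert len(pairs) == 2 and all(p.spacer == "ACG" for p in pairs)

    def test_empty_spacer_is_admissible(self):
        fam, seed, next_mr = _pair_fixture(["", ""])
        pairs = collect_pairs(seed, next_mr, 100.0, fam)
        assert len(pairs) == 2 and all(p.spacer == "" for p in pairs)

    def test_similar_long_spacers_are_compatible(self):
        # equal-length spacers at edit distance 2, below both part sizes
        x, y = "AAAACCCCGGGGTTTT", "AAAACGCCGGGGTTAT"
        assert edit_distance(x, y) == 2
        g = build_compatibility_graph(
            [_mk_candidate(x, 5, 0), _mk_candidate(y, 5, 1)]
        )
        assert g.number_of_edges() == 1

    def test_distant_spacers_are_rejected(self):
        # edit distance 4 exceeds the smaller part size 3: no edge
        x, y = "ACGT", "TGCA"
        assert edit_distance(x, y) == 4
        g = build_compatibility_graph(
            [_mk_candidate(x, 3, 0), _mk_candidate(y, 3, 1)]
        )
        assert g.number_of_edges() == 0

    def test_identical_spacers_always_edge(self):
        g = build_compatibility_graph(
            [_mk_candidate("ACGT", 1, 0), _mk_candidate("ACGT", 1, 1)]
        )
        assert g.number_of_edges() == 1

    def test_length_condition_with_maxratio(self):
        # spacer longer than |A| * maxratio/100 is excluded up front
        fam, seed, next_mr = _pair_fixture(["ACGTACGTAC", "ACGTACGTAC"])  # |x|=10
        assert len(collect_pairs(seed, next_mr, 100.0, fam)) == 2
        assert len(collect_pairs(seed, next_mr, 25.0, fam)) == 0  # window 5


class TestSupportClique:
    def test_complete_graph_covers_all_sequences(self):
        cands = [
            _mk_candidate("ACGT", 8, seq_index=i, seed_index=i) for i in range(4)
        ]
        g = build_compatibility_graph(cands)
        clique = find_support_clique(g, 4)
        assert clique is not None
        assert {c.seq_index for c in clique} == {0, 1, 2, 3}
        for a, b in itertools.combinations(clique, 2):
            assert g.has_edge(a, b)

    def test_edgeless_graph_yields_none(self):
        cands = [
            _mk_candidate("AAAA", 2, seq_index=0),
            _mk_candidate("TTTT", 2, seq_index=1),
        ]
        g = build_compatibility_graph(cands)
        assert find_support_clique(g, 2) is None

    @pytest.mark.parametrize("seed", range(8))
    def test_heuristic_result_is_always_a_valid_clique(self, seed):
        """On random graphs (<= 12 vertices) the heuristic either returns a
        clique covering the requested sequences or None; it may miss a
        qualifying clique the exact oracle finds (documented contract)."""
        rng = random.Random(seed)
        n = rng.randint(3, 12)
        cands = [
            _mk_candidate(
                random_sequence(np.random.default_rng(seed * 100 + i), 4),
                3,
                seq_index=rng.randint(0, 3),
                seed_index=i,
                start=i * 10,
            )
            for i in range(n)
        ]
        g = nx.Graph()
        g.add_nodes_from(cands)
        for a, b in itertools.combinations(cands, 2):
            if rng.random() < 0.5:
                g.add_edge(a, b)
        min_seq = 2
        clique = find_support_clique(g, min_seq)
        exact_exists = any(
            len({c.seq_index for c in cl}) >= min_seq
            for cl in nx.find_cliques(g)
        )
        if clique is not None:
            assert len({c.seq_index for c in clique}) >= min_seq
            for a, b in itertools.combinations(clique, 2):
                assert g.has_edge(a, b)
            assert exact_exists


class TestBuildPair:
    def _view(self, fam, min_support):
        return enumerate_mrs(fam, min_support).filtered(min_support)

    def test_planted_unique_partner_is_found(self):
        rng = np.random.default_rng(0)
        a, b = random_sequence(rng, 20), random_sequence(rng, 10)
        seqs = [
            random_sequence(rng, 25) + a + random_sequence(rng, 4) + b
            + random_sequence(rng, 25)
            for _ in range(3)
        ]
        fam = SequenceFamily.from_sequences(seqs)
        view = self._view(fam, 3)
        seed_rank = next(i for i, mr in enumerate(view) if a in mr.word)
        seed = FlexibleRepeat.single(view[seed_rank].word, view[seed_rank].occurrences)
        res = build_pair(view, seed, seed_rank + 1, 3, 100.0, fam)
        assert res.ok and b in res.next_mr.word

    def test_exhausted_view_returns_not_ok(self):
        fam = SequenceFamily.from_sequences(["GATTACAGATT", "GATTACAGATT"])
        view = self._view(fam, 2)
        seed = FlexibleRepeat.single(view[0].word, view[0].occurrences)
        res = build_pair(view, seed, len(view), 2, 100.0, fam)
        assert not res.ok

    def test_largest_qualifying_mr_preferred(self):
        """Of two equally admissible partners the one earlier in the sorted
        list (larger, then more occurrences) is chosen."""
        rng = np.random.default_rng(1)
        a = random_sequence(rng, 20)
        b_small, b_large = random_sequence(rng, 8), random_sequence(rng, 14)
        seqs = [
            random_sequence(rng, 20) + b_large + random_sequence(rng, 2) + a
            + random_sequence(rng, 2) + b_small + random_sequence(rng, 20)
            for _ in range(3)
        ]
        fam = SequenceFamily.from_sequences(seqs)
        view = self._view(fam, 3)
        seed_rank = next(i for i, mr in enumerate(view) if a in mr.word)
        seed = FlexibleRepeat.single(view[seed_rank].word, view[seed_rank].occurrences)
        res = build_pair(view, seed, 0, 3, 100.0, fam)
        assert res.ok and b_large in res.next_mr.word


class TestBuildModules:
    def test_similar_spacers_merge_into_one_module(self, planted_pair_family):
        fam, a, b = planted_pair_family("ACGTAC")
        L = enumerate_mrs(fam, 1)
        flex, used = build_modules(L, 3, 20, 100.0, fam)
        assert flex is not None
        assert flex.support == 3
        # the chain spans both planted blocks in every sequence
        for occ in flex.occurrences:
            seq = fam.sequences[occ.seq_index]
            assert a in seq[occ.start : occ.end]
            assert b in seq[occ.start : occ.end]

    def test_dissimilar_spacers_never_merge(self, planted_pair_family):
        # per-copy random 16-nt spacers against a 6-nt partner: pairwise
        # edit distance exceeds the smaller part, so no association
        fam, a, b = planted_pair_family(None, b_len=6, spacer_len=16)
        L = enumerate_mrs(fam, 1)
        flex, used = build_modules(L, 3, 18, 100.0, fam)
        assert flex is not None
        for occ in flex.occurrences:
            text = fam.sequences[occ.seq_index][occ.start : occ.end]
            assert a in text and b not in text

    def test_maxratio_monotonicity(self):
        rng = np.random.default_rng(3)
        a, b = random_sequence(rng, 22), random_sequence(rng, 20)
        spacer = random_sequence(rng, 10)
        seqs = [
            random_sequence(rng, 30) + a + spacer + b + random_sequence(rng, 30)
            for _ in range(3)
        ]
        fam = SequenceFamily.from_sequences(seqs)
        prev_max_spacer = None
        for ratio in (100.0, 75.0, 50.0, 25.0):
            cat = detect_modules(
                fam, DetectionParams(min_size_module=18, maxratio=ratio)
            )
            spacer_lens = [
                len(x)
                for mod in cat.modules
                for o in mod.flex.occurrences
                for x in o.spacers
            ]
            cur = max(spacer_lens, default=0)
            if prev_max_spacer is not None:
                assert cur <= prev_max_spacer
            prev_max_spacer = cur

    def test_length_condition_keeps_distant_blocks_apart(self):
        """With the length condition enforced, blocks separated by gaps
        longer than any block stay in distinct modules instead of fusing
        into one chain spanning the whole sequence."""
        rng = np.random.default_rng(4)
        a, b = random_sequence(rng, 24), random_sequence(rng, 24)
        seqs = [
            random_sequence(rng, 20) + a + random_sequence(rng, 60) + b
            + random_sequence(rng, 20)
            for _ in range(4)
        ]
        fam = SequenceFamily.from_sequences(seqs)
        cat = detect_modules(fam, DetectionParams(min_size_module=18))
        assert cat.m >= 2
        for mod in cat.modules:
            for occ in mod.occurrences:
                text = fam.sequences[occ.seq_index][occ.start : occ.end]
                assert not (a in text and b in text)

    def test_replayed_conditions_hold_for_every_module(self, planted_pair_family):
        fam, _, _ = planted_pair_family("GGATCC")
        L = enumerate_mrs(fam, 1)
        flex, _ = build_modules(L, 3, 20, 100.0, fam)
        assert flex is not None
        histories = [o.history for o in flex.occurrences]
        n_steps = {len(h) for h in histories}
        assert len(n_steps) == 1
        for step in range(n_steps.pop()):
            recs = [h[step] for h in histories]
            for (ai, bi, xi), (aj, bj, xj) in itertools.combinations(recs, 2):
                assert edit_distance(xi, xj) <= min(ai, aj, bi, bj)
            for a_span, b_len, x in recs:
                assert len(x) <= a_span


@pytest.fixture
def planted_pair_family():
    def make(shared_spacer, a_len=22, b_len=20, spacer_len=None, n=3):
        rng = np.random.default_rng(99)
        a, b = random_sequence(rng, a_len), random_sequence(rng, b_len)
        seqs = []
        for _ in range(n):
            x = (
                shared_spacer
                if shared_spacer is not None
                else random_sequence(rng, spacer_len)
            )
            seqs.append(
                random_sequence(rng, 30) + a + x + b + random_sequence(rng, 30)
            )
        return SequenceFamily.from_sequences(seqs), a, b

    return make
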