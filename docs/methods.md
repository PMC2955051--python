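# Methods

## Problem and model

A transposable-element family is a set of sequences descended from one
ancestor but reshaped by deletions, tandem duplications, inversions and
sequence capture. `temodules` abstracts each copy as a succession of
*modules*: chains of exact maximal repeats (MRs) with variable spacers,
shared by enough copies. The core assumptions are:

* conserved blocks are **exact** repeated words (maximal repeats) —
  point mutations inside a block split it into smaller MRs, they do not
  become mismatches;
* variation is confined to the **spacers** between blocks, bounded in
  length by the parts they connect (length condition, scaled by
  `Maxratio`) and in pairwise edit distance by the smaller part
  (distance condition) — flexibility can never exceed the parts it
  links;
* module occurrences partition the sequences: no position belongs to
  two modules.

## Maximal repeat enumeration

Sequences are concatenated with one unique sentinel symbol per
sequence; with the reverse option, reverse-complemented copies are
appended so both strands are indexed at once. A suffix array is built
by prefix doubling (numpy sorts, O(N log² N)), the LCP array by Kasai's
algorithm, and every LCP interval is tested for left-maximality via the
preceding-symbol set. An MR and its reverse complement are merged under
the lexicographically smaller word; occurrences found through the
reverse-complemented copies are mapped back to minus-strand coordinates
on the originals, and a palindromic site is counted once (plus strand).
`N` is accepted on input but treated as a per-position unique symbol:
it breaks repeats, so no reported MR contains an ambiguous base.

A brute-force enumerator (`brute_force_mrs`, capped at 2 kb) grows
repeated words letter by letter and applies the flank-diversity
definition directly; the test suite checks exact agreement on hundreds
of random and adversarial fixtures at every support level.

## Assembly

The MR list L is sorted by decreasing length, then decreasing
occurrence count, then word, then first position (determinism). Seeds
are taken in this order. For a seed, candidate partners are collected
by a windowed sweep over occurrence positions — equivalent to testing
every MR of the list but linear in the occurrences near the seed — and
examined in list order, so the largest qualifying partner wins.

All quantities are expressed in the **module frame**: an occurrence on
the reverse strand realizes the reverse-complemented chain, so its
genomic left side is the frame right side and its spacers are
reverse-complemented before comparison. Support may therefore be
reached by a combination of both directions at assembly time.

Candidates of one partner are grouped into spacer equivalence classes
(identical frame spacers are interchangeable under the edge rule
`e(x, y) ≤ min(b_x, b_y)`), the class graph is built with a
length-difference prefilter before computing edit distances (edlib),
and a clique covering enough distinct sequences is sought by a
deterministic greedy heuristic: drop vertices whose closed neighborhood
cannot cover the required sequences, then repeatedly take the
heaviest-degree vertex among those still mutually adjacent (ties by
lowest sequence/position). The heuristic can miss a qualifying clique;
this is the documented contract. Within an accepted clique each seed
occurrence and each partner occurrence is used once, and extended spans
must be pairwise disjoint.

Accepted associations consume exactly the participating MR occurrences
from L; other occurrences of the same MRs stay available. A chain grows
at either end until no extension qualifies. If the final chain's
shortest occurrence is below `MinSizeModule` the round returns nothing
— with its occurrences nevertheless consumed — and the support level
ends; this mirrors the greedy construction faithfully rather than
back-tracking.

Two deliberate choices refine the construction:

* **single-part modules** — a seed that pairs with nothing but meets
  the size and support conditions is emitted as a one-part module at
  its place in the scan (every maximal repeat is a flexible repeat).
  Without this, conserved isolated blocks such as TE termini would
  vanish, and chains of the block's own subwords would claim its region
  instead. MRs whose word already belongs to a discovered module are
  not re-emitted this way: a leftover occurrence of a known module part
  is the business of the truncated pass.
* **minimum partner length 2** — with a one-nucleotide partner the
  distance condition degenerates (spacers of length ≤ 1 are compatible
  by construction), so single-nucleotide MRs would attach to any chain
  by chance at any support level and blur module boundaries. They
  remain in L and may still seed.

## Detection loop, reverse and truncated occurrences

Support sweeps from *n* down to 1 (or runs one user-fixed level). After
each accepted module its intervals are claimed, the list is pruned of
overlapping occurrences (partition condition), and failed seeds are
memoized for the rest of the level (pruning only removes occurrences,
so failure is monotone).

**Orientation convention.** A module is stored in the orientation of
its first occurrence (lowest sequence index, then position), which is
labelled `direct`; occurrences realizing the reverse-complemented chain
are `reverse`. Under this convention an inverted copy inside a mostly
direct family is always reported as reverse. The price is that
re-orienting the entire input does not simply swap direct/reverse
labels at the catalog level (position-based tie-breaks are not
mirror-invariant); the strand-swap symmetry is exact at the MR layer
and is tested there.

When the reverse option is on, the reverse module (parts reversed and
complemented) is searched in uncovered regions immediately after each
module is finalized, so its occurrences cannot be re-consumed by later
modules. A candidate's spacers must satisfy the length condition
against the larger flanking part and be within edit distance of the
smaller flanking part from the corresponding spacer of at least one
complete occurrence.

Truncated occurrences are attached in a second pass, module by module
in discovery order, once all complete modules are known. An occurrence
anchors on an exact, uncovered match of the module's largest MR
(mandatory part) and gathers the other parts greedily in their original
order, within the observed per-gap spacer-length bounds widened by the
`Maxratio` slack of the part being attached; a missing part widens the
window for the next one by its own length. The conserved fraction is
the summed length of the present parts over the module's total MR
length; a scan that finds every part is classified as a full
occurrence. The `MinSizeModule` bound applies to complete occurrences,
not truncated ones. Truncated-reverse occurrences are supported and
labelled `truncated_reverse`.

A post-hoc verifier (`verify_catalog`) replays the length and distance
conditions from each module's assembly audit trail, re-reads every part
and spacer from the genome, and checks interval disjointness; it runs
in the test suite on every pipeline fixture.

## Clustering and rendering

The incidence matrix has one counter per module, or three with the
reverse option (direct `Mi`, reverse `rMi`, total `Mi|rMi`); a
truncated occurrence adds its conserved fraction to its orientation
counter and to the total. Ward clustering uses
Δ(x, y) = (1/2n) Σ (xᵢ − yᵢ)² between sequences, cluster weights start
at 1/n and add, and merged distances follow
Δ(x∪y, z) = ((n_x+n_z)Δ(x,z) + (n_y+n_z)Δ(y,z) − n_zΔ(x,y)) /
(n_x+n_y+n_z). The global 1/(2n) scaling affects heights only, never
the topology (tested). Ties on the minimum merge are broken toward the
pair with the lowest smallest leaf index. The tree is written as Newick
with branch lengths equal to height differences; the SVG lays the tree
left of one track per sequence in leaf order, boxes textured per module
id, triangles marking reverse and crossed boxes truncated occurrences.

## Synthetic families

`synth` plants a consensus layout `gap₀ B₁ gap₁ … B_k gap_k` and
realizes copies with per-copy events (delete, tandem-duplicate, invert
a block) — block interiors are never mutated, matching the exact-MR
assumption, while spacers carry the variation. Gaps are either *shared*
(one consensus realization point-mutated per copy at rate 0.05/nt, the
default) or independent per copy. Independent gaps have their
block-adjacent bases cycled over A/C/G/T by copy index so planted
boundaries are sharp, emulating the unrelated host DNA flanking real
insertions. `demo_architecture` is the standard study condition used by
the tests and the acceptance script: one close block pair over a short
independent spacer (3–8 nt, merging into a two-part module), remaining
blocks isolated by 40–65 nt independent gaps (one module each), blocks
of 12–30 nt, and one deletion (the pair's smaller member), one
inversion and one tandem duplication on distinct copies with copy 0
intact.

What the generator does **not** emulate: point mutations inside
conserved blocks, indel drift of block boundaries, nested insertions,
and realistic base composition. Passing recovery tests therefore show
that the method recovers architectures whose blocks are exactly
conserved — the regime the model is built for — not that it tolerates
degraded blocks, which by design fragment into smaller MRs.

## Problem sizes and numerical choices

Tests and the acceptance script run on families of 5–15 copies of
~150–450 nt (total 1–5 kb), the scale of a typical MITE family
alignment set; detection takes well under a minute per family. The
planted-recovery condition fixes `MinSequences = n − 1` (the pair
module's support once one copy lost its smaller member) and
`MinSizeModule = 15`, between the small and large planted block sizes.
Edit distances are computed by edlib with an LRU cache keyed on the
ordered string pair; empty strings short-circuit. Maxratio comparisons
use a 1e-9 absolute epsilon; Ward oracle agreement is asserted at
1e-9. All iteration orders are explicitly keyed, so identical inputs
and parameters give byte-identical outputs.

## Known limitations

* The clique search is the stated greedy heuristic: a qualifying
  module can occasionally be missed, and the emitted module for a
  support level depends on the greedy seed order.
* An undersized chain ends its support level with its occurrences
  consumed; those regions are only recoverable by the truncated pass.
* Support counted during assembly combines both strands, but a module
  whose direct and reverse copies lie in disjoint sequence subsets is
  found at the level of the larger subset and completed by the reverse
  search, not discovered jointly at the combined level in one clique
  when the geometry differs.
* Full mirror-equivariance of the catalog under reverse-complementing
  the input is not guaranteed (tie-breaks are position-based).
* The default support sweep (n → 1) reports a leftover occurrence of a
  large block as its own later module rather than as a truncated
  occurrence; truncated occurrences arise when a fixed `MinSequences`
  excludes the damaged copies from discovery, as in the standard study
  condition.
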