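# temodules

Segmentation of transposable-element (TE) families into **modules**:
flexible assemblies of exact maximal repeats separated by constrained
spacers.

Many TE families — MITEs and other non-autonomous elements in
particular — are so rearranged internally (deletions, tandem
duplications, inversions, captured host DNA) that multiple alignment
fails to recover their architecture. `temodules` takes the family's
sequences (a multi-FASTA of tens of copies, hundreds to thousands of nt
each), decomposes each copy into a succession of modules shared across
copies, labels reverse-complemented and truncated module occurrences,
clusters the copies by their modular profile and renders the whole
family as one annotated figure. It is aimed at people studying TE
family structure and evolution, and more generally at any set of
related nucleotide sequences whose block architecture alignment cannot
capture.

## The model

A word *w* is a **maximal repeat** (MR) in sequences *S₁…Sₙ* when it has
two occurrences *awc* and *bwd* with *a ≠ b* and *c ≠ d* (sequence ends
act as per-sequence unique sentinel letters). A **flexible repeat**
chains MRs *A* and *B* through spacers *xᵢ*, one per supporting
sequence, under two constraints:

* **length condition** — |xᵢ| ≤ max(|Aᵢ|, |Bᵢ|), tunable to
  |xᵢ| ≤ |Aᵢ| · Maxratio/100 with *A* the larger part;
* **distance condition** — e(xᵢ, xⱼ) ≤ min(|Aᵢ|, |Aⱼ|, |Bᵢ|, |Bⱼ|) for
  all sequence pairs, where *e* is the Levenshtein distance.

Flexibility can never exceed the parts it links. A **module** is a
flexible repeat whose every occurrence spans at least `MinSizeModule`
nt and which is supported by at least `MinSequences` sequences; module
occurrences never overlap (partition condition). Construction is greedy
seed-and-extend: the largest MRs seed chains that grow at either end
while a clique of mutually-compatible spacer associations covers enough
sequences, sweeping the support level from *n* down to 1. Reverse
(palindromic) modules are searched as the reverse-complemented,
order-reversed chain; truncated occurrences — partial copies retaining
the module's largest MR — are attached in a second pass and contribute
fractionally (conserved MR length / total MR length).

Sequences are then clustered by Ward's criterion on the module
incidence matrix (three counters per module when the reverse search is
on: direct, reverse, total), Δ(x, y) = (1/2n) Σᵢ (xᵢ − yᵢ)², merged via
the Lance–Williams recurrence with additive weights starting at 1/n.

## Worked example

Generate a synthetic family of six copies with three planted blocks —
copy 2 lost the small block, copy 3 carries an inverted block, copy 4 a
tandem duplication — then segment it:

```sh
python - <<'PY'
from temodules import demo_architecture, generate_family, write_fasta
arch = demo_architecture(seed=11, n_copies=6, n_blocks=3)
family, truth = generate_family(arch, 6)
write_fasta(family, "family.fa")
PY
temodules family.fa --min-size-module 15 --min-sequences 5 \
    --reverse --truncated --out-prefix demo
```

which prints

```
2 modules in 6 sequences; outputs under prefix demo
```

and writes `demo.composition.tsv` (the per-sequence segmentation),
`demo.nwk` (the classification tree), `demo.svg` (the figure) and
`demo.manifest.json` (all resolved parameters; re-run exactly with
`temodules --from-manifest demo.manifest.json`). The composition file
reads:

```
sequence_id	module_id	start	end	kind	conserved_fraction
copy1	1	48	87	direct	1.0000
copy1	2	142	160	direct	1.0000
copy2	1	58	80	truncated_direct	0.6216
copy2	2	127	145	direct	1.0000
copy3	1	61	103	direct	1.0000
copy3	2	153	171	reverse	1.0000
copy4	1	50	89	direct	1.0000
copy4	2	138	156	direct	1.0000
copy4	2	157	175	direct	1.0000
copy5	1	50	93	direct	1.0000
copy5	2	143	161	direct	1.0000
copy6	1	50	92	direct	1.0000
copy6	2	158	176	direct	1.0000
```

Coordinates are 1-based inclusive. Module 1 is the two-block pair: in
copy2 only its larger part survives, reported as a truncated occurrence
conserving 23 of the 37 module nt (fraction 0.6216). Module 2 is the
isolated block: inverted in copy3 (`reverse`) and tandem-duplicated in
copy4 (two occurrences). The SVG shows each module as a textured box,
triangles marking reverse occurrences and crossed boxes truncated ones,
with the Ward tree on the left.

Key parameters (see `temodules --help`): `--min-size-module` (default:
the smallest *k* such that some *k*-mer is absent from the input),
`--maxratio` (default 100), `--min-sequences` (default: sweep *n* → 1),
`--reverse`, `--truncated`.

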