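# Methods

## Graph semantics

`cdbg` operates on the bidirected, edge-centric de Bruijn graph of a string
collection. Vertices are canonical k-mers; an edge exists for every distinct
(k+1)-mer occurring in the input (edge-centric), not for every pair of
vertices with a (k−1)-overlap (node-centric). Incidence sides follow the
orientation rule: for an edge *e*, the k-prefix's vertex is attached through
its back side iff the prefix is canonical, and the k-suffix's vertex through
its front side iff the suffix is canonical. k must be odd and ≥ 3: an even k
would admit k-mers equal to their own reverse complement, for which front
and back are not well defined, so even k is rejected at input validation
rather than patched with a tie-break.

Input sequences are uppercased and split at any non-ACGT character into
maximal *valid runs*; runs shorter than k are dropped. Each run carries
empty-symbol (ε) sentinels at both ends. The sentinels make the entry side
of a run's first vertex (and the exit side of its last) permanently
branching, which is exactly what prevents a unitig from spanning two runs or
two input sequences. The conceptual "sentinel hub" vertex that all ε-edges
point to is never materialised; the ε inputs encode it completely.

## Per-instance automaton inputs

Every k-mer instance contributes one input symbol (c_front, c_back) to its
vertex's automaton, derived purely from the instance and its two flanking
characters — no lookahead or neighbour state is consulted:

* canonical instance: (front, back) = (prev, next);
* non-canonical instance: (front, back) = (complement(next),
  complement(prev));
* ε on either flank makes the corresponding output side ambiguous;
* **crossing loops**: if prev+instance (or instance+next) is a palindromic
  (k+1)-mer, the adjacent instance maps to the same vertex in the opposite
  orientation, so that one edge is incident to a single side twice. The side
  that flanking character encodes is forced ambiguous. Detecting this via
  palindromy needs only (instance, prev, next), which keeps the state pass
  strictly local.

This per-side character convention (front: edge reads c·label with the label
as suffix; back: label·d) is the unique encoding invariant under strand —
the same edge seen from any context yields the same character at the same
vertex side — and it bounds the distinct edges per side by four, one per
base. Both properties are tested exhaustively at k = 3.

## The 26-state automaton

A side status is one of five values (`unique(A|C|G|T)` or `ambiguous`);
a vertex state is a pair of side statuses, plus one joint `unvisited`
initial state, giving 5×5+1 = 26 states. Processing is per vertex, not per
edge: both incident edges of an instance are folded in simultaneously, which
is what allows a single unvisited state for both sides (per-side processing
would need 6×6 = 36 states). The transition is, per side, a monotone join —
unique(X) stays on X, becomes ambiguous on anything else; ambiguous is
absorbing — so folding a multiset of symbols is commutative and idempotent.
The full transition table is generated from these two rules rather than
hard-coded; a snapshot test freezes the generated table's digest. Visited
states partition into four classes by which sides are ambiguous
(single-in single-out: 16 states, multi-in single-out: 4,
single-in multi-out: 4, multi-in multi-out: 1), and the module deliberately
exposes no per-single-side transition entry point.

## State store

The canonical k-mer set is static after one enumeration pass, so states live
in a keyless table addressed by a minimal perfect index. Here that index is
a sorted key array with binary search; a hashed MPHF would be a drop-in
replacement behind the same contract (bijection onto [0, n), alien keys
never queried — querying one raises). State codes are 5-bit values in a
bit-packed array; the extractor's "already emitted" marker is a separate
1-bit flag rather than extra tagged state codes, because 26 states plus
tagged variants would not fit 5 bits. Total: a constant 6 bits per vertex
regardless of k and n, which the suite checks structurally. The store
serialises to a versioned binary file (magic, k, n, code width, keys, code
and flag payloads) so a computed state table can be built once and reused;
reuse skips the state pass and only re-runs extraction.

## Unitig extraction

A second pass walks each run. The walk enters a vertex through its front
side iff the instance is canonical (for a run's first vertex the rule gives
the sentinel side, the opposite of its exit side). A vertex initiates a
maximal unitig if its class is multi-in multi-out, or it is entered through
a branching side, or the previous vertex terminated; termination is the
mirror image, or the next vertex initiating by its own first three
conditions (the cross-references deliberately do not recurse). A vertex can
initiate and terminate in the same step; the single-vertex unitig is emitted
and initiation is re-checked at the next vertex. A run of length exactly k
has ε on both flanks, is multi-in multi-out, and becomes its own unitig.

Each unitig is reported once globally, in canonical orientation
(min of spelling and reverse complement; never palindromic, because a
palindromic spelling would repeat a vertex). The emission guard is a
test-and-set of the flag on the unitig's *signature* k-mer — the canonical
form of the first k-mer of the canonical spelling. Any unique constituent
k-mer would do (node decomposition makes every one of them exclusive to the
unitig); this choice is orientation-stable and needs no extra bookkeeping.
Unitig ids are assigned in sorted canonical-spelling order so that FASTA and
GFA outputs are byte-identical across runs and chunk counts.

## Chunked processing

Because state updates are an order-independent join, a run's instance stream
may be split into contiguous chunks and processed in any order or
interleaving; each k-mer belongs to the chunk containing its first
character, and chunks see the true flanking characters at their borders.
The `--threads` CLI option sets this chunk count. Processing remains
serialized — the package's contracts (order-independence of transitions,
per-vertex atomic update, idempotent emission) are what make actual
concurrency legal, but concurrency engineering is out of scope here, and
the tests assert bit-identical stores for adversarial chunk interleavings
instead.

## Independent oracle and validator

The explicit-adjacency compactor in `cdbg.oracle` is the ground truth the
pipeline is compared against. It builds, per (vertex, side), the set of
incident edge characters plus ε-sentinel and double-incidence (crossing
loop) marks, then enumerates maximal unitigs by path-walking from every
flanking side (a side is traversable only if it has exactly one incident
edge character and no ε or double mark; a flank is a non-traversable free
side or a free side whose single neighbour side is non-traversable). It
shares no classification logic with the automaton path, so agreement on
randomized fixtures is meaningful evidence; it self-checks that its walks
cover every vertex exactly once. It is not built to scale past a few
thousand vertices.

The validator checks the two defining properties of a correct compaction:
(i) every distinct canonical input k-mer occurs in exactly one unitig
exactly once, and (ii) every valid run is coverable by oriented unitigs
glued with (k−1)-overlaps, computed by an iterative right-to-left dynamic
program over run positions. Deliberately corrupted outputs (a dropped or
duplicated unitig) must fail the corresponding check, and the suite asserts
that they do.

## Synthetic data

The fixture generator models the tool's two input regimes: a single uniform
random genome, and a "colored" collection — one base genome plus closely
related variants. Defaults: 5 references of 5 kb, 1% per-base substitution
rate (related strains; divergence an order of magnitude above
within-species variation keeps small fixtures from being trivial copies),
0.1% indel rate with 1–3 bp events, and 0.1% N-run injection (1–10 bp)
emulating assembly gaps. Base composition is uniform with no GC skew or
repeat structure: the algorithm is composition-agnostic, so what matters
for coverage is branching density, strand mixing, N-induced run splitting
and crossing loops — the randomized test fixtures additionally splice in
engineered palindromic (k+1)-mers to force the latter. Everything is
deterministic given the seed. Consequently, passing tests demonstrate
correctness of the graph semantics on realistic branching structure, not
performance or robustness on chromosome-scale repeat-rich genomes.

## Problem sizes and numerical choices

Randomized equivalence and invariance tests use collections of 1–5
sequences totalling ≤ 2 kb at k ∈ {3, 5, 7}, with 35+ seeded fixtures per
k — small enough for the quadratic-ish oracle, large enough that every
state class, sentinel case and loop case occurs many times (verified by the
exhaustive k = 3 side-character tests). There are no tolerances anywhere:
every comparison in the package is exact (sets of strings, integer counts,
byte-identical files).

## Known limitations

* No 2-bit-packed k-mer arithmetic: k-mers are Python strings, so memory
  and speed are desk-scale (the 6-bit-per-vertex claim concerns the state
  table, not the index keys).
* The colored aspect of a multi-reference collection is captured by
  per-reference tilings (GFA paths), not per-unitig color bitmaps.
* FASTQ/read input is unsupported; inputs are assembled references.
* GFA output carries only LN/VN tags and the package's own documented
  record layout; no BCALM-style header conventions.
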