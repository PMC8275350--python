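# cdbg — compacted de Bruijn graph construction from reference genomes

`cdbg` builds the (colored) compacted de Bruijn graph of one or more
assembled DNA reference collections: it collapses every maximal
non-branching path (maximal *unitig*) of the bidirected, edge-centric
de Bruijn graph into a single sequence, without ever materialising the
graph itself. It is aimed at people who need the unitig decomposition of
one genome or of a collection of related genomes — as FASTA, or as a GFA1/GFA2
assembly graph with per-reference paths — and at developers who want a small,
fully tested reference implementation of the automaton-based compaction
algorithm to build on.

## The model

For a string set *S* and odd *k* ≥ 3, the de Bruijn graph *G*(*S*, *k*) has
one vertex per distinct *canonical* k-mer (x̂ = min(x, x̄) under the
lexicographic order, x̄ the reverse complement) and one edge per distinct
(k+1)-mer of *S*. Each vertex has a *front* and a *back* side; an edge enters
the side determined by the orientation of its endpoint k-mer, which makes the
graph bidirected. A unitig is a path entered and exited through opposite
sides whose internal vertices have exactly one edge per side; maximal unitigs
partition the vertex set (a node decomposition), and every input sequence is
a tiling of maximal unitigs with (k−1)-overlaps.

Instead of building adjacency lists, `cdbg` attaches to every vertex a small
deterministic finite automaton. A side's status is either `unique(c)` — all
edges seen on that side so far are the single edge encoded by character
*c* — or `ambiguous` (more than one distinct edge, a sequence-boundary
sentinel, or a crossing loop from a palindromic (k+1)-mer). With five
statuses per side plus one joint initial "unvisited" state, the state space
has 5×5+1 = 26 states. One linear scan over the input feeds every k-mer
instance's two flanking characters to its vertex's automaton; because the
update is a commutative, idempotent join, the final states are independent of
processing order. A second scan reads the per-vertex state classes
(single/multi × in/out) to decide where maximal unitigs start and end, and
emits each one exactly once via a per-vertex emission flag. The state table
costs a constant 5 + 1 bits per vertex, independent of *k* and *n*.

## Worked example

The two references `CGACATGTCTTAG` and `GCTCTTAG` at k = 3 contain 10
distinct canonical 3-mers and compact into exactly four maximal unitigs.
This input exercises every delicate case at once: boundary sentinels, the
palindromic 4-mer `CATG` (an edge incident twice to the front of vertex
`ATG`), orientation flips, and a unitig shared by both references.

```
$ printf '>s1\nCGACATGTCTTAG\n>s2\nGCTCTTAG\n' > refs.fa
$ cdbg build -i refs.fa -k 3 -o toy -f fasta
[cdbg] 4 maximal unitigs -> toy.fa
$ cat toy.fa
>cf_0 LN:i:5
ATGTC
>cf_1 LN:i:3
CGA
>cf_2 LN:i:6
CTAAGA
>cf_3 LN:i:4
GAGC
```

Each record is one maximal unitig in canonical orientation with its length
tag; ids are assigned in sorted spelling order, so output is byte-identical
across runs. `ATGTC` is the canonical spelling of the walk
(GAC, ACA, ATG), which reads `GACAT` on the forward strand of `s1`.
`cdbg build ... -f gfa1` (or `gfa2`) writes the same graph with S/L/P
(S/E/O) records, where every link overlap is k−1 and each reference run
becomes a path; `cdbg validate -i refs.fa -k 3 -u toy.fa` re-checks that
every input k-mer occurs in exactly one unitig exactly once and that every
reference is reconstructible by tiling the unitigs:

```
[cdbg] node decomposition: PASS
[cdbg] reference reconstruction: PASS
```

`cdbg fixtures --seed 1 --base-length 5000 --n-references 5 -o synth.fa`
generates a deterministic synthetic collection (a base genome plus closely
related mutants) for experimentation.

The same pipeline is available as a library:

```python
>>> import cdbg
>>> result = cdbg.compact_sequences(["CGACATGTCTTAG", "GCTCTTAG"], k=3)
>>> sorted(result.spellings)
['ATGTC', 'CGA', 'CTAAGA', 'GAGC']
>>> result.store.bits_per_vertex
6
```

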