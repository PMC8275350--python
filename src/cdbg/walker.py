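"""Implicit graph traversal: computing every vertex automaton's state.

Input sequences are first split into maximal ACGT runs (case-folded;
anything else — N, IUPAC codes, gaps — breaks a run). Each run of length
>= k is walked once; every k-mer instance yields one automaton input
symbol from its two flanking characters (the empty symbol at run
boundaries), and that symbol is folded into the state of the instance's
canonical vertex. Because the per-vertex update is an order-independent
join, the instance stream may be chunked and processed in any
interleaving without changing the result.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .kmers import EPS, canonical, derive_input_symbol, validate_k

_ACGT_RUN = re.compile(r"[ACGT]+")


@dataclass(frozen=True)
class ValidRun:
    """A maximal ACGT substring of one input sequence, length >= k.

    ``start``/``end`` are 1-based inclusive coordinates in the original
    sequence; each run carries its own empty-symbol sentinels, so unitigs
    never span two runs.
    """

    seq_id: str
    start: int
    end: int
    text: str


@dataclass(frozen=True)
class WalkContext:
    """One k-mer instance with its flanking characters.

    ``prev``/``nxt`` are :data:`~cdbg.kmers.EPS` exactly at run
    boundaries; ``position`` is the 1-based start of the instance in the
    original sequence.
    """

    instance: str
    prev: str
    nxt: str
    position: int


def split_valid_runs(sequence: str, k: int, seq_id: str = "") -> list[ValidRun]:
    """Maximal uppercase ACGT runs of length >= k, with 1-based coordinates."""
    validate_k(k)
    seq = sequence.upper()
    return [
        ValidRun(seq_id=seq_id, start=m.start() + 1, end=m.end(), text=m.group())
        for m in _ACGT_RUN.finditer(seq)
        if m.end() - m.start() >= k
    ]


def walk_contexts(run: ValidRun, k: int) -> Iterator[WalkContext]:
    """The instance stream of one run, in walk order."""
    t = run.text
    for i in range(len(t) - k + 1):
        yield WalkContext(
            instance=t[i:i + k],
            prev=t[i - 1] if i > 0 else EPS,
            nxt=t[i + k] if i + k < len(t) else EPS,
            position=run.start + i,
        )


def chunk_contexts(run: ValidRun, k: int, n_chunks: int) -> list[list[WalkContext]]:
    """Partition a run's instance stream into contiguous chunks.

    A k-mer belongs to the chunk containing its first character, and every
    chunk sees the true flanking characters of its instances (the chunks
    of text overlap by k characters), so processing chunks in any order or
    interleaving reproduces the unchunked result exactly.
    """
    contexts = list(walk_contexts(run, k))
    if n_chunks <= 1 or not contexts:
        return [contexts] if contexts else []
    size = max(1, -(-len(contexts) // n_chunks))
    return [contexts[i:i + size] for i in range(0, len(contexts), size)]


def compute_states(runs: Iterable[ValidRun], store, k: int | None = None) -> None:
    """State-computation pass: drive every automaton over every instance.

    ``store`` must have been built from exactly the k-mer content of
    ``runs``; a k-mer absent from it indicates inconsistent input and
    raises. After this pass no vertex is left unvisited.
    """
    k = store.k if k is None else k
    for run in runs:
        for ctx in walk_contexts(run, k):
            store.update_state(canonical(ctx.instance), derive_input_symbol(ctx.instance, ctx.prev, ctx.nxt))


def compute_states_chunked(runs: Sequence[ValidRun], store, n_chunks: int,
                           chunk_order: Sequence[int] | None = None) -> None:
    """Chunked variant of :func:`compute_states`.

    All runs' chunks are gathered and processed in ``chunk_order`` (any
    permutation; default natural order). Bit-identical to the sequential
    pass by the order-independence of the transition join.
    """
    chunks = [c for run in runs for c in chunk_contexts(run, store.k, n_chunks)]
    order = range(len(chunks)) if chunk_order is None else chunk_order
    if chunk_order is not None and sorted(chunk_order) != list(range(len(chunks))):
        raise ValueError("chunk_order must be a permutation of all chunk indices")
    for i in order:
        for ctx in chunks[i]:
            store.update_state(canonical(ctx.instance), derive_input_symbol(ctx.instance, ctx.prev, ctx.nxt))
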