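"""Extraction of maximal unitigs from the computed automaton states.

A second pass walks every run again. The walk enters each vertex through
its front side when the instance on the sequence is canonical and through
its back side otherwise; combined with the vertex's state class this
decides where maximal unitigs start and stop:

* a vertex initiates a unitig if its state class is multi-in multi-out,
  or it is entered through a branching side (front of a multi-in
  single-out vertex, back of a single-in multi-out one), or the previous
  vertex terminated;
* termination is symmetric (exit through a branching side), or the next
  vertex initiates by its own first three conditions.

Each maximal unitig is emitted exactly once globally, guarded by an
emission flag on its signature k-mer — the canonical form of the first
k-mer of its canonical spelling, which is stable under orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .automaton import StateClass, state_class
from .kmers import GlueError, Side, canonical, glue, is_canonical, reverse_complement
from .walker import ValidRun, WalkContext, walk_contexts


@dataclass(frozen=True)
class UnitigRecord:
    """One maximal unitig, in canonical orientation."""

    id: int
    spelling: str
    length: int
    first_vertex: str
    last_vertex: str


@dataclass(frozen=True)
class TilingStep:
    """One occurrence of a unitig in the tiling of an input run.

    ``orientation`` is "+" when the run shows the unitig's canonical
    spelling and "-" when it shows the reverse complement; ``start`` is
    1-based in the original sequence. Consecutive steps of one run
    overlap by exactly k-1 characters.
    """

    unitig_id: int
    orientation: str
    seq_id: str
    start: int


class ExtractionError(RuntimeError):
    """An invariant of the state-guided walk was violated."""


def entry_side(instance: str) -> Side:
    """Side through which a walk enters the vertex of this instance.

    The entering edge reads ``c + instance``; its k-suffix is the
    instance itself, so the edge attaches to the front iff the instance is
    canonical. For a run's first vertex (no entering edge) the same rule
    gives the side carrying the empty-symbol sentinel, which is the
    opposite of the exit side, as input-consistency requires.
    """
    return Side.FRONT if is_canonical(instance) else Side.BACK


def initiates(cls: StateClass, entry: Side) -> bool:
    """First three initiation conditions (the non-recursive ones)."""
    return (
        cls is StateClass.MULTI_IN_MULTI_OUT
        or (entry is Side.FRONT and cls is StateClass.MULTI_IN_SINGLE_OUT)
        or (entry is Side.BACK and cls is StateClass.SINGLE_IN_MULTI_OUT)
    )


def terminates(cls: StateClass, entry: Side) -> bool:
    """First three termination conditions (the non-recursive ones)."""
    return (
        cls is StateClass.MULTI_IN_MULTI_OUT
        or (entry is Side.FRONT and cls is StateClass.SINGLE_IN_MULTI_OUT)
        or (entry is Side.BACK and cls is StateClass.MULTI_IN_SINGLE_OUT)
    )


def seen_spelling(instance: str) -> str:
    """The spelling a walk sees for a vertex: the instance itself."""
    return instance


def spell_walk(subwalk: Sequence[WalkContext | str], k: int | None = None) -> str:
    """Spell a walk by gluing consecutive per-vertex seen spellings.

    :class:`~cdbg.walker.WalkContext` items are already oriented as they
    appear on the sequence and are glued directly. Bare strings are
    treated as vertex labels whose orientation (label or its reverse
    complement) is resolved so that consecutive spellings overlap by k-1
    characters — the first vertex's orientation is fixed by its exit
    edge, i.e. by whichever choice glues onto the second vertex.
    """
    if not subwalk:
        raise ValueError("cannot spell an empty walk")
    oriented = isinstance(subwalk[0], WalkContext)
    items = [c.instance if isinstance(c, WalkContext) else c for c in subwalk]
    k = len(items[0]) if k is None else k
    if oriented or len(items) == 1:
        out = items[0]
        for inst in items[1:]:
            out = glue(out, inst, k - 1)
        return out
    for first in (items[0], reverse_complement(items[0])):
        try:
            out = first
            for label in items[1:]:
                out = glue(out, _oriented_label(out, label, k), k - 1)
            return out
        except GlueError:
            continue
    raise GlueError(f"walk {items!r} has no consistent orientation")


def _oriented_label(prefix: str, label: str, k: int) -> str:
    for cand in (label, reverse_complement(label)):
        if prefix[-(k - 1):] == cand[:k - 1]:
            return cand
    raise GlueError(f"label {label!r} does not extend {prefix!r}")


def canonical_spelling(s: str) -> str:
    """Canonical orientation of a unitig spelling: min(s, rc(s))."""
    return min(s, reverse_complement(s))


def extract_maximal_unitigs(
    runs: Iterable[ValidRun], store
) -> tuple[list[UnitigRecord], dict[tuple[str, int], list[TilingStep]]]:
    """Enumerate all maximal unitigs and the tiling of every run.

    Returns unitig records with deterministic ids (sorted canonical
    spelling order) and, per run keyed by ``(seq_id, run_start)``, the
    ordered tiling steps that reconstruct the run by (k-1)-overlap gluing.
    """
    k = store.k
    spellings: dict[str, UnitigRecord] = {}
    raw_tilings: dict[tuple[str, int], list[tuple[str, str, str, int]]] = {}

    for run in runs:
        contexts = list(walk_contexts(run, k))
        classes = [state_class(store.get_state(canonical(c.instance))) for c in contexts]
        entries = [entry_side(c.instance) for c in contexts]
        steps: list[tuple[str, str, str, int]] = []
        i = 0
        while i < len(contexts):
            if i == 0 and not initiates(classes[0], entries[0]):
                # the sentinel on the entry side forces a branching class
                raise ExtractionError(
                    f"run does not initiate at its first vertex (run {run.seq_id}:{run.start})"
                )
            j = i
            while not _terminated_at(classes, entries, j):
                j += 1
                if j == len(contexts):
                    raise ExtractionError(
                        f"run boundary reached without termination (run {run.seq_id}:{run.start})"
                    )
            spelled = spell_walk(contexts[i:j + 1], k)
            spelling = canonical_spelling(spelled)
            signature = canonical(spelling[:k])
            if not store.is_emitted(signature):
                store.mark_emitted(signature)
                spellings[spelling] = UnitigRecord(
                    id=-1,
                    spelling=spelling,
                    length=len(spelling),
                    first_vertex=canonical(spelling[:k]),
                    last_vertex=canonical(spelling[-k:]),
                )
            orientation = "+" if spelled == spelling else "-"
            steps.append((spelling, orientation, run.seq_id, contexts[i].position))
            i = j + 1
        raw_tilings[(run.seq_id, run.start)] = steps

    records = [
        UnitigRecord(
            id=uid,
            spelling=rec.spelling,
            length=rec.length,
            first_vertex=rec.first_vertex,
            last_vertex=rec.last_vertex,
        )
        for uid, rec in enumerate(
            (spellings[s] for s in sorted(spellings)), start=0
        )
    ]
    id_of = {rec.spelling: rec.id for rec in records}
    tilings = {
        key: [
            TilingStep(unitig_id=id_of[s], orientation=o, seq_id=sid, start=pos)
            for (s, o, sid, pos) in steps
        ]
        for key, steps in raw_tilings.items()
    }
    return records, tilings


def _terminated_at(classes: list[StateClass], entries: list[Side], j: int) -> bool:
    if terminates(classes[j], entries[j]):
        return True
    return j + 1 < len(classes) and initiates(classes[j + 1], entries[j + 1])
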