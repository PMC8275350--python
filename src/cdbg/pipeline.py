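"""End-to-end orchestration of the compaction pipeline.

The four stages mirror the algorithm's structure: enumerate the distinct
canonical k-mer set, build the state store over it, compute every vertex
automaton's state by implicit traversal, and extract the maximal unitigs
in a second traversal. The full graph is never materialised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .extract import TilingStep, UnitigRecord, extract_maximal_unitigs
from .store import StateStore, build_store, enumerate_kmers
from .walker import ValidRun, compute_states, compute_states_chunked, split_valid_runs


@dataclass
class CompactionResult:
    """Everything the pipeline produces for one input collection."""

    k: int
    unitigs: list[UnitigRecord]
    tilings: dict[tuple[str, int], list[TilingStep]]
    store: StateStore
    runs: list[ValidRun]

    @property
    def spellings(self) -> set[str]:
        return {u.spelling for u in self.unitigs}


def compact(
    records: Iterable[tuple[str, str]],
    k: int,
    n_chunks: int = 1,
    store: StateStore | None = None,
) -> CompactionResult:
    """Build the compacted de Bruijn graph of a reference collection.

    ``records`` are ``(id, sequence)`` pairs. If ``store`` is given (e.g.
    loaded from disk) its computed states are reused and the
    state-computation pass is skipped; otherwise the store is built and
    populated here, chunking each sequence into ``n_chunks`` pieces.
    """
    records = list(records)
    runs = [run for rid, seq in records for run in split_valid_runs(seq, k, seq_id=rid)]
    if store is None:
        kmers = enumerate_kmers((seq for _, seq in records), k)
        store = build_store(kmers)
        if n_chunks > 1:
            compute_states_chunked(runs, store, n_chunks)
        else:
            compute_states(runs, store)
    else:
        if store.k != k:
            raise ValueError(f"store was built for k={store.k}, requested k={k}")
        store.reset_emitted()
    unitigs, tilings = extract_maximal_unitigs(runs, store)
    return CompactionResult(k=k, unitigs=unitigs, tilings=tilings, store=store, runs=runs)


def compact_sequences(sequences: Sequence[str], k: int, **kwargs) -> CompactionResult:
    """Convenience wrapper for anonymous sequences."""
    return compact([(f"seq_{i}", s) for i, s in enumerate(sequences)], k, **kwargs)
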