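"""Per-vertex finite-state automaton for branching classification.

Each graph vertex carries a small DFA whose state summarises, per side,
either the single character encoding the sole incident edge seen so far,
or the fact that the side is branching (multiple distinct edges, a
boundary edge, or a crossing loop). With 5 possible statuses per side
plus one joint "unvisited" initial state, the state space has
5 * 5 + 1 = 26 states. Both sides are updated simultaneously from one
:class:`~cdbg.kmers.SideSymbol` per k-mer instance, which is what keeps a
single unvisited state sufficient.

The per-side update is a commutative, idempotent, monotone join, so the
final state of a vertex is independent of the order in which its
instances are processed — the property that makes chunked traversal legal.
"""

from __future__ import annotations

import enum
import itertools
from typing import NamedTuple

from .kmers import ALPHABET, AMBIGUOUS, SideSymbol

#: The five per-side statuses: a unique incident-edge character, or branching.
SIDE_STATUSES = tuple(ALPHABET) + (AMBIGUOUS,)


class VertexState(NamedTuple):
    """State of one vertex automaton.

    ``front``/``back`` hold a base character (unique incident edge), the
    :data:`~cdbg.kmers.AMBIGUOUS` marker, or ``None`` for the joint
    initial (unvisited) state.
    """

    front: str | None
    back: str | None

    @property
    def visited(self) -> bool:
        return self.front is not None


UNVISITED = VertexState(None, None)


class StateClass(enum.Enum):
    """The four classes of visited states ("in" = front, "out" = back)."""

    SINGLE_IN_SINGLE_OUT = "single-in single-out"
    MULTI_IN_SINGLE_OUT = "multi-in single-out"
    SINGLE_IN_MULTI_OUT = "single-in multi-out"
    MULTI_IN_MULTI_OUT = "multi-in multi-out"


class UnvisitedQueryError(RuntimeError):
    """A vertex was classified before ever being visited.

    After a complete state-computation pass every vertex of the graph has
    been seen at least once, so this signals an upstream inconsistency.
    """


def _join(current: str, observed: str) -> str:
    # ambiguous is absorbing; a repeated identical character is a no-op
    return current if current == observed else AMBIGUOUS


def transition(state: VertexState, symbol: SideSymbol) -> VertexState:
    """One step of the DFA: fold a per-instance symbol into the state."""
    if not state.visited:
        return VertexState(symbol.front, symbol.back)
    return VertexState(_join(state.front, symbol.front), _join(state.back, symbol.back))


def state_class(state: VertexState) -> StateClass:
    """Classify a visited state by which of its sides are branching."""
    if not state.visited:
        raise UnvisitedQueryError("cannot classify the unvisited state")
    multi_in = state.front == AMBIGUOUS
    multi_out = state.back == AMBIGUOUS
    if multi_in and multi_out:
        return StateClass.MULTI_IN_MULTI_OUT
    if multi_in:
        return StateClass.MULTI_IN_SINGLE_OUT
    if multi_out:
        return StateClass.SINGLE_IN_MULTI_OUT
    return StateClass.SINGLE_IN_SINGLE_OUT


def all_symbols() -> list[SideSymbol]:
    """All 25 possible input symbols (5 statuses per side)."""
    return [SideSymbol(f, b) for f, b in itertools.product(SIDE_STATUSES, SIDE_STATUSES)]


def enumerate_reachable_states() -> set[VertexState]:
    """Closure of :func:`transition` from the initial state, inclusive.

    Returns all 26 states: the unvisited state plus the 25 visited
    configurations.
    """
    symbols = all_symbols()
    seen: set[VertexState] = {UNVISITED}
    frontier = [UNVISITED]
    while frontier:
        state = frontier.pop()
        for symbol in symbols:
            nxt = transition(state, symbol)
            if nxt not in seen:
                seen.add(nxt)
                frontier.append(nxt)
    return seen


def transition_table() -> dict[tuple[VertexState, SideSymbol], VertexState]:
    """The full DFA table, generated from the per-side join rules."""
    return {
        (state, symbol): transition(state, symbol)
        for state in sorted(enumerate_reachable_states(), key=lambda s: (s.front or "", s.back or ""))
        for symbol in all_symbols()
    }
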